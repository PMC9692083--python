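"""Deterministic generator of complete synthetic input bundles.

Everything the scoring pipeline consumes -- aligned feature table, extract
metadata, annotation tables, class predictions, an offline occurrence
table and MS2 spectra -- is generated from one seeded RNG with *planted*
ground truth, so every stage can be exercised and checked end-to-end
without any download:

* ``n_features`` is the number of features each extract detects: a
  per-extract block of *exclusive* features (area only in the home
  extract, hence specific by construction) plus a pool of *shared*
  features detected in every extract with balanced areas (never specific).
* A chosen fraction of each extract's exclusive features carries a
  passing annotation, fixing FS and FC exactly.
* Each extract's exclusive features share one confident chemical class --
  a class absent from the literature sets for extracts designated to
  carry a novel class (CC = 1), a reported class otherwise (CC = 0).
* One extract may be planted as a spectral outlier: its spectra draw
  fragments from a disjoint m/z vocabulary, so its MS2 word fingerprint
  is maximally dissimilar (SC = 1).
* An optional solvent blank contributes background words that appear in
  every sample spectrum and must be removed by blank filtering.

The planted component scores are returned alongside the bundle as ground
truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import FeatureTable, Spectrum, SpectrumSet, write_spectra

REPORTED_CLASS = "Reported benchmark class"
BLANK_FILENAME = "blank_01"


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle.

    ``n_features`` = features detected per extract; ``fraction_specific``
    of them are exclusive to the extract, the rest shared across all.
    ``fraction_annotated`` of the exclusive features carry passing
    annotations.  ``novel_class_extracts`` lists extract indices whose
    planted chemical class is absent from the literature class sets.
    """

    n_extracts: int = 10
    n_features: int = 100
    species_layout: tuple[int, ...] | None = None  # extracts per species
    fraction_specific: float = 0.6
    fraction_annotated: float = 0.0
    novel_class_extracts: tuple[int, ...] = (0,)
    planted_outlier: int | None = None
    rcs: int = 2
    rcg: int = 8
    rcf: int = 100
    include_blank: bool = True
    n_fragments: int = 15
    seed: int = 0

    def validate(self) -> "FixtureSpec":
        if self.n_extracts < 2:
            raise ValidationError("need at least 2 extracts")
        if not (0 <= self.fraction_specific <= 1):
            raise ValidationError("fraction_specific must be in [0, 1]")
        if not (0 <= self.fraction_annotated <= 1):
            raise ValidationError("fraction_annotated must be in [0, 1]")
        if round(self.fraction_specific * self.n_features) * self.n_extracts > 10_000_000:
            raise ValidationError("fixture too large")
        n_spec = round(self.fraction_specific * self.n_features)
        if n_spec > self.n_features:
            raise ValidationError("more specific features requested than features")
        if self.planted_outlier is not None and not (0 <= self.planted_outlier < self.n_extracts):
            raise ValidationError("planted_outlier index out of range")
        layout = self.species_layout
        if layout is not None and sum(layout) != self.n_extracts:
            raise ValidationError("species_layout must sum to n_extracts")
        return self


@dataclass
class FixtureBundle:
    """All pipeline inputs plus the planted ground truth."""

    table: FeatureTable
    metadata: pd.DataFrame
    gnps: pd.DataFrame
    isdb: pd.DataFrame
    sirius: pd.DataFrame
    class_predictions: pd.DataFrame
    occurrences: pd.DataFrame
    spectra: SpectrumSet
    extract_assignment: dict[int, str]
    ground_truth: dict = field(default_factory=dict)


def _species_names(spec: FixtureSpec) -> list[str]:
    layout = spec.species_layout or tuple([1] * spec.n_extracts)
    names = []
    for i, count in enumerate(layout):
        names.extend([f"Synthea species{i:02d}"] * count)
    return names


def generate_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Generate one bundle; a fixed seed yields byte-identical outputs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    extracts = [f"sample_{i:02d}" for i in range(spec.n_extracts)]
    species = _species_names(spec)
    genera = [s.split()[0] + f"_gen{s[-2:]}" for s in species]
    family = "Synthaceae"

    meta_rows = [
        {
            "filename": extracts[i],
            "species": species[i],
            "genus": genera[i],
            "family": family,
            "organ": ["roots", "leaves", "stems", "fruits"][i % 4],
            "sample_type": "sample",
        }
        for i in range(spec.n_extracts)
    ]
    if spec.include_blank:
        meta_rows.append(
            {
                "filename": BLANK_FILENAME,
                "species": "none",
                "genus": "none",
                "family": "none",
                "organ": "none",
                "sample_type": "blank",
            }
        )
    metadata = pd.DataFrame(meta_rows)
    metadata["resolved_taxon"] = metadata["species"]

    n_spec = round(spec.fraction_specific * spec.n_features)
    n_shared = spec.n_features - n_spec
    n_total = n_shared + n_spec * spec.n_extracts
    feature_ids = np.arange(1, n_total + 1)
    shared_ids = feature_ids[:n_shared]
    exclusive_ids = {
        e: feature_ids[n_shared + i * n_spec : n_shared + (i + 1) * n_spec]
        for i, e in enumerate(extracts)
    }

    all_cols = list(metadata["filename"])
    areas = pd.DataFrame(
        0.0, index=pd.Index(feature_ids, name="feature_id"), columns=all_cols
    )
    # shared features: balanced areas everywhere (max share < 0.9 by design)
    if n_shared:
        areas.loc[shared_ids, extracts] = rng.uniform(5e5, 1e6, size=(n_shared, spec.n_extracts))
    for e in extracts:
        ids = exclusive_ids[e]
        if len(ids):
            areas.loc[ids, e] = rng.uniform(1e6, 1e7, size=len(ids))

    features = pd.DataFrame(
        {
            "mz": rng.uniform(150.0, 1000.0, size=n_total).round(4),
            "rt": rng.uniform(0.5, 8.0, size=n_total).round(3),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    features["iin_id"] = pd.array([pd.NA] * n_total, dtype="Int64")
    features["adduct"] = None
    table = FeatureTable(features, areas).validate(metadata)

    # annotations: a fixed count of each extract's exclusive features gets a
    # passing GNPS hit; some shared features get in-silico / prediction hits
    n_ann = round(spec.fraction_annotated * n_spec)
    gnps_rows = []
    annotated_ids: set[int] = set()
    for e in extracts:
        for fid in exclusive_ids[e][:n_ann]:
            gnps_rows.append(
                {
                    "feature_id": int(fid),
                    "cosine": round(rng.uniform(0.7, 0.99), 3),
                    "ppm_error": round(rng.uniform(-4, 4), 2),
                    "shared_peaks": int(rng.integers(10, 30)),
                    "charge": 1,
                    "ion_mode": "pos",
                }
            )
            annotated_ids.add(int(fid))
        # a low-quality hit that must be filtered out
        if len(exclusive_ids[e]) > n_ann:
            gnps_rows.append(
                {
                    "feature_id": int(exclusive_ids[e][-1]),
                    "cosine": round(rng.uniform(0.2, 0.55), 3),
                    "ppm_error": round(rng.uniform(6, 20), 2),
                    "shared_peaks": int(rng.integers(1, 9)),
                    "charge": 1,
                    "ion_mode": "pos",
                }
            )
    gnps = pd.DataFrame(
        gnps_rows,
        columns=["feature_id", "cosine", "ppm_error", "shared_peaks", "charge", "ion_mode"],
    )

    isdb_ids = shared_ids[: n_shared // 2]
    isdb = pd.DataFrame(
        {
            "feature_id": isdb_ids.astype(int),
            "score_final": rng.uniform(0.35, 0.9, size=len(isdb_ids)).round(3),
        }
    )
    annotated_shared = set(int(i) for i in isdb_ids)
    sirius_ids = shared_ids[n_shared // 2 :]
    sirius = pd.DataFrame(
        {
            "feature_id": sirius_ids.astype(int),
            "zodiac_score": rng.uniform(0.95, 1.0, size=len(sirius_ids)).round(4),
            "confidence_score": rng.uniform(0.3, 0.9, size=len(sirius_ids)).round(3),
        }
    )
    annotated_shared |= set(int(i) for i in sirius_ids)

    # class predictions: one confident class per extract over its exclusive
    # features; shared features get low-confidence predictions only
    class_rows = []
    planted_class = {}
    for i, e in enumerate(extracts):
        cls = f"Novel synthetic class {i:02d}" if i in spec.novel_class_extracts else REPORTED_CLASS
        planted_class[e] = cls
        for fid in exclusive_ids[e]:
            class_rows.append(
                {
                    "feature_id": int(fid),
                    "npc_class": cls,
                    "npc_probability": round(rng.uniform(0.85, 0.99), 3),
                }
            )
    for fid in shared_ids:
        class_rows.append(
            {
                "feature_id": int(fid),
                "npc_class": REPORTED_CLASS,
                "npc_probability": round(rng.uniform(0.2, 0.7), 3),
            }
        )
    class_predictions = pd.DataFrame(
        class_rows, columns=["feature_id", "npc_class", "npc_probability"]
    )

    # offline occurrence table: every taxon known, reported class present
    occ_rows = []
    for sp, gen in sorted(set(zip(species, genera))):
        occ_rows.append({"rank": "species", "name": sp, "compound_count": spec.rcs, "classes": REPORTED_CLASS})
        occ_rows.append({"rank": "genus", "name": gen, "compound_count": spec.rcg, "classes": REPORTED_CLASS})
    occ_rows.append({"rank": "family", "name": family, "compound_count": spec.rcf, "classes": REPORTED_CLASS})
    occurrences = pd.DataFrame(occ_rows)

    # MS2 spectra: one per exclusive feature; common vs disjoint vocabularies
    common_vocab = np.sort(rng.uniform(100.0, 440.0, size=80).round(3))
    outlier_vocab = np.sort(rng.uniform(500.0, 900.0, size=80).round(3))
    blank_vocab = np.sort(rng.uniform(60.0, 95.0, size=20).round(3))
    spectra: dict[int, Spectrum] = {}
    assignment: dict[int, str] = {}
    outlier_extract = extracts[spec.planted_outlier] if spec.planted_outlier is not None else None
    for i, e in enumerate(extracts):
        vocab = outlier_vocab if e == outlier_extract else common_vocab
        for fid in exclusive_ids[e]:
            frags = rng.choice(vocab, size=spec.n_fragments, replace=False)
            if spec.include_blank:
                frags = np.concatenate([frags, rng.choice(blank_vocab, size=3, replace=False)])
            intens = rng.uniform(0.05, 1.0, size=len(frags))
            intens[0] = 1.0
            precursor = float(max(frags.max() + rng.uniform(20.0, 180.0), 50.0))
            spectra[int(fid)] = Spectrum(
                feature_id=int(fid),
                precursor_mz=round(precursor, 4),
                mz=frags,
                intensities=(intens * 1e6).round(1),
            )
            assignment[int(fid)] = e
    if spec.include_blank:
        next_id = n_total + 1
        for _ in range(5):
            frags = rng.choice(blank_vocab, size=12, replace=False)
            intens = rng.uniform(0.05, 1.0, size=len(frags))
            intens[0] = 1.0
            spectra[next_id] = Spectrum(
                feature_id=next_id,
                precursor_mz=round(float(frags.max() + 50.0), 4),
                mz=frags,
                intensities=(intens * 1e6).round(1),
            )
            assignment[next_id] = BLANK_FILENAME
            next_id += 1

    fs_true = n_spec / spec.n_features
    fc_true = (n_spec - n_ann) / spec.n_features
    ground_truth = {
        "FS": {e: fs_true for e in extracts},
        "FC": {e: fc_true for e in extracts},
        "CC": {
            e: (1.0 if i in spec.novel_class_extracts else 0.0)
            for i, e in enumerate(extracts)
        },
        "SC": {e: (1 if e == outlier_extract else 0) for e in extracts},
        "specific_ids": {e: [int(i) for i in exclusive_ids[e]] for e in extracts},
        "annotated_ids": sorted(annotated_ids | annotated_shared),
        "planted_class": planted_class,
        "outlier_extract": outlier_extract,
    }

    return FixtureBundle(
        table=table,
        metadata=metadata,
        gnps=gnps,
        isdb=isdb,
        sirius=sirius,
        class_predictions=class_predictions,
        occurrences=occurrences,
        spectra=SpectrumSet(spectra),
        extract_assignment=assignment,
        ground_truth=ground_truth,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize a bundle in the exact external formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": outdir / "feature_table.csv",
        "metadata": outdir / "metadata.tsv",
        "gnps": outdir / "gnps_annotations.tsv",
        "isdb": outdir / "isdb_annotations.tsv",
        "sirius": outdir / "sirius_annotations.tsv",
        "class_predictions": outdir / "class_predictions.tsv",
        "occurrences": outdir / "occurrences.tsv",
        "spectra": outdir / "spectra.mgf",
        "assignment": outdir / "spectrum_assignment.tsv",
    }
    bundle.table.write_csv(paths["feature_table"])
    bundle.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    bundle.gnps.to_csv(paths["gnps"], sep="\t", index=False)
    bundle.isdb.to_csv(paths["isdb"], sep="\t", index=False)
    bundle.sirius.to_csv(paths["sirius"], sep="\t", index=False)
    bundle.class_predictions.to_csv(paths["class_predictions"], sep="\t", index=False)
    bundle.occurrences.to_csv(paths["occurrences"], sep="\t", index=False)
    write_spectra(bundle.spectra, paths["spectra"])
    pd.DataFrame(
        [(fid, e) for fid, e in bundle.extract_assignment.items()],
        columns=["feature_id", "filename"],
    ).to_csv(paths["assignment"], sep="\t", index=False)
    return paths
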