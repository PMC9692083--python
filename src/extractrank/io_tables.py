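"""Readers, writers and the shared data model for all tabular/spectral inputs.

The quantitative backbone is the :class:`FeatureTable`: one row per aligned
chromatographic feature (m/z, retention time, optional ion-identity-network
group id) and one non-negative peak area/height column per extract.  Extract
metadata carries the taxonomy (species / genus / family), the organ and the
sample type (``sample`` / ``blank`` / ``QC``).  MS2 spectra are read from MGF.

Ion identity networks (IIN) group features that arise from the same neutral
molecule (adducts, in-source fragments); :func:`collapse_iin` reduces each
group to one row whose per-extract area is the element-wise maximum over the
group members, i.e. the most representative ion form per extract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

SAMPLE_TYPES = frozenset({"sample", "blank", "QC"})

#: Header aliases accepted for the three mandatory feature-table columns.
_ID_ALIASES = ("row ID", "row id", "id", "feature_id")
_MZ_ALIASES = ("row m/z", "row mz", "mz", "m/z")
_RT_ALIASES = ("row retention time", "row rt", "rt", "retention time")
_IIN_ALIASES = (
    "correlation group ID",
    "annotation network number",
    "iin_id",
    "iin id",
)
_ADDUCT_ALIASES = ("best ion", "adduct", "ion identities")

#: Suffixes stripped from per-extract column labels before matching the
#: metadata filenames (MZmine appends these on export).
_AREA_SUFFIXES = (" Peak area", " Peak height", ".Peak.area", ".Peak.height")
_FILE_SUFFIXES = (".mzML", ".mzXML", ".mzml", ".mzxml", ".raw", ".RAW")


def _strip_extract_label(label: str) -> str:
    label = label.strip()
    for suf in _AREA_SUFFIXES:
        if label.endswith(suf):
            label = label[: -len(suf)]
            break
    for suf in _FILE_SUFFIXES:
        if label.endswith(suf):
            label = label[: -len(suf)]
            break
    return label


@dataclass
class FeatureTable:
    """Aligned features x extracts, split into descriptors and areas.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by integer ``feature_id``; columns ``mz``, ``rt`` and the
        optional ``iin_id`` (nullable integer) and ``adduct``.
    areas : pandas.DataFrame
        Indexed identically; one float column per extract filename holding
        the non-negative peak area (or height).
    """

    features: pd.DataFrame
    areas: pd.DataFrame

    @property
    def extracts(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.areas.copy())

    def validate(self, metadata: pd.DataFrame | None = None) -> "FeatureTable":
        """Check data-model invariants; raise :class:`ValidationError` on failure."""
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature_id values: {list(dupes)[:5]}")
        if not self.features.index.equals(self.areas.index):
            raise ValidationError("features and areas indices differ")
        if (self.areas.to_numpy() < 0).any():
            raise ValidationError("negative peak area encountered")
        if (self.features["mz"].to_numpy() <= 0).any():
            raise ValidationError("non-positive m/z encountered")
        if (self.features["rt"].to_numpy() < 0).any():
            raise ValidationError("negative retention time encountered")
        if metadata is not None:
            expected = set(metadata["filename"])
            got = set(self.areas.columns)
            if expected != got:
                raise ValidationError(
                    "extract columns do not match metadata filenames: "
                    f"missing={sorted(expected - got)} extra={sorted(got - expected)}"
                )
        return self

    def write_csv(self, path: str | Path) -> None:
        """Serialize in the MZmine aligned-quant dialect (round-trippable)."""
        out = pd.DataFrame(index=self.features.index)
        out["row ID"] = self.features.index
        out["row m/z"] = self.features["mz"]
        out["row retention time"] = self.features["rt"]
        if "iin_id" in self.features.columns and self.features["iin_id"].notna().any():
            out["correlation group ID"] = self.features["iin_id"]
        if "adduct" in self.features.columns and self.features["adduct"].notna().any():
            out["best ion"] = self.features["adduct"]
        for col in self.areas.columns:
            out[f"{col} Peak area"] = self.areas[col]
        out.to_csv(path, index=False)


@dataclass
class Spectrum:
    """One MS2 spectrum: precursor m/z plus fragment (m/z, intensity) arrays."""

    feature_id: int
    precursor_mz: float
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise ValidationError(
                f"spectrum {self.feature_id}: negative fragment intensity"
            )
        if (self.mz <= 0).any():
            raise ValidationError(f"spectrum {self.feature_id}: non-positive fragment m/z")


@dataclass
class SpectrumSet:
    """MS2 spectra keyed by the feature id they belong to."""

    spectra: dict[int, Spectrum] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra.values())

    def __getitem__(self, feature_id: int) -> Spectrum:
        return self.spectra[feature_id]

    def __contains__(self, feature_id: int) -> bool:
        return feature_id in self.spectra


def _find_column(columns: Iterable[str], aliases: tuple[str, ...]) -> str | None:
    lowered = {c.strip().lower(): c for c in columns}
    for alias in aliases:
        if alias.lower() in lowered:
            return lowered[alias.lower()]
    return None


def load_feature_table(
    path: str | Path,
    dialect: str = "mzmine_csv",
    metadata: pd.DataFrame | None = None,
) -> FeatureTable:
    """Read an aligned feature quantification table (MZmine CSV dialect).

    Accepts both the ``row ID / row m/z / row retention time`` export header
    and the plain ``id / mz / rt`` variant; per-extract columns are matched
    to metadata filenames after stripping `` Peak area`` / `` Peak height``
    and ``.mzML`` / ``.mzXML`` suffixes.
    """
    if dialect != "mzmine_csv":
        raise FormatError(f"unknown feature-table dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    if raw.empty and raw.columns.empty:
        raise FormatError(f"{path}: empty feature table")

    id_col = _find_column(raw.columns, _ID_ALIASES)
    mz_col = _find_column(raw.columns, _MZ_ALIASES)
    rt_col = _find_column(raw.columns, _RT_ALIASES)
    for name, col in (("id", id_col), ("m/z", mz_col), ("RT", rt_col)):
        if col is None:
            raise FormatError(f"{path}: missing required column {name!r}")
    iin_col = _find_column(raw.columns, _IIN_ALIASES)
    adduct_col = _find_column(raw.columns, _ADDUCT_ALIASES)

    meta_cols = {id_col, mz_col, rt_col, iin_col, adduct_col} - {None}
    area_cols = [c for c in raw.columns if c not in meta_cols and not c.startswith("Unnamed")]
    if not area_cols:
        raise FormatError(f"{path}: no per-extract area columns found")

    features = pd.DataFrame(
        {
            "mz": raw[mz_col].astype(float).to_numpy(),
            "rt": raw[rt_col].astype(float).to_numpy(),
        },
        index=pd.Index(raw[id_col].astype(int), name="feature_id"),
    )
    features["iin_id"] = (
        raw[iin_col].astype("Int64").to_numpy() if iin_col else pd.array([pd.NA] * len(raw), dtype="Int64")
    )
    features["adduct"] = raw[adduct_col].to_numpy() if adduct_col else None

    areas = raw[area_cols].astype(float)
    areas.index = features.index
    areas.columns = [_strip_extract_label(c) for c in area_cols]
    areas = areas.fillna(0.0)

    return FeatureTable(features, areas).validate(metadata)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the extract metadata table (CSV or TSV).

    Required columns: ``filename``, ``species``, ``genus``, ``family``,
    ``organ``, ``sample_type``; ``sample_type`` must be one of ``sample``,
    ``blank``, ``QC``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        meta = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty metadata file") from exc
    required = ["filename", "species", "genus", "family", "organ", "sample_type"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    if meta.empty:
        raise ValidationError(f"{path}: metadata has no rows")
    if meta["filename"].duplicated().any():
        dupes = meta.loc[meta["filename"].duplicated(), "filename"].tolist()
        raise ValidationError(f"{path}: duplicate filename(s) {dupes}")
    bad = set(meta["sample_type"]) - SAMPLE_TYPES
    if bad:
        raise ValidationError(
            f"{path}: sample_type must be one of {sorted(SAMPLE_TYPES)}, got {sorted(bad)}"
        )
    if "resolved_taxon" not in meta.columns:
        meta["resolved_taxon"] = meta["species"]
    return meta.reset_index(drop=True)


def sample_extracts(metadata: pd.DataFrame) -> list[str]:
    """Filenames of true samples (blanks and QCs excluded from all scoring)."""
    return metadata.loc[metadata["sample_type"] == "sample", "filename"].tolist()


def blank_extracts(metadata: pd.DataFrame) -> list[str]:
    return metadata.loc[metadata["sample_type"] == "blank", "filename"].tolist()


def collapse_iin(table: FeatureTable) -> FeatureTable:
    """Collapse ion-identity networks to one row per neutral molecule.

    Per-extract area of a group is the element-wise maximum over member
    rows (the most representative ion form per extract).  The surviving
    ``feature_id`` is the member with the greatest summed area, ties broken
    by the lowest id.  Features without an ``iin_id`` pass through unchanged.
    """
    if "iin_id" not in table.features.columns or table.features["iin_id"].isna().all():
        logger.info("no iin_id column present; collapse_iin is an identity transform")
        return table.copy()

    grouped = table.features["iin_id"]
    in_group = grouped.notna()
    keep_features = []
    keep_areas = []

    # pass-through rows
    solo_ids = table.features.index[~in_group]
    keep_features.append(table.features.loc[solo_ids])
    keep_areas.append(table.areas.loc[solo_ids])

    for _, sub in table.features[in_group].groupby("iin_id"):
        members = sub.index
        sub_areas = table.areas.loc[members]
        totals = sub_areas.sum(axis=1)
        rep = totals[totals == totals.max()].index.min()
        feat_row = table.features.loc[[rep]]
        area_row = sub_areas.max(axis=0).to_frame().T
        area_row.index = pd.Index([rep], name="feature_id")
        keep_features.append(feat_row)
        keep_areas.append(area_row)

    features = pd.concat(keep_features).sort_index()
    areas = pd.concat(keep_areas).sort_index()
    return FeatureTable(features, areas)


def load_spectra(path: str | Path) -> SpectrumSet:
    """Read MS2 spectra from an MGF file, keyed by SCANS/feature id."""
    path = Path(path)
    out: dict[int, Spectrum] = {}
    if path.stat().st_size == 0:
        return SpectrumSet(out)
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise FormatError(f"{path}: spectrum block {i} lacks PEPMASS")
            scans = params.get("scans", params.get("title", i))
            try:
                feature_id = int(scans)
            except (TypeError, ValueError):
                feature_id = i
            out[feature_id] = Spectrum(
                feature_id=feature_id,
                precursor_mz=float(pepmass[0]),
                mz=entry["m/z array"],
                intensities=entry["intensity array"],
            )
    return SpectrumSet(out)


def write_spectra(spectra: SpectrumSet | Iterable[Spectrum], path: str | Path) -> None:
    """Serialize spectra to MGF (SCANS carries the feature id)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensities,
                "params": {"pepmass": s.precursor_mz, "scans": s.feature_id},
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
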