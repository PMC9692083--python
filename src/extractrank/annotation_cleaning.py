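"""Quality-filter spectral-library hits and merge all annotation sources.

A feature counts as *annotated* if any of three evidence routes fires:

* a GNPS library match surviving the quality filter (cosine, ppm error,
  shared peaks, ion mode, charge),
* an in-silico spectral-database match with a sufficient final score,
* a formula/structure prediction whose formula score (ZODIAC) and
  structure confidence both clear their thresholds.

Everything downstream only consumes the boolean status plus the set of
sources that fired; unannotated specific features are the ones worth
isolating.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

GNPS_QUALITY_COLUMNS = ("cosine", "ppm_error", "shared_peaks", "charge", "ion_mode")

#: Config-mappable aliases for columns of a raw GNPS annotation TSV.
GNPS_COLUMN_ALIASES = {
    "cosine": ("cosine", "MQScore"),
    "ppm_error": ("ppm_error", "MZErrorPPM"),
    "shared_peaks": ("shared_peaks", "SharedPeaks"),
    "charge": ("charge", "Charge"),
    "ion_mode": ("ion_mode", "IonMode"),
    "feature_id": ("feature_id", "#Scan#", "cluster index"),
}


def normalize_gnps_columns(annotations: pd.DataFrame) -> pd.DataFrame:
    """Rename known GNPS export headers to the canonical field names."""
    renames = {}
    for canonical, aliases in GNPS_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in annotations.columns:
                renames[alias] = canonical
                break
    return annotations.rename(columns=renames)


def clean_gnps(
    annotations: pd.DataFrame,
    max_ppm_error: float = 5.0,
    min_shared_peaks: int = 10,
    min_cosine: float = 0.6,
    ion_mode: str = "pos",
    max_charge: int = 2,
) -> pd.DataFrame:
    """Retain only high-quality library matches (boundaries inclusive).

    Keeps rows with |ppm_error| <= max_ppm_error, shared_peaks >=
    min_shared_peaks, cosine >= min_cosine, matching ion mode and
    charge <= max_charge.  The ppm filter uses the absolute value because
    the sign of the mass error is instrument-dependent.
    """
    annotations = normalize_gnps_columns(annotations)
    missing = [c for c in GNPS_QUALITY_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValidationError(f"GNPS annotation table lacks column(s): {missing}")
    mask = (
        (annotations["ppm_error"].abs() <= max_ppm_error)
        & (annotations["shared_peaks"] >= min_shared_peaks)
        & (annotations["cosine"] >= min_cosine)
        & (annotations["ion_mode"].astype(str).str.strip().str.lower() == ion_mode.lower())
        & (annotations["charge"] <= max_charge)
    )
    return annotations.loc[mask].copy()


def merge_annotation_status(
    gnps_clean: pd.DataFrame | None,
    isdb: pd.DataFrame | None,
    sirius: pd.DataFrame | None,
    feature_ids,
    min_score_final: float = 0.3,
    min_zodiac: float = 0.9,
    min_confidence: float = 0.25,
    annotation_preference: int = 0,
) -> pd.DataFrame:
    """Build the per-feature annotation ledger.

    A feature is annotated iff it has a surviving GNPS hit, OR an
    in-silico match with ``score_final >= min_score_final``, OR a
    prediction with ``zodiac_score >= min_zodiac`` AND
    ``confidence_score >= min_confidence``.  ``annotation_preference = 0``
    selects this OR-combination; other gating modes are reserved.

    Returns a DataFrame indexed by feature_id with boolean ``annotated``
    and a ``annotation_source`` column holding the subset of
    ``{gnps, isdb, sirius}`` that fired (as a frozenset).
    """
    if annotation_preference != 0:
        raise ValidationError(
            f"annotation_preference {annotation_preference} not supported (only 0 = OR)"
        )

    index = pd.Index(feature_ids, name="feature_id")

    def _hit_ids(df: pd.DataFrame | None, predicate) -> set[int]:
        if df is None or df.empty:
            return set()
        if "feature_id" not in df.columns:
            raise ValidationError("annotation table lacks a feature_id column")
        kept = df.loc[predicate(df), "feature_id"]
        return set(kept.astype(int))

    gnps_ids = _hit_ids(gnps_clean, lambda d: pd.Series(True, index=d.index))
    isdb_ids = _hit_ids(isdb, lambda d: d["score_final"] >= min_score_final)
    sirius_ids = _hit_ids(
        sirius,
        lambda d: (d["zodiac_score"] >= min_zodiac) & (d["confidence_score"] >= min_confidence),
    )

    sources = []
    for fid in index:
        fired = frozenset(
            name
            for name, ids in (("gnps", gnps_ids), ("isdb", isdb_ids), ("sirius", sirius_ids))
            if fid in ids
        )
        sources.append(fired)
    ledger = pd.DataFrame(
        {"annotation_source": sources}, index=index
    )
    ledger["annotated"] = ledger["annotation_source"].map(bool)
    return ledger[["annotated", "annotation_source"]]
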