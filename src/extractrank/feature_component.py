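"""Feature specificity (FS) and the Feature Component (FC).

The aligned table is normalized row-wise over the scored extracts (blanks
and QCs excluded), so each feature's areas become proportions.  A feature
is *specific* to an extract when at least ``min_specificity`` (default
0.90) of its normalized area falls there.  When a species contributes
several extracts (organs, solvents, ...), raising the maximum occurrence
``N`` lets up to ``N`` same-species extracts share that specificity mass:
the top-N extracts of the species by normalized value are jointly specific
when their summed proportion clears the threshold.

FS(e) is the fraction of extract *e*'s detected features that are specific
to it; FC(e) additionally requires the feature to be unannotated.  Two
optional intensity filters (a fraction-of-maximum floor and a per-extract
quantile cut) zero out low-abundance features before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_tables import FeatureTable

__all__ = [
    "NormalizedFeatureTable",
    "SpecificityResult",
    "normalize_rowwise",
    "compute_specificity",
    "compute_fs_fc",
    "apply_intensity_filter",
    "apply_quantile_filter",
]


@dataclass
class NormalizedFeatureTable:
    """Row-wise proportions of a feature table over the scored extracts."""

    values: pd.DataFrame  # index feature_id, columns scored extracts; rows sum to 1 or 0

    @property
    def extracts(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SpecificityResult:
    """Boolean specificity matrix plus the FS/FC ratios per extract."""

    specific: pd.DataFrame  # features x extracts, boolean
    min_specificity: float
    max_occurrence_n: int
    fs: pd.Series | None = None
    fc: pd.Series | None = None
    detected: pd.DataFrame | None = field(default=None, repr=False)


def normalize_rowwise(table: FeatureTable, scored_extracts: list[str]) -> NormalizedFeatureTable:
    """Divide each feature row by its total area over the scored extracts.

    All-zero rows are preserved as zeros (0/0 defined as 0).
    """
    sub = table.areas[list(scored_extracts)].astype(float)
    totals = sub.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = sub.div(totals, axis=0)
    norm[totals == 0] = 0.0
    return NormalizedFeatureTable(norm)


def compute_specificity(
    norm: NormalizedFeatureTable,
    metadata: pd.DataFrame,
    min_specificity: float = 0.90,
    max_occurrence_n: int = 1,
) -> SpecificityResult:
    """Flag which features are specific to which extracts.

    With ``max_occurrence_n = 1`` a feature is specific to extract *e* iff
    its normalized proportion there is >= ``min_specificity``.  With
    ``N > 1`` the proportion may be shared by up to N extracts of the same
    species: for each species, the feature's top-``min(N, #extracts)``
    extracts by proportion are jointly specific when their summed
    proportion reaches the threshold (each sharing extract must carry a
    nonzero proportion).  At most one species can win per feature because
    two disjoint sums cannot both reach 0.9.
    """
    if not (0 < min_specificity <= 1):
        raise ParameterError(f"min_specificity must be in (0, 1], got {min_specificity}")
    if max_occurrence_n < 1:
        raise ParameterError(f"max_occurrence_N must be >= 1, got {max_occurrence_n}")

    values = norm.values
    specific = pd.DataFrame(False, index=values.index, columns=values.columns)

    if max_occurrence_n == 1:
        specific[:] = values.to_numpy() >= min_specificity
        return SpecificityResult(specific, min_specificity, max_occurrence_n)

    meta = metadata.set_index("filename")
    species_of = meta.loc[values.columns, "species"]
    for _, cols_idx in species_of.groupby(species_of).groups.items():
        cols = [c for c in values.columns if c in set(cols_idx)]
        k = min(max_occurrence_n, len(cols))
        block = values[cols].to_numpy()
        # top-k proportions per feature within this species' extracts
        order = np.argsort(-block, axis=1, kind="stable")
        topk = order[:, :k]
        rows = np.arange(block.shape[0])[:, None]
        topk_sum = block[rows, topk].sum(axis=1)
        qualifies = topk_sum >= min_specificity
        mask = np.zeros_like(block, dtype=bool)
        mask[rows, topk] = True
        mask &= block > 0
        mask &= qualifies[:, None]
        specific.loc[:, cols] = specific[cols].to_numpy() | mask
    return SpecificityResult(specific, min_specificity, max_occurrence_n)


def compute_fs_fc(
    result: SpecificityResult,
    ledger: pd.DataFrame,
    table: FeatureTable,
) -> SpecificityResult:
    """Fill in FS and FC per extract.

    detected(e) = features with area > 0 in e (after any active filters);
    FS(e) = |specific & detected| / |detected|;
    FC(e) = |specific & detected & unannotated| / |detected|; 0/0 -> 0.
    """
    extracts = list(result.specific.columns)
    detected = table.areas[extracts].loc[result.specific.index] > 0
    annotated = ledger["annotated"].reindex(result.specific.index).fillna(False).astype(bool)

    n_detected = detected.sum(axis=0)
    spec_and_detected = result.specific & detected
    spec_detected = spec_and_detected.sum(axis=0)
    spec_unannot = spec_and_detected.loc[~annotated].sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        fs = spec_detected / n_detected
        fc = spec_unannot / n_detected
    result.fs = fs.fillna(0.0)
    result.fc = fc.fillna(0.0)
    result.detected = detected
    return result


def apply_intensity_filter(table: FeatureTable, min_fraction: float = 0.02) -> FeatureTable:
    """Zero out features below ``min_fraction`` of each extract's largest peak.

    The table is normalized sample-wise (each extract column divided by its
    maximum), and values whose normalized intensity falls below the floor
    are set to 0; surviving values are untouched.
    """
    if not (0 <= min_fraction < 1):
        raise ParameterError(f"min_fraction must be in [0, 1), got {min_fraction}")
    out = table.copy()
    col_max = out.areas.max(axis=0).replace(0, np.nan)
    frac = out.areas.div(col_max, axis=1).fillna(0.0)
    out.areas = out.areas.where(frac >= min_fraction, 0.0)
    return out


def apply_quantile_filter(table: FeatureTable, q: float = 0.75) -> FeatureTable:
    """Zero out features below the per-extract ``q``-quantile.

    The quantile (linear interpolation) is taken over each extract's
    *nonzero* areas only -- zeros dominate sparse aligned tables and would
    collapse the cut -- and values >= the quantile are kept.
    """
    if not (0 <= q < 1):
        raise ParameterError(f"q must be in [0, 1), got {q}")
    out = table.copy()
    for col in out.areas.columns:
        vals = out.areas[col].to_numpy()
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            continue
        cut = float(np.quantile(nonzero, q))
        out.areas[col] = np.where(vals >= cut, vals, 0.0)
    return out
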