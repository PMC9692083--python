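"""Similarity Component (SC): alignment-free extract comparison.

Each extract's MS2 spectra are vectorized into counts of *words* -- binned
fragment peaks (``peak@x.xx``) and precursor-minus-fragment neutral losses
(``loss@x.xx``) -- a fingerprint that needs no retention-time alignment.
Words observed in solvent blanks are background and removed.  A
Bray-Curtis dissimilarity matrix over the word-count rows is then mined by
three unsupervised outlier detectors (Local Outlier Factor, One-Class SVM,
Isolation Forest); an extract flagged by at least one detector gets
SC = 1, otherwise 0.  A spectrally dissimilar extract plausibly hides
singular chemistry, which is why outlierness is rewarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

from .errors import ParameterError, ValidationError
from .io_tables import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass
class MemoParams:
    """Parameters of the MS2 word vectorization.

    Intensities are scaled to the base peak; fragments with relative
    intensity in [min_rel_intensity, max_rel_intensity] are kept; spectra
    with fewer than ``min_peaks_required`` surviving fragments contribute
    nothing.  Neutral losses are counted within [losses_from, losses_to]
    daltons; word labels round m/z to ``n_decimal`` places.
    """

    min_rel_intensity: float = 0.01
    max_rel_intensity: float = 1.0
    min_peaks_required: int = 10
    losses_from: float = 10.0
    losses_to: float = 200.0
    n_decimal: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.min_rel_intensity < self.max_rel_intensity <= 1):
            raise ParameterError("need 0 <= min_rel_intensity < max_rel_intensity <= 1")
        if self.losses_from >= self.losses_to:
            raise ParameterError("need losses_from < losses_to")
        if self.n_decimal < 0:
            raise ParameterError("n_decimal must be >= 0")


def round_half_away(value: float, n_decimal: int) -> str:
    """Fixed-point formatting with half-away-from-zero rounding.

    Rounds the decimal literal of ``value`` (not its binary expansion), so
    word labels are bit-stable across platforms.
    """
    q = Decimal(1).scaleb(-n_decimal)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def memo_vectorize(
    spectra: SpectrumSet,
    extract_assignment: dict[int, str],
    params: MemoParams | None = None,
    extracts: list[str] | None = None,
) -> pd.DataFrame:
    """Count peak/loss words per extract.

    ``extract_assignment`` maps each spectrum's feature id to the extract
    it was acquired from.  Rows are extracts (all of ``extracts`` if
    given, else those observed), columns are word labels, cells are
    occurrence counts.
    """
    p = params or MemoParams()
    counts: dict[str, dict[str, int]] = {}
    if extracts is not None:
        for e in extracts:
            counts[e] = {}
    skipped_no_precursor = 0

    for spectrum in spectra:
        extract = extract_assignment.get(spectrum.feature_id)
        if extract is None:
            continue
        if not np.isfinite(spectrum.precursor_mz) or spectrum.precursor_mz <= 0:
            skipped_no_precursor += 1
            continue
        row = counts.setdefault(extract, {})
        if spectrum.mz.size == 0:
            continue
        base = spectrum.intensities.max()
        if base <= 0:
            continue
        rel = spectrum.intensities / base
        keep = (rel >= p.min_rel_intensity) & (rel <= p.max_rel_intensity)
        frag_mz = spectrum.mz[keep]
        if frag_mz.size < p.min_peaks_required:
            continue
        for mz in frag_mz:
            word = f"peak@{round_half_away(float(mz), p.n_decimal)}"
            row[word] = row.get(word, 0) + 1
            loss = spectrum.precursor_mz - float(mz)
            if p.losses_from <= loss <= p.losses_to:
                word = f"loss@{round_half_away(loss, p.n_decimal)}"
                row[word] = row.get(word, 0) + 1

    if skipped_no_precursor:
        logger.info("skipped %d spectra without a precursor mass", skipped_no_precursor)

    matrix = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    matrix = matrix.sort_index(axis=1)
    if extracts is not None:
        matrix = matrix.reindex(extracts).fillna(0).astype(int)
    return matrix


def remove_blank_words(memo: pd.DataFrame, blank_extracts: list[str]) -> pd.DataFrame:
    """Drop every word seen in any blank, then drop the blank rows."""
    blanks = [b for b in blank_extracts if b in memo.index]
    if not blanks:
        return memo.copy()
    blank_support = memo.loc[blanks].sum(axis=0) > 0
    kept_cols = memo.columns[~blank_support]
    return memo.loc[memo.index.difference(blanks, sort=False), kept_cols].copy()


def distance_matrix(memo: pd.DataFrame, metric: str = "braycurtis") -> pd.DataFrame:
    """Symmetric dissimilarity matrix over extract word-count rows."""
    if len(memo) < 2:
        raise ValidationError("need at least 2 extracts for a dissimilarity matrix")
    condensed = pdist(memo.to_numpy(dtype=float), metric=metric)
    dist = squareform(np.nan_to_num(condensed, nan=0.0))
    return pd.DataFrame(dist, index=memo.index, columns=memo.index)


@dataclass
class OutlierVerdict:
    """Per-extract detector flags, SC = OR of the three, plus provenance."""

    flags: pd.DataFrame  # columns lof, ocsvm, iforest (bool)
    sc: pd.Series  # 0/1 per extract
    params: dict


def detect_outliers(
    dist: pd.DataFrame,
    n_neighbors: int | None = None,
    nu: float = 0.1,
    n_estimators: int = 100,
    contamination: str | float = "auto",
    seed: int = 42,
    svm_margin_tol: float | None = None,
) -> OutlierVerdict:
    """Run the three-detector ensemble on a dissimilarity matrix.

    LOF consumes the matrix directly (precomputed metric, neighborhood
    min(5, n-1) unless given); the One-Class SVM (rbf, nu) and the
    Isolation Forest (seeded) embed each extract as its row of distances
    to all extracts.  SC = 1 iff at least one detector votes outlier.

    The SVM votes outlier only when the decision function is below the
    boundary by more than ``svm_margin_tol`` (default: the solver
    tolerance).  On small extract sets many points sit numerically *on*
    the margin (|decision| ~ solver tolerance); the raw sign would label
    such boundary support vectors as outliers essentially at random.
    """
    n = len(dist)
    if n < 2:
        raise ValidationError("need at least 2 extracts for outlier detection")
    k = n_neighbors if n_neighbors is not None else min(5, n - 1)
    if k >= n:
        logger.warning("n_neighbors %d >= n extracts %d; shrinking to %d", k, n, n - 1)
        k = n - 1

    x = dist.to_numpy(dtype=float)

    lof = LocalOutlierFactor(n_neighbors=k, metric="precomputed", contamination=contamination)
    lof_flags = lof.fit_predict(x) == -1

    ocsvm = OneClassSVM(kernel="rbf", nu=nu).fit(x)
    margin_tol = ocsvm.tol if svm_margin_tol is None else svm_margin_tol
    ocsvm_flags = ocsvm.decision_function(x) < -margin_tol

    iforest = IsolationForest(
        n_estimators=n_estimators, contamination=contamination, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iforest_flags = iforest.fit_predict(x) == -1

    flags = pd.DataFrame(
        {"lof": lof_flags, "ocsvm": ocsvm_flags, "iforest": iforest_flags},
        index=dist.index,
    )
    sc = flags.any(axis=1).astype(int)
    return OutlierVerdict(
        flags=flags,
        sc=sc,
        params={
            "n_neighbors": k,
            "nu": nu,
            "n_estimators": n_estimators,
            "contamination": contamination,
            "svm_margin_tol": margin_tol,
            "seed": seed,
            "aggregation": "or",
        },
    )
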