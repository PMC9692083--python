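"""End-to-end orchestration: inputs -> component scores -> ranked table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation_cleaning import clean_gnps, merge_annotation_status
from .class_component import CCResult, compute_cc, recurrent_classes
from .feature_component import (
    apply_intensity_filter,
    apply_quantile_filter,
    compute_fs_fc,
    compute_specificity,
    normalize_rowwise,
)
from .io_tables import FeatureTable, SpectrumSet, blank_extracts, collapse_iin, sample_extracts
from .literature_component import LCParams, LiteratureSummary, compute_lc, lookup_taxon
from .scoring_report import build_results_table, compute_ps
from .similarity_component import (
    MemoParams,
    OutlierVerdict,
    detect_outliers,
    distance_matrix,
    memo_vectorize,
    remove_blank_words,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    components: pd.DataFrame  # per extract: FS FC LC CCs CCg CC SC PS rank
    results_table: pd.DataFrame
    ledger: pd.DataFrame
    specificity: object
    summaries: dict[str, LiteratureSummary]
    cc_results: dict[str, CCResult]
    verdict: OutlierVerdict | None
    prefilter_table: FeatureTable = field(repr=False, default=None)
    table: FeatureTable = field(repr=False, default=None)


def assignment_by_max_area(table: FeatureTable, scored: list[str]) -> dict[int, str]:
    """Assign each feature's MS2 spectrum to the extract with its largest area."""
    sub = table.areas[scored]
    detected = sub.sum(axis=1) > 0
    return sub.loc[detected].idxmax(axis=1).to_dict()


def run_pipeline(
    table: FeatureTable,
    metadata: pd.DataFrame,
    gnps: pd.DataFrame | None = None,
    isdb: pd.DataFrame | None = None,
    sirius: pd.DataFrame | None = None,
    class_predictions: pd.DataFrame | None = None,
    occurrences: pd.DataFrame | None = None,
    spectra: SpectrumSet | None = None,
    extract_assignment: dict[int, str] | None = None,
    *,
    min_specificity: float = 0.90,
    max_occurrence_n: int = 1,
    intensity_min_fraction: float | None = None,
    quantile_q: float | None = None,
    lc_params: LCParams | None = None,
    min_class_confidence: float = 0.8,
    min_recurrence: float = 0.8,
    memo_params: MemoParams | None = None,
    sc_metric: str = "braycurtis",
    sc_seed: int = 42,
    weights: dict[str, float] | None = None,
    gnps_filter_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the full prioritization on in-memory inputs.

    Absent inputs degrade gracefully: no annotations -> every feature
    unannotated (FC = FS); no occurrence table -> LC from zero counts (1);
    no class predictions -> CC = 0; no spectra -> SC = 0.
    """
    table = table.validate(metadata)
    prefilter = collapse_iin(table)
    working = prefilter
    if intensity_min_fraction is not None:
        working = apply_intensity_filter(working, intensity_min_fraction)
    if quantile_q is not None:
        working = apply_quantile_filter(working, quantile_q)

    scored = sample_extracts(metadata)
    blanks = blank_extracts(metadata)
    meta_scored = metadata[metadata["filename"].isin(scored)]

    gnps_clean = clean_gnps(gnps, **(gnps_filter_kwargs or {})) if gnps is not None else None
    ledger = merge_annotation_status(gnps_clean, isdb, sirius, working.feature_ids)

    norm = normalize_rowwise(working, scored)
    specificity = compute_specificity(norm, meta_scored, min_specificity, max_occurrence_n)
    specificity = compute_fs_fc(specificity, ledger, working)

    if occurrences is not None:
        summaries = lookup_taxon(meta_scored, occurrences)
    else:
        summaries = {e: LiteratureSummary(filename=e) for e in scored}
    lc = pd.Series({e: compute_lc(summaries[e], lc_params) for e in scored})

    cc_results: dict[str, CCResult] = {}
    for e in scored:
        classes = (
            recurrent_classes(class_predictions, working, e, min_class_confidence, min_recurrence)
            if class_predictions is not None
            else frozenset()
        )
        cc_results[e] = compute_cc(classes, summaries[e])

    verdict = None
    sc = pd.Series(0, index=pd.Index(scored))
    if spectra is not None and len(spectra) and len(scored) >= 2:
        assignment = extract_assignment or assignment_by_max_area(working, scored)
        memo = memo_vectorize(spectra, assignment, memo_params, extracts=scored + blanks)
        memo = remove_blank_words(memo, blanks)
        dist = distance_matrix(memo, metric=sc_metric)
        verdict = detect_outliers(dist, seed=sc_seed)
        sc = verdict.sc.reindex(scored).fillna(0).astype(int)

    components = pd.DataFrame(
        {
            "FS": specificity.fs.reindex(scored),
            "FC": specificity.fc.reindex(scored),
            "LC": lc,
            "CCs": pd.Series({e: cc_results[e].ccs for e in scored}),
            "CCg": pd.Series({e: cc_results[e].ccg for e in scored}),
            "CC": pd.Series({e: cc_results[e].cc for e in scored}),
            "SC": sc,
        }
    )
    components.index.name = "filename"
    ranked = compute_ps(components, weights)
    results = build_results_table(ranked, metadata, summaries, cc_results)

    return PipelineResult(
        components=ranked,
        results_table=results,
        ledger=ledger,
        specificity=specificity,
        summaries=summaries,
        cc_results=cc_results,
        verdict=verdict,
        prefilter_table=prefilter,
        table=working,
    )
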