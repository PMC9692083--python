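"""Priority Score assembly, ranking, results table and ion-map export.

PS = w_fc*FC + w_lc*LC + w_cc*CC + w_sc*SC, computed on unrounded
components (display rounding to 2 decimals happens only in the results
table).  Extracts are ranked by descending PS; ties break by descending
FC, then filename.  The ion map classifies each feature of one extract as
``specific_unannotated`` (worth isolating), ``specific_annotated`` or
``nonspecific``, with areas taken from the pre-filter table so spot sizes
reflect the original quantification.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .class_component import CCResult
from .feature_component import SpecificityResult
from .io_tables import FeatureTable
from .literature_component import LiteratureSummary

DEFAULT_WEIGHTS = {"w_fc": 1.0, "w_lc": 1.0, "w_cc": 1.0, "w_sc": 1.0}

_COMPONENT_OF_WEIGHT = {"w_fc": "FC", "w_lc": "LC", "w_cc": "CC", "w_sc": "SC"}


def compute_ps(components: pd.DataFrame, weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Add the Priority Score and rank columns to a per-extract component table.

    ``components`` must carry FC, LC, CC and SC columns (FS optional),
    indexed by extract filename.  Returns a copy sorted by rank.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        unknown = set(weights) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ValidationError(f"unknown weight(s): {sorted(unknown)}")
        w.update(weights)
    out = components.copy()
    for wname, col in _COMPONENT_OF_WEIGHT.items():
        if col not in out.columns:
            raise ValidationError(f"missing component column {col!r}")
        bad = out.index[out[col].isna()]
        if len(bad):
            raise ValidationError(f"component {col} missing for extract(s) {list(bad)}")
    out["PS"] = sum(w[wname] * out[col] for wname, col in _COMPONENT_OF_WEIGHT.items())
    # stable sort on a filename-ordered frame: ties break by descending FC,
    # then ascending filename
    order = (
        out.assign(_fc=out["FC"])
        .sort_index()
        .sort_values(by=["PS", "_fc"], ascending=[False, False], kind="mergesort")
        .drop(columns="_fc")
    )
    order["rank"] = range(1, len(order) + 1)
    for wname, val in w.items():
        order.attrs[wname] = val
    return order


def build_results_table(
    components: pd.DataFrame,
    metadata: pd.DataFrame,
    summaries: dict[str, LiteratureSummary],
    cc_results: dict[str, CCResult],
) -> pd.DataFrame:
    """One row per extract: rank, taxonomy, all scores, new-class names.

    Numeric scores are rounded to 2 decimals for display; the PS column is
    the rounded unrounded-sum (ranking always uses unrounded values).
    """
    ranked = components if "rank" in components.columns else compute_ps(components)
    meta = metadata.set_index("filename")
    rows = []
    for extract, rec in ranked.iterrows():
        taxon = meta.loc[extract]
        summ = summaries.get(extract, LiteratureSummary(filename=extract))
        ccr = cc_results.get(extract, CCResult(0.0, 0.0))
        rows.append(
            {
                "rank": int(rec["rank"]),
                "filename": extract,
                "genus": taxon["genus"],
                "species": taxon["species"],
                "organ": taxon["organ"],
                "FS": round(float(rec.get("FS", float("nan"))), 2),
                "FC": round(float(rec["FC"]), 2),
                "LC": round(float(rec["LC"]), 2),
                "rcs": summ.rcs,
                "rcg": summ.rcg,
                "CC": round(float(rec["CC"]), 2),
                "nccs": ", ".join(sorted(ccr.new_classes_species)),
                "nccg": ", ".join(sorted(ccr.new_classes_genus)),
                "SC": int(rec["SC"]),
                "PS": round(float(rec["PS"]), 2),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


def export_ion_map(
    table: FeatureTable,
    specificity: SpecificityResult,
    ledger: pd.DataFrame,
    class_predictions: pd.DataFrame | None,
    extract: str,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-feature status records for one extract's ion map.

    ``table`` should be the pre-filter (IIN-collapsed) table so that
    intensities reflect the original quantification.  Categories partition
    the extract's detected features: ``specific_unannotated``,
    ``specific_annotated``, ``nonspecific``.
    """
    if extract not in table.areas.columns:
        raise ValidationError(f"unknown extract {extract!r}")
    detected_ids = table.feature_ids[table.areas[extract] > 0]
    spec = specificity.specific[extract].reindex(detected_ids).fillna(False)
    annotated = ledger["annotated"].reindex(detected_ids).fillna(False).astype(bool)
    category = pd.Series("nonspecific", index=detected_ids, dtype=object)
    category[spec & ~annotated] = "specific_unannotated"
    category[spec & annotated] = "specific_annotated"

    records = pd.DataFrame(
        {
            "feature_id": detected_ids,
            "mz": table.features.loc[detected_ids, "mz"].to_numpy(),
            "rt": table.features.loc[detected_ids, "rt"].to_numpy(),
            "area": table.areas.loc[detected_ids, extract].to_numpy(),
            "iin_id": table.features.loc[detected_ids, "iin_id"].to_numpy(),
            "adduct": table.features.loc[detected_ids, "adduct"].to_numpy()
            if "adduct" in table.features.columns
            else None,
            "category": category.to_numpy(),
        }
    )
    if class_predictions is not None and not class_predictions.empty:
        best = (
            class_predictions.sort_values("npc_probability", ascending=False)
            .drop_duplicates("feature_id")
            .set_index("feature_id")
        )
        records["predicted_class"] = best["npc_class"].reindex(records["feature_id"]).to_numpy()
    else:
        records["predicted_class"] = None
    if path is not None:
        records.to_csv(path, sep="\t", index=False)
    return records
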