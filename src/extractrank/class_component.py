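"""Class Component (CC): are recurrent predicted chemical classes new?

Chemical classes predicted per feature (NPClassifier ontology, e.g. from
CANOPUS) are compared, per extract, against the classes already reported
in the literature for the species and the genus.  Only *recurrent*,
*confident* predictions count: a class must be predicted with probability
>= ``min_class_confidence`` on more than *n* of the extract's features
(``min_recurrence``: values >= 1 are absolute counts, values in (0, 1)
are fractions of the extract's confidently classified features).

The comparison itself is string-set subtraction on canonicalized class
names: any recurrent class absent from the species set adds CCs = 0.5,
any absent from the genus set adds CCg = 0.5, so CC in {0, 0.5, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParameterError, ValidationError
from .io_tables import FeatureTable
from .literature_component import LiteratureSummary, canonical_class

#: Config-mappable aliases for a CANOPUS-style summary TSV.
CANOPUS_COLUMN_ALIASES = {
    "feature_id": ("feature_id", "id", "mappingFeatureId", "featureId"),
    "npc_class": ("npc_class", "NPC#class", "class"),
    "npc_probability": ("npc_probability", "NPC#class Probability", "classProbability"),
}


@dataclass
class CCResult:
    ccs: float  # 0 or 0.5: a recurrent class is new to the species
    ccg: float  # 0 or 0.5: ... new to the genus
    new_classes_species: frozenset[str] = field(default_factory=frozenset)
    new_classes_genus: frozenset[str] = field(default_factory=frozenset)

    @property
    def cc(self) -> float:
        return self.ccs + self.ccg


def load_class_predictions(path: str | Path) -> pd.DataFrame:
    """Read a class-prediction TSV into (feature_id, npc_class, npc_probability)."""
    table = pd.read_csv(path, sep="\t")
    renames = {}
    for canonical, aliases in CANOPUS_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in table.columns:
                renames[alias] = canonical
                break
    table = table.rename(columns=renames)
    missing = [c for c in CANOPUS_COLUMN_ALIASES if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: class-prediction table lacks column(s) {missing}")
    bad = ~table["npc_probability"].between(0, 1)
    if bad.any():
        raise ValidationError(f"{path}: class probabilities outside [0, 1]")
    return table


def recurrent_classes(
    predictions: pd.DataFrame,
    table: FeatureTable,
    extract: str,
    min_class_confidence: float = 0.8,
    min_recurrence: float = 0.8,
) -> frozenset[str]:
    """Classes confidently and recurrently predicted among an extract's features.

    A prediction is confident when ``npc_probability >= min_class_confidence``.
    A class is recurrent when its confident feature count in the extract is
    strictly greater than the threshold: ``min_recurrence >= 1`` is an
    absolute count *n*; ``min_recurrence`` in (0, 1) is a fraction of the
    extract's confidently classified features.
    """
    if not (0 <= min_class_confidence <= 1):
        raise ParameterError(f"min_class_confidence must be in [0, 1], got {min_class_confidence}")
    if min_recurrence <= 0:
        raise ParameterError(f"min_recurrence must be positive, got {min_recurrence}")
    if predictions is None or predictions.empty:
        return frozenset()
    if extract not in table.areas.columns:
        raise ValidationError(f"unknown extract {extract!r}")

    detected = set(table.feature_ids[table.areas[extract] > 0])
    conf = predictions.loc[
        predictions["feature_id"].isin(detected)
        & (predictions["npc_probability"] >= min_class_confidence)
    ]
    if conf.empty:
        return frozenset()
    counts = conf["npc_class"].map(canonical_class).value_counts()
    if min_recurrence >= 1:
        threshold = float(min_recurrence)
    else:
        threshold = min_recurrence * int(counts.sum())
    return frozenset(counts.index[counts > threshold])


def compute_cc(extract_classes: frozenset[str], summary: LiteratureSummary) -> CCResult:
    """Set-subtract the extract's recurrent classes against the literature."""
    classes = frozenset(canonical_class(c) for c in extract_classes)
    new_sp = classes - summary.species_classes
    new_g = classes - summary.genus_classes
    return CCResult(
        ccs=0.5 if new_sp else 0.0,
        ccg=0.5 if new_g else 0.0,
        new_classes_species=frozenset(new_sp),
        new_classes_genus=frozenset(new_g),
    )
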