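"""Literature Component (LC) from offline per-taxon occurrence counts.

LC summarizes how heavily a taxon has already been studied.  It starts at
1 (no reported compounds) and subtracts, for each rank, a weighted
fraction of the reported compound count over a user-defined maximum:

    LC = 1 - [w_sp * rcs/max_sp + w_g * rcg/max_g + w_f * rcf/max_f]

with equal default weights (1/3 each) and default maxima 20 / 100 / 500
for species / genus / family.  Fractions are uncapped by default, so a
taxon with far more reports than the maximum drives LC negative --
heavily studied species rank last on this axis.  Optionally each fraction
can be capped at 1.

Occurrence counts come from an offline table (standing in for live
natural-product occurrence databases); taxon names are expected to be
already resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

_RANKS = ("species", "genus", "family")


def canonical_class(name: str) -> str:
    """Canonicalize a chemical-class string: trim, collapse whitespace, casefold."""
    return " ".join(str(name).split()).casefold()


@dataclass
class LiteratureSummary:
    """Reported-compound counts and literature class sets for one extract."""

    filename: str
    rcs: int = 0  # reported compounds in the species
    rcg: int = 0  # ... in the genus
    rcf: int = 0  # ... in the family
    species_classes: frozenset[str] = field(default_factory=frozenset)
    genus_classes: frozenset[str] = field(default_factory=frozenset)


@dataclass
class LCParams:
    max_sp: int = 20
    max_g: int = 100
    max_f: int = 500
    w_sp: float = 1 / 3
    w_g: float = 1 / 3
    w_f: float = 1 / 3
    cap_fractions: bool = False

    def __post_init__(self) -> None:
        if min(self.max_sp, self.max_g, self.max_f) <= 0:
            raise ParameterError("occurrence maxima must be positive")
        if min(self.w_sp, self.w_g, self.w_f) < 0:
            raise ParameterError("weights must be non-negative")


def load_occurrence_table(path: str | Path) -> pd.DataFrame:
    """Read the offline occurrence TSV: rank, name, compound_count, classes.

    ``classes`` holds pipe-separated chemical-class strings (may be empty).
    """
    table = pd.read_csv(path, sep="\t", dtype={"classes": str}, keep_default_na=False)
    required = ["rank", "name", "compound_count"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: occurrence table lacks column(s) {missing}")
    bad = set(table["rank"]) - set(_RANKS)
    if bad:
        raise ValidationError(f"{path}: unknown taxon rank(s) {sorted(bad)}")
    if "classes" not in table.columns:
        table["classes"] = ""
    return table


def _class_set(cell: str) -> frozenset[str]:
    if not cell or pd.isna(cell):
        return frozenset()
    return frozenset(canonical_class(c) for c in str(cell).split("|") if c.strip())


def lookup_taxon(metadata: pd.DataFrame, occurrence_table: pd.DataFrame) -> dict[str, LiteratureSummary]:
    """Join each extract's taxonomy against the occurrence table.

    Exact name match at each rank; a taxon absent from the table yields a
    count of 0 and an empty class set (with a logged warning).
    """
    if not {"rank", "name", "compound_count"} <= set(occurrence_table.columns):
        raise ValidationError("malformed occurrence table")
    lut: dict[tuple[str, str], tuple[int, frozenset[str]]] = {}
    for _, row in occurrence_table.iterrows():
        lut[(row["rank"], str(row["name"]))] = (
            int(row["compound_count"]),
            _class_set(row.get("classes", "")),
        )

    out: dict[str, LiteratureSummary] = {}
    for _, rec in metadata.iterrows():
        counts = {}
        classes = {}
        for rank, taxon in (("species", rec["species"]), ("genus", rec["genus"]), ("family", rec["family"])):
            hit = lut.get((rank, str(taxon)))
            if hit is None:
                logger.warning("taxon %r (%s) absent from occurrence table", taxon, rank)
                counts[rank], classes[rank] = 0, frozenset()
            else:
                counts[rank], classes[rank] = hit
        out[rec["filename"]] = LiteratureSummary(
            filename=rec["filename"],
            rcs=counts["species"],
            rcg=counts["genus"],
            rcf=counts["family"],
            species_classes=classes["species"],
            genus_classes=classes["genus"],
        )
    return out


def compute_lc(summary: LiteratureSummary, params: LCParams | None = None) -> float:
    """Literature Component for one extract (may be negative when uncapped)."""
    p = params or LCParams()
    cap = (lambda x: min(x, 1.0)) if p.cap_fractions else (lambda x: x)
    return 1.0 - (
        p.w_sp * cap(summary.rcs / p.max_sp)
        + p.w_g * cap(summary.rcg / p.max_g)
        + p.w_f * cap(summary.rcf / p.max_f)
    )
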