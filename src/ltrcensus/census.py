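"""Genome-ecology census: per-genome element counts and cross-genome
aggregate statistics.

A census row summarises one genome: total detected LTR retrotransposons,
how many are functional (carry at least one of Gag/INT/RT/AP/RH), the
superfamily breakdown (Ty1/Copia, Ty3/Gypsy, chromoviral Gypsy,
unclassified) and the number of >=80%-identity families. Aggregation gives
group means and medians (midpoint convention for even group sizes), the
statistics used to compare phyla.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CensusRow",
    "AggregateStats",
    "BASIDIOMYCOTA_FUNCTIONAL_COUNTS",
    "genome_summary",
    "aggregate",
    "load_census_table",
    "write_census_table",
]

#: Published counts of potentially functional LTR retrotransposons for the
#: eight Basidiomycota genomes of the fungal census dataset — a complete
#: taxon group usable as a worked aggregation example (group mean ~607,
#: median ~278).
BASIDIOMYCOTA_FUNCTIONAL_COUNTS: dict[str, int] = {
    "Postia placenta": 3108,
    "Laccaria bicolor": 453,
    "Coprinopsis cinerea": 400,
    "Phanerochaete chrysosporium": 614,
    "Ustilago maydis": 35,
    "Sporobolomyces roseus": 47,
    "Cryptococcus neoformans grubii": 155,
    "Cryptococcus bacillisporus": 40,
}


@dataclass
class CensusRow:
    genome_id: str
    phylum: str = ""
    order: str = ""
    total_elements: int = 0
    functional_elements: int = 0
    copia_count: int = 0
    gypsy_count: int = 0
    chromoviral_count: int = 0
    unclassified_count: int = 0
    family_count: int = 0
    mse_superfamily: str | None = None

    def violations(self) -> list[str]:
        out = []
        if self.functional_elements > self.total_elements:
            out.append("functional_elements > total_elements")
        breakdown = self.copia_count + self.gypsy_count + self.unclassified_count
        # an all-zero breakdown means the table did not report one
        if breakdown and breakdown != self.total_elements:
            out.append("copia + gypsy + unclassified != total")
        if self.chromoviral_count > self.gypsy_count:
            out.append("chromoviral_count > gypsy_count")
        for f in ("total_elements", "functional_elements", "copia_count",
                  "gypsy_count", "chromoviral_count", "unclassified_count",
                  "family_count"):
            if getattr(self, f) < 0:
                out.append(f"negative {f}")
        return out


@dataclass
class AggregateStats:
    group: str
    n_genomes: int
    mean: float
    median: float


def genome_summary(classifications: dict[str, object],
                   families: list,
                   genome_id: str,
                   phylum: str = "",
                   order: str = "",
                   mse_superfamily: str | None = None) -> CensusRow:
    """Census row for one genome from its element classifications and
    family partition. ``classifications`` maps element id to an
    ElementClassification."""
    total = len(classifications)
    functional = sum(1 for c in classifications.values() if c.functional)
    copia = sum(1 for c in classifications.values() if c.superfamily == "Copia")
    gypsy = sum(1 for c in classifications.values() if c.superfamily == "Gypsy")
    chromo = sum(1 for c in classifications.values()
                 if c.superfamily == "Gypsy" and c.chromoviral)
    row = CensusRow(
        genome_id=genome_id, phylum=phylum, order=order,
        total_elements=total, functional_elements=functional,
        copia_count=copia, gypsy_count=gypsy, chromoviral_count=chromo,
        unclassified_count=total - copia - gypsy,
        family_count=len(families),
        mse_superfamily=mse_superfamily)
    return row


def aggregate(rows: list[CensusRow] | pd.DataFrame,
              column: str,
              group_by: str | None = None) -> list[AggregateStats]:
    """Mean and median of ``column`` per group (midpoint median for even
    group sizes). Empty groups are omitted with a warning."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        warnings.warn("no census rows to aggregate")
        return []
    if column not in df.columns:
        raise KeyError(f"census table has no column {column!r}")
    out: list[AggregateStats] = []
    if group_by is None:
        groups = [("all", df)]
    else:
        groups = [(str(k), g) for k, g in df.groupby(group_by, sort=True)]
    for label, g in groups:
        values = g[column].dropna().astype(float)
        if values.empty:
            warnings.warn(f"group {label!r} has no values for {column!r}; omitted")
            continue
        out.append(AggregateStats(
            group=label, n_genomes=len(values),
            mean=float(values.mean()), median=float(values.median())))
    return out


_REQUIRED_COLUMNS = ("genome_id", "total_elements", "functional_elements")


def load_census_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> tuple[list[CensusRow], list[tuple[dict, list[str]]]]:
    """Load a per-genome census TSV.

    ``column_map`` renames file columns to census fields (the adaptation
    point for externally produced tables). Rows breaching the row
    invariants are quarantined — returned separately with their reasons —
    rather than silently dropped.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census table is missing required columns: {missing}")

    known = {f.name for f in fields(CensusRow)}
    rows: list[CensusRow] = []
    quarantined: list[tuple[dict, list[str]]] = []
    for raw in df.to_dict(orient="records"):
        kwargs = {k: v for k, v in raw.items() if k in known and pd.notna(v)}
        for f in ("total_elements", "functional_elements", "copia_count",
                  "gypsy_count", "chromoviral_count", "unclassified_count",
                  "family_count"):
            if f in kwargs:
                kwargs[f] = int(kwargs[f])
        row = CensusRow(**kwargs)
        bad = row.violations()
        if bad:
            quarantined.append((raw, bad))
        else:
            rows.append(row)
    return rows, quarantined


def write_census_table(rows: list[CensusRow], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in rows]).to_csv(path, sep="\t", index=False)
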