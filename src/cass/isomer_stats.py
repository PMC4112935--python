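"""Formula-level isomerism censuses, cross-database overlap and trends.

A formula is *isomeric* when two or more entries carry it.  Percentages
report on two denominators: distinct formulae (how much of formula space is
ambiguous) and entries (how many compounds a bare-formula lookup cannot
pin down).  The historical trend replays either census over growing
id-sorted prefixes of the database, one step per percent added.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .fg_database import FGDatabase

__all__ = [
    "FormulaCensus",
    "OverlapReport",
    "formula_census",
    "overlap_report",
    "historical_trend",
]


@dataclass(frozen=True)
class FormulaCensus:
    n_entries: int
    n_distinct_formulae: int
    n_isomeric_formulae: int
    pct_isomeric_formulae: float
    n_isomeric_entries: int
    pct_isomeric_entries: float


@dataclass(frozen=True)
class OverlapReport:
    formulae_only_A: frozenset[str]
    formulae_only_B: frozenset[str]
    formulae_shared: frozenset[str]
    shared_isomeric_in: dict[str, str]  # formula -> neither|A_only|B_only|both


def _census_of(formulae: list[str]) -> FormulaCensus:
    counts = Counter(formulae)
    n_entries = len(formulae)
    n_distinct = len(counts)
    isomeric = {f for f, n in counts.items() if n >= 2}
    n_iso_entries = sum(counts[f] for f in isomeric)
    return FormulaCensus(
        n_entries=n_entries,
        n_distinct_formulae=n_distinct,
        n_isomeric_formulae=len(isomeric),
        pct_isomeric_formulae=(
            100.0 * len(isomeric) / n_distinct if n_distinct else 0.0
        ),
        n_isomeric_entries=n_iso_entries,
        pct_isomeric_entries=(
            100.0 * n_iso_entries / n_entries if n_entries else 0.0
        ),
    )


def _formulae(db: FGDatabase) -> dict[str, str]:
    return {
        cid: db.get_entry(cid).formula for cid in db.ids()
    }


def formula_census(db: FGDatabase) -> FormulaCensus:
    """Distinct/isomeric formula and entry tallies for one database."""
    return _census_of(list(_formulae(db).values()))


def overlap_report(db_A: FGDatabase, db_B: FGDatabase) -> OverlapReport:
    """Formula-set overlap plus per-shared-formula isomerism class."""
    counts_a = Counter(_formulae(db_A).values())
    counts_b = Counter(_formulae(db_B).values())
    set_a, set_b = set(counts_a), set(counts_b)
    shared = set_a & set_b
    classes = {}
    for f in shared:
        iso_a = counts_a[f] >= 2
        iso_b = counts_b[f] >= 2
        classes[f] = (
            "both" if iso_a and iso_b
            else "A_only" if iso_a
            else "B_only" if iso_b
            else "neither"
        )
    return OverlapReport(
        formulae_only_A=frozenset(set_a - shared),
        formulae_only_B=frozenset(set_b - shared),
        formulae_shared=frozenset(shared),
        shared_isomeric_in=classes,
    )


def _prefix(sorted_vals: list[str], k: int, steps: int) -> list[str]:
    # First ceil(n * k / steps) entries; the last step covers everything.
    n = len(sorted_vals)
    take = -(-n * k // steps)
    return sorted_vals[:take]


def historical_trend(
    db: FGDatabase,
    db2: FGDatabase | None = None,
    step_percent: float = 1.0,
    metric: str = "pct_isomeric_formulae",
) -> list[tuple[float, float]]:
    """Census metric over growing id-sorted prefixes.

    Returns (percent of database included, metric value) points.  With two
    databases, each step appends the next slice of *both* sources (A block
    then B block), emulating combined growth.  The final point always
    equals the full-database census.
    """
    if metric not in ("pct_isomeric_formulae", "pct_isomeric_entries"):
        raise ValueError(f"unknown metric {metric!r}")
    steps = round(100.0 / step_percent)
    ids_a = sorted(_formulae(db).items())
    formulae_a = [f for _, f in ids_a]
    formulae_b: list[str] = []
    if db2 is not None:
        formulae_b = [f for _, f in sorted(_formulae(db2).items())]
    series = []
    for k in range(1, steps + 1):
        chunk = _prefix(formulae_a, k, steps) + _prefix(formulae_b, k, steps)
        census = _census_of(chunk)
        series.append((100.0 * k / steps, getattr(census, metric)))
    return series
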