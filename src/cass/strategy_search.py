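"""Chemoselective-tagging strategy scoring and beam search.

A tagging strategy is a set of functional groups assumed to be detectable
by chemoselective derivatization.  Each database compound then presents a
*signature*: its molecular formula plus, per strategy group, a transformed
effective count.  The transform models what the adduct chemistry can
resolve:

* ``stoichiometric`` — the exact instance count,
* ``pseudostoichiometric`` — 0, 1 or 2 exactly; three or more collapse to
  a single saturated symbol ``"3+"``,
* ``non_stoichiometric`` — presence only (0 or 1).

Strategy *performance* is the percentage of compounds whose signature is
unique in the database.  Adding a group can only refine signatures, so
performance is monotone in the group set and the three modes order
stoichiometric >= pseudostoichiometric >= non-stoichiometric.

Because exhaustive search over group subsets is infeasible for real
libraries, strategies grow iteratively: score all singletons, keep the top
``keep_first``; then repeatedly expand every survivor with every library
group, discard children improving on their parent by less than ``cutoff``
percentage points, deduplicate set-equal children and keep the top
``keep``.  The search ends after ``iterations`` rounds or when no child
survives the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fg_database import CompoundRecord, FGDatabase
from .match_classify import SCOPES, CountingScope, GroupCountTable

__all__ = [
    "MODES",
    "Strategy",
    "transform_count",
    "signature",
    "strategy_performance",
    "baseline_performance",
    "theoretical_ceiling",
    "beam_search",
]

MODES = ("stoichiometric", "pseudostoichiometric", "non_stoichiometric")


def transform_count(count: int, mode: str):
    """Apply the quantification-mode transform to one instance count."""
    if mode == "stoichiometric":
        return count
    if mode == "non_stoichiometric":
        return min(count, 1)
    if mode == "pseudostoichiometric":
        return count if count <= 2 else "3+"
    raise ValueError(f"unknown quantification mode {mode!r}")


@dataclass(frozen=True)
class Strategy:
    groups: frozenset[str]
    mode: str = "stoichiometric"
    scope: str = "distinct"
    performance: float = float("nan")

    def sorted_groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.groups))


class _ScopedCounts:
    """Effective per-group counts for every record, computed once."""

    def __init__(self, db: FGDatabase, scope: str):
        library = db.load_library()
        self.names = [g.name for g in library]
        supers = {g.name for g in library if g.is_super}
        scope_obj: CountingScope = SCOPES[scope]
        self.records: list[CompoundRecord] = db.records()
        self.counts: list[dict[str, int]] = []
        for rec in self.records:
            table = GroupCountTable()
            for g, cats in rec.counts.items():
                for cat, n in cats.items():
                    for _ in range(n):
                        table.add(g, cat)
            self.counts.append({
                name: scope_obj.effective_count(table, name, name in supers)
                for name in self.names
            })


def _unique_percent(cache: _ScopedCounts, groups: tuple[str, ...],
                    mode: str) -> float:
    from collections import Counter

    sigs = []
    for rec, counts in zip(cache.records, cache.counts):
        sigs.append(
            (rec.formula,)
            + tuple(transform_count(counts[g], mode) for g in groups)
        )
    tally = Counter(sigs)
    n = len(sigs)
    if n == 0:
        return 0.0
    unique = sum(1 for s in sigs if tally[s] == 1)
    return 100.0 * unique / n


def signature(
    record: CompoundRecord,
    strategy: Strategy,
    db: FGDatabase,
) -> tuple:
    """(formula, transformed count per sorted strategy group)."""
    library = db.load_library()
    names = {g.name for g in library}
    supers = {g.name for g in library if g.is_super}
    for g in strategy.groups:
        if g not in names:
            raise KeyError(f"unknown functional group {g!r}")
    scope_obj = SCOPES[strategy.scope]
    table = GroupCountTable()
    for g, cats in record.counts.items():
        for cat, n in cats.items():
            for _ in range(n):
                table.add(g, cat)
    return (record.formula,) + tuple(
        transform_count(
            scope_obj.effective_count(table, g, g in supers), strategy.mode
        )
        for g in strategy.sorted_groups()
    )


def strategy_performance(db: FGDatabase, strategy: Strategy) -> float:
    """Percent of database compounds with a unique signature."""
    cache = _ScopedCounts(db, strategy.scope)
    unknown = set(strategy.groups) - set(cache.names)
    if unknown:
        raise KeyError(f"unknown functional groups {sorted(unknown)}")
    return _unique_percent(cache, strategy.sorted_groups(), strategy.mode)


def baseline_performance(db: FGDatabase) -> float:
    """Percent of compounds already unique on bare molecular formula."""
    return strategy_performance(
        db, Strategy(groups=frozenset(), mode="stoichiometric")
    )


def theoretical_ceiling(
    db: FGDatabase, depth: int = 2, omit_hydrogens: bool = True
) -> float:
    """Percent of compounds not in any confirmed stereo pair.

    Connectivity-identical entries can never be separated by formula plus
    functional-group counts, so this bounds every strategy's performance.
    """
    from .stereo_analysis import stereo_census

    census = stereo_census(db, depth=depth, omit_hydrogens=omit_hydrogens)
    n = census["n_compounds"]
    if n == 0:
        return 100.0
    return 100.0 * (n - census["n_in_stereo_pairs"]) / n


def _rank_key(s: Strategy):
    return (-s.performance, len(s.groups), s.sorted_groups())


def beam_search(
    db: FGDatabase,
    mode: str = "stoichiometric",
    scope: str = "distinct",
    iterations: int = 15,
    keep_first: int = 50,
    keep: int = 15,
    cutoff: float = 0.1,
) -> list[Strategy]:
    """Iterative keep-top search over strategy space.

    Returns every surviving strategy across iterations, ranked by
    performance (descending), then group-set size, then lexicographic
    group list.  ``cutoff`` is the child-minus-parent improvement, in
    percentage points, a child needs to survive.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    cache = _ScopedCounts(db, scope)
    names = sorted(cache.names)
    if not names:
        raise ValueError("empty functional-group library")

    def score(groups: frozenset[str]) -> float:
        return _unique_percent(cache, tuple(sorted(groups)), mode)

    singles = [
        Strategy(groups=frozenset({g}), mode=mode, scope=scope,
                 performance=score(frozenset({g})))
        for g in names
    ]
    singles.sort(key=_rank_key)
    frontier = singles[:keep_first]
    survivors: dict[frozenset[str], Strategy] = {
        s.groups: s for s in frontier
    }

    for _ in range(1, iterations):
        children: dict[frozenset[str], Strategy] = {}
        for parent in frontier:
            for g in names:
                if g in parent.groups:
                    continue
                groups = parent.groups | {g}
                if groups in children or groups in survivors:
                    continue
                perf = score(groups)
                # A child whose improvement does not exceed the cutoff is
                # dropped (strict: improving by exactly the cutoff is out).
                if perf - parent.performance <= cutoff:
                    continue
                children[groups] = Strategy(
                    groups=groups, mode=mode, scope=scope, performance=perf
                )
        if not children:
            break
        ranked = sorted(children.values(), key=_rank_key)
        frontier = ranked[:keep]
        for s in frontier:
            survivors[s.groups] = s

    return sorted(survivors.values(), key=_rank_key)
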