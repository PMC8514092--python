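"""Pareto-optimal radical selection in the (delocalization, protection) plane.

A radical is Pareto-optimal if no other record is superior in both
objectives: maximize percent buried volume, minimize maximum fractional
spin. Dominance uses weak inequalities with at least one strict, so
exact duplicates in both coordinates are all retained on the frontier.
Fronts are extracted per radical-center element (C, N, O, S, ...) as
well as globally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .stability_score import StabilityRecord

__all__ = ["ParetoResult", "pareto_front", "pareto_by_element"]


@dataclass(frozen=True)
class ParetoResult:
    """Frontier plus bookkeeping for one stratum."""

    frontier: list[StabilityRecord]
    dominated_count: int
    element_stratum: str = "all"

    @property
    def size(self) -> int:
        return len(self.frontier)


def pareto_front(
    records: Sequence[StabilityRecord], element_stratum: str = "all"
) -> ParetoResult:
    """Non-dominated subset under (max %V_bur, min max_fraction).

    Record ``a`` is dominated iff some ``b`` has
    ``b.percent_buried >= a.percent_buried`` and
    ``b.max_fraction <= a.max_fraction`` with at least one strict
    inequality.

    Implemented as a sorted sweep: sort by buried volume descending,
    keep a running minimum of max_fraction; within a group of equal
    buried volume only the group's minimum-fraction members can be on
    the front, and only if they strictly beat the running minimum from
    strictly higher buried volumes.
    """
    if not records:
        raise ValueError("pareto_front requires a nonempty record list")
    order = sorted(range(len(records)), key=lambda i: (-records[i].percent_buried, records[i].max_fraction))
    on_front = [False] * len(records)
    best_fraction = float("inf")  # min max_fraction among strictly higher V_bur
    i = 0
    while i < len(order):
        j = i
        v = records[order[i]].percent_buried
        while j < len(order) and records[order[j]].percent_buried == v:
            j += 1
        group = order[i:j]
        group_min = min(records[k].max_fraction for k in group)
        if group_min < best_fraction:
            for k in group:
                if records[k].max_fraction == group_min:
                    on_front[k] = True
            best_fraction = group_min
        i = j
    frontier = [r for r, keep in zip(records, on_front) if keep]
    return ParetoResult(
        frontier=frontier,
        dominated_count=len(records) - len(frontier),
        element_stratum=element_stratum,
    )


def pareto_by_element(records: Sequence[StabilityRecord]) -> dict[str, ParetoResult]:
    """Independent Pareto fronts per radical-center element.

    Every element present forms its own stratum (not only C/N/O/S); the
    union of strata is the input. A record dominated globally can still
    be on its own element's frontier.
    """
    strata: dict[str, list[StabilityRecord]] = {}
    for r in records:
        strata.setdefault(r.center_element, []).append(r)
    return {el: pareto_front(rs, element_stratum=el) for el, rs in sorted(strata.items())}
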