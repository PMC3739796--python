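"""Exact unsigned reversal distance and minimal inversion-scenario search.

Given two arrangements of the same chromosome arm, the minimum number of
inversions (reversals of contiguous segment windows) separating them is found
by best-first search with the admissible breakpoint bound
``ceil(breakpoints / 2)`` — each inversion can repair at most two breakpoints.
All minimal step sequences can then be enumerated, and ranked by how many of
their intermediate arrangements occur in an observed (extant) set: among
equally short derivations, the preferred one passes through arrangements that
actually segregate in sampled populations.

Unsigned sorting by reversals is NP-hard in general; this module targets desk
scale (arm length <= 20 segments, enumeration depth <= 6) and refuses larger
inputs rather than approximating.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from math import ceil

from .arms import Reversal, SegmentOrder, adjacency_set, apply_reversal, _LEFT, _RIGHT, _check_comparable
from .errors import CapExceededError

DEFAULT_MAX_LENGTH = 20
DEFAULT_MAX_DEPTH = 6


@dataclass
class Scenario:
    """One minimal inversion series from a source to a target arrangement.

    ``intermediates`` holds the arrangement after each step (the last entry is
    the target).  ``observed_hits`` counts intermediates *before* the target
    that match an observed arrangement; ``matched_names`` gives the matching
    observed name per step (None for hypothetical intermediates and for the
    final, target-producing step).
    """

    steps: list[Reversal]
    intermediates: list[SegmentOrder]
    observed_hits: int = 0
    hypothetical_count: int = 0
    matched_names: list[str | None] = field(default_factory=list)

    def replay(self, source: SegmentOrder) -> SegmentOrder:
        cur = source
        for rev in self.steps:
            cur = apply_reversal(cur, rev)
        return cur

    def windows(self) -> tuple[tuple[int, int], ...]:
        return tuple((r.start, r.end) for r in self.steps)


@dataclass
class ScenarioSet:
    """Result bundle of a scenario enumeration."""

    scenarios: list[Scenario]
    truncated: bool = False
    optimum_unique: bool | None = None  # set by constrained search


def _bp_lower_bound(segments: tuple, target_adj: frozenset) -> int:
    chain = (_LEFT, *segments, _RIGHT)
    bp = sum(1 for p in zip(chain, chain[1:]) if frozenset(p) not in target_adj)
    return ceil(bp / 2)


def _windows(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n - 1) for j in range(i + 2, n + 1)]


def _rev(segments: tuple, i: int, j: int) -> tuple:
    return segments[:i] + tuple(reversed(segments[i:j])) + segments[j:]


def _check_caps(source: SegmentOrder, target: SegmentOrder, max_length: int) -> None:
    _check_comparable(source, target)
    if len(source) > max_length:
        raise CapExceededError(
            f"arrangement length {len(source)} exceeds cap {max_length}; "
            "exact unsigned reversal search is refused at this size"
        )


def reversal_distance(
    source: SegmentOrder, target: SegmentOrder, *, max_length: int = DEFAULT_MAX_LENGTH
) -> int:
    """Exact minimum number of reversals transforming ``source`` into ``target``.

    A* search over arrangement space with the admissible heuristic
    ``ceil(breakpoints/2)``; symmetric in its arguments.
    """
    _check_caps(source, target, max_length)
    start, goal = source.segments, target.segments
    if start == goal:
        return 0
    target_adj = adjacency_set(goal)
    n = len(start)
    windows = _windows(n)
    h0 = _bp_lower_bound(start, target_adj)
    best_g: dict[tuple, int] = {start: 0}
    heap: list[tuple[int, int, int, tuple]] = [(h0, 0, 0, start)]
    counter = 1
    while heap:
        f, g, _, state = heapq.heappop(heap)
        if state == goal:
            return g
        if g > best_g.get(state, g):
            continue
        for i, j in windows:
            child = _rev(state, i, j)
            g2 = g + 1
            if g2 < best_g.get(child, g2 + 1):
                best_g[child] = g2
                h = _bp_lower_bound(child, target_adj)
                heapq.heappush(heap, (g2 + h, g2, counter, child))
                counter += 1
    raise AssertionError("reversal search exhausted without reaching target")


def enumerate_minimal_series(
    source: SegmentOrder,
    target: SegmentOrder,
    limit: int = 1000,
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> ScenarioSet:
    """Enumerate every distinct minimal-length reversal series.

    Depth-first search at exactly the minimal depth, pruned by the breakpoint
    bound; series emerge in lexicographic order of successive window index
    pairs.  ``limit`` truncates the output (flagged in the result).
    """
    _check_caps(source, target, max_length)
    d = reversal_distance(source, target, max_length=max_length)
    if d > max_depth:
        raise CapExceededError(
            f"minimal distance {d} exceeds enumeration depth cap {max_depth}"
        )
    if d == 0:
        return ScenarioSet([Scenario(steps=[], intermediates=[])])
    goal = target.segments
    target_adj = adjacency_set(goal)
    n = len(source)
    windows = _windows(n)
    out: list[Scenario] = []
    truncated = False
    path: list[tuple[int, int]] = []

    def dfs(state: tuple, depth_left: int) -> bool:
        """Return False once the limit is hit (aborts the search)."""
        nonlocal truncated
        if state == goal:
            if depth_left == 0:
                if len(out) >= limit:
                    truncated = True
                    return False
                steps = [Reversal(i, j) for i, j in path]
                inter: list[SegmentOrder] = []
                cur = source
                for rev in steps:
                    cur = apply_reversal(cur, rev)
                    inter.append(cur)
                out.append(Scenario(steps=steps, intermediates=inter))
            # Passing through the target early can never complete minimally.
            return True
        if depth_left == 0 or _bp_lower_bound(state, target_adj) > depth_left:
            return True
        for i, j in windows:
            child = _rev(state, i, j)
            path.append((i, j))
            ok = dfs(child, depth_left - 1)
            path.pop()
            if not ok:
                return False
        return True

    dfs(source.segments, d)
    return ScenarioSet(out, truncated=truncated)


def constrained_scenarios(
    source: SegmentOrder,
    target: SegmentOrder,
    observed: dict[str, SegmentOrder],
    limit: int = 1000,
    *,
    max_length: int = DEFAULT_MAX_LENGTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> ScenarioSet:
    """Minimal scenarios ranked by observed extant intermediates.

    ``observed`` maps arrangement names to orders.  Each scenario's
    intermediates (excluding the target itself) are matched by exact segment
    equality against the observed set; scenarios sort by ``observed_hits``
    descending, ties broken lexicographically by window index pairs.
    ``optimum_unique`` on the result records whether a single scenario attains
    the maximal count — the published derivations assert uniqueness, which is
    verified here rather than assumed.
    """
    for name, order in observed.items():
        _check_comparable(source, order)
    full = enumerate_minimal_series(
        source, target, limit=10**9, max_length=max_length, max_depth=max_depth
    )
    by_segments = {order.segments: name for name, order in observed.items()}
    for sc in full.scenarios:
        matched: list[str | None] = []
        for inter in sc.intermediates[:-1]:  # target never counts as intermediate
            matched.append(by_segments.get(inter.segments))
        matched.append(None)
        sc.matched_names = matched
        sc.observed_hits = sum(1 for m in matched if m is not None)
        sc.hypothetical_count = max(len(sc.steps) - 1, 0) - sc.observed_hits
    ranked = sorted(full.scenarios, key=lambda s: (-s.observed_hits, s.windows()))
    unique = True
    if len(ranked) > 1 and ranked[0].observed_hits == ranked[1].observed_hits:
        unique = False
    truncated = len(ranked) > limit
    return ScenarioSet(ranked[:limit], truncated=truncated, optimum_unique=unique)
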