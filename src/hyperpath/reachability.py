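"""Forward closure on a directed hypergraph.

``find_all`` computes, in time linear in the number of vertices, arcs and
the total coordination, the set B(H, S) of compounds linkable to the source
S by some hyperpath, together with a firing order F of the arcs: each arc
appears in F once its whole tail is covered by S plus the heads of earlier
arcs.  F is simultaneously

* a certificate that every compound in B is reachable,
* a pruning device (arcs outside F belong to no hyperpath from S), and
* a hyperpath membership test (a hypergraph is a hyperpath from S iff the
  closure fires every one of its arcs).
"""

from __future__ import annotations

import logging
from collections import deque
from collections.abc import Iterable
from dataclasses import dataclass

from .network import Hypergraph

log = logging.getLogger(__name__)

__all__ = ["ReachabilityResult", "find_all", "prune", "is_hyperpath"]


@dataclass(frozen=True)
class ReachabilityResult:
    """Output of the closure: firing order F, reachable set B (source
    compounds excluded), and the source it was computed from."""

    ordering: tuple[str, ...]
    reachable: frozenset[str]
    source: frozenset[str]

    @property
    def covered(self) -> frozenset[str]:
        """D = S union B: everything available after the closure."""
        return self.source | self.reachable


def find_all(H: Hypergraph, S: Iterable[str]) -> ReachabilityResult:
    """Fire every arc whose tail becomes fully covered, breadth first.

    The worklist is a FIFO seeded with the source compounds in sorted id
    order; arcs sharing a newly covered compound fire in input arc order.
    Both choices only pin down the reported ordering, not the reachable
    set, and make runs reproducible.
    """
    S = frozenset(S)
    remaining = {a.id: len(a.tail) for a in H.arcs}
    ordering: list[str] = []
    produced: set[str] = set()
    done: set[str] = set()
    queue: deque[str] = deque(sorted(S))

    def fire(arc_id: str) -> None:
        ordering.append(arc_id)
        for j in sorted(H.arc(arc_id).head):
            produced.add(j)
            if j not in done:
                queue.append(j)

    for a in H.arcs:  # degenerate guard: tail-less arcs fire immediately
        if remaining[a.id] == 0:
            fire(a.id)
    while queue:
        i = queue.popleft()
        if i in done:
            continue
        done.add(i)
        for arc_id in H.tail_index.get(i, ()):
            remaining[arc_id] -= 1
            if remaining[arc_id] == 0:
                fire(arc_id)
    return ReachabilityResult(tuple(ordering), frozenset(produced) - S, S)


def prune(H: Hypergraph, S: Iterable[str], verbose: bool = False) -> Hypergraph:
    """Restrict H to the arcs of the closure ordering and the vertices
    S union B; no arc outside any hyperpath from S survives."""
    res = find_all(H, S)
    kept = set(res.ordering)
    if verbose:
        dropped = [a for a in H.arc_ids() if a not in kept]
        if dropped:
            log.info("prune: dropping %d unusable arc(s): %s", len(dropped), dropped)
    sub = H.restrict(res.ordering, keep_vertices=set(S) | res.reachable)
    return sub


def is_hyperpath(candidate: Hypergraph, S: Iterable[str]) -> bool:
    """True iff the closure from S fires every arc of ``candidate``; the
    resulting ordering is then a valid witness."""
    res = find_all(candidate, S)
    return len(res.ordering) == candidate.m
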