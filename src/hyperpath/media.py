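"""Growth-media analysis: supplement candidates and bootstrap compounds.

A *supplement* for a target T is a compound outside the reachable set whose
addition to the source enables pathways otherwise impassable.  ``find_supp``
collects candidates by a backward closure from T over producing arcs and
then subtracts everything already available (source plus reachable set).

A *bootstrap* is a compound that cannot be produced from the source unless
it is itself supplied first: it participates (directly or through a cycle)
in producing its own precursors.  ``find_bootstraps`` removes the reachable
set from every arc, drops arcs whose head empties, and then iteratively
peels head compounds consumed by no remaining arc; the heads that survive
are exactly the self-sustaining unreachable compounds.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Iterable
from dataclasses import dataclass

from .network import Hypergraph
from .reachability import find_all

__all__ = ["SupplementReport", "BootstrapSet", "find_supp", "find_bootstraps"]


@dataclass(frozen=True)
class SupplementReport:
    """Raw candidate set D plus a labelled breakdown.

    ``candidates`` is the algorithm's verbatim output.  Because the target
    itself and bootstrap compounds can land in D, the report also exposes
    ``target_echo`` (candidates that are targets), ``bootstraps``
    (candidates that are bootstrap compounds) and ``plain`` (the rest);
    the three subsets partition ``candidates``.
    """

    candidates: frozenset[str]
    target: frozenset[str]
    source: frozenset[str]
    target_echo: frozenset[str]
    bootstraps: frozenset[str]
    plain: frozenset[str]


@dataclass(frozen=True)
class BootstrapSet:
    """The bootstrap compounds b(H, S); depends on the source only."""

    compounds: frozenset[str]


def find_supp(H: Hypergraph, S: Iterable[str], T: Iterable[str]) -> SupplementReport:
    """Backward closure from T over producing arcs, accumulating tail
    compounds outside S, minus everything the forward closure reaches."""
    S = frozenset(S)
    T = frozenset(T)
    wish: deque[str] = deque(sorted(T))
    D: set[str] = set()
    while wish:
        i = wish.popleft()
        if i in D:
            continue
        D.add(i)
        aux: set[str] = set()
        for rid in H.head_index.get(i, ()):
            aux |= set(H.arc(rid).tail) - (S | D)
        wish.extend(sorted(aux))
    res = find_all(H, S)
    candidates = frozenset(D) - res.covered
    boots = find_bootstraps(H, S).compounds & candidates
    echo = (candidates & T) - boots
    return SupplementReport(
        candidates=candidates,
        target=T,
        source=S,
        target_echo=echo,
        bootstraps=boots,
        plain=candidates - boots - echo,
    )


def find_bootstraps(H: Hypergraph, S: Iterable[str]) -> BootstrapSet:
    """Peeling algorithm on the network reduced by the reachable set.

    Arcs lose every compound of D = S union B(H, S) from both sides and are
    discarded when their head empties.  Then, while some compound appears
    in a reduced head but in no reduced tail, it is removed from all heads
    (dropping arcs whose head empties or that would self-loop).  The union
    of surviving heads is the bootstrap set.  Runs in time linear in the
    vertices, arcs and total coordination.
    """
    S = frozenset(S)
    D = find_all(H, S).covered
    tails: dict[str, set[str]] = {}
    heads: dict[str, set[str]] = {}
    for a in H.arcs:
        y = set(a.head) - D
        if y:
            tails[a.id] = set(a.tail) - D
            heads[a.id] = y
    while True:
        head_union: set[str] = set().union(*heads.values()) if heads else set()
        tail_union: set[str] = set().union(*tails.values()) if tails else set()
        peelable = head_union - tail_union
        if not peelable:
            break
        v = min(peelable)  # one compound per round, smallest id first
        for rid in [r for r, y in heads.items() if v in y]:
            heads[rid].discard(v)
            if not heads[rid] or v in tails[rid]:
                del heads[rid]
                del tails[rid]
    B = set().union(*heads.values()) if heads else set()
    return BootstrapSet(frozenset(B))
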