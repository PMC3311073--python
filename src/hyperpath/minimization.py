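"""Greedy hyperpath minimization and the well-separation diagnostic.

``minimize`` reduces a hypergraph P to a hyperpath linking target T to
source S by removing, one arc at a time, every arc whose removal keeps T
reachable -- except for the mandatory arcs Rf, which are never touched.
With Rf empty the single greedy sweep provably returns a minimal hyperpath
(once an arc survives its removal trial it stays essential, because
reachability only shrinks as arcs are deleted).  With Rf non-empty the
result may be non-minimal: deciding whether a minimal hyperpath containing
Rf exists is NP-complete in general, but ``well_separated`` recognises the
instances where the greedy sweep is exact.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass

from .network import Hypergraph, Hyperpath
from .reachability import find_all, is_hyperpath

log = logging.getLogger(__name__)

__all__ = ["ConstraintSets", "minimize", "is_minimal", "well_separated"]


@dataclass(frozen=True)
class ConstraintSets:
    """A node of the enumeration partition: arcs that must appear
    (mandatory, R_f) and arcs that must not (forbidden, R_n)."""

    mandatory: frozenset[str]
    forbidden: frozenset[str]

    def __post_init__(self):
        if self.mandatory & self.forbidden:
            raise ValueError("mandatory and forbidden arc sets must be disjoint")


def minimize(
    P: Hypergraph,
    Rf: Iterable[str],
    T: Iterable[str],
    S: Iterable[str],
) -> Hyperpath | None:
    """Return a hyperpath within P, containing Rf and linking T to S, or
    ``None`` when P does not link T to S (or a never-firable mandatory arc
    makes the contract unsatisfiable).

    Arcs are tried for removal in the closure-ordering of P (forward),
    followed by any arcs the closure never fires; the order is a
    determinism convention, not semantics -- different orders may return
    different, equally valid, minimal hyperpaths.

    A removal is accepted only if the target stays covered *and* every
    mandatory arc stays firable.  The second condition closes a gap in the
    plain target-coverage test, which can discard the sole producer of a
    mandatory arc's substrate and thereby lose constrained solutions that
    do exist (breaking the completeness of the enumeration that calls this
    routine).
    """
    Rf = frozenset(Rf)
    T = frozenset(T)
    S = frozenset(S)
    missing = Rf - set(P.arc_ids())
    if missing:
        raise ValueError(f"mandatory arcs not in hypergraph: {sorted(missing)}")
    res = find_all(P, S)
    if not T <= res.covered:
        return None
    if not Rf <= set(res.ordering):
        # No hyperpath within P can contain a mandatory arc that the full
        # closure cannot fire, so the constrained problem has no solution.
        return None
    current = set(P.arc_ids())
    order = list(res.ordering) + [a for a in P.arc_ids() if a not in set(res.ordering)]
    for r in order:
        if r in Rf:
            continue
        trial = current - {r}
        trial_res = find_all(P.restrict(trial), S)
        # A removal must keep the target covered and every mandatory arc
        # firable, otherwise the sweep could strand an arc of Rf and break
        # the contract of returning a hyperpath that contains Rf.
        if T <= trial_res.covered and Rf <= set(trial_res.ordering):
            current = trial
    sub = P.restrict(current)
    final = find_all(sub, S)
    if len(final.ordering) != len(current):
        # A mandatory arc can never fire: the greedy sweep kept the target
        # covered but the result is not a hyperpath.  The contract promises
        # a hyperpath, so report failure instead.
        log.warning(
            "minimize: mandatory arcs %s are not firable; no hyperpath returned",
            sorted(current - set(final.ordering)),
        )
        return None
    return Hyperpath(
        frozenset(current),
        final.ordering,
        T,
        minimal=True if not Rf else None,
    )


def is_minimal(P: Hypergraph, T: Iterable[str], S: Iterable[str]) -> bool:
    """Minimality test: P (which must be a hyperpath for S) is minimal iff
    the unconstrained greedy sweep returns P itself."""
    if not is_hyperpath(P, S):
        raise ValueError("is_minimal requires a hyperpath")
    reduced = minimize(P, (), T, S)
    if reduced is None:
        raise ValueError("hyperpath does not link the target to the source")
    return reduced.arcs == set(P.arc_ids())


def well_separated(
    H: Hypergraph, Rf: Iterable[str], Rn: Iterable[str] = ()
) -> bool:
    """Well-separation condition under which the greedy sweep solves the
    minimal constrained hyperpath problem exactly: every unconstrained
    arc's head is either entirely inside Y(Rf) (the products of the
    mandatory arcs) or disjoint from it.

    Holds vacuously when Rf is empty and always when every reaction has a
    single product.
    """
    Rf = frozenset(Rf)
    Rn = frozenset(Rn)
    y_rf: set[str] = set()
    for r in Rf:
        y_rf |= set(H.arc(r).head)
    for a in H.arcs:
        if a.id in Rf or a.id in Rn:
            continue
        head = set(a.head)
        if not (head <= y_rf or not (head & y_rf)):
            return False
    return True
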