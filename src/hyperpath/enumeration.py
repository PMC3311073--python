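"""Complete enumeration of minimal hyperpaths.

``find_path`` enumerates every minimal hyperpath linking a target set T to
a source S (optionally constrained to contain a mandatory arc set Rf) by
iteratively partitioning the solution space.  Each partition cell is
described by a mandatory set R_f and a forbidden set R_n (realised
implicitly by deleting the forbidden arcs from the working hypergraph); a
cell with a solution P spawns one child cell per non-mandatory arc r of P,
scanned in reverse witness order: the child forbids r and additionally
mandates every arc of P preceding r that was still unconstrained.  The
partition guarantees that all minimal hyperpaths are visited and that no
two cells can yield the same hyperpath.

Because the greedy constrained minimization can return non-minimal
hyperpaths (the exact constrained problem is NP-complete), every output is
audited with the exact minimality test; non-minimal outputs are dropped
only when their unconstrained reduction is already present, otherwise kept
and flagged.

``brute_force_minimal`` is an independent exact oracle: it scans every arc
subset and keeps the inclusion-minimal hyperpaths producing the target.

``enumerate_pathways`` is the user-facing pipeline: optional bootstrap
augmentation of the media, restriction to the heterologous subnetwork,
pruning, enumeration, audit, and an optional stoichiometric-balance filter.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from dataclasses import dataclass, field

from .errors import CapExceededError
from .media import find_bootstraps
from .minimization import minimize
from .network import Hypergraph, Hyperpath, heterologous_subnetwork
from .reachability import find_all, prune

__all__ = [
    "EnumerationNode",
    "EnumerationResult",
    "find_path",
    "brute_force_minimal",
    "brute_force_minimal_by_target",
    "enumerate_pathways",
]

MAX_PATHWAYS_DEFAULT = 100_000


@dataclass(frozen=True)
class EnumerationNode:
    """One cell of the solution-space partition (kept for trace export)."""

    mandatory: frozenset[str]
    removed: frozenset[str]
    solution: Hyperpath | None = None


@dataclass
class EnumerationResult:
    """Deduplicated, audited enumeration output.

    ``pathways`` never contains two entries with the same arc set; every
    entry passes the hyperpath test by construction.  ``node_count`` is the
    size of the partition tree actually explored.
    """

    pathways: list[Hyperpath]
    node_count: int
    truncated: bool = False
    dropped_nonminimal: list[Hyperpath] = field(default_factory=list)
    source: frozenset[str] = frozenset()
    bootstraps_added: frozenset[str] = frozenset()

    @property
    def minimal_count(self) -> int:
        return sum(1 for p in self.pathways if p.minimal)

    def minimal_arc_sets(self) -> set[frozenset[str]]:
        return {p.arcs for p in self.pathways if p.minimal}

    def arc_sets(self) -> set[frozenset[str]]:
        return {p.arcs for p in self.pathways}

    def report(self) -> dict:
        """JSON-ready machine report."""
        return {
            "pathways": [
                {
                    "arcs": sorted(p.arcs),
                    "ordering": list(p.ordering),
                    "minimal": p.minimal,
                    **({"balanced": p.balanced} if p.balanced is not None else {}),
                }
                for p in self.pathways
            ],
            "truncated": self.truncated,
            "nodes": self.node_count,
        }


def _audit(
    raw: list[Hyperpath],
    H: Hypergraph,
    T: frozenset[str],
    S: frozenset[str],
) -> tuple[list[Hyperpath], list[Hyperpath]]:
    """Deduplicate, flag minimality, and drop non-minimal outputs whose
    unconstrained reduction is already present."""
    unique: dict[frozenset[str], Hyperpath] = {}
    for p in raw:
        unique.setdefault(p.arcs, p)
    for p in unique.values():
        if p.minimal is None:
            reduced = minimize(H.restrict(p.arcs), (), T, S)
            p.minimal = reduced is not None and reduced.arcs == p.arcs
    minimal_sets = {a for a, p in unique.items() if p.minimal}
    kept: list[Hyperpath] = []
    dropped: list[Hyperpath] = []
    for p in unique.values():
        if p.minimal:
            kept.append(p)
            continue
        reduced = minimize(H.restrict(p.arcs), (), T, S)
        if reduced is not None and reduced.arcs in minimal_sets:
            dropped.append(p)
        else:
            kept.append(p)
    return kept, dropped


def find_path(
    H: Hypergraph,
    Rf: Iterable[str],
    T: Iterable[str],
    S: Iterable[str],
    max_pathways: int = MAX_PATHWAYS_DEFAULT,
) -> EnumerationResult:
    """Enumerate all minimal hyperpaths from S to T containing Rf.

    The result may additionally contain non-minimal constrained hyperpaths
    (flagged ``minimal=False`` after the audit); the completeness guarantee
    covers the minimal ones.  Traversal is depth-first over an explicit
    work stack, matching the recursive call order, so results are
    deterministic given the input arc order.
    """
    Rf0 = frozenset(Rf)
    T = frozenset(T)
    S = frozenset(S)
    missing = Rf0 - set(H.arc_ids())
    if missing:
        raise ValueError(f"mandatory arcs not in hypergraph: {sorted(missing)}")

    raw: list[Hyperpath] = []
    nodes = 0
    truncated = False
    stack: list[tuple[frozenset[str], frozenset[str]]] = [
        (frozenset(H.arc_ids()), Rf0)
    ]
    while stack:
        arcs, rf = stack.pop()
        nodes += 1
        sub = H.restrict(arcs, keep_vertices=S)
        reach = find_all(sub, S)
        candidate = sub.restrict(set(reach.ordering) | rf, keep_vertices=S)
        P = minimize(candidate, rf, T, S)
        if P is None:
            continue
        raw.append(P)
        if len(raw) >= max_pathways:
            truncated = True
            break
        children: list[tuple[frozenset[str], frozenset[str]]] = []
        acc = set(rf)
        ordering = P.ordering  # witness order of the found hyperpath
        for k in range(len(ordering) - 1, -1, -1):
            r = ordering[k]
            if r in rf:
                continue
            children.append((arcs - {r}, frozenset(acc)))
            acc.add(r)
        # LIFO stack: push in reverse so the first-generated child (the one
        # forbidding the last arc of the witness) is explored first.
        stack.extend(reversed(children))

    kept, dropped = _audit(raw, H, T, S)
    return EnumerationResult(
        pathways=kept,
        node_count=nodes,
        truncated=truncated,
        dropped_nonminimal=dropped,
        source=S,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle


def _bit_setup(H: Hypergraph, S: frozenset[str]):
    comp_idx = {c: i for i, c in enumerate(sorted(H.vertices | S))}
    tails, heads = [], []
    for a in H.arcs:
        t = h = 0
        for c in a.tail:
            t |= 1 << comp_idx[c]
        for c in a.head:
            h |= 1 << comp_idx[c]
        tails.append(t)
        heads.append(h)
    src = 0
    for c in S:
        src |= 1 << comp_idx[c]
    return comp_idx, tails, heads, src


def _subset_scan(H: Hypergraph, S: frozenset[str], cap: int):
    """Yield (mask, is_hyperpath, covered_bitmask) for every arc subset."""
    m = H.m
    if m > cap:
        raise CapExceededError("brute-force subset scan", m, cap)
    comp_idx, tails, heads, src = _bit_setup(H, S)
    arc_bits = list(range(m))
    out = []
    for mask in range(1 << m):
        covered = src
        pending = [b for b in arc_bits if mask >> b & 1]
        progress = True
        while pending and progress:
            progress = False
            rest = []
            for b in pending:
                if tails[b] & ~covered == 0:
                    covered |= heads[b]
                    progress = True
                else:
                    rest.append(b)
            pending = rest
        out.append((mask, not pending, covered))
    return comp_idx, out


def _minimal_masks(scan, target_bits: int) -> list[int]:
    qualifying = [
        mask for mask, ok, covered in scan if ok and target_bits & ~covered == 0
    ]
    qualifying.sort(key=lambda m: bin(m).count("1"))
    minimal: list[int] = []
    for q in qualifying:
        if not any(k & q == k for k in minimal):
            minimal.append(q)
    return minimal


def brute_force_minimal(
    H: Hypergraph,
    T: Iterable[str],
    S: Iterable[str],
    cap: int = 20,
) -> list[Hyperpath]:
    """Exact-by-construction enumeration of minimal hyperpaths: scan every
    arc subset, keep the hyperpaths producing T with no qualifying proper
    subset.  Refuses to run above ``cap`` arcs."""
    return brute_force_minimal_by_target(H, [frozenset(T)], S, cap)[0]


def brute_force_minimal_by_target(
    H: Hypergraph,
    targets: Iterable[frozenset[str]],
    S: Iterable[str],
    cap: int = 20,
) -> list[list[Hyperpath]]:
    """Same oracle, sharing the subset scan across several target sets."""
    S = frozenset(S)
    comp_idx, scan = _subset_scan(H, S, cap)
    ids = H.arc_ids()
    results: list[list[Hyperpath]] = []
    for T in targets:
        T = frozenset(T)
        target_bits = 0
        for t in T:
            if t in comp_idx:
                target_bits |= 1 << comp_idx[t]
            elif t not in S:
                target_bits = -1  # unknown compound: unreachable
                break
        if target_bits == -1:
            results.append([])
            continue
        paths = []
        for mask in _minimal_masks(scan, target_bits):
            arc_set = frozenset(ids[b] for b in range(H.m) if mask >> b & 1)
            ordering = find_all(H.restrict(arc_set, keep_vertices=S), S).ordering
            paths.append(Hyperpath(arc_set, ordering, T, minimal=True))
        results.append(paths)
    return results


# ---------------------------------------------------------------------------
# high-level pipeline


def enumerate_pathways(
    H: Hypergraph,
    S: Iterable[str],
    T: Iterable[str],
    with_bootstraps: bool = False,
    balance_filter: bool = False,
    max_pathways: int = MAX_PATHWAYS_DEFAULT,
) -> EnumerationResult:
    """Enumerate minimal heterologous pathways from a chassis source S to a
    target set T.

    Pipeline: optionally add the bootstrap compounds to the media, restrict
    to the heterologous subnetwork (arcs touching a compound outside the
    source), prune to the reachable part, enumerate with ``find_path``,
    audit, and optionally drop pathways that admit no balanced flux.
    """
    S0 = frozenset(S)
    T = frozenset(T)
    boots: frozenset[str] = frozenset()
    if with_bootstraps:
        boots = find_bootstraps(H, S0).compounds
    S1 = S0 | boots
    if T <= S1:
        warnings.warn(
            "target set is contained in the (augmented) source; returning the"
            " empty pathway",
            stacklevel=2,
        )
        empty = Hyperpath(frozenset(), (), T, minimal=True)
        return EnumerationResult([empty], 0, source=S1, bootstraps_added=boots)
    RT = heterologous_subnetwork(H, S1)
    Hp = prune(RT, S1)
    res = find_path(Hp, (), T, S1, max_pathways=max_pathways)
    res.source = S1
    res.bootstraps_added = boots
    if balance_filter:
        from .steady_state import pathway_flux_feasible

        kept = []
        for p in res.pathways:
            verdict = pathway_flux_feasible(p.arcs, Hp, S1, T)
            p.balanced = verdict.feasible
            if verdict.feasible:
                kept.append(p)
        res.pathways = kept
    return res
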