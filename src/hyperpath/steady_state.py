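"""Stoichiometric verification of enumerated pathways.

At steady state every metabolite produced from the source must be consumed
except for targets and co-products.  Closing the system with exchange
columns -- substrate-free *input* reactions feeding the source compounds
and product-free *output* reactions draining every product -- turns the
balance condition into the pointed-cone problem

    S v = 0,   v >= 0,

whose support-minimal solutions are the elementary flux modes (identical
to the extreme pathways here, because splitting has made every reaction
irreversible).  This module provides

* :func:`augment_exchanges` -- append the exchange columns,
* :func:`enumerate_efms` -- exact small-scale elementary-mode enumeration
  (double description tableau over exact rationals),
* :func:`pathway_flux_feasible` -- LP balance check for one pathway,
* :func:`efm_pathways` / :func:`cross_check` -- the topological-vs-steady
  state comparison.

It is a verification oracle, deliberately capped in size, not a
competitive elementary-mode tool.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from fractions import Fraction

from .errors import CapExceededError
from .network import (
    Hypergraph,
    StoichiometricSystem,
    build_stoichiometric_matrix,
    heterologous_subnetwork,
)
from .minimization import is_minimal
from .reachability import is_hyperpath

__all__ = [
    "ElementaryMode",
    "BalanceVerdict",
    "CrossCheckReport",
    "augment_exchanges",
    "enumerate_efms",
    "pathway_flux_feasible",
    "efm_pathways",
    "cross_check",
]

EFM_CAP_DEFAULT = 24
ACTIVATION_DEFAULT = 1e-6
TOL_DEFAULT = 1e-9


@dataclass(frozen=True)
class ElementaryMode:
    """A support-minimal non-negative flux vector with S v = 0, normalized
    so the smallest positive flux equals 1 (exact rationals)."""

    support: frozenset[str]
    flux: dict[str, Fraction]


@dataclass(frozen=True)
class BalanceVerdict:
    feasible: bool
    witness: dict[str, float] | None = None


def input_column_label(compound: str) -> str:
    return f"EX_in_{compound}"


def output_column_label(compound: str) -> str:
    return f"EX_out_{compound}"


def augment_exchanges(
    sys: StoichiometricSystem,
    inputs: Iterable[str],
    outputs: Iterable[str],
) -> StoichiometricSystem:
    """Append one +1 input column per compound in ``inputs`` and one -1
    output column per compound in ``outputs``; original columns untouched.

    For the heterologous setting the inputs are the source compounds that
    appear as substrates of RT and the outputs are all products of RT.
    """
    inputs = sorted(set(inputs))
    outputs = sorted(set(outputs))
    unknown = (set(inputs) | set(outputs)) - set(sys.row_labels)
    if unknown:
        raise ValueError(f"unknown compounds: {sorted(unknown)}")
    row_pos = {c: i for i, c in enumerate(sys.row_labels)}
    n_new = len(inputs) + len(outputs)
    matrix = [list(row) + [Fraction(0)] * n_new for row in sys.matrix]
    labels = list(sys.col_labels)
    kinds = list(sys.col_kinds)
    j = len(labels)
    for c in inputs:
        matrix[row_pos[c]][j] = Fraction(1)
        labels.append(input_column_label(c))
        kinds.append("input")
        j += 1
    for c in outputs:
        matrix[row_pos[c]][j] = Fraction(-1)
        labels.append(output_column_label(c))
        kinds.append("output")
        j += 1
    return StoichiometricSystem(matrix, sys.row_labels, tuple(labels), tuple(kinds))


# ---------------------------------------------------------------------------
# elementary modes


def _normalize(ray: list[Fraction]) -> tuple[Fraction, ...]:
    positives = [v for v in ray if v > 0]
    scale = min(positives)
    return tuple(v / scale for v in ray)


def _support(ray) -> frozenset[int]:
    return frozenset(j for j, v in enumerate(ray) if v != 0)


def _minimal_support_filter(rays: list[tuple[Fraction, ...]]):
    """Keep only rays whose support contains no other ray's support as a
    proper subset; exact duplicates collapse to one."""
    with_supp = [(r, _support(r)) for r in rays]
    with_supp.sort(key=lambda rs: (len(rs[1]), rs[0]))
    kept: list[tuple[tuple[Fraction, ...], frozenset[int]]] = []
    for r, s in with_supp:
        drop = False
        for rk, sk in kept:
            if sk < s:
                drop = True
                break
            if sk == s and rk == r:
                drop = True
                break
        if not drop:
            kept.append((r, s))
    return [r for r, _ in kept]


def enumerate_efms(
    sys: StoichiometricSystem, cap: int = EFM_CAP_DEFAULT
) -> list[ElementaryMode]:
    """Exact elementary-mode enumeration of {v >= 0 : S v = 0}.

    Double description tableau: start from the unit rays of the positive
    orthant and impose one balance row at a time, keeping the zero rays and
    all positive/negative combinations, with a support-minimality filter
    after every row.  All arithmetic is in exact rationals, so rank and
    tolerance problems cannot occur.  Refuses systems with more than
    ``cap`` internal columns.
    """
    n_internal = sum(1 for k in sys.col_kinds if k == "internal")
    if n_internal > cap:
        raise CapExceededError("elementary-mode enumeration", n_internal, cap)
    n = len(sys.col_labels)
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(1) if j == i else Fraction(0) for j in range(n))
        for i in range(n)
    ]
    for row in sys.matrix:
        if all(v == 0 for v in row):
            continue
        dotted = [(r, sum(c * v for c, v in zip(row, r))) for r in rays]
        zeros = [r for r, d in dotted if d == 0]
        pos = [(r, d) for r, d in dotted if d > 0]
        neg = [(r, d) for r, d in dotted if d < 0]
        combos = [
            _normalize([dp * vn - dn * vp for vp, vn in zip(rp, rn)])
            for rp, dp in pos
            for rn, dn in neg
        ]
        rays = _minimal_support_filter(zeros + combos)
    labels = sys.col_labels
    modes = []
    for r in rays:
        support = frozenset(labels[j] for j, v in enumerate(r) if v != 0)
        flux = {labels[j]: v for j, v in enumerate(r) if v != 0}
        modes.append(ElementaryMode(support, flux))
    modes.sort(key=lambda m: sorted(m.support))
    return modes


def efm_pathways(
    modes: Iterable[ElementaryMode],
    sys: StoichiometricSystem,
    heterologous: Iterable[str],
) -> set[frozenset[str]]:
    """Strip exchange columns from each mode's support and keep the
    supports that involve at least one heterologous reaction."""
    internal = set(sys.internal_labels())
    heterologous = set(heterologous)
    out: set[frozenset[str]] = set()
    for m in modes:
        support = frozenset(m.support & internal)
        if support & heterologous:
            out.add(support)
    return out


# ---------------------------------------------------------------------------
# LP balance check


def _pathway_system(P, H, S, T):
    """Closed system for one pathway: its columns plus input columns for
    source substrates and output columns for the target and heterologous
    co-products (products outside the source).

    Source compounds get no output column: that realises the sign pattern
    in which source rows must not be net-produced, so a pathway that
    overproduces an endogenous metabolite it cannot itself consume is
    reported as inconsistent.
    """
    sub = H.restrict(P, keep_vertices=set())
    sys = build_stoichiometric_matrix(sub)
    tails: set[str] = set()
    heads: set[str] = set()
    for a in sub.arcs:
        tails |= set(a.tail)
        heads |= set(a.head)
    aug = augment_exchanges(
        sys, sorted(set(S) & tails), sorted(heads - set(S))
    )
    return aug, sub, heads


def pathway_flux_feasible(
    P: Iterable[str],
    H: Hypergraph,
    S: Iterable[str],
    T: Iterable[str],
    activation: float = ACTIVATION_DEFAULT,
    tol: float = TOL_DEFAULT,
    method: str = "exchange",
) -> BalanceVerdict:
    """Decide by linear programming whether the pathway P admits a
    stoichiometrically balanced flux.

    ``exchange`` (default): close the system with exchange columns and ask
    for v >= 0 with S v = 0, every pathway reaction at flux >= activation,
    and net production >= activation for each target outside the source (a
    pathway unable to net-produce its target is inconsistent).

    ``inequality``: the sign-pattern form without exchange columns --
    source rows <= 0, target rows >= 0, every other row exactly 0.  This is
    stricter: intermediate co-products must be consumed exactly.
    """
    from scipy.optimize import linprog

    P = frozenset(P)
    S = frozenset(S)
    T = frozenset(T)
    missing = P - set(H.arc_ids())
    if missing:
        raise ValueError(f"pathway arcs not in hypergraph: {sorted(missing)}")
    if not P:
        return BalanceVerdict(feasible=T <= S, witness={} if T <= S else None)

    if method == "exchange":
        sys, sub, heads = _pathway_system(P, H, S, T)
        if not (T - S) <= heads:
            return BalanceVerdict(False)
        A = sys.to_float()
        bounds = []
        for label, kind in zip(sys.col_labels, sys.col_kinds):
            if kind == "internal":
                bounds.append((activation, None))
            elif kind == "output" and label in {
                output_column_label(t) for t in T - S
            }:
                bounds.append((activation, None))
            else:
                bounds.append((0, None))
        res = linprog(
            c=[0.0] * A.shape[1],
            A_eq=A,
            b_eq=[0.0] * A.shape[0],
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:
            return BalanceVerdict(False)
        witness = {
            label: float(v) for label, v in zip(sys.col_labels, res.x) if v > tol
        }
        return BalanceVerdict(True, witness)

    if method == "inequality":
        sub = H.restrict(P, keep_vertices=set())
        sys = build_stoichiometric_matrix(sub)
        A = sys.to_float()
        rows_ub, b_ub, rows_eq, b_eq = [], [], [], []
        for i, c in enumerate(sys.row_labels):
            if c in S:
                rows_ub.append(A[i])  # S row <= 0
                b_ub.append(0.0)
            elif c in T:
                rows_ub.append(-A[i])  # T row >= 0
                b_ub.append(0.0)
            else:
                rows_eq.append(A[i])
                b_eq.append(0.0)
        res = linprog(
            c=[0.0] * A.shape[1],
            A_ub=rows_ub or None,
            b_ub=b_ub or None,
            A_eq=rows_eq or None,
            b_eq=b_eq or None,
            bounds=[(activation, None)] * A.shape[1],
            method="highs",
        )
        if res.status != 0:
            return BalanceVerdict(False)
        witness = {
            label: float(v) for label, v in zip(sys.col_labels, res.x) if v > tol
        }
        return BalanceVerdict(True, witness)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cross check


@dataclass(frozen=True)
class CrossCheckReport:
    """Comparison of the two enumeration routes for one target set."""

    topological: frozenset[frozenset[str]]
    steady_state: frozenset[frozenset[str]]

    @property
    def only_topological(self) -> frozenset[frozenset[str]]:
        return self.topological - self.steady_state

    @property
    def only_steady_state(self) -> frozenset[frozenset[str]]:
        return self.steady_state - self.topological

    @property
    def agree(self) -> bool:
        return self.topological == self.steady_state

    def summary(self) -> dict:
        return {
            "topological": len(self.topological),
            "steady_state": len(self.steady_state),
            "only_topological": [sorted(p) for p in sorted(
                self.only_topological, key=sorted)],
            "only_steady_state": [sorted(p) for p in sorted(
                self.only_steady_state, key=sorted)],
            "agree": self.agree,
        }

    @classmethod
    def compare(cls, topological, steady_state) -> "CrossCheckReport":
        return cls(
            frozenset(frozenset(p) for p in topological),
            frozenset(frozenset(p) for p in steady_state),
        )


def steady_state_pathways(
    H: Hypergraph,
    S: Iterable[str],
    T: Iterable[str],
    efm_cap: int = EFM_CAP_DEFAULT,
    tol: float = TOL_DEFAULT,
) -> set[frozenset[str]]:
    """Minimal pathways to T derived through elementary modes.

    Build the closed heterologous system (inputs: source substrates of RT,
    outputs: target and heterologous co-products, i.e. products of RT
    outside the source), enumerate its elementary modes, keep the modes
    that net-produce every target, strip the exchange columns, and keep
    the supports that are themselves minimal hyperpaths (modes whose
    support needs a compound before producing it are cyclic solutions, not
    pathways).
    """
    S = frozenset(S)
    T = frozenset(T)
    RT = heterologous_subnetwork(H, S)
    sys = build_stoichiometric_matrix(RT)
    tails: set[str] = set()
    heads: set[str] = set()
    for a in RT.arcs:
        tails |= set(a.tail)
        heads |= set(a.head)
    aug = augment_exchanges(sys, sorted(S & tails), sorted(heads - S))
    modes = enumerate_efms(aug, cap=efm_cap)
    wanted = {output_column_label(t) for t in T - S}
    if (T - S) - heads:
        return set()
    producing = [m for m in modes if all(
        m.flux.get(w, Fraction(0)) > 0 for w in wanted)]
    supports = efm_pathways(producing, aug, RT.arc_ids())
    out: set[frozenset[str]] = set()
    for Q in supports:
        sub = RT.restrict(Q, keep_vertices=S)
        if is_hyperpath(sub, S) and is_minimal(sub, T, S):
            out.add(Q)
    return out


def cross_check(
    H: Hypergraph,
    S: Iterable[str],
    T: Iterable[str],
    efm_cap: int = EFM_CAP_DEFAULT,
    max_pathways: int = 100_000,
) -> CrossCheckReport:
    """Compare balance-filtered topological enumeration against the
    elementary-mode route on the same source set; the symmetric difference
    is expected to be empty."""
    from .enumeration import enumerate_pathways

    S = frozenset(S)
    T = frozenset(T)
    topo = enumerate_pathways(
        H, S, T, balance_filter=True, max_pathways=max_pathways
    )
    topo_sets = {p.arcs for p in topo.pathways if p.minimal}
    steady = steady_state_pathways(H, S, T, efm_cap=efm_cap)
    return CrossCheckReport.compare(topo_sets, steady)
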