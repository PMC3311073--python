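"""Deterministic test-network generators.

Contents:

* two documented reconstructions of small published example networks (a
  12-compound toy network with bootstrap and supplement structure, and the
  liquiritigenin biosynthesis network with four minimal routes),
* the 3-SAT reduction that makes the minimal *constrained* hyperpath
  problem NP-complete (counting minimal constrained hyperpaths counts
  satisfying assignments),
* a seeded random hypergraph generator,
* layered parallel-branch networks with a closed-form pathway count.

The two reconstructions convey topology that the original figures present
graphically; the reaction tables below are normative for this package and
reproduce every assertion used in the tests (reachable set, bootstraps,
supplements, pathway counts).
"""

from __future__ import annotations

import itertools
import math
import random
from collections.abc import Sequence
from dataclasses import dataclass

from .network import Hypergraph, arc

__all__ = [
    "SatInstance",
    "RandomNetworkSpec",
    "make_sat_hypergraph",
    "count_satisfying_assignments",
    "random_sat_instance",
    "make_toy_fixture",
    "make_liquiritigenin_fixture",
    "random_hypergraph",
    "make_layered",
    "FIXTURES",
]


# ---------------------------------------------------------------------------
# toy network with bootstraps and supplements (12 compounds, 9 reactions)


def make_toy_fixture() -> tuple[Hypergraph, frozenset[str]]:
    """Sources v1, v4.  Reachable: v5, v7, v8, v9, v12.  Bootstraps: v2, v3
    (each permits its own production through R5/R6).  Supplements for v8
    include v10, v11.  Exactly two minimal pathways reach v8: {R3,R4} and
    {R4,R7}."""
    arcs = [
        arc("R3", ["v4"], ["v7"]),
        arc("R7", ["v1"], ["v7"]),
        arc("R4", ["v1", "v7"], ["v8"]),
        arc("R8", ["v1"], ["v5"]),
        arc("R9", ["v5"], ["v9", "v12"]),
        arc("R5", ["v1", "v2"], ["v3"]),
        arc("R6", ["v3"], ["v2", "v6"]),
        arc("R10", ["v10", "v11"], ["v2"]),
        arc("R11", ["v6"], ["v8"]),
    ]
    H = Hypergraph(arcs, vertices=[f"v{i}" for i in range(1, 13)])
    return H, frozenset({"v1", "v4"})


# ---------------------------------------------------------------------------
# liquiritigenin biosynthesis (4 minimal routes from chassis metabolites)


def make_liquiritigenin_fixture() -> tuple[Hypergraph, frozenset[str], str]:
    """Two alternative entry reactions produce 4-coumarate (v16), a shared
    activation reaction yields p-coumaroyl-CoA (v14), and two alternative
    finishing chains reach liquiritigenin (v1): 2 x 2 = 4 minimal
    pathways, among them {R1,R2,R4,R7} and {R1,R2,R5,R9}."""
    arcs = [
        arc("R1", ["v10"], ["v16"]),          # from L-tyrosine
        arc("R3", ["v12"], ["v16"]),          # from 4-hydroxybenzoate
        arc("R2", ["v16", "v2", "v7"], ["v14"]),   # CoA activation (ATP, CoA)
        arc("R4", ["v14", "v11"], ["v17"]),   # chalcone route (malonyl-CoA)
        arc("R7", ["v17"], ["v1"]),
        arc("R5", ["v14", "v3"], ["v20"]),    # aldehyde route (NADH)
        arc("R9", ["v20", "v11"], ["v1"]),
    ]
    H = Hypergraph(arcs)
    source = frozenset({"v2", "v3", "v7", "v10", "v11", "v12"})
    return H, source, "v1"


# ---------------------------------------------------------------------------
# 3-SAT reduction


@dataclass(frozen=True)
class SatInstance:
    """A 3-SAT instance: ``clauses`` is a sequence of 3-tuples of literals
    ``(variable_index, polarity)``; repeated literals are permitted."""

    n_vars: int
    clauses: tuple[tuple[tuple[int, bool], ...], ...]

    def __post_init__(self):
        if not self.clauses:
            raise ValueError("clause list must be non-empty")
        for cl in self.clauses:
            if len(cl) != 3:
                raise ValueError("every clause must have exactly 3 literals")
            for v, _ in cl:
                if not 0 <= v < self.n_vars:
                    raise ValueError(f"literal variable {v} out of range")

    def used_variables(self) -> tuple[int, ...]:
        return tuple(sorted({v for cl in self.clauses for v, _ in cl}))


def _clause_satisfying_assignments(clause) -> list[dict[int, bool]]:
    variables = sorted({v for v, _ in clause})
    out = []
    for values in itertools.product((False, True), repeat=len(variables)):
        assignment = dict(zip(variables, values))
        if any(assignment[v] == pol for v, pol in clause):
            out.append(assignment)
    return out


def count_satisfying_assignments(inst: SatInstance) -> int:
    """Exhaustive scan over the variables that appear in clauses."""
    variables = inst.used_variables()
    count = 0
    for values in itertools.product((False, True), repeat=len(variables)):
        assignment = dict(zip(variables, values))
        if all(
            any(assignment[v] == pol for v, pol in cl) for cl in inst.clauses
        ):
            count += 1
    return count


def _vertex(i: int, value: bool) -> str:
    return f"x{i}_{'T' if value else 'F'}"


def make_sat_hypergraph(
    inst: SatInstance,
) -> tuple[Hypergraph, frozenset[str], str, frozenset[str]]:
    """Reduction of 3-SAT to the minimal constrained hyperpath problem.

    Per used variable i: a mandatory arc ``eps_i`` producing both truth
    vertices x_i_T, x_i_F.  Per clause j and each distinct satisfying
    assignment of its variables: an arc ``mu_j_k`` producing the matching
    truth vertices plus the clause vertex nu_j.  A final collector arc
    consumes every clause vertex and every truth vertex and produces the
    target.  One shared source compound feeds every eps/mu tail.  Minimal
    hyperpaths containing all eps arcs correspond one-to-one to satisfying
    assignments of the variables that appear in clauses.
    """
    src = "src"
    used = inst.used_variables()
    arcs = []
    mandatory = []
    for i in used:
        a = arc(f"eps_{i}", [src], [_vertex(i, True), _vertex(i, False)])
        arcs.append(a)
        mandatory.append(a.id)
    for j, clause in enumerate(inst.clauses):
        for k, assignment in enumerate(_clause_satisfying_assignments(clause)):
            head = {_vertex(v, val) for v, val in assignment.items()}
            head.add(f"nu_{j}")
            arcs.append(arc(f"mu_{j}_{k}", [src], sorted(head)))
    collector_tail = [f"nu_{j}" for j in range(len(inst.clauses))]
    collector_tail += [_vertex(i, val) for i in used for val in (True, False)]
    arcs.append(arc("R_target", sorted(collector_tail), ["target"]))
    return Hypergraph(arcs), frozenset({src}), "target", frozenset(mandatory)


def random_sat_instance(
    n_vars: int, n_clauses: int, seed: int
) -> SatInstance:
    rng = random.Random(seed)
    clauses = tuple(
        tuple(
            (rng.randrange(n_vars), rng.random() < 0.5) for _ in range(3)
        )
        for _ in range(n_clauses)
    )
    return SatInstance(n_vars, clauses)


# ---------------------------------------------------------------------------
# random hypergraphs


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of the seeded generator.  Defaults mirror small sparse
    metabolic motifs: reactions with 1-3 substrates and 1-2 products over
    a pool of compounds, 30% of which form the source set."""

    compounds: int = 10
    reactions: int = 12
    tail_size: tuple[int, int] = (1, 3)
    head_size: tuple[int, int] = (1, 2)
    source_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.compounds <= 0 or self.reactions < 0:
            raise ValueError("compound and reaction counts must be positive")
        if not (0 < self.source_fraction < 1):
            raise ValueError("source_fraction must lie in (0, 1)")
        for lo, hi in (self.tail_size, self.head_size):
            if lo < 1 or hi < lo:
                raise ValueError("size ranges must satisfy 1 <= lo <= hi")
        if self.tail_size[1] + self.head_size[1] > self.compounds:
            raise ValueError("tail+head sizes cannot exceed the compound pool")


def random_hypergraph(
    spec: RandomNetworkSpec,
) -> tuple[Hypergraph, frozenset[str]]:
    """Seeded, reproducible network; tails and heads are disjoint samples;
    the source is the first ceil(fraction * compounds) compounds in sorted
    order."""
    rng = random.Random(spec.seed)
    width = len(str(spec.compounds - 1))
    names = [f"c{str(i).zfill(width)}" for i in range(spec.compounds)]
    arcs = []
    for r in range(spec.reactions):
        t_size = rng.randint(*spec.tail_size)
        h_size = rng.randint(*spec.head_size)
        tail = rng.sample(names, t_size)
        head = rng.sample([c for c in names if c not in tail], h_size)
        arcs.append(arc(f"R{str(r).zfill(2)}", sorted(tail), sorted(head)))
    H = Hypergraph(arcs, vertices=names)
    n_source = math.ceil(spec.compounds * spec.source_fraction)
    source = frozenset(sorted(names)[:n_source])
    return H, source


# ---------------------------------------------------------------------------
# layered networks with closed-form counts


def make_layered(
    branches: Sequence[int],
) -> tuple[Hypergraph, frozenset[str], str]:
    """A chain of intermediates m0 -> m1 -> ... -> mL where layer l offers
    ``branches[l]`` parallel single-reaction routes; the number of minimal
    pathways to the final compound is the product of the branch counts."""
    if not branches or any(b < 1 for b in branches):
        raise ValueError("every layer needs at least one branch")
    arcs = []
    for layer, width in enumerate(branches):
        for b in range(width):
            arcs.append(arc(f"L{layer}B{b}", [f"m{layer}"], [f"m{layer + 1}"]))
    H = Hypergraph(arcs)
    return H, frozenset({"m0"}), f"m{len(branches)}"


FIXTURES = {
    "toy": lambda: make_toy_fixture(),
    "liquiritigenin": lambda: make_liquiritigenin_fixture()[:2],
}
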