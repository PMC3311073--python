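"""Exchange augmentation, elementary modes, LP balance, cross-checking."""

import itertools
from fractions import Fraction

import pytest

from hyperpath import (
    CrossCheckReport,
    Hypergraph,
    arc,
    augment_exchanges,
    build_stoichiometric_matrix,
    cross_check,
    efm_pathways,
    enumerate_efms,
    find_all,
    is_hyperpath,
    pathway_flux_feasible,
)
from hyperpath.errors import CapExceededError
from hyperpath.steady_state import (
    input_column_label,
    output_column_label,
    steady_state_pathways,
)


def closed_system(H, S):
    """Heterologous closure: inputs for source substrates, outputs for
    products outside the source (mirrors the library pipeline)."""
    sys = build_stoichiometric_matrix(H)
    tails = {c for a in H.arcs for c in a.tail}
    heads = {c for a in H.arcs for c in a.head}
    return augment_exchanges(
        sys, sorted(set(S) & tails), sorted(heads - set(S))
    )


class TestAugmentExchanges:
    def test_column_counts_and_flags(self):
        H = Hypergraph([arc("R1", ["a"], ["b"]), arc("R2", ["b"], ["c"])])
        sys = build_stoichiometric_matrix(H)
        aug = augment_exchanges(sys, ["a"], ["c"])
        assert aug.shape == (3, 4)
        assert aug.col_kinds == ("internal", "internal", "input", "output")

    def test_input_column_is_a_unit_vector(self):
        H = Hypergraph([arc("R1", ["a"], ["b"])])
        aug = augment_exchanges(build_stoichiometric_matrix(H), ["a"], ["b"])
        j = aug.col_of(input_column_label("a"))
        col = [aug.matrix[i][j] for i in range(2)]
        assert col == [1, 0]

    def test_unknown_compound_rejected(self):
        H = Hypergraph([arc("R1", ["a"], ["b"])])
        with pytest.raises(ValueError):
            augment_exchanges(build_stoichiometric_matrix(H), ["zz"], [])


class TestEnumerateEfms:
    def test_chain_single_mode(self):
        H = Hypergraph([arc("R1", ["a"], ["b"]), arc("R2", ["b"], ["c"])])
        sys = build_stoichiometric_matrix(H)
        modes = enumerate_efms(augment_exchanges(sys, ["a"], ["c"]))
        assert len(modes) == 1
        assert all(v == 1 for v in modes[0].flux.values())

    def test_parallel_routes_two_modes(self):
        H = Hypergraph([arc("R1", ["a"], ["c"]), arc("R2", ["b"], ["c"])])
        modes = enumerate_efms(closed_system(H, {"a", "b"}))
        supports = {frozenset(m.support & {"R1", "R2"}) for m in modes}
        assert supports == {frozenset({"R1"}), frozenset({"R2"})}

    def test_stoichiometry_shapes_the_flux_ratio(self):
        H = Hypergraph([arc("R1", {"a": 1}, {"b": 2}), arc("R2", ["b"], ["c"])])
        sys = build_stoichiometric_matrix(H)
        modes = enumerate_efms(augment_exchanges(sys, ["a"], ["c"]))
        assert len(modes) == 1
        flux = modes[0].flux
        assert flux["R2"] == 2 * flux["R1"]

    def test_every_mode_balances_and_is_normalized(self, random_nets):
        for seed in range(8):
            H, S = random_nets(seed, compounds=7, reactions=7)
            sys = closed_system(H, S)
            for m in enumerate_efms(sys):
                # exact balance, row by row
                for row in sys.matrix:
                    total = sum(
                        row[sys.col_of(c)] * v for c, v in m.flux.items()
                    )
                    assert total == 0
                assert min(m.flux.values()) == 1
                assert all(v > 0 for v in m.flux.values())

    def test_supports_pairwise_minimal(self, random_nets):
        for seed in range(8):
            H, S = random_nets(seed, compounds=7, reactions=7)
            modes = enumerate_efms(closed_system(H, S))
            for m1, m2 in itertools.combinations(modes, 2):
                assert not m1.support < m2.support
                assert not m2.support < m1.support

    def test_invariant_under_column_permutation(self, random_nets):
        H, S = random_nets(3, compounds=7, reactions=7)
        sys = closed_system(H, S)
        perm = list(range(len(sys.col_labels)))[::-1]
        permuted = type(sys)(
            [[row[j] for j in perm] for row in sys.matrix],
            sys.row_labels,
            tuple(sys.col_labels[j] for j in perm),
            tuple(sys.col_kinds[j] for j in perm),
        )
        a = {m.support for m in enumerate_efms(sys)}
        b = {m.support for m in enumerate_efms(permuted)}
        assert a == b

    def test_matches_nullspace_subset_oracle(self, random_nets):
        """Independent oracle: a support carries an elementary mode iff the
        restricted matrix has a 1-dimensional nullspace spanned by a
        strictly signed vector and no qualifying proper subset."""
        import sympy

        def oracle(sys):
            n = len(sys.col_labels)
            M = sympy.Matrix([[sympy.Rational(v) for v in row] for row in sys.matrix])
            supports = []
            for size in range(1, n + 1):
                for cols in itertools.combinations(range(n), size):
                    if any(set(s) < set(cols) for s in supports):
                        continue
                    ns = M[:, list(cols)].nullspace()
                    if len(ns) == 1 and (
                        all(x > 0 for x in ns[0]) or all(x < 0 for x in ns[0])
                    ):
                        supports.append(cols)
            return {
                frozenset(sys.col_labels[j] for j in s) for s in supports
            }

        for seed in range(5):
            H, S = random_nets(seed, compounds=6, reactions=5)
            sys = closed_system(H, S)
            assert {m.support for m in enumerate_efms(sys)} == oracle(sys)

    def test_cap_refusal(self):
        arcs = [arc(f"R{i}", [f"a{i}"], [f"b{i}"]) for i in range(30)]
        sys = build_stoichiometric_matrix(Hypergraph(arcs))
        with pytest.raises(CapExceededError):
            enumerate_efms(sys, cap=24)


class TestPathwayFluxFeasible:
    def test_coefficients_force_witness_ratio(self):
        H = Hypergraph([arc("R1", ["a"], ["b"]), arc("R2", {"b": 2}, {"c": 1})])
        v = pathway_flux_feasible({"R1", "R2"}, H, {"a"}, {"c"})
        assert v.feasible
        assert v.witness["R1"] == pytest.approx(2 * v.witness["R2"], rel=1e-6)

    def test_bootstrap_cycle_is_flux_feasible_but_not_a_hyperpath(self):
        H = Hypergraph(
            [arc("R1", ["a", "b"], ["c"]), arc("R2", ["c"], ["b", "d"])]
        )
        assert not is_hyperpath(H, {"a"})
        v = pathway_flux_feasible({"R1", "R2"}, H, {"a"}, {"d"})
        assert v.feasible

    def test_empty_pathway_trivially_feasible_when_target_in_source(self):
        H = Hypergraph([arc("R1", ["a"], ["b"])])
        assert pathway_flux_feasible(set(), H, {"a"}, {"a"}).feasible
        assert not pathway_flux_feasible(set(), H, {"a"}, {"b"}).feasible

    def test_endogenous_coproduct_overproduction_is_infeasible(self):
        # the pathway net-produces source compound b and cannot consume it:
        # the source row would be positive, so no balanced flux exists
        H = Hypergraph([arc("R1", ["a"], ["c", "b"])])
        v = pathway_flux_feasible({"R1"}, H, {"a", "b"}, {"c"})
        assert not v.feasible
        # the same co-product outside the source drains freely
        assert pathway_flux_feasible({"R1"}, H, {"a"}, {"c"}).feasible

    def test_scaling_invariance(self, toy):
        H, S = toy
        scaled = Hypergraph(
            [
                arc(
                    a.id,
                    {c: 7 * v for c, v in a.tail.items()},
                    {c: 7 * v for c, v in a.head.items()},
                )
                for a in H.arcs
            ]
        )
        for P in ({"R3", "R4"}, {"R4", "R7"}):
            assert (
                pathway_flux_feasible(P, H, S, {"v8"}).feasible
                == pathway_flux_feasible(P, scaled, S, {"v8"}).feasible
            )

    def test_inequality_form_agrees_on_simple_chain(self):
        H = Hypergraph([arc("R1", ["a"], ["b"]), arc("R2", ["b"], ["c"])])
        for method in ("exchange", "inequality"):
            assert pathway_flux_feasible(
                {"R1", "R2"}, H, {"a"}, {"c"}, method=method
            ).feasible


class TestEfmPathways:
    def test_exchange_columns_stripped_and_source_modes_discarded(self):
        H = Hypergraph([arc("R1", ["a"], ["b"]), arc("R2", ["b"], ["c"])])
        sys = augment_exchanges(build_stoichiometric_matrix(H), ["a"], ["c"])
        modes = enumerate_efms(sys)
        paths = efm_pathways(modes, sys, {"R1", "R2"})
        assert paths == {frozenset({"R1", "R2"})}
        # with no heterologous overlap nothing survives
        assert efm_pathways(modes, sys, {"other"}) == set()

    def test_duplicate_internal_supports_merge(self):
        H = Hypergraph([arc("R1", ["a"], ["b", "c"])])
        sys = closed_system(H, {"a"})
        modes = enumerate_efms(sys)
        # one mode per output split, same internal support
        assert len(efm_pathways(modes, sys, {"R1"})) == 1


class TestCrossCheck:
    def test_toy_agrees(self, toy):
        H, S = toy
        rep = cross_check(H, S, {"v8"})
        assert rep.agree
        assert rep.topological == {
            frozenset({"R3", "R4"}),
            frozenset({"R4", "R7"}),
        }

    def test_injected_fake_pathway_reported_topological_only(self, toy):
        H, S = toy
        rep = cross_check(H, S, {"v8"})
        forged = CrossCheckReport.compare(
            set(rep.topological) | {frozenset({"R9"})}, rep.steady_state
        )
        assert frozenset({"R9"}) in forged.only_topological
        assert not forged.agree

    def test_steady_side_is_subset_and_disagreements_are_motif_certified(
        self, random_nets
    ):
        """Provable direction of the agreement claim: every elementary-mode
        derived pathway is found (and balanced) topologically.  Any
        topological-only pathway must be a balanced minimal hyperpath whose
        target-producing flux hides a non-hyperpath cycle, i.e. a genuine
        superposition of a cyclic mode with a seeding route."""
        from hyperpath.network import heterologous_subnetwork

        disagreements = 0
        for seed in range(25):
            H, S = random_nets(seed)
            reach = find_all(H, S)
            for t in sorted(reach.reachable):
                rep = cross_check(H, S, {t})
                assert not rep.only_steady_state
                for P in rep.only_topological:
                    disagreements += 1
                    RT = heterologous_subnetwork(H, S)
                    sys = closed_system(RT, S)
                    wanted = output_column_label(t)
                    inner = [
                        frozenset(m.support & set(RT.arc_ids()))
                        for m in enumerate_efms(sys)
                        if m.flux.get(wanted, Fraction(0)) > 0
                        and frozenset(m.support & set(RT.arc_ids())) <= P
                    ]
                    assert inner, "a balanced pathway must contain a mode"
                    assert all(
                        not is_hyperpath(
                            RT.restrict(q, keep_vertices=S), S
                        )
                        for q in inner
                    )
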