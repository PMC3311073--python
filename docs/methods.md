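# Methods

## Model and scope

Networks are directed hypergraphs: compounds are vertices, reactions are
hyperarcs `(X, Y)` with disjoint, non-empty substrate and product sets and
strictly positive rational coefficients.  All arcs are irreversible;
reversible input reactions are doubled (`*_fwd` / `*_rev`) before any
analysis.  The topological algorithms deliberately ignore stoichiometric
coefficients — only the steady-state module reads them.  Compounds
appearing on both sides of a reaction (catalytic self-appearance) violate
the disjointness invariant and are rejected at load time; a `strip_overlap`
load option removes the shared compound from both sides with a warning
instead.

The package targets the *enumeration* problem — every minimal hyperpath
from a source set to a target — not pathway ranking, retrosynthetic
network generation, yield optimisation, or competitive-scale elementary
mode computation.

## Determinism conventions

Several of the underlying procedures are nondeterministic on paper; the
implementation pins them down so identical inputs give byte-identical
outputs:

* the reachability closure uses a FIFO worklist seeded with source
  compounds in sorted id order; arcs sharing a newly covered compound fire
  in input arc order;
* the greedy minimization sweeps arcs in the closure ordering (forward),
  then any never-fired arcs in input order — different sweep orders can
  return different, equally valid minimal hyperpaths, so this is a
  convention, not semantics;
* enumeration runs depth-first over an explicit work stack, reproducing
  the recursive call order of the partition scheme;
* bootstrap peeling removes one compound per round, smallest id first.

Arc order in a `Hypergraph` is file/input order throughout.

## Constrained minimization and the sweep-acceptance rule

`minimize(P, R_f, T, S)` accepts the removal of an arc only if the target
stays covered **and every mandatory arc stays inside the closure
ordering**.  With the target-coverage test alone, a sweep can delete the
only producer of a mandatory arc's substrate; the result then violates the
contract (a hyperpath containing `R_f`) and — worse — enumeration cells
whose constraints do admit solutions would come back empty, silently
dropping minimal pathways (observable on the toy network once bootstraps
are in the media).  An upfront check rejects calls whose mandatory arcs
can never fire in `P` at all.  A final hyperpath post-check remains as a
safety net and logs before returning empty.

With `R_f = ∅` a single sweep returns a minimal hyperpath: once an arc
survives its removal trial it stays essential, because reachability only
shrinks as arcs are deleted.  The audit `is_minimal` is exact for the same
reason, and is verified against an exhaustive subset oracle in the tests.
Finding a *minimal* hyperpath containing a non-empty `R_f` is NP-complete;
the greedy sweep is exact on well-separated instances (every unconstrained
head either inside or disjoint from the mandatory products,
`well_separated`), in particular whenever all reactions have a single
product.

## Enumeration, audit and dedup policy

`find_path` partitions the solution space by mandatory/forbidden arc sets,
spawning one child per non-mandatory arc of each found pathway, scanned in
reverse witness order.  Because the constrained sweep may return
non-minimal hyperpaths on ill-separated instances, every deduplicated
output is audited with `is_minimal`.  Non-minimal outputs are dropped only
when their unconstrained reduction is already present in the result;
otherwise they are kept and flagged `minimal=False`, never silently
discarded (the completeness guarantee covers minimal hyperpaths only).
Degenerate targets inside the source return a single empty pathway with a
warning.  `max_pathways` (default 100 000) truncates with a flag rather
than raising; the partition-tree node count is reported for complexity
diagnostics.

`enumerate_pathways` composes the pipeline: optional bootstrap
augmentation of the media → restriction to the heterologous subnetwork
(arcs touching at least one compound outside the source, which also
removes cycles internal to the chassis) → pruning to the reachable part →
enumeration → audit → optional balance filter.

## Steady-state verification

The closed heterologous system gets one substrate-free **input** column
per source compound appearing as a substrate and one product-free
**output** column per product *outside the source* (the target and the
heterologous co-products).  Source compounds receive no outlet on purpose:
with an output column for every product, any hyperpath admits a balanced
flux (demands can be back-propagated along the witness ordering), so the
balance check would be vacuous; without it, a pathway that net-produces an
endogenous metabolite it cannot itself consume is correctly reported as
inconsistent, and the source rows keep their required "never net-produced"
sign.

`pathway_flux_feasible` solves the resulting LP (HiGHS via
`scipy.optimize.linprog`) with every pathway reaction's flux bounded below
by the activation threshold `ε = 1e-6` and, additionally, net production
of at least `ε` for each target outside the source — a pathway unable to
net-produce its target is inconsistent by definition.  Witness fluxes
below the tolerance `1e-9` are suppressed from the report.  A stricter
sign-pattern variant without exchange columns (intermediate rows exactly
zero) is available as `method="inequality"`.  Both `ε` values are
arbitrary-but-fixed numerical choices; verdicts are invariant under
uniform rescaling of the coefficients.

Elementary flux modes are enumerated with a canonical double-description
tableau: start from the unit rays of the non-negative orthant, impose one
balance row at a time, keep the zero rays plus all positive/negative
combinations, and filter to support-minimal vectors after every row.  All
arithmetic is over exact rationals (`fractions.Fraction`), so rank and
tolerance artefacts cannot occur; modes are normalized so the smallest
positive flux is 1.  This is a verification oracle with a deliberate cap
of 24 internal columns, not a production EFM tool.  A
nullspace-initialized tableau would reduce intermediate ray counts but
complicates the invariant; at the capped sizes the canonical form is fast
and easier to validate — the tests compare it against an independent
subset/nullspace oracle.

`cross_check` compares, on the same source set, (i) balance-filtered
topological enumeration with (ii) pathways derived from elementary modes:
modes of the closed heterologous system that net-produce the target,
stripped of exchange columns, keeping the supports that are themselves
minimal hyperpaths.  The hyperpath filter on side (ii) is essential:
modes can traverse self-sustaining cycles (a compound consumed before
being reproduced), which are valid flux solutions but not pathways — on
the toy network the `v2/v3` cycle yields exactly such a target-producing
mode.  Bootstraps are *not* pre-added to the media by `cross_check`; the
cycle modes are removed by the hyperpath filter instead, so both routes
see the same source set.

### Known, deliberate divergence of the two routes

The elementary-mode-derived pathway set is provably a subset of the
balance-filtered topological set (each such mode is its own feasibility
witness, and enumeration is complete).  The converse fails on a specific
motif: a minimal hyperpath that *borrows* a reachable compound which one
of its arcs regenerates.  Example — `R3: a→c`, `R1: {a,c}→x`,
`R2: x→{c,t}` with source `{a}`: the minimal hyperpath `{R1,R2,R3}` is
balanced, but its only `t`-producing elementary mode has internal support
`{R1,R2}`, which is not a hyperpath (the `c` loop), so no mode's support
equals the pathway.  At the default generator settings roughly 5–7% of
(instance, target) pairs exhibit the motif; every observed disagreement is
of this one-sided kind, and the test suite certifies the motif for each.
On strongly hierarchical networks (single-product reactions, no
regeneration cycles) the two routes coincide.

## Media analysis

`find_supp` is a backward closure from the target over producing arcs,
accumulating substrate compounds outside the source, minus everything the
forward closure already reaches.  This over-approximates the
supplements-in-a-minimal-pathway notion — it can include compounds with no
viable forward route — and is kept as such by design; the report
partitions the raw candidates into bootstraps, unreachable targets, and
plain supplements without altering the algorithmic output.  `find_supp`
visits each compound once via a sorted FIFO worklist.

`find_bootstraps` reduces every arc by the reachable set, drops arcs whose
head empties, then iteratively peels head compounds consumed by no
remaining arc.  Arcs whose tails retain unreachable, non-bootstrap
compounds may survive the peeling with their heads intact (the toy
network's `R10` with `v10, v11`); the algorithm is taken as normative,
and the affected heads are genuine bootstraps through other routes in all
bundled cases.  The returned set is always disjoint from the reachable
set, and re-running after supplying it returns the empty set (tested).

## Synthetic data

The random generator draws reactions with 1–3 substrates and 1–2 products
over a pool of 10 compounds (12 reactions, unit coefficients), and takes
the first 30% of compounds in sorted order as the source — small, sparse
networks in which exhaustive subset oracles (2^m scans) and exact
rational EFM enumeration stay cheap, while still producing branching,
dead ends, unreachable regions, bootstrap cycles and the regeneration
motif above.  It does not emulate real metabolism: no hub metabolites or
degree heterogeneity, no mass conservation across coefficients, no
compartments, no reversibility by default.  Passing tests therefore
establish algorithmic correctness (closure, minimality, completeness,
balance) on the model, not biological fidelity of any particular network.

Study sizes: oracle equivalence on 200 seeded networks (every reachable
target), steady-state comparison on 100, SAT counting on 20 instances
(≤8 variables, ≤6 clauses), layered closed-form counts on 11 branch
vectors with products up to 100.  The 3-SAT generator creates the
mandatory arc for every variable that appears in at least one clause, and
its satisfying-assignment oracle counts over those same variables, so the
pathway/assignment bijection is exact even with repeated literals.

## Limitations

* Enumeration is output-sensitive but worst-case exponential; the
  NP-completeness of the constrained subproblem is inherent, and
  ill-separated instances can emit (flagged) non-minimal pathways.
* The EFM cap (24 internal columns) and the brute-force cap (20 arcs)
  restrict the verification routes to small systems by design.
* The supplement set is an over-approximation (see above).
* SBML import is available only when `cobra` is installed (`load_sbml`),
  and no source set is inferred from SBML; export is limited to the two
  text dialects.
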