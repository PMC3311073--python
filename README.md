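# hyperpath

Enumeration of **all minimal heterologous metabolic pathways** linking a
source set of compounds — typically the endogenous metabolites of a chassis
organism such as *E. coli* — to a target compound, on a directed-hypergraph
model of the reaction network, with an independent steady-state
(elementary-flux-mode) verification route.

It is written for metabolic engineers and systems biologists who need the
*complete* list of enzyme sets capable of producing a heterologous target,
rather than the `k` shortest or a yield-optimal one: enumeration is
decoupled from ranking, so any downstream cost function can be applied to
the full list.

## The model

A reaction network is a directed hypergraph `H = (V, E)`: vertices are
compounds, and each hyperarc `e = (X(e), Y(e))` is an irreversible reaction
turning the substrate set `X(e)` into the product set `Y(e)` (reversible
reactions are split into a forward and a reverse arc).  A **hyperpath**
from a source `S` to a target `T` is an arc subset admitting an ordering
`F` with

* `X(F_k) ⊆ S ∪ ⋃_{j<k} Y(F_j)` for every position `k` (each reaction's
  substrates are available before it fires), and
* `T ⊆ S ∪ ⋃_e Y(e)` (the target is produced).

A hyperpath is **minimal** when no proper sub-hyperpath produces the same
target; minimal hyperpaths are the engineering-relevant pathways — the
smallest enzyme sets to clone into the chassis.

The core algorithms:

* `find_all(H, S)` — linear-time closure computing the reachable set
  `B(H, S)` and a firing order; doubles as hyperpath test and pruning
  device.
* `minimize(P, R_f, T, S)` — greedy removal of inessential arcs, keeping a
  mandatory set `R_f`; exact for `R_f = ∅` and on well-separated instances
  (the constrained problem is NP-complete in general — the package ships
  the 3-SAT reduction as a test-instance generator).
* `find_path(H, R_f, T, S)` — complete enumeration by iterative partition
  of the solution space into cells `(R_f, R_n)` of mandatory/forbidden
  arcs, with an exact minimality audit of every output.
* `find_supp` / `find_bootstraps` — growth-media analysis: compounds whose
  supplementation unlocks additional pathways, and *bootstrap* compounds
  that participate in producing their own precursors and therefore must be
  supplied before they can be (re)produced.
* `enumerate_efms` / `cross_check` — exact elementary-flux-mode
  enumeration (`S·v = 0, v ≥ 0` over exact rationals) of the closed
  heterologous system, used as an independent steady-state check of the
  topological enumeration, plus an LP balance filter for single pathways.

## Worked example

The bundled 12-compound toy network (`hyperpath fixtures toy`) has
sources `v1, v4`; compounds `v2, v3` form a self-feeding cycle and
`v10, v11` are unreachable precursors.

```
$ hyperpath fixtures toy --out toy.json
$ hyperpath enumerate --network toy.json --target v8
2 pathway(s), 2 minimal, 4 enumeration node(s)
R3+R4
R4+R7
```

Exactly two minimal pathways reach `v8`: reaction `R4` (which makes `v8`
from `v1 + v7`) fed by either producer of `v7`.  Media analysis:

```
$ hyperpath bootstraps --network toy.json
v2 v3
$ hyperpath supplements --network toy.json --target v8
candidates: v10 v11 v2 v3 v6
  of which bootstraps: v2 v3
  of which unreachable targets: (none)
```

`v2` and `v3` are bootstraps — each one, once supplied, permits its own
regeneration (`v2 → v3 → v2` through `R5`/`R6`).  Adding them to the
growth media unlocks a third route:

```
$ hyperpath enumerate --network toy.json --target v8 --with-bootstraps
3 pathway(s), 3 minimal, 6 enumeration node(s)
bootstraps added to media: v2 v3
R3+R4
R11+R6
R4+R7
```

And the steady-state route independently recovers the same pathway set:

```
$ hyperpath crosscheck --network toy.json --target v8
topological pathways: 2
steady-state pathways: 2
agreement: yes
```

The same operations are available as library calls
(`hyperpath.enumerate_pathways`, `hyperpath.find_bootstraps`, ...) on
networks loaded from the reaction-table or JSON document formats, from
generators (`hyperpath.fixtures`), or built directly from
`hyperpath.arc(...)` objects.

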