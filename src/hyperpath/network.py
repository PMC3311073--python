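"""Directed-hypergraph model of a metabolic reaction network.

A reaction network is a directed hypergraph H = (V, E): vertices are
compounds and every hyperarc e = (X(e), Y(e)) is one irreversible
enzyme-catalysed reaction transforming the tail compounds X(e) (substrates)
into the head compounds Y(e) (products).  Tail and head are disjoint,
non-empty sets with strictly positive stoichiometric coefficients.

The topological algorithms (reachability, minimization, enumeration, media)
deliberately ignore the stoichiometric coefficients; only the steady-state
module reads them.  Reversible reactions are represented by keeping a
``reversible`` flag on the arc until :func:`split_reversible` doubles them
into a forward and a reverse arc.

This module also provides the two text formats (a line-oriented reaction
table and a JSON network document), network validation, stoichiometric
matrix construction and extraction of the heterologous subnetwork RT.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO

from .errors import HyperpathError, ParseError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "Hyperarc",
    "Hypergraph",
    "Hyperpath",
    "Diagnostic",
    "StoichiometricSystem",
    "arc",
    "validate_network",
    "validate_arcs",
    "split_reversible",
    "build_stoichiometric_matrix",
    "heterologous_subnetwork",
    "load_network",
    "load_sbml",
    "write_network",
]


def _coeff(value) -> Fraction:
    """Coerce a coefficient to an exact rational."""
    if isinstance(value, float):
        return Fraction(str(value))
    return Fraction(value)


def _side(side) -> dict[str, Fraction]:
    if isinstance(side, Mapping):
        return {str(c): _coeff(v) for c, v in side.items()}
    return {str(c): Fraction(1) for c in side}


@dataclass(frozen=True)
class Hyperarc:
    """One reaction: an ordered pair of disjoint compound sets.

    ``tail`` maps substrate ids to positive coefficients, ``head`` maps
    product ids to positive coefficients.  ``reversible`` is carried from
    the input format and is only consumed by :func:`split_reversible`.
    """

    id: str
    tail: Mapping[str, Fraction]
    head: Mapping[str, Fraction]
    enzyme: str | None = None
    reversible: bool = False

    def reversed(self, new_id: str) -> "Hyperarc":
        return Hyperarc(new_id, dict(self.head), dict(self.tail), self.enzyme, False)


def arc(arc_id, tail, head, enzyme=None, reversible=False) -> Hyperarc:
    """Convenience constructor: sides may be mappings or plain iterables
    (iterables get unit coefficients)."""
    return Hyperarc(str(arc_id), _side(tail), _side(head), enzyme, reversible)


class Hypergraph:
    """A directed hypergraph with stable arc order.

    Arc order equals input order; every deterministic tie-break downstream
    (closure queues, minimization sweeps, enumeration partition order)
    derives from it.  ``tail_index`` / ``head_index`` map a compound id to
    the ids of arcs containing it in their tail / head, in arc order.
    """

    __slots__ = ("vertices", "arcs", "_by_id", "tail_index", "head_index")

    def __init__(self, arcs: Iterable[Hyperarc], vertices: Iterable[str] = ()):
        self.arcs: tuple[Hyperarc, ...] = tuple(arcs)
        by_id: dict[str, Hyperarc] = {}
        for a in self.arcs:
            if a.id in by_id:
                raise ValidationError(
                    [Diagnostic("duplicate-id", a.id, f"duplicate arc id {a.id!r}")]
                )
            by_id[a.id] = a
        self._by_id = by_id
        verts = set(vertices)
        tail_index: dict[str, list[str]] = {}
        head_index: dict[str, list[str]] = {}
        for a in self.arcs:
            for c in a.tail:
                verts.add(c)
                tail_index.setdefault(c, []).append(a.id)
            for c in a.head:
                verts.add(c)
                head_index.setdefault(c, []).append(a.id)
        self.vertices: frozenset[str] = frozenset(verts)
        self.tail_index = tail_index
        self.head_index = head_index

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def m(self) -> int:
        return len(self.arcs)

    def arc(self, arc_id: str) -> Hyperarc:
        return self._by_id[arc_id]

    def arc_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.arcs)

    def __contains__(self, arc_id: str) -> bool:
        return arc_id in self._by_id

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypergraph)
            and self.vertices == other.vertices
            and self.arcs == other.arcs
        )

    def __repr__(self) -> str:
        return f"Hypergraph(n={self.n}, m={self.m})"

    def total_coordination(self) -> int:
        return sum(len(a.tail) + len(a.head) for a in self.arcs)

    # -- derived hypergraphs ---------------------------------------------
    def restrict(self, arc_ids: Iterable[str], keep_vertices: Iterable[str] = ()):
        """Sub-hypergraph on a subset of arcs (input order preserved);
        vertices are the incident compounds plus ``keep_vertices`` already
        present in this hypergraph."""
        keep = set(arc_ids)
        extra = set(keep_vertices) & self.vertices
        return Hypergraph((a for a in self.arcs if a.id in keep), extra)

    def without(self, arc_ids: Iterable[str]) -> "Hypergraph":
        drop = {arc_ids} if isinstance(arc_ids, str) else set(arc_ids)
        return Hypergraph(a for a in self.arcs if a.id not in drop)


@dataclass
class Hyperpath:
    """A hyperarc subset together with a witness ordering.

    The ordering F proves the defining property of a hyperpath: each arc's
    tail is covered by the source plus the heads of earlier arcs, and the
    target set is covered overall.  ``minimal`` is tri-state: ``True`` /
    ``False`` after an audit, ``None`` while unaudited.  ``balanced`` is
    filled in by the steady-state balance filter when requested.
    """

    arcs: frozenset[str]
    ordering: tuple[str, ...]
    targets: frozenset[str]
    minimal: bool | None = None
    balanced: bool | None = None

    def __post_init__(self):
        if set(self.ordering) != set(self.arcs) or len(self.ordering) != len(self.arcs):
            raise ValueError("ordering must be a permutation of the arc set")

    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.arcs))

    def __str__(self) -> str:
        return "+".join(self.sorted_ids()) if self.arcs else "(empty)"


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the violated rule and the offending object."""

    rule: str
    subject: str
    message: str


def validate_arcs(arcs: Iterable[Hyperarc]) -> list[Diagnostic]:
    out: list[Diagnostic] = []
    seen: set[str] = set()
    for a in arcs:
        if a.id in seen:
            out.append(
                Diagnostic("duplicate-id", a.id, f"duplicate arc id {a.id!r}")
            )
        seen.add(a.id)
        overlap = set(a.tail) & set(a.head)
        if overlap:
            out.append(
                Diagnostic(
                    "tail-head-overlap",
                    a.id,
                    f"arc {a.id!r}: compounds {sorted(overlap)} appear in both"
                    " tail and head",
                )
            )
        if not a.tail:
            out.append(Diagnostic("empty-tail", a.id, f"arc {a.id!r} has empty tail"))
        if not a.head:
            out.append(Diagnostic("empty-head", a.id, f"arc {a.id!r} has empty head"))
        for c, v in list(a.tail.items()) + list(a.head.items()):
            if v <= 0:
                out.append(
                    Diagnostic(
                        "non-positive-coefficient",
                        a.id,
                        f"arc {a.id!r}: coefficient of {c!r} is {v}",
                    )
                )
    return out


def validate_network(H: Hypergraph) -> list[Diagnostic]:
    """Return diagnostics for every violated invariant (empty list == valid)."""
    out = validate_arcs(H.arcs)
    for a in H.arcs:
        for c in list(a.tail) + list(a.head):
            if c not in H.vertices:  # pragma: no cover - ctor makes this unreachable
                out.append(
                    Diagnostic(
                        "unknown-compound", a.id, f"arc {a.id!r} uses unknown {c!r}"
                    )
                )
    return out


# ---------------------------------------------------------------------------
# reversible splitting


def split_reversible(H: Hypergraph) -> Hypergraph:
    """Double every reversible arc into ``<id>_fwd`` / ``<id>_rev`` with
    tail and head swapped; irreversible arcs pass through unchanged."""
    existing = set(H.arc_ids())
    out: list[Hyperarc] = []
    for a in H.arcs:
        if not a.reversible:
            out.append(a)
            continue
        fwd, rev = a.id + "_fwd", a.id + "_rev"
        for new in (fwd, rev):
            if new in existing:
                raise ValidationError(
                    [
                        Diagnostic(
                            "split-collision",
                            a.id,
                            f"cannot split {a.id!r}: id {new!r} already exists",
                        )
                    ]
                )
        out.append(Hyperarc(fwd, dict(a.tail), dict(a.head), a.enzyme, False))
        out.append(a.reversed(rev))
    return Hypergraph(out, H.vertices)


# ---------------------------------------------------------------------------
# stoichiometric matrix


@dataclass
class StoichiometricSystem:
    """Signed rational stoichiometric matrix with labels and column kinds.

    Rows are compounds (sorted ids), columns are reactions in arc order.
    Reactants carry negative coefficients, products positive ones.  Column
    kinds are ``internal`` for true reactions and ``input`` / ``output``
    for the exchange columns added by the steady-state module.
    """

    matrix: list[list[Fraction]]
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    col_kinds: tuple[str, ...]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.col_labels))

    def row_of(self, compound: str) -> int:
        return self.row_labels.index(compound)

    def col_of(self, label: str) -> int:
        return self.col_labels.index(label)

    def internal_labels(self) -> tuple[str, ...]:
        return tuple(
            l for l, k in zip(self.col_labels, self.col_kinds) if k == "internal"
        )

    def to_float(self):
        import numpy as np

        return np.array([[float(v) for v in row] for row in self.matrix])

    # coordinate (MatrixMarket-style) text export / import; values are
    # written as exact rationals so a round trip is lossless.
    def write_coordinate(self, stream: IO[str]) -> None:
        entries = [
            (i, j, v)
            for i, row in enumerate(self.matrix)
            for j, v in enumerate(row)
            if v != 0
        ]
        stream.write("%%coordinate rational general\n")
        stream.write(f"% rows: {' '.join(self.row_labels)}\n")
        stream.write(f"% cols: {' '.join(self.col_labels)}\n")
        stream.write(f"% kinds: {' '.join(self.col_kinds)}\n")
        stream.write(f"{len(self.row_labels)} {len(self.col_labels)} {len(entries)}\n")
        for i, j, v in entries:
            stream.write(f"{i + 1} {j + 1} {v}\n")

    @classmethod
    def read_coordinate(cls, stream: IO[str]) -> "StoichiometricSystem":
        rows = cols = kinds = None
        header = None
        entries = []
        for line in stream:
            line = line.strip()
            if not line:
                continue
            if line.startswith("%"):
                body = line.lstrip("%").strip()
                for tag in ("rows:", "cols:", "kinds:"):
                    if body.startswith(tag):
                        vals = tuple(body[len(tag):].split())
                        if tag == "rows:":
                            rows = vals
                        elif tag == "cols:":
                            cols = vals
                        else:
                            kinds = vals
                continue
            if header is None:
                header = tuple(int(t) for t in line.split())
                continue
            i, j, v = line.split()
            entries.append((int(i) - 1, int(j) - 1, Fraction(v)))
        if rows is None or cols is None or header is None:
            raise ParseError("incomplete coordinate matrix")
        kinds = kinds or ("internal",) * len(cols)
        mat = [[Fraction(0)] * len(cols) for _ in rows]
        for i, j, v in entries:
            mat[i][j] = v
        return cls(mat, rows, cols, kinds)


def build_stoichiometric_matrix(H: Hypergraph) -> StoichiometricSystem:
    """m_compounds x n_reactions matrix; entry (i, j) is -tail coefficient
    if compound i is a reactant of reaction j, +head coefficient if a
    product, 0 otherwise."""
    rows = tuple(sorted(H.vertices))
    idx = {c: i for i, c in enumerate(rows)}
    mat = [[Fraction(0)] * H.m for _ in rows]
    for j, a in enumerate(H.arcs):
        for c, v in a.tail.items():
            mat[idx[c]][j] -= v
        for c, v in a.head.items():
            mat[idx[c]][j] += v
    return StoichiometricSystem(mat, rows, H.arc_ids(), ("internal",) * H.m)


# ---------------------------------------------------------------------------
# heterologous subnetwork


def heterologous_subnetwork(H: Hypergraph, S: Iterable[str]) -> Hypergraph:
    """RT: the sub-hypergraph of arcs touching at least one compound outside
    the source set S (reactions entirely within the chassis are dropped, so
    cycles internal to the chassis cannot enter downstream enumeration)."""
    S = set(S)
    keep = [
        a.id for a in H.arcs if (set(a.tail) | set(a.head)) - S
    ]
    return H.restrict(keep)


# ---------------------------------------------------------------------------
# reaction-table dialect
#
#   id <TAB> substrates <TAB> products <TAB> rev|irrev
#
# with '|' accepted as an alternative separator, substrate/product syntax
# "2 b + c" (coefficient optional, default 1), '#' comments, and an optional
# header "!source: a b c" declaring the source set.


def _parse_side(text: str, line_no: int) -> dict[str, Fraction]:
    side: dict[str, Fraction] = {}
    text = text.strip()
    if not text:
        return side
    for part in text.split("+"):
        tokens = part.split()
        if not tokens:
            raise ParseError("empty term between '+' signs", line_no)
        if len(tokens) == 1:
            coeff, comp = Fraction(1), tokens[0]
        elif len(tokens) == 2:
            try:
                coeff = Fraction(tokens[0])
            except ValueError as exc:
                raise ParseError(f"bad coefficient {tokens[0]!r}", line_no) from exc
            comp = tokens[1]
        else:
            raise ParseError(f"cannot parse term {part.strip()!r}", line_no)
        side[comp] = side.get(comp, Fraction(0)) + coeff
    return side


def _format_side(side: Mapping[str, Fraction]) -> str:
    parts = []
    for c in sorted(side):
        v = side[c]
        parts.append(c if v == 1 else f"{v} {c}")
    return " + ".join(parts)


def _load_table(stream: IO[str]):
    arcs: list[Hyperarc] = []
    source: frozenset[str] | None = None
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("!source:"):
            source = frozenset(line[len("!source:"):].split())
            continue
        fields = line.split("\t") if "\t" in line else line.split("|")
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 fields (id, substrates, products, flag), got"
                f" {len(fields)}",
                line_no,
            )
        rid, subs, prods, flag = (f.strip() for f in fields)
        if flag not in ("rev", "irrev"):
            raise ParseError(f"reversibility flag must be rev|irrev, got {flag!r}",
                             line_no)
        arcs.append(
            Hyperarc(
                rid,
                _parse_side(subs, line_no),
                _parse_side(prods, line_no),
                reversible=(flag == "rev"),
            )
        )
    return arcs, source


def _write_table(H: Hypergraph, S) -> str:
    lines = []
    if S:
        lines.append("!source: " + " ".join(sorted(S)))
    for a in H.arcs:
        flag = "rev" if a.reversible else "irrev"
        lines.append(
            "\t".join((a.id, _format_side(a.tail), _format_side(a.head), flag))
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON document dialect


def _load_document(stream: IO[str]):
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", exc.lineno) from exc
    if not isinstance(doc, dict):
        raise ParseError("document root must be an object")
    vertices = [c["id"] for c in doc.get("compounds", [])]
    arcs = []
    for r in doc.get("reactions", []):
        arcs.append(
            Hyperarc(
                str(r["id"]),
                {s["id"]: _coeff(s.get("coeff", 1)) for s in r.get("substrates", [])},
                {p["id"]: _coeff(p.get("coeff", 1)) for p in r.get("products", [])},
                r.get("enzyme"),
                bool(r.get("reversible", False)),
            )
        )
    source = frozenset(doc["source"]) if "source" in doc else None
    return arcs, source, vertices


def _write_document(H: Hypergraph, S) -> str:
    doc: dict = {
        "compounds": [{"id": c} for c in sorted(H.vertices)],
        "reactions": [
            {
                "id": a.id,
                "substrates": [
                    {"id": c, "coeff": _num(a.tail[c])} for c in sorted(a.tail)
                ],
                "products": [
                    {"id": c, "coeff": _num(a.head[c])} for c in sorted(a.head)
                ],
                "reversible": a.reversible,
                **({"enzyme": a.enzyme} if a.enzyme else {}),
            }
            for a in H.arcs
        ],
    }
    if S is not None:
        doc["source"] = sorted(S)
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _num(v: Fraction):
    """JSON-friendly coefficient: int when integral, else rational string."""
    return int(v) if v.denominator == 1 else str(v)


# ---------------------------------------------------------------------------
# public I/O


def load_network(
    stream: IO[str],
    format: str = "table",
    strip_overlap: bool = False,
) -> tuple[Hypergraph, frozenset[str] | None]:
    """Parse a network; reversible entries are kept as flagged single arcs
    (call :func:`split_reversible` afterwards to double them).

    ``strip_overlap`` removes a compound occurring on both sides of a
    reaction from both sides (with a logged warning) instead of failing.
    """
    if format == "table":
        arcs, source = _load_table(stream)
        vertices: list[str] = []
    elif format == "document":
        arcs, source, vertices = _load_document(stream)
    else:
        raise ValueError(f"unknown format {format!r}")
    if strip_overlap:
        arcs = [_strip_overlap(a) for a in arcs]
    diags = validate_arcs(arcs)
    if diags:
        raise ValidationError(diags)
    return Hypergraph(arcs, vertices), source


def _strip_overlap(a: Hyperarc) -> Hyperarc:
    overlap = set(a.tail) & set(a.head)
    if not overlap:
        return a
    log.warning(
        "arc %s: stripping catalytic compounds %s from both sides",
        a.id,
        sorted(overlap),
    )
    tail = {c: v for c, v in a.tail.items() if c not in overlap}
    head = {c: v for c, v in a.head.items() if c not in overlap}
    return Hyperarc(a.id, tail, head, a.enzyme, a.reversible)


def load_sbml(path: str) -> tuple[Hypergraph, frozenset[str] | None]:
    """Optional SBML import (requires the ``cobra`` package).

    Species map to compounds and reactions to arcs; the reversibility flag
    is honoured (call :func:`split_reversible` afterwards).  Reactions
    running only backwards are stored in their forward-feasible direction.
    No source set is inferred.  SBML export is not provided.
    """
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - cobra is normally present
        raise HyperpathError(
            "SBML import requires the optional 'cobra' dependency"
        ) from exc
    model = cobra.io.read_sbml_model(path)
    arcs: list[Hyperarc] = []
    for rxn in model.reactions:
        tail = {m.id: _coeff(-c) for m, c in rxn.metabolites.items() if c < 0}
        head = {m.id: _coeff(c) for m, c in rxn.metabolites.items() if c > 0}
        if not tail and not head:
            continue
        if rxn.upper_bound <= 0 < abs(rxn.lower_bound):  # backwards-only
            tail, head = head, tail
            reversible = False
        else:
            reversible = bool(rxn.reversibility)
        arcs.append(Hyperarc(rxn.id, tail, head, reversible=reversible))
    diags = validate_arcs(arcs)
    if diags:
        raise ValidationError(diags)
    vertices = [m.id for m in model.metabolites]
    return Hypergraph(arcs, vertices), None


def write_network(H: Hypergraph, S=None, format: str = "table") -> str:
    """Serialize to the named dialect; output is byte-stable (arc order is
    preserved, compound lists are sorted)."""
    if format == "table":
        return _write_table(H, S)
    if format == "document":
        return _write_document(H, S)
    raise ValueError(f"unknown format {format!r}")
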