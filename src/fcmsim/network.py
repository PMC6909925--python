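"""Signed concept networks: data model, edge-list I/O, statistics, random generator.

A :class:`ConceptNetwork` is a signed, weighted, directed graph over named
biological concepts (genes, proteins, phenotypes, compounds).  It is the
substrate of the qualitative simulator: the weight matrix ``W`` with
``W[t, s]`` holding the influence of concept ``s`` on concept ``t`` is what
the dynamics engine iterates.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Concept",
    "Relation",
    "ConceptNetwork",
    "NetworkStats",
    "NetworkError",
    "parse_edge_list",
    "parse_sif",
    "write_edge_list",
    "write_concept_table",
    "network_stats",
    "generate_random_network",
]

VALID_KINDS = ("gene", "protein", "phenotype", "compound")


class NetworkError(ValueError):
    """Raised for malformed networks, rows, or unresolvable concept references."""


@dataclass(frozen=True)
class Concept:
    """A node: a gene/protein/phenotype/compound with a unique id."""

    id: str
    label: str = ""
    kind: str = "gene"
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.id:
            raise NetworkError("concept id must be non-empty")
        if self.kind not in VALID_KINDS:
            raise NetworkError(f"unknown concept kind {self.kind!r} for {self.id!r}")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Relation:
    """A signed directed edge; weight in [-1, 1], never zero."""

    source: str
    target: str
    weight: float
    provenance: str = ""

    def __post_init__(self):
        w = float(self.weight)
        if not np.isfinite(w) or w == 0.0 or abs(w) > 1.0:
            raise NetworkError(
                f"relation {self.source}->{self.target}: weight {self.weight!r} "
                "must be non-zero and within [-1, 1]"
            )
        object.__setattr__(self, "weight", w)


class ConceptNetwork:
    """Ordered concepts plus at most one relation per ordered (source, target) pair.

    Concept lookup is case-insensitive over ids and aliases; canonical ids are
    stored verbatim.
    """

    def __init__(self, concepts=(), relations=()):
        self.concepts: list[Concept] = []
        self.relations: list[Relation] = []
        self._index: dict[str, int] = {}
        self._lookup: dict[str, str] = {}  # lowercased id/alias -> canonical id
        self._pairs: set[tuple[str, str]] = set()
        for c in concepts:
            self.add_concept(c)
        for r in relations:
            self.add_relation(r)

    # -- construction -----------------------------------------------------
    def add_concept(self, concept: Concept) -> None:
        if concept.id.lower() in self._lookup:
            raise NetworkError(f"duplicate concept id {concept.id!r}")
        for a in concept.aliases:
            if a.lower() in self._lookup and self._lookup[a.lower()] != concept.id:
                raise NetworkError(f"alias {a!r} clashes with {self._lookup[a.lower()]!r}")
        self._index[concept.id] = len(self.concepts)
        self._lookup[concept.id.lower()] = concept.id
        for a in concept.aliases:
            self._lookup[a.lower()] = concept.id
        self.concepts.append(concept)

    def add_relation(self, relation: Relation, *, overwrite: bool = False) -> None:
        src = self.resolve(relation.source)
        tgt = self.resolve(relation.target)
        relation = replace(relation, source=src, target=tgt)
        pair = (src, tgt)
        if pair in self._pairs:
            if not overwrite:
                raise NetworkError(f"duplicate relation for pair {src!r} -> {tgt!r}")
            self.relations = [r for r in self.relations if (r.source, r.target) != pair]
        self._pairs.add(pair)
        self.relations.append(relation)

    def ensure_concept(self, cid: str, **kwargs) -> str:
        """Register ``cid`` if unknown (default kind 'gene'); return canonical id."""
        if cid.lower() in self._lookup:
            return self._lookup[cid.lower()]
        self.add_concept(Concept(id=cid, **kwargs))
        return cid

    # -- lookup -----------------------------------------------------------
    def resolve(self, name: str) -> str:
        try:
            return self._lookup[name.lower()]
        except KeyError:
            raise NetworkError(f"unknown concept {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._lookup

    def index_of(self, name: str) -> int:
        return self._index[self.resolve(name)]

    @property
    def concept_ids(self) -> list[str]:
        return [c.id for c in self.concepts]

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    # -- matrix -----------------------------------------------------------
    def weight_matrix(self) -> np.ndarray:
        """N x N matrix with ``W[t, s]`` = weight of the relation s -> t."""
        n = self.n_concepts
        W = np.zeros((n, n))
        for r in self.relations:
            W[self._index[r.target], self._index[r.source]] = r.weight
        return W

    def __eq__(self, other):
        """Content equality: same concepts (any order) and same relations."""
        if not isinstance(other, ConceptNetwork):
            return NotImplemented
        return (
            sorted(self.concepts, key=lambda c: c.id)
            == sorted(other.concepts, key=lambda c: c.id)
            and sorted(self.relations, key=lambda r: (r.source, r.target))
            == sorted(other.relations, key=lambda r: (r.source, r.target))
        )

    def __repr__(self):
        return f"<ConceptNetwork {self.n_concepts} concepts, {self.n_relations} relations>"


@dataclass(frozen=True)
class NetworkStats:
    n_concepts: int
    n_relations: int
    mean_in_degree: float
    mean_out_degree: float
    positive_fraction: float
    pretest_positive: float = field(init=False)
    pretest_negative: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "pretest_positive", self.positive_fraction)
        object.__setattr__(self, "pretest_negative", 1.0 - self.positive_fraction)


def network_stats(net: ConceptNetwork) -> NetworkStats:
    """Degree and sign-bias summaries; the positive fraction doubles as the
    pretest probability used by the bias-adjusted binomial validation test."""
    if net.n_concepts == 0:
        raise NetworkError("network_stats requires a non-empty network")
    n_pos = sum(1 for r in net.relations if r.weight > 0)
    m = net.n_relations
    return NetworkStats(
        n_concepts=net.n_concepts,
        n_relations=m,
        mean_in_degree=m / net.n_concepts,
        mean_out_degree=m / net.n_concepts,
        positive_fraction=(n_pos / m) if m else 0.0,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sniff_rows(path) -> list[list[str]]:
    with open(path, newline="") as fh:
        text = fh.read()
    if not text.strip():
        return []
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    return [row for row in csv.reader(io.StringIO(text), delimiter=delim) if any(row)]


def _is_header(row: list[str]) -> bool:
    if len(row) < 3:
        return True
    try:
        float(row[2])
        return False
    except ValueError:
        return True


def read_concept_table(path) -> list[Concept]:
    """Companion concept table: columns id,label,kind,aliases(';'-separated)."""
    rows = _sniff_rows(path)
    if rows and rows[0] and rows[0][0].lower() == "id":
        rows = rows[1:]
    out = []
    for row in rows:
        row = row + [""] * (4 - len(row))
        aliases = tuple(a.strip() for a in row[3].split(";") if a.strip())
        out.append(Concept(id=row[0], label=row[1] or row[0], kind=row[2] or "gene", aliases=aliases))
    return out


def parse_edge_list(path, strict: bool = False, concept_table=None) -> ConceptNetwork:
    """Read a CSV/TSV of rows ``source,target,weight[,provenance]``.

    The header is auto-detected.  Concepts are auto-registered from edge
    endpoints (kind ``gene``) unless a companion concept table supplies them.
    Duplicate (source, target) rows are an error when ``strict``, otherwise
    last-wins with a warning.  Edge endpoints absent from a supplied concept
    table are an error (dangling reference).
    """
    net = ConceptNetwork()
    have_table = concept_table is not None
    if have_table:
        for c in read_concept_table(concept_table):
            net.add_concept(c)
    rows = _sniff_rows(path)
    if rows and _is_header(rows[0]):
        rows = rows[1:]
    for i, row in enumerate(rows):
        if len(row) < 3:
            raise NetworkError(f"row {i}: expected source,target,weight, got {row!r}")
        src, tgt = row[0].strip(), row[1].strip()
        try:
            w = float(row[2])
        except ValueError:
            raise NetworkError(f"row {i}: weight {row[2]!r} is not a number") from None
        prov = row[3].strip() if len(row) > 3 else ""
        if have_table:
            if src not in net or tgt not in net:
                missing = src if src not in net else tgt
                raise NetworkError(f"row {i}: concept {missing!r} missing from concept table")
        else:
            net.ensure_concept(src)
            net.ensure_concept(tgt)
        rel = Relation(source=src, target=tgt, weight=w, provenance=prov)
        pair = (net.resolve(src), net.resolve(tgt))
        if pair in net._pairs:
            if strict:
                raise NetworkError(f"duplicate edge for pair {pair[0]!r} -> {pair[1]!r}")
            warnings.warn(f"duplicate edge {pair[0]} -> {pair[1]}: keeping last value", stacklevel=2)
            net.add_relation(rel, overwrite=True)
        else:
            net.add_relation(rel)
    return net


def parse_sif(path) -> ConceptNetwork:
    """Simple interaction format: ``source<TAB>sign<TAB>target`` with sign in
    {activates, inhibits}, mapped to weights +1 / -1."""
    signs = {"activates": 1.0, "inhibits": -1.0}
    net = ConceptNetwork()
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise NetworkError(f"SIF line {i}: expected 3 tab-separated fields")
            src, sign, tgt = parts
            if sign not in signs:
                raise NetworkError(f"SIF line {i}: unknown sign {sign!r}")
            net.ensure_concept(src)
            net.ensure_concept(tgt)
            net.add_relation(Relation(src, tgt, signs[sign]))
    return net


def write_edge_list(net: ConceptNetwork, path) -> None:
    """Write ``source,target,weight[,provenance]``; round-trips through
    :func:`parse_edge_list`."""
    has_prov = any(r.provenance for r in net.relations)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["source", "target", "weight"] + (["provenance"] if has_prov else [])
        w.writerow(header)
        for r in net.relations:
            row = [r.source, r.target, repr(r.weight)]
            if has_prov:
                row.append(r.provenance)
            w.writerow(row)


def write_concept_table(net: ConceptNetwork, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "kind", "aliases"])
        for c in net.concepts:
            w.writerow([c.id, c.label, c.kind, ";".join(c.aliases)])


# ---------------------------------------------------------------------------
# random networks
# ---------------------------------------------------------------------------

def generate_random_network(
    n_concepts: int,
    mean_degree: float = 8.0,
    positive_fraction: float = 0.66,
    weight_magnitudes=1.0,
    seed: int = 0,
    self_loops: bool = False,
) -> ConceptNetwork:
    """Random network matching published degree/sign statistics.

    Each node receives exactly ``round(mean_degree)`` out-edges to distinct
    targets (fixed out-degree scheme, so the relation count is exact), edge
    signs are i.i.d. positive with probability ``positive_fraction``, and
    magnitudes default to 1.0 (``weight_magnitudes`` may be a constant or a
    ``("uniform", lo, hi)`` spec).  Deterministic for a fixed seed.
    """
    if n_concepts < 2:
        raise NetworkError("need at least 2 concepts")
    if not 0.0 <= positive_fraction <= 1.0:
        raise NetworkError("positive_fraction must be in [0, 1]")
    k = int(round(mean_degree))
    max_k = n_concepts if self_loops else n_concepts - 1
    if k < 0 or k > max_k:
        raise NetworkError(f"mean_degree {mean_degree} infeasible for {n_concepts} concepts")
    rng = np.random.default_rng(seed)
    ids = [f"C{i:04d}" for i in range(n_concepts)]
    net = ConceptNetwork(concepts=[Concept(id=i) for i in ids])
    for s in range(n_concepts):
        pool = np.arange(n_concepts) if self_loops else np.delete(np.arange(n_concepts), s)
        targets = rng.choice(pool, size=k, replace=False)
        signs = np.where(rng.random(k) < positive_fraction, 1.0, -1.0)
        if isinstance(weight_magnitudes, tuple) and weight_magnitudes[0] == "uniform":
            lo, hi = weight_magnitudes[1], weight_magnitudes[2]
            mags = rng.uniform(lo, hi, size=k)
        else:
            mags = np.full(k, float(weight_magnitudes))
        for t, sign, mag in zip(targets, signs, mags):
            net.add_relation(Relation(ids[s], ids[int(t)], float(sign * mag)))
    return net
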