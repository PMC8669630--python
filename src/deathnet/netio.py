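"""Typed multilayer gene-network containers and plain-text I/O.

A multilayer network keeps one undirected edge layer per molecular relation
type (protein-protein binding, activation, phosphorylation, ...).  The
default relation vocabulary has sixteen entries; the two relation types that
share the short code ``T`` in curated sources (translocation and
transcription) are disambiguated here as ``TL`` and ``TS``, and a bare ``T``
is only accepted when the caller says which one it means.

File formats are deliberately minimal and diff-able: tab-separated edge
tables (SIF-style ``gene_a  relation  gene_b`` plus optional weight and
provenance columns), GMT gene-set files, and a tab-separated node-attribute
table.  Comment lines start with ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, TextIO

from .errors import ContractError, FormatError

__all__ = [
    "Relation",
    "RelationVocabulary",
    "DEFAULT_VOCABULARY",
    "GeneNode",
    "TypedEdge",
    "MultilayerNetwork",
    "GeneSetCollection",
    "read_edge_table",
    "write_network",
    "census",
    "read_gmt",
    "write_gmt",
    "read_node_attributes",
    "write_node_attributes",
]

logger = logging.getLogger(__name__)

TOOL_TAG = "deathnet"


def canon(symbol: str) -> str:
    """Canonical form used for case-insensitive symbol matching."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class Relation:
    label: str
    description: str
    directed: bool = False


class RelationVocabulary:
    """Ordered set of relation types; labels are unique keys.

    Order follows the source listing but carries no semantics.
    """

    def __init__(self, entries: Iterable[Relation]):
        self._entries: list[Relation] = list(entries)
        seen: set[str] = set()
        for e in self._entries:
            if not e.label:
                raise ContractError("relation label must be non-empty")
            if e.label in seen:
                raise ContractError(f"duplicate relation label {e.label!r}")
            seen.add(e.label)
        self._by_label = {e.label: e for e in self._entries}

    @property
    def entries(self) -> list[Relation]:
        return list(self._entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self._entries]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, label: str) -> Relation:
        return self._by_label[label]

    def resolve(self, label: str, t_means: Optional[str] = None) -> str:
        """Map a raw file label onto a vocabulary label.

        The ambiguous code ``T`` is accepted only when ``t_means`` names the
        intended layer (``"TL"`` or ``"TS"``).
        """
        if label in self._by_label:
            return label
        if label == "T" and t_means in ("TL", "TS") and t_means in self._by_label:
            return t_means
        raise KeyError(label)


#: The sixteen relation types of the curated cell-death knowledge base.
#: Binding-style relations are symmetric; causal ones keep a directed flag
#: as metadata only (all layers are stored undirected).
DEFAULT_VOCABULARY = RelationVocabulary(
    [
        Relation("PP", "Protein-protein binding", False),
        Relation("A", "Activation", True),
        Relation("E", "Expression (includes metabolism/synthesis)", True),
        Relation("RB", "Regulation of binding", True),
        Relation("P", "Phosphorylation", True),
        Relation("LO", "Localization", True),
        Relation("M", "Membership", False),
        Relation("MC", "Molecular cleavage", True),
        Relation("TL", "Translocation", True),
        Relation("I", "Inhibition", True),
        Relation("TS", "Transcription", True),
        Relation("MO", "Modification", True),
        Relation("PD", "Protein-DNA interactions", True),
        Relation("U", "Ubiquitination", True),
        Relation("PR", "Protein-RNA interactions", True),
        Relation("CP", "Chemical-protein interactions", True),
    ]
)


@dataclass
class GeneNode:
    """A gene with optional curation metadata.

    ``attributes`` carries opaque key/value pairs (e.g. gene-disease
    association scores DSI/DPI/EI/Score); they are never computed on.
    """

    symbol: str
    hallmark: bool = False
    modes: set[str] = field(default_factory=set)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ContractError("gene symbol must be non-empty")


@dataclass(frozen=True)
class TypedEdge:
    """One undirected typed interaction between two distinct genes."""

    a: str
    b: str
    relation: str
    weight: float = 1.0
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if canon(self.a) == canon(self.b):
            raise ContractError(f"self-loop {self.a!r} rejected")
        if self.weight < 0:
            raise ContractError(f"negative edge weight {self.weight}")

    def key(self) -> tuple[str, str]:
        """Unordered canonical endpoint pair."""
        ua, ub = canon(self.a), canon(self.b)
        return (ua, ub) if ua <= ub else (ub, ua)


class MultilayerNetwork:
    """Shared gene vocabulary plus one undirected edge layer per relation.

    Gene symbols are case-preserved but matched case-insensitively (a
    ``strict_case`` flag at construction disables the folding).  Edge
    endpoints are always registered as genes; duplicate edges within a layer
    collapse keeping the maximum weight.
    """

    def __init__(
        self,
        vocabulary: RelationVocabulary = DEFAULT_VOCABULARY,
        mode: Optional[str] = None,
        strict_case: bool = False,
    ):
        self.vocabulary = vocabulary
        self.mode = mode
        self.strict_case = strict_case
        self._genes: dict[str, GeneNode] = {}  # canonical symbol -> node
        self._layers: dict[str, dict[tuple[str, str], TypedEdge]] = {}

    # -- gene bookkeeping -------------------------------------------------
    def _key(self, symbol: str) -> str:
        return symbol.strip() if self.strict_case else canon(symbol)

    def add_gene(self, node: GeneNode | str) -> GeneNode:
        if isinstance(node, str):
            node = GeneNode(symbol=node.strip())
        k = self._key(node.symbol)
        existing = self._genes.get(k)
        if existing is None:
            self._genes[k] = node
            return node
        # merge metadata, keep first-seen display symbol
        existing.hallmark = existing.hallmark or node.hallmark
        existing.modes |= node.modes
        for a, v in node.attributes.items():
            existing.attributes.setdefault(a, v)
        return existing

    def has_gene(self, symbol: str) -> bool:
        return self._key(symbol) in self._genes

    def get_gene(self, symbol: str) -> GeneNode:
        return self._genes[self._key(symbol)]

    @property
    def genes(self) -> list[GeneNode]:
        """Gene nodes sorted by canonical symbol (stable, order-free)."""
        return [self._genes[k] for k in sorted(self._genes)]

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def n_genes(self) -> int:
        return len(self._genes)

    # -- edges ------------------------------------------------------------
    def add_edge(self, edge: TypedEdge) -> TypedEdge:
        if edge.relation not in self.vocabulary:
            raise ContractError(
                f"relation {edge.relation!r} not in vocabulary "
                f"({len(self.vocabulary)} labels)"
            )
        self.add_gene(edge.a)
        self.add_gene(edge.b)
        layer = self._layers.setdefault(edge.relation, {})
        k = edge.key() if not self.strict_case else tuple(sorted((edge.a, edge.b)))
        old = layer.get(k)
        if old is None or edge.weight > old.weight:
            layer[k] = edge
        return layer[k]

    @property
    def layers(self) -> dict[str, list[TypedEdge]]:
        """Label -> edges, both in deterministic sorted order."""
        return {
            lab: [self._layers[lab][k] for k in sorted(self._layers[lab])]
            for lab in sorted(self._layers)
        }

    def layer_labels(self) -> list[str]:
        return sorted(self._layers)

    def edges(self, relation: Optional[str] = None) -> Iterator[TypedEdge]:
        labels = [relation] if relation is not None else self.layer_labels()
        for lab in labels:
            for k in sorted(self._layers.get(lab, {})):
                yield self._layers[lab][k]

    def n_edges(self, relation: Optional[str] = None) -> int:
        if relation is not None:
            return len(self._layers.get(relation, {}))
        return sum(len(d) for d in self._layers.values())

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Distinct unordered endpoint pairs across all layers."""
        pairs: set[tuple[str, str]] = set()
        for d in self._layers.values():
            pairs.update(d.keys())
        return pairs

    def neighbors(self, symbol: str) -> set[str]:
        k = self._key(symbol)
        out: set[str] = set()
        for a, b in self.edge_pairs():
            if a == k:
                out.add(b)
            elif b == k:
                out.add(a)
        return out

    def induced_pairs(self, symbols: Iterable[str]) -> set[tuple[str, str]]:
        keys = {self._key(s) for s in symbols}
        return {p for p in self.edge_pairs() if p[0] in keys and p[1] in keys}


def census(net: MultilayerNetwork) -> tuple[int, dict[str, int]]:
    """(number of genes, edges per layer) — stable under round-trip I/O."""
    return net.n_genes(), {lab: net.n_edges(lab) for lab in net.layer_labels()}


# -- edge tables -----------------------------------------------------------

def read_edge_table(
    stream: TextIO | Iterable[str],
    vocabulary: RelationVocabulary = DEFAULT_VOCABULARY,
    strict: bool = True,
    t_means: Optional[str] = None,
    mode: Optional[str] = None,
    strict_case: bool = False,
) -> MultilayerNetwork:
    """Parse a tab-separated typed edge list into a multilayer network.

    Each non-comment line has ``gene_a<TAB>relation<TAB>gene_b`` plus
    optional ``weight`` and ``provenance`` columns.  Unknown relation labels
    and malformed lines raise :class:`FormatError` when ``strict`` (the
    default) or are skipped with a logged line number otherwise; self-loops
    are always rejected with a warning.
    """
    net = MultilayerNetwork(vocabulary=vocabulary, mode=mode, strict_case=strict_case)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            msg = f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            if strict:
                raise FormatError(msg)
            logger.warning("skipping %s", msg)
            continue
        a, rel_raw, b = (f.strip() for f in fields[:3])
        try:
            rel = vocabulary.resolve(rel_raw, t_means=t_means)
        except KeyError:
            msg = f"line {lineno}: unknown relation label {rel_raw!r}"
            if strict:
                raise FormatError(msg) from None
            logger.warning("skipping %s", msg)
            continue
        weight = 1.0
        if len(fields) >= 4 and fields[3].strip():
            try:
                weight = float(fields[3])
            except ValueError:
                msg = f"line {lineno}: malformed weight {fields[3]!r}"
                if strict:
                    raise FormatError(msg) from None
                logger.warning("skipping %s", msg)
                continue
        provenance = fields[4].strip() if len(fields) >= 5 and fields[4].strip() else None
        try:
            edge = TypedEdge(a=a, b=b, relation=rel, weight=weight, provenance=provenance)
        except ContractError as exc:
            logger.warning("line %d rejected: %s", lineno, exc)
            continue
        net.add_edge(edge)
    return net


def write_network(net: MultilayerNetwork, stream: TextIO) -> None:
    """Write the edge table so that ``read_edge_table`` round-trips it."""
    stream.write(f"# {TOOL_TAG}\tgene_a\trelation\tgene_b\tweight\tprovenance\n")
    for lab in net.layer_labels():
        for e in net.edges(lab):
            prov = e.provenance if e.provenance is not None else ""
            stream.write(f"{e.a}\t{e.relation}\t{e.b}\t{e.weight:g}\t{prov}\n")


# -- GMT gene sets ---------------------------------------------------------

class GeneSetCollection:
    """Named gene sets (pathways); no empty set, names unique."""

    def __init__(self, sets: Optional[Mapping[str, tuple[str, set[str]]]] = None):
        self._sets: dict[str, tuple[str, set[str]]] = {}
        if sets:
            for name, (desc, genes) in sets.items():
                self.add(name, desc, genes)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self._sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        gset = {g.strip() for g in genes if g.strip()}
        if not gset:
            raise ContractError(f"gene set {name!r} is empty")
        self._sets[name] = (description, gset)

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._sets))

    @property
    def names(self) -> list[str]:
        return sorted(self._sets)

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def genes(self, name: str) -> set[str]:
        return set(self._sets[name][1])

    def genes_canon(self, name: str) -> set[str]:
        return {canon(g) for g in self._sets[name][1]}


def read_gmt(stream: TextIO | Iterable[str]) -> GeneSetCollection:
    """Parse GMT lines: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    coll = GeneSetCollection()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: GMT line needs >=3 fields, got {len(fields)}")
        name, desc = fields[0].strip(), fields[1].strip()
        try:
            coll.add(name, desc, fields[2:])
        except (FormatError, ContractError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return coll


def write_gmt(coll: GeneSetCollection, stream: TextIO) -> None:
    for name in coll.names:
        genes = "\t".join(sorted(coll.genes(name)))
        stream.write(f"{name}\t{coll.description(name)}\t{genes}\n")


# -- node attributes -------------------------------------------------------

def read_node_attributes(
    stream: TextIO | Iterable[str], net: MultilayerNetwork
) -> MultilayerNetwork:
    """Attach a node-attribute table: symbol, hallmark {0,1}, modes, extras.

    Modes are semicolon-separated; any further ``key=value`` columns land in
    the node's opaque attribute map.  Unknown genes are added.
    """
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: node attribute line needs >=2 fields")
        symbol = fields[0].strip()
        if fields[1].strip() not in ("0", "1"):
            raise FormatError(f"line {lineno}: hallmark flag must be 0 or 1")
        hallmark = fields[1].strip() == "1"
        modes = set()
        if len(fields) >= 3 and fields[2].strip():
            modes = {m.strip() for m in fields[2].split(";") if m.strip()}
        attrs: dict[str, str] = {}
        for extra in fields[3:]:
            if "=" in extra:
                k, v = extra.split("=", 1)
                attrs[k.strip()] = v.strip()
        net.add_gene(GeneNode(symbol=symbol, hallmark=hallmark, modes=modes, attributes=attrs))
    return net


def write_node_attributes(net: MultilayerNetwork, stream: TextIO) -> None:
    stream.write(f"# {TOOL_TAG}\tsymbol\thallmark\tmodes\tattributes\n")
    for g in net.genes:
        modes = ";".join(sorted(g.modes))
        attrs = "\t".join(f"{k}={v}" for k, v in sorted(g.attributes.items()))
        row = f"{g.symbol}\t{int(g.hallmark)}\t{modes}"
        stream.write(row + ("\t" + attrs if attrs else "") + "\n")
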