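"""Subnetwork/pathway enrichment scoring and annotation.

The core statistic is the hypergeometric upper tail: out of N elements in
the reference biology-process network (gene pairs by default, genes
optionally), G belong to the focus subnetwork and s to a pathway; the
probability of seeing at least the observed overlap f is

    p = 1 - sum_{i=0}^{f-1} C(G, i) C(N-G, s-i) / C(N, s),

and the network score is -log10(p).  A pathway passes at score > 4
(p < 1e-4).  The tail is accumulated in log space from the smallest term
with compensated summation, so scores up to ~300 stay finite and accurate;
p is clamped to >= 1e-320.

``fisher_enrichment`` is the same quantity computed as a one-sided Fisher
exact test on the 2x2 table [[f, G-f], [s-f, N-G-s+f]] via scipy; the two
routes agree to ~1e-12 and cross-check each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma, log, log10
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ContractError
from .modules import ModulePartition
from .netio import GeneSetCollection, MultilayerNetwork, TypedEdge, canon

__all__ = [
    "EnrichmentInput",
    "EnrichmentRecord",
    "AnnotationMatrix",
    "network_score",
    "fisher_enrichment",
    "passes_threshold",
    "annotate_modules",
    "build_annotation_matrix",
    "compose_network",
    "report_top",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

P_FLOOR = 1e-320
DEFAULT_THRESHOLD = 4.0


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts feeding the hypergeometric tail.

    N: universe size; G: focus elements; s: pathway elements; f: focus
    elements in the pathway.  ``element_mode`` records whether elements are
    gene pairs (edges) or genes.
    """

    N: int
    G: int
    s: int
    f: int
    element_mode: str = "edges"

    def __post_init__(self) -> None:
        for name in ("N", "G", "s", "f"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ContractError(f"{name} must be a non-negative integer, got {v!r}")
        if self.G > self.N:
            raise ContractError(f"violated G <= N: G={self.G}, N={self.N}")
        if self.s > self.N:
            raise ContractError(f"violated s <= N: s={self.s}, N={self.N}")
        if self.f > min(self.G, self.s):
            raise ContractError(
                f"violated f <= min(G, s): f={self.f}, G={self.G}, s={self.s}"
            )
        if self.element_mode not in ("edges", "genes"):
            raise ContractError(f"unknown element_mode {self.element_mode!r}")


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def _hyper_upper_tail(N: int, G: int, s: int, f: int) -> float:
    """P(X >= f) for X ~ Hypergeometric(N, G, s), in plain probability.

    Summed as the upper tail directly (no 1 - lower-tail cancellation):
    log-space terms, exponentiated relative to the largest and accumulated
    smallest-first with Kahan compensation.
    """
    lo_support = max(0, G + s - N)
    hi_support = min(G, s)
    if f <= lo_support:
        return 1.0
    log_denom = _log_comb(N, s)
    logs = [
        _log_comb(G, i) + _log_comb(N - G, s - i) - log_denom
        for i in range(f, hi_support + 1)
    ]
    if not logs:
        return P_FLOOR
    m = max(logs)
    if m < log(P_FLOOR):
        return P_FLOOR
    # smallest terms first + Kahan compensation
    total = 0.0
    c = 0.0
    for lv in sorted(logs):
        y = np.exp(lv - m) - c
        t = total + y
        c = (t - total) - y
        total = t
    p = float(np.exp(m) * total) if m < 0 else float(total * np.exp(m))
    return min(max(p, P_FLOOR), 1.0)


def network_score(
    inp: Union[EnrichmentInput, int],
    G: Optional[int] = None,
    s: Optional[int] = None,
    f: Optional[int] = None,
) -> tuple[float, float]:
    """Hypergeometric upper-tail p-value and score = -log10(p).

    Accepts either an :class:`EnrichmentInput` or the four counts
    ``network_score(N, G, s, f)``.
    """
    if not isinstance(inp, EnrichmentInput):
        inp = EnrichmentInput(N=int(inp), G=int(G), s=int(s), f=int(f))
    p = _hyper_upper_tail(inp.N, inp.G, inp.s, inp.f)
    score = -log10(p) if p < 1.0 else 0.0
    return p, score


def fisher_enrichment(inp: EnrichmentInput) -> float:
    """One-sided (enrichment) Fisher exact p for the induced 2x2 table.

    Identical in value to :func:`network_score`'s p; kept as an independent
    computational route.
    """
    # f below the support floor max(0, G+s-N) cannot form a valid table;
    # observing at least that overlap is then certain, so clamp to the floor
    f = max(inp.f, inp.G + inp.s - inp.N)
    table = [[f, inp.G - f], [inp.s - f, inp.N - inp.G - inp.s + f]]
    return float(fisher_exact(table, alternative="greater")[1])


def passes_threshold(p_value: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Inclusion rule: score > threshold, evaluated as p < 10**-threshold.

    Comparing on the probability scale keeps the flip exact at the
    boundary (p = 1e-4 for the default threshold 4), where a round trip
    through log10 can lose the last bit.
    """
    return p_value < 10.0 ** (-threshold)


@dataclass
class EnrichmentRecord:
    """Scored (module, pathway) pair."""

    module: int
    pathway: str
    input: EnrichmentInput
    p_value: float
    score: float
    passed: bool
    q_value: Optional[float] = None


def _reference_pairs(reference: MultilayerNetwork) -> set[tuple[str, str]]:
    return reference.edge_pairs()


def annotate_modules(
    partition: ModulePartition,
    reference: MultilayerNetwork,
    genesets: GeneSetCollection,
    element_mode: str = "edges",
    threshold: float = DEFAULT_THRESHOLD,
    add_qvalues: bool = True,
) -> list[EnrichmentRecord]:
    """Score every (module, pathway) pair against the reference network.

    In ``edges`` mode the universe is the reference's distinct gene pairs:
    G counts module-internal reference edges, s pathway-induced reference
    edges and f their intersection.  In ``genes`` mode the analogous gene
    counts are used.  Pathways with no element in the universe yield a
    record with s=0 and p=1 (logged, never dropped).  Benjamini-Hochberg
    q-values are appended across all records as an advisory column.
    """
    if element_mode not in ("edges", "genes"):
        raise ContractError(f"unknown element_mode {element_mode!r}")
    universe_genes = {canon(g) for g in reference.gene_symbols}
    part_genes = {canon(g) for g in partition.universe()}
    if not part_genes <= universe_genes:
        missing = sorted(part_genes - universe_genes)
        raise ContractError(f"partition genes outside reference universe: {missing[:5]}")
    records: list[EnrichmentRecord] = []
    if element_mode == "edges":
        ref_pairs = _reference_pairs(reference)
        N = len(ref_pairs)
        pathway_pairs = {
            name: {
                p
                for p in ref_pairs
                if p[0] in genesets.genes_canon(name) and p[1] in genesets.genes_canon(name)
            }
            for name in genesets.names
        }
        for mod, members in sorted(partition.modules().items()):
            mem = {canon(g) for g in members}
            g_pairs = {p for p in ref_pairs if p[0] in mem and p[1] in mem}
            G = len(g_pairs)
            for name in genesets.names:
                s_pairs = pathway_pairs[name]
                s = len(s_pairs)
                f = len(g_pairs & s_pairs)
                inp = EnrichmentInput(N=N, G=G, s=s, f=f, element_mode="edges")
                p, score = network_score(inp)
                if s == 0:
                    logger.info("pathway %s induces no reference edges", name)
                records.append(
                    EnrichmentRecord(mod, name, inp, p, score, passes_threshold(p, threshold))
                )
    else:
        N = len(universe_genes)
        pathway_genes = {
            name: genesets.genes_canon(name) & universe_genes for name in genesets.names
        }
        for mod, members in sorted(partition.modules().items()):
            mem = {canon(g) for g in members}
            G = len(mem)
            for name in genesets.names:
                sset = pathway_genes[name]
                s = len(sset)
                f = len(mem & sset)
                inp = EnrichmentInput(N=N, G=G, s=s, f=f, element_mode="genes")
                p, score = network_score(inp)
                if s == 0:
                    logger.info("pathway %s has no gene in the universe", name)
                records.append(
                    EnrichmentRecord(mod, name, inp, p, score, passes_threshold(p, threshold))
                )
    if add_qvalues and records:
        pvals = [r.p_value for r in records]
        q = multipletests(pvals, method="fdr_bh")[1]
        for r, qv in zip(records, q):
            r.q_value = float(qv)
    return records


Element = Union[str, tuple[str, str]]


@dataclass
class AnnotationMatrix:
    """Binary element x term matrix: 1 is a positive match, 0 unknown.

    Rows are genes or gene pairs; a pair matches a term only when both
    endpoints do.  Row profiles are the objects compared downstream
    (e.g. Jaccard similarity between two modules' term profiles).
    """

    rows: list[Element]
    columns: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.rows), len(self.columns)):
            raise ContractError("annotation matrix shape mismatch")
        if not np.isin(self.data, (0, 1)).all():
            raise ContractError("annotation cells must be binary")

    def row_profile(self, element: Element) -> np.ndarray:
        return self.data[self.rows.index(element)]

    def profile_of_genes(self, genes: Iterable[str]) -> np.ndarray:
        """OR of the row profiles of the given genes (unknown genes ignored)."""
        keys = {canon(g) for g in genes}
        mask = [
            isinstance(r, str) and canon(r) in keys for r in self.rows
        ]
        if not any(mask):
            return np.zeros(len(self.columns), dtype=np.int8)
        return self.data[np.array(mask)].max(axis=0)

    def to_frame(self) -> pd.DataFrame:
        labels = [r if isinstance(r, str) else f"{r[0]}|{r[1]}" for r in self.rows]
        return pd.DataFrame(self.data, index=labels, columns=self.columns)


def build_annotation_matrix(
    elements: Sequence[Element],
    genesets: GeneSetCollection,
    mode_labels: Optional[dict[str, set[str]]] = None,
) -> AnnotationMatrix:
    """Binary membership of each element in each pathway / cell-death mode.

    ``mode_labels`` optionally appends mode-name columns (mode -> member
    genes).  A gene in no term yields an all-zero row (logged).
    """
    if len(elements) == 0:
        raise ContractError("no elements to annotate")
    terms: list[tuple[str, set[str]]] = [
        (name, genesets.genes_canon(name)) for name in genesets.names
    ]
    if mode_labels:
        terms += [
            (m, {canon(g) for g in gs}) for m, gs in sorted(mode_labels.items())
        ]
    data = np.zeros((len(elements), len(terms)), dtype=np.int8)
    for i, el in enumerate(elements):
        if isinstance(el, str):
            keys = [canon(el)]
        else:
            keys = [canon(el[0]), canon(el[1])]
        for j, (_, members) in enumerate(terms):
            if all(k in members for k in keys):
                data[i, j] = 1
        if not data[i].any():
            logger.info("element %r matches no term", el)
    return AnnotationMatrix(rows=list(elements), columns=[t[0] for t in terms], data=data)


def compose_network(
    records: Iterable[EnrichmentRecord],
    genesets: GeneSetCollection,
    reference: MultilayerNetwork,
) -> MultilayerNetwork:
    """Union of the reference-induced subgraphs of all passing pathways.

    Edges carry the contributing pathway names in their provenance field.
    Returns an empty composite with a warning when nothing passes.
    """
    passing = sorted({r.pathway for r in records if r.passed})
    composite = MultilayerNetwork(vocabulary=reference.vocabulary, mode=reference.mode)
    if not passing:
        logger.warning("no record passes the threshold; composite network is empty")
        return composite
    contributors: dict[tuple[str, str, str], set[str]] = {}
    for name in passing:
        members = genesets.genes_canon(name)
        for lab in reference.layer_labels():
            for e in reference.edges(lab):
                if canon(e.a) in members and canon(e.b) in members:
                    contributors.setdefault((lab,) + e.key(), set()).add(name)
    for lab in reference.layer_labels():
        for e in reference.edges(lab):
            key = (lab,) + e.key()
            if key in contributors:
                composite.add_edge(
                    TypedEdge(
                        a=e.a,
                        b=e.b,
                        relation=e.relation,
                        weight=e.weight,
                        provenance=";".join(sorted(contributors[key])),
                    )
                )
    return composite


def report_top(records: Iterable[EnrichmentRecord], top_k: int = 25) -> pd.DataFrame:
    """Top-k records by score (ties: smaller p, then pathway name)."""
    recs = sorted(records, key=lambda r: (-r.score, r.p_value, r.pathway, r.module))
    return records_to_frame(recs[:top_k])


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "module": r.module,
            "pathway": r.pathway,
            "N": r.input.N,
            "G": r.input.G,
            "s": r.input.s,
            "f": r.input.f,
            "p_value": r.p_value,
            "score": r.score,
            "q_value": r.q_value,
            "passed": r.passed,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "module",
            "pathway",
            "N",
            "G",
            "s",
            "f",
            "p_value",
            "score",
            "q_value",
            "passed",
        ],
    )
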