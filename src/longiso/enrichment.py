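"""Hypergeometric over-representation of gene sets against a GO annotation.

The most differentially spliced genes (or any query set) are tested term by
term: with N annotated background genes, K of them in a term, and a query of
n annotated genes containing k term members, the enrichment p-value is the
hypergeometric upper tail P(X >= k).  Benjamini-Hochberg controls the FDR
across tested terms.  The annotation is taken as given — no ontology-graph
propagation — so users wanting ancestor terms counted should pre-propagate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term_id -> gene set, with term names and the annotated background."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items() if g}
        if not self.background:
            for genes in self.terms.values():
                self.background |= genes
        for t, genes in self.terms.items():
            extra = genes - self.background
            if extra:
                raise ValueError(f"term {t}: genes outside background: {sorted(extra)[:5]}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query genes in term
    K: int  # background genes in term
    n: int  # annotated query size
    N: int  # background size
    p: float
    p_adj: float = 1.0


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read gene->term annotation from TSV (gene, term[, name]) or GAF 2.x.

    GAF is recognized by a ``!gaf-version`` header or a 15+ column layout;
    unparseable GAF lines are skipped with a logged count.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    skipped = 0
    n_rows = 0
    with path.open() as fh:
        lines = fh.readlines()
    is_gaf = any(l.startswith("!") for l in lines[:5])
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "!")):
            continue
        fields = line.split("\t")
        if is_gaf or len(fields) >= 15:
            if len(fields) < 15:
                skipped += 1
                continue
            gene, term = fields[1], fields[4]
        else:
            if len(fields) < 2:
                skipped += 1
                continue
            gene, term = fields[0], fields[1]
            if len(fields) >= 3 and fields[2]:
                names[term] = fields[2]
        if not gene or not term:
            skipped += 1
            continue
        terms.setdefault(term, set()).add(gene)
        n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: no annotation rows parsed")
    if skipped:
        logger.warning("%s: skipped %d unparseable line(s)", path, skipped)
    return AnnotationMap(terms=terms, names=names)


def write_annotation(annot: AnnotationMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(annot.terms):
            name = annot.names.get(term, "")
            for gene in sorted(annot.terms[term]):
                if name:
                    fh.write(f"{gene}\t{term}\t{name}\n")
                else:
                    fh.write(f"{gene}\t{term}\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term members among n genes drawn without replacement from a
    background of N genes of which K are in the term.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """Step-up FDR adjustment; returns p_adj in the input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        # guard the p_adj >= p contract against float rounding in p*m/rank
        adj[i] = max(running, pvals[i])
    return adj


def go_enrich(
    query: set[str] | list[str],
    annot: AnnotationMap,
    min_term_size: int = 3,
) -> list[EnrichmentResult]:
    """Term-by-term over-representation of a query gene set.

    Query genes outside the annotated background are dropped (logged); terms
    smaller than ``min_term_size`` are not tested.  Results are sorted by
    (p_adj, p, term_id).
    """
    qset = set(query)
    effective = qset & annot.background
    dropped = len(qset) - len(effective)
    if dropped:
        logger.warning("query: %d gene(s) outside annotated background dropped", dropped)
    if not effective:
        raise ValueError("no query genes in the annotated background")
    N = len(annot.background)
    n = len(effective)
    results = []
    for term, genes in annot.terms.items():
        if len(genes) < min_term_size:
            continue
        k = len(effective & genes)
        K = len(genes)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=annot.names.get(term, ""),
                k=k, K=K, n=n, N=N,
                p=hypergeom_upper(k, K, n, N),
            )
        )
    padj = benjamini_hochberg([r.p for r in results])
    for r, a in zip(results, padj):
        r.p_adj = a
    results.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return results
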