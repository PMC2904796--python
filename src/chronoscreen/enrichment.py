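"""Hypergeometric term enrichment of a gene list against a universe.

Given direct gene -> term annotations (no ontology-graph propagation; users
may pre-propagate if they want ancestors counted), each term's p-value is
the hypergeometric upper tail: the probability of drawing at least the
observed number of annotated genes when sampling the list's size without
replacement from the universe.  Bonferroni adjustment across the terms
tested; results report relative (in-list) versus background frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError, ParseError

__all__ = ["AnnotationMap", "hypergeom_tail", "enrich"]

log = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Forward (gene -> terms) and inverse (term -> genes) annotation index."""

    gene_to_terms: dict[str, set[str]]
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.term_to_genes:
            inv: dict[str, set[str]] = {}
            for g, terms in self.gene_to_terms.items():
                for t in terms:
                    inv.setdefault(t, set()).add(g)
            self.term_to_genes = inv
        if not self.universe:
            self.universe = set(self.gene_to_terms)
        missing = set(self.gene_to_terms) - self.universe
        if missing:
            raise InputError(f"annotated genes outside the universe: {sorted(missing)[:5]}")

    @classmethod
    def from_tsv(cls, path, universe=None) -> "AnnotationMap":
        """Two-column TSV gene<TAB>term, no header required ('gene'/'term' header allowed)."""
        table = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
        if table.iloc[0].tolist() == ["gene", "term"]:
            table = table.iloc[1:]
        if table.isna().any().any():
            raise ParseError("annotation TSV has missing fields")
        fwd: dict[str, set[str]] = {}
        for g, t in table.itertuples(index=False):
            fwd.setdefault(g, set()).add(t)
        return cls(gene_to_terms=fwd, universe=set(universe) if universe else set())

    def restrict(self, universe) -> "AnnotationMap":
        universe = set(universe)
        fwd = {g: t for g, t in self.gene_to_terms.items() if g in universe}
        return AnnotationMap(gene_to_terms=fwd, universe=universe)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    N = universe size, K = genes annotated to the term, n = list size,
    k = annotated genes in the list.  Evaluated through the survival
    function, which works in log space internally, so small tails are
    stable.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise InputError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(gene_list, annotation: AnnotationMap, alpha: float = 0.01) -> pd.DataFrame:
    """Term enrichment of ``gene_list`` against the annotation universe.

    One row per term with at least one gene in the list: counts, relative
    vs background frequency, raw p, Bonferroni-adjusted p over the terms
    tested, and a significance flag at ``adjusted_p < alpha``.  Genes not in
    the universe are logged and dropped.  Sorted by p.
    """
    genes = set(gene_list)
    if not genes:
        raise InputError("empty gene list")
    if not annotation.universe:
        raise InputError("empty annotation universe")
    outside = genes - annotation.universe
    if outside:
        log.warning("dropping %d gene(s) outside the universe: %s",
                    len(outside), sorted(outside)[:5])
        genes -= outside
    if not genes:
        raise InputError("no genes from the list are in the universe")
    N = len(annotation.universe)
    n = len(genes)
    rows = []
    for term, annotated in annotation.term_to_genes.items():
        k = len(annotated & genes)
        if k < 1:
            continue
        K = len(annotated)
        rows.append(
            {
                "term": term,
                "sample_count": k,
                "sample_size": n,
                "background_count": K,
                "universe_size": N,
                "relative_frequency": k / n,
                "background_frequency": K / N,
                "p_value": hypergeom_tail(N, K, n, k),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "sample_count", "sample_size", "background_count",
                     "universe_size", "relative_frequency", "background_frequency",
                     "p_value", "adjusted_p", "significant"]
        ).set_index("term")
    out = pd.DataFrame(rows)
    out["adjusted_p"] = (out["p_value"] * len(out)).clip(upper=1.0)
    out["significant"] = out["adjusted_p"] < alpha
    return out.sort_values(["p_value", "term"], ignore_index=True).set_index("term")
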