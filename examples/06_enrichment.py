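"""Hypergeometric term enrichment of a hit list.

Given direct gene -> term annotations, each term's p-value is the chance of
seeing at least the observed number of annotated genes in a random sample
of the hit list's size drawn from the universe without replacement.
"""

from chronoscreen import AnnotationMap, enrich

# toy annotation: 200-gene universe, one term covering 30 genes
genes = [f"gene{i:03d}" for i in range(200)]
annotation = AnnotationMap(
    gene_to_terms={g: ({"mitochondrion"} if i < 30 else {"other"})
                   for i, g in enumerate(genes)},
)

# a 40-gene hit list that contains 18 of the 30 mitochondrial genes
hits = genes[:18] + genes[150:172]
results = enrich(hits, annotation, alpha=0.01)

for term, row in results.iterrows():
    print(f"{term:14s} {row.sample_count:2d}/{row.sample_size} in list vs "
          f"{row.background_count}/{row.universe_size} in universe "
          f"({100 * row.relative_frequency:.1f}% vs {100 * row.background_frequency:.1f}%), "
          f"p = {row.p_value:.2e}, adjusted p = {row.adjusted_p:.2e}"
          f"{'  *significant*' if row.significant else ''}")
# The relative-vs-background frequency pair is the standard way such hits
# are reported; Bonferroni adjustment runs over the terms actually tested.
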