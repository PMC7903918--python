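"""Heptamer enrichment landscape over a ranked gene list.

Emulates the genome-wide word-enrichment view of a knockout transcriptome:
genes are ranked from most up- to most downregulated, and for every
heptamer the hypergeometric enrichment in cumulative leading bins is
scored.  A miRNA's seed complement peaking on the left means its targets
are concentrated among the upregulated (derepressed) genes.
"""

from corenet import (
    bonferroni_line,
    build_universe,
    gen_ranked_list,
    landscape,
    top_heptamers,
)

seed_word = "GTGCCAA"  # the miR-96 seed complement
ranked, utrs = gen_ranked_list(200, seed_word, top_fraction=0.1, seed=8,
                               plant_prob=1.0, copies=3)
universe = build_universe([g for g, _ in ranked], utrs)
cells = landscape(universe, bin_step=25)

best = top_heptamers(cells, k=3, annotate=[seed_word])
peak = max(c.signed_score for c in cells if c.heptamer == seed_word)
print(f"universe: {len(universe.genes)} genes, {universe.total_words} words")
print(f"top heptamers: {best}")
print(f"peak signed score of {seed_word}: {peak:.1f} "
      f"(Bonferroni guide line: {bonferroni_line():.1f})")
# A signed score above the guide line marks enrichment stronger than
# expected for any of the 4^7 heptamers at alpha = 0.05.
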