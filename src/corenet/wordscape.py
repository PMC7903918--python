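"""Hypergeometric word-enrichment landscapes over ranked gene lists.

Given a gene list ranked from most upregulated to most downregulated and
the genes' 3'UTR sequences, this module computes, for every heptamer and
every cumulative leading bin of the ranking, the hypergeometric
significance of the word's enrichment or depletion in the bin relative to
the whole UTR word universe.  The signed score is -log10(p_enrich) when
enrichment is the smaller tail and +log10(p_deplete) otherwise, so
positive peaks mean enrichment among upregulated genes.

The universe is defined over word positions (tokens): a UTR of length L
contributes max(0, L-6) overlapping 7-mer windows.  Composition-bias
correction and word purging (as in dedicated word-landscape tools) are
deliberately not applied; raw hypergeometric p-values are reported and a
Bonferroni guide line over all 4^7 heptamers serves as annotation only.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import hypergeom

from .seedscan import DEFAULT_HEADER_REGEX, _gene_of

logger = logging.getLogger(__name__)


@dataclass
class RankedUniverse:
    """Ranked genes plus their UTR word content.

    ``genes`` is ordered most-upregulated first; ``gene_words[i]`` is the
    word multiset (Counter) of the i-th gene's UTRs; ``total_words`` is N,
    the token universe size; ``word_totals[w]`` is K_w.
    """

    genes: list[str]
    gene_words: list[Counter]
    total_words: int
    word_totals: Counter
    word_len: int = 7


@dataclass
class LandscapeCell:
    """Enrichment of one heptamer in one cumulative leading bin."""

    heptamer: str
    bin_genes: int      # genes in the leading bin
    n: int              # words in the leading bin
    x: int              # occurrences of the heptamer in the bin
    K: int              # occurrences in the whole universe
    p_enrich: float     # P[X >= x] under Hypergeometric(N, K, n)
    p_deplete: float    # P[X <= x]
    signed_score: float


def words_of(seq: str, word_len: int = 7) -> Iterable[str]:
    """Overlapping windows of ``seq``; windows containing non-ACGT are skipped."""
    seq = seq.upper()
    valid = set("ACGT")
    for i in range(len(seq) - word_len + 1):
        w = seq[i : i + word_len]
        if set(w) <= valid:
            yield w


def build_universe(
    ranked_genes: Sequence[str],
    utrs: str | Path | Mapping[str, Sequence[str]] | Iterable,
    word_len: int = 7,
    header_regex=DEFAULT_HEADER_REGEX,
) -> RankedUniverse:
    """Assemble the ranked word universe from a gene ranking and UTR set.

    ``utrs`` may be a FASTA path, an iterable of SeqRecord, or a mapping
    gene -> list of UTR sequences.  Several UTR records per gene are
    pooled.  Ranked genes without any UTR are dropped with a warning;
    an empty overlap between ranking and UTR set is fatal.  Duplicate
    gene IDs in the ranking are rejected.
    """
    if len(set(ranked_genes)) != len(ranked_genes):
        raise ValueError("ranking contains duplicate gene IDs")

    if isinstance(utrs, Mapping):
        seqs = {g: list(v) for g, v in utrs.items()}
    else:
        records = (
            SeqIO.parse(str(utrs), "fasta") if isinstance(utrs, (str, Path)) else utrs
        )
        seqs = {}
        for rec in records:
            seqs.setdefault(_gene_of(rec.id, header_regex), []).append(str(rec.seq))

    genes, gene_words = [], []
    dropped = 0
    for gene in ranked_genes:
        if gene not in seqs:
            dropped += 1
            continue
        counter = Counter()
        for seq in seqs[gene]:
            counter.update(words_of(seq, word_len))
        genes.append(gene)
        gene_words.append(counter)
    if dropped:
        logger.warning("%d ranked genes had no UTR sequence and were dropped", dropped)
    if not genes:
        raise ValueError("no overlap between the ranking and the UTR set")

    word_totals = Counter()
    for counter in gene_words:
        word_totals.update(counter)
    total = sum(word_totals.values())
    return RankedUniverse(genes, gene_words, total, word_totals, word_len)


def landscape(universe: RankedUniverse, bin_step: int = 500) -> list[LandscapeCell]:
    """Hypergeometric enrichment/depletion cells for every present heptamer.

    Bins are cumulative leading prefixes of the ranking at gene counts
    bin_step, 2*bin_step, ... up to the full universe (always included as
    the final bin, where every signed score is exactly 0).  Heptamers
    absent from the universe (K_w = 0) are omitted: their p_enrich is 1
    and signed score 0 in every bin.
    """
    if bin_step < 1:
        raise ValueError("bin_step must be >= 1")
    n_genes = len(universe.genes)
    if bin_step > n_genes:
        logger.warning(
            "bin_step %d exceeds the %d-gene universe; single full bin used",
            bin_step, n_genes,
        )
    boundaries = list(range(bin_step, n_genes, bin_step)) + [n_genes]

    words = sorted(universe.word_totals)
    index = {w: i for i, w in enumerate(words)}
    K = np.array([universe.word_totals[w] for w in words], dtype=np.int64)
    N = universe.total_words

    cells: list[LandscapeCell] = []
    x = np.zeros(len(words), dtype=np.int64)
    n = 0
    gene_idx = 0
    for boundary in boundaries:
        while gene_idx < boundary:
            for w, c in universe.gene_words[gene_idx].items():
                x[index[w]] += c
            n += universe.gene_words[gene_idx].total()
            gene_idx += 1
        p_enrich = hypergeom.sf(x - 1, N, K, n)
        p_deplete = hypergeom.cdf(x, N, K, n)
        # clip: sf/cdf can round to tiny negatives or >1 at extreme tails
        p_enrich = np.clip(p_enrich, np.finfo(float).tiny, 1.0)
        p_deplete = np.clip(p_deplete, np.finfo(float).tiny, 1.0)
        enriched = p_enrich <= p_deplete
        signed = np.where(enriched, -np.log10(p_enrich), np.log10(p_deplete))
        if boundary == n_genes:
            signed = np.zeros_like(signed)  # full bin: x == K_w exactly
        for i, w in enumerate(words):
            cells.append(
                LandscapeCell(
                    heptamer=w,
                    bin_genes=boundary,
                    n=n,
                    x=int(x[i]),
                    K=int(K[i]),
                    p_enrich=float(p_enrich[i]),
                    p_deplete=float(p_deplete[i]),
                    signed_score=float(signed[i]),
                )
            )
    return cells


def top_heptamers(
    cells: Iterable[LandscapeCell],
    k: int = 3,
    annotate: Iterable[str] = (),
) -> list[str]:
    """The k heptamers with the highest peaks, the k with the lowest
    troughs, and any annotated (e.g. seed-complement) heptamers.

    Order: top peaks (descending), bottom troughs (ascending), annotations;
    duplicates removed keeping first occurrence.
    """
    peaks: dict[str, float] = {}
    troughs: dict[str, float] = {}
    for cell in cells:
        peaks[cell.heptamer] = max(peaks.get(cell.heptamer, -np.inf), cell.signed_score)
        troughs[cell.heptamer] = min(
            troughs.get(cell.heptamer, np.inf), cell.signed_score
        )
    best = sorted(peaks, key=lambda w: (-peaks[w], w))[: max(k, 0)]
    worst = sorted(troughs, key=lambda w: (troughs[w], w))[: max(k, 0)]
    out: list[str] = []
    for w in [*best, *worst, *annotate]:
        if w not in out:
            out.append(w)
    return out


def bonferroni_line(alpha: float = 0.05, word_len: int = 7) -> float:
    """-log10 of the Bonferroni-corrected threshold over all 4^word_len words.

    Drawn as an annotation only; the landscape reports raw p-values.
    """
    return float(-np.log10(alpha / 4**word_len))


def landscape_frame(cells: Iterable[LandscapeCell]) -> pd.DataFrame:
    """Long-format table (heptamer, bin, x, n, signed_score) for plotting/TSV."""
    return pd.DataFrame(
        [
            {
                "heptamer": c.heptamer,
                "bin_genes": c.bin_genes,
                "x": c.x,
                "n": c.n,
                "K": c.K,
                "p_enrich": c.p_enrich,
                "p_deplete": c.p_deplete,
                "signed_score": c.signed_score,
            }
            for c in cells
        ]
    )
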