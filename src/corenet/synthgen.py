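"""Deterministic, seeded generators for every input class the toolkit reads.

Three generators cover the pipeline end to end without any downloads:
signed regulatory cascades with planted node directions (for the
propagation stages), random UTR sets with optionally planted heptamers
(for seed scanning), and ranked gene lists with bin-concentrated word
enrichment (for the landscape).  Each generator draws from its own named
pseudo-random stream derived from a single integer seed, so adding a
generator never perturbs existing fixtures, and identical seeds give
byte-identical output.

The planted cascade grows a spanning tree from the root and assigns true
directions top-down through the signed edges (knockout convention: the
root is "down"), then adds extra cross-edges only where they are
consistent with the planted directions.  Noise-free observation of every
leaf therefore lets propagation provably recover every internal direction
with zero links pruned, which makes parameter-recovery checks sharp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iodb import Interaction, MisregulationTable

logger = logging.getLogger(__name__)

# Fixed per-generator stream tags (kept < 2**31); combined with the user
# seed so each generator has an independent reproducible stream.
_STREAM = {"cascade": 101, "utrs": 202, "ranked": 303}


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], int(seed) % 2**31])


@dataclass
class CascadeSpec:
    """Parameters of a planted signed regulatory cascade.

    ``sign_probs`` gives the probabilities of edge signs (+1, -1, 0).
    Unsigned edges are off by default: they can never be consistent with
    any direction assignment, so they only serve as decoys.  ``noise`` is
    the probability that an observed leaf direction is flipped;
    ``fraction_observed`` is the fraction of leaves exported as observed.
    """

    n_nodes: int = 200
    depth: int = 6
    p_cross: float = 0.15
    sign_probs: tuple[float, float, float] = (0.5, 0.5, 0.0)
    fraction_observed: float = 1.0
    noise: float = 0.0
    seed: int = 0
    root: str = "RootReg"

    def __post_init__(self) -> None:
        if abs(sum(self.sign_probs) - 1.0) > 1e-9 or min(self.sign_probs) < 0:
            raise ValueError("sign_probs must be non-negative and sum to 1")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")
        if not 0.0 <= self.fraction_observed <= 1.0:
            raise ValueError("fraction_observed must be in [0, 1]")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.depth < 1 or self.depth > self.n_nodes:
            raise ValueError("need 1 <= depth <= n_nodes")


@dataclass
class Cascade:
    """A generated cascade: edges, planted truth, and the observed table."""

    interactions: list[Interaction]
    truth: dict[str, int]            # planted direction per node (root included)
    observed: MisregulationTable     # exported (possibly noisy) leaf directions
    root: str
    leaves: list[str] = field(default_factory=list)

    def internal_nodes(self) -> list[str]:
        exported = set(self.observed.directions)
        return [
            g for g in self.truth
            if g != self.root and g not in exported
        ]


def gen_cascade(spec: CascadeSpec) -> Cascade:
    """Generate a rooted signed digraph with planted node directions.

    True directions flow top-down from the root (knockout: root = -1)
    through a random spanning tree, d(child) = d(parent) * sign(edge);
    cross-edges are added between level-ordered pairs with probability
    ``p_cross`` per node, signed so that they are consistent with the
    planted directions (or unsigned, per ``sign_probs[2]``).  Leaves are
    exported as observed with probability ``fraction_observed``, flipped
    with probability ``noise``.
    """
    rng = _rng("cascade", spec.seed)
    root = spec.root
    truth = {root: -1}
    if spec.n_nodes == 1:
        logger.warning("n_nodes=1: root-only cascade, empty misregulation table")
        return Cascade([], truth, MisregulationTable(), root, leaves=[])

    names = [f"G{i:04d}" for i in range(1, spec.n_nodes)]
    level = {root: 0}
    parentable = [root]  # nodes with level < depth
    interactions: list[Interaction] = []
    children: dict[str, list[str]] = {root: []}

    p_plus, p_minus, p_zero = spec.sign_probs
    p_signed = p_plus + p_minus
    if p_signed <= 0:
        raise ValueError("tree edges need non-zero probability of a signed edge")

    for node in names:
        parent = parentable[rng.integers(len(parentable))]
        # tree edges must be signed so truth propagates
        sign = +1 if rng.random() < p_plus / p_signed else -1
        truth[node] = truth[parent] * sign
        interactions.append(Interaction(parent, sign, node, "synthetic-tree"))
        children[parent].append(node)
        children[node] = []
        level[node] = level[parent] + 1
        if level[node] < spec.depth:
            parentable.append(node)

    # consistent cross-edges between level-ordered pairs (keeps the graph acyclic)
    nodes = [root] + names
    for v in names:
        if rng.random() >= spec.p_cross:
            continue
        shallower = [u for u in nodes if level[u] < level[v] and v not in children[u]]
        if not shallower:
            continue
        u = shallower[rng.integers(len(shallower))]
        if p_zero > 0 and rng.random() < p_zero:
            interactions.append(Interaction(u, 0, v, "synthetic-unsigned"))
        else:
            sign = truth[u] * truth[v]  # d(u) * sign == d(v) by construction
            interactions.append(Interaction(u, sign, v, "synthetic-cross"))
        children[u].append(v)

    leaves = sorted(n for n in names if not children[n])
    observed = MisregulationTable()
    for leaf in leaves:
        if rng.random() <= spec.fraction_observed and (
            spec.fraction_observed > 0.0
        ):
            d = truth[leaf]
            if rng.random() < spec.noise:
                d = -d
            observed.directions[leaf] = d
    return Cascade(interactions, truth, observed, root, leaves=leaves)


def gen_utr_set(
    n_genes: int,
    length_range: tuple[int, int] = (50, 300),
    planted: str | None = None,
    planted_genes: Sequence[str] = (),
    seed: int = 0,
    gene_prefix: str = "G",
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Uniform-random DNA UTRs with an optional planted heptamer.

    The planted word overwrites a random window of each planted gene's
    UTR; insertion positions are returned so expected minimum counts are
    known.  Gene IDs are ``<prefix>0001 ...``; unknown planted genes are
    an error.
    """
    rng = _rng("utrs", seed)
    lo, hi = length_range
    if planted is not None and len(planted) != 7:
        raise ValueError("planted heptamer must have length 7")
    if planted is not None and lo < 7:
        raise ValueError("length_range minimum must be >= 7 when planting")
    genes = [f"{gene_prefix}{i:04d}" for i in range(1, n_genes + 1)]
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the generated set: {sorted(unknown)}")

    records, positions = [], {}
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if planted is not None and gene in set(planted_genes):
            pos = int(rng.integers(0, length - 7 + 1))
            seq = seq[:pos] + planted + seq[pos + 7 :]
            positions[gene] = pos
        records.append(SeqRecord(Seq(seq), id=gene, description=""))
    return records, positions


def gen_ranked_list(
    n_genes: int,
    enriched_heptamer: str,
    top_fraction: float,
    seed: int = 0,
    utr_length: int = 120,
    plant_prob: float = 0.9,
    copies: int = 2,
) -> tuple[list[tuple[str, float]], list[SeqRecord]]:
    """Ranked gene list with a heptamer planted in the leading fraction.

    Genes are ranked by a decreasing synthetic statistic (most upregulated
    first).  Each gene in the top ``top_fraction`` of the ranking receives
    ``copies`` non-overlapping insertions of the heptamer with probability
    ``plant_prob``; the rest carry background sequence only.  With
    ``top_fraction=1.0`` the planting is uniform along the ranking, so no
    positional enrichment exists.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(enriched_heptamer) != 7:
        raise ValueError("enriched heptamer must have length 7")
    rng = _rng("ranked", seed)
    genes = [f"R{i:04d}" for i in range(1, n_genes + 1)]
    stats = np.sort(rng.normal(size=n_genes))[::-1]
    ranked = list(zip(genes, (float(s) for s in stats)))

    n_top = max(1, int(round(top_fraction * n_genes)))
    records = []
    for idx, gene in enumerate(genes):
        seq = "".join(rng.choice(list("ACGT"), size=utr_length))
        if idx < n_top and rng.random() < plant_prob:
            # non-overlapping slots keep every planted copy countable
            slots = utr_length // 7
            chosen = rng.choice(slots, size=min(copies, slots), replace=False)
            for slot in chosen:
                pos = int(slot) * 7
                seq = seq[:pos] + enriched_heptamer + seq[pos + 7 :]
        records.append(SeqRecord(Seq(seq), id=gene, description=""))
    return ranked, records


def write_fasta(records: Sequence[SeqRecord], path: str | Path) -> None:
    """Write records as plain FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def write_ranked_tsv(ranked: Sequence[tuple[str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, stat in ranked:
            fh.write(f"{gene}\t{stat}\n")
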