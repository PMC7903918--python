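"""miRNA seed-complement derivation and 3'UTR seed-match scanning.

A mature miRNA recognises targets chiefly through its seed region, bases
2-8 of the mature sequence.  A "seed match" in a 3'UTR is the reverse
complement of that heptamer in DNA alphabet (for miR-96 the seed GCUUUAU...
bases 2-8 yield the printed complement GTGCCAA).  Matching here is exact
heptamer matching with overlapping windows; no thermodynamic or
3'-supplementary pairing model is applied.

UTR FASTA headers are parsed as ``>geneID[|transcriptID]`` by default; the
dialect is configurable by regex.  Counts for genes with several UTR
isoforms are summed over all records sharing the gene ID, with the
per-record breakdown retained.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

#: Strain-comparison categories (a partition of the shared-ID gene universe).
CATEGORIES = (
    "same_count",
    "both_present_different_count",
    "only_in_A",
    "only_in_B",
    "absent_in_both",
    "missing_utr_A",
    "missing_utr_B",
    "missing_utr_both",
)

DEFAULT_HEADER_REGEX = re.compile(r"^(?P<gene>[^|\s]+)(?:\|(?P<transcript>\S+))?")


@dataclass(frozen=True)
class SeedComplement:
    """A 7-mer DNA word complementary to one miRNA's seed region."""

    mirna: str
    heptamer: str

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7 or set(self.heptamer) - set("ACGT"):
            raise ValueError(
                f"seed complement must be a 7-mer over ACGT, got {self.heptamer!r}"
            )


@dataclass
class SeedMatchProfile:
    """Per-gene, per-strain seed-match counts.

    ``counts[strain][heptamer]`` is only meaningful where
    ``utr_available[strain]`` is true.
    """

    gene: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    utr_available: dict[str, bool] = field(default_factory=dict)


def seed_complement(
    mature_sequence: str,
    seed_start: int = 2,
    seed_len: int = 7,
    name: str = "",
) -> SeedComplement:
    """Reverse complement (DNA alphabet) of the miRNA seed region.

    ``seed_start``/``seed_len`` are 1-based inclusive coordinates on the
    mature sequence; the default bases 2-8 are the canonical seed.  The
    input is RNA or DNA (U and T both accepted, case-insensitive).
    """
    seq = mature_sequence.strip().upper()
    if set(seq) - set("ACGU" + "T"):
        raise ValueError(f"invalid character in mature sequence {mature_sequence!r}")
    if len(seq) < seed_start - 1 + seed_len:
        raise ValueError(
            f"mature sequence of length {len(seq)} too short for seed "
            f"{seed_start}..{seed_start + seed_len - 1}"
        )
    seed = seq[seed_start - 1 : seed_start - 1 + seed_len].replace("U", "T")
    heptamer = str(Seq(seed).reverse_complement())
    return SeedComplement(mirna=name, heptamer=heptamer)


def count_matches(utr: str, heptamer: SeedComplement | str) -> int:
    """Count overlapping occurrences of a seed-complement heptamer in a UTR.

    Case-insensitive sliding-window scan; ``N`` never matches; a UTR
    shorter than the word returns 0.
    """
    word = heptamer.heptamer if isinstance(heptamer, SeedComplement) else heptamer.upper()
    utr = utr.upper()
    k = len(word)
    return sum(1 for i in range(len(utr) - k + 1) if utr[i : i + k] == word)


def _gene_of(header: str, header_regex: re.Pattern) -> str:
    m = header_regex.match(header)
    if not m:
        raise ValueError(f"FASTA header {header!r} does not match the gene-ID dialect")
    return m.group("gene")


def scan_fasta(
    utr_fasta: str | Path | Iterable,
    heptamers: Iterable[SeedComplement],
    header_regex: re.Pattern = DEFAULT_HEADER_REGEX,
) -> tuple[dict[str, dict[str, int]], list[tuple[str, str, str, int]]]:
    """Scan every UTR record for every seed complement.

    Accepts a FASTA path or an iterable of ``SeqRecord``.  Returns
    ``(per_mirna, breakdown)`` where ``per_mirna[mirna][gene]`` sums match
    counts over all records of that gene, and ``breakdown`` lists
    ``(mirna, gene, record_id, count)`` per record.
    """
    heptamers = list(heptamers)
    records = (
        SeqIO.parse(str(utr_fasta), "fasta")
        if isinstance(utr_fasta, (str, Path))
        else utr_fasta
    )
    per_mirna: dict[str, dict[str, int]] = {h.mirna: defaultdict(int) for h in heptamers}
    breakdown = []
    for rec in records:
        gene = _gene_of(rec.id, header_regex)
        seq = str(rec.seq)
        for h in heptamers:
            n = count_matches(seq, h)
            per_mirna[h.mirna][gene] += n
            breakdown.append((h.mirna, gene, rec.id, n))
    return {m: dict(c) for m, c in per_mirna.items()}, breakdown


def classify_counts(
    count_a: int | None,
    count_b: int | None,
    avail_a: bool = True,
    avail_b: bool = True,
) -> str:
    """Classify one gene's seed-match counts in two strains.

    Returns exactly one of :data:`CATEGORIES`.  Missing-UTR states take
    precedence (counts are undefined there).
    """
    if not avail_a and not avail_b:
        return "missing_utr_both"
    if not avail_a:
        return "missing_utr_A"
    if not avail_b:
        return "missing_utr_B"
    a, b = int(count_a or 0), int(count_b or 0)
    if a == 0 and b == 0:
        return "absent_in_both"
    if a == b:
        return "same_count"
    if a > 0 and b > 0:
        return "both_present_different_count"
    return "only_in_B" if a == 0 else "only_in_A"


def compare_strains(
    profile: SeedMatchProfile, strain_a: str, strain_b: str, heptamer: str | None = None
) -> str:
    """Classify one gene's profile between two strains (one heptamer or total)."""
    avail_a = profile.utr_available.get(strain_a, False)
    avail_b = profile.utr_available.get(strain_b, False)

    def total(strain: str) -> int:
        counts = profile.counts.get(strain, {})
        if heptamer is not None:
            return counts.get(heptamer, 0)
        return sum(counts.values())

    return classify_counts(
        total(strain_a) if avail_a else None,
        total(strain_b) if avail_b else None,
        avail_a,
        avail_b,
    )


def compare_strain_sets(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    shared_ids: Iterable[str] | None = None,
) -> tuple[dict[str, str], dict[str, int]]:
    """Compare per-gene seed-match counts between two strains' UTR sets.

    A gene absent from a strain's count table is treated as having no UTR
    sequence available for that strain.  ``shared_ids`` restricts the
    universe to genes with a shared (MGI-style) identifier — genes without
    one cannot be matched across strains and are excluded up front.
    Returns ``(per_gene_category, category_totals)``; the categories
    partition the universe.
    """
    if shared_ids is None:
        universe = set(counts_a) | set(counts_b)
    else:
        universe = set(shared_ids)
    per_gene = {}
    totals = dict.fromkeys(CATEGORIES, 0)
    for gene in sorted(universe):
        avail_a, avail_b = gene in counts_a, gene in counts_b
        cat = classify_counts(
            counts_a.get(gene), counts_b.get(gene), avail_a, avail_b
        )
        per_gene[gene] = cat
        totals[cat] += 1
    return per_gene, totals
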