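"""Reading, normalising and merging regulatory-interaction tables.

The toolkit consumes pre-flattened TSV exports of curated interaction
databases (one row per regulation: source gene, interaction word, target
gene, optional evidence tag).  This module turns those rows into signed
:class:`Interaction` records, deduplicates them, restricts them by
evidence class, converts identifiers across species through one-to-one
orthologue maps, and derives miRNA->target repression edges from seed
matches found in 3'UTRs.

Gene identifiers are compared case-sensitively after whitespace trimming:
the public databases mix symbol conventions and silent case-folding risks
merging distinct genes.  A casing-normalisation hook can be supplied where
a single convention is known to apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Default interaction-word vocabulary (matched case-insensitively).
#: Unknown words map to sign 0 ("regulates", direction unknown) with a warning.
DEFAULT_SIGN_VOCAB: dict[str, int] = {
    "activates": +1,
    "upregulates": +1,
    "represses": -1,
    "inhibits": -1,
    "downregulates": -1,
    "regulates": 0,
}

SIGN_WORD = {+1: "activates", -1: "represses", 0: "regulates"}


@dataclass(frozen=True)
class Interaction:
    """One signed, directed regulatory link with evidence provenance.

    ``sign`` is +1 (activation), -1 (repression) or 0 (direction unknown).
    Identity for deduplication is the triple ``(source, sign, target)``;
    evidence tags of collapsed duplicates are ";"-joined.
    """

    source: str
    sign: int
    target: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("interaction endpoints must be non-empty")
        if self.sign not in (-1, 0, +1):
            raise ValueError(f"sign must be -1, 0 or +1, got {self.sign!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.source, self.sign, self.target)


@dataclass
class OrthologueMap:
    """Foreign gene ID -> set of native gene IDs.

    A lookup resolving to exactly one native ID is "one-to-one"; lookups
    with zero or several native IDs are ambiguous and cause the interaction
    touching them to be dropped.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologueMap":
        """Read a two-column TSV (foreign_id, native_id), one row per pair."""
        entries: dict[str, set[str]] = {}
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for foreign, native in zip(df[0], df[1]):
            if pd.isna(foreign) or pd.isna(native):
                continue
            entries.setdefault(foreign.strip(), set()).add(native.strip())
        return cls(entries)

    def one_to_one(self, gene: str) -> str | None:
        """Return the unique native ID for ``gene``, or None if not 1:1."""
        hits = self.entries.get(gene)
        if hits is not None and len(hits) == 1:
            return next(iter(hits))
        return None


@dataclass
class MisregulationTable:
    """Observed misregulation directions (+1 up, -1 down) per gene.

    Optional log-fold-change and FDR are carried for reporting; the
    propagation algebra uses only the sign.
    """

    directions: dict[str, int] = field(default_factory=dict)
    logfc: dict[str, float] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, d in self.directions.items():
            if d not in (-1, +1):
                raise ValueError(f"direction for {gene} must be +1 or -1, got {d!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MisregulationTable":
        """Read a misregulation TSV: gene, direction[up|down|+1|-1][, logFC[, FDR]]."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        tab = cls()
        for row in df.itertuples(index=False):
            gene = str(row[0]).strip()
            tab.directions[gene] = _parse_direction(str(row[1]).strip())
            if len(row) > 2 and not pd.isna(row[2]):
                tab.logfc[gene] = float(row[2])
            if len(row) > 3 and not pd.isna(row[3]):
                tab.fdr[gene] = float(row[3])
        return tab

    def genes(self) -> set[str]:
        return set(self.directions)

    def upregulated(self) -> set[str]:
        return {g for g, d in self.directions.items() if d == +1}

    def subset(self, genes: Iterable[str]) -> "MisregulationTable":
        keep = set(genes)
        return MisregulationTable(
            directions={g: d for g, d in self.directions.items() if g in keep},
            logfc={g: v for g, v in self.logfc.items() if g in keep},
            fdr={g: v for g, v in self.fdr.items() if g in keep},
        )


def _parse_direction(token: str) -> int:
    t = token.lower()
    if t in ("up", "+1", "1", "+"):
        return +1
    if t in ("down", "-1", "-"):
        return -1
    raise ValueError(f"cannot parse misregulation direction {token!r}")


def load_interactions(
    path: str | Path,
    vocab: Mapping[str, int] | None = None,
    normalise: Callable[[str], str] | None = None,
    stats: dict | None = None,
) -> list[Interaction]:
    """Load and deduplicate an interaction TSV.

    Columns: source, interaction word, target, optional evidence; ``#``
    comment lines are skipped.  Interaction words are mapped to signs
    case-insensitively via ``vocab`` (default :data:`DEFAULT_SIGN_VOCAB`);
    unknown words map to 0 with a warning.  Exact (source, sign, target)
    duplicates are collapsed with evidence tags ";"-joined (unique,
    first-seen order).  Malformed rows are skipped with a warning, never
    silently.  Pass a ``stats`` dict to receive row accounting
    (``rows``, ``kept``, ``duplicates``, ``skipped``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interaction table not found: {path}")
    vocab = {k.lower(): v for k, v in (vocab or DEFAULT_SIGN_VOCAB).items()}
    normalise = normalise or (lambda g: g)

    merged: dict[tuple[str, int, str], list[str]] = {}
    n_rows = n_skipped = n_dup = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            n_rows += 1
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3 or not fields[0] or not fields[2]:
                logger.warning("%s:%d: malformed row skipped: %r", path, lineno, line)
                n_skipped += 1
                continue
            word = fields[1].lower()
            if word in vocab:
                sign = vocab[word]
            else:
                logger.warning(
                    "%s:%d: unknown interaction word %r mapped to sign 0",
                    path, lineno, fields[1],
                )
                sign = 0
            source = normalise(fields[0])
            target = normalise(fields[2])
            evidence = fields[3] if len(fields) > 3 else ""
            key = (source, sign, target)
            if key in merged:
                n_dup += 1
                if evidence and evidence not in merged[key]:
                    merged[key].append(evidence)
            else:
                merged[key] = [evidence] if evidence else []

    out = [
        Interaction(src, sign, tgt, ";".join(tags))
        for (src, sign, tgt), tags in merged.items()
    ]
    if n_rows == 0:
        logger.warning("%s: empty interaction table", path)
    logger.info(
        "%s: %d rows -> %d unique interactions (%d duplicates, %d skipped)",
        path, n_rows, len(out), n_dup, n_skipped,
    )
    if stats is not None:
        stats.update(rows=n_rows, kept=len(out), duplicates=n_dup, skipped=n_skipped)
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    """Write interactions as a 4-column TSV readable by :func:`load_interactions`."""
    with open(path, "w") as handle:
        for ia in interactions:
            handle.write(f"{ia.source}\t{SIGN_WORD[ia.sign]}\t{ia.target}\t{ia.evidence}\n")


def filter_by_evidence(
    interactions: Iterable[Interaction], allowed: Iterable[str]
) -> list[Interaction]:
    """Keep interactions whose evidence matches any allowed class.

    Matching is a case-insensitive substring test against each allowed
    class (so "western" retains "Western blotting").  Order is preserved;
    an empty result is permitted.
    """
    allowed = [a.lower() for a in allowed]
    if not allowed:
        raise ValueError("allowed evidence classes must be non-empty")
    return [
        ia
        for ia in interactions
        if any(a in ia.evidence.lower() for a in allowed)
    ]


def map_orthologues(
    interactions: Iterable[Interaction],
    omap: OrthologueMap,
    stats: dict | None = None,
) -> list[Interaction]:
    """Convert interaction endpoints across species via one-to-one orthologues.

    Endpoints with exactly one native counterpart are renamed; interactions
    touching an endpoint that maps to zero or >=2 native IDs are dropped
    (and counted).  Endpoints absent from the map are assumed already
    native and pass through unchanged.
    """
    kept: list[Interaction] = []
    n_dropped = 0
    for ia in interactions:
        endpoints = []
        ok = True
        for gene in (ia.source, ia.target):
            if gene in omap.entries:
                native = omap.one_to_one(gene)
                if native is None:  # ambiguous or empty mapping
                    ok = False
                    break
                endpoints.append(native)
            else:
                endpoints.append(gene)
        if ok:
            kept.append(Interaction(endpoints[0], ia.sign, endpoints[1], ia.evidence))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("orthologue mapping dropped %d non-1:1 interactions", n_dropped)
    if stats is not None:
        stats.update(kept=len(kept), dropped=n_dropped)
    return kept


def add_mirna_target_edges(
    upregulated: Iterable[str] | MisregulationTable,
    seed_hits: Mapping[str, Mapping[str, int]],
) -> list[Interaction]:
    """Derive miRNA -| gene repression edges from seed matches.

    Only genes upregulated in the knockout qualify (derepression logic: a
    gene whose repressor is gone goes up).  ``seed_hits`` maps miRNA name
    -> gene -> match count; any gene with >=1 match to a miRNA's seed
    complement yields exactly one edge for that miRNA regardless of match
    count, tagged evidence="seed-match".
    """
    if isinstance(upregulated, MisregulationTable):
        up = upregulated.upregulated()
    else:
        up = set(upregulated)
    edges = []
    for mirna in sorted(seed_hits):
        counts = seed_hits[mirna]
        for gene in sorted(counts):
            if gene in up and counts[gene] >= 1:
                edges.append(Interaction(mirna, -1, gene, "seed-match"))
    return edges
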