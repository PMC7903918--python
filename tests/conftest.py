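import re
from itertools import permutations

import pytest


def count_occurrences_oracle(seq: str, word: str) -> int:
    """Overlap-counting oracle via regex lookahead (independent of the scan)."""
    return len(re.findall(f"(?={re.escape(word.upper())})", seq.upper()))


def all_paths(edges, start, end, _seen=None):
    """Exhaustively enumerate simple directed paths start->end."""
    _seen = _seen or {start}
    if start == end:
        yield [start]
        return
    for u, v in edges:
        if u == start and v not in _seen:
            for rest in all_paths(edges, v, end, _seen | {v}):
                yield [start] + rest


def brute_shortest_paths(edges, start, end):
    """All minimum-length simple paths start->end by full enumeration."""
    paths = list(all_paths(edges, start, end))
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def brute_betweenness(nodes, edges):
    """Directed betweenness by exhaustive shortest-path enumeration."""
    nodes = sorted(nodes)
    n = len(nodes)
    acc = dict.fromkeys(nodes, 0.0)
    for s, t in permutations(nodes, 2):
        shortest = brute_shortest_paths(edges, s, t)
        if not shortest:
            continue
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            acc[v] += sum(v in p for p in shortest) / sigma
    if n > 2:
        norm = (n - 1) * (n - 2)
        acc = {v: x / norm for v, x in acc.items()}
    return acc


def random_signed_digraph(rng, n_max=8, p_edge=0.35):
    """Random simple digraph with +/-1 edge signs, as (nodes, edge list)."""
    from corenet import Interaction

    n = int(rng.integers(3, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p_edge:
                sign = -1 if rng.random() < 0.5 else 1
                edges.append(Interaction(u, sign, v))
    return nodes, edges


@pytest.fixture
def tiny_interactions_tsv(tmp_path):
    """Four-row table with one exact duplicate and one unsigned row."""
    path = tmp_path / "links.tsv"
    path.write_text(
        "# source\tinteraction\ttarget\tevidence\n"
        "Hnf4a\tactivates\tGrp\tliterature\n"
        "Hnf4a\tactivates\tGrp\tliterature\n"
        "Mir96\trepresses\tSlc26a5\treporter assay\n"
        "Trp53\tregulates\tFos\tmicroarray\n"
    )
    return path
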