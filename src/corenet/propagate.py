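"""Sign propagation from misregulated genes to a root regulator.

The causal-network procedure restricts a compiled signed interaction graph
to the paths linking a root regulator (typically the knocked-out miRNA) to
the observed misregulated genes, predicts the misregulation direction of
every intermediate gene by iterative integer sign scoring, discards links
whose sign is inconsistent with the assigned directions, and finally keeps
the union of all shortest root-to-target paths as the explanatory network.

Scoring rule: for a node u with signed out-edges u->v, the score is the
integer sum over edges with known child direction of sign(edge) *
direction(v); the predicted direction is the sign of the score, and a zero
score yields no prediction.  Updates are synchronous sweeps to a fixed
point (cycles are capped at ``max_iter``; still-oscillating nodes get no
prediction).  Observed directions and the root's direction are immutable:
in knockout mode the root itself is "down" (-1, the regulator is absent),
so a repressive edge from the root predicts derepression (target up).

A link u->v with sign s is *consistent* when s != 0, both directions are
assigned, and direction(u) * s == direction(v).  Unsigned links can carry
connectivity during path restriction but contribute nothing to scores and
are always removed by consistency pruning — a sign-free edge cannot be
checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .iodb import SIGN_WORD, Interaction, MisregulationTable

logger = logging.getLogger(__name__)

ROOT_DIRECTION = {"knockout": -1, "overexpression": +1}


@dataclass
class NodeState:
    """Per-gene propagation outcome.

    ``direction`` is +1/-1 or None (no prediction); ``status`` is one of
    observed / predicted / no_prediction / root.  Observed and root
    directions never change during propagation.
    """

    gene: str
    direction: int | None
    score: int
    status: str


@dataclass
class CausalNetwork:
    """Consistency-pruned union of shortest root-to-target paths."""

    nodes: dict[str, NodeState]
    edges: list[Interaction]
    excluded_targets: list[tuple[str, str]]  # (gene, reason)
    paths: dict[str, list[list[str]]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(interactions: Iterable[Interaction]) -> nx.MultiDiGraph:
    """Signed interaction list -> MultiDiGraph with sign/evidence edge attrs."""
    g = nx.MultiDiGraph()
    for ia in interactions:
        g.add_edge(ia.source, ia.target, sign=ia.sign, evidence=ia.evidence)
    return g


def restrict_to_paths(
    interactions: Sequence[Interaction],
    roots: Iterable[str],
    targets: Iterable[str],
) -> tuple[list[Interaction], list[tuple[str, str]]]:
    """Keep exactly the nodes and edges on some directed root->target path.

    The retained node set is the intersection of the roots' descendants
    (plus the roots) and the targets' ancestors (plus the targets); every
    edge between two retained nodes lies on at least one root->target
    path.  Targets absent from the graph or unreachable from every root
    are returned as excluded with a reason.  All targets excluded is fatal.
    """
    roots, targets = set(roots), set(targets)
    if not roots or not targets:
        raise ValueError("roots and targets must be non-empty")
    g = build_graph(interactions)

    downstream: set[str] = set()
    for root in roots & set(g.nodes):
        downstream |= nx.descendants(g, root) | {root}
    upstream: set[str] = set()
    for target in targets & set(g.nodes):
        upstream |= nx.ancestors(g, target) | {target}
    keep = downstream & upstream

    excluded = []
    for target in sorted(targets):
        if target not in g.nodes:
            excluded.append((target, "not_in_graph"))
        elif target not in keep:
            excluded.append((target, "unreachable_from_root"))
    if len(excluded) == len(targets):
        raise ValueError(
            "no target is reachable from any root; excluded: "
            + ", ".join(f"{g_} ({r})" for g_, r in excluded)
        )
    kept = [ia for ia in interactions if ia.source in keep and ia.target in keep]
    return kept, excluded


def propagate_scores(
    subgraph: Sequence[Interaction],
    observed: MisregulationTable | Mapping[str, int],
    roots: Iterable[str],
    root_mode: str = "knockout",
    max_iter: int = 100,
) -> dict[str, NodeState]:
    """Iteratively score and orient every gene on the restricted graph.

    Synchronous sweeps: each free node's score is recomputed from the
    previous sweep's directions; iteration stops at a fixed point or after
    ``max_iter`` sweeps (nodes still changing are marked no_prediction
    with a warning).  Observed genes keep their observed direction and
    score; roots keep the mode-determined direction (-1 knockout,
    +1 overexpression).
    """
    if root_mode not in ROOT_DIRECTION:
        raise ValueError(f"root_mode must be one of {sorted(ROOT_DIRECTION)}")
    root_dir = ROOT_DIRECTION[root_mode]
    roots = set(roots)
    obs = observed.directions if isinstance(observed, MisregulationTable) else dict(observed)

    nodes = {ia.source for ia in subgraph} | {ia.target for ia in subgraph}
    nodes |= roots | set(obs)
    out_edges: dict[str, list[tuple[int, str]]] = {n: [] for n in nodes}
    for ia in subgraph:
        if ia.sign != 0:
            out_edges[ia.source].append((ia.sign, ia.target))

    direction: dict[str, int | None] = {}
    for n in nodes:
        if n in roots:
            direction[n] = root_dir
        elif n in obs:
            direction[n] = obs[n]
        else:
            direction[n] = None
    free = [n for n in nodes if n not in roots and n not in obs]

    score: dict[str, int] = dict.fromkeys(nodes, 0)
    changed_last: set[str] = set()
    converged = False
    for _ in range(max_iter):
        changed_last = set()
        new_dir = dict(direction)
        for u in free:
            s = sum(
                sign * direction[v]
                for sign, v in out_edges[u]
                if direction[v] is not None
            )
            score[u] = s
            d = (s > 0) - (s < 0) or None
            new_dir[u] = d
            if d != direction[u]:
                changed_last.add(u)
        direction = new_dir
        if not changed_last:
            converged = True
            break
    if not converged and changed_last:
        logger.warning(
            "propagation did not converge within %d sweeps; %d oscillating "
            "nodes marked no_prediction", max_iter, len(changed_last),
        )
        for u in changed_last:
            direction[u] = None

    states = {}
    for n in nodes:
        if n in roots:
            states[n] = NodeState(n, root_dir, root_dir, "root")
        elif n in obs:
            states[n] = NodeState(n, obs[n], obs[n], "observed")
        elif direction[n] is None:
            states[n] = NodeState(n, None, score[n] if n not in changed_last else 0,
                                  "no_prediction")
        else:
            states[n] = NodeState(n, direction[n], score[n], "predicted")
    return states


def is_consistent(d_source: int | None, sign: int, d_target: int | None) -> bool:
    """Truth table for link consistency: d(u) * sign == d(v), both assigned."""
    return (
        sign != 0
        and d_source in (-1, +1)
        and d_target in (-1, +1)
        and d_source * sign == d_target
    )


def prune_inconsistent(
    subgraph: Sequence[Interaction], states: Mapping[str, NodeState]
) -> list[Interaction]:
    """Keep only links whose sign agrees with the assigned directions."""
    kept = []
    for ia in subgraph:
        d_u = states[ia.source].direction if ia.source in states else None
        d_v = states[ia.target].direction if ia.target in states else None
        if is_consistent(d_u, ia.sign, d_v):
            kept.append(ia)
    removed = len(subgraph) - len(kept)
    logger.info("consistency pruning removed %d of %d links", removed, len(subgraph))
    return kept


def shortest_path_network(
    consistent: Sequence[Interaction],
    roots: Iterable[str],
    targets: Iterable[str],
    states: Mapping[str, NodeState] | None = None,
    excluded: Sequence[tuple[str, str]] = (),
) -> CausalNetwork:
    """Union of every minimum-length root->target path in the pruned graph.

    For each (root, target) pair all tied shortest paths are kept; the
    per-root path sets are unioned.  Targets rendered unreachable by the
    pruning are appended to the excluded list with reason "inconsistent".
    """
    roots, targets = sorted(set(roots)), sorted(set(targets))
    g = nx.DiGraph()
    g.add_nodes_from(roots)
    for ia in consistent:
        g.add_edge(ia.source, ia.target)

    keep_edges: set[tuple[str, str]] = set()
    keep_nodes: set[str] = set()
    paths: dict[str, list[list[str]]] = {}
    excluded_out = list(excluded)
    for target in targets:
        found = []
        for root in roots:
            if target in g.nodes and root in g.nodes and nx.has_path(g, root, target):
                found.extend(nx.all_shortest_paths(g, root, target))
        if not found:
            excluded_out.append((target, "inconsistent"))
            continue
        paths[target] = found
        for path in found:
            keep_nodes.update(path)
            keep_edges.update(zip(path, path[1:]))

    edges = [ia for ia in consistent if (ia.source, ia.target) in keep_edges]
    node_states: dict[str, NodeState] = {}
    for n in sorted(keep_nodes):
        if states and n in states:
            node_states[n] = states[n]
        else:
            node_states[n] = NodeState(n, None, 0, "no_prediction")
    return CausalNetwork(node_states, edges, excluded_out, paths)


def build_causal_network(
    interactions: Sequence[Interaction],
    observed: MisregulationTable | Mapping[str, int],
    roots: Iterable[str],
    root_mode: str = "knockout",
    max_iter: int = 100,
) -> CausalNetwork:
    """Full pipeline: restrict -> propagate -> prune -> shortest paths."""
    obs = observed.directions if isinstance(observed, MisregulationTable) else dict(observed)
    targets = set(obs)
    subgraph, excluded = restrict_to_paths(interactions, roots, targets)
    reachable = targets - {g for g, _ in excluded}
    states = propagate_scores(subgraph, obs, roots, root_mode, max_iter)
    consistent = prune_inconsistent(subgraph, states)
    return shortest_path_network(consistent, roots, reachable, states, excluded)


def validate_against_study(
    interactions: Sequence[Interaction],
    observed: MisregulationTable | Mapping[str, int],
    roots: Iterable[str],
    held_out: Mapping[str, int],
    root_mode: str = "knockout",
) -> tuple[dict[str, str], dict[str, int]]:
    """Hold out intermediate genes with known directions and test predictions.

    The held-out genes are removed from the observed input before network
    creation; each is then classed correct / incorrect / no_prediction by
    comparing the propagated direction with its known direction.  Returns
    per-gene verdicts and summary counts.
    """
    obs = observed.directions if isinstance(observed, MisregulationTable) else dict(observed)
    obs = {g: d for g, d in obs.items() if g not in held_out}
    if not obs:
        raise ValueError("no observed genes left after removing the held-out set")
    subgraph, excluded = restrict_to_paths(interactions, roots, set(obs))
    states = propagate_scores(subgraph, obs, roots, root_mode)

    verdicts = {}
    for gene, known in held_out.items():
        state = states.get(gene)
        if state is None or state.direction is None or state.status in ("observed",):
            verdicts[gene] = "no_prediction"
        elif state.direction == known:
            verdicts[gene] = "correct"
        else:
            verdicts[gene] = "incorrect"
    summary = {
        "correct": sum(v == "correct" for v in verdicts.values()),
        "incorrect": sum(v == "incorrect" for v in verdicts.values()),
        "no_prediction": sum(v == "no_prediction" for v in verdicts.values()),
    }
    return verdicts, summary


def write_sif(network: CausalNetwork, prefix: str | Path) -> None:
    """Write the network as Cytoscape-loadable text files.

    ``<prefix>.sif`` holds one edge per line (source, relation, target);
    ``<prefix>.nodes.tsv`` the node attributes (gene, direction, status,
    score); ``<prefix>.edges.tsv`` the edge evidence.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".sif"), "w") as fh:
        for ia in network.edges:
            fh.write(f"{ia.source}\t{SIGN_WORD[ia.sign]}\t{ia.target}\n")
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("gene\tdirection\tstatus\tscore\n")
        for gene in sorted(network.nodes):
            st = network.nodes[gene]
            d = "" if st.direction is None else str(st.direction)
            fh.write(f"{gene}\t{d}\t{st.status}\t{st.score}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\trelation\ttarget\tevidence\n")
        for ia in network.edges:
            fh.write(f"{ia.source}\t{SIGN_WORD[ia.sign]}\t{ia.target}\t{ia.evidence}\n")
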