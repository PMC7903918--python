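"""Sign propagation, consistency pruning and shortest-path extraction."""

from itertools import product

import numpy as np
import pytest

from corenet import (
    CascadeSpec,
    Interaction,
    build_causal_network,
    gen_cascade,
    is_consistent,
    propagate_scores,
    prune_inconsistent,
    restrict_to_paths,
    shortest_path_network,
    validate_against_study,
    write_sif,
)

from conftest import brute_shortest_paths, random_signed_digraph


def edge(u, s, v):
    return Interaction(u, s, v)


class TestRestrictToPaths:
    def test_off_path_branches_removed(self):
        links = [edge("R", 1, "A"), edge("A", 1, "G"), edge("A", 1, "X")]
        kept, excluded = restrict_to_paths(links, ["R"], ["G"])
        assert {ia.key for ia in kept} == {("R", 1, "A"), ("A", 1, "G")}
        assert excluded == []

    def test_target_without_regulators_excluded(self):
        links = [edge("R", 1, "A"), edge("A", 1, "G")]
        kept, excluded = restrict_to_paths(links, ["R"], ["G", "Ccer2"])
        assert ("Ccer2", "not_in_graph") in excluded
        assert {ia.key for ia in kept} == {("R", 1, "A"), ("A", 1, "G")}

    def test_unreachable_target_excluded_with_reason(self):
        links = [edge("R", 1, "G"), edge("Z", 1, "T")]
        _, excluded = restrict_to_paths(links, ["R"], ["G", "T"])
        assert ("T", "unreachable_from_root") in excluded

    def test_all_targets_excluded_is_fatal(self):
        links = [edge("A", 1, "B")]
        with pytest.raises(ValueError, match="no target"):
            restrict_to_paths(links, ["R"], ["X", "Y"])

    def test_unsigned_edges_carry_connectivity(self):
        links = [edge("R", 0, "A"), edge("A", 1, "G")]
        kept, excluded = restrict_to_paths(links, ["R"], ["G"])
        assert len(kept) == 2 and excluded == []


class TestPropagateScores:
    def test_three_node_derepression_chain(self):
        """Root -| A -| target(down): A is scored up and both links are
        consistent under the knockout convention (root down)."""
        links = [edge("Mir96", -1, "A"), edge("A", -1, "Slc26a5")]
        states = propagate_scores(links, {"Slc26a5": -1}, ["Mir96"], "knockout")
        assert states["A"].direction == +1
        assert states["A"].score == +1
        assert states["A"].status == "predicted"
        assert states["Mir96"].direction == -1 and states["Mir96"].status == "root"
        assert prune_inconsistent(links, states) == links

    def test_conflicting_children_give_no_prediction(self):
        # U activates one up gene (+1) and represses another up gene (-1): sum 0
        links = [edge("R", 1, "U"), edge("U", 1, "A"), edge("U", -1, "B")]
        states = propagate_scores(links, {"A": 1, "B": 1}, ["R"], "knockout")
        assert states["U"].score == 0
        assert states["U"].direction is None
        assert states["U"].status == "no_prediction"

    def test_odd_symmetry_of_predictions(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            _, links = random_signed_digraph(rng)
            observed = {"n1": 1, "n2": -1}
            a = propagate_scores(links, observed, ["n0"], "knockout")
            flipped = {g: -d for g, d in observed.items()}
            b = propagate_scores(links, flipped, ["n0"], "overexpression")
            for gene in a:
                if a[gene].direction is None:
                    assert b[gene].direction is None
                else:
                    assert b[gene].direction == -a[gene].direction

    def test_observed_directions_are_immutable(self):
        links = [edge("R", 1, "A"), edge("A", 1, "G"), edge("B", -1, "G")]
        states = propagate_scores(links, {"G": 1, "A": -1}, ["R"])
        assert states["A"].direction == -1 and states["A"].status == "observed"

    def test_oscillating_cycle_marked_no_prediction(self, caplog):
        # A -| B, B -| A with both driven by the same observed up gene:
        # the pair alternates between (+1,+1) and (None,None) forever.
        links = [
            edge("A", -1, "B"),
            edge("B", -1, "A"),
            edge("A", 1, "T"),
            edge("B", 1, "T"),
        ]
        with caplog.at_level("WARNING"):
            states = propagate_scores(links, {"T": 1}, ["R"], max_iter=10)
        assert states["A"].status == "no_prediction"
        assert states["B"].status == "no_prediction"
        assert "did not converge" in caplog.text


class TestConsistencyTruthTable:
    @pytest.mark.parametrize(
        "d_u,s,d_v", list(product((-1, 1), (-1, 0, 1), (-1, 1)))
    )
    def test_matches_exhaustive_truth_table(self, d_u, s, d_v):
        """All 12 signed cases: kept iff s != 0 and d(u)*s == d(v)."""
        expected = s != 0 and d_u * s == d_v
        assert is_consistent(d_u, s, d_v) is expected

    def test_edge_touching_no_prediction_node_removed(self):
        links = [edge("R", 1, "U"), edge("U", 1, "A"), edge("U", -1, "B")]
        states = propagate_scores(links, {"A": 1, "B": 1}, ["R"])
        kept = prune_inconsistent(links, states)
        assert all("U" not in (ia.source, ia.target) for ia in kept)

    def test_sign_algebra_examples(self):
        links = [edge("A", 1, "B"), edge("A", -1, "C")]
        states = propagate_scores(
            [], {"A": 1, "B": 1, "C": 1}, ["R"]
        )
        kept = prune_inconsistent(links, states)
        assert [ia.key for ia in kept] == [("A", 1, "B")]  # up-activates-up kept


class TestShortestPathNetwork:
    def test_shorter_path_wins(self):
        links = [
            edge("R", 1, "G"),                      # length 1
            edge("R", 1, "A"), edge("A", 1, "G"),   # length 2
        ]
        net = shortest_path_network(links, ["R"], ["G"])
        assert {ia.key for ia in net.edges} == {("R", 1, "G")}

    def test_tied_paths_all_kept(self):
        links = [
            edge("R", 1, "A"), edge("A", 1, "G"),
            edge("R", 1, "B"), edge("B", 1, "G"),
        ]
        net = shortest_path_network(links, ["R"], ["G"])
        assert len(net.edges) == 4
        assert len(net.paths["G"]) == 2

    def test_pruned_away_target_reported_inconsistent(self):
        net = shortest_path_network([edge("R", 1, "A")], ["R"], ["A", "G"])
        assert ("G", "inconsistent") in net.excluded_targets

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for trial in range(60):
            nodes, links = random_signed_digraph(rng)
            root, targets = nodes[0], set(nodes[-2:])
            pairs = [(ia.source, ia.target) for ia in links]
            expected_edges = set()
            reachable = set()
            for t in targets:
                for path in brute_shortest_paths(pairs, root, t):
                    reachable.add(t)
                    expected_edges.update(zip(path, path[1:]))
            if not reachable:
                continue
            net = shortest_path_network(links, [root], targets)
            got = {(ia.source, ia.target) for ia in net.edges}
            assert got == expected_edges


class TestPipeline:
    def test_monotone_shrinkage(self):
        spec = CascadeSpec(n_nodes=80, noise=0.3, fraction_observed=0.8, seed=5)
        cascade = gen_cascade(spec)
        restricted, _ = restrict_to_paths(
            cascade.interactions, [cascade.root], set(cascade.observed.directions)
        )
        states = propagate_scores(restricted, cascade.observed, [cascade.root])
        pruned = prune_inconsistent(restricted, states)
        net = build_causal_network(
            cascade.interactions, cascade.observed, [cascade.root]
        )
        as_keys = lambda links: {ia.key for ia in links}
        assert as_keys(net.edges) <= as_keys(pruned)
        assert as_keys(pruned) <= as_keys(restricted)
        assert as_keys(restricted) <= as_keys(cascade.interactions)

    def test_noise_free_cascade_fully_recovered(self):
        cascade = gen_cascade(CascadeSpec(n_nodes=120, seed=2))
        restricted, excluded = restrict_to_paths(
            cascade.interactions, [cascade.root], set(cascade.observed.directions)
        )
        assert excluded == []
        states = propagate_scores(restricted, cascade.observed, [cascade.root])
        for gene, state in states.items():
            if state.status == "predicted":
                assert state.direction == cascade.truth[gene]
        assert prune_inconsistent(restricted, states) == restricted

    def test_sif_round_trip(self, tmp_path):
        from corenet import read_sif

        cascade = gen_cascade(CascadeSpec(n_nodes=30, seed=4))
        net = build_causal_network(
            cascade.interactions, cascade.observed, [cascade.root]
        )
        prefix = tmp_path / "net"
        write_sif(net, prefix)
        again = read_sif(tmp_path / "net.sif")
        assert {ia.key for ia in again} == {ia.key for ia in net.edges}
        nodes_tsv = (tmp_path / "net.nodes.tsv").read_text()
        assert nodes_tsv.startswith("gene\tdirection\tstatus\tscore")

    def test_determinism(self):
        cascade = gen_cascade(CascadeSpec(n_nodes=60, seed=8))
        nets = [
            build_causal_network(cascade.interactions, cascade.observed, [cascade.root])
            for _ in range(2)
        ]
        assert [ia.key for ia in nets[0].edges] == [ia.key for ia in nets[1].edges]
        assert {
            g: (s.direction, s.score) for g, s in nets[0].nodes.items()
        } == {g: (s.direction, s.score) for g, s in nets[1].nodes.items()}


class TestValidateAgainstStudy:
    def make_chain_study(self):
        """Root -| M -| T: truth has M up, T down under knockout."""
        links = [edge("Root", -1, "M"), edge("M", -1, "T")]
        observed = {"T": -1, "M": 1}
        return links, observed

    def test_held_out_gene_on_consistent_path_is_correct(self):
        links, observed = self.make_chain_study()
        verdicts, summary = validate_against_study(
            links, observed, ["Root"], {"M": 1}
        )
        assert verdicts == {"M": "correct"}
        assert summary == {"correct": 1, "incorrect": 0, "no_prediction": 0}

    def test_inverted_known_direction_is_incorrect(self):
        links, observed = self.make_chain_study()
        verdicts, _ = validate_against_study(links, observed, ["Root"], {"M": -1})
        assert verdicts == {"M": "incorrect"}

    def test_zero_score_gene_is_no_prediction(self):
        links = [
            edge("Root", -1, "M"),
            edge("M", 1, "T1"),
            edge("M", -1, "T2"),
        ]
        observed = {"T1": 1, "T2": 1, "M": 1}
        verdicts, _ = validate_against_study(links, observed, ["Root"], {"M": 1})
        assert verdicts == {"M": "no_prediction"}

    def test_gene_absent_from_subnetwork_is_no_prediction(self):
        links, observed = self.make_chain_study()
        verdicts, _ = validate_against_study(links, observed, ["Root"], {"Ghost": 1})
        assert verdicts == {"Ghost": "no_prediction"}

    def test_removing_all_observed_is_error(self):
        links, observed = self.make_chain_study()
        with pytest.raises(ValueError):
            validate_against_study(links, observed, ["Root"], {"T": -1, "M": 1})
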