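"""Binary alteration matrix, Manhattan distances and neighbor joining."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

from mmclone import (
    build_feature_matrix,
    manhattan_distance_matrix,
    neighbor_joining,
    to_newick,
)
from mmclone.phylogeny import Clade, tree_distance_matrix, write_newick


def random_tree_metric(n_leaves, rng):
    """Distances on a random tree built by attaching each leaf to a random
    edge — an additive (tree) metric by construction."""
    adjacency = {}

    def add_edge(a, b, length):
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    counter = [0]
    add_edge("L0", "L1", float(rng.uniform(0.1, 2.0)))
    for k in range(2, n_leaves):
        edges = [(a, b) for a in adjacency for b in adjacency[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        length = adjacency[a][b]
        del adjacency[a][b], adjacency[b][a]
        counter[0] += 1
        mid = f"I{counter[0]}"
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, length * split)
        add_edge(mid, b, length * (1 - split))
        add_edge(mid, f"L{k}", float(rng.uniform(0.1, 2.0)))

    leaves = sorted(node for node in adjacency if node.startswith("L"))

    def distances_from(source):
        dist = {source: 0.0}
        stack = [source]
        while stack:
            u = stack.pop()
            for v, length in adjacency[u].items():
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        return dist

    matrix = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for a in leaves:
        from_a = distances_from(a)
        for b in leaves:
            matrix.loc[a, b] = from_a[b]
    return matrix


class TestFeatureMatrix:
    def test_s4_columns_and_truncal_column(self, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S4"])
        assert "chr22:deletion" in matrix.columns
        snv_cols = [c for c in matrix.columns if ">" in c]
        assert len(snv_cols) == 2          # two distinct NF2 mutations
        tumour_rows = matrix.drop(index="germline")
        assert (tumour_rows["chr22:deletion"] == 1).all()

    def test_outgroup_row_is_all_zeros(self, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S1"])
        assert (matrix.loc["germline"] == 0).all()

    def test_identical_profiles_give_identical_rows(self, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S3"])
        assert matrix.loc["S3-T1"].equals(matrix.loc["S3-T2"])

    def test_no_features_raises(self):
        from mmclone.case import LesionProfile, PatientCase
        case = PatientCase("P", [LesionProfile("T1", [], []),
                                 LesionProfile("T2", [], [])])
        with pytest.raises(ValueError, match="threshold"):
            build_feature_matrix(case)


class TestManhattanDistance:
    def test_single_differing_feature(self):
        m = pd.DataFrame([[1, 1, 0], [1, 1, 1]], index=["A", "B"])
        d = manhattan_distance_matrix(m)
        assert d.loc["A", "B"] == 1.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 20)),
                         index=list("ABCDE"))
        d = manhattan_distance_matrix(m)
        for a in m.index:
            for b in m.index:
                want = sum(abs(x - y) for x, y in zip(m.loc[a], m.loc[b]))
                assert d.loc[a, b] == want

    def test_is_a_metric_on_random_binary_data(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = pd.DataFrame(rng.integers(0, 2, size=(6, 15)))
            d = manhattan_distance_matrix(m).to_numpy()
            assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = neighbor_joining(d, outgroup=None)
        assert to_newick(tree) == "(A:1,B:1,C:3);"

    def test_recovers_additive_four_leaf_tree(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels, columns=labels, dtype=float)
        tree = neighbor_joining(d, outgroup=None)
        recovered = tree_distance_matrix(tree).loc[labels, labels]
        assert np.allclose(recovered.to_numpy(), d.to_numpy(), atol=1e-9)
        newick = to_newick(tree)
        # AB | CD split present
        assert "(A:1,B:2)" in newick

    def test_identical_rows_joined_with_zero_branches(self):
        m = pd.DataFrame([[1, 0], [1, 0], [0, 1]], index=list("ABC"))
        tree = neighbor_joining(manhattan_distance_matrix(m), outgroup=None)
        lengths = {c.name: c.branch_length for c in tree.children
                   if c.is_leaf}
        assert lengths["A"] == 0.0 and lengths["B"] == 0.0

    def test_exact_on_random_additive_metrics(self):
        """NJ recovers topology and branch lengths from tree metrics with
        4-8 leaves (additivity check: output path lengths == input)."""
        rng = np.random.default_rng(12345)
        for _ in range(60):
            n = int(rng.integers(4, 9))
            d = random_tree_metric(n, rng)
            tree = neighbor_joining(d, outgroup=None)
            recovered = tree_distance_matrix(tree).loc[d.index, d.columns]
            assert np.allclose(recovered.to_numpy(), d.to_numpy(),
                               atol=1e-9)

    def test_agrees_with_reference_nj_topology(self):
        rng = np.random.default_rng(99)
        d = random_tree_metric(7, rng)
        d = (d + d.T) / 2  # exact symmetry for the reference implementation
        ours = skbio.TreeNode.read(
            io.StringIO(to_newick(neighbor_joining(d, outgroup=None))))
        reference = skbio.tree.nj(skbio.DistanceMatrix(
            d.to_numpy(), ids=list(d.index)))
        rf = ours.compare_rfd(reference)
        assert rf == 0.0

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)

    def test_fewer_than_three_labels_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"),
                         columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_deterministic_under_ties(self):
        # fully tied distances: result must not depend on float noise
        d = pd.DataFrame(1.0 - np.eye(4), index=list("ABCD"),
                         columns=list("ABCD"))
        newicks = {to_newick(neighbor_joining(d, outgroup=None))
                   for _ in range(5)}
        assert len(newicks) == 1

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = pd.DataFrame(rng.integers(0, 2, size=(6, 10)),
                             index=[f"T{i}" for i in range(6)])
            tree = neighbor_joining(manhattan_distance_matrix(m),
                                    outgroup=None)
            stack = [tree]
            while stack:
                node = stack.pop()
                if node.branch_length is not None:
                    assert node.branch_length >= 0
                stack.extend(node.children)


class TestNewickOutput:
    def test_round_trip_preserves_topology_and_lengths(self, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S1"])
        tree = neighbor_joining(manhattan_distance_matrix(matrix))
        parsed = skbio.TreeNode.read(io.StringIO(to_newick(tree)))
        ours = tree_distance_matrix(tree)
        for a in ours.index:
            for b in ours.columns:
                if a != b:
                    assert parsed.find(a).distance(
                        parsed.find(b)) == pytest.approx(ours.loc[a, b])

    def test_germline_outgroup_attached_at_root(self, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S2"])
        tree = neighbor_joining(manhattan_distance_matrix(matrix),
                                outgroup="germline")
        assert "germline" in [c.name for c in tree.children]

    def test_reserved_characters_are_quoted(self):
        tree = Clade(children=[
            Clade(name="T(1)", branch_length=1.0),
            Clade(name="T2", branch_length=1.0),
            Clade(name="T3", branch_length=2.0),
        ])
        newick = to_newick(tree)
        assert "'T(1)'" in newick
        parsed = skbio.TreeNode.read(io.StringIO(newick))
        assert {t.name for t in parsed.tips()} == {"T(1)", "T2", "T3"}

    def test_write_newick_writes_file(self, tmp_path, cases_by_id):
        matrix = build_feature_matrix(cases_by_id["S4"])
        tree = neighbor_joining(manhattan_distance_matrix(matrix))
        path = tmp_path / "tree.nwk"
        newick = write_newick(tree, path)
        assert path.read_text().strip() == newick


class TestTreeInterpretation:
    def test_truncal_dominated_case_places_outgroup_off_the_trunk(self):
        """With many truncal and few private features, the germline leaf's
        branch (the trunk) is the longest edge at the root."""
        from mmclone import SimulationConfig, simulate_patient
        config = SimulationConfig(
            seed=2, lesions_per_patient=3, n_truncal_snv=8,
            n_private_snv_per_lesion=1, sequencing_depth=100000)
        case, _ = simulate_patient(config, 0)
        matrix = build_feature_matrix(case)
        tree = neighbor_joining(manhattan_distance_matrix(matrix))
        germline = next(c for c in tree.children if c.name == "germline")
        others = [c.branch_length for c in tree.children
                  if c.name != "germline"]
        assert germline.branch_length > max(others)
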