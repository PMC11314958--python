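"""Connectome I/O, validation, proportional thresholding, ROI resolution."""
import numpy as np
import pytest

from connectolesion import (
    ConnectomeError,
    WeightedConnectome,
    binarize,
    default_node_labels,
    default_roi_table,
    read_connectome,
    resolve_rois,
    threshold_proportional,
    write_connectome,
)
from connectolesion.connectome import ROI_NAMES


def write_tsv(path, labels, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")


class TestReadWrite:
    def test_direct_read_back(self, tmp_path):
        f = tmp_path / "c.tsv"
        write_tsv(f, ["A", "B", "C"], [[0, 2, 0], [2, 0, 1], [0, 1, 0]])
        c = read_connectome(f)
        assert c.n == 3
        assert c.labels == ("A", "B", "C")
        assert c.weights[0][1] == 2

    def test_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(7)
        w = rng.lognormal(size=(6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        c = WeightedConnectome(labels=tuple("abcdef"), weights=w)
        f = tmp_path / "c.tsv"
        write_connectome(c, f)
        c2 = read_connectome(f)
        assert c2.labels == c.labels
        assert np.array_equal(c2.weights, c.weights)

    def test_small_asymmetry_averaged(self, tmp_path):
        f = tmp_path / "c.tsv"
        write_tsv(f, ["A", "B", "C"], [[0, 1.0000001, 0], [1, 0, 1], [0, 1, 0]])
        c = read_connectome(f)
        assert c.weights[0, 1] == pytest.approx(1.00000005)

    @pytest.mark.parametrize(
        "labels,rows,match",
        [
            (["A", "B", "C"], [[0, 1, 0], [5, 0, 1], [0, 1, 0]], "asymmetry"),
            (["A", "B", "C"], [[0, -1, 0], [-1, 0, 1], [0, 1, 0]], "negative"),
            (["A", "A", "C"], [[0, 1, 0], [1, 0, 1], [0, 1, 0]], "duplicate"),
            (["A", "B", "C"], [[0, 1, 0], [1, 0, 1]], "square"),
        ],
    )
    def test_malformed_inputs_rejected(self, tmp_path, labels, rows, match):
        f = tmp_path / "c.tsv"
        write_tsv(f, labels, rows)
        with pytest.raises(ConnectomeError, match=match):
            read_connectome(f)

    def test_expected_n_mismatch(self, tmp_path):
        f = tmp_path / "c.tsv"
        write_tsv(f, ["A", "B", "C"], [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        with pytest.raises(ConnectomeError, match="expected 4"):
            read_connectome(f, expected_n=4)


class TestThreshold:
    def test_forced_ordering(self, toy_weighted):
        out = threshold_proportional(toy_weighted, 0.5)
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(out.weights)))}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_proportion_one_is_identity(self, toy_weighted):
        out = threshold_proportional(toy_weighted, 1.0)
        assert np.array_equal(out.weights, toy_weighted.weights)

    def test_tie_broken_row_major(self):
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 5, (0, 2): 4, (0, 3): 3, (1, 2): 3, (1, 3): 1, (2, 3): 0.5}.items():
            w[i, j] = w[j, i] = v
        out = threshold_proportional(WeightedConnectome(labels=tuple("ABCD"), weights=w), 0.5)
        kept = {(i, j) for i, j in zip(*np.nonzero(np.triu(out.weights)))}
        # (0,3) precedes (1,2) in row-major order, so the tie at rank k goes to it
        assert kept == {(0, 1), (0, 2), (0, 3)}

    @pytest.mark.parametrize("prop", [0.0, -0.1, 1.2])
    def test_bad_proportion(self, toy_weighted, prop):
        with pytest.raises(ValueError):
            threshold_proportional(toy_weighted, prop)

    def test_all_zero_rejected(self):
        c = WeightedConnectome(labels=tuple("ABC"), weights=np.zeros((3, 3)))
        with pytest.raises(ConnectomeError):
            threshold_proportional(c)

    def test_fewer_positive_than_k_keeps_all(self, caplog):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        c = WeightedConnectome(labels=tuple("ABCDE"), weights=w)
        out = threshold_proportional(c, 0.9)
        assert np.count_nonzero(np.triu(out.weights)) == 1

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        w = rng.random((10, 10))
        w = np.triu(w, 1)
        w = w + w.T
        c = WeightedConnectome(labels=tuple(f"n{i}" for i in range(10)), weights=w)
        c2 = WeightedConnectome(labels=c.labels, weights=w * 37.5)
        g1 = binarize(threshold_proportional(c, 0.3))
        g2 = binarize(threshold_proportional(c2, 0.3))
        assert np.array_equal(g1.adjacency, g2.adjacency)

    def test_nested_retention(self):
        rng = np.random.default_rng(4)
        w = rng.random((12, 12))
        w = np.triu(w, 1)
        w = w + w.T
        c = WeightedConnectome(labels=tuple(f"n{i}" for i in range(12)), weights=w)
        e1 = set(zip(*np.nonzero(threshold_proportional(c, 0.2).weights)))
        e2 = set(zip(*np.nonzero(threshold_proportional(c, 0.5).weights)))
        assert e1 <= e2

    def test_default_density_near_20_percent(self):
        rng = np.random.default_rng(5)
        n = 50
        w = rng.random((n, n))
        w = np.triu(w, 1)
        w = w + w.T
        c = WeightedConnectome(labels=tuple(f"n{i}" for i in range(n)), weights=w)
        g = binarize(threshold_proportional(c))
        assert abs(g.density - 0.20) <= 1 / (n * (n - 1) / 2)


class TestBinarize:
    def test_toy_density(self, toy_weighted):
        g = binarize(threshold_proportional(toy_weighted, 0.5))
        assert g.density == pytest.approx(0.5)
        assert g.adjacency[0, 1] == 1 and g.adjacency[2, 3] == 0

    def test_all_zero(self):
        g = binarize(WeightedConnectome(labels=tuple("ABC"), weights=np.zeros((3, 3))))
        assert g.density == 0 and not g.adjacency.any()

    def test_idempotent_on_binary(self):
        rng = np.random.default_rng(6)
        a = np.triu((rng.random((8, 8)) < 0.4).astype(float), 1)
        a = a + a.T
        c = WeightedConnectome(labels=tuple(f"n{i}" for i in range(8)), weights=a)
        g1 = binarize(c)
        g2 = binarize(WeightedConnectome(labels=c.labels, weights=g1.adjacency.astype(float)))
        assert np.array_equal(g1.adjacency, g2.adjacency)


class TestRois:
    def test_lookup(self):
        labels = default_node_labels(225)
        rs = resolve_rois(labels)
        assert len(rs.node_indices) == 8
        assert labels[rs.node_indices["parahippocampal"]] == "R_PhG"

    def test_missing_label(self):
        with pytest.raises(ConnectomeError, match="not found"):
            resolve_rois(["a", "b", "c"], {"parahippocampal": "R_PhG"})

    def test_ambiguous_label(self):
        labels = list(default_node_labels(30)) + ["R_PhG"]
        with pytest.raises(ConnectomeError, match="ambiguous"):
            resolve_rois(labels)

    def test_permutation_consistency(self):
        labels = list(default_node_labels(40))
        rng = np.random.default_rng(0)
        perm = rng.permutation(40)
        permuted = [labels[i] for i in perm]
        a = resolve_rois(labels)
        b = resolve_rois(permuted)
        for roi in a.roi_names:
            assert permuted[b.node_indices[roi]] == labels[a.node_indices[roi]]

    def test_default_table_shape(self):
        t = default_roi_table()
        assert tuple(t) == ROI_NAMES
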