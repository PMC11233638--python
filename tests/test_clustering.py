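"""Hamming distances, UPGMA agglomeration, Newick export, zone concordance."""

import io

import numpy as np
import pytest

from cerebmotif import (
    ConnectivityDataset,
    CellConnectivity,
    Lobule,
    Zone,
    hamming_matrix,
    to_newick,
    upgma,
    zone_concordance,
)
from cerebmotif.clustering import (
    Clade,
    DistanceMatrix,
    cophenetic_heights,
)
from cerebmotif.connectivity import TABLE_LOBULES

L = Lobule


def _dataset(columns: dict[Lobule, list[int]]):
    n = len(next(iter(columns.values())))
    cells = []
    for i in range(n):
        connected = {lob: bool(columns.get(lob, [0] * n)[i]) for lob in TABLE_LOBULES}
        cells.append(CellConnectivity(cell_id=f"c{i}", connected=connected))
    return ConnectivityDataset(cells=tuple(cells))


class TestHammingMatrix:
    def test_identical_and_complementary_columns(self):
        ds = _dataset({L.III: [1, 0, 1], L.IV_V: [1, 0, 1], L.X: [0, 1, 0]})
        dm = hamming_matrix(ds, labels=[L.III, L.IV_V, L.X])
        i, j, k = 0, 1, 2
        assert dm.values[i, j] == 0.0
        assert dm.values[i, k] == 1.0

    def test_single_mismatch_fraction(self):
        ds = _dataset({L.VIII: [0, 0, 1], L.IX: [1, 0, 1]})
        dm = hamming_matrix(ds, labels=[L.VIII, L.IX])
        # analysis set = 2 connected cells; columns differ on one of them
        assert dm.values[0, 1] == pytest.approx(1 / 2)

    def test_invariant_to_cell_order_and_duplication(self, canonical):
        dm = hamming_matrix(canonical)
        reversed_ds = ConnectivityDataset(cells=tuple(reversed(canonical.cells)))
        assert np.allclose(hamming_matrix(reversed_ds).values, dm.values)
        doubled = ConnectivityDataset(
            cells=canonical.cells
            + tuple(
                CellConnectivity(
                    cell_id=c.cell_id + "_dup",
                    connected=c.connected,
                    amplitude_pA=c.amplitude_pA,
                )
                for c in canonical.cells
            )
        )
        assert np.allclose(hamming_matrix(doubled).values, dm.values)

    def test_empty_analysis_set_rejected(self):
        ds = _dataset({L.III: [0, 0]})
        with pytest.raises(ValueError, match="empty analysis set"):
            hamming_matrix(ds)


def _dm(labels, d):
    return DistanceMatrix(labels=tuple(labels), values=np.asarray(d, dtype=float))


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        dm = _dm("ABC", [[0, 0.2, 0.6], [0.2, 0, 0.4], [0.6, 0.4, 0]])
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.5)  # mean of 0.6 and 0.4
        inner = next(c for c in tree.children if not c.is_leaf)
        assert inner.height == pytest.approx(0.2)
        assert sorted(inner.leaves()) == ["A", "B"]

    def test_equidistant_matrix_single_height(self):
        dm = _dm("ABCD", 0.3 * (1 - np.eye(4)))
        tree = upgma(dm)
        heights = sorted(h for _, h in _merges(tree))
        assert heights == pytest.approx([0.3, 0.3, 0.3])

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(7)
        for n in range(3, 9):
            for _ in range(10):
                cond = rng.random(n * (n - 1) // 2)
                d = squareform(cond)
                tree = upgma(_dm([f"l{i}" for i in range(n)], d))
                ref = average(cond)
                # same merge heights
                ours = sorted(h for _, h in _merges(tree))
                assert np.allclose(ours, sorted(ref[:, 2]), atol=1e-12)
                # same cophenetic structure
                coph_ref = squareform(cophenet(ref))
                coph = cophenetic_heights(tree)
                for i in range(n):
                    for j in range(i + 1, n):
                        assert coph[frozenset((f"l{i}", f"l{j}"))] == pytest.approx(
                            coph_ref[i, j], abs=1e-12
                        )

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(11)
        n = 7
        from scipy.spatial.distance import squareform

        d = squareform(rng.random(n * (n - 1) // 2))
        tree = upgma(_dm([f"l{i}" for i in range(n)], d))
        coph = cophenetic_heights(tree)
        names = [f"l{i}" for i in range(n)]
        for a in names:
            for b in names:
                for c in names:
                    if len({a, b, c}) < 3:
                        continue
                    dab = coph[frozenset((a, b))]
                    dac = coph[frozenset((a, c))]
                    dbc = coph[frozenset((b, c))]
                    assert dab <= max(dac, dbc) + 1e-12

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            upgma(_dm("A", [[0.0]]))


def _merges(tree):
    if tree.is_leaf:
        return []
    return [(tree, tree.height)] + _merges(tree.children[0]) + _merges(tree.children[1])


class TestNewick:
    def test_two_leaf_half_height_convention(self):
        tree = Clade(children=(Clade(name="III"), Clade(name="IV/V")), height=0.2)
        assert to_newick(tree) == "(III:0.1,IV_V:0.1);"

    def test_three_leaf_serialization(self):
        inner = Clade(children=(Clade(name="A"), Clade(name="B")), height=0.2)
        tree = Clade(children=(inner, Clade(name="C")), height=0.5)
        assert to_newick(tree) == "((A:0.1,B:0.1):0.15,C:0.25);"

    def test_round_trip_topology_and_heights(self, canonical):
        import skbio

        tree = upgma(hamming_matrix(canonical))
        parsed = skbio.TreeNode.read(io.StringIO(to_newick(tree)))
        tip_dists = parsed.tip_tip_distances()
        coph = cophenetic_heights(tree)
        # Newick readers render unquoted underscores as spaces; map back
        ids = [str(x).replace(" ", "_") for x in tip_dists.ids]
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                assert tip_dists[i, j] == pytest.approx(coph[frozenset((a, b))], abs=1e-9)


class TestZoneConcordance:
    def test_fixture_tree_is_concordant(self, canonical):
        tree = upgma(hamming_matrix(canonical))
        report = zone_concordance(tree)
        assert report.concordant
        assert report.violations == ()
        # within-zone pairs are the first merges
        coph = cophenetic_heights(tree)
        within = [coph[frozenset(("III", "IV_V"))], coph[frozenset(("VIII", "IX"))]]
        cross = [
            h for pair, h in coph.items()
            if pair not in ({"III", "IV_V"}, {"VIII", "IX"})
        ]
        assert max(within) < min(cross)

    def test_single_zone_vacuous(self):
        tree = Clade(children=(Clade(name="a"), Clade(name="b")), height=0.4)
        report = zone_concordance(tree, {"a": Zone.CENTRAL, "b": Zone.CENTRAL})
        assert report.concordant

    def test_discordant_tree_reports_violation(self):
        # a (anterior) merges with x (nodular) before b (anterior)
        inner = Clade(children=(Clade(name="a"), Clade(name="x")), height=0.1)
        tree = Clade(children=(inner, Clade(name="b")), height=0.5)
        report = zone_concordance(
            tree, {"a": Zone.ANTERIOR, "b": Zone.ANTERIOR, "x": Zone.NODULAR}
        )
        assert not report.concordant
        assert report.violations

    def test_unassigned_leaf_rejected(self):
        tree = Clade(children=(Clade(name="a"), Clade(name="b")), height=0.4)
        with pytest.raises(ValueError, match="zone assignment"):
            zone_concordance(tree, {"a": Zone.ANTERIOR})

    def test_random_null_trees_often_discordant(self):
        """Independence-model datasets give discordant lobule trees at an
        appreciable rate (the fixture's concordance is not automatic)."""
        from cerebmotif.synthetic import SimConnectivityConfig, simulate_connectivity

        discordant = 0
        n = 60
        for seed in range(n):
            ds = simulate_connectivity(SimConnectivityConfig(seed=seed))
            if not ds.connected_cells():
                continue
            tree = upgma(hamming_matrix(ds))
            if not zone_concordance(tree).concordant:
                discordant += 1
        assert discordant >= n // 4
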