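"""Transfer-pair selection criteria, proximity filtering, and network aggregation."""

import itertools

import numpy as np
import pytest

from protonpocket.correlation import CorrelationMatrix
from protonpocket.errors import StructuralDataError
from protonpocket.network import (
    aggregate_network,
    candidate_pairs,
    export_network,
    network_to_table,
    pair_min_oo_distance,
    proximity_filter,
    rank_transfer_likelihood,
    residue_depths,
)
from protonpocket.pka import PocketFrame
from protonpocket.states import POCKET, parse_label

RESIDUES = tuple(r.name for r in POCKET)


def _matrix(pairs, state_label, n=100):
    """Correlation matrix with specified off-diagonal entries."""
    r = np.eye(5)
    idx = {name: i for i, name in enumerate(RESIDUES)}
    for (a, b), val in pairs.items():
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = val
    return CorrelationMatrix(RESIDUES, r, n, (150.0, 249.0), state=parse_label(state_label))


class TestCandidatePairs:
    def test_single_protonated_member_becomes_donor(self):
        mat = _matrix({("E795", "E820"): -0.923}, "E795+D824+D942+")
        (pair,) = candidate_pairs(mat)
        assert (pair.donor, pair.acceptor) == ("E795", "E820")
        assert pair.r == pytest.approx(-0.923)

    def test_both_protonated_pair_excluded(self):
        mat = _matrix({("E795", "E820"): -0.9}, "E795+E820+")
        assert candidate_pairs(mat) == []

    def test_both_deprotonated_pair_excluded(self):
        mat = _matrix({("E795", "E820"): -0.9}, "D824+D942+")
        assert candidate_pairs(mat) == []

    def test_weak_correlations_give_empty_list(self):
        mat = _matrix({("E795", "E820"): -0.49, ("E343", "D824"): 0.7}, "E795+D824+")
        assert candidate_pairs(mat) == []

    def test_threshold_is_strict(self):
        mat = _matrix({("E795", "E820"): -0.5}, "E795+D824+D942+")
        assert candidate_pairs(mat, threshold=-0.5) == []

    def test_matches_exhaustive_filter_oracle(self, rng):
        for _ in range(20):
            a = rng.uniform(-1, 1, size=(5, 5))
            r = (a + a.T) / 2
            np.fill_diagonal(r, 1.0)
            protonated = set(rng.choice(RESIDUES, size=rng.integers(0, 5), replace=False))
            label = "".join(n + "+" for n in RESIDUES if n in protonated)
            mat = CorrelationMatrix(RESIDUES, r, 100, (0, 99), state=parse_label(label))
            got = {(p.donor, p.acceptor) for p in candidate_pairs(mat, threshold=-0.3)}
            idx = {n: i for i, n in enumerate(RESIDUES)}
            brute = set()
            for x, y in itertools.combinations(RESIDUES, 2):
                if r[idx[x], idx[y]] < -0.3 and (x in protonated) != (y in protonated):
                    brute.add((x, y) if x in protonated else (y, x))
            assert got == brute

    def test_filter_decomposition_limits(self):
        mat = _matrix({("E795", "E820"): -0.9, ("E343", "D824"): -0.7}, "E795+D824+D942+")
        assert candidate_pairs(mat, threshold=-1.0) == []
        # threshold +1 keeps exactly the one-protonated pairs (r < 1 for all off-diag)
        all_one_prot = candidate_pairs(mat, threshold=1.0)
        state = mat.state
        expected = sum(
            1 for x, y in itertools.combinations(RESIDUES, 2)
            if state.is_protonated(x) != state.is_protonated(y)
        )
        assert len(all_one_prot) == expected

    def test_low_pka_consistency_flag(self):
        mat = _matrix({("E795", "E820"): -0.9}, "E795+D824+D942+")
        mat.means = {"E795": 3.0, "E820": 6.0, "E343": 4.5, "D824": 3.8, "D942": 3.8}
        (pair,) = candidate_pairs(mat)
        assert pair.low_pka_consistent is True
        mat.means["E795"] = 8.0
        (pair,) = candidate_pairs(mat)
        assert pair.low_pka_consistent is False


def _frame_with_pair(dist, a="E795", b="E820"):
    oxygens = {
        a: np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]]),
        b: np.array([[dist, 0.0, 0.0], [dist + 0.1, 0.0, 0.0]]),
    }
    return PocketFrame(0.0, oxygens)


class TestProximityFilter:
    def _pair(self):
        mat = _matrix({("E795", "E820"): -0.9}, "E795+D824+D942+")
        return candidate_pairs(mat)

    def test_close_pair_kept(self):
        kept = proximity_filter(self._pair(), [_frame_with_pair(0.35)], cutoff_nm=0.6)
        assert len(kept) == 1
        assert kept[0].min_oo_distance_nm == pytest.approx(0.25)  # inner oxygens

    def test_distant_pair_removed(self):
        assert proximity_filter(self._pair(), [_frame_with_pair(1.5)], cutoff_nm=0.6) == []

    def test_fluctuating_geometry_uses_mean_of_minima(self, rng):
        dists = rng.uniform(0.3, 1.2, size=15)
        frames = [_frame_with_pair(d) for d in dists]
        oracle = float(np.mean(dists - 0.1))  # min O-O is inner-oxygen gap
        assert pair_min_oo_distance("E795", "E820", frames) == pytest.approx(oracle)
        kept = proximity_filter(self._pair(), frames, cutoff_nm=0.6)
        assert bool(kept) == (oracle <= 0.6)

    def test_missing_atoms_is_structural_error(self):
        frame = PocketFrame(0.0, {"E795": np.zeros((2, 3))})
        with pytest.raises(StructuralDataError):
            proximity_filter(self._pair(), [frame], cutoff_nm=0.6)


def _pairs_from_counts(counts):
    """Build per-trajectory TransferPair lists reproducing a donor/acceptor count table."""
    pairs = []
    for (donor, acceptor), m in counts.items():
        for rep in range(m):
            # each instance from a distinct (state, replicate); state must
            # protonate the donor and not the acceptor
            label = donor + "+"
            mat = _matrix({(donor, acceptor): -0.8}, label)
            mat.replicate = rep
            pairs.extend(candidate_pairs(mat))
    return pairs


class TestAggregation:
    TABLE = {
        ("E795", "E820"): 5,
        ("E820", "E795"): 5,
        ("E820", "E343"): 4,
        ("E343", "E820"): 2,
        ("D824", "E795"): 2,
        ("E820", "D824"): 1,
        ("D942", "E795"): 1,
        ("D942", "D824"): 1,
    }

    def test_reproduces_instance_table(self):
        net = aggregate_network(_pairs_from_counts(self.TABLE))
        assert net.instance_count("E795", "E820") == 5
        assert net.instance_count("D942", "E795") == 1
        table = network_to_table(net)
        got = {(d.rstrip("+"), a): int(n) for d, a, n in table.itertuples(index=False)}
        assert got == self.TABLE

    def test_instance_conservation(self):
        pairs = _pairs_from_counts(self.TABLE)
        net = aggregate_network(pairs)
        assert net.total_instances == len(pairs) == sum(self.TABLE.values())

    def test_single_trajectory_single_edge(self):
        net = aggregate_network(_pairs_from_counts({("E795", "E820"): 1}))
        assert net.edges() == [("E795", "E820", 1)]

    def test_duplicates_deduplicated_with_warning(self):
        pairs = _pairs_from_counts({("E795", "E820"): 1})
        with pytest.warns(UserWarning, match="duplicate"):
            net = aggregate_network(pairs * 2)
        assert net.instance_count("E795", "E820") == 1

    def test_ranking_matches_sort_oracle(self, rng):
        counts = dict(self.TABLE)
        net = aggregate_network(_pairs_from_counts(counts))
        ranking = rank_transfer_likelihood(net)
        values = [e["instances"] for e in ranking]
        assert values == sorted(values, reverse=True)
        # the glutamate exchange pair outranks the single-instance aspartate routes
        top2 = {(e["donor"], e["acceptor"]) for e in ranking[:2]}
        assert top2 == {("E795", "E820"), ("E820", "E795")}

    def test_empty_network_empty_report(self):
        assert rank_transfer_likelihood(aggregate_network([])) == []


class TestExport:
    def test_formats_and_depth_annotation(self, tmp_path):
        net = aggregate_network(_pairs_from_counts({("E795", "E820"): 3}))
        frame = _frame_with_pair(0.4)
        depths = residue_depths([frame], np.array([0.0, 0.0, 1.0]))
        assert depths["E795"] == pytest.approx(np.linalg.norm([0.05, 0.0, -1.0]))
        export_network(net, tmp_path / "n.json", "json", depths=depths)
        export_network(net, tmp_path / "n.dot", "dot")
        export_network(net, tmp_path / "n.csv", "csv")
        dot = (tmp_path / "n.dot").read_text()
        assert '"E795" -> "E820" [weight=3' in dot
        with pytest.raises(ValueError, match="format"):
            export_network(net, tmp_path / "n.x", "xml")
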