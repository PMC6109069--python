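"""Statistical contracts of the synthetic-data generators."""

import numpy as np
import pytest

from protonpocket.correlation import correlation_matrix, pearson_r
from protonpocket.errors import SyntheticSpecError
from protonpocket.ions import SITE_III, binding_trace
from protonpocket.pka import StandInParams, estimate_pka_frame
from protonpocket.states import enumerate_states, parse_label
from protonpocket.synth import (
    IonKineticsSpec,
    PkaEnsembleSpec,
    UmbrellaLayout,
    FLAT_POTENTIAL,
    gen_ion_trajectory,
    gen_pka_ensemble,
    gen_pka_series,
    gen_pocket_structure,
    gen_umbrella_samples,
    make_target_matrix,
    occupancy_target,
    read_window_samples,
    write_window_samples,
)
from protonpocket.network import pair_min_oo_distance


class TestPkaGenerator:
    def test_identity_target_gives_null_correlations(self):
        # independent residues, uncorrelated samples: |r| < 0.3 for at least
        # 95% of (replicate, pair) draws at n = 100
        spec = PkaEnsembleSpec(seed=3, n_frames=250, ar_tau_ns=1e-9)
        state = parse_label("E343+E795+")
        n_rep, below = 40, 0
        total = 0
        for rep in range(n_rep):
            series = gen_pka_series(state, rep, spec)
            mat = correlation_matrix(series, window_ns=100)
            off = np.abs(mat.r[np.triu_indices(5, k=1)])
            below += int(np.sum(off < 0.3))
            total += off.size
        assert below >= 0.95 * total

    def test_autocorrelated_null_widens_r_distribution(self):
        # the default 5 ns autocorrelation time leaves ~10 effective samples
        # per 100 ns window, so null |r| values spread far beyond the iid case
        state = parse_label("E343+E795+")
        spreads = {}
        for tau in (1e-9, 5.0):
            spec = PkaEnsembleSpec(seed=3, n_frames=250, ar_tau_ns=tau)
            rs = []
            for rep in range(30):
                mat = correlation_matrix(gen_pka_series(state, rep, spec), window_ns=100)
                rs.extend(np.abs(mat.r[np.triu_indices(5, k=1)]))
            spreads[tau] = np.std(rs)
        assert spreads[5.0] > 1.5 * spreads[1e-9]

    def test_planted_pair_mean_r_recovered(self):
        spec = PkaEnsembleSpec(seed=5, n_frames=100, ar_tau_ns=1e-9,
                               planted_pairs={("E795", "E820"): -0.923})
        state = parse_label("E795+D824+D942+")
        rs = []
        for rep in range(100):
            series = gen_pka_series(state, rep, spec)
            rs.append(pearson_r(series.column("E795"), series.column("E820")))
        assert np.mean(rs) == pytest.approx(-0.923, abs=0.05)

    def test_change_point_swaps_pair_means(self):
        spec = PkaEnsembleSpec(seed=1, n_frames=250,
                               change_point=(150.0, "E795", "E820"))
        state = parse_label("E795+D824+D942+")  # E795 protonated: higher mean
        series = gen_pka_series(state, 0, spec)
        before = series.times < 150
        e795, e820 = series.column("E795"), series.column("E820")
        assert e795[before].mean() > e820[before].mean()
        assert e795[~before].mean() < e820[~before].mean()

    def test_non_psd_target_rejected(self):
        with pytest.raises(SyntheticSpecError):
            make_target_matrix(
                ("A", "B", "C"),
                {("A", "B"): -0.95, ("B", "C"): -0.95, ("A", "C"): -0.95},
            )

    def test_bit_reproducible_per_seed(self):
        spec = PkaEnsembleSpec(seed=9)
        s1 = gen_pka_series(parse_label("E343+E820+"), 1, spec, state_index=4)
        s2 = gen_pka_series(parse_label("E343+E820+"), 1, spec, state_index=4)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_ensemble_covers_states_and_replicates(self):
        states = enumerate_states()[:4]
        ens = gen_pka_ensemble(PkaEnsembleSpec(seed=0), states=states, replicates=2)
        assert len(ens) == 8
        assert all(v.n_frames == 250 for v in ens.values())


class TestPocketStructure:
    def test_e795_e820_proximal_by_default(self):
        frame = gen_pocket_structure()
        assert pair_min_oo_distance("E795", "E820", [frame]) < 0.6

    def test_scaled_template_breaks_all_proximity(self):
        frame = gen_pocket_structure(scale=3.0)
        names = list(frame.oxygens)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert pair_min_oo_distance(a, b, [frame]) > 0.6

    def test_standin_pka_matches_term_oracle_on_template(self):
        params = StandInParams()
        state = parse_label("E795+D824+")
        frame = gen_pocket_structure(state=state)
        got = estimate_pka_frame(frame, "E343", params)
        # independent term-by-term evaluation from the template coordinates
        centroid = frame.oxygens["E343"].mean(axis=0)
        n_heavy = int(np.sum(np.linalg.norm(frame.heavy_atoms - centroid, axis=1)
                             <= params.r_burial_nm))
        expected = params.model_pka_glu + np.clip(
            params.w_burial * (n_heavy - params.n_ref), 0, params.max_burial_shift)
        d_k791 = np.linalg.norm(frame.k791 - centroid)
        if d_k791 <= params.r_charge_nm:
            expected -= params.w_charge / d_k791
        for other in ("E820", "D942"):  # the deprotonated residues in this state
            d = np.linalg.norm(frame.oxygens[other].mean(axis=0) - centroid)
            if d <= params.r_charge_nm:
                expected += params.w_charge / d
        assert got == pytest.approx(expected)


class TestIonGenerator:
    def test_zero_target_never_binds(self):
        spec = IonKineticsSpec(seed=0, two_proton_target=0.0, site_iii_share=0.0)
        frames = gen_ion_trajectory(spec, parse_label("E343+E795+"), 0, n_frames=40)
        trace = binding_trace(frames, state=parse_label("E343+E795+"))
        assert trace.first_binding_time_ns == {}

    def test_group_targets_match_design_means(self):
        spec = IonKineticsSpec()
        states = enumerate_states()
        totals = {2: [], 3: []}
        for s in states:
            totals[s.n_protons].append(sum(occupancy_target(s, spec)))
        assert np.mean(totals[2]) == pytest.approx(1.87, abs=1e-9)
        assert np.mean(totals[3]) == pytest.approx(1.10, abs=0.005)

    def test_endpoint_counts_match_targets_in_expectation(self):
        spec = IonKineticsSpec(seed=2)
        state = parse_label("E795+E820+D824+")  # 3 protons, target 1.01
        ends = []
        for rep in range(40):
            frames = gen_ion_trajectory(spec, state, rep, n_frames=30)
            ends.append(sum(binding_trace(frames, state=state).end_counts().values()))
        assert np.mean(ends) == pytest.approx(1.01, abs=0.15)

    def test_site_iii_appears_when_both_aspartates_deprotonated(self):
        spec = IonKineticsSpec(seed=4)
        state = parse_label("E343+E795+")  # D824/D942 both deprotonated
        n_site3 = 0
        for rep in range(20):
            frames = gen_ion_trajectory(spec, state, rep, n_frames=25)
            n_site3 += binding_trace(frames, state=state).end_counts()[SITE_III]
        assert n_site3 > 0

    def test_deterministic_per_seed(self):
        spec = IonKineticsSpec(seed=6)
        s = parse_label("E343+D824+")
        f1 = gen_ion_trajectory(spec, s, 2, n_frames=10, state_index=3)
        f2 = gen_ion_trajectory(spec, s, 2, n_frames=10, state_index=3)
        for a, b in zip(f1, f2):
            for ion in a.ions:
                np.testing.assert_array_equal(a.ions[ion], b.ions[ion])


class TestUmbrellaGenerator:
    def test_flat_potential_gaussian_limit(self):
        layout = UmbrellaLayout(z_min=1.0, z_max=1.2, spacing=0.1)
        windows = gen_umbrella_samples(FLAT_POTENTIAL, layout, n_samples=30000, seed=3)
        from protonpocket.constants import kt_kj_per_mol
        sigma2 = kt_kj_per_mol(layout.temperature_k) / layout.force_constant
        for w in windows:
            assert w.samples.mean() == pytest.approx(w.center, abs=4e-4)
            assert w.samples.var() == pytest.approx(sigma2, rel=0.05)

    def test_harmonic_potential_completes_the_square(self):
        # U = ku/2 (z - zu)^2 plus bias k/2 (z - c)^2 is Gaussian with
        # mean (k c + ku zu)/(k + ku) and variance kT/(k + ku)
        ku, zu = 2000.0, 0.9
        layout = UmbrellaLayout(z_min=0.6, z_max=0.7, spacing=0.1)
        pot = lambda z: 0.5 * ku * (np.asarray(z) - zu) ** 2
        windows = gen_umbrella_samples(pot, layout, n_samples=30000, seed=7)
        from protonpocket.constants import kt_kj_per_mol
        kt = kt_kj_per_mol(layout.temperature_k)
        for w in windows:
            k = layout.force_constant
            mean = (k * w.center + ku * zu) / (k + ku)
            assert w.samples.mean() == pytest.approx(mean, abs=5e-4)
            assert w.samples.var() == pytest.approx(kt / (k + ku), rel=0.05)

    def test_autocorrelated_mode_preserves_marginal(self):
        layout = UmbrellaLayout(z_min=0.5, z_max=0.6, spacing=0.1)
        iid = gen_umbrella_samples(FLAT_POTENTIAL, layout, n_samples=20000,
                                   seed=11, autocorr_samples=1)
        ar = gen_umbrella_samples(FLAT_POTENTIAL, layout, n_samples=20000,
                                  seed=11, autocorr_samples=8)
        for wi, wa in zip(iid, ar):
            assert wa.samples.mean() == pytest.approx(wi.samples.mean(), abs=2e-3)
            assert wa.samples.std() == pytest.approx(wi.samples.std(), rel=0.1)
            # and the AR stream really is autocorrelated
            x = wa.samples - wa.samples.mean()
            rho1 = (x[:-1] @ x[1:]) / (x @ x)
            assert rho1 > 0.6

    def test_window_file_round_trip(self, tmp_path):
        (window,) = gen_umbrella_samples(
            FLAT_POTENTIAL, UmbrellaLayout(z_min=0.5, z_max=0.6, spacing=0.1),
            n_samples=100, seed=1,
        )[:1]
        p = tmp_path / "window.dat"
        write_window_samples(window, p, seed=1)
        back = read_window_samples(p)
        assert back.center == pytest.approx(window.center)
        assert back.force_constant == pytest.approx(window.force_constant)
        np.testing.assert_array_equal(back.samples, window.samples)

    def test_divergent_potential_rejected(self):
        bad = lambda z: np.full_like(np.asarray(z, dtype=float), np.nan)
        with pytest.raises(SyntheticSpecError):
            gen_umbrella_samples(bad, UmbrellaLayout(z_min=0.5, z_max=0.6, spacing=0.1),
                                 n_samples=10, seed=0)
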