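"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without MD trajectories or downloads:

* pKa ensembles: stationary Gaussian AR(1) series (default 250 frames at
  1 ns, autocorrelation time 5 ns) whose cross-residue correlation is set by
  a Cholesky-factorised target matrix; pairs such as E795/E820 can be planted
  at a prescribed coefficient (e.g. rho = -0.923), and an optional
  change-point mode swaps a pair's means mid-trajectory to mimic abrupt
  pKa exchanges.
* Ion trajectories: candidate K+ ions bind the pocket by exponential waiting
  times calibrated so end-of-run bound counts hit per-state targets in
  expectation (group means 1.87 for two-proton and 1.10 for three-proton
  states, with a planted negative trend in protonated-glutamate count).
* Umbrella windows: Boltzmann samples from a known 1-D potential under
  harmonic biases (47 windows, 0.20-2.50 nm, 0.05 nm spacing,
  k = 5000 kJ/mol nm^2, 310 K) via inverse-CDF on a fine grid, with a
  Gaussian-copula AR(1) reshuffle imposing a stated autocorrelation time.

Generators are bit-reproducible given (seed, spec); no physical realism is
claimed beyond the statistical structure the analysis consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .constants import DEFAULT_TEMPERATURE_K, KB_KJ_PER_MOL_K
from .errors import SyntheticSpecError
from .pka import PkaSeries, PocketFrame
from .pmf import UmbrellaWindow, generate_windows
from .states import POCKET, ProtonationState, enumerate_states

POCKET_NAMES = tuple(r.name for r in POCKET)

_DOMAIN_PKA, _DOMAIN_IONS, _DOMAIN_UMBRELLA = 1, 2, 3


def _rng(seed: int, domain: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(domain, *key))
    )


def spec_digest(spec) -> str:
    """Short stable hash of a spec dataclass, for provenance headers."""
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pKa ensembles

@dataclass
class PkaEnsembleSpec:
    """Statistical design of the synthetic pKa ensemble."""

    seed: int = 0
    n_frames: int = 250
    interval_ns: float = 1.0
    ar_tau_ns: float = 5.0  # autocorrelation time; ~20 effective samples per 100 ns
    base_sd: float = 0.8  # per-residue pKa standard deviation
    protonated_mean_shift: float = 2.0  # protonated residues sit at higher mean pKa
    planted_pairs: dict = field(default_factory=dict)  # (resA, resB) -> rho
    planted_states: tuple[str, ...] | None = None  # labels; None = all states
    change_point: tuple[float, str, str] | None = None  # (t_ns, resA, resB): swap means


def make_target_matrix(
    residues: Sequence[str], planted: Mapping[tuple[str, str], float]
) -> np.ndarray:
    """Identity-based correlation target with planted pair coefficients; must be PSD."""
    k = len(residues)
    idx = {r: i for i, r in enumerate(residues)}
    target = np.eye(k)
    for (a, b), rho in planted.items():
        if a in idx and b in idx:
            target[idx[a], idx[b]] = target[idx[b], idx[a]] = rho
    try:
        np.linalg.cholesky(target + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as exc:
        raise SyntheticSpecError("target correlation matrix is not positive semi-definite") from exc
    return target


def gen_pka_series(
    state: ProtonationState,
    replicate: int,
    spec: PkaEnsembleSpec,
    state_index: int = 0,
) -> PkaSeries:
    """One synthetic pKa trajectory for (state, replicate); deterministic per seed."""
    residues = POCKET_NAMES
    planted = spec.planted_pairs
    if spec.planted_states is not None and state.label not in spec.planted_states:
        planted = {}
    target = make_target_matrix(residues, planted)
    chol = np.linalg.cholesky(target + 1e-12 * np.eye(len(residues)))

    rng = _rng(spec.seed, _DOMAIN_PKA, state_index, replicate)
    n, k = spec.n_frames, len(residues)
    phi = float(np.exp(-spec.interval_ns / spec.ar_tau_ns))
    innov_sd = np.sqrt(1.0 - phi**2)
    e = np.empty((n, k))
    e[0] = rng.standard_normal(k)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov_sd * rng.standard_normal(k)
    corr = e @ chol.T  # unit-variance series with the target cross-correlation

    means = np.array([
        (4.5 if r.startswith("E") else 3.8) +
        (spec.protonated_mean_shift if state.is_protonated(r) else 0.0)
        for r in residues
    ])
    values = means[None, :] + spec.base_sd * corr

    times = np.arange(n, dtype=float) * spec.interval_ns
    if spec.change_point is not None:
        t_switch, ra, rb = spec.change_point
        ia, ib = residues.index(ra), residues.index(rb)
        after = times >= t_switch
        delta = means[ib] - means[ia]
        values[after, ia] += delta
        values[after, ib] -= delta
    return PkaSeries(residues, times, values, spec.interval_ns, state=state, replicate=replicate)


def gen_pka_ensemble(
    spec: PkaEnsembleSpec,
    states: Sequence[ProtonationState] | None = None,
    replicates: int = 3,
) -> dict[tuple[str, int], PkaSeries]:
    """Full ensemble of pKa trajectories keyed by (state label, replicate)."""
    if states is None:
        states = enumerate_states()
    out = {}
    for si, state in enumerate(states):
        for rep in range(replicates):
            out[(state.label, rep)] = gen_pka_series(state, rep, spec, state_index=si)
    return out


# ---------------------------------------------------------------------------
# Pocket geometry and ion trajectories

#: Carboxylate centroids (nm): glutamates ring the site I/II locus near the
#: luminal mouth (+z up the exit pathway); aspartates sit deeper at site III.
_CENTROIDS = {
    "E343": np.array([0.30, 0.00, 0.00]),
    "E795": np.array([0.05, 0.22, 0.00]),
    "E820": np.array([0.05, -0.22, 0.00]),
    "D824": np.array([-0.35, 0.10, -0.30]),
    "D942": np.array([-0.35, -0.10, -0.30]),
}
_O_OFFSET = np.array([0.06, 0.0, 0.0])
SITE_I_II_LOCUS = np.array([0.12, 0.0, 0.02])
SITE_III_LOCUS = np.array([-0.30, 0.0, -0.30])
BULK_POSITION = np.array([0.0, 0.0, 3.0])
K791_POSITION = np.array([0.15, 0.0, -0.15])
LUMINAL_ACCESS_POINT = np.array([0.1, 0.0, 1.2])


def gen_pocket_structure(
    scale: float = 1.0,
    n_shell_atoms: int = 12,
    shell_radius_nm: float = 0.55,
    state: ProtonationState | None = None,
    time_ns: float = 0.0,
) -> PocketFrame:
    """Reproducible toy pocket geometry (E795/E820 proximal by construction).

    ``scale`` multiplies all coordinates, so scaled-up templates fail the
    proximity filter as expected. Shell atoms are placed deterministically on
    a golden-angle spiral for burial counting.
    """
    oxygens = {
        name: scale * np.stack([c + _O_OFFSET, c - _O_OFFSET])
        for name, c in _CENTROIDS.items()
    }
    i = np.arange(n_shell_atoms)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zs = 1.0 - 2.0 * (i + 0.5) / max(n_shell_atoms, 1)
    rad = np.sqrt(np.clip(1.0 - zs**2, 0.0, 1.0))
    shell = scale * shell_radius_nm * np.stack(
        [rad * np.cos(golden * i), rad * np.sin(golden * i), zs], axis=1
    )
    return PocketFrame(
        time_ns=time_ns,
        oxygens=oxygens,
        ions={},
        k791=scale * K791_POSITION,
        heavy_atoms=shell,
        state=state,
    )


@dataclass
class IonKineticsSpec:
    """Calibration of the stochastic K+ binding generator.

    End-of-run targets: a flat 1.87 bound K+ for two-proton states (with a
    site III share when both aspartates are deprotonated) and
    1.91 - 0.45 * (#protonated Glu) for three-proton states, whose
    state-weighted mean over the ten three-proton states is 1.10.
    """

    seed: int = 0
    n_candidate_ions: int = 4
    two_proton_target: float = 1.87
    three_proton_intercept: float = 1.91
    three_proton_glu_slope: float = 0.45
    site_iii_share: float = 0.5  # of the total target, when both Asp deprotonated
    unbind_rate_per_ns: float = 0.0
    position_jitter_nm: float = 0.01


def occupancy_target(state: ProtonationState, spec: IonKineticsSpec) -> tuple[float, float]:
    """(site I/II, site III) expected end-of-run bound counts for a state."""
    both_asp_deprot = not state.is_protonated("D824") and not state.is_protonated("D942")
    if state.n_protons == 3:
        g = state.n_protonated_of_class("glutamate")
        total = max(spec.three_proton_intercept - spec.three_proton_glu_slope * g, 0.0)
        return (total, 0.0)
    total = spec.two_proton_target
    if both_asp_deprot:
        t3 = spec.site_iii_share
        return (total - t3, t3)
    return (total, 0.0)


def gen_ion_trajectory(
    spec: IonKineticsSpec,
    state: ProtonationState,
    replicate: int = 0,
    n_frames: int = 250,
    interval_ns: float = 1.0,
    state_index: int = 0,
    geometry_scale: float = 1.0,
) -> list[PocketFrame]:
    """Frames with stochastic K+ binding to the pocket loci.

    Each candidate ion binds by an exponential waiting time calibrated so
    the probability of being bound by the end of the run equals
    target / n_candidates; bound ions sit at their site locus (with jitter),
    unbound ions in bulk. Deterministic per (seed, state, replicate).
    """
    if spec.unbind_rate_per_ns < 0:
        raise SyntheticSpecError("unbind rate must be >= 0")
    t12, t3 = occupancy_target(state, spec)
    total = t12 + t3
    n_cand = spec.n_candidate_ions
    if total > n_cand:
        raise SyntheticSpecError("occupancy target exceeds candidate ion count")
    rng = _rng(spec.seed, _DOMAIN_IONS, state_index, replicate)
    duration = (n_frames - 1) * interval_ns

    # Endpoint-count target hit with low dispersion: floor(target) ions bind
    # for sure plus one more with the fractional probability; binding times
    # are truncated-exponential (many events early, some as late as the end).
    n_bind = int(np.floor(total)) + int(rng.random() < (total - np.floor(total)))
    bound_ions = rng.permutation(n_cand)[:n_bind]
    bind_times = np.full(n_cand, np.inf)
    unbind_times = np.full(n_cand, np.inf)
    sites = ["site_I_II"] * n_cand
    for i in bound_ions:
        u = rng.random()
        lam = 3.0 / max(duration, 1e-9)  # mean waiting time = duration / 3
        bind_times[i] = -np.log(1.0 - u * (1.0 - np.exp(-lam * duration))) / lam
        if spec.unbind_rate_per_ns > 0:
            unbind_times[i] = bind_times[i] + rng.exponential(1.0 / spec.unbind_rate_per_ns)
        if total > 0 and rng.random() < t3 / total:
            sites[i] = "site_III"

    template = gen_pocket_structure(geometry_scale, state=state)
    site_pos = {"site_I_II": geometry_scale * SITE_I_II_LOCUS,
                "site_III": geometry_scale * SITE_III_LOCUS}
    # Spread simultaneous site I/II occupants slightly so both stay coordinated
    lateral = [np.array([0.0, 0.04, 0.0]), np.array([0.0, -0.04, 0.0]),
               np.array([0.04, 0.0, 0.0]), np.array([-0.04, 0.0, 0.0])]

    frames: list[PocketFrame] = []
    for f in range(n_frames):
        t = f * interval_ns
        ions = {}
        for i in range(n_cand):
            ion_id = f"K{i + 1}"
            if bind_times[i] <= t < unbind_times[i]:
                base = site_pos[sites[i]] + lateral[i % len(lateral)]
            else:
                base = BULK_POSITION + np.array([0.4 * i, 0.0, 0.1 * i])
            jitter = spec.position_jitter_nm * rng.standard_normal(3)
            ions[ion_id] = base + jitter
        frames.append(PocketFrame(
            time_ns=t, oxygens=template.oxygens, ions=ions,
            k791=template.k791, heavy_atoms=template.heavy_atoms, state=state,
        ))
    return frames


def gen_ion_frames_fixed(
    placements: Mapping[str, str],
    state: ProtonationState | None = None,
    n_frames: int = 1,
    interval_ns: float = 1.0,
) -> list[PocketFrame]:
    """Deterministic frames with ions pinned at named sites
    (``{"K1": "site_I_II", "K2": "site_III"}``); for constructed scenarios."""
    template = gen_pocket_structure(state=state)
    site_pos = {"site_I_II": SITE_I_II_LOCUS, "site_III": SITE_III_LOCUS,
                "bulk": BULK_POSITION}
    lateral = [np.array([0.0, 0.04, 0.0]), np.array([0.0, -0.04, 0.0])]
    used: dict[str, int] = {}
    ions = {}
    for ion_id, site in placements.items():
        k = used.get(site, 0)
        used[site] = k + 1
        ions[ion_id] = site_pos[site] + (lateral[k % 2] if site == "site_I_II" else 0.0)
    return [
        PocketFrame(time_ns=f * interval_ns, oxygens=template.oxygens,
                    ions=dict(ions), k791=template.k791,
                    heavy_atoms=template.heavy_atoms, state=state)
        for f in range(n_frames)
    ]


# ---------------------------------------------------------------------------
# Umbrella sampling

@dataclass
class UmbrellaLayout:
    """Window layout and thermodynamic conditions of the sampling runs."""

    z_min: float = 0.20
    z_max: float = 2.50
    spacing: float = 0.05
    force_constant: float = 5000.0  # kJ/mol nm^2
    temperature_k: float = DEFAULT_TEMPERATURE_K


def gaussian_wells_potential(
    wells: Sequence[tuple[float, float, float]],
) -> Callable[[np.ndarray], np.ndarray]:
    """Sum of Gaussians U(z) = sum_i amp_i exp(-(z-z_i)^2 / 2 w_i^2), kJ/mol."""
    def u(z):
        z = np.asarray(z, dtype=float)
        total = np.zeros_like(z)
        for z0, amp, width in wells:
            total = total + amp * np.exp(-((z - z0) ** 2) / (2.0 * width**2))
        return total
    return u


#: Default generator potential: a binding well at 0.5 nm (-12 kJ/mol) and a
#: barrier at 1.1 nm (+6 kJ/mol), flat (0) in bulk; barrier height from the
#: well bottom is ~7 k_B T at 310 K.
DEFAULT_BINDING_POTENTIAL = gaussian_wells_potential([(0.5, -12.0, 0.12), (1.1, 6.0, 0.12)])

FLAT_POTENTIAL = gaussian_wells_potential([])


def gen_umbrella_samples(
    potential: Callable[[np.ndarray], np.ndarray] = DEFAULT_BINDING_POTENTIAL,
    layout: UmbrellaLayout | None = None,
    n_samples: int = 4000,
    autocorr_samples: float = 1.0,
    seed: int = 0,
    grid_points: int = 10_000,
    grid_pad_nm: float = 0.15,
) -> list[UmbrellaWindow]:
    """Boltzmann-distributed window samples from a known potential.

    Per window, p_i(z) is proportional to exp(-beta [U(z) + k/2 (z - z_i)^2]),
    sampled by inverse-CDF on a fine grid. For ``autocorr_samples`` > 1 the
    uniforms come from a Gaussian-copula AR(1) stream, imposing the stated
    autocorrelation time while preserving the marginal exactly.
    """
    layout = layout or UmbrellaLayout()
    centers = generate_windows(layout.z_min, layout.z_max, layout.spacing)
    beta = 1.0 / (KB_KJ_PER_MOL_K * layout.temperature_k)
    grid = np.linspace(layout.z_min - grid_pad_nm, layout.z_max + grid_pad_nm, grid_points)
    u_grid = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(u_grid)):
        raise SyntheticSpecError("potential is not finite on the sampling grid")
    phi = float(np.exp(-1.0 / autocorr_samples)) if autocorr_samples > 1 else 0.0

    windows = []
    for wi, c in enumerate(centers):
        logw = -beta * (u_grid + 0.5 * layout.force_constant * (grid - c) ** 2)
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise SyntheticSpecError(f"unnormalizable biased density at window {c:.3f} nm")
        # midpoint CDF: treat each grid weight as a cell mass centred on its
        # node, otherwise every sample shifts by half a cell and the stiff
        # harmonic bias turns that into a systematic tilt of the WHAM profile
        cdf = (np.cumsum(w) - 0.5 * w) / total
        rng = _rng(seed, _DOMAIN_UMBRELLA, wi)
        if phi > 0:
            a = np.empty(n_samples)
            a[0] = rng.standard_normal()
            innov = np.sqrt(1 - phi**2) * rng.standard_normal(n_samples)
            for t in range(1, n_samples):
                a[t] = phi * a[t - 1] + innov[t]
            uniforms = norm.cdf(a)
        else:
            uniforms = rng.random(n_samples)
        samples = np.interp(uniforms, cdf, grid)
        windows.append(UmbrellaWindow(float(c), layout.force_constant, samples))
    return windows


def gen_pull_trace(
    z_start: float = 0.15,
    z_end: float = 2.60,
    n_frames: int = 5000,
    noise_nm: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic steered-pull reaction-coordinate trace (monotone drift + noise)."""
    rng = np.random.default_rng(seed)
    base = np.linspace(z_start, z_end, n_frames)
    return base + noise_nm * rng.standard_normal(n_frames)


# ---------------------------------------------------------------------------
# File output in the formats the analysis modules read

def write_window_samples(
    window: UmbrellaWindow, path: str | Path, interval_ps: float = 10.0,
    seed: int | None = None,
) -> None:
    """Two-column (time_ps, z_nm) pull-style file with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# protonpocket umbrella window | center_nm={window.center:.6f} "
                 f"| force_constant_kjmolnm2={window.force_constant:.6f}"
                 + (f" | seed={seed}" if seed is not None else "") + "\n")
        for i, z in enumerate(window.samples):
            fh.write(f"{i * interval_ps:.1f}\t{format(z, '.17g')}\n")


def read_window_samples(path: str | Path) -> UmbrellaWindow:
    path = Path(path)
    center = force = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").split("|"):
            tok = tok.strip()
            if tok.startswith("center_nm="):
                center = float(tok.split("=", 1)[1])
            elif tok.startswith("force_constant_kjmolnm2="):
                force = float(tok.split("=", 1)[1])
    if center is None or force is None:
        raise SyntheticSpecError(f"window file {path} lacks center/force-constant header")
    data = np.loadtxt(path, comments="#")
    samples = np.atleast_2d(data)[:, 1]
    return UmbrellaWindow(center, force, samples)
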