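"""Umbrella-sampling window planning and 1-D WHAM potentials of mean force.

Windows restrain the K+ ion along z with harmonic biases (default layout:
47 windows from 0.20 to 2.50 nm at 0.05 nm spacing, force constant
5000 kJ/mol nm^2, T = 310 K). The weighted histogram analysis method (WHAM)
self-consistently solves

    P(z_b) = sum_i n_i(b) / sum_i N_i exp(beta (f_i - U_i(z_b)))
    exp(-beta f_i) = sum_b P(z_b) exp(-beta U_i(z_b))

for the unbiased distribution P and the window free-energy constants f_i,
giving G(z) = -k_B T ln P(z). Errors come from a block bootstrap over each
window's (autocorrelated) time series. Profiles are conventionally shifted
so the bulk region is zero; the binding free energy is the well minimum on
that scale.

The lateral flat-bottom cylindrical restraint used when generating window
samples does not enter the 1-D estimator; it only shapes the sampled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE_K, KB_KJ_PER_MOL_K
from .errors import (
    ConfigError,
    ConvergenceError,
    CoverageError,
    HistogramOverlapError,
    WindowLayoutError,
)

logger = logging.getLogger(__name__)

DEFAULT_FORCE_CONSTANT = 5000.0  # kJ/mol nm^2
DEFAULT_N_BINS = 200
DEFAULT_TOL_KT = 1e-7
DEFAULT_MAX_ITER = 100_000
DEFAULT_N_BOOT = 200
DEFAULT_BLOCK_LENGTH = 50


@dataclass
class UmbrellaWindow:
    """One biased window: harmonic center, force constant, post-equilibration samples."""

    center: float  # nm
    force_constant: float = DEFAULT_FORCE_CONSTANT  # kJ/mol nm^2
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    equil_discard_ns: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


@dataclass
class PmfProfile:
    """Binned 1-D free-energy profile; NaN marks unsampled bins."""

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol
    temperature_k: float = DEFAULT_TEMPERATURE_K
    errors: np.ndarray | None = None  # kJ/mol, per bin
    bin_edges: np.ndarray | None = None
    anchor_region: tuple[float, float] | None = None
    n_iterations: int = 0
    window_offsets: np.ndarray | None = None  # converged beta*f_i

    @property
    def free_energy_kt(self) -> np.ndarray:
        return self.free_energy / (KB_KJ_PER_MOL_K * self.temperature_k)

    def sampled(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def generate_windows(z_min: float, z_max: float, spacing: float) -> np.ndarray:
    """Equidistant window centers from z_min to z_max inclusive (floating-point safe)."""
    if z_max <= z_min or spacing <= 0:
        raise ValueError("require z_max > z_min and spacing > 0")
    n = int(round((z_max - z_min) / spacing)) + 1
    if abs(z_min + (n - 1) * spacing - z_max) > 1e-9:
        raise WindowLayoutError(
            f"span [{z_min}, {z_max}] is not commensurate with spacing {spacing}"
        )
    return np.linspace(z_min, z_max, n)


def select_initial_frames(pull_trace: Sequence[float], centers: Sequence[float]) -> np.ndarray:
    """Index of the frame nearest each window center; earliest frame wins ties."""
    trace = np.asarray(pull_trace, dtype=float)
    centers = np.asarray(centers, dtype=float)
    lo, hi = trace.min(), trace.max()
    for c in centers:
        if not lo <= c <= hi:
            raise CoverageError(
                f"window center {c} nm outside pull-trace range [{lo:.4f}, {hi:.4f}] nm"
            )
    # np.argmin returns the first minimiser -> earliest-frame tie-break
    return np.array([int(np.argmin(np.abs(trace - c))) for c in centers])


def _bias_log_weights(
    windows: Sequence[UmbrellaWindow], bin_edges: np.ndarray, beta: float
) -> np.ndarray:
    """log of the bin-averaged bias Boltzmann factor, per window and bin.

    The harmonic bias varies strongly within a bin (beta*k*h^2 is not small
    at typical force constants), so using the bin-center value accumulates a
    stitching drift across windows. The bin average
    (1/h) int_bin exp(-beta k/2 (z - c)^2) dz has an erf closed form and
    removes the leading discretisation bias. Zero-force-constant windows
    reduce to a flat factor.
    """
    from scipy.special import erf

    lo, hi = bin_edges[:-1], bin_edges[1:]
    h = hi - lo
    centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    out = np.empty((len(windows), lo.size))
    for i, (c, k) in enumerate(zip(centers, ks)):
        if beta * k <= 0:
            out[i] = 0.0
            continue
        a = np.sqrt(beta * k / 2.0)
        integral = np.sqrt(np.pi) / (2.0 * a) * (erf(a * (hi - c)) - erf(a * (lo - c)))
        with np.errstate(divide="ignore"):
            out[i] = np.log(np.maximum(integral, 0.0)) - np.log(h)
    return out


def _check_overlap(windows: Sequence[UmbrellaWindow], counts: np.ndarray) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise HistogramOverlapError(
                f"no histogram overlap between windows at {windows[a].center:.3f} nm "
                f"and {windows[b].center:.3f} nm"
            )


def wham(
    windows: Sequence[UmbrellaWindow],
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    n_bins: int = DEFAULT_N_BINS,
    tol: float = DEFAULT_TOL_KT,
    max_iter: int = DEFAULT_MAX_ITER,
    bin_edges: np.ndarray | None = None,
    check_overlap: bool = True,
    g_init: np.ndarray | None = None,
) -> PmfProfile:
    """Self-consistent 1-D WHAM solution over equal-width bins.

    Iterates the window constants until max |delta(beta f_i)| < ``tol``
    (units of k_B T); non-convergence raises :class:`ConvergenceError` with
    the final residual. With a single unbiased window the estimator reduces
    exactly to Boltzmann inversion of the histogram. The returned profile is
    unshifted (normalised so its sampled minimum is zero); use
    :func:`align_pmf` for the bulk-zero convention.
    """
    windows = [w for w in windows if w.samples.size > 0]
    if not windows:
        raise ValueError("no non-empty windows")
    kt = KB_KJ_PER_MOL_K * temperature_k
    beta = 1.0 / kt

    if bin_edges is None:
        zmin = min(w.samples.min() for w in windows)
        zmax = max(w.samples.max() for w in windows)
        if zmax <= zmin:
            zmax = zmin + 1e-6
        bin_edges = np.linspace(zmin, zmax, n_bins + 1)
    else:
        bin_edges = np.asarray(bin_edges, dtype=float)
    bin_centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=bin_edges)[0] for w in windows])
    if check_overlap and len(windows) > 1:
        _check_overlap(windows, counts)

    log_n = np.log(np.array([w.samples.size for w in windows], dtype=float))
    m_b = counts.sum(axis=0).astype(float)
    occupied = m_b > 0
    with np.errstate(divide="ignore"):
        log_m = np.where(occupied, np.log(np.where(occupied, m_b, 1.0)), -np.inf)

    neg_bu = _bias_log_weights(windows, bin_edges, beta)  # log bin-avg bias factor
    g = np.zeros(len(windows)) if g_init is None else np.array(g_init, dtype=float)

    # The bias factors exp(-beta U_ib) never change across iterations, so the
    # self-consistency loop runs in linear space on a precomputed matrix
    # (underflow of far-off-window factors to zero is harmless). Falls back to
    # log-space iterations if the window constants grow beyond float range.
    bias_fac = np.exp(neg_bu)  # (n_windows, n_bins), entries in [0, 1]
    m_occ = np.where(occupied, m_b, 0.0)

    residual = np.inf
    for iteration in range(1, max_iter + 1):
        scaled = g + log_n
        if np.max(scaled) < 600.0:
            denom = np.exp(scaled) @ bias_fac
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(occupied & (denom > 0), m_occ / np.where(denom > 0, denom, 1.0), 0.0)
            conv = bias_fac @ p
            with np.errstate(divide="ignore"):
                g_new = -np.log(conv)
        else:  # pragma: no cover - extreme free-energy ranges
            log_denom = logsumexp(scaled[:, None] + neg_bu, axis=0)
            log_p = np.where(occupied, log_m - log_denom, -np.inf)
            g_new = -logsumexp(np.where(occupied, log_p[None, :] + neg_bu, -np.inf), axis=1)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)))
        g = g_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3e} kT)",
            residual=residual,
        )
    log_denom = logsumexp((g + log_n)[:, None] + neg_bu, axis=0)
    log_p = np.where(occupied, log_m - log_denom, -np.inf)

    with np.errstate(invalid="ignore"):
        free = np.where(occupied, -kt * log_p, np.nan)
    free -= np.nanmin(free)
    return PmfProfile(
        bin_centers, free, temperature_k, bin_edges=bin_edges,
        n_iterations=iteration, window_offsets=g,
    )


def boltzmann_inversion(
    samples: np.ndarray,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    n_bins: int = DEFAULT_N_BINS,
    bin_edges: np.ndarray | None = None,
) -> PmfProfile:
    """G(z) = -k_B T ln(histogram) for unbiased samples (WHAM's degenerate limit)."""
    w = UmbrellaWindow(center=0.0, force_constant=0.0, samples=np.asarray(samples, float))
    return wham([w], temperature_k, n_bins, bin_edges=bin_edges, check_overlap=False)


def _block_resample(samples: np.ndarray, block_length: int, rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap preserving short-range autocorrelation."""
    n = samples.size
    block = max(1, min(block_length, n))
    n_blocks = -(-n // block)  # ceil
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
    return samples[idx]


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    block_length: int = DEFAULT_BLOCK_LENGTH,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    n_bins: int = DEFAULT_N_BINS,
    tol: float = 1e-6,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Per-bin bootstrap standard errors of the WHAM profile (kJ/mol).

    Each replicate block-resamples every window's time series, recomputes
    WHAM on the full-data bin grid (warm-started from the full-data
    solution), and recentres the replicate profile over its sampled bins
    before the per-bin standard deviation is taken — the overall additive
    constant of a PMF carries no information. Deterministic for fixed seed.
    """
    if n_boot < 2:
        raise ConfigError("need at least 2 bootstrap replicates")
    # overlap validity is the caller's concern (checked in the headline wham
    # call); resampling noise is well-defined even for degenerate windows
    full = wham(windows, temperature_k, n_bins, max_iter=max_iter, check_overlap=False)
    edges = full.bin_edges
    rng = np.random.default_rng(seed)
    profiles = np.full((n_boot, full.bin_centers.size), np.nan)
    for b in range(n_boot):
        resampled = [
            UmbrellaWindow(w.center, w.force_constant,
                           _block_resample(w.samples, block_length, rng))
            for w in windows
        ]
        prof = wham(resampled, temperature_k, n_bins, tol=tol, max_iter=max_iter,
                    bin_edges=edges, check_overlap=False, g_init=full.window_offsets)
        centred = prof.free_energy - np.nanmean(prof.free_energy)
        profiles[b] = centred
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # bins sampled in < 2 replicates legitimately yield NaN errors
        warnings.simplefilter("ignore", RuntimeWarning)
        errors = np.nanstd(profiles, axis=0, ddof=1)
    return errors


def align_pmf(profile: PmfProfile, bulk_region: tuple[float, float]) -> PmfProfile:
    """Shift the profile so its mean over ``bulk_region`` (nm) is zero."""
    lo, hi = bulk_region
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.sampled()
    if not np.any(mask):
        raise ValueError(f"bulk region [{lo}, {hi}] nm contains no sampled bins")
    shift = float(np.nanmean(profile.free_energy[mask]))
    return PmfProfile(
        profile.bin_centers, profile.free_energy - shift, profile.temperature_k,
        errors=profile.errors, bin_edges=profile.bin_edges,
        anchor_region=(lo, hi), n_iterations=profile.n_iterations,
        window_offsets=profile.window_offsets,
    )


def binding_free_energy(
    profile: PmfProfile, binding_region: tuple[float, float] | None = None
) -> dict[str, float]:
    """Well depth on the bulk-zero scale: min G over the binding region.

    Requires an aligned profile (anchor_region set). Returns the value in
    kJ/mol and in k_B T at the profile temperature.
    """
    if profile.anchor_region is None:
        raise ValueError("profile must be bulk-aligned first (align_pmf)")
    mask = profile.sampled()
    if binding_region is not None:
        lo, hi = binding_region
        mask &= (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    else:
        mask &= profile.bin_centers < profile.anchor_region[0]
    if not np.any(mask):
        raise ValueError("binding region contains no sampled bins")
    dg = float(np.nanmin(profile.free_energy[mask]))
    kt = KB_KJ_PER_MOL_K * profile.temperature_k
    return {"dg_kj_per_mol": dg, "dg_kt": dg / kt}


def profile_to_csv(profile: PmfProfile, path: str | Path) -> None:
    kt = KB_KJ_PER_MOL_K * profile.temperature_k
    df = pd.DataFrame({
        "z_nm": profile.bin_centers,
        "G_kJmol": profile.free_energy,
        "G_kT": profile.free_energy / kt,
        "err_kJmol": profile.errors if profile.errors is not None else np.nan,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def overlap_histograms(
    windows: Sequence[UmbrellaWindow], n_bins: int = DEFAULT_N_BINS
) -> pd.DataFrame:
    """Per-window histograms on a common grid (overlap diagnostic export)."""
    zmin = min(w.samples.min() for w in windows)
    zmax = max(w.samples.max() for w in windows)
    edges = np.linspace(zmin, zmax, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    data = {"z_nm": centers}
    for w in windows:
        data[f"w_{w.center:.3f}"] = np.histogram(w.samples, bins=edges)[0]
    return pd.DataFrame(data)


def plot_pmf(profiles: dict[str, PmfProfile], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, prof in profiles.items():
        err = prof.errors if prof.errors is not None else None
        ax.errorbar(prof.bin_centers, prof.free_energy, yerr=err, label=label,
                    errorevery=8, capsize=2, linewidth=1.2)
    ax.set_xlabel("z (nm)")
    ax.set_ylabel("PMF (kJ/mol)")
    ax.axhline(0, color="grey", linewidth=0.6)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
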