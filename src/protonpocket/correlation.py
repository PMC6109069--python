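"""Pairwise Pearson correlation of pKa time series with Fisher-z intervals.

The correlation coefficient of two windowed pKa series,

    r = sum_t (x_t - xbar)(y_t - ybar)
        / sqrt(sum_t (x_t - xbar)^2) / sqrt(sum_t (y_t - ybar)^2),

is computed on the trailing window of each trajectory (default the last
100 ns, i.e. n = 100 samples at 1 ns spacing). Strong negative r between a
protonated/deprotonated residue pair is read downstream as proton-transfer
propensity. Confidence intervals use the Fisher z-transform.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateIntervalError, UndefinedCorrelationError, WindowError
from .pka import PkaSeries
from .states import ProtonationState

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_NS = 100.0


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient; missing values are dropped pairwise.

    Raises :class:`UndefinedCorrelationError` (never returns NaN) if either
    series has zero variance after pairwise deletion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    mask = np.isfinite(x) & np.isfinite(y)
    n_dropped = int(x.size - mask.sum())
    if n_dropped:
        logger.debug("pearson_r: dropped %d frames pairwise", n_dropped)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired samples, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in a series; r undefined")
    return float(np.clip(float(dx @ dy) / (sx * sy), -1.0, 1.0))


def confidence_interval(r: float, n: int, level: float = 0.99) -> tuple[float, float]:
    """Two-sided Fisher-z confidence interval for a Pearson coefficient."""
    if not -1.0 < r < 1.0:
        raise DegenerateIntervalError(f"|r| = 1 gives a degenerate interval (r={r})")
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = math.tanh(z - crit * se), math.tanh(z + crit * se)
    return (lo, hi)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over the pocket residues for one trajectory window."""

    residues: tuple[str, ...]
    r: np.ndarray
    n: int
    window: tuple[float, float]  # (t_start, t_end) ns
    state: ProtonationState | None = None
    replicate: int = 0
    means: dict[str, float] = field(default_factory=dict)
    ci: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.residues)
        if self.r.shape != (k, k):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if self.n < 3:
            raise ValueError("need n >= 3 samples")

    def value(self, a: str, b: str) -> float:
        return float(self.r[self.residues.index(a), self.residues.index(b)])

    def pairs(self):
        """All unordered residue pairs (i < j) in canonical order."""
        for i in range(len(self.residues)):
            for j in range(i + 1, len(self.residues)):
                yield (self.residues[i], self.residues[j], float(self.r[i, j]))


def correlation_matrix(
    series: PkaSeries,
    window_ns: float = DEFAULT_WINDOW_NS,
    ci_level: float | None = None,
) -> CorrelationMatrix:
    """Pearson matrix on the trailing ``window_ns`` of the trajectory.

    Both the sums and the means of the correlation formula are evaluated on
    the windowed data only (standard Pearson on the trailing window). If
    ``window_ns`` is not a multiple of the sampling interval, the sample
    count is floored to full samples (logged).
    """
    n_samples = int(math.floor(window_ns / series.interval_ns + 1e-9))
    if abs(n_samples * series.interval_ns - window_ns) > 1e-9:
        logger.info(
            "window %.3f ns floored to %d samples at %.3f ns interval",
            window_ns, n_samples, series.interval_ns,
        )
    if n_samples > series.n_frames:
        raise WindowError(
            f"window of {n_samples} samples exceeds series length {series.n_frames}"
        )
    if n_samples < 3:
        raise WindowError("window must contain at least 3 samples")
    sub = series.values[-n_samples:]
    times = series.times[-n_samples:]
    k = len(series.residues)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = pearson_r(sub[:, i], sub[:, j])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = {res: float(np.nanmean(sub[:, i])) for i, res in enumerate(series.residues)}
    mat = CorrelationMatrix(
        series.residues, r, n_samples, (float(times[0]), float(times[-1])),
        state=series.state, replicate=series.replicate, means=means,
    )
    if ci_level is not None:
        for a, b, rv in mat.pairs():
            if abs(rv) < 1.0:
                mat.ci[(a, b)] = confidence_interval(rv, n_samples, ci_level)
    return mat


def top_k_pairs(
    matrix: CorrelationMatrix, k: int = 3, ci_level: float = 0.99
) -> list[dict]:
    """The k pairs of largest |r|, descending; ties broken by canonical pocket order."""
    idx = {res: i for i, res in enumerate(matrix.residues)}
    ranked = sorted(
        matrix.pairs(), key=lambda p: (-abs(p[2]), idx[p[0]], idx[p[1]])
    )
    n_pairs = len(ranked)
    if k > n_pairs:
        warnings.warn(f"requested top {k} pairs but only {n_pairs} exist; truncating")
        k = n_pairs
    out = []
    for a, b, rv in ranked[:k]:
        ci = confidence_interval(rv, matrix.n, ci_level) if abs(rv) < 1.0 else None
        out.append({"pair": (a, b), "r": rv, "ci": ci, "level": ci_level})
    return out


# ---------------------------------------------------------------------------
# Export

def matrix_to_csv(matrix: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.r, index=list(matrix.residues),
                 columns=list(matrix.residues)).to_csv(path, float_format="%.6f")


def matrix_to_json(matrix: CorrelationMatrix, path: str | Path) -> None:
    payload = {
        "residues": list(matrix.residues),
        "r": [[round(float(v), 6) for v in row] for row in matrix.r],
        "n": matrix.n,
        "window_ns": list(matrix.window),
        "state": matrix.state.label if matrix.state is not None else None,
        "replicate": matrix.replicate,
        "means": {k: round(v, 6) for k, v in matrix.means.items()},
        "ci": {f"{a}|{b}": [round(lo, 6), round(hi, 6)]
               for (a, b), (lo, hi) in matrix.ci.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def plot_correlation_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Heat map with red = -1, green = +1."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(matrix.r, cmap="RdYlGn", vmin=-1.0, vmax=1.0)
    ax.set_xticks(range(len(matrix.residues)), matrix.residues, rotation=45)
    ax.set_yticks(range(len(matrix.residues)), matrix.residues)
    title = matrix.state.label if matrix.state is not None else ""
    ax.set_title(f"{title} (n={matrix.n})", fontsize=9)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
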