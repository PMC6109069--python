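"""Per-frame pKa series: ingestion of external predictor tables and a stand-in estimator.

Production pKa values come from an external empirical predictor run on
trajectory snapshots (one value per titratable residue per frame, typically
every 1 ns over 250 ns). This module validates and loads such tables into
:class:`PkaSeries`. For end-to-end runs on synthetic structures it also
provides a deliberately simple distance-based stand-in estimator: a model
pKa per residue class plus a burial shift (heavy-atom count) and Coulomb-like
shifts from nearby charges. The stand-in is NOT a re-implementation of any
published predictor; only the downstream correlation structure matters here.
Like the external predictor it uses heavy-atom geometry only.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataQualityError, ResolutionError, SchemaError, TableFormatError
from .states import POCKET, ProtonationState, ResidueID

logger = logging.getLogger(__name__)

POCKET_COLUMNS = tuple(r.name for r in POCKET)


@dataclass
class StandInParams:
    """Parameters of the stand-in pKa estimator.

    pKa = model_pKa(class) + burial_shift + sum_j charge_shift(d_j), with
    burial_shift = w_burial * (N_heavy within r_burial - n_ref), clamped to
    [0, max_burial_shift], and charge_shift = -w_charge/d for positive and
    +w_charge/d for negative neighbours within r_charge. Distances in nm.
    """

    model_pka_asp: float = 3.80
    model_pka_glu: float = 4.50
    r_burial_nm: float = 0.9
    r_charge_nm: float = 1.2
    w_charge: float = 2.4  # pKa units * nm
    w_burial: float = 0.02  # pKa units per heavy atom
    n_ref: int = 10
    max_burial_shift: float = 2.0


@dataclass
class PocketFrame:
    """Minimal structural view of the binding pocket at one frame.

    Coordinates in nm. ``oxygens`` maps residue name to an (n_O, 3) array of
    carboxylate oxygen positions; ``ions`` maps K+ ion ids to positions;
    ``k791`` is the K791 amine nitrogen; ``heavy_atoms`` is the shell used
    for burial counting (excluding each residue's own atoms is the builder's
    responsibility).
    """

    time_ns: float
    oxygens: Mapping[str, np.ndarray]
    ions: Mapping[str, np.ndarray] = field(default_factory=dict)
    k791: np.ndarray | None = None
    heavy_atoms: np.ndarray | None = None
    state: ProtonationState | None = None

    def carboxylate_centroid(self, residue: str) -> np.ndarray:
        ox = np.asarray(self.oxygens[residue], dtype=float)
        return ox.mean(axis=0)


@dataclass
class PkaSeries:
    """pKa time series for a set of residues at a fixed sampling interval."""

    residues: tuple[str, ...]
    times: np.ndarray  # ns, strictly increasing
    values: np.ndarray  # (n_times, n_residues)
    interval_ns: float = 1.0
    state: ProtonationState | None = None
    replicate: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.residues)):
            raise ValueError("values shape does not match times x residues")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def column(self, residue: str) -> np.ndarray:
        return self.values[:, self.residues.index(residue)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.residues))
        df.insert(0, "time_ns", self.times)
        return df


def _positive_charges(frame: PocketFrame) -> list[np.ndarray]:
    charges = [np.asarray(p, dtype=float) for p in frame.ions.values()]
    if frame.k791 is not None:
        charges.append(np.asarray(frame.k791, dtype=float))
    return charges


def _negative_charges(frame: PocketFrame, exclude: str) -> list[np.ndarray]:
    # Deprotonated carboxylates of the other pocket residues carry -1.
    out = []
    for name in frame.oxygens:
        if name == exclude:
            continue
        if frame.state is not None and frame.state.is_protonated(name):
            continue
        out.append(frame.carboxylate_centroid(name))
    return out


def estimate_pka_frame(
    frame: PocketFrame, residue: ResidueID | str, params: StandInParams | None = None
) -> float:
    """Stand-in pKa for one residue in one frame (heavy-atom geometry only)."""
    params = params or StandInParams()
    name = residue.name if isinstance(residue, ResidueID) else residue
    if name not in frame.oxygens:
        raise LookupError(f"residue {name} absent from frame at t={frame.time_ns} ns")
    rc = ResidueID(name).residue_class
    if rc == "aspartate":
        pka = params.model_pka_asp
    elif rc == "glutamate":
        pka = params.model_pka_glu
    else:
        raise ValueError(f"no model pKa for residue class {rc!r}")

    centroid = frame.carboxylate_centroid(name)

    n_heavy = 0
    if frame.heavy_atoms is not None and len(frame.heavy_atoms):
        d = np.linalg.norm(np.asarray(frame.heavy_atoms, dtype=float) - centroid, axis=1)
        n_heavy = int(np.sum(d <= params.r_burial_nm))
    burial = np.clip(params.w_burial * (n_heavy - params.n_ref), 0.0, params.max_burial_shift)
    pka += float(burial)

    for pos in _positive_charges(frame):
        d = float(np.linalg.norm(pos - centroid))
        if 0 < d <= params.r_charge_nm:
            pka -= params.w_charge / d
    for pos in _negative_charges(frame, exclude=name):
        d = float(np.linalg.norm(pos - centroid))
        if 0 < d <= params.r_charge_nm:
            pka += params.w_charge / d
    return float(pka)


def compute_pka_series(
    frames: Sequence[PocketFrame],
    residues: Sequence[str] = POCKET_COLUMNS,
    interval_ns: float = 1.0,
    params: StandInParams | None = None,
) -> PkaSeries:
    """Apply the stand-in estimator at every sampled time; deterministic."""
    if not frames:
        raise ValueError("no frames supplied")
    times = np.array([f.time_ns for f in frames], dtype=float)
    order = np.argsort(times)
    frames = [frames[i] for i in order]
    times = times[order]
    spacing = np.min(np.diff(times)) if times.size > 1 else interval_ns
    if interval_ns < spacing - 1e-9:
        raise ResolutionError(
            f"requested interval {interval_ns} ns finer than frame spacing {spacing} ns"
        )
    t0 = times[0]
    keep = [
        i for i, t in enumerate(times)
        if abs(((t - t0) / interval_ns) - round((t - t0) / interval_ns)) < 1e-6
    ]
    sel = [frames[i] for i in keep]
    values = np.array(
        [[estimate_pka_frame(f, r, params) for r in residues] for f in sel], dtype=float
    )
    state = sel[0].state
    return PkaSeries(tuple(residues), times[keep], values, interval_ns, state=state)


# ---------------------------------------------------------------------------
# Table ingestion (CSV dialect: header "time_ns,E343,E795,E820,D824,D942")

def load_pka_table(
    path: str | Path | io.StringIO,
    state: ProtonationState | None = None,
    replicate: int = 0,
    residues: Sequence[str] = POCKET_COLUMNS,
    max_missing_frac: float = 0.10,
) -> PkaSeries:
    """Load and validate a per-frame pKa table.

    Rows are sorted by time; duplicate times are rejected; a missing pocket
    column is a :class:`SchemaError`; a non-numeric cell is a
    :class:`TableFormatError` carrying the row index; more than
    ``max_missing_frac`` missing values in any residue column is a
    :class:`DataQualityError` (downstream correlation drops missing frames
    pairwise rather than imputing).
    """
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty pKa table") from exc
    if df.empty:
        raise SchemaError("pKa table has a header but no rows")
    if "time_ns" not in df.columns:
        raise SchemaError("pKa table missing required 'time_ns' column")
    missing_cols = [r for r in residues if r not in df.columns]
    if missing_cols:
        raise SchemaError(f"pKa table missing residue columns: {missing_cols}")

    for col in ["time_ns", *residues]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col}, row {row}", row=row
            )
        df[col] = coerced

    if df["time_ns"].duplicated().any():
        dup = df["time_ns"][df["time_ns"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate time {dup} ns in pKa table")
    df = df.sort_values("time_ns").reset_index(drop=True)

    values = df[list(residues)].to_numpy(dtype=float)
    miss = np.isnan(values).mean(axis=0)
    if np.any(miss > max_missing_frac):
        worst = residues[int(np.argmax(miss))]
        raise DataQualityError(
            f"residue {worst}: {miss.max():.1%} missing pKa values exceeds "
            f"{max_missing_frac:.0%} limit"
        )
    n_missing = int(np.isnan(values).sum())
    if n_missing:
        logger.warning("pKa table contains %d missing values (handled pairwise)", n_missing)

    times = df["time_ns"].to_numpy(dtype=float)
    interval = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    return PkaSeries(tuple(residues), times, values, interval, state=state, replicate=replicate)


def write_pka_table(series: PkaSeries, path: str | Path, header_comment: str | None = None) -> None:
    """Write a pKa table; values round-trip bit-exactly through %.17g."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("time_ns," + ",".join(series.residues) + "\n")
        for t, row in zip(series.times, series.values):
            cells = ",".join("" if np.isnan(v) else format(v, ".17g") for v in row)
            fh.write(f"{format(t, '.17g')},{cells}\n")
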