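"""Structural input adapters: MD trajectories and a columnar CSV fallback.

Two routes into :class:`~protonpocket.pka.PocketFrame`:

* ``frames_from_mdanalysis`` reads any topology/trajectory pair MDAnalysis
  understands (PDB, GRO/XTC, ...) and extracts the pocket view from atom
  selections. Coordinates are converted from Angstrom to nm.
* ``frames_from_table`` / ``frames_to_table`` use an internal columnar CSV
  (time_ns, atom_label, x, y, z in nm) with labels like ``E343:O1``,
  ``K791:NZ``, ``ION:K1`` and ``SHELL:7`` — handy for plain-text fixtures.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import StructuralDataError
from .pka import PocketFrame
from .states import POCKET, ProtonationState

_A_TO_NM = 0.1

DEFAULT_SELECTIONS = {
    **{r.name: f"resid {r.name[1:]} and name OE1 OE2 OD1 OD2" for r in POCKET},
    "K791": "resid 791 and name NZ",
    "ions": "name K POT K+",
    "shell": "protein and not name H*",
}


def frames_from_mdanalysis(
    universe,
    selections: Mapping[str, str] | None = None,
    state: ProtonationState | None = None,
    time_scale_ns: float = 1e-3,
) -> list[PocketFrame]:
    """Extract pocket frames from an MDAnalysis Universe (coordinates A -> nm).

    ``selections`` maps each pocket residue name to its carboxylate-oxygen
    selection, plus optional "K791", "ions" and "shell" entries;
    ``time_scale_ns`` converts the trajectory time unit (ps by default) to ns.
    """
    sel = dict(DEFAULT_SELECTIONS, **(selections or {}))
    groups = {}
    for key, expr in sel.items():
        try:
            groups[key] = universe.select_atoms(expr)
        except Exception as exc:  # selection syntax errors surface as data errors
            raise StructuralDataError(f"bad selection for {key!r}: {expr!r}") from exc
    for r in POCKET:
        if r.name in groups and groups[r.name].n_atoms == 0:
            raise StructuralDataError(f"selection for {r.name} matched no atoms")

    frames = []
    for ts in universe.trajectory:
        oxygens = {
            r.name: groups[r.name].positions * _A_TO_NM
            for r in POCKET if r.name in groups and groups[r.name].n_atoms
        }
        ions = {}
        if "ions" in groups:
            for i, pos in enumerate(groups["ions"].positions):
                ions[f"K{i + 1}"] = pos * _A_TO_NM
        k791 = None
        if "K791" in groups and groups["K791"].n_atoms:
            k791 = groups["K791"].positions[0] * _A_TO_NM
        shell = None
        if "shell" in groups and groups["shell"].n_atoms:
            shell = groups["shell"].positions * _A_TO_NM
        frames.append(PocketFrame(
            time_ns=float(ts.time) * time_scale_ns, oxygens=oxygens, ions=ions,
            k791=k791, heavy_atoms=shell, state=state,
        ))
    return frames


def load_universe(topology: str | Path, trajectory: str | Path | None = None):
    """Thin wrapper so callers need not import MDAnalysis themselves."""
    import MDAnalysis as mda

    if trajectory is None:
        return mda.Universe(str(topology))
    return mda.Universe(str(topology), str(trajectory))


# ---------------------------------------------------------------------------
# Columnar fallback format

def frames_to_table(frames: Sequence[PocketFrame], path: str | Path) -> None:
    rows = []
    for f in frames:
        for res, ox in f.oxygens.items():
            for i, p in enumerate(np.atleast_2d(ox)):
                rows.append((f.time_ns, f"{res}:O{i + 1}", *p))
        if f.k791 is not None:
            rows.append((f.time_ns, "K791:NZ", *np.asarray(f.k791)))
        for ion_id, p in f.ions.items():
            rows.append((f.time_ns, f"ION:{ion_id}", *np.asarray(p)))
        if f.heavy_atoms is not None:
            for i, p in enumerate(np.atleast_2d(f.heavy_atoms)):
                rows.append((f.time_ns, f"SHELL:{i}", *p))
    df = pd.DataFrame(rows, columns=["time_ns", "atom_label", "x", "y", "z"])
    df.to_csv(path, index=False, float_format="%.9g")


def frames_from_table(
    path: str | Path, state: ProtonationState | None = None
) -> list[PocketFrame]:
    df = pd.read_csv(path, comment="#")
    required = {"time_ns", "atom_label", "x", "y", "z"}
    if not required <= set(df.columns):
        raise StructuralDataError(f"frame table missing columns {required - set(df.columns)}")
    frames = []
    for t, sub in df.groupby("time_ns", sort=True):
        oxygens: dict[str, list] = {}
        ions = {}
        shell = []
        k791 = None
        for _, row in sub.iterrows():
            label = str(row["atom_label"])
            pos = np.array([row["x"], row["y"], row["z"]], dtype=float)
            prefix, _, rest = label.partition(":")
            if prefix == "ION":
                ions[rest] = pos
            elif prefix == "SHELL":
                shell.append(pos)
            elif prefix == "K791":
                k791 = pos
            else:
                oxygens.setdefault(prefix, []).append(pos)
        frames.append(PocketFrame(
            time_ns=float(t),
            oxygens={k: np.stack(v) for k, v in oxygens.items()},
            ions=ions, k791=k791,
            heavy_atoms=np.stack(shell) if shell else None,
            state=state,
        ))
    return frames
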