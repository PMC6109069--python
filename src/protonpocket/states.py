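"""Protonation microstates of the cation-binding pocket.

The gastric H+,K+-ATPase binds K+ in a transmembrane pocket formed by five
acidic residues (E343, E795, E820, D824, D942). In classical MD each
trajectory is run with a fixed assignment of protons to these carboxylates;
this module enumerates and names those assignments. The canonical notation
suffixes each protonated residue with '+', concatenated in pocket order,
e.g. ``"E343+E795+"`` for the state where only E343 and E795 carry protons.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_CLASS_BY_PREFIX = {"E": "glutamate", "D": "aspartate"}


@dataclass(frozen=True, order=True)
class ResidueID:
    """A titratable residue, named by one-letter type plus sequence number."""

    name: str

    @property
    def residue_class(self) -> str:
        return _CLASS_BY_PREFIX.get(self.name[:1], "other")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: Canonical pocket order used for all labels and joins across modules.
POCKET: tuple[ResidueID, ...] = tuple(
    ResidueID(n) for n in ("E343", "E795", "E820", "D824", "D942")
)

#: Ensemble default: states with 1, 4 or 5 protons are enumerable but excluded
#: (a single proton leaves the pocket too negative to be stable; 4-5 protons
#: essentially abolish K+ binding).
DEFAULT_PROTON_COUNTS: frozenset[int] = frozenset({2, 3})


@dataclass(frozen=True)
class ProtonationState:
    """A fixed assignment of protons to the pocket carboxylates."""

    pocket: tuple[ResidueID, ...] = POCKET
    protonated: frozenset[ResidueID] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.protonated <= set(self.pocket):
            extra = {r.name for r in self.protonated - set(self.pocket)}
            raise ValueError(f"protonated residues not in pocket: {sorted(extra)}")

    @property
    def label(self) -> str:
        return "".join(r.name + "+" for r in self.pocket if r in self.protonated)

    @property
    def n_protons(self) -> int:
        return len(self.protonated)

    def is_protonated(self, residue: ResidueID | str) -> bool:
        name = residue.name if isinstance(residue, ResidueID) else residue
        return any(r.name == name for r in self.protonated)

    def n_protonated_of_class(self, residue_class: str) -> int:
        return sum(1 for r in self.protonated if r.residue_class == residue_class)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label or "(none)"


def enumerate_states(
    pocket: Sequence[ResidueID] = POCKET,
    proton_counts: Iterable[int] = DEFAULT_PROTON_COUNTS,
) -> list[ProtonationState]:
    """All protonation states of ``pocket`` whose proton count is in ``proton_counts``.

    Returned in deterministic lexicographic order of the canonical labels,
    with no duplicates. With the five-residue pocket and counts {2, 3} this
    yields the 20-state simulation ensemble (10 two-proton + 10 three-proton).
    """
    if not pocket:
        raise ValueError("pocket must be non-empty")
    counts = sorted(set(proton_counts))
    for k in counts:
        if not 0 <= k <= len(pocket):
            raise ValueError(f"proton count {k} outside [0, {len(pocket)}]")
    pocket = tuple(pocket)
    states = [
        ProtonationState(pocket, frozenset(combo))
        for k in counts
        for combo in itertools.combinations(pocket, k)
    ]
    return sorted(states, key=lambda s: s.label)


def state_label(state: ProtonationState) -> str:
    """Canonical '+'-suffixed label in pocket order."""
    return state.label


def parse_label(label: str, pocket: Sequence[ResidueID] = POCKET) -> ProtonationState:
    """Inverse of :func:`state_label`; unknown residue tokens raise ``ValueError``."""
    pocket = tuple(pocket)
    by_name = {r.name: r for r in pocket}
    tokens = [t for t in label.strip().split("+") if t]
    protonated = set()
    for tok in tokens:
        if tok not in by_name:
            raise ValueError(f"unknown residue token {tok!r} in label {label!r}")
        protonated.add(by_name[tok])
    return ProtonationState(pocket, frozenset(protonated))


def ensemble_manifest(
    states: Sequence[ProtonationState] | None = None,
    replicates: int = 3,
    seed: int = 0,
) -> dict:
    """JSON-serialisable manifest of the ensemble: states, replicates, per-replicate seeds."""
    if states is None:
        states = enumerate_states()
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root = np.random.SeedSequence(seed)
    entries = []
    for si, state in enumerate(states):
        seeds = [
            int(np.random.SeedSequence(entropy=seed, spawn_key=(si, rep)).generate_state(1)[0]
                % (2**31))
            for rep in range(replicates)
        ]
        entries.append(
            {"label": state.label, "n_protons": state.n_protons,
             "replicates": replicates, "seeds": seeds}
        )
    return {
        "pocket": [r.name for r in (states[0].pocket if states else POCKET)],
        "seed": seed,
        "root_entropy": int(root.entropy),
        "states": entries,
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
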