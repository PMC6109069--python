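"""Spontaneous K+ binding: per-frame detection, site classification, occupancy stats.

An ion counts as bound when at least ``min_coord`` pocket carboxylate oxygens
lie within a coordination cutoff (default 0.35 nm, a typical K+-O distance).
Bound ions are classified as site III when the majority of their coordinating
oxygens come from the aspartates D824/D942 (the deeper locus); everything
else is the promiscuous site I/II region near the glutamates, where sites I
and II cannot be distinguished. Occupancy summaries use the end-of-trajectory
bound count averaged over replicates, with the grand means over the
two-proton and three-proton state groups probing the transport-stoichiometry
variation hypothesis (fewer K+ bound at lower pH, i.e. more pocket protons).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation import pearson_r
from .pka import PocketFrame
from .states import ProtonationState

logger = logging.getLogger(__name__)

DEFAULT_COORDINATION_CUTOFF_NM = 0.35
DEFAULT_MIN_COORDINATION = 2

SITE_I_II = "site_I_II"
SITE_III = "site_III"
_ASPARTATES = {"D824", "D942"}


def detect_bound_ions(
    frame: PocketFrame,
    cutoff_nm: float = DEFAULT_COORDINATION_CUTOFF_NM,
    min_coord: int = DEFAULT_MIN_COORDINATION,
) -> dict[str, Counter]:
    """Coordination record per bound ion: {ion_id: multiset of coordinating residues}.

    An ion is bound iff >= ``min_coord`` pocket oxygens are within
    ``cutoff_nm``; the multiset counts one entry per coordinating oxygen.
    A frame without K+ yields an empty record.
    """
    out: dict[str, Counter] = {}
    for ion_id, pos in frame.ions.items():
        pos = np.asarray(pos, dtype=float)
        coord: Counter = Counter()
        for res, ox in frame.oxygens.items():
            ox = np.asarray(ox, dtype=float)
            d = np.linalg.norm(ox - pos, axis=1)
            n = int(np.sum(d <= cutoff_nm))
            if n:
                coord[res] += n
        if sum(coord.values()) >= min_coord:
            out[ion_id] = coord
    return out


def classify_site(coordination: Mapping[str, int]) -> str:
    """Site label from a coordination multiset (pure function of the multiset).

    ``site_III`` iff a strict majority of coordinating oxygens come from
    D824/D942; ties fall to ``site_I_II`` with a logged flag.
    """
    total = sum(coordination.values())
    if total == 0:
        raise ValueError("empty coordination set")
    asp = sum(n for res, n in coordination.items() if res in _ASPARTATES)
    if asp * 2 > total:
        return SITE_III
    if asp * 2 == total and asp > 0:
        logger.info("site tie (asp=%d of %d oxygens); assigning site I/II", asp, total)
    return SITE_I_II


@dataclass
class BindingTrace:
    """Per-frame bound-ion record for one trajectory."""

    times: np.ndarray  # ns
    records: list[dict[str, dict]]  # per frame: ion_id -> {site, coordination}
    state: ProtonationState | None = None
    replicate: int = 0
    first_binding_time_ns: dict[str, float] = field(default_factory=dict)

    def bound_counts_at(self, index: int) -> dict[str, int]:
        counts = {SITE_I_II: 0, SITE_III: 0}
        for rec in self.records[index].values():
            counts[rec["site"]] += 1
        return counts

    def end_counts(self) -> dict[str, int]:
        return self.bound_counts_at(-1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t, rec in zip(self.times, self.records):
            for ion_id, r in rec.items():
                rows.append({
                    "time_ns": float(t), "ion_id": ion_id, "bound": True,
                    "site": r["site"],
                    "coordinating_residues": "+".join(sorted(r["coordination"].elements())),
                })
        return pd.DataFrame(rows, columns=["time_ns", "ion_id", "bound", "site",
                                           "coordinating_residues"])


def binding_trace(
    frames: Sequence[PocketFrame],
    cutoff_nm: float = DEFAULT_COORDINATION_CUTOFF_NM,
    min_coord: int = DEFAULT_MIN_COORDINATION,
    state: ProtonationState | None = None,
    replicate: int = 0,
) -> BindingTrace:
    """Apply detection + site classification frame by frame.

    Frames must be time-ordered. The first binding time per ion is the time
    of the first frame in which it is bound; binding already present at the
    first frame (i.e. during equilibration) is reported as t = 0.
    """
    times = np.array([f.time_ns for f in frames], dtype=float)
    if times.size == 0:
        raise ValueError("no frames")
    if np.any(np.diff(times) <= 0):
        raise ValueError("frames must be strictly time-ordered")
    records = []
    first_bind: dict[str, float] = {}
    for i, f in enumerate(frames):
        rec = {}
        for ion_id, coord in detect_bound_ions(f, cutoff_nm, min_coord).items():
            rec[ion_id] = {"site": classify_site(coord), "coordination": coord}
            if ion_id not in first_bind:
                first_bind[ion_id] = 0.0 if i == 0 else float(times[i])
        records.append(rec)
    st = state if state is not None else frames[0].state
    return BindingTrace(times, records, st, replicate, first_bind)


@dataclass
class OccupancySummary:
    """Per-state occupancy means/SEs plus group means over proton counts."""

    per_state: pd.DataFrame  # state, n_protons, per-site mean/se, total mean/se
    group_means: dict[int, float]  # n_protons -> grand mean of total bound K+

    def state_row(self, label: str) -> pd.Series:
        return self.per_state.set_index("state").loc[label]


def occupancy_summary(traces: Sequence[BindingTrace]) -> OccupancySummary:
    """End-of-trajectory bound counts aggregated per state and proton-count group.

    Mean and standard error (n-1 denominator) are over the replicates of
    each state; group means average the per-state total means within the
    two-proton and three-proton groups.
    """
    if not traces:
        raise ValueError("no traces supplied")
    by_state: dict[str, list[BindingTrace]] = {}
    protons: dict[str, int] = {}
    for tr in traces:
        if tr.state is None:
            raise ValueError("trace missing its protonation state")
        by_state.setdefault(tr.state.label, []).append(tr)
        protons[tr.state.label] = tr.state.n_protons

    rows = []
    for label, trs in by_state.items():
        ends = [t.end_counts() for t in trs]
        n = len(ends)
        cols = {}
        for site in (SITE_I_II, SITE_III):
            vals = np.array([e[site] for e in ends], dtype=float)
            cols[f"{site}_mean"] = float(vals.mean())
            cols[f"{site}_se"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        totals = np.array([e[SITE_I_II] + e[SITE_III] for e in ends], dtype=float)
        rows.append({
            "state": label, "n_protons": protons[label], "n_replicates": n,
            **cols,
            "total_mean": float(totals.mean()),
            "total_se": float(totals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        })
    df = pd.DataFrame(rows).sort_values("state").reset_index(drop=True)
    group = {
        int(k): float(sub["total_mean"].mean())
        for k, sub in df.groupby("n_protons")
    }
    return OccupancySummary(df, group)


def stoichiometry_correlation(
    summary: OccupancySummary,
    n_protons: int | None = 3,
) -> dict[str, float]:
    """Correlation of bound-K+ count with protonated-Glu (and -Asp) count.

    Over the states of a proton-count group (default the three-proton group),
    Pearson r between each state's protonated-glutamate count and its mean
    total bound K+; the aspartate analogue is reported alongside. Within a
    fixed-proton group the Glu and Asp counts are exactly complementary, so
    the aspartate analogue there is forced to mirror the glutamate value;
    pass ``n_protons=None`` to correlate over all states, where a
    glutamate-driven occupancy leaves the aspartate correlation near zero.
    """
    from .states import parse_label

    if n_protons is None:
        sub = summary.per_state
    else:
        sub = summary.per_state[summary.per_state["n_protons"] == n_protons]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 states in the {n_protons}-proton group")
    occ = sub["total_mean"].to_numpy(dtype=float)
    out = {}
    for cls in ("glutamate", "aspartate"):
        counts = np.array([
            parse_label(lbl).n_protonated_of_class(cls) for lbl in sub["state"]
        ], dtype=float)
        out[cls] = pearson_r(counts, occ)
    return out


def summary_to_csv(summary: OccupancySummary, path) -> None:
    summary.per_state.to_csv(path, index=False, float_format="%.4f")


def plot_occupancy_bars(summary: OccupancySummary, path) -> None:
    """Bar chart of per-state occupancy: red site I/II, blue site III,
    dashed group-mean lines for the 2- and 3-proton groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.per_state.sort_values(["n_protons", "state"])
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(10, 3.6))
    ax.bar(x, df[f"{SITE_I_II}_mean"], color="firebrick", label="site I/II",
           yerr=df[f"{SITE_I_II}_se"], capsize=2)
    ax.bar(x, df[f"{SITE_III}_mean"], bottom=df[f"{SITE_I_II}_mean"],
           color="steelblue", label="site III", yerr=df[f"{SITE_III}_se"], capsize=2)
    for npr, color in ((2, "green"), (3, "saddlebrown")):
        if npr in summary.group_means:
            ax.axhline(summary.group_means[npr], color=color, linestyle="--",
                       linewidth=1, label=f"{npr}-proton mean")
    ax.set_xticks(x, df["state"], rotation=90, fontsize=7)
    ax.set_ylabel("bound K$^+$ (end of run)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
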