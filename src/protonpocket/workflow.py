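"""Ensemble-scale orchestration: generate -> analyze -> report.

Drives the full pipeline over the 20-state x 3-replicate ensemble (or any
configured subset): per-trajectory correlation matrices, the aggregated
donor/acceptor instance table, the transfer-network export, the per-state
occupancy table, and optionally umbrella PMF profiles. Every output is
reproducible from (config, seed); the report bundle carries a manifest of
parameters and seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .correlation import correlation_matrix, matrix_to_csv, matrix_to_json
from .errors import ConfigError
from .ions import binding_trace, occupancy_summary, stoichiometry_correlation, summary_to_csv
from .network import (
    aggregate_network,
    candidate_pairs,
    export_network,
    network_to_table,
    proximity_filter,
    rank_transfer_likelihood,
    residue_depths,
)
from .pmf import align_pmf, binding_free_energy, bootstrap_pmf, profile_to_csv, wham
from .states import enumerate_states, ensemble_manifest, write_manifest
from .synth import (
    DEFAULT_BINDING_POTENTIAL,
    IonKineticsSpec,
    LUMINAL_ACCESS_POINT,
    PkaEnsembleSpec,
    UmbrellaLayout,
    gen_ion_trajectory,
    gen_pka_ensemble,
    gen_umbrella_samples,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of an ensemble run; round-trips through YAML."""

    seed: int = 0
    output_dir: str = "protonpocket_run"
    replicates: int = 3
    n_frames: int = 250
    interval_ns: float = 1.0
    correlation_window_ns: float = 100.0
    r_threshold: float = -0.5
    ci_level: float = 0.99
    proximity_cutoff_nm: float = 0.6
    binding_cutoff_nm: float = 0.35
    min_coordination: int = 2
    temperature_k: float = 310.0
    wham_bins: int = 200
    wham_tol: float = 1e-7
    n_bootstraps: int = 200
    run_pmf: bool = False
    pmf_samples_per_window: int = 2000
    make_plots: bool = False
    planted_pair: tuple[str, str] = ("E795", "E820")
    planted_rho: float = -0.923
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "planted_pair" in data:
            data["planted_pair"] = tuple(data["planted_pair"])
        return cls(**data)


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_config(config: RunConfig) -> list[Finding]:
    """Check threshold ranges and internal consistency; never mutates inputs."""
    findings: list[Finding] = []
    if config.r_threshold >= 0:
        findings.append(Finding(
            "warning",
            "positive r threshold defeats the negative-correlation transfer criterion",
        ))
    if not -1.0 <= config.r_threshold <= 1.0:
        findings.append(Finding("error", "r threshold outside [-1, 1]"))
    if config.correlation_window_ns > config.n_frames * config.interval_ns:
        findings.append(Finding(
            "error",
            f"correlation window {config.correlation_window_ns} ns exceeds trajectory "
            f"length {config.n_frames * config.interval_ns} ns",
        ))
    if not 0 < config.ci_level < 1:
        findings.append(Finding("error", "confidence level must be in (0, 1)"))
    if config.binding_cutoff_nm <= 0 or config.proximity_cutoff_nm <= 0:
        findings.append(Finding("error", "distance cutoffs must be positive"))
    if config.min_coordination < 1:
        findings.append(Finding("error", "min coordination must be >= 1"))
    if config.replicates < 1 or config.n_frames < 3:
        findings.append(Finding("error", "need >= 1 replicate and >= 3 frames"))
    if config.temperature_k <= 0:
        findings.append(Finding("error", "temperature must be positive"))
    if config.n_bootstraps < 2:
        findings.append(Finding("error", "need >= 2 bootstrap replicates"))
    return findings


def run_ensemble_analysis(config: RunConfig, states=None) -> dict:
    """Synthetic-mode end-to-end run; returns a summary dict, writes the bundle.

    Outputs under ``config.output_dir``: per-trajectory correlation matrices
    (CSV + JSON), the donor/acceptor instance table, the network in JSON and
    DOT, the per-state occupancy table, optional PMF profiles, and a
    manifest recording versions, seeds and parameters.
    """
    errors = [f for f in validate_config(config) if f.level == "error"]
    if errors:
        raise ConfigError("; ".join(f.message for f in errors))

    out = Path(config.output_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)

    if states is None:
        states = enumerate_states()
    pka_spec = PkaEnsembleSpec(
        seed=config.seed, n_frames=config.n_frames, interval_ns=config.interval_ns,
        planted_pairs={tuple(config.planted_pair): config.planted_rho},
    )
    ensemble = gen_pka_ensemble(pka_spec, states=states, replicates=config.replicates)

    all_pairs = []
    audit = []
    state_index = {s.label: i for i, s in enumerate(states)}
    ion_spec = IonKineticsSpec(seed=config.seed)
    traces = []
    frames_by_state = {}
    for (label, rep), series in sorted(ensemble.items()):
        mat = correlation_matrix(series, config.correlation_window_ns, ci_level=config.ci_level)
        stem = out / "matrices" / f"{label or 'none'}_rep{rep}"
        matrix_to_csv(mat, f"{stem}.csv")
        matrix_to_json(mat, f"{stem}.json")
        if config.make_plots:
            from .correlation import plot_correlation_heatmap
            plot_correlation_heatmap(mat, f"{stem}.png")

        cands = candidate_pairs(mat, config.r_threshold)
        frames = gen_ion_trajectory(
            ion_spec, series.state, rep, config.n_frames, config.interval_ns,
            state_index=state_index[label],
        )
        frames_by_state[(label, rep)] = frames
        kept = proximity_filter(cands, frames[:1], config.proximity_cutoff_nm)
        audit.append({"state": label, "replicate": rep,
                      "candidates": len(cands), "accepted": len(kept)})
        all_pairs.extend(kept)
        traces.append(binding_trace(
            frames, config.binding_cutoff_nm, config.min_coordination,
            state=series.state, replicate=rep,
        ))

    network = aggregate_network(all_pairs)
    table = network_to_table(network)
    table.to_csv(out / "transfer_instances.csv", index=False)
    some_frames = next(iter(frames_by_state.values()))
    depths = residue_depths(some_frames[:1], LUMINAL_ACCESS_POINT)
    export_network(network, out / "transfer_network.json", "json", depths=depths)
    export_network(network, out / "transfer_network.dot", "dot", depths=depths)
    ranking = rank_transfer_likelihood(network)

    summary = occupancy_summary(traces)
    summary_to_csv(summary, out / "occupancy.csv")
    if config.make_plots:
        from .ions import plot_occupancy_bars
        plot_occupancy_bars(summary, out / "occupancy.png")
    try:
        stoich = {
            "glutamate_3proton_group": stoichiometry_correlation(summary, 3)["glutamate"],
            "aspartate_all_states": stoichiometry_correlation(summary, None)["aspartate"],
        }
    except ValueError:
        stoich = None

    pmf_result = None
    if config.run_pmf:
        layout = UmbrellaLayout(temperature_k=config.temperature_k)
        windows = gen_umbrella_samples(
            DEFAULT_BINDING_POTENTIAL, layout,
            n_samples=config.pmf_samples_per_window, seed=config.seed,
        )
        profile = wham(windows, config.temperature_k, config.wham_bins, tol=config.wham_tol)
        profile.errors = bootstrap_pmf(
            windows, n_boot=config.n_bootstraps, seed=config.seed,
            temperature_k=config.temperature_k, n_bins=config.wham_bins,
        )
        aligned = align_pmf(profile, (2.0, 2.45))
        profile_to_csv(aligned, out / "pmf.csv")
        pmf_result = binding_free_energy(aligned)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "ensemble": ensemble_manifest(states, config.replicates, config.seed),
        "per_trajectory_audit": audit,
        "transfer_ranking": ranking,
        "occupancy_group_means": {str(k): v for k, v in summary.group_means.items()},
        "stoichiometry_correlation": stoich,
        "binding_free_energy": pmf_result,
    }
    write_manifest(manifest, out / "manifest.json")
    return manifest
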