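"""End-to-end analysis pipeline.

Sequences the full workflow — distance table -> NHB coordinate ->
microstates -> rate matrix -> {relaxation, widest paths, coarse model,
committors, diffusion, pattern statistics} — from a single validated
configuration, writing one JSON master report plus per-stage TSV
tables. Runs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coarse import odr_fit, pcca_plus, two_state_summary
from .committor import committor, transition_states
from .constants import DEFAULT_TEMPERATURE, HELIX_RISE_ANGSTROM, PATTERN_THRESHOLD
from .diffusion import diffusion_profile
from .hbonds import (
    MicrostateTrajectory,
    discretize,
    helix_fraction,
    nhb_series,
    read_distance_tsv,
    write_nhb_tsv,
)
from .kinetics import (
    count_transitions,
    rate_matrix_from_transition,
    relaxation_times,
    stationary_distribution,
    transition_matrix,
    write_rate_matrix_tsv,
)
from .network import flux_weights, gmwp
from .patterns import pattern_table, terminal_helix_report
from .peptide import PeptideSpec

log = logging.getLogger("hbfold")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated configuration for a full analysis run."""

    n_residues: int
    dt: float  # ns
    lag: float  # ns
    distances_tsv: str | None = None  # input distance table
    states_tsv: str | None = None  # or a pre-discretised state table
    output_dir: str = "hbfold_out"
    coarse_dims: tuple[int, ...] = (2,)
    temperature: float = DEFAULT_TEMPERATURE
    step_angstrom: float = HELIX_RISE_ANGSTROM
    pattern_threshold: float = PATTERN_THRESHOLD
    committor_band: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag <= 0 or self.dt <= 0:
            raise ValueError("dt and lag must be positive")
        if abs(self.lag / self.dt - round(self.lag / self.dt)) > 1e-9:
            raise ValueError("lag must be an integer multiple of dt")
        if self.distances_tsv is None and self.states_tsv is None:
            raise ValueError("either distances_tsv or states_tsv is required")
        for d in self.coarse_dims:
            if not 2 <= d <= 4:
                raise ValueError("coarse dimensions default to the 2-4 range")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "coarse_dims" in raw:
            raw["coarse_dims"] = tuple(raw["coarse_dims"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_states(config: AnalysisConfig) -> tuple[MicrostateTrajectory, dict]:
    spec = PeptideSpec(n_residues=config.n_residues)
    extras: dict = {}
    if config.distances_tsv is not None:
        ds = read_distance_tsv(config.distances_tsv, dt=config.dt)
        if ds.maxhb != spec.maxhb:
            raise PipelineError(
                f"stage nhb: distance table has {ds.maxhb} bond columns, "
                f"peptide expects {spec.maxhb}"
            )
        series = nhb_series(ds)
        traj = discretize(series, spec.maxhb)
        extras["series"] = series
    else:
        df = pd.read_csv(config.states_tsv, sep="\t")
        traj = MicrostateTrajectory(
            states=df["state"].to_numpy(), dt=config.dt, maxhb=spec.maxhb
        )
    return traj, extras


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute every analysis stage and write the report bundle.

    Returns the master report (also written to report.json in the
    output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = PeptideSpec(n_residues=config.n_residues)
    report: dict = {
        "hbfold_version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
    }

    current = "setup"

    def stage(name):
        nonlocal current
        current = name
        log.info("stage %s", name)

    try:
        stage("coordinate")
        traj, extras = _load_states(config)
        f = helix_fraction(traj, spec.maxhb)
        report["maxhb"] = spec.maxhb
        report["n_frames"] = len(traj)
        report["helix_fraction"] = f
        if "series" in extras:
            write_nhb_tsv(out / "nhb.tsv", extras["series"], traj)

        stage("kinetics")
        counts = count_transitions(traj, config.lag)
        T = transition_matrix(counts)
        K = rate_matrix_from_transition(T)
        p = stationary_distribution(K)
        taus = relaxation_times(K)
        write_rate_matrix_tsv(out / "rate_matrix.tsv", K)
        report["kinetics"] = {
            "lag_ns": config.lag,
            "stationary": p.p.tolist(),
            "relaxation_times_ns": taus.tolist(),
        }

        stage("gmwp")
        net = flux_weights(K, p)
        path = gmwp(net, 0, spec.maxhb)
        report["gmwp"] = {
            "path": list(path.path),
            "bottleneck_edge": list(path.bottleneck_edge),
            "bottleneck_weight": path.bottleneck_weight,
        }
        edges = [
            {"i": i, "j": j, "weight": net.weights[i, j]}
            for i in range(net.n_nodes)
            for j in range(i + 1, net.n_nodes)
            if net.weights[i, j] > 0
        ]
        pd.DataFrame(edges).to_csv(out / "flux_network.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"state": range(net.n_nodes), "population": p.p,
             "dG_kcal_mol": net.free_energies}
        ).to_csv(out / "free_energy_profile.tsv", sep="\t", index=False)

        stage("coarse")
        report["coarse"] = {}
        for N in config.coarse_dims:
            part = pcca_plus(T, N)
            model = odr_fit(K, part, config.lag, maxhb=spec.maxhb)
            entry = {
                "partition": model.partition.assignment.tolist(),
                "R_per_us": model.R.tolist(),
                "Pi": model.Pi.tolist(),
                "labels": list(model.labels),
                "relaxations_ns": model.relaxations.tolist(),
            }
            if N == 2:
                ts2 = two_state_summary(model, config.temperature)
                entry["two_state"] = asdict(ts2)
            report["coarse"][str(N)] = entry

        stage("tpt")
        prof = committor(K, [0], [spec.maxhb])
        ts = transition_states(prof, config.committor_band)
        report["tpt"] = {"committor": prof.q.tolist(), "transition_states": ts}

        stage("diffusion")
        dp = diffusion_profile(
            K, a=config.step_angstrom * 1e-10, temperature=config.temperature
        )
        pd.DataFrame(
            {"edge": [f"{i}-{j}" for i, j in dp.edges],
             "D_m2_per_s": dp.D, "friction_kg_per_s": dp.friction}
        ).to_csv(out / "diffusion.tsv", sep="\t", index=False)
        report["diffusion"] = {
            "D_avg_m2_per_s": dp.D_avg, "D_spread": dp.D_spread,
            "f_avg_kg_per_s": dp.f_avg, "f_spread": dp.f_spread,
        }

        stage("patterns")
        if "series" in extras:
            table = pattern_table(extras["series"].weights, config.pattern_threshold)
            terminal_helix_report(table).to_csv(
                out / "patterns.tsv", sep="\t", index=False
            )
            report["patterns"] = {
                "n_patterns": len(table.table),
                "microstate_populations": table.microstate_populations().tolist(),
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{current}' failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
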