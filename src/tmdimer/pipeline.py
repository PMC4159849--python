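"""End-to-end analysis pipeline over synthetic two-helix trajectories.

The pipeline mirrors a self-assembly study: ensembles of short
assembly runs per condition (one final interface each) plus a few long
switching trajectories per condition are generated from a planted
Markov interface model; contact maps are computed, pooled into one
global clustering (a shared "cluster space" so cluster ids are
comparable across conditions), and the downstream summaries are
written as CSV: per-condition cluster frequencies, per-cluster contact
frequency maps and crossing-angle statistics, retention times, the
pruned transition network, and subsampled correlation curves with
their double-exponential fits.

Every stage draws its randomness from one seed; re-running with the
same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_frequencies, cluster_interfaces, contact_frequency_map
from .contacts import AnalysisConfig, compute_contact_map
from .geometry import dimer_geometry
from .io import save_contact_map_csv
from .kinetics import (
    LabeledTrajectory,
    build_transition_net,
    is_strongly_connected,
    retention_summary,
    retention_times,
    transition_table,
)
from .stats import fit_double_exponential, subsampled_correlation
from .synthetic import (
    DEFAULT_STATES,
    ConditionSpec,
    InterfaceState,
    MarkovInterfaceModel,
    render_assembly_frames,
    sample_condition_assemblies,
    simulate_interface_markov,
)

_FLOAT_FORMAT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated configuration of :func:`run_pipeline`."""

    seed: int = 0
    dt: float = 50.0  # ns between stored frames
    n_assemblies: int = 120  # short self-assembly runs per condition
    long_duration: float = 20000.0  # ns per long trajectory
    n_long: int = 2  # long trajectories per condition
    noise_sigma: float = 0.05
    states: list[dict] | None = None
    transition_matrix: list[list[float]] | None = None
    mean_dwell: list[float] | float | None = None
    conditions: list[dict] = field(default_factory=list)
    analysis: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)
    min_cluster_count: int = 3
    top_clusters_for_maps: int = 6

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.build_analysis_config()  # validate early
        config.build_model()
        config.build_conditions()
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def build_analysis_config(self) -> AnalysisConfig:
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(self.analysis) - known
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
        return AnalysisConfig(**self.analysis)

    def build_model(self) -> MarkovInterfaceModel:
        if self.states is None:
            states = DEFAULT_STATES
        else:
            states = tuple(InterfaceState(**s) for s in self.states)
        mean_dwell = self.mean_dwell
        if isinstance(mean_dwell, (int, float)):
            mean_dwell = np.full(len(states), float(mean_dwell))
        matrix = None
        if self.transition_matrix is not None:
            matrix = np.asarray(self.transition_matrix, dtype=float)
        return MarkovInterfaceModel(
            states=states,
            transition_matrix=matrix,
            mean_dwell=None if mean_dwell is None else np.asarray(mean_dwell, float),
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )

    def build_conditions(self) -> list[ConditionSpec]:
        if not self.conditions:
            raise ValueError("config needs at least one condition")
        return [
            ConditionSpec(c["condition_id"], dict(c["state_frequencies"]))
            for c in self.conditions
        ]


@dataclass
class PipelineReport:
    """In-memory results plus the paths of everything written."""

    outdir: Path
    clustering: object
    frequency_table: pd.DataFrame
    transition_net: object
    fits: pd.DataFrame
    manifest: dict
    paths: dict[str, Path]

    @property
    def n_clusters(self) -> int:
        return self.clustering.n_clusters


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _stage_seeds(seed: int, n: int) -> list[int]:
    # stay below 2**31 so downstream consumers can treat these as plain ints
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Run simulate -> contacts -> cluster -> geometry -> kinetics -> statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    analysis = config.build_analysis_config()
    model = config.build_model()
    conditions = config.build_conditions()
    seeds = _stage_seeds(config.seed, 6)
    paths: dict[str, Path] = {}

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        records = []  # (kind, condition, replicate, time, true_state, frame)
        rng_seeds = _stage_seeds(seeds[0], len(conditions) * (1 + config.n_long))
        si = 0
        long_runs = {}
        for cond in conditions:
            labels = sample_condition_assemblies(
                cond, config.n_assemblies, seed=rng_seeds[si]
            )
            frames = render_assembly_frames(model, labels, seed=rng_seeds[si])
            si += 1
            for k, (lab, frame) in enumerate(zip(labels, frames)):
                records.append(("short", cond.condition_id, k, frame.time, lab, frame))
            runs = []
            for rep in range(config.n_long):
                traj, true_labels = simulate_interface_markov(
                    model, config.long_duration, config.dt, seed=rng_seeds[si]
                )
                si += 1
                runs.append((traj, true_labels))
                for k, (frame, lab) in enumerate(zip(traj, true_labels)):
                    records.append(
                        ("long", cond.condition_id, rep, frame.time, lab, frame)
                    )
            long_runs[cond.condition_id] = runs
        return records, long_runs

    records, long_runs = simulate()

    # -- contacts + clustering --------------------------------------------
    @_stage("contacts")
    def contacts():
        return [
            compute_contact_map(frame, cutoff=analysis.contact_cutoff)
            for (_, _, _, _, _, frame) in records
        ]

    maps = contacts()

    @_stage("cluster")
    def cluster():
        clustering = cluster_interfaces(maps, analysis)
        rows = []
        for (kind, cond, rep, time, true_state, _), label in zip(
            records, clustering.labels
        ):
            rows.append(
                {
                    "kind": kind,
                    "condition": cond,
                    "replicate": rep,
                    "time_ns": time,
                    "true_state": true_state,
                    "cluster": label,
                }
            )
        assignments = pd.DataFrame(rows)
        return clustering, assignments

    clustering, assignments = cluster()
    paths["assignments"] = outdir / "assignments.csv"
    assignments.to_csv(paths["assignments"], index=False, float_format=_FLOAT_FORMAT)

    short_mask = assignments["kind"] == "short"
    freq_table = cluster_frequencies(
        assignments.loc[short_mask, "cluster"].to_numpy(),
        assignments.loc[short_mask, "condition"].to_numpy(),
        min_count=config.min_cluster_count,
    )
    paths["frequencies"] = outdir / "frequencies.csv"
    freq_table.to_csv(paths["frequencies"], float_format=_FLOAT_FORMAT)

    @_stage("contact-frequency-maps")
    def frequency_maps():
        from .io import save_contact_map_png

        for cid in clustering.cluster_ids[: config.top_clusters_for_maps]:
            cfm = contact_frequency_map(clustering, int(cid), maps)
            path = outdir / f"contact_frequency_cluster_{int(cid)}.csv"
            save_contact_map_csv(path, cfm.matrix, cfm.residues_a, cfm.residues_b)
            paths[f"contact_frequency_{int(cid)}"] = path
            save_contact_map_png(
                path.with_suffix(".png"),
                cfm.matrix,
                cfm.residues_a,
                cfm.residues_b,
                title=f"cluster {int(cid)} (n={cfm.n_members})",
            )

    frequency_maps()

    # -- geometry ----------------------------------------------------------
    @_stage("geometry")
    def geometry():
        rows = []
        for (kind, cond, rep, time, true_state, frame), label in zip(
            records, clustering.labels
        ):
            if kind != "short":
                continue
            geo = dimer_geometry(frame)
            rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "cluster": label,
                    "crossing_angle_deg": geo.crossing_angle,
                    "tilt_a_deg": geo.tilt_a,
                    "tilt_b_deg": geo.tilt_b,
                }
            )
        return pd.DataFrame(rows)

    geometry_df = geometry()
    paths["geometry"] = outdir / "geometry.csv"
    geometry_df.to_csv(paths["geometry"], index=False, float_format=_FLOAT_FORMAT)

    # -- kinetics ----------------------------------------------------------
    @_stage("kinetics")
    def kinetics():
        long_df = assignments[assignments["kind"] == "long"]
        sequences = []
        summaries = []
        for cond in conditions:
            for rep in range(config.n_long):
                sel = long_df[
                    (long_df["condition"] == cond.condition_id)
                    & (long_df["replicate"] == rep)
                ]
                labeled = LabeledTrajectory(
                    sel["time_ns"].to_numpy(), sel["cluster"].to_numpy()
                )
                sequences.append(list(labeled.labels))
                dwells = retention_times(labeled)
                if dwells:
                    summary = retention_summary(dwells)
                    summary.insert(0, "condition", cond.condition_id)
                    summary.insert(1, "replicate", rep)
                    summaries.append(summary)
        retention = (
            pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
        )
        net = build_transition_net(sequences)
        return retention, net

    retention_df, net = kinetics()
    paths["retention"] = outdir / "retention.csv"
    retention_df.to_csv(paths["retention"], index=False, float_format=_FLOAT_FORMAT)
    paths["transitions"] = outdir / "transitions.csv"
    transition_table(net).to_csv(paths["transitions"], index=False)
    paths["transitions_graphml"] = outdir / "transitions.graphml"
    import networkx as nx

    nx.write_graphml(nx.relabel_nodes(net, {n: str(n) for n in net.nodes}), paths["transitions_graphml"])

    # -- statistics --------------------------------------------------------
    @_stage("statistics")
    def statistics():
        corr_cfg = dict(config.correlation)
        n_perm = int(corr_cfg.pop("n_permutations", 200))
        n_values = corr_cfg.pop("n_values", None)
        if corr_cfg:
            raise ValueError(f"unknown correlation keys: {sorted(corr_cfg)}")
        if n_values is None:
            n_max = config.n_assemblies // 2
            n_values = [
                n
                for n in (3, 5, 8, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150)
                if n <= n_max
            ]
        pools = {
            cond.condition_id: assignments.loc[
                short_mask & (assignments["condition"] == cond.condition_id), "cluster"
            ].tolist()
            for cond in conditions
        }
        space = sorted({c for pool in pools.values() for c in pool})
        curve_rows, fit_rows = [], []
        stat_seeds = _stage_seeds(seeds[4], len(conditions) ** 2)
        si = 0
        for i, cond_x in enumerate(conditions):
            for cond_y in conditions[i:]:
                auto = cond_x.condition_id == cond_y.condition_id
                curve = subsampled_correlation(
                    pools[cond_x.condition_id],
                    None if auto else pools[cond_y.condition_id],
                    n_values=n_values,
                    n_permutations=n_perm,
                    seed=stat_seeds[si],
                    mode="auto" if auto else "cross",
                    cluster_space=space,
                )
                si += 1
                pair = f"{cond_x.condition_id}-{cond_y.condition_id}"
                for n, m, s in zip(curve.n_values, curve.mean_r, curve.sd_r):
                    curve_rows.append(
                        {"pair": pair, "n": int(n), "mean_r": m, "sd_r": s}
                    )
                fit = fit_double_exponential(curve, seed=seeds[5])
                fit_rows.append(
                    {
                        "pair": pair,
                        "a": fit.a,
                        "b": fit.b,
                        "c": fit.c,
                        "d": fit.d,
                        "limit": fit.limit,
                    }
                )
        return pd.DataFrame(curve_rows), pd.DataFrame(fit_rows)

    curves_df, fits_df = statistics()
    paths["correlation"] = outdir / "correlation.csv"
    curves_df.to_csv(paths["correlation"], index=False, float_format=_FLOAT_FORMAT)
    paths["fits"] = outdir / "fits.csv"
    fits_df.to_csv(paths["fits"], index=False, float_format=_FLOAT_FORMAT)

    # -- manifest ----------------------------------------------------------
    config_dump = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    manifest = {
        "tmdimer_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_dump.encode()).hexdigest(),
        "n_clusters": int(clustering.n_clusters),
        "strongly_connected": bool(is_strongly_connected(net)),
        "outputs": sorted(str(p.name) for p in paths.values()),
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineReport(
        outdir, clustering, freq_table, net, fits_df, manifest, paths
    )
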