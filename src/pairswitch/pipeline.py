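"""End-to-end orchestration: simulate/load -> classify -> dwell stats ->
van't Hoff thermodynamics -> barrier kinetics, with reproducible outputs.

Every stage writes its table or JSON report under the output directory
and the run closes with a manifest recording the config snapshot, seeds,
output digests and package version, so an identical configuration
reproduces byte-identical files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ClassifierThresholds, classify_trajectory
from .dwell import (
    cumulative_occupancy,
    mean_lifetimes,
    lifetime_histogram,
    occupancy,
    segment,
    transition_path_times,
)
from .io import (
    dump_generator_config,
    file_digest,
    read_trajectory,
    write_json,
    write_labeled_trajectory,
    write_state_path,
    write_trajectory,
    write_tsv,
)
from .kinetics import barrier_fit, rate_constants, ratio_curves
from .synthetic import GeneratorConfig, simulate_ensemble
from .thermo import vant_hoff_fit

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("pairswitch")


@dataclass
class PipelineConfig:
    """What to run and on what inputs.

    Either ``generator`` is set (synthetic mode) or ``input_tables`` maps
    temperatures to feature-TSV paths.  ``stats_only`` stops after the
    per-temperature dwell statistics (valid with a single temperature);
    the full pipeline needs at least two temperatures for the fits.
    """

    generator: GeneratorConfig | None = None
    input_tables: dict[float, str] = field(default_factory=dict)
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    stats_only: bool = False
    n_boot: int = 200
    seed: int = 0
    occupancy_stride: int = 1000
    histogram_bins: int = 20

    def __post_init__(self) -> None:
        if self.generator is None and not self.input_tables:
            raise ValueError("either a generator config or input tables are required")
        if self.generator is not None and self.input_tables:
            raise ValueError("provide a generator config or input tables, not both")
        n_temps = (
            len(self.generator.temperatures_K)
            if self.generator is not None
            else len(self.input_tables)
        )
        if not self.stats_only and n_temps < 2:
            raise ValueError("thermo/kinetics fitting needs >= 2 temperatures")


@dataclass
class RunManifest:
    config_path: str
    seeds: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256
    version: str
    stages: list[str]

    def as_dict(self) -> dict:
        return {
            "config_path": self.config_path,
            "seeds": self.seeds,
            "outputs": self.outputs,
            "version": self.version,
            "stages": self.stages,
        }


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute all requested stages, writing reports under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages: list[str] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # halt with stage name, keep partials
                (out / "FAILED").write_text(f"{name}: {exc}\n", encoding="utf-8")
                raise StageFailure(name, exc) from exc
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            stages.append(name)
            return result

        return wrap

    # --- acquire per-temperature feature tables -------------------------
    truth = {}
    if config.generator is not None:
        def simulate():
            ensemble = simulate_ensemble(config.generator)
            tables = {}
            for T in ensemble.temperatures():
                run = ensemble[T]
                tag = f"T{T:g}K_seed{config.generator.seed}"
                outputs[f"trajectory_{tag}.tsv"] = write_trajectory(
                    run.trajectory, out / f"trajectory_{tag}.tsv"
                )
                outputs[f"truth_{tag}.tsv"] = write_state_path(
                    run.path, out / f"truth_{tag}.tsv"
                )
                tables[T] = run.trajectory
                truth[T] = run.path
            return tables

        tables = stage("simulate")(simulate)
        config_path = dump_generator_config(config.generator, out / "generator_config.yaml")
        outputs["generator_config.yaml"] = config_path
    else:
        tables = stage("load")(
            lambda: {T: read_trajectory(p) for T, p in config.input_tables.items()}
        )
        config_path = out / "generator_config.yaml"  # not written in load mode

    # --- classify and per-temperature statistics ------------------------
    per_T = {}

    def classify_and_stats():
        rows = []
        for T, table in sorted(tables.items()):
            seq = classify_trajectory(table, config.thresholds)
            segs = segment(seq)
            occ = occupancy(segs, seq.total_time_ns)
            lifetimes = mean_lifetimes(
                segs, n_boot=config.n_boot, seed=config.seed + 1
            )
            tpt = transition_path_times(segs, n_boot=config.n_boot, seed=config.seed + 2)
            per_T[T] = {
                "seq": seq,
                "segments": segs,
                "occupancy": occ,
                "lifetimes": lifetimes,
                "tpt": tpt,
            }
            tag = f"T{T:g}K"
            outputs[f"states_{tag}.tsv"] = write_labeled_trajectory(
                table, seq, out / f"states_{tag}.tsv"
            )
            outputs[f"episodes_{tag}.tsv"] = write_tsv(
                seq.episode_table(), out / f"episodes_{tag}.tsv"
            )
            outputs[f"occupancy_vs_time_{tag}.tsv"] = write_tsv(
                cumulative_occupancy(seq, stride=config.occupancy_stride),
                out / f"occupancy_vs_time_{tag}.tsv",
            )
            hist_frames = []
            for label in ("A", "D", "ata", "dtd"):
                try:
                    counts, edges = lifetime_histogram(
                        segs, label, n_bins=config.histogram_bins
                    )
                except ValueError:
                    continue
                hist_frames.append(
                    pd.DataFrame(
                        {
                            "label": label,
                            "bin_left_ns": edges[:-1],
                            "bin_right_ns": edges[1:],
                            "count": counts,
                        }
                    )
                )
            if hist_frames:
                outputs[f"lifetime_histograms_{tag}.tsv"] = write_tsv(
                    pd.concat(hist_frames, ignore_index=True),
                    out / f"lifetime_histograms_{tag}.tsv",
                )
            for label in ("A", "D", "T", "U"):
                stat = lifetimes.get(label)
                p = {"A": occ.p_a, "D": occ.p_d, "T": occ.p_t, "U": occ.p_u}[label]
                if stat is None and p == 0:
                    continue
                rows.append(
                    {
                        "temperature_K": T,
                        "label": label,
                        "tau_ave_ns": stat.tau_ave_ns if stat else float("nan"),
                        "p": p,
                        "N": stat.n if stat else 0,
                    }
                )
        summary = pd.DataFrame(rows)
        outputs["state_summary.tsv"] = write_tsv(summary, out / "state_summary.tsv")
        return summary

    stage("stats")(classify_and_stats)

    manifest_seeds = {
        "pipeline": config.seed,
        "generator": config.generator.seed if config.generator else -1,
    }
    if config.stats_only:
        return _finish(out, config_path, manifest_seeds, outputs, stages)

    # --- van't Hoff thermodynamics --------------------------------------
    def thermo_stage():
        points = [
            (T, d["occupancy"].p_a, d["occupancy"].p_d) for T, d in sorted(per_T.items())
        ]
        fit = vant_hoff_fit(points)
        outputs["vant_hoff_points.tsv"] = write_tsv(
            fit.per_temperature(), out / "vant_hoff_points.tsv"
        )
        outputs["thermo_fit.json"] = write_json(fit.report(), out / "thermo_fit.json")
        return fit

    thermo_fit = stage("thermo")(thermo_stage)

    # --- kinetics: rates, ratio curves, barrier decomposition ----------
    def kinetics_stage():
        rates = {
            T: rate_constants(d["lifetimes"]) for T, d in sorted(per_T.items())
        }
        ratios = ratio_curves(
            {T: (d["lifetimes"], d["tpt"]) for T, d in per_T.items()}
        )
        outputs["ratio_curves.tsv"] = write_tsv(ratios, out / "ratio_curves.tsv")
        report = {
            "rates_per_ns": {
                str(T): {
                    "k_plus": r.k_plus,
                    "k_minus": r.k_minus,
                    "k_t_to_a": r.k_t_to_a,
                    "k_t_to_d": r.k_t_to_d,
                }
                for T, r in rates.items()
            }
        }
        if len(ratios) >= 2:
            fit = barrier_fit(ratios, thermo_fit, seed=config.seed + 3)
            report["barrier_fit"] = fit.report()
        else:
            report["barrier_fit"] = None
        outputs["kinetics_report.json"] = write_json(report, out / "kinetics_report.json")
        return report

    stage("kinetics")(kinetics_stage)
    return _finish(out, config_path, manifest_seeds, outputs, stages)


def _finish(out: Path, config_path, seeds, outputs, stages) -> RunManifest:
    digests = {name: file_digest(p) for name, p in sorted(outputs.items())}
    manifest = RunManifest(
        config_path=str(config_path),
        seeds=seeds,
        outputs=digests,
        version=__version__,
        stages=stages,
    )
    write_json(manifest.as_dict(), out / "manifest.json")
    return manifest
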