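"""End-to-end experiment: generate a scene, run both response models,
optimize AED siting, and compare the arms statistically.

Two simulations are performed for every demand point — ambulance travel
from the station, and bystander round-trip retrieval from the nearest
optimized AED — on the identical demand set and in identical order, so
the comparison is paired. Every artifact written carries the config hash
and seed, and a fixed config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from aedsim._version import __version__ as _version
from aedsim.coverage import (
    CoverageParams,
    ResponseTimes,
    ambulance_response_times,
    build_coverage_matrix,
    bystander_roundtrip_times,
    coverage_count,
)
from aedsim.mclp import MCLPProblem, min_facilities_for_target, solve_mclp_exact, solve_mclp_greedy
from aedsim.network import (
    PointSet,
    get_mode,
    snap_points,
    write_network_geojson,
    write_points_geojson,
)
from aedsim.stats import (
    NormalityResult,
    PairedComparison,
    SummaryStats,
    WilcoxonResult,
    shapiro_wilk,
    summarize_times,
    wilcoxon_signed_rank,
)
from aedsim.synthetic import (
    CityConfig,
    generate_grid_city,
    place_candidates,
    place_station,
    sample_demand_points,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "StageError",
    "run_experiment",
    "export_violin_data",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ExperimentConfig:
    """One config drives the whole replication experiment."""

    city: CityConfig = field(default_factory=CityConfig)
    threshold_s: float = 300.0
    walk_speed_kmh: float = 10.0
    ambulance_speed_kmh: float = 50.0
    station_position: str = "corner"
    mclp_mode: str = "fixed_p"  # fixed_p | min_for_target
    p: int = 18
    target_fraction: float = 0.9
    solver: str = "greedy"  # greedy | exact
    ci_method: str = "t"
    exact_limit: int = 25
    continuity: bool = False
    seed: int = 0

    def coverage_params(self) -> CoverageParams:
        return CoverageParams(
            threshold_s=self.threshold_s,
            stretch_limit_s=self.threshold_s / 2.0,
            bystander_mode=get_mode("walk", self.walk_speed_kmh),
            ambulance_mode=get_mode("ambulance", self.ambulance_speed_kmh),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["city"] = self.city.to_dict()
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "city" in d and isinstance(d["city"], dict):
            d["city"] = CityConfig(**d["city"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ArmResult:
    times: ResponseTimes
    summary: SummaryStats
    covered: int
    fraction: float


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    ambulance: ArmResult
    bystander: ArmResult
    mclp_selected: list[str]
    mclp_objective: float
    mclp_method: str
    mclp_optimal: bool
    mclp_p_used: int
    normality_ambulance: NormalityResult
    normality_bystander: NormalityResult
    comparison: WilcoxonResult
    n_excluded_pairs: int

    def to_dict(self) -> dict:
        def arm(a: ArmResult) -> dict:
            return {
                "times_s": [float(t) for t in a.times.times],
                "demand_ids": a.times.demand.ids,
                "model": a.times.model,
                "summary": asdict(a.summary),
                "covered": a.covered,
                "fraction": a.fraction,
            }

        return {
            "provenance": {
                "config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                "seed": self.config.seed,
                "version": _version,
            },
            "ambulance": arm(self.ambulance),
            "bystander": arm(self.bystander),
            "mclp": {
                "selected": self.mclp_selected,
                "objective": self.mclp_objective,
                "method": self.mclp_method,
                "optimal": self.mclp_optimal,
                "p_used": self.mclp_p_used,
            },
            "normality": {
                "ambulance": asdict(self.normality_ambulance),
                "bystander": asdict(self.normality_bystander),
            },
            "comparison": asdict(self.comparison),
            "n_excluded_pairs": self.n_excluded_pairs,
        }


def _finite_summary(times: np.ndarray, cfg: ExperimentConfig) -> SummaryStats:
    finite = times[np.isfinite(times)]
    return summarize_times(finite, ci_method=cfg.ci_method, level=0.95, seed=cfg.seed)


def run_experiment(
    config: ExperimentConfig, output_dir: str | Path | None = None
) -> ExperimentReport:
    """Run the full simulation pipeline from one config.

    Stages: generate city → sample demand → place station & candidates →
    ambulance times & coverage → coverage matrix → MCLP → bystander times
    & coverage → normality per arm → Wilcoxon → report (+ file outputs
    when ``output_dir`` is given). Any stage failure aborts with the
    stage name attached.
    """
    params = config.coverage_params()
    seed = config.seed

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    city_cfg = CityConfig(**{**config.city.to_dict(), "seed": seed})
    network = stage("generate_city", lambda: generate_grid_city(city_cfg))
    demand = stage(
        "sample_demand",
        lambda: snap_points(
            network,
            sample_demand_points(
                network, city_cfg.n_demand, city_cfg.center_fraction, seed + 1
            ),
        ),
    )
    candidates = stage(
        "place_candidates", lambda: place_candidates(network, city_cfg.n_candidates, seed + 2)
    )
    station = stage(
        "place_station", lambda: place_station(network, config.station_position, seed + 3)
    )

    amb_times = stage(
        "ambulance_times", lambda: ambulance_response_times(network, station, demand, params)
    )
    cov_matrix = stage(
        "coverage_matrix", lambda: build_coverage_matrix(network, demand, candidates, params)
    )

    def solve():
        if config.mclp_mode == "fixed_p":
            prob = MCLPProblem(coverage=cov_matrix, p=min(config.p, len(candidates)))
            if config.solver == "exact":
                return solve_mclp_exact(prob)
            return solve_mclp_greedy(prob)
        if config.mclp_mode == "min_for_target":
            return min_facilities_for_target(
                cov_matrix, config.target_fraction, solver=config.solver
            ).solution
        raise ValueError(f"unknown mclp_mode {config.mclp_mode!r}")

    mclp_sol = stage("mclp", solve)
    selected_ids = set(mclp_sol.selected)
    aed_sites = PointSet([p for p in candidates if p.id in selected_ids])
    byst_times = stage(
        "bystander_times", lambda: bystander_roundtrip_times(network, demand, aed_sites, params)
    )

    amb_cov, amb_frac = coverage_count(amb_times, params)
    byst_cov, byst_frac = coverage_count(byst_times, params)

    # paired comparison on points finite in both arms
    finite = np.isfinite(amb_times.times) & np.isfinite(byst_times.times)
    n_excluded = int((~finite).sum())
    pc = PairedComparison(
        labels=("ambulance", "bystander_roundtrip"),
        a=amb_times.times[finite],
        b=byst_times.times[finite],
    )
    norm_amb = stage("normality", lambda: shapiro_wilk(pc.a))
    norm_byst = stage("normality", lambda: shapiro_wilk(pc.b))
    comparison = stage(
        "wilcoxon",
        lambda: wilcoxon_signed_rank(
            pc, exact_limit=config.exact_limit, continuity=config.continuity
        ),
    )

    report = ExperimentReport(
        config=config,
        ambulance=ArmResult(amb_times, _finite_summary(amb_times.times, config), amb_cov, amb_frac),
        bystander=ArmResult(byst_times, _finite_summary(byst_times.times, config), byst_cov, byst_frac),
        mclp_selected=mclp_sol.selected,
        mclp_objective=mclp_sol.objective,
        mclp_method=mclp_sol.method,
        mclp_optimal=mclp_sol.optimal,
        mclp_p_used=len(mclp_sol.selected),
        normality_ambulance=norm_amb,
        normality_bystander=norm_byst,
        comparison=comparison,
        n_excluded_pairs=n_excluded,
    )
    if output_dir is not None:
        stage(
            "write_outputs",
            lambda: _write_outputs(
                Path(output_dir), config, network, demand, candidates, station, aed_sites, report
            ),
        )
    return report


def _write_outputs(out, config, network, demand, candidates, station, aed_sites, report):
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.config_hash(), "seed": config.seed, "version": _version}
    prov_line = f"provenance: config_hash={prov['config_hash']} seed={prov['seed']}"
    write_network_geojson(network, out / "network.geojson", provenance=prov)
    write_points_geojson(demand, out / "demand.geojson", provenance=prov)
    write_points_geojson(candidates, out / "candidates.geojson", provenance=prov)
    write_points_geojson(station, out / "station.geojson", provenance=prov)
    write_points_geojson(aed_sites, out / "aed_selected.geojson", provenance=prov)
    for name, arm in (("ambulance", report.ambulance), ("bystander", report.bystander)):
        df = pd.DataFrame(
            {"demand_id": arm.times.demand.ids, "seconds": arm.times.times}
        )
        with open(out / f"{name}_times.csv", "w") as fh:
            fh.write(f"# {prov_line}\n")
            df.to_csv(fh, index=False, lineterminator="\n")
    with open(out / "violin.csv", "w") as fh:
        fh.write(f"# {prov_line}\n")
        export_violin_data(report).to_csv(fh, index=False, lineterminator="\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
        fh.write("\n")


def export_violin_data(report: ExperimentReport) -> pd.DataFrame:
    """Long-format paired times (demand_id, arm, seconds) for plotting.

    Arms preserve the demand-id pairing: joining on demand_id
    reconstructs the paired differences exactly.
    """
    rows = []
    for arm_name, arm in (
        ("ambulance", report.ambulance),
        ("bystander_roundtrip", report.bystander),
    ):
        for pid, t in zip(arm.times.demand.ids, arm.times.times):
            rows.append({"demand_id": pid, "arm": arm_name, "seconds": float(t)})
    return pd.DataFrame(rows, columns=["demand_id", "arm", "seconds"])
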