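"""Campaign layer: generate, execute, collect and analyze Saltelli designs.

A campaign directory holds ``design.csv`` plus one sub-directory per run
(``runs/<run_id>/{config.toml, trajectory.csv, snapshots.h5, status.json}``);
analysis writes ``analysis/{moments.csv, sobol.csv, summary.json, maps.h5}``.
Runs are independent: execution order and worker count never change results,
because each run's randomness is fully determined by its own seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.proportion import proportion_confint

from . import saltelli as sal
from .config_io import load_config, save_config
from .engine import SimulationConfig, run_simulation
from .saltelli import (ParameterSpace, SaltelliDesign, aleatory_variance,
                       bootstrap_estimate, build_design, estimate_moments,
                       first_order_index, total_index)

__all__ = [
    "CampaignResult",
    "SpatialField",
    "CampaignIncompleteError",
    "generate_campaign",
    "run_campaign",
    "load_campaign",
    "evaluate_design",
    "analyze_outputs",
    "analyze_campaign",
    "presence_probability",
    "spatial_sensitivity_maps",
]


class CampaignIncompleteError(RuntimeError):
    """Some design runs are missing or failed; analysis refuses to proceed."""


@dataclass
class CampaignResult:
    """Collected outputs of a completed campaign, in design-row order."""

    design: SaltelliDesign
    times: np.ndarray                # (T,) days
    area: np.ndarray                 # (R, T) mm^2
    width: np.ndarray                # (R, T) mm
    coverage: np.ndarray             # (R, T)
    restenosis: np.ndarray           # (R,) bool
    final_snapshots: np.ndarray      # (R, ny, nx) bool
    lattice_spacing: float           # mm
    original_lumen_area: float       # mm^2

    def block_outputs(self, values: np.ndarray, block: str, i: int = 0
                      ) -> np.ndarray:
        """Rows of ``values`` belonging to one design block, ordered by j."""
        sub = self.design.block_rows(block, i)
        return values[sub.index.to_numpy()]


@dataclass
class SpatialField:
    """Per-lattice-site scalar field (probability, variance, FOSI or TSI)."""

    data: np.ndarray        # (ny, nx)
    spacing: float          # mm
    kind: str


# ---------------------------------------------------------------------------
# Generation and execution
# ---------------------------------------------------------------------------

_INPUT_NAMES = ("flow_velocity", "deployment_depth", "regen_time")


def _apply_inputs(base: SimulationConfig, x: dict[str, float],
                  seed: int) -> SimulationConfig:
    cfg = replace(base, master_seed=int(seed))
    if "flow_velocity" in x:
        cfg = replace(cfg, flow=replace(cfg.flow, velocity=float(x["flow_velocity"])))
    if "deployment_depth" in x:
        cfg = replace(cfg, deployment_depth=float(x["deployment_depth"]))
    if "regen_time" in x:
        cfg = replace(cfg, scenario=replace(
            cfg.scenario, total_recovery_time=float(x["regen_time"])))
    unknown = set(x) - set(_INPUT_NAMES)
    if unknown:
        raise ValueError(f"no setter for inputs: {sorted(unknown)}")
    return cfg


def generate_campaign(base_config: SimulationConfig, space: ParameterSpace,
                      M: int, seed_root: int, out_dir: str | Path,
                      overwrite: bool = False) -> SaltelliDesign:
    """Write the design table and one config file per run.  Idempotent."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"campaign directory {out} exists; "
                              "pass overwrite=True to regenerate")
    out.mkdir(parents=True, exist_ok=True)
    design = build_design(space, M, seed_root)
    design.runs.to_csv(out / "design.csv", index=False)
    for row in design.runs.itertuples():
        run_dir = out / "runs" / row.run_id
        run_dir.mkdir(parents=True, exist_ok=True)
        x = {name: getattr(row, name) for name in design.names}
        cfg = _apply_inputs(base_config, x, row.seed)
        save_config(cfg, run_dir / "config.toml")
    return design


def _execute_one(run_dir: Path) -> str | None:
    """Run one design entry; returns an error string or None on success."""
    status_path = run_dir / "status.json"
    try:
        cfg = load_config(run_dir / "config.toml")
        traj = run_simulation(cfg)
        frame = pd.DataFrame({
            "time_days": traj.times,
            "neointimal_area_mm2": traj.neointimal_area,
            "mean_lumen_width_mm": traj.mean_lumen_width,
            "coverage": traj.coverage,
        })
        frame.to_csv(run_dir / "trajectory.csv", index=False)
        with h5py.File(run_dir / "snapshots.h5", "w") as fh:
            fh.attrs["lattice_spacing_mm"] = traj.lattice_spacing
            fh.attrs["baseline_lumen_area_mm2"] = traj.baseline_lumen_area
            fh.attrs["original_lumen_area_mm2"] = traj.original_lumen_area
            fh.attrs["restenosis"] = bool(traj.restenosis)
            fh.attrs["closed"] = bool(traj.closed)
            for day, mask in sorted(traj.snapshots.items()):
                fh.create_dataset(f"day_{day:08.3f}", data=mask,
                                  compression="gzip")
        status_path.write_text(json.dumps({"state": "done"}))
        return None
    except Exception as exc:  # noqa: BLE001 - recorded, campaign continues
        status_path.write_text(json.dumps({"state": "failed",
                                           "error": repr(exc)}))
        return f"{run_dir.name}: {exc!r}"


def run_campaign(campaign_dir: str | Path, workers: int = 1) -> CampaignResult:
    """Execute all pending runs (resumable), then collect the results."""
    root = Path(campaign_dir)
    design_path = root / "design.csv"
    if not design_path.exists():
        raise FileNotFoundError(f"no design.csv in {root}; generate first")
    runs = pd.read_csv(design_path)
    if len(runs) == 0:
        raise ValueError("empty campaign design")
    pending = []
    for run_id in runs["run_id"]:
        status = root / "runs" / run_id / "status.json"
        if status.exists() and json.loads(status.read_text()).get("state") == "done":
            continue
        pending.append(root / "runs" / run_id)
    if workers > 1 and len(pending) > 1:
        errors = Parallel(n_jobs=workers)(
            delayed(_execute_one)(rd) for rd in pending)
    else:
        errors = [_execute_one(rd) for rd in pending]
    errors = [e for e in errors if e]
    if errors:
        raise CampaignIncompleteError(
            f"{len(errors)} run(s) failed: " + "; ".join(errors[:5]))
    return load_campaign(root)


def load_campaign(campaign_dir: str | Path) -> CampaignResult:
    """Load a completed campaign; refuses if any run is missing or failed."""
    root = Path(campaign_dir)
    runs = pd.read_csv(root / "design.csv")
    input_names = tuple(c for c in runs.columns
                        if c not in ("run_id", "block", "i", "j", "seed"))
    n = len(input_names)
    m = int(runs["j"].max()) + 1
    design = SaltelliDesign(M=m, n=n, names=input_names, runs=runs)

    missing = []
    for run_id in runs["run_id"]:
        status = root / "runs" / run_id / "status.json"
        if (not status.exists()
                or json.loads(status.read_text()).get("state") != "done"):
            missing.append(str(run_id))
    if missing:
        raise CampaignIncompleteError(
            f"{len(missing)} run(s) incomplete: {missing[:10]}")

    areas, widths, covs, snaps, restens = [], [], [], [], []
    times = None
    spacing = orig_area = None
    for run_id in runs["run_id"]:
        run_dir = root / "runs" / run_id
        frame = pd.read_csv(run_dir / "trajectory.csv")
        if times is None:
            times = frame["time_days"].to_numpy()
        areas.append(frame["neointimal_area_mm2"].to_numpy())
        widths.append(frame["mean_lumen_width_mm"].to_numpy())
        covs.append(frame["coverage"].to_numpy())
        with h5py.File(run_dir / "snapshots.h5", "r") as fh:
            spacing = float(fh.attrs["lattice_spacing_mm"])
            orig_area = float(fh.attrs["original_lumen_area_mm2"])
            restens.append(bool(fh.attrs["restenosis"]))
            last = sorted(fh.keys())[-1]
            snaps.append(fh[last][...])
    return CampaignResult(
        design=design, times=times, area=np.vstack(areas),
        width=np.vstack(widths), coverage=np.vstack(covs),
        restenosis=np.array(restens, dtype=bool),
        final_snapshots=np.stack(snaps).astype(bool),
        lattice_spacing=spacing, original_lumen_area=orig_area)


def evaluate_design(design: SaltelliDesign,
                    model: Callable[[np.ndarray, int], float | np.ndarray]
                    ) -> np.ndarray:
    """Evaluate a cheap model f(x, seed) on every design row (test helper)."""
    outputs = []
    x_cols = list(design.names)
    for row in design.runs.itertuples():
        x = np.array([getattr(row, c) for c in x_cols])
        outputs.append(np.asarray(model(x, int(row.seed)), dtype=float))
    return np.stack(outputs)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def _design_blocks(design: SaltelliDesign, values: np.ndarray
                   ) -> dict[str, np.ndarray]:
    """Split design-row-ordered outputs into per-block (M, ...) arrays."""
    runs = design.runs
    blocks: dict[str, np.ndarray] = {}
    for block in ("A", "A_RESEED"):
        sub = runs[runs["block"] == block].sort_values("j")
        blocks[block] = values[sub.index.to_numpy()]
    for block in ("FO", "TO"):
        for i in range(design.n):
            sub = runs[(runs["block"] == block) & (runs["i"] == i)].sort_values("j")
            blocks[f"{block}{i}"] = values[sub.index.to_numpy()]
    return blocks


def _all_statistics(blocks: dict[str, np.ndarray], n_inputs: int
                    ) -> dict[str, np.ndarray]:
    """Every campaign statistic from one set of (possibly resampled) blocks."""
    pooled = np.concatenate([blocks[k] for k in sorted(blocks)], axis=0)
    mean, var, sd, cv = estimate_moments(pooled)
    al_var, al_sd = aleatory_variance(blocks["A"], blocks["A_RESEED"])
    out = {"mean": mean, "variance": var, "sd": sd, "cv": cv,
           "aleatory_variance": al_var, "aleatory_sd_bound": al_sd}
    for i in range(n_inputs):
        _, s_i = first_order_index(blocks["A"], blocks[f"FO{i}"])
        _, st_i = total_index(blocks["A"], blocks[f"TO{i}"])
        out[f"S_{i}"] = s_i
        out[f"ST_{i}"] = st_i
    return out


def analyze_outputs(design: SaltelliDesign, values: np.ndarray,
                    K: int = 10000, seed: int = 0
                    ) -> dict[str, dict[str, np.ndarray]]:
    """Point estimates plus row-paired bootstrap (mean, sd) of every statistic.

    ``values`` holds one output per design row (row order of ``design.runs``)
    and may be 1D (scalar output) or 2D (output per time point / site).
    """
    blocks = _design_blocks(design, values)
    point = _all_statistics(blocks, design.n)
    names = sorted(point)
    rng = np.random.default_rng(seed)

    def statistic(resampled: dict[str, np.ndarray]) -> np.ndarray:
        stats = _all_statistics(resampled, design.n)
        return np.stack([np.atleast_1d(stats[k]) for k in names])

    boot_mean, boot_sd = bootstrap_estimate(blocks, statistic, K, rng)
    report: dict[str, dict[str, np.ndarray]] = {}
    for pos, name in enumerate(names):
        report[name] = {
            "value": np.atleast_1d(point[name]),
            "bootstrap_mean": boot_mean[pos],
            "bootstrap_sd": boot_sd[pos],
        }
    return report


def analyze_campaign(result: CampaignResult, K: int = 10000, seed: int = 0,
                     out_dir: str | Path | None = None) -> dict:
    """The paper-style campaign analysis over the neointimal-area series.

    Produces, per time point: mean, variance, SD, CV, aleatory variance and
    its Jensen SD bound, first-order and total Sobol indices per input, each
    with bootstrap error bars; plus the final-time area histogram and the
    restenosis probability with a Wilson 95% interval.  Writes
    ``moments.csv``, ``sobol.csv`` and ``summary.json`` when ``out_dir`` is
    given.  Deterministic for fixed inputs and seed.
    """
    report = analyze_outputs(result.design, result.area, K=K, seed=seed)
    names = result.design.names
    times = result.times

    moments = pd.DataFrame({"time_days": times})
    for key in ("mean", "variance", "sd", "cv", "aleatory_variance",
                "aleatory_sd_bound"):
        moments[key] = report[key]["value"]
        moments[key + "_boot_sd"] = report[key]["bootstrap_sd"]
    sobol_rows = []
    for i, name in enumerate(names):
        for t_idx, t in enumerate(times):
            sobol_rows.append({
                "time_days": t, "input": name,
                "S": report[f"S_{i}"]["value"][t_idx],
                "S_boot_sd": report[f"S_{i}"]["bootstrap_sd"][t_idx],
                "ST": report[f"ST_{i}"]["value"][t_idx],
                "ST_boot_sd": report[f"ST_{i}"]["bootstrap_sd"][t_idx],
            })
    sobol = pd.DataFrame(sobol_rows)

    final_area = result.area[:, -1]
    hist, edges = np.histogram(final_area, bins=20)
    n_rest = int(result.restenosis.sum())
    n_runs = len(result.restenosis)
    lo, hi = proportion_confint(n_rest, n_runs, alpha=0.05, method="wilson")
    summary = {
        "n_runs": n_runs,
        "M": result.design.M,
        "inputs": list(names),
        "final_time_days": float(times[-1]),
        "final_mean_area_mm2": float(report["mean"]["value"][-1]),
        "final_sd_area_mm2": float(report["sd"]["value"][-1]),
        "final_cv_percent": float(report["cv"]["value"][-1]),
        "final_aleatory_sd_bound_mm2": float(
            report["aleatory_sd_bound"]["value"][-1]),
        "final_first_order_percent": {
            name: float(report[f"S_{i}"]["value"][-1])
            for i, name in enumerate(names)},
        "final_total_percent": {
            name: float(report[f"ST_{i}"]["value"][-1])
            for i, name in enumerate(names)},
        "restenosis_probability": n_rest / n_runs,
        "restenosis_wilson95": [float(lo), float(hi)],
        "final_area_histogram": {"counts": hist.tolist(),
                                 "edges": edges.tolist()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        moments.to_csv(out / "moments.csv", index=False)
        sobol.to_csv(out / "sobol.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {"moments": moments, "sobol": sobol, "summary": summary,
            "report": report}


# ---------------------------------------------------------------------------
# Spatial products
# ---------------------------------------------------------------------------

def presence_probability(snapshots: np.ndarray,
                         spacing: float = 1.0) -> SpatialField:
    """Per-site fraction of runs in which the site was tissue-covered."""
    snapshots = np.asarray(snapshots)
    if snapshots.ndim != 3:
        raise ValueError("snapshots must be (runs, ny, nx)")
    return SpatialField(data=snapshots.mean(axis=0).astype(float),
                        spacing=spacing, kind="presence_probability")


def spatial_sensitivity_maps(result: CampaignResult,
                             out_path: str | Path | None = None
                             ) -> dict[str, SpatialField]:
    """Sitewise variance, aleatory variance, FOSI and TSI maps.

    Each lattice site's presence indicator is treated as the model output and
    the scalar estimators are applied sitewise; sites whose A-block variance
    is zero (always or never covered) are masked with NaN.
    """
    snaps = result.final_snapshots.astype(float)
    r, ny, nx = snaps.shape
    flat = snaps.reshape(r, ny * nx)
    blocks = _design_blocks(result.design, flat)
    var_tot = blocks["A"].var(axis=0, ddof=1)
    mask = var_tot > 0
    al_var, _ = aleatory_variance(blocks["A"], blocks["A_RESEED"])

    def shape(values: np.ndarray, masked: bool = True) -> np.ndarray:
        arr = np.asarray(values, dtype=float).copy()
        if masked:
            arr[~mask] = np.nan
        return arr.reshape(ny, nx)

    spacing = result.lattice_spacing
    fields = {
        "variance": SpatialField(shape(var_tot, masked=False), spacing, "variance"),
        "aleatory_variance": SpatialField(shape(al_var), spacing,
                                          "aleatory_variance"),
    }
    for i, name in enumerate(result.design.names):
        _, s_i = first_order_index(blocks["A"], blocks[f"FO{i}"])
        _, st_i = total_index(blocks["A"], blocks[f"TO{i}"])
        fields[f"FOSI_{name}"] = SpatialField(shape(s_i), spacing, "FOSI")
        fields[f"TSI_{name}"] = SpatialField(shape(st_i), spacing, "TSI")
    if out_path is not None:
        with h5py.File(out_path, "w") as fh:
            fh.attrs["lattice_spacing_mm"] = spacing
            for key, fieldv in fields.items():
                fh.create_dataset(key, data=fieldv.data, compression="gzip")
    return fields
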