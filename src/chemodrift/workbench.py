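"""Experiment configuration, canonical scenario fixtures, and orchestration.

The configuration file is a small YAML dialect with five optional blocks —
``pathway``, ``motor``, ``environment``, ``phenotypes``, ``simulation`` —
whose keys mirror the parameter records; omitted keys take the standard
constants.  Unknown keys are rejected by name.  Every artifact written by
``run_figure`` embeds the seed and a hash of the fully-resolved config so
runs are reproducible from (config, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analytic, motor, simulate
from .params import Environment, MotorParams, PathwayParams, Phenotype

__all__ = [
    "SimControls",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "FIXTURES",
    "run_figure",
    "compare_runs",
]

_SCALES = {"full": 10000, "desk": 2000, "smoke": 200}


@dataclass(frozen=True)
class SimControls:
    n_cells: int = 10000
    T: float = 300.0
    dt: float = 0.01
    window: tuple[float, float] = (60.0, 300.0)
    seed: int = 0
    sample_every: float = 0.1

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.window[1]:
            raise ValueError("T must cover the measurement window")


@dataclass
class ExperimentConfig:
    pathway: PathwayParams = field(default_factory=PathwayParams)
    motor: MotorParams = field(default_factory=MotorParams)
    environment: Environment = field(default_factory=Environment)
    phenotypes: list[Phenotype] = field(default_factory=list)
    simulation: SimControls = field(default_factory=SimControls)

    def to_dict(self) -> dict:
        d = {
            "pathway": dataclasses.asdict(self.pathway),
            "motor": dataclasses.asdict(self.motor),
            "environment": dataclasses.asdict(self.environment),
            "phenotypes": [{"Y0": p.Y0, "tau": p.tau} for p in self.phenotypes],
            "simulation": dataclasses.asdict(self.simulation),
        }
        d["simulation"]["window"] = list(self.simulation.window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block '{name}'; "
            f"valid keys: {sorted(valid)}")
    if cls is SimControls and "window" in block:
        block = dict(block, window=tuple(block["window"]))
    return cls(**block)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; defaults fill gaps."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"pathway", "motor", "environment", "phenotypes", "simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}; "
                         f"valid blocks: {sorted(known)}")
    pw = _build(PathwayParams, raw.get("pathway", {}), "pathway")
    phenos = []
    for i, p in enumerate(raw.get("phenotypes", [])):
        extra = set(p) - {"Y0", "tau"}
        if extra:
            raise ValueError(f"unknown key(s) {sorted(extra)} in phenotype {i}")
        phenos.append(Phenotype(Y0=float(p["Y0"]), tau=float(p["tau"]),
                                alpha=pw.alpha))
    return ExperimentConfig(
        pathway=pw,
        motor=_build(MotorParams, raw.get("motor", {}), "motor"),
        environment=_build(Environment, raw.get("environment", {}),
                           "environment"),
        phenotypes=phenos,
        simulation=_build(SimControls, raw.get("simulation", {}), "simulation"),
    )


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# canonical scenario fixtures

def _env(g_inv: float, **kw) -> Environment:
    return Environment(g=1.0 / g_inv, **kw)


FIXTURES: dict[str, dict] = {
    # shallow gradient, Y0 sweep for three adaptation times
    "fig2a": {"g_inv": 5000.0, "taus": [5.0, 10.0, 30.0],
              "y0_sweep": (1.0, 4.0)},
    # rotational-diffusion sweep at tau = 10 s
    "fig2c": {"g_inv": 5000.0, "taus": [10.0], "y0_sweep": (1.0, 4.0),
              "Dr": [0.031, 0.062, 0.124]},
    # motor switching-frequency sweep at tau = 10 s
    "fig2d": {"g_inv": 5000.0, "taus": [10.0], "y0_sweep": (1.0, 4.0),
              "omega": [0.65, 1.3, 2.6]},
    # steep gradient, behavioral feedback phenotypes
    "fig3": {"g_inv": 1000.0,
             "phenotypes": [(2.4, 10.0), (2.4, 30.0), (3.0, 10.0),
                            (2.6, 10.0), (3.0, 30.0)]},
    # bistable "trap" phenotypes
    "fig4": {"g_inv": 1000.0,
             "phenotypes": [(2.7, 5.0), (3.5, 30.0), (2.6, 10.0),
                            (3.0, 30.0)]},
    # motor adaptation
    "fig5": {"g_inv": 1000.0, "phenotypes": [(3.5, 30.0)], "motor_adapt": True},
    # phenotype trade-off maps
    "fig6": {"g_invs": [1000.0, 2000.0, 5000.0], "motor_adapt": True},
    # asymmetric methylation kinetics
    "s1": {"g_inv": 5000.0, "VR": [0.1, 0.2, 0.4],
           "phenotypes": [(2.4, 10.0)]},
}


def _sim_summary(phenos, env, mp, pp, n_cells, seed, dt=0.01) -> pd.DataFrame:
    rows = []
    for i, (y0, tau) in enumerate(phenos):
        res = simulate.run_population(
            n_cells, 300.0, Phenotype(Y0=y0, tau=tau), env, mp,
            pp.with_tau(tau), dt=dt, seed=seed + i)
        rows.append(res.summary_row())
    return pd.DataFrame(rows)


def run_figure(name: str, out_dir: str | Path, scale: str = "desk",
               seed: int = 0) -> dict[str, Path]:
    """Execute a canonical scenario and write its summary tables as CSV.

    ``scale`` picks the population size: full (10000 cells), desk (2000) or
    smoke (200, for quick checks).  Returns the paths written.  Every file
    gets a sibling ``<name>_manifest.json`` with seed, scale, config hash
    and wall time.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"available: {sorted(FIXTURES)}")
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; one of {sorted(_SCALES)}")
    n_cells = _SCALES[scale]
    fx = FIXTURES[name]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    pp = PathwayParams()
    mp = MotorParams(adapt=bool(fx.get("motor_adapt", False)))
    written: dict[str, Path] = {}

    def emit(tag: str, df: pd.DataFrame):
        path = out / f"{name}_{tag}.csv"
        df.to_csv(path, index=False)
        written[tag] = path

    if name in ("fig2a", "fig2c", "fig2d"):
        lo, hi = fx["y0_sweep"]
        y0s = np.round(np.arange(lo, hi + 1e-9, 0.25), 4)
        sweep_vals = fx.get("Dr", fx.get("omega", [None]))
        ana_rows, sim_rows = [], []
        for sv in sweep_vals:
            env = _env(fx["g_inv"],
                       **({"Dr": sv} if "Dr" in fx else {}))
            mp_s = MotorParams(omega=sv) if "omega" in fx else mp
            for tau in fx["taus"]:
                vd = analytic.drift_curve(y0s, tau, env, mp_s,
                                          alpha=pp.alpha, N=pp.N)
                for y0, v in zip(y0s, vd):
                    ana_rows.append({"Y0_uM": y0, "tau_s": tau,
                                     "sweep": sv, "V_D_um_per_s": v})
                # simulate only the near-peak portion to keep runs short
                sim_y0 = y0s[(y0s >= 2.0) & (y0s <= 3.0)]
                for j, y0 in enumerate(sim_y0):
                    res = simulate.run_population(
                        n_cells, 300.0, Phenotype(Y0=float(y0), tau=tau),
                        env, mp_s, pp.with_tau(tau), seed=seed + j)
                    sim_rows.append({**res.summary_row(), "sweep": sv})
        emit("analytic", pd.DataFrame(ana_rows))
        emit("sim", pd.DataFrame(sim_rows))

    elif name in ("fig3", "s1"):
        env = _env(fx["g_inv"])
        if name == "s1":
            frames = []
            for vr in fx["VR"]:
                pp_vr = PathwayParams(variant="asymmetric", VR=vr)
                df = _sim_summary(fx["phenotypes"], env, mp, pp_vr,
                                  n_cells, seed)
                df["VR_per_s"] = vr
                frames.append(df)
            emit("sim", pd.concat(frames, ignore_index=True))
        else:
            emit("sim", _sim_summary(fx["phenotypes"], env, mp, pp,
                                     n_cells, seed))

    elif name in ("fig4", "fig5"):
        env = _env(fx["g_inv"])
        adapt = bool(fx.get("motor_adapt", False))
        rows = []
        for y0, tau in fx["phenotypes"]:
            for fp in analytic.fixed_points(Phenotype(Y0=y0, tau=tau), env,
                                            mp, motor_adapt=adapt, N=pp.N):
                rows.append({"Y0_uM": y0, "tau_s": tau, "Y_m_uM": fp.Y_m,
                             "V_D_um_per_s": fp.V_D,
                             "stability": fp.stability})
        emit("fixed_points", pd.DataFrame(rows))
        if name == "fig5":
            ygrid = np.linspace(0.5, 5.5, 201)
            cw_ad, e3, pinned = motor.adapted_cw_curve(ygrid, mp)
            emit("adapted_cw", pd.DataFrame({
                "Y_uM": ygrid, "CW_adapted": cw_ad, "eps3_eff": e3,
                "boundary_pinned": pinned,
                "CW_fixed_ring": motor.cw_bias(ygrid, mp)}))

    elif name == "fig6":
        n_grid = {"full": 50, "desk": 40, "smoke": 10}[scale]
        taus = np.linspace(1.0, 30.0, n_grid)
        tb0s = np.geomspace(0.01, 0.4, n_grid)
        pmap = analytic.phenotype_map(taus, tb0s,
                                      [1.0 / gi for gi in fx["g_invs"]],
                                      mp=MotorParams(adapt=True),
                                      motor_adapt=True, N=pp.N)
        rows = []
        for kg, g in enumerate(pmap.gradients):
            for it, tau in enumerate(pmap.tau_grid):
                for ib, tb in enumerate(pmap.tb0_grid):
                    rows.append({"g_per_um": g, "tau_s": tau, "TB0": tb,
                                 "Y0_uM": pmap.y0_grid[ib],
                                 "V_D_um_per_s": pmap.vd[kg, it, ib],
                                 "relative": pmap.relative[kg, it, ib]})
        emit("map", pd.DataFrame(rows))
        emit("maximin", pd.DataFrame([{
            "tau_s": pmap.maximin_tau, "TB0": pmap.maximin_tb0,
            "min_relative": pmap.maximin_value}]))

    cfg = ExperimentConfig(pathway=pp, motor=mp,
                           simulation=SimControls(n_cells=n_cells, seed=seed))
    manifest = {
        "fixture": name, "scale": scale, "seed": seed,
        "n_cells": n_cells, "config_hash": cfg.config_hash(),
        "wall_time_s": round(time.perf_counter() - t_start, 2),
        "files": {k: str(v) for k, v in written.items()},
    }
    mpath = out / f"{name}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = mpath
    return written


def compare_runs(analytic_table: pd.DataFrame,
                 sim_table: pd.DataFrame,
                 tol_peak: float = 0.15) -> dict:
    """Point-wise and peak concordance between theory and simulation tables.

    Both tables need columns ``Y0_uM``, ``tau_s`` and ``V_D_um_per_s``.
    Returns per-point relative errors, the peak-location difference per tau,
    and a pass flag against ``tol_peak`` at the simulated peak.
    """
    keys = ["tau_s", "Y0_uM"]
    for df, lab in ((analytic_table, "analytic"), (sim_table, "sim")):
        missing = set(keys + ["V_D_um_per_s"]) - set(df.columns)
        if missing:
            raise ValueError(f"{lab} table lacks columns {sorted(missing)}")
    merged = sim_table.merge(analytic_table, on=keys,
                             suffixes=("_sim", "_ana"))
    if merged.empty:
        raise ValueError("tables share no (tau, Y0) grid points")
    merged["rel_err"] = (merged["V_D_um_per_s_sim"]
                         - merged["V_D_um_per_s_ana"]) \
        / merged["V_D_um_per_s_ana"].abs()
    report = {"points": merged, "per_tau": {}}
    ok = True
    for tau, grp in merged.groupby("tau_s"):
        i_sim = grp["V_D_um_per_s_sim"].idxmax()
        i_ana = grp["V_D_um_per_s_ana"].idxmax()
        peak_err = abs(grp.loc[i_sim, "rel_err"])
        report["per_tau"][float(tau)] = {
            "peak_rel_err": float(peak_err),
            "peak_Y0_sim": float(grp.loc[i_sim, "Y0_uM"]),
            "peak_Y0_ana": float(grp.loc[i_ana, "Y0_uM"]),
            "pass": bool(peak_err <= tol_peak),
        }
        ok &= peak_err <= tol_peak
    report["pass"] = bool(ok)
    report["max_abs_rel_err"] = float(merged["rel_err"].abs().max())
    return report
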