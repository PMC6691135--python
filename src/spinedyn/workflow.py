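"""Config-driven scenarios, parameter sweeps and kinetics comparisons.

A scenario config is a nested mapping (YAML/JSON or a plain dict) with the
blocks ``geometry``, ``layout``, ``flux``, ``kinetics``, ``solver`` and
optional ``metrics``/``output``.  External units follow the literature
(D in um^2/s, K_N in um/s); they are converted to the canonical internal
units (um, ms, uM) here, at the boundary of the package.

``run_scenario`` executes one deterministic end-to-end run; ``run_sweep``
executes a geometry grid and collects the lifetime table; and
``compare_kinetics`` pairs a linear and a Michaelis-Menten run on the
identical mesh and time grid.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
import os
import time
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fluxes import FluxModel
from .geometry import BoundaryLayout, GeometryError, build_geometry, mesh_axisymmetric
from .metrics import MetricsSeries, compute_metrics, theoretical_lifetime
from .rd_solver import KineticsSpec, Solution, SolverConfig, solve_axisymmetric

__all__ = [
    "ConfigError",
    "SweepSpec",
    "load_config",
    "validate_config",
    "run_scenario",
    "run_sweep",
    "compare_kinetics",
    "preset",
    "PRESETS",
]

#: reference head size at which the 0.2 um membrane patches are defined;
#: PSD and neck cap diameters scale with R_o / this value by default
_REFERENCE_R_O = 0.25
_REFERENCE_CAP = 0.2


class ConfigError(ValueError):
    """Invalid scenario configuration; message lists every problem found."""


_DEFAULTS = {
    "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.5, "e_i": 0.5, "e_o": 0.5},
    "layout": {
        "influx": "uniform_minus_neck",
        "cap_diameter_um": None,  # None -> 0.2 um scaled by R_o/0.25
        "center_polar_angle_rad": math.pi / 3,
        "phi0_rad": None,
        "neck_diameter_um": None,
    },
    "flux": {
        "gamma_abs": 1.14e-6,
        "alpha_ms": 2.5,
        "beta_ms": 2.0,
        "zeta": 0.2,
        "t_er_ms": 20.0,
        "K_N_um_per_s": 1.0,
    },
    "kinetics": {"kind": "linear", "tau_ms": 50.0, "C_max_ref_uM": 4.0, "K_M_uM": 2.0},
    "solver": {
        "D_um2_per_s": 10.0,
        "dt_ms": 0.05,
        "T_ms": 100.0,
        "n_s": 16,
        "n_phi": 96,
        "output_stride": 1,
    },
    "metrics": {"psi_threshold": 0.25},
    "output": {"dir": None, "save_fields": False},
}


def load_config(source) -> dict:
    """Load a config from a dict, a YAML/JSON path, or a YAML string."""
    if isinstance(source, dict):
        raw = copy.deepcopy(source)
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raise ConfigError(f"cannot interpret config source {source!r}")
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")
    cfg = copy.deepcopy(_DEFAULTS)
    for section, values in raw.items():
        if section not in cfg:
            raise ConfigError(
                f"unknown config section {section!r}; expected one of {sorted(cfg)}"
            )
        if values is None:
            continue
        for key, val in values.items():
            if key not in cfg[section]:
                raise ConfigError(
                    f"unknown key {section}.{key}; expected one of {sorted(cfg[section])}"
                )
            cfg[section][key] = val
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Return the full list of validation problems (empty = valid)."""
    errors = []
    g = cfg["geometry"]
    try:
        build_geometry(g["family"], g["R_o_um"], g.get("rho", 0.0), g["e_i"], g["e_o"])
    except (GeometryError, ValueError) as exc:
        errors.append(f"geometry: {exc}")
    try:
        _make_layout(cfg)
    except (GeometryError, ValueError) as exc:
        errors.append(f"layout: {exc}")
    try:
        _make_flux(cfg)
    except ValueError as exc:
        errors.append(f"flux: {exc}")
    try:
        _make_kinetics(cfg)
    except ValueError as exc:
        errors.append(f"kinetics: {exc}")
    try:
        _make_solver(cfg)
    except ValueError as exc:
        errors.append(f"solver: {exc}")
    th = cfg["metrics"]["psi_threshold"]
    if not (0.0 < th < 1.0):
        errors.append(f"metrics: psi_threshold must be in (0,1), got {th}")
    return errors


def _scaled_cap(value, R_o: float) -> float:
    if value is None:
        return _REFERENCE_CAP * (R_o / _REFERENCE_R_O)
    return float(value)


def _make_layout(cfg: dict) -> BoundaryLayout:
    lay = cfg["layout"]
    R_o = cfg["geometry"]["R_o_um"]
    return BoundaryLayout(
        influx=lay["influx"],
        cap_diameter=_scaled_cap(lay["cap_diameter_um"], R_o),
        center_polar_angle=lay["center_polar_angle_rad"],
        phi0=lay["phi0_rad"],
        neck_diameter=_scaled_cap(lay["neck_diameter_um"], R_o),
    )


def _make_flux(cfg: dict) -> FluxModel:
    f = cfg["flux"]
    return FluxModel(
        gamma_abs=f["gamma_abs"],
        alpha=f["alpha_ms"],
        beta=f["beta_ms"],
        zeta=f["zeta"],
        t_ER=f["t_er_ms"],
        K_N=f["K_N_um_per_s"] / 1000.0,
    )


def _make_kinetics(cfg: dict) -> KineticsSpec:
    k = cfg["kinetics"]
    if k["kind"] == "linear":
        return KineticsSpec("linear", tau=k["tau_ms"])
    return KineticsSpec.michaelis_menten(k["C_max_ref_uM"], k["tau_ms"], k["K_M_uM"])


def _make_solver(cfg: dict) -> SolverConfig:
    s = cfg["solver"]
    return SolverConfig(
        D=s["D_um2_per_s"] / 1000.0,
        dt=s["dt_ms"],
        T=s["T_ms"],
        n_s=s["n_s"],
        n_phi=s["n_phi"],
        output_stride=s["output_stride"],
    )


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def run_scenario(config, out_dir: Optional[str] = None):
    """Execute one scenario end-to-end; returns (Solution, MetricsSeries).

    Writes a metrics CSV, a summary JSON and a manifest (config echo +
    hash + version + timing) when an output directory is given either in
    the config or via ``out_dir``.
    """
    cfg = load_config(config)
    problems = validate_config(cfg)
    if problems:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(problems))

    t0 = time.perf_counter()
    g = cfg["geometry"]
    geom = build_geometry(g["family"], g["R_o_um"], g.get("rho", 0.0), g["e_i"], g["e_o"])
    layout = _make_layout(cfg)
    mesh = mesh_axisymmetric(geom, layout, n_s=cfg["solver"]["n_s"], n_phi=cfg["solver"]["n_phi"])
    sol = solve_axisymmetric(mesh, _make_flux(cfg), _make_kinetics(cfg), _make_solver(cfg))
    series = compute_metrics(sol, psi_th=cfg["metrics"]["psi_threshold"])
    elapsed = time.perf_counter() - t0

    out_dir = out_dir or cfg["output"]["dir"]
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        series.to_frame().to_csv(os.path.join(out_dir, "metrics.csv"), index=False)
        summary = series.summary()
        summary["mass_residual_max"] = float(np.max(sol.mass_residual))
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest = {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "version": __version__,
            "runtime_s": elapsed,
            "n_nodes": int(len(mesh.nodes)),
            "n_tris": int(len(mesh.tris)),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        if cfg["output"]["save_fields"]:
            from ._vtk import write_vtk

            np.savez_compressed(
                os.path.join(out_dir, "solution.npz"),
                times=sol.times,
                C=sol.C,
                node_weights=sol.node_weights,
                cell_volumes=sol.cell_volumes,
                grad_mag_cells=sol.grad_magnitude_cells(),
                nodes=mesh.nodes,
                tris=mesh.tris,
            )
            stride = max(1, len(sol.times) // 20)
            for i in range(0, len(sol.times), stride):
                write_vtk(
                    os.path.join(out_dir, f"field_{i:05d}.vtk"),
                    mesh.nodes,
                    mesh.tris,
                    {"C_uM": sol.C[i]},
                )
    return sol, series


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

#: documented valid ranges for sweep grids
_SWEEP_RANGES = {"rho": (0.02, 0.9), "e_o": (0.1, 0.9), "e_i": (0.0, 1.0)}


@dataclass
class SweepSpec:
    """A geometry sweep: a base scenario config plus per-axis value grids.

    ``grids`` may contain ``rho``, ``e_o``, ``e_i``, ``R_o_um`` and
    ``D_um2_per_s``.  Combinations violating the shell-nesting invariant
    are recorded with an error code rather than aborting the sweep.
    """

    base: dict
    grids: dict = dc_field(default_factory=dict)
    out_dir: Optional[str] = None

    def __post_init__(self):
        self.base = load_config(self.base)
        for axis, values in self.grids.items():
            if axis in _SWEEP_RANGES:
                lo, hi = _SWEEP_RANGES[axis]
                bad = [v for v in values if not (lo <= v <= hi)]
                if bad:
                    raise ConfigError(
                        f"sweep axis {axis}: values {bad} outside the valid "
                        f"range [{lo}, {hi}]"
                    )

    @property
    def run_count(self) -> int:
        n = 1
        for values in self.grids.values():
            n *= len(values)
        return n


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run every grid combination; one row per combination.

    Rows carry tau_psi, tau_theory, the peak mean gradient, concentration
    extrema, the worst mass-balance residual and an error code ("ok",
    "invalid_geometry", "not_reached", or "error").  When ``out_dir`` is
    set, completed combinations are cached as JSON rows keyed by config
    hash and skipped on resume.
    """
    axes = list(spec.grids.keys())
    mesh_grids = np.meshgrid(*[spec.grids[a] for a in axes], indexing="ij")
    combos = (
        [dict(zip(axes, vals)) for vals in zip(*[g.ravel() for g in mesh_grids])]
        if axes
        else [{}]
    )
    cache_dir = None
    if spec.out_dir:
        cache_dir = os.path.join(spec.out_dir, "rows")
        os.makedirs(cache_dir, exist_ok=True)

    rows = []
    for combo in combos:
        cfg = copy.deepcopy(spec.base)
        for axis, val in combo.items():
            if axis in ("rho", "e_o", "e_i"):
                cfg["geometry"][axis] = float(val)
            elif axis == "R_o_um":
                cfg["geometry"]["R_o_um"] = float(val)
            elif axis == "D_um2_per_s":
                cfg["solver"]["D_um2_per_s"] = float(val)
            else:
                raise ConfigError(f"unknown sweep axis {axis!r}")
        row = {k: float(v) for k, v in combo.items()}
        h = config_hash(cfg)
        row["config_hash"] = h
        cache_path = os.path.join(cache_dir, f"{h}.json") if cache_dir else None
        if cache_path and os.path.exists(cache_path):
            with open(cache_path) as fh:
                rows.append(json.load(fh))
            continue

        problems = validate_config(cfg)
        if problems:
            row.update(
                tau_psi_ms=np.nan,
                tau_theory_ms=np.nan,
                grad_peak=np.nan,
                C_max=np.nan,
                C_min=np.nan,
                mass_residual_max=np.nan,
                error="invalid_geometry",
            )
        else:
            try:
                sol, series = run_scenario(cfg)
                gcfg = cfg["geometry"]
                row.update(
                    tau_psi_ms=float(series.tau_psi),
                    tau_theory_ms=theoretical_lifetime(
                        gcfg["rho"], gcfg["e_o"], gcfg["R_o_um"],
                        cfg["solver"]["D_um2_per_s"] / 1000.0,
                    ),
                    grad_peak=float(np.max(series.grad_mean)),
                    C_max=float(np.max(series.C_max)),
                    C_min=float(np.min(series.C_min)),
                    mass_residual_max=float(np.max(sol.mass_residual)),
                    error="ok" if series.reached else "not_reached",
                )
            except Exception as exc:  # recorded, sweep continues
                row.update(
                    tau_psi_ms=np.nan,
                    tau_theory_ms=np.nan,
                    grad_peak=np.nan,
                    C_max=np.nan,
                    C_min=np.nan,
                    mass_residual_max=np.nan,
                    error=f"error: {exc}",
                )
        if cache_path:
            with open(cache_path, "w") as fh:
                json.dump(row, fh, default=float)
        rows.append(row)

    table = pd.DataFrame(rows)
    if spec.out_dir:
        table.to_csv(os.path.join(spec.out_dir, "sweep.csv"), index=False)
    return table


def compare_kinetics(config) -> dict:
    """Paired linear vs Michaelis-Menten runs on the identical mesh/grid.

    Returns both metrics series, the max-|C| locations, and the maximum
    relative divergence of the C_mean trajectories split at 10 ms.
    """
    cfg = load_config(config)
    cfg_lin = copy.deepcopy(cfg)
    cfg_lin["kinetics"]["kind"] = "linear"
    cfg_mm = copy.deepcopy(cfg)
    cfg_mm["kinetics"]["kind"] = "michaelis_menten"

    sol_lin, met_lin = run_scenario(cfg_lin)
    sol_mm, met_mm = run_scenario(cfg_mm)

    t = sol_lin.times
    scale = float(np.max(np.abs(met_lin.C_mean))) or 1.0
    dev = np.abs(met_lin.C_mean - met_mm.C_mean) / scale
    early = t <= 10.0
    frame_peak = int(np.argmax(met_lin.C_max))
    return {
        "linear": met_lin,
        "michaelis_menten": met_mm,
        "solution_linear": sol_lin,
        "solution_mm": sol_mm,
        "max_rel_divergence_early": float(dev[early].max()),
        "max_rel_divergence_late": float(dev[~early].max()) if (~early).any() else 0.0,
        "argmax_location_linear": sol_lin.max_location(frame_peak),
        "argmax_location_mm": sol_mm.max_location(frame_peak),
        "argmin_location_linear": sol_lin.min_location(frame_peak),
        "argmin_location_mm": sol_mm.min_location(frame_peak),
    }


# ---------------------------------------------------------------------------
# named presets for the canonical scenarios
# ---------------------------------------------------------------------------

PRESETS = {
    # uniformly driven spherical shell, fast diffusion, no outlet — the
    # baseline pulse whose midpoint trace shows the canonical rise/decay
    "sphere_uniform_baseline": {
        "geometry": {"family": "sphere_shell", "R_o_um": 0.25, "rho": 0.5},
        "layout": {"influx": "uniform"},
        "solver": {"D_um2_per_s": 100.0},
    },
    # small spine apparatus, crowded cytosol: long-lived radial gradient
    "sphere_small_sa_slow_diffusion": {
        "geometry": {"family": "sphere_shell", "R_o_um": 0.25, "rho": 0.1},
        "layout": {"influx": "uniform"},
        "solver": {"D_um2_per_s": 1.0},
    },
    # large spine apparatus in a near-spherical head, uniform influx + neck
    "big_sa_round_head": {
        "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.9, "e_i": 0.5, "e_o": 0.9},
        "layout": {"influx": "uniform_minus_neck"},
    },
    # flattened head with a nearly absent spine apparatus
    "flat_head_tiny_sa": {
        "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.02, "e_i": 0.5, "e_o": 0.1},
        "layout": {"influx": "uniform_minus_neck"},
    },
    # PSD-like influx confined to the top pole
    "pole_influx": {
        "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.9, "e_i": 0.1, "e_o": 0.8},
        "layout": {"influx": "pole_cap"},
    },
    # influx on the side of the head, near the neck
    "side_influx": {
        "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.9, "e_i": 0.1, "e_o": 0.8},
        "layout": {"influx": "side_leaf"},
    },
    # mushroom-shaped head with pole influx
    "mushroom_pole_influx": {
        "geometry": {"family": "mushroom", "R_o_um": 0.25, "rho": 0.6, "e_i": 0.1, "e_o": 0.5},
        "layout": {"influx": "pole_cap"},
    },
    # amplitude raised so peak concentrations reach the uM range where the
    # Michaelis-Menten saturation is actually exercised
    "kinetics_comparison_pole": {
        "geometry": {"family": "oblate_shell", "R_o_um": 0.25, "rho": 0.9, "e_i": 0.1, "e_o": 0.8},
        "layout": {"influx": "pole_cap"},
        "flux": {"gamma_abs": 10.0},
        "kinetics": {"kind": "linear", "tau_ms": 50.0, "C_max_ref_uM": 4.0, "K_M_uM": 2.0},
    },
}


def preset(name: str) -> dict:
    """A deep copy of a named scenario config, ready to edit."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return load_config(PRESETS[name])
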