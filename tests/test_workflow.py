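import copy
import json
import math

import numpy as np
import pandas as pd
import pytest

import spinedyn as sd
from spinedyn.workflow import (
    ConfigError,
    SweepSpec,
    compare_kinetics,
    load_config,
    preset,
    run_scenario,
    run_sweep,
    validate_config,
)


def small(cfg, T=30.0):
    """Shrink a scenario config for fast test runs."""
    cfg = copy.deepcopy(cfg)
    cfg["solver"].update(n_s=10, n_phi=48, T_ms=T, dt_ms=0.1)
    return cfg


class TestConfig:
    def test_unknown_section_and_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown config section"):
            load_config({"geom": {}})
        with pytest.raises(ConfigError, match="unknown key"):
            load_config({"geometry": {"radius": 1}})

    def test_invalid_family_lists_allowed_values(self):
        cfg = load_config({"geometry": {"family": "torus"}})
        problems = validate_config(cfg)
        assert any("sphere_shell" in p for p in problems)

    def test_all_errors_reported_at_once(self):
        cfg = load_config(
            {"geometry": {"family": "torus"}, "flux": {"alpha_ms": -1.0},
             "metrics": {"psi_threshold": 2.0}}
        )
        problems = validate_config(cfg)
        assert len(problems) >= 3

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("geometry:\n  family: sphere_shell\n  rho: 0.5\n")
        cfg = load_config(str(p))
        assert cfg["geometry"]["family"] == "sphere_shell"

    def test_cap_diameters_scale_with_head_size(self):
        from spinedyn.workflow import _make_layout

        cfg = load_config({"geometry": {"R_o_um": 0.6}})
        lay = _make_layout(cfg)
        assert lay.cap_diameter == pytest.approx(0.2 * 0.6 / 0.25)
        cfg = load_config({"geometry": {"R_o_um": 0.6},
                           "layout": {"cap_diameter_um": 0.2}})
        assert _make_layout(cfg).cap_diameter == 0.2


class TestRunScenario:
    def test_baseline_midpoint_pulse_shape(self):
        # uniformly driven sphere, fast diffusion: the midpoint trace rises,
        # peaks within ~10 ms and decays
        cfg = small(preset("sphere_uniform_baseline"), T=60.0)
        sol, met = run_scenario(cfg)
        geom = sol.geom
        rstar = (geom.R_o - geom.R_i) / 2 + geom.R_i
        d = np.linalg.norm(sol.mesh.nodes - [rstar, 0.0], axis=1)
        trace = sol.C[:, int(np.argmin(d))]
        i_peak = int(np.argmax(trace))
        assert 0 < sol.times[i_peak] < 15.0
        assert trace[-1] < 0.8 * trace[i_peak]

    def test_radial_gradient_stronger_when_diffusion_slow(self):
        # small spine apparatus: strong early radial gradient only in the
        # crowded regime
        grads = {}
        for D in (1.0, 100.0):
            geom = sd.build_geometry("sphere_shell", 0.25, 0.1)
            sol = sd.solve_radial_shell(
                geom, sd.FluxModel(), sd.KineticsSpec("linear", tau=50.0),
                sd.SolverConfig(D=D / 1000, dt=0.05, T=2.0, n_r=150),
            )
            i1 = int(np.argmin(np.abs(sol.times - 1.0)))
            grads[D] = sd.grad_norm_mean(sol, i1)
        assert grads[1.0] > 5 * grads[100.0]

    def test_invalid_config_raises_before_solving(self):
        cfg = preset("big_sa_round_head")
        cfg["geometry"]["rho"] = 1.5
        with pytest.raises(ConfigError):
            run_scenario(cfg)

    def test_outputs_and_manifest(self, tmp_path):
        cfg = small(preset("flat_head_tiny_sa"), T=10.0)
        run_scenario(cfg, out_dir=str(tmp_path))
        table = pd.read_csv(tmp_path / "metrics.csv")
        assert {"t_ms", "psi"} <= set(table.columns)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["config"]["geometry"]["rho"] == 0.02
        assert len(manifest["config_hash"]) == 16

    def test_determinism_bitwise(self):
        cfg = small(preset("pole_influx"), T=40.0)
        _, m1 = run_scenario(cfg)
        _, m2 = run_scenario(cfg)
        assert np.array_equal(m1.grad_mean, m2.grad_mean)
        assert m1.tau_psi == m2.tau_psi


class TestSweep:
    def test_degenerate_sweep_matches_scenario(self):
        base = small(preset("big_sa_round_head"), T=40.0)
        table = run_sweep(SweepSpec(base=base, grids={"rho": [0.9]}))
        assert len(table) == 1
        _, met = run_scenario(base)
        assert table.tau_psi_ms.iloc[0] == pytest.approx(met.tau_psi, rel=1e-12)

    def test_invalid_combo_recorded_not_fatal(self):
        base = small(preset("big_sa_round_head"), T=10.0)
        table = run_sweep(
            SweepSpec(base=base, grids={"rho": [0.5, 0.9], "e_o": [0.1]})
        )
        # e_i=0.5: rho=0.5 -> b_i=0.0625 > b_o=0.025 both invalid here
        assert set(table.error) == {"invalid_geometry"}
        assert len(table) == 2

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ConfigError, match="valid"):
            SweepSpec(base=preset("big_sa_round_head"), grids={"rho": [0.95]})

    def test_resume_uses_cached_rows(self, tmp_path):
        base = small(preset("flat_head_tiny_sa"), T=10.0)
        spec = SweepSpec(base=base, grids={"e_o": [0.1, 0.2]}, out_dir=str(tmp_path))
        t1 = run_sweep(spec)
        import time

        t0 = time.perf_counter()
        t2 = run_sweep(spec)
        assert time.perf_counter() - t0 < 0.5  # cached, no re-solve
        pd.testing.assert_frame_equal(t1, t2)


class TestCompareKinetics:
    def test_short_time_agreement_long_time_divergence(self):
        cfg = small(preset("kinetics_comparison_pole"), T=60.0)
        res = compare_kinetics(cfg)
        assert res["max_rel_divergence_early"] < 0.02
        assert res["max_rel_divergence_late"] > 5 * res["max_rel_divergence_early"]
        assert np.allclose(
            res["argmax_location_linear"], res["argmax_location_mm"]
        )
        lin, mm = res["linear"], res["michaelis_menten"]
        assert mm.tau_psi == pytest.approx(lin.tau_psi, rel=0.05)


class TestCLI:
    def test_eigen_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from spinedyn.cli import main

        out = tmp_path / "eig.json"
        res = CliRunner().invoke(
            main, ["eigen", "--rho", "0.5", "--n", "4", "--json", str(out)]
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert len(payload["roots_dimensionless"]) == 4
        assert payload["roots_dimensionless"][0] == pytest.approx(6.572, abs=1e-3)

    def test_simulate_preset(self):
        from click.testing import CliRunner

        from spinedyn.cli import main

        res = CliRunner().invoke(main, ["simulate", "--preset", "flat_head_tiny_sa"])
        assert res.exit_code == 0, res.output
        assert "tau_psi_ms" in res.output

    def test_metrics_roundtrip_from_saved_fields(self, tmp_path):
        from click.testing import CliRunner

        from spinedyn.cli import main

        cfg = small(preset("big_sa_round_head"), T=40.0)
        cfg["output"]["save_fields"] = True
        sol, met = run_scenario(cfg, out_dir=str(tmp_path))
        out_csv = tmp_path / "recomputed.csv"
        res = CliRunner().invoke(
            main,
            ["metrics", "--fields", str(tmp_path / "solution.npz"),
             "--out", str(out_csv)],
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["tau_psi_ms"] == pytest.approx(met.tau_psi, rel=1e-12)
        table = pd.read_csv(out_csv)
        assert np.allclose(table.psi.max(), 1.0)
        # VTK field snapshots written alongside
        assert list(tmp_path.glob("field_*.vtk"))
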