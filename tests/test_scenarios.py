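"""Synthetic fixtures, end-to-end scenario runs, sweeps and the CLI."""

import hashlib
import json

import numpy as np
import pytest

import lignosim as ls
from lignosim.scenarios import ScenarioConfig


class TestSyntheticSubstrates:
    def test_deterministic_per_seed_and_archetype(self):
        a = ls.generate_synthetic_substrate(seed=7, archetype="mild")
        b = ls.generate_synthetic_substrate(seed=7, archetype="mild")
        np.testing.assert_array_equal(a.psd.volumes_cm3_per_g, b.psd.volumes_cm3_per_g)
        assert a.digestibility == b.digestibility
        c = ls.generate_synthetic_substrate(seed=8, archetype="mild")
        assert not np.array_equal(a.psd.volumes_cm3_per_g, c.psd.volumes_cm3_per_g)

    @pytest.mark.parametrize("seed", [0, 1, 5, 42])
    def test_severe_archetype_constraints(self, seed):
        """Severe pretreatment fixtures must stay physically feasible with a
        site density in the span reported for acid-pretreated substrates."""
        spec = ls.generate_synthetic_substrate(seed=seed, archetype="severe")
        der = ls.derive_substrate(spec)
        assert der.eps_f <= 1.0
        assert 0.12 <= der.site_density / spec.f_cell * 1e6 <= 1.5

    @pytest.mark.parametrize("seed", [0, 1, 5])
    def test_pretreatment_ordering(self, seed):
        native = ls.derive_substrate(ls.generate_synthetic_substrate(seed, "native"))
        severe = ls.derive_substrate(ls.generate_synthetic_substrate(seed, "severe"))
        assert severe.eps_0 > native.eps_0
        assert severe.site_density > native.site_density

    def test_ds2_beech_scale(self):
        spec = ls.generate_synthetic_substrate(seed=1, archetype="ds2_beech")
        assert spec.radius_cm == pytest.approx(0.02)  # 400 um diameter sieve cut
        der = ls.derive_substrate(spec)
        assert der.s_spec / 1e4 == pytest.approx(24.0, rel=0.2)  # ~24 m^2/g


class TestRunScenario:
    def test_no_enzyme_writes_zero_yield(self, tmp_path):
        cfg = ScenarioConfig(
            substrate="severe", e_l=[0.0], b_l=[0.02], n=12,
            times_min=[30.0, 60.0], output_dir=tmp_path, seed=1, label="zero",
        )
        result, traj, manifest = ls.run_scenario(cfg)
        assert result.yield_fraction.max() == 0.0
        frame = (tmp_path / "zero_results.csv").read_text()
        assert "yield_fraction" in frame
        assert json.loads((tmp_path / "zero_manifest.json").read_text())[
            "diagnostics"
        ]["conservation_drift"] < 0.02

    def test_rerun_is_bitwise_reproducible(self, tmp_path):
        def run(subdir):
            cfg = ScenarioConfig(
                substrate="severe", e_l=[1.0], b_l=[0.02], n=12,
                times_min=[30.0], output_dir=tmp_path / subdir, seed=1, label="rep",
            )
            ls.run_scenario(cfg)
            return {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted((tmp_path / subdir).iterdir())
            }

        assert run("a") == run("b")

    def test_multi_point_axes_rejected(self):
        cfg = ScenarioConfig(substrate="severe", e_l=[0.5, 1.0], seed=1)
        with pytest.raises(ValueError):
            ls.run_scenario(cfg)

    def test_config_yaml_roundtrip(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text(
            "substrate: severe\nseed: 1\ne_l: [1.0]\nb_l: [0.02]\nn: 12\n"
            "times_min: [30.0]\nlabel: fromyaml\n"
        )
        cfg = ScenarioConfig.from_yaml(tmp_path / "cfg.yaml")
        result, _, manifest = ls.run_scenario(cfg)
        assert manifest["label"] == "fromyaml"
        assert result.yield_fraction[-1] > 0

    def test_empty_axes_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(substrate="severe", e_l=[])


class TestSweep:
    def test_degenerate_sweep_matches_run_scenario(self, tmp_path):
        cfg = ScenarioConfig(
            substrate="severe", e_l=[1.0], b_l=[0.02], n=12,
            times_min=[30.0], seed=1,
        )
        result, _, _ = ls.run_scenario(cfg)
        df = ls.sweep(cfg)
        row = df[(df.time_min == 30.0) & (df.status == "ok")]
        assert row["yield_fraction"].iloc[0] == pytest.approx(
            result.yield_fraction[-1], rel=1e-12
        )

    def test_yield_non_increasing_in_radius(self):
        cfg = ScenarioConfig(
            substrate="severe", e_l=[1.0], b_l=[0.02], n=14,
            radius_cm=[10e-4, 100e-4, 0.1], times_min=[60.0], seed=1,
        )
        df = ls.sweep(cfg)
        ok = df[(df.time_min == 60.0) & (df.status == "ok")].sort_values("radius_cm")
        assert len(ok) == 3
        assert np.all(np.diff(ok["yield_fraction"].to_numpy()) <= 1e-12)

    def test_yield_non_decreasing_in_enzyme_loading(self):
        cfg = ScenarioConfig(
            substrate="severe", e_l=[0.25, 0.5, 1.0, 2.0], b_l=[0.02], n=12,
            times_min=[30.0], seed=1,
        )
        df = ls.sweep(cfg)
        ok = df[(df.time_min == 30.0) & (df.status == "ok")].sort_values("e_l")
        assert np.all(np.diff(ok["yield_fraction"].to_numpy()) >= -1e-12)

    def test_excess_enzyme_pays_off_only_for_large_particles(self):
        """Raising e_l from 1 to 2 buys little for a small, reaction-limited
        particle but clearly helps a large, diffusion-limited one."""
        cfg = ScenarioConfig(
            substrate="severe", e_l=[1.0, 2.0], b_l=[0.02], n=14,
            radius_cm=[12.5e-4, 0.08], times_min=[60.0], seed=1,
        )
        df = ls.sweep(cfg)
        ok = df[(df.time_min == 60.0) & (df.status == "ok")]

        def gain(r):
            sub = ok[np.isclose(ok.radius_cm, r)].sort_values("e_l")
            y = sub["yield_fraction"].to_numpy()
            return y[1] - y[0]

        assert gain(0.08) > gain(12.5e-4)

    def test_failures_recorded_not_raised(self):
        cfg = ScenarioConfig(
            substrate="severe", e_l=[1.0], b_l=[0.02, 50.0], n=12,
            times_min=[30.0], seed=1,
        )
        df = ls.sweep(cfg)  # b_l = 50 g/cm^3 is infeasible
        assert (df.status == "ok").any()
        assert df.status.str.startswith("error").any()


class TestCLI:
    def test_fixture_simulate_audit_roundtrip(self, tmp_path, monkeypatch):
        from click.testing import CliRunner
        from lignosim.cli import main

        monkeypatch.chdir(tmp_path)
        runner = CliRunner()
        out = runner.invoke(main, ["fixture", "--archetype", "severe", "--seed", "1",
                                   "--out", "sub.yaml"])
        assert out.exit_code == 0, out.output
        out = runner.invoke(
            main,
            ["simulate", "--substrate", "sub.yaml", "--e-l", "1.0", "--b-l", "0.02",
             "--n", "12", "--t-end", "60", "--out", "run", "--label", "demo"],
        )
        assert out.exit_code == 0, out.output
        assert (tmp_path / "run" / "demo_results.csv").exists()
        out = runner.invoke(
            main,
            ["audit", "--substrate", "sub.yaml", "--n", "12", "--t-end", "60"],
        )
        assert out.exit_code == 0, out.output
        assert "drift" in out.output
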