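"""Study drivers: baseline comparison, sweeps, variants, CLI plumbing."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from minicoag.calibrate import GAConfig
from minicoag.cli import main as cli_main
from minicoag.experiments import (
    ExperimentConfig,
    run_reference_case,
    run_species_sweep,
    run_tf_sweep,
    run_variant_optimizations,
)


@pytest.fixture(scope="module")
def short_cfg():
    """625 s horizon, adaptive reference: fast but fully quantitative."""
    return ExperimentConfig(t_end=625.0, reference_fidelity=False)


class TestReferenceCase:
    def test_baseline_report_structure(self):
        cfg = ExperimentConfig(t_end=5000.0)
        report = run_reference_case(cfg)
        ids = [m.model_id for m in report.metrics]
        assert ids == ["reference", "minimal_default", "minimal_optimal"]
        default = report.metric("minimal_default")
        optimal = report.metric("minimal_optimal")
        assert default.sssd_full > optimal.sssd_full
        # calibration cut the error by well over an order of magnitude
        assert default.sssd_full / optimal.sssd_full > 10.0

    def test_artifacts_written(self, tmp_path):
        cfg = ExperimentConfig(t_end=625.0, outdir=tmp_path)
        report = run_reference_case(cfg)
        from pathlib import Path

        assert report.artifacts, "expected artifact paths in the report"
        for path in report.artifacts.values():
            assert Path(path).exists()
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert "config_hash" in manifest and "versions" in manifest


class TestSpeciesSweep:
    def test_at_sweep_scenario_concentrations(self, short_cfg):
        reports = run_species_sweep("AT", (0.25, 0.5, 2.0, 4.0), short_cfg)
        assert [r.scenario for r in reports] == ["ATx0.25", "ATx0.5", "ATx2", "ATx4"]
        for r in reports:
            assert all(m.stable for m in r.metrics)
            assert r.metric("minimal_optimal").sssd_window is not None

    def test_pt_sweep_flags_reference_instability_only(self):
        """Under the fixed-step study protocol the reference diverges for
        increased prothrombin; the minimal models never do."""
        cfg = ExperimentConfig(t_end=625.0, reference_fidelity=True)
        reports = run_species_sweep("PT", (0.25, 4.0), cfg)
        low, high = reports
        assert low.metric("reference").stable
        ref4 = high.metric("reference")
        assert not ref4.stable
        assert ref4.failure_time is not None
        assert ref4.sssd_window is None  # no metrics for the unstable run
        assert high.metric("minimal_default").stable
        assert high.metric("minimal_optimal").stable

    def test_identity_factor_reproduces_baseline_bitwise(self, short_cfg):
        base = run_reference_case(short_cfg)
        (one,) = run_species_sweep("X", (1.0,), short_cfg)
        for model_id in ("minimal_default", "minimal_optimal"):
            assert one.metric(model_id).sssd_window == base.metric(model_id).sssd_window
            assert one.metric(model_id).peak_value == base.metric(model_id).peak_value

    def test_unknown_species_rejected(self, short_cfg):
        with pytest.raises(ValueError):
            run_species_sweep("TFPI", (2.0,), short_cfg)


class TestTfSweep:
    def test_default_tf_value_reproduces_baseline(self, short_cfg):
        base = run_reference_case(short_cfg)
        (rep,) = run_tf_sweep([2.5e-8], short_cfg)
        for model_id in ("minimal_default", "minimal_optimal"):
            assert rep.metric(model_id).sssd_window == base.metric(model_id).sssd_window

    def test_default_model_weakly_sensitive_to_tf(self):
        """The literature-parameter model's thrombin curve barely responds
        to the TF level (its peak value shifts by ~2%), while the calibrated
        model's curves move visibly with TF.  Sensitivity is measured as the
        maximum pointwise spread across TF conditions relative to the
        model's peak — peak TIME is ill-conditioned for the default model's
        broad flat maximum."""
        import numpy as np

        from minicoag.models import (
            DEFAULT_PARAMETERS, OPTIMAL_PARAMETERS, Scenario, apply_scenario,
            minimal_model,
        )
        from minicoag.simulate import SimulationProtocol, simulate

        prot = SimulationProtocol(t_end=5000.0)
        spreads = {}
        peak_ranges = {}
        for label, params in (("default", DEFAULT_PARAMETERS),
                              ("optimal", OPTIMAL_PARAMETERS)):
            curves = []
            for tf in (1.0e-9, 5.0e-9, 1.0e-8, 2.0e-8):
                net = apply_scenario(minimal_model(params), Scenario(tf_initial=tf))
                curves.append(simulate(net, prot).series("TH"))
            curves = np.array(curves)
            spreads[label] = np.max(curves.max(0) - curves.min(0)) / curves.max()
            peak_ranges[label] = (curves.max(1).max() - curves.max(1).min()) / curves.max()
        assert spreads["default"] < spreads["optimal"]
        assert peak_ranges["default"] < 0.05  # "only the peak values vary slightly"


class TestVariantOptimizations:
    def test_variant_table_covers_requested_variants(self, tmp_path):
        cfg = ExperimentConfig(t_end=625.0, outdir=tmp_path, seed=0)
        ga = GAConfig(population_size=6, generations=3, seed=0)
        table = run_variant_optimizations(("vii_sink", "at_sink"), None, cfg, ga)
        assert list(table.index) == ["vii_sink", "at_sink"]
        assert (table["best_sssd"] > 0).all()
        assert (tmp_path / "variant_comparison.csv").exists()

    def test_single_tf_condition_averaged_equals_plain(self):
        """With one TF condition the averaged objective degenerates to the
        plain objective, so the same seed yields the same optimum."""
        cfg = ExperimentConfig(t_end=625.0, seed=4)
        ga = GAConfig(population_size=6, generations=3, seed=4)
        plain = run_variant_optimizations(("none",), None, cfg, ga)
        averaged = run_variant_optimizations(("none",), [2.5e-8], cfg, ga)
        assert plain.loc["none", "best_sssd"] == pytest.approx(
            averaged.loc["none", "best_sssd"], rel=1e-12)

    def test_empty_variant_list_rejected(self):
        with pytest.raises(ValueError):
            run_variant_optimizations((), None)


class TestCli:
    def test_simulate_verb_writes_csv(self, tmp_path):
        out = tmp_path / "traj.csv"
        result = CliRunner().invoke(
            cli_main, ["simulate", "--model", "minimal-optimal",
                       "--t-end", "125", "--out", str(out)])
        assert result.exit_code == 0, result.output
        assert out.exists()
        header = out.read_text().splitlines()[0]
        assert header.startswith("time_s,")

    def test_compare_verb_reports_sssd(self, tmp_path):
        result = CliRunner().invoke(
            cli_main, ["compare", "--outdir", str(tmp_path), "--t-end", "625"])
        assert result.exit_code == 0, result.output
        assert "SSSD" in result.output
        assert (tmp_path / "manifest.json").exists()
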