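"""Registry ingestion, per-trial audits, survey summaries, CLI."""

import json

import pytest
from click.testing import CliRunner

from cpaudit import (
    DesignSpec,
    DomainError,
    FutureHypothesis,
    InterimState,
    RegistryConfig,
    RegistryFormatError,
    TrialRecord,
    audit_table,
    audit_trial,
    bin_cp,
    conditional_power,
    generate_registry,
    read_trial_table,
    records_from_frame,
    summarize_survey,
    write_registry,
)
from cpaudit.cli import main as cli_main

WELL_FORMED_CSV = """trial_id,alpha,sidedness,planned_power,design_effect,design_effect_scale,outcome_kind,estimate,se,z_value,info_fraction,sponsor,reported_cp,p_value,p_is_bound
A1,0.05,two,0.8,0.3,natural,binary,0.08,0.1,0.8,0.5,industry,,,
A2,0.025,one,0.9,0.25,natural,continuous,0.05,0.125,0.4,0.4,non_industry,,,
A3,0.05,two,0.8,0.3,natural,binary,,,,,non_industry,0.54,0.2,true
"""


@pytest.fixture
def fixture_path(tmp_path):
    path = tmp_path / "registry.csv"
    path.write_text(WELL_FORMED_CSV)
    return path


class TestReadTrialTable:
    def test_well_formed_rows_load_cleanly(self, fixture_path):
        records = read_trial_table(fixture_path)
        assert len(records) == 3
        assert all(not r.issues for r in records)
        assert records[0].alpha == 0.05
        assert records[2].reported_cp == 0.54
        assert records[2].p_is_bound is True

    def test_domain_violation_collected_not_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("trial_id,alpha,sidedness\nB1,1.5,two\n")
        records = read_trial_table(path)
        assert len(records) == 1
        assert any("alpha" in issue for issue in records[0].issues)
        assert records[0].alpha is None

    def test_duplicate_trial_id_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("trial_id,alpha\nC1,0.05\nC1,0.05\n")
        with pytest.raises(RegistryFormatError, match="duplicate"):
            read_trial_table(path)

    def test_missing_trial_id_is_hard_error(self, tmp_path):
        path = tmp_path / "noid.csv"
        path.write_text("trial_id,alpha\n,0.05\n")
        with pytest.raises(RegistryFormatError, match="missing trial_id"):
            read_trial_table(path)

    def test_unknown_columns_preserved_as_extra(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text("trial_id,alpha,clinical_area\nD1,0.05,oncology\n")
        (record,) = read_trial_table(path)
        assert record.extra == {"clinical_area": "oncology"}

    def test_percent_info_fraction_autodetected(self, tmp_path):
        path = tmp_path / "pct.csv"
        path.write_text("trial_id,info_fraction\nE1,55\n")
        (record,) = read_trial_table(path)
        assert record.info_fraction == pytest.approx(0.55)


def _computable_record(**overrides):
    base = dict(
        trial_id="T1", alpha=0.05, sidedness="two", planned_power=0.8,
        design_effect=0.3, design_effect_scale="natural", z_value=0.8,
        estimate=0.08, se=0.1, info_fraction=0.5,
    )
    base.update(overrides)
    return TrialRecord(**base)


class TestAuditTrial:
    def test_delegates_to_cp_engine(self):
        record = _computable_record()
        audit = audit_trial(record)
        design = DesignSpec(alpha=0.05, sidedness="two", planned_power=0.8,
                            design_effect=0.3)
        interim = InterimState(look_index=1, z_value=0.8, info_fraction=0.5,
                               estimate=0.08, se=0.1)
        assert audit.status == "computed"
        assert audit.cp_current_trend == pytest.approx(
            conditional_power(interim, design, FutureHypothesis("current_trend")).cp
        )
        assert audit.cp_design == pytest.approx(
            conditional_power(interim, design, FutureHypothesis("design")).cp
        )
        assert audit.futile_at_threshold is (audit.cp_current_trend < 0.15)

    def test_p_bound_only_is_insufficient(self):
        record = TrialRecord(trial_id="T2", alpha=0.05, sidedness="two",
                             planned_power=0.8, design_effect=0.3,
                             p_value=0.001, p_is_bound=True, info_fraction=0.5)
        audit = audit_trial(record)
        assert audit.status == "insufficient"
        assert "bound" in audit.failure_reason

    def test_reported_cp_retained_verbatim(self):
        record = TrialRecord(trial_id="T3", reported_cp=0.54)
        audit = audit_trial(record)
        assert audit.status == "reported_only"
        assert audit.reported_cp == 0.54
        assert audit.cp_current_trend is None

    def test_exact_p_value_enables_computation(self):
        record = TrialRecord(trial_id="T4", alpha=0.05, sidedness="two",
                             planned_power=0.8, design_effect=0.3,
                             p_value=0.4, p_is_bound=False, info_fraction=0.5)
        audit = audit_trial(record)
        # z reconstructable but no estimate => design CP only
        assert audit.status == "computed"
        assert audit.cp_design is not None
        assert audit.cp_current_trend is None

    def test_arm_level_summaries_used_as_last_resort(self):
        record = TrialRecord(trial_id="T5", alpha=0.05, sidedness="two",
                             planned_power=0.8, design_effect=0.1,
                             outcome_kind="binary", measure="risk_difference",
                             events_treat=30, n_treat=100, events_ctrl=20,
                             n_ctrl=100, info_fraction=0.5)
        audit = audit_trial(record)
        assert audit.status == "computed"
        assert audit.cp_current_trend is not None
        assert any("per-arm" in a for a in audit.assumptions)

    def test_missing_sidedness_defaults_with_assumption(self):
        record = _computable_record(sidedness=None)
        audit = audit_trial(record)
        assert audit.status == "computed"
        assert any("sidedness" in a for a in audit.assumptions)

    def test_log_ratio_design_effect_converted(self):
        record = _computable_record(design_effect=0.65,
                                    design_effect_scale="log_ratio")
        audit = audit_trial(record)
        assert audit.status == "computed"
        assert any("ratio" in a for a in audit.assumptions)

    def test_beyond_full_information_surfaces_as_flag(self):
        # info fraction resolved from sample sizes exceeds 1
        record = _computable_record(info_fraction=None, interim_n=210,
                                    planned_total_n=200)
        audit = audit_trial(record)
        assert audit.status == "insufficient"
        assert "full information" in audit.failure_reason

    def test_stripped_record_never_computes(self):
        record = TrialRecord(trial_id="T6", alpha=0.05, sidedness="two",
                             planned_power=0.8, design_effect=0.3)
        audit = audit_trial(record)
        assert audit.status == "insufficient"

    def test_parse_issue_excludes_from_computation(self):
        record = _computable_record(issues=("alpha: alpha out of domain (0, 0.5]",))
        audit = audit_trial(record)
        assert audit.status == "insufficient"
        assert "alpha" in audit.failure_reason


class TestBinCp:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.05, 0.20, 0.40, 0.60], (1, 1, 1, 1)),
            ([0.15], (0, 1, 0, 0)),
            ([], (0, 0, 0, 0)),
            ([0.0, 1.0, 0.5, 0.30, 0.2999], (1, 1, 1, 2)),
        ],
    )
    def test_binning(self, values, expected):
        assert bin_cp(values) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bin_cp([1.2])


class TestSummarizeSurvey:
    def test_two_trial_summary(self):
        records = [_computable_record(trial_id="X1", z_value=-1.0, estimate=-0.1),
                   _computable_record(trial_id="X2", z_value=2.2, estimate=0.22)]
        audits = audit_table(records)
        summary = summarize_survey(audits, records)
        assert summary.n_trials == 2
        assert summary.status_counts == {"computed": 2}
        assert sum(summary.bins_current_trend) == 2

    def test_reported_only_binned_under_current_trend(self):
        records = [TrialRecord(trial_id="R1", reported_cp=0.10, sponsor="industry")]
        audits = audit_table(records)
        summary = summarize_survey(audits, records)
        assert summary.bins_current_trend == (1, 0, 0, 0)
        assert summary.bins_by_sponsor["industry"] == (1, 0, 0, 0)
        assert sum(summary.bins_design) == 0

    def test_key_mismatch_rejected(self):
        records = [_computable_record(trial_id="Y1")]
        audits = audit_table([_computable_record(trial_id="Z9")])
        with pytest.raises(DomainError, match="orphan"):
            summarize_survey(audits, records)

    def test_conservation_on_generated_registry(self, tmp_path):
        frame = generate_registry(RegistryConfig(seed=11))
        path = tmp_path / "reg.csv"
        write_registry(frame, path)
        records = read_trial_table(path)
        audits = audit_table(records)
        summary = summarize_survey(audits, records)
        assert sum(summary.status_counts.values()) == 52
        n_current = sum(1 for a in audits if a.cp_current_trend is not None)
        n_reported_only = summary.status_counts.get("reported_only", 0)
        assert sum(summary.bins_current_trend) == n_current + n_reported_only

    def test_no_missingness_means_all_computed(self, tmp_path):
        config = RegistryConfig(seed=13, insufficient_fraction=0.0,
                                reported_only_fraction=0.0)
        frame = generate_registry(config)
        path = tmp_path / "full.csv"
        write_registry(frame, path)
        audits = audit_table(read_trial_table(path))
        assert all(a.status == "computed" for a in audits)


class TestCli:
    def test_compute_cp_planned_power_limit(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "compute-cp", "--z", "0", "--t", "1e-12", "--alpha", "0.025",
            "--sidedness", "one", "--design-effect", "0.3", "--power", "0.9",
            "--hypothesis", "design",
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["cp"] == pytest.approx(0.90, abs=1e-6)
        assert payload["sidedness"] == "one"

    def test_audit_fixture(self, fixture_path, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "audits.csv"
        result = runner.invoke(cli_main, [
            "audit", str(fixture_path), "--out-audits", str(out_csv),
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["n_trials"] == 3
        assert sum(payload["status_counts"].values()) == 3
        assert out_csv.exists()

    def test_generate_registry_deterministic(self, tmp_path):
        runner = CliRunner()
        paths = [tmp_path / "r1.csv", tmp_path / "r2.csv"]
        for path in paths:
            result = runner.invoke(cli_main, [
                "generate-registry", "--n", "52", "--seed", "1",
                "--out", str(path),
            ])
            assert result.exit_code == 0, result.output
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_simulate_from_yaml(self, tmp_path):
        config = tmp_path / "sim.yaml"
        config.write_text(
            "theta_true: 0.15\n"
            "design:\n  alpha: 0.025\n  sidedness: one\n"
            "  planned_power: 0.9\n  design_effect: 0.3\n"
            "look_fractions: [0.5]\nthreshold: 0.15\nn_sim: 200\n"
        )
        runner = CliRunner()
        out = tmp_path / "records.csv"
        result = runner.invoke(cli_main, [
            "simulate", "--config", str(config), "--seed", "2", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["overall"]["n"] == 200
        assert out.exists()

    def test_bad_flags_nonzero_exit(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["compute-cp", "--z", "1"])
        assert result.exit_code != 0
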