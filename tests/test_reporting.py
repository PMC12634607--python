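"""Demographic summaries, pipeline driver, CLI."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

import pvsignal as pv
from pvsignal.cli import main as cli_main
from pvsignal.reporting import age_in_years


class TestAgeNormalization:
    @pytest.mark.parametrize("value,code,years", [
        ("64", "YR", 64.0),
        ("6", "DEC", 60.0),
        ("18", "MON", 1.5),
        ("730", "DY", pytest.approx(2.0, abs=0.01)),
        ("", "YR", None),
        ("64", "??", None),     # unknown unit -> missing
        ("abc", "YR", None),
    ])
    def test_units(self, value, code, years):
        assert age_in_years(value, code) == years


class TestDemographicSummary:
    def _cohort(self, rows):
        cols = pv.io.DEMO_COLUMNS
        frame = pd.DataFrame([{c: "" for c in cols} | r for r in rows],
                             dtype=str)
        return frame

    def test_singleton_male(self):
        summary = pv.demographic_summary(self._cohort([{"sex": "M"}]))
        sex = summary[summary["characteristic"] == "Sex"].set_index("category")
        assert sex.loc["Male", "count"] == 1
        assert sex.loc["Male", "pct"] == 100.00
        assert (sex.drop("Male")["count"] == 0).all()

    @pytest.mark.parametrize("age,band", [
        ("17", "<18"), ("18", "18–30"), ("30", "18–30"), ("31", "31–50"),
        ("50", "31–50"), ("51", "51–65"), ("65", "51–65"), ("66", ">65"),
    ])
    def test_age_band_edges(self, age, band):
        summary = pv.demographic_summary(
            self._cohort([{"age": age, "age_cod": "YR"}]))
        rows = summary[(summary["characteristic"] == "Age") &
                       (summary["count"] == 1)]
        assert list(rows["category"]) == [band]

    def test_unknown_sex_distinct_from_missing(self):
        summary = pv.demographic_summary(
            self._cohort([{"sex": "UNK"}, {"sex": ""}]))
        sex = summary[summary["characteristic"] == "Sex"].set_index("category")
        assert sex.loc["Unknown", "count"] == 1
        assert sex.loc["Missing", "count"] == 1

    def test_weight_bands_and_lbs_conversion(self):
        summary = pv.demographic_summary(self._cohort([
            {"wt": "50", "wt_cod": "KG"},
            {"wt": "220", "wt_cod": "LBS"},   # ~99.8 kg
            {"wt": "101", "wt_cod": "KG"},
        ]))
        wt = summary[summary["characteristic"] == "Weight"].set_index("category")
        assert wt.loc["≤50 kg", "count"] == 1
        assert wt.loc[">50–≤100 kg", "count"] == 1
        assert wt.loc[">100 kg", "count"] == 1

    def test_unnamed_countries_pool_as_others(self):
        summary = pv.demographic_summary(self._cohort([
            {"reporter_country": "UNITED STATES"},
            {"reporter_country": "FRANCE"},
            {"reporter_country": "JAPAN"},
        ]))
        country = summary[summary["characteristic"] == "Reporter Country"] \
            .set_index("category")
        assert country.loc["United States", "count"] == 1
        assert country.loc["Others", "count"] == 2

    def test_counts_sum_to_cohort_and_pct_recomputes(self, small_bundle,
                                                     small_background):
        kept, _, _ = pv.deduplicate(small_bundle.demo)
        events = small_background.loc[small_background["event"], "primaryid"]
        cohort = kept[kept["primaryid"].isin(events)]
        summary = pv.demographic_summary(cohort)
        total = len(cohort)
        for _, group in summary.groupby("characteristic"):
            assert group["count"].sum() == total
        for _, row in summary.iterrows():
            assert row["pct"] == pv.percentage(row["count"], total, 2)


class TestRunPipeline:
    def _config(self, bundle, atc_map, **extra):
        return {"bundle_objects": [bundle], "atc_map_object": atc_map, **extra}

    def test_determinism_byte_identical_outputs(self, tmp_path, small_config,
                                                small_bundle):
        atc_map = pv.default_atc_map(small_config)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        pv.run_pipeline(self._config(small_bundle, atc_map), out_a)
        pv.run_pipeline(self._config(small_bundle, atc_map), out_b)
        names = sorted(p.name for p in out_a.iterdir())
        assert names == sorted(p.name for p in out_b.iterdir())
        for name in names:
            assert (out_a / name).read_bytes() == (out_b / name).read_bytes()

    def test_manifest_counts_monotone(self, tmp_path, small_config,
                                      small_bundle):
        manifest = pv.run_pipeline(
            self._config(small_bundle, pv.default_atc_map(small_config)),
            tmp_path / "out")
        stages = manifest["stages"]
        raw = stages["ingest"]["rows"]["demo"]
        kept = stages["dedup"]["kept"]
        background = stages["cohort"]["background_reports"]
        cohort = stages["cohort"]["event_reports"]
        assert raw >= kept >= background >= cohort

    def test_zero_event_bundle_is_valid(self, tmp_path, small_config,
                                        small_bundle):
        manifest = pv.run_pipeline(
            self._config(small_bundle, pv.default_atc_map(small_config),
                         event_pt="No Such Term"), tmp_path / "out")
        assert manifest["stages"]["cohort"]["event_reports"] == 0
        signals = pd.read_csv(tmp_path / "out" / "signals_drug.tsv", sep="\t")
        assert (signals["frequency"] == 0).all()
        assert not signals["signal"].any()

    @staticmethod
    def _signal_frame(config):
        bundle = pv.generate_bundle(config)
        kept, _, _ = pv.deduplicate(bundle.demo)
        background, _ = pv.build_background(kept, bundle.drug)
        background = pv.add_event_flag(background, bundle.reac)
        return pv.drug_signal_frame(background, top_n=1000)

    PLANTED = {"OFATUMUMAB", "GLECAPREVIR\\PIBRENTASVIR", "ABALOPARATIDE"}

    def test_planted_signals_all_flagged_in_default_run(self):
        """The study-default run flags every planted association."""
        frame = self._signal_frame(pv.default_config(n_cases=50_000))
        flagged = set(frame.loc[frame["signal"], "drug"])
        assert self.PLANTED <= flagged

    def test_null_drugs_flagged_near_nominal_rate(self):
        """Null flag rate over 20 replicates stays near the nominal level.

        The joint rule (both lower bounds > 1) has one-sided nominal level
        2.5% per null drug; the observed rate must stay below that level
        plus three binomial standard errors.
        """
        n_null_flagged = n_null = 0
        for seed in range(20):
            frame = self._signal_frame(
                pv.default_config(n_cases=50_000, seed=100 + seed))
            flagged = set(frame.loc[frame["signal"], "drug"])
            nulls = set(frame["drug"]) - self.PLANTED
            n_null += len(nulls)
            n_null_flagged += len(nulls & flagged)
        p = 0.025
        bound = p + 3 * (p * (1 - p) / n_null) ** 0.5
        assert n_null_flagged / n_null <= bound


class TestCli:
    def test_stats_calculator(self):
        result = CliRunner().invoke(cli_main,
                                    ["stats", "--table", "20,80,100,900"])
        assert result.exit_code == 0
        assert "ROR 2.25 (95% CI 1.322–3.829)" in result.output
        assert "PRR 2.0 (95% CI 1.296–3.086)" in result.output
        assert "signal: yes" in result.output

    def test_stats_zero_cell(self):
        result = CliRunner().invoke(cli_main, ["stats", "--table", "0,5,5,5"])
        assert result.exit_code == 0
        assert "ROR undefined" in result.output

    def test_synth_then_run_end_to_end(self, tmp_path):
        runner = CliRunner()
        bundle_dir = tmp_path / "bundle"
        result = runner.invoke(cli_main, ["synth", "--n-cases", "2000",
                                          "--seed", "5", "--out",
                                          str(bundle_dir)])
        assert result.exit_code == 0, result.output

        atc_path = tmp_path / "atc.tsv"
        config = pv.default_config()
        atc_path.write_text("".join(f"{k}\t{v}\n" for k, v in
                                    pv.default_atc_map(config).items()))
        cfg_path = tmp_path / "run.toml"
        cfg_path.write_text(f'bundles = ["{bundle_dir}"]\n')
        out = tmp_path / "out"
        result = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                          "--out", str(out),
                                          "--atc-map", str(atc_path)])
        assert result.exit_code == 0, result.output
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["stages"]["dedup"]["kept"] == 2000
        for name in ("signals_drug.tsv", "signals_atc.tsv", "tto_drug.tsv",
                     "tto_atc.tsv", "demographics.tsv", "dedup_audit.tsv"):
            assert (out / name).exists()

    def test_run_missing_map_fails_before_compute(self, tmp_path):
        cfg_path = tmp_path / "run.toml"
        cfg_path.write_text('bundles = ["/nonexistent"]\natc_map = "/missing.tsv"\n')
        result = CliRunner().invoke(cli_main, ["run", "--config", str(cfg_path),
                                               "--out", str(tmp_path / "o")])
        assert result.exit_code != 0
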