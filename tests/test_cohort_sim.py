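"""Synthetic cohort generator: determinism, planted signals, validation."""

import json

import numpy as np
import pandas as pd
import pytest

from natscreen import cohort_sim
from natscreen.cohort_sim import (
    ConfigError,
    SimConfig,
    null_config,
    simulate_cohort,
    strong_config,
    write_cohort,
)


def _file_bytes(directory):
    return {p.name: p.read_bytes() for p in sorted(directory.iterdir())}


class TestDeterminism:
    def test_same_seed_identical_in_memory(self):
        a = simulate_cohort(strong_config(7))
        b = simulate_cohort(strong_config(7))
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.methylation, b.methylation)
        pd.testing.assert_frame_equal(a.mutations, b.mutations)
        pd.testing.assert_frame_equal(a.gene_effect, b.gene_effect)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        assert a.truth == b.truth

    def test_same_seed_byte_identical_on_disk(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(strong_config(7)), d1)
        write_cohort(simulate_cohort(strong_config(7)), d2)
        assert _file_bytes(d1) == _file_bytes(d2)

    def test_different_seeds_differ(self):
        a = simulate_cohort(null_config(1))
        b = simulate_cohort(null_config(2))
        assert not a.expression.equals(b.expression)


class TestPlantedSignals:
    def test_hotspot_contributes_exact_count(self):
        cfg = SimConfig(seed=3, planted_hotspot=[("G0009", 1, "C", 5)])
        cohort = simulate_cohort(cfg)
        hits = cohort.mutations[
            (cohort.mutations["gene"] == "G0009")
            & (cohort.mutations["protein_pos"] == 1)
            & (cohort.mutations["alt_aa"] == "C")
        ]
        assert len(hits) == 5
        assert (hits["consequence"] == "missense").all()

    def test_truncating_hotspot_star_alt(self):
        cfg = SimConfig(seed=3, planted_hotspot=[("G0004", 7, "*", 5)])
        cohort = simulate_cohort(cfg)
        hits = cohort.mutations[
            (cohort.mutations["gene"] == "G0004")
            & (cohort.mutations["protein_pos"] == 7)
            & (cohort.mutations["alt_aa"] == "*")
        ]
        assert len(hits) == 5
        assert (hits["consequence"] == "nonsense").all()

    def test_planted_de_shifts_mean(self):
        # Average over several seeds: the planted group mean shift matches
        # the configured log2 effect in expectation.
        shifts = []
        for seed in range(5):
            cfg = SimConfig(seed=seed, planted_de=[("G0001", "T01", 1.0)])
            cohort = simulate_cohort(cfg)
            s = cohort.samples
            t_ids = s[(s["tumour_type"] == "T01") & (s["tumour_or_normal"] == "tumour")]["sample"]
            n_ids = s[(s["tumour_type"] == "T01") & (s["tumour_or_normal"] == "normal")]["sample"]
            shifts.append(
                cohort.expression.loc["G0001", t_ids].mean()
                - cohort.expression.loc["G0001", n_ids].mean()
            )
        assert abs(np.mean(shifts) - 1.0) < 0.25

    def test_planted_meth_anticorrelated(self):
        cfg = SimConfig(seed=5, planted_meth=[("G0002", "T01", -0.6, -0.2)])
        cohort = simulate_cohort(cfg)
        probe = cohort.truth["planted_meth"][0]["probe_id"]
        s = cohort.samples
        t_ids = s[(s["tumour_type"] == "T01") & (s["tumour_or_normal"] == "tumour")]["sample"]
        beta = cohort.methylation.loc[probe, t_ids].to_numpy()
        expr = cohort.expression.loc["G0002", t_ids].to_numpy()
        r = np.corrcoef(beta, expr)[0, 1]
        assert r < -0.3  # population target -0.6 with sampling noise at n=30

    def test_planted_amp_carriers_and_boost(self):
        cfg = SimConfig(seed=5, planted_amp=[("G0003", "T01", 0.2, 1.0)])
        cohort = simulate_cohort(cfg)
        amp = cohort.cnv[(cohort.cnv["gene"] == "G0003") & (cohort.cnv["call"] == 2)]
        assert len(amp) == round(0.2 * cfg.n_tumour_samples_per_type)

    def test_compensation_couples_expression_to_effect(self):
        cfg = SimConfig(seed=5, planted_compensation=[("G0006", "G0007", 0.6)])
        cohort = simulate_cohort(cfg)
        r = np.corrcoef(
            cohort.cell_line_expression.loc["G0007"],
            cohort.gene_effect.loc["G0006"],
        )[0, 1]
        assert r > 0.7

    def test_truth_records_every_planted_signal(self):
        cfg = strong_config(1)
        truth = simulate_cohort(cfg).truth
        assert len(truth["planted_de"]) == len(cfg.planted_de)
        assert len(truth["planted_meth"]) == len(cfg.planted_meth)
        assert len(truth["planted_amp"]) == len(cfg.planted_amp)
        assert len(truth["planted_hotspot"]) == len(cfg.planted_hotspot)
        assert len(truth["planted_essential"]) == len(cfg.planted_essential)
        assert len(truth["planted_compensation"]) == len(cfg.planted_compensation)
        assert len(truth["planted_survival"]) == len(cfg.planted_survival)


class TestStructure:
    def test_beta_values_in_unit_interval(self, strong_cohort):
        values = strong_cohort.methylation.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_all_matrix_samples_in_metadata(self, strong_cohort):
        known = set(strong_cohort.samples["sample"])
        assert set(strong_cohort.expression.columns) <= known
        assert set(strong_cohort.methylation.columns) <= known
        assert set(strong_cohort.mutations["sample"]) <= known
        assert set(strong_cohort.survival["sample"]) <= known

    def test_survival_times_positive_events_binary(self, strong_cohort):
        assert (strong_cohort.survival["time"] > 0).all()
        assert set(strong_cohort.survival["event"]) <= {0, 1}

    def test_tumour_type_count_in_metadata(self):
        cohort = simulate_cohort(SimConfig(seed=1, n_tumour_types=2))
        assert cohort.samples["tumour_type"].nunique() == 2


class TestValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_genes", 0),
            ("n_tumour_types", -1),
            ("n_cell_lines", 0),
            ("censoring_rate", 1.5),
            ("expr_sd", 0.0),
        ],
    )
    def test_invalid_scalar_named(self, field, value):
        cfg = SimConfig(seed=1)
        setattr(cfg, field, value)
        with pytest.raises(ConfigError, match=field):
            simulate_cohort(cfg)

    def test_unknown_planted_gene_named(self):
        cfg = SimConfig(seed=1, planted_de=[("NOPE", "T01", 1.0)])
        with pytest.raises(ConfigError, match="planted_de"):
            simulate_cohort(cfg)

    def test_target_r_out_of_range(self):
        cfg = SimConfig(seed=1, planted_meth=[("G0001", "T01", 0.5, 0.2)])
        with pytest.raises(ConfigError, match="target_r"):
            simulate_cohort(cfg)

    def test_amp_frequency_out_of_range(self):
        cfg = SimConfig(seed=1, planted_amp=[("G0001", "T01", 1.2, 1.0)])
        with pytest.raises(ConfigError, match="frequency"):
            simulate_cohort(cfg)


class TestWriteCohort:
    def test_manifest_and_files(self, tmp_path, strong_cohort):
        manifest = write_cohort(strong_cohort, tmp_path)
        for name in (
            "expression.tsv", "methylation.tsv", "probes.tsv", "mutations.tsv",
            "cnv.tsv", "gene_effect.tsv", "cell_line_expression.tsv",
            "survival.tsv", "samples.tsv", "genes.tsv", "truth.json",
        ):
            assert name in manifest
            assert (tmp_path / name).exists()

    def test_empty_mutation_table_header_only(self, tmp_path):
        cfg = SimConfig(seed=1, mut_rate_per_residue=0.0)
        cohort = simulate_cohort(cfg)
        assert cohort.mutations.empty
        write_cohort(cohort, tmp_path)
        lines = (tmp_path / "mutations.tsv").read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "sample"

    def test_truth_json_round_trips(self, tmp_path, strong_cohort):
        write_cohort(strong_cohort, tmp_path)
        loaded = json.loads((tmp_path / "truth.json").read_text())
        assert loaded == strong_cohort.truth
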