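"""Mutation/CNV burden, recurrence, positional profile, amplification test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from natscreen import cohort_sim
from natscreen.genomic_screen import (
    alteration_frequencies,
    amplification_expression_association,
    normalised_burden,
    positional_mutation_profile,
    recurrent_mutations,
)


def _mut(sample, gene, pos=10, ref="A", alt="V", consequence="missense", ttype="T01"):
    return dict(sample=sample, gene=gene, protein_pos=pos, ref_aa=ref, alt_aa=alt,
                consequence=consequence, tumour_type=ttype)


def _samples(n, ttype="T01", kind="tumour"):
    return pd.DataFrame({
        "sample": [f"{ttype}-{kind[0].upper()}{i:04d}" for i in range(n)],
        "tissue": ttype,
        "tumour_or_normal": kind,
        "tumour_type": ttype,
    })


EMPTY_CNV = pd.DataFrame(columns=["sample", "gene", "call"])


class TestAlterationFrequencies:
    def test_three_of_sixty_flagged_at_boundary(self):
        samples = _samples(60)
        muts = pd.DataFrame([_mut(samples["sample"][i], "GENE") for i in range(3)])
        out = alteration_frequencies(muts, EMPTY_CNV, samples, freq_threshold=0.05)
        row = out[(out["gene"] == "GENE") & (out["tumour_type"] == "T01")
                  & (out["alteration_class"] == "mutation")].iloc[0]
        assert row["frequency"] == pytest.approx(0.05)
        assert row["flagged"]

    def test_sample_with_two_mutations_counted_once(self):
        samples = _samples(10)
        sid = samples["sample"][0]
        muts = pd.DataFrame([_mut(sid, "GENE", pos=5), _mut(sid, "GENE", pos=9)])
        out = alteration_frequencies(muts, EMPTY_CNV, samples)
        row = out[(out["tumour_type"] == "T01")
                  & (out["alteration_class"] == "mutation")].iloc[0]
        assert row["n_altered"] == 1
        assert row["frequency"] == pytest.approx(0.1)

    def test_denominator_is_profiled_samples(self):
        samples = _samples(100)
        muts = pd.DataFrame([_mut(samples["sample"][i], "GENE") for i in range(4)])
        out = alteration_frequencies(muts, EMPTY_CNV, samples)
        assert (out["frequency"] <= 1).all()
        assert (out["n_profiled"] == 100).all()

    def test_unknown_sample_error_lists_ids(self):
        samples = _samples(5)
        muts = pd.DataFrame([_mut("GHOST", "GENE")])
        with pytest.raises(ValueError, match="GHOST"):
            alteration_frequencies(muts, EMPTY_CNV, samples)

    def test_planted_amplification_flagged(self, strong_cohort):
        out = alteration_frequencies(
            strong_cohort.mutations, strong_cohort.cnv, strong_cohort.samples
        )
        planted = strong_cohort.truth["planted_amp"][0]
        row = out[
            (out["gene"] == planted["gene"])
            & (out["tumour_type"] == planted["tumour_type"])
            & (out["alteration_class"] == "amplification")
        ]
        assert len(row) == 1 and bool(row.iloc[0]["flagged"])


class TestNormalisedBurden:
    GENES = pd.DataFrame({
        "symbol": ["GA", "REF"],
        "role": ["catalytic", "catalytic"],
        "orf_length_aa": [500, 250],
        "nterm_seq": ["MSLKLKQWER", "MDLKLKQWER"],
    })

    def test_equal_per_residue_rates_normalise_to_one(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "GA") for i in range(10)]
            + [_mut(f"s{i}", "REF") for i in range(5)]
        )
        out = normalised_burden(muts, self.GENES, "REF").set_index("gene")
        assert out.loc["GA", "normalised_missense"] == pytest.approx(1.0)
        assert out.loc["REF", "normalised_missense"] == pytest.approx(1.0)

    def test_doubling_orf_length_halves_value(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "GA") for i in range(10)]
            + [_mut(f"s{i}", "REF") for i in range(5)]
        )
        doubled = self.GENES.copy()
        doubled.loc[doubled["symbol"] == "GA", "orf_length_aa"] = 1000
        base = normalised_burden(muts, self.GENES, "REF").set_index("gene")
        out = normalised_burden(muts, doubled, "REF").set_index("gene")
        assert out.loc["GA", "normalised_missense"] == pytest.approx(
            base.loc["GA", "normalised_missense"] / 2
        )

    def test_reference_zero_count_undefined_not_zero(self):
        muts = pd.DataFrame([_mut("s1", "GA", consequence="nonsense", alt="*")])
        out = normalised_burden(muts, self.GENES, "REF").set_index("gene")
        assert np.isnan(out.loc["GA", "normalised_truncating"])
        assert np.isnan(out.loc["GA", "normalised_missense"])

    def test_classes_normalised_independently(self):
        muts = pd.DataFrame([
            _mut("s1", "GA", consequence="missense"),
            _mut("s2", "GA", consequence="nonsense", alt="*"),
            _mut("s3", "REF", consequence="missense"),
            _mut("s4", "REF", consequence="frameshift", alt="-"),
        ])
        out = normalised_burden(muts, self.GENES, "REF").set_index("gene")
        # GA: 1/500 vs REF 1/250 in each class -> 0.5 in both, independently.
        assert out.loc["GA", "normalised_missense"] == pytest.approx(0.5)
        assert out.loc["GA", "normalised_truncating"] == pytest.approx(0.5)

    def test_invariant_to_sample_relabelling(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "GA") for i in range(6)]
            + [_mut("x", "REF"), _mut("y", "REF")]
        )
        relabelled = muts.copy()
        relabelled["sample"] = "only-one-sample"
        a = normalised_burden(muts, self.GENES, "REF")
        b = normalised_burden(relabelled, self.GENES, "REF")
        pd.testing.assert_frame_equal(a, b)

    def test_hotspot_gene_tops_truncating_ranking(self, strong_cohort):
        planted = strong_cohort.truth["planted_hotspot"][0]
        out = normalised_burden(
            strong_cohort.mutations, strong_cohort.genes, planted["gene"]
        )
        top = out.sort_values("normalised_truncating", ascending=False).iloc[0]
        assert top["gene"] == planted["gene"]


class TestRecurrentMutations:
    def test_planted_hotspot_returned(self):
        muts = pd.DataFrame([_mut(f"s{i}", "GX", pos=1, ref="M", alt="C")
                             for i in range(5)])
        out = recurrent_mutations(muts, min_count=3)
        assert len(out) == 1
        assert out.iloc[0]["count"] == 5

    def test_below_threshold_excluded(self):
        muts = pd.DataFrame([_mut(f"s{i}", "GX", pos=1) for i in range(2)])
        assert recurrent_mutations(muts, min_count=3).empty

    def test_tie_ordered_by_gene_name(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "ZZ", pos=3) for i in range(4)]
            + [_mut(f"t{i}", "AA", pos=9) for i in range(4)]
        )
        out = recurrent_mutations(muts, min_count=3)
        assert list(out["gene"]) == ["AA", "ZZ"]

    def test_identity_requires_matching_alt(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "GX", pos=1, alt="C") for i in range(2)]
            + [_mut(f"t{i}", "GX", pos=1, alt="W") for i in range(2)]
        )
        assert recurrent_mutations(muts, min_count=3).empty  # two distinct events

    def test_gene_group_pooling(self):
        muts = pd.DataFrame(
            [_mut(f"s{i}", "H4A", pos=2, ref="S", alt="C") for i in range(2)]
            + [_mut(f"t{i}", "H4B", pos=2, ref="S", alt="C") for i in range(2)]
        )
        groups = {"H4A": "H4", "H4B": "H4"}
        out = recurrent_mutations(muts, min_count=3, gene_groups=groups)
        assert len(out) == 1 and out.iloc[0]["count"] == 4

    def test_output_subset_of_input_support(self, strong_cohort):
        out = recurrent_mutations(strong_cohort.mutations, min_count=2)
        support = set(
            zip(strong_cohort.mutations["gene"],
                strong_cohort.mutations["protein_pos"],
                strong_cohort.mutations["alt_aa"])
        )
        assert set(zip(out["gene"], out["protein_pos"], out["alt_aa"])) <= support

    def test_min_count_validated(self):
        with pytest.raises(ValueError, match="min_count"):
            recurrent_mutations(pd.DataFrame([_mut("s", "G")]), min_count=1)


class TestPositionalProfile:
    def test_toy_preserving_fraction(self):
        muts = pd.DataFrame([
            _mut("s1", "G1", pos=2, ref="S", alt="A"),
            _mut("s2", "G2", pos=2, ref="D", alt="E"),
            _mut("s3", "G3", pos=2, ref="S", alt="W"),
            _mut("s4", "G4", pos=2, ref="D", alt="K"),
        ])
        profile = positional_mutation_profile(muts)
        assert profile["preserving_fraction"] == pytest.approx(0.5)
        counts = profile["position_counts"].set_index("position")["missense_count"]
        assert counts.loc[2] == 4 and counts.loc[1] == 0

    def test_empty_table_all_zero(self):
        muts = pd.DataFrame(
            columns=["sample", "gene", "protein_pos", "ref_aa", "alt_aa",
                     "consequence", "tumour_type"]
        )
        profile = positional_mutation_profile(muts)
        assert (profile["position_counts"]["missense_count"] == 0).all()
        assert np.isnan(profile["preserving_fraction"])

    def test_uniform_positions_balanced(self):
        # Under the generator's uniform-position model, P1..P5 counts are
        # equal within multinomial error (chi-square goodness of fit).
        cfg = cohort_sim.SimConfig(seed=21, n_genes=40,
                                   mut_rate_per_residue=8e-3)
        cohort = cohort_sim.simulate_cohort(cfg)
        profile = positional_mutation_profile(cohort.mutations)
        counts = profile["position_counts"]["missense_count"].to_numpy()
        assert counts.sum() > 50
        p = stats.chisquare(counts).pvalue
        assert p > 1e-3


class TestAmplificationAssociation:
    @staticmethod
    def _setup(n_amp=4, n_non=26, boost=1.0, sd=0.5, seed=0):
        rng = np.random.default_rng(seed)
        samples = _samples(n_amp + n_non)
        ids = list(samples["sample"])
        expr = pd.DataFrame(
            [np.r_[rng.normal(5 + boost, sd, n_amp), rng.normal(5, sd, n_non)]],
            index=pd.Index(["GENE"], name="gene"), columns=ids,
        )
        cnv = pd.DataFrame({"sample": ids[:n_amp], "gene": "GENE", "call": 2})
        return cnv, expr, samples

    def test_separation_limit(self):
        cnv, expr, samples = self._setup(sd=1e-12)
        res = amplification_expression_association(cnv, expr, samples, "GENE", "T01")
        assert res.log2_fc == pytest.approx(1.0, abs=1e-6)
        assert res.p < 1e-20

    def test_identical_groups_zero_fc(self):
        cnv, expr, samples = self._setup(boost=0.0, sd=1e-12)
        res = amplification_expression_association(cnv, expr, samples, "GENE", "T01")
        assert res.log2_fc == pytest.approx(0.0, abs=1e-6)

    def test_small_group_not_evaluable(self):
        cnv, expr, samples = self._setup(n_amp=2)
        res = amplification_expression_association(cnv, expr, samples, "GENE", "T01")
        assert not res.evaluable
        assert np.isnan(res.p)

    def test_gains_not_counted_as_amplification(self):
        cnv, expr, samples = self._setup()
        cnv["call"] = 1
        res = amplification_expression_association(cnv, expr, samples, "GENE", "T01")
        assert not res.evaluable  # no +2 calls at all

    def test_power_thirty_vs_thirty(self):
        # Planted boost 1.0 with 30 amplified vs 30 background samples is
        # significant at p < 0.001 in at least 90% of 50 generator seeds.
        hits = 0
        for seed in range(1, 51):
            cfg = cohort_sim.SimConfig(
                seed=seed, n_genes=5, n_tumour_types=1,
                n_tumour_samples_per_type=60, n_normal_samples_per_type=2,
                planted_amp=[("G0003", "T01", 0.5, 1.0)],
            )
            cohort = cohort_sim.simulate_cohort(cfg)
            res = amplification_expression_association(
                cohort.cnv, cohort.expression, cohort.samples, "G0003", "T01"
            )
            hits += res.evaluable and res.p < 0.001 and res.log2_fc > 0
        assert hits >= 45
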