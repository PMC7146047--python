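"""Per-study effects, heterogeneity, and MH/DL pooling."""

import math

import numpy as np
import pytest

from genmeta import (
    ContrastTable,
    EffectEstimate,
    EffectModel,
    GeneticModel,
    build_contrast,
    cochran_q,
    pool_dl,
    pool_mh,
    select_and_pool,
    study_effect,
)


def table(a, b, c, d, sid="s", model=GeneticModel.ALLELE):
    return ContrastTable(a=a, b=b, c=c, d=d, study_id=sid, model=model)


class TestStudyEffect:
    def test_null_table(self):
        e = study_effect(table(10, 10, 10, 10))
        assert e.or_ == pytest.approx(1.0)
        assert e.se == pytest.approx(math.sqrt(0.4))
        assert e.ci_low < 1.0 < e.ci_high

    def test_kondo_homozygote(self, total_studies):
        kondo = next(s for s in total_studies if s.study_id == "Kondo 2010")
        e = study_effect(build_contrast(kondo, GeneticModel.HOMOZYGOTE))
        assert e.or_ == pytest.approx(438 / 1581, rel=1e-12)

    def test_zero_cell_haldane_correction(self):
        e = study_effect(table(0, 10, 10, 10))
        assert e.or_ == pytest.approx((0.5 * 10.5) / (10.5 * 10.5), rel=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="effect undefined"):
            study_effect(table(0, 0, 5, 5))

    def test_ci_consistency(self, allele_tables):
        for t in allele_tables:
            e = study_effect(t)
            assert e.ci_low < e.or_ < e.ci_high
            assert e.or_ == pytest.approx(math.exp(e.log_or))


def make_effect(sid, log_or, se):
    return EffectEstimate(
        study_id=sid, log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se), ci_high=math.exp(log_or + 1.96 * se),
    )


class TestCochranQ:
    def test_identical_effects(self):
        effs = [make_effect(f"s{i}", 0.3, 0.1) for i in range(2)]
        het = cochran_q(effs)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.p_value == pytest.approx(1.0)
        assert het.tau2 == 0.0 and het.i2 == 0.0

    def test_brute_force_oracle(self):
        """Q, I2, tau2 against a direct summation of the definitions."""
        los, ses = [0.2, -0.1, 0.5], [0.1, 0.2, 0.15]
        effs = [make_effect(f"s{i}", lo, se) for i, (lo, se) in enumerate(zip(los, ses))]
        het = cochran_q(effs)
        w = [1 / s**2 for s in ses]
        theta = sum(wi * lo for wi, lo in zip(w, los)) / sum(w)
        q = sum(wi * (lo - theta) ** 2 for wi, lo in zip(w, los))
        assert het.q == pytest.approx(q, rel=1e-12)
        assert het.i2 == pytest.approx(max(0.0, (q - 2) / q), rel=1e-12)
        tau2 = max(0.0, (q - 2) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
        assert het.tau2 == pytest.approx(tau2, rel=1e-12)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q([make_effect("s", 0.1, 0.1)])


class TestMantelHaenszel:
    def test_single_table_identity(self):
        t = table(12, 34, 21, 43)
        assert pool_mh([t]).or_ == pytest.approx(study_effect(t).or_, rel=1e-12)

    def test_replication_invariance(self):
        t = table(12, 34, 21, 43)
        single = pool_mh([t])
        double = pool_mh([t, t])
        assert double.or_ == pytest.approx(single.or_, rel=1e-12)

    def test_pooled_or_between_study_extremes(self, total_studies):
        for model in GeneticModel:
            tables = [build_contrast(s, model) for s in total_studies]
            pooled = pool_mh(tables)
            ors = [study_effect(t).or_ for t in tables]
            assert min(ors) <= pooled.or_ <= max(ors)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            pool_mh([table(0, 5, 0, 5), table(0, 7, 0, 3)])


class TestDerSimonianLaird:
    def test_reduces_to_inverse_variance_when_homogeneous(self):
        effs = [make_effect(f"s{i}", 0.25, se) for i, se in enumerate([0.1, 0.2, 0.3])]
        pooled = pool_dl(effs)
        assert pooled.heterogeneity.tau2 == 0.0
        w = [1 / e.se**2 for e in effs]
        theta = sum(wi * e.log_or for wi, e in zip(w, effs)) / sum(w)
        assert math.log(pooled.or_) == pytest.approx(theta, rel=1e-12)
        assert pooled.z == pytest.approx(theta * math.sqrt(sum(w)), rel=1e-12)

    def test_brute_force_oracle(self):
        los, ses = [0.6, -0.2, 0.1], [0.12, 0.25, 0.2]
        effs = [make_effect(f"s{i}", lo, se) for i, (lo, se) in enumerate(zip(los, ses))]
        pooled = pool_dl(effs)
        w = [1 / s**2 for s in ses]
        theta = sum(wi * lo for wi, lo in zip(w, los)) / sum(w)
        q = sum(wi * (lo - theta) ** 2 for wi, lo in zip(w, los))
        tau2 = max(0.0, (q - 2) / (sum(w) - sum(wi**2 for wi in w) / sum(w)))
        ws = [1 / (s**2 + tau2) for s in ses]
        theta_star = sum(wi * lo for wi, lo in zip(ws, los)) / sum(ws)
        se_star = 1 / math.sqrt(sum(ws))
        assert math.log(pooled.or_) == pytest.approx(theta_star, rel=1e-12)
        assert pooled.ci_high / pooled.ci_low == pytest.approx(
            math.exp(2 * 1.959963984540054 * se_star), rel=1e-9
        )

    def test_random_ci_never_narrower_than_fixed(self, total_studies):
        for model in GeneticModel:
            effs = [study_effect(build_contrast(s, model)) for s in total_studies]
            re = pool_dl(effs)
            w = [1 / e.se**2 for e in effs]
            theta = sum(wi * e.log_or for wi, e in zip(w, effs)) / sum(w)
            fixed_width = 2 * 1.959963984540054 / math.sqrt(sum(w))
            re_width = math.log(re.ci_high) - math.log(re.ci_low)
            assert re_width >= fixed_width - 1e-12

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            pool_dl([make_effect("s", 0.1, 0.1)])


class TestModelSelection:
    def test_heterogeneous_set_uses_random_effects(self, allele_tables):
        pooled = select_and_pool(allele_tables)
        assert pooled.effect_model is EffectModel.RANDOM_DL
        assert pooled.heterogeneity.p_value <= 0.10

    def test_homogeneous_subgroup_uses_fixed_mh(self, total_studies):
        caucasian = [
            build_contrast(s, GeneticModel.ALLELE)
            for s in total_studies
            if s.ethnicity.value == "Caucasian"
        ]
        pooled = select_and_pool(caucasian)
        assert pooled.effect_model is EffectModel.FIXED_MH
        assert pooled.heterogeneity.p_value > 0.10

    def test_identical_studies_select_fixed(self):
        t = table(12, 34, 21, 43)
        pooled = select_and_pool([t, t])
        assert pooled.effect_model is EffectModel.FIXED_MH
        assert pooled.heterogeneity.p_value == pytest.approx(1.0)

    def test_threshold_is_respected(self, allele_tables):
        # with an extreme threshold the same data pools fixed
        pooled = select_and_pool(allele_tables, threshold=1e-6)
        assert pooled.effect_model is EffectModel.FIXED_MH
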