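"""Polygenic scoring, carrier flags and the joint PRS + rare-carrier model."""

import numpy as np
import pandas as pd
import pytest

from cogexome.prs import carrier_flags, joint_model, quantile_summary, score_prs


def _toy_prs_inputs(rng, n=40, m=50):
    pairs = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A")]
    refalt = [pairs[rng.integers(0, len(pairs))] for _ in range(m)]
    vids = [f"v{j}" for j in range(m)]
    genos = pd.DataFrame(
        rng.integers(0, 3, size=(n, m)).astype(float), columns=vids
    )
    info = pd.DataFrame(
        {"variant_id": vids, "ref": [r for r, _ in refalt], "alt": [a for _, a in refalt]}
    )
    weights = pd.DataFrame(
        {
            "variant_id": vids,
            "effect_allele": [refalt[j][rng.integers(0, 2)] for j in range(m)],
            "weight": rng.normal(size=m),
        }
    )
    return genos, info, weights


class TestScorePrs:
    def test_zero_weights_give_zero_scores(self):
        rng = np.random.default_rng(0)
        genos, info, weights = _toy_prs_inputs(rng)
        weights["weight"] = 0.0
        assert np.allclose(score_prs(genos, info, weights), 0.0)

    def test_single_variant_dosage_two(self):
        genos = pd.DataFrame({"v0": [2.0, 0.0]})
        info = pd.DataFrame({"variant_id": ["v0"], "ref": ["A"], "alt": ["C"]})
        weights = pd.DataFrame(
            {"variant_id": ["v0"], "effect_allele": ["C"], "weight": [0.7]}
        )
        assert np.allclose(score_prs(genos, info, weights), [1.4, 0.0])

    def test_ref_effect_allele_flips_dosage(self):
        genos = pd.DataFrame({"v0": [2.0, 1.0, 0.0]})
        info = pd.DataFrame({"variant_id": ["v0"], "ref": ["A"], "alt": ["C"]})
        weights = pd.DataFrame(
            {"variant_id": ["v0"], "effect_allele": ["A"], "weight": [1.0]}
        )
        assert np.allclose(score_prs(genos, info, weights), [0.0, 1.0, 2.0])

    def test_strand_ambiguous_variants_dropped(self):
        genos = pd.DataFrame({"v0": [2.0], "v1": [2.0]})
        info = pd.DataFrame(
            {"variant_id": ["v0", "v1"], "ref": ["A", "A"], "alt": ["T", "C"]}
        )
        weights = pd.DataFrame(
            {"variant_id": ["v0", "v1"], "effect_allele": ["T", "C"], "weight": [1.0, 1.0]}
        )
        assert np.allclose(score_prs(genos, info, weights), [2.0])

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        genos, info, weights = _toy_prs_inputs(rng)
        genos.iloc[0, 0] = np.nan
        expected = np.zeros(len(genos))
        lookup = info.set_index("variant_id")
        for row in weights.itertuples(index=False):
            ref, alt = lookup.loc[row.variant_id]
            d = genos[row.variant_id].to_numpy()
            d = np.where(np.isnan(d), np.nanmean(d), d)
            if row.effect_allele == alt:
                expected += row.weight * d
            elif row.effect_allele == ref:
                expected += row.weight * (2 - d)
        assert np.allclose(score_prs(genos, info, weights), expected)

    def test_empty_intersection_rejected(self):
        genos = pd.DataFrame({"v0": [1.0]})
        info = pd.DataFrame({"variant_id": ["v0"], "ref": ["A"], "alt": ["T"]})
        weights = pd.DataFrame(
            {"variant_id": ["v0"], "effect_allele": ["T"], "weight": [1.0]}
        )
        with pytest.raises(ValueError, match="no usable overlap"):
            score_prs(genos, info, weights)  # only an ambiguous variant


class TestCarrierFlags:
    def _ann(self):
        return pd.DataFrame(
            {
                "variant_id": ["p1", "m1", "m2", "s1", "p2"],
                "gene": ["G1", "G1", "G2", "G2", "G3"],
                "consequence": ["stop_gained", "missense", "missense", "synonymous", "stop_gained"],
                "lof_confidence": ["HC", "NA", "NA", "NA", "HC"],
                "mpc": [np.nan, 2.5, 2.0, np.nan, np.nan],
                "pli": [0.95, 0.95, 0.95, 0.95, 0.5],
                "maf": [1e-6] * 5,
            }
        )

    def test_flag_rules(self):
        genos = pd.DataFrame(
            {
                "p1": [1, 0, 0, 0],
                "m1": [0, 1, 0, 0],
                "m2": [0, 0, 1, 0],  # MPC = 2.0, not damaging (strict > 2)
                "s1": [0, 0, 0, 1],
                "p2": [0, 0, 0, 1],  # PTV in a tolerant gene
            }
        )
        ptv, mis = carrier_flags(genos, self._ann())
        assert ptv.tolist() == [True, False, False, False]
        assert mis.tolist() == [False, True, False, False]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        ann = self._ann()
        genos = pd.DataFrame(
            rng.binomial(1, 0.1, size=(50, 5)), columns=ann["variant_id"]
        )
        ptv, mis = carrier_flags(genos, ann)
        from cogexome.variants import classify_annotations

        cl = classify_annotations(ann)
        for i in range(50):
            exp_ptv = exp_mis = False
            for row in cl.itertuples(index=False):
                if row.maf >= 1e-5 or row.pli <= 0.9 or genos.iloc[i][row.variant_id] < 1:
                    continue
                if row.variant_class == "PTV":
                    exp_ptv = True
                if row.variant_class in ("missense_t1", "missense_t2"):
                    exp_mis = True
            assert ptv[i] == exp_ptv and mis[i] == exp_mis

    def test_monotone_in_pli_threshold(self):
        rng = np.random.default_rng(3)
        ann = self._ann()
        genos = pd.DataFrame(
            rng.binomial(1, 0.3, size=(30, 5)), columns=ann["variant_id"]
        )
        strict_ptv, _ = carrier_flags(genos, ann, pli_min=0.9)
        loose_ptv, _ = carrier_flags(genos, ann, pli_min=0.4)
        assert np.all(loose_ptv >= strict_ptv)


class TestJointModel:
    def test_recovers_additive_conditional_effects(self):
        rng = np.random.default_rng(4)
        n = 40_000
        prs = rng.normal(size=n)
        ptv = rng.random(n) < 0.02
        mis = rng.random(n) < 0.05
        y = 0.116 * prs - 0.095 * ptv - 0.053 * mis + rng.normal(0, 0.99, n)
        res = joint_model(y, prs, ptv, mis)
        for name, truth in (("prs", 0.116), ("ptv", -0.095), ("missense", -0.053)):
            assert abs(res.beta[name] - truth) < 2 * res.se[name]

    def test_zero_effect_predictor_has_negligible_partial_r2(self):
        rng = np.random.default_rng(5)
        n = 50_000
        prs = rng.normal(size=n)
        ptv = rng.random(n) < 0.05
        mis = rng.random(n) < 0.05
        y = 0.3 * prs + rng.normal(size=n)
        res = joint_model(y, prs, ptv, mis)
        assert res.partial_r2["ptv"] < 1e-4
        assert res.partial_r2["missense"] < 1e-4
        assert res.partial_r2["prs"] > 0.05

    def test_interaction_term_reported(self):
        rng = np.random.default_rng(6)
        n = 5_000
        prs = rng.normal(size=n)
        ptv = rng.random(n) < 0.1
        mis = rng.random(n) < 0.1
        y = 0.2 * prs - 0.1 * ptv + 0.3 * prs * ptv + rng.normal(size=n)
        res = joint_model(y, prs, ptv, mis, interaction=True)
        assert res.interaction_p["prs_x_ptv"] < 1e-4
        assert res.interaction_p["prs_x_missense"] > 1e-4

    def test_zero_carrier_flag_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 200
        with pytest.warns(UserWarning, match="zero carriers"):
            res = joint_model(
                rng.normal(size=n), rng.normal(size=n),
                np.zeros(n, bool), rng.random(n) < 0.2,
            )
        assert "ptv" not in res.beta and "missense" in res.beta

    def test_additivity_of_orthogonal_contributions(self):
        rng = np.random.default_rng(8)
        n = 60_000
        prs = rng.normal(size=n)
        ptv = rng.random(n) < 0.5  # orthogonal, balanced
        mis = rng.random(n) < 0.5
        y = 0.2 * prs + 0.1 * ptv - 0.15 * mis + rng.normal(size=n)
        res = joint_model(y, prs, ptv, mis)
        assert res.r2_full == pytest.approx(sum(res.partial_r2.values()), abs=0.005)


class TestQuantileSummary:
    def test_two_groups_nearly_equal_sizes(self):
        rng = np.random.default_rng(9)
        n = 1001
        out = quantile_summary(
            rng.normal(size=n), rng.normal(size=n), rng.random(n) < 0.1, q=0.5
        )
        sizes = out.groupby("group")["n"].sum()
        assert len(sizes) == 2 and abs(sizes.iloc[0] - sizes.iloc[1]) <= 1

    def test_null_phenotype_medians_near_zero(self):
        rng = np.random.default_rng(10)
        n = 20_000
        out = quantile_summary(
            rng.normal(size=n), rng.normal(size=n), np.zeros(n, bool), q=0.2
        )
        # median SE ~ 1.253 / sqrt(n_group)
        tol = 2 * 1.253 / np.sqrt(out["n"].min())
        assert np.all(np.abs(out["median"]) < tol + 0.02)

    def test_monotone_prs_effect_gives_monotone_medians(self):
        rng = np.random.default_rng(11)
        n = 50_000
        prs = rng.normal(size=n)
        y = 0.5 * prs + rng.normal(0, 0.5, size=n)
        out = quantile_summary(prs, y, np.zeros(n, bool), q=0.2)
        med = out.sort_values("group")["median"].to_numpy()
        assert np.all(np.diff(med) > 0)

    def test_top_decile_split(self):
        rng = np.random.default_rng(12)
        n = 10_000
        out = quantile_summary(
            rng.normal(size=n), rng.normal(size=n), np.zeros(n, bool), top_binary=True
        )
        sizes = out.groupby("group")["n"].sum()
        assert abs(sizes["top10"] - 0.1 * n) < 0.02 * n

    def test_uneven_quantile_rejected(self):
        with pytest.raises(ValueError):
            quantile_summary(np.arange(10.0), np.arange(10.0), np.zeros(10, bool), q=0.3)
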