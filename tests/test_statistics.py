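"""Statistical operations against exact and hand-computed oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from timingfit import statistics as st


def exact_wilcoxon_p(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_pairs_convention(self):
        z, p = st.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (z, p) == (0.0, 1.0)

    @pytest.mark.parametrize("n", [8, 10])
    def test_matches_exact_enumeration_small_n(self, rng, n):
        """Default (auto) p equals brute-force enumeration at small n."""
        for _ in range(15):
            d = rng.normal(size=n)
            _, p = st.wilcoxon_signed_rank(d)
            assert p == pytest.approx(exact_wilcoxon_p(d), abs=1e-9)

    def test_normal_approximation_accuracy(self, rng):
        """The continuity-corrected approximation tracks exact p closely."""
        for _ in range(15):
            d = rng.normal(size=10)
            _, p = st.wilcoxon_signed_rank(d, method="approx")
            assert abs(p - exact_wilcoxon_p(d)) < 0.03

    def test_exact_method_rejects_ties(self):
        with pytest.raises(ValueError):
            st.wilcoxon_signed_rank([1, 1, 2, -2, 3, -3], method="exact")

    def test_all_positive_differences_n20(self):
        z, p = st.wilcoxon_signed_rank(np.arange(1.0, 21.0))
        # W+ = n(n+1)/2 = 210, the extreme of the null distribution
        assert z > 0
        assert p < 0.001

    def test_sign_convention(self):
        z_pos, _ = st.wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [0, 0, 0, 0, 0, 0])
        z_neg, _ = st.wilcoxon_signed_rank([0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6])
        assert z_pos > 0 > z_neg


class TestFDR:
    def test_single_p_unchanged(self):
        assert st.fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        assert np.allclose(st.fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_worked_stepup_example(self):
        # p_(i) * m / i = (.04, .04, .04, .04) after the step-up minimum
        adj = st.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_monotone_and_never_decreases(self, rng):
        p = rng.uniform(size=30)
        adj = st.fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEffectSize:
    @pytest.mark.parametrize("z,n,r", [(0, 10, 0.0), (2, 16, 0.5), (-1.5, 25, -0.3)])
    def test_r_formula(self, z, n, r):
        assert st.effect_size_r(z, n) == pytest.approx(r)


class TestBootstrapCI:
    def test_constant_vector(self):
        lo, hi = st.bootstrap_median_ci(np.full(20, 3.7), seed=1)
        assert (lo, hi) == (3.7, 3.7)

    def test_brackets_sample_median(self, rng):
        v = rng.normal(size=31)
        lo, hi = st.bootstrap_median_ci(v, seed=2)
        assert lo <= np.median(v) <= hi

    def test_coverage_near_nominal(self):
        """~95% of CIs should contain the true median of a normal."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 400
        for i in range(n_sim):
            v = rng.normal(size=32)
            lo, hi = st.bootstrap_median_ci(v, n_iter=400, seed=i)
            hits += lo <= 0 <= hi
        assert abs(hits / n_sim - 0.95) < 0.04


class TestAnova:
    def test_one_factor_f_equals_t_squared(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.8, size=12)
        tbl = pd.DataFrame(
            dict(ve=np.r_[a, b], group=["a"] * 12 + ["b"] * 12)
        )
        out = st.anova_nfactor(tbl, "ve", ["group"])
        t = sps.ttest_ind(a, b).statistic
        assert out.F.iloc[0] == pytest.approx(t**2, rel=1e-9)

    def test_constant_response(self):
        tbl = pd.DataFrame(dict(ve=np.ones(8), g=list("aabbaabb"), h=list("abababab")))
        out = st.anova_nfactor(tbl, "ve", ["g", "h"])
        assert (out.F == 0).all()

    def test_balanced_2x2_hand_decomposition(self):
        # cell means: a1b1=1, a1b2=3, a2b1=5, a2b2=7 (2 reps, +-1 within cell)
        tbl = pd.DataFrame(
            dict(
                y=[0, 2, 2, 4, 4, 6, 6, 8],
                a=["a1"] * 4 + ["a2"] * 4,
                b=(["b1", "b1", "b2", "b2"] * 2),
            )
        )
        out = st.anova_nfactor(tbl, "y", ["a", "b"], interactions=[("a", "b")]).set_index("term")
        # hand SS: SSa = 8*(2**2) = 32, SSb = 8, SSint = 0, SSerr = 8 (df 4)
        assert out.loc["a", "F"] == pytest.approx(32 / (8 / 4))
        assert out.loc["b", "F"] == pytest.approx(8 / (8 / 4))
        assert out.loc["a:b", "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["a", "partial_eta_sq"] == pytest.approx(32 / 40)

    def test_single_level_factor_rejected(self):
        tbl = pd.DataFrame(dict(ve=[1.0, 2.0], g=["a", "a"]))
        with pytest.raises(ValueError, match="g"):
            st.anova_nfactor(tbl, "ve", ["g"])


class TestDunnHolmSidak:
    def test_identical_groups(self):
        out = st.dunn_holm_sidak({"x": [1, 2, 3, 4], "y": [1, 2, 3, 4]})
        assert out.p_adj.iloc[0] > 0.9

    def test_z_matches_manual_rank_computation(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        out = st.dunn_holm_sidak(groups).set_index(["group_a", "group_b"])
        # pooled ranks 1..9, no ties; mean ranks 2, 5, 8; var term N(N+1)/12 = 7.5
        se = np.sqrt(7.5 * (1 / 3 + 1 / 3))
        assert out.loc[("a", "b"), "z"] == pytest.approx((2 - 5) / se)
        assert out.loc[("a", "c"), "z"] == pytest.approx((2 - 8) / se)

    def test_holm_sidak_worked_example(self):
        adj = st.holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 2)
        assert adj[1] == pytest.approx(max(adj[0], 0.04))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.dunn_holm_sidak({"a": [1.0], "b": []})


class TestJarqueBera:
    def test_symmetric_mesokurtic_sample(self):
        # moments matched to a normal: skew 0, excess kurtosis ~0
        v = sps.norm.ppf(np.linspace(0.005, 0.995, 200))
        jb, p = st.jarque_bera(v)
        assert jb < 1.0

    def test_formula_on_hand_sample(self):
        v = np.array([1.0, 2, 2, 3, 3, 3, 4, 4, 5, 9])
        n = len(v)
        s = sps.skew(v)
        k = sps.kurtosis(v)  # excess
        want = n / 6 * (s**2 + k**2 / 4)
        jb, p = st.jarque_bera(v)
        assert jb == pytest.approx(want, rel=1e-9)
        assert p == pytest.approx(1 - sps.chi2.cdf(want, 2), rel=1e-9)

    def test_detects_exponential_skew(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            st.jarque_bera(rng.exponential(size=200))[1] < 0.01 for _ in range(40)
        )
        assert rejections >= 38  # >= 95% of draws


class TestEccentricityBins:
    def _toy(self, rng, n=600):
        fits = []
        ann = []
        for v in range(n):
            ecc = rng.uniform(0, 2.0)
            for split in "AB":
                for model, ve in (("monotonic", 0.5), ("tuned", 0.3)):
                    fits.append(
                        dict(
                            voxel_id=v,
                            model=model,
                            split=split,
                            ve_train=0.5,
                            ve_cv=ve + 0.01 * rng.normal(),
                            out_of_range=False,
                        )
                    )
            ann.append(dict(voxel_id=v, visual_field_map="V1", eccentricity_deg=ecc))
        return pd.DataFrame(fits), pd.DataFrame(ann)

    def test_edge_voxel_lands_in_first_bin(self, rng):
        fits, ann = self._toy(rng)
        ann.loc[0, "eccentricity_deg"] = 0.05
        out = st.eccentricity_bins(fits, ann, min_count=1)
        assert out.bin_center.min() == pytest.approx(0.1)

    def test_underpopulated_bins_dropped(self, rng):
        fits, ann = self._toy(rng, n=30)  # 60 voxel x split entries over 10 bins
        out = st.eccentricity_bins(fits, ann, min_count=50)
        assert len(out) == 0

    def test_bin_means_match_direct_computation(self, rng):
        fits, ann = self._toy(rng)
        out = st.eccentricity_bins(fits, ann, min_count=10)
        row = out.iloc[0]
        merged = (
            fits.pivot_table(index=["voxel_id", "split"], columns="model", values="ve_cv")
            .reset_index()
            .merge(ann, on="voxel_id")
        )
        lo, hi = row.bin_center - 0.1, row.bin_center + 0.1
        sel = merged[(merged.eccentricity_deg >= lo) & (merged.eccentricity_deg < hi)]
        assert row.n == len(sel)
        assert row.mean_monotonic == pytest.approx(sel.monotonic.mean())
        assert row.sem_tuned == pytest.approx(sel.tuned.sem())


class TestEccentricityProgression:
    def test_sigmoid_recovery(self, rng):
        x = np.arange(0.1, 5.51, 0.2)
        true = st._sigmoid(x, 1.5, -2.0, 0.5, 0.1)
        y = true + 0.005 * rng.normal(size=x.size)
        out = st.fit_eccentricity_progression(x, y, n_boot=100, seed=0)
        assert out["chosen"] == "sigmoid"
        assert abs(out["sigmoid"]["inflection"] - 1.5) < 0.3

    def test_linear_data_selects_quadratic(self):
        x = np.arange(0.1, 3.01, 0.2)
        y = 0.4 - 0.1 * x
        out = st.fit_eccentricity_progression(x, y, n_boot=50, seed=0)
        assert out["chosen"] == "quadratic"
        assert abs(out["quadratic"]["coefficients"][0]) < 1e-8  # quadratic term ~ 0

    def test_constant_data_deterministic_tie(self):
        x = np.arange(0.1, 2.01, 0.2)
        out = st.fit_eccentricity_progression(x, np.full(x.size, 0.25), n_boot=10, seed=0)
        assert out["chosen"] == "quadratic"

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            st.fit_eccentricity_progression([1, 2, 3], [0.1, 0.2, 0.3])


class TestNearFar:
    def _cohort_frames(self, rng, effect=0.0):
        """Paired measurements from a toy two-map cohort."""
        fits, ann = [], []
        v = 0
        for part in range(4):
            for hemi in "LR":
                for m in ("V1", "IPS1"):
                    for _ in range(30):
                        ecc = rng.uniform(0, 5.5)
                        near = ecc < 1.0
                        for split in "AB":
                            mono = 0.3 + (effect if (near and m == "V1") else 0.0)
                            for model, ve in (("monotonic", mono), ("tuned", 0.25)):
                                fits.append(
                                    dict(
                                        voxel_id=v,
                                        model=model,
                                        split=split,
                                        ve_train=0.5,
                                        ve_cv=max(ve + 0.05 * rng.normal(), 0),
                                        out_of_range=False,
                                    )
                                )
                        ann.append(
                            dict(
                                voxel_id=v,
                                participant_id=f"P{part}",
                                hemisphere_id=hemi,
                                visual_field_map=m,
                                eccentricity_deg=ecc,
                            )
                        )
                        v += 1
        return pd.DataFrame(fits), pd.DataFrame(ann)

    def test_identical_populations_nonsignificant(self, rng):
        fits, ann = self._cohort_frames(rng, effect=0.0)
        out = st.near_far_compare(fits, ann)
        assert (out["monotonic"]["table"].p_adj > 0.05).all()

    def test_engineered_near_effect_detected_in_target_map(self, rng):
        fits, ann = self._cohort_frames(rng, effect=0.3)
        out = st.near_far_compare(fits, ann)
        tbl = out["monotonic"]["table"].set_index("map")
        assert tbl.loc["V1", "p_adj"] < 0.05
        assert tbl.loc["V1", "mean_near"] > tbl.loc["V1", "mean_far"]
        assert tbl.loc["IPS1", "p_adj"] > 0.05


class TestMapMedianParams:
    def test_amplitude_ratio_excludes_zero_and_infinite(self):
        fits = pd.DataFrame(
            [
                dict(voxel_id=0, model="monotonic", split="A", ve_train=0.5,
                     ve_cv=0.4, amplitude_ratio=2.0, out_of_range=False),
                dict(voxel_id=1, model="monotonic", split="A", ve_train=0.5,
                     ve_cv=0.4, amplitude_ratio=0.0, out_of_range=False),
                dict(voxel_id=2, model="monotonic", split="A", ve_train=0.5,
                     ve_cv=0.4, amplitude_ratio=np.inf, out_of_range=False),
            ]
        )
        ann = pd.DataFrame(
            dict(
                voxel_id=[0, 1, 2],
                participant_id="P1",
                hemisphere_id="L",
                visual_field_map="V1",
            )
        )
        out = st.map_median_params(fits, ann, "amplitude_ratio", "monotonic")
        assert len(out) == 1
        assert out.median_value.iloc[0] == 2.0


class TestMapMedianVE:
    def _frames(self):
        fits = pd.DataFrame(
            [
                dict(voxel_id=v, model=m, split=s, ve_train=vt, ve_cv=vc, out_of_range=False)
                for v, vt, vc in [(0, 0.5, 0.4), (1, 0.1, 0.05), (2, 0.3, 0.2)]
                for m in ("monotonic", "tuned")
                for s in ("A", "B")
            ]
        )
        ann = pd.DataFrame(
            [
                dict(voxel_id=0, participant_id="P1", hemisphere_id="L", visual_field_map="V1"),
                dict(voxel_id=1, participant_id="P1", hemisphere_id="L", visual_field_map="V1"),
                dict(voxel_id=2, participant_id="P1", hemisphere_id="L", visual_field_map="V2"),
            ]
        )
        return fits, ann

    def test_threshold_excludes_voxels_and_cells(self):
        fits, ann = self._frames()
        out = st.map_median_ve(fits, ann, threshold=0.2)
        v1 = out[out.visual_field_map == "V1"]
        assert (v1.n_voxels == 1).all()  # voxel 1 fails the gate
        out4 = st.map_median_ve(fits, ann, threshold=0.4)
        assert "V2" not in set(out4.visual_field_map)  # cell absent entirely

    def test_single_passing_voxel_median_is_that_voxel(self):
        fits, ann = self._frames()
        out = st.map_median_ve(fits, ann, threshold=0.2)
        v2 = out[(out.visual_field_map == "V2") & (out.model == "monotonic")]
        assert (v2.median_ve == 0.2).all()

    def test_permutation_invariance(self, rng):
        fits, ann = self._frames()
        shuffled = fits.sample(frac=1, random_state=3).reset_index(drop=True)
        a = st.map_median_ve(fits, ann).sort_values(
            ["visual_field_map", "split", "model"]
        ).reset_index(drop=True)
        b = st.map_median_ve(shuffled, ann).sort_values(
            ["visual_field_map", "split", "model"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
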