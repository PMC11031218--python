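import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betainc, polygamma
from sklearn.metrics import adjusted_rand_score

from responderomics.diff_analysis import (
    ContrastSpec,
    GeneStats,
    Prior,
    cluster_profiles,
    estimate_prior,
    fit_gene_stats,
    moderated_t,
    run_contrast,
    select_deg,
    trigamma_inverse,
)
from responderomics.errors import DataError, DesignError
from responderomics.io_formats import OmicsMatrix, SampleSheet

PAIRED_RES = ContrastSpec("paired_within_group", group="RES")
UNPAIRED_W0 = ContrastSpec("unpaired_between_groups", timepoint="w0")


def _sheet(rows):
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "group", "timepoint", "sex"])
    )


def _paired_matrix(diffs):
    """One gene; RES subjects with w10 - w0 equal to the given differences."""
    rows = []
    samples = []
    values = []
    for i, d in enumerate(diffs):
        subj = f"r{i}"
        rows += [
            (f"{subj}_w0", subj, "RES", "w0", "F"),
            (f"{subj}_w10", subj, "RES", "w10", "F"),
        ]
        samples += [f"{subj}_w0", f"{subj}_w10"]
        values += [5.0, 5.0 + d]
    m = OmicsMatrix(["g1"], samples, np.array([values]), "expression_log2")
    return m, _sheet(rows)


class TestFitGeneStats:
    def test_paired_textbook_quantities(self):
        m, sheet = _paired_matrix([1.0, 2.0, 3.0])
        gs = fit_gene_stats(m, sheet, PAIRED_RES)
        assert gs.beta_hat[0] == pytest.approx(2.0)
        assert gs.s2[0] == pytest.approx(1.0)
        assert gs.df_res == 2
        assert gs.u == pytest.approx(1 / math.sqrt(3))

    def test_unpaired_textbook_quantities(self):
        rows = [
            ("a_w0", "a", "RES", "w0", "F"), ("b_w0", "b", "RES", "w0", "M"),
            ("c_w0", "c", "LRE", "w0", "F"), ("d_w0", "d", "LRE", "w0", "M"),
        ]
        m = OmicsMatrix(["g1"], [r[0] for r in rows], np.array([[0.0, 0.0, 1.0, 1.0]]),
                        "expression_log2")
        gs = fit_gene_stats(m, _sheet(rows), UNPAIRED_W0)
        assert gs.beta_hat[0] == pytest.approx(-1.0)  # RES minus LRE
        assert gs.s2[0] == 0.0
        assert gs.df_res == 2
        assert gs.u == pytest.approx(1.0)

    def test_unpaired_matches_least_squares_oracle(self, rng):
        rows = []
        vals = []
        for i in range(4):
            rows.append((f"r{i}_w0", f"r{i}", "RES", "w0", "F"))
        for i in range(4):
            rows.append((f"l{i}_w0", f"l{i}", "LRE", "w0", "M"))
        x = rng.normal(7, 1, size=8)
        m = OmicsMatrix(["g1"], [r[0] for r in rows], x[None, :], "expression_log2")
        gs = fit_gene_stats(m, _sheet(rows), UNPAIRED_W0)
        design = np.column_stack([np.ones(8), [1, 1, 1, 1, 0, 0, 0, 0]])
        coef, rss, *_ = np.linalg.lstsq(design, x, rcond=None)
        assert gs.beta_hat[0] == pytest.approx(coef[1], rel=1e-10)
        assert gs.s2[0] == pytest.approx(float(rss[0]) / 6, rel=1e-10)

    def test_subject_missing_timepoint_names_subject(self):
        m, sheet = _paired_matrix([1.0, 2.0])
        broken = sheet.table[sheet.table["sample_id"] != "r1_w10"]
        with pytest.raises(DesignError, match="r1"):
            fit_gene_stats(m.subset_samples(broken["sample_id"].tolist()),
                           SampleSheet(broken), PAIRED_RES)


class TestPriorEstimation:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_generating_hyperparameters(self, seed):
        rng = np.random.default_rng(seed)
        d0, s0, df = 4.0, 0.25, 6
        sigma2 = d0 * s0**2 / rng.chisquare(d0, 10_000)
        s2 = sigma2 * rng.chisquare(df, 10_000) / df
        prior = estimate_prior(s2, df)
        assert abs(prior.d0 - d0) < 0.5
        assert abs(math.sqrt(prior.s0_sq) - s0) / s0 < 0.05

    def test_identical_variances_give_infinite_prior_df(self):
        prior = estimate_prior(np.full(50, 0.3), 6)
        assert math.isinf(prior.d0)
        # s0^2 = exp(mean e) with e the debiased log variance
        expected = 0.3 * math.exp(math.log(3.0) - float(polygamma(0, 3.0)))
        assert prior.s0_sq == pytest.approx(expected, rel=1e-9)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DataError):
            estimate_prior(np.zeros(50), 6)

    @pytest.mark.parametrize("target", [1e-4, 0.05, 0.8, 5.0, 300.0])
    def test_trigamma_inverse_satisfies_root_equation(self, target):
        x_hat = trigamma_inverse(target)
        assert abs(float(polygamma(1, x_hat)) - target) < 1e-10


class TestModeratedT:
    def _random_stats(self, rng, n=200):
        return GeneStats(
            feature_ids=[f"f{i}" for i in range(n)],
            beta_hat=rng.normal(size=n),
            s2=rng.chisquare(5, n) / 5,
            df_res=5.0,
            u=1 / math.sqrt(6),
            contrast=PAIRED_RES,
        )

    def test_zero_prior_df_reduces_to_ordinary_t(self, rng):
        gs = self._random_stats(rng)
        res = moderated_t(gs, None)
        ordinary = gs.beta_hat / (gs.u * np.sqrt(gs.s2))
        np.testing.assert_allclose(res.table["t_mod"], ordinary, rtol=1e-12)
        p_ref = 2 * stats.t.sf(np.abs(ordinary), df=5)
        np.testing.assert_allclose(res.table["p_value"], p_ref, rtol=1e-12)

    def test_infinite_prior_df_uses_prior_variance_everywhere(self, rng):
        gs = self._random_stats(rng)
        res = moderated_t(gs, Prior(d0=math.inf, s0_sq=0.2))
        np.testing.assert_allclose(res.table["s2_post"], 0.2)

    def test_p_values_match_incomplete_beta_oracle(self, rng):
        gs = self._random_stats(rng)
        prior = Prior(d0=4.0, s0_sq=0.15)
        res = moderated_t(gs, prior)
        df_tot = 4.0 + 5.0
        t = res.table["t_mod"].to_numpy()
        p_oracle = betainc(df_tot / 2, 0.5, df_tot / (df_tot + t**2))
        np.testing.assert_allclose(res.table["p_value"], p_oracle, atol=1e-10)

    def test_posterior_variance_between_prior_and_sample(self, rng):
        gs = self._random_stats(rng)
        prior = Prior(d0=4.0, s0_sq=0.15)
        res = moderated_t(gs, prior)
        lo = np.minimum(gs.s2, prior.s0_sq)
        hi = np.maximum(gs.s2, prior.s0_sq)
        s2_post = res.table["s2_post"].to_numpy()
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_moderated_and_ordinary_t_agree_in_sign(self, rng):
        gs = self._random_stats(rng)
        res = moderated_t(gs, Prior(d0=4.0, s0_sq=0.15))
        assert (np.sign(res.table["t_mod"]) == np.sign(gs.beta_hat)).all()


class TestDegSelection:
    def _result(self, p_values):
        gs = GeneStats(
            feature_ids=[f"f{i}" for i in range(len(p_values))],
            beta_hat=np.ones(len(p_values)),
            s2=np.ones(len(p_values)),
            df_res=5.0,
            u=1.0,
            contrast=PAIRED_RES,
        )
        res = moderated_t(gs, None)
        res.table["p_value"] = p_values
        return res

    def test_all_p_one_gives_empty_list(self):
        assert select_deg(self._result([1.0, 1.0, 1.0])) == []

    def test_threshold_one_selects_everything(self):
        assert len(select_deg(self._result([0.5, 0.9, 1.0]), p_threshold=1.0)) == 3

    def test_sorted_by_p_with_id_tie_break(self):
        res = self._result([0.04, 0.01, 0.04])
        assert select_deg(res) == ["f1", "f0", "f2"]


class TestClusterProfiles:
    def _planted(self, small_sheet, rng, noise=0.05):
        shapes = np.array(
            [[2, 2, -2, -2], [-2, -2, 2, 2], [2, -2, 2, -2], [-2, 2, -2, 2]], float
        )
        genes = [f"G{i:02d}" for i in range(40)]
        labels = [i % 4 for i in range(40)]
        meta = small_sheet.table
        cells = [(g, t) for g in ("LRE", "RES") for t in ("w0", "w10")]
        base = np.zeros((40, len(meta)))
        for si, (_, row) in enumerate(meta.iterrows()):
            ci = cells.index((row["group"], row["timepoint"]))
            base[:, si] = shapes[labels, ci]
        vals = 7.0 + base + rng.normal(0, noise, base.shape)
        m = OmicsMatrix(genes, meta["sample_id"].tolist(), vals, "expression_log2")
        return m, genes, labels

    def test_recovers_planted_orthogonal_profiles(self, small_sheet, rng):
        m, genes, labels = self._planted(small_sheet, rng)
        found = cluster_profiles(m, small_sheet, genes, k=4)
        assert adjusted_rand_score(labels, found.loc[genes]) == 1.0

    def test_k_one_labels_everything_one(self, small_sheet, rng):
        m, genes, _ = self._planted(small_sheet, rng)
        found = cluster_profiles(m, small_sheet, genes, k=1)
        assert set(found) == {1}

    def test_duplicated_rows_cluster_together(self, small_sheet, rng):
        m, genes, _ = self._planted(small_sheet, rng)
        dup_vals = np.vstack([m.values, m.values[:1]])
        m2 = OmicsMatrix(genes + ["Gdup"], m.sample_ids, dup_vals, "expression_log2")
        found = cluster_profiles(m2, small_sheet, genes + ["Gdup"], k=4)
        assert found["Gdup"] == found["G00"]

    def test_labels_ordered_by_descending_cluster_size(self, small_sheet, rng):
        m, genes, _ = self._planted(small_sheet, rng)
        found = cluster_profiles(m, small_sheet, genes, k=4)
        sizes = found.value_counts().loc[[1, 2, 3, 4]]
        assert (sizes.diff().dropna() <= 0).all()


class TestLayerIntegration:
    def test_methylation_tested_on_m_values_with_beta_effect_reported(self, small_sim):
        res = run_contrast(small_sim["methylation"], small_sim["sheet"], UNPAIRED_W0)
        assert "effect_beta" in res.table.columns
        # beta-scale and M-scale effects agree in sign (logit is monotone)
        sig = res.table[res.table["p_value"] < 0.01]
        assert (np.sign(sig["effect_beta"]) == np.sign(sig["beta_hat"])).all()
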