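"""Screen analytics: PCA, contrasts, probe sets, enrichment, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from idseq import (
    ProbeSet,
    ScreenMatrix,
    annotate_pcs,
    assign_probe_sets,
    decile_contrast,
    enrichment_score,
    gsea,
    kinase_profiles,
    profile_cluster_compare,
    screen_pca,
)
from idseq.screen import _ranked, enrichment_table
from idseq.synth import simulate_screen


def frame(arr, prefix_r="p", prefix_c="ph"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix_r}{i:03d}" for i in range(arr.shape[0])],
        columns=[f"{prefix_c}{j:02d}" for j in range(arr.shape[1])],
    )


def brute_force_es(ranked_scores, member_pos, weight=1.0):
    """Walk the full ranking and track the running sum explicitly."""
    n = len(ranked_scores)
    member_set = set(member_pos)
    w = np.abs(ranked_scores[list(sorted(member_set))]) ** weight
    nr = w.sum() if w.sum() > 0 else float(len(member_set))
    running, best = 0.0, 0.0
    for i in range(n):
        if i in member_set:
            inc = abs(ranked_scores[i]) ** weight / nr if nr else 0
            running += inc
        else:
            running -= 1.0 / (n - len(member_set))
        if abs(running) > abs(best):
            best = running
    return best


class TestPCA:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        m = frame(np.outer(rng.normal(size=25), rng.normal(size=6)))
        pca = screen_pca(m, k=3)
        assert pca.variance_explained[0] == pytest.approx(1.0)
        assert pca.variance_explained[1:] == pytest.approx([0, 0], abs=1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        pca = screen_pca(frame(rng.normal(size=(40, 10))), k=5)
        L = pca.loadings.to_numpy()
        assert np.max(np.abs(L.T @ L - np.eye(5))) < 1e-10

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        m = frame(rng.normal(size=(15, 6)))
        pca = screen_pca(m, k=6)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T + pca.center
        assert np.max(np.abs(recon - m.to_numpy())) < 1e-10
        assert pca.variance_explained.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        m = frame(rng.normal(size=(30, 8)))
        p1 = screen_pca(m, k=4)
        p2 = screen_pca(m, k=4)
        pd.testing.assert_frame_equal(p1.loadings, p2.loadings)
        for pc in p1.loadings.columns:
            col = p1.loadings[pc]
            assert col.iloc[int(np.argmax(np.abs(col)))] > 0

    def test_variance_shares_non_increasing(self):
        rng = np.random.default_rng(4)
        pca = screen_pca(frame(rng.normal(size=(50, 12))), k=6)
        assert (np.diff(pca.variance_explained) <= 1e-12).all()
        assert pca.variance_explained.sum() <= 1 + 1e-12

    def test_missing_values_rejected(self):
        m = frame(np.ones((5, 3)))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            screen_pca(m, k=2)

    def test_planted_axes_recovered(self):
        matrix, _, truth = simulate_screen(n_probes=150, n_kinases=30, seed=5)
        pca = screen_pca(matrix, k=2)
        axes = np.asarray(truth.truth["axes"])
        best = [
            max(abs(np.corrcoef(pca.loadings[pc], ax)[0, 1]) for pc in pca.loadings)
            for ax in axes
        ]
        assert min(best) > 0.9


class TestAnnotate:
    def test_phenotype_equal_to_pc_scores(self):
        rng = np.random.default_rng(6)
        m = frame(rng.normal(size=(40, 5)))
        pca = screen_pca(m, k=2)
        m2 = m.copy()
        m2["phmirror"] = pca.scores["PC1"].to_numpy()
        table, order = annotate_pcs(ScreenMatrix(m2), pca)
        assert table.loc["phmirror", "PC1"] == pytest.approx(1.0, abs=1e-12)
        assert set(order) == set(m2.columns) | {"PC1", "PC2"}

    def test_correlations_bounded(self):
        rng = np.random.default_rng(7)
        m = frame(rng.normal(size=(30, 6)))
        pca = screen_pca(m, k=3)
        table, _ = annotate_pcs(m, pca)
        assert (table.to_numpy() <= 1).all() and (table.to_numpy() >= -1).all()

    def test_constant_phenotype_warns_and_zeroes(self):
        rng = np.random.default_rng(8)
        m = frame(rng.normal(size=(20, 4)))
        m.iloc[:, 2] = 5.0
        pca = screen_pca(m, k=2)
        with pytest.warns(UserWarning, match="constant"):
            table, _ = annotate_pcs(m, pca)
        assert (table.iloc[2] == 0).all()


class TestDecileContrast:
    def test_identical_groups_p_one(self):
        values = frame(np.tile([1.0, 2.0, 3.0], (20, 1)))
        scores = pd.Series(np.arange(20), index=values.index, dtype=float)
        out = decile_contrast(values, scores, fraction=0.25)
        assert (out["p_value"] == 1.0).all()

    def test_antisymmetry_under_score_reversal(self):
        rng = np.random.default_rng(9)
        values = frame(rng.normal(size=(40, 5)))
        scores = pd.Series(rng.normal(size=40), index=values.index)
        a = decile_contrast(values, scores, fraction=0.2)
        b = decile_contrast(values, -scores, fraction=0.2)
        assert (a["direction"].to_numpy() == -b["direction"].to_numpy()).all()
        assert a["p_value"].to_numpy() == pytest.approx(b["p_value"].to_numpy())

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(10)
        values = frame(rng.normal(size=(100, 4)))
        scores = pd.Series(np.linspace(5, -5, 100), index=values.index)
        top = scores.nlargest(10).index
        values.loc[top, values.columns[0]] += 2.0  # 2 s.d. shift in the top decile
        out = decile_contrast(values, scores, fraction=0.10).set_index("phenotype")
        assert out.loc[values.columns[0], "significant"]
        assert out.loc[values.columns[0], "direction"] == 1

    def test_invalid_fraction(self):
        values = frame(np.zeros((10, 2)))
        scores = pd.Series(np.arange(10), index=values.index, dtype=float)
        with pytest.raises(ValueError):
            decile_contrast(values, scores, fraction=0.7)


class TestProbeSets:
    def test_single_strong_outlier_assigned(self):
        rng = np.random.default_rng(11)
        col = rng.normal(10, 3, size=50).clip(0, 100)
        col[7] = 90.0
        inhib = frame(col[:, None], prefix_c="KIN")
        sets = assign_probe_sets(inhib, alpha=0.01)
        assert "p007" in sets[0].members

    def test_alpha_one_assigns_everything(self):
        rng = np.random.default_rng(12)
        inhib = frame(rng.uniform(0, 50, size=(20, 3)), prefix_c="KIN")
        sets = assign_probe_sets(inhib, alpha=1.0)
        assert all(len(ps) == 20 for ps in sets)

    def test_constant_column_empty_with_warning(self):
        inhib = frame(np.full((10, 1), 5.0), prefix_c="KIN")
        with pytest.warns(UserWarning, match="constant"):
            sets = assign_probe_sets(inhib)
        assert len(sets[0]) == 0

    def test_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(13)
        inhib = frame(rng.normal(30, 5, size=(300, 60)).clip(0, 100), prefix_c="KIN")
        sets = assign_probe_sets(inhib, alpha=0.05)
        rate = np.mean([len(ps) for ps in sets]) / 300
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_out_of_range_rejected(self):
        inhib = frame(np.full((5, 1), 120.0), prefix_c="KIN")
        with pytest.raises(ValueError, match="inhibition"):
            assign_probe_sets(inhib)


class TestEnrichment:
    def test_es_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n = int(rng.integers(20, 120))
            scores = np.sort(rng.normal(size=n))[::-1]
            m = int(rng.integers(2, min(10, n - 1)))
            pos = rng.choice(n, size=m, replace=False)
            es, _ = enrichment_score(scores, pos)
            assert es == pytest.approx(brute_force_es(scores, pos), abs=1e-12)

    def test_top_set_es_near_one(self):
        scores = np.linspace(4, -4, 50)
        es, ext = enrichment_score(scores, np.arange(5))
        assert es == pytest.approx(1.0, abs=1e-12)
        assert ext == 4

    def test_reversed_ranking_negates_es(self):
        rng = np.random.default_rng(15)
        scores = np.sort(rng.normal(size=60))[::-1]
        pos = rng.choice(60, size=6, replace=False)
        es_fwd, _ = enrichment_score(scores, pos)
        es_rev, _ = enrichment_score(scores[::-1], 59 - pos)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_gsea_detects_top_set(self):
        rng = np.random.default_rng(16)
        scores = pd.Series(
            np.sort(rng.normal(size=80))[::-1], index=[f"p{i:03d}" for i in range(80)]
        )
        members = list(scores.index[:6])
        ps = ProbeSet("KIN1", members, pd.Series(80.0, index=members),
                      pd.Series(0.001, index=members))
        res = gsea(scores, [ps], n_perm=500, seed=17)
        assert res[0].es > 0.8
        assert res[0].p_value < 0.01
        assert set(res[0].leading_edge) == set(members)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(18)
        probes = [f"p{i:03d}" for i in range(120)]
        scores = pd.Series(rng.normal(size=120), index=probes)
        sets = []
        for k in range(120):
            members = list(rng.choice(probes, size=8, replace=False))
            sets.append(ProbeSet(f"K{k}", members, pd.Series(50.0, index=members),
                                 pd.Series(0.5, index=members)))
        res = gsea(scores, sets, n_perm=400, seed=19)
        ks = stats.kstest([r.p_value for r in res], "uniform")
        assert ks.pvalue > 0.001

    def test_small_sets_skipped_with_warning(self):
        scores = pd.Series([3.0, 2.0, 1.0, 0.0], index=list("abcd"))
        tiny = ProbeSet("K", ["a"], pd.Series([50.0], index=["a"]),
                        pd.Series([0.5], index=["a"]))
        with pytest.warns(UserWarning, match="smaller"):
            assert gsea(scores, [tiny], n_perm=10, seed=0) == []

    def test_missing_member_rejected(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        ps = ProbeSet("K", ["a", "b", "z"], pd.Series(50.0, index=["a", "b", "z"]),
                      pd.Series(0.5, index=["a", "b", "z"]))
        with pytest.raises(ValueError, match="absent"):
            gsea(scores, [ps], n_perm=10, seed=0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(20)
        probes = [f"p{i:03d}" for i in range(60)]
        scores = pd.Series(rng.normal(size=60), index=probes)
        members = probes[:5]
        ps = ProbeSet("K", members, pd.Series(50.0, index=members),
                      pd.Series(0.5, index=members))
        r1 = gsea(scores, [ps], n_perm=200, seed=21)
        r2 = gsea(scores, [ps], n_perm=200, seed=21)
        assert r1[0].p_value == r2[0].p_value


class TestProfiles:
    def test_identical_probes_zero_sem(self):
        est = frame(np.tile([1.0, -2.0, 0.5], (4, 1)))
        members = list(est.index[:3])
        ps = ProbeSet("K", members, pd.Series(80.0, index=members),
                      pd.Series(0.001, index=members))
        means, sems = kinase_profiles(est, [ps])
        assert means.loc["K"].to_numpy() == pytest.approx([1.0, -2.0, 0.5])
        assert sems.loc["K"].to_numpy() == pytest.approx([0, 0, 0])

    def test_two_probe_mean(self):
        est = frame([[1.0, 3.0], [3.0, 5.0]])
        members = list(est.index)
        ps = ProbeSet("K", members, pd.Series(80.0, index=members),
                      pd.Series(0.001, index=members))
        means, sems = kinase_profiles(est, [ps])
        assert means.loc["K"].to_numpy() == pytest.approx([2.0, 4.0])
        assert sems.loc["K"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_singleton_sem_nan(self):
        est = frame([[1.0, 2.0], [0.0, 0.0]])
        ps = ProbeSet("K", [est.index[0]], pd.Series([80.0], index=[est.index[0]]),
                      pd.Series([0.001], index=[est.index[0]]))
        _, sems = kinase_profiles(est, [ps])
        assert sems.loc["K"].isna().all()

    def test_cluster_recovery_and_reference_p(self):
        rng = np.random.default_rng(22)
        est = frame(
            np.vstack([rng.normal(0, 0.2, size=(12, 6)),
                       rng.normal(4, 0.2, size=(12, 6))])
        )
        sets = []
        for k in range(6):
            members = list(est.index[2 * k: 2 * k + 2]) if k < 3 else list(
                est.index[12 + 2 * (k - 3): 14 + 2 * (k - 3)]
            )
            members += [est.index[2 * k + 6]] if k < 3 else [est.index[18 + 2 * (k - 3)]]
            sets.append(ProbeSet(f"K{k}", sorted(set(members)),
                                 pd.Series(80.0, index=sorted(set(members))),
                                 pd.Series(0.001, index=sorted(set(members)))))
        profiles, _ = kinase_profiles(est, sets)
        labels, pvals = profile_cluster_compare(
            profiles, est, sets, reference_kinase="K0", k_clusters=2, seed=0
        )
        # kinases built from the low block separate from the high block
        low = {f"K{k}" for k in range(3)}
        lab_low = {labels[k] for k in low}
        lab_high = {labels[k] for k in labels.index if k not in low}
        assert len(lab_low) == 1 and len(lab_high) == 1 and lab_low != lab_high
        assert (pvals.loc["K0"] == 1.0).all()

    def test_k_too_large_rejected(self):
        profiles = frame(np.eye(3))
        with pytest.raises(ValueError):
            profile_cluster_compare(profiles, profiles, [], "x", k_clusters=3)


def test_ranking_tie_break_is_lexicographic():
    scores = pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"])
    assert list(_ranked(scores).index) == ["a", "b", "c"]


def test_enrichment_table_columns():
    rng = np.random.default_rng(23)
    probes = [f"p{i}" for i in range(30)]
    scores = pd.Series(rng.normal(size=30), index=probes)
    members = probes[:4]
    ps = ProbeSet("K", members, pd.Series(60.0, index=members),
                  pd.Series(0.01, index=members))
    tab = enrichment_table(gsea(scores, [ps], n_perm=100, seed=1))
    assert list(tab.columns) == ["kinase", "es", "p_value", "q_value", "n_members", "leading_edge"]
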