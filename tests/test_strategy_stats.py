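import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st_
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist

from mycopattern import (
    anova_lsd,
    cluster_strategies,
    centroid_table,
    compute_indices,
    fit_regression,
    histogram,
    nmds,
    pca,
    records_to_frame,
    render_map,
    strategy_report,
)
from mycopattern.indices import INDEX_COLUMNS

from conftest import random_grids
from test_indices import record_from_values


def frame_from(param_values, param="frequency", group_col=None):
    """Small index-table frame with one varying column (and optional groups)."""
    rows = []
    for i, v in enumerate(param_values):
        rec = {c: 0.0 for c in INDEX_COLUMNS}
        rec[param] = float(v)
        rec.update(replication=1, segment=1, field=i + 1, freq_class="M1")
        rows.append(rec)
    df = pd.DataFrame(rows)
    if group_col is not None:
        df["freq_class"] = group_col
    return df


class TestHistogram:
    def test_identical_values_single_occupied_bin(self):
        h = histogram(frame_from([37.0] * 100), "frequency")
        assert h.counts.sum() == 100
        assert (h.counts > 0).sum() == 1

    def test_uniform_values_class_restricted_five_bins_of_20(self):
        h = histogram(frame_from(np.arange(1, 101)), "frequency", "class_restricted")
        assert list(h.bin_edges) == [0, 20, 40, 60, 80, 100]
        assert list(h.counts) == [20, 20, 20, 20, 20]

    def test_class_restricted_is_right_closed(self):
        h = histogram(frame_from([0.0, 20.0, 20.5, 100.0]), "frequency",
                      "class_restricted")
        assert list(h.counts) == [2, 1, 0, 0, 1]

    def test_counts_always_sum_to_n(self, festuca_frame):
        for sol in ("best_fitted", "class_restricted"):
            h = histogram(festuca_frame, "intensity", sol)
            assert h.counts.sum() == len(festuca_frame)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            histogram(frame_from([1.0]), "biomass")


class TestAnovaLSD:
    def test_identical_groups_f_zero_single_letter(self):
        df = frame_from([5.0] * 6, group_col=["g1"] * 3 + ["g2"] * 3)
        res = anova_lsd(df, "frequency")
        assert res.f_statistic == 0.0
        assert set(res.letters.values()) == {"a"}

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.01, 3), rng.normal(10, 0.01, 3)]
        df = frame_from(vals, group_col=["g1"] * 3 + ["g2"] * 3)
        res = anova_lsd(df, "frequency")
        assert res.p_value < 0.001
        assert res.letters["g1"] != res.letters["g2"]
        assert not set(res.letters["g1"]) & set(res.letters["g2"])

    def test_five_ordered_classes_get_letters_a_to_e(self):
        rng = np.random.default_rng(1)
        vals, groups = [], []
        for i, mu in enumerate([90, 70, 50, 30, 10]):
            vals.extend(rng.normal(mu, 1.0, 10))
            groups.extend([f"M{5 - i}"] * 10)
        res = anova_lsd(frame_from(vals, group_col=groups), "frequency")
        by_desc_mean = sorted(res.means, key=lambda g: -res.means[g])
        assert [res.letters[g] for g in by_desc_mean] == list("abcde")

    def test_letters_match_exhaustive_pairwise_oracle(self):
        """Groups share a letter iff the pooled-variance pairwise t-test
        (the LSD criterion) does not separate them."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            k, n = 4, 5
            mus = rng.uniform(0, 12, k)
            data = {f"g{j}": rng.normal(mus[j], 2.0, n) for j in range(k)}
            vals = np.concatenate(list(data.values()))
            groups = sum(([g] * n for g in data), [])
            res = anova_lsd(frame_from(vals, group_col=groups), "frequency")
            # independent oracle: classic LSD arithmetic
            msw = np.mean([np.var(v, ddof=1) for v in data.values()])
            dfw = k * (n - 1)
            for a, b in itertools.combinations(data, 2):
                t = abs(data[a].mean() - data[b].mean()) / np.sqrt(msw * 2 / n)
                signif = (res.p_value < 0.05) and (2 * st_.t.sf(t, dfw) < 0.05)
                share = bool(set(res.letters[a]) & set(res.letters[b]))
                assert share == (not signif)

    def test_small_groups_excluded_and_too_few_groups_rejected(self):
        df = frame_from([1.0, 2.0, 3.0], group_col=["g1", "g1", "g2"])
        with pytest.raises(ValueError):
            anova_lsd(df, "frequency")

    def test_null_type_one_error_rate_near_alpha(self):
        """Protected LSD: under the complete null the letter display
        collapses to one letter in ~95% of datasets."""
        rng = np.random.default_rng(0)
        failures = 0
        n_sim = 200
        for _ in range(n_sim):
            vals = rng.normal(50, 5, 50)
            groups = [f"g{j}" for j in range(5) for _ in range(10)]
            res = anova_lsd(frame_from(vals, group_col=groups), "frequency")
            if len(set(res.letters.values())) > 1:
                failures += 1
        assert 0.02 <= failures / n_sim <= 0.08


class TestRegression:
    def test_perfect_line(self):
        df = frame_from([1, 2, 3, 4])
        df["intensity"] = df["frequency"]
        r = fit_regression(df, "frequency", "intensity")
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        x = np.array([1.0, 3.0, 4.0, 7.0, 9.5])
        y = np.array([2.0, 2.5, 6.0, 5.5, 11.0])
        df = frame_from(x)
        df["intensity"] = y
        r = fit_regression(df, "frequency", "intensity")
        A = np.c_[np.ones_like(x), x]
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert r.intercept == pytest.approx(beta[0], abs=1e-8)
        assert r.slope == pytest.approx(beta[1], abs=1e-8)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(11)
        I = rng.uniform(0, 60, 500)
        arb = 0.16 * I + rng.normal(0, 1, 500)
        df = frame_from(I, param="intensity")
        df["arbuscules"] = arb
        r = fit_regression(df, "intensity", "arbuscules")
        assert abs(r.slope - 0.16) < 0.02

    def test_residuals_orthogonal_to_predictor(self, festuca_frame):
        r = fit_regression(festuca_frame, "frequency", "intensity")
        x = festuca_frame["frequency"].to_numpy()
        resid = festuca_frame["intensity"].to_numpy() - r.predict(x)
        assert abs(resid @ x) < 1e-6 * len(x)

    def test_zero_variance_predictor_rejected(self):
        df = frame_from([5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="variance"):
            fit_regression(df, "frequency", "intensity")


class TestPCA:
    def test_two_correlated_variables_one_axis(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(0, 100, 30)
        df = frame_from(f)
        df["intensity"] = 0.4 * f + 3.0
        res = pca(df, variables=["frequency", "intensity"])
        assert res.variance_pct[0] == pytest.approx(100.0)

    def test_eigenvalues_match_hand_computed_decomposition(self):
        X = np.array([[1.0, 2.0], [4.0, 0.5], [2.5, 5.0]])
        df = frame_from(X[:, 0])
        df["intensity"] = X[:, 1]
        res = pca(df, variables=["frequency", "intensity"])
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        assert res.variance_pct == pytest.approx(100 * eig / eig.sum())

    def test_variances_non_increasing_and_sum_to_100(self, festuca_frame):
        res = pca(festuca_frame)
        assert np.all(np.diff(res.variance_pct) <= 1e-9)
        assert res.variance_pct.sum() == pytest.approx(100.0)

    def test_intensity_and_nonM_vectors_antagonistic(self, festuca_frame):
        res = pca(festuca_frame)
        vi = res.loadings.loc["intensity"].to_numpy()
        vn = res.loadings.loc["non_mycorrhizal"].to_numpy()
        assert float(vi @ vn) < 0

    def test_constant_variable_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        df = frame_from(rng.uniform(0, 100, 20))
        df["intensity"] = 0.3 * df["frequency"]
        with caplog.at_level("WARNING"):
            res = pca(df, variables=["frequency", "intensity", "vesicles"])
        assert "vesicles" not in res.loadings.index
        assert any("constant" in r.message for r in caplog.records)


class TestNMDS:
    def test_four_equidistant_points_near_optimal_stress(self):
        # a regular 3-simplex cannot embed in the plane; with tied
        # dissimilarities the best planar configuration is a square, whose
        # Kruskal stress-1 is sqrt(sum((d-dbar)^2)/sum(d^2)) ~= 0.1716
        df = frame_from([0.0] * 4)
        df.loc[:, ["frequency", "intensity", "arbuscules", "vesicles"]] = np.eye(4) * 10
        res = nmds(df, distance="euclidean", seed=0)
        assert 0.0 <= res.stress <= 0.18

    def test_configuration_preserves_dissimilarity_ranks(self):
        rng = np.random.default_rng(5)
        grids = random_grids(rng, 20)
        df = records_to_frame([compute_indices(g) for g in grids])
        res = nmds(df, seed=0)
        d_in = pdist(df[INDEX_COLUMNS].to_numpy(), metric="braycurtis")
        d_out = pdist(res.scores)
        rho = st_.spearmanr(d_in, d_out).statistic
        assert rho > 0.95

    def test_ordination_similar_to_pca(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        res_n = nmds(seg, seed=0)
        res_p = pca(seg)
        _, _, disparity = procrustes(res_p.scores, res_n.scores)
        assert np.sqrt(1.0 - disparity) > 0.8

    def test_degenerate_identical_data_rejected(self):
        df = frame_from([5.0] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            nmds(df)


class TestClustering:
    def test_k1_centroid_is_global_mean(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        (c,) = cluster_strategies(seg, k=1)
        assert c.share_pct == 100.0
        for col in INDEX_COLUMNS:
            assert c.centroid[col] == pytest.approx(seg[col].mean())

    def test_two_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(6)
        rows = []
        for i in range(20):
            lo = i < 10
            f = rng.normal(10 if lo else 80, 2)
            rec = {c: 0.0 for c in INDEX_COLUMNS}
            rec.update(frequency=f, intensity=f / 3, replication=1, segment=i + 1,
                       field=1, freq_class="M1")
            rows.append(rec)
        df = pd.DataFrame(rows)
        clusters = cluster_strategies(df, k=2)
        parts = [set(s for (_, s, _) in c.member_ids) for c in clusters]
        assert parts == [set(range(1, 11)), set(range(11, 21))]

    def test_partition_invariant_to_input_order(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        clusters = cluster_strategies(seg, k=9)
        rng = np.random.default_rng(8)
        shuffled = seg.sample(frac=1.0, random_state=8).reset_index(drop=True)
        clusters2 = cluster_strategies(shuffled, k=9)
        parts1 = {frozenset(c.member_ids) for c in clusters}
        parts2 = {frozenset(c.member_ids) for c in clusters2}
        assert parts1 == parts2

    def test_centroids_satisfy_complement_identity(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        for c in cluster_strategies(seg, k=9):
            assert c.centroid["non_mycorrhizal"] == pytest.approx(
                100.0 - c.centroid["intensity"]
            )
        shares = sum(c.share_pct for c in cluster_strategies(seg, k=9))
        assert shares == pytest.approx(100.0)

    def test_k_exceeding_n_rejected(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        with pytest.raises(ValueError):
            cluster_strategies(seg.head(5), k=9)


class TestStrategyReport:
    def test_single_cluster_single_map(self, festuca_grids, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        clusters = cluster_strategies(seg, k=1)
        report = strategy_report(clusters, festuca_grids)
        assert len(report.maps) == 1
        assert report.maps["C1"] is not None
        assert report.centroids.shape[0] == 1

    def test_representative_is_argmin_distance_to_centroid(self, festuca_grids,
                                                           festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        clusters = cluster_strategies(seg, k=4)
        report = strategy_report(clusters, festuca_grids)
        df = festuca_frame
        X = df[INDEX_COLUMNS].to_numpy()
        mu, sd = X.mean(0), X.std(0, ddof=1)
        for c in clusters:
            members = {tuple(m) for m in c.member_ids}
            mask = df.apply(
                lambda r: (int(r["replication"]), int(r["segment"])) in members, axis=1
            ).to_numpy()
            cz = (np.array([c.centroid[k] for k in INDEX_COLUMNS]) - mu) / sd
            Z = (X[mask] - mu) / sd
            best = np.argmin(((Z - cz) ** 2).sum(1))
            row = df.loc[mask].iloc[best]
            expected = (int(row["replication"]), int(row["segment"]), int(row["field"]))
            assert tuple(report.representatives[c.cluster_id]) == expected

    def test_cluster_without_grids_gets_placeholder(self, festuca_frame):
        seg = (festuca_frame.groupby(["replication", "segment"])[INDEX_COLUMNS]
               .mean().reset_index())
        clusters = cluster_strategies(seg, k=2)
        report = strategy_report(clusters, [])  # no grids at all
        assert all(v is None for v in report.maps.values())
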