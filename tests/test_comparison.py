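"""Tests for the cross-method comparison statistics with independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iladyn.comparison import (
    MEASURE_COLUMNS,
    bonferroni_pairwise,
    cohen_q,
    compare_measures,
    compare_networks,
    comparison_table,
    correlation_network,
    critical_r,
    dependent_correlation_wald,
    fisher_z,
    fisher_z_inv,
    health_associations,
    health_summary,
    incremental_regression,
    mean_abs_q,
    rm_anova,
    wald_dependent_correlations,
)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def test_rm_anova_identical_columns():
    x = np.tile(np.arange(10.0)[:, None], (1, 3))
    f, dfn, dfd, p = rm_anova(x)
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_rm_anova_df_for_n90_k3(rng):
    x = rng.normal(0, 1, (90, 3))
    _, dfn, dfd, _ = rm_anova(x)
    assert (dfn, dfd) == (2, 178)


def brute_force_rm_anova(x):
    """Oracle: direct sums-of-squares partition of a complete n x k matrix."""
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_err = ss_total - ss_cond - ss_subj
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return f


def test_rm_anova_matches_brute_force():
    x = np.array(
        [[3.0, 5.0, 4.0], [7.0, 9.0, 6.0], [2.0, 4.0, 5.0], [6.0, 8.0, 8.0]]
    )
    f, dfn, dfd, p = rm_anova(x)
    assert f == pytest.approx(brute_force_rm_anova(x), rel=1e-12)
    assert (dfn, dfd) == (2, 6)


def test_rm_anova_drops_incomplete_rows(rng):
    x = rng.normal(0, 1, (20, 3))
    x_missing = np.vstack([x, [[np.nan, 0.0, 0.0]]])
    assert rm_anova(x)[0] == pytest.approx(rm_anova(x_missing)[0])


def test_rm_anova_permutation_p(rng):
    # p from the F distribution should agree with a within-person label
    # permutation p on a synthetic dataset
    n = 40
    base = rng.normal(50, 10, n)
    x = np.column_stack([base + rng.normal(1.5, 4, n) * j for j in range(3)])
    f_obs, _, _, p_f = rm_anova(x)
    count = 0
    n_perm = 5000
    for _ in range(n_perm):
        perm = np.array([row[rng.permutation(3)] for row in x])
        if brute_force_rm_anova(perm) >= f_obs:
            count += 1
    p_perm = (count + 1) / (n_perm + 1)
    assert abs(p_f - p_perm) <= 0.02


# ---------------------------------------------------------------------------
# pairwise mean tests


def test_bonferroni_identical_columns(rng):
    base = rng.normal(0, 1, 20)
    df = pd.DataFrame({"a": base, "b": base, "c": base})
    results = bonferroni_pairwise(df)
    assert all(not r.significant for r in results)


def test_bonferroni_shifted_column(rng):
    base = rng.normal(50, 5, 30)
    df = pd.DataFrame({"a": base + rng.normal(0, 1, 30),
                       "b": base + rng.normal(0, 1, 30),
                       "c": base + 50})
    results = bonferroni_pairwise(df)
    by_pair = {r.pair: r for r in results}
    assert by_pair[("a", "c")].significant
    assert by_pair[("b", "c")].significant
    assert not by_pair[("a", "b")].significant
    assert by_pair[("a", "c")].direction == -1


def test_bonferroni_threshold_is_alpha_over_three(rng):
    # construct p right between alpha/3 and alpha: significant only without
    # the correction
    df = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=list("abc"))
    results = bonferroni_pairwise(df, alpha=0.05)
    for r in results:
        assert r.significant == (r.p < 0.05 / 3)


# ---------------------------------------------------------------------------
# Fisher z / Cohen q / critical r


def test_fisher_identities():
    assert fisher_z(0.0) == 0.0
    assert cohen_q(0.4, 0.4) == 0.0
    assert cohen_q(0.5, 0.2) == pytest.approx(-cohen_q(0.2, 0.5))
    assert fisher_z(0.5) == pytest.approx(0.5493061, abs=1e-6)
    assert fisher_z_inv(fisher_z(0.73)) == pytest.approx(0.73)


def test_fisher_domain():
    with pytest.raises(ValueError):
        fisher_z(1.0)


def test_critical_r_n90():
    assert round(critical_r(90, 0.05), 2) == 0.21


def test_critical_r_alpha_one_limit():
    assert critical_r(90, 0.9999) < 1e-3


def brute_force_critical_r(n, alpha):
    """Oracle: bisection on the two-sided p of the t-transformed r."""
    def pval(r):
        t = r * math.sqrt((n - 2) / (1 - r * r))
        return 2 * stats.t.sf(t, n - 2)

    lo, hi = 1e-12, 1 - 1e-12
    for _ in range(200):
        mid = (lo + hi) / 2
        if pval(mid) > alpha:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


@pytest.mark.parametrize("n", [5, 10, 30, 90, 200])
def test_critical_r_matches_numerical_inversion(n):
    assert critical_r(n, 0.05) == pytest.approx(
        brute_force_critical_r(n, 0.05), abs=1e-6
    )


# ---------------------------------------------------------------------------
# dependent-correlation Wald test


def test_wald_duplicated_columns(rng):
    base = rng.normal(0, 1, 60)
    noise = rng.normal(0, 1, 60)
    df = pd.DataFrame({"a": base + noise, "b": base + noise, "c": base + noise})
    res = wald_dependent_correlations(df)
    assert res.chi2 == pytest.approx(0.0, abs=1e-8)
    assert res.df == 2


def test_wald_detects_unequal_correlations(rng):
    n = 200
    base = rng.normal(0, 1, n)
    df = pd.DataFrame(
        {
            "a": base + 0.3 * rng.normal(0, 1, n),
            "b": base + 0.3 * rng.normal(0, 1, n),
            "c": rng.normal(0, 1, n),
        }
    )
    res = wald_dependent_correlations(df)
    assert res.p < 0.001


def test_wald_type_one_error_calibration(rng):
    # equicorrelated trivariate normal null at n=90
    rho = 0.5
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    n_reps, hits = 2000, 0
    for _ in range(n_reps):
        x = rng.standard_normal((90, 3)) @ chol.T
        res = dependent_correlation_wald(x, [(0, 1), (0, 2), (1, 2)])
        if res.p < 0.05:
            hits += 1
    rate = hits / n_reps
    assert 0.03 <= rate <= 0.07


def test_wald_delta_vs_bootstrap(rng):
    n = 90
    base = rng.normal(0, 1, n)
    df = pd.DataFrame(
        {
            "a": base + 0.8 * rng.normal(0, 1, n),
            "b": base + 1.0 * rng.normal(0, 1, n),
            "c": base + 1.6 * rng.normal(0, 1, n),
        }
    )
    delta = wald_dependent_correlations(df, method="delta")
    boot = wald_dependent_correlations(
        df, method="bootstrap", n_boot=5000, rng=np.random.default_rng(0)
    )
    assert abs(delta.p - boot.p) <= 0.03


def test_wald_needs_ten_cases(rng):
    df = pd.DataFrame(rng.normal(0, 1, (5, 3)), columns=list("abc"))
    with pytest.raises(ValueError):
        wald_dependent_correlations(df)


def test_wald_pairwise_cohen_q_consistency(rng):
    df = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
    res = wald_dependent_correlations(df)
    labels = list(res.correlations)
    for pw in res.pairwise:
        a, b = pw["pair"]
        expected = cohen_q(res.correlations[a], res.correlations[b])
        assert pw["cohen_q"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# networks


def _profiles_frame(rng, n=60, method="EMA"):
    data = rng.normal(0, 1, (n, len(MEASURE_COLUMNS)))
    df = pd.DataFrame(data, columns=MEASURE_COLUMNS)
    df.insert(0, "person_id", [f"p{i}" for i in range(n)])
    df.insert(1, "method", method)
    return df


def test_network_strength_bounds(rng):
    net = correlation_network(_profiles_frame(rng), method="EMA")
    assert (net.strengths >= 0).all()
    assert (net.strengths <= 10).all()


def test_network_null_strength_small(rng):
    net = correlation_network(_profiles_frame(rng, n=500), method="EMA")
    assert net.strengths.max() < 1.5  # 10 null correlations ~ N(0, 1/sqrt(n))


def test_network_column_order_invariant(rng):
    prof = _profiles_frame(rng)
    net_a = correlation_network(prof, method="EMA")
    shuffled = prof[list(prof.columns[:2]) + list(reversed(MEASURE_COLUMNS))]
    net_b = correlation_network(shuffled, method="EMA")
    for m in MEASURE_COLUMNS:
        assert net_a.strengths[m] == pytest.approx(net_b.strengths[m])


def test_compare_networks_identical_and_reversed(rng):
    net = correlation_network(_profiles_frame(rng), method="EMA")
    assert compare_networks(net, net) == pytest.approx(1.0)
    import copy

    rev = copy.deepcopy(net)
    rev.strengths = pd.Series(
        net.strengths.max() + net.strengths.min() - net.strengths,
        index=net.strengths.index,
    )
    assert compare_networks(net, rev) == pytest.approx(-1.0)


def test_compare_networks_matches_direct_correlation(rng):
    a = correlation_network(_profiles_frame(rng), method="EMA")
    b = correlation_network(_profiles_frame(rng), method="EOD")
    direct = np.corrcoef(a.strengths, b.strengths)[0, 1]
    assert compare_networks(a, b) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# health associations


def _health_frame(rng, person_ids, na_set=None):
    rows = []
    for i, pid in enumerate(person_ids):
        for day in range(1, 8):
            loading = 0.0 if na_set is None else na_set[i]
            rows.append(
                {
                    "person_id": pid,
                    "day_index": day,
                    "general_health": int(np.clip(round(rng.normal(3.5, 1)), 1, 5)),
                    "pain": float(np.clip(rng.normal(20 + loading, 10), 0, 100)),
                    "fatigue": float(np.clip(rng.normal(30, 10), 0, 100)),
                }
            )
    return pd.DataFrame(rows)


def _stacked_profiles(rng, n=90):
    frames = []
    for method in ("EMA", "EOD", "DRM"):
        frames.append(_profiles_frame(rng, n=n, method=method))
    return pd.concat(frames, ignore_index=True)


def test_health_associations_count_and_null(rng):
    prof = _stacked_profiles(rng)
    health = _health_frame(rng, [f"p{i}" for i in range(90)])
    assoc = health_associations(prof, health)
    assert len(assoc) == 33  # 11 measures x 3 outcomes
    sig = (assoc["wald_p"] < 0.05).mean()
    assert sig < 0.2  # null: around 5% expected
    r_cols = [c for c in assoc.columns if c.startswith("r_")]
    assert assoc[r_cols].abs().mean().mean() < 0.12


def test_health_associations_recovers_signal(rng):
    n = 120
    na_mean_true = rng.normal(0, 1, n)
    prof = _stacked_profiles(rng, n=n)
    # make na_mean the true driver under every method
    for method in ("EMA", "EOD", "DRM"):
        mask = prof["method"] == method
        prof.loc[mask, "na_mean"] = na_mean_true + rng.normal(0, 0.4, n)
    health = _health_frame(rng, [f"p{i}" for i in range(n)], na_set=30 * na_mean_true)
    assoc = health_associations(prof, health)
    row = assoc[(assoc["measure"] == "na_mean") & (assoc["outcome"] == "pain")]
    for col in ("r_EMA", "r_EOD", "r_DRM"):
        assert row[col].iloc[0] > 0.4
    pain = assoc[assoc["outcome"] == "pain"].set_index("measure")
    assert pain.loc["na_mean", "r_EMA"] == pain["r_EMA"].max()


def test_mean_abs_q_shape(rng):
    assoc = health_associations(
        _stacked_profiles(rng), _health_frame(rng, [f"p{i}" for i in range(90)])
    )
    q = mean_abs_q(assoc)
    assert set(q.index) == {"general_health", "pain", "fatigue"}
    assert (q >= 0).all().all()


# ---------------------------------------------------------------------------
# incremental regression


def test_incremental_regression_normal_equations(rng):
    # 5-person toy: coefficients must match the closed-form OLS solution
    prof = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(5)],
            "method": "EMA",
            "pa_mean": [60.0, 55.0, 70.0, 40.0, 66.0],
            "na_mean": [10.0, 20.0, 5.0, 30.0, 12.0],
            "pa_sd": [8.0, 12.0, 6.0, 15.0, 9.0],
        }
    )
    health = pd.DataFrame(
        {
            "person_id": np.repeat([f"p{i}" for i in range(5)], 2),
            "day_index": [1, 2] * 5,
            "general_health": [4, 4, 3, 3, 5, 5, 2, 2, 4, 4],
            "pain": [10.0, 12.0, 30.0, 28.0, 5.0, 7.0, 50.0, 52.0, 15.0, 13.0],
            "fatigue": [20.0] * 10,
        }
    )
    # relax the complete-case minimum by padding with 5 more persons
    extra_ids = [f"q{i}" for i in range(5)]
    prof2 = pd.concat(
        [
            prof,
            prof.assign(person_id=extra_ids, pa_sd=[7.0, 11.0, 5.5, 14.0, 10.0]),
        ],
        ignore_index=True,
    )
    health2 = pd.concat(
        [health, health.assign(person_id=np.repeat(extra_ids, 2))],
        ignore_index=True,
    )
    res = incremental_regression(prof2, health2, "pain", "pa_sd")
    summ = health_summary(health2)
    df = prof2.set_index("person_id").join(summ["pain"])
    X = np.column_stack(
        [np.ones(len(df)), df["pa_sd"], df["pa_mean"], df["na_mean"]]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ df["pain"].to_numpy())
    assert res["coef"] == pytest.approx(beta[1], rel=1e-8)


def test_incremental_regression_null_measure(rng):
    n = 150
    pa_mean = rng.normal(60, 10, n)
    na_mean = rng.normal(15, 8, n)
    measure = rng.normal(0, 1, n)
    prof = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n)],
            "method": "EMA",
            "pa_mean": pa_mean,
            "na_mean": na_mean,
            "pa_sd": measure,
        }
    )
    rows = []
    for i in range(n):
        for day in range(1, 8):
            rows.append(
                {
                    "person_id": f"p{i}",
                    "day_index": day,
                    "general_health": 3,
                    "pain": float(np.clip(na_mean[i] * 2 + rng.normal(0, 5), 0, 100)),
                    "fatigue": 30.0,
                }
            )
    res = incremental_regression(prof, pd.DataFrame(rows), "pain", "pa_sd")
    assert abs(res["coef"]) < 1.0
    assert res["p"] > 0.01


def test_incremental_regression_collinear_control(rng):
    prof = _profiles_frame(rng, n=20)
    health = _health_frame(rng, prof["person_id"])
    with pytest.raises(ValueError):
        incremental_regression(prof, health, "pain", "pa_mean")


# ---------------------------------------------------------------------------
# orchestration


def test_compare_measures_end_to_end(small_study):
    from iladyn.dynamics import compute_profiles

    ds, _, _ = small_study
    prof = compute_profiles(ds)
    results = compare_measures(prof)
    assert [r.measure for r in results] == MEASURE_COLUMNS
    table = comparison_table(results)
    assert len(table) == 11
    assert table["anova_df_num"].eq(2).all()
    assert (table["anova_df_den"] == 2 * (table["n"] - 1)).all()
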