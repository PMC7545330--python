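"""Cross-method comparison statistics.

Three analysis steps operate on the person x method table of dynamics
measures:

1. per-measure repeated-measures ANOVA with Bonferroni pairwise tests,
   cross-method correlations, and Wald tests for equality of dependent
   correlations (with Cohen q effect sizes);
2. within-method correlation networks over the 11 measures with
   node-strength centrality;
3. associations of each measure with person-level health outcomes,
   including cross-method Wald tests and incremental-validity
   regressions controlling mean PA and NA.

The dependent-correlation Wald test uses the asymptotic (Olkin-Siotani)
covariance of sample correlations sharing variables, delta-transformed
to the Fisher-z scale, with a nonparametric-bootstrap covariance as a
fallback and cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import MEASURE_COLUMNS

__all__ = [
    "MethodComparisonResult",
    "NetworkSummary",
    "WaldResult",
    "rm_anova",
    "bonferroni_pairwise",
    "fisher_z",
    "fisher_z_inv",
    "cohen_q",
    "critical_r",
    "dependent_correlation_wald",
    "wald_dependent_correlations",
    "correlation_network",
    "compare_networks",
    "health_summary",
    "health_associations",
    "incremental_regression",
    "compare_measures",
    "plot_network",
]

METHOD_ORDER = ["EMA", "EOD", "DRM"]
HEALTH_OUTCOMES = ["general_health", "pain", "fatigue"]


# ---------------------------------------------------------------------------
# step 1: mean differences and dependent correlations


def rm_anova(values: np.ndarray | pd.DataFrame) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA F test (sphericity assumed).

    ``values`` is an n x k matrix of persons by conditions; rows with any
    missing cell are dropped. Returns ``(F, df_num, df_den, p)`` with
    df = (k-1, (k-1)(n-1)).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    if ms_err <= 0:
        return 0.0, df_num, df_den, 1.0
    f = (ss_cond / df_num) / ms_err
    return float(f), df_num, df_den, float(stats.f.sf(f, df_num, df_den))


@dataclass(frozen=True)
class PairwiseMeanTest:
    pair: tuple[str, str]
    t: float
    df: int
    p: float
    significant: bool
    direction: int  # sign of mean(first) - mean(second)


def bonferroni_pairwise(
    values: pd.DataFrame, alpha: float = 0.05
) -> list[PairwiseMeanTest]:
    """Paired t-tests per column pair, significant at ``alpha / n_pairs``."""
    cols = list(values.columns)
    x = values.dropna()
    pairs = list(itertools.combinations(cols, 2))
    threshold = alpha / len(pairs)
    out = []
    for a, b in pairs:
        d = x[a].to_numpy() - x[b].to_numpy()
        if np.allclose(d, d[0]):
            t, p = 0.0, 1.0
            if np.any(d != 0):  # constant nonzero shift
                t, p = math.inf, 0.0
        else:
            res = stats.ttest_rel(x[a], x[b])
            t, p = float(res.statistic), float(res.pvalue)
        out.append(
            PairwiseMeanTest(
                pair=(a, b),
                t=t,
                df=len(d) - 1,
                p=p,
                significant=bool(p < threshold),
                direction=int(np.sign(np.mean(d))) if np.mean(d) != 0 else 0,
            )
        )
    return out


def fisher_z(r: float) -> float:
    """Fisher z-transform, ``atanh(r)``; requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def fisher_z_inv(z: float) -> float:
    """Inverse Fisher transform, ``tanh(z)``."""
    return math.tanh(float(z))


def cohen_q(r1: float, r2: float) -> float:
    """Difference of Fisher-z correlations; 0.1/0.3/0.5 = small/medium/large."""
    return fisher_z(r1) - fisher_z(r2)


def critical_r(n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Smallest |r| significant at ``alpha`` under the t-transform, df = n-2.

    Inverts ``t = r * sqrt((n - 2) / (1 - r^2))`` at the t critical value.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    df = n - 2
    t_crit = stats.t.ppf(1.0 - alpha / tails, df)
    if not np.isfinite(t_crit) or t_crit <= 0:
        return 0.0
    return float(t_crit / math.sqrt(df + t_crit**2))


def _corr_cov_element(R: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Olkin-Siotani asymptotic n*cov(r_ij, r_kl) for a correlation matrix R."""
    rij, rkl = R[i, j], R[k, l]
    rik, ril, rjk, rjl = R[i, k], R[i, l], R[j, k], R[j, l]
    return (
        0.5 * rij * rkl * (rik**2 + ril**2 + rjk**2 + rjl**2)
        + rik * rjl
        + ril * rjk
        - rij * (rjk * rjl + rik * ril)
        - rkl * (rjk * rik + rjl * ril)
    )


@dataclass
class WaldResult:
    """Omnibus equality test of dependent correlations plus follow-ups."""

    correlations: dict[str, float]
    chi2: float
    df: int
    p: float
    pairwise: list[dict] = field(default_factory=list)
    method: str = "delta"
    n: int = 0


def _corr_and_cov(
    data: np.ndarray, pairs: list[tuple[int, int]], rank: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if rank:
        data = stats.rankdata(data, axis=0)
    R = np.corrcoef(data, rowvar=False)
    n = data.shape[0]
    rs = np.array([R[i, j] for i, j in pairs])
    m = len(pairs)
    S = np.empty((m, m))
    for a, (i, j) in enumerate(pairs):
        for b, (k, l) in enumerate(pairs):
            S[a, b] = _corr_cov_element(R, i, j, k, l) / n
    d = 1.0 / (1.0 - rs**2)
    Sz = S * np.outer(d, d)
    return rs, Sz, R


def dependent_correlation_wald(
    data: pd.DataFrame | np.ndarray,
    pairs: list[tuple, ...],
    method: str = "delta",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    rank: bool = False,
) -> WaldResult:
    """Test equality of several dependent correlations on the Fisher-z scale.

    ``pairs`` names the correlations under test as column pairs of
    ``data`` (complete cases). With ``method="delta"`` the covariance of
    the z-transformed correlations comes from the asymptotic formula for
    correlations sharing variables; ``method="bootstrap"`` replaces it
    with a nonparametric bootstrap covariance. A singular delta
    covariance automatically falls back to the bootstrap.
    """
    if isinstance(data, pd.DataFrame):
        cols = list(data.columns)
        idx_pairs = [(cols.index(a), cols.index(b)) for a, b in pairs]
        labels = [f"{a}~{b}" for a, b in pairs]
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        idx_pairs = [tuple(p) for p in pairs]
        labels = [f"{i}~{j}" for i, j in idx_pairs]
    x = x[~np.isnan(x).any(axis=1)]
    n = x.shape[0]
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    rs, Sz, _ = _corr_and_cov(x, idx_pairs, rank)
    zs = np.arctanh(rs)
    m = len(idx_pairs)

    used = method
    if method == "bootstrap" or _needs_bootstrap(Sz, m):
        rng = rng or np.random.default_rng(0)
        boot = np.empty((n_boot, m))
        for b in range(n_boot):
            xb = x[rng.integers(0, n, n)]
            if rank:
                xb = stats.rankdata(xb, axis=0)
            Rb = np.corrcoef(xb, rowvar=False)
            boot[b] = [np.clip(Rb[i, j], -0.9999, 0.9999) for i, j in idx_pairs]
        Sz = np.cov(np.arctanh(boot), rowvar=False)
        used = "bootstrap"

    C = np.diff(np.eye(m), axis=0) * -1.0  # rows: e_a - e_{a+1}
    diff = C @ zs
    cov = C @ Sz @ C.T
    try:
        chi2 = float(diff @ np.linalg.solve(cov, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(cov) @ diff)
    dfree = m - 1
    p = float(stats.chi2.sf(chi2, dfree))

    pairwise = []
    for a, b in itertools.combinations(range(m), 2):
        var = Sz[a, a] + Sz[b, b] - 2 * Sz[a, b]
        zstat = (zs[a] - zs[b]) / math.sqrt(var) if var > 0 else 0.0
        pairwise.append(
            {
                "pair": (labels[a], labels[b]),
                "z": float(zstat),
                "p": float(2 * stats.norm.sf(abs(zstat))),
                "cohen_q": float(zs[a] - zs[b]),
            }
        )
    return WaldResult(
        correlations=dict(zip(labels, map(float, rs))),
        chi2=max(chi2, 0.0),
        df=dfree,
        p=p,
        pairwise=pairwise,
        method=used,
        n=n,
    )


def _needs_bootstrap(Sz: np.ndarray, m: int) -> bool:
    if not np.all(np.isfinite(Sz)):
        return True
    eig = np.linalg.eigvalsh(Sz)
    return bool(eig.min() <= 0 or eig.min() / eig.max() < 1e-10)


def wald_dependent_correlations(
    measure_by_method: pd.DataFrame, **kwargs
) -> WaldResult:
    """Equality test of the 3 cross-method correlations of one measure.

    ``measure_by_method`` has one column per method (same measure).
    """
    cols = list(measure_by_method.columns)
    pairs = list(itertools.combinations(cols, 2))
    return dependent_correlation_wald(measure_by_method, pairs, **kwargs)


# ---------------------------------------------------------------------------
# step 2: correlation networks


@dataclass
class NetworkSummary:
    """Correlation matrix over measures with node-strength centrality."""

    method: str
    matrix: pd.DataFrame
    strengths: pd.Series
    threshold: float
    n: int
    degenerate_nodes: list[str] = field(default_factory=list)


def correlation_network(
    profiles_one_method: pd.DataFrame,
    method: str = "",
    measures: list[str] | None = None,
    alpha: float = 0.05,
    rank: bool = False,
) -> NetworkSummary:
    """Pairwise-complete correlation network with node strengths.

    Node strength is the sum of a measure's absolute correlations with
    all other measures; zero-variance measures are flagged and their
    strengths computed over available entries.
    """
    measures = measures or MEASURE_COLUMNS
    df = profiles_one_method[measures]
    if len(df) < 4:
        raise ValueError("need at least 4 persons")
    corr = df.corr(method="spearman" if rank else "pearson", min_periods=4)
    np.fill_diagonal(corr.values, 1.0)
    degenerate = [c for c in measures if df[c].std(skipna=True) == 0 or df[c].count() < 4]
    off = corr.where(~np.eye(len(measures), dtype=bool))
    strengths = off.abs().sum(axis=1, skipna=True)
    n = int(df.dropna(how="any").shape[0]) or int(df.count().min())
    return NetworkSummary(
        method=method,
        matrix=corr,
        strengths=strengths,
        threshold=critical_r(max(int(df.count().min()), 4), alpha),
        n=n,
        degenerate_nodes=degenerate,
    )


def compare_networks(a: NetworkSummary, b: NetworkSummary, rank: bool = False) -> float:
    """Correlation between the two networks' node-strength vectors."""
    sa, sb = a.strengths.align(b.strengths, join="inner")
    if rank:
        return float(stats.spearmanr(sa, sb).statistic)
    return float(np.corrcoef(sa, sb)[0, 1])


def plot_network(summary: NetworkSummary, path) -> None:
    """Minimal network plot (edges above the display threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    g = nx.Graph()
    nodes = list(summary.matrix.columns)
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            r = summary.matrix.loc[a, b]
            if np.isfinite(r) and abs(r) > summary.threshold:
                g.add_edge(a, b, weight=abs(r), sign=np.sign(r))
    pos = nx.circular_layout(g)
    fig, ax = plt.subplots(figsize=(7, 7))
    colors = ["green" if g.edges[e]["sign"] > 0 else "red" for e in g.edges]
    widths = [4 * g.edges[e]["weight"] for e in g.edges]
    nx.draw_networkx(g, pos, ax=ax, edge_color=colors, width=widths, node_color="#ddddee")
    ax.set_title(f"{summary.method} (|r| > {summary.threshold:.2f})")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# step 3: health associations


def health_summary(health: pd.DataFrame) -> pd.DataFrame:
    """Per-person means of the daily outcomes over available days.

    General health is coded 1 = poor ... 5 = excellent (larger = better).
    """
    g = health.groupby("person_id")[HEALTH_OUTCOMES].mean()
    g["n_days"] = health.groupby("person_id").size()
    return g


def _pivot(profiles: pd.DataFrame, measure: str) -> pd.DataFrame:
    wide = profiles.pivot(index="person_id", columns="method", values=measure)
    return wide[[m for m in METHOD_ORDER if m in wide.columns]]


def _corr(x: pd.Series, y: pd.Series, rank: bool) -> float:
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        return math.nan
    if rank:
        return float(stats.spearmanr(x[ok], y[ok]).statistic)
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def health_associations(
    profiles: pd.DataFrame,
    health: pd.DataFrame,
    rank: bool = False,
) -> pd.DataFrame:
    """Correlate every measure with every outcome per method; Wald per row.

    Returns one row per (measure, outcome) with per-method correlations,
    the cross-method Wald test, and Cohen q per method pair.
    """
    summ = health_summary(health)
    rows = []
    for measure in MEASURE_COLUMNS:
        wide = _pivot(profiles, measure)
        joined = wide.join(summ, how="inner")
        for outcome in HEALTH_OUTCOMES:
            cols = list(wide.columns)
            data = joined[cols + [outcome]].dropna()
            pairs = [(c, outcome) for c in cols]
            wald = dependent_correlation_wald(data, pairs, rank=rank)
            rec = {"measure": measure, "outcome": outcome}
            for c in cols:
                rec[f"r_{c}"] = wald.correlations[f"{c}~{outcome}"]
            rec.update(
                {
                    "wald_chi2": wald.chi2,
                    "wald_df": wald.df,
                    "wald_p": wald.p,
                    "n": wald.n,
                }
            )
            for pw in wald.pairwise:
                a = pw["pair"][0].split("~")[0]
                b = pw["pair"][1].split("~")[0]
                rec[f"q_{a}_{b}"] = pw["cohen_q"]
            rows.append(rec)
    return pd.DataFrame(rows)


def mean_abs_q(health_assoc: pd.DataFrame) -> pd.DataFrame:
    """Mean |Cohen q| per outcome per method pair (Figure-3 style summary)."""
    qcols = [c for c in health_assoc.columns if c.startswith("q_")]
    out = health_assoc.groupby("outcome")[qcols].agg(lambda s: s.abs().mean())
    return out


def incremental_regression(
    profiles_one_method: pd.DataFrame,
    health: pd.DataFrame,
    outcome: str,
    measure: str,
    controls: tuple[str, str] = ("pa_mean", "na_mean"),
) -> dict:
    """OLS of an outcome on one measure controlling mean PA and NA levels.

    Returns the measure's partial coefficient and p-value (plus the full
    coefficient table). Raises on collinearity with the controls.
    """
    import statsmodels.api as sm

    if measure in controls:
        raise ValueError(f"measure {measure!r} is one of the controls")
    summ = health_summary(health)
    df = (
        profiles_one_method.set_index("person_id")[[measure, *controls]]
        .join(summ[[outcome]], how="inner")
        .dropna()
    )
    if len(df) < 10:
        raise ValueError("need at least 10 complete cases")
    X = df[[measure, *controls]]
    for c in controls:
        r = np.corrcoef(X[measure], X[c])[0, 1]
        if abs(r) > 0.999:
            raise ValueError(f"measure {measure!r} collinear with control {c!r}")
    res = sm.OLS(df[outcome], sm.add_constant(X)).fit()
    return {
        "outcome": outcome,
        "measure": measure,
        "coef": float(res.params[measure]),
        "p": float(res.pvalues[measure]),
        "n": int(len(df)),
        "params": res.params.to_dict(),
        "pvalues": res.pvalues.to_dict(),
    }


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class MethodComparisonResult:
    """Per-measure cross-method comparison record (Tables 2-3 analogue)."""

    measure: str
    means: dict[str, float]
    sds: dict[str, float]
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    pairwise_means: list[PairwiseMeanTest]
    correlations: dict[str, float]
    wald: WaldResult
    n: int


def compare_measures(
    profiles: pd.DataFrame, alpha: float = 0.05, rank: bool = False
) -> list[MethodComparisonResult]:
    """Step-1 analysis for every measure."""
    out = []
    for measure in MEASURE_COLUMNS:
        wide = _pivot(profiles, measure).dropna()
        f, dfn, dfd, p = rm_anova(wide)
        pw = bonferroni_pairwise(wide, alpha=alpha)
        wald = wald_dependent_correlations(wide, rank=rank)
        out.append(
            MethodComparisonResult(
                measure=measure,
                means={c: float(wide[c].mean()) for c in wide.columns},
                sds={c: float(wide[c].std(ddof=1)) for c in wide.columns},
                anova_f=f,
                anova_df=(dfn, dfd),
                anova_p=p,
                pairwise_means=pw,
                correlations=wald.correlations,
                wald=wald,
                n=len(wide),
            )
        )
    return out


def comparison_table(results: list[MethodComparisonResult]) -> pd.DataFrame:
    """Flatten step-1 results into one row per measure."""
    rows = []
    for r in results:
        rec = {"measure": r.measure, "n": r.n}
        for m, v in r.means.items():
            rec[f"mean_{m}"] = v
        for m, v in r.sds.items():
            rec[f"sd_{m}"] = v
        rec.update(
            {
                "anova_f": r.anova_f,
                "anova_df_num": r.anova_df[0],
                "anova_df_den": r.anova_df[1],
                "anova_p": r.anova_p,
            }
        )
        for t in r.pairwise_means:
            key = f"{t.pair[0]}_{t.pair[1]}"
            rec[f"meandiff_sig_{key}"] = t.significant
        for label, v in r.correlations.items():
            rec[f"r_{label.replace('~', '_')}"] = v
        rec.update(
            {"wald_chi2": r.wald.chi2, "wald_df": r.wald.df, "wald_p": r.wald.p}
        )
        for pw in r.wald.pairwise:
            a = pw["pair"][0].replace("~", "")
            b = pw["pair"][1].replace("~", "")
            rec[f"q_{a}_vs_{b}"] = pw["cohen_q"]
        rows.append(rec)
    return pd.DataFrame(rows)
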