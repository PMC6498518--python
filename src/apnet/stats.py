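"""Group inference: Welch sweeps, permutation edge tests, regressions.

The density-sweep comparison runs a Welch two-sample t test per
(metric, band, condition, density) cell.  Because graph metrics at
neighboring densities are strongly dependent (nested networks), multiple
comparisons are handled with a successive-threshold rule: a cell only
counts as significant when an adjacent density in the same
metric x band x condition strip is significant too, and each surviving run
is summarized by its representative density — the cell with the largest
absolute Cohen's d.

Edge-level group differences use permutation tests (group-label shuffles,
add-one p-value estimator, two-sided) with Benjamini-Hochberg FDR across
the n(n-1)/2 unique edges, optionally after z-standardizing each subject's
matrix over its unique off-diagonal entries.

Regression support: OLS with R^2, adjusted R^2, F, AIC; model ranking by
AIC; percentile-bootstrap mediation over the product of coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from apnet.spectral_connectivity import ConnectivityMatrix

__all__ = [
    "GroupComparisonCell",
    "SweepResult",
    "PermutationEdgeResult",
    "RegressionResult",
    "MediationResult",
    "welch_t",
    "welch_t_from_stats",
    "cohens_d",
    "cohens_d_from_stats",
    "sweep_group_tests",
    "zscore_matrix",
    "permutation_edge_test",
    "bh_fdr",
    "ols_regression",
    "compare_models",
    "mediation",
    "pearson_corr_table",
]


@dataclass(frozen=True)
class GroupComparisonCell:
    metric: str
    band: str
    condition: str
    density: float
    t: float
    df: float
    p: float
    d: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.t))


@dataclass
class SweepResult:
    """Welch-test grid with the successive-threshold significance mask."""

    cells: pd.DataFrame  # columns: metric band condition density t df p d
    alpha: float
    mask: pd.Series  # boolean, aligned with cells
    secondary_mask: pd.Series  # same rule at the marginal alpha (default 0.10)
    representatives: pd.DataFrame  # one row per surviving run

    def surviving(self) -> pd.DataFrame:
        return self.cells[self.mask.values]


@dataclass
class PermutationEdgeResult:
    observed_diff: np.ndarray
    d: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    n_perm: int
    q: float
    standardized: bool
    channel_labels: tuple[str, ...] = ()
    seed: int | None = None


@dataclass
class RegressionResult:
    name: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    fvalue: float
    df_model: int
    df_resid: int
    aic: float
    n: int


@dataclass
class MediationResult:
    a: float
    b: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"sample {name} needs at least 2 values")
    if np.var(x, ddof=1) == 0:
        raise ValueError(f"sample {name} has zero variance")
    return x


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Welch-Satterthwaite df, two-sided p)."""
    x = _check_sample(np.asarray(x), "x")
    y = _check_sample(np.asarray(y), "y")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t test from group summary statistics (means, SDs, sizes)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    se1, se2 = sd1**2 / n1, sd2**2 / n2
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled SD ((n-1)-weighted)."""
    x = _check_sample(np.asarray(x), "x")
    y = _check_sample(np.asarray(y), "y")
    return cohens_d_from_stats(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def cohens_d_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((mean1 - mean2) / pooled)


def sweep_group_tests(
    metrics: pd.DataFrame,
    group_col: str = "group",
    groups: tuple[str, str] = ("AP", "RP"),
    value_cols: Sequence[str] = ("C", "L", "sigma"),
    alpha: float = 0.05,
    alpha_secondary: float = 0.10,
) -> SweepResult:
    """Welch-test sweep over (metric, band, condition, density) cells.

    ``metrics`` holds one row per subject x band x condition x density with
    the metric values in ``value_cols``.  The significance mask keeps cells
    with p < alpha whose adjacent density in the same strip is also
    significant; the representative density of each surviving run is the
    max-|d| cell.  A secondary mask applies the same rule at the marginal
    level (default 0.10).
    """
    required = {group_col, "band", "condition", "density"}
    if not required <= set(metrics.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    g1_all = metrics[metrics[group_col] == groups[0]]
    g2_all = metrics[metrics[group_col] == groups[1]]
    if g1_all.empty or g2_all.empty:
        raise ValueError(f"both groups {groups} must be present")
    # Common density grid check per band x condition.
    rows = []
    for (band, cond), sub in metrics.groupby(["band", "condition"], sort=True):
        d1 = np.sort(sub[sub[group_col] == groups[0]]["density"].unique())
        d2 = np.sort(sub[sub[group_col] == groups[1]]["density"].unique())
        if not np.array_equal(d1, d2):
            raise ValueError(
                f"density grids differ between groups in {band}/{cond}"
            )
        for dens in d1:
            cell = sub[sub["density"] == dens]
            for metric in value_cols:
                x = cell[cell[group_col] == groups[0]][metric].to_numpy(float)
                y = cell[cell[group_col] == groups[1]][metric].to_numpy(float)
                try:
                    t, df, p = welch_t(x, y)
                    d = cohens_d(x, y)
                except ValueError:
                    # Degenerate cell (e.g. clustering identically 0 on the
                    # MST-clamped density): no evidence either way.
                    t, df, p, d = float("nan"), float("nan"), 1.0, 0.0
                rows.append(
                    dict(
                        metric=metric, band=band, condition=cond,
                        density=float(dens), t=t, df=df, p=p, d=d,
                    )
                )
    cells = pd.DataFrame(rows)
    mask = _successive_mask(cells, alpha)
    secondary = _successive_mask(cells, alpha_secondary)
    reps = _representatives(cells, mask)
    return SweepResult(
        cells=cells,
        alpha=alpha,
        mask=mask,
        secondary_mask=secondary,
        representatives=reps,
    )


def _successive_mask(cells: pd.DataFrame, alpha: float) -> pd.Series:
    mask = pd.Series(False, index=cells.index)
    for _, strip in cells.groupby(["metric", "band", "condition"], sort=False):
        strip = strip.sort_values("density")
        sig = (strip["p"] < alpha).to_numpy()
        keep = np.zeros_like(sig)
        for i in range(len(sig)):
            if sig[i] and (
                (i > 0 and sig[i - 1]) or (i < len(sig) - 1 and sig[i + 1])
            ):
                keep[i] = True
        mask.loc[strip.index] = keep
    return mask


def _representatives(cells: pd.DataFrame, mask: pd.Series) -> pd.DataFrame:
    """Max-|d| cell of each contiguous surviving run."""
    reps = []
    kept = cells[mask.values]
    for (metric, band, cond), strip in kept.groupby(
        ["metric", "band", "condition"], sort=False
    ):
        strip = strip.sort_values("density").reset_index(drop=True)
        # split into contiguous runs by position in the full density grid
        grid = np.sort(
            cells[
                (cells["metric"] == metric)
                & (cells["band"] == band)
                & (cells["condition"] == cond)
            ]["density"].unique()
        )
        pos = {d: i for i, d in enumerate(grid)}
        run: list[int] = []
        prev = None
        for idx, row in strip.iterrows():
            p = pos[row["density"]]
            if prev is not None and p != prev + 1:
                reps.append(strip.loc[run].loc[strip.loc[run, "d"].abs().idxmax()])
                run = []
            run.append(idx)
            prev = p
        if run:
            reps.append(strip.loc[run].loc[strip.loc[run, "d"].abs().idxmax()])
    if not reps:
        return pd.DataFrame(columns=cells.columns)
    return pd.DataFrame(reps).reset_index(drop=True)


def zscore_matrix(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Z-standardize a symmetric matrix over its unique off-diagonal entries."""
    w = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    n = w.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = w[iu]
    sd = vals.std(ddof=1)
    if sd == 0 or np.unique(vals).size < 2:
        raise ValueError("matrix has no off-diagonal variance")
    z = (vals - vals.mean()) / sd
    out = np.zeros_like(w, dtype=float)
    out[iu] = z
    out = out + out.T
    return out


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def permutation_edge_test(
    matrices_g1: Sequence[np.ndarray | ConnectivityMatrix],
    matrices_g2: Sequence[np.ndarray | ConnectivityMatrix],
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int = 0,
    standardized: bool = False,
) -> PermutationEdgeResult:
    """Edge-wise permutation test between two groups of connectivity matrices.

    Observed statistic per edge: group mean difference (g1 - g2).  Null
    distribution: group-label permutations, the same shuffle applied to all
    edges; two-sided add-one p-values, then a BH-FDR mask at level q.  With
    ``standardized=True`` each subject's matrix is z-scored over its unique
    off-diagonal entries first.
    """

    def to_array(m):
        w = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, float)
        return zscore_matrix(w) if standardized else w

    labels: tuple[str, ...] = ()
    if matrices_g1 and isinstance(matrices_g1[0], ConnectivityMatrix):
        labels = matrices_g1[0].channel_labels
    g1 = [to_array(m) for m in matrices_g1]
    g2 = [to_array(m) for m in matrices_g2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = g1[0].shape[0]
    iu = np.triu_indices(n, k=1)
    X = np.array([m[iu] for m in g1 + g2])  # (m_total, n_edges)
    m1, m2 = len(g1), len(g2)
    m_total = m1 + m2
    obs = X[:m1].mean(axis=0) - X[m1:].mean(axis=0)
    rng = np.random.default_rng(seed)
    # All permutations at once: row-shuffled index matrix.
    idx = np.argsort(rng.random((n_perm, m_total)), axis=1)
    sums1 = X[idx[:, :m1]].sum(axis=1)  # (n_perm, n_edges)
    total = X.sum(axis=0)
    perm_diff = sums1 / m1 - (total - sums1) / m2
    exceed = (np.abs(perm_diff) >= np.abs(obs)[None, :]).sum(axis=0)
    p_edge = (exceed + 1) / (n_perm + 1)
    mask_edge = bh_fdr(p_edge, q)
    # Cohen's d per edge.
    x1, x2 = X[:m1], X[m1:]
    pooled = np.sqrt(
        ((m1 - 1) * x1.var(axis=0, ddof=1) + (m2 - 1) * x2.var(axis=0, ddof=1))
        / (m_total - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d_edge = np.where(pooled > 0, obs / np.where(pooled > 0, pooled, 1.0), 0.0)

    def square(v, dtype=float):
        out = np.zeros((n, n), dtype=dtype)
        out[iu] = v
        return out + out.T

    return PermutationEdgeResult(
        observed_diff=square(obs),
        d=square(d_edge),
        p=square(p_edge) + np.eye(n),  # diagonal p = 1 by convention
        fdr_mask=square(mask_edge, dtype=bool),
        n_perm=n_perm,
        q=q,
        standardized=standardized,
        channel_labels=labels,
        seed=seed,
    )


def ols_regression(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    name: str = "model",
) -> RegressionResult:
    """OLS with intercept: coefficients, R^2, adjusted R^2, F, AIC.

    AIC follows the Gaussian-likelihood convention used by statsmodels,
    -2*loglik + 2*(p+1); rankings between models on the same data are
    invariant to the additive constant.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X)
    if len(y) != len(X):
        raise ValueError("y and X must have the same length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError("predictor matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        name=name,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        fvalue=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        aic=float(fit.aic),
        n=int(fit.nobs),
    )


def compare_models(fits: Sequence[RegressionResult]) -> pd.DataFrame:
    """Rank models by AIC ascending; ties by adjusted R^2 descending."""
    if len({f.n for f in fits}) > 1:
        raise ValueError("models must be fit on the same number of observations")
    rows = [
        dict(
            name=f.name, aic=f.aic, r2=f.r2, r2_adj=f.r2_adj,
            fvalue=f.fvalue, df_model=f.df_model, df_resid=f.df_resid,
        )
        for f in fits
    ]
    table = pd.DataFrame(rows)
    table["_neg_adj"] = -table["r2_adj"]
    table = (
        table.sort_values(["aic", "_neg_adj"], kind="stable")
        .drop(columns="_neg_adj")
        .reset_index(drop=True)
    )
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table


def mediation(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    ci: float = 0.95,
) -> MediationResult:
    """Percentile-bootstrap mediation (product of coefficients a*b).

    a = slope of m ~ x; b = coefficient of m in y ~ x + m; the indirect
    effect a*b is bootstrapped by case resampling.  The effect is
    "significant" when the percentile CI excludes zero.
    """
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must have equal length")
    if len(x) < 10:
        raise ValueError("mediation needs at least 10 cases")
    for name, v in (("x", x), ("m", m), ("y", y)):
        if np.var(v) == 0:
            raise ValueError(f"{name} has zero variance")

    def indirect(xi, mi, yi) -> float:
        Xa = np.column_stack([np.ones_like(xi), xi])
        a = np.linalg.lstsq(Xa, mi, rcond=None)[0][1]
        Xb = np.column_stack([np.ones_like(xi), xi, mi])
        b = np.linalg.lstsq(Xb, yi, rcond=None)[0][2]
        return a, b

    a, b = indirect(x, m, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            ab, bb = indirect(x[idx], m[idx], y[idx])
            boots[i] = ab * bb
        except np.linalg.LinAlgError:  # degenerate resample
            boots[i] = np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return MediationResult(
        a=float(a), b=float(b), indirect=float(a * b),
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed,
    )


def pearson_corr_table(
    scores: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the numeric columns."""
    cols = list(columns) if columns is not None else list(scores.columns)
    data = scores[cols].astype(float)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = data[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete cases for {cols[i]} vs {cols[j]}"
                )
            for name in (cols[i], cols[j]):
                if pair[name].nunique() < 2:
                    raise ValueError(f"column {name!r} is constant")
            res = sps.pearsonr(pair[cols[i]], pair[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.pvalue
    return r, p
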