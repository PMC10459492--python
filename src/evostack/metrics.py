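"""Goodness-of-fit metrics and rank-based model comparison.

Variance accounted for (VAF) is the headline metric:

    VAF = 100 * (1 - var(y - yhat) / var(y))

with the sample variance (divisor n-1) in both terms: 100 means a perfect
fit, 0 no better than the output mean, and negative values are possible.
VAF is blind to a constant offset in the prediction. RMSE is the usual root
mean squared residual.

Model comparison across participants uses the Friedman omnibus test
(within-participant ranks, average ranks on ties, chi-squared reference
with k-1 degrees of freedom) followed by the Nemenyi critical difference

    CD = (q_{inf,k,alpha} / sqrt(2)) * sqrt(k (k+1) / (6 n))

with the studentized-range quantile taken from a bundled table
(k = 2..20, alpha in {0.05, 0.10}).

Table summaries use the population standard deviation (divisor n), which
is the convention the packaged literature result tables follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "vaf",
    "rmse",
    "summarize",
    "relative_improvement",
    "FriedmanResult",
    "friedman_test",
    "nemenyi_cd",
    "NemenyiResult",
    "nemenyi_test",
    "residual_whiteness",
    "make_metrics_table",
]


def vaf(y, yhat) -> float:
    """Variance accounted for, in percent."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must have equal length >= 2")
    vy = np.var(y, ddof=1)
    if vy == 0:
        raise ValueError("VAF undefined for a constant output")
    return float(100.0 * (1.0 - np.var(y - yhat, ddof=1) / vy))


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("y and yhat must have equal, positive length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def make_metrics_table(records) -> pd.DataFrame:
    """Long-format table with one row per (participant, model, horizon)."""
    df = pd.DataFrame(records, columns=["participant", "model", "horizon", "vaf", "rmse"])
    if df.duplicated(["participant", "model", "horizon"]).any():
        raise ValueError("duplicate (participant, model, horizon) record")
    return df


def summarize(table: pd.DataFrame, model: str, horizon: int,
              metric: str = "vaf") -> tuple[float, float]:
    """(mean, population std) of one model/horizon column of the table."""
    sel = table[(table["model"] == model) & (table["horizon"] == horizon)][metric]
    vals = sel.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError(f"no records for model={model!r}, horizon={horizon}")
    return float(vals.mean()), float(vals.std(ddof=0))


def relative_improvement(mean_a: float, mean_b: float) -> float:
    """Percent improvement of a over the baseline b: 100 (a - b) / b."""
    if mean_b == 0:
        raise ValueError("zero baseline")
    return 100.0 * (mean_a - mean_b) / mean_b


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    ranks: np.ndarray       # blocks x treatments, rank 1 = best
    mean_ranks: pd.Series


def friedman_test(values, better: str = "higher") -> FriedmanResult:
    """Friedman rank test across k >= 3 related treatments in n >= 2 blocks.

    ``values`` is an (n, k) array or DataFrame (blocks = rows). Ties get
    average ranks; the statistic is the mean-rank form
    ``12 n / (k (k+1)) * (sum R_j^2 - k (k+1)^2 / 4)``.
    """
    if isinstance(values, pd.DataFrame):
        M = values.to_numpy(dtype=float)
        names = list(values.columns)
    else:
        M = np.asarray(values, dtype=float)
        names = [f"m{j+1}" for j in range(M.shape[1])]
    n, k = M.shape
    if k < 3:
        raise ValueError("the Friedman test needs at least 3 treatments")
    if n < 2:
        raise ValueError("the Friedman test needs at least 2 blocks")
    signed = -M if better == "higher" else M
    ranks = np.apply_along_axis(sps.rankdata, 1, signed)
    rbar = ranks.mean(axis=0)
    fd = 12.0 * n / (k * (k + 1)) * (np.sum(rbar**2) - k * (k + 1) ** 2 / 4.0)
    p = float(sps.chi2.sf(fd, k - 1))
    return FriedmanResult(float(fd), k - 1, p, ranks, pd.Series(rbar, index=names))


def _q_table() -> pd.DataFrame:
    path = resources.files("evostack.data").joinpath("studentized_range_qinf.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference on the mean-rank scale."""
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 treatments and n >= 1 blocks")
    tab = _q_table()
    row = tab[(tab["k"] == k) & (np.isclose(tab["alpha"], alpha))]
    if row.empty:
        raise ValueError(
            f"no bundled studentized-range quantile for k={k}, alpha={alpha}; "
            "supported: k in 2..20, alpha in {0.05, 0.10}"
        )
    q = float(row["q"].iloc[0])
    return (q / np.sqrt(2.0)) * np.sqrt(k * (k + 1) / (6.0 * n))


@dataclass
class NemenyiResult:
    cd: float
    mean_ranks: pd.Series
    significant: pd.DataFrame  # pairwise |mean rank difference| > CD


def nemenyi_test(values, alpha: float = 0.05, better: str = "higher") -> NemenyiResult:
    """Post hoc pairwise comparison after a Friedman rejection."""
    fr = friedman_test(values, better=better)
    n = fr.ranks.shape[0]
    k = fr.ranks.shape[1]
    cd = nemenyi_cd(k, n, alpha)
    r = fr.mean_ranks.to_numpy()
    diff = np.abs(r[:, None] - r[None, :])
    sig = pd.DataFrame(diff > cd, index=fr.mean_ranks.index, columns=fr.mean_ranks.index)
    return NemenyiResult(cd, fr.mean_ranks, sig)


def residual_whiteness(residuals) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov check of standardized residuals
    against the standard normal; returns (K statistic, p-value)."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 10:
        raise ValueError("need at least 10 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate residuals (zero variance)")
    z = (r - r.mean()) / sd
    res = sps.kstest(z, "norm")
    return float(res.statistic), float(res.pvalue)
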