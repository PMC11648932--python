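"""Negative-binomial two-group differential expression (Wald test).

The model per feature i and library j is

    c_ij ~ NB(mu_ij, alpha_i),    var = mu + alpha * mu^2
    log mu_ij = log s_j + beta_{g(j)}

with median-of-ratios size factors s_j, per-feature dispersion alpha_i
estimated by method of moments and shrunk in log space toward a fitted
mean-dispersion trend, and a saturated two-group design.  Because the
design is saturated, the GLM maximum likelihood decomposes into two
independent one-dimensional problems (one beta per group), each solved by
Newton iteration; the Wald statistic uses the expected Fisher information
I(beta_g) = sum_j mu_ij / (1 + alpha_i * mu_ij).  log2FC is reported on the
log2 scale with its standard error, a two-sided normal p-value, and a
Benjamini-Hochberg adjusted p-value.  No fold-change shrinkage is applied.

The model/results surface follows the statsmodels convention:
``NBDEModel(counts, stage=...).fit()`` returns :class:`NBDEResults` whose
``table`` holds the per-feature estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MUTANT, WT, CountMatrix

DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Uses features with nonzero counts in every library; if none exist,
    ``pseudo_reference=True`` falls back to a positive-counts geometric mean
    reference (each library's ratios taken over its own positive features).
    """
    arr = counts.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        sub = arr[all_pos]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        log_sf = np.median(np.log(sub) - log_geo, axis=0)
    elif pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(arr), np.nan)
        log_geo = np.nanmean(logs, axis=1, keepdims=True)
        ratios = logs - log_geo
        log_sf = np.nanmedian(ratios, axis=0)
        if np.isnan(log_sf).any():
            raise ValueError("size factors undefined even with pseudo-reference")
    else:
        raise ValueError(
            "no feature with nonzero counts in all libraries; "
            "set pseudo_reference=True to use the positive-counts fallback"
        )
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns)


def estimate_dispersion(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    floor: float = DISPERSION_FLOOR,
    trend_weight: float = 0.5,
) -> pd.Series:
    """Per-feature NB dispersion: method of moments + trend shrinkage.

    Raw estimate alpha_i = (var - mean) / mean^2 from pooled within-group
    moments of normalized counts; a gamma-style trend a0 + a1/mean is fitted
    by least squares over the unclipped raw estimates, and the final
    dispersion is the log-space weighted average (``trend_weight`` on the
    trend) of the trend and the raw estimate clamped from below at the
    trend.  The clamp makes the shrinkage one-sided: with few residual
    degrees of freedom a moment estimate *below* the trend is mostly
    sampling noise (it is frequently negative even at substantial true
    dispersion) and carries no usable evidence, whereas estimates above the
    trend do flag genuinely noisy features and are retained, damped.
    """
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need two groups")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ValueError(f"group {lev!r} has a single replicate; dispersion inestimable")
    q = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    ss = np.zeros(q.shape[0])
    df = 0
    for lev in levels:
        idx = np.asarray(groups == lev)
        sub = q[:, idx]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += idx.sum() - 1
    var = ss / df
    mean = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mean) / mean**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.clip(raw, -50.0, 50.0)

    ok = mean > 0
    if ok.sum() >= 3:
        m = mean[ok]
        X = np.column_stack([np.ones_like(m), 1.0 / m])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        coef = np.clip(coef, 0.0, None)
        trend = coef[0] + coef[1] / np.where(ok, mean, np.inf)
    else:
        trend = np.full_like(raw, max(np.median(raw), floor))
    trend = np.clip(trend, floor, 50.0)
    clamped = np.clip(raw, trend, 50.0)
    final = np.exp(
        (1.0 - trend_weight) * np.log(clamped) + trend_weight * np.log(trend)
    )
    return pd.Series(np.clip(final, floor, None), index=counts.index)


def _group_mle(
    c: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised 1-D Newton solve of the per-group NB log-link MLE.

    Returns (beta_hat, fisher_information) per feature.  Features whose
    group total is zero come back with beta = -inf and information 0.
    """
    total = c.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(np.maximum(total, 1e-10) / s.sum())
    for _ in range(n_iter):
        mu = s[None, :] * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((c - mu) / denom).sum(axis=1)
        hess = -(mu * (1.0 + alpha[:, None] * c) / denom**2).sum(axis=1)
        step = np.where(hess < 0, score / hess, 0.0)
        step = np.clip(step, -5.0, 5.0)  # damp early oscillations
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = s[None, :] * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    beta = np.where(total > 0, beta, -np.inf)
    info = np.where(total > 0, info, 0.0)
    return beta, info


def nb_wald_test(
    counts: pd.DataFrame,
    sf: pd.Series,
    disp: pd.Series,
    groups: pd.Series,
    reference: str = WT,
) -> pd.DataFrame:
    """Wald test of the group effect; log2FC is treatment vs reference.

    Features with zero counts everywhere get status ``all-zero``; features
    with a zero total in one group get status ``low-count`` (the MLE is at
    the boundary and the Wald statistic is undefined).  Everything else is
    ``tested``.
    """
    levels = [lev for lev in dict.fromkeys(groups)]
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not in design")
    treat = next(lev for lev in levels if lev != reference)
    g = np.asarray(groups)
    ref_idx, trt_idx = g == reference, g == treat
    if not ref_idx.any() or not trt_idx.any():
        raise ValueError("degenerate design: one group is empty")

    c = counts.to_numpy(dtype=float)
    s = sf.to_numpy(dtype=float)
    alpha = disp.reindex(counts.index).to_numpy(dtype=float)
    b0, i0 = _group_mle(c[:, ref_idx], s[ref_idx], alpha)
    b1, i1 = _group_mle(c[:, trt_idx], s[trt_idx], alpha)

    base_mean = (c / s[None, :]).mean(axis=1)
    all_zero = c.sum(axis=1) == 0
    low_count = (~all_zero) & ((c[:, ref_idx].sum(axis=1) == 0) | (c[:, trt_idx].sum(axis=1) == 0))
    tested = ~(all_zero | low_count)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = (b1 - b0) / _LN2
        se = np.sqrt(1.0 / i1 + 1.0 / i0) / _LN2
        z = (b1 - b0) / (se * _LN2)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": np.where(tested, log2fc, np.nan),
            "se": np.where(tested, se, np.nan),
            "pvalue": np.where(tested, p, np.nan),
            "status": np.where(
                all_zero, "all-zero", np.where(low_count, "low-count", "tested")
            ),
        },
        index=counts.index,
    )
    padj = np.full(len(table), np.nan)
    mask = tested
    if mask.any():
        padj[mask] = bh_adjust(table.loc[mask, "pvalue"].to_numpy())
    table["padj"] = padj
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Model / Results surface


class NBDEModel:
    """Two-group NB differential-expression model over a CountMatrix.

    Parameters
    ----------
    counts
        CountMatrix (or plain DataFrame, with ``groups`` given explicitly).
    stage
        Restrict a multi-stage CountMatrix to one stage before fitting.
    groups
        Per-library group labels; defaults to the genotype column of the
        CountMatrix metadata.
    reference
        The baseline group (fold changes are treatment over reference).
    """

    def __init__(
        self,
        counts: CountMatrix | pd.DataFrame,
        stage: str | None = None,
        groups: pd.Series | None = None,
        reference: str = WT,
    ):
        if isinstance(counts, CountMatrix):
            if stage is not None:
                counts = counts.subset_libraries(counts.libraries(stage=stage))
            self.counts = counts.counts
            self.groups = counts.meta["genotype"] if groups is None else groups
        else:
            if groups is None:
                raise ValueError("groups required with a plain DataFrame")
            self.counts = counts
            self.groups = groups
        self.reference = reference
        self.stage = stage

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, groups, reference: str = WT
    ) -> "NBDEModel":
        return cls(counts, groups=pd.Series(list(groups), index=counts.columns),
                   reference=reference)

    def fit(
        self,
        trend_weight: float = 0.5,
        dispersion: pd.Series | float | None = None,
        pseudo_reference: bool = False,
    ) -> "NBDEResults":
        sf = size_factors(self.counts, pseudo_reference=pseudo_reference)
        if dispersion is None:
            disp = estimate_dispersion(
                self.counts, sf, self.groups, trend_weight=trend_weight
            )
        elif np.isscalar(dispersion):
            disp = pd.Series(float(dispersion), index=self.counts.index)
        else:
            disp = dispersion
        table = nb_wald_test(self.counts, sf, disp, self.groups, self.reference)
        return NBDEResults(self, table, sf, disp)


@dataclass
class NBDEResults:
    """Fitted differential-expression results.

    ``table`` columns: baseMean, log2fc, se, pvalue, padj, status.
    """

    model: NBDEModel
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series

    def summary(self, alpha: float = 0.05) -> str:
        t = self.table
        tested = t[t["status"] == "tested"]
        sig = tested[tested["padj"] < alpha]
        lines = [
            "NB differential expression (Wald test)",
            f"  features: {len(t)}  tested: {len(tested)}  "
            f"all-zero: {(t['status'] == 'all-zero').sum()}  "
            f"low-count: {(t['status'] == 'low-count').sum()}",
            f"  size factors: "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.size_factors.items()),
            f"  median dispersion: {self.dispersions.median():.4g}",
            f"  padj < {alpha}: {len(sig)} "
            f"(up {int((sig['log2fc'] > 0).sum())}, down {int((sig['log2fc'] < 0).sum())})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path, sep="\t")
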