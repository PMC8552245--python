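"""Negative-binomial differential testing.

A plain NB Wald test over a count matrix with condition labels:

1. median-of-ratios size factors;
2. per-feature method-of-moments dispersion from within-condition
   residuals, shrunk toward a fitted mean-dispersion trend
   ``alpha(mu) = a0 + a1/mu`` (prior weight ``prior_df``);
3. Wald statistic on the difference of log mean normalized counts, with
   variance from the NB model ``Var = mu + alpha * mu^2``; two-sided
   normal p-values and Benjamini-Hochberg adjustment.

No fold-change shrinkage and no outlier refitting are performed; the test
is deterministic given its inputs.  Log2 fold changes use a 0.5
pseudo-count so they stay finite for features observed in one condition
only.

Threshold rules applied downstream of the test:

* expression: up if padj < 0.01 and LFC > 0.5849 (log2 of ~1.5); down if
  padj < 0.01 and LFC < -1;
* mark loss: LFC < 0 at a caller-supplied padj threshold (0.001 for
  gene-body H2A.Z, 0.01 for promoter H3K9me2);
* differential binding: padj < 0.001 with the LFC sign giving the
  direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "size_factors",
    "estimate_dispersions",
    "nb_test",
    "classify_de",
    "call_signal_loss",
    "classify_binding_change",
    "FDR_DE",
    "LFC_UP",
    "LFC_DOWN",
    "PADJ_HTZ_LOSS",
    "PADJ_K9_LOSS",
    "PADJ_BINDING",
]

FDR_DE = 0.01
LFC_UP = 0.5849
LFC_DOWN = -1.0
PADJ_HTZ_LOSS = 0.001
PADJ_K9_LOSS = 0.01
PADJ_BINDING = 0.001

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 10.0


@dataclass
class CountMatrix:
    """Integer counts (features x samples) with per-sample condition labels."""

    counts: pd.DataFrame
    conditions: pd.Series  # index: sample name -> condition label

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if not set(self.counts.columns) <= set(self.conditions.index):
            missing = set(self.counts.columns) - set(self.conditions.index)
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.rint(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(int)

    def samples_for(self, condition: str) -> list[str]:
        names = [s for s in self.counts.columns if self.conditions.get(s) == condition]
        if not names:
            raise KeyError(f"condition {condition!r} has no samples in the matrix")
        return names


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (features with all-positive counts)."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "supply external size factors or a pseudo-reference"
        )
    geo = np.exp(np.log(arr[positive]).mean(axis=1))
    ratios = arr[positive] / geo[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative features."""
    ok = (mu > 0) & (alpha > 0)
    if ok.sum() < 3:
        med = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return max(med, _DISPERSION_FLOOR), 0.0
    x = 1.0 / mu[ok]
    y = alpha[ok]
    A = np.column_stack([np.ones(x.size), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a0 = max(float(coef[0]), _DISPERSION_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def estimate_dispersions(
    norm_counts: np.ndarray, groups: list[np.ndarray], prior_df: float = 40.0
) -> np.ndarray:
    """Trend-shrunk NB dispersions (variance model mu + alpha * mu^2).

    ``groups`` lists column-index arrays, one per condition.  The raw
    method-of-moments estimate pools within-condition residual variance;
    the final dispersion is a convex combination of the raw and trend
    values weighted by the residual degrees of freedom versus ``prior_df``.
    """
    resid_ss = np.zeros(norm_counts.shape[0])
    mean_ss = np.zeros(norm_counts.shape[0])
    df = 0
    grand = np.zeros(norm_counts.shape[0])
    ntot = 0
    for idx in groups:
        sub = norm_counts[:, idx]
        m = sub.mean(axis=1)
        resid_ss += ((sub - m[:, None]) ** 2).sum(axis=1) - (sub.shape[1] - 1) * m
        mean_ss += (sub.shape[1] - 1) * m**2
        df += sub.shape[1] - 1
        grand += sub.sum(axis=1)
        ntot += sub.shape[1]
    mu = grand / max(ntot, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mean_ss > 0, resid_ss / np.maximum(mean_ss, 1e-12), 0.0)
    a0, a1 = _fit_trend(mu, alpha_raw)
    with np.errstate(divide="ignore"):
        alpha_tr = a0 + a1 / np.maximum(mu, 1e-12)
    alpha_tr = np.clip(alpha_tr, _DISPERSION_FLOOR, _DISPERSION_CEIL)
    # arithmetic shrinkage: the raw MoM estimate is ~unbiased, so a convex
    # combination stays calibrated (a log-space combination would be biased
    # low by Jensen's inequality)
    clipped = np.clip(alpha_raw, 0.0, _DISPERSION_CEIL)
    w = df / (df + prior_df)
    alpha = w * clipped + (1 - w) * alpha_tr
    return np.clip(alpha, _DISPERSION_FLOOR, _DISPERSION_CEIL)


def nb_test(
    cm: CountMatrix,
    case: str,
    control: str,
    prior_df: float = 40.0,
    external_size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test of case vs control; returns a per-feature result frame.

    Columns: ``base_mean`` (mean normalized count over tested samples),
    ``lfc`` (log2 fold change case/control with 0.5 pseudo-count),
    ``pvalue``, ``padj`` (BH).  All-zero features get lfc 0 and p 1.
    """
    case_samples = cm.samples_for(case)
    ctrl_samples = cm.samples_for(control)
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    samples = ctrl_samples + case_samples
    sub = cm.counts[samples]
    sf = (
        external_size_factors.reindex(samples)
        if external_size_factors is not None
        else size_factors(sub)
    )
    sf_arr = sf.to_numpy(dtype=float)
    if np.any(~np.isfinite(sf_arr)) or np.any(sf_arr <= 0):
        raise ValueError("size factors must be positive and finite")
    norm = sub.to_numpy(dtype=float) / sf_arr[None, :]
    idx_ctrl = np.arange(len(ctrl_samples))
    idx_case = np.arange(len(ctrl_samples), len(samples))
    alpha = estimate_dispersions(norm, [idx_ctrl, idx_case], prior_df=prior_df)

    def _group_stats(idx: np.ndarray):
        q = norm[:, idx].mean(axis=1)
        s = sf_arr[idx]
        # Var(mean of normalized counts) under NB(mu_j = s_j q, mu + alpha mu^2)
        var = (q[:, None] / s[None, :] + alpha[:, None] * q[:, None] ** 2).sum(axis=1) / idx.size**2
        return q, var

    q1, v1 = _group_stats(idx_case)
    q0, v0 = _group_stats(idx_ctrl)
    lfc = np.log2(q1 + 0.5) - np.log2(q0 + 0.5)
    # delta method on log(q + 0.5)
    se2 = v1 / (q1 + 0.5) ** 2 + v0 / (q0 + 0.5) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(q1 + 0.5) - np.log(q0 + 0.5)) / np.sqrt(se2)
    pvalue = 2.0 * sps.norm.sf(np.abs(z))
    allzero = (q1 == 0) & (q0 == 0)
    lfc[allzero] = 0.0
    pvalue[allzero] = 1.0
    pvalue = np.clip(pvalue, np.nextafter(0, 1), 1.0)
    res = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "lfc": lfc,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        },
        index=sub.index.rename("feature_id"),
    )
    return res


def classify_de(
    results: pd.DataFrame,
    fdr: float = FDR_DE,
    lfc_up: float = LFC_UP,
    lfc_down: float = LFC_DOWN,
) -> pd.Series:
    """Per-feature label in {up, down, ns} from padj/LFC thresholds.

    Strict inequalities throughout: up requires padj < fdr and LFC > lfc_up;
    down requires padj < fdr and LFC < lfc_down.
    """
    sig = results["padj"] < fdr
    label = pd.Series("ns", index=results.index, name="label")
    label[sig & (results["lfc"] > lfc_up)] = "up"
    label[sig & (results["lfc"] < lfc_down)] = "down"
    return label


def call_signal_loss(results: pd.DataFrame, padj_threshold: float) -> pd.Series:
    """Loss flag: LFC < 0 and padj < threshold."""
    if not (0 < padj_threshold < 1):
        raise ValueError("padj_threshold must be in (0, 1)")
    return (results["lfc"] < 0) & (results["padj"] < padj_threshold)


def classify_binding_change(
    results: pd.DataFrame, padj_threshold: float = PADJ_BINDING
) -> pd.Series:
    """Per-peak label in {increased, decreased, unchanged} (padj < 0.001, LFC sign)."""
    sig = results["padj"] < padj_threshold
    label = pd.Series("unchanged", index=results.index, name="label")
    label[sig & (results["lfc"] > 0)] = "increased"
    label[sig & (results["lfc"] < 0)] = "decreased"
    return label
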