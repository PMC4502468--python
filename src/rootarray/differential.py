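"""Differential expression among shared genes, and global Z-scores.

Shared genes (fully present at every stage) are tested for quantitative
change against the first-stage reference: the per-stage fold change is the
difference of replicate-mean log2 intensities (so linear FC = 2**log2FC),
and significance comes from a plain one-way fixed-effects ANOVA across the
stage groups.  A gene is differentially expressed when |log2FC| >= 1
(i.e. at least 2-fold, boundary inclusive, in either direction) in at least
one non-reference stage and the ANOVA p-value is below alpha.  No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available via ``adjust="bh"``.

Z-scores standardize the whole matrix against a single global mean and
standard deviation, z_ij = (x_ij - mu_G) / sigma_G.  Two conventions for
(mu_G, sigma_G) are offered: ``"global"`` (over all gene × sample values,
the default) and ``"sample_means"`` (over the per-sample mean intensities);
the convention used is recorded on the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .detection import stage_mean_matrix
from .io import ExpressionMatrix

__all__ = [
    "DEResult",
    "stage_means",
    "fold_changes",
    "anova_pvalues",
    "select_de",
    "zscores",
    "FoldChangeANOVA",
    "ZScoreTransformer",
]


def stage_means(em: ExpressionMatrix, probes=None) -> pd.DataFrame:
    """Gene × stage arithmetic means over replicates."""
    sm = stage_mean_matrix(em)
    return sm if probes is None else sm.loc[probes]


def fold_changes(stage_means_df: pd.DataFrame, reference_stage) -> pd.DataFrame:
    """log2 fold change of every non-reference stage versus the reference.

    On log2-scale input the fold change is a difference of means; the
    linear-scale FC is ``2 ** log2FC`` and both directions count toward a
    "at least k-fold" criterion via ``abs(log2FC) >= log2(k)``.
    """
    reference_stage = str(reference_stage)
    if reference_stage not in stage_means_df.columns:
        raise ValueError(
            f"reference stage {reference_stage!r} not among stages "
            f"{list(stage_means_df.columns)}"
        )
    ref = stage_means_df[reference_stage]
    others = [c for c in stage_means_df.columns if c != reference_stage]
    return stage_means_df[others].sub(ref, axis=0)


def anova_pvalues(em: ExpressionMatrix, probes=None) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA across stage groups per gene.

    Returns a DataFrame with columns ``F`` and ``p``.  Degenerate inputs
    follow a documented convention: zero within-group variance with zero
    between-group variance gives (F=0, p=1); zero within-group variance
    with non-zero between-group variance gives (F=inf, p=0).
    """
    values = em.values if probes is None else em.values.loc[probes]
    groups = [values[em.stage_columns(s)].to_numpy() for s in em.stage_order]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two stages")
    n_total = sum(g.shape[1] for g in groups)
    k = len(groups)
    if n_total - k <= 0:
        raise ValueError("no within-group degrees of freedom")

    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ss_between = np.zeros(values.shape[0])
    ss_within = np.zeros(values.shape[0])
    for g in groups:
        m = g.mean(axis=1)
        ss_between += g.shape[1] * (m - grand) ** 2
        ss_within += ((g - m[:, None]) ** 2).sum(axis=1)

    df_b, df_w = k - 1, n_total - k
    scale = np.maximum(np.abs(grand), 1.0)
    tol = 1e-12 * scale**2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(F, df_b, df_w)
    degenerate = ss_within <= tol
    F = np.where(degenerate & (ss_between <= tol), 0.0,
                 np.where(degenerate, np.inf, F))
    p = np.where(degenerate & (ss_between <= tol), 1.0,
                 np.where(degenerate, 0.0, p))
    return pd.DataFrame({"F": F, "p": p}, index=values.index)


@dataclass
class DEResult:
    """Per-shared-gene DE table and the thresholds that produced it.

    ``table`` columns: ``log2fc_<stage>`` per non-reference stage, ``max_abs_log2fc``,
    ``F``, ``p``, optional ``p_adj``, and boolean ``de``.
    """

    table: pd.DataFrame
    reference_stage: str
    fc_threshold: float
    alpha: float
    adjust: str = "none"

    @property
    def de_genes(self) -> pd.Index:
        return self.table.index[self.table["de"]]

    @property
    def de_count(self) -> int:
        return int(self.table["de"].sum())

    @property
    def de_fraction(self) -> float:
        return self.de_count / len(self.table) if len(self.table) else float("nan")


def select_de(log2fc: pd.DataFrame, pvals: pd.DataFrame,
              fc_threshold=2.0, alpha=0.05, adjust="none",
              reference_stage="") -> DEResult:
    """Apply the fold-change and p-value gates.

    A gene is DE when max over stages of |log2FC| >= log2(fc_threshold)
    (boundary inclusive) and its (optionally adjusted) p-value < alpha.
    """
    if fc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    if not log2fc.index.equals(pvals.index):
        raise ValueError("fold changes and p-values cover different genes")
    table = log2fc.add_prefix("log2fc_")
    table["max_abs_log2fc"] = log2fc.abs().max(axis=1)
    table["F"] = pvals["F"]
    table["p"] = pvals["p"]
    p_for_gate = pvals["p"]
    if adjust == "bh":
        table["p_adj"] = stats.false_discovery_control(
            pvals["p"].to_numpy(), method="bh"
        )
        p_for_gate = table["p_adj"]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["de"] = (table["max_abs_log2fc"] >= np.log2(fc_threshold)) & (
        p_for_gate < alpha
    )
    return DEResult(table=table, reference_stage=str(reference_stage),
                    fc_threshold=fc_threshold, alpha=alpha, adjust=adjust)


def zscores(values: pd.DataFrame, convention="global"):
    """Standardize a matrix with one global mean and standard deviation.

    Returns ``(z, mu, sigma)``; the convention is recorded in
    ``z.attrs["zscore_convention"]``.  Raises when sigma is zero.
    """
    values = values.values if isinstance(values, ExpressionMatrix) else pd.DataFrame(values)
    arr = values.to_numpy(dtype=float)
    if convention == "global":
        mu, sigma = float(arr.mean()), float(arr.std(ddof=0))
    elif convention == "sample_means":
        col_means = arr.mean(axis=0)
        mu, sigma = float(col_means.mean()), float(col_means.std(ddof=0))
    else:
        raise ValueError(f"unknown z-score convention {convention!r}")
    if sigma == 0:
        raise ValueError("sigma is zero; cannot standardize a constant matrix")
    z = (values - mu) / sigma
    z.attrs["zscore_convention"] = convention
    z.attrs["mu"] = mu
    z.attrs["sigma"] = sigma
    return z, mu, sigma


class FoldChangeANOVA(BaseEstimator):
    """Reference-anchored fold change + one-way ANOVA DE selector.

    Parameters
    ----------
    reference_stage : str
        Stage label used as the fold-change reference (default first stage
        when fitting, i.e. "10" DAT in the standard design).
    fc_threshold : float
        Linear fold-change gate, boundary inclusive (default 2.0).
    alpha : float
        ANOVA p-value gate, strict (default 0.05).
    adjust : {"none", "bh"}
        Optional Benjamini–Hochberg correction applied before the gate.

    Attributes after ``fit``: ``stage_means_``, ``log2fc_``, ``anova_``
    (F and p per gene), ``result_`` (:class:`DEResult`), ``de_mask_``.
    """

    def __init__(self, reference_stage=None, fc_threshold=2.0, alpha=0.05,
                 adjust="none"):
        self.reference_stage = reference_stage
        self.fc_threshold = fc_threshold
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, X: ExpressionMatrix, y=None, probes=None):
        ref = self.reference_stage or X.stage_order[0]
        self.stage_means_ = stage_means(X, probes=probes)
        self.log2fc_ = fold_changes(self.stage_means_, ref)
        self.anova_ = anova_pvalues(X, probes=probes)
        self.result_ = select_de(
            self.log2fc_, self.anova_, fc_threshold=self.fc_threshold,
            alpha=self.alpha, adjust=self.adjust, reference_stage=str(ref),
        )
        self.de_mask_ = self.result_.table["de"]
        return self


class ZScoreTransformer(TransformerMixin, BaseEstimator):
    """Global Z-score standardization, z = (x - mu_G) / sigma_G.

    ``convention="global"`` takes mu_G and sigma_G over all gene × sample
    values; ``"sample_means"`` derives them from the per-sample means.
    """

    def __init__(self, convention="global"):
        self.convention = convention

    def fit(self, X, y=None):
        _, self.mu_, self.sigma_ = zscores(X, convention=self.convention)
        return self

    def transform(self, X):
        values = X.values if isinstance(X, ExpressionMatrix) else pd.DataFrame(X)
        z = (values - self.mu_) / self.sigma_
        z.attrs["zscore_convention"] = self.convention
        return z
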