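"""Present/absent detection calls, replicate consensus, and replicate QC.

A probe is called present (``P``) in a sample when its log2 intensity is at
or above the platform detection limit, absent (``A``) otherwise; the limit
is a platform property and must be supplied explicitly.  Per stage, the
replicate calls are collapsed to a consensus: ``PP`` when every replicate is
present, ``AA`` when every replicate is absent, and ``INS`` (insufficient)
when the replicates disagree — the rule generalizes unchanged to more than
two replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix

__all__ = [
    "call_detection",
    "consensus",
    "concordance_stats",
    "pearson_replicates",
    "pearson_stages",
    "stage_mean_matrix",
    "DetectionCaller",
]


def _values_and_design(matrix, design=None):
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values, matrix.design, matrix.stage_order
    if design is None:
        raise ValueError("a design table is required with a plain DataFrame")
    stages = list(dict.fromkeys(design["stage"].astype(str)))
    return pd.DataFrame(matrix), design, stages


def call_detection(matrix, detection_limit) -> pd.DataFrame:
    """Elementwise P/A calls; intensity equal to the limit counts as P.

    Returns a probes × samples DataFrame of ``"P"``/``"A"`` tokens with the
    limit recorded in ``.attrs["detection_limit"]``.
    """
    detection_limit = float(detection_limit)
    if not np.isfinite(detection_limit):
        raise ValueError("detection_limit must be finite")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else pd.DataFrame(matrix)
    calls = pd.DataFrame(
        np.where(values.to_numpy() >= detection_limit, "P", "A"),
        index=values.index,
        columns=values.columns,
    )
    calls.attrs["detection_limit"] = detection_limit
    return calls


def _stage_columns(design, stage):
    return list(design.index[design["stage"].astype(str) == str(stage)])


def consensus(calls, design, allow_single_replicate=False) -> pd.DataFrame:
    """Collapse per-sample calls to per-stage consensus PP/AA/INS.

    All replicates present → PP; all absent → AA; otherwise INS.  A stage
    with a single replicate is rejected unless ``allow_single_replicate``
    is set, in which case P→PP and A→AA.
    """
    design = pd.DataFrame(design)
    if set(design.index) != set(calls.columns):
        raise ValueError("design samples do not match call-matrix columns")
    stages = list(dict.fromkeys(design["stage"].astype(str)))
    is_p = calls.to_numpy() == "P"
    out = {}
    for stage in stages:
        cols = _stage_columns(design, stage)
        if len(cols) < 2 and not allow_single_replicate:
            raise ValueError(
                f"stage {stage!r} has {len(cols)} replicate(s); pass "
                "allow_single_replicate=True to accept single-replicate stages"
            )
        sub = is_p[:, [calls.columns.get_loc(c) for c in cols]]
        all_p = sub.all(axis=1)
        all_a = (~sub).all(axis=1)
        out[stage] = np.where(all_p, "PP", np.where(all_a, "AA", "INS"))
    return pd.DataFrame(out, index=calls.index)


def concordance_stats(calls, design) -> pd.DataFrame:
    """Per-stage replicate agreement and INS fractions.

    ``agreement_fraction`` is the fraction of probes whose replicate calls
    all agree in that stage; ``ins_fraction`` is its complement (for two
    replicates, exactly the fraction of discordant probes).  The cross-stage
    mean is available as ``.mean()`` of the returned frame.
    """
    cons = consensus(calls, design)
    ins = (cons == "INS").mean(axis=0)
    out = pd.DataFrame(
        {"agreement_fraction": 1.0 - ins, "ins_fraction": ins}
    )
    out.index.name = "stage"
    return out


def _safe_corr(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def pearson_replicates(em: ExpressionMatrix) -> pd.Series:
    """Per-stage Pearson correlation between replicates (mean of pairwise
    correlations when a stage has more than two).  Zero-variance columns
    yield NaN, reported as undefined rather than 0."""
    out = {}
    for stage in em.stage_order:
        cols = em.stage_columns(stage)
        if len(cols) < 2:
            out[stage] = np.nan
            continue
        rs = [
            _safe_corr(em.values[a].to_numpy(), em.values[b].to_numpy())
            for i, a in enumerate(cols)
            for b in cols[i + 1:]
        ]
        out[stage] = float(np.mean(rs))
    return pd.Series(out, name="replicate_pearson")


def stage_mean_matrix(em: ExpressionMatrix) -> pd.DataFrame:
    """Probes × stages matrix of replicate-mean intensities."""
    return pd.DataFrame(
        {s: em.values[em.stage_columns(s)].mean(axis=1) for s in em.stage_order}
    )


def pearson_stages(em: ExpressionMatrix) -> pd.DataFrame:
    """Stage × stage Pearson correlation of stage-mean expression profiles;
    symmetric with unit diagonal."""
    corr = stage_mean_matrix(em).corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


class DetectionCaller(TransformerMixin, BaseEstimator):
    """Transformer turning intensities into P/A detection calls.

    Parameters
    ----------
    detection_limit : float
        Log2-intensity threshold; values >= the limit are called present.
    """

    def __init__(self, detection_limit=6.0):
        self.detection_limit = detection_limit

    def fit(self, X, y=None):
        limit = float(self.detection_limit)
        if not np.isfinite(limit):
            raise ValueError("detection_limit must be finite")
        self.detection_limit_ = limit
        return self

    def transform(self, X):
        return call_detection(X, self.detection_limit)

    def consensus(self, X: ExpressionMatrix, allow_single_replicate=False):
        """Convenience: calls plus per-stage consensus in one step."""
        calls = self.transform(X)
        return consensus(calls, X.design,
                         allow_single_replicate=allow_single_replicate)
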