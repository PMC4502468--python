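"""Filtering protocol and stage/period-specificity classification.

Probes whose replicates disagree (consensus ``INS``) in at least one stage
are removed first; probes absent (``AA``) in every stage are removed next.
The remaining probes are partitioned by the number of stages in which they
are fully present (``PP``): exactly one stage → stage-specific; two or more
but not all → period-specific; all stages → shared.  The five labels
partition the probe universe, and the counts obey the conservation identity
``removed_INS + removed_AA + passing = total``.

The cumulative-expressed count — probes PP in at least one stage — is taken
on the pre-filter consensus, so a probe discordant in one stage but cleanly
present in another still counts as expressed somewhere; this is why the
cumulative count exceeds the number of probes passing filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SpecificityResult",
    "filter_probes",
    "classify_passing",
    "classify",
    "cumulative_expressed",
    "tally",
    "family_spectrum",
    "SpecificityClassifier",
]

LABELS = ("removed_INS", "removed_AA", "stage_specific", "period_specific", "shared")


@dataclass
class SpecificityResult:
    """Exhaustive partition of the probe universe into specificity classes.

    ``table`` is indexed by probe_id with columns ``label`` (one of
    ``removed_INS``, ``removed_AA``, ``stage_specific``, ``period_specific``,
    ``shared``), ``stage_set`` ('+'-joined PP stages, empty for removed
    probes), ``n_pp`` and ``contiguous``.
    """

    table: pd.DataFrame
    stage_order: list = field(default_factory=list)

    @property
    def removed_ins(self) -> pd.Index:
        return self.table.index[self.table["label"] == "removed_INS"]

    @property
    def removed_aa(self) -> pd.Index:
        return self.table.index[self.table["label"] == "removed_AA"]

    @property
    def passing(self) -> pd.Index:
        return self.table.index[
            ~self.table["label"].isin(["removed_INS", "removed_AA"])
        ]

    @property
    def shared(self) -> pd.Index:
        return self.table.index[self.table["label"] == "shared"]

    def probes(self, label) -> pd.Index:
        return self.table.index[self.table["label"] == label]

    def class_counts(self) -> dict:
        counts = self.table["label"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}

    def stage_specific_counts(self) -> pd.Series:
        sub = self.table[self.table["label"] == "stage_specific"]
        counts = sub["stage_set"].value_counts()
        return pd.Series(
            {s: int(counts.get(s, 0)) for s in self.stage_order},
            name="stage_specific",
        )

    def period_by_cardinality(self) -> pd.Series:
        sub = self.table[self.table["label"] == "period_specific"]
        counts = sub["n_pp"].value_counts()
        n = len(self.stage_order)
        return pd.Series({k: int(counts.get(k, 0)) for k in range(2, n)},
                         name="period_specific")

    def period_specific_count(self, min_stages=2, max_stages=None) -> int:
        if max_stages is None:
            max_stages = len(self.stage_order) - 1
        sub = self.table[self.table["label"] == "period_specific"]
        return int(sub["n_pp"].between(min_stages, max_stages).sum())

    def contiguous_fraction(self) -> float:
        """Fraction of period-specific probes whose PP stages form a
        temporally contiguous run."""
        sub = self.table[self.table["label"] == "period_specific"]
        if len(sub) == 0:
            return float("nan")
        return float(sub["contiguous"].mean())


def filter_probes(consensus: pd.DataFrame):
    """Split probes into (passing, removed_INS, removed_AA).

    INS removal takes precedence: a probe that is INS somewhere and AA
    everywhere else is counted as removed_INS, never removed_AA.
    """
    if consensus.shape[1] < 1:
        raise ValueError("consensus needs at least one stage")
    arr = consensus.to_numpy()
    any_ins = (arr == "INS").any(axis=1)
    any_pp = (arr == "PP").any(axis=1)
    removed_ins = consensus.index[any_ins]
    removed_aa = consensus.index[~any_ins & ~any_pp]
    passing = consensus.index[~any_ins & any_pp]
    return passing, removed_ins, removed_aa


def _classify_pp(consensus: pd.DataFrame) -> pd.DataFrame:
    stages = list(consensus.columns)
    n = len(stages)
    pp = consensus.to_numpy() == "PP"
    k = pp.sum(axis=1)
    label = np.where(k == n, "shared",
                     np.where(k == 1, "stage_specific", "period_specific"))
    stage_set = ["+".join(s for s, p in zip(stages, row) if p) for row in pp]
    contiguous = []
    for row in pp:
        idx = np.flatnonzero(row)
        contiguous.append(bool(len(idx) and idx[-1] - idx[0] == len(idx) - 1))
    return pd.DataFrame(
        {"label": label, "stage_set": stage_set, "n_pp": k,
         "contiguous": contiguous},
        index=consensus.index,
    )


def classify_passing(consensus: pd.DataFrame) -> pd.DataFrame:
    """Classify probes that already passed filtering.

    Raises if any INS call remains (the filtering contract was violated)
    or if a probe is AA everywhere.
    """
    arr = consensus.to_numpy()
    if (arr == "INS").any():
        bad = consensus.index[(arr == "INS").any(axis=1)][0]
        raise ValueError(
            f"INS consensus encountered for probe {bad!r}; run filter_probes first"
        )
    if (~(arr == "PP").any(axis=1)).any():
        bad = consensus.index[~(arr == "PP").any(axis=1)][0]
        raise ValueError(f"all-AA probe {bad!r} should have been removed")
    return _classify_pp(consensus)


def classify(consensus: pd.DataFrame) -> SpecificityResult:
    """Filter and classify the full consensus matrix in one step."""
    passing, removed_ins, removed_aa = filter_probes(consensus)
    parts = []
    if len(passing):
        parts.append(classify_passing(consensus.loc[passing]))
    for idx, lab in ((removed_ins, "removed_INS"), (removed_aa, "removed_AA")):
        if len(idx):
            parts.append(pd.DataFrame(
                {"label": lab, "stage_set": "", "n_pp": 0, "contiguous": False},
                index=idx,
            ))
    table = pd.concat(parts).loc[consensus.index]
    return SpecificityResult(table=table, stage_order=list(consensus.columns))


def cumulative_expressed(consensus: pd.DataFrame):
    """Count probes PP in >=1 stage (pre-filter) and the running union.

    Returns ``(count, curve)`` where ``curve[s]`` is the number of distinct
    probes seen PP in any stage up to and including ``s`` (stage order =
    column order of the consensus matrix).
    """
    pp = consensus.to_numpy() == "PP"
    seen = np.zeros(pp.shape[0], dtype=bool)
    curve = {}
    for j, stage in enumerate(consensus.columns):
        seen |= pp[:, j]
        curve[stage] = int(seen.sum())
    return int(pp.any(axis=1).sum()), pd.Series(curve, name="cumulative_expressed")


def tally(result: SpecificityResult, annotation=None) -> pd.DataFrame:
    """Per-class gene and TF counts.

    Without an annotation table the TF column is reported as missing
    (pandas NA), not zero.
    """
    rows = {}
    for lab in LABELS:
        probes = result.probes(lab)
        if annotation is None:
            n_tf = pd.NA
        else:
            known = probes.intersection(annotation.index)
            n_tf = int(annotation.loc[known, "is_TF"].sum())
        rows[lab] = {"n_genes": len(probes), "n_TF": n_tf}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "class"
    return out


def family_spectrum(consensus: pd.DataFrame, annotation) -> pd.DataFrame:
    """TF-family × stage counts over probes fully present (PP) per stage."""
    tf = annotation[annotation["is_TF"]]
    out = {}
    for stage in consensus.columns:
        pp_probes = consensus.index[consensus[stage] == "PP"]
        fams = tf.loc[tf.index.intersection(pp_probes), "TF_family"]
        out[stage] = fams.value_counts()
    return pd.DataFrame(out).fillna(0).astype(int)


class SpecificityClassifier(BaseEstimator):
    """Estimator wrapper: fit on a consensus matrix, expose the partition.

    Attributes (after ``fit``): ``result_`` (:class:`SpecificityResult`),
    ``labels_`` (Series probe → class label), ``cumulative_expressed_``.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.result_ = classify(X)
        self.labels_ = self.result_.table["label"]
        self.cumulative_expressed_, self.cumulative_curve_ = cumulative_expressed(X)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
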