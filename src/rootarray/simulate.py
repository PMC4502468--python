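"""Synthetic seven-stage, two-replicate expression matrices with planted truth.

The generator emulates a developmental time-course microarray: seven sampling
stages (labelled in days after transplanting), two biological replicates per
stage, and a hard platform detection limit below which a probe is called
absent.  Every probe is planted in an explicit class —

* ``absent_all``              below the limit in every replicate of every stage
* ``constitutive``            present everywhere, flat temporal profile
* ``de_cluster_I .. _VI``     present everywhere, one of six canonical
                              temporal shapes relative to the first stage
* ``stage_specific:<stage>``  present in exactly one stage
* ``period_specific:...``     present in a 2..(n-1)-stage period, either an
                              explicit set (``period_specific:10+15``) or a
                              cardinality (``period_specific:k=3``) assigned
                              to contiguous stage windows by the seed
* ``discordant``              present everywhere but with exactly one
                              replicate forced below the limit in one or two
                              stages, producing replicate-discordant cells

— and the planted assignment is returned as a ground-truth table so every
downstream step of the pipeline can be scored against it.

The noise model is built for deterministic bookkeeping: replicate noise is a
3σ-truncated Gaussian, present cells are floored at the detection limit,
absent cells are drawn strictly below it with a one-``replicate_sd`` margin,
and per-probe baselines are clipped so the lowest template stage stays at
least ``present_margin`` above the limit.  With the default ``replicate_sd``
and ``de_fold_range`` these margins guarantee that planted DE probes clear a
2-fold gate and constitutive probes never do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix

__all__ = [
    "DEFAULT_STAGE_LABELS",
    "TEMPLATE_NAMES",
    "SimulationConfig",
    "canonical_templates",
    "study_class_counts",
    "simulate",
    "simulate_annotation",
    "write_truth",
    "read_truth",
    "config_to_yaml",
    "config_from_yaml",
    "expected_specificity_label",
]

DEFAULT_STAGE_LABELS = ("10", "15", "20", "30", "60", "90", "120")

TEMPLATE_NAMES = ("I", "II", "III", "IV", "V", "VI")

#: per-stage positions of the monotone templates along a "developmental
#: drift" axis: adjacent early stages close, 30-90 DAT nearly flat, large
#: 20→30 and 90→120 steps — mirroring how stage-to-stage similarity of root
#: transcriptomes falls with developmental (not calendar) distance.
_DRIFT = (0.00, 0.08, 0.16, 0.60, 0.66, 0.72, 1.00)


def canonical_templates(stage_labels=DEFAULT_STAGE_LABELS) -> pd.DataFrame:
    """Unit-amplitude log2-offset shapes of the six temporal clusters.

    I    up-regulated at the fourth stage (30 DAT)
    II   up-regulated at the fifth stage (60 DAT)
    III  up-regulated from the second through the next-to-last stage
         (15–90 DAT)
    IV   down-regulated at the third stage (20 DAT)
    V    monotonically increasing
    VI   monotonically decreasing

    All shapes are zero at the first (reference) stage.  Rows are the
    template labels, columns the stage labels; multiply by a per-gene
    log2-fold amplitude to obtain planted offsets.
    """
    n = len(stage_labels)
    if n < 3:
        raise ValueError("templates need at least 3 stages")
    shapes = np.zeros((6, n))
    shapes[0, min(3, n - 1)] = 1.0                      # I
    shapes[1, min(4, n - 1)] = 1.0                      # II
    shapes[2, 1:n - 1] = 1.0                            # III
    shapes[3, min(2, n - 1)] = -1.0                     # IV
    drift = np.asarray(_DRIFT[:n]) if n <= len(_DRIFT) else np.linspace(0, 1, n)
    drift = drift / drift[-1]
    shapes[4] = drift                                   # V
    shapes[5] = -drift                                  # VI
    return pd.DataFrame(shapes, index=list(TEMPLATE_NAMES),
                        columns=[str(s) for s in stage_labels])


def study_class_counts() -> dict:
    """Default planted composition: 39,724 probes arranged as in the study.

    8,942 absent everywhere; 8,275 replicate-discordant in ≥1 stage;
    712 stage-specific (141/48/475 at 10/30/120 DAT, 12 at each remaining
    stage); 1,840 period-specific (58 at 10+15, 16 at 15+20, 123 further
    two-stage, 1,643 across three-to-six-stage periods); 19,955 shared,
    of which 5,368 follow the six DE templates and 14,587 are flat.
    """
    return {
        "absent_all": 8942,
        "discordant": 8275,
        "stage_specific:10": 141,
        "stage_specific:15": 12,
        "stage_specific:20": 12,
        "stage_specific:30": 48,
        "stage_specific:60": 12,
        "stage_specific:90": 12,
        "stage_specific:120": 475,
        "period_specific:10+15": 58,
        "period_specific:15+20": 16,
        "period_specific:k=2": 123,
        "period_specific:k=3": 411,
        "period_specific:k=4": 411,
        "period_specific:k=5": 411,
        "period_specific:k=6": 410,
        "constitutive": 14587,
        "de_cluster_I": 895,
        "de_cluster_II": 895,
        "de_cluster_III": 895,
        "de_cluster_IV": 895,
        "de_cluster_V": 894,
        "de_cluster_VI": 894,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study design.

    Units: all intensities and spreads are on the normalized log2 scale;
    ``de_fold_range`` is on the linear fold-change scale.
    """

    n_stages: int = 7
    n_replicates: int = 2
    stage_labels: tuple = DEFAULT_STAGE_LABELS
    detection_limit: float = 6.0
    baseline_mean: float = 11.0
    baseline_sd: float = 1.0
    replicate_sd: float = 0.15
    discordance_rate: float = 0.0
    class_counts: dict = field(default_factory=study_class_counts)
    de_fold_range: tuple = (4.0, 12.0)
    seed: int = 0
    contiguous_periods: bool = True
    #: probability a planted-discordant probe gets a second discordant stage
    #: (default tuned so discordant cells are ≈4.7% of all probe-stage cells
    #: under the default composition)
    discordant_extra_stage_p: float = 0.58
    absent_spread: float = 2.0
    present_margin: float = 1.0

    def validate(self):
        if self.n_stages != len(self.stage_labels):
            raise ValueError("n_stages must match stage_labels")
        vals = [float(s) for s in self.stage_labels]
        if not all(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage_labels must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("zero total probes")
        if not (0.0 <= self.discordance_rate <= 1.0):
            raise ValueError("discordance_rate must be in [0, 1]")
        if self.detection_limit >= self.baseline_mean:
            raise ValueError("detection_limit must be below baseline_mean")
        if self.de_fold_range[0] < 2.0:
            raise ValueError("de_fold_range lower bound must be >= 2")
        if self.de_fold_range[1] < self.de_fold_range[0]:
            raise ValueError("de_fold_range must be (low, high)")
        if self.replicate_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.absent_spread <= self.replicate_sd:
            raise ValueError("absent_spread must exceed replicate_sd")


def _contiguous_windows(n_stages, k):
    return [tuple(range(i, i + k)) for i in range(n_stages - k + 1)]


def _parse_class_key(key, config):
    """Return (kind, detail) for one class_counts key."""
    labels = [str(s) for s in config.stage_labels]
    if key in ("absent_all", "constitutive", "discordant"):
        return key, None
    if key.startswith("de_cluster_"):
        name = key[len("de_cluster_"):]
        if name not in TEMPLATE_NAMES:
            raise ValueError(f"unknown DE cluster in class key {key!r}")
        return "de_cluster", name
    if key.startswith("stage_specific:"):
        stage = key.split(":", 1)[1]
        if stage not in labels:
            raise ValueError(f"unknown stage in class key {key!r}")
        return "stage_specific", labels.index(stage)
    if key.startswith("period_specific:"):
        detail = key.split(":", 1)[1]
        if detail.startswith("k="):
            k = int(detail[2:])
            if not (2 <= k <= config.n_stages - 1):
                raise ValueError(
                    f"period cardinality must be 2..{config.n_stages - 1}: {key!r}"
                )
            return "period_k", k
        stages = detail.split("+")
        idx = tuple(sorted(labels.index(s) for s in stages))
        if not (2 <= len(idx) <= config.n_stages - 1) or len(set(idx)) != len(idx):
            raise ValueError(f"invalid period stage set in class key {key!r}")
        return "period_set", idx
    raise ValueError(f"unknown planted class key {key!r}")


def simulate(config: SimulationConfig):
    """Generate an expression matrix plus ground truth for ``config``.

    Returns
    -------
    (ExpressionMatrix, DataFrame)
        The matrix has ``n_stages * n_replicates`` columns named
        ``<stage>D_r<rep>``; the truth table is indexed by probe_id with
        columns ``planted_class``, ``stage_set``, ``discordant_stages``,
        ``cluster``, ``amplitude`` and per-stage expected log2 means
        ``template_<stage>`` (NaN for absent stages).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    S, R = config.n_stages, config.n_replicates
    labels = [str(s) for s in config.stage_labels]
    templates = canonical_templates(labels)
    lo, hi = config.de_fold_range

    class_keys, present_rows, offset_rows, disc_rows = [], [], [], []
    cluster_col, amp_col = [], []
    for key, count in config.class_counts.items():
        if count == 0:
            continue
        kind, detail = _parse_class_key(key, config)
        present = np.ones((count, S), dtype=bool)
        offsets = np.zeros((count, S))
        disc = np.zeros((count, S), dtype=bool)
        cluster = [""] * count
        amps = np.zeros(count)
        if kind == "absent_all":
            present[:] = False
        elif kind == "stage_specific":
            present[:] = False
            present[:, detail] = True
        elif kind == "period_set":
            present[:] = False
            present[:, list(detail)] = True
        elif kind == "period_k":
            present[:] = False
            if config.contiguous_periods:
                windows = _contiguous_windows(S, detail)
                choice = rng.integers(0, len(windows), count)
                for i, w in enumerate(windows):
                    present[np.ix_(choice == i, list(w))] = True
            else:
                for i in range(count):
                    w = rng.choice(S, size=detail, replace=False)
                    present[i, w] = True
        elif kind == "discordant":
            n_extra = (rng.random(count) < config.discordant_extra_stage_p)
            for i in range(count):
                k = min(1 + int(n_extra[i]), S)
                w = rng.choice(S, size=k, replace=False)
                disc[i, w] = True
        elif kind == "de_cluster":
            amps = np.log2(rng.uniform(lo, hi, count))
            offsets = templates.loc[detail].to_numpy()[None, :] * amps[:, None]
            cluster = [detail] * count
        class_keys.extend([key] * count)
        present_rows.append(present)
        offset_rows.append(offsets)
        disc_rows.append(disc)
        cluster_col.extend(cluster)
        amp_col.append(amps)

    present = np.vstack(present_rows)
    offsets = np.vstack(offset_rows)
    disc = np.vstack(disc_rows)
    amps = np.concatenate(amp_col)
    P = present.shape[0]
    probe_ids = [f"SP{i:06d}" for i in range(P)]

    limit = config.detection_limit
    sd = config.replicate_sd
    absent_margin = max(sd, 1e-6)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, P)
    # clip so the lowest present template stage keeps a hard margin above
    # the detection limit (down-regulated templates included)
    min_offset = np.where(present, offsets, np.inf).min(axis=1)
    has_present = np.isfinite(min_offset)
    floor = limit + config.present_margin - np.where(has_present, min_offset, 0.0)
    baseline = np.maximum(baseline, floor)

    means = baseline[:, None] + offsets                      # P x S

    noise = rng.normal(0.0, sd, (P, S, R)) if sd > 0 else np.zeros((P, S, R))
    np.clip(noise, -3 * sd, 3 * sd, out=noise)
    below = rng.uniform(limit - config.absent_spread,
                        limit - absent_margin, (P, S, R))
    present3 = np.broadcast_to(present[:, :, None], (P, S, R))
    vals = np.where(present3, np.maximum(means[:, :, None] + noise, limit), below)

    # planted discordance: exactly one replicate forced below the limit
    rep_choice = rng.integers(0, R, (P, S))
    pp, ss = np.nonzero(disc)
    vals[pp, ss, rep_choice[pp, ss]] = below[pp, ss, rep_choice[pp, ss]]

    # stochastic discordance on remaining fully-present probe-stage cells
    if config.discordance_rate > 0:
        eligible = present & ~disc
        hit = (rng.random((P, S)) < config.discordance_rate) & eligible
        rep2 = rng.integers(0, R, (P, S))
        pp, ss = np.nonzero(hit)
        vals[pp, ss, rep2[pp, ss]] = below[pp, ss, rep2[pp, ss]]

    columns, design_rows = [], {}
    for s, lab in enumerate(labels):
        for r in range(1, R + 1):
            col = f"{lab}D_r{r}"
            columns.append(col)
            design_rows[col] = {"stage": lab, "replicate": r}
    data = vals.reshape(P, S * R)
    values = pd.DataFrame(data, index=probe_ids, columns=columns)
    em = ExpressionMatrix(values, pd.DataFrame.from_dict(design_rows, "index"),
                          stage_order=labels)

    truth = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
    truth["planted_class"] = class_keys
    truth["stage_set"] = [
        "+".join(lab for lab, p in zip(labels, row) if p) for row in present
    ]
    truth["discordant_stages"] = [
        "+".join(lab for lab, d in zip(labels, row) if d) for row in disc
    ]
    truth["cluster"] = cluster_col
    truth["amplitude"] = amps
    template_means = np.where(present, means, np.nan)
    for s, lab in enumerate(labels):
        truth[f"template_{lab}"] = template_means[:, s]
    return em, truth


def simulate_annotation(truth, tf_fraction=0.06, seed=0,
                        families=("MYB", "WRKY", "bHLH", "NAC", "MADS",
                                  "AP2-EREBP", "bZIP", "C2H2", "HB", "ARF")):
    """Synthetic probe annotation: ~``tf_fraction`` of probes flagged as TFs,
    each assigned one of a small set of family labels."""
    rng = np.random.default_rng(seed)
    n = len(truth)
    is_tf = rng.random(n) < tf_fraction
    fam = np.where(is_tf, rng.choice(families, n), None)
    return pd.DataFrame(
        {
            "description": [
                "synthetic transcription factor" if t else "synthetic probe"
                for t in is_tf
            ],
            "is_TF": is_tf,
            "TF_family": fam,
        },
        index=truth.index,
    )


def write_truth(truth, path):
    truth.to_csv(path, sep="\t", float_format="%.8g")


def read_truth(path):
    return pd.read_csv(path, sep="\t", index_col=0,
                       keep_default_na=False, na_values=[""]).fillna({
                           "stage_set": "", "discordant_stages": "",
                           "cluster": ""})


def config_to_yaml(config: SimulationConfig, path):
    d = dataclasses.asdict(config)
    d["stage_labels"] = list(d["stage_labels"])
    d["de_fold_range"] = list(d["de_fold_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["stage_labels"] = tuple(str(s) for s in d["stage_labels"])
    d["de_fold_range"] = tuple(d["de_fold_range"])
    return SimulationConfig(**d)


def expected_specificity_label(planted_class: str) -> str:
    """Specificity-class label a perfect pipeline should assign to a probe
    of the given planted class (valid when ``discordance_rate`` is 0)."""
    if planted_class == "absent_all":
        return "removed_AA"
    if planted_class == "discordant":
        return "removed_INS"
    if planted_class.startswith("stage_specific"):
        return "stage_specific"
    if planted_class.startswith("period_specific"):
        return "period_specific"
    return "shared"
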