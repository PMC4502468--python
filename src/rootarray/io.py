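"""Readers, writers and validated containers for the pipeline's inputs.

Everything downstream operates on an :class:`ExpressionMatrix` — a probes ×
samples table of normalized log2 intensities together with a design table
mapping every sample column to a developmental stage (DAT label) and a
replicate index.  The sample→stage mapping can come from a sidecar
tab-delimited design file or be parsed from column names of the form
``<stage>D_r<replicate>`` (e.g. ``10D_r1``); when both are available the
sidecar wins.

Term sets for enrichment are read from standard GMT files (term id,
description, then member genes, tab-separated), and probe annotations from a
tab-delimited table with a transcription-factor flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleInfo",
    "TermSet",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "annotation_for",
]

#: column-name convention used when no sidecar design is given
_SAMPLE_RE = re.compile(r"^(?P<stage>.+?)D?_r(?P<rep>\d+)$")


@dataclass(frozen=True)
class SampleInfo:
    """One array: its column name, stage label (DAT) and replicate index."""

    sample_id: str
    stage_label: str
    replicate_index: int


def _stage_sort_key(stages):
    """Order stages numerically when every label parses as a number,
    otherwise keep first-appearance order."""
    try:
        vals = [float(s) for s in stages]
    except ValueError:
        return list(stages)
    return [s for _, s in sorted(zip(vals, stages))]


class ExpressionMatrix:
    """Validated probes × samples log2 expression matrix with its design.

    Parameters
    ----------
    values : DataFrame
        Probes (index) × samples (columns), finite log2 intensities.
    design : DataFrame
        Indexed by sample id with columns ``stage`` and ``replicate``.
    stage_order : sequence of str, optional
        Explicit stage ordering; default is numeric order of the labels.

    Columns are normalized to stage-major, replicate-minor order.
    """

    def __init__(self, values, design, stage_order=None):
        values = pd.DataFrame(values).copy()
        design = pd.DataFrame(design).copy()

        dup = values.index[values.index.duplicated()].unique()
        if len(dup):
            raise ValueError(
                f"duplicate probe ids: {', '.join(map(str, dup[:5]))}"
            )
        if not {"stage", "replicate"}.issubset(design.columns):
            raise ValueError("design needs 'stage' and 'replicate' columns")
        design["stage"] = design["stage"].astype(str)
        design["replicate"] = design["replicate"].astype(int)

        unmapped = [c for c in values.columns if c not in design.index]
        if unmapped:
            raise ValueError(f"samples without a design entry: {unmapped}")
        design = design.loc[list(values.columns)]
        dup_sr = design[design.duplicated(["stage", "replicate"], keep=False)]
        if len(dup_sr):
            raise ValueError(
                "duplicate (stage, replicate) pairs for samples: "
                f"{list(dup_sr.index)}"
            )

        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            for col in values.columns:
                coerced = pd.to_numeric(values[col], errors="coerce")
                bad = values.index[coerced.isna()]
                if len(bad):
                    raise ValueError(
                        f"non-numeric value for probe {bad[0]!r} in sample {col!r}"
                    )
            values = values.astype(float)
            arr = values.to_numpy()
        bad = ~np.isfinite(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite value for probe {values.index[i]!r} "
                f"in sample {values.columns[j]!r}"
            )

        if stage_order is None:
            stage_order = _stage_sort_key(design["stage"].unique())
        else:
            stage_order = [str(s) for s in stage_order]
            missing = set(design["stage"]) - set(stage_order)
            if missing:
                raise ValueError(f"stage_order missing stages: {sorted(missing)}")

        ordered = []
        for stage in stage_order:
            cols = design.index[design["stage"] == stage]
            reps = design.loc[cols, "replicate"].sort_values()
            ordered.extend(reps.index)
        self.values = values.loc[:, ordered].astype(float)
        self.design = design.loc[ordered]
        self.stage_order = [s for s in stage_order
                            if (self.design["stage"] == s).any()]

    # -- accessors ---------------------------------------------------------
    @property
    def probe_ids(self):
        return self.values.index

    @property
    def samples(self):
        return [
            SampleInfo(s, row["stage"], int(row["replicate"]))
            for s, row in self.design.iterrows()
        ]

    @property
    def stages(self):
        return list(self.stage_order)

    @property
    def n_stages(self):
        return len(self.stage_order)

    def stage_columns(self, stage):
        stage = str(stage)
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return list(self.design.index[self.design["stage"] == stage])

    def replicate_counts(self):
        return {s: len(self.stage_columns(s)) for s in self.stage_order}

    def subset(self, probes):
        em = object.__new__(ExpressionMatrix)
        em.values = self.values.loc[probes]
        em.design = self.design
        em.stage_order = list(self.stage_order)
        return em

    def __repr__(self):
        return (
            f"ExpressionMatrix({self.values.shape[0]} probes, "
            f"{self.values.shape[1]} samples, {self.n_stages} stages)"
        )


def _design_from_columns(columns):
    rows = {}
    for col in columns:
        m = _SAMPLE_RE.match(str(col))
        if m is None:
            raise ValueError(
                f"cannot parse stage/replicate from column {col!r}; "
                "expected '<stage>D_r<replicate>' or give a design file"
            )
        rows[col] = {"stage": m.group("stage"), "replicate": int(m.group("rep"))}
    return pd.DataFrame.from_dict(rows, orient="index")


def read_design(path):
    """Read a sidecar design table (sample_id, stage, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(int)
    return df[["stage", "replicate"]]


def write_design(em: ExpressionMatrix, path):
    out = em.design.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_matrix(path, design=None, stage_order=None) -> ExpressionMatrix:
    """Read a tab-delimited probes × samples matrix.

    ``design`` may be a sidecar file path, a prepared DataFrame, or None,
    in which case stage and replicate are parsed from the column names.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if design is None:
        design_df = _design_from_columns(df.columns)
    elif isinstance(design, (str, Path)):
        design_df = read_design(design)
    else:
        design_df = design
    return ExpressionMatrix(df, design_df, stage_order=stage_order)


def write_matrix(em: ExpressionMatrix, path, design_path=None):
    """Write the matrix as tab-delimited text (probe_id first column).

    Values are written with 8 significant digits, so a write/read round
    trip preserves intensities to well beyond 6 significant digits.
    """
    out = em.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.8g")
    if design_path is not None:
        write_design(em, design_path)


# -- term sets (GMT) -------------------------------------------------------

@dataclass(frozen=True)
class TermSet:
    """A named gene set: GO term, pathway, or any user-defined category."""

    term_id: str
    name: str
    genes: frozenset


def read_gmt(path) -> dict:
    """Read a GMT file into ``{term_id: TermSet}``.

    Each line is ``term_id <TAB> description <TAB> gene [<TAB> gene ...]``;
    duplicate members within one term are counted once.
    """
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term_id, name, *genes = fields
            members = frozenset(g for g in genes if g)
            terms[term_id] = TermSet(term_id, name, members)
    return terms


def write_gmt(terms: dict, path):
    with open(path, "w") as fh:
        for term in terms.values():
            fh.write(
                "\t".join([term.term_id, term.name, *sorted(term.genes)]) + "\n"
            )


# -- probe annotation ------------------------------------------------------

_UNANNOTATED = {"description": "unannotated", "is_TF": False, "TF_family": None}


def read_annotation(path) -> pd.DataFrame:
    """Read a tab-delimited probe annotation table.

    Columns: ``probe_id``, ``description``, ``is_TF`` (0/1 or true/false),
    optional ``TF_family``.  Probes absent from the table are treated as
    unannotated by :func:`annotation_for`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("probe_id")
    if "description" not in df.columns:
        df["description"] = "unannotated"
    if "is_TF" in df.columns:
        df["is_TF"] = (
            df["is_TF"].str.lower().isin({"1", "true", "yes"})
        )
    else:
        df["is_TF"] = False
    if "TF_family" not in df.columns:
        df["TF_family"] = None
    return df[["description", "is_TF", "TF_family"]]


def annotation_for(annotation, probe_id) -> dict:
    """Annotation record for one probe; missing probes are 'unannotated'."""
    if annotation is None or probe_id not in annotation.index:
        return dict(_UNANNOTATED)
    row = annotation.loc[probe_id]
    return {
        "description": row["description"],
        "is_TF": bool(row["is_TF"]),
        "TF_family": row["TF_family"] if row["is_TF"] else None,
    }
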