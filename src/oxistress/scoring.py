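"""Apply a trained predictor to score samples and summarise by stage.

The stress score of a sample is the model's linear combination of its
log2(x+1)-transformed expression values. Scores of tumor samples are
summarised per clinical stage (I-IV) next to matching controls, which are
scored with the tumor-trained model as-is.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regression import RegressionModel, transform_expression

logger = logging.getLogger("oxistress")

_ROMAN = {"IV": 4, "III": 3, "II": 2, "I": 1}
_STAGE_RE = re.compile(r"^\s*(?:stage\s*)?(IV|III|II|I|[1-4])", re.IGNORECASE)


def score_samples(model: RegressionModel, expr: pd.DataFrame) -> pd.Series:
    """Predicted oxidative-stress score per sample.

    Applies the same log2(x+1) transform used in training. All model genes
    must be present in the matrix; missing genes raise with their names.
    """
    if expr.columns.duplicated().any():
        dupes = sorted(set(expr.columns[expr.columns.duplicated()]))
        raise ValueError(f"duplicated sample IDs: {dupes}")
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise ValueError(f"model genes missing from expression: {missing}")
    Xt = transform_expression(expr.loc[model.genes])
    coef = np.array([model.coefficients[g] for g in model.genes])
    scores = model.intercept + coef @ Xt.to_numpy()
    return pd.Series(scores, index=expr.columns, name="score")


def parse_stage(label: object) -> int | None:
    """Collapse stage labels like 'Stage IA', 'II', 3 to an integer 1-4.

    Returns None for missing or unparseable labels.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)) or \
            pd.isna(label):
        return None
    m = _STAGE_RE.match(str(label))
    if not m:
        return None
    token = m.group(1).upper()
    return int(token) if token.isdigit() else _ROMAN[token]


@dataclass
class StageSummary:
    """Group-wise score summary plus the two qualitative claims checked on
    it: tumors score above controls, and stage means increase."""

    table: pd.DataFrame               # rows: control, stage_1..4, tumor_unstaged
    tumor_gt_control: bool
    stage_strictly_increasing: bool   # strict increase across all stage means
    at_most_one_inversion: bool       # <= 1 non-increasing adjacent pair


def stage_summary(scores: pd.Series, meta: pd.DataFrame) -> StageSummary:
    """Summarise scores per group (control, stage 1-4, unstaged tumors).

    Emits n, mean, median and quartiles per group, whether the tumor mean
    exceeds the control mean, and whether stage means increase strictly
    (also a relaxed variant tolerating a single out-of-order stage).
    """
    shared = scores.index.intersection(meta.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between scores and metadata")
    scores = scores.loc[shared]
    meta = meta.loc[shared]

    tumor_mask = meta["group"] == "tumor"
    if not tumor_mask.any():
        raise ValueError("no tumor samples to summarise")

    stages = meta["stage"].map(parse_stage) if "stage" in meta.columns \
        else pd.Series(None, index=meta.index, dtype=object)
    unparsed = meta["stage"].notna() & stages.isna() if "stage" in meta.columns \
        else pd.Series(False, index=meta.index)
    if unparsed.any():
        logger.warning("dropping %d unparseable stage labels: %s",
                       int(unparsed.sum()),
                       sorted(set(meta.loc[unparsed, "stage"].astype(str)))[:5])

    groups: list[tuple[str, pd.Series]] = []
    ctrl = scores[meta["group"] == "control"]
    if len(ctrl):
        groups.append(("control", ctrl))
    for k in (1, 2, 3, 4):
        grp = scores[tumor_mask & (stages == k)]
        if len(grp):
            groups.append((f"stage_{k}", grp))
    unstaged = scores[tumor_mask & stages.isna()]
    if len(unstaged):
        groups.append(("tumor_unstaged", unstaged))

    rows = []
    for name, vals in groups:
        rows.append({
            "group": name,
            "n": len(vals),
            "mean": float(vals.mean()),
            "median": float(vals.median()),
            "q1": float(vals.quantile(0.25)),
            "q3": float(vals.quantile(0.75)),
        })
    table = pd.DataFrame(rows).set_index("group")

    tumor_mean = float(scores[tumor_mask].mean())
    tumor_gt_control = bool(len(ctrl)) and tumor_mean > float(ctrl.mean())

    stage_means = [table.loc[f"stage_{k}", "mean"] for k in (1, 2, 3, 4)
                   if f"stage_{k}" in table.index]
    diffs = np.diff(stage_means)
    strictly = len(stage_means) >= 2 and bool((diffs > 0).all())
    one_inv = len(stage_means) >= 2 and int((diffs <= 0).sum()) <= 1
    return StageSummary(table=table, tumor_gt_control=tumor_gt_control,
                        stage_strictly_increasing=strictly,
                        at_most_one_inversion=one_inv)


def stage_boxplot(scores: pd.Series, meta: pd.DataFrame,
                  path: str | Path) -> None:
    """Boxplot of scores per group (control, stages), saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = stage_summary(scores, meta)
    shared = scores.index.intersection(meta.index)
    scores, meta = scores.loc[shared], meta.loc[shared]
    stages = meta["stage"].map(parse_stage)
    data, labels = [], []
    for name in summary.table.index:
        if name == "control":
            vals = scores[meta["group"] == "control"]
        elif name == "tumor_unstaged":
            vals = scores[(meta["group"] == "tumor") & stages.isna()]
        else:
            k = int(name.split("_")[1])
            vals = scores[(meta["group"] == "tumor") & (stages == k)]
        data.append(vals.to_numpy())
        labels.append(name)
    fig, ax = plt.subplots(figsize=(1.2 * len(data) + 2, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("predicted oxidative-stress score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
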