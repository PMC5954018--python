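"""qPCR relative quantification (2^-ddCt) and its comparison with RNA-seq.

Each measurement pairs a target-gene Ct with a reference-gene Ct (an
18S-equivalent housekeeping control) in the same sample.  Per sample,
dCt = Ct_target - Ct_reference; ddCt is the case group mean dCt minus the
control group mean dCt; the relative fold change is 2^-ddCt.  Group
comparison uses one-way ANOVA; agreement with sequencing is quantified by
ordinary least-squares regression of qPCR log2 fold changes on RNA-seq
log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

CT_RANGE = (0.0, 45.0)


@dataclass
class QpcrResult:
    target_gene: str
    delta_ct: dict[str, float]  # sample_id -> dCt (technical reps averaged)
    delta_delta_ct: float
    fold_change: float
    mean_dct_control: float
    mean_dct_case: float
    se_dct_control: float
    se_dct_case: float
    per_sample_fold: dict[str, float]  # 2^-(dCt - mean control dCt)
    anova_F: float
    anova_p: float


def _validate_ct(df: pd.DataFrame) -> None:
    for col in ("sample_id", "condition", "target_gene", "ct_target", "ct_reference"):
        if col not in df.columns:
            raise ValidationError(f"Ct table missing column {col!r}")
    if df["ct_reference"].isna().any() or df["ct_target"].isna().any():
        raise ValidationError("missing Ct value")
    for col in ("ct_target", "ct_reference"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals <= CT_RANGE[0]) | (vals >= CT_RANGE[1])).any():
            raise ValidationError(f"{col} outside plausible cycle range {CT_RANGE}")


def delta_delta_ct(measurements: pd.DataFrame, target_gene: str | None = None) -> QpcrResult:
    """2^-ddCt relative quantification for one target gene.

    Technical replicates (repeated rows per sample) are averaged before
    analysis.  ddCt is computed from group-mean dCt; per-sample fold changes
    (2^-(dCt_i - mean control dCt)) are also returned, and the two groups'
    per-sample dCt values are compared by one-way ANOVA.
    """
    df = measurements.copy()
    if target_gene is not None:
        df = df[df["target_gene"] == target_gene]
    genes = df["target_gene"].unique()
    if len(genes) != 1:
        raise ValidationError(f"expected one target gene, got {list(genes)}")
    _validate_ct(df)
    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    per_sample = df.groupby(["sample_id", "condition"], sort=True)["dct"].mean().reset_index()
    groups = {
        cond: sub["dct"].to_numpy()
        for cond, sub in per_sample.groupby("condition")
    }
    for cond in ("control", "case"):
        if cond not in groups or len(groups[cond]) < 1:
            raise ValidationError(f"no {cond!r} samples with Ct values")
    mean_ctrl = float(np.mean(groups["control"]))
    mean_case = float(np.mean(groups["case"]))
    ddct = mean_case - mean_ctrl
    if len(groups["control"]) >= 2 and len(groups["case"]) >= 2:
        try:
            f, p = one_way_anova([groups["control"], groups["case"]])
        except ValidationError:  # all dCt identical (e.g. noise-free fold 1)
            f, p = float("nan"), float("nan")
    else:
        f, p = float("nan"), float("nan")

    def _se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    return QpcrResult(
        target_gene=str(genes[0]),
        delta_ct=dict(zip(per_sample["sample_id"], per_sample["dct"])),
        delta_delta_ct=float(ddct),
        fold_change=float(2.0 ** (-ddct)),
        mean_dct_control=mean_ctrl,
        mean_dct_case=mean_case,
        se_dct_control=_se(groups["control"]),
        se_dct_case=_se(groups["case"]),
        per_sample_fold={
            sid: float(2.0 ** (-(d - mean_ctrl)))
            for sid, d in zip(per_sample["sample_id"], per_sample["dct"])
        },
        anova_F=float(f),
        anova_p=float(p),
    )


def one_way_anova(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(groups)) == 0:
        raise ValidationError("F undefined: zero variance everywhere")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def fold_change_regression(
    log2fc_qpcr: np.ndarray | list[float],
    log2fc_rnaseq: np.ndarray | list[float],
) -> dict[str, float]:
    """OLS of qPCR log2 fold changes on RNA-seq log2 fold changes.

    Returns slope, intercept, Pearson r, and the p-value for slope != 0.
    """
    x = np.asarray(log2fc_rnaseq, dtype=float)
    y = np.asarray(log2fc_qpcr, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired fold-change vectors differ in length")
    if x.size < 3:
        raise ValidationError("need >= 3 paired fold changes")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
    }
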