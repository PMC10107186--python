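"""Tooth-collagen quality control and the conditional C:N-based d13C correction.

Collagen with atomic C:N inside 3.0-3.3 is considered uncontaminated; values
above 3.3 suggest residual lipid or non-collagenous protein that biases d13C
and are corrected when the sample set shows a significant negative C:N-d13C
relationship; values between 2.9 and 3.0 are retained uncorrected (the lower
limit is conservative); values below 2.9 are excluded.

The correction is an anchored linear de-trend: the fitted slope is removed
above the threshold, ``d13C_corrected = d13C - slope * (cn - threshold)``,
so the correction magnitude grows with the C:N excess and vanishes at the
threshold. The functional form is isolated in :func:`correct_d13c` so an
alternative scaled-offset equation can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CN_EXCLUDE_BELOW",
    "CN_LOW",
    "CN_HIGH",
    "LinearFit",
    "QCRecord",
    "classify_cn",
    "fit_cn_d13c",
    "correct_d13c",
    "run_qc",
    "qc_report_frame",
]

CN_EXCLUDE_BELOW = 2.9
CN_LOW = 3.0
CN_HIGH = 3.3


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of d13C on atomic C:N with a two-sided t-test on the slope."""

    slope: float
    intercept: float
    p_value: float
    n: int

    @property
    def significant_negative(self) -> bool:
        return self.slope < 0 and self.p_value < 0.05


@dataclass(frozen=True)
class QCRecord:
    sample_id: str
    cn_atomic: float
    status: str  # pass | low_cn | high_cn_corrected | high_cn_uncorrectable | excluded
    d13C_raw: float
    d13C_used: float | None  # None when excluded

    def __post_init__(self) -> None:
        if self.status == "high_cn_corrected" and not self.cn_atomic > CN_HIGH:
            raise ValueError("corrected status requires cn_atomic > threshold")


def classify_cn(cn_atomic: float) -> str:
    """Classify a sample by its atomic C:N ratio.

    Returns ``pass`` (3.0-3.3), ``low_cn`` (2.9-3.0, retained uncorrected),
    ``high_cn`` (> 3.3, candidate for correction) or ``excluded`` (< 2.9).
    """
    if cn_atomic <= 0:
        raise ValueError("cn_atomic must be > 0")
    if cn_atomic < CN_EXCLUDE_BELOW:
        return "excluded"
    if cn_atomic < CN_LOW:
        return "low_cn"
    if cn_atomic <= CN_HIGH:
        return "pass"
    return "high_cn"


def fit_cn_d13c(cn_atomic, d13C) -> LinearFit:
    """OLS of d13C on atomic C:N across the sample set."""
    cn = np.asarray(cn_atomic, dtype=float)
    y = np.asarray(d13C, dtype=float)
    if cn.size != y.size or cn.size < 3:
        raise ValueError("need >= 3 paired (cn, d13C) samples")
    if np.var(cn) == 0:
        raise ValueError("zero variance in cn_atomic")
    res = stats.linregress(cn, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.pvalue), int(cn.size))


def correct_d13c(
    d13C: float, cn_atomic: float, fit: LinearFit, threshold: float = CN_HIGH
) -> float:
    """Apply the anchored linear de-trend above the C:N threshold.

    Pass-through unless the fitted slope is significantly negative
    (two-sided p < 0.05) and ``cn_atomic`` exceeds the threshold.
    """
    if not fit.significant_negative or cn_atomic <= threshold:
        return d13C
    return d13C - fit.slope * (cn_atomic - threshold)


def run_qc(records, threshold: float = CN_HIGH) -> tuple[list[QCRecord], LinearFit]:
    """QC a list of consumer records (see :mod:`nichemix.tables_io`).

    Fits the C:N-d13C relationship across all non-excluded samples, then
    classifies and (where warranted) corrects each record. Returns the QC
    records, in input order, plus the fitted relationship.
    """
    kept = [r for r in records if classify_cn(r.cn_atomic) != "excluded"]
    cns = [r.cn_atomic for r in kept]
    if len(kept) >= 3 and np.var(cns) > 0:
        fit = fit_cn_d13c(cns, [r.iso.d13C for r in kept])
    else:
        # too few samples to model the relationship: no correction possible
        fit = LinearFit(slope=0.0, intercept=0.0, p_value=1.0, n=len(kept))
    out = []
    for r in records:
        cls = classify_cn(r.cn_atomic)
        sample_id = f"{r.individual_id}:{r.row_index}"
        if cls == "excluded":
            out.append(QCRecord(sample_id, r.cn_atomic, "excluded", r.iso.d13C, None))
        elif cls == "high_cn":
            if fit.significant_negative:
                corrected = correct_d13c(r.iso.d13C, r.cn_atomic, fit, threshold)
                out.append(
                    QCRecord(sample_id, r.cn_atomic, "high_cn_corrected", r.iso.d13C, corrected)
                )
            else:
                out.append(
                    QCRecord(sample_id, r.cn_atomic, "high_cn_uncorrectable", r.iso.d13C, r.iso.d13C)
                )
        else:
            out.append(QCRecord(sample_id, r.cn_atomic, cls, r.iso.d13C, r.iso.d13C))
    return out, fit


def qc_report_frame(qc_records):
    """QC report as a DataFrame (sample_id, cn_atomic, status, d13C_raw, d13C_used)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [q.sample_id for q in qc_records],
            "cn_atomic": [q.cn_atomic for q in qc_records],
            "status": [q.status for q in qc_records],
            "d13C_raw": [q.d13C_raw for q in qc_records],
            "d13C_used": [q.d13C_used for q in qc_records],
        }
    )
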