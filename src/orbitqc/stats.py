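"""Cohort-level volume statistics: paired comparisons and group summaries.

Volumes are compared pairwise within patients (unaffected vs affected vs
reconstructed; CT vs CBCT) with a paired t-test by default and the
Wilcoxon signed-rank test on request; modality agreement additionally
reports Bland–Altman limits. No multiple-testing correction is applied by
default (a Holm option exists), mirroring common single-comparison
reporting practice in clinical volumetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "AgreementResult",
    "paired_volume_test",
    "modality_agreement",
    "group_summary",
    "holm_adjust",
]

_FRACTURE_CLASSES = (
    "anterior_central_floor",
    "posterior_ledge",
    "complex_medial",
    "complex_lateral",
)
_GROUPS = ("Navi", "conv")


@dataclass
class PairedTestResult:
    """Outcome of a paired two-sided location test on volumes (ml)."""

    mean_difference_ml: float
    p_value: float
    statistic: float
    n: int
    method: str
    degenerate: bool = False   # zero-variance differences: p reported as 1


@dataclass
class AgreementResult:
    """Bland–Altman style modality agreement."""

    mean_difference_ml: float
    loa_lower_ml: float
    loa_upper_ml: float
    p_value: float
    n: int


def _paired(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length ({len(a)} vs {len(b)})")
    if len(a) < 3:
        raise ValueError("need n >= 3 pairs")
    return a, b


def paired_volume_test(a, b, method: str = "t") -> PairedTestResult:
    """Two-sided paired test of volumes ``b`` against ``a``.

    The reported effect is mean(b - a) in ml. ``method`` is ``'t'``
    (paired t-test, default) or ``'wilcoxon'`` (signed-rank). Identical
    vectors have zero variance, where both tests are undefined; this is
    reported as p = 1 with ``degenerate=True`` rather than NaN.
    """
    a, b = _paired(a, b)
    diff = b - a
    effect = float(diff.mean())
    if np.allclose(diff, diff[0]):
        if diff[0] == 0:
            return PairedTestResult(0.0, 1.0, 0.0, len(a), method, degenerate=True)
        if method == "t":
            # constant nonzero shift: t is infinite, p -> 0
            return PairedTestResult(effect, 0.0, np.inf * np.sign(diff[0]),
                                    len(a), method, degenerate=True)
    if method == "t":
        res = sps.ttest_rel(b, a)
        return PairedTestResult(effect, float(res.pvalue), float(res.statistic),
                                len(a), "t")
    if method == "wilcoxon":
        res = sps.wilcoxon(b, a, zero_method="wilcox", method="auto")
        return PairedTestResult(effect, float(res.pvalue), float(res.statistic),
                                len(a), "wilcoxon")
    raise ValueError(f"unknown method {method!r}")


def modality_agreement(volumes_ct, volumes_cbct) -> AgreementResult:
    """Paired CT-vs-CBCT agreement: mean difference, 1.96 SD limits, p."""
    ct, cbct = _paired(volumes_ct, volumes_cbct)
    diff = cbct - ct
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    test = paired_volume_test(ct, cbct)
    return AgreementResult(
        mean_difference_ml=md,
        loa_lower_ml=md - 1.96 * sd,
        loa_upper_ml=md + 1.96 * sd,
        p_value=test.p_value,
        n=len(ct),
    )


def group_summary(records: pd.DataFrame, stratifiers: Sequence[str] = ("gender",),
                  volume_columns: Sequence[str] = ("unaffected_CT", "affected_CT",
                                                   "unaffected_CBCT",
                                                   "reconstructed_CBCT")) -> pd.DataFrame:
    """Mean +/- SD volume table stratified by gender / fracture class / group.

    One row per stratum; empty strata appear with n = 0. A single-record
    stratum reports SD = 0 with ``sd_flagged`` set.
    """
    known = {"gender": ("male", "female"), "fracture_class": _FRACTURE_CLASSES,
             "group": _GROUPS, "side": ("right", "left")}
    for s in stratifiers:
        if s not in known:
            raise ValueError(f"unknown stratifier {s!r}; choose from {sorted(known)}")
        if s not in records.columns:
            raise ValueError(f"records lack column {s!r}")
    rows = []
    levels = [known[s] for s in stratifiers]
    index = pd.MultiIndex.from_product(levels, names=list(stratifiers))
    for combo in index:
        sel = np.ones(len(records), dtype=bool)
        for s, value in zip(stratifiers, combo):
            sel &= (records[s] == value).to_numpy()
        sub = records[sel]
        row = dict(zip(stratifiers, combo))
        row["n"] = int(sel.sum())
        row["sd_flagged"] = bool(0 < row["n"] < 2)
        for col in volume_columns:
            if row["n"] == 0:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sd"] = np.nan
            else:
                vals = sub[col].to_numpy(dtype=float)
                row[f"{col}_mean"] = float(vals.mean())
                row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def holm_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in reports)."""
    p = np.asarray(list(p_values), dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
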