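"""Blank-corrected detection calling and group statistics.

Detection: each feature gets one threshold, ``max(3 x mean blank signal,
10,000)`` (not-found blanks count as zero signal). Sample cells at or above
the threshold are *detected*; everything else is annotated not-detected and
the threshold value is imputed so that a fold-change estimate remains
possible. Imputation can only shrink apparent fold changes toward zero.

Statistics per two-group contrast: a single-pass two-sided Grubbs outlier
test within each group (on the detection-called values), log2 transform,
log2 fold change = difference of group means with its standard error
(quadrature sum of the group SEMs), and a two-sided Welch t-test (Student's
available by config). No multiple-testing correction gates the results —
the screening criterion is the plain p < 0.05 — but a Benjamini-Hochberg
q-value column is emitted for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import IntensityMatrix, ToleranceConfig

__all__ = ["blank_threshold", "call_detection", "DetectionTable",
           "grubbs_critical", "grubbs_outlier", "compare_groups"]

CLASS_SIGNIFICANT = "enriched_sig"
CLASS_NONSIG = "changed_nonsig"
CLASS_UNDETECTED = "undetected"


def blank_threshold(blank_values: Sequence[float], cfg: ToleranceConfig) -> float:
    """Detection threshold from blank-control signals.

    ``max(blank_snr x aggregate(blanks), detection_floor)``; not-found
    (NaN) blanks count as zero signal, and an empty blank list leaves the
    floor in charge. The aggregate is the mean by default (``blank_agg``
    switches to max).
    """
    vals = np.nan_to_num(np.asarray(list(blank_values), dtype=float), nan=0.0)
    if vals.size == 0:
        agg = 0.0
    elif cfg.blank_agg == "mean":
        agg = float(vals.mean())
    elif cfg.blank_agg == "max":
        agg = float(vals.max())
    else:
        raise ValueError(f"unknown blank_agg {cfg.blank_agg!r}")
    return max(cfg.blank_snr * agg, cfg.detection_floor)


@dataclass
class DetectionTable:
    """Detection calls for a whole matrix, in wide form.

    ``raw`` keeps the sample columns of the input matrix (NaN = not found);
    ``detected`` and ``imputed`` are boolean masks; ``value_for_stats`` is
    raw where detected, the feature threshold where not.
    """

    raw: pd.DataFrame
    thresholds: pd.Series
    detected: pd.DataFrame
    value_for_stats: pd.DataFrame
    groups: dict[str, str]

    @property
    def imputed(self) -> pd.DataFrame:
        return ~self.detected

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.raw.columns if self.groups.get(c) == group]

    def to_frame(self) -> pd.DataFrame:
        """Long form: one row per (id, sample) detection call."""
        rows = []
        for sid in self.raw.columns:
            for fid in self.raw.index:
                raw = self.raw.at[fid, sid]
                det = bool(self.detected.at[fid, sid])
                rows.append({
                    "id": fid, "sample_id": sid, "raw": raw,
                    "threshold": self.thresholds[fid], "detected": det,
                    "value_for_stats": self.value_for_stats.at[fid, sid],
                    "imputed": not det,
                })
        return pd.DataFrame(rows)


def call_detection(m: IntensityMatrix, cfg: ToleranceConfig,
                   blank_columns: Sequence[str] | None = None) -> DetectionTable:
    """Apply the blank-threshold rule to every cell of the matrix.

    One threshold per feature, shared across samples; the boundary is
    inclusive (raw == threshold counts as detected).
    """
    blanks = list(blank_columns) if blank_columns is not None else m.blank_columns
    sample_cols = [c for c in m.values.columns if c not in blanks]
    blank_block = np.nan_to_num(m.values[blanks].to_numpy(), nan=0.0) \
        if blanks else np.zeros((len(m.values), 0))
    if blanks:
        agg = blank_block.mean(axis=1) if cfg.blank_agg == "mean" \
            else blank_block.max(axis=1)
    else:
        agg = np.zeros(len(m.values))
    thresholds = pd.Series(np.maximum(cfg.blank_snr * agg, cfg.detection_floor),
                           index=m.values.index, name="threshold")
    raw = m.values[sample_cols]
    detected = raw.ge(thresholds, axis=0) & raw.notna()
    value_for_stats = raw.where(detected, thresholds, axis=0)
    return DetectionTable(raw=raw, thresholds=thresholds, detected=detected,
                          value_for_stats=value_for_stats, groups=dict(m.groups))


# ---------------------------------------------------------------------------
# Grubbs outlier test
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided single-outlier Grubbs critical value.

    Closed form from the Student t quantile:
    ``G = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with
    ``t = t_{alpha/(2n), n-2}``.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_outlier(values: Sequence[float], alpha: float) -> int | None:
    """Index of the single most extreme point if it is a Grubbs outlier.

    Two-sided test; at most one point flagged; returns None for n < 3 or
    zero variance.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        return None
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    k = int(np.argmax(dev))
    if dev[k] / sd > grubbs_critical(x.size, alpha):
        return k
    return None


def _grubbs_mask(X: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise vectorized single-outlier Grubbs; True marks removals."""
    mask = np.zeros_like(X, dtype=bool)
    n = X.shape[1]
    if n < 3:
        return mask
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1)
    dev = np.abs(X - mean)
    k = dev.argmax(axis=1)
    rows = np.arange(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(sd > 0, dev[rows, k] / sd, 0.0)
    flag = (sd > 0) & (G > grubbs_critical(n, alpha))
    mask[rows[flag], k[flag]] = True
    return mask


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def _welch(mean_a, var_a, n_a, mean_b, var_b, n_b):
    se2 = var_a / n_a + var_b / n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean_a - mean_b) / np.sqrt(se2)
        df = se2 ** 2 / ((var_a / n_a) ** 2 / (n_a - 1) +
                         (var_b / n_b) ** 2 / (n_b - 1))
    return t, df


def _student(mean_a, var_a, n_a, mean_b, var_b, n_b):
    df = n_a + n_b - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    return t, np.broadcast_to(np.asarray(df, dtype=float), np.shape(t)).copy()


def compare_groups(calls: DetectionTable, group_a: str, group_b: str,
                   cfg: ToleranceConfig) -> pd.DataFrame:
    """Per-id statistics for the contrast ``group_a`` over ``group_b``.

    Returns one row per matrix id with n_a/n_b after outlier removal, the
    log2 fold change and its SEM, the two-sided p-value, the detection
    class, the removed sample ids and the detection threshold. A row whose
    groups are entirely undetected is classed ``undetected`` (its fold
    change is 0 by construction of imputation).
    """
    cols_a = calls.group_columns(group_a)
    cols_b = calls.group_columns(group_b)
    if not cols_a:
        raise KeyError(f"group {group_a!r} absent from detection calls")
    if not cols_b:
        raise KeyError(f"group {group_b!r} absent from detection calls")
    A = calls.value_for_stats[cols_a].to_numpy(dtype=float)
    B = calls.value_for_stats[cols_b].to_numpy(dtype=float)
    mask_a = _grubbs_mask(A, cfg.grubbs_alpha)
    mask_b = _grubbs_mask(B, cfg.grubbs_alpha)
    A = np.where(mask_a, np.nan, A)
    B = np.where(mask_b, np.nan, B)
    La, Lb = np.log2(A), np.log2(B)
    if cfg.test_scale == "log2":
        Ta, Tb = La, Lb
    elif cfg.test_scale == "linear":
        Ta, Tb = A, B
    else:
        raise ValueError(f"unknown test_scale {cfg.test_scale!r}")

    n_a = np.sum(~np.isnan(Ta), axis=1)
    n_b = np.sum(~np.isnan(Tb), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.nanmean(La, axis=1) - np.nanmean(Lb, axis=1)
        sem = np.sqrt(np.nanvar(La, axis=1, ddof=1) / n_a +
                      np.nanvar(Lb, axis=1, ddof=1) / n_b)
        mean_a, mean_b = np.nanmean(Ta, axis=1), np.nanmean(Tb, axis=1)
        var_a, var_b = (np.nanvar(Ta, axis=1, ddof=1),
                        np.nanvar(Tb, axis=1, ddof=1))
    test = _welch if cfg.ttest == "welch" else _student
    t, df = test(mean_a, var_a, n_a, mean_b, var_b, n_b)
    with np.errstate(invalid="ignore"):
        p = 2 * sps.t.sf(np.abs(t), df)
    # degenerate cases: zero variance in both groups
    zero_se = (var_a + var_b) == 0
    p = np.where(zero_se & (mean_a == mean_b), 1.0, p)
    p = np.where(zero_se & (mean_a != mean_b), 0.0, p)
    p = np.where((n_a < 2) | (n_b < 2), np.nan, p)

    any_detected = (calls.detected[cols_a].any(axis=1) |
                    calls.detected[cols_b].any(axis=1)).to_numpy()
    significant = np.nan_to_num(p, nan=1.0) < cfg.alpha
    cls = np.where(~any_detected, CLASS_UNDETECTED,
                   np.where(significant, CLASS_SIGNIFICANT, CLASS_NONSIG))

    finite_p = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite_p.any():
        q[finite_p] = multipletests(p[finite_p], method="fdr_bh")[1]

    ids = calls.raw.index
    outliers = []
    for i in range(len(ids)):
        removed = [cols_a[j] for j in np.flatnonzero(mask_a[i])] + \
                  [cols_b[j] for j in np.flatnonzero(mask_b[i])]
        outliers.append(",".join(removed))
    return pd.DataFrame({
        "id": ids, "group_a": group_a, "group_b": group_b,
        "n_a": n_a, "n_b": n_b, "log2fc": log2fc, "sem": sem,
        "p_value": p, "q_value": q, "class": cls,
        "outliers_removed": outliers,
        "threshold": calls.thresholds.to_numpy(),
    }).set_index("id", drop=False)
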