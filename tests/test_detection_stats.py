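"""Detection thresholds, Grubbs outliers and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from svmet.detection_stats import (CLASS_NONSIG, CLASS_SIGNIFICANT,
                                   CLASS_UNDETECTED, blank_threshold,
                                   call_detection, compare_groups,
                                   grubbs_critical, grubbs_outlier)
from svmet.io_formats import NOT_FOUND, IntensityMatrix, ToleranceConfig


def _matrix(rows: dict, groups: dict, roles: dict) -> IntensityMatrix:
    return IntensityMatrix(pd.DataFrame(rows).T, groups, roles)


@pytest.mark.parametrize("blanks,expected", [
    ([2000.0, 2000.0, 2000.0], 10000.0),   # floor dominates 3x2000
    ([5000.0, 5000.0], 15000.0),           # 3x rule
    ([], 10000.0),                         # no blanks -> floor
    ([NOT_FOUND, NOT_FOUND], 10000.0),     # ND blanks count as zero
    ([NOT_FOUND, 12000.0], 18000.0),       # mean over all blanks, ND as 0
])
def test_blank_threshold(cfg, blanks, expected):
    assert blank_threshold(blanks, cfg) == expected


def test_call_detection_boundary_and_imputation(cfg):
    groups = {"s1": "a", "s2": "a", "b1": "blank"}
    roles = {"s1": "sample", "s2": "sample", "b1": "blank"}
    m = _matrix({"x": {"s1": 9000.0, "s2": 10000.0, "b1": NOT_FOUND}},
                groups, roles)
    calls = call_detection(m, cfg)
    assert calls.thresholds["x"] == 10000.0
    assert not calls.detected.loc["x", "s1"]          # below threshold
    assert calls.detected.loc["x", "s2"]              # boundary inclusive
    assert calls.value_for_stats.loc["x", "s1"] == 10000.0
    assert calls.value_for_stats.loc["x", "s2"] == 10000.0
    assert calls.imputed.loc["x", "s1"] and not calls.imputed.loc["x", "s2"]


def test_call_detection_matches_cell_by_cell_oracle(cfg):
    rng = np.random.default_rng(3)
    n_feat, samples, blanks = 40, ["s1", "s2", "s3"], ["b1", "b2"]
    raw = rng.uniform(0, 5e4, size=(n_feat, 5))
    raw[rng.random(raw.shape) < 0.2] = np.nan
    df = pd.DataFrame(raw, columns=samples + blanks,
                      index=[f"f{i}" for i in range(n_feat)])
    groups = {**{s: "g" for s in samples}, **{b: "blank" for b in blanks}}
    roles = {**{s: "sample" for s in samples}, **{b: "blank" for b in blanks}}
    calls = call_detection(IntensityMatrix(df, groups, roles), cfg)
    for fid in df.index:
        bvals = [0.0 if math.isnan(df.loc[fid, b]) else df.loc[fid, b]
                 for b in blanks]
        thr = max(cfg.blank_snr * np.mean(bvals), cfg.detection_floor)
        assert calls.thresholds[fid] == thr
        for s in samples:
            r = df.loc[fid, s]
            detected = (not math.isnan(r)) and r >= thr
            assert calls.detected.loc[fid, s] == detected
            assert calls.value_for_stats.loc[fid, s] == (r if detected else thr)


def test_grubbs_examples():
    assert grubbs_outlier([10, 11, 12, 50], 0.05) == 3   # G=1.4987 > 1.4812
    assert grubbs_outlier([10, 11, 12, 13], 0.05) is None
    assert grubbs_outlier([5, 5, 5], 0.05) is None       # zero variance
    assert grubbs_outlier([1, 100], 0.05) is None        # n < 3


def test_grubbs_critical_matches_published_table():
    # published two-sided alpha=0.05 critical values
    published = {3: 1.1543, 4: 1.4812, 5: 1.7150, 6: 1.8871,
                 7: 2.0200, 10: 2.2900, 15: 2.5483, 20: 2.7082}
    for n, g in published.items():
        assert grubbs_critical(n, 0.05) == pytest.approx(g, abs=1e-3)


def test_grubbs_critical_matches_t_closed_form():
    for n in range(3, 31):
        t = sps.t.ppf(1 - 0.05 / (2 * n), n - 2)
        expected = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        assert grubbs_critical(n, 0.05) == pytest.approx(expected, abs=1e-4)


def _calls_from_log2(cfg, a_log2, b_log2, blank=0.0):
    groups = {f"a{i}": "A" for i in range(len(a_log2))}
    groups.update({f"b{i}": "B" for i in range(len(b_log2))})
    groups["bl"] = "blank"
    roles = {c: ("blank" if c == "bl" else "sample") for c in groups}
    row = {f"a{i}": 2.0 ** v for i, v in enumerate(a_log2)}
    row.update({f"b{i}": 2.0 ** v for i, v in enumerate(b_log2)})
    row["bl"] = blank
    m = _matrix({"x": row}, groups, roles)
    return call_detection(m, cfg)


def test_compare_groups_worked_example(cfg):
    calls = _calls_from_log2(cfg, [20, 21, 22], [18, 19, 20])
    out = compare_groups(calls, "A", "B", cfg).loc["x"]
    assert out["log2fc"] == pytest.approx(2.0)
    assert out["sem"] == pytest.approx(0.8165, abs=1e-4)
    assert out["p_value"] == pytest.approx(0.0705, abs=1e-3)
    assert out["class"] == CLASS_NONSIG
    assert (out["n_a"], out["n_b"]) == (3, 3)


def test_compare_groups_antisymmetry(cfg):
    calls = _calls_from_log2(cfg, [20.3, 21.1, 22.4, 20.9], [18.2, 19.5, 20.1])
    ab = compare_groups(calls, "A", "B", cfg).loc["x"]
    ba = compare_groups(calls, "B", "A", cfg).loc["x"]
    assert ab["log2fc"] == pytest.approx(-ba["log2fc"])
    assert ab["p_value"] == pytest.approx(ba["p_value"])


def test_compare_groups_identical_groups(cfg):
    calls = _calls_from_log2(cfg, [20, 20, 20], [20, 20, 20])
    out = compare_groups(calls, "A", "B", cfg).loc["x"]
    assert out["log2fc"] == 0.0
    assert out["p_value"] == 1.0


def test_compare_groups_all_imputed_is_undetected(cfg):
    # every cell below the floor: both groups collapse onto the threshold
    calls = _calls_from_log2(cfg, [3, 4, 5], [6, 7, 8])
    out = compare_groups(calls, "A", "B", cfg).loc["x"]
    assert out["class"] == CLASS_UNDETECTED
    assert out["log2fc"] == 0.0


def test_compare_groups_applies_grubbs(cfg):
    # one wild replicate in A is removed before testing
    calls = _calls_from_log2(cfg, [20.0, 20.1, 20.2, 28.0], [18.0, 18.1, 18.2])
    out = compare_groups(calls, "A", "B", cfg).loc["x"]
    assert out["n_a"] == 3
    assert out["outliers_removed"] == "a3"
    assert out["log2fc"] == pytest.approx(2.0, abs=0.01)


def test_compare_groups_significant_class(cfg):
    calls = _calls_from_log2(cfg, [22.0, 22.1, 21.9, 22.05], [20.0, 20.1, 19.9, 20.05])
    out = compare_groups(calls, "A", "B", cfg).loc["x"]
    assert out["class"] == CLASS_SIGNIFICANT
    assert out["p_value"] < 0.05


def test_compare_groups_missing_group_errors(cfg):
    calls = _calls_from_log2(cfg, [20, 21, 22], [18, 19, 20])
    with pytest.raises(KeyError, match="nope"):
        compare_groups(calls, "nope", "B", cfg)


def test_imputation_shrinks_fold_change_toward_zero(cfg):
    # raw sub-threshold values in B would exaggerate the ratio; imputation
    # replaces them with the (higher) threshold, shrinking |log2fc|
    groups = {"a0": "A", "a1": "A", "a2": "A",
              "b0": "B", "b1": "B", "b2": "B", "bl": "blank"}
    roles = {c: ("blank" if c == "bl" else "sample") for c in groups}
    row = {"a0": 2e6, "a1": 2.1e6, "a2": 1.9e6,
           "b0": 500.0, "b1": 600.0, "b2": 400.0, "bl": 0.0}
    m = _matrix({"x": row}, groups, roles)
    out = compare_groups(call_detection(m, cfg), "A", "B", cfg).loc["x"]
    raw_fc = np.mean(np.log2([2e6, 2.1e6, 1.9e6])) - \
        np.mean(np.log2([500.0, 600.0, 400.0]))
    assert 0 < out["log2fc"] < raw_fc


def test_student_config_switch():
    cfg_w = ToleranceConfig()
    cfg_s = ToleranceConfig(ttest="student")
    calls = _calls_from_log2(cfg_w, [20.0, 21.5, 22.4], [18.2, 19.5, 19.6, 20.8])
    p_w = compare_groups(calls, "A", "B", cfg_w).loc["x", "p_value"]
    p_s = compare_groups(calls, "A", "B", cfg_s).loc["x", "p_value"]
    a = np.log2([2.0 ** v for v in [20.0, 21.5, 22.4]])
    b = np.log2([2.0 ** v for v in [18.2, 19.5, 19.6, 20.8]])
    assert p_w == pytest.approx(sps.ttest_ind(a, b, equal_var=False).pvalue)
    assert p_s == pytest.approx(sps.ttest_ind(a, b, equal_var=True).pvalue)
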