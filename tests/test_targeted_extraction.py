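"""Targeted extraction: XIC gates, apex semantics, oracle equivalence."""

import math

import numpy as np
import pytest

from svmet.io_formats import RtLibrary, SampleRun, ToleranceConfig
from svmet.targeted_extraction import (extract_matrix, find_study_apex,
                                       normalize_internal_standard, xic)

from conftest import make_run, make_spectrum, mass_entry, random_small_fixture


def brute_force_matrix(runs, library, cfg):
    """Definitional extraction: scan every peak of every spectrum, no index.

    Mirrors the two-pass contract: study apex from non-blank runs in the
    ±search-window, then per-sample max within apex ± apex tolerance.
    """
    out = {}
    for e in library:
        lo = e.theoretical_mz * (1 - cfg.targeted_ppm * 1e-6)
        hi = e.theoretical_mz * (1 + cfg.targeted_ppm * 1e-6)

        def trace(run, rt_lo, rt_hi):
            pts = []
            for s in run.spectra:
                if s.polarity != e.polarity or not rt_lo <= s.rt <= rt_hi:
                    continue
                total = sum(i for m, i in zip(s.mz, s.intensity)
                            if lo <= m <= hi)
                pts.append((s.rt, total))
            return pts

        if cfg.apex_reference == "study":
            best, apex = 0.0, None
            for run in runs:
                if run.role == "blank":
                    continue
                for rt, total in trace(run, e.expected_rt - cfg.rt_search_window,
                                       e.expected_rt + cfg.rt_search_window):
                    if total > best:
                        best, apex = total, rt
        else:
            apex = e.expected_rt
        for run in runs:
            if apex is None:
                out[(e.name, run.sample_id)] = math.nan
                continue
            pts = trace(run, apex - cfg.apex_rt_tol_min, apex + cfg.apex_rt_tol_min)
            h = max((t for _, t in pts), default=0.0)
            out[(e.name, run.sample_id)] = h if h > 0 else math.nan
    return out


def test_xic_single_planted_peak(cfg):
    run = make_run("r", [make_spectrum(5.0, [(200.0000002, 3.3e5)]),
                         make_spectrum(5.2, [(300.0, 1e6)])])
    rts, inten = xic(run, 200.0, 5, 4.5, 5.5, "positive")
    assert list(inten) == [3.3e5, 0.0]
    assert rts[0] == 5.0


def test_xic_excludes_out_of_tolerance_mz(cfg):
    run = make_run("r", [make_spectrum(5.0, [(200.0 * (1 + 6e-6), 1e6)])])
    _, inten = xic(run, 200.0, 5, 4.5, 5.5, "positive")
    assert inten.sum() == 0.0


def test_xic_sums_isobaric_peaks_in_one_scan(cfg):
    mzs = [(200.0 * (1 - 3e-6), 4e5), (200.0 * (1 + 2e-6), 6e5)]
    run = make_run("r", [make_spectrum(5.0, mzs)])
    _, inten = xic(run, 200.0, 5, 4.9, 5.1, "positive")
    assert inten[0] == pytest.approx(1e6)


def test_xic_polarity_is_a_hard_partition(cfg):
    run = make_run("r", [make_spectrum(5.0, [(200.0, 1e6)], "negative")])
    rts, _ = xic(run, 200.0, 5, 4.5, 5.5, "positive")
    assert rts.size == 0


def test_find_study_apex_basic(cfg):
    e = mass_entry("m", 200.0, rt=5.0)
    runs = [make_run(f"r{i}", [make_spectrum(4.8, [(200.0, 1e6)])])
            for i in range(3)]
    assert find_study_apex(runs, e, cfg) == pytest.approx(4.8)


def test_find_study_apex_not_found(cfg):
    e = mass_entry("m", 200.0, rt=5.0)
    runs = [make_run("r", [make_spectrum(5.0, [(300.0, 1e6)])])]
    assert math.isnan(find_study_apex(runs, e, cfg))


def test_find_study_apex_takes_global_maximum(cfg):
    e = mass_entry("m", 200.0, rt=7.5)
    r1 = make_run("r1", [make_spectrum(7.4, [(200.0, 1e6)])])
    r2 = make_run("r2", [make_spectrum(7.6, [(200.0, 2e6)])])
    assert find_study_apex([r1, r2], e, cfg) == pytest.approx(7.6)


def test_find_study_apex_ignores_blanks(cfg):
    e = mass_entry("m", 200.0, rt=5.0)
    blank = make_run("b", [make_spectrum(5.3, [(200.0, 9e9)])], role="blank")
    sample = make_run("s", [make_spectrum(4.9, [(200.0, 1e6)])])
    assert find_study_apex([blank, sample], e, cfg) == pytest.approx(4.9)


def test_extract_matrix_noiseless_recovery(cfg):
    lib = RtLibrary([mass_entry("a", 200.0, rt=5.0),
                     mass_entry("b", 350.0, "negative", rt=8.0)])
    runs = [make_run(f"r{i}", [
        make_spectrum(5.0, [(200.0, 1e6 * (i + 1))]),
        make_spectrum(8.0, [(350.0, 5e5)], "negative")]) for i in range(3)]
    m, detail = extract_matrix(runs, lib, cfg)
    assert list(m.values.loc["a"]) == [1e6, 2e6, 3e6]
    assert list(m.values.loc["b"]) == [5e5] * 3
    assert set(detail["name"]) == {"a", "b"}


def test_extract_matrix_apex_displacement_beyond_tolerance(cfg):
    lib = RtLibrary([mass_entry("a", 200.0, rt=5.0)])
    # run 1 defines the study apex at 5.0; run 2's peak sits +20 s away
    r1 = make_run("r1", [make_spectrum(5.0, [(200.0, 2e6)])])
    r2 = make_run("r2", [make_spectrum(5.0 + 20 / 60, [(200.0, 1e6)])])
    m, _ = extract_matrix([r1, r2], lib, cfg)
    assert m.values.loc["a", "r1"] == 2e6
    assert math.isnan(m.values.loc["a", "r2"])


def test_extract_matrix_polarity_mismatch_warns_not_crashes(cfg):
    lib = RtLibrary([mass_entry("neg_only", 200.0, "negative", rt=5.0)])
    runs = [make_run("r", [make_spectrum(5.0, [(200.0, 1e6)], "positive")])]
    with pytest.warns(UserWarning, match="polarity"):
        m, _ = extract_matrix(runs, lib, cfg)
    assert math.isnan(m.values.loc["neg_only", "r"])


@pytest.mark.filterwarnings("ignore:library entry")
@pytest.mark.parametrize("apex_reference", ["study", "library"])
def test_extract_matrix_equals_brute_force_oracle(apex_reference):
    cfg = ToleranceConfig(apex_reference=apex_reference)
    rng = np.random.default_rng(20240917)
    for _ in range(200):
        runs, lib = random_small_fixture(rng)
        m, _ = extract_matrix(runs, lib, cfg)
        oracle = brute_force_matrix(runs, lib, cfg)
        for e in lib:
            for run in runs:
                got = m.values.loc[e.name, run.sample_id]
                want = oracle[(e.name, run.sample_id)]
                assert (math.isnan(got) and math.isnan(want)) or got == want


def test_height_invariant_to_peaks_outside_gates(cfg):
    lib = RtLibrary([mass_entry("a", 200.0, rt=5.0)])
    base = [make_spectrum(5.0, [(200.0, 1e6)])]
    decoys = [make_spectrum(5.0, [(200.0 * (1 + 8e-6), 9e9)]),   # outside ppm
              make_spectrum(6.0, [(200.0, 9e9)]),                 # outside RT search
              make_spectrum(5.0, [(200.0, 9e9)], "negative")]     # other polarity
    m1, _ = extract_matrix([make_run("r", base)], lib, cfg)
    m2, _ = extract_matrix([make_run("r", base + decoys)], lib, cfg)
    assert m1.values.loc["a", "r"] == m2.values.loc["a", "r"] == 1e6


@pytest.mark.filterwarnings("ignore:library entry")
def test_tightening_tolerances_never_increases_height():
    rng = np.random.default_rng(7)
    for _ in range(50):
        runs, lib = random_small_fixture(rng)
        heights = []
        for ppm, tol_s in [(10, 30.0), (5, 7.5), (2, 3.0)]:
            cfg = ToleranceConfig(targeted_ppm=ppm, apex_rt_tol=tol_s,
                                  apex_reference="library")
            m, _ = extract_matrix(runs, lib, cfg)
            heights.append(m.values.fillna(0.0))
        assert (heights[1] <= heights[0]).all().all()
        assert (heights[2] <= heights[1]).all().all()


def test_normalize_internal_standard(cfg):
    lib = RtLibrary([mass_entry("istd", 176.113484, rt=3.0),
                     mass_entry("x", 200.0, rt=5.0)])
    runs = [make_run("r1", [make_spectrum(3.0, [(176.113484, 2e6)]),
                            make_spectrum(5.0, [(200.0, 4e6)])]),
            make_run("r2", [make_spectrum(3.0, [(176.113484, 1e6)]),
                            make_spectrum(5.0, [(200.0, 4e6)])])]
    m, _ = extract_matrix(runs, lib, cfg)
    norm = normalize_internal_standard(m, "istd")
    assert list(norm.values.loc["istd"]) == [1.0, 1.0]
    assert norm.values.loc["x", "r1"] == pytest.approx(2.0)
    assert norm.values.loc["x", "r2"] == pytest.approx(4.0)


def test_normalize_internal_standard_missing_names_sample(cfg):
    lib = RtLibrary([mass_entry("istd", 176.113484, rt=3.0),
                     mass_entry("x", 200.0, rt=5.0)])
    runs = [make_run("r1", [make_spectrum(3.0, [(176.113484, 2e6)]),
                            make_spectrum(5.0, [(200.0, 4e6)])]),
            make_run("r2", [make_spectrum(5.0, [(200.0, 4e6)])])]
    m, _ = extract_matrix(runs, lib, cfg)
    with pytest.raises(ValueError, match="r2"):
        normalize_internal_standard(m, "istd")
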