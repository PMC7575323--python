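"""Targeted peak-height extraction against a retention-time library.

For each library entry the pipeline first locates a *study apex* — the
retention time of the maximum extracted-ion-chromatogram point across all
non-blank runs inside the entry's expected RT ± the 0.5 min search window —
and then, per sample, reports the maximum XIC intensity within ±7.5 s of
that apex under a ±5 ppm m/z gate. Height means apex intensity (the maximum
point), not integrated area. Cells with no matching peak carry the
NOT_FOUND sentinel; the matrix always has exactly one row per library
entry.

The ``apex_reference`` config switch selects whether pass 2 anchors on the
study-wide apex (default) or directly on the library's expected RT.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (NOT_FOUND, IntensityMatrix, LibraryEntry, RtLibrary,
                         SampleRun, ToleranceConfig)

__all__ = ["LibraryEntry", "xic", "find_study_apex", "extract_matrix",
           "normalize_internal_standard"]


def xic(run: SampleRun, mz: float, ppm: float, rt_lo: float, rt_hi: float,
        polarity: str) -> tuple[np.ndarray, np.ndarray]:
    """Extracted-ion chromatogram: per-spectrum summed intensity in a window.

    Returns (rt, intensity) arrays, one point per spectrum of the requested
    polarity whose rt lies in [rt_lo, rt_hi]; intensity is the sum of all
    peaks inside the closed ppm window (0 if none). Lookup is binary search
    on the run's m/z-sorted flat index.
    """
    rts, sums, _ = _xic_indexed(run, mz, ppm, rt_lo, rt_hi, polarity)
    return rts, sums


def _xic_indexed(run: SampleRun, mz: float, ppm: float, rt_lo: float,
                 rt_hi: float, polarity: str):
    """XIC plus the per-polarity spectrum indices of each trace point."""
    if rt_lo >= rt_hi:
        raise ValueError("rt_lo must be < rt_hi")
    idx = run.flat_index(polarity)
    spec_rts = idx["spec_rts"]
    j0 = int(np.searchsorted(spec_rts, rt_lo, side="left"))
    j1 = int(np.searchsorted(spec_rts, rt_hi, side="right"))
    if j0 == j1:
        return np.empty(0), np.empty(0), np.empty(0, dtype=np.int64)
    fmz = idx["mz"]
    lo = mz * (1 - ppm * 1e-6)
    hi = mz * (1 + ppm * 1e-6)
    i0 = int(np.searchsorted(fmz, lo, side="left"))
    i1 = int(np.searchsorted(fmz, hi, side="right"))  # closed upper bound
    sums = np.zeros(j1 - j0)
    sid = idx["sid"][i0:i1]
    inside = (sid >= j0) & (sid < j1)
    np.add.at(sums, sid[inside] - j0, idx["intensity"][i0:i1][inside])
    return spec_rts[j0:j1], sums, np.arange(j0, j1, dtype=np.int64)


def _window_max(run: SampleRun, mz: float, ppm: float, rt_lo: float,
                rt_hi: float, polarity: str) -> tuple[float, float, float]:
    """(max summed intensity, rt of max, observed mz nearest theory) in window.

    Returns (0, nan, nan) when nothing matches.
    """
    rts, inten, spec_idx = _xic_indexed(run, mz, ppm, rt_lo, rt_hi, polarity)
    if rts.size == 0 or inten.max() <= 0:
        return 0.0, float("nan"), float("nan")
    k = int(np.argmax(inten))
    apex_rt = float(rts[k])
    # observed mz: the window peak nearest theory in the apex spectrum
    spec = run.flat_index(polarity)["specs"][int(spec_idx[k])]
    lo, hi = mz * (1 - ppm * 1e-6), mz * (1 + ppm * 1e-6)
    mask = (spec.mz >= lo) & (spec.mz <= hi)
    obs = spec.mz[mask]
    observed = float(obs[np.argmin(np.abs(obs - mz))]) if obs.size else float("nan")
    return float(inten[k]), apex_rt, observed


def find_study_apex(runs: Sequence[SampleRun], entry: LibraryEntry,
                    cfg: ToleranceConfig) -> float:
    """RT of the max-intensity XIC point across all non-blank runs.

    Searched within expected_rt ± rt_search_window; NOT_FOUND (NaN) when
    every trace is zero.
    """
    if not runs:
        raise ValueError("need at least one run")
    rt_lo = entry.expected_rt - cfg.rt_search_window
    rt_hi = entry.expected_rt + cfg.rt_search_window
    best, best_rt = 0.0, NOT_FOUND
    for run in runs:
        if run.role == "blank":
            continue
        h, rt, _ = _window_max(run, entry.theoretical_mz, cfg.targeted_ppm,
                               rt_lo, rt_hi, entry.polarity)
        if h > best:
            best, best_rt = h, rt
    return best_rt


def extract_matrix(runs: Sequence[SampleRun], library: RtLibrary,
                   cfg: ToleranceConfig) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Two-pass targeted extraction of the full library across all runs.

    Pass 1 finds each entry's study apex from the non-blank runs; pass 2
    takes, per sample (blanks included), the maximum XIC point within the
    apex ± apex_rt_tol and ± targeted_ppm gates. Returns the intensity
    matrix (one row per entry, never dropped) and a per-cell detail table
    with observed m/z, apex rt and ppm error.
    """
    if not runs:
        raise ValueError("need at least one run")
    run_pols = {s.polarity for r in runs for s in r.spectra}
    detail_rows = []
    data: dict[str, dict[str, float]] = {e.name: {} for e in library}
    for entry in library:
        if entry.polarity not in run_pols:
            warnings.warn(f"library entry {entry.name!r} has polarity "
                          f"{entry.polarity} absent from all runs; reporting ND")
            for run in runs:
                data[entry.name][run.sample_id] = NOT_FOUND
            continue
        if cfg.apex_reference == "study":
            anchor = find_study_apex(runs, entry, cfg)
        else:
            anchor = entry.expected_rt
        for run in runs:
            if np.isnan(anchor):
                h, rt, obs = 0.0, float("nan"), float("nan")
            else:
                h, rt, obs = _window_max(
                    run, entry.theoretical_mz, cfg.targeted_ppm,
                    anchor - cfg.apex_rt_tol_min, anchor + cfg.apex_rt_tol_min,
                    entry.polarity)
            found = h > 0
            data[entry.name][run.sample_id] = h if found else NOT_FOUND
            detail_rows.append({
                "name": entry.name, "sample_id": run.sample_id,
                "height": h if found else NOT_FOUND,
                "observed_mz": obs, "apex_rt": rt,
                "ppm_error": ((obs - entry.theoretical_mz) / entry.theoretical_mz * 1e6
                              if found and np.isfinite(obs) else float("nan")),
                "study_apex": anchor,
            })
    values = pd.DataFrame(data).T.reindex(
        index=[e.name for e in library],
        columns=[r.sample_id for r in runs])
    matrix = IntensityMatrix.from_runs(values, runs)
    return matrix, pd.DataFrame(detail_rows)


def normalize_internal_standard(m: IntensityMatrix, standard: str) -> IntensityMatrix:
    """Divide every cell by its sample's internal-standard height.

    The standard row becomes all 1.0; NOT_FOUND cells stay NOT_FOUND. A
    standard that is itself NOT_FOUND in any sample is an error naming the
    offending samples.
    """
    if standard not in m.values.index:
        raise KeyError(f"internal standard {standard!r} not in matrix")
    std = m.values.loc[standard]
    missing = [c for c in m.values.columns if not np.isfinite(std[c]) or std[c] <= 0]
    if missing:
        raise ValueError(
            f"internal standard {standard!r} not detected in samples: {missing}")
    return IntensityMatrix(m.values.div(std, axis=1), m.groups, m.roles)
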