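"""Untargeted MS1 feature discovery by greedy intensity-descending binning.

All MS1 peaks across the non-blank runs of a study are filtered by a
minimum intensity (1e5) and a within-spectrum signal-to-noise gate (10x the
spectrum's median peak intensity), then reduced to representative features:
candidates are visited in strictly non-increasing intensity order and each
is either absorbed by an existing same-polarity feature within 25 ppm in
m/z *and* 0.5 min in RT of that feature's founder values, or founds a new
feature. Feature lookup is bisection on an m/z-sorted index, never a full
scan. The founder's m/z and RT are the feature's representatives for good:
they are not re-averaged as members join, which keeps the pass order-stable.

Ties in intensity are broken by ascending m/z, then RT, then sample id, so
the pass is a total order and the output deterministic. Among several
eligible features the nearest in ppm wins, then the nearest in RT.

Feature intensities across samples (blanks included) are then quantified
with the targeted extraction engine, treating each feature as a transient
library entry anchored at its representative m/z and RT.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right, insort
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (IntensityMatrix, LibraryEntry, RtLibrary, SampleRun,
                         Spectrum, ToleranceConfig, get_adduct)
from .targeted_extraction import extract_matrix

__all__ = ["CandidatePeak", "FeatureDescriptor", "spectrum_noise",
           "pool_candidates", "bin_features", "quantify_features",
           "features_to_library"]


@dataclass(frozen=True)
class CandidatePeak:
    """An MS1 peak that passed the intensity and S/N gates."""

    mz: float
    intensity: float
    rt: float
    polarity: str
    sample_id: str
    noise: float

    @property
    def sort_key(self):
        # total order: intensity high->low, then mz, rt, sample_id ascending
        return (-self.intensity, self.mz, self.rt, self.sample_id)


@dataclass
class FeatureDescriptor:
    """A representative (m/z, RT, polarity) feature founded by its most
    intense member."""

    feature_id: str
    mz: float
    rt: float
    polarity: str
    founder_intensity: float
    member_count: int = 1


def spectrum_noise(s: Spectrum, proxy: str = "median") -> float:
    """Within-spectrum noise estimate.

    ``median`` (default) is the median peak intensity; the alternative is
    the mean of the lowest decile of intensities. An empty spectrum returns
    +inf so nothing in it can pass a signal-to-noise gate.
    """
    if len(s) == 0:
        return float("inf")
    if proxy == "median":
        return float(np.median(s.intensity))
    if proxy == "lowest_decile_mean":
        k = max(1, len(s) // 10)
        return float(np.sort(s.intensity)[:k].mean())
    raise ValueError(f"unknown noise proxy {proxy!r}")


def pool_candidates(runs: Sequence[SampleRun],
                    cfg: ToleranceConfig) -> list[CandidatePeak]:
    """All peaks from non-blank runs passing both gates, both polarities.

    A peak qualifies iff intensity >= min_intensity and intensity >=
    spectrum_snr x the within-spectrum noise estimate.
    """
    if not runs:
        raise ValueError("need at least one run")
    out: list[CandidatePeak] = []
    for run in runs:
        if run.role == "blank":
            continue
        for pol in ("positive", "negative"):
            idx = run.flat_index(pol)
            inten, sid = idx["intensity"], idx["sid"]
            if inten.size == 0:
                continue
            n_spec = idx["spec_rts"].size
            noise = _grouped_noise(inten, sid, n_spec, cfg.noise_proxy)
            mask = (inten >= cfg.min_intensity) & \
                   (inten >= cfg.spectrum_snr * noise[sid])
            for k in np.flatnonzero(mask):
                s = int(sid[k])
                out.append(CandidatePeak(float(idx["mz"][k]), float(inten[k]),
                                         float(idx["spec_rts"][s]), pol,
                                         run.sample_id, float(noise[s])))
    return out


def _grouped_noise(inten: np.ndarray, sid: np.ndarray, n_spec: int,
                   proxy: str) -> np.ndarray:
    """Per-spectrum noise for flattened peak arrays, matching
    :func:`spectrum_noise` exactly; empty spectra get +inf."""
    order = np.lexsort((inten, sid))
    si, vals = sid[order], inten[order]
    counts = np.bincount(si, minlength=n_spec)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    noise = np.full(n_spec, np.inf)
    nz = counts > 0
    if proxy == "median":
        lo = offsets + (counts - 1) // 2
        hi = offsets + counts // 2
        noise[nz] = 0.5 * (vals[lo[nz]] + vals[hi[nz]])
    elif proxy == "lowest_decile_mean":
        k = np.maximum(1, counts // 10)
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        noise[nz] = (cs[(offsets + k)[nz]] - cs[offsets[nz]]) / k[nz]
    else:
        raise ValueError(f"unknown noise proxy {proxy!r}")
    return noise


def bin_features(cands: Sequence[CandidatePeak],
                 cfg: ToleranceConfig) -> list[FeatureDescriptor]:
    """Greedy intensity-descending binning with bisection lookup."""
    ordered = sorted(cands, key=lambda c: c.sort_key)
    features: list[FeatureDescriptor] = []
    # per-polarity parallel sorted lists: founder mz -> feature list index
    index: dict[str, tuple[list[float], list[int]]] = {
        "positive": ([], []), "negative": ([], [])}
    for c in ordered:
        mzs, idxs = index[c.polarity]
        lo = c.mz / (1 + cfg.bin_ppm * 1e-6)
        hi = c.mz / (1 - cfg.bin_ppm * 1e-6)
        i0 = bisect_left(mzs, lo)
        i1 = bisect_right(mzs, hi)
        best = None
        for j in range(i0, i1):
            f = features[idxs[j]]
            dppm = abs(c.mz - f.mz) / f.mz * 1e6
            drt = abs(c.rt - f.rt)
            if dppm <= cfg.bin_ppm and drt <= cfg.bin_rt_delta:
                key = (dppm, drt, f.feature_id)
                if best is None or key < best[0]:
                    best = (key, f)
        if best is not None:
            best[1].member_count += 1
        else:
            f = FeatureDescriptor(
                feature_id=f"F{len(features) + 1:05d}_{'pos' if c.polarity == 'positive' else 'neg'}",
                mz=c.mz, rt=c.rt, polarity=c.polarity,
                founder_intensity=c.intensity)
            features.append(f)
            k = bisect_left(mzs, c.mz)
            mzs.insert(k, c.mz)
            idxs.insert(k, len(features) - 1)
    return features


def features_to_library(features: Sequence[FeatureDescriptor]) -> RtLibrary:
    """View features as transient library entries anchored at their
    representative m/z and RT (the m/z is taken as-is, not recomputed)."""
    entries = []
    for f in features:
        adduct = get_adduct("[M+H]+" if f.polarity == "positive" else "[M-H]-")
        entries.append(LibraryEntry(
            name=f.feature_id,
            monoisotopic_mass=f.mz * abs(adduct.charge) - adduct.mass_shift,
            adduct=adduct, polarity=f.polarity, expected_rt=f.rt))
    return RtLibrary(entries)


def quantify_features(features: Sequence[FeatureDescriptor],
                      runs: Sequence[SampleRun], cfg: ToleranceConfig,
                      apex_reference: str = "library",
                      ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Extract every feature's height across all samples, blanks included.

    Uses the targeted engine with the feature-definition tolerances — the
    binning ppm for m/z and the binning RT delta around the feature's
    representative RT — since an untargeted feature is defined by its m/z
    (25 ppm) at a retention time window, not by the much tighter targeted
    apex gate. By default the feature's own RT is the anchor
    (``apex_reference="library"``); pass ``"study"`` to re-locate the
    study-wide apex near the feature RT first.
    """
    lib = features_to_library(features)
    qcfg = cfg.replace(targeted_ppm=cfg.bin_ppm,
                       apex_rt_tol=cfg.bin_rt_delta * 60.0,
                       apex_reference=apex_reference)
    return extract_matrix(runs, lib, qcfg)


def features_table(features: Sequence[FeatureDescriptor]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": f.feature_id, "mz": f.mz, "rt_min": f.rt,
        "polarity": f.polarity, "founder_intensity": f.founder_intensity,
        "n_members": f.member_count,
    } for f in features])
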