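"""Shared fixtures: hand-built runs and random small study fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from svmet.io_formats import (LibraryEntry, RtLibrary, SampleRun, Spectrum,
                              ToleranceConfig, get_adduct)


@pytest.fixture
def cfg() -> ToleranceConfig:
    return ToleranceConfig()


def make_spectrum(rt: float, peaks: list[tuple[float, float]],
                  polarity: str = "positive") -> Spectrum:
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    return Spectrum(rt, polarity, mz, inten)


def make_run(sample_id: str, spectra: list[Spectrum], group: str = "g",
             role: str = "sample") -> SampleRun:
    return SampleRun(sample_id, spectra, group=group, role=role)


def mass_entry(name: str, mz: float, polarity: str = "positive",
               rt: float = 5.0) -> LibraryEntry:
    """Library entry pinned at an observed m/z (mass back-computed)."""
    adduct = get_adduct("[M+H]+" if polarity == "positive" else "[M-H]-")
    return LibraryEntry(name=name, monoisotopic_mass=mz - adduct.mass_shift,
                        adduct=adduct, polarity=polarity, expected_rt=rt)


def random_small_fixture(rng: np.random.Generator,
                         n_runs: int = 3, n_spectra: int = 4,
                         n_entries: int = 3):
    """A tiny random study: runs with scattered peaks plus a small library.

    Peaks are placed both near library m/z values (within a few ppm) and
    far away, at retention times inside and outside the search window, so
    oracle comparisons exercise every gate.
    """
    entries = [mass_entry(f"m{j}", 150.0 + 37.0 * j,
                          "positive" if j % 2 == 0 else "negative",
                          rt=4.0 + j)
               for j in range(n_entries)]
    library = RtLibrary(entries)
    runs = []
    for i in range(n_runs):
        spectra = []
        for k in range(n_spectra):
            rt = float(rng.uniform(3.0, 4.0 + n_entries + 1.0))
            pol = "positive" if rng.random() < 0.5 else "negative"
            peaks = []
            for _ in range(rng.integers(1, 8)):
                if rng.random() < 0.5:
                    e = entries[int(rng.integers(0, n_entries))]
                    mz = e.theoretical_mz * (1 + rng.normal(0, 4e-6))
                else:
                    mz = float(rng.uniform(100, 400))
                peaks.append((mz, float(rng.uniform(1e3, 1e7))))
            spectra.append(make_spectrum(rt, peaks, pol))
        runs.append(make_run(f"s{i}", spectra))
    return runs, library
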