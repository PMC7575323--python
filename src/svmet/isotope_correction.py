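"""Natural-isotope-abundance correction of mass-isotopomer distributions.

GC/MS fragment intensities for M+0 .. M+k are contaminated by naturally
occurring heavy isotopes. The standard correction builds a lower-triangular
matrix whose column j is the natural envelope of the species carrying j
tracer-derived mass shifts (those j tracer atoms have defined mass and are
removed from the natural pool), then solves the linear system under a
non-negativity constraint and renormalizes to fractions.

For unlabeled samples only column 0 matters; the general tracer machinery
is included because the correction lineage is tracer-oriented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .chem import Formula, isotope_distribution

__all__ = ["MidVector", "CorrectionMatrix", "build_correction_matrix",
           "correct_mid"]


@dataclass(frozen=True)
class MidVector:
    """Raw fragment intensities for M+0 .. M+k (arbitrary units, >= 0)."""

    formula: Formula
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("intensities must be a non-empty 1-D vector")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class CorrectionMatrix:
    """(k+1) x (k+1) natural-abundance convolution matrix.

    Column j holds the envelope of the j-shift species; every column sums
    to at most 1, and column 0 is the fragment's plain natural envelope.
    """

    formula: Formula
    tracer_element: str
    matrix: np.ndarray

    @property
    def k(self) -> int:
        return self.matrix.shape[0] - 1


def build_correction_matrix(f: Formula, k: int,
                            tracer_element: str) -> CorrectionMatrix:
    """Build the correction matrix for up to k tracer mass shifts.

    The tracer element must appear in the formula with count >= k; for
    column j the j labeled atoms are excluded from the natural-abundance
    convolution (they contribute a fixed +j shift instead).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    counts = dict(f.element_counts)
    n_tracer = counts.get(tracer_element, 0)
    if k > 0 and n_tracer < k:
        raise ValueError(
            f"formula has {n_tracer} {tracer_element} atoms, fewer than k={k}")
    size = k + 1
    M = np.zeros((size, size))
    for j in range(size):
        cj = dict(counts)
        if j:
            cj[tracer_element] = n_tracer - j
            if cj[tracer_element] == 0:
                del cj[tracer_element]
        env = isotope_distribution(Formula(cj), size - j)
        M[j:, j] = env
    return CorrectionMatrix(f, tracer_element, M)


def correct_mid(mid: MidVector | np.ndarray, cm: CorrectionMatrix) -> np.ndarray:
    """Recover the tracer-shift fractions underlying a measured MID.

    Solves ``cm.matrix @ x = mid`` with x >= 0 and returns x normalized to
    sum 1. A plain triangular solve is used when it already yields a
    non-negative solution (the well-conditioned, noise-free case);
    otherwise non-negative least squares.
    """
    y = mid.intensities if isinstance(mid, MidVector) else \
        np.asarray(mid, dtype=float)
    if y.shape != (cm.matrix.shape[0],):
        raise ValueError(f"MID length {y.size} does not match matrix size "
                         f"{cm.matrix.shape[0]}")
    if not np.any(y > 0):
        raise ValueError("all-zero MID cannot be corrected")
    try:
        x = np.linalg.solve(cm.matrix, y)
    except np.linalg.LinAlgError:
        x = None
    if x is None or np.any(x < -1e-12 * max(1.0, np.abs(x).max())):
        x, _ = nnls(cm.matrix, y)
    x = np.clip(x, 0.0, None)
    return x / x.sum()
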