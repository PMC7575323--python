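"""Molecular-formula arithmetic for small-molecule mass spectrometry.

Monoisotopic masses, adduct m/z values, ppm matching windows and natural
isotope distributions, backed by a single embedded element-constants table
(CODATA/IUPAC monoisotopic masses and representative natural abundances) so
that every downstream number is bit-reproducible.

Conventions
-----------
* Masses are in daltons (Da), m/z in thomson (Th).
* The proton mass is fixed at 1.00727646 Da; the electron mass is ignored
  in adduct arithmetic (sub-ppm effect, well below the 5 ppm matching gate
  used for targeted extraction).
* Only singly charged adducts ship by default; the registry is extensible.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

import numpy as np

PROTON_MASS = 1.00727646  # Da

__all__ = [
    "PROTON_MASS",
    "Formula",
    "Adduct",
    "PpmWindow",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_window",
    "isotope_distribution",
]


def _load_elements() -> dict[str, tuple[float, np.ndarray]]:
    """Read the embedded constants table.

    Returns element -> (monoisotopic mass, per-atom abundance vector indexed
    by nominal mass shift; zeros fill missing shifts).
    """
    table: dict[str, tuple[float, np.ndarray]] = {}
    path = resources.files("svmet.data").joinpath("elements.csv")
    with path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            shifts = [int(s) for s in row["isotope_shifts"].split(";")]
            abund = [float(a) for a in row["isotope_abundances"].split(";")]
            vec = np.zeros(max(shifts) + 1)
            vec[shifts] = abund
            table[row["element"]] = (float(row["monoisotopic_mass"]), vec)
    return table


_ELEMENTS: dict[str, tuple[float, np.ndarray]] = _load_elements()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition; counts are strictly positive."""

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n <= 0:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.element_counts)
        for el, n in other.element_counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.element_counts.items()))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        items = dict(self.element_counts)
        out = []
        for el in ("C", "H"):
            if el in items:
                n = items.pop(el)
                out.append(el + (str(n) if n > 1 else ""))
        for el in sorted(items):
            n = items[el]
            out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)


def parse_formula(text: str) -> Formula:
    """Parse a plain Hill-style formula string such as ``"C5H9NO4"``.

    Omitted counts mean 1. Parentheses and isotope labels are not part of
    the grammar; raises :class:`FormulaError` on unknown symbols, explicit
    zero counts or anything that does not tokenize cleanly.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(num) if num else 1
        if n == 0:
            raise FormulaError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return Formula(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of principal-isotope masses, in Da. The empty formula weighs 0."""
    return float(sum(n * _ELEMENTS[el][0] for el, n in f.element_counts.items()))


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: name, integer charge and mass shift in Da."""

    name: str
    charge: int
    mass_shift: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
    "[M+Na]+": Adduct("[M+Na]+", +1, +_ELEMENTS["Na"][0] - 0.00054858),
    "[M+K]+": Adduct("[M+K]+", +1, +_ELEMENTS["K"][0] - 0.00054858),
}
# Na/K adducts subtract one electron mass since the cation donates no proton;
# for [M+H]+/[M-H]- the proton-mass convention already absorbs it (the
# residual is < 4 ppb at m/z 150, far below any matching tolerance here).


def get_adduct(name: str) -> Adduct:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}") from None


def adduct_mz(mass: float, adduct: Adduct) -> float:
    """m/z of the adduct ion of a neutral of the given monoisotopic mass."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {mass}")
    return (mass + adduct.mass_shift) / abs(adduct.charge)


@dataclass(frozen=True)
class PpmWindow:
    """A symmetric multiplicative m/z window, closed on both ends."""

    center: float
    ppm: float
    lo: float
    hi: float

    def __contains__(self, mz: float) -> bool:
        return self.lo <= mz <= self.hi


def ppm_window(center: float, ppm: float) -> PpmWindow:
    """Build the closed window ``center * (1 ± ppm 1e-6)``."""
    if center <= 0:
        raise ValueError("window center must be positive")
    if ppm < 0:
        raise ValueError("ppm tolerance must be non-negative")
    return PpmWindow(center, ppm, center * (1 - ppm * 1e-6), center * (1 + ppm * 1e-6))


def _element_distribution(el: str, count: int, n_peaks: int) -> np.ndarray:
    """Distribution of nominal mass shifts for `count` atoms of one element."""
    _, per_atom = _ELEMENTS[el]
    if per_atom.sum() == 0:
        raise ValueError(f"no natural-abundance data for element {el}")
    out = np.array([1.0])
    for _ in range(count):
        out = np.convolve(out, per_atom)[:n_peaks]
    return out


def isotope_distribution(f: Formula, n_peaks: int) -> np.ndarray:
    """Natural-abundance probabilities of the M+0 .. M+(n_peaks-1) species.

    Computed by convolving per-element shift distributions; entries are
    non-negative and sum to at most 1 (exactly 1 in the limit of many peaks).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    out = np.array([1.0])
    for el, n in f.element_counts.items():
        out = np.convolve(out, _element_distribution(el, n, n_peaks))[:n_peaks]
    full = np.zeros(n_peaks)
    full[: len(out)] = out
    return full
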