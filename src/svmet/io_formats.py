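"""File formats and in-memory containers for the pipeline.

Supported formats:

* **mzXML** (read/write, centroided MS1 only) — the interchange format the
  pipeline consumes; base64 network-byte-order peak pairs, 32- or 64-bit,
  optionally zlib-compressed.
* **peak-table TSV** — a plain-text dialect of the same data (columns
  ``scan_id, rt_min, polarity, mz, intensity``) convenient for fixtures and
  inspection; lossless round-trip with the in-memory model.
* **retention-time library CSV** — columns ``name``, ``formula`` or
  ``monoisotopic_mass``, ``adduct``, ``polarity``, ``rt_min``; theoretical
  m/z is computed at load time.
* **sample-sheet CSV** — columns ``sample_id, group, role, path`` mapping
  acquisitions to experimental arms; blanks carry role ``blank``.

Retention time is stored in minutes everywhere; the 7.5 s apex tolerance is
exposed in minutes via :attr:`ToleranceConfig.apex_rt_tol_min`. Polarity is
a hard partition: peaks, features and library entries never match across
polarities.
"""

from __future__ import annotations

import base64
import math
import struct
import tomllib
import zlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mzxml as _pyteomics_mzxml

from . import chem
from .chem import Adduct, Formula, adduct_mz, get_adduct, parse_formula

NOT_FOUND = float("nan")

POSITIVE = "positive"
NEGATIVE = "negative"
_POLARITIES = (POSITIVE, NEGATIVE)


def is_not_found(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


class FileFormatError(ValueError):
    """Raised when an input file violates the supported dialect."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mz) and math.isfinite(self.intensity)):
            raise ValueError("peak fields must be finite")
        if self.mz <= 0 or self.intensity < 0:
            raise ValueError("peak requires mz > 0 and intensity >= 0")


class Spectrum:
    """One centroided MS1 scan: rt (minutes), polarity and mz-sorted peaks.

    Peaks are held as parallel numpy arrays sorted ascending by m/z.
    """

    __slots__ = ("rt", "polarity", "mz", "intensity", "scan_id")

    def __init__(self, rt: float, polarity: str, mz, intensity, scan_id: int = 0,
                 presorted: bool = False):
        if polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}, got {polarity!r}")
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if not presorted and mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, intensity = mz[order], intensity[order]
        self.rt = float(rt)
        self.polarity = polarity
        self.mz = mz
        self.intensity = intensity
        self.scan_id = int(scan_id)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return int(self.mz.size)

    def __repr__(self) -> str:
        return f"Spectrum(rt={self.rt:.3f} min, {self.polarity}, {len(self)} peaks)"


class SampleRun:
    """One LC-MS acquisition plus its sample metadata."""

    def __init__(self, sample_id: str, spectra: Sequence[Spectrum],
                 group: str = "", role: str = "sample"):
        if role not in ("sample", "blank"):
            raise ValueError("role must be 'sample' or 'blank'")
        self.sample_id = sample_id
        self.group = group if group else ("blank" if role == "blank" else "")
        self.role = role
        self.spectra = sorted(spectra, key=lambda s: s.rt)
        self._flat: dict | None = None  # lazy m/z-sorted index, per polarity

    def flat_index(self, polarity: str) -> dict:
        """m/z-sorted flattening of all spectra of one polarity.

        Returns a dict with keys ``mz``, ``intensity``, ``sid`` (peak arrays
        sorted by m/z; ``sid`` indexes into the per-polarity spectrum list),
        ``spec_rts`` (rt per spectrum, non-decreasing) and ``specs`` (the
        spectra themselves). This index backs binary-search XIC extraction.
        """
        if self._flat is None:
            self._flat = {}
            for pol in _POLARITIES:
                specs = [s for s in self.spectra if s.polarity == pol]
                if specs:
                    mz = np.concatenate([s.mz for s in specs])
                    inten = np.concatenate([s.intensity for s in specs])
                    sid = np.repeat(np.arange(len(specs), dtype=np.int64),
                                    [len(s) for s in specs])
                    order = np.argsort(mz, kind="stable")
                    mz, inten, sid = mz[order], inten[order], sid[order]
                else:
                    mz = inten = np.empty(0)
                    sid = np.empty(0, dtype=np.int64)
                self._flat[pol] = {
                    "mz": mz, "intensity": inten, "sid": sid,
                    "spec_rts": np.array([s.rt for s in specs]),
                    "specs": specs,
                }
        return self._flat[polarity]

    def __repr__(self) -> str:
        return (f"SampleRun({self.sample_id!r}, group={self.group!r}, "
                f"role={self.role!r}, {len(self.spectra)} spectra)")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToleranceConfig:
    """All pipeline tolerances and statistical settings.

    Defaults are the processing parameters of the profiling workflow this
    package implements: 5 ppm / ±7.5 s apex tolerance inside a ±0.5 min
    search window for targeted extraction; 25 ppm / 0.5 min / 1e5 minimum
    intensity / 10x within-spectrum S/N for untargeted binning; 3x blank
    S/N with a 10,000-unit floor for detection; alpha 0.05 and two-fold
    thresholds for the screen.
    """

    targeted_ppm: float = 5.0          # ppm, targeted extraction window
    apex_rt_tol: float = 7.5           # seconds, per-sample apex tolerance
    rt_search_window: float = 0.5      # minutes, initial apex search window
    bin_ppm: float = 25.0              # ppm, untargeted feature discrimination
    bin_rt_delta: float = 0.5          # minutes, untargeted RT discrimination
    min_intensity: float = 1e5         # units, untargeted candidate floor
    spectrum_snr: float = 10.0         # x within-spectrum noise
    blank_snr: float = 3.0             # x mean blank signal
    detection_floor: float = 10000.0   # units
    alpha: float = 0.05
    fc_threshold: float = 2.0          # fold, screen threshold
    grubbs_alpha: float = 0.05
    rng_seed: int = 0
    # documented open choices, config-switchable
    apex_reference: str = "study"      # study | library
    ttest: str = "welch"               # welch | student
    test_scale: str = "log2"           # log2 | linear
    blank_agg: str = "mean"            # mean | max
    noise_proxy: str = "median"        # median | lowest_decile_mean
    require_depletion_significance: bool = True

    def __post_init__(self) -> None:
        for name in ("targeted_ppm", "apex_rt_tol", "rt_search_window", "bin_ppm",
                     "bin_rt_delta", "min_intensity", "spectrum_snr", "blank_snr",
                     "detection_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha", "grubbs_alpha"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.apex_reference not in ("study", "library"):
            raise ValueError("apex_reference must be 'study' or 'library'")

    @property
    def apex_rt_tol_min(self) -> float:
        """Apex tolerance converted to minutes (7.5 s -> 0.125 min)."""
        return self.apex_rt_tol / 60.0

    def replace(self, **kw) -> "ToleranceConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "ToleranceConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise FileFormatError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Retention-time library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryEntry:
    """A targeted metabolite: identity, adduct, polarity and expected RT."""

    name: str
    monoisotopic_mass: float
    adduct: Adduct
    polarity: str
    expected_rt: float            # minutes
    formula: Formula | None = None
    theoretical_mz: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValueError(f"bad polarity {self.polarity!r} for {self.name}")
        if self.adduct.polarity != self.polarity:
            raise ValueError(
                f"{self.name}: adduct {self.adduct.name} charge sign conflicts "
                f"with polarity {self.polarity}")
        mz = adduct_mz(self.monoisotopic_mass, self.adduct)
        if self.theoretical_mz == 0.0:
            object.__setattr__(self, "theoretical_mz", mz)
        elif abs(self.theoretical_mz - mz) > 1e-9:
            raise ValueError(f"{self.name}: theoretical_mz inconsistent with mass/adduct")


class RtLibrary:
    """An ordered collection of LibraryEntry with unique names."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.name in seen:
                raise FileFormatError(f"duplicate library entry name {e.name!r}")
            seen.add(e.name)
        self._by_name = {e.name: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> LibraryEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name


def read_library(path: str | Path) -> RtLibrary:
    """Load a retention-time library CSV.

    Each row needs ``name``, ``adduct``, ``polarity``, ``rt_min`` and either
    ``formula`` or ``monoisotopic_mass``; theoretical m/z is derived from the
    mass and adduct at load time.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"name", "adduct", "polarity", "rt_min"}
    missing = required - set(df.columns)
    if missing:
        raise FileFormatError(f"library missing columns: {sorted(missing)}")
    if "formula" not in df.columns and "monoisotopic_mass" not in df.columns:
        raise FileFormatError("library needs a 'formula' or 'monoisotopic_mass' column")
    entries = []
    for _, row in df.iterrows():
        formula = None
        if row.get("formula", ""):
            formula = parse_formula(row["formula"])
            mass = chem.monoisotopic_mass(formula)
        elif row.get("monoisotopic_mass", ""):
            mass = float(row["monoisotopic_mass"])
        else:
            raise FileFormatError(f"library row {row['name']!r}: no formula or mass")
        entries.append(LibraryEntry(
            name=row["name"], monoisotopic_mass=mass, formula=formula,
            adduct=get_adduct(row["adduct"]), polarity=row["polarity"],
            expected_rt=float(row["rt_min"])))
    return RtLibrary(entries)


def write_library(lib: RtLibrary, path: str | Path) -> None:
    rows = [{
        "name": e.name,
        "formula": str(e.formula) if e.formula is not None else "",
        "monoisotopic_mass": repr(e.monoisotopic_mass),
        "adduct": e.adduct.name,
        "polarity": e.polarity,
        "rt_min": repr(e.expected_rt),
    } for e in lib]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samplesheet(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Load the sample sheet: (sample_id, group, role, data path) per run."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = {"sample_id", "group", "role", "path"} - set(df.columns)
    if missing:
        raise FileFormatError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FileFormatError(f"duplicate sample_id {dup!r} in sample sheet")
    out = []
    for _, row in df.iterrows():
        role = row["role"]
        if role not in ("sample", "blank"):
            raise FileFormatError(f"bad role {role!r} for {row['sample_id']!r}")
        out.append((row["sample_id"], row["group"], role, row["path"]))
    return out


def load_study(samplesheet: str | Path) -> list[SampleRun]:
    """Load every run listed in a sample sheet (mzXML or peak-table TSV)."""
    base = Path(samplesheet).parent
    runs = []
    for sample_id, group, role, rel in read_samplesheet(samplesheet):
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if p.suffix.lower() == ".mzxml":
            run = read_mzxml(p)
        else:
            run = read_peak_table(p)
        run.sample_id, run.group, run.role = sample_id, group or (
            "blank" if role == "blank" else ""), role
        runs.append(run)
    return runs


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------

_MZXML_NS = "http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"


def read_mzxml(path: str | Path) -> SampleRun:
    """Read centroided MS1 scans from an mzXML file.

    Retention times are converted to minutes whatever the source units;
    MS2+ scans are skipped; profile-mode scans are rejected.
    """
    path = Path(path)
    spectra = []
    n_scans_seen = 0
    try:
        with _pyteomics_mzxml.MzXML(str(path)) as reader:
            for scan in reader:
                n_scans_seen += 1
                if int(scan.get("msLevel", 1)) != 1:
                    continue
                centroided = scan.get("centroided")
                if centroided is not None and not centroided:
                    raise FileFormatError(
                        f"{path.name}: scan {scan.get('num')} is profile mode; "
                        "only centroided MS1 data are supported")
                rt = scan["retentionTime"]
                rt_min = float(rt)  # pyteomics reports minutes
                if getattr(rt, "unit_info", "minute") == "second":
                    rt_min /= 60.0
                pol = scan.get("polarity", "+")
                polarity = POSITIVE if pol == "+" else NEGATIVE
                mz = np.asarray(scan["m/z array"], dtype=float)
                inten = np.asarray(scan["intensity array"], dtype=float)
                expected = scan.get("peaksCount")
                if expected is not None and int(expected) != mz.size:
                    raise FileFormatError(
                        f"{path.name}: scan {scan.get('num')} truncated: "
                        f"expected {expected} peaks, decoded {mz.size}")
                spectra.append(Spectrum(rt_min, polarity, mz, inten,
                                        scan_id=int(scan.get("num", len(spectra) + 1))))
    except etree.XMLSyntaxError as exc:
        raise FileFormatError(f"{path.name}: malformed XML: {exc}") from exc
    declared = _declared_scan_count(path)
    if declared is not None and declared != n_scans_seen:
        raise FileFormatError(
            f"{path.name}: scanCount says {declared} scans but file holds {n_scans_seen}")
    return SampleRun(path.stem, spectra)


def _declared_scan_count(path: Path) -> int | None:
    for _, el in etree.iterparse(str(path), events=("start",)):
        if etree.QName(el).localname == "msRun":
            sc = el.get("scanCount")
            return int(sc) if sc is not None else None
        if etree.QName(el).localname == "scan":
            return None
    return None


def write_mzxml(run: SampleRun, path: str | Path, precision: int = 64,
                compression: str = "none") -> None:
    """Write a SampleRun as centroided MS1 mzXML.

    ``precision`` is 32 or 64 bits; ``compression`` is ``none`` or ``zlib``.
    Reading the file back reproduces rt exactly and m/z / intensity to the
    float precision written.
    """
    if precision not in (32, 64):
        raise ValueError("precision must be 32 or 64")
    if compression not in ("none", "zlib"):
        raise ValueError("compression must be 'none' or 'zlib'")
    root = etree.Element("mzXML", nsmap={None: _MZXML_NS})
    msrun = etree.SubElement(root, "msRun", scanCount=str(len(run.spectra)))
    fmt_char = "f" if precision == 32 else "d"
    for i, s in enumerate(run.spectra, start=1):
        scan = etree.SubElement(
            msrun, "scan", num=str(i), msLevel="1",
            peaksCount=str(len(s)),
            polarity="+" if s.polarity == POSITIVE else "-",
            retentionTime=f"PT{s.rt * 60.0!r}S".replace("'", ""),
            centroided="1")
        interleaved = np.empty(2 * len(s))
        interleaved[0::2] = s.mz
        interleaved[1::2] = s.intensity
        raw = struct.pack(f">{interleaved.size}{fmt_char}", *interleaved)
        if compression == "zlib":
            raw = zlib.compress(raw)
        peaks = etree.SubElement(
            scan, "peaks", compressionType=compression,
            compressedLen=str(len(raw)), precision=str(precision),
            byteOrder="network", contentType="m/z-int")
        peaks.text = base64.b64encode(raw).decode()
    Path(path).write_bytes(etree.tostring(root, xml_declaration=True,
                                          encoding="ISO-8859-1", pretty_print=True))


# ---------------------------------------------------------------------------
# Peak-table TSV
# ---------------------------------------------------------------------------

_PEAK_TABLE_COLUMNS = ["scan_id", "rt_min", "polarity", "mz", "intensity"]


def write_peak_table(run: SampleRun, path: str | Path) -> None:
    """Write the plain-text peak-table dialect (TSV, one row per peak)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_PEAK_TABLE_COLUMNS) + "\n")
        for i, s in enumerate(run.spectra, start=1):
            pol = s.polarity
            rt = repr(float(s.rt))
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{i}\t{rt}\t{pol}\t{float(mz)!r}\t{float(inten)!r}\n")


def read_peak_table(path: str | Path) -> SampleRun:
    """Read the peak-table TSV dialect back into a SampleRun."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FileFormatError(f"{path.name}: missing columns {sorted(missing)}")
    for col in ("rt_min", "mz", "intensity"):
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            raise FileFormatError(f"{path.name}: non-numeric values in {col!r}")
    spectra = []
    if len(df):
        for (sid, rt, pol), grp in df.groupby(["scan_id", "rt_min", "polarity"],
                                              sort=True):
            spectra.append(Spectrum(rt, pol, grp["mz"].to_numpy(),
                                    grp["intensity"].to_numpy(), scan_id=int(sid)))
    return SampleRun(path.stem, spectra)


# ---------------------------------------------------------------------------
# Intensity matrix
# ---------------------------------------------------------------------------

class IntensityMatrix:
    """Features x samples peak-height matrix.

    Not-detected cells carry NaN (the NOT_FOUND sentinel) and render as
    ``ND`` in the TSV form. ``groups`` / ``roles`` map sample_id to its arm
    label and sample/blank role.
    """

    def __init__(self, values: pd.DataFrame, groups: dict[str, str],
                 roles: dict[str, str]):
        self.values = values.astype(float)
        self.groups = dict(groups)
        self.roles = dict(roles)
        missing = set(values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    @classmethod
    def from_runs(cls, values: pd.DataFrame, runs: Sequence[SampleRun]) -> "IntensityMatrix":
        return cls(values, {r.sample_id: r.group for r in runs},
                   {r.sample_id: r.role for r in runs})

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.roles.get(c) != "blank"]

    @property
    def blank_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.roles.get(c) == "blank"]

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups.get(c) == group]

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "id"
        out.to_csv(path, sep="\t", na_rep="ND")

    @classmethod
    def from_tsv(cls, path: str | Path, groups: dict[str, str],
                 roles: dict[str, str]) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id", na_values=["ND"])
        df.index.name = None
        return cls(df, groups, roles)

    def __repr__(self) -> str:
        return f"IntensityMatrix({self.values.shape[0]} ids x {self.values.shape[1]} samples)"
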