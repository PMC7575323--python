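"""Seeded generator of synthetic LC-MS study data with known ground truth.

The generator emulates the design of an immunoisolation metabolomics study:
replicate IPs from a tagged arm and a control arm (n = 3-4 each), a
proton-gradient-inhibitor arm against its vehicle, blank IP controls, a
~153-entry polar retention-time panel, an untargeted background of ~2,724
features, log-normally distributed peak heights, ppm-scale m/z error and
seconds-scale retention-time jitter. Designated true-positive metabolites
carry planted enrichment and inhibitor-depletion effects; everything else
is null.

Each detectable species is rendered as a short Gaussian elution profile
(FWHM ~6 s) sampled at scans spaced 0.2 min within ±0.5 min of its
retention time, with the apex scan placed exactly at the (jittered) apex so
that peak-height extraction is exact in the noiseless limit. Every rendered
spectrum also carries a few sub-threshold chemical-noise peaks, which is
what allows real peaks to clear the within-spectrum signal-to-noise gate
downstream. Blanks contain a low carry-over fraction of each species plus
the same chemical noise.

All randomness flows from a single integer seed; identical (scenario, seed)
pairs produce identical runs, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem
from .io_formats import (IntensityMatrix, LibraryEntry, RtLibrary, SampleRun,
                         Spectrum, get_adduct, parse_formula, write_library,
                         write_peak_table)

# Generator defaults: the replicate noise model the study design implies but
# does not state. Chosen once as realistic for an Orbitrap HILIC method.
DEFAULT_CV = 0.15                # replicate coefficient of variation
DEFAULT_MZ_ERROR_SD = 1.0        # ppm, per-scan mass error
DEFAULT_RT_JITTER_SD = 0.75     # seconds, per-run apex jitter
DEFAULT_CARRYOVER = 0.01         # blank carry-over fraction
SCAN_SPACING_MIN = 0.2           # minutes between rendered scans
ELUTION_FWHM_S = 6.0             # chromatographic peak width
NOISE_PEAKS_PER_SPECTRUM = 4     # sub-threshold chemical noise peaks
MZ_RANGE = (70.0, 1000.0)        # Th, instrument scan range (67-1000)
RT_RANGE = (1.0, 28.0)           # minutes, within the 30-min method

_SCAN_OFFSETS = SCAN_SPACING_MIN * np.arange(-2, 3)
_SIGMA_T_MIN = ELUTION_FWHM_S / 2.3548 / 60.0
_ELUTION_FACTORS = np.exp(-(_SCAN_OFFSETS ** 2) / (2 * _SIGMA_T_MIN ** 2))

PRESETS = ("targeted-panel", "global-screen", "mge-gaba", "dopamine-tbz", "null")


@dataclass(frozen=True)
class PlantedMetabolite:
    """Ground-truth effect specification for one panel metabolite."""

    name: str
    base_log2_intensity: float = 21.0
    enrichment_log2fc: float = 0.0   # tagged IP vs control IP
    bafa_log2fc: float = 0.0         # inhibitor arm vs vehicle arm
    cv: float | None = None          # None -> scenario default
    mz_error_sd: float | None = None
    rt_jitter_sd: float | None = None
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.cv is not None and self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A complete simulated study design."""

    name: str
    panel: RtLibrary
    planted: list[PlantedMetabolite]
    n_background_features: int
    groups: dict[str, int]          # group label -> replicate count
    blanks: int
    seed: int
    control_group: str = "controlIP"
    sv_group: str = "SVtag"
    vehicle_group: str | None = None
    drug_group: str | None = None
    render_panel: bool = True       # render all panel species (vs planted only)
    cv: float = DEFAULT_CV
    mz_error_sd: float = DEFAULT_MZ_ERROR_SD
    rt_jitter_sd: float = DEFAULT_RT_JITTER_SD
    carryover: float = DEFAULT_CARRYOVER

    @property
    def sv_contrast(self) -> tuple[str, str]:
        return (self.sv_group, self.control_group)

    @property
    def bafa_contrast(self) -> tuple[str, str] | None:
        if self.drug_group and self.vehicle_group:
            return (self.drug_group, self.vehicle_group)
        return None


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------

_NAMED_PANEL = [
    # name, formula, adduct, rt_min
    ("glutamate", "C5H9NO4", "[M-H]-", 14.20),
    ("gaba", "C4H9NO2", "[M+H]+", 15.10),
    ("dopamine", "C8H11NO2", "[M+H]+", 8.20),
    ("aspartate", "C4H7NO4", "[M-H]-", 14.90),
    ("glycine", "C2H5NO2", "[M+H]+", 16.30),
    ("serotonin", "C10H12N2O", "[M+H]+", 7.40),
    ("epinephrine", "C9H13NO3", "[M+H]+", 9.10),
    ("taurine", "C2H7NO3S", "[M-H]-", 12.70),
    ("cystine", "C6H12N2O4S2", "[M-H]-", 17.20),
    ("glutamine", "C5H10N2O3", "[M+H]+", 13.60),
]

# A potassium-associated cation observed in carbonate-containing LC buffers;
# modelled as a synthetic low-mass cationic entry (its exact ion formula is
# not chemically asserted), plus a stable-isotope internal standard
# (phenylalanine-13C9-15N) whose mass is entered directly.
_POTASSIUM_ION = ("potassium-ion", 98.9496, "[M+H]+", 25.50)
_PHE_ISTD_MASS = 165.078979 + 9 * 1.0033548378 + 0.9970348934
_INTERNAL_STANDARD = ("phenylalanine-13C9-15N", _PHE_ISTD_MASS, "[M+H]+", 11.80)


def build_panel(n_entries: int, include_internal_standard: bool = False) -> RtLibrary:
    """Deterministically construct a polar panel of the requested size.

    Real metabolite entries come first; synthetic filler entries named
    ``panel_###`` pad the panel to size with masses and retention times
    spaced widely enough that no two entries fall inside each other's
    binning tolerances.
    """
    entries: list[LibraryEntry] = []
    for name, formula, adduct_name, rt in _NAMED_PANEL:
        f = parse_formula(formula)
        adduct = get_adduct(adduct_name)
        entries.append(LibraryEntry(name=name, formula=f,
                                    monoisotopic_mass=chem.monoisotopic_mass(f),
                                    adduct=adduct, polarity=adduct.polarity,
                                    expected_rt=rt))
    name, mass, adduct_name, rt = _POTASSIUM_ION
    adduct = get_adduct(adduct_name)
    entries.append(LibraryEntry(name=name, monoisotopic_mass=mass, adduct=adduct,
                                polarity=adduct.polarity, expected_rt=rt))
    if include_internal_standard:
        name, mass, adduct_name, rt = _INTERNAL_STANDARD
        adduct = get_adduct(adduct_name)
        entries.append(LibraryEntry(name=name, monoisotopic_mass=mass,
                                    adduct=adduct, polarity=adduct.polarity,
                                    expected_rt=rt))
    if n_entries < len(entries):
        return RtLibrary(entries[:n_entries])
    i = 0
    while len(entries) < n_entries:
        mass = 88.0 + 5.17 * i + 0.0137 * (i % 7)
        adduct = get_adduct("[M+H]+" if i % 2 == 0 else "[M-H]-")
        rt = 2.0 + (i * 1.83) % 25.0
        entries.append(LibraryEntry(
            name=f"panel_{i:03d}", monoisotopic_mass=mass, adduct=adduct,
            polarity=adduct.polarity, expected_rt=round(rt, 3)))
        i += 1
    return RtLibrary(entries)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def build_scenario(name: str, seed: int) -> Scenario:
    """Instantiate one of the named study presets.

    * ``targeted-panel`` — 153-entry polar panel; glutamate planted +2.5
      log2 enriched and -2.0 log2 depleted by the inhibitor; all else null.
    * ``global-screen`` — 2,724 null background features plus three planted
      true positives (glutamate, GABA, the potassium-associated cation),
      each >= +2.3 log2 enriched and <= -2.3 log2 depleted.
    * ``mge-gaba`` — GABA enriched, glutamate null (inhibitory-culture
      design).
    * ``dopamine-tbz`` — dopamine enriched and depleted in a VMAT2-inhibitor
      arm, plus a constant-intensity stable-isotope internal standard.
    * ``null`` — 500 features, no planted effects (calibration preset).
    """
    if name == "targeted-panel":
        return Scenario(
            name=name, panel=build_panel(153),
            planted=[PlantedMetabolite("glutamate", 21.0, 2.5, -2.0)],
            n_background_features=0,
            groups={"SVtag": 4, "controlIP": 4, "BafA": 3, "DMSO": 3},
            blanks=2, seed=seed, vehicle_group="DMSO", drug_group="BafA")
    if name == "global-screen":
        return Scenario(
            name=name, panel=build_panel(153),
            planted=[PlantedMetabolite("glutamate", 21.0, 2.5, -2.5),
                     PlantedMetabolite("gaba", 20.5, 2.4, -2.3),
                     PlantedMetabolite("potassium-ion", 21.5, 2.6, -2.4)],
            n_background_features=2724,
            groups={"SVtag": 4, "controlIP": 4, "BafA": 3, "DMSO": 3},
            blanks=2, seed=seed, vehicle_group="DMSO", drug_group="BafA",
            render_panel=False)
    if name == "mge-gaba":
        return Scenario(
            name=name, panel=build_panel(153),
            planted=[PlantedMetabolite("gaba", 21.0, 2.5, 0.0)],
            n_background_features=0,
            groups={"SVtag": 3, "controlIP": 3}, blanks=2, seed=seed)
    if name == "dopamine-tbz":
        return Scenario(
            name=name, panel=build_panel(153, include_internal_standard=True),
            planted=[PlantedMetabolite("dopamine", 21.0, 2.5, -2.3),
                     PlantedMetabolite("phenylalanine-13C9-15N", 21.0, cv=0.0,
                                       is_internal_standard=True)],
            n_background_features=0,
            groups={"SVtag": 3, "controlIP": 3, "TBZ": 3, "DMSO": 3},
            blanks=2, seed=seed, vehicle_group="DMSO", drug_group="TBZ")
    if name == "null":
        return Scenario(
            name=name, panel=build_panel(500), planted=[],
            n_background_features=0,
            groups={"SVtag": 4, "controlIP": 4}, blanks=2, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# Species table and replicate heights
# ---------------------------------------------------------------------------

def _species_table(sc: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    """All species rendered into the runs, with per-group log2 means.

    Background features are rejection-sampled so that every same-polarity
    pair is separated by more than 3x the binning tolerance in m/z or RT,
    relative to each other and to the panel.
    """
    rows = []
    planted_by_name = {p.name: p for p in sc.planted}
    for e in sc.panel:
        p = planted_by_name.get(e.name)
        if not sc.render_panel and p is None:
            continue
        if p is None:
            base = float(rng.normal(21.0, 0.8))
            p = PlantedMetabolite(e.name, base)
        rows.append({
            "name": e.name, "kind": "panel", "mz": e.theoretical_mz,
            "rt": e.expected_rt, "polarity": e.polarity,
            "base_log2_intensity": p.base_log2_intensity,
            "enrichment_log2fc": p.enrichment_log2fc,
            "bafa_log2fc": p.bafa_log2fc,
            "cv": sc.cv if p.cv is None else p.cv,
            "mz_error_sd": sc.mz_error_sd if p.mz_error_sd is None else p.mz_error_sd,
            "rt_jitter_sd": sc.rt_jitter_sd if p.rt_jitter_sd is None else p.rt_jitter_sd,
            "is_internal_standard": p.is_internal_standard,
        })
    missing = set(planted_by_name) - {r["name"] for r in rows}
    if missing:
        raise ValueError(f"planted metabolites not in panel: {sorted(missing)}")

    if sc.n_background_features:
        mz_sep = 3 * 25e-6          # 3x the 25 ppm binning tolerance
        rt_sep = 3 * 0.5            # 3x the 0.5 min RT tolerance
        acc_mz = {pol: [np.array([r["mz"] for r in rows if r["polarity"] == pol])]
                  for pol in ("positive", "negative")}
        acc_rt = {pol: [np.array([r["rt"] for r in rows if r["polarity"] == pol])]
                  for pol in ("positive", "negative")}
        n_accepted = 0
        while n_accepted < sc.n_background_features:
            mz = float(rng.uniform(*MZ_RANGE))
            rt = float(rng.uniform(*RT_RANGE))
            pol = "positive" if rng.random() < 0.5 else "negative"
            mzs = np.concatenate(acc_mz[pol])
            rts = np.concatenate(acc_rt[pol]) if len(acc_rt[pol]) else np.empty(0)
            clash = (np.abs(mzs - mz) <= mz_sep * np.maximum(mzs, mz)) & \
                    (np.abs(rts - rt) <= rt_sep)
            if clash.any():
                continue
            acc_mz[pol].append(np.array([mz]))
            acc_rt[pol].append(np.array([rt]))
            rows.append({
                "name": f"bg_{n_accepted:04d}", "kind": "background", "mz": mz,
                "rt": rt, "polarity": pol,
                "base_log2_intensity": float(np.clip(rng.normal(21.0, 1.2), 18.0, 24.0)),
                "enrichment_log2fc": 0.0, "bafa_log2fc": 0.0,
                "cv": sc.cv, "mz_error_sd": sc.mz_error_sd,
                "rt_jitter_sd": sc.rt_jitter_sd, "is_internal_standard": False,
            })
            n_accepted += 1
    return pd.DataFrame(rows)


def _run_plan(sc: Scenario) -> list[tuple[str, str, str]]:
    """(sample_id, group, role) for every acquisition in the scenario."""
    plan = [(f"{group}_{i + 1}", group, "sample")
            for group in sc.groups for i in range(sc.groups[group])]
    plan += [(f"blank_{i + 1}", "blank", "blank") for i in range(sc.blanks)]
    return plan


def _group_offsets(sc: Scenario, species: pd.DataFrame, group: str) -> np.ndarray:
    """log2 offsets of every species' mean in one experimental arm.

    The control arm sits at the base level; the tagged arm and the drug
    vehicle arm (both tagged material) carry the enrichment effect; the
    drug arm additionally carries the depletion effect. Internal standards
    are spiked at a constant level everywhere.
    """
    enr = species["enrichment_log2fc"].to_numpy()
    baf = species["bafa_log2fc"].to_numpy()
    if group == sc.sv_group or group == sc.vehicle_group:
        off = enr.copy()
    elif group == sc.drug_group:
        off = enr + baf
    else:
        off = np.zeros(len(species))
    off[species["is_internal_standard"].to_numpy()] = 0.0
    return off


def _draw_heights(sc: Scenario, rng: np.random.Generator,
                  species: pd.DataFrame) -> pd.DataFrame:
    """Replicate apex heights (linear units), species x runs.

    Heights are log-normal about the group mean: H = 2**mu * exp(sigma z)
    with sigma = sqrt(ln(1 + cv^2)), so the expected log2 fold change
    between arms equals the planted value exactly. Blanks receive the
    carry-over fraction of the base level (internal standards are spiked
    into blanks at full strength).
    """
    sigma = np.sqrt(np.log1p(species["cv"].to_numpy() ** 2))
    cols = {}
    for sample_id, group, role in _run_plan(sc):
        mu = species["base_log2_intensity"].to_numpy().copy()
        if role == "blank":
            istd = species["is_internal_standard"].to_numpy()
            mu = mu + np.where(istd, 0.0, np.log2(sc.carryover))
        else:
            mu = mu + _group_offsets(sc, species, group)
        z = rng.standard_normal(len(species))
        cols[sample_id] = np.exp2(mu) * np.exp(sigma * z)
    return pd.DataFrame(cols, index=species["name"])


def simulate_intensity_matrix(sc: Scenario) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Draw the replicate intensity matrix directly, skipping rendering.

    Produces exactly the heights that chromatographic rendering followed by
    noiseless extraction would recover; used for large pooled-seed
    calibration where rendering every scan would be wasteful.
    """
    rng = np.random.default_rng(sc.seed)
    species = _species_table(sc, rng)
    heights = _draw_heights(sc, rng, species)
    plan = _run_plan(sc)
    matrix = IntensityMatrix(heights,
                             {sid: g for sid, g, _ in plan},
                             {sid: r for sid, _, r in plan})
    return matrix, ground_truth(sc, species)


def ground_truth(sc: Scenario, species: pd.DataFrame) -> pd.DataFrame:
    gt = species[["name", "kind", "mz", "rt", "polarity", "base_log2_intensity",
                  "enrichment_log2fc", "bafa_log2fc", "cv",
                  "is_internal_standard"]].copy()
    gt["is_true_positive"] = (np.abs(gt["enrichment_log2fc"]) > 0) | \
                             (np.abs(gt["bafa_log2fc"]) > 0)
    return gt


# ---------------------------------------------------------------------------
# Chromatographic rendering
# ---------------------------------------------------------------------------

def generate_runs(sc: Scenario) -> tuple[list[SampleRun], pd.DataFrame]:
    """Render the scenario into SampleRuns plus its ground-truth table.

    Deterministic for a given (scenario, seed): the same object graph, the
    same bytes when written out.
    """
    rng = np.random.default_rng(sc.seed)
    species = _species_table(sc, rng)
    heights = _draw_heights(sc, rng, species)
    n_sp = len(species)
    theo_mz = species["mz"].to_numpy()
    base_rt = species["rt"].to_numpy()
    mz_sd = species["mz_error_sd"].to_numpy()
    rt_sd_min = species["rt_jitter_sd"].to_numpy() / 60.0
    n_scans = _SCAN_OFFSETS.size
    n_noise = NOISE_PEAKS_PER_SPECTRUM

    runs = []
    for sample_id, group, role in _run_plan(sc):
        H = heights[sample_id].to_numpy()
        jitter = rng.standard_normal(n_sp) * rt_sd_min
        apex_rt = base_rt + jitter
        scan_rts = apex_rt[:, None] + _SCAN_OFFSETS[None, :]
        sig_int = H[:, None] * _ELUTION_FACTORS[None, :]
        eps = rng.standard_normal((n_sp, n_scans)) * mz_sd[:, None]
        sig_mz = theo_mz[:, None] * (1 + eps * 1e-6)
        noise_mz = rng.uniform(*MZ_RANGE, size=(n_sp, n_scans, n_noise))
        noise_int = 10.0 ** rng.uniform(2, 4, size=(n_sp, n_scans, n_noise))
        # assemble (species, scan, peak) blocks: signal peak + noise peaks
        all_mz = np.concatenate([sig_mz[:, :, None], noise_mz], axis=2)
        all_int = np.concatenate([sig_int[:, :, None], noise_int], axis=2)
        order = np.argsort(all_mz, axis=2)
        all_mz = np.take_along_axis(all_mz, order, axis=2)
        all_int = np.take_along_axis(all_int, order, axis=2)
        pols = species["polarity"].to_numpy()
        spectra = []
        for i in range(n_sp):
            pol = pols[i]
            for k in range(n_scans):
                spectra.append(Spectrum(scan_rts[i, k], pol, all_mz[i, k],
                                        all_int[i, k], presorted=True))
        run = SampleRun(sample_id, spectra, group=group, role=role)
        for j, s in enumerate(run.spectra, start=1):
            s.scan_id = j
        runs.append(run)
    return runs, ground_truth(sc, species)


def write_scenario(sc: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit runs (peak tables), sample sheet, library CSV and ground truth.

    The ground-truth TSV sits beside the runs for tests and audits; the
    pipeline itself never reads it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs, gt = generate_runs(sc)
    sheet_rows = []
    for run in runs:
        p = out / f"{run.sample_id}.tsv"
        write_peak_table(run, p)
        sheet_rows.append({"sample_id": run.sample_id, "group": run.group,
                           "role": run.role, "path": p.name})
    paths = {
        "samplesheet": out / "samplesheet.csv",
        "library": out / "library.csv",
        "ground_truth": out / "ground_truth.tsv",
    }
    pd.DataFrame(sheet_rows).to_csv(paths["samplesheet"], index=False)
    write_library(sc.panel, paths["library"])
    gt.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
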