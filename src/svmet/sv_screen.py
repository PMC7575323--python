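"""The synaptic-vesicle content screen and end-to-end pipeline.

A feature (or panel metabolite) passes the screen iff it is significantly
enriched at least two-fold in the tagged-IP arm over the control IP *and*
depleted at least two-fold by the vATPase-inhibitor arm over its vehicle.
Fold thresholds are compared on the log2 scale with inclusive boundaries;
by default the depletion arm must also be significant (config flag
``require_depletion_significance`` restores the looser reading where only
enrichment needs a p-value).

``run_pipeline`` composes the full study analysis: targeted mode extracts
the retention-time library, global mode discovers untargeted features
first; both then run detection calling, group statistics and the screen,
and write every intermediate table.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection_stats import call_detection, compare_groups
from .io_formats import IntensityMatrix, RtLibrary, SampleRun, ToleranceConfig
from .targeted_extraction import extract_matrix
from .untargeted_features import (bin_features, features_table,
                                  pool_candidates, quantify_features)

__all__ = ["screen", "annotate_features", "run_study", "run_pipeline"]


def screen(sv_contrast: pd.DataFrame, bafa_contrast: pd.DataFrame,
           cfg: ToleranceConfig) -> pd.DataFrame:
    """Apply the enrichment x depletion screen to two contrast tables.

    Both tables are GroupComparison frames indexed by id; ids present in
    only one table are excluded (their count is reported in the frame's
    ``attrs["n_unmatched"]``). Output is sorted by descending enrichment
    log2 fold change.
    """
    common = sv_contrast.index.intersection(bafa_contrast.index)
    n_unmatched = (len(sv_contrast.index.union(bafa_contrast.index))
                   - len(common))
    sv = sv_contrast.loc[common]
    ba = bafa_contrast.loc[common]
    lfc_gate = np.log2(cfg.fc_threshold)
    p_sv = sv["p_value"].to_numpy()
    p_ba = ba["p_value"].to_numpy()
    enriched = (sv["log2fc"].to_numpy() >= lfc_gate) & \
               (np.nan_to_num(p_sv, nan=1.0) < cfg.alpha)
    depleted = ba["log2fc"].to_numpy() <= -lfc_gate
    if cfg.require_depletion_significance:
        depleted &= np.nan_to_num(p_ba, nan=1.0) < cfg.alpha
    out = pd.DataFrame({
        "id": common,
        "log2fc_sv": sv["log2fc"].to_numpy(), "p_sv": p_sv,
        "log2fc_bafa": ba["log2fc"].to_numpy(), "p_bafa": p_ba,
        "class_sv": sv["class"].to_numpy(),
        "enriched": enriched, "depleted_by_bafa": depleted,
        "passes": enriched & depleted,
    }).set_index("id", drop=False)
    out = out.sort_values("log2fc_sv", ascending=False)
    out.attrs["n_unmatched"] = n_unmatched
    return out


def annotate_features(results: pd.DataFrame, library: RtLibrary,
                      cfg: ToleranceConfig,
                      features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach library identities to screen results by accurate mass and RT.

    A row is annotated with a library name iff a same-polarity entry lies
    within the targeted ppm tolerance in m/z and the apex RT tolerance in
    RT; the nearest in ppm wins, equidistant candidates tie-break by name
    order and are flagged ambiguous. Rows without a match (or without
    feature coordinates) are annotated ``unknown``. ``features`` supplies
    the (mz, rt_min, polarity) coordinates per feature id; when omitted,
    ids are assumed to be metabolite names already and annotation is the
    identity.
    """
    out = results.copy()
    if features is None:
        out["annotation"] = [i if i in library else "unknown" for i in out.index]
        out["annotation_ambiguous"] = False
        return out
    feat = features.set_index("feature_id") if "feature_id" in features.columns \
        else features
    names, ambiguous = [], []
    for fid in out.index:
        if fid not in feat.index:
            names.append("unknown")
            ambiguous.append(False)
            continue
        row = feat.loc[fid]
        cands = []
        for e in library:
            if e.polarity != row["polarity"]:
                continue
            dppm = abs(row["mz"] - e.theoretical_mz) / e.theoretical_mz * 1e6
            drt = abs(row["rt_min"] - e.expected_rt)
            if dppm <= cfg.targeted_ppm and drt <= cfg.apex_rt_tol_min:
                cands.append((dppm, e.name))
        if not cands:
            names.append("unknown")
            ambiguous.append(False)
        else:
            cands.sort()
            names.append(cands[0][1])
            ambiguous.append(len(cands) > 1 and cands[1][0] == cands[0][0])
    out["annotation"] = names
    out["annotation_ambiguous"] = ambiguous
    return out


def run_study(runs: Sequence[SampleRun], library: RtLibrary,
              cfg: ToleranceConfig, mode: str,
              sv_contrast: tuple[str, str],
              bafa_contrast: tuple[str, str] | None = None) -> dict:
    """Execute the full pipeline on in-memory runs.

    Returns a dict with the intensity matrix, detail/feature tables,
    detection calls, per-contrast statistics and (when a depletion contrast
    exists) the screen table.
    """
    if mode not in ("targeted", "global"):
        raise ValueError("mode must be 'targeted' or 'global'")
    result: dict = {"mode": mode}
    if mode == "targeted":
        matrix, detail = extract_matrix(runs, library, cfg)
        result["detail"] = detail
    else:
        cands = pool_candidates(runs, cfg)
        features = bin_features(cands, cfg)
        result["features"] = features_table(features)
        matrix, detail = quantify_features(features, runs, cfg)
        result["detail"] = detail
    result["matrix"] = matrix
    calls = call_detection(matrix, cfg)
    result["calls"] = calls
    stats = {}
    stats["sv"] = compare_groups(calls, sv_contrast[0], sv_contrast[1], cfg)
    if bafa_contrast is not None:
        stats["bafa"] = compare_groups(calls, bafa_contrast[0],
                                       bafa_contrast[1], cfg)
        scr = screen(stats["sv"], stats["bafa"], cfg)
        scr = annotate_features(scr, library, cfg,
                                features=result.get("features"))
        result["screen"] = scr
    result["stats"] = stats
    return result


def run_pipeline(samplesheet: str | Path, library_path: str | Path,
                 cfg: ToleranceConfig, mode: str, out_dir: str | Path,
                 sv_contrast: tuple[str, str] = ("SVtag", "controlIP"),
                 bafa_contrast: tuple[str, str] | None = ("BafA", "DMSO"),
                 ) -> dict:
    """File-level pipeline entry point: load, analyze, write all tables."""
    from .io_formats import load_study, read_library

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs = load_study(samplesheet)
    library = read_library(library_path)
    groups = {r.group for r in runs if r.role == "sample"}
    if bafa_contrast is not None and not set(bafa_contrast) <= groups:
        bafa_contrast = None
    result = run_study(runs, library, cfg, mode, sv_contrast, bafa_contrast)
    result["matrix"].to_tsv(out / "matrix.tsv")
    result["detail"].to_csv(out / "detail.tsv", sep="\t", index=False)
    if "features" in result:
        result["features"].to_csv(out / "features.tsv", sep="\t", index=False)
    stats_frames = []
    for key, frame in result["stats"].items():
        f = frame.copy()
        f.insert(1, "contrast", key)
        stats_frames.append(f)
    pd.concat(stats_frames).to_csv(out / "stats.tsv", sep="\t", index=False)
    if "screen" in result:
        result["screen"].to_csv(out / "screen.tsv", sep="\t", index=False)
        passing = result["screen"][result["screen"]["passes"]]
        lines = [f"{len(passing)} feature(s) pass the screen"]
        for _, row in passing.iterrows():
            lines.append(f"  {row['id']}\tannotation={row.get('annotation', '')}\t"
                         f"log2fc_sv={row['log2fc_sv']:.3f}\t"
                         f"log2fc_bafa={row['log2fc_bafa']:.3f}")
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
    (out / "run_log.json").write_text(json.dumps({
        "mode": mode, "sv_contrast": sv_contrast,
        "bafa_contrast": bafa_contrast, "config": asdict(cfg),
        "n_runs": len(runs),
    }, indent=2, default=str) + "\n")
    return result
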