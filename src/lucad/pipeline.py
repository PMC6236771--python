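"""End-to-end orchestration of the four pipeline stages.

Stage I enhances the slice and extracts the lung fields (LUVEM);
Stage II detects circle candidates (CHT) and segments each nodule with a
per-ROI SOM; Stage III computes the 123-feature vector per nodule and
reduces it with PCA; Stage IV classifies with the PNN, evaluated by
nodule-level leave-one-out cross-validation.

Every tunable default is a named config key so deviations are
auditable, and a fixed seed makes a run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lucad.classify import MALIGN
from lucad.detect import ChtParams, detect_all_bands, CandidateNodule
from lucad.evaluate import loocv, size_stratified_report
from lucad.features import FEATURE_NAMES, GLCMConfig, extract_all
from lucad.imaging import CTSlice, read_dicom_slice, read_image, write_mask
from lucad.luvem import LuvemConfig, luvem_extract
from lucad.phantom import NoduleTruth
from lucad.preprocess import EnhanceConfig, enhance
from lucad.segment import SOMConfig, extract_roi, pixel_features, som_segment, som_train

#: Feature ROIs must support the 4-level wavelet decomposition.
FEATURE_ROI_MIN_SIDE = 17


@dataclass
class PipelineConfig:
    """All stage configurations plus the run seed."""

    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)
    luvem: LuvemConfig = field(default_factory=LuvemConfig)
    cht: ChtParams = field(default_factory=ChtParams)
    som: SOMConfig = field(default_factory=SOMConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    split_fraction: float = 0.5
    sigma: float | str = "auto"
    pca_global: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {"enhance": EnhanceConfig, "luvem": LuvemConfig, "cht": ChtParams,
               "som": SOMConfig, "glcm": GLCMConfig}
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                known = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(value) - known
                if bad:
                    raise ValueError(f"unknown keys in '{key}': {sorted(bad)}")
                if key == "glcm" and "angles" in value:
                    value["angles"] = tuple(value["angles"])
                kwargs[key] = sub[key](**value)
            elif key in ("split_fraction", "sigma", "pca_global", "seed"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: '{key}'")
        return cls(**kwargs)


def load_slice(path: str | Path, pixel_spacing_mm: float = 0.7) -> CTSlice:
    """Read a slice, dispatching on extension (.dcm → DICOM, else raster)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        return read_dicom_slice(path)
    return read_image(path, pixel_spacing_mm)


def process_slice(ct: CTSlice, config: PipelineConfig
                  ) -> dict:
    """Stages I–II up to candidate detection on one slice."""
    enhanced = enhance(ct, config.enhance)
    lung_mask, lung_image = luvem_extract(enhanced, config.luvem)
    candidates = detect_all_bands(enhanced, lung_mask, config.cht)
    return {"enhanced": enhanced, "lung_mask": lung_mask,
            "lung_image": lung_image, "candidates": candidates}


def match_candidate(candidates: list[CandidateNodule], truth: NoduleTruth,
                    pixel_spacing_mm: float) -> CandidateNodule | None:
    """Highest-score candidate within the truth radius (>= 5 px) of the
    truth center, or None if the nodule was missed."""
    r_px = truth.diameter_mm / 2.0 / pixel_spacing_mm
    tol = max(5.0, r_px)
    best = None
    for c in candidates:
        d = np.hypot(c.center_rc[0] - truth.center_rc[0],
                     c.center_rc[1] - truth.center_rc[1])
        if d <= tol and (best is None or c.score > best.score):
            best = c
    return best


def nodule_features(ct_enhanced: CTSlice, candidate: CandidateNodule,
                    config: PipelineConfig, seed: int) -> tuple[np.ndarray, dict]:
    """Stage II segmentation + Stage III feature extraction for one
    candidate. Returns the 123-vector and a per-nodule log entry."""
    roi = extract_roi(ct_enhanced, candidate, min_side=FEATURE_ROI_MIN_SIDE)
    model = som_train(pixel_features(roi.pixels), config.som, seed=seed)
    _, mask = som_segment(roi, model)
    if not mask.any():
        # fall back to the candidate circle so the nodule is not dropped
        rr, cc = np.ogrid[: roi.pixels.shape[0], : roi.pixels.shape[1]]
        cr, cc0 = roi.center_in_roi
        mask = (rr - cr) ** 2 + (cc - cc0) ** 2 <= candidate.radius_px**2
        fallback = True
    else:
        fallback = False
    fv = extract_all(roi.pixels, mask, config.glcm)
    log = {"center": list(candidate.center_rc), "radius_px": candidate.radius_px,
           "segmentation_fallback": fallback, "mask_area_px": int(mask.sum())}
    return fv.values, log


def run_pipeline(slices: list[tuple[CTSlice, list[NoduleTruth] | None]],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run Stages I–IV over in-memory slices with optional nodule truth.

    For each slice the stages produce the enhanced image, lung mask and
    candidate list; each annotated nodule is matched to its candidate
    (falling back to a circle at the annotation when detection missed
    it, which is logged) and yields one feature row. When labels exist
    for at least two nodules per class, the PCA+PNN stage is evaluated
    by leave-one-out cross-validation.

    Returns a result dict; when `out_dir` is given, artifacts (PNG masks,
    features.csv, report.json, run_log.json) are also written.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows, run_log = [], []
    for ct, truths in slices:
        stage = process_slice(ct, config)
        entry = {"slice_id": ct.slice_id,
                 "n_candidates": len(stage["candidates"]),
                 "lung_area_px": int(stage["lung_mask"].sum())}
        if out_dir is not None:
            write_mask(stage["lung_mask"], out_dir / f"{ct.slice_id}_lung.png")
        if truths:
            for k, truth in enumerate(truths):
                cand = match_candidate(stage["candidates"], truth, ct.pixel_spacing_mm)
                detected = cand is not None
                if cand is None:
                    r_px = truth.diameter_mm / 2.0 / ct.pixel_spacing_mm
                    cand = CandidateNodule(center_rc=truth.center_rc,
                                           radius_px=float(r_px),
                                           radius_mm=truth.diameter_mm / 2.0,
                                           score=0.0, band="fallback")
                values, nlog = nodule_features(stage["enhanced"], cand,
                                               config, seed=config.seed)
                nlog.update({"slice_id": ct.slice_id, "nodule_id": f"{ct.slice_id}-n{k}",
                             "detected": detected})
                run_log.append(nlog)
                row = dict(zip(FEATURE_NAMES, values))
                row.update({"slice_id": ct.slice_id,
                            "nodule_id": f"{ct.slice_id}-n{k}",
                            "diameter_mm": truth.diameter_mm,
                            "label": truth.label, "detected": detected})
                rows.append(row)
        run_log.append(entry)

    features = pd.DataFrame(rows)
    result: dict = {"features": features, "log": run_log, "config": config}

    labeled = not features.empty and features["label"].notna().all()
    if labeled:
        y = features["label"].to_numpy()
        counts = features["label"].value_counts()
        if counts.size == 2 and counts.min() >= 2:
            X = features[list(FEATURE_NAMES)].to_numpy()
            cm, report, case_log = loocv(
                X, y, split_fraction=config.split_fraction, sigma=config.sigma,
                pca_global=config.pca_global, seed=config.seed)
            preds = np.array([e["pred"] for e in case_log])
            bands = size_stratified_report(y, preds,
                                           features["diameter_mm"].to_numpy())
            result.update({"confusion": cm, "report": report,
                           "cases": case_log, "bands": bands})

    if out_dir is not None:
        features.to_csv(out_dir / "features.csv", index=False)
        (out_dir / "run_log.json").write_text(json.dumps(run_log, default=str, indent=1))
        if "report" in result:
            (out_dir / "report.json").write_text(json.dumps(
                report_payload(result), indent=1))
    return result


def report_payload(result: dict) -> dict:
    """JSON-serializable summary of a labeled run (Table-style rows)."""
    cm = result["confusion"]
    payload = {
        "overall": {"n": cm.total, "TP": cm.tp, "FP": cm.fp, "FN": cm.fn,
                    "TN": cm.tn, **result["report"].rounded()},
        "bands": {},
    }
    for name, (bcm, brep) in result.get("bands", {}).items():
        if name == "overall":
            continue
        payload["bands"][name] = {"n": bcm.total, "TP": bcm.tp, "FP": bcm.fp,
                                  "FN": bcm.fn, "TN": bcm.tn, **brep.rounded()}
    return payload


def run_report(result_or_dir: dict | str | Path) -> str:
    """Text table of a completed run in the standard column order
    (Nodule size, n, TP, FP, FN, TN, Acc, Sen, Spc, PDV, NDV, F1)."""
    if isinstance(result_or_dir, (str, Path)):
        path = Path(result_or_dir) / "report.json"
        if not path.exists():
            return "run incomplete: no classification report (detection-only run)"
        payload = json.loads(path.read_text())
    else:
        if "report" not in result_or_dir:
            return "run incomplete: no classification report (detection-only run)"
        payload = report_payload(result_or_dir)

    cols = ["n", "TP", "FP", "FN", "TN", "Acc", "Sen", "Spc", "PDV", "NDV", "F1"]
    lines = ["Nodule size\t" + "\t".join(cols)]
    rows = dict(payload["bands"])
    rows["Overall"] = payload["overall"]
    for name, row in rows.items():
        cells = [str(row.get(c, "-")) for c in cols]
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines)
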