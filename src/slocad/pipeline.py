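"""End-to-end orchestration: simulate -> detect -> couple -> design -> fit
-> threshold -> aggregate (cohort mode) or deviate (subject mode).

``run_pipeline`` executes a YAML-loadable configuration describing either a
synthetic cohort (producing a probability map and reference mask) or a
single synthetic subject scored against a reference mask (producing a
SloCAD result).  Every artifact is written to the output directory with a
manifest recording parameters, seeds, and SHA-256 hashes, so identical
configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .coupling import classify_coupling
from .design import assemble_design
from .deviation import SloCadResult, slocad_deviation
from .glm import fit_glm, t_contrast, threshold_statmap
from .maps import ReferenceMapBuilder, ReferenceMask
from .simulate import (BoldSimConfig, EegSimConfig, Roi, SpindleTruth,
                       SweTruth, generate_bold, generate_eeg,
                       generate_hypnogram)
from .spindles import detect_spindles
from .swe import detect_swes

DEFAULT_CONFIG: dict = {
    "mode": "cohort",
    "seed": 0,
    "variant": "main",
    "contrast": "swe",
    "q": 0.05,
    "k": 10,
    "connectivity": 26,
    "prob_threshold": 0.20,
    "n_subjects": 5,
    "stages": [["N2", 180.0], ["N3", 180.0]],
    "eeg": {
        "n_channels": 8,
        "sfreq": 200.0,
        "noise_sd": 2.0,
        "swe_rate_per_min": 8.0,
        "swe_amp": -40.0,
        "swe_amp_jitter": 10.0,
        "swe_duration": 0.6,
        "swe_duration_jitter": 0.15,
        "spindle_rate_per_min": 2.0,
        "spindle_amp": 15.0,
        "spindle_freq": 13.0,
        "spindle_duration": 1.0,
    },
    "bold": {
        "grid_shape": [24, 24, 16],
        "tr": 2.0,
        "n_volumes": 180,
        "noise_sd": 1.0,
        "drift_order": 1,
        "confound_leak": {"motion": 0.3, "csf": 0.3},
    },
    "rois": [
        {"name": "cortical", "block": [[4, 7], [4, 6], [6, 8]], "beta": 1.0},
    ],
    "subject": {"drop_rois": [], "reference": None},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = default_config()
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def subject_seed(seed: int, index: int) -> int:
    return int((seed * 10007 + index) % 2**31)


def _block_mask(grid_shape, block) -> np.ndarray:
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = block
    mask[x0:x1, y0:y1, z0:z1] = True
    return mask


def simulate_subject(seed: int, config: dict,
                     drop_rois: list[str] | None = None) -> dict:
    """Generate one subject's EEG, hypnogram, BOLD run and confounds."""
    drop_rois = drop_rois or []
    eeg_cfg = config["eeg"]
    bold_cfg = config["bold"]
    duration = bold_cfg["n_volumes"] * bold_cfg["tr"]
    rng = np.random.default_rng(seed)

    n_swe = int(round(eeg_cfg["swe_rate_per_min"] * duration / 60.0))
    spacing = duration / (n_swe + 1)
    swe_truth = []
    for i in range(n_swe):
        dur = eeg_cfg["swe_duration"] + rng.uniform(
            -eeg_cfg["swe_duration_jitter"], eeg_cfg["swe_duration_jitter"])
        onset = (i + 0.5) * spacing + rng.uniform(-0.2, 0.2) * spacing
        onset = float(np.clip(onset, 1.0, duration - dur - 1.0))
        amp = eeg_cfg["swe_amp"] + rng.uniform(
            -eeg_cfg["swe_amp_jitter"], eeg_cfg["swe_amp_jitter"])
        swe_truth.append(SweTruth(onset=onset, duration=float(dur),
                                  peak_amp=float(min(amp, -10.0))))

    n_spin = int(round(eeg_cfg["spindle_rate_per_min"] * duration / 60.0))
    spindle_truth = [
        SpindleTruth(
            onset=float(rng.uniform(2.0,
                                    duration - eeg_cfg["spindle_duration"] - 2.0)),
            duration=eeg_cfg["spindle_duration"],
            freq=eeg_cfg["spindle_freq"], amp=eeg_cfg["spindle_amp"])
        for _ in range(n_spin)
    ]

    rec, eeg_truth = generate_eeg(EegSimConfig(
        n_channels=eeg_cfg["n_channels"], duration=duration,
        sfreq=eeg_cfg["sfreq"], swe_truth=swe_truth,
        spindle_truth=spindle_truth, noise_sd=eeg_cfg["noise_sd"],
        seed=seed))
    hyp = generate_hypnogram(duration,
                             [(s, float(t)) for s, t in config["stages"]])

    rois = [Roi(mask=_block_mask(bold_cfg["grid_shape"], r["block"]),
                beta=r["beta"], condition=r.get("condition", "swe"))
            for r in config["rois"] if r["name"] not in drop_rois]
    bold, bold_truth = generate_bold(
        BoldSimConfig(grid_shape=tuple(bold_cfg["grid_shape"]),
                      n_volumes=bold_cfg["n_volumes"], tr=bold_cfg["tr"],
                      active_rois=rois, noise_sd=bold_cfg["noise_sd"],
                      drift_order=bold_cfg["drift_order"],
                      confound_leak=bold_cfg.get("confound_leak", {}),
                      seed=seed),
        eeg_truth.swe_events[["onset", "duration"]])

    return {"rec": rec, "hypnogram": hyp, "bold": bold,
            "eeg_truth": eeg_truth, "bold_truth": bold_truth,
            "roi_masks": {r["name"]: _block_mask(bold_cfg["grid_shape"],
                                                 r["block"])
                          for r in config["rois"]}}


def analyze_subject(subject: dict, config: dict) -> dict:
    """Detection, coupling, design, GLM fit, and thresholding for one run."""
    rec = subject["rec"]
    swes = detect_swes(rec, hypnogram=subject["hypnogram"])
    spindles = detect_spindles(rec, channel=0)
    swes = classify_coupling(swes, spindles)

    bold = subject["bold"]
    truth = subject["bold_truth"]
    design = assemble_design(config["variant"], swes, spindles,
                             truth.motion, truth.csf, bold.frame_times,
                             drift_order=config["bold"]["drift_order"])
    fit = fit_glm(bold, design)
    stat = t_contrast(fit, config["contrast"])
    binary, t_thresh = threshold_statmap(stat, q=config["q"], k=config["k"],
                                         connectivity=config["connectivity"])
    return {"swes": swes, "spindles": spindles, "design": design,
            "fit": fit, "stat": stat, "binary": binary,
            "t_thresholded": t_thresh}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute a cohort or subject configuration and write all artifacts.

    Returns the manifest (also written as ``manifest.json``): the resolved
    configuration, per-subject seeds, artifact hashes, and the scalar
    summary of the run.
    """
    config = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = config["mode"]
    if mode not in ("cohort", "subject"):
        raise ValueError(f"unknown mode {mode!r}")

    artifacts: dict[str, str] = {}
    summary: dict = {}

    def _write_vol(name: str, data: np.ndarray) -> None:
        path = out / name
        sio.save_volume(np.asarray(data, dtype=np.float32), path)
        artifacts[name] = _sha256(path)

    def _write_tsv(name: str, table: pd.DataFrame) -> None:
        path = out / name
        sio.write_events_tsv(table, path)
        artifacts[name] = _sha256(path)

    if mode == "cohort":
        binary_maps = []
        seeds = []
        for s in range(config["n_subjects"]):
            seed_s = subject_seed(config["seed"], s)
            seeds.append(seed_s)
            subj = simulate_subject(seed_s, config)
            res = analyze_subject(subj, config)
            binary_maps.append(res["binary"])
            _write_vol(f"sub-{s:02d}_binary.nii.gz", res["binary"])
            _write_vol(f"sub-{s:02d}_tmap.nii.gz",
                       np.nan_to_num(res["stat"].t))
            _write_tsv(f"sub-{s:02d}_swe_events.tsv", res["swes"])
            _write_tsv(f"sub-{s:02d}_spindle_events.tsv", res["spindles"])
        builder = ReferenceMapBuilder(threshold=config["prob_threshold"]).fit(
            binary_maps)
        _write_vol("probability_map.nii.gz", builder.probability_map_.values)
        _write_vol("reference_mask.nii.gz",
                   builder.mask_.mask.astype(float))
        summary = {
            "n_subjects": config["n_subjects"],
            "subject_seeds": seeds,
            "reference_n_voxels": int(builder.mask_.mask.sum()),
            "prob_threshold": config["prob_threshold"],
        }
    else:
        ref_spec = config["subject"].get("reference")
        if ref_spec is None:
            raise ValueError("subject mode requires a reference mask "
                             "(path or array)")
        if isinstance(ref_spec, (str, Path)):
            ref_data, _ = sio.load_volume(ref_spec)
            reference = ReferenceMask(mask=ref_data > 0.5,
                                      threshold=config["prob_threshold"])
        else:
            reference = ReferenceMask(mask=np.asarray(ref_spec, dtype=bool),
                                      threshold=config["prob_threshold"])
        seed_s = subject_seed(config["seed"], 0)
        subj = simulate_subject(seed_s, config,
                                drop_rois=config["subject"]["drop_rois"])
        res = analyze_subject(subj, config)
        result: SloCadResult = slocad_deviation(res["binary"], reference,
                                                t_map=res["stat"].t)
        _write_vol("subject_binary.nii.gz", res["binary"])
        _write_vol("slocad_missing.nii.gz", result.missing.astype(float))
        _write_vol("slocad_extra.nii.gz", result.extra.astype(float))
        _write_tsv("subject_swe_events.tsv", res["swes"])
        summary = {"subject_seed": seed_s, **result.summary()}

    manifest = {"config": _jsonable(config), "mode": mode,
                "summary": summary, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(_jsonable(config)))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
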