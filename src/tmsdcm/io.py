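"""Format adapters: NIfTI volumes, TSV tables, JSON posteriors and configs.

All adapters are lossless round-trips for the objects they carry; TSV
readers validate structure and report the offending line on malformed
input.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spdcm import Posterior

__all__ = [
    "save_volume", "load_volume", "save_motion", "load_motion",
    "save_scores", "load_scores", "save_posterior", "load_posterior",
    "load_targets_table", "sha256_of",
]

SCORE_COLUMNS = ["subject_id", "scale", "timepoint", "value"]
MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
TARGET_COLUMNS = [
    "patient", "x", "y", "z", "depth_mm", "rmt_pct",
    "bsi_cv_reduction", "hamd17_reduction", "madrs_reduction",
]


def save_volume(img, path: str | Path) -> Path:
    path = Path(path)
    img.to_filename(str(path))
    return path


def load_volume(path: str | Path):
    import nibabel as nib

    return nib.load(str(path))


def _read_tsv_strict(path: str | Path, expected_columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in expected_columns if c not in header]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    width = len(header)
    for i, line in enumerate(lines[1:], start=2):
        if line and len(line.split("\t")) != width:
            raise ValueError(
                f"{path}: line {i}: expected {width} fields, got {len(line.split(chr(9)))}"
            )
    return pd.read_csv(path, sep="\t")


def save_motion(motion: np.ndarray, path: str | Path) -> Path:
    df = pd.DataFrame(np.asarray(motion, float), columns=MOTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def load_motion(path: str | Path) -> np.ndarray:
    return _read_tsv_strict(path, MOTION_COLUMNS)[MOTION_COLUMNS].to_numpy(float)


def save_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    scores[SCORE_COLUMNS].to_csv(path, sep="\t", index=False)
    return Path(path)


def load_scores(path: str | Path) -> pd.DataFrame:
    return _read_tsv_strict(path, SCORE_COLUMNS)


def load_targets_table(path: str | Path) -> pd.DataFrame:
    """Per-patient target table (coordinates, depth, RMT, reductions)."""
    return _read_tsv_strict(path, TARGET_COLUMNS)


def save_posterior(post: Posterior, path: str | Path) -> Path:
    payload = {
        "mean": post.mean.tolist(),
        "cov": post.cov.tolist(),
        "free_energy": post.free_energy,
        "iterations": post.iterations,
        "accepted": post.accepted,
        "param_names": post.param_names,
        "trace": post.trace,
        "meta": post.meta,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
    return Path(path)


def load_posterior(path: str | Path) -> Posterior:
    d = json.loads(Path(path).read_text())
    return Posterior(
        mean=np.asarray(d["mean"], float),
        cov=np.asarray(d["cov"], float),
        free_energy=float(d["free_energy"]),
        iterations=int(d["iterations"]),
        accepted=int(d["accepted"]),
        param_names=list(d["param_names"]),
        trace=list(d["trace"]),
        meta=dict(d["meta"]),
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
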