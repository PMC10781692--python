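"""Temporal and spatial cleaning of already-aligned fMRI data.

Implements the stages that act on aligned data: initial volume discarding,
motion-based subject exclusion, linear detrending, nuisance regression
(Friston-24 motion expansion, WM/CSF, optional global signal), zero-phase
bandpass filtering and Gaussian spatial smoothing. Slice timing,
realignment and spatial normalization are out of scope here: synthetic
volumes are generated already aligned.

The canonical stage order, mirroring common practice for this analysis
family, is: discard -> smooth -> detrend -> confound regression (+ GSR)
-> bandpass (the bandpass always last). :func:`run_chain` applies the
temporal stages in that order and logs what it did.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MotionDecision",
    "ConfoundDesign",
    "discard_initial",
    "motion_exclusion",
    "friston24",
    "detrend",
    "regress_confounds",
    "bandpass",
    "smooth_gaussian",
    "run_chain",
]


@dataclass
class MotionDecision:
    """Keep/drop verdict for one subject's motion trace."""

    keep: bool
    max_translation: float
    max_rotation: float
    offending: list[tuple[int, int, float]] = field(default_factory=list)  # (volume, column, value)


@dataclass
class ConfoundDesign:
    """Nuisance regressor matrix (volumes x k) with column labels."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("design matrix shape does not match labels")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")


def discard_initial(data: np.ndarray, k: int, motion: np.ndarray | None = None):
    """Remove the first ``k`` frames (and the paired motion rows, if given).

    ``data`` may be a 2D (volumes x regions/voxels) series or a 4D volume
    with time on the last axis.
    """
    data = np.asarray(data)
    n = data.shape[-1] if data.ndim == 4 else data.shape[0]
    if k >= n:
        raise ValueError(f"cannot discard {k} of {n} frames")
    out = data[..., k:] if data.ndim == 4 else data[k:]
    if motion is None:
        return out
    motion = np.asarray(motion)
    if motion.shape[0] != n:
        raise ValueError("motion table rows do not match frame count")
    return out, motion[k:]


def motion_exclusion(motion: np.ndarray, trans_limit: float = 3.5, rot_limit: float = 3.5) -> MotionDecision:
    """Exclude iff any |translation| or |rotation| is strictly larger than its limit.

    Columns 0-2 are translations (mm), 3-5 rotations (degrees); the rule is
    strict ('larger than'), so a value exactly at the limit is retained.
    """
    if trans_limit <= 0 or rot_limit <= 0:
        raise ValueError("motion limits must be positive")
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must have 6 columns")
    offending = []
    limits = [trans_limit] * 3 + [rot_limit] * 3
    for c in range(6):
        bad = np.nonzero(np.abs(motion[:, c]) > limits[c])[0]
        offending.extend((int(t), c, float(motion[t, c])) for t in bad)
    return MotionDecision(
        keep=not offending,
        max_translation=float(np.abs(motion[:, :3]).max()),
        max_rotation=float(np.abs(motion[:, 3:]).max()),
        offending=offending,
    )


def friston24(motion: np.ndarray) -> ConfoundDesign:
    """24-parameter motion expansion.

    Columns: the 6 realignment parameters, their one-volume-lagged copies
    (first row zero-padded), the squares of the parameters, and the squares
    of the lagged copies. Column order is fixed.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] < 6:
        raise ValueError("need at least 6 motion columns")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    m = motion[:, :6]
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    mat = np.hstack([m, lag, m**2, lag**2])
    labels = (
        [f"mot{i+1}" for i in range(6)]
        + [f"mot{i+1}_lag" for i in range(6)]
        + [f"mot{i+1}_sq" for i in range(6)]
        + [f"mot{i+1}_lag_sq" for i in range(6)]
    )
    return ConfoundDesign(mat, labels)


def detrend(series: np.ndarray) -> np.ndarray:
    """Remove a per-column linear trend (and mean)."""
    return sps.detrend(np.asarray(series, float), axis=0, type="linear")


def regress_confounds(
    series: np.ndarray,
    design: ConfoundDesign | None = None,
    add_global: bool = False,
    wm_csf: tuple[np.ndarray, np.ndarray] | None = None,
    global_signal: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of ``series`` after projecting out nuisance regressors.

    The projection always includes an intercept; optionally the confound
    design (e.g. Friston-24), WM and CSF mean series, and the global
    signal. If ``add_global`` is set and no explicit global signal is
    given, the row mean of ``series`` is used. Rank-deficient designs are
    reduced to an independent column subset with a logged warning.
    """
    y = np.asarray(series, float)
    T = y.shape[0]
    cols = [np.ones((T, 1))]
    names = ["intercept"]
    if design is not None and design.matrix.size:
        if design.matrix.shape[0] != T:
            raise ValueError("design rows do not match series length")
        cols.append(design.matrix)
        names.extend(design.labels)
    if wm_csf is not None:
        for nm, s in zip(("wm", "csf"), wm_csf):
            s = np.asarray(s, float).reshape(T, 1)
            cols.append(s)
            names.append(nm)
    if add_global:
        g = np.asarray(global_signal, float) if global_signal is not None else y.mean(axis=1)
        cols.append(g.reshape(T, 1))
        names.append("global")
    X = np.hstack(cols)
    # rank reduction: QR with column pivoting via successive projection
    q, r, piv = _qr_pivot(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))))
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        logger.warning("dropping %d dependent confound column(s): %s", len(dropped), dropped)
        X = X[:, sorted(piv[:rank])]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, list(piv)


def bandpass(series: np.ndarray, low: float, high: float, TR: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass along axis 0.

    Forward-backward filtering (no phase distortion); the default 4th-order
    design attenuates a component one octave outside the band by far more
    than the 20 dB contract.
    """
    nyq = 0.5 / TR
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz infeasible for TR={TR} (Nyquist {nyq} Hz)")
    sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, float), axis=0)


def smooth_gaussian(volume: np.ndarray, fwhm: float, voxel_size: float | np.ndarray = 1.0) -> np.ndarray:
    """Separable Gaussian smoothing of a 3D volume (or 4D, frame-wise).

    ``sigma = FWHM / (2 * sqrt(2 ln 2))`` converted from mm to voxels.
    Reflective boundaries conserve the total image sum.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    vol = np.asarray(volume, float)
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    sigma_vox = (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vs
    if vol.ndim == 3:
        return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")
    if vol.ndim == 4:
        sig = list(sigma_vox) + [0.0]
        return ndimage.gaussian_filter(vol, sigma=sig, mode="reflect")
    raise ValueError("volume must be 3D or 4D")


def run_chain(
    series: np.ndarray,
    motion: np.ndarray | None = None,
    n_discard: int = 10,
    TR: float = 2.0,
    band: tuple[float, float] | None = (0.01, 0.1),
    wm_csf: tuple[np.ndarray, np.ndarray] | None = None,
    add_global: bool = False,
    global_signal: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Apply the temporal pipeline to an ROI/voxel series.

    Order: discard -> detrend -> Friston-24 + WM/CSF (+ global) regression
    -> bandpass. Returns the cleaned series and the list of applied stages.
    Motion rows are trimmed in lockstep with the discarded volumes.
    """
    stages = []
    if n_discard:
        if motion is not None:
            series, motion = discard_initial(series, n_discard, motion)
        else:
            series = discard_initial(series, n_discard)
        stages.append(f"discard:{n_discard}")
    series = detrend(series)
    stages.append("detrend:linear")
    design = friston24(motion) if motion is not None else None
    if design is not None or wm_csf is not None or add_global:
        series = regress_confounds(
            series, design, add_global=add_global, wm_csf=wm_csf, global_signal=global_signal
        )
        stages.append("confounds" + ("+gsr" if add_global else ""))
    if band is not None:
        series = bandpass(series, band[0], band[1], TR)
        stages.append(f"bandpass:{band[0]}-{band[1]}Hz")
    logger.info("preprocess chain: %s", " -> ".join(stages))
    return series, stages
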