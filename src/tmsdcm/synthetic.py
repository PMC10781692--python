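"""Synthetic resting-state fMRI cohorts with known effective connectivity.

This module generates everything the analysis pipeline consumes, from a
ground truth it controls: latent neuronal dynamics driven by a known coupling
matrix A (``dx/dt = A x + v``), hemodynamic convolution to BOLD via the
balloon model, optional embedding into small labelled NIfTI volumes, motion
tables, and longitudinal clinical scales with planted connectivity–outcome
associations.

The default :class:`CohortConfig` emulates the study design this package is
built around: 28 scanned patients (2 of whom carry a motion spike and are
excluded downstream, leaving 26 analyzable), two sessions (pre/post a 5-day
accelerated iTBS course), TR = 2 s, 360 acquired volumes of which the first
10 are discarded, a 5-region network around the stimulation target
(DLPFC, PCUN, HIP, INS, sgACC), and clinical scales whose baselines match
the published cohort means (e.g. BSI-CV 17.63, HAMD-17 27.91).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hemodynamics import HemodynamicParams, integrate_balloon

__all__ = [
    "EffectiveConnectivityMatrix",
    "FluctuationSpec",
    "LatentStateTrajectory",
    "TreatmentEffect",
    "ClinicalEffect",
    "CohortConfig",
    "Session",
    "SubjectRecord",
    "simulate_neuronal",
    "hemodynamic_forward",
    "power_law_noise",
    "make_block_atlas",
    "embed_volume",
    "generate_cohort",
    "default_population_matrix",
    "default_clinical_effects",
    "analytic_state_spectrum",
]

NCECM_REGIONS = ("DLPFC", "PCUN", "HIP", "INS", "sgACC")
EXTENDED_REGIONS = ("DLPFC", "PCUN", "HIP", "INS", "sgACC", "CAU", "mPFC")
TIMEPOINTS = ("baseline", "post", "week2", "week4")


class UnstableConnectivityError(ValueError):
    """Raised when a coupling matrix has eigenvalues with non-negative real part."""


@dataclass
class EffectiveConnectivityMatrix:
    """Directed coupling matrix A (Hz).

    ``values[i, j]`` is the influence of region j on region i; the diagonal
    holds (negative) self-connections. All eigenvalues must have strictly
    negative real part for the dynamics to be stationary.
    """

    values: np.ndarray
    region_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.region_names = tuple(self.region_names)
        n = len(self.region_names)
        if self.values.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("A contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.values)

    def assert_stable(self) -> None:
        ev = self.eigenvalues()
        bad = ev[ev.real >= 0]
        if bad.size:
            raise UnstableConnectivityError(
                "coupling matrix is unstable; eigenvalues with Re >= 0: "
                + ", ".join(f"{z:.4f}" for z in bad)
            )


@dataclass
class FluctuationSpec:
    """Power-law spectra of endogenous fluctuations and observation noise.

    Both spectra are two-sided power spectral densities ``a * f**(-b)``
    (units: signal**2 / Hz, f in Hz). ``alpha_state``/``beta_state``
    parameterize the neuronal fluctuations v(t); ``alpha_obs``/``beta_obs``
    the additive noise on the sampled BOLD series.
    """

    alpha_state: float = 2e-5
    beta_state: float = 1.0
    alpha_obs: float = 8e-6
    beta_obs: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_state < 0 or self.alpha_obs < 0:
            raise ValueError("noise amplitudes must be non-negative")
        for b in (self.beta_state, self.beta_obs):
            if not (0.0 <= b <= 2.0):
                raise ValueError("spectral exponents must lie in [0, 2]")


@dataclass
class LatentStateTrajectory:
    """Neuronal states on a uniform time grid (post burn-in)."""

    dt: float
    states: np.ndarray  # (T, n) or (batch, T, n)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.shape[-2]) * self.dt


def power_law_noise(
    rng: np.random.Generator,
    n_samples: int,
    dt: float,
    alpha: float,
    beta: float,
    batch_shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Zero-mean Gaussian noise with two-sided PSD ``alpha * f**(-beta)``.

    Realized by spectrally shaping white noise with an FFT filter, so the
    target spectrum is exact on the simulation grid. The DC component is set
    to zero and the power law is clamped below the first resolvable
    frequency.
    """
    if alpha == 0:
        return np.zeros(batch_shape + (n_samples,))
    white = rng.standard_normal(batch_shape + (n_samples,))
    W = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, dt)
    f_clamped = np.maximum(f, f[1] if n_samples > 1 else 1.0)
    psd = alpha * f_clamped ** (-beta)
    scale = np.sqrt(psd / dt)
    scale[0] = 0.0
    return np.fft.irfft(W * scale, n=n_samples, axis=-1)


def _simulate_latent(
    A: np.ndarray,
    fluct: FluctuationSpec,
    dt: float,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler–Maruyama integration of ``dx/dt = A x + v``.

    ``A`` has shape ``(n, n)`` or ``(B, n, n)``; returns ``(T, n)`` or
    ``(B, T, n)`` including any burn-in steps the caller asked for.
    """
    A = np.asarray(A, float)
    batched = A.ndim == 3
    B = A.shape[0] if batched else 1
    n = A.shape[-1]
    A3 = A if batched else A[None]
    v = power_law_noise(rng, n_steps, dt, fluct.alpha_state, fluct.beta_state, (B, n))
    v = np.swapaxes(v, -1, -2)  # (B, T, n)
    x = np.zeros((B, n))
    out = np.empty((B, n_steps, n))
    for t in range(n_steps):
        out[:, t] = x
        x = x + dt * (np.einsum("bij,bj->bi", A3, x) + v[:, t])
    return out if batched else out[0]


def simulate_neuronal(
    A: EffectiveConnectivityMatrix | np.ndarray,
    fluct: FluctuationSpec,
    dt: float = 0.05,
    duration: float = 700.0,
    seed: int | np.random.Generator = 0,
    burn_in: float = 60.0,
) -> LatentStateTrajectory:
    """Simulate latent neuronal dynamics from a known coupling matrix.

    The burn-in segment is simulated and discarded so the returned
    trajectory is (approximately) stationary. An unstable A is rejected
    with a diagnostic listing the offending eigenvalues.
    """
    if isinstance(A, EffectiveConnectivityMatrix):
        ecm = A
    else:
        A = np.asarray(A, float)
        ecm = EffectiveConnectivityMatrix(A, tuple(f"R{i}" for i in range(A.shape[0])))
    ecm.assert_stable()
    timescale = 1.0 / np.abs(np.diag(ecm.values)).max()
    if dt > 0.1 * timescale:
        raise ValueError(f"dt={dt} too coarse for fastest self-connection timescale {timescale:.3f} s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    states = _simulate_latent(ecm.values, fluct, dt, n_burn + n_keep, rng)
    return LatentStateTrajectory(dt=dt, states=states[..., n_burn:, :])


def hemodynamic_forward(
    states: LatentStateTrajectory,
    hemo: HemodynamicParams,
    TR: float,
) -> np.ndarray:
    """Convolve neuronal states through the balloon model and sample at TR.

    Returns a ``(volumes, n_regions)`` BOLD array (fractional signal change).
    TR must be an integer multiple of the trajectory's dt.
    """
    k = TR / states.dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"TR={TR} is not a multiple of dt={states.dt}")
    k = int(round(k))
    y = integrate_balloon(states.states, hemo, states.dt)
    return y[..., ::k, :]


def analytic_state_spectrum(
    A: np.ndarray, fluct: FluctuationSpec, freqs_hz: np.ndarray
) -> np.ndarray:
    """Analytic cross-spectrum of the latent states.

    ``S_x(f) = (i 2 pi f I - A)^{-1} G_v(f) (i 2 pi f I - A)^{-H}`` with
    ``G_v(f) = alpha_state * f**(-beta_state) * I``. Used as the oracle for
    spectral-consistency checks of the simulator.
    """
    A = np.asarray(A, float)
    n = A.shape[0]
    freqs_hz = np.asarray(freqs_hz, float)
    M = 1j * 2 * np.pi * freqs_hz[:, None, None] * np.eye(n) - A[None]
    Minv = np.linalg.inv(M)
    gv = fluct.alpha_state * freqs_hz ** (-fluct.beta_state)
    return np.einsum("fij,f,fkj->fik", Minv, gv, Minv.conj())


# ---------------------------------------------------------------------------
# Volume embedding


def make_block_atlas(
    region_names: tuple[str, ...] = NCECM_REGIONS,
    grid_shape: tuple[int, int, int] = (16, 16, 14),
    voxel_size: float = 4.0,
    block: int = 2,
):
    """Build a small labelled atlas volume for synthetic data.

    Each region gets one (or, for midline regions, two mirrored) cubic
    blocks of ``block**3`` voxels. Lateral regions sit in the left
    hemisphere (MNI x < 0); 'sgACC' and 'mPFC' straddle the midline and are
    labelled 187/188 ('sgACC') following the convention that those two
    atlas labels jointly define the subgenual cingulate.

    Returns ``(labels, affine, label_map)`` where ``label_map`` maps region
    name -> list of integer labels.
    """
    nx, ny, nz = grid_shape
    labels = np.zeros(grid_shape, dtype=np.int16)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.array(grid_shape) - 1) / 2.0

    cx = nx // 2
    label_map: dict[str, list[int]] = {}

    def lattice(x_max):
        for z0 in range(1, nz - block, block + 1):
            for y0 in range(1, ny - block, block + 1):
                for x0 in range(1, x_max + 1, block + 1):
                    yield (x0, y0, z0)

    # lateral blocks stay strictly left of the midline blocks
    lateral_slots = lattice(cx - 2 * block - 1)
    midline_slots = ((y0, z0) for z0 in range(1, nz - block, block + 1)
                     for y0 in range(1, ny - block, block + 1))
    next_label = 1
    for name in region_names:
        if name in ("sgACC", "mPFC"):
            # two mirrored midline blocks; sgACC uses the conventional 187/188
            if name == "sgACC":
                labs = [187, 188]
            else:
                labs = [next_label, next_label + 1]
                next_label += 2
            try:
                y0, z0 = next(midline_slots)
            except StopIteration:
                raise ValueError(f"grid {grid_shape} too small for region {name!r}")
            for lab, x0 in zip(labs, (cx - block, cx)):
                labels[x0 : x0 + block, y0 : y0 + block, z0 : z0 + block] = lab
            label_map[name] = labs
        else:
            try:
                x0, y0, z0 = next(lateral_slots)
            except StopIteration:
                raise ValueError(f"grid {grid_shape} too small for region {name!r}")
            sl = (slice(x0, x0 + block), slice(y0, y0 + block), slice(z0, z0 + block))
            if np.any(labels[sl]):  # pragma: no cover
                raise ValueError("overlapping atlas blocks")
            labels[sl] = next_label
            label_map[name] = [next_label]
            next_label += 1
    for name, labs in label_map.items():
        for lab in labs:
            if not np.any(labels == lab):  # pragma: no cover
                raise ValueError(f"region {name} got no voxels")
    return labels, affine, label_map


def embed_volume(
    roi_series: np.ndarray,
    labels: np.ndarray,
    affine: np.ndarray,
    label_map: dict[str, list[int]],
    region_names: tuple[str, ...],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Embed ROI time series into a 4D volume matching a label atlas.

    Every voxel of a region's labels carries that region's series plus
    i.i.d. Gaussian noise; background voxels carry pure noise (zero
    temporal mean). Returns ``(nibabel 4D image, nibabel label image)``.
    """
    import nibabel as nib

    roi_series = np.asarray(roi_series, float)
    T, n = roi_series.shape
    if n != len(region_names):
        raise ValueError("roi_series columns must match region_names")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # guard against overlapping label definitions
    seen: set[int] = set()
    for name in region_names:
        for lab in label_map[name]:
            if lab in seen:
                raise ValueError(f"label {lab} assigned to more than one region")
            seen.add(lab)
    data = np.zeros(labels.shape + (T,), dtype=np.float64)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    for r, name in enumerate(region_names):
        for lab in label_map[name]:
            data[labels == lab] += roi_series[:, r]
    img = nib.Nifti1Image(data, affine)
    limg = nib.Nifti1Image(labels.astype(np.int16), affine)
    return img, limg


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class TreatmentEffect:
    """Per-connection shift applied to the post-session coupling matrix.

    Keys are ``(destination, source)`` region-name pairs; each maps to a
    (mean, sd) pair — the realized per-subject shift is drawn from
    N(mean, sd**2) so the cohort carries between-subject variation in
    treatment response.
    """

    shifts: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


@dataclass
class ClinicalEffect:
    """Generator for one clinical scale with a planted connectivity link.

    Percent reduction at follow-up timepoint t for subject s:

        reduction = reduction_means[t]
                    + sum_c weights[c] * (shift[s, c] - mean_shift[c])
                    + N(0, noise_sd**2)

    so the planted correlation acts on the subject-level deviation of the
    connectivity shift from its cohort mean, leaving the cohort-mean
    reduction at the configured value. Follow-up scores are
    ``baseline * (1 - reduction)`` floored at zero (which caps realized
    reductions at 100%, as in real bounded scales).
    """

    baseline_mean: float
    baseline_sd: float
    reduction_means: dict[str, float]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.12
    minimum_baseline: float = 1.0


def default_population_matrix() -> EffectiveConnectivityMatrix:
    """Population-mean coupling matrix of the 5-region target network.

    Encodes the directed architecture the analysis is designed to recover:
    inhibitory influence of the stimulation target on PCUN and INS,
    excitatory relay from INS to sgACC and HIP, and inhibitory feedback
    from HIP and sgACC. Self-connections are -0.5 Hz.
    """
    names = NCECM_REGIONS
    idx = {r: i for i, r in enumerate(names)}
    A = np.zeros((5, 5))
    def put(dst, src, w):
        A[idx[dst], idx[src]] = w
    put("PCUN", "DLPFC", -0.35)
    put("INS", "DLPFC", -0.35)
    put("sgACC", "DLPFC", -0.20)
    put("HIP", "DLPFC", -0.20)
    put("sgACC", "INS", 0.35)
    put("HIP", "INS", 0.30)
    put("INS", "HIP", 0.15)
    put("sgACC", "HIP", -0.15)
    put("PCUN", "sgACC", -0.15)
    np.fill_diagonal(A, -0.5)
    ecm = EffectiveConnectivityMatrix(A, names)
    ecm.assert_stable()
    return ecm


def extended_population_matrix() -> EffectiveConnectivityMatrix:
    """7-region population matrix adding the positively coupled network.

    Extends the 5-region target network with the caudate and midline PFC:
    excitatory drive from the target to CAU, with inhibitory feedback from
    CAU to the target and to mPFC — the architecture of the
    positive-correlation model.
    """
    base = default_population_matrix()
    names = EXTENDED_REGIONS
    idx = {r: i for i, r in enumerate(names)}
    A = np.zeros((7, 7))
    A[:5, :5] = base.values
    A[idx["CAU"], idx["DLPFC"]] = 0.40
    A[idx["DLPFC"], idx["CAU"]] = -0.20
    A[idx["mPFC"], idx["CAU"]] = -0.20
    A[idx["mPFC"], idx["DLPFC"]] = 0.30
    np.fill_diagonal(A, -0.5)
    ecm = EffectiveConnectivityMatrix(A, names)
    ecm.assert_stable()
    return ecm


def default_treatment_effect() -> TreatmentEffect:
    """Planted pre→post shifts: HIP→INS strengthens, HIP→sgACC weakens."""
    return TreatmentEffect(
        shifts={
            ("INS", "HIP"): (0.20, 0.10),
            ("sgACC", "HIP"): (-0.20, 0.10),
        }
    )


def default_clinical_effects() -> dict[str, ClinicalEffect]:
    """Clinical scales on the published cohort's baseline magnitudes.

    Baseline means/SDs and cohort-mean reductions follow the published
    summary table (BSI-CV 17.63 ± 7.06 with a 65% immediate reduction,
    etc.). The suicidal-ideation and depression scales carry a planted
    negative association with the HIP→INS connectivity shift.
    """
    hip_ins = {("INS", "HIP"): -1.0}
    hip_ins_weak = {("INS", "HIP"): -0.8}
    return {
        "BSI-CV": ClinicalEffect(17.63, 7.06, {"post": 0.65, "week2": 0.67, "week4": 0.81},
                                 weights=hip_ins, noise_sd=0.12, minimum_baseline=6.0),
        "HAMD-17": ClinicalEffect(27.91, 4.31, {"post": 0.66, "week2": 0.72, "week4": 0.80},
                                  weights=hip_ins_weak, noise_sd=0.12, minimum_baseline=18.0),
        "MADRS": ClinicalEffect(36.69, 4.49, {"post": 0.59, "week2": 0.69, "week4": 0.77},
                                weights=hip_ins_weak, noise_sd=0.12, minimum_baseline=10.0),
        "BDI": ClinicalEffect(35.75, 9.17, {"post": 0.40, "week2": 0.46, "week4": 0.60},
                              noise_sd=0.15, minimum_baseline=5.0),
        "HAMD-6": ClinicalEffect(13.63, 2.17, {"post": 0.68}, noise_sd=0.12, minimum_baseline=5.0),
        "PDQ-D": ClinicalEffect(42.13, 15.65, {"post": 0.28}, noise_sd=0.15, minimum_baseline=5.0),
        "DST": ClinicalEffect(13.50, 2.31, {"post": -0.10}, noise_sd=0.08, minimum_baseline=5.0),
        "DSST": ClinicalEffect(55.19, 11.60, {"post": -0.15}, noise_sd=0.08, minimum_baseline=10.0),
    }


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible cohort."""

    n_subjects: int = 28
    region_names: tuple[str, ...] = NCECM_REGIONS
    TR: float = 2.0
    n_volumes: int = 360
    A_population: EffectiveConnectivityMatrix | None = None
    a_offdiag_sd: float = 0.10
    a_self_logsd: float = 0.05
    fluctuation: FluctuationSpec = field(default_factory=FluctuationSpec)
    hemodynamics: HemodynamicParams = field(default_factory=HemodynamicParams)
    treatment_effect: TreatmentEffect = field(default_factory=default_treatment_effect)
    clinical_effects: dict[str, ClinicalEffect] = field(default_factory=default_clinical_effects)
    n_motion_outliers: int = 2
    motion_limit: float = 3.5
    n_missing_week4: int = 1
    volume_grid: tuple[int, int, int] | None = None
    volume_noise_sd: float = 0.005
    dt: float = 0.05
    burn_in: float = 60.0
    timeseries: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 50:
            raise ValueError("n_volumes must be at least 50")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.A_population is None:
            if tuple(self.region_names) == NCECM_REGIONS:
                self.A_population = default_population_matrix()
            elif tuple(self.region_names) == EXTENDED_REGIONS:
                self.A_population = extended_population_matrix()
            else:
                raise ValueError("A_population must be given for non-default region sets")
        names = set(self.region_names)
        for key in self.treatment_effect.shifts:
            if key[0] not in names or key[1] not in names:
                raise ValueError(f"treatment effect references unknown connection {key}")
        for scale, eff in self.clinical_effects.items():
            for key in eff.weights:
                if key[0] not in names or key[1] not in names:
                    raise ValueError(f"clinical effect for {scale} references unknown connection {key}")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, EffectiveConnectivityMatrix):
                return {"values": o.values.tolist(), "region_names": list(o.region_names)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return o
            return asdict(o)
        d = asdict(self)
        d["treatment_effect"] = {f"{k[0]}<-{k[1]}": v for k, v in self.treatment_effect.shifts.items()}
        d["clinical_effects"] = {
            s: {**asdict(e), "weights": {f"{k[0]}<-{k[1]}": w for k, w in e.weights.items()}}
            for s, e in self.clinical_effects.items()
        }
        return json.dumps(d, default=default, indent=2)


@dataclass
class Session:
    """One scanning session of one synthetic subject."""

    roi_series: np.ndarray            # (n_volumes, n_regions) BOLD incl. noise
    A_true: np.ndarray                # realized coupling matrix (n, n)
    motion: np.ndarray                # (n_volumes, 6): 3 translations mm, 3 rotations deg
    volume: object = None             # optional nibabel 4D image
    label_image: object = None        # optional nibabel label image
    label_map: dict | None = None


@dataclass
class SubjectRecord:
    """Cohort container: sessions, ground truth, clinical scores, target."""

    subject_id: str
    region_names: tuple[str, ...]
    sessions: dict[str, Session]
    clinical: pd.DataFrame            # columns: scale, timepoint, value
    target_coordinate: tuple[int, int, int]
    shifts: dict[tuple[str, str], float]
    seed: int


def _draw_subject_A(
    rng: np.random.Generator, pop: EffectiveConnectivityMatrix,
    offdiag_sd: float, self_logsd: float, max_tries: int = 200,
) -> np.ndarray:
    n = pop.n_regions
    for _ in range(max_tries):
        A = pop.values.copy()
        off = ~np.eye(n, dtype=bool)
        A[off] += rng.normal(0.0, offdiag_sd, size=off.sum())
        np.fill_diagonal(A, -0.5 * np.exp(rng.normal(0.0, self_logsd, size=n)))
        if np.all(np.linalg.eigvals(A).real < 0):
            return A
    raise UnstableConnectivityError("could not draw a stable subject-level A")


def _apply_shift(A: np.ndarray, names: tuple[str, ...], shifts: dict[tuple[str, str], float]) -> np.ndarray:
    idx = {r: i for i, r in enumerate(names)}
    out = A.copy()
    for (dst, src), val in shifts.items():
        out[idx[dst], idx[src]] += val
    if np.any(np.linalg.eigvals(out).real >= 0):
        raise UnstableConnectivityError("treatment shift destabilized the coupling matrix")
    return out


def _motion_table(rng: np.random.Generator, n_volumes: int, spike: bool, limit: float) -> np.ndarray:
    """Slow random-walk motion; optionally one super-threshold spike."""
    steps = rng.normal(0.0, 0.01, size=(n_volumes, 6))
    m = np.cumsum(steps, axis=0)
    m -= m.mean(axis=0)
    if spike:
        t = rng.integers(n_volumes // 2, n_volumes)
        col = rng.integers(0, 6)
        m[t:, col] += limit + 0.5 + rng.uniform(0, 1)
    return m


def generate_cohort(cfg: CohortConfig) -> list[SubjectRecord]:
    """Generate a fully reproducible cohort from a :class:`CohortConfig`.

    The per-subject pipeline: draw A around the population mean, apply the
    treatment shift to obtain the post-session A, simulate both sessions'
    latent dynamics and BOLD, add observation noise, synthesize motion
    tables and clinical scores with the planted connectivity–outcome link.
    With ``cfg.timeseries=False`` only ground truth and clinical scores are
    generated (cheap mode for purely clinical experiments).
    """
    ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = ss.spawn(cfg.n_subjects)
    master = np.random.default_rng(ss.spawn(1)[0])

    spike_ids = set(
        master.choice(cfg.n_subjects, size=cfg.n_motion_outliers, replace=False).tolist()
    ) if cfg.n_motion_outliers else set()
    missing_ids = set(
        master.choice(
            sorted(set(range(cfg.n_subjects)) - spike_ids),
            size=min(cfg.n_missing_week4, cfg.n_subjects), replace=False,
        ).tolist()
    ) if cfg.n_missing_week4 else set()

    duration = cfg.n_volumes * cfg.TR
    n_steps = int(round((duration + cfg.burn_in) / cfg.dt))
    n_burn = int(round(cfg.burn_in / cfg.dt))
    stride = int(round(cfg.TR / cfg.dt))

    atlas = None
    if cfg.volume_grid is not None:
        atlas = make_block_atlas(cfg.region_names, cfg.volume_grid)

    records: list[SubjectRecord] = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng(subject_seeds[s])
        # rejection sampling keeps both sessions stable; the subject-level
        # coupling and shift distributions are therefore (mildly) truncated
        for _ in range(100):
            A_pre = _draw_subject_A(rng, cfg.A_population, cfg.a_offdiag_sd, cfg.a_self_logsd)
            shifts = {
                key: rng.normal(mean, sd)
                for key, (mean, sd) in cfg.treatment_effect.shifts.items()
            }
            try:
                A_post = _apply_shift(A_pre, cfg.region_names, shifts)
                break
            except UnstableConnectivityError:
                continue
        else:
            raise UnstableConnectivityError(
                "could not find a stable pre/post matrix pair for subject "
                f"{s}; treatment effect too large for the population matrix"
            )

        sessions: dict[str, Session] = {}
        for name, A in (("pre", A_pre), ("post", A_post)):
            if cfg.timeseries:
                latent = _simulate_latent(A, cfg.fluctuation, cfg.dt, n_steps, rng)
                bold = integrate_balloon(latent, cfg.hemodynamics, cfg.dt)
                bold = bold[n_burn::stride][: cfg.n_volumes]
                obs = power_law_noise(
                    rng, cfg.n_volumes, cfg.TR, cfg.fluctuation.alpha_obs,
                    cfg.fluctuation.beta_obs, (cfg.n_regions,),
                ).T
                roi = bold + obs
            else:
                roi = np.zeros((0, cfg.n_regions))
            motion = _motion_table(rng, cfg.n_volumes, s in spike_ids, cfg.motion_limit)
            sess = Session(roi_series=roi, A_true=A, motion=motion)
            if atlas is not None and cfg.timeseries:
                labels, affine, label_map = atlas
                img, limg = embed_volume(
                    roi, labels, affine, label_map, cfg.region_names,
                    noise_sd=cfg.volume_noise_sd, seed=rng,
                )
                sess.volume = img
                sess.label_image = limg
                sess.label_map = label_map
            sessions[name] = sess

        rows = []
        for scale, eff in cfg.clinical_effects.items():
            base = max(rng.normal(eff.baseline_mean, eff.baseline_sd), eff.minimum_baseline)
            rows.append({"scale": scale, "timepoint": "baseline", "value": base})
            for tp, mean_red in eff.reduction_means.items():
                red = mean_red + rng.normal(0.0, eff.noise_sd)
                for key, w in eff.weights.items():
                    red += w * (shifts[key] - cfg.treatment_effect.shifts[key][0])
                value = max(base * (1.0 - red), 0.0)
                if tp == "week4" and s in missing_ids:
                    value = np.nan
                rows.append({"scale": scale, "timepoint": tp, "value": value})
        clinical = pd.DataFrame(rows)

        target = (
            int(round(rng.normal(-32, 5))),
            int(round(rng.normal(47, 7))),
            int(round(rng.normal(26, 9))),
        )
        records.append(
            SubjectRecord(
                subject_id=f"sub-{s + 1:02d}",
                region_names=cfg.region_names,
                sessions=sessions,
                clinical=clinical,
                target_coordinate=target,
                shifts=shifts,
                seed=cfg.seed,
            )
        )
    return records
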