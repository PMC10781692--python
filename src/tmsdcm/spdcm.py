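"""Spectral dynamic causal modelling of resting-state ROI time series.

First-level effective-connectivity inference in the frequency domain.
The data feature is the complex cross-spectral density (CSD) of the ROI
series, estimated from a multivariate autoregressive model. The generative
model predicts the CSD from linear neuronal dynamics ``dx/dt = A x + v``
with power-law endogenous fluctuations, passed through the first-order
(linearized balloon) hemodynamic transfer function, plus a power-law
observation-noise floor:

    G_y(f) = H(f) G_v(f) H(f)^H + G_e(f),   H(f) = B(f) (i 2 pi f I - A)^{-1}

Model inversion is a Variational Laplace scheme: Gaussian priors and an
approximate Gaussian posterior over the parameters, with noise precision
hyperparameters per frequency band, optimized by damped Gauss–Newton
ascent on the variational free energy (accuracy minus complexity). A step
is accepted only if the free energy increases, so accepted-step free
energies are non-decreasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import HemodynamicParams, bold_transfer_function
from .synthetic import FluctuationSpec

__all__ = [
    "CrossSpectra",
    "ParamIndex",
    "Priors",
    "Posterior",
    "estimate_csd",
    "predict_csd",
    "csd_to_vector",
    "variational_laplace",
    "invert_subject",
    "default_priors",
]


@dataclass
class CrossSpectra:
    """Complex cross-spectral density on a frequency grid.

    ``values[k]`` is the Hermitian n x n CSD matrix at ``freqs[k]`` (Hz);
    diagonals are real and non-negative.
    """

    freqs: np.ndarray
    values: np.ndarray
    source: str = "estimated"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.values = np.asarray(self.values, complex)
        if np.any(self.freqs <= 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be positive and ascending")
        herm_err = np.abs(self.values - np.conj(np.swapaxes(self.values, -1, -2))).max()
        if herm_err > 1e-10 * max(1.0, np.abs(self.values).max()):
            raise ValueError(f"CSD is not Hermitian (max asymmetry {herm_err:.2e})")
        d = np.diagonal(self.values, axis1=-2, axis2=-1)
        if np.any(d.real < -1e-12 * max(1.0, np.abs(d).max())):
            raise ValueError("CSD diagonals must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.values.shape[-1]


class ParamIndex:
    """Lossless bijection between named DCM parameters and a flat vector.

    Layout: ``n*(n-1)`` off-diagonal couplings (row-major, A[i,j] = j -> i),
    ``n`` self-connection log-deviations (A[i,i] = -0.5 * exp(theta)),
    4 fluctuation parameters (log-amplitude and exponent deviation for the
    neuronal and the observation spectrum), and ``2n`` hemodynamic
    log-deviations (transit time, signal decay) per region.
    """

    def __init__(self, region_names: tuple[str, ...]):
        self.region_names = tuple(region_names)
        n = len(self.region_names)
        if n < 2:
            raise ValueError("need at least 2 regions")
        self.n = n
        self.offdiag_pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
        self.sl_offdiag = slice(0, len(self.offdiag_pairs))
        self.sl_self = slice(self.sl_offdiag.stop, self.sl_offdiag.stop + n)
        self.sl_fluct = slice(self.sl_self.stop, self.sl_self.stop + 4)
        self.sl_hemo = slice(self.sl_fluct.stop, self.sl_fluct.stop + 2 * n)
        self.size = self.sl_hemo.stop

    @property
    def names(self) -> list[str]:
        r = self.region_names
        out = [f"A[{r[i]}<-{r[j]}]" for i, j in self.offdiag_pairs]
        out += [f"self[{x}]" for x in r]
        out += ["log_alpha_state", "d_beta_state", "log_alpha_obs", "d_beta_obs"]
        out += [f"log_tau[{x}]" for x in r] + [f"log_kappa[{x}]" for x in r]
        return out

    def realize_A(self, theta: np.ndarray) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        off = theta[self.sl_offdiag]
        for k, (i, j) in enumerate(self.offdiag_pairs):
            A[i, j] = off[k]
        np.fill_diagonal(A, -0.5 * np.exp(theta[self.sl_self]))
        return A

    def pack_A(self, A: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        """Write a coupling matrix into (a copy of) a flat vector."""
        th = np.zeros(self.size) if theta is None else theta.copy()
        for k, (i, j) in enumerate(self.offdiag_pairs):
            th[k] = A[i, j]
        d = np.diag(A)
        if np.any(d >= 0):
            raise ValueError("self-connections must be negative")
        th[self.sl_self] = np.log(d / -0.5)
        return th


@dataclass
class Priors:
    """Gaussian prior over the flat parameter vector."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        if self.cov.ndim == 1:
            self.cov = np.diag(self.cov)
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) < -1e-12):
            raise ValueError("prior covariance must be PSD")


@dataclass
class Posterior:
    """Gaussian parameter posterior plus free energy and convergence record."""

    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    iterations: int = 0
    accepted: int = 0
    param_names: list[str] = field(default_factory=list)
    trace: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.free_energy):
            raise ValueError("free energy must be finite")


def default_priors(index: ParamIndex) -> Priors:
    """Shrinkage priors: couplings N(0, 1/64) Hz, self-connection and
    hemodynamic log-deviations N(0, 1/256) and N(0, 1/64), fluctuation
    log-parameters N(0, 1/64)."""
    var = np.empty(index.size)
    var[index.sl_offdiag] = 1.0 / 64.0
    var[index.sl_self] = 1.0 / 256.0
    var[index.sl_fluct] = 1.0 / 64.0
    var[index.sl_hemo] = 1.0 / 64.0
    return Priors(np.zeros(index.size), np.diag(var))


# ---------------------------------------------------------------------------
# CSD estimation (multivariate autoregressive model)


def default_frequency_grid(n_frames: int, TR: float, n_freq: int = 32) -> np.ndarray:
    """Linear grid from the fundamental 1/(N*TR) to 0.25/TR Hz."""
    return np.linspace(1.0 / (n_frames * TR), 0.25 / TR, n_freq)


def estimate_csd(
    roi_series: np.ndarray,
    TR: float,
    ar_order: int = 8,
    freqs: np.ndarray | None = None,
    n_freq: int = 32,
) -> CrossSpectra:
    """CSD of ROI series from a least-squares MVAR model.

    The series are demeaned, an MVAR(ar_order) model is fitted by ordinary
    least squares (ridge-regularized with a warning if the normal equations
    are near singular), and the CSD follows from the AR coefficients and
    innovation covariance:

        S(f) = TR * A(f)^{-1} Sigma A(f)^{-H},
        A(f) = I - sum_l A_l exp(-i 2 pi f l TR).
    """
    x = np.asarray(roi_series, float)
    T, n = x.shape
    if T < 8 * ar_order:
        raise ValueError(f"need at least {8 * ar_order} frames for AR order {ar_order}")
    x = x - x.mean(axis=0)
    Y = x[ar_order:]
    X = np.hstack([x[ar_order - l - 1 : T - l - 1] for l in range(ar_order)])
    G = X.T @ X
    cond = np.linalg.cond(G)
    if cond > 1e10:
        warnings.warn(f"ill-conditioned AR normal equations (cond={cond:.1e}); ridge added", stacklevel=2)
        G = G + 1e-8 * np.trace(G) / G.shape[0] * np.eye(G.shape[0])
    W = np.linalg.solve(G, X.T @ Y)
    resid = Y - X @ W
    Sigma = resid.T @ resid / (Y.shape[0] - ar_order * n)
    if freqs is None:
        freqs = default_frequency_grid(T, TR, n_freq)
    A_l = np.stack([W[l * n : (l + 1) * n].T for l in range(ar_order)])  # (p, n, n)
    z = np.exp(-2j * np.pi * np.asarray(freqs)[:, None] * TR * np.arange(1, ar_order + 1)[None, :])
    Af = np.eye(n)[None] - np.einsum("fl,lij->fij", z, A_l)
    Ainv = np.linalg.inv(Af)
    S = TR * np.einsum("fij,jk,flk->fil", Ainv, Sigma, Ainv.conj())
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    return CrossSpectra(freqs, S, source="estimated")


# ---------------------------------------------------------------------------
# Generative spectral prediction


def predict_csd(
    theta: np.ndarray,
    index: ParamIndex,
    freqs: np.ndarray,
    fluct_ref: FluctuationSpec,
    hemo_ref: HemodynamicParams | None = None,
) -> np.ndarray:
    """Predicted CSD (F, n, n) for a flat parameter vector.

    Fluctuation amplitudes scale ``fluct_ref`` multiplicatively via the
    log-amplitude parameters; exponents are additive deviations. The
    hemodynamic transfer uses per-region transit-time and decay
    log-deviations around ``hemo_ref``. Raises on an unstable realized A.
    """
    freqs = np.asarray(freqs, float)
    n = index.n
    A = index.realize_A(theta)
    ev = np.linalg.eigvals(A)
    if np.any(ev.real >= 0):
        raise FloatingPointError("realized coupling matrix unstable: " + str(ev[ev.real >= 0]))
    if hemo_ref is None:
        hemo_ref = HemodynamicParams()
    f_th = theta[index.sl_fluct]
    a_s = fluct_ref.alpha_state * np.exp(f_th[0])
    b_s = fluct_ref.beta_state + f_th[1]
    a_o = fluct_ref.alpha_obs * np.exp(f_th[2])
    b_o = fluct_ref.beta_obs + f_th[3]
    h_th = theta[index.sl_hemo]
    hemo = HemodynamicParams(
        kappa=np.asarray(hemo_ref.kappa) * np.exp(h_th[n:]),
        gamma=hemo_ref.gamma,
        tau=np.asarray(hemo_ref.tau) * np.exp(h_th[:n]),
        alpha=hemo_ref.alpha,
        rho=hemo_ref.rho,
        epsilon=hemo_ref.epsilon,
        V0=hemo_ref.V0,
        k1=hemo_ref.k1, k2=hemo_ref.k2, k3=hemo_ref.k3,
    )
    B = bold_transfer_function(freqs, hemo, n)  # (F, n)
    M = 1j * 2 * np.pi * freqs[:, None, None] * np.eye(n) - A[None]
    Minv = np.linalg.inv(M)
    H = B[:, :, None] * Minv  # row-scale: hemodynamics applied per output region
    gv = a_s * freqs ** (-b_s)
    ge = a_o * freqs ** (-b_o)
    S = np.einsum("fij,f,fkj->fik", H, gv, H.conj())
    S = S + ge[:, None, None] * np.eye(n)[None]
    return 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))


def csd_to_vector(S: np.ndarray) -> np.ndarray:
    """Stack real upper-triangular (incl. diagonal) and imaginary strict
    upper-triangular CSD entries over frequencies into one real vector."""
    n = S.shape[-1]
    iu = np.triu_indices(n)
    ius = np.triu_indices(n, k=1)
    re = S[:, iu[0], iu[1]].real
    im = S[:, ius[0], ius[1]].imag
    return np.concatenate([re.ravel(), im.ravel()])


def _band_indices(n_freq: int, n_entries_re: int, n_entries_im: int, n_bands: int = 4):
    """Observation-index sets for per-band noise precisions."""
    edges = np.linspace(0, n_freq, n_bands + 1).astype(int)
    bands = []
    for b in range(n_bands):
        fsel = np.zeros(n_freq, bool)
        fsel[edges[b] : edges[b + 1]] = True
        re_idx = np.repeat(fsel, n_entries_re)
        im_idx = np.repeat(fsel, n_entries_im)
        bands.append(np.concatenate([re_idx, im_idx]))
    return bands


# ---------------------------------------------------------------------------
# Variational Laplace


def _jacobian(g, theta: np.ndarray, n_out: int, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Jacobian of a vector predictor."""
    J = np.empty((n_out, theta.size))
    for k in range(theta.size):
        dp = theta.copy(); dp[k] += step
        dm = theta.copy(); dm[k] -= step
        J[:, k] = (g(dp) - g(dm)) / (2.0 * step)
    return J


def _logdet_psd(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0:
        M = M + 1e-10 * np.trace(M) / M.shape[0] * np.eye(M.shape[0])
        sign, ld = np.linalg.slogdet(M)
    return ld


def variational_laplace(
    predictor,
    data: np.ndarray,
    priors: Priors,
    bands: list[np.ndarray] | None = None,
    lambda_prior: tuple[float, float] = (0.0, 16.0),
    lambda_fixed: np.ndarray | None = None,
    max_iter: int = 64,
    tol: float = 0.01,
    fd_step: float = 1e-4,
) -> Posterior:
    """Gaussian variational inversion of ``data = predictor(theta) + noise``.

    Parameters
    ----------
    predictor
        Maps a flat parameter vector to the predicted observation vector.
        May raise ``FloatingPointError`` for infeasible parameters (treated
        as a rejected step).
    data
        Real observation vector.
    priors
        Gaussian prior over the parameters.
    bands
        Boolean index arrays partitioning the observations; each gets its
        own noise log-precision hyperparameter. Defaults to a single band.
    lambda_prior
        (mean, variance) of the Gaussian prior on each log-precision.
    lambda_fixed
        If given, noise log-precisions are fixed at these values (no
        hyperparameter optimization) — the conjugate linear-Gaussian case.

    Notes
    -----
    Damped Gauss–Newton with central finite-difference derivatives; a step
    is accepted only if the (freshly evaluated) free energy increases, and
    the scheme stops when the improvement stays below ``tol`` for three
    consecutive iterations or after ``max_iter`` iterations.
    """
    y = np.asarray(data, float)
    ny = y.size
    m0 = priors.mean
    Pi0 = np.linalg.inv(priors.cov)
    if bands is None:
        bands = [np.ones(ny, bool)]
    nb = len(bands)
    counts = np.array([b.sum() for b in bands], float)
    l0, lvar = lambda_prior
    fixed = lambda_fixed is not None
    lam = np.asarray(lambda_fixed, float).copy() if fixed else np.full(nb, l0)

    def precision_vector(lam):
        p = np.zeros(ny)
        for b, idx in enumerate(bands):
            p[idx] = np.exp(lam[b])
        return p

    def optimize_lambda(e, J, lam):
        if fixed:
            return lam, np.full(nb, np.inf)
        lam = lam.copy()
        for _ in range(8):
            p = precision_vector(lam)
            Sig = np.linalg.inv(J.T @ (J * p[:, None]) + Pi0)
            D = np.einsum("ik,kl,il->i", J, Sig, J)  # diag(J Sigma J')
            grad = np.empty(nb)
            curv = np.empty(nb)
            for b, idx in enumerate(bands):
                s2 = np.sum(e[idx] ** 2) + np.sum(D[idx])
                grad[b] = 0.5 * (counts[b] - np.exp(lam[b]) * s2) - (lam[b] - l0) / lvar
                curv[b] = 0.5 * np.exp(lam[b]) * s2 + 1.0 / lvar
            step = np.clip(grad / curv, -2.0, 2.0)
            lam = lam + step
            if np.max(np.abs(step)) < 1e-4:
                break
        return lam, curv

    def free_energy(e, J, lam, dmu):
        p = precision_vector(lam)
        H = J.T @ (J * p[:, None]) + Pi0
        Sig = np.linalg.inv(H)
        D = np.einsum("ik,kl,il->i", J, Sig, J)
        F = -0.5 * np.sum(p * e**2) - 0.5 * np.sum(p * D)
        F += 0.5 * np.sum(np.log(p)) - 0.5 * ny * np.log(2 * np.pi)
        F += -0.5 * dmu @ Pi0 @ dmu
        F += 0.5 * (_logdet_psd(Sig) + _logdet_psd(Pi0))
        if not fixed:
            F += -0.5 * np.sum((lam - l0) ** 2) / lvar
            # entropy/complexity of the hyper posterior (Laplace)
            curv = np.maximum(curv_state[0], 1e-12)
            F += 0.5 * np.sum(-np.log(curv)) + 0.5 * nb * np.log(1.0)
        return F, H, Sig

    mu = m0.copy()
    g0 = predictor(mu)
    if g0.size != ny:
        raise ValueError("predictor output length does not match data")
    J = _jacobian(predictor, mu, ny, fd_step)
    e = y - g0
    curv_state = [np.full(nb, 1.0 / lvar if not fixed else np.inf)]
    lam, curv = optimize_lambda(e, J, lam)
    curv_state[0] = curv
    F, H, Sig = free_energy(e, J, lam, mu - m0)
    if not np.isfinite(F):
        raise RuntimeError(f"non-finite initial free energy; parameter snapshot: {mu}")

    trace = [F]
    accepted = 0
    stall = 0
    damp = 1e-6
    it = 0
    for it in range(1, max_iter + 1):
        p = precision_vector(lam)
        grad = J.T @ (p * e) - Pi0 @ (mu - m0)
        ok = False
        for _ in range(16):
            Hreg = H + damp * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hreg, grad)
            except np.linalg.LinAlgError:
                damp *= 8
                continue
            mu_c = mu + step
            try:
                g_c = predictor(mu_c)
                J_c = _jacobian(predictor, mu_c, ny, fd_step)
                e_c = y - g_c
                lam_c, curv_c = optimize_lambda(e_c, J_c, lam)
                curv_state[0] = curv_c
                F_c, H_c, Sig_c = free_energy(e_c, J_c, lam_c, mu_c - m0)
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                F_c = -np.inf
            if np.isfinite(F_c) and F_c > F:
                dF = F_c - F
                mu, e, J, lam, F, H, Sig = mu_c, e_c, J_c, lam_c, F_c, H_c, Sig_c
                accepted += 1
                damp = max(damp / 4.0, 1e-6)
                ok = True
                break
            damp *= 8.0
        if not ok:
            break
        trace.append(F)
        stall = stall + 1 if dF < tol else 0
        if stall >= 3:
            break

    Sig = 0.5 * (Sig + Sig.T)
    return Posterior(
        mean=mu, cov=Sig, free_energy=float(F), iterations=it, accepted=accepted,
        trace=trace, meta={"lambda": lam.tolist()},
    )


# ---------------------------------------------------------------------------
# Subject-level inversion


def _calibrate_fluct_reference(
    S_data: np.ndarray, index: ParamIndex, freqs: np.ndarray,
    hemo_ref: HemodynamicParams,
) -> FluctuationSpec:
    """Reference fluctuation amplitudes matched to the data CSD.

    The log-amplitude parameters are shrinkage-prior deviations around a
    reference; starting that reference in the right ballpark (signal power
    from the in-band diagonal CSD, noise floor from the top frequency
    quartile) keeps the deviations small, exactly as data scaling does in
    standard spectral-DCM practice.
    """
    diag = np.real(np.diagonal(S_data, axis1=-2, axis2=-1))
    top = max(1, len(freqs) // 4)
    noise_level = float(np.clip(diag[-top:].mean(), 1e-12, None))
    probe = FluctuationSpec(alpha_state=1.0, beta_state=1.0, alpha_obs=0.0, beta_obs=0.0)
    S_sig = predict_csd(np.zeros(index.size), index, freqs, probe, hemo_ref)
    sig_gain = float(np.real(np.diagonal(S_sig, axis1=-2, axis2=-1)).mean())
    target = float(np.clip(diag.mean() - 0.5 * noise_level, 1e-12, None))
    return FluctuationSpec(
        alpha_state=target / max(sig_gain, 1e-12),
        beta_state=1.0,
        alpha_obs=0.5 * noise_level,
        beta_obs=0.0,
    )


def invert_subject(
    roi_series_by_session: dict[str, np.ndarray],
    TR: float,
    region_names: tuple[str, ...],
    ar_order: int = 8,
    n_freq: int = 32,
    priors: Priors | None = None,
    hemo_ref: HemodynamicParams | None = None,
    max_iter: int = 64,
    n_bands: int = 4,
) -> dict[str, Posterior]:
    """Invert the fully connected spectral DCM for each session.

    Builds the parameter index over all ``n*(n-1)`` reciprocal couplings
    plus self-connections, estimates the CSD per session, and runs
    Variational Laplace. Sessions are inverted separately; the returned
    posteriors share the parameter index and are ready for group-level
    (empirical Bayes) analysis.
    """
    index = ParamIndex(region_names)
    if priors is None:
        priors = default_priors(index)
    if hemo_ref is None:
        hemo_ref = HemodynamicParams()
    out: dict[str, Posterior] = {}
    for session, series in roi_series_by_session.items():
        series = np.asarray(series, float)
        csd = estimate_csd(series, TR, ar_order=ar_order, n_freq=n_freq)
        scale = float(np.real(np.diagonal(csd.values, axis1=-2, axis2=-1)).mean())
        S = csd.values / scale
        fluct_ref = _calibrate_fluct_reference(S, index, csd.freqs, hemo_ref)
        y = csd_to_vector(S)
        n = index.n
        bands = _band_indices(len(csd.freqs), n * (n + 1) // 2, n * (n - 1) // 2, n_bands)

        def predictor(theta, _f=fluct_ref):
            return csd_to_vector(predict_csd(theta, index, csd.freqs, _f, hemo_ref))

        post = variational_laplace(
            predictor, y, priors, bands=bands, max_iter=max_iter,
        )
        post.param_names = index.names
        post.meta.update({
            "session": session, "csd_scale": scale, "freqs": csd.freqs.tolist(),
            "region_names": list(region_names),
        })
        out[session] = post
    return out
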