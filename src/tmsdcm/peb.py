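"""Hierarchical (parametric empirical Bayes) group inference over DCM posteriors.

Second level of the hierarchical model: each subject/session posterior over
DCM parameters enters as a Gaussian likelihood (its mean with its
covariance), and group effects are estimated with a GLM whose design
matrix encodes commonalities (a constant), pre/post session, and
responder-status covariates:

    theta(1)_i = X_i theta(2) + eps(2),   theta(2) = eta + eps(3)

``eps(2)`` carries random between-subject effects with an estimated
precision scale. Because the model is linear-Gaussian given that scale,
the group posterior and the (marginal-likelihood) free energy are exact;
the precision scale is optimized by type-II maximum likelihood with a
Laplace correction.

Model comparison uses Bayesian model reduction: the evidence and
posterior of any model with tightened priors follow analytically from the
full model's fit, without refitting. A greedy pruning search plus an
exhaustive terminal neighborhood replaces the infeasible enumeration of
all reduced models, and Bayesian model averaging summarizes parameters
over the plausible models.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .spdcm import Posterior, Priors

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "PEBModel",
    "BMAResult",
    "build_design",
    "peb_fit",
    "bmr",
    "greedy_search",
    "bma",
]

REDUCED_VARIANCE = 1e-8  # prior variance of a switched-off parameter


@dataclass
class Design:
    """Second-level design matrix with named columns."""

    matrix: np.ndarray
    names: list[str]
    warnings: list[str] = field(default_factory=list)


@dataclass
class PEBModel:
    """Fitted second-level model."""

    design: Design
    param_names: list[str]          # first-level parameters entering the GLM
    group_names: list[str]          # covariate x parameter names (flat)
    mean: np.ndarray                # posterior mean of theta(2)
    cov: np.ndarray                 # posterior covariance of theta(2)
    prior: Priors                   # prior over theta(2)
    gamma: float                    # log precision scale of between-subject effects
    between_cov: np.ndarray         # realized between-subject covariance (q x q)
    free_energy: float


@dataclass
class BMAResult:
    """Moment-matched average over candidate reduced models."""

    names: list[str]
    mean: np.ndarray
    variance: np.ndarray
    prob_nonzero: np.ndarray
    weights: np.ndarray
    switches: np.ndarray            # (n_models, n_params) on/off patterns


def build_design(subject_table: pd.DataFrame) -> Design:
    """Design matrix over subject-session rows.

    ``subject_table`` needs columns ``subject_id``, ``session`` ('pre' or
    'post'), ``si_responder`` and ``dep_responder`` (booleans; suicidal
    ideation and depression response). Columns: a constant (commonalities);
    session coded -0.5/+0.5; responder flags effect-coded (+-0.5) and
    mean-centered. A covariate with no variance is flagged non-estimable.
    """
    required = {"subject_id", "session", "si_responder", "dep_responder"}
    missing = required - set(subject_table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    sess = subject_table["session"].map({"pre": -0.5, "post": 0.5})
    if sess.isna().any():
        raise ValueError("session column must be 'pre' or 'post'")
    cols = [np.ones(len(subject_table)), sess.to_numpy(float)]
    names = ["mean", "session"]
    warns = []
    for col, nm in (("si_responder", "si_response"), ("dep_responder", "dep_response")):
        v = subject_table[col].astype(bool).map({True: 0.5, False: -0.5}).to_numpy(float)
        v = v - v.mean()
        if np.allclose(v, 0):
            warns.append(f"covariate {nm} has no variance (non-estimable)")
            warnings.warn(warns[-1], stacklevel=2)
        cols.append(v)
        names.append(nm)
    return Design(np.column_stack(cols), names, warns)


def _stack_first_level(posteriors: list[Posterior], param_subset: list[int]):
    names = None
    mus, covs = [], []
    for p in posteriors:
        pn = [p.param_names[k] for k in param_subset] if p.param_names else None
        if names is None:
            names = pn
        elif pn != names:
            raise ValueError("posteriors do not share a parameter index")
        mus.append(p.mean[param_subset])
        covs.append(p.cov[np.ix_(param_subset, param_subset)])
    return names, np.array(mus), np.array(covs)


def peb_fit(
    posteriors: list[Posterior],
    design: Design,
    param_subset: list[int] | None = None,
    prior_variance: np.ndarray | None = None,
    between_scale: float = 1.0 / 16.0,
    gamma_prior: tuple[float, float] = (0.0, 1.0),
    gamma_fixed: float | None = None,
) -> PEBModel:
    """Empirical-Bayes estimation of group effects.

    Parameters
    ----------
    posteriors
        First-level posteriors (one per row of the design), sharing a
        parameter index.
    design
        Output of :func:`build_design` (rows aligned with ``posteriors``).
    param_subset
        Indices of the first-level parameters modelled at the second level
        (default: all).
    prior_variance
        Prior variance per (covariate x parameter) group effect; defaults
        to 1/64.
    between_scale
        The between-subject covariance is
        ``exp(-gamma) * between_scale * diag(prior_variance_per_param)``;
        ``gamma`` is optimized (type-II ML with a Gaussian prior).
    """
    if len(posteriors) != design.matrix.shape[0]:
        raise ValueError("design rows must align with posteriors")
    q = posteriors[0].mean.size
    subset = list(range(q)) if param_subset is None else list(param_subset)
    names, mus, covs = _stack_first_level(posteriors, subset)
    if names is None:
        names = [f"p{k}" for k in subset]
    N, q = mus.shape
    X = design.matrix
    nc = X.shape[1]

    pv = np.full(nc * q, 1.0 / 64.0) if prior_variance is None else np.asarray(prior_variance, float)
    prior = Priors(np.zeros(nc * q), np.diag(pv))
    base_between = between_scale * np.diag(pv[:q])  # per-parameter scale

    y = mus.ravel()  # subject-major: [subject 0 params..., subject 1 params...]
    eta = prior.mean
    Sigma2 = prior.cov

    def fit_given_gamma(gamma: float):
        Sb = np.exp(-gamma) * base_between
        # per-subject marginal covariance and its inverse
        Ci = covs + Sb[None]
        Ci_inv = np.linalg.inv(Ci)
        # Xtilde^T C^-1 Xtilde and Xtilde^T C^-1 (y - Xtilde eta), exploiting
        # the Kronecker structure of row blocks x_i (x) I_q
        G = np.zeros((nc * q, nc * q))
        b = np.zeros(nc * q)
        logdetC = 0.0
        quad = 0.0
        eta_mat = eta.reshape(nc, q)
        for i in range(N):
            xi = X[i]
            ri = mus[i] - xi @ eta_mat
            Pi = Ci_inv[i]
            G += np.kron(np.outer(xi, xi), Pi)
            b += np.kron(xi, Pi @ ri)
            s, ld = np.linalg.slogdet(Ci[i])
            logdetC += ld
            quad += ri @ Pi @ ri
        Pi2 = np.linalg.inv(Sigma2)
        H = Pi2 + G
        Sig_post = np.linalg.inv(H)
        mu_post = eta + Sig_post @ b
        # log marginal likelihood via the matrix determinant lemma
        s2, ld2 = np.linalg.slogdet(Sigma2)
        sH, ldH = np.linalg.slogdet(H)
        logml = -0.5 * (N * q * np.log(2 * np.pi) + logdetC + ld2 + ldH + quad - b @ Sig_post @ b)
        return logml, mu_post, Sig_post, Sb

    g0, gv = gamma_prior

    def neg_obj(gamma):
        logml, *_ = fit_given_gamma(gamma)
        return -(logml - 0.5 * (gamma - g0) ** 2 / gv)

    if gamma_fixed is not None:
        gamma = float(gamma_fixed)
        logml, mu_post, Sig_post, Sb = fit_given_gamma(gamma)
        F = logml
    else:
        res = minimize_scalar(neg_obj, bounds=(-6.0, 6.0), method="bounded",
                              options={"xatol": 1e-3})
        gamma = float(res.x)
        logml, mu_post, Sig_post, Sb = fit_given_gamma(gamma)
        # Laplace correction for gamma uncertainty
        h = 1e-3
        d2 = (neg_obj(gamma + h) - 2 * neg_obj(gamma) + neg_obj(gamma - h)) / h**2
        prec = max(d2, 1e-6)
        F = logml - 0.5 * (gamma - g0) ** 2 / gv + 0.5 * np.log(2 * np.pi / prec)

    group_names = [f"{cn}:{pn}" for cn in design.names for pn in names]
    return PEBModel(
        design=design, param_names=names, group_names=group_names,
        mean=mu_post, cov=0.5 * (Sig_post + Sig_post.T), prior=prior,
        gamma=gamma, between_cov=Sb, free_energy=float(F),
    )


def bmr(
    post_mean: np.ndarray,
    post_cov: np.ndarray,
    priors_full: Priors,
    priors_reduced: Priors,
):
    """Analytic Bayesian model reduction.

    Given a Gaussian posterior obtained under ``priors_full``, returns
    ``(delta_F, reduced_mean, reduced_cov)`` for the model with
    ``priors_reduced`` — the change in log evidence and the posterior the
    reduced model would have produced, computed without refitting.
    """
    m, S = np.asarray(post_mean, float), np.asarray(post_cov, float)
    m0, S0 = priors_full.mean, priors_full.cov
    m0r, S0r = priors_reduced.mean, priors_reduced.cov

    def inv(M):
        try:
            return np.linalg.inv(M)
        except np.linalg.LinAlgError:
            cond = np.linalg.cond(M)
            logger.warning("singular precision combination (cond=%.2e); pseudo-inverse used", cond)
            return np.linalg.pinv(M)

    P, P0, P0r = inv(S), inv(S0), inv(S0r)
    Pr = P - P0 + P0r
    Sr = inv(Pr)
    mr = Sr @ (P @ m - P0 @ m0 + P0r @ m0r)
    _, ldS0 = np.linalg.slogdet(S0)
    _, ldS0r = np.linalg.slogdet(S0r)
    _, ldS = np.linalg.slogdet(S)
    _, ldSr = np.linalg.slogdet(Sr)
    dF = 0.5 * (ldS0 - ldS - ldS0r + ldSr)
    dF += 0.5 * (mr @ Pr @ mr - m @ P @ m + m0 @ P0 @ m0 - m0r @ P0r @ m0r)
    return float(dF), mr, 0.5 * (Sr + Sr.T)


def _reduced_priors(prior: Priors, on: np.ndarray) -> Priors:
    """Prior with switched-off parameters shrunk to ~zero variance."""
    var = np.diag(prior.cov).copy()
    var[~on] = REDUCED_VARIANCE
    mean = prior.mean.copy()
    mean[~on] = 0.0
    return Priors(mean, np.diag(var))


def greedy_search(
    peb: PEBModel,
    searchable: np.ndarray | None = None,
    max_passes: int = 8,
    k_cap: int = 8,
):
    """Greedy pruning over group parameters plus a terminal neighborhood.

    At each pass every currently-on (searchable) parameter is provisionally
    switched off via BMR; all prunings that increase the evidence are
    applied. After convergence (or ``max_passes``), the ``k`` parameters
    with the weakest evidence either way (|delta F| smallest, capped at
    ``k_cap``) span an exhaustive 2^k neighborhood whose members are all
    scored. Returns a list of ``(on_vector, free_energy, mean, cov)``
    sorted by free energy (descending). Deterministic given its inputs.
    """
    p = peb.mean.size
    searchable = np.ones(p, bool) if searchable is None else np.asarray(searchable, bool)
    on = np.ones(p, bool)

    def score(on_vec):
        dF, mr, Sr = bmr(peb.mean, peb.cov, peb.prior, _reduced_priors(peb.prior, on_vec))
        return dF, mr, Sr

    F_cur, _, _ = score(on)
    for _ in range(max_passes):
        improved = []
        for k in np.nonzero(on & searchable)[0]:
            trial = on.copy()
            trial[k] = False
            dFk, _, _ = score(trial)
            if dFk > F_cur:
                improved.append(k)
        if not improved:
            break
        on[improved] = False
        F_cur, _, _ = score(on)
    # terminal neighborhood over the most uncertain searchable parameters
    deltas = {}
    for k in np.nonzero(searchable)[0]:
        trial = on.copy()
        trial[k] = not trial[k]
        dFk, _, _ = score(trial)
        deltas[int(k)] = abs(dFk - F_cur)
    uncertain = sorted(deltas, key=lambda k: deltas[k])[: min(k_cap, len(deltas))]
    models = {}
    for bits in itertools.product([True, False], repeat=len(uncertain)):
        trial = on.copy()
        for k, b in zip(uncertain, bits):
            trial[k] = b
        key = tuple(trial.tolist())
        if key not in models:
            dFk, mr, Sr = score(trial)
            models[key] = (np.array(key), dFk, mr, Sr)
    out = sorted(models.values(), key=lambda t: -t[1])
    return out


def bma(models: list[tuple[np.ndarray, float, np.ndarray, np.ndarray]]) -> BMAResult:
    """Evidence-weighted, moment-matched average over reduced models.

    ``models`` holds ``(on_vector, free_energy, mean, cov)`` tuples.
    Weights are softmax over free energies; the averaged distribution is
    the moment-matched Gaussian of the mixture, and each parameter's
    posterior probability of being nonzero is the summed weight of the
    models in which it is switched on.
    """
    if not models:
        raise ValueError("need at least one model")
    Fs = np.array([m[1] for m in models], float)
    if not np.all(np.isfinite(Fs)):
        raise ValueError("non-finite model evidences")
    w = np.exp(Fs - Fs.max())
    w /= w.sum()
    switches = np.stack([m[0] for m in models])
    means = np.stack([m[2] for m in models])
    variances = np.stack([np.diag(m[3]) for m in models])
    mean = w @ means
    second = w @ (variances + means**2)
    var = np.maximum(second - mean**2, 0.0)
    prob = w @ switches.astype(float)
    return BMAResult(
        names=[], mean=mean, variance=var, prob_nonzero=prob, weights=w, switches=switches
    )
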