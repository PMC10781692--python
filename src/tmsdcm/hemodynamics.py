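"""Balloon–Windkessel hemodynamic model.

The model maps neuronal activity ``u(t)`` to a BOLD signal through four
hemodynamic states per region: vasodilatory signal ``s``, normalized blood
inflow ``f``, venous volume ``v`` and deoxyhemoglobin content ``q``:

    ds/dt = eps*u - kappa*s - gamma*(f - 1)
    df/dt = s
    dv/dt = (f - v**(1/alpha)) / tau
    dq/dt = (f*E(f,rho)/rho - v**(1/alpha) * q/v) / tau

with oxygen extraction ``E(f, rho) = 1 - (1 - rho)**(1/f)`` and readout

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

Two views of the model are provided: full nonlinear integration (used when
simulating BOLD data) and the first-order transfer function obtained by
linearizing around the resting fixed point ``(s, f, v, q) = (0, 1, 1, 1)``
(used inside the spectral likelihood, where only the small-signal kernel
matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HemodynamicParams", "integrate_balloon", "bold_transfer_function"]


@dataclass
class HemodynamicParams:
    """Parameters of the balloon model.

    Region-wise parameters may be scalars (shared) or arrays of length
    ``n_regions``. Units: ``kappa`` and ``gamma`` in 1/s, ``tau`` in s;
    ``alpha``, ``rho``, ``epsilon``, ``V0`` and the BOLD coefficients are
    dimensionless. ``k1/k2/k3`` default to the classic 1.5 T expressions
    ``7*rho``, ``2`` and ``2*rho - 0.2``.
    """

    kappa: float | np.ndarray = 0.64
    gamma: float | np.ndarray = 0.32
    tau: float | np.ndarray = 2.0
    alpha: float | np.ndarray = 0.32
    rho: float | np.ndarray = 0.4
    epsilon: float | np.ndarray = 1.0
    V0: float = 0.04
    k1: float = field(default=None)  # type: ignore[assignment]
    k2: float = field(default=None)  # type: ignore[assignment]
    k3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k1 is None:
            self.k1 = 7.0 * float(np.mean(self.rho))
        if self.k2 is None:
            self.k2 = 2.0
        if self.k3 is None:
            self.k3 = 2.0 * float(np.mean(self.rho)) - 0.2
        for name in ("kappa", "gamma", "tau", "rho", "epsilon"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"hemodynamic parameter {name!r} must be strictly positive")
        a = np.asarray(self.alpha)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.V0 <= 0:
            raise ValueError("V0 must be strictly positive")

    def broadcast(self, n_regions: int) -> dict[str, np.ndarray]:
        """Return region-wise parameter arrays of length ``n_regions``."""
        out = {}
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "epsilon"):
            out[name] = np.broadcast_to(np.asarray(getattr(self, name), float), (n_regions,)).copy()
        return out


def integrate_balloon(neural: np.ndarray, params: HemodynamicParams, dt: float) -> np.ndarray:
    """Integrate the balloon model driven by ``neural`` activity.

    Parameters
    ----------
    neural
        Array of shape ``(..., T, n)`` — neuronal activity on a uniform grid
        with step ``dt`` (leading axes are batch axes).
    params
        Hemodynamic parameters (scalars or per-region arrays of length n).
    dt
        Integration step in seconds.

    Returns
    -------
    Array of shape ``(..., T, n)`` with the BOLD signal (fractional signal
    change; zero at the resting fixed point).

    Notes
    -----
    Flow, volume and deoxyhemoglobin are integrated in log space so the
    states stay positive regardless of noise amplitude.
    """
    neural = np.asarray(neural, float)
    if not np.all(np.isfinite(neural)):
        raise ValueError("neuronal input contains non-finite values")
    n = neural.shape[-1]
    T = neural.shape[-2]
    batch = neural.shape[:-2]
    p = params.broadcast(n)
    kappa, gamma, tau, alpha, rho, eps = (
        p["kappa"], p["gamma"], p["tau"], p["alpha"], p["rho"], p["epsilon"],
    )
    ia = 1.0 / alpha

    s = np.zeros(batch + (n,))
    lf = np.zeros(batch + (n,))  # ln f
    lv = np.zeros(batch + (n,))  # ln v
    lq = np.zeros(batch + (n,))  # ln q
    y = np.empty(batch + (T, n))

    k1, k2, k3, V0 = params.k1, params.k2, params.k3, params.V0
    for t in range(T):
        f = np.exp(lf)
        v = np.exp(lv)
        q = np.exp(lq)
        E = 1.0 - (1.0 - rho) ** (1.0 / f)
        ds = eps * neural[..., t, :] - kappa * s - gamma * (f - 1.0)
        dlf = s / f
        outflow = v ** ia
        dlv = (f - outflow) / (tau * v)
        dlq = (f * E / rho - outflow * q / v) / (tau * q)
        s = s + dt * ds
        # clamp log-states: keeps the integrator finite under extreme
        # fluctuation draws (physiological range is |log state| << 2)
        lf = np.clip(lf + dt * dlf, -2.0, 2.0)
        lv = np.clip(lv + dt * dlv, -2.0, 2.0)
        lq = np.clip(lq + dt * dlq, -2.0, 2.0)
        vv = np.exp(lv)
        qq = np.exp(lq)
        y[..., t, :] = V0 * (k1 * (1.0 - qq) + k2 * (1.0 - qq / vv) + k3 * (1.0 - vv))
    return y


def _linearized_system(params: HemodynamicParams, n: int):
    """Jacobian, input and output vectors of the balloon model at rest.

    Returns ``(J, B, C)`` with shapes ``(n, 4, 4)``, ``(n, 4)``, ``(n, 4)``
    for state ordering ``(s, f, v, q)``.
    """
    p = params.broadcast(n)
    kappa, gamma, tau, alpha, rho, eps = (
        p["kappa"], p["gamma"], p["tau"], p["alpha"], p["rho"], p["epsilon"],
    )
    J = np.zeros((n, 4, 4))
    J[:, 0, 0] = -kappa
    J[:, 0, 1] = -gamma
    J[:, 1, 0] = 1.0
    J[:, 2, 1] = 1.0 / tau
    J[:, 2, 2] = -1.0 / (alpha * tau)
    # d/df [f*E(f)/rho] at f=1 = (rho + (1-rho)*ln(1-rho)) / rho
    cf = (rho + (1.0 - rho) * np.log(1.0 - rho)) / rho
    J[:, 3, 1] = cf / tau
    J[:, 3, 2] = -(1.0 / alpha - 1.0) / tau
    J[:, 3, 3] = -1.0 / tau

    B = np.zeros((n, 4))
    B[:, 0] = eps

    C = np.zeros((n, 4))
    C[:, 2] = params.V0 * (params.k2 - params.k3)
    C[:, 3] = -params.V0 * (params.k1 + params.k2)
    return J, B, C


def bold_transfer_function(freqs_hz: np.ndarray, params: HemodynamicParams, n_regions: int) -> np.ndarray:
    """First-order neuronal→BOLD transfer function per region.

    Parameters
    ----------
    freqs_hz
        Frequencies in Hz, shape ``(F,)``.
    params
        Hemodynamic parameters (may be region-wise).
    n_regions
        Number of regions.

    Returns
    -------
    Complex array ``(F, n_regions)``: ``b_i(f) = C_i (i 2 pi f I - J_i)^{-1} B_i``.
    """
    freqs_hz = np.asarray(freqs_hz, float)
    J, B, C = _linearized_system(params, n_regions)
    omega = 2.0 * np.pi * freqs_hz
    # (F, n, 4, 4) systems solved in one batched call
    eye = np.eye(4)
    M = 1j * omega[:, None, None, None] * eye - J[None, :, :, :]
    x = np.linalg.solve(M, np.broadcast_to(B[None, :, :, None], M.shape[:-1] + (1,)).copy())
    return np.einsum("nk,fnko->fn", C, x)
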