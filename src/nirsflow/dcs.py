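"""DCS inversion: curve averaging and correlation-diffusion fitting.

One measurement comprises ~12 intensity-autocorrelation curves g2(τ)
collected over 10 s at a single 2 cm separation.  The curves are averaged
pointwise and the semi-infinite correlation-diffusion model with the
Siegert relation, g2 = 1 + β·g1², is fitted to the mean curve for the
blood flow index CBFi and the coherence factor β by Nelder-Mead simplex
minimization of the summed squared residual.  CBFi is log-parameterized
inside the search to enforce positivity; β is fitted jointly, initialized
from the early-τ intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .forward import (
    CorrelationModelParams,
    InstrumentConfig,
    correlation_params,
    g1_semi_infinite,
)

CBFI_INIT = 1e-8          # cm²/s
FIT_XTOL = 1e-10
FIT_FTOL = 1e-10
FIT_MAX_ITER = 2000


@dataclass
class DCSMeasurement:
    """A set of g2 curves from one probe placement."""

    tau_s: np.ndarray
    curves: np.ndarray  # (n_curves, n_tau)
    rho_cm: float = 2.0

    def __post_init__(self) -> None:
        self.tau_s = np.asarray(self.tau_s, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != self.tau_s.size:
            raise ValueError("curve length does not match tau grid")
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("curves must be finite")


@dataclass
class DCSFit:
    """Result of fitting the correlation-diffusion model to a mean g2 curve."""

    cbfi: float
    beta: float
    residual_ss: float
    converged: bool
    n_iterations: int
    degenerate: bool = False  # no measurable decay (flat curve, β→0)


def average_curves(meas: DCSMeasurement) -> np.ndarray:
    """Pointwise arithmetic mean over the measurement's curves."""
    if meas.curves.shape[0] < 1:
        raise ValueError("no curves to average")
    return meas.curves.mean(axis=0)


def fit_cbfi(
    mean_g2: np.ndarray,
    mua_850: float,
    musp_850: float,
    config: InstrumentConfig,
    tau_min: float | None = None,
    tau_max: float | None = None,
    cbfi_init: float = CBFI_INIT,
    beta_init: float | None = None,
    max_iter: int = FIT_MAX_ITER,
) -> DCSFit:
    """Fit (CBFi, β) to a mean intensity-autocorrelation curve.

    Parameters
    ----------
    mean_g2
        Averaged g2 on the instrument τ grid.
    mua_850, musp_850
        Tissue optical coefficients at the DCS wavelength, cm⁻¹.  In the
        standard configuration μa comes from the per-measurement FDNIRS
        extrapolation and μs′ is the fixed cohort-average 6.4 cm⁻¹.
    tau_min, tau_max
        Optional clipping of the fitted τ range (full grid by default).
    beta_init
        Initial coherence factor; defaults to the mean of the three
        earliest-τ g2 values minus 1.

    Returns
    -------
    DCSFit
        Estimates with residual and convergence diagnostics.  A curve with
        no measurable decay (initial intercept ≤ 0) is flagged degenerate
        and returned with β = 0 without running the optimizer.
    """
    if mua_850 <= 0 or musp_850 <= 0:
        raise ValueError("mua_850 and musp_850 must be positive")
    tau = config.tau_array()
    mean_g2 = np.asarray(mean_g2, dtype=float)
    if mean_g2.shape != tau.shape:
        raise ValueError("mean_g2 must be on the instrument tau grid")
    if not np.all(np.isfinite(mean_g2)):
        raise ValueError("mean_g2 must be finite")
    sel = np.ones_like(tau, dtype=bool)
    if tau_min is not None:
        sel &= tau >= tau_min
    if tau_max is not None:
        sel &= tau <= tau_max
    tau_fit = tau[sel]
    y = mean_g2[sel]

    if beta_init is None:
        beta_init = float(np.mean(y[:3]) - 1.0)
    if beta_init <= 1e-6:
        # flat curve: no decay information, nothing to fit
        return DCSFit(cbfi=float("nan"), beta=0.0,
                      residual_ss=float(np.sum((y - 1.0) ** 2)),
                      converged=False, n_iterations=0, degenerate=True)
    beta_init = min(beta_init, 1.0)

    base = correlation_params(mua_850, musp_850, cbfi_init, config)

    def model(log_cbfi: float, beta: float) -> np.ndarray:
        p = CorrelationModelParams(
            rho=base.rho, mua=base.mua, musp=base.musp, k0=base.k0,
            zb=base.zb, cbfi=float(np.exp(log_cbfi)), beta=min(max(beta, 1e-9), 1.0),
        )
        return 1.0 + p.beta * g1_semi_infinite(p, tau_fit) ** 2

    def objective(x: np.ndarray) -> float:
        r = model(x[0], x[1]) - y
        return float(r @ r)

    res = optimize.minimize(
        objective,
        x0=np.array([np.log(cbfi_init), beta_init]),
        method="Nelder-Mead",
        options={"xatol": FIT_XTOL, "fatol": FIT_FTOL,
                 "maxiter": max_iter, "maxfev": 4 * max_iter},
    )
    cbfi = float(np.exp(res.x[0]))
    beta = float(min(max(res.x[1], 0.0), 1.0))
    return DCSFit(cbfi=cbfi, beta=beta, residual_ss=float(res.fun),
                  converged=bool(res.success), n_iterations=int(res.nit))
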