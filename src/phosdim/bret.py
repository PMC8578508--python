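"""NanoBRET quantification and dose-response fitting.

The BRET ratio is reported in milliBRET units,
``1000 * acceptor(610 nm) / donor(450 nm)``.  Three fit models are provided:
a one-site total binding curve for acceptor-DNA titrations,

    Y = Bmax * X / (Kd + X) + NS * X,

and variable-slope four-parameter logistic curves on log10 dose for
agonist-type (EC50) and inhibitor-type (IC50) experiments,

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogX50 - X) * HillSlope)).

Fits are nonlinear least squares with data-driven initialization and
positivity bounds on Kd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; the message carries diagnostics."""


def millibret(a610: float | np.ndarray, d450: float | np.ndarray) -> float | np.ndarray:
    """milliBRET units: 1000 x acceptor emission / donor emission."""
    d = np.asarray(d450, dtype=float)
    if np.any(d <= 0):
        raise ValueError("donor emission must be > 0")
    out = 1000.0 * np.asarray(a610, dtype=float) / d
    return float(out) if out.ndim == 0 else out


def one_site_total(x, bmax, kd, ns):
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x) + ns * x


def four_pl(x_log, bottom, top, log_x50, hill):
    x_log = np.asarray(x_log, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_x50 - x_log) * hill))


@dataclass
class OneSiteTotalFit:
    bmax: float
    kd: float
    ns: float
    residual: float  # sum of squared residuals

    def predict(self, x):
        return one_site_total(x, self.bmax, self.kd, self.ns)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    log_x50: float
    hill: float
    residual: float
    mode: str  # "EC50" or "IC50"

    @property
    def x50(self) -> float:
        """EC50 / IC50 on the linear dose scale."""
        return 10.0 ** self.log_x50

    def predict(self, x_log):
        return four_pl(x_log, self.bottom, self.top, self.log_x50, self.hill)


def fit_one_site_total(x, y) -> OneSiteTotalFit:
    """Fit the one-site total binding model (Kd constrained positive)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    bmax0 = float(np.max(y)) or 1.0
    kd0 = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    ns0 = 0.0
    try:
        popt, _ = optimize.curve_fit(
            one_site_total, x, y, p0=[bmax0, kd0, ns0],
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"one-site fit did not converge: {exc}") from exc
    rss = float(np.sum((y - one_site_total(x, *popt)) ** 2))
    return OneSiteTotalFit(float(popt[0]), float(popt[1]), float(popt[2]), rss)


def fit_4pl(x_log, y, mode: str = "EC50") -> FourPLFit:
    """Fit a variable-slope four-parameter logistic on log10 dose.

    ``mode`` records whether the midpoint is an EC50 (signal rising with
    dose) or IC50 (falling); the functional form is identical and the fit is
    canonicalized so Bottom is the low-dose asymptote (HillSlope sign flips
    accordingly).
    """
    if mode not in ("EC50", "IC50"):
        raise ValueError("mode must be 'EC50' or 'IC50'")
    x_log = np.asarray(x_log, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_log.size < 5:
        raise ValueError("need at least 5 points")
    lo, hi = float(np.min(y)), float(np.max(y))
    # midpoint guess: log-dose whose response is nearest the half-range
    mid = lo + 0.5 * (hi - lo)
    x0 = float(x_log[np.argmin(np.abs(y - mid))])
    hill0 = 1.0 if mode == "EC50" else -1.0
    bottom0, top0 = (lo, hi)
    try:
        popt, _ = optimize.curve_fit(
            four_pl, x_log, y, p0=[bottom0, top0, x0, hill0],
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_x50, hill = (float(v) for v in popt)
    # canonical form: Bottom is the low-dose asymptote
    if hill < 0:
        bottom, top, hill = top, bottom, -hill
    rss = float(np.sum((y - four_pl(x_log, bottom, top, log_x50, hill)) ** 2))
    return FourPLFit(bottom, top, log_x50, hill, rss, mode)


def simulate_bret_series(
    model: str,
    params: dict,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (dose, response) series for fit-recovery studies.

    ``model`` is ``'one_site'`` (linear doses) or ``'4pl'`` (log10 doses).
    Noiseless mode reproduces the model curve exactly; noise is Gaussian and
    seeded.
    """
    doses = np.asarray(doses, dtype=float)
    if model == "one_site":
        y = one_site_total(doses, params["bmax"], params["kd"], params["ns"])
    elif model == "4pl":
        y = four_pl(
            doses, params["bottom"], params["top"], params["log_x50"], params["hill"]
        )
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_sd:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=doses.shape)
    return doses, y
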