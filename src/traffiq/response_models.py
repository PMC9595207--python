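"""Dose-response and kinetic models: 3-parameter Hill fits (EC50/IC50),
one-phase association kinetics (t1/2), and AIC-based shared-vs-independent
curve comparison.

The 3-parameter Hill model is the standard agonist/antagonist model with
the slope fixed at 1:

    stimulation:  R(d) = Bottom + (Top - Bottom) * d / (EC50 + d)
    inhibition:   R(c) = Bottom + (Top - Bottom) * IC50 / (IC50 + c)

so R(0) = Bottom (stimulation) or Top (inhibition) is handled natively.
One-phase association is S(t) = S0 + (Splateau - S0) * (1 - exp(-k t)) with
t1/2 = ln 2 / k. AIC is computed from the least-squares residuals as
``n * ln(RSS / n) + 2k`` with k the number of fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

__all__ = ["FitResult", "fit_hill3", "fit_one_phase",
           "compare_shared_vs_independent", "hill_curve", "one_phase_curve"]


@dataclass
class FitResult:
    model: str
    params: Dict[str, float]
    se: Dict[str, float]
    rss: float
    n: int
    aic: float
    converged: bool
    extra: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def aic_from_rss(rss: float, n: int, k: int) -> float:
    rss = max(float(rss), 1e-300)  # guard exact fits
    return n * np.log(rss / n) + 2 * k


def hill_curve(dose, bottom, top, xc50, direction="stimulation"):
    d = np.asarray(dose, dtype=float)
    if direction == "stimulation":
        frac = d / (xc50 + d)
    elif direction == "inhibition":
        frac = xc50 / (xc50 + d)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return bottom + (top - bottom) * frac


def one_phase_curve(t, s0, splateau, k):
    t = np.asarray(t, dtype=float)
    return s0 + (splateau - s0) * (1.0 - np.exp(-k * t))


def _try_fits(fun, x, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                fun, x, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((fun(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    return best


def fit_hill3(doses: Sequence[float], responses: Sequence[float],
              direction: str = "stimulation") -> FitResult:
    """Least-squares 3-parameter Hill fit on per-dose summary responses.

    Multistart initialization: the half-maximal dose is started at every
    observed non-zero dose (and their geometric mean), Bottom/Top at the
    observed response extremes. The half-maximal parameter is reported as
    ``ec50`` for stimulation and ``ic50`` for inhibition fits.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct doses for a 3-parameter fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("doses and responses must be finite")

    pname = "ec50" if direction == "stimulation" else "ic50"
    lo, hi = float(y.min()), float(y.max())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    nz = np.unique(x[x > 0])
    starts = [(lo, hi, c) for c in nz] + [(lo, hi, float(np.exp(np.mean(np.log(nz)))))]

    def fun(d, bottom, top, xc50):
        return hill_curve(d, bottom, top, xc50, direction)

    bounds = ([lo - 10 * span, lo - 10 * span, nz.min() * 1e-4],
              [hi + 10 * span, hi + 10 * span, nz.max() * 1e4])
    best = _try_fits(fun, x, y, starts, bounds)
    if best is None:
        return FitResult(model=f"hill3:{direction}", params={}, se={},
                         rss=np.nan, n=len(x), aic=np.nan, converged=False)
    popt, pcov, rss = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    params = {"bottom": popt[0], "top": popt[1], pname: popt[2]}
    se = {"bottom": perr[0], "top": perr[1], pname: perr[2]}
    return FitResult(model=f"hill3:{direction}", params=params, se=se,
                     rss=rss, n=len(x), aic=aic_from_rss(rss, len(x), 3),
                     converged=True)


def fit_one_phase(times: Sequence[float], responses: Sequence[float]) -> FitResult:
    """Least-squares one-phase association fit; reports t1/2 = ln2/k.

    The standard error of t1/2 comes from the delta method applied to the
    rate constant: se(t1/2) = ln2 / k^2 * se(k).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError("need >= 4 distinct time points")
    if np.ptp(y) == 0:
        return FitResult(model="one_phase", params={}, se={}, rss=np.nan,
                         n=len(t), aic=np.nan, converged=False)

    tmax = t[t > 0].max()
    starts = [(y[np.argmin(t)], y[np.argmax(t)], np.log(2) / h)
              for h in np.geomspace(tmax / 50, tmax * 2, 6)]
    span = float(np.ptp(y))
    bounds = ([y.min() - 10 * span, y.min() - 10 * span, 1e-6],
              [y.max() + 10 * span, y.max() + 10 * span, 1e4])
    best = _try_fits(one_phase_curve, t, y, starts, bounds)
    if best is None:
        return FitResult(model="one_phase", params={}, se={}, rss=np.nan,
                         n=len(t), aic=np.nan, converged=False)
    popt, pcov, rss = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    k = popt[2]
    thalf = np.log(2) / k
    se_thalf = np.log(2) / k ** 2 * perr[2]
    params = {"s0": popt[0], "splateau": popt[1], "k": k, "t_half": thalf}
    se = {"s0": perr[0], "splateau": perr[1], "k": perr[2], "t_half": se_thalf}
    return FitResult(model="one_phase", params=params, se=se, rss=rss,
                     n=len(t), aic=aic_from_rss(rss, len(t), 3), converged=True)


def compare_shared_vs_independent(datasets: Sequence[Tuple[Sequence[float], Sequence[float]]],
                                  shared: str = "ec50",
                                  direction: Optional[str] = None):
    """Compare independent Hill fits against a global fit sharing one parameter.

    ``shared`` names the half-maximal parameter (``ec50`` or ``ic50``, which
    also sets the fit direction unless overridden). Both models are scored
    under a common Gaussian error variance on the pooled residuals:
    ``AIC = N ln(RSS_total / N) + 2k`` with N the total number of points and
    k = 3m (independent) or 2m + 1 (shared, one common half-maximal dose and
    per-dataset Bottom/Top). Returns a dict with both AICs, ``delta_aic``
    (shared minus independent) and the preferred model (lower AIC wins).
    """
    if len(datasets) < 2:
        raise ValueError("need >= 2 datasets to compare")
    if shared not in ("ec50", "ic50"):
        raise ValueError("shared parameter must be 'ec50' or 'ic50'")
    direction = direction or ("stimulation" if shared == "ec50" else "inhibition")

    indep = []
    for i, (d, r) in enumerate(datasets):
        fit = fit_hill3(d, r, direction)
        if not fit.converged:
            raise RuntimeError(f"independent fit failed for dataset {i}")
        indep.append(fit)

    xs = [np.asarray(d, dtype=float) for d, _ in datasets]
    ys = [np.asarray(r, dtype=float) for _, r in datasets]
    n_total = sum(len(y) for y in ys)
    m = len(datasets)
    rss_indep = sum(f.rss for f in indep)
    aic_indep = aic_from_rss(rss_indep, n_total, 3 * m)

    def resid(theta):
        log_xc = theta[0]
        out = []
        for i in range(m):
            b, tpar = theta[1 + 2 * i], theta[2 + 2 * i]
            out.append(hill_curve(xs[i], b, tpar, np.exp(log_xc), direction) - ys[i])
        return np.concatenate(out)

    xc0 = np.exp(np.mean([np.log(f.params[shared]) for f in indep]))
    theta0 = [np.log(xc0)]
    for f in indep:
        theta0 += [f.params["bottom"], f.params["top"]]
    sol = optimize.least_squares(resid, theta0, method="lm", max_nfev=20000)
    rss_shared = float(np.sum(sol.fun ** 2))
    k_shared = 2 * m + 1
    aic_shared = aic_from_rss(rss_shared, n_total, k_shared)

    delta = aic_shared - aic_indep
    return {
        "aic_shared": aic_shared,
        "aic_independent": aic_indep,
        "delta_aic": delta,
        "preferred": "shared" if delta < 0 else "independent",
        "shared_value": float(np.exp(sol.x[0])),
        "independent_fits": indep,
    }
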