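"""Equilibrium one-site binding and competitive-displacement models.

Three pieces of biophysics, all in the free-ligand approximation (no
depletion; appropriate for plate assays with trace immobilised target):

* the one-site isotherm ``theta(L) = L / (Kd + L)`` and its least-squares fit
  to saturation (ELISA-style) curves,
* mutually exclusive one-site competition between a TF (affinity ``K_T``,
  free concentration ``T``) and a G4-stabilising ligand (affinity ``K_P``):
  ``theta(P) = (T/K_T) / (1 + T/K_T + P/K_P)``,
* the closed-form competitor concentration that halves occupancy relative to
  the ligand-free baseline, ``IC50 = K_P * (1 + T/K_T)`` — a Cheng-Prusoff
  style amplification: a tightly bound, abundant TF takes far more competitor
  to displace than the competitor's intrinsic affinity alone suggests.

Concentrations are in nM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingParams",
    "CompetitionModel",
    "DoseResponse",
    "FitError",
    "bound_fraction",
    "fit_saturation",
    "competition_fraction",
    "predicted_ic50",
    "fit_dose_response",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails or is unidentifiable."""


@dataclass
class BindingParams:
    """One-site saturation parameters (concentrations in nM)."""

    k_d: float
    a_max: float
    background: float = 0.0
    k_d_se: Optional[float] = None
    a_max_se: Optional[float] = None
    background_se: Optional[float] = None
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("K_d must be > 0")
        if self.a_max <= 0:
            raise ValueError("A_max must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")

    def signal(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.background + self.a_max * conc / (self.k_d + conc)


@dataclass
class CompetitionModel:
    """Mutually exclusive TF/ligand binding at one G4 site (nM units)."""

    k_t: float  # TF-G4 dissociation constant
    k_p: float  # ligand-G4 dissociation constant
    t: float    # free TF concentration

    def __post_init__(self) -> None:
        if self.k_t <= 0 or self.k_p <= 0 or self.t <= 0:
            raise ValueError("all competition-model parameters must be > 0")


@dataclass
class DoseResponse:
    """Fitted one-site displacement curve."""

    doses: np.ndarray
    responses: np.ndarray
    ic50: float
    top: float
    bottom: float
    hill: float
    ic50_se: Optional[float]
    in_dose_range: bool
    defined: bool = True


def bound_fraction(conc: float, k_d: float) -> float:
    """One-site isotherm occupancy ``L / (K_d + L)`` (depletion-free)."""
    if k_d <= 0:
        raise ValueError("K_d must be > 0")
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = conc_arr / (k_d + conc_arr)
    return float(out) if out.ndim == 0 else out


def fit_saturation(conc: Sequence[float], signal: Sequence[float]) -> BindingParams:
    """Least-squares fit of ``signal = background + A_max * L / (K_d + L)``.

    Initialisation: background = min(signal), A_max = max - min, K_d = the
    concentration nearest half-maximum by linear interpolation.  Asymptotic
    standard errors come from the covariance of the fit.  Raises
    :class:`FitError` on non-convergence or an unidentifiable (e.g.
    non-increasing) curve; an estimate pinned at a parameter bound is flagged.
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if conc.ndim != 1 or conc.shape != signal.shape or len(conc) < 4:
        raise ValueError("need >= 4 (concentration, signal) pairs")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    smin, smax = float(signal.min()), float(signal.max())
    if smax <= smin:
        raise FitError("flat signal: saturation curve is unidentifiable")
    half = smin + 0.5 * (smax - smin)
    order = np.argsort(conc)
    cs, ss = conc[order], signal[order]
    # linear interpolation of the concentration at half-max (first crossing)
    k0 = float(cs[-1])
    for i in range(len(cs) - 1):
        lo, hi = ss[i], ss[i + 1]
        if (lo - half) * (hi - half) <= 0 and lo != hi:
            frac = (half - lo) / (hi - lo)
            k0 = float(cs[i] + frac * (cs[i + 1] - cs[i]))
            break
    k0 = max(k0, 1e-6)
    p0 = (k0, smax - smin, smin)

    def model(L, k_d, a_max, background):
        return background + a_max * L / (k_d + L)

    upper_kd = max(1e4 * conc.max(), 1.0)
    try:
        popt, pcov = curve_fit(
            model, conc, signal, p0=p0,
            bounds=([1e-9, 1e-12, 0.0], [upper_kd, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"saturation fit did not converge (init K_d={p0[0]:.3g}, "
            f"A_max={p0[1]:.3g}, background={p0[2]:.3g}): {exc}"
        ) from exc
    k_d, a_max, background = (float(v) for v in popt)
    resid = signal - model(conc, *popt)
    if a_max < 1e-9 or not np.isfinite(pcov).all():
        raise FitError(
            "saturation fit unidentifiable "
            f"(A_max={a_max:.3g}, residual SS={float(resid @ resid):.3g})"
        )
    se = np.sqrt(np.diag(pcov))
    at_bound = bool(k_d <= 2e-9 or k_d >= 0.99 * upper_kd)
    return BindingParams(
        k_d, a_max, background,
        k_d_se=float(se[0]), a_max_se=float(se[1]), background_se=float(se[2]),
        at_bound=at_bound,
    )


def competition_fraction(model: CompetitionModel, p: float):
    """TF occupancy of the G4 under mutually exclusive competition.

    ``theta(P) = (T/K_T) / (1 + T/K_T + P/K_P)``; at ``P = 0`` this reduces to
    the isotherm ``T / (K_T + T)`` and it decreases monotonically to 0.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("competitor concentration must be >= 0")
    ratio = model.t / model.k_t
    out = ratio / (1.0 + ratio + p_arr / model.k_p)
    return float(out) if out.ndim == 0 else out


def predicted_ic50(model: CompetitionModel) -> float:
    """Competitor concentration halving occupancy relative to ``theta(0)``.

    Closed form ``IC50 = K_P * (1 + T/K_T)``; with no TF (T -> 0) it reduces
    to the competitor's own affinity ``K_P``.
    """
    return model.k_p * (1.0 + model.t / model.k_t)


def fit_dose_response(
    doses: Sequence[float],
    responses: Sequence[float],
    free_hill: bool = False,
) -> DoseResponse:
    """Least-squares fit of a one-site displacement curve.

    ``response = bottom + (top - bottom) / (1 + (P / IC50)^h)`` with the Hill
    slope ``h`` fixed at 1 unless ``free_hill``.  A flat curve yields an
    undefined IC50 (``defined=False``) rather than an error; an IC50 outside
    the measured dose range is flagged via ``in_dose_range`` (the "> 5 uM"
    style of reporting).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.ndim != 1 or doses.shape != responses.shape or len(doses) < 4:
        raise ValueError("need >= 4 (dose, response) pairs")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be given in increasing order")
    rmin, rmax = float(responses.min()), float(responses.max())
    if np.isclose(rmin, rmax, rtol=0.0, atol=1e-12 + 1e-9 * max(abs(rmax), 1.0)):
        return DoseResponse(doses, responses, float("nan"), rmax, rmin, 1.0,
                            None, False, defined=False)
    pos = doses[doses > 0]
    ic0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0

    def model(P, ic50, top, bottom, hill):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(P > 0, (P / ic50) ** hill, 0.0)
        return bottom + (top - bottom) / (1.0 + frac)

    if free_hill:
        p0 = (ic0, rmax, rmin, 1.0)
        bounds = ([1e-9, -np.inf, -np.inf, 0.2], [np.inf, np.inf, np.inf, 5.0])
        fit = lambda P, ic50, top, bottom, hill: model(P, ic50, top, bottom, hill)
    else:
        p0 = (ic0, rmax, rmin)
        bounds = ([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        fit = lambda P, ic50, top, bottom: model(P, ic50, top, bottom, 1.0)
    try:
        popt, pcov = curve_fit(fit, doses, responses, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"dose-response fit did not converge (init IC50={ic0:.3g}): {exc}") from exc
    ic50 = float(popt[0])
    top, bottom = float(popt[1]), float(popt[2])
    hill = float(popt[3]) if free_hill else 1.0
    se = np.sqrt(np.diag(pcov))
    in_range = bool(doses[doses > 0].min() <= ic50 <= doses.max()) if len(pos) else False
    return DoseResponse(doses, responses, ic50, top, bottom, hill,
                        float(se[0]) if np.isfinite(se[0]) else None, in_range)
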