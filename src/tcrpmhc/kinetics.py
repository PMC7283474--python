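"""1:1 Langmuir binding model for SPR: simulation and fitting.

The reversible bimolecular interaction A + B <-> AB at constant analyte
concentration C admits closed-form sensorgram phases:

association (0 <= t <= t_assoc):
    R(t) = Req * (1 - exp(-(kon*C + koff) * t)),   Req = Rmax * C / (C + KD)
dissociation (t > t_assoc):
    R(t) = R(t_assoc) * exp(-koff * (t - t_assoc))

with KD = koff / kon.  Equilibrium analysis fits Req(C) = Rmax*C/(C + KD) to
steady-state responses; kinetic analysis fits the full closed-form model
globally across analyte concentrations.  No ODE integration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import FitError, IdentifiabilityError

R_GAS = 8.314462618  # J/(mol K), unused by the model but handy for reporting


def kd_from_rates(kon: float, koff: float) -> float:
    """KD (M) from kinetic rate constants: KD = koff / kon."""
    if kon <= 0:
        raise ValueError(f"kon must be positive, got {kon}")
    if koff < 0:
        raise ValueError(f"koff must be non-negative, got {koff}")
    return koff / kon


@dataclass
class KineticParams:
    kon: float   # M^-1 s^-1
    koff: float  # s^-1
    rmax: float  # response units
    kon_se: Optional[float] = None
    koff_se: Optional[float] = None
    rmax_se: Optional[float] = None
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.kon <= 0:
            raise ValueError("kon must be positive")
        if self.koff < 0:
            raise ValueError("koff must be non-negative")
        if self.rmax <= 0:
            raise ValueError("rmax must be positive")

    @property
    def kd(self) -> float:
        return kd_from_rates(self.kon, self.koff)


@dataclass
class Sensorgram:
    analyte_conc: float        # M
    time: np.ndarray           # s, strictly increasing
    response: np.ndarray       # RU
    t_assoc_end: float         # s, end of the association phase

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.analyte_conc < 0:
            raise ValueError("analyte concentration must be non-negative")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite values")


def langmuir_response(
    t: np.ndarray, kon: float, koff: float, rmax: float, conc: float, t_assoc_end: float
) -> np.ndarray:
    """Closed-form 1:1 sensorgram at analyte concentration ``conc``."""
    t = np.asarray(t, dtype=float)
    kobs = kon * conc + koff
    kd = koff / kon
    req = rmax * conc / (conc + kd) if conc + kd > 0 else 0.0
    with np.errstate(over="ignore"):
        assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc_end)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc_end))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc_end, 0.0))
    return np.where(t <= t_assoc_end, assoc, dissoc)


def simulate_sensorgram(
    params: KineticParams,
    conc: float,
    t_assoc: float,
    t_dissoc: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    dt: float = 0.1,
) -> Sensorgram:
    """Simulate a pre-subtracted 1:1 sensorgram with additive Gaussian noise."""
    if conc < 0:
        raise ValueError("analyte concentration must be non-negative")
    if t_assoc <= 0 or t_dissoc < 0:
        raise ValueError("phase durations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    time = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    response = langmuir_response(time, params.kon, params.koff, params.rmax,
                                 conc, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return Sensorgram(analyte_conc=conc, time=time, response=response,
                      t_assoc_end=t_assoc)


@dataclass
class EquilibriumFit:
    kd: float                 # M
    rmax: float               # RU
    kd_se: Optional[float]
    rmax_se: Optional[float]
    residual_sse: float       # RU^2
    well_determined: bool = True


def fit_equilibrium(points: Sequence[Tuple[float, float]]) -> EquilibriumFit:
    """Fit Req(C) = Rmax*C/(C + KD) to (concentration, steady response) points.

    Unweighted nonlinear least squares.  The fit is flagged poorly determined
    when the concentration series does not bracket the fitted KD.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (conc, response) pairs")
    conc, resp = pts[:, 0], pts[:, 1]
    if len(np.unique(conc)) < 3:
        raise IdentifiabilityError(
            "equilibrium fit needs >= 3 distinct analyte concentrations"
        )
    if np.allclose(resp, 0.0):
        raise FitError("all responses are zero; KD is unidentifiable")

    rmax0 = float(resp.max()) * 1.5
    half = rmax0 / 3.0
    above = conc[resp >= half]
    kd0 = float(above.min()) if above.size else float(np.median(conc))

    def model(c, kd, rmax):
        return rmax * c / (c + kd)

    try:
        popt, pcov = optimize.curve_fit(
            model, conc, resp, p0=[kd0, rmax0],
            bounds=([1e-15, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"equilibrium fit did not converge: {exc}") from exc
    kd, rmax = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [None, None]
    sse = float(np.sum((model(conc, *popt) - resp) ** 2))
    bracketed = bool(conc.min() < kd < conc.max())
    return EquilibriumFit(
        kd=kd, rmax=rmax,
        kd_se=float(perr[0]) if perr[0] is not None else None,
        rmax_se=float(perr[1]) if perr[1] is not None else None,
        residual_sse=sse, well_determined=bracketed,
    )


def steady_state_points(
    sensorgrams: Sequence[Sensorgram], window_fraction: float = 0.05
) -> List[Tuple[float, float]]:
    """Extract (conc, plateau response) pairs from the association-phase tail."""
    out = []
    for sg in sensorgrams:
        assoc = sg.response[sg.time <= sg.t_assoc_end]
        n = max(1, int(len(assoc) * window_fraction))
        out.append((sg.analyte_conc, float(np.mean(assoc[-n:]))))
    return out


def fit_kinetics(
    sensorgrams: Sequence[Sensorgram],
    resolvability_threshold: Optional[float] = None,
) -> KineticParams:
    """Global fit of the closed-form 1:1 model across analyte concentrations.

    Fits log10(kon), log10(koff) and a shared Rmax by unweighted least
    squares over all sensorgram points (both phases).  The ``reliable`` flag
    is cleared when the fastest observed rate kobs = kon*C + koff exceeds the
    resolvability threshold (default: 1 / (3 * median sampling interval)),
    i.e. when the exponential phases are too fast for the time sampling.
    """
    if len(sensorgrams) < 2:
        raise IdentifiabilityError("kinetic fit needs >= 2 analyte concentrations")
    for sg in sensorgrams:
        if sg.t_assoc_end >= sg.time[-1]:
            raise FitError(
                "sensorgram has no dissociation phase; both phases are required"
            )
        if sg.t_assoc_end <= sg.time[0]:
            raise FitError("sensorgram has no association phase")

    rmax0 = max(float(sg.response.max()) for sg in sensorgrams) * 1.2
    rmax0 = max(rmax0, 1e-6)

    def residuals(theta):
        log_kon, log_koff, rmax = theta
        kon, koff = 10.0**log_kon, 10.0**log_koff
        res = []
        for sg in sensorgrams:
            model = langmuir_response(sg.time, kon, koff, rmax,
                                      sg.analyte_conc, sg.t_assoc_end)
            res.append(model - sg.response)
        return np.concatenate(res)

    best = None
    # multistart over plausible rate scales; the 1:1 surface is well-behaved
    for log_kon0 in (3.0, 4.0, 5.0, 6.0):
        for log_koff0 in (-3.0, -2.0, -1.0, 0.0):
            try:
                sol = optimize.least_squares(
                    residuals, x0=[log_kon0, log_koff0, rmax0],
                    bounds=([-2, -8, 1e-9], [12, 4, np.inf]),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except ValueError:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not best.success and best.cost > 1e-6:
        raise FitError("kinetic fit did not converge")

    log_kon, log_koff, rmax = best.x
    kon, koff = float(10.0**log_kon), float(10.0**log_koff)

    dts = np.concatenate([np.diff(sg.time) for sg in sensorgrams])
    if resolvability_threshold is None:
        resolvability_threshold = 1.0 / (3.0 * float(np.median(dts)))
    kobs_max = max(kon * sg.analyte_conc + koff for sg in sensorgrams)
    reliable = kobs_max <= resolvability_threshold

    # standard errors from the Gauss-Newton approximation at the optimum
    se = [None, None, None]
    try:
        jac = best.jac
        dof = max(len(best.fun) - 3, 1)
        cov = np.linalg.inv(jac.T @ jac) * (2 * best.cost / dof)
        se_log = np.sqrt(np.diag(cov))
        se = [
            kon * np.log(10) * se_log[0],
            koff * np.log(10) * se_log[1],
            se_log[2],
        ]
    except np.linalg.LinAlgError:
        pass

    return KineticParams(
        kon=kon, koff=koff, rmax=float(rmax),
        kon_se=se[0], koff_se=se[1], rmax_se=se[2],
        reliable=bool(reliable),
    )
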