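"""Force-curve analysis: DLVO fitting, feature extraction, reporting.

The centrepiece is :func:`fit_dlvo`, a weighted nonlinear least-squares fit
of the charge-regulated DLVO energy to a windowed force curve.  Positivity
of ``psi_eff`` and ``kappa`` is enforced by fitting their logarithms and the
regulation parameter is mapped to [0, 1] through a smooth sine bijection,
so the optimizer itself is unconstrained (Levenberg-Marquardt).  Shallow
local minima in ``p`` are avoided by a small multi-start.

Feature extraction recovers the mechanical signatures of the measurement:
jump-in/jump-out discontinuities, squeeze-out step heights between
consecutive hard-wall branches, and the pull-off (adhesion) energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import least_squares

from . import electrolyte
from .constants import DEFAULT_HAMAKER, round_sig
from .dlvo import DlvoParams, total_energy
from .simulate import ForceCurve

__all__ = [
    "FitConfig",
    "FitResult",
    "FeatureReport",
    "fit_dlvo",
    "detect_jumps",
    "step_heights",
    "adhesion_energy",
    "fit_report",
]

_PARAM_ORDER = ("psi_eff", "kappa", "p", "hamaker", "offset")


class FitConfig(BaseModel):
    """Fit window, free parameters, starting values and options.

    ``window`` is (D_min, D_max) in metres.  ``free`` lists the parameters
    to optimize out of {psi_eff, kappa, p, hamaker, offset}; everything else
    is clamped at its value in ``fixed``.  ``offset`` is an additive
    separation offset (m), useful for real data where the absolute contact
    position is uncertain; it defaults to fixed at zero.
    """

    window: tuple[float, float]
    free: tuple[str, ...] = ("psi_eff", "kappa", "p")
    fixed: dict[str, float] = Field(
        default_factory=lambda: {"hamaker": DEFAULT_HAMAKER, "offset": 0.0}
    )
    weighting: str = "uniform"  # uniform | inverse-variance
    noise_sigma: float | None = None  # J/m^2, used by inverse-variance weighting
    p_starts: tuple[float, ...] = (0.1, 0.5, 0.9)
    bootstrap_replicates: int = Field(default=0, ge=0)
    seed: int = 0
    min_points: int = 10

    @model_validator(mode="after")
    def _check(self) -> "FitConfig":
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy D_min < D_max")
        if not self.free:
            raise ValueError("at least one parameter must be free")
        for name in self.free:
            if name not in _PARAM_ORDER:
                raise ValueError(f"unknown parameter {name!r}")
        if self.weighting not in ("uniform", "inverse-variance"):
            raise ValueError("weighting must be 'uniform' or 'inverse-variance'")
        return self


@dataclass
class FitResult:
    """Estimated parameters with 1-sigma uncertainties and diagnostics."""

    params: DlvoParams
    offset: float
    uncertainties: dict[str, float]
    residual_rms: float  # J/m^2
    window: tuple[float, float]
    n_points: int
    converged: bool
    cost: float = 0.0
    meta: dict = field(default_factory=dict)


@dataclass
class FeatureReport:
    """Mechanical features of one approach/retraction cycle (SI units)."""

    jump_in: float | None = None  # m, approach instability position
    jump_out_release: float | None = None  # m, separation after pull-off
    step_heights: list[float] = field(default_factory=list)  # m
    hard_wall: float | None = None  # m, smallest recorded separation
    adhesion_energy: float | None = None  # J/m^2, <= 0


# ---------------------------------------------------------------------------
# parameter transforms: unconstrained internal coords <-> natural values
# ---------------------------------------------------------------------------

_P_EDGE = 1e-3  # estimates within this of 0/1 are reported at the boundary


def _to_internal(name: str, value: float) -> float:
    if name in ("psi_eff", "kappa", "hamaker"):
        return math.log(max(value, 1e-300))
    if name == "p":
        return math.asin(min(1.0, max(-1.0, 2.0 * value - 1.0)))
    return value  # offset


def _from_internal(name: str, u: float) -> float:
    if name in ("psi_eff", "kappa", "hamaker"):
        return math.exp(u)
    if name == "p":
        return 0.5 * (1.0 + math.sin(u))
    return u


def _jacobian_factor(name: str, u: float) -> float:
    """d(natural)/d(internal) at the solution, for covariance transport."""
    if name in ("psi_eff", "kappa", "hamaker"):
        return math.exp(u)
    if name == "p":
        return 0.5 * math.cos(u)
    return 1.0


def _initial_guess(d: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Crude (psi_eff, kappa) from the log-linear repulsive tail."""
    mask = w > 0
    if mask.sum() >= 4:
        dd, lw = d[mask], np.log(w[mask])
        outer = dd >= np.median(dd)
        if outer.sum() >= 3:
            slope, intercept = np.polyfit(dd[outer], lw[outer], 1)
            if slope < 0:
                kappa = -slope
                from .constants import VACUUM_PERMITTIVITY, WATER_RELATIVE_PERMITTIVITY

                pref = math.exp(intercept)
                psi2 = pref / (
                    2.0 * VACUUM_PERMITTIVITY * WATER_RELATIVE_PERMITTIVITY * kappa
                )
                if psi2 > 0:
                    return math.sqrt(psi2), kappa
    span = float(d.max() - d.min())
    return 0.05, 4.0 / max(span, 1e-9)


def fit_dlvo(
    curve: ForceCurve,
    spec: electrolyte.SolutionSpec | float,
    config: FitConfig,
) -> FitResult:
    """Fit the charge-regulated DLVO model to a windowed force curve.

    ``spec`` supplies the electrolyte relative permittivity entering the
    double-layer prefactor (a plain float is accepted for synthetic work).
    Uncertainties are 1-sigma from the Jacobian covariance, or from a
    seeded residual bootstrap when ``config.bootstrap_replicates > 0``.
    The window must exclude the post-jump contact region.
    """
    eps_e = (
        electrolyte.relative_permittivity(spec)
        if isinstance(spec, electrolyte.SolutionSpec)
        else float(spec)
    )
    lo, hi = config.window
    mask = (curve.separation >= lo) & (curve.separation <= hi)
    d = curve.separation[mask]
    y = curve.signal[mask]
    if d.size < config.min_points:
        raise ValueError(
            f"window [{lo * 1e9:.2f}, {hi * 1e9:.2f}] nm holds {d.size} points; "
            f"need >= {config.min_points}"
        )

    if config.weighting == "inverse-variance":
        sigma = config.noise_sigma or (
            curve.instrument.noise_sigma if curve.instrument else None
        )
        if not sigma:
            raise ValueError("inverse-variance weighting needs a noise sigma")
        weights = np.full_like(y, 1.0 / sigma)
    else:
        weights = np.ones_like(y)

    defaults = {"hamaker": DEFAULT_HAMAKER, "offset": 0.0}
    defaults.update(config.fixed)
    psi0_guess, kappa0_guess = _initial_guess(d, y)
    start_natural = {
        "psi_eff": defaults.get("psi_eff", psi0_guess),
        "kappa": defaults.get("kappa", kappa0_guess),
        "p": 0.5,
        "hamaker": defaults["hamaker"],
        "offset": defaults["offset"],
    }
    free = [n for n in _PARAM_ORDER if n in config.free]

    def unpack(u: np.ndarray) -> dict[str, float]:
        values = dict(start_natural)
        for name, ui in zip(free, u):
            values[name] = _from_internal(name, ui)
        return values

    def residuals(u: np.ndarray) -> np.ndarray:
        v = unpack(u)
        params = DlvoParams(
            psi_eff=v["psi_eff"], kappa=v["kappa"], p=v["p"], hamaker=v["hamaker"]
        )
        model = total_energy(d + v["offset"], params, eps_e)
        return weights * (model - y)

    best = None
    p_starts = config.p_starts if "p" in free else (start_natural["p"],)
    for p0 in p_starts:
        u0 = np.array(
            [
                _to_internal(name, p0 if name == "p" else start_natural[name])
                for name in free
            ]
        )
        try:
            res = least_squares(
                residuals, u0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=4000,
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.cost < best.cost * (1.0 - 1e-12):
            best = res
        elif (
            abs(res.cost - best.cost) <= 1e-12 * max(best.cost, 1e-300)
            and "p" in free
        ):
            # tie-break: smallest p
            if unpack(res.x)["p"] < unpack(best.x)["p"]:
                best = res
    if best is None:
        raise RuntimeError("all fit starts failed")

    values = unpack(best.x)
    # snap p to the boundary when indistinguishable from it
    if "p" in free:
        if values["p"] < _P_EDGE:
            values["p"] = 0.0
        elif values["p"] > 1.0 - _P_EDGE:
            values["p"] = 1.0

    n, k = d.size, len(free)
    dof = max(n - k, 1)
    s2 = 2.0 * best.cost / dof
    uncertainties: dict[str, float] = {}
    try:
        jtj = best.jac.T @ best.jac
        cov_u = np.linalg.inv(jtj) * s2
        g = np.array([_jacobian_factor(name, ui) for name, ui in zip(free, best.x)])
        var_nat = np.clip(np.diag(cov_u), 0.0, None) * g**2
        uncertainties = {name: float(math.sqrt(v)) for name, v in zip(free, var_nat)}
    except np.linalg.LinAlgError:
        uncertainties = {name: float("nan") for name in free}

    converged = bool(best.status > 0)
    residual_vec = residuals(best.x) / weights
    result = FitResult(
        params=DlvoParams(
            psi_eff=values["psi_eff"],
            kappa=values["kappa"],
            p=values["p"],
            hamaker=values["hamaker"],
        ),
        offset=values["offset"],
        uncertainties=uncertainties,
        residual_rms=float(np.sqrt(np.mean(residual_vec**2))),
        window=(lo, hi),
        n_points=int(n),
        converged=converged,
        cost=float(best.cost),
        meta={"eps_e": eps_e, "free": tuple(free)},
    )
    if config.bootstrap_replicates > 0:
        result.uncertainties = _bootstrap_uncertainties(
            d, y, weights, eps_e, free, best.x, start_natural, config
        )
        result.meta["uncertainty_method"] = "bootstrap"
    else:
        result.meta["uncertainty_method"] = "jacobian"
    return result


def _bootstrap_uncertainties(d, y, weights, eps_e, free, u_hat, start_natural, config):
    """Seeded residual bootstrap: resample residuals, refit from the solution."""
    values = dict(start_natural)
    for name, ui in zip(free, u_hat):
        values[name] = _from_internal(name, ui)
    params = DlvoParams(
        psi_eff=values["psi_eff"], kappa=values["kappa"], p=values["p"],
        hamaker=values["hamaker"],
    )
    fitted = total_energy(d + values["offset"], params, eps_e)
    residual = y - fitted
    rng = np.random.default_rng(config.seed)
    draws: list[list[float]] = []
    for _ in range(config.bootstrap_replicates):
        y_star = fitted + rng.choice(residual, size=residual.size, replace=True)

        def resid_star(u: np.ndarray) -> np.ndarray:
            v = dict(start_natural)
            for name, ui in zip(free, u):
                v[name] = _from_internal(name, ui)
            p_star = DlvoParams(
                psi_eff=v["psi_eff"], kappa=v["kappa"], p=v["p"], hamaker=v["hamaker"]
            )
            return weights * (total_energy(d + v["offset"], p_star, eps_e) - y_star)

        res = least_squares(resid_star, u_hat, method="lm", xtol=1e-12, ftol=1e-12)
        draws.append([_from_internal(n_, u_) for n_, u_ in zip(free, res.x)])
    spread = np.std(np.array(draws), axis=0, ddof=1)
    return {name: float(s) for name, s in zip(free, spread)}


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _drive_step(curve: ForceCurve) -> float:
    if curve.instrument is not None:
        return curve.instrument.sampling_step
    return float(np.median(np.abs(np.diff(curve.separation))))


def detect_jumps(curve: ForceCurve, jump_threshold: float | None = None):
    """Find spring-instability jumps in a recorded curve.

    A jump is a maximal run of consecutive samples whose separation changes
    by more than ``jump_threshold`` (default three drive steps) in the
    direction of motion.  Runs are merged because a soft spring produces a
    square-root "creep" of growing steps just before an instability; the
    reported ``D_before`` is taken at the largest single step of the run
    (the physical discontinuity).  Returns a list of ``(D_before, D_after)``
    pairs; an empty list is a valid result.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 samples to detect jumps")
    if jump_threshold is None:
        jump_threshold = 3.0 * _drive_step(curve)
    d = curve.separation
    delta = np.diff(d)
    sign = -1.0 if curve.direction == "approach" else 1.0
    big = sign * delta > jump_threshold
    jumps: list[tuple[float, float]] = []
    i = 0
    while i < big.size:
        if big[i]:
            j = i
            while j + 1 < big.size and big[j + 1]:
                j += 1
            core = i + int(np.argmax(np.abs(delta[i : j + 1])))
            jumps.append((float(d[core]), float(d[j + 1])))
            i = j + 1
        else:
            i += 1
    return jumps


def step_heights(
    curve: ForceCurve,
    near_contact: float = 5e-9,
    jump_threshold: float | None = None,
) -> list[float]:
    """Squeeze-out step heights from the near-contact jump sequence, metres.

    Each inward jump terminates one hard-wall branch; the separation change
    between the limits of consecutive branches - i.e. between start
    positions of consecutive inward jumps inside the near-contact region -
    is the thickness of the molecular layer expelled.  At least two
    near-contact jumps are required; otherwise (e.g. a plain DLVO jump-in)
    the list is empty.
    """
    jumps = detect_jumps(curve, jump_threshold)
    starts = sorted(
        (before for before, _ in jumps if before <= near_contact), reverse=True
    )
    return [float(a - b) for a, b in zip(starts, starts[1:])]


def adhesion_energy(retraction: ForceCurve, jump_threshold: float | None = None):
    """Pull-off energy: the most negative signal at the jump-out point.

    Looks for the outward spring instability on a retraction curve and
    returns the minimum recorded energy over the last stable samples before
    it (a handful of samples guards against single-point noise).  Returns
    ``None`` - "no adhesion", distinct from 0 - when the retraction shows
    no jump-out.
    """
    if retraction.direction != "retract":
        raise ValueError("adhesion analysis requires a retraction curve")
    jumps = detect_jumps(retraction, jump_threshold)
    if not jumps:
        return None
    d = retraction.separation
    before, _after = max(jumps, key=lambda j: j[1] - j[0])
    idx = int(np.argmin(np.abs(d - before)))
    lo = max(0, idx - 4)
    value = float(np.min(retraction.signal[lo : idx + 1]))
    return min(value, 0.0)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def fit_report(
    results: list[FitResult],
    specs: list[electrolyte.SolutionSpec],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Parameter table: one row per solution, two significant figures.

    Columns carry explicit units; the predicted screening length column is
    left blank for solutions of zero ionic strength (no prediction exists;
    the measured value is then the only estimate).
    """
    if not results:
        raise ValueError("need at least one fit result")
    if len(results) != len(specs):
        raise ValueError("results and specs must align")
    rows = []
    for idx, (fit, spec) in enumerate(zip(results, specs)):
        molal = {s.name: s.molality for s in spec.species}
        try:
            kappa_pred = round_sig(electrolyte.debye_length(spec) * 1e9, 2)
        except electrolyte.ZeroIonicStrengthError:
            kappa_pred = None
        u = fit.uncertainties
        rows.append(
            {
                "label": labels[idx] if labels else f"fit{idx}",
                "c_Pro_molal": molal.get("proline", 0.0),
                "c_KCl_molal": molal.get("K+", 0.0),
                "psi_eff_mV": round_sig(fit.params.psi_eff * 1e3, 2),
                "psi_eff_sd_mV": round_sig(u.get("psi_eff", float("nan")) * 1e3, 2),
                "kappa_inv_nm": round_sig(fit.params.kappa_inv * 1e9, 2),
                "kappa_inv_sd_nm": round_sig(
                    u.get("kappa", float("nan")) / fit.params.kappa**2 * 1e9, 2
                ),
                "p": round_sig(fit.params.p, 2),
                "p_sd": round_sig(u.get("p", float("nan")), 2),
                "kappa_pred_inv_nm": kappa_pred,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
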