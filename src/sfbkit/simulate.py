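"""Quasi-static surface force balance simulator.

A crossed-cylinder lens (radius ``R``) is mounted on a normal spring of
constant ``k_N`` whose base is driven at constant increments.  At each drive
position the recorded separation is a mechanically stable equilibrium of

    k_N (D - x_d) = F(D),        F(D) = 2 pi R W(D),

with stability requiring ``dF/dD < k_N``.  Where a branch loses stability
the surfaces jump to the next stable branch reachable in the drive
direction - inward on approach, outward on retraction.  This single
mechanism produces the jump-in, squeeze-out steps and adhesive jump-out
seen in measured force curves; no discontinuity is ever drawn by hand.

The interaction law is the charge-regulated DLVO energy of
:mod:`sfbkit.dlvo`, optionally augmented with a short-range structural
term: an exponentially decaying oscillation (molecular layering) riding on
a steep power-law hard wall.  Measurement noise is additive Gaussian on the
energy signal; the mechanics themselves are noise-free (quasi-static limit,
no drift or drainage).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .constants import WATER_RELATIVE_PERMITTIVITY
from .dlvo import DlvoParams, total_energy, total_energy_gradient

__all__ = [
    "InstrumentSpec",
    "StructuralForceSpec",
    "GroundTruth",
    "ForceCurve",
    "SimulationError",
    "structural_energy",
    "structural_energy_gradient",
    "energy_model",
    "simulate_quasistatic",
    "synthesize_curve",
    "DatasetConfig",
    "generate_dataset",
]


class SimulationError(RuntimeError):
    """No mechanically stable equilibrium could be found."""


class InstrumentSpec(BaseModel, frozen=True):
    """Mechanical and sampling parameters of the instrument.

    ``sampling_step`` is the drive displacement between recorded samples;
    ``noise_sigma`` is the additive Gaussian noise on the energy signal
    (J/m^2).  Any noisy output requires an explicit ``seed``.
    """

    radius: float = Field(default=0.01, gt=0.0)
    spring_constant: float = Field(default=150.0, gt=0.0)
    sampling_step: float = Field(default=5e-11, gt=0.0)
    noise_sigma: float = Field(default=0.0, ge=0.0)
    seed: int = 0


class StructuralForceSpec(BaseModel, frozen=True):
    """Layered (oscillatory) structural force near contact.

    ``layer_thickness`` is the oscillation period d (the molecular layer
    size), ``amplitude`` the oscillation energy scale at contact,
    ``decay_length`` the envelope decay, ``hard_wall`` the closest-approach
    distance D0 backed by a steep (D0/D)^12 wall of scale ``wall_energy``.
    """

    layer_thickness: float = Field(gt=0.0)
    amplitude: float = Field(ge=0.0)
    decay_length: float = Field(gt=0.0)
    phase_offset: float = 0.0
    hard_wall: float = Field(default=3e-10, gt=0.0)
    wall_energy: float = Field(default=1e-3, gt=0.0)


class GroundTruth(BaseModel, frozen=True):
    """Everything the generator needs: DLVO parameters plus phenomenology.

    ``adhesion_minimum`` (J/m^2, <= 0) overrides the depth of the contact
    minimum: the hard-wall stiffness is calibrated so the composed energy
    profile has exactly that minimum (see :func:`energy_model`).
    """

    dlvo: DlvoParams
    structural: StructuralForceSpec | None = None
    adhesion_minimum: float | None = None
    eps_e: float = WATER_RELATIVE_PERMITTIVITY

    @model_validator(mode="after")
    def _check(self) -> "GroundTruth":
        if self.adhesion_minimum is not None and self.adhesion_minimum > 0:
            raise ValueError("adhesion_minimum must be <= 0")
        return self


@dataclass
class ForceCurve:
    """Ordered (D, W) samples with direction and instrument metadata.

    Approach curves are ordered by decreasing separation, retraction curves
    by increasing separation.  ``signal`` is the parallel-plate interaction
    free energy W in J/m^2 (already Derjaguin-converted).
    """

    separation: np.ndarray  # m
    signal: np.ndarray  # J/m^2
    direction: Literal["approach", "retract"]
    instrument: InstrumentSpec | None = None
    ground_truth_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.separation.shape != self.signal.shape:
            raise ValueError("separation and signal must have the same length")

    def __len__(self) -> int:
        return self.separation.size


# ---------------------------------------------------------------------------
# interaction law
# ---------------------------------------------------------------------------

def structural_energy(d, spec: StructuralForceSpec):
    """Oscillatory layering energy plus hard wall, J/m^2.

    amplitude * exp(-(D-D0)/decay) * cos(2 pi (D-D0-phase)/d_layer)
    + wall_energy * (D0/D)^12.

    The expression is smooth for all D > 0; below D0 the wall term
    dominates, so no non-finite values ever appear.
    """
    d = np.asarray(d, dtype=float)
    x = d - spec.hard_wall
    osc = (
        spec.amplitude
        * np.exp(-x / spec.decay_length)
        * np.cos(2.0 * np.pi * (x - spec.phase_offset) / spec.layer_thickness)
    )
    wall = spec.wall_energy * (spec.hard_wall / d) ** 12
    return osc + wall


def structural_energy_gradient(d, spec: StructuralForceSpec):
    """Analytic dW/dD of :func:`structural_energy`."""
    d = np.asarray(d, dtype=float)
    x = d - spec.hard_wall
    theta = 2.0 * np.pi * (x - spec.phase_offset) / spec.layer_thickness
    envelope = spec.amplitude * np.exp(-x / spec.decay_length)
    osc = envelope * (
        -np.cos(theta) / spec.decay_length
        - (2.0 * np.pi / spec.layer_thickness) * np.sin(theta)
    )
    wall = -12.0 * spec.wall_energy * spec.hard_wall**12 / d**13
    return osc + wall


#: Implicit rigid wall used when no structural term is configured, so a
#: stable contact branch always exists.
_DEFAULT_WALL_POSITION = 2e-10
_DEFAULT_WALL_ENERGY = 1e-3


class EnergyModel:
    """Composed interaction law W(D), dW/dD(D) for one ground truth.

    Exposes vectorized :meth:`energy`/:meth:`gradient` plus fast scalar
    equivalents used by the mechanics inner loop.  The oscillatory part (if
    any) rides on a ``wall_energy * (wall_position/D)^12`` hard wall; when
    no structural term is configured an implicit wall still backs the
    profile so a stable contact branch always exists.
    """

    def __init__(self, truth: GroundTruth, wall_position: float, wall_energy: float):
        self.truth = truth
        self.wall_position = wall_position
        self.wall_energy = wall_energy

    def _osc(self, d: np.ndarray) -> np.ndarray:
        s = self.truth.structural
        x = d - self.wall_position
        theta = 2.0 * np.pi * (x - s.phase_offset) / s.layer_thickness
        return s.amplitude * np.exp(-x / s.decay_length) * np.cos(theta)

    def _osc_gradient(self, d: np.ndarray) -> np.ndarray:
        s = self.truth.structural
        x = d - self.wall_position
        theta = 2.0 * np.pi * (x - s.phase_offset) / s.layer_thickness
        envelope = s.amplitude * np.exp(-x / s.decay_length)
        return envelope * (
            -np.cos(theta) / s.decay_length
            - (2.0 * np.pi / s.layer_thickness) * np.sin(theta)
        )

    def energy(self, d):
        d = np.asarray(d, dtype=float)
        w = total_energy(d, self.truth.dlvo, self.truth.eps_e)
        if self.truth.structural is not None and self.truth.structural.amplitude > 0:
            w = w + self._osc(d)
        return w + self.wall_energy * (self.wall_position / d) ** 12

    def gradient(self, d):
        d = np.asarray(d, dtype=float)
        g = total_energy_gradient(d, self.truth.dlvo, self.truth.eps_e)
        if self.truth.structural is not None and self.truth.structural.amplitude > 0:
            g = g + self._osc_gradient(d)
        return g - 12.0 * self.wall_energy * self.wall_position**12 / d**13

    def scalar_callables(self):
        """Return (w, dw) plain-float callables with all coefficients bound.

        Roughly two orders of magnitude faster than the numpy path for the
        one-point evaluations dominating the Newton polish of equilibria.
        """
        from .constants import VACUUM_PERMITTIVITY

        dl = self.truth.dlvo
        a_ham = dl.hamaker
        kap = dl.kappa
        b = 1.0 - 2.0 * dl.p
        pref = 2.0 * VACUUM_PERMITTIVITY * self.truth.eps_e * kap * dl.psi_eff**2
        s = self.truth.structural
        has_osc = s is not None and s.amplitude > 0
        if has_osc:
            amp, lam, per, phase = s.amplitude, s.decay_length, s.layer_thickness, s.phase_offset
        d0, we = self.wall_position, self.wall_energy
        twelfth = we * d0**12
        twopi = 2.0 * math.pi

        def w(d: float) -> float:
            e = math.exp(-kap * d)
            den = 1.0 + b * e
            val = -a_ham / (12.0 * math.pi * d * d) + pref * e / den
            if has_osc:
                x = d - d0
                val += amp * math.exp(-x / lam) * math.cos(twopi * (x - phase) / per)
            return val + twelfth / d**12

        def dw(d: float) -> float:
            e = math.exp(-kap * d)
            den = 1.0 + b * e
            val = a_ham / (6.0 * math.pi * d**3) - kap * pref * e / (den * den)
            if has_osc:
                x = d - d0
                env = amp * math.exp(-x / lam)
                theta = twopi * (x - phase) / per
                val += env * (-math.cos(theta) / lam - (twopi / per) * math.sin(theta))
            return val - 12.0 * twelfth / d**13

        return w, dw

    @property
    def floor(self) -> float:
        """Innermost separation the solver ever evaluates."""
        return 0.4 * self.wall_position


def energy_model(truth: GroundTruth) -> EnergyModel:
    """Build the composed interaction law, calibrating the wall if needed.

    When ``truth.adhesion_minimum`` is set, the hard-wall energy scale is
    adjusted by a 1-D root find so that the minimum of the composed profile
    equals the requested pull-off energy exactly.
    """
    if truth.structural is not None:
        d0 = truth.structural.hard_wall
        w0 = truth.structural.wall_energy
    else:
        d0 = _DEFAULT_WALL_POSITION
        w0 = _DEFAULT_WALL_ENERGY
    model = EnergyModel(truth=truth, wall_position=d0, wall_energy=w0)
    if truth.adhesion_minimum is None:
        return model

    target = truth.adhesion_minimum
    scan = np.geomspace(model.floor * 1.05, max(1e-8, 10 * d0), 4000)

    def depth_error(log10_w: float) -> float:
        model.wall_energy = 10.0**log10_w
        return float(np.min(model.energy(scan))) - target

    lo, hi = -9.0, 3.0
    if depth_error(lo) > 0 or depth_error(hi) < 0:
        raise SimulationError(
            f"cannot calibrate wall for adhesion minimum {target:g} J/m^2"
        )
    model.wall_energy = 10.0 ** brentq(depth_error, lo, hi, xtol=1e-12)
    return model


# ---------------------------------------------------------------------------
# quasi-static mechanics
# ---------------------------------------------------------------------------

def _run_drive(
    model: EnergyModel,
    instrument: InstrumentSpec,
    x_start: float,
    d_init: float,
    mode: Literal["approach", "retract"],
    stop_load: float,
    d_release: float,
    grid: np.ndarray,
    base: np.ndarray,
    max_samples: int = 400_000,
):
    """March the drive and track the stable equilibrium branch.

    Per sample the equilibrium is polished by a damped Newton iteration from
    the previous state (the common, on-branch case); whenever that fails,
    lands on an unstable root, or moves suspiciously far, the equilibrium is
    re-bracketed globally on ``grid`` (``base`` holds the precomputed
    ``k_N * grid - F(grid)``) and the nearest stable branch in the drive
    direction is selected - this is where jumps happen.

    Returns (separations, drive_end, d_end).
    """
    k_n = instrument.spring_constant
    two_pi_r = 2.0 * np.pi * instrument.radius
    step = instrument.sampling_step if mode == "retract" else -instrument.sampling_step
    w_s, dw_s = model.scalar_callables()
    d_floor, d_ceil = float(grid[0]), float(grid[-1])

    def balance(d: float, xd: float) -> float:
        return k_n * (d - xd) - two_pi_r * w_s(d)

    def balance_slope(d: float) -> float:
        return k_n - two_pi_r * dw_s(d)

    def newton(d: float, xd: float) -> float | None:
        for _ in range(40):
            h = balance(d, xd)
            hp = balance_slope(d)
            if hp <= 0:
                return None
            d_new = d - h / hp
            if d_new <= d_floor or d_new >= d_ceil:
                return None
            if abs(d_new - d) < 1e-15:
                return d_new if balance_slope(d_new) > 0 else None
            d = d_new
        return None

    def global_pick(xd: float, d_prev: float) -> float:
        hg = base - k_n * xd
        neg = hg < 0.0
        up = np.nonzero(neg[:-1] & ~neg[1:])[0]  # upward zero crossings = stable
        if up.size == 0:
            raise SimulationError(
                f"no stable equilibrium at drive position {xd * 1e9:.2f} nm"
            )
        if mode == "approach":
            ok = up[grid[up] <= d_prev + spacing_tol]
            if ok.size == 0:
                raise SimulationError(
                    f"no stable branch inward of the current state; drive {xd * 1e9:.2f} nm"
                )
            i = int(ok[-1])
        else:
            ok = up[grid[up + 1] >= d_prev - spacing_tol]
            if ok.size == 0:
                raise SimulationError(
                    f"no stable branch outward of the current state; drive {xd * 1e9:.2f} nm"
                )
            i = int(ok[0])
        return brentq(balance, grid[i], grid[i + 1], args=(xd,), xtol=1e-14, rtol=1e-15)

    spacing_tol = 0.25 * instrument.sampling_step
    trust = 5.0 * instrument.sampling_step

    # settle onto the equilibrium branch nearest the requested start state
    hg0 = base - k_n * x_start
    neg0 = hg0 < 0.0
    up0 = np.nonzero(neg0[:-1] & ~neg0[1:])[0]
    if up0.size == 0:
        raise SimulationError("no stable equilibrium at the starting drive position")
    i0 = int(up0[np.argmin(np.abs(grid[up0] - d_init))])
    d_prev = brentq(balance, grid[i0], grid[i0 + 1], args=(x_start,), xtol=1e-14, rtol=1e-15)

    xd = x_start
    out: list[float] = []
    for _ in range(max_samples):
        xd += step
        d_eq = newton(d_prev, xd)
        wrong_way = d_eq is not None and (
            (mode == "approach" and d_eq > d_prev + spacing_tol)
            or (mode == "retract" and d_eq < d_prev - spacing_tol)
        )
        if d_eq is None or wrong_way or abs(d_eq - d_prev) > trust:
            d_eq = global_pick(xd, d_prev)
        out.append(d_eq)
        d_prev = d_eq
        if mode == "approach" and w_s(d_eq) >= stop_load:
            break
        if mode == "retract" and d_eq >= d_release:
            break
    else:
        raise SimulationError("drive exceeded the sample budget without terminating")
    return np.array(out), xd, d_prev


def _default_d_start(truth: GroundTruth) -> float:
    return max(3e-8, 5.0 / truth.dlvo.kappa)


def simulate_quasistatic(
    truth: GroundTruth,
    instrument: InstrumentSpec,
    direction: Literal["approach", "retract", "both"] = "approach",
    d_start: float | None = None,
    stop_load: float | None = None,
    ground_truth_id: str | None = None,
):
    """Simulate one approach and/or retraction force curve.

    The drive starts with the surfaces at ``d_start`` (default five
    screening lengths, at least 30 nm) and advances in steps of the
    instrument ``sampling_step``; the approach terminates once the recorded
    energy reaches ``stop_load`` (default: 1.2x the largest energy scale of
    the interaction, i.e. firmly on the hard wall), and retraction once the
    surfaces have released to 85 % of the start separation.

    Returns a single :class:`ForceCurve`, or an (approach, retract) tuple
    for ``direction="both"``.
    """
    model = energy_model(truth)
    if d_start is None:
        d_start = _default_d_start(truth)
    if instrument.radius / d_start < 1e3:
        raise ValueError("Derjaguin validity requires R/D > 1000 over the whole curve")
    if stop_load is None:
        scales = [5e-4]
        if truth.structural is not None:
            scales.append(truth.structural.amplitude)
        if truth.adhesion_minimum is not None:
            scales.append(abs(truth.adhesion_minimum))
        stop_load = 1.2 * max(scales)

    # dense bracketing grid; extend outward to cover spring extension at pull-off
    scan = np.geomspace(model.floor, max(1e-8, 4 * model.wall_position), 2000)
    w_min = float(np.min(model.energy(scan)))
    pulloff_extension = 2.0 * np.pi * instrument.radius * abs(min(w_min, 0.0)) / (
        instrument.spring_constant
    )
    load_extension = 2.0 * np.pi * instrument.radius * stop_load / instrument.spring_constant
    grid_max = 1.1 * d_start + pulloff_extension + load_extension + 2e-8
    grid = np.geomspace(model.floor, grid_max, 9000)
    base = instrument.spring_constant * grid - 2.0 * np.pi * instrument.radius * model.energy(
        grid
    )

    x0 = d_start  # far from contact the spring is undeflected, D ~ x_d
    d_app, xd_end, d_end = _run_drive(
        model, instrument, x0, d_start, "approach", stop_load, 0.0, grid, base
    )
    rng = np.random.default_rng(instrument.seed)

    def finish(seps: np.ndarray, direction_label: str) -> ForceCurve:
        signal = model.energy(seps)
        if instrument.noise_sigma > 0:
            signal = signal + rng.normal(0.0, instrument.noise_sigma, size=seps.size)
        return ForceCurve(
            separation=seps,
            signal=signal,
            direction=direction_label,
            instrument=instrument,
            ground_truth_id=ground_truth_id,
            meta={"d_start": d_start, "stop_load": stop_load},
        )

    approach_curve = finish(d_app, "approach")
    if direction == "approach":
        return approach_curve
    d_ret, _, _ = _run_drive(
        model,
        instrument,
        xd_end,
        d_end,
        "retract",
        stop_load,
        0.85 * d_start,
        grid,
        base,
    )
    retract_curve = finish(d_ret, "retract")
    if direction == "retract":
        return retract_curve
    return approach_curve, retract_curve


def synthesize_curve(
    truth: GroundTruth,
    separations,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ground_truth_id: str | None = None,
) -> ForceCurve:
    """Sample the interaction law directly on a separation grid.

    The idealized (infinitely stiff) counterpart of
    :func:`simulate_quasistatic`: no spring mechanics, no jumps - just
    W(D) plus seeded Gaussian noise.  Used for estimator-calibration
    experiments where the separation axis is taken as known.
    """
    d = np.sort(np.asarray(separations, dtype=float))[::-1]  # approach ordering
    w = total_energy(d, truth.dlvo, truth.eps_e)
    if truth.structural is not None:
        w = w + structural_energy(d, truth.structural)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sigma, size=d.size)
    instrument = InstrumentSpec(noise_sigma=noise_sigma, seed=seed)
    return ForceCurve(
        separation=d,
        signal=w,
        direction="approach",
        instrument=instrument,
        ground_truth_id=ground_truth_id,
        meta={"synthesis": "ideal-grid"},
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

class DatasetConfig(BaseModel):
    """Recipe for a reproducible synthetic dataset.

    ``mode="mechanics"`` runs the quasi-static simulator; ``mode="ideal"``
    samples the interaction law on ``grid_nm`` directly.  Replicate ``i`` of
    every truth uses seed ``base_seed + i``: determinism is part of the
    contract.
    """

    truths: dict[str, GroundTruth]
    instrument: InstrumentSpec = InstrumentSpec()
    replicates: int = Field(default=1, ge=1)
    base_seed: int = 0
    noise_sigma: float = Field(default=0.0, ge=0.0)
    mode: Literal["mechanics", "ideal"] = "mechanics"
    directions: tuple[str, ...] = ("approach",)
    d_start_nm: float | None = None
    grid_nm: tuple[float, float, int] = (1.5, 25.0, 300)


def generate_dataset(config: DatasetConfig, out_dir: str | Path) -> dict:
    """Write one curve file per truth/replicate/direction plus a manifest.

    The manifest records every ground-truth parameter and seed so recovery
    experiments can be scored later.  Identical configs produce
    byte-identical outputs.
    """
    from . import io as curve_io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "files": [],
    }
    seen: set[str] = set()
    for truth_id, truth in config.truths.items():
        for rep in range(config.replicates):
            seed = config.base_seed + rep
            instrument = config.instrument.model_copy(
                update={"seed": seed, "noise_sigma": config.noise_sigma}
            )
            if config.mode == "ideal":
                lo, hi, n = config.grid_nm
                curve = synthesize_curve(
                    truth,
                    np.linspace(lo, hi, n) * 1e-9,
                    noise_sigma=config.noise_sigma,
                    seed=seed,
                    ground_truth_id=truth_id,
                )
                curves = [curve]
            else:
                d_start = None if config.d_start_nm is None else config.d_start_nm * 1e-9
                result = simulate_quasistatic(
                    truth,
                    instrument,
                    direction="both" if set(config.directions) == {"approach", "retract"}
                    else config.directions[0],
                    d_start=d_start,
                    ground_truth_id=truth_id,
                )
                curves = list(result) if isinstance(result, tuple) else [result]
            for curve in curves:
                name = f"{truth_id}_rep{rep:03d}_{curve.direction}.csv"
                if name in seen:
                    raise ValueError(f"duplicate output path {name}")
                seen.add(name)
                curve_io.write_curve(curve, out / name)
                manifest["files"].append(
                    {"path": name, "truth": truth_id, "seed": seed,
                     "direction": curve.direction}
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
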