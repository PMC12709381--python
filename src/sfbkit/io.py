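"""Force-curve file format: '#'-headed CSV, human-auditable.

Layout::

    # sfb-curve v1
    # direction: approach
    # signal_kind: W_mJ_per_m2
    # radius_m: 0.01
    # spring_constant_N_per_m: 150
    # sampling_step_m: 5e-11
    # noise_sigma_J_per_m2: 0
    # seed: 1
    # solution_id: pro-0.07m
    separation_nm,signal
    1.500000000e+00,4.23e-01
    ...

Separations are stored in nanometres at the file interface (SI metres
internally); the signal column is either the plate interaction energy W in
mJ/m^2 or the normalized force F/R in mN/m, declared by ``signal_kind``.
F/R files are converted to W on read through the Derjaguin relation
``W = (F/R) / 2 pi`` and the conversion is recorded in the curve metadata.
Values round-trip losslessly at nine significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .simulate import ForceCurve, InstrumentSpec

__all__ = ["read_curve", "write_curve", "CurveFormatError"]

_MAGIC = "# sfb-curve v1"
_SIGNAL_KINDS = ("W_mJ_per_m2", "F_over_R_mN_per_m")


class CurveFormatError(ValueError):
    """Malformed curve file; the message names the offending line."""


def write_curve(curve: ForceCurve, path: str | Path, signal_kind: str = "W_mJ_per_m2") -> None:
    """Write a force curve; all numbers at nine significant digits."""
    if signal_kind not in _SIGNAL_KINDS:
        raise ValueError(f"unknown signal kind {signal_kind!r}")
    inst = curve.instrument or InstrumentSpec()
    if signal_kind == "W_mJ_per_m2":
        signal = curve.signal * 1e3
    else:
        signal = curve.signal * 2.0 * np.pi * 1e3  # W [J/m^2] -> F/R [mN/m]
    lines = [
        _MAGIC,
        f"# direction: {curve.direction}",
        f"# signal_kind: {signal_kind}",
        f"# radius_m: {inst.radius:.9g}",
        f"# spring_constant_N_per_m: {inst.spring_constant:.9g}",
        f"# sampling_step_m: {inst.sampling_step:.9g}",
        f"# noise_sigma_J_per_m2: {inst.noise_sigma:.9g}",
        f"# seed: {inst.seed}",
    ]
    if curve.ground_truth_id:
        lines.append(f"# solution_id: {curve.ground_truth_id}")
    lines.append("separation_nm,signal")
    for d, s in zip(curve.separation, signal):
        lines.append(f"{d * 1e9:.9g},{s:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path, convert_to_energy: bool = True) -> ForceCurve:
    """Read a curve file, validating units, monotonicity and column counts."""
    text = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    data_start = None
    for lineno, line in enumerate(text, start=1):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
        elif line.strip():
            data_start = lineno
            break
    if not text or not text[0].startswith(_MAGIC):
        raise CurveFormatError(f"{path}: line 1: missing '{_MAGIC}' magic header")
    if "signal_kind" not in header:
        raise CurveFormatError(f"{path}: missing 'signal_kind' units declaration in header")
    if header["signal_kind"] not in _SIGNAL_KINDS:
        raise CurveFormatError(
            f"{path}: unknown signal_kind {header['signal_kind']!r}"
        )
    if "direction" not in header or header["direction"] not in ("approach", "retract"):
        raise CurveFormatError(f"{path}: missing or invalid 'direction' in header")
    if data_start is None:
        raise CurveFormatError(f"{path}: no data section found")
    columns = text[data_start - 1].split(",")
    if [c.strip() for c in columns] != ["separation_nm", "signal"]:
        raise CurveFormatError(
            f"{path}: line {data_start}: expected 'separation_nm,signal' column header"
        )
    seps: list[float] = []
    sigs: list[float] = []
    for lineno in range(data_start + 1, len(text) + 1):
        line = text[lineno - 1].strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise CurveFormatError(
                f"{path}: line {lineno}: expected 2 comma-separated values, got {len(parts)}"
            )
        try:
            seps.append(float(parts[0]))
            sigs.append(float(parts[1]))
        except ValueError as exc:
            raise CurveFormatError(f"{path}: line {lineno}: {exc}") from None
    separation = np.array(seps) * 1e-9
    signal = np.array(sigs)
    direction = header["direction"]
    delta = np.diff(separation)
    if delta.size and (
        (direction == "approach" and np.any(delta >= 0))
        or (direction == "retract" and np.any(delta <= 0))
    ):
        raise CurveFormatError(
            f"{path}: separations not strictly monotone for direction '{direction}'"
        )
    meta: dict = {"signal_kind": header["signal_kind"]}
    if header["signal_kind"] == "W_mJ_per_m2":
        energy = signal * 1e-3
    elif convert_to_energy:
        energy = signal * 1e-3 / (2.0 * np.pi)  # F/R [mN/m] -> W [J/m^2]
        meta["converted"] = "F_over_R_mN_per_m -> W via Derjaguin W = (F/R)/2pi"
    else:
        energy = signal * 1e-3  # raw F/R in N/m, caller's responsibility
        meta["raw_f_over_r"] = True
    instrument = InstrumentSpec(
        radius=float(header.get("radius_m", 0.01)),
        spring_constant=float(header.get("spring_constant_N_per_m", 150.0)),
        sampling_step=float(header.get("sampling_step_m", 5e-11)),
        noise_sigma=float(header.get("noise_sigma_J_per_m2", 0.0)),
        seed=int(header.get("seed", 0)),
    )
    return ForceCurve(
        separation=separation,
        signal=energy,
        direction=direction,
        instrument=instrument,
        ground_truth_id=header.get("solution_id"),
        meta=meta,
    )
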