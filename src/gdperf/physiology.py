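"""Oxygen-transport physiology for cardiopulmonary bypass.

Pure functions for arterial oxygen content, indexed oxygen delivery
(DO2i), the cardiac index required to meet a DO2i target, the oxygen
extraction ratio, and Fick-principle oxygen consumption.  Every function
accepts scalars or numpy arrays and returns the matching shape.

Units follow perfusion convention throughout:

* haemoglobin (``hb``)            g/dL
* saturations (``sao2``/``svo2``) fractions in [0, 1]
* oxygen tensions (``pao2``)      mmHg
* pump flow (``flow``)            L/min
* body surface area (``bsa``)     m**2
* oxygen content                  mL O2 / dL blood
* DO2i / VO2i                     mL O2 / min / m**2
* cardiac index (CI)              L / min / m**2

Because content is per decilitre while flow is per litre, delivery in
mL/min needs a factor of 10 (dL per L); it is carried explicitly in
:class:`PhysioConstants` rather than folded into the binding constants.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "PhysioConstants",
    "OxygenState",
    "DEFAULT_CONSTANTS",
    "arterial_o2_content",
    "do2i",
    "do2i_from_ci",
    "required_ci",
    "o2_extraction_ratio",
    "vo2i_fick",
]


@dataclass(frozen=True)
class PhysioConstants:
    """Physical constants of blood oxygen carriage.

    Attributes
    ----------
    hb_o2_capacity
        mL of O2 bound per gram of fully saturated haemoglobin
        (Huefner constant), default 1.36.
    dissolved_o2_coeff
        mL of O2 physically dissolved per dL of blood per mmHg of
        oxygen tension, default 0.003.
    dl_per_l
        Unit factor converting content (per dL) times flow (per L)
        into mL/min; always 10 in consistent units.
    """

    hb_o2_capacity: float = 1.36
    dissolved_o2_coeff: float = 0.003
    dl_per_l: float = 10.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


DEFAULT_CONSTANTS = PhysioConstants()

#: physiological plausibility bounds used by input validation
_HB_MAX = 25.0
_BSA_BOUNDS = (0.5, 3.5)


@dataclass(frozen=True)
class OxygenState:
    """One snapshot of the oxygen-transport state of a patient on bypass."""

    hb: float
    sao2: float
    svo2: float
    pao2: float
    flow: float
    bsa: float

    def __post_init__(self) -> None:
        _check("hb", self.hb, 0.0, _HB_MAX, lo_open=True)
        _check("sao2", self.sao2, 0.0, 1.0)
        _check("svo2", self.svo2, 0.0, 1.0)
        if self.svo2 > self.sao2:
            raise ValueError("svo2: venous saturation cannot exceed sao2")
        _check("pao2", self.pao2, 0.0, np.inf)
        _check("flow", self.flow, 0.0, np.inf)
        _check("bsa", self.bsa, *_BSA_BOUNDS, lo_open=True, hi_open=True)


def _check(name, value, lo, hi, *, lo_open=False, hi_open=False):
    """Raise ValueError naming *name* if any element of *value* is outside [lo, hi]."""
    v = np.asarray(value, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError(f"{name}: value is missing (NaN)")
    bad = (v < lo) | (v > hi) | (lo_open & (v == lo)) | (hi_open & (v == hi))
    if np.any(bad):
        offender = v[bad].flat[0] if v.ndim else float(v)
        raise ValueError(
            f"{name}: value {offender!r} outside allowed range "
            f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}"
        )


def _as_result(x, *inputs):
    """Return a python float when every input was scalar, else the array."""
    if all(np.ndim(i) == 0 for i in inputs):
        return float(x)
    return x


def arterial_o2_content(hb, sao2, pao2=0.0, constants: PhysioConstants = DEFAULT_CONSTANTS,
                        *, validate: bool = True):
    """Oxygen content of arterial blood, mL O2 per dL.

    ``content = 1.36 * hb * sao2 + 0.003 * pao2`` with the defaults:
    haemoglobin-bound oxygen plus the physically dissolved fraction.
    """
    if validate:
        _check("hb", hb, 0.0, _HB_MAX)
        _check("sao2", sao2, 0.0, 1.0)
        _check("pao2", pao2, 0.0, np.inf)
    hb = np.asarray(hb, dtype=float)
    out = constants.hb_o2_capacity * hb * np.asarray(sao2, float) \
        + constants.dissolved_o2_coeff * np.asarray(pao2, float)
    return _as_result(out, hb, sao2, pao2)


def do2i(flow, bsa, hb, sao2, pao2=0.0, constants: PhysioConstants = DEFAULT_CONSTANTS,
         *, validate: bool = True):
    """Indexed oxygen delivery, mL O2/min/m**2: ``(flow/bsa) * content * 10``."""
    if validate:
        _check("flow", flow, 0.0, np.inf)
        _check("bsa", bsa, *_BSA_BOUNDS, lo_open=True, hi_open=True)
    ci = np.asarray(flow, float) / np.asarray(bsa, float)
    out = ci * constants.dl_per_l * np.asarray(
        arterial_o2_content(hb, sao2, pao2, constants, validate=validate))
    return _as_result(out, flow, bsa, hb, sao2, pao2)


def do2i_from_ci(ci, hb, sao2, pao2=0.0, constants: PhysioConstants = DEFAULT_CONSTANTS,
                 *, validate: bool = True):
    """DO2i when the flow is already indexed: ``ci * content * 10``."""
    if validate:
        _check("ci", ci, 0.0, np.inf)
    out = np.asarray(ci, float) * constants.dl_per_l * np.asarray(
        arterial_o2_content(hb, sao2, pao2, constants, validate=validate))
    return _as_result(out, ci, hb, sao2, pao2)


def required_ci(do2i_target, hb, sao2=1.0, pao2=0.0,
                constants: PhysioConstants = DEFAULT_CONSTANTS,
                *, validate: bool = True):
    """Minimum cardiac index (L/min/m**2) delivering *do2i_target*.

    Inverts the delivery equation: ``ci = target / (10 * content)``.
    A zero target needs zero flow; a positive target with zero oxygen
    content is unattainable and raises ``ValueError``.
    """
    if validate:
        _check("do2i_target", do2i_target, 0.0, np.inf)
    target = np.asarray(do2i_target, dtype=float)
    content = np.asarray(
        arterial_o2_content(hb, sao2, pao2, constants, validate=validate), float)
    impossible = (content <= 0) & (target > 0)
    if np.any(impossible):
        raise ValueError(
            "do2i_target: positive delivery target with zero arterial "
            "oxygen content is unattainable")
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(target == 0, 0.0, target / (constants.dl_per_l * content))
    return _as_result(ci, do2i_target, hb, sao2, pao2)


def o2_extraction_ratio(sao2, svo2, *, validate: bool = True):
    """Fraction of delivered oxygen consumed: ``(sao2 - svo2) / sao2``."""
    if validate:
        _check("sao2", sao2, 0.0, 1.0, lo_open=True)
        _check("svo2", svo2, 0.0, 1.0)
        if np.any(np.asarray(svo2, float) > np.asarray(sao2, float)):
            raise ValueError("svo2: venous saturation cannot exceed sao2")
    out = (np.asarray(sao2, float) - np.asarray(svo2, float)) / np.asarray(sao2, float)
    return _as_result(out, sao2, svo2)


def vo2i_fick(flow, bsa, hb, sao2, svo2, pao2=0.0, pvo2=0.0,
              constants: PhysioConstants = DEFAULT_CONSTANTS,
              *, validate: bool = True):
    """Indexed oxygen consumption by the Fick principle, mL O2/min/m**2.

    ``(flow/bsa) * 10 * (CaO2 - CvO2)`` where venous content uses the
    same carriage constants with venous saturation and tension.
    """
    if validate:
        _check("flow", flow, 0.0, np.inf)
        _check("bsa", bsa, *_BSA_BOUNDS, lo_open=True, hi_open=True)
        _check("svo2", svo2, 0.0, 1.0)
        _check("pvo2", pvo2, 0.0, np.inf)
    ca = np.asarray(arterial_o2_content(hb, sao2, pao2, constants, validate=validate), float)
    cv = np.asarray(arterial_o2_content(hb, svo2, pvo2, constants, validate=validate), float)
    ci = np.asarray(flow, float) / np.asarray(bsa, float)
    out = ci * constants.dl_per_l * (ca - cv)
    return _as_result(out, flow, bsa, hb, sao2, svo2, pao2, pvo2)
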