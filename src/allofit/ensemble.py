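"""Closed-form state-ensemble calculations for two-state allosteric models.

Three model families of increasing resolution are provided, all for a
homodimeric receptor whose periplasmic sensor binds one divalent cation per
monomer (binding polynomial ``(1 + [L]/Kd)**2``):

* concerted -- the whole protein is a single two-state unit;
* two-domain -- sensor and autokinase each two-state, coupled by ``alpha``;
* three-domain -- sensor, HAMP and autokinase each two-state, with separate
  sensor-HAMP (``alpha1``) and HAMP-autokinase (``alpha2``) couplings.

Statistical weights are defined relative to the reference state in which
every domain is in its "off"/state-1 conformation at zero ligand.  Fractions
are ratios of partial partition sums; a brute-force eight-state enumeration
(:func:`enumerate_states_oracle`) is provided as an independent oracle for
the factored closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import NamedTuple, Sequence, Tuple

import numpy as np

__all__ = [
    "AllostericParameters",
    "ConcertedParameters",
    "TwoDomainParameters",
    "DomainState",
    "DoseResponsePrediction",
    "ALL_STATES",
    "binding_polynomial",
    "state_weight",
    "fractions_three_domain",
    "fractions_two_domain",
    "fraction_concerted",
    "enumerate_states_oracle",
]


def _check_positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not np.isfinite(v) or v <= 0:
            raise ValueError(
                f"{type(obj).__name__}.{f.name} must be strictly positive "
                f"and finite, got {v!r}"
            )


@dataclass(frozen=True)
class AllostericParameters:
    """Constants of the three-domain two-state ensemble for one dataset.

    All equilibrium constants are dimensionless and defined with the fully
    "off" (sensor-off, HAMP-1, autokinase-off) conformation as reference.

    Attributes
    ----------
    k_sen : sensor off->on equilibrium, HAMP in state 1.
    k_hamp : HAMP 1->2 equilibrium, sensor and autokinase off.
    k_ak : autokinase off->on equilibrium, HAMP in state 1.
    alpha1 : coupling factor applied when sensor-on coincides with HAMP-2.
    alpha2 : coupling factor applied when HAMP-2 coincides with autokinase-on.
    s : activity-scale factor (rescaled activity units per unit on-fraction).
    kd_off : ligand dissociation constant of the sensor-off state, molar.
    kd_on : ligand dissociation constant of the sensor-on state, molar.
    """

    k_sen: float
    k_hamp: float
    k_ak: float
    alpha1: float
    alpha2: float
    s: float
    kd_off: float
    kd_on: float

    def __post_init__(self) -> None:
        _check_positive(self)


@dataclass(frozen=True)
class ConcertedParameters:
    """Whole-protein two-state model: one equilibrium, two ligand affinities."""

    k: float
    kd_off: float
    kd_on: float

    def __post_init__(self) -> None:
        _check_positive(self)


@dataclass(frozen=True)
class TwoDomainParameters:
    """Sensor + autokinase two-state model with a single coupling ``alpha``."""

    k_sen: float
    k_ak: float
    alpha: float
    s: float
    kd_off: float
    kd_on: float

    def __post_init__(self) -> None:
        _check_positive(self)


class DomainState(NamedTuple):
    """One of the eight conformations of the three-domain ensemble."""

    sensor_on: bool
    hamp2: bool
    ak_on: bool


#: The eight distinct states of the three-domain model.
ALL_STATES: Tuple[DomainState, ...] = tuple(
    DomainState(bool(s), bool(h), bool(a))
    for s in (0, 1)
    for h in (0, 1)
    for a in (0, 1)
)


@dataclass(frozen=True)
class DoseResponsePrediction:
    """Model output along a ligand grid (concentrations in molar)."""

    mg: np.ndarray
    f_sensor_on: np.ndarray
    f_ak_on: np.ndarray
    activity: np.ndarray  # s * f_ak_on, rescaled-activity units

    def __post_init__(self) -> None:
        n = len(self.mg)
        if not (len(self.f_sensor_on) == len(self.f_ak_on) == len(self.activity) == n):
            raise ValueError("all prediction sequences must share the grid length")


def binding_polynomial(mg, kd):
    """Dimeric ligand-binding factor ``(1 + mg/kd)**2``.

    The square encodes one independent binding site per monomer of the
    homodimer (stoichiometry factor of 2).  ``mg`` may be a scalar or array
    of molar concentrations; ``kd`` must be a positive dissociation constant.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0) or not np.all(np.isfinite(kd)):
        raise ValueError(f"kd must be strictly positive and finite, got {kd!r}")
    mg = np.asarray(mg, dtype=float)
    if np.any(mg < 0):
        raise ValueError("ligand concentration must be non-negative")
    return (1.0 + mg / kd) ** 2


def state_weight(state: DomainState, params: AllostericParameters, mg: float) -> float:
    """Statistical weight of one eight-state conformation at ligand ``mg``.

    The reference state (sensor-off, HAMP-1, autokinase-off) at ``mg = 0``
    has weight 1.  Ligand binding is tied to the sensor conformation only.
    """
    w = 1.0
    if state.sensor_on:
        w *= params.k_sen
    if state.hamp2:
        w *= params.k_hamp
    if state.ak_on:
        w *= params.k_ak
    if state.sensor_on and state.hamp2:
        w *= params.alpha1
    if state.hamp2 and state.ak_on:
        w *= params.alpha2
    kd = params.kd_on if state.sensor_on else params.kd_off
    return w * float(binding_polynomial(mg, kd))


def fractions_three_domain(mg, params: AllostericParameters):
    """On-fractions of sensor and autokinase in the eight-state ensemble.

    Parameters
    ----------
    mg : scalar or array of molar ligand concentrations.
    params : AllostericParameters.

    Returns
    -------
    (f_sensor_on, f_ak_on) with the shape of ``mg``; both in (0, 1).
    """
    p = params
    # Conditional sums over HAMP for each (sensor, autokinase) corner; the
    # binding polynomial factors out per sensor state.
    s_off_aoff = 1.0 + p.k_hamp
    s_off_aon = p.k_ak * (1.0 + p.alpha2 * p.k_hamp)
    s_on_aoff = p.k_sen * (1.0 + p.alpha1 * p.k_hamp)
    s_on_aon = p.k_sen * p.k_ak * (1.0 + p.alpha1 * p.alpha2 * p.k_hamp)
    return _two_branch_fractions(
        mg, p.kd_off, p.kd_on, s_off_aoff, s_off_aon, s_on_aoff, s_on_aon
    )


def fractions_two_domain(mg, params: TwoDomainParameters):
    """On-fractions of sensor and autokinase in the four-state ensemble."""
    p = params
    return _two_branch_fractions(
        mg, p.kd_off, p.kd_on, 1.0, p.k_ak, p.k_sen, p.alpha * p.k_sen * p.k_ak
    )


def _two_branch_fractions(mg, kd_off, kd_on, s_off_aoff, s_off_aon, s_on_aoff, s_on_aon):
    # Shared core: ensembles whose states split by (sensor, autokinase) with
    # the ligand polynomial attached to the sensor state.  Weights are
    # rescaled by their maxima before mixing so intermediates stay bounded
    # even for extreme parameter draws.
    b_off = binding_polynomial(mg, kd_off)
    b_on = binding_polynomial(mg, kd_on)
    b_max = np.maximum(b_off, b_on)
    b_off = b_off / b_max
    b_on = b_on / b_max

    s_max = max(s_off_aoff, s_off_aon, s_on_aoff, s_on_aon)
    s_off_aoff, s_off_aon, s_on_aoff, s_on_aon = (
        s_off_aoff / s_max,
        s_off_aon / s_max,
        s_on_aoff / s_max,
        s_on_aon / s_max,
    )

    on_branch = b_on * (s_on_aoff + s_on_aon)
    off_branch = b_off * (s_off_aoff + s_off_aon)
    total = on_branch + off_branch
    f_sensor = on_branch / total
    f_ak = (b_on * s_on_aon + b_off * s_off_aon) / total
    return f_sensor, f_ak


def fraction_concerted(mg, params: ConcertedParameters):
    """Fraction of the concerted two-state protein in the on state."""
    b_off = binding_polynomial(mg, params.kd_off)
    b_on = binding_polynomial(mg, params.kd_on)
    b_max = np.maximum(b_off, b_on)
    num = (b_on / b_max) * params.k
    return num / (num + b_off / b_max)


def enumerate_states_oracle(mg: float, params: AllostericParameters):
    """Brute-force eight-state enumeration of the three-domain fractions.

    Computes both on-fractions by explicit summation over :data:`ALL_STATES`
    using :func:`state_weight` only, with no algebraic simplification.  Used
    as the independent oracle for :func:`fractions_three_domain`.
    """
    weights = [state_weight(s, params, mg) for s in ALL_STATES]
    total = sum(weights)
    f_sensor = sum(w for s, w in zip(ALL_STATES, weights) if s.sensor_on) / total
    f_ak = sum(w for s, w in zip(ALL_STATES, weights) if s.ak_on) / total
    return f_sensor, f_ak


def predict_three_domain(params: AllostericParameters, mg) -> DoseResponsePrediction:
    """Full dose-response prediction (fractions plus scaled activity)."""
    mg = np.atleast_1d(np.asarray(mg, dtype=float))
    f_sen, f_ak = fractions_three_domain(mg, params)
    return DoseResponsePrediction(mg=mg, f_sensor_on=f_sen, f_ak_on=f_ak,
                                  activity=params.s * f_ak)
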