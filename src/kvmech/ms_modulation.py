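"""Mechanosensitive perturbations of gating schemes and patch mechanics.

Two rival mechanisms are implemented as multiplicative perturbations of a
scheme's equilibrium constants:

* **vMS** -- tension acts on a voltage-dependent closed-closed transition
  near the open state (the concerted C5<->C6 step of scheme 3, the last
  sensor step a/4b of scheme 1, or the TabMor pair C3<->C4 / C4<->C5).
* **LMS** -- tension acts on the thermal closed<->open step, scaling
  L = k_o/k_c itself (and hence the apparent maximal open probability).

A perturbation multiplies the target equilibrium constant by a factor m.
How m splits between forward and backward rates depends on where the
transition state sits along the in-plane area change: with the default
symmetric barrier (a* = 0.5) the forward rate gains sqrt(m) and the
backward rate loses sqrt(m), leaving the product of the two rates
invariant.  Any a* in [0, 1] yields the same equilibria but different
kinetics.

The tension chain maps pipette suction to the factor m:
pressure -> membrane strain (spherical-cap patch geometry) -> tension
(gamma = K_A * eps) -> m = exp(gamma * dA / kT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import (
    DEFAULT_CONSTANTS,
    MMHG_TO_PA,
    MN_PER_M_NM2_TO_J,
    PhysicalConstants,
)
from .scheme_core import SchemeSpec, TransitionSpec

__all__ = [
    "MSModulation",
    "PatchMechanics",
    "apply_modulation",
    "scale_equilibrium_constant",
    "tension_from_factor",
    "strain_from_pressure",
    "v05_vs_pressure",
]


# --------------------------------------------------------------------------
# modulation
# --------------------------------------------------------------------------

_MODES = ("none", "vms_tabmor", "vms_concerted", "vms_last_sensor", "lms", "ilt_vms")


@dataclass(frozen=True)
class MSModulation:
    """A mechanosensitive perturbation of one or two scheme transitions.

    ``factors`` maps a transition kind to the equilibrium factor m applied
    to it.  Recognized keys: ``concerted``, ``thermal``, ``sensor_3``,
    ``sensor_4`` (the C3<->C4 and C4<->C5 steps).  ``barrier_position`` is
    a*: the fraction of the area change reached at the transition state.
    """

    mode: str = "none"
    factors: dict = field(default_factory=dict)
    barrier_position: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown modulation mode {self.mode!r}")
        if not 0.0 <= self.barrier_position <= 1.0:
            raise ValueError("barrier_position must lie in [0, 1]")
        for m in self.factors.values():
            if m < 0:
                raise ValueError("equilibrium factors must be >= 0")

    @classmethod
    def none(cls) -> "MSModulation":
        return cls("none")

    @classmethod
    def lms(cls, m: float, barrier_position: float = 0.5) -> "MSModulation":
        """Scale the thermal equilibrium constant L by ``m``."""
        return cls("lms", {"thermal": m}, barrier_position)

    @classmethod
    def vms_concerted(cls, m: float, barrier_position: float = 0.5) -> "MSModulation":
        """Scale the concerted pre-opening equilibrium f/b by ``m``."""
        return cls("vms_concerted", {"concerted": m}, barrier_position)

    @classmethod
    def vms_last_sensor(cls, m: float, barrier_position: float = 0.5) -> "MSModulation":
        """Scale the last sensor step's equilibrium (a/4b) by ``m``."""
        return cls("vms_last_sensor", {"sensor_4": m}, barrier_position)

    @classmethod
    def vms_tabmor(
        cls,
        ms_34: float = 1.3,
        ms_45: float = 2.0,
        barrier_position: float = 0.5,
    ) -> "MSModulation":
        """TabMor-style stretch factors on the penultimate and ultimate
        voltage-dependent steps (stronger on the later one); the defaults
        produce a ~7 mV left-shift of the Table-1 scheme, the magnitude of
        near-lytic stretch responses."""
        return cls(
            "vms_tabmor", {"sensor_3": ms_34, "sensor_4": ms_45}, barrier_position
        )

    @classmethod
    def ilt_vms(cls, forward_factor: float = 0.75) -> "MSModulation":
        """ILT-type stretch: concerted forward rate x ``forward_factor``,
        backward rate / ``forward_factor`` (equilibrium factor m = factor^2)."""
        return cls("ilt_vms", {"concerted": forward_factor**2}, 0.5)


def _targets(scheme: SchemeSpec, mod: MSModulation) -> dict[str, float]:
    """Resolve factor keys to transition names for this scheme."""
    sensors = scheme.transitions_of_kind("sensor")
    out: dict[str, float] = {}
    for key, m in mod.factors.items():
        if key == "thermal":
            trans = scheme.transitions_of_kind("thermal")
            if not trans:
                raise ValueError(
                    f"LMS modulation requires a thermal opening step; "
                    f"scheme {scheme.name!r} has none"
                )
            out[trans[0].name] = m
        elif key == "concerted":
            trans = scheme.transitions_of_kind("concerted")
            if not trans:
                raise ValueError(
                    f"scheme {scheme.name!r} has no concerted transition"
                )
            out[trans[0].name] = m
        elif key in ("sensor_3", "sensor_4"):
            idx = int(key[-1]) - 1
            out[sensors[idx].name] = m
        else:
            raise ValueError(f"unknown modulation target {key!r}")
    return out


def apply_modulation(scheme: SchemeSpec, mod: MSModulation | None) -> SchemeSpec:
    """Return a scheme with the perturbed rate prefactors.

    For each targeted transition the forward prefactor is multiplied by
    m**a* and the backward by m**(a*-1), so the equilibrium ratio scales by
    exactly m for any barrier position a*.
    """
    if mod is None or mod.mode == "none" or not mod.factors:
        return scheme
    by_name = _targets(scheme, mod)
    a = mod.barrier_position
    new: list[TransitionSpec] = []
    for t in scheme.transitions:
        m = by_name.get(t.name)
        if m is None or m == 1.0:
            new.append(t)
            continue
        if not t.ms_eligible:
            raise ValueError(f"transition {t.name!r} is not MS-eligible")
        new.append(
            TransitionSpec(
                name=t.name,
                source=t.source,
                target=t.target,
                forward=t.forward.scaled(m**a),
                backward=t.backward.scaled(m ** (a - 1.0)),
                charge_per_event=t.charge_per_event,
                kind=t.kind,
                multiplicity=t.multiplicity,
                ms_eligible=t.ms_eligible,
            )
        )
    return scheme.with_transitions(new)


# --------------------------------------------------------------------------
# tension <-> equilibrium factor
# --------------------------------------------------------------------------

def scale_equilibrium_constant(
    base_ratio: float,
    tension: float,
    delta_area: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium constant under membrane tension.

    Tension ``gamma`` (mN/m) acting on an in-plane area change
    ``delta_area`` (nm^2) biases the expanded state by the Boltzmann factor
    exp(gamma*dA/kT), so the ratio becomes base * exp(gamma*dA/kT).
    Negative tension (hyperbaric compression) is allowed.
    """
    if delta_area <= 0:
        raise ValueError("delta_area must be positive")
    energy = tension * delta_area * MN_PER_M_NM2_TO_J
    return base_ratio * math.exp(energy / constants.kt)


def tension_from_factor(
    m: float,
    delta_area: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert the Boltzmann factor: gamma = (kT/dA) ln m, in mN/m."""
    if m <= 0:
        raise ValueError("equilibrium factor must be positive")
    return constants.kt * math.log(m) / (delta_area * MN_PER_M_NM2_TO_J)


# --------------------------------------------------------------------------
# patch mechanics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatchMechanics:
    """Spherical-cap model of a pipette patch under suction.

    The patch membrane spans the pipette mouth (radius ``patch_radius``)
    as a spherical cap; suction increases the cap's curvature, the bilayer
    stretches elastically and tension follows gamma = K_A * eps.  The map
    from suction to strain is calibrated to two anchors: ``strain_at_ref``
    at ``reference_pressure`` and the lytic strain at a full hemisphere.
    Any smooth monotone map through the same anchors gives nearly the same
    midpoint-shift-versus-pressure curves.
    """

    area_stiffness: float = 250.0  # K_A, mN/m
    delta_area: float = 3.0  # conformational area change, nm^2
    patch_radius: float = 0.5  # um
    reference_pressure: float = 80.0  # mmHg
    strain_at_ref: float = 0.014
    lytic_strain: float = 0.04

    def _cos_rest(self) -> float:
        # cap area / rest area - 1 = lytic strain at a full hemisphere
        # (cos theta = 0) fixes the unstressed cap angle.
        return self.lytic_strain

    def _strain_of_cos(self, c: float) -> float:
        return (1.0 + self._cos_rest()) / (1.0 + c) - 1.0

    def _pressure_scale(self) -> float:
        # Laplace-law shape dP ~ eps * sin(theta), scaled to the reference
        # anchor (reference_pressure at strain_at_ref).
        c_ref = (1.0 + self._cos_rest()) / (1.0 + self.strain_at_ref) - 1.0
        s_ref = math.sqrt(1.0 - c_ref**2)
        return self.reference_pressure / (self.strain_at_ref * s_ref)

    def pressure_from_strain(self, strain: float) -> float:
        """Suction dP (mmHg) producing area strain ``strain``."""
        if strain < 0:
            raise ValueError("strain must be >= 0")
        if strain == 0:
            return 0.0
        c = (1.0 + self._cos_rest()) / (1.0 + strain) - 1.0
        if c < 0:
            raise ValueError("strain beyond the full-hemisphere (lytic) limit")
        return self._pressure_scale() * strain * math.sqrt(1.0 - c**2)

    @property
    def lytic_pressure(self) -> float:
        """Suction (mmHg) at which the cap reaches a full hemisphere."""
        return self.pressure_from_strain(self.lytic_strain)


@dataclass(frozen=True)
class StrainResult:
    strain: float
    tension: float  # mN/m
    lysis: bool


def strain_from_pressure(mech: PatchMechanics, pressure: float) -> StrainResult:
    """Membrane area strain and tension at pipette suction ``pressure`` (mmHg).

    Monotone in pressure, 0 at 0 and equal to the calibration strain at the
    reference suction.  Pressures beyond the lytic limit flag ``lysis`` and
    clamp the strain at the lytic value.
    """
    if pressure < 0:
        raise ValueError("suction must be >= 0 mmHg")
    if pressure == 0:
        return StrainResult(0.0, 0.0, False)
    if pressure >= mech.lytic_pressure:
        eps = mech.lytic_strain
        return StrainResult(eps, mech.area_stiffness * eps, True)
    eps = brentq(
        lambda e: mech.pressure_from_strain(e) - pressure,
        0.0,
        mech.lytic_strain,
        xtol=1e-12,
    )
    return StrainResult(eps, mech.area_stiffness * eps, False)


def v05_vs_pressure(
    scheme: SchemeSpec,
    mode: str,
    mech: PatchMechanics,
    pressures,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Midpoint left-shift as a function of pipette suction.

    For each suction: strain -> tension -> equilibrium factor m ->
    modulated scheme -> fitted V0.5; the returned shift is relative to the
    zero-suction curve (positive = left, i.e. hyperpolarizing).

    Returns a pandas DataFrame with columns dP_mmHg, strain,
    tension_mN_per_m, m_factor, V05_shift_mV, lysis.
    """
    import pandas as pd

    from .equilibrium_analysis import gv_curve, measure_shift

    if mode not in ("vms_concerted", "lms"):
        raise ValueError("mode must be 'vms_concerted' or 'lms'")
    make = (
        MSModulation.vms_concerted if mode == "vms_concerted" else MSModulation.lms
    )
    ref = gv_curve(scheme)
    rows = []
    for dp in np.asarray(pressures, dtype=float):
        res = strain_from_pressure(mech, dp)
        m = scale_equilibrium_constant(1.0, res.tension, mech.delta_area, constants)
        shift = 0.0 if m == 1.0 else measure_shift(ref, gv_curve(scheme, make(m)))
        rows.append(
            {
                "dP_mmHg": dp,
                "strain": res.strain,
                "tension_mN_per_m": res.tension,
                "m_factor": m,
                "V05_shift_mV": shift,
                "lysis": res.lysis,
            }
        )
    return pd.DataFrame(rows)
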