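"""Conductance-voltage curves, Boltzmann fits and shift measurements.

g(V) is proportional to the equilibrium open probability Popen(V); curves
are summarized by a single-Boltzmann fit max / (1 + exp(-(V - V0.5)/s)).
Mechanosensitive shifts are reported under one of two conventions:

* ``normalized_boltzmann`` (default): each curve is normalized to its own
  fitted maximum and the shift is the difference of fitted midpoints.
* ``fixed_criterion``: the shift is the voltage displacement at the
  reference curve's absolute half-maximum Popen level.

The two conventions agree for pure midpoint shifts and differ by a couple
of millivolts when the perturbation also changes the apparent maximum
(LMS-type modulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .scheme_core import SchemeSpec, stationary_distribution

__all__ = [
    "GVCurve",
    "BoltzmannFit",
    "gv_curve",
    "boltzmann_fit",
    "measure_shift",
    "apparent_gmax",
    "DEFAULT_GRID",
]

#: 1 mV spacing for fitting; covers the dynamic range of every packaged scheme
DEFAULT_GRID = np.arange(-150.0, 150.0 + 0.5, 1.0)


@dataclass(frozen=True)
class BoltzmannFit:
    v05: float  # mV
    slope: float  # mV
    max: float
    residual: float


@dataclass
class GVCurve:
    """Equilibrium (or protocol-derived) open-probability curve."""

    voltage: np.ndarray
    popen: np.ndarray
    provenance: str = "equilibrium"
    _fit: BoltzmannFit | None = field(default=None, repr=False)

    @property
    def fit(self) -> BoltzmannFit:
        if self._fit is None:
            self._fit = boltzmann_fit(self)
        return self._fit

    def normalized(self) -> np.ndarray:
        return self.popen / self.fit.max


def gv_curve(
    scheme: SchemeSpec,
    mod=None,
    voltages: np.ndarray | None = None,
) -> GVCurve:
    """Stationary Popen(V) of ``scheme`` under optional modulation."""
    if voltages is None:
        voltages = DEFAULT_GRID
    voltages = np.asarray(voltages, dtype=float)
    popen = np.array(
        [
            stationary_distribution(scheme, v, mod)[scheme.open_index]
            for v in voltages
        ]
    )
    return GVCurve(voltage=voltages, popen=popen)


def _boltzmann(v, v05, slope, pmax):
    return pmax / (1.0 + np.exp(-(v - v05) / slope))


def boltzmann_fit(curve: GVCurve) -> BoltzmannFit:
    """Least-squares single-Boltzmann summary of a monotone g(V) curve.

    Initialized from the curve's empirical half-maximum crossing.
    """
    v, p = curve.voltage, curve.popen
    pmax0 = float(p.max())
    if pmax0 <= 0:
        raise ValueError("curve has no conductance to fit")
    half = pmax0 / 2.0
    idx = int(np.argmax(p >= half))
    v05_0 = float(v[idx])
    try:
        popt, _ = curve_fit(
            _boltzmann,
            v,
            p,
            p0=[v05_0, 10.0, pmax0],
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"Boltzmann fit failed to converge (init V0.5={v05_0}, "
            f"max={pmax0}): {exc}"
        ) from exc
    resid = float(np.linalg.norm(p - _boltzmann(v, *popt)))
    if popt[1] <= 0:
        raise RuntimeError("Boltzmann fit produced a non-positive slope")
    return BoltzmannFit(v05=float(popt[0]), slope=float(popt[1]), max=float(popt[2]),
                        residual=resid)


def measure_shift(
    ref: GVCurve,
    test: GVCurve,
    convention: str = "normalized_boltzmann",
) -> float:
    """Voltage shift of ``test`` relative to ``ref`` in mV (positive = left).

    ``normalized_boltzmann``: difference of fitted midpoints after each
    curve is normalized to its own fitted maximum (normalization does not
    move the midpoint of a Boltzmann, so this is V05_ref - V05_test).
    ``fixed_criterion``: voltage displacement measured at the reference
    curve's absolute half-max Popen level.
    """
    if convention == "normalized_boltzmann":
        return ref.fit.v05 - test.fit.v05
    if convention != "fixed_criterion":
        raise ValueError(f"unknown shift convention {convention!r}")
    level = ref.fit.max / 2.0
    out = []
    for curve in (ref, test):
        v, p = curve.voltage, curve.popen
        if level <= p.min() or level >= p.max():
            raise ValueError(
                "criterion level outside the curve's range; shift unmeasurable"
            )
        fit = curve.fit
        out.append(
            brentq(
                lambda x: _boltzmann(x, fit.v05, fit.slope, fit.max) - level,
                v.min(),
                v.max(),
            )
        )
    return out[0] - out[1]


def apparent_gmax(scheme: SchemeSpec, mod=None) -> float:
    """Maximal equilibrium open probability L_eff/(1 + L_eff).

    The saturating value of Popen(V) is set entirely by the (possibly
    modulated) thermal equilibrium constant.
    """
    from .ms_modulation import apply_modulation

    if mod is not None:
        scheme = apply_modulation(scheme, mod)
    L = scheme.thermal_equilibrium_constant
    return L / (1.0 + L)
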