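"""Linear-chain Markov gating schemes for Shaker-type Kv channels.

A scheme is an ordered chain of closed states ending in the open state,
optionally with a slow-inactivated state attached off the chain.  Three
canonical schemes are packaged:

* ``scheme1`` -- 6 states (C1..C5, O): four independent voltage-sensor steps
  with statistical multiplicities 4a/b .. a/4b, then a voltage-independent
  ("thermal") opening step with equilibrium constant L = k_o/k_c.
* ``scheme2`` -- scheme 1 plus a slow-inactivated state I reached from O by
  voltage-independent rates (entry ~0.05/s, recovery ~0.005/s, i.e. recovery
  takes minutes).
* ``scheme3`` -- 7 states (C1..C6, O): the four sensor steps, a concerted
  voltage-dependent pre-opening C5<->C6 carrying ~13% of the gating charge,
  then the thermal opening C6<->O.

Stationary occupancies are obtained from the detailed-balance product along
the chain, evaluated in log space; a null-space solve of the generator is
provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.special import logsumexp

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "RateLaw",
    "TransitionSpec",
    "SchemeSpec",
    "QVCurve",
    "evaluate_rate",
    "build_generator",
    "stationary_distribution",
    "stationary_distribution_nullspace",
    "popen_closed_form",
    "qv_curve",
    "sensor_midpoint",
    "load_parameter_set",
    "get_scheme",
    "PARAMETER_SET_NAMES",
]


# --------------------------------------------------------------------------
# rate laws
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateLaw:
    """A voltage-dependent (or voltage-independent) first-order rate.

    Forms
    -----
    ``exponential``
        prefactor * exp(sign * charge * V / (RT/F)); ``charge`` is the
        effective gating charge in elementary charges, ``sign`` +1 for
        forward (depolarization-favored) and -1 for backward rates.
        With charge = 0 this is a voltage-independent (thermal) rate.
    ``hh_linexp``
        prefactor * (V - offset) / (1 - exp(-(V - offset)/slope)), the
        classic Hodgkin-Huxley alpha_n form; finite at its removable
        singularity V = offset, where it equals prefactor * slope.
    ``hh_exp``
        prefactor * exp(-(V - offset)/slope), the HH beta_n form.
    """

    form: str = "exponential"
    prefactor: float = 0.0
    charge: float = 0.0
    sign: int = +1
    offset: float = 0.0  # mV, hh forms only
    slope: float = 0.0  # mV, hh forms only

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "hh_linexp", "hh_exp"):
            raise ValueError(f"unknown rate-law form {self.form!r}")
        if self.prefactor < 0:
            raise ValueError("rate prefactor must be non-negative")
        if self.form in ("hh_linexp", "hh_exp") and self.slope <= 0:
            raise ValueError("hh rate laws require a positive slope (mV)")

    def scaled(self, factor: float) -> "RateLaw":
        """Return a copy with the prefactor multiplied by ``factor``."""
        return replace(self, prefactor=self.prefactor * factor)


def evaluate_rate(
    law: RateLaw,
    V: float | np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float | np.ndarray:
    """Evaluate a rate law at membrane voltage ``V`` (mV), in s^-1."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    if law.form == "exponential":
        out = law.prefactor * np.exp(
            law.sign * law.charge * V / constants.thermal_voltage
        )
    elif law.form == "hh_linexp":
        x = (V - law.offset) / law.slope
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                np.abs(x) < 1e-9,
                law.prefactor * law.slope,
                law.prefactor * (V - law.offset) / (1.0 - np.exp(-x)),
            )
    else:  # hh_exp
        out = law.prefactor * np.exp(-(V - law.offset) / law.slope)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# transitions and schemes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionSpec:
    """One reversible transition of a gating scheme.

    Statistical multiplicities (e.g. 4a vs b for the first sensor step) are
    baked into the forward/backward prefactors; the underlying pair is kept
    in ``multiplicity`` for introspection.  ``charge_per_event`` is the
    gating charge (elementary charges) moved in the forward direction:
    z_alpha + z_beta for sensor steps, z_f + z_b for the concerted step and
    zero for thermal and inactivation steps.
    """

    name: str
    source: int
    target: int
    forward: RateLaw
    backward: RateLaw
    charge_per_event: float = 0.0
    kind: str = "sensor"  # sensor | concerted | thermal | inactivation
    multiplicity: tuple[int, int] = (1, 1)
    ms_eligible: bool = True

    def __post_init__(self) -> None:
        if self.charge_per_event < 0:
            raise ValueError("charge_per_event must be >= 0")
        if self.kind in ("thermal", "inactivation") and self.charge_per_event != 0:
            raise ValueError(f"{self.kind} transitions carry no gating charge")


@dataclass(frozen=True)
class SchemeSpec:
    """A linear chain of states, optionally with one inactivation branch."""

    name: str
    states: tuple[str, ...]
    transitions: tuple[TransitionSpec, ...]
    open_index: int
    inactivated_index: int | None = None
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def chain_transitions(self) -> tuple[TransitionSpec, ...]:
        return tuple(t for t in self.transitions if t.kind != "inactivation")

    def transition(self, name: str) -> TransitionSpec:
        for t in self.transitions:
            if t.name == name:
                return t
        raise KeyError(f"scheme {self.name!r} has no transition {name!r}")

    def transitions_of_kind(self, kind: str) -> tuple[TransitionSpec, ...]:
        return tuple(t for t in self.transitions if t.kind == kind)

    @property
    def thermal_equilibrium_constant(self) -> float:
        """L = k_o/k_c of the thermal opening step (voltage-independent)."""
        thermal = self.transitions_of_kind("thermal")
        if not thermal:
            raise ValueError(f"scheme {self.name!r} has no thermal opening step")
        (t,) = thermal
        return t.forward.prefactor / t.backward.prefactor

    def cumulative_charges(self) -> np.ndarray:
        """Gating charge q_i (e) accumulated from C1 to each state."""
        q = np.zeros(self.n_states)
        for t in sorted(self.chain_transitions, key=lambda t: t.source):
            q[t.target] = q[t.source] + t.charge_per_event
        if self.inactivated_index is not None:
            (branch,) = self.transitions_of_kind("inactivation")
            q[branch.target] = q[branch.source]
        return q

    def with_transitions(self, transitions: Iterable[TransitionSpec]) -> "SchemeSpec":
        return replace(self, transitions=tuple(transitions))


@dataclass
class QVCurve:
    """Normalized gating-charge curve on a voltage grid."""

    voltage: np.ndarray
    charge: np.ndarray  # expected charge per channel, e
    charge_normalized: np.ndarray
    components: str  # "all" | "sensors_only"
    total_charge: float


# --------------------------------------------------------------------------
# generator and stationary occupancy
# --------------------------------------------------------------------------

def build_generator(
    scheme: SchemeSpec,
    V: float,
    mod=None,
) -> np.ndarray:
    """Master-equation generator Q at voltage ``V``: Q[i, j] is the rate
    i -> j for i != j; every row sums to zero.

    ``mod`` is an optional :class:`~kvmech.ms_modulation.MSModulation`
    applied before evaluating the rates.
    """
    if mod is not None:
        from .ms_modulation import apply_modulation

        scheme = apply_modulation(scheme, mod)
    n = scheme.n_states
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        kf = evaluate_rate(t.forward, V, scheme.constants)
        kb = evaluate_rate(t.backward, V, scheme.constants)
        Q[t.source, t.target] += kf
        Q[t.target, t.source] += kb
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(
    scheme: SchemeSpec,
    V: float,
    mod=None,
) -> np.ndarray:
    """Stationary occupancy by the detailed-balance product along the chain.

    The chain topology (a tree) guarantees detailed balance at stationarity,
    so log-occupancies accumulate as log forward/backward rate ratios; the
    normalization uses logsumexp for stability at extreme voltages.
    """
    if mod is not None:
        from .ms_modulation import apply_modulation

        scheme = apply_modulation(scheme, mod)
    n = scheme.n_states
    logpi = np.zeros(n)
    for t in scheme.transitions:
        kf = evaluate_rate(t.forward, V, scheme.constants)
        kb = evaluate_rate(t.backward, V, scheme.constants)
        if kb <= 0 or kf <= 0:
            raise ValueError(
                f"transition {t.name!r} has a non-positive rate at V={V} mV"
            )
        logpi[t.target] = logpi[t.source] + math.log(kf) - math.log(kb)
    return np.exp(logpi - logsumexp(logpi))


def stationary_distribution_nullspace(
    scheme: SchemeSpec,
    V: float,
    mod=None,
) -> np.ndarray:
    """Stationary occupancy from the generator's left null space.

    Independent cross-check of :func:`stationary_distribution`; solves
    Q^T p = 0 with the normalization row appended (least squares).
    """
    Q = build_generator(scheme, V, mod)
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return p


def popen_closed_form(
    scheme: SchemeSpec,
    V: float | np.ndarray,
) -> float | np.ndarray:
    """Closed-form equilibrium open probability for schemes 1 and 3.

    Scheme 1: Popen = [K/(1+K)]^4 L / (1 + [K/(1+K)]^4 L) with K = a/b
    and L = k_o/k_c.  Scheme 3 adds the concerted factor F = f/b:
    Popen = K^4 F L / ((1+K)^4 + K^4 F (1 + L)), where (1+K)^4 expands the
    binomial closed-state weights 1, 4K, 6K^2, 4K^3, K^4.
    """
    consts = scheme.constants
    sensors = scheme.transitions_of_kind("sensor")
    first = sensors[0]
    # strip the 4a/b multiplicity to recover the per-sensor K = a/b
    mf, mb = first.multiplicity
    K = (
        evaluate_rate(first.forward, V, consts)
        / mf
        / (evaluate_rate(first.backward, V, consts) / mb)
    )
    L = scheme.thermal_equilibrium_constant
    concerted = scheme.transitions_of_kind("concerted")
    if concerted:
        (c,) = concerted
        F = evaluate_rate(c.forward, V, consts) / evaluate_rate(
            c.backward, V, consts
        )
        return K**4 * F * L / ((1 + K) ** 4 + K**4 * F * (1 + L))
    x = (K / (1 + K)) ** 4 * L
    return x / (1 + x)


# --------------------------------------------------------------------------
# gating charge
# --------------------------------------------------------------------------

def qv_curve(
    scheme: SchemeSpec,
    voltages: Sequence[float] | np.ndarray,
    mod=None,
    components: str = "all",
) -> QVCurve:
    """Stationary gating-charge curve Q(V) = sum_i P_i(V) q_i.

    ``components='sensors_only'`` counts only the charge of the four
    independent sensor steps (omitting the concerted step), the component
    that dominates finite-pulse charge measurements in sensor-uncoupled
    mutants such as ILT.
    """
    if components not in ("all", "sensors_only"):
        raise ValueError("components must be 'all' or 'sensors_only'")
    voltages = np.asarray(voltages, dtype=float)
    q = scheme.cumulative_charges()
    if components == "sensors_only":
        q = np.zeros(scheme.n_states)
        for t in sorted(scheme.chain_transitions, key=lambda t: t.source):
            step = t.charge_per_event if t.kind == "sensor" else 0.0
            q[t.target] = q[t.source] + step
        if scheme.inactivated_index is not None:
            (branch,) = scheme.transitions_of_kind("inactivation")
            q[branch.target] = q[branch.source]
    total = float(q.max())
    charge = np.array(
        [stationary_distribution(scheme, v, mod) @ q for v in voltages]
    )
    return QVCurve(
        voltage=voltages,
        charge=charge,
        charge_normalized=charge / total,
        components=components,
        total_charge=total,
    )


def sensor_midpoint(scheme: SchemeSpec) -> float:
    """Per-sensor equilibrium midpoint -(RT/F) ln(a0/b0) / (z_a + z_b), mV.

    Diagnostic midpoint of one independent voltage sensor; for schemes whose
    later steps are strongly right-shifted (ILT) it approximates the midpoint
    of the sensor component of Q(V).
    """
    sensors = scheme.transitions_of_kind("sensor")
    first = sensors[0]
    mf, mb = first.multiplicity
    a0 = first.forward.prefactor / mf
    b0 = first.backward.prefactor / mb
    z = first.forward.charge + first.backward.charge
    return -scheme.constants.thermal_voltage * math.log(a0 / b0) / z


# --------------------------------------------------------------------------
# parameter library
# --------------------------------------------------------------------------

PARAMETER_SET_NAMES = (
    "scheme1_table1",
    "scheme2_table1",
    "scheme3_WT_table2",
    "scheme3_ILT_table2",
    "scheme1_table3_L4",
    "scheme1_table3_L1",
)

_SENSOR_MULTIPLICITIES = ((4, 1), (3, 2), (2, 3), (1, 4))


def load_parameter_set(name: str) -> dict:
    """Load one of the packaged parameter sets as a plain dict."""
    if name not in PARAMETER_SET_NAMES:
        raise KeyError(
            f"unknown parameter set {name!r}; available: {PARAMETER_SET_NAMES}"
        )
    text = resources.files("kvmech.data").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def _sensor_transitions_exponential(p: dict) -> list[TransitionSpec]:
    out = []
    for i, (mf, mb) in enumerate(_SENSOR_MULTIPLICITIES):
        out.append(
            TransitionSpec(
                name=f"C{i + 1}-C{i + 2}",
                source=i,
                target=i + 1,
                forward=RateLaw(
                    "exponential", mf * p["alpha0"], p["z_alpha"], +1
                ),
                backward=RateLaw(
                    "exponential", mb * p["beta0"], p["z_beta"], -1
                ),
                charge_per_event=p["z_alpha"] + p["z_beta"],
                kind="sensor",
                multiplicity=(mf, mb),
            )
        )
    return out


def _sensor_transitions_hh(p: dict) -> list[TransitionSpec]:
    shift = p.get("voltage_shift", 0.0)
    out = []
    for i, (mf, mb) in enumerate(_SENSOR_MULTIPLICITIES):
        out.append(
            TransitionSpec(
                name=f"C{i + 1}-C{i + 2}",
                source=i,
                target=i + 1,
                forward=RateLaw(
                    "hh_linexp",
                    mf * p["alpha_prefactor"],
                    offset=p["alpha_offset"] - shift,
                    slope=p["alpha_slope"],
                ),
                backward=RateLaw(
                    "hh_exp",
                    mb * p["beta_prefactor"],
                    offset=p["beta_offset"] - shift,
                    slope=p["beta_slope"],
                ),
                charge_per_event=0.0,
                kind="sensor",
                multiplicity=(mf, mb),
            )
        )
    return out


def get_scheme(
    name: str,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    inactivation_attachment: str = "O",
) -> SchemeSpec:
    """Build one of the packaged schemes by parameter-set name.

    ``inactivation_attachment`` selects the state the slow-inactivated state
    connects to in scheme 2 (default the open state, which reproduces
    multi-minute recovery at -100 mV).
    """
    p = load_parameter_set(name)
    kind = p["scheme"]

    if kind in ("scheme1", "scheme2"):
        if p.get("rate_form") == "hh":
            transitions = _sensor_transitions_hh(p)
        else:
            transitions = _sensor_transitions_exponential(p)
        states = ["C1", "C2", "C3", "C4", "C5", "O"]
        transitions.append(
            TransitionSpec(
                name="C5-O",
                source=4,
                target=5,
                forward=RateLaw("exponential", p["k_o"]),
                backward=RateLaw("exponential", p["k_c"]),
                kind="thermal",
            )
        )
        open_index, inact_index = 5, None
        if kind == "scheme2":
            states.append("I")
            attach = states.index(inactivation_attachment)
            transitions.append(
                TransitionSpec(
                    name=f"{inactivation_attachment}-I",
                    source=attach,
                    target=6,
                    forward=RateLaw("exponential", p["inac"]),
                    backward=RateLaw("exponential", p["recov"]),
                    kind="inactivation",
                    ms_eligible=False,
                )
            )
            inact_index = 6
    elif kind == "scheme3":
        states = ["C1", "C2", "C3", "C4", "C5", "C6", "O"]
        transitions = _sensor_transitions_exponential(p)
        transitions.append(
            TransitionSpec(
                name="C5-C6",
                source=4,
                target=5,
                forward=RateLaw("exponential", p["f0"], p["z_f"], +1),
                backward=RateLaw("exponential", p["b0"], p["z_b"], -1),
                charge_per_event=p["z_f"] + p["z_b"],
                kind="concerted",
            )
        )
        transitions.append(
            TransitionSpec(
                name="C6-O",
                source=5,
                target=6,
                forward=RateLaw("exponential", p["k_o"]),
                backward=RateLaw("exponential", p["k_c"]),
                kind="thermal",
            )
        )
        open_index, inact_index = 6, None
    else:
        raise ValueError(f"unknown scheme kind {kind!r}")

    return SchemeSpec(
        name=name,
        states=tuple(states),
        transitions=tuple(transitions),
        open_index=open_index,
        inactivated_index=inact_index,
        constants=constants,
    )
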