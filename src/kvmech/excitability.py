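"""Hybrid Hodgkin-Huxley / Markov excitable membrane.

A standard squid-axon HH membrane in which a fraction f_M (default 0.3) of
the delayed-rectifier conductance is replaced by a 6-state Markov Kv whose
rate functions were matched to the HH n-gate.  The total K current is

    IK = gK * (f_HH * n^4 + f_M * Po / Po_max(L0)) * (V - EK),

so at rest tension the apparent maximal K conductance equals gK.  Only the
Markov subpopulation is mechanosensitive: stretch left-shifts its
activation either through the last voltage-dependent step (vMS, factor on
alpha/4beta) or through the thermal opening constant L (LMS).  The printed
left-shift levels LS = 1.5, 2.5, 4.0, 7.0 mV map onto fixed factor/L
schedules for each mode and rest-L family.

Raising L also raises the apparent maximal conductance by
    dg_max = gK * f_M * (L - L0) / (L0 * (1 + L)),
the "double-faceted" aspect of LMS modulation.

Time is in seconds; voltages mV; conductances mS/cm^2; currents uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .ms_modulation import MSModulation, apply_modulation
from .scheme_core import (
    SchemeSpec,
    build_generator,
    get_scheme,
    stationary_distribution,
)

__all__ = [
    "MembraneModel",
    "StimulusProtocol",
    "APTrain",
    "LS_LEVELS",
    "VMS_FACTORS",
    "LMS_L_FROM_4",
    "LMS_L_FROM_1",
    "modulation_for_ls",
    "delta_gmax",
    "simulate",
    "rheobase",
    "detect_spikes",
]

#: left-shift levels (mV) with their printed per-mode schedules
LS_LEVELS = (1.5, 2.5, 4.0, 7.0)
VMS_FACTORS = {1.5: 1.05, 2.5: 1.079, 4.0: 1.14, 7.0: 1.26}  # alpha/4beta factor
LMS_L_FROM_4 = {1.5: 4.5, 2.5: 4.8, 4.0: 5.4, 7.0: 6.9}
LMS_L_FROM_1 = {1.5: 1.13, 2.5: 1.22, 4.0: 1.38, 7.0: 1.76}


# standard squid-axon HH rate functions, s^-1, V in mV
def _linexp(V, prefactor, offset, slope):
    x = (np.asarray(V, dtype=float) - offset) / slope
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            np.abs(x) < 1e-9,
            prefactor * slope,
            prefactor * (V - offset) / (1.0 - np.exp(-x)),
        )


def _alpha_m(V):
    return _linexp(V, 100.0, -40.0, 10.0)


def _beta_m(V):
    return 4000.0 * np.exp(-(V + 65.0) / 18.0)


def _alpha_h(V):
    return 70.0 * np.exp(-(V + 65.0) / 20.0)


def _beta_h(V):
    return 1000.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


def _alpha_n(V):
    return _linexp(V, 10.0, -55.0, 10.0)


def _beta_n(V):
    return 125.0 * np.exp(-(V + 65.0) / 80.0)


@dataclass(frozen=True)
class MembraneModel:
    """HH membrane with a Markov Kv subpopulation."""

    cm: float = 1.0  # uF/cm^2
    g_na: float = 120.0  # mS/cm^2
    g_k: float = 36.0
    g_leak: float = 0.25
    e_na: float = 50.0  # mV
    e_k: float = -77.0
    e_leak: float = -54.4
    f_m: float = 0.3  # mechanosensitive (Markov) fraction of gK
    markov_set: str = "scheme1_table3_L4"
    spike_threshold: float = 0.0  # mV, upward crossing
    refractory: float = 0.002  # s

    @property
    def f_hh(self) -> float:
        return 1.0 - self.f_m

    def scheme(self) -> SchemeSpec:
        return get_scheme(self.markov_set)

    @property
    def rest_L(self) -> float:
        return self.scheme().thermal_equilibrium_constant

    @property
    def po_max(self) -> float:
        """Normalizer Po_max(L0) = L0/(1+L0) at rest tension."""
        L0 = self.rest_L
        return L0 / (1.0 + L0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-clamp stimulus with an optional distinct stretch window."""

    amplitude: float = 8.0  # uA/cm^2
    onset: float = 0.05  # s
    offset: float = 0.55  # s
    stretch_onset: float | None = None  # defaults to the stimulus window
    stretch_offset: float | None = None
    t_end: float = 0.65  # s

    @property
    def stretch_window(self) -> tuple[float, float]:
        on = self.onset if self.stretch_onset is None else self.stretch_onset
        off = self.offset if self.stretch_offset is None else self.stretch_offset
        return on, off


@dataclass
class APTrain:
    spike_times: np.ndarray  # s
    threshold: float

    @property
    def count(self) -> int:
        return len(self.spike_times)

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.spike_times)


def modulation_for_ls(mode: str, ls: float, rest_L: float) -> MSModulation | None:
    """Map a left-shift level (mV) to its printed modulation for ``mode``.

    vMS: the alpha/4beta equilibrium of the last sensor step scales by the
    printed factor; LMS: L moves to the printed target for the rest-L
    family (L0 = 4 or L0 = 1), both with the symmetric barrier split.
    """
    if ls == 0:
        return None
    if ls not in LS_LEVELS:
        raise ValueError(f"unknown LS level {ls}; printed levels: {LS_LEVELS}")
    if mode == "vms":
        return MSModulation.vms_last_sensor(VMS_FACTORS[ls])
    if mode == "lms":
        table = LMS_L_FROM_4 if abs(rest_L - 4.0) < 1e-9 else LMS_L_FROM_1
        return MSModulation.lms(table[ls] / rest_L)
    raise ValueError(f"unknown mode {mode!r}")


def delta_gmax(membrane: MembraneModel, L: float) -> float:
    """Increase of the apparent maximal K conductance when L0 -> L, mS/cm^2."""
    L0 = membrane.rest_L
    if L0 <= 0:
        raise ValueError("rest L must be positive")
    return membrane.g_k * membrane.f_m * (L - L0) / (L0 * (1.0 + L))


def _rhs_factory(membrane: MembraneModel, scheme: SchemeSpec, i_stim: float):
    m_ = membrane
    open_idx = scheme.open_index
    po_max = m_.po_max

    def rhs(t, y):
        V = y[0]
        m, h, n = y[1], y[2], y[3]
        p = y[4:]
        po = p[open_idx]
        i_na = m_.g_na * m**3 * h * (V - m_.e_na)
        i_k = m_.g_k * (m_.f_hh * n**4 + m_.f_m * po / po_max) * (V - m_.e_k)
        i_leak = m_.g_leak * (V - m_.e_leak)
        dV = 1000.0 * (i_stim - i_na - i_k - i_leak) / m_.cm
        dm = _alpha_m(V) * (1 - m) - _beta_m(V) * m
        dh = _alpha_h(V) * (1 - h) - _beta_h(V) * h
        dn = _alpha_n(V) * (1 - n) - _beta_n(V) * n
        dp = build_generator(scheme, V).T @ p
        return np.concatenate(([dV, dm, dh, dn], dp))

    return rhs


def _rest_state(membrane: MembraneModel, scheme: SchemeSpec) -> np.ndarray:
    """Resting state: relax the full system at zero stimulus for 0.5 s."""
    V0 = -65.0
    y0 = np.concatenate(
        (
            [
                V0,
                _alpha_m(V0) / (_alpha_m(V0) + _beta_m(V0)),
                _alpha_h(V0) / (_alpha_h(V0) + _beta_h(V0)),
                _alpha_n(V0) / (_alpha_n(V0) + _beta_n(V0)),
            ],
            stationary_distribution(scheme, V0),
        )
    )
    sol = solve_ivp(
        _rhs_factory(membrane, scheme, 0.0),
        (0.0, 0.5),
        y0,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    return sol.y[:, -1]


def detect_spikes(
    t: np.ndarray, v: np.ndarray, threshold: float = 0.0, refractory: float = 0.002
) -> np.ndarray:
    """Upward threshold crossings with a refractory dead time (s)."""
    above = v >= threshold
    crossings = t[1:][above[1:] & ~above[:-1]]
    spikes: list[float] = []
    for tc in crossings:
        if not spikes or tc - spikes[-1] >= refractory:
            spikes.append(float(tc))
    return np.asarray(spikes)


def rheobase(
    membrane: MembraneModel,
    stimulus: StimulusProtocol | None = None,
    mode: str = "vms",
    ls: float = 0.0,
    train_spikes: int = 5,
    lo: float = 4.0,
    hi: float = 24.0,
    tol: float = 0.25,
) -> float:
    """Smallest stimulus amplitude evoking a sustained train (uA/cm^2).

    Bisects on amplitude until the response contains at least
    ``train_spikes`` spikes; the onset of repetitive firing is abrupt
    (type-II), so the count criterion is insensitive to the exact
    ``train_spikes`` choice.  Used to place a stimulus "marginally
    suprathreshold" relative to a given membrane, as the braking and
    extinction comparisons require.
    """
    if stimulus is None:
        stimulus = StimulusProtocol()
    from dataclasses import replace as _replace

    def fires(amp: float) -> bool:
        _, _, train = simulate(membrane, _replace(stimulus, amplitude=amp), mode, ls)
        return train.count >= train_spikes

    if not fires(hi):
        raise ValueError(f"no sustained train up to {hi} uA/cm^2")
    if fires(lo):
        raise ValueError(f"already firing at {lo} uA/cm^2; lower the bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def simulate(
    membrane: MembraneModel,
    stimulus: StimulusProtocol,
    mode: str = "vms",
    ls: float = 0.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    dt_sample: float = 5e-5,
) -> tuple[np.ndarray, np.ndarray, APTrain]:
    """Current-clamp response of the hybrid membrane under graded stretch.

    Integrates piecewise over the stimulus/stretch breakpoints (the RHS is
    discontinuous there) from the relaxed resting state.  Returns
    (time, voltage, APTrain); spikes are counted over the whole trace.
    """
    scheme0 = membrane.scheme()
    mod = modulation_for_ls(mode, ls, membrane.rest_L)
    scheme_stretch = apply_modulation(scheme0, mod)
    y = _rest_state(membrane, scheme0)

    s_on, s_off = stimulus.stretch_window
    breaks = sorted(
        {0.0, stimulus.onset, stimulus.offset, s_on, s_off, stimulus.t_end}
    )
    breaks = [b for b in breaks if 0.0 <= b <= stimulus.t_end]

    t_all: list[np.ndarray] = []
    v_all: list[np.ndarray] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        i_stim = (
            stimulus.amplitude if stimulus.onset <= mid < stimulus.offset else 0.0
        )
        scheme = scheme_stretch if s_on <= mid < s_off else scheme0
        t_eval = np.linspace(a, b, max(2, int(round((b - a) / dt_sample)) + 1))
        sol = solve_ivp(
            _rhs_factory(membrane, scheme, i_stim),
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"membrane integration failed on [{a}, {b}] s")
        y = sol.y[:, -1]
        t_all.append(sol.t)
        v_all.append(sol.y[0])
    t = np.concatenate(t_all)
    v = np.concatenate(v_all)
    train = APTrain(
        spike_times=detect_spikes(
            t, v, membrane.spike_threshold, membrane.refractory
        ),
        threshold=membrane.spike_threshold,
    )
    return t, v, train
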