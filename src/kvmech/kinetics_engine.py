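"""Voltage-clamp simulation of gating schemes.

The command voltage is piecewise constant, so within each protocol segment
the master equation dp/dt = Q(V)^T p has the exact solution
p(t) = expm(Q^T t) p(0); the default integrator propagates that matrix
exponential segment by segment with exact state handoff at voltage steps.
A stiff BDF route (scipy.integrate.solve_ivp) is kept as an independent
cross-check.

Provided protocol analyses:

* onset/tail half-times and their stretch sensitivity (the kinetic
  fingerprint separating vMS from LMS modulation);
* the tail-current g(V) acquisition protocol run repeatedly while the
  system recovers from slow inactivation ("conversion mimicry");
* finite-duration-pulse g(V) for schemes whose opening is too slow to
  equilibrate within a realistic pulse (ILT).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .equilibrium_analysis import GVCurve
from .ms_modulation import MSModulation, apply_modulation
from .scheme_core import SchemeSpec, build_generator, stationary_distribution

__all__ = [
    "Segment",
    "VoltageProtocol",
    "TraceResult",
    "HalftimeReport",
    "integrate",
    "step_response",
    "onset_halftime",
    "tail_halftime",
    "halftimes",
    "tail_gv_family",
    "finite_pulse_gv",
]


@dataclass(frozen=True)
class Segment:
    duration: float  # s
    voltage: float  # mV

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant command voltage.

    ``initial_condition`` is one of ``equilibrium`` (stationary occupancy at
    the first segment's voltage), ``all_inactivated`` (everything in the
    inactivated state), or an explicit probability vector.
    """

    segments: tuple[Segment, ...]
    initial_condition: str | np.ndarray = "equilibrium"

    @classmethod
    def step(
        cls,
        holding: float,
        test: float,
        duration: float,
        pre: float = 0.02,
    ) -> "VoltageProtocol":
        return cls((Segment(pre, holding), Segment(duration, test)))

    @classmethod
    def step_with_tail(
        cls,
        holding: float,
        test: float,
        pulse: float,
        tail_voltage: float,
        tail_duration: float,
    ) -> "VoltageProtocol":
        return cls(
            (
                Segment(0.02, holding),
                Segment(pulse, test),
                Segment(tail_duration, tail_voltage),
            )
        )

    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass
class TraceResult:
    """State occupancies along a protocol."""

    time: np.ndarray  # s
    voltage: np.ndarray  # command V at each sample, mV
    occupancy: np.ndarray  # (n_t, n_states)
    popen: np.ndarray
    segment_starts: np.ndarray  # s
    scheme_name: str

    def popen_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.popen))


def _initial_vector(
    scheme: SchemeSpec, protocol: VoltageProtocol
) -> np.ndarray:
    ic = protocol.initial_condition
    if isinstance(ic, str):
        if ic == "equilibrium":
            return stationary_distribution(scheme, protocol.segments[0].voltage)
        if ic == "all_inactivated":
            if scheme.inactivated_index is None:
                raise ValueError(
                    f"scheme {scheme.name!r} has no inactivated state"
                )
            p0 = np.zeros(scheme.n_states)
            p0[scheme.inactivated_index] = 1.0
            return p0
        raise ValueError(f"unknown initial condition {ic!r}")
    p0 = np.asarray(ic, dtype=float)
    if p0.shape != (scheme.n_states,) or abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("explicit initial condition must be a normalized vector")
    return p0


def integrate(
    scheme: SchemeSpec,
    mod: MSModulation | None,
    protocol: VoltageProtocol,
    samples_per_segment: int = 200,
    method: str = "expm",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TraceResult:
    """Solve the master equation along a protocol.

    ``method='expm'`` (default) propagates the exact matrix exponential on a
    uniform sample grid per segment; ``method='bdf'`` uses a stiff implicit
    ODE solver with the given tolerances.
    """
    scheme = apply_modulation(scheme, mod)
    p = _initial_vector(scheme, protocol)
    times: list[np.ndarray] = []
    volts: list[np.ndarray] = []
    occ: list[np.ndarray] = []
    seg_starts = []
    t0 = 0.0
    for seg in protocol.segments:
        seg_starts.append(t0)
        A = build_generator(scheme, seg.voltage).T
        t_local = np.linspace(0.0, seg.duration, samples_per_segment)
        if method == "expm":
            E = expm(A * (t_local[1] - t_local[0]))
            block = np.empty((samples_per_segment, scheme.n_states))
            block[0] = p
            for k in range(1, samples_per_segment):
                block[k] = E @ block[k - 1]
        elif method == "bdf":
            sol = solve_ivp(
                lambda t, y: A @ y,
                (0.0, seg.duration),
                p,
                method="BDF",
                t_eval=t_local,
                rtol=rtol,
                atol=atol,
                jac=lambda t, y: A,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed in segment at t={t0}s: {sol.message}"
                )
            block = sol.y.T
        else:
            raise ValueError(f"unknown method {method!r}")
        times.append(t0 + t_local)
        volts.append(np.full(samples_per_segment, seg.voltage))
        occ.append(block)
        p = block[-1].copy()
        t0 += seg.duration
    occupancy = np.vstack(occ)
    return TraceResult(
        time=np.concatenate(times),
        voltage=np.concatenate(volts),
        occupancy=occupancy,
        popen=occupancy[:, scheme.open_index],
        segment_starts=np.asarray(seg_starts),
        scheme_name=scheme.name,
    )


# --------------------------------------------------------------------------
# half-times
# --------------------------------------------------------------------------

def _half_crossing(t: np.ndarray, y: np.ndarray, y_half: float, rising: bool) -> float:
    if rising:
        idx = np.argmax(y >= y_half)
    else:
        idx = np.argmax(y <= y_half)
    if idx == 0:
        raise ValueError("relaxation never reaches its half level")
    return float(
        np.interp(y_half, [y[idx - 1], y[idx]][:: 1 if rising else -1],
                  [t[idx - 1], t[idx]][:: 1 if rising else -1])
    )


def step_response(
    scheme: SchemeSpec,
    mod: MSModulation | None,
    holding: float,
    test: float,
    duration: float,
    samples: int = 2000,
) -> TraceResult:
    """Popen time course for a single voltage step from equilibrium."""
    scheme_m = apply_modulation(scheme, mod)
    p0 = stationary_distribution(scheme_m, holding)
    proto = VoltageProtocol((Segment(duration, test),), initial_condition=p0)
    return integrate(scheme_m, None, proto, samples_per_segment=samples)


def onset_halftime(
    scheme: SchemeSpec,
    mod: MSModulation | None,
    holding: float,
    test: float,
    duration: float = 0.5,
) -> float:
    """Time to half of the asymptotic Popen change after a step (s)."""
    scheme_m = apply_modulation(scheme, mod)
    p0 = stationary_distribution(scheme_m, holding)[scheme.open_index]
    p_inf = stationary_distribution(scheme_m, test)[scheme.open_index]
    tr = step_response(scheme, mod, holding, test, duration)
    y_half = p0 + 0.5 * (p_inf - p0)
    return _half_crossing(tr.time, tr.popen, y_half, rising=p_inf > p0)


def tail_halftime(
    scheme: SchemeSpec,
    mod: MSModulation | None,
    depol: float,
    tail_voltage: float = -120.0,
    duration: float = 0.5,
) -> float:
    """Half-decay time of Popen upon repolarization (s), measured from the
    tail-segment start after any rising transient."""
    scheme_m = apply_modulation(scheme, mod)
    p0 = stationary_distribution(scheme_m, depol)
    proto = VoltageProtocol(
        (Segment(duration, tail_voltage),), initial_condition=p0
    )
    tr = integrate(scheme_m, None, proto, samples_per_segment=4000)
    peak = int(np.argmax(tr.popen))
    t, y = tr.time[peak:], tr.popen[peak:]
    p_inf = stationary_distribution(scheme_m, tail_voltage)[scheme.open_index]
    y_half = p_inf + 0.5 * (y[0] - p_inf)
    return _half_crossing(t, y, y_half, rising=False) - t[0]


@dataclass
class HalftimeReport:
    onset_voltages: np.ndarray
    onset_control: np.ndarray  # s
    onset_stretch: np.ndarray  # s
    tail_voltage: float
    tail_control: float  # s
    tail_stretch: float  # s
    crossover_voltage: float | None  # mV, where stretch - control changes sign


def halftimes(
    scheme: SchemeSpec,
    control: MSModulation | None,
    stretch: MSModulation,
    onset_voltages=None,
    tail_voltage: float = -120.0,
    holding: float = -100.0,
    depol: float = 40.0,
) -> HalftimeReport:
    """Onset and tail half-times for control versus stretch modulation.

    The crossover voltage is where the stretch-minus-control onset
    half-time difference changes sign (stretch accelerates onset above it).
    """
    if onset_voltages is None:
        onset_voltages = np.arange(-40.0, 61.0, 10.0)
    onset_voltages = np.asarray(onset_voltages, dtype=float)
    on_c = np.array(
        [onset_halftime(scheme, control, holding, v) for v in onset_voltages]
    )
    on_s = np.array(
        [onset_halftime(scheme, stretch, holding, v) for v in onset_voltages]
    )
    diff = on_s - on_c
    crossover = None
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size:
        i = int(sign_change[0])
        x0, x1 = diff[i], diff[i + 1]
        v0, v1 = onset_voltages[i], onset_voltages[i + 1]
        crossover = float(v0 + (0.0 - x0) * (v1 - v0) / (x1 - x0))
    return HalftimeReport(
        onset_voltages=onset_voltages,
        onset_control=on_c,
        onset_stretch=on_s,
        tail_voltage=tail_voltage,
        tail_control=tail_halftime(scheme, control, depol, tail_voltage),
        tail_stretch=tail_halftime(scheme, stretch, depol, tail_voltage),
        crossover_voltage=crossover,
    )


# --------------------------------------------------------------------------
# conversion-mimicry g(V) families
# --------------------------------------------------------------------------

def tail_gv_family(
    scheme: SchemeSpec,
    mods: list[MSModulation | None] | None = None,
    n_runs: int = 4,
    run_interval: float = 240.0,
    holding: float = -100.0,
    test_voltages=None,
    pulse: float = 0.1,
    tail_duration: float = 0.05,
    start: str | np.ndarray = "all_inactivated",
) -> list[GVCurve]:
    """Repeated tail-current g(V) acquisitions on a recovering system.

    Runs ``n_runs`` sweep families at ``run_interval`` (s) spacing, each
    sweeping ``test_voltages`` in ascending order from ``holding``; per
    sweep the conductance is the instantaneous Popen at the start of the
    tail segment.  The state vector carries over continuously, so a system
    started in the slow-inactivated state produces curves that grow in
    amplitude as recovery proceeds (the "conversion" pattern).  ``mods``
    optionally supplies one modulation per run (e.g. progressively stronger
    stretch factors).
    """
    if test_voltages is None:
        test_voltages = np.arange(-80.0, 61.0, 10.0)
    test_voltages = np.asarray(test_voltages, dtype=float)
    if mods is None:
        mods = [None] * n_runs
    if len(mods) != n_runs:
        raise ValueError("need one modulation (or None) per run")
    if isinstance(start, str) and start == "all_inactivated" and (
        scheme.inactivated_index is None
    ):
        raise ValueError("all_inactivated start requires an inactivated state")

    n_sweeps = len(test_voltages)
    sweep_period = run_interval / n_sweeps
    inter_sweep = sweep_period - pulse - tail_duration
    if inter_sweep <= 0:
        raise ValueError("run_interval too short for the sweep count")

    proto0 = VoltageProtocol((Segment(1e-6, holding),), initial_condition=start)
    p = _initial_vector(scheme, proto0)

    curves: list[GVCurve] = []
    for run in range(n_runs):
        scheme_m = apply_modulation(scheme, mods[run])
        amps = np.empty(n_sweeps)
        for i, v in enumerate(test_voltages):
            proto = VoltageProtocol(
                (
                    Segment(inter_sweep, holding),
                    Segment(pulse, v),
                    Segment(tail_duration, holding),
                ),
                initial_condition=p,
            )
            tr = integrate(scheme_m, None, proto, samples_per_segment=60)
            # Popen at the start of the tail segment = tail amplitude
            amps[i] = tr.popen_at(tr.segment_starts[2])
            p = tr.occupancy[-1].copy()
        curves.append(
            GVCurve(voltage=test_voltages.copy(), popen=amps,
                    provenance="protocol")
        )
    return curves


def finite_pulse_gv(
    scheme: SchemeSpec,
    mod: MSModulation | None = None,
    pulse: float = 0.1,
    holding: float = -100.0,
    test_voltages=None,
) -> GVCurve:
    """Popen at the end of a finite test pulse, per test voltage.

    For slowly opening channels (ILT) the pulse-limited curve lies far to
    the right of the equilibrium curve; as the pulse lengthens it converges
    to equilibrium.
    """
    if test_voltages is None:
        test_voltages = np.arange(-40.0, 201.0, 5.0)
    test_voltages = np.asarray(test_voltages, dtype=float)
    scheme_m = apply_modulation(scheme, mod)
    p0 = stationary_distribution(scheme_m, holding)
    amps = np.empty(len(test_voltages))
    for i, v in enumerate(test_voltages):
        A = build_generator(scheme_m, v).T
        amps[i] = (expm(A * pulse) @ p0)[scheme.open_index]
    return GVCurve(voltage=test_voltages, popen=amps, provenance="protocol")
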