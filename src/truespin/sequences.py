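"""Pulse-sequence programs built on the Liouville engine.

Implemented experiments:

* CPMG        90x - [tau - 180y - tau]^n            encoding time n*2*tau
* PROJECT     90x - [tau - 180y - tau - 90y - tau - 180y - tau]^n   (n*4*tau)
* TRUE        90x - [tau_e - purge - selective 180(observe) - purge - tau_e]^n
* inversion recovery (hard or spin-selective 180 - delay - 90x - read mz)
* Hahn echo (nonselective), used as the J-modulation yardstick for TRUE.

Refocusing pulses are phase y (the Meiboom-Gill choice, 90 degrees from the
excitation pulse).  TRUE's encoding-time axis counts the transverse evolution
delays (2*n*tau_e) only; the selective element is a constant per-loop overhead
whose relaxation is simulated but which, at fixed loop count, contributes the
same attenuation to every point and is absorbed by the fitted amplitude.
Both TRUE schedulings are supported: fixed loop count with variable tau_e
(the default) and fixed tau_e with a variable number of loops.

Detected amplitudes are signed: each complex echo signal is projected onto
the phase of an unrelaxed reference excitation, so J modulation shows up as
sign oscillation rather than being folded by a magnitude.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .engine import LiouvilleState, Simulator
from .spin_system import SpinSystem

__all__ = [
    "DecayCurve",
    "RecoveryCurve",
    "simulate_cpmg",
    "simulate_project",
    "simulate_true",
    "simulate_hahn",
    "simulate_inversion_recovery",
    "write_decay_curve",
    "read_decay_curve",
    "write_recovery_curve",
    "read_recovery_curve",
]


@dataclass
class DecayCurve:
    """(time, amplitude[, sigma]) series for one observed resonance."""

    times: np.ndarray
    amplitudes: np.ndarray
    sigma: np.ndarray | None = None
    observe: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must be matching 1-D arrays")
        if self.times.size and self.times[0] <= 0:
            raise ValueError("first time must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape or np.any(self.sigma < 0):
                raise ValueError("sigma must match times and be >= 0")


@dataclass
class RecoveryCurve:
    """Longitudinal recovery of one or more sites after an inversion."""

    delays: np.ndarray
    mz: np.ndarray  # shape (n_delays, n_sites)
    sites: tuple = ()
    inverted: tuple = ()
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.mz = np.atleast_2d(np.asarray(self.mz, dtype=float))
        if self.mz.shape[0] != self.delays.size:
            self.mz = self.mz.T
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if not np.all(np.isfinite(self.mz)):
            raise ValueError("mz must be finite")
        if isinstance(self.inverted, str):
            self.inverted = (self.inverted,)
        self.sites = tuple(self.sites) if self.sites else tuple(
            "site%d" % i for i in range(self.mz.shape[1])
        )

    def column(self, site: str) -> np.ndarray:
        return self.mz[:, self.sites.index(site)]


# -- helpers -----------------------------------------------------------------

def _signed_amplitudes(signals, reference: complex) -> np.ndarray:
    ref = reference / abs(reference)
    return np.array([float(np.real(s * np.conj(ref))) for s in signals])


def _reference_signal(sim: Simulator, observe, sites=None) -> complex:
    st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
    return sim.detect(st, observe, sites=sites)


# -- multiple-echo sequences ---------------------------------------------------

def simulate_cpmg(system: SpinSystem, tau: float, n_values, observe,
                  sim: Simulator | None = None, observe_sites=None) -> DecayCurve:
    """CPMG echo train; amplitudes detected after n echoes, times n*2*tau."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    n_values = sorted(int(n) for n in n_values)
    if any(n <= 0 for n in n_values):
        raise ValueError("echo counts must be positive")
    sim = sim or Simulator(system)
    ref = _reference_signal(sim, observe, observe_sites)
    p90 = sim.pulse_matrix(90.0, 0.0)
    p180 = sim.pulse_matrix(180.0, 90.0)
    E = sim.propagator(tau)
    eq = sim._c_eq.reshape(-1)
    c = p90 @ sim.equilibrium().coeffs.reshape(-1)
    signals = []
    done = 0
    for n in n_values:
        for _ in range(n - done):
            c = eq + E @ (c - eq)
            c = p180 @ c
            c = eq + E @ (c - eq)
        done = n
        st = LiouvilleState(c.reshape(sim.n_sites, sim.dim), sim)
        signals.append(sim.detect(st, observe, sites=observe_sites))
    times = np.array([n * 2.0 * tau for n in n_values])
    return DecayCurve(times, _signed_amplitudes(signals, ref), observe=str(observe),
                      meta={"sequence": "cpmg", "tau_s": tau})


def simulate_project(system: SpinSystem, tau: float, n_values, observe,
                     sim: Simulator | None = None, observe_sites=None) -> DecayCurve:
    """PROJECT (perfect echo) train; encoding time n*4*tau."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    n_values = sorted(int(n) for n in n_values)
    if any(n <= 0 for n in n_values):
        raise ValueError("echo counts must be positive")
    sim = sim or Simulator(system)
    ref = _reference_signal(sim, observe, observe_sites)
    p90y = sim.pulse_matrix(90.0, 90.0)
    p180 = sim.pulse_matrix(180.0, 90.0)
    E = sim.propagator(tau)
    eq = sim._c_eq.reshape(-1)

    def half_echo(c):
        c = eq + E @ (c - eq)
        c = p180 @ c
        return eq + E @ (c - eq)

    c = sim.pulse_matrix(90.0, 0.0) @ sim.equilibrium().coeffs.reshape(-1)
    signals = []
    done = 0
    for n in n_values:
        for _ in range(n - done):
            c = half_echo(c)
            c = p90y @ c
            c = half_echo(c)
        done = n
        st = LiouvilleState(c.reshape(sim.n_sites, sim.dim), sim)
        signals.append(sim.detect(st, observe, sites=observe_sites))
    times = np.array([n * 4.0 * tau for n in n_values])
    return DecayCurve(times, _signed_amplitudes(signals, ref), observe=str(observe),
                      meta={"sequence": "project", "tau_s": tau})


def simulate_hahn(system: SpinSystem, encoding_times, observe,
                  sim: Simulator | None = None) -> DecayCurve:
    """Plain nonselective spin echo 90x - tau_e - 180y - tau_e (J-modulated)."""
    sim = sim or Simulator(system)
    ref = _reference_signal(sim, observe)
    times = np.sort(np.asarray(encoding_times, dtype=float))
    signals = []
    for t in times:
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        st = sim.evolve(st, t / 2.0)
        st = sim.hard_pulse(st, 180.0, 90.0)
        st = sim.evolve(st, t / 2.0)
        signals.append(sim.detect(st, observe))
    return DecayCurve(times, _signed_amplitudes(signals, ref), observe=str(observe),
                      meta={"sequence": "hahn"})


def simulate_true(system: SpinSystem, observe, encoding_times=None,
                  n_loops: int = 1, tau_e: float | None = None, n_values=None,
                  selective_mode: str = "ideal", selective_duration: float = 0.0185,
                  waveform=None, sim: Simulator | None = None,
                  observe_sites=None) -> DecayCurve:
    """TRUE: spin-selective echo without J modulation of the observed spin.

    Scheduling: either pass ``encoding_times`` (total delay time; each point
    uses ``n_loops`` selective echoes with tau_e = t/(2*n_loops)), or pass a
    fixed ``tau_e`` with a list of loop counts ``n_values`` (times are then
    n*2*tau_e).  The selective element is flanked by purge filters whose
    survivors are the observed spins (and, for exchanging ensembles, the
    observed site).
    """
    if isinstance(observe, str):
        observe_t = (observe,)
    else:
        observe_t = tuple(observe)
    sim = sim or Simulator(system)
    sel_sites = observe_sites if observe_sites is not None else range(sim.n_sites)

    if encoding_times is not None:
        if n_values is not None or tau_e is not None:
            raise ValueError("give either encoding_times or (tau_e, n_values)")
        # variable tau_e at fixed loop count: the time axis is the transverse
        # delay time 2*n*tau_e; the selective element is a constant overhead
        # absorbed by the fitted amplitude
        schedule = [(float(t), int(n_loops), float(t) / (2.0 * n_loops))
                    for t in np.sort(np.asarray(encoding_times, float))]
    else:
        if tau_e is None or n_values is None:
            raise ValueError("fixed-tau_e scheduling needs tau_e and n_values")
        # variable loop count at fixed tau_e: the per-loop overhead scales with
        # the point, so the time axis counts the full loop duration
        schedule = [(int(n) * (2.0 * tau_e + selective_duration), int(n), float(tau_e))
                    for n in sorted(n_values)]
    if any(t <= 0 or n <= 0 or te <= 0 for t, n, te in schedule):
        raise ValueError("encoding times and loop counts must be positive")

    ref = _reference_signal(sim, observe_t, observe_sites)
    signals, times = [], []
    for t_total, nl, te in schedule:
        st = sim.hard_pulse(sim.equilibrium(), 90.0, 0.0)
        for _ in range(nl):
            st = sim.evolve(st, te)
            st = sim.gradient_purge(st, observe_t, survivor_sites=sel_sites)
            st = sim.selective_pulse(st, observe_t, 180.0, 90.0, mode=selective_mode,
                                     duration=selective_duration, waveform=waveform,
                                     sites=sel_sites)
            st = sim.gradient_purge(st, observe_t, survivor_sites=sel_sites)
            st = sim.evolve(st, te)
        signals.append(sim.detect(st, observe_t, sites=observe_sites))
        times.append(t_total)
    return DecayCurve(np.array(times), _signed_amplitudes(signals, ref),
                      observe=",".join(observe_t),
                      meta={"sequence": "true", "n_loops": schedule[0][1],
                            "selective_duration_s": selective_duration,
                            "selective_mode": selective_mode})


# -- inversion recovery --------------------------------------------------------

def simulate_inversion_recovery(system: SpinSystem, delays, invert="all",
                                observe=None, selective_duration: float = 0.0,
                                sim: Simulator | None = None) -> RecoveryCurve:
    """(Hard or selective) 180 - delay - 90x - longitudinal readout per site."""
    delays = np.sort(np.asarray(delays, dtype=float))
    if np.any(delays < 0):
        raise ValueError("delays must be >= 0")
    sim = sim or Simulator(system)
    observe = tuple(observe) if observe is not None else system.labels
    mz = np.empty((delays.size, len(observe)))
    for r, d in enumerate(delays):
        st = sim.equilibrium()
        if invert == "all":
            st = sim.hard_pulse(st, 180.0, 0.0)
        else:
            st = sim.selective_pulse(st, invert, 180.0, 0.0, mode="ideal",
                                     duration=selective_duration)
        st = sim.evolve(st, d)
        # longitudinal readout: a 90x read pulse converts z to -y; report mz
        for c, lab in enumerate(observe):
            mz[r, c] = sim.mz(st, lab)
    inverted = system.labels if invert == "all" else (
        (invert,) if isinstance(invert, str) else tuple(invert))
    return RecoveryCurve(delays, mz, sites=observe, inverted=inverted,
                         meta={"sequence": "inversion_recovery",
                               "invert": ",".join(inverted)})


# -- table IO ------------------------------------------------------------------

def _fmt(x) -> str:
    return repr(float(x))


def write_decay_curve(curve: DecayCurve) -> str:
    out = io.StringIO()
    out.write("# truespin decay curve\n")
    for k, v in sorted(curve.meta.items()):
        out.write("# %s: %s\n" % (k, v))
    out.write("# observe: %s\n" % curve.observe)
    cols = ["time_s", "amplitude"] + (["sigma"] if curve.sigma is not None else [])
    out.write("\t".join(cols) + "\n")
    for i in range(curve.times.size):
        row = [_fmt(curve.times[i]), _fmt(curve.amplitudes[i])]
        if curve.sigma is not None:
            row.append(_fmt(curve.sigma[i]))
        out.write("\t".join(row) + "\n")
    return out.getvalue()


def _read_table(text: str):
    meta, header, rows = {}, None, []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append([float(x) for x in line.split("\t")])
    if header is None or not rows:
        raise ValueError("table has no data rows")
    return meta, header, np.array(rows)


def read_decay_curve(text: str) -> DecayCurve:
    meta, header, data = _read_table(text)
    cols = {h: data[:, i] for i, h in enumerate(header)}
    if "time_s" not in cols or "amplitude" not in cols:
        raise ValueError("decay table needs time_s and amplitude columns")
    observe = meta.pop("observe", "")
    return DecayCurve(cols["time_s"], cols["amplitude"], sigma=cols.get("sigma"),
                      observe=observe, meta=meta)


def write_recovery_curve(curve: RecoveryCurve) -> str:
    out = io.StringIO()
    out.write("# truespin recovery curve\n")
    for k, v in sorted(curve.meta.items()):
        out.write("# %s: %s\n" % (k, v))
    out.write("# inverted: %s\n" % ",".join(curve.inverted))
    cols = ["delay_s"] + ["mz_%s" % s for s in curve.sites]
    if curve.sigma is not None:
        cols.append("sigma")
    out.write("\t".join(cols) + "\n")
    for i in range(curve.delays.size):
        row = [_fmt(curve.delays[i])] + [_fmt(v) for v in curve.mz[i]]
        if curve.sigma is not None:
            row.append(_fmt(curve.sigma[i]))
        out.write("\t".join(row) + "\n")
    return out.getvalue()


def read_recovery_curve(text: str) -> RecoveryCurve:
    meta, header, data = _read_table(text)
    if header[0] != "delay_s":
        raise ValueError("recovery table must start with a delay_s column")
    sites = tuple(h[3:] for h in header[1:] if h.startswith("mz_"))
    mz_cols = [i for i, h in enumerate(header) if h.startswith("mz_")]
    sigma = data[:, header.index("sigma")] if "sigma" in header else None
    inverted = tuple(meta.pop("inverted", "").split(",")) if meta.get("inverted") else ()
    return RecoveryCurve(data[:, 0], data[:, mz_cols], sites=sites,
                         inverted=inverted, sigma=sigma, meta=meta)
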