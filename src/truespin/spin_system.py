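"""Spin-system definitions and validation.

A :class:`SpinSystem` collects everything the simulation engine needs to know
about a set of scalar-coupled spin-1/2 nuclei in the rotating frame: offset
frequencies (Hz), the symmetric J-coupling matrix (Hz), and per-spin
longitudinal (R1 = 1/T1) and intrinsic transverse (R2 = 1/T2_0) relaxation
rates.  Frequencies are rotating-frame offsets relative to a user-defined
carrier; only frequency *differences* affect observable relaxation behaviour.

The module also provides the canonical two-spin AX benchmark used throughout
the test suite and documentation: a 500 Hz shift difference (carrier centred,
so shifts are -250 and +250 Hz), T1 = 0.2 s (A) and 0.8 s (X), intrinsic
T2 equal to T1 (extreme narrowing), and a switchable J coupling.
"""

from __future__ import annotations

import configparser
import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpinSystem",
    "SequenceTimings",
    "ax_benchmark",
    "load_system",
    "write_system",
]

#: Largest explicitly simulated spin count: the Liouville dimension is 4**n.
MAX_SPINS = 6


@dataclass(frozen=True)
class SpinSystem:
    """An isotropically coupled system of spin-1/2 nuclei.

    Parameters
    ----------
    labels:
        Spin identifiers, e.g. ``("A", "X")``.
    shifts_hz:
        Rotating-frame offset frequency of each spin in Hz.
    j_hz:
        Symmetric scalar-coupling matrix in Hz with zero diagonal.
    r1, r2:
        Per-spin longitudinal and intrinsic transverse relaxation rates in
        s^-1 (both strictly positive).
    multiplicity:
        Number of magnetically equivalent protons represented by each label.
        Multiplicities > 1 are honoured by the analytic scalar-relaxation
        formulas (see :mod:`truespin.relaxfit`); the Liouville engine always
        simulates one explicit spin per label.
    """

    labels: tuple
    shifts_hz: tuple
    j_hz: tuple
    r1: tuple
    r2: tuple
    multiplicity: tuple = ()

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        n = len(labels)
        if n == 0:
            raise ValueError("spin system must contain at least one spin")
        if len(set(labels)) != n:
            raise ValueError("duplicate spin labels: %r" % (labels,))
        shifts = np.asarray(self.shifts_hz, dtype=float)
        if shifts.shape != (n,) or not np.all(np.isfinite(shifts)):
            raise ValueError("shifts_hz must be %d finite values" % n)
        j = np.asarray(self.j_hz, dtype=float)
        if j.shape != (n, n):
            raise ValueError("j_hz must be an %dx%d matrix" % (n, n))
        if not np.all(np.isfinite(j)):
            raise ValueError("j_hz must be finite")
        if not np.allclose(j, j.T, rtol=0.0, atol=0.0):
            raise ValueError("j_hz must be exactly symmetric")
        if np.any(np.diag(j) != 0.0):
            raise ValueError("j_hz must have a zero diagonal")
        r1 = np.asarray(self.r1, dtype=float)
        r2 = np.asarray(self.r2, dtype=float)
        for name, r in (("r1", r1), ("r2", r2)):
            if r.shape != (n,) or not np.all(np.isfinite(r)) or np.any(r <= 0):
                raise ValueError("%s must be %d positive rates in s^-1" % (name, n))
        mult = self.multiplicity or tuple([1] * n)
        mult = tuple(int(m) for m in mult)
        if len(mult) != n or any(m < 1 for m in mult):
            raise ValueError("multiplicity must be %d integers >= 1" % n)
        if n > MAX_SPINS:
            raise ValueError(
                "explicit simulation limited to %d spins (got %d); represent "
                "equivalent groups with multiplicity instead" % (MAX_SPINS, n)
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "shifts_hz", tuple(shifts.tolist()))
        object.__setattr__(self, "j_hz", tuple(map(tuple, j.tolist())))
        object.__setattr__(self, "r1", tuple(r1.tolist()))
        object.__setattr__(self, "r2", tuple(r2.tolist()))
        object.__setattr__(self, "multiplicity", mult)

    # -- convenience ------------------------------------------------------

    @property
    def n_spins(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError("unknown spin label %r (have %r)" % (label, self.labels))

    def indices(self, labels) -> tuple:
        if isinstance(labels, str):
            labels = (labels,)
        return tuple(self.index(l) for l in labels)

    @property
    def shifts(self) -> np.ndarray:
        return np.asarray(self.shifts_hz, dtype=float)

    @property
    def j_matrix(self) -> np.ndarray:
        return np.asarray(self.j_hz, dtype=float)

    @property
    def r1_rates(self) -> np.ndarray:
        return np.asarray(self.r1, dtype=float)

    @property
    def r2_rates(self) -> np.ndarray:
        return np.asarray(self.r2, dtype=float)

    def t1(self, label: str) -> float:
        return 1.0 / self.r1[self.index(label)]

    def t2(self, label: str) -> float:
        return 1.0 / self.r2[self.index(label)]


@dataclass(frozen=True)
class SequenceTimings:
    """Timing book-keeping for multiple-echo relaxation experiments.

    ``encoding_times`` are the total transverse relaxation-encoding durations;
    for CPMG and PROJECT each must be an integer multiple of the basic echo
    unit (2*tau and 4*tau respectively), while a selective echo accepts
    arbitrary encoding times.
    """

    tau: float = 0.0
    n_values: tuple = ()
    encoding_times: tuple = ()
    selective_duration: float = 0.0
    selective_bandwidth: float = 0.0

    def __post_init__(self):
        if self.tau < 0 or self.selective_duration < 0 or self.selective_bandwidth < 0:
            raise ValueError("durations and bandwidths must be >= 0")
        n_values = tuple(int(n) for n in self.n_values)
        if any(n <= 0 for n in n_values):
            raise ValueError("echo-loop counts must be positive integers")
        enc = tuple(float(t) for t in self.encoding_times)
        if any(t <= 0 for t in enc):
            raise ValueError("encoding times must be positive")
        object.__setattr__(self, "n_values", n_values)
        object.__setattr__(self, "encoding_times", enc)

    def validate_encoding(self, sequence: str, rtol: float = 1e-9):
        """Check the integer-multiple constraint for multi-echo sequences."""
        units = {"cpmg": 2.0, "project": 4.0}
        if sequence == "true":
            return  # arbitrary encoding times allowed
        if sequence not in units:
            raise ValueError("unknown sequence %r" % sequence)
        if self.tau <= 0:
            raise ValueError("%s requires tau > 0" % sequence)
        unit = units[sequence] * self.tau
        for t in self.encoding_times:
            n = t / unit
            if abs(n - round(n)) > rtol * max(1.0, n):
                raise ValueError(
                    "encoding time %g s is not an integer multiple of the "
                    "basic %s echo unit %g s" % (t, sequence, unit)
                )

    def loop_counts(self, sequence: str) -> tuple:
        """Echo-loop counts reproducing ``encoding_times`` for cpmg/project."""
        self.validate_encoding(sequence)
        unit = {"cpmg": 2.0, "project": 4.0}[sequence] * self.tau
        return tuple(int(round(t / unit)) for t in self.encoding_times)


# -- the benchmark system --------------------------------------------------

def ax_benchmark(j_hz: float = 10.0) -> SpinSystem:
    """Two-spin AX benchmark: 500 Hz shift difference, T1 = 0.2/0.8 s, T2 = T1.

    The carrier is centred between the two resonances (shifts of -250 and
    +250 Hz).  ``j_hz`` is typically 0 or 10 Hz.
    """
    if j_hz < 0:
        raise ValueError("j_hz must be >= 0")
    j = float(j_hz)
    return SpinSystem(
        labels=("A", "X"),
        shifts_hz=(-250.0, 250.0),
        j_hz=((0.0, j), (j, 0.0)),
        r1=(1.0 / 0.2, 1.0 / 0.8),
        r2=(1.0 / 0.2, 1.0 / 0.8),
    )


# -- config file format ----------------------------------------------------
#
# [spins]            label = shift_hz
# [multiplicity]     label = int           (optional section)
# [couplings]        label1 label2 = J_hz  (symmetric completion applied)
# [relaxation]       label.t1 = s | label.r1 = s^-1, likewise t2/r2

def _parser() -> configparser.ConfigParser:
    p = configparser.ConfigParser(delimiters=("=",), comment_prefixes=("#", ";"))
    p.optionxform = str  # case-sensitive labels
    return p


def load_system(config_text: str) -> SpinSystem:
    """Parse a spin-system config (see module docstring for the format).

    Relaxation may be given as times (``t1``/``t2``, seconds) or rates
    (``r1``/``r2``, s^-1); times are converted to rates.  Couplings are
    completed symmetrically; conflicting duplicate entries are rejected
    naming the offending pair.
    """
    p = _parser()
    p.read_string(config_text)
    if "spins" not in p:
        raise ValueError("config must contain a [spins] section")

    labels = list(p["spins"].keys())
    shifts = [float(p["spins"][l]) for l in labels]
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}

    mult = [1] * n
    if "multiplicity" in p:
        for l, v in p["multiplicity"].items():
            if l not in idx:
                raise ValueError("multiplicity for unknown spin %r" % l)
            mult[idx[l]] = int(v)

    j = np.zeros((n, n))
    seen = {}
    if "couplings" in p:
        for key, v in p["couplings"].items():
            parts = key.split()
            if len(parts) != 2:
                raise ValueError("coupling key %r must name two spins" % key)
            a, b = parts
            if a not in idx or b not in idx:
                raise ValueError("coupling between unknown spins (%s, %s)" % (a, b))
            if a == b:
                raise ValueError("self-coupling (%s, %s) is not allowed" % (a, b))
            val = float(v)
            pair = tuple(sorted((a, b)))
            if pair in seen and seen[pair] != val:
                raise ValueError(
                    "conflicting couplings for pair (%s, %s): %g vs %g"
                    % (pair[0], pair[1], seen[pair], val)
                )
            seen[pair] = val
            j[idx[a], idx[b]] = val
            j[idx[b], idx[a]] = val

    if "relaxation" not in p:
        raise ValueError("config must contain a [relaxation] section")
    r1 = [None] * n
    r2 = [None] * n
    for key, v in p["relaxation"].items():
        if "." not in key:
            raise ValueError("relaxation key %r must look like 'label.t1'" % key)
        label, what = key.rsplit(".", 1)
        if label not in idx:
            raise ValueError("relaxation for unknown spin %r" % label)
        val = float(v)
        what = what.lower()
        if what in ("t1", "t2"):
            if val <= 0:
                raise ValueError(
                    "non-positive time constant %s = %g for spin %s" % (what, val, label)
                )
            rate = 1.0 / val
        elif what in ("r1", "r2"):
            if val <= 0:
                raise ValueError(
                    "non-positive rate %s = %g for spin %s" % (what, val, label)
                )
            rate = val
        else:
            raise ValueError("unknown relaxation key %r (use t1/t2/r1/r2)" % what)
        target = r1 if what.endswith("1") else r2
        if target[idx[label]] is not None:
            raise ValueError("duplicate relaxation entry for spin %s (%s)" % (label, what))
        target[idx[label]] = rate
    for i, l in enumerate(labels):
        if r1[i] is None or r2[i] is None:
            raise ValueError("spin %s is missing a T1/R1 or T2/R2 entry" % l)

    return SpinSystem(
        labels=tuple(labels),
        shifts_hz=tuple(shifts),
        j_hz=tuple(map(tuple, j.tolist())),
        r1=tuple(r1),
        r2=tuple(r2),
        multiplicity=tuple(mult),
    )


def write_system(system: SpinSystem) -> str:
    """Serialize a system to the config format; round-trips bit-exactly."""
    out = io.StringIO()
    out.write("# truespin spin-system config\n[spins]\n")
    for l, s in zip(system.labels, system.shifts_hz):
        out.write("%s = %s\n" % (l, repr(float(s))))
    if any(m != 1 for m in system.multiplicity):
        out.write("\n[multiplicity]\n")
        for l, m in zip(system.labels, system.multiplicity):
            if m != 1:
                out.write("%s = %d\n" % (l, m))
    out.write("\n[couplings]\n")
    j = system.j_matrix
    for i in range(system.n_spins):
        for k in range(i + 1, system.n_spins):
            if j[i, k] != 0.0:
                out.write("%s %s = %s\n"
                          % (system.labels[i], system.labels[k], repr(float(j[i, k]))))
    out.write("\n[relaxation]\n")
    for l, a, b in zip(system.labels, system.r1, system.r2):
        out.write("%s.r1 = %s\n" % (l, repr(float(a))))
        out.write("%s.r2 = %s\n" % (l, repr(float(b))))
    return out.getvalue()
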