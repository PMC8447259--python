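"""Liouville-space numerical core.

The density operator of ``n`` coupled spins-1/2 is expanded in the orthonormal
product-operator basis built from the normalized single-spin operators

    e = E/sqrt(2),   z = sqrt(2) I_z,   + = I_+,   - = I_-

so a state is a coefficient vector of dimension ``4**n``.  The coherent
generator is the commutation superoperator ``-i[H, .]`` of the isotropic
scalar-coupling Hamiltonian (the full, non-secular coupling term: rapid
refocusing must be able to drive the spins effectively strongly coupled and
suppress J modulation, which a secular ZZ truncation cannot reproduce),

    H = sum_i 2*pi*nu_i I_iz + sum_{i<j} 2*pi*J_ij (I_ix I_jx + I_iy I_jy + I_iz I_jz).

Relaxation follows the phenomenological "T1T2" model: the relaxation
superoperator is diagonal in the product basis, each basis term decaying at
the sum over spins of 0 (unit part), R1_i (z part) or R2_i (transverse part),
with an inhomogeneous drive returning every single-spin z term to its
equilibrium amplitude.  The drive is implemented exactly through the affine
fixed-point form of :meth:`Simulator.evolve`,

    c(t) = c_eq + expm(G t) (c(0) - c_eq),

which is the closed-form solution of dc/dt = G c - R c_eq because the
equilibrium state (total z magnetization) is annihilated by the coherent
generator.

Everything observable in the accompanying experiments - scalar relaxation of
a spin by the longitudinal relaxation of its coupling partners, J modulation
of echoes and its quenching by rapid refocusing, isotropic mixing in CPMG -
emerges from these two superoperators; none of it is hard-coded.

A :class:`Simulator` may optionally hold *two* chemical environments ("sites")
of the same spin topology connected by symmetric two-site exchange with hop
rate ``k_exchange``; the state vector is then the direct sum of the two site
coefficient vectors and the generator gains the kinetic coupling
``k * [[-1, 1], [1, -1]]`` between corresponding coefficients.  This is the
mechanism used to inject a known exchange rate into simulated decay data.

Rotation convention: right-handed, a 90 degree pulse about +x takes I_z to
-I_y.  Field-gradient coherence selection is modelled as an ideal pathway
filter (:meth:`Simulator.gradient_purge`), not as spatially resolved
propagation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .spin_system import SpinSystem

__all__ = [
    "ProductBasis",
    "LiouvilleState",
    "Spectrum",
    "Simulator",
    "hamiltonian",
    "coherent_generator",
    "relaxation_rates",
    "relaxation_generator",
    "peak_halfwidth",
    "read_spectrum",
    "write_spectrum",
    "read_waveform",
    "write_waveform",
]

_SQRT2 = float(np.sqrt(2.0))
_E2 = np.eye(2, dtype=complex)
_IX = np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex)
_IY = np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex)
_IZ = np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex)
_IP = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)  # I+
_IM = np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex)  # I-

#: normalized single-spin basis operators, Hilbert-Schmidt orthonormal
_SINGLE = {
    "e": _E2 / _SQRT2,
    "z": _SQRT2 * _IZ,
    "+": _IP,
    "-": _IM,
}
_ADJOINT = {"e": "e", "z": "z", "+": "-", "-": "+"}


def _kronN(mats) -> np.ndarray:
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def _embed(n: int, i: int, op: np.ndarray) -> np.ndarray:
    """Single-spin operator ``op`` at position ``i``, identity elsewhere."""
    return _kronN([op if j == i else _E2 for j in range(n)])


class ProductBasis:
    """Orthonormal product-operator basis of ``n`` spins-1/2.

    ``labels[k]`` is a tuple over spins drawn from {'e','z','+','-'};
    column ``k`` of :attr:`B` is the row-major vectorization of the
    corresponding operator, so ``B`` is unitary and maps coefficient vectors
    to vectorized Hilbert-space matrices.
    """

    _cache: dict = {}

    def __new__(cls, n_spins: int):
        if n_spins in cls._cache:
            return cls._cache[n_spins]
        self = super().__new__(cls)
        self.n_spins = int(n_spins)
        self.hdim = 2 ** self.n_spins
        self.dim = 4 ** self.n_spins
        self.labels = tuple(itertools.product("ez+-", repeat=self.n_spins))
        cols = np.empty((self.dim, self.hdim * self.hdim), dtype=complex)
        for k, lab in enumerate(self.labels):
            cols[k] = _kronN([_SINGLE[c] for c in lab]).reshape(-1)
        self.B = cols.T.copy()
        self.index = {lab: k for k, lab in enumerate(self.labels)}
        # adjoint pairing for Hermiticity checks
        self.adjoint_index = np.array(
            [self.index[tuple(_ADJOINT[c] for c in lab)] for lab in self.labels]
        )
        cls._cache[n_spins] = self
        return self

    def to_matrix(self, coeffs: np.ndarray) -> np.ndarray:
        return (self.B @ coeffs).reshape(self.hdim, self.hdim)

    def to_coeffs(self, rho: np.ndarray) -> np.ndarray:
        return self.B.conj().T @ rho.reshape(-1)

    def coeffs_of(self, label_tuple) -> int:
        return self.index[tuple(label_tuple)]

    def term(self, label_tuple) -> np.ndarray:
        """The (normalized) basis operator for a label tuple, as a matrix."""
        return _kronN([_SINGLE[c] for c in label_tuple])


# -- generators -------------------------------------------------------------

def hamiltonian(system: SpinSystem) -> np.ndarray:
    """Rotating-frame Hamiltonian in rad/s, as a Hilbert-space matrix."""
    n = system.n_spins
    H = np.zeros((2 ** n, 2 ** n), dtype=complex)
    for i, nu in enumerate(system.shifts):
        H += 2.0 * np.pi * nu * _embed(n, i, _IZ)
    j = system.j_matrix
    for i in range(n):
        for k in range(i + 1, n):
            if j[i, k] != 0.0:
                coup = (
                    _embed(n, i, _IX) @ _embed(n, k, _IX)
                    + _embed(n, i, _IY) @ _embed(n, k, _IY)
                    + _embed(n, i, _IZ) @ _embed(n, k, _IZ)
                )
                H += 2.0 * np.pi * j[i, k] * coup
    return H


def coherent_generator(system: SpinSystem, basis: ProductBasis | None = None) -> np.ndarray:
    """Commutation superoperator ``-i[H, .]`` in the product basis (dim 4**n)."""
    basis = basis or ProductBasis(system.n_spins)
    H = hamiltonian(system)
    eye = np.eye(basis.hdim, dtype=complex)
    lvec = -1j * (np.kron(H, eye) - np.kron(eye, H.T))
    return basis.B.conj().T @ lvec @ basis.B


def relaxation_rates(system: SpinSystem, basis: ProductBasis | None = None) -> np.ndarray:
    """Decay rate of every product-basis term under the T1T2 sum rule."""
    basis = basis or ProductBasis(system.n_spins)
    per_spin = {"e": np.zeros(system.n_spins)}
    per_spin["z"] = system.r1_rates
    per_spin["+"] = per_spin["-"] = system.r2_rates
    rates = np.zeros(basis.dim)
    for k, lab in enumerate(basis.labels):
        rates[k] = sum(per_spin[c][i] for i, c in enumerate(lab))
    return rates


def relaxation_generator(system: SpinSystem, basis: ProductBasis | None = None) -> np.ndarray:
    """Diagonal T1T2 relaxation superoperator (homogeneous part).

    The equilibrium drive on single-spin z terms is applied by
    :meth:`Simulator.evolve` through the affine fixed-point form; the matrix
    returned here is the homogeneous (decay) part only.
    """
    basis = basis or ProductBasis(system.n_spins)
    return np.diag(-relaxation_rates(system, basis)).astype(complex)


# -- state ------------------------------------------------------------------

@dataclass
class LiouvilleState:
    """Coefficient vector(s) of the density operator in the product basis.

    ``coeffs`` has shape ``(n_sites, 4**n)``; plain (non-exchanging) systems
    have a single site.
    """

    coeffs: np.ndarray
    space: "Simulator"

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=complex))

    @property
    def basis_labels(self) -> tuple:
        return self.space.basis.labels

    @property
    def n_sites(self) -> int:
        return self.coeffs.shape[0]

    def copy(self) -> "LiouvilleState":
        return LiouvilleState(self.coeffs.copy(), self.space)

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def as_matrix(self, site: int = 0) -> np.ndarray:
        return self.space.basis.to_matrix(self.coeffs[site])

    def hermiticity_defect(self) -> float:
        """Max |c_adjoint - conj(c)| over all sites; 0 for physical states."""
        adj = self.space.basis.adjoint_index
        return float(
            np.max(np.abs(self.coeffs[:, adj] - np.conj(self.coeffs)))
        )

    def coefficient(self, label_tuple, site: int = 0) -> complex:
        return complex(self.coeffs[site, self.space.basis.coeffs_of(label_tuple)])


# -- spectra ----------------------------------------------------------------

@dataclass
class Spectrum:
    """Real absorption-mode spectrum on a monotonically increasing Hz axis."""

    freq_hz: np.ndarray
    intensity: np.ndarray
    line_broadening: float = 0.0

    def __post_init__(self):
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.freq_hz.ndim != 1 or self.freq_hz.shape != self.intensity.shape:
            raise ValueError("freq_hz and intensity must be matching 1-D arrays")
        if np.any(np.diff(self.freq_hz) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if not (np.all(np.isfinite(self.intensity)) and np.all(np.isfinite(self.freq_hz))):
            raise ValueError("spectrum values must be finite")


def write_spectrum(spectrum: Spectrum) -> str:
    lines = ["# truespin spectrum", "# line_broadening_hz: %s" % repr(spectrum.line_broadening),
             "# columns: freq_hz intensity"]
    for f, y in zip(spectrum.freq_hz, spectrum.intensity):
        lines.append("%s\t%s" % (repr(float(f)), repr(float(y))))
    return "\n".join(lines) + "\n"


def read_spectrum(text: str) -> Spectrum:
    lb = 0.0
    freqs, vals = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "line_broadening_hz:" in line:
                lb = float(line.split(":", 1)[1])
            continue
        a, b = line.split()
        freqs.append(float(a))
        vals.append(float(b))
    return Spectrum(np.array(freqs), np.array(vals), line_broadening=lb)


def write_waveform(amplitude: np.ndarray, phase_deg: np.ndarray) -> str:
    lines = ["# truespin shaped-pulse waveform", "# columns: amplitude phase_deg"]
    for a, p in zip(amplitude, phase_deg):
        lines.append("%s\t%s" % (repr(float(a)), repr(float(p))))
    return "\n".join(lines) + "\n"


def read_waveform(text: str):
    amp, ph = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, p = line.split()
        amp.append(float(a))
        ph.append(float(p))
    return np.array(amp), np.array(ph)


# -- the simulator ----------------------------------------------------------

class Simulator:
    """Propagation workspace for one spin system (optionally two-site exchange).

    Parameters
    ----------
    system:
        The (site-A) spin system.
    exchange_with:
        Optional second environment with identical labels (site B); the two
        sites interconvert with symmetric hop rate ``k_exchange`` (equal
        populations).
    k_exchange:
        Site hop rate constant in s^-1.
    """

    def __init__(self, system: SpinSystem, exchange_with: SpinSystem | None = None,
                 k_exchange: float = 0.0):
        self.system = system
        self.basis = ProductBasis(system.n_spins)
        if exchange_with is not None:
            if exchange_with.labels != system.labels:
                raise ValueError("exchange sites must share the same spin labels")
            if k_exchange < 0:
                raise ValueError("k_exchange must be >= 0")
            self.systems = (system, exchange_with)
        else:
            if k_exchange:
                raise ValueError("k_exchange requires exchange_with")
            self.systems = (system,)
        self.k_exchange = float(k_exchange)
        self.n_sites = len(self.systems)
        self._site_coherent = [coherent_generator(s, self.basis) for s in self.systems]
        self._site_rates = [relaxation_rates(s, self.basis) for s in self.systems]
        self._gen_cache: dict = {}
        self._prop_cache: dict = {}
        self._detect_cache: dict = {}
        # equilibrium: unit z per spin, shared equally between sites
        rho_eq = sum(_embed(system.n_spins, i, _IZ) for i in range(system.n_spins))
        ceq = self.basis.to_coeffs(rho_eq)
        self._c_eq = np.tile(ceq / self.n_sites, (self.n_sites, 1))

    # -- states ---------------------------------------------------------

    @property
    def dim(self) -> int:
        return self.basis.dim

    def equilibrium(self) -> LiouvilleState:
        return LiouvilleState(self._c_eq.copy(), self)

    def state_from_matrix(self, rho: np.ndarray, site: int = 0) -> LiouvilleState:
        c = np.zeros((self.n_sites, self.dim), dtype=complex)
        c[site] = self.basis.to_coeffs(np.asarray(rho, dtype=complex))
        return LiouvilleState(c, self)

    # -- generators and propagators --------------------------------------

    def generator(self, coherent: bool = True, relaxation: bool = True) -> np.ndarray:
        """Total generator on the stacked (site, basis) coefficient vector."""
        key = (coherent, relaxation)
        if key not in self._gen_cache:
            d, ns = self.dim, self.n_sites
            G = np.zeros((ns * d, ns * d), dtype=complex)
            for s in range(ns):
                block = np.zeros((d, d), dtype=complex)
                if coherent:
                    block += self._site_coherent[s]
                if relaxation:
                    block -= np.diag(self._site_rates[s])
                G[s * d:(s + 1) * d, s * d:(s + 1) * d] = block
            if relaxation and self.n_sites == 2 and self.k_exchange > 0:
                k = self.k_exchange
                eye = np.eye(d)
                G[:d, :d] -= k * eye
                G[d:, d:] -= k * eye
                G[:d, d:] += k * eye
                G[d:, :d] += k * eye
            self._gen_cache[key] = G
        return self._gen_cache[key]

    def propagator(self, duration: float, coherent: bool = True,
                   relaxation: bool = True) -> np.ndarray:
        key = (coherent, relaxation, float(duration))
        if key not in self._prop_cache:
            self._prop_cache[key] = expm(self.generator(coherent, relaxation) * duration)
        return self._prop_cache[key]

    def evolve(self, state: LiouvilleState, duration: float, coherent: bool = True,
               relaxation: bool = True) -> LiouvilleState:
        """Propagate by the matrix exponential of the selected generator.

        Uses the affine fixed-point form ``c_eq + expm(G t)(c - c_eq)``,
        which applies the equilibrium drive of the T1T2 model exactly.
        """
        if duration < 0:
            raise ValueError("duration must be >= 0")
        if duration == 0:
            return state.copy()
        P = self.propagator(duration, coherent, relaxation)
        flat = state.coeffs.reshape(-1)
        eq = self._c_eq.reshape(-1)
        out = eq + P @ (flat - eq)
        return LiouvilleState(out.reshape(self.n_sites, self.dim), self)

    # -- pulses -----------------------------------------------------------

    def _rotation_unitary(self, flip_deg: float, phase_deg: float,
                          targets=None) -> np.ndarray:
        n = self.system.n_spins
        idx = range(n) if targets is None else self.system.indices(targets)
        phi = np.deg2rad(phase_deg)
        axis = sum(
            np.cos(phi) * _embed(n, i, _IX) + np.sin(phi) * _embed(n, i, _IY)
            for i in idx
        )
        return expm(-1j * np.deg2rad(flip_deg) * axis)

    def _apply_unitary(self, state: LiouvilleState, U: np.ndarray, sites) -> LiouvilleState:
        out = state.copy()
        for s in sites:
            rho = self.basis.to_matrix(out.coeffs[s])
            out.coeffs[s] = self.basis.to_coeffs(U @ rho @ U.conj().T)
        return out

    def hard_pulse(self, state: LiouvilleState, flip: float, phase: float) -> LiouvilleState:
        """Ideal nonselective rotation of all spins (zero duration)."""
        U = self._rotation_unitary(flip, phase)
        return self._apply_unitary(state, U, range(self.n_sites))

    def pulse_matrix(self, flip: float, phase: float, targets=None, sites=None) -> np.ndarray:
        """Coefficient-space superoperator of an ideal rotation (for fast loops)."""
        U = self._rotation_unitary(flip, phase, targets)
        uvec = np.kron(U, U.conj())
        block = self.basis.B.conj().T @ uvec @ self.basis.B
        sites = range(self.n_sites) if sites is None else sites
        d, ns = self.dim, self.n_sites
        M = np.eye(ns * d, dtype=complex)
        for s in sites:
            M[s * d:(s + 1) * d, s * d:(s + 1) * d] = block
        return M

    def selective_pulse(self, state: LiouvilleState, targets, flip: float, phase: float,
                        mode: str = "ideal", duration: float = 0.0,
                        waveform=None, sites=None) -> LiouvilleState:
        """Spin-selective rotation.

        ideal mode: instantaneous rotation of the target spins (on the given
        sites) followed by relaxation-only evolution for ``duration`` - the
        coherent shift/J evolution during a selective refocusing pulse is
        refocused by construction in a selective echo, while relaxation is
        not, so only the latter is kept.

        shaped mode: piecewise-constant propagation of the full generator
        plus an RF term defined by a user waveform (relative amplitude 0-1,
        phase in degrees) applied at the target spins' mean offset.
        """
        if isinstance(targets, str):
            targets = (targets,)
        if not targets:
            raise ValueError("selective pulse needs a non-empty target set")
        sites = range(self.n_sites) if sites is None else tuple(sites)
        if mode == "ideal":
            U = self._rotation_unitary(flip, phase, targets)
            out = self._apply_unitary(state, U, sites)
            if duration > 0:
                out = self.evolve(out, duration, coherent=False, relaxation=True)
            return out
        if mode != "shaped":
            raise ValueError("mode must be 'ideal' or 'shaped'")
        if waveform is None:
            raise ValueError("shaped mode requires a waveform")
        if duration <= 0:
            raise ValueError("shaped mode requires duration > 0")
        amp, ph_deg = waveform
        amp = np.asarray(amp, dtype=float)
        ph = np.deg2rad(np.asarray(ph_deg, dtype=float))
        if amp.shape != ph.shape or amp.ndim != 1 or amp.size == 0:
            raise ValueError("waveform must be two equal-length 1-D columns")
        nslice = amp.size
        dt = duration / nslice
        n = self.system.n_spins
        idx = self.system.indices(targets)
        carrier = float(np.mean([self.system.shifts[i] for i in idx]))
        # calibrate peak RF amplitude so the integrated rotation equals `flip`
        w1max = np.deg2rad(flip) / (np.sum(amp) * dt)
        sx = sum(_embed(n, i, _IX) for i in range(n))
        sy = sum(_embed(n, i, _IY) for i in range(n))
        eye = np.eye(self.basis.hdim, dtype=complex)
        d, ns = self.dim, self.n_sites
        # inhomogeneous relaxation drive: dc/dt = G c + b, b = rates * c_eq
        # (with RF on, equilibrium is no longer a fixed point, so the affine
        # fixed-point shortcut of evolve() does not apply - use an augmented
        # matrix exponential instead)
        b_drive = np.concatenate([self._site_rates[s] * self._c_eq[s]
                                  for s in range(ns)])
        out = state.copy()
        base_phase = np.deg2rad(phase)
        for j in range(nslice):
            t_mid = (j + 0.5) * dt
            # RF applied at the carrier offset: in this frame its phase ramps
            phi = base_phase + ph[j] + 2.0 * np.pi * carrier * t_mid
            w1 = w1max * amp[j]
            flat = out.coeffs.reshape(-1)
            Gtot = np.array(self.generator(True, True), copy=True)
            Hrf = w1 * (np.cos(phi) * sx + np.sin(phi) * sy)
            lrf = -1j * (np.kron(Hrf, eye) - np.kron(eye, Hrf.T))
            lrf_basis = self.basis.B.conj().T @ lrf @ self.basis.B
            for s in range(ns):
                Gtot[s * d:(s + 1) * d, s * d:(s + 1) * d] += lrf_basis
            aug = np.zeros((ns * d + 1, ns * d + 1), dtype=complex)
            aug[:-1, :-1] = Gtot * dt
            aug[:-1, -1] = b_drive * dt
            prop = expm(aug)
            flat = prop[:-1, :-1] @ flat + prop[:-1, -1]
            out = LiouvilleState(flat.reshape(ns, d), self)
        return out

    # -- gradients --------------------------------------------------------

    def purge_mask(self, survivors, survivor_sites=None) -> np.ndarray:
        if isinstance(survivors, str):
            survivors = (survivors,)
        surv = set(self.system.indices(survivors)) if survivors else set()
        sites = set(range(self.n_sites)) if survivor_sites is None else set(survivor_sites)
        mask = np.ones((self.n_sites, self.dim))
        for k, lab in enumerate(self.basis.labels):
            transverse = {i for i, c in enumerate(lab) if c in "+-"}
            if not transverse:
                continue  # longitudinal / unit terms are immune to gradients
            for s in range(self.n_sites):
                if s not in sites or not transverse.issubset(surv):
                    mask[s, k] = 0.0
        return mask

    def gradient_purge(self, state: LiouvilleState, survivors,
                       survivor_sites=None) -> LiouvilleState:
        """Ideal coherence-pathway filter.

        Zeros every basis term carrying transverse character on a
        non-survivor spin (or on a non-survivor site); survivor-spin
        coherences - the ones refocused by the paired selective 180 - are
        retained, as are all longitudinal and unit terms.
        """
        out = state.copy()
        out.coeffs = out.coeffs * self.purge_mask(survivors, survivor_sites)
        return out

    # -- detection --------------------------------------------------------

    def _detect_weights(self, spin_index: int) -> np.ndarray:
        key = spin_index
        if key not in self._detect_cache:
            n = self.system.n_spins
            a = _embed(n, spin_index, _IP)  # Tr(rho I+) picks the I- component
            scale = 2.0 / (2.0 ** (n - 1))
            self._detect_cache[key] = scale * (self.basis.B.T @ a.T.reshape(-1))
        return self._detect_cache[key]

    def detect(self, state: LiouvilleState, observe, sites=None) -> complex:
        """In-phase complex signal sum_i <I_i-> over the observed spins.

        Antiphase terms contribute zero, matching peak-amplitude fitting of
        resolved resonances.  Normalized so one spin at equilibrium gives a
        unit-magnitude signal after a 90 degree pulse.
        """
        if isinstance(observe, str):
            observe = (observe,)
        if not observe:
            raise ValueError("observe must name at least one spin")
        sites = range(self.n_sites) if sites is None else sites
        amp = 0.0 + 0.0j
        for i in self.system.indices(observe):
            w = self._detect_weights(i)
            for s in sites:
                amp += w @ state.coeffs[s]
        return complex(amp)

    def mz(self, state: LiouvilleState, observe, sites=None) -> float:
        """Longitudinal magnetization of the observed spins (equilibrium = 1).

        The embedded I_iz operator has coefficient sqrt(2)**(n-2) on the
        normalized single-z basis term, so dividing by that factor returns
        <I_iz> on the equilibrium scale of one unit per spin.
        """
        if isinstance(observe, str):
            observe = (observe,)
        sites = range(self.n_sites) if sites is None else sites
        n = self.system.n_spins
        scale = _SQRT2 ** (n - 2)
        total = 0.0
        for i in self.system.indices(observe):
            lab_z = tuple("z" if j == i else "e" for j in range(n))
            k = self.basis.coeffs_of(lab_z)
            for s in sites:
                total += float(np.real(state.coeffs[s, k])) / scale
        return total

    # -- acquisition ------------------------------------------------------

    def acquire_spectrum(self, state: LiouvilleState, dwell: float, npoints: int,
                         line_broadening: float = 0.0, observe=None,
                         zero_fill: int = 4) -> Spectrum:
        """Sample an FID under the full generator, FFT, zero-order phase.

        ``npoints`` must be a power of two >= 1024 and the spectral width
        1/dwell must cover every shift +- 5 J (aliasing guard).  Exponential
        apodization, when requested, is recorded on the returned
        :class:`Spectrum` so that measured widths can be corrected.
        """
        npoints = int(npoints)
        if npoints < 1024 or (npoints & (npoints - 1)) != 0:
            raise ValueError("npoints must be a power of two >= 1024")
        jmax = float(np.max(np.abs(self.system.j_matrix))) if self.system.n_spins > 1 else 0.0
        span = max(
            max(abs(s) for s in sys.shifts_hz) + 5.0 * jmax for sys in self.systems
        )
        nyquist = 0.5 / dwell
        if span > nyquist:
            raise ValueError(
                "spectral width %.1f Hz does not cover shifts +- 5J (%.1f Hz): "
                "decrease dwell" % (2 * nyquist, 2 * span)
            )
        observe = observe if observe is not None else self.system.labels
        P = self.propagator(dwell, True, True)
        eq = self._c_eq.reshape(-1)
        flat = state.coeffs.reshape(-1).copy()
        fid = np.empty(npoints, dtype=complex)
        st = LiouvilleState(flat.reshape(self.n_sites, self.dim), self)
        for m in range(npoints):
            fid[m] = self.detect(st, observe)
            flat = eq + P @ (flat - eq)
            st = LiouvilleState(flat.reshape(self.n_sites, self.dim), self)
        if line_broadening > 0:
            t = np.arange(npoints) * dwell
            fid = fid * np.exp(-np.pi * line_broadening * t)
        # zero-order phase from the total integral (the first FID point):
        # unbiased by the small phase twist that relaxation-coupled multiplet
        # components acquire, unlike phasing on the tallest peak
        phi0 = np.angle(fid[0]) if abs(fid[0]) > 0 else 0.0
        fid = fid * np.exp(-1j * phi0)
        fid[0] *= 0.5
        nfft = npoints * int(zero_fill)
        spec = np.fft.fftshift(np.fft.fft(fid, n=nfft))
        freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=dwell))
        return Spectrum(freqs, np.real(spec), line_broadening=float(line_broadening))


# -- module-level wrappers (operate on a state's own simulator) -------------

def hard_pulse(state: LiouvilleState, flip: float, phase: float) -> LiouvilleState:
    return state.space.hard_pulse(state, flip, phase)


def selective_pulse(state: LiouvilleState, targets, flip: float, phase: float,
                    mode: str = "ideal", duration: float = 0.0, waveform=None,
                    sites=None) -> LiouvilleState:
    return state.space.selective_pulse(state, targets, flip, phase, mode=mode,
                                       duration=duration, waveform=waveform, sites=sites)


def gradient_purge(state: LiouvilleState, survivors, survivor_sites=None) -> LiouvilleState:
    return state.space.gradient_purge(state, survivors, survivor_sites)


def evolve(state: LiouvilleState, duration: float, coherent: bool = True,
           relaxation: bool = True) -> LiouvilleState:
    return state.space.evolve(state, duration, coherent, relaxation)


def detect(state: LiouvilleState, observe, sites=None) -> complex:
    return state.space.detect(state, observe, sites)


# -- spectral measurement ----------------------------------------------------

def peak_halfwidth(spectrum: Spectrum, center: float, window: float) -> float:
    """Full width at half maximum of the single peak inside a window.

    Linear interpolation between the samples flanking each half-height
    crossing.  Raises if the window contains no interior maximum or if the
    half height is not crossed inside the window.
    """
    f, y = spectrum.freq_hz, spectrum.intensity
    sel = (f >= center - window / 2.0) & (f <= center + window / 2.0)
    if not np.any(sel):
        raise ValueError("window contains no spectrum samples")
    fi, yi = f[sel], y[sel]
    k = int(np.argmax(yi))
    if k == 0 or k == len(yi) - 1 or yi[k] <= 0:
        raise ValueError("no interior maximum in the window")
    half = yi[k] / 2.0
    # walk left
    i = k
    while i > 0 and yi[i] > half:
        i -= 1
    if yi[i] > half:
        raise ValueError("half height not crossed on the low-frequency side")
    f_lo = fi[i] + (half - yi[i]) * (fi[i + 1] - fi[i]) / (yi[i + 1] - yi[i])
    # walk right
    i = k
    while i < len(yi) - 1 and yi[i] > half:
        i += 1
    if yi[i] > half:
        raise ValueError("half height not crossed on the high-frequency side")
    f_hi = fi[i - 1] + (half - yi[i - 1]) * (fi[i] - fi[i - 1]) / (yi[i] - yi[i - 1])
    return float(f_hi - f_lo)
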