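"""Analytic two-site Bloch-McConnell machinery.

Three complementary routes to slow-exchange rate constants:

* **Bandshape analysis** - the steady-state absorption lineshape of two
  exchanging sites, from the closed-form inverse of the 2x2 McConnell
  matrix.  Instrumental broadening (field inhomogeneity, residual
  decoupling) enters as a Lorentzian full-width ``l_inst`` added to each
  site's R2 as pi*l_inst; because it cannot be measured exactly, bandshape
  fitting is performed twice, with ``l_inst`` pinned at a lower and an upper
  bound, and the resulting [k_low, k_high] interval - not the fit
  covariance - is the uncertainty statement.

* **Selective inversion recovery** (Hoffman-Forsen) - closed-form
  biexponential solution of the longitudinal 2x2 system
  d(dM)/dt = -(R1 + K + S) dM, with optional cross-relaxation ``sigma_cross``
  (the mechanism that biases Hoffman-Forsen rates when through-space
  magnetization exchange is present but unmodelled).  Inverting each site in
  turn and fitting all four trajectories jointly determines k and both R1s.

* **Arrhenius analysis** - weighted linear regression of ln k on 1/T,
  E_a = -slope * R_gas, pooling rate constants from any method and honouring
  per-record exclusion flags.

Exchange convention: ``k`` is the rate constant of the site-interconversion
process in the McConnell matrix [[-k, k], [k, -k]] for equal populations;
with unequal populations (bandshape only) the hop rates are
k_ab = 2*p_b*k, k_ba = 2*p_a*k, which satisfy detailed balance and reduce to
k at p = 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import lmfit
import numpy as np

from .engine import Spectrum

__all__ = [
    "TwoSiteExchange",
    "HFModel",
    "RateSeries",
    "ArrheniusFit",
    "BandshapeFit",
    "HFFit",
    "bm_bandshape",
    "fit_bandshape",
    "hf_solution",
    "hf_eigenvalues",
    "fit_hoffman_forsen",
    "fit_arrhenius",
    "coalescence_rate",
    "write_rate_series",
    "read_rate_series",
]

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass(frozen=True)
class TwoSiteExchange:
    """Two exchanging environments of one spin for bandshape analysis."""

    nu_a: float
    nu_b: float
    k: float
    r2_a: float
    r2_b: float
    p_a: float = 0.5
    l_inst: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.p_a < 1.0:
            raise ValueError("p_a must lie strictly between 0 and 1")
        if self.k < 0 or self.r2_a < 0 or self.r2_b < 0 or self.l_inst < 0:
            raise ValueError("k, r2 and l_inst must be >= 0")

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_a

    @property
    def k_ab(self) -> float:
        return 2.0 * self.p_b * self.k

    @property
    def k_ba(self) -> float:
        return 2.0 * self.p_a * self.k


def bm_bandshape(model: TwoSiteExchange, freq_grid) -> Spectrum:
    """Steady-state absorption lineshape of the 2x2 McConnell system.

    I(nu) = Re[ 1^T (R + K - i 2 pi (nu - N))^-1 p ]; the integral over nu
    equals (p_a + p_b)/2 = 1/2 independently of k (1^T K = 0), which is the
    conservation property the tests check.
    """
    nu = np.asarray(freq_grid, dtype=float)
    if nu.ndim != 1 or nu.size < 2:
        raise ValueError("freq_grid must be a 1-D grid")
    lo, hi = min(model.nu_a, model.nu_b), max(model.nu_a, model.nu_b)
    if nu[0] > lo or nu[-1] < hi:
        raise ValueError("freq_grid must span both site frequencies")
    rr = np.pi * model.l_inst
    # M(nu) = R + K - i*2pi*(nu - N), elementwise over the grid
    m11 = model.r2_a + rr + model.k_ab - 2j * np.pi * (nu - model.nu_a)
    m22 = model.r2_b + rr + model.k_ba - 2j * np.pi * (nu - model.nu_b)
    m12 = -model.k_ba
    m21 = -model.k_ab
    det = m11 * m22 - m12 * m21
    if np.any(np.abs(det) == 0):
        raise ValueError("singular McConnell matrix: unphysical parameters")
    # 1^T M^-1 p with p = (p_a, p_b)
    inv_p_top = (m22 * model.p_a - m12 * model.p_b) / det
    inv_p_bot = (-m21 * model.p_a + m11 * model.p_b) / det
    return Spectrum(nu, np.real(inv_p_top + inv_p_bot))


def coalescence_rate(model: TwoSiteExchange) -> float:
    """Classic equal-population coalescence estimate k = pi*|dnu|/sqrt(2)."""
    return float(np.pi * abs(model.nu_a - model.nu_b) / np.sqrt(2.0))


@dataclass
class BandshapeFit:
    """Bandshape fit at both instrumental-linewidth bounds.

    ``k_low``/``k_high`` bracket the exchange rate; ``k_high`` comes from the
    lower linewidth bound (all unexplained broadening attributed to exchange).
    ``pinned_at_zero`` flags a bound fit driven to k = 0 because the assumed
    instrumental width overshoots the observed one.
    """

    k_low: float
    k_high: float
    fits: tuple
    pinned_at_zero: bool

    @property
    def k_mid(self) -> float:
        return 0.5 * (self.k_low + self.k_high)

    @property
    def k_halfwidth(self) -> float:
        return 0.5 * (self.k_high - self.k_low)


def _fit_bandshape_once(spectrum: Spectrum, init: TwoSiteExchange,
                        l_inst: float) -> lmfit.minimizer.MinimizerResult:
    params = lmfit.Parameters()
    params.add("k", value=max(init.k, 1e-3), min=0.0)
    params.add("scale", value=1.0, min=0.0)

    y = spectrum.intensity
    nu = spectrum.freq_hz
    norm = float(np.max(np.abs(y))) or 1.0

    def residual(p):
        m = replace(init, k=p["k"].value, l_inst=l_inst)
        model = bm_bandshape(m, nu).intensity
        mmax = float(np.max(np.abs(model))) or 1.0
        return (p["scale"].value * model / mmax * norm - y) / norm

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError("bandshape fit failed to converge at l_inst=%g" % l_inst)
    return out


def fit_bandshape(spectrum: Spectrum, init: TwoSiteExchange,
                  l_inst_bounds) -> BandshapeFit:
    """Least-squares k at each instrumental-linewidth bound.

    Site frequencies, populations and intrinsic R2s are taken from ``init``
    (they are known from slow-exchange spectra and T1/CPMG measurements);
    only the exchange rate and an overall amplitude are free.
    """
    lo, hi = float(l_inst_bounds[0]), float(l_inst_bounds[1])
    if lo > hi or lo < 0:
        raise ValueError("l_inst bounds must be ordered and >= 0")
    fit_hi_l = _fit_bandshape_once(spectrum, init, hi)  # -> lower k
    fit_lo_l = _fit_bandshape_once(spectrum, init, lo)  # -> upper k
    k_low = float(fit_hi_l.params["k"].value)
    k_high = float(fit_lo_l.params["k"].value)
    pinned = bool(k_low < 1e-9)
    if k_low > k_high:  # numerically possible only for degenerate bounds
        k_low, k_high = k_high, k_low
    return BandshapeFit(k_low=k_low, k_high=k_high, fits=(fit_lo_l, fit_hi_l),
                        pinned_at_zero=pinned)


# -- Hoffman-Forsen ----------------------------------------------------------

@dataclass(frozen=True)
class HFModel:
    """Longitudinal two-site model for selective inversion recovery."""

    r1_a: float
    r1_b: float
    k: float
    sigma_cross: float = 0.0
    meq_a: float = 1.0
    meq_b: float = 1.0
    inv_eff: float = 1.0

    def __post_init__(self):
        if self.r1_a < 0 or self.r1_b < 0 or self.k < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 < self.inv_eff <= 1.0:
            raise ValueError("inv_eff must lie in (0, 1]")


def hf_solution(model: HFModel, t, inverted: str):
    """Closed-form biexponential recovery of both sites after inverting one.

    The deviation from equilibrium obeys d(dM)/dt = -A dM with the symmetric
    matrix A = [[r1_a + k, sigma - k], [sigma - k, r1_b + k]]; its exact
    eigendecomposition gives

        dM(t) = v1 e^{-l1 t} (v1 . dM0) + v2 e^{-l2 t} (v2 . dM0).

    ``inverted`` is 'a' or 'b'; the initial condition is
    dM = -2 * inv_eff * meq on the inverted site only (ideal selectivity).
    Returns (m_a(t), m_b(t)) on the absolute magnetization scale.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    a = model.r1_a + model.k
    b = model.sigma_cross - model.k
    c = model.r1_b + model.k
    # analytic eigen-decomposition of [[a, b], [b, c]]
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(0.25 * (a - c) ** 2 + b ** 2)
    l1, l2 = half_tr - disc, half_tr + disc
    if b == 0.0 and a <= c:
        v1 = np.array([1.0, 0.0])
    elif b == 0.0:
        v1 = np.array([0.0, 1.0])
    else:
        v1 = np.array([b, l1 - a])
        v1 /= np.linalg.norm(v1)
    v2 = np.array([-v1[1], v1[0]])
    meq = np.array([model.meq_a, model.meq_b])
    dm0 = np.zeros(2)
    site = {"a": 0, "b": 1}[inverted.lower()]
    dm0[site] = -2.0 * model.inv_eff * meq[site]
    dm = (np.outer(np.exp(-l1 * t), v1) * (v1 @ dm0)
          + np.outer(np.exp(-l2 * t), v2) * (v2 @ dm0))
    m = meq[None, :] + dm
    return m[:, 0], m[:, 1]


def hf_eigenvalues(model: HFModel):
    """The two recovery eigenvalues (s^-1), slow first."""
    a = model.r1_a + model.k
    b = model.sigma_cross - model.k
    c = model.r1_b + model.k
    half_tr = 0.5 * (a + c)
    disc = np.sqrt(0.25 * (a - c) ** 2 + b ** 2)
    return half_tr - disc, half_tr + disc


@dataclass
class HFFit:
    model: HFModel
    se: dict
    inv_eff: tuple
    result: object


def fit_hoffman_forsen(curves, fix_r1=None, fit_sigma: bool = False,
                       sigma_cross: float = 0.0) -> HFFit:
    """Joint fit of selective inversion recovery for both sites.

    ``curves`` are :class:`~truespin.sequences.RecoveryCurve` objects, one
    per inversion experiment (normally A-inverted and B-inverted), each
    carrying both sites' trajectories.  A single experiment is accepted only
    with ``fix_r1`` supplied (k and R1 otherwise trade off).  Cross-relaxation
    is fixed at ``sigma_cross`` (default 0) unless ``fit_sigma``.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no recovery curves supplied")
    sites = curves[0].sites
    if len(sites) != 2:
        raise ValueError("Hoffman-Forsen fitting needs exactly two sites")
    for c in curves:
        if c.sites != sites:
            raise ValueError("all curves must share the same two sites")
        if len(c.inverted) != 1 or c.inverted[0] not in sites:
            raise ValueError("each curve must record a single inverted site")
    if len(curves) < 2 and fix_r1 is None:
        raise ValueError(
            "a single inversion experiment is under-determined (k and R1 "
            "trade off); supply both experiments or fix_r1"
        )

    p = lmfit.Parameters()
    p.add("k", value=0.5, min=0.0)
    if fix_r1 is not None:
        p.add("r1_a", value=float(fix_r1[0]), vary=False)
        p.add("r1_b", value=float(fix_r1[1]), vary=False)
    else:
        guess = 1.0 / np.mean([c.delays.mean() for c in curves])
        p.add("r1_a", value=guess, min=1e-6)
        p.add("r1_b", value=guess, min=1e-6)
    p.add("sigma", value=float(sigma_cross), vary=bool(fit_sigma))
    meq_guess = [np.mean([abs(c.mz[-1, i]) for c in curves]) or 1.0 for i in range(2)]
    p.add("meq_a", value=meq_guess[0], min=1e-9)
    p.add("meq_b", value=meq_guess[1], min=1e-9)
    for i, _ in enumerate(curves):
        p.add("eta_%d" % i, value=0.9, min=0.05, max=1.0)

    def residual(params):
        res = []
        for i, c in enumerate(curves):
            m = HFModel(r1_a=params["r1_a"].value, r1_b=params["r1_b"].value,
                        k=params["k"].value, sigma_cross=params["sigma"].value,
                        meq_a=params["meq_a"].value, meq_b=params["meq_b"].value,
                        inv_eff=params["eta_%d" % i].value)
            ma, mb = hf_solution(m, c.delays, "a" if c.inverted[0] == sites[0] else "b")
            pred = np.column_stack([ma, mb])
            r = (pred - c.mz)
            if c.sigma is not None and np.any(c.sigma > 0):
                r = r / c.sigma[:, None]
            res.append(r.ravel())
        return np.concatenate(res)

    out = lmfit.minimize(residual, p, method="leastsq")
    if not out.success:
        raise RuntimeError("Hoffman-Forsen joint fit did not converge")
    q = out.params
    model = HFModel(r1_a=q["r1_a"].value, r1_b=q["r1_b"].value, k=q["k"].value,
                    sigma_cross=q["sigma"].value, meq_a=q["meq_a"].value,
                    meq_b=q["meq_b"].value, inv_eff=q["eta_0"].value)
    se = {name: (q[name].stderr if q[name].stderr is not None else float("nan"))
          for name in ("k", "r1_a", "r1_b", "sigma", "meq_a", "meq_b")}
    return HFFit(model=model, se=se,
                 inv_eff=tuple(q["eta_%d" % i].value for i in range(len(curves))),
                 result=out)


# -- Arrhenius ---------------------------------------------------------------

@dataclass
class RateSeries:
    """(temperature, k, k_se, method, omitted) records for Arrhenius fitting."""

    temperature_k: np.ndarray
    k_per_s: np.ndarray
    k_se: np.ndarray
    method: tuple
    omitted: np.ndarray

    METHODS = ("bandshape", "hoffman_forsen", "true")

    def __init__(self, temperature_k, k_per_s, k_se=None, method=None, omitted=None):
        self.temperature_k = np.asarray(temperature_k, dtype=float)
        self.k_per_s = np.asarray(k_per_s, dtype=float)
        n = self.temperature_k.size
        self.k_se = (np.zeros(n) if k_se is None else np.asarray(k_se, dtype=float))
        self.method = tuple(method) if method is not None else ("true",) * n
        self.omitted = (np.zeros(n, dtype=bool) if omitted is None
                        else np.asarray(omitted, dtype=bool))
        if not (self.k_per_s.size == n and self.k_se.size == n
                and len(self.method) == n and self.omitted.size == n):
            raise ValueError("all record columns must have equal length")
        if np.any(self.temperature_k <= 0):
            raise ValueError("temperatures must be positive (K)")
        if np.any(self.k_per_s[~self.omitted] <= 0):
            raise ValueError("fitted (non-omitted) rate constants must be positive")
        if np.any(self.k_se < 0):
            raise ValueError("rate uncertainties must be >= 0")

    @property
    def n_used(self) -> int:
        return int(np.sum(~self.omitted))


@dataclass(frozen=True)
class ArrheniusFit:
    ea_kj_per_mol: float
    ln_a: float
    ea_se_kj_per_mol: float
    ln_a_se: float
    n_used: int

    def k_at(self, temperature_k: float) -> float:
        return float(np.exp(self.ln_a - 1000.0 * self.ea_kj_per_mol
                            / (R_GAS * temperature_k)))


def fit_arrhenius(series: RateSeries) -> ArrheniusFit:
    """Weighted linear regression of ln k on 1/T; E_a = -slope * R_gas.

    Weights come from delta(ln k) = k_se / k; records with k_se = 0 (exact
    synthetic rates) fall back to unit weights, and the parameter covariance
    is then scaled by the residual variance instead of the stated errors.
    Omitted records are excluded from the regression but remain in the
    series for plotting.
    """
    use = ~series.omitted
    if np.sum(use) < 2:
        raise ValueError("need at least 2 non-omitted records")
    x = 1.0 / series.temperature_k[use]
    y = np.log(series.k_per_s[use])
    se_ln = np.where(series.k_per_s[use] > 0,
                     series.k_se[use] / series.k_per_s[use], 0.0)
    absolute = bool(np.all(se_ln > 0))
    w = 1.0 / se_ln ** 2 if absolute else np.ones_like(x)
    X = np.column_stack([x, np.ones_like(x)])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    beta = cov_unscaled @ (XtW @ y)
    resid = y - X @ beta
    if absolute:
        cov = cov_unscaled
    else:
        dof = max(x.size - 2, 1)
        cov = cov_unscaled * float(resid @ (w * resid)) / dof
    slope, intercept = beta
    return ArrheniusFit(
        ea_kj_per_mol=float(-slope * R_GAS / 1000.0),
        ln_a=float(intercept),
        ea_se_kj_per_mol=float(np.sqrt(max(cov[0, 0], 0.0)) * R_GAS / 1000.0),
        ln_a_se=float(np.sqrt(max(cov[1, 1], 0.0))),
        n_used=int(x.size),
    )


# -- rate-series tables -------------------------------------------------------

def write_rate_series(series: RateSeries) -> str:
    lines = ["# truespin rate series",
             "T_K\tk_per_s\tk_se\tmethod\tomitted"]
    for i in range(series.temperature_k.size):
        lines.append("%s\t%s\t%s\t%s\t%d" % (
            repr(float(series.temperature_k[i])), repr(float(series.k_per_s[i])),
            repr(float(series.k_se[i])), series.method[i], int(series.omitted[i])))
    return "\n".join(lines) + "\n"


def read_rate_series(text: str) -> RateSeries:
    temps, ks, ses, methods, omitted = [], [], [], [], []
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t")[0] != "T_K":
                raise ValueError("rate series must start with a T_K header")
            header_seen = True
            continue
        t, k, se, m, o = line.split("\t")
        temps.append(float(t))
        ks.append(float(k))
        ses.append(float(se))
        methods.append(m)
        omitted.append(bool(int(o)))
    return RateSeries(temps, ks, ses, methods, omitted)
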