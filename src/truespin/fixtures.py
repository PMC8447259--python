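"""Seeded synthetic-fixture generation and the AX benchmark study.

Everything here is computed at run time from the package's own simulators and
analytic models; no stored data are involved.  Fixtures are deterministic for
a fixed (seed, spec): random-number streams are spawned per output file from
a single ``numpy.random.SeedSequence`` so that adding a file never perturbs
the others.

Scenarios
---------
ax_benchmark
    The two-spin simulation study: CPMG (tau = 200 us), PROJECT
    (tau = 800 us) and TRUE (18.5 ms selective element) decay tables for both
    spins of the AX benchmark (shift difference 500 Hz, T1 = 0.2/0.8 s,
    T2 = T1, J = 10 Hz by default) on the standard encoding-time grid
    6.4 ... 819.2 ms.
exchanging_doublet
    A single resonance hopping between two environments +-30 Hz with
    R1 = R2 = 2 s^-1 and a ladder of injected hop rates; TRUE and CPMG decay
    tables plus the matching analytic bandshape for every rate.
hf_pair
    Selective inversion recovery pairs (each site inverted in turn) from the
    closed-form two-site longitudinal model, for a ladder of exchange rates.
arrhenius_series
    Rate-constant records on a temperature grid generated from an Arrhenius
    law (defaults E_a = 78.3 kJ/mol, ln A = 32 - rates of order 1-300 s^-1
    between 298 and 358 K, the span over which selective-inversion, echo and
    bandshape methods hand over to one another).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import sequences as seqs
from .engine import Simulator, write_spectrum
from .exchange_models import RateSeries, TwoSiteExchange, bm_bandshape, write_rate_series
from .relaxfit import fit_monoexponential
from .spin_system import SpinSystem, ax_benchmark

__all__ = ["FixtureSpec", "make_fixtures", "ENCODING_GRID_S",
           "ax_relaxation_study", "doublet_sites", "hf_delay_grid"]

#: the standard relaxation-encoding grid (s): 6.4 ms doubling to 819.2 ms
ENCODING_GRID_S = tuple(0.0064 * 2 ** i for i in range(8))

CPMG_TAU_S = 200e-6
PROJECT_TAU_S = 800e-6
TRUE_SELECTIVE_S = 0.0185

SCENARIOS = ("ax_benchmark", "exchanging_doublet", "hf_pair", "arrhenius_series")


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic-fixture set."""

    scenario: str
    seed: int = 0
    noise_frac: float = 0.0
    replicate_count: int = 1

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError("unknown scenario %r (choose from %s)"
                             % (self.scenario, ", ".join(SCENARIOS)))
        if self.noise_frac < 0:
            raise ValueError("noise_frac must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def doublet_sites(delta_nu: float = 60.0, r: float = 2.0):
    """The exchanging-doublet fixture: one spin, sites at +-delta_nu/2."""
    mk = lambda nu: SpinSystem(("A",), (nu,), ((0.0,),), (r,), (r,))
    return mk(-delta_nu / 2.0), mk(+delta_nu / 2.0)


def hf_delay_grid() -> np.ndarray:
    """Ten recovery delays spanning 20 ms - 4 s (log-ish spacing)."""
    return np.array([0.02, 0.05, 0.1, 0.2, 0.35, 0.6, 1.0, 1.6, 2.5, 4.0])


def _noisy(rng, values: np.ndarray, noise_frac: float, scale: float):
    if noise_frac <= 0:
        return values, None
    sigma = noise_frac * scale
    return values + rng.normal(0.0, sigma, values.shape), np.full(values.shape, sigma)


def _cpmg_loops(grid) -> np.ndarray:
    return np.round(np.asarray(grid) / (2.0 * CPMG_TAU_S)).astype(int)


def _project_loops(grid) -> np.ndarray:
    return np.round(np.asarray(grid) / (4.0 * PROJECT_TAU_S)).astype(int)


def make_fixtures(spec: FixtureSpec, out_dir) -> list:
    """Write the scenario's files under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = iter(np.random.SeedSequence(spec.seed).spawn(64))
    paths = []

    def save(name: str, text: str):
        p = out_dir / name
        p.write_text(text)
        paths.append(p)

    def save_decay(name: str, curve: seqs.DecayCurve):
        rng = np.random.default_rng(next(streams))
        amps, sig = _noisy(rng, curve.amplitudes, spec.noise_frac,
                           float(np.abs(curve.amplitudes).max()))
        out = seqs.DecayCurve(curve.times, amps, sigma=sig, observe=curve.observe,
                              meta=dict(curve.meta, noise_frac=spec.noise_frac,
                                        seed=spec.seed))
        save(name, seqs.write_decay_curve(out))

    grid = np.array(ENCODING_GRID_S)

    if spec.scenario == "ax_benchmark":
        system = ax_benchmark(10.0)
        for obs in ("A", "X"):
            save_decay("cpmg_%s.tsv" % obs,
                       seqs.simulate_cpmg(system, CPMG_TAU_S, _cpmg_loops(grid), obs))
            save_decay("project_%s.tsv" % obs,
                       seqs.simulate_project(system, PROJECT_TAU_S, _project_loops(grid), obs))
            save_decay("true_%s.tsv" % obs,
                       seqs.simulate_true(system, obs, encoding_times=grid,
                                          selective_duration=TRUE_SELECTIVE_S))

    elif spec.scenario == "exchanging_doublet":
        site_a, site_b = doublet_sites()
        for k in (1.0, 3.0, 10.0):
            sim = Simulator(site_a, exchange_with=site_b, k_exchange=k)
            save_decay("true_k%g.tsv" % k,
                       seqs.simulate_true(site_a, "A", encoding_times=grid,
                                          selective_duration=0.010, sim=sim,
                                          observe_sites=(0,)))
            save_decay("cpmg_k%g.tsv" % k,
                       seqs.simulate_cpmg(site_a, CPMG_TAU_S, _cpmg_loops(grid), "A",
                                          sim=sim, observe_sites=(0,)))
            bs = TwoSiteExchange(nu_a=site_a.shifts_hz[0], nu_b=site_b.shifts_hz[0],
                                 k=k, r2_a=site_a.r2[0], r2_b=site_b.r2[0],
                                 p_a=0.5, l_inst=0.5)
            save("bandshape_k%g.tsv" % k,
                 write_spectrum(bm_bandshape(bs, np.linspace(-200.0, 200.0, 4001))))

    elif spec.scenario == "hf_pair":
        from .exchange_models import HFModel, hf_solution
        t = hf_delay_grid()
        for k in (0.5, 1.5, 5.0):
            model = HFModel(r1_a=0.8, r1_b=1.2, k=k, inv_eff=0.95)
            for inv, name in (("a", "A"), ("b", "B")):
                rng = np.random.default_rng(next(streams))
                ma, mb = hf_solution(model, t, inv)
                mz = np.column_stack([ma, mb])
                mz_n, sig = _noisy(rng, mz, spec.noise_frac, 1.0)
                curve = seqs.RecoveryCurve(
                    t, mz_n, sites=("A", "B"), inverted=(name,),
                    sigma=(sig[:, 0] if sig is not None else None),
                    meta={"k_injected": k, "noise_frac": spec.noise_frac,
                          "seed": spec.seed})
                save("hf_k%g_invert%s.tsv" % (k, name),
                     seqs.write_recovery_curve(curve))

    elif spec.scenario == "arrhenius_series":
        rng = np.random.default_rng(next(streams))
        temps = np.arange(298.0, 359.0, 10.0)
        ea_kj, ln_a = 78.3, 32.0
        lnk = ln_a - ea_kj * 1000.0 / (8.314 * temps)
        if spec.noise_frac > 0:
            lnk = lnk + rng.normal(0.0, spec.noise_frac, temps.shape)
        k = np.exp(lnk)
        k_se = spec.noise_frac * k
        # method hand-over with rate, mirroring how slow-exchange studies
        # combine techniques across a temperature range
        method = tuple("hoffman_forsen" if ki < 5 else
                       ("true" if ki < 50 else "bandshape") for ki in k)
        series = RateSeries(temps, k, k_se, method)
        save("rate_series.tsv", write_rate_series(series))

    return paths


# -- the benchmark relaxation study -------------------------------------------

def ax_relaxation_study(j_hz: float, grid=ENCODING_GRID_S,
                        selective_duration: float = TRUE_SELECTIVE_S) -> dict:
    """Fitted decay rates of both AX spins under CPMG, PROJECT and TRUE.

    Returns {(sequence, spin): rate in s^-1}.  Fits use relative weighting:
    the only residual source in these noiseless decays is multiplicative
    (residual coupling modulation), for which proportional errors are the
    appropriate model.
    """
    grid = np.asarray(grid, dtype=float)
    system = ax_benchmark(j_hz)
    out = {}
    for obs in ("A", "X"):
        curves = {
            "cpmg": seqs.simulate_cpmg(system, CPMG_TAU_S, _cpmg_loops(grid), obs),
            "project": seqs.simulate_project(system, PROJECT_TAU_S,
                                             _project_loops(grid), obs),
            "true": seqs.simulate_true(system, obs, encoding_times=grid,
                                       selective_duration=selective_duration),
        }
        for name, curve in curves.items():
            out[(name, obs)] = fit_monoexponential(curve, weights="relative").rate
    return out
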