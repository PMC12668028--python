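"""Thermodynamics of inferred K-pairwise models.

Introducing a temperature T rescales all inferred parameters by 1/T,
P(sigma, T) = exp(-H(sigma)/T) / Z(T); T = 1 recovers the data-fitted
distribution.  Specific heat and susceptibility follow from the
fluctuation-dissipation relations

    Cv(T) = Var(H) / T^2        chi(T) = Var(M) / T,

with H the T=1 Hamiltonian and M the total magnetization.  A maximum of
Cv or chi near T = 1, growing superlinearly with system size, is the
static (thermodynamic) signature of criticality; initial-condition
dependence of the sampled curves below a temperature T* marks the onset
of a glassy, multi-valley energy landscape where Metropolis sampling is
no longer ergodic on feasible timescales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .maxent import ENUMERATION_LIMIT, KPairwiseModel, SamplerConfig, enumerate_exact, metropolis_moments

__all__ = [
    "ThermoCurve",
    "ScalingFit",
    "default_grid",
    "response_curve",
    "exact_response_curve",
    "locate_maximum",
    "glassy_onset",
    "finite_size_scaling",
]

T_MIN, T_MAX = 0.01, 3.00


def default_grid(n_coarse: int = 60, n_fine: int = 21) -> np.ndarray:
    """Geometric grid on [0.01, 3] with a linear insert on [0.8, 1.6]
    where the response maxima live."""
    coarse = np.geomspace(T_MIN, T_MAX, n_coarse)
    fine = np.linspace(0.8, 1.6, n_fine)
    return np.unique(np.concatenate([coarse, fine]))


@dataclass
class ThermoCurve:
    temperatures: np.ndarray
    cv: np.ndarray
    chi: np.ndarray
    cv_se: np.ndarray
    chi_se: np.ndarray
    init_mode: str = "random"
    n_spins: int = 0


def response_curve(
    model: KPairwiseModel,
    t_grid: np.ndarray | None = None,
    cfg: SamplerConfig | None = None,
    init_mode: str = "random",
) -> ThermoCurve:
    """Metropolis sweep of Cv(T) and chi(T) over a temperature grid.

    At each T, ``cfg.n_chains`` chains are run from fresh initial states
    (``random`` or the all-silent state ``silent``); standard errors are
    across chains."""
    t_grid = default_grid() if t_grid is None else np.asarray(t_grid, float)
    cfg = cfg or SamplerConfig()
    cv = np.empty_like(t_grid)
    chi = np.empty_like(t_grid)
    cv_se = np.empty_like(t_grid)
    chi_se = np.empty_like(t_grid)
    for m, t in enumerate(t_grid):
        sub = replace(cfg, seed=cfg.seed + 7919 * m)
        _, stats = metropolis_moments(model, float(t), sub, init_mode=init_mode)
        cv[m], chi[m] = stats.cv, stats.chi
        cv_se[m], chi_se[m] = stats.se_cv, stats.se_chi
    return ThermoCurve(t_grid, cv, chi, cv_se, chi_se, init_mode, model.n_spins)


def exact_response_curve(model: KPairwiseModel, t_grid: np.ndarray) -> ThermoCurve:
    """Enumeration-based Cv/chi curve (oracle, N <= 20)."""
    if model.n_spins > ENUMERATION_LIMIT:
        raise ValueError("exact curve limited to small N")
    t_grid = np.asarray(t_grid, float)
    cv = np.empty_like(t_grid)
    chi = np.empty_like(t_grid)
    for m, t in enumerate(t_grid):
        ex = enumerate_exact(model, float(t))
        cv[m], chi[m] = ex.cv(float(t)), ex.chi(float(t))
    z = np.zeros_like(t_grid)
    return ThermoCurve(t_grid, cv, chi, z, z, "exact", model.n_spins)


@dataclass
class MaximumLocation:
    t_max: float
    value: float
    interior: bool


def locate_maximum(
    temperatures: np.ndarray, values: np.ndarray, t_min: float | None = None
) -> MaximumLocation:
    """Grid argmax refined by a local quadratic fit over 5 points.

    ``t_min`` restricts the search to T > t_min (used to exclude the
    glassy regime, where the curves are a sampling artifact).  Edge
    maxima are flagged as non-interior and returned unrefined."""
    t = np.asarray(temperatures, float)
    v = np.asarray(values, float)
    if t_min is not None:
        keep = t > t_min
        t, v = t[keep], v[keep]
    m = int(np.argmax(v))
    if m == 0 or m == t.size - 1:
        return MaximumLocation(float(t[m]), float(v[m]), False)
    lo, hi = max(0, m - 2), min(t.size, m + 3)
    coeff = np.polyfit(t[lo:hi], v[lo:hi], 2)
    if coeff[0] < 0:
        t_ref = float(np.clip(-coeff[1] / (2 * coeff[0]), t[m - 1], t[m + 1]))
        v_ref = float(np.polyval(coeff, t_ref))
    else:
        t_ref, v_ref = float(t[m]), float(v[m])
    return MaximumLocation(t_ref, max(v_ref, float(v[m])), True)


@dataclass
class GlassyOnset:
    t_star: float
    found: bool
    curve_random: ThermoCurve
    curve_silent: ThermoCurve


def glassy_onset(
    model: KPairwiseModel,
    t_grid: np.ndarray | None = None,
    cfg: SamplerConfig | None = None,
    n_sigma: float = 3.0,
) -> GlassyOnset:
    """Temperature below which sampling depends on the initial state.

    Paired sweeps are run from uniformly random starts and from the
    all-silent reference state.  T* is the largest grid temperature below
    which Cv or chi disagree by more than ``n_sigma`` combined standard
    errors on two consecutive grid points; if no such temperature exists
    the grid minimum is returned with ``found=False``.

    The comparison is made on log scale: in the non-ergodic regime the
    random-start chains scatter across metastable valleys, so the values
    (and their chain-to-chain errors) span orders of magnitude, and a
    linear z-score would be swamped by the very scatter that constitutes
    the signal."""
    t_grid = default_grid() if t_grid is None else np.asarray(t_grid, float)
    cur_r = response_curve(model, t_grid, cfg, init_mode="random")
    cur_s = response_curve(model, t_grid, cfg, init_mode="silent")

    def signif(a, a_se, b, b_se, floor=1e-3):
        log_gap = np.abs(np.log(a + floor) - np.log(b + floor))
        rel = np.sqrt((a_se / (a + floor)) ** 2 + (b_se / (b + floor)) ** 2)
        rel = np.where(rel > 0, rel, np.inf)
        both_dead = (a < floor) & (b < floor)
        return (log_gap > n_sigma * rel) & ~both_dead

    sig = signif(cur_r.cv, cur_r.cv_se, cur_s.cv, cur_s.cv_se) | \
        signif(cur_r.chi, cur_r.chi_se, cur_s.chi, cur_s.chi_se)
    t_star, found = float(t_grid.min()), False
    for m in range(t_grid.size - 2, -1, -1):
        if sig[m] and sig[m + 1]:
            t_star, found = float(t_grid[m + 1]), True
            break
    return GlassyOnset(t_star, found, cur_r, cur_s)


@dataclass
class ScalingFit:
    n_values: np.ndarray
    max_values: np.ndarray        # mean maximum per N
    exponent: float
    exponent_se: float
    tmax_values: np.ndarray


def finite_size_scaling(
    n_values,
    max_values,
    tmax_values=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ScalingFit:
    """Least-squares scaling exponent of response maxima, max ~ N**e.

    ``max_values`` is a sequence of per-N replicate arrays (one entry per
    independent network realization); the exponent error is bootstrapped
    over replicates (``n_boot`` resamples)."""
    n_values = np.asarray(n_values, float)
    reps = [np.atleast_1d(np.asarray(v, float)) for v in max_values]
    if len(reps) != n_values.size or n_values.size < 2:
        raise ValueError("need replicate maxima for at least two system sizes")
    means = np.array([r.mean() for r in reps])
    if np.any(means <= 0):
        raise ValueError("maxima must be positive for a log-log fit")
    x = np.log(n_values)
    exponent = float(np.polyfit(x, np.log(means), 1)[0])
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        y = np.log([r[rng.integers(0, r.size, r.size)].mean() for r in reps])
        boots.append(np.polyfit(x, y, 1)[0])
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else 0.0
    tmax = np.asarray(tmax_values, float) if tmax_values is not None else np.full(n_values.size, np.nan)
    return ScalingFit(n_values, means, exponent, max(se, 1e-12), tmax)
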