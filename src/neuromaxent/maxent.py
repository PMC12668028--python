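"""K-pairwise maximum-entropy (generalized Ising) models of binary
population activity.

The model assigns each +/-1 pattern sigma the probability
P(sigma) = exp(-H(sigma)) / Z with

    H(sigma) = - sum_i h_i sigma_i - 1/2 sum_{i != j} J_ij sigma_i sigma_j
               - sum_K V_K delta(K, K'(sigma)),

where K'(sigma) counts the up-spins.  The fields h_i, couplings J_ij and
synchrony potentials V_K are the Lagrange multipliers of the constraints
<sigma_i>, <sigma_i sigma_j> and P(K); V_0 is pinned to zero (one value of
P(K) is fixed by normalization).  The inverse problem is solved by
Boltzmann-machine learning: Metropolis sampling of the current model,
followed by gradient steps proportional to the gap between sampled and
data moments.  Exact enumeration (N <= 20) serves as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import FINAL_E, N_ACC, N_PAIR, N_SAMP, SUM_E, SUM_E2, SUM_M, SUM_M2
from .spike_stats import BinnedRaster, MomentSet, pair_index, three_point, triple_index

__all__ = [
    "KPairwiseModel",
    "LearningSchedule",
    "SamplerConfig",
    "SampleStats",
    "ExactResult",
    "BMDivergenceError",
    "random_model",
    "independent_model",
    "energy",
    "delta_energy",
    "enumerate_exact",
    "exact_three_point",
    "metropolis_moments",
    "bm_fit",
    "sample_raster",
    "predict_three_point",
]

ENUMERATION_LIMIT = 20


@dataclass
class KPairwiseModel:
    """Fields, couplings and synchrony potentials of the K-pairwise model."""

    h: np.ndarray                  # (N,)
    J: np.ndarray                  # (N, N) symmetric, zero diagonal
    V: np.ndarray                  # (N+1,), V[0] == 0
    fitted_mask: np.ndarray | None = None   # (N+1,) bool: which V_K were learned

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        n = self.h.size
        if self.J.shape != (n, n):
            raise ValueError("J must be N x N")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.diag(self.J) != 0):
            raise ValueError("J must have a zero diagonal")
        if self.V.shape != (n + 1,):
            raise ValueError("V must have N+1 entries")
        if self.V[0] != 0:
            raise ValueError("V[0] is the gauge-fixed potential and must be 0")
        if self.fitted_mask is None:
            self.fitted_mask = np.zeros(n + 1, dtype=np.bool_)

    @property
    def n_spins(self) -> int:
        return int(self.h.size)

    def copy(self) -> "KPairwiseModel":
        return KPairwiseModel(self.h.copy(), self.J.copy(), self.V.copy(),
                              self.fitted_mask.copy())


def independent_model(h: np.ndarray) -> KPairwiseModel:
    h = np.asarray(h, dtype=float)
    n = h.size
    return KPairwiseModel(h, np.zeros((n, n)), np.zeros(n + 1))


def random_model(n: int, seed: int, h_scale: float = 0.5, j_scale: float = 0.3,
                 v_scale: float = 0.0) -> KPairwiseModel:
    """Random model for oracle tests; couplings scale as j_scale/sqrt(N)."""
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, h_scale, n)
    J = rng.normal(0.0, j_scale / np.sqrt(n), (n, n))
    J = np.triu(J, 1)
    J = J + J.T
    V = rng.normal(0.0, v_scale, n + 1)
    V[0] = 0.0
    return KPairwiseModel(h, J, V)


def energy(model: KPairwiseModel, sigma: np.ndarray) -> float:
    """H(sigma); each unordered pair counted once."""
    sigma = np.asarray(sigma, dtype=np.float64)
    k = int((sigma > 0).sum())
    return float(-model.h @ sigma - 0.5 * sigma @ model.J @ sigma - model.V[k])


def delta_energy(model: KPairwiseModel, sigma: np.ndarray, flip_index: int) -> float:
    """H(sigma with spin flipped) - H(sigma) in O(N)."""
    sigma = np.asarray(sigma, dtype=np.float64)
    i = flip_index
    si = sigma[i]
    k = int((sigma > 0).sum())
    k_new = k - (1 if si > 0 else -1)
    return float(2.0 * model.h[i] * si + 2.0 * si * (model.J[i] @ sigma)
                 + model.V[k] - model.V[k_new])


# --------------------------------------------------------------------------
# exact enumeration (oracle for N <= 20)

@dataclass
class ExactResult:
    log_z: float
    moments: MomentSet
    mean_energy: float
    var_energy: float
    mean_mag: float
    var_mag: float

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def cv(self, temperature: float) -> float:
        return self.var_energy / temperature ** 2

    def chi(self, temperature: float) -> float:
        return self.var_mag / temperature


def _state_chunks(n: int, chunk: int = 1 << 16):
    total = 1 << n
    bits = np.arange(n)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        yield ((idx[:, None] >> bits) & 1).astype(np.float64) * 2.0 - 1.0


def enumerate_exact(model: KPairwiseModel, temperature: float = 1.0) -> ExactResult:
    """Exact partition function and moments by summing all 2^N states."""
    n = model.n_spins
    if n > ENUMERATION_LIMIT:
        raise ValueError(f"exact enumeration limited to N <= {ENUMERATION_LIMIT}")
    # first pass: log-sum-exp shift
    max_neg = -np.inf
    energies, kk = [], []
    for s in _state_chunks(n):
        e = -(s @ model.h) - 0.5 * np.einsum("bi,ij,bj->b", s, model.J, s)
        k = ((s > 0).sum(axis=1)).astype(np.int64)
        e -= model.V[k]
        energies.append(e)
        kk.append(k)
        max_neg = max(max_neg, float((-e / temperature).max()))
    log_z = 0.0
    acc = {"z": 0.0, "m1": np.zeros(n), "m2": np.zeros((n, n)),
           "pk": np.zeros(n + 1), "e": 0.0, "e2": 0.0, "m": 0.0, "msq": 0.0}
    for s, e, k in zip(_state_chunks(n), energies, kk):
        w = np.exp(-e / temperature - max_neg)
        acc["z"] += w.sum()
        acc["m1"] += w @ s
        acc["m2"] += (s * w[:, None]).T @ s
        acc["pk"] += np.bincount(k, weights=w, minlength=n + 1)
        acc["e"] += w @ e
        acc["e2"] += w @ e ** 2
        mag = s.sum(axis=1)
        acc["m"] += w @ mag
        acc["msq"] += w @ mag ** 2
    z = acc["z"]
    log_z = float(np.log(z) + max_neg)
    mean = acc["m1"] / z
    gram = acc["m2"] / z
    iu, ju = pair_index(n)
    pair = gram[iu, ju]
    moments = MomentSet(n, 1 << n, mean, pair, pair - mean[iu] * mean[ju],
                        acc["pk"] / z)
    me, me2 = acc["e"] / z, acc["e2"] / z
    mm, mm2 = acc["m"] / z, acc["msq"] / z
    return ExactResult(log_z, moments, float(me), float(me2 - me ** 2),
                       float(mm), float(mm2 - mm ** 2))


def exact_three_point(model: KPairwiseModel, temperature: float = 1.0) -> np.ndarray:
    """Exact connected three-point correlations, aligned with triple_index."""
    n = model.n_spins
    if n > 16:
        raise ValueError("exact three-point correlations limited to N <= 16")
    s = np.vstack(list(_state_chunks(n)))
    e = -(s @ model.h) - 0.5 * np.einsum("bi,ij,bj->b", s, model.J, s)
    e -= model.V[((s > 0).sum(axis=1)).astype(np.int64)]
    w = np.exp(-e / temperature - (-e / temperature).max())
    w /= w.sum()
    x = s - w @ s
    out = []
    for i in range(n - 2):
        y = x[:, i + 1:] * x[:, [i]]
        m = (y * w[:, None]).T @ x[:, i + 1:]
        ju, ku = np.triu_indices(n - i - 1, k=1)
        out.append(m[ju, ku])
    return np.concatenate(out) if out else np.empty(0)


# --------------------------------------------------------------------------
# Metropolis sampling

@dataclass
class SamplerConfig:
    """Monte Carlo budget per chain and chain layout.

    ``n_samples`` counts post-burn-in flip attempts per chain; ``burn_in``
    defaults to 150 N attempts; pair moments are accumulated every
    ``pair_stride`` attempts (default: every sweep of N attempts for
    N > 16, every attempt otherwise)."""

    n_samples: int = 300_000
    burn_in: int | None = None
    n_chains: int = 10
    seed: int = 0
    stride: int = 1
    pair_stride: int | None = None

    def resolve(self, n: int) -> tuple[int, int]:
        burn = 150 * n if self.burn_in is None else self.burn_in
        ps = self.pair_stride if self.pair_stride is not None else (1 if n <= 16 else n)
        return burn, ps


@dataclass
class SampleStats:
    """Energy/magnetization fluctuation summaries across chains."""

    mean_energy: float
    var_energy: float
    mean_mag: float
    var_mag: float
    cv: float
    chi: float
    se_cv: float
    se_chi: float
    acceptance: float
    per_chain_cv: np.ndarray
    per_chain_chi: np.ndarray


def _chain_seeds(cfg: SamplerConfig, n_chains: int) -> list[int]:
    ss = np.random.SeedSequence(int(cfg.seed))
    return [int(x & 0x7FFFFFFF) for x in ss.generate_state(n_chains, dtype=np.uint32)]


def _init_sigma(n: int, seed: int, mode: str) -> np.ndarray:
    if mode == "silent":
        return -np.ones(n, dtype=np.int64)
    rng = np.random.default_rng(seed)
    return rng.choice(np.array([-1, 1], dtype=np.int64), size=n)


def metropolis_moments(
    model: KPairwiseModel,
    temperature: float = 1.0,
    cfg: SamplerConfig | None = None,
    init_mode: str = "random",
) -> tuple[MomentSet, SampleStats]:
    """Estimate model moments and fluctuations by Metropolis sampling.

    Runs ``cfg.n_chains`` independent chains; the returned moments are
    chain means, with standard errors across chains.  ``Cv`` and ``chi``
    follow the fluctuation-dissipation relations Var(H)/T^2 and Var(M)/T,
    with H always the T=1 Hamiltonian (temperature enters the acceptance
    rule and the prefactors only).
    """
    cfg = cfg or SamplerConfig()
    n = model.n_spins
    burn, pair_stride = cfg.resolve(n)
    seeds = _chain_seeds(cfg, cfg.n_chains)
    iu, ju = pair_index(n)
    means, pairs, pks, cvs, chis, accs = [], [], [], [], [], []
    es, ms = [], []
    for c, s0 in enumerate(seeds):
        sigma = _init_sigma(n, s0 ^ 0x5EED, init_mode)
        sum_s = np.zeros(n)
        sum_pair = np.zeros((n, n))
        hist_k = np.zeros(n + 1)
        scal = np.zeros(8)
        _kernels.metropolis_kernel(model.h, model.J, model.V, float(temperature),
                                   sigma, int(cfg.n_samples), int(burn),
                                   int(cfg.stride), int(pair_stride), s0,
                                   sum_s, sum_pair, hist_k, scal)
        ns, npair = scal[N_SAMP], scal[N_PAIR]
        means.append(sum_s / ns)
        pairs.append((sum_pair + sum_pair.T)[iu, ju] / npair)
        pks.append(hist_k / ns)
        me, me2 = scal[SUM_E] / ns, scal[SUM_E2] / ns
        mm, mm2 = scal[SUM_M] / ns, scal[SUM_M2] / ns
        es.append((me, me2 - me ** 2))
        ms.append((mm, mm2 - mm ** 2))
        cvs.append((me2 - me ** 2) / temperature ** 2)
        chis.append((mm2 - mm ** 2) / temperature)
        accs.append(scal[N_ACC] / (burn + cfg.n_samples))
    means, pairs, pks = np.array(means), np.array(pairs), np.array(pks)
    nc = cfg.n_chains
    mean = means.mean(axis=0)
    pair = pairs.mean(axis=0)
    pk = pks.mean(axis=0)

    def se(a):
        return a.std(axis=0, ddof=1) / np.sqrt(nc) if nc > 1 else np.zeros(a.shape[1:])

    moments = MomentSet(n, int(cfg.n_samples // cfg.stride * nc), mean, pair,
                        pair - mean[iu] * mean[ju], pk,
                        se_mean=se(means), se_pair=se(pairs), se_pk=se(pks))
    cvs, chis = np.array(cvs), np.array(chis)
    stats = SampleStats(
        mean_energy=float(np.mean([e[0] for e in es])),
        var_energy=float(np.mean([e[1] for e in es])),
        mean_mag=float(np.mean([m[0] for m in ms])),
        var_mag=float(np.mean([m[1] for m in ms])),
        cv=float(cvs.mean()), chi=float(chis.mean()),
        se_cv=float(cvs.std(ddof=1) / np.sqrt(nc)) if nc > 1 else 0.0,
        se_chi=float(chis.std(ddof=1) / np.sqrt(nc)) if nc > 1 else 0.0,
        acceptance=float(np.mean(accs)),
        per_chain_cv=cvs, per_chain_chi=chis,
    )
    return moments, stats


def sample_raster(model: KPairwiseModel, n_bins: int, seed: int = 0,
                  temperature: float = 1.0, thin: int | None = None,
                  init_mode: str = "random") -> BinnedRaster:
    """Draw a raster of Metropolis states, one column per kept state.

    States are thinned by ``thin`` flip attempts (default N) after a
    burn-in of 150 N attempts."""
    n = model.n_spins
    if n_bins == 0:
        return BinnedRaster(np.empty((n, 0), dtype=np.int8), 1.0)
    thin = thin or n
    s0 = _chain_seeds(SamplerConfig(seed=seed), 1)[0]
    sigma = _init_sigma(n, s0 ^ 0x5EED, init_mode)
    out = np.empty((n, int(n_bins)), dtype=np.int8)
    _kernels.raster_kernel(model.h, model.J, model.V, float(temperature),
                           sigma, int(n_bins), int(thin), 150 * n, s0, out)
    return BinnedRaster(out, 1.0)


def predict_three_point(
    model: KPairwiseModel, cfg: SamplerConfig | None = None, temperature: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Model-predicted connected three-point correlations T_ijk.

    Sampled over ``cfg.n_chains`` independent random-start chains; returns
    (mean, standard error) aligned with ``triple_index(N)``."""
    cfg = cfg or SamplerConfig(n_chains=100, n_samples=30_000)
    n = model.n_spins
    rows = max(int(cfg.n_samples) // n, 10)
    seeds = _chain_seeds(cfg, cfg.n_chains)
    vals = []
    for s0 in seeds:
        raster = sample_raster(model, rows, seed=s0, temperature=temperature)
        vals.append(three_point(raster))
    vals = np.array(vals)
    se = vals.std(axis=0, ddof=1) / np.sqrt(cfg.n_chains) if cfg.n_chains > 1 else np.zeros(vals.shape[1])
    return vals.mean(axis=0), se


# --------------------------------------------------------------------------
# Boltzmann-machine learning

class BMDivergenceError(RuntimeError):
    def __init__(self, message: str, trace: dict):
        super().__init__(message)
        self.trace = trace


@dataclass
class LearningSchedule:
    """Learning-rate schedule and stopping rules for the inverse problem.

    theta(n) = theta0 * n**-alpha; couplings learn at theta/2; after
    ``vk_rate_switch_iter`` iterations the V_K rate becomes
    theta / P(K)_data for the fitted K.  Only V_K with
    P(K)_data > ``pk_fit_threshold`` are learned (None: 1e-5 when the data
    have >= 1e6 bins, 1e-4 otherwise)."""

    theta0: float = 0.1
    alpha: float = 0.6
    theta_j_ratio: float = 0.5
    vk_rate_switch_iter: int = 5000
    max_iters: int = 200_000
    mc_samples: int = 300_000
    pk_fit_threshold: float | None = None
    tol_mean: float = 5e-3
    tol_pair: float = 5e-3
    tol_pk_rel: float = 0.1
    #: fraction of final iterations over which parameters are averaged
    #: (Robbins-Monro tail averaging; cancels the Monte Carlo gradient noise)
    average_tail: float = 0.2

    def threshold_for(self, n_bins: int) -> float:
        if self.pk_fit_threshold is not None:
            return self.pk_fit_threshold
        return 1e-5 if n_bins >= 1_000_000 else 1e-4


def bm_fit(
    data: MomentSet,
    schedule: LearningSchedule | None = None,
    cfg: SamplerConfig | None = None,
    seed: int = 0,
    fit_pk: bool = True,
    verbose: bool = False,
) -> tuple[KPairwiseModel, dict]:
    """Infer a K-pairwise model from data moments by BM learning.

    Initialization: h_i = <sigma_i>_data, J = 0, V = 0.  Each iteration
    samples the current model with one persistent Metropolis chain
    (burn-in applied every iteration) and moves every parameter against
    its moment discrepancy.  Stops when the mean, pair and fitted-P(K)
    discrepancies are all within tolerance, or at ``max_iters``.
    With ``fit_pk=False`` the synchrony constraint is dropped (plain
    pairwise model).

    Returns the model and a trace dictionary with per-iteration maximum
    discrepancies.
    """
    sched = schedule or LearningSchedule()
    n = data.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels")
    if data.n_bins < 10_000:
        raise ValueError("need at least 1e4 bins of data for a stable fit")
    cfg = cfg or SamplerConfig(n_samples=sched.mc_samples, n_chains=1)
    burn, pair_stride = cfg.resolve(n)
    iu, ju = pair_index(n)

    thr = sched.threshold_for(data.n_bins)
    mask = (data.pk > thr) if fit_pk else np.zeros(n + 1, dtype=bool)
    mask[0] = False  # gauge: V_0 pinned to zero

    h = data.mean_sigma.astype(float).copy()
    J = np.zeros((n, n))
    V = np.zeros(n + 1)
    sigma = _init_sigma(n, seed ^ 0xBF17, "random")
    seeds = _chain_seeds(replace(cfg, seed=seed), sched.max_iters)

    trace = {"max_dmean": [], "max_dpair": [], "max_dpk_rel": [], "iters": 0}
    safe_pk = np.where(mask, data.pk, 1.0)
    tail_start = int(np.ceil(sched.max_iters * (1.0 - sched.average_tail))) or 1
    avg = {"h": np.zeros(n), "J": np.zeros((n, n)), "V": np.zeros(n + 1), "k": 0}
    for it in range(1, sched.max_iters + 1):
        sum_s = np.zeros(n)
        sum_pair = np.zeros((n, n))
        hist_k = np.zeros(n + 1)
        scal = np.zeros(8)
        _kernels.metropolis_kernel(h, J, V, 1.0, sigma, int(cfg.n_samples),
                                   int(burn), int(cfg.stride), int(pair_stride),
                                   seeds[it - 1], sum_s, sum_pair, hist_k, scal)
        m_mean = sum_s / scal[N_SAMP]
        m_pair = (sum_pair + sum_pair.T)[iu, ju] / scal[N_PAIR]
        m_pk = hist_k / scal[N_SAMP]

        d_mean = m_mean - data.mean_sigma
        d_pair = m_pair - data.pair_sigma
        d_pk = m_pk - data.pk

        theta = sched.theta0 * it ** (-sched.alpha)
        h -= theta * d_mean
        upd = sched.theta_j_ratio * theta * d_pair
        J[iu, ju] -= upd
        J[ju, iu] -= upd
        if fit_pk:
            rate = theta if it <= sched.vk_rate_switch_iter else theta / safe_pk
            V = V - np.where(mask, rate * d_pk, 0.0)
            V[~mask] = 0.0
            V[0] = 0.0

        md = float(np.abs(d_mean).max())
        mp = float(np.abs(d_pair).max())
        mk = float(np.abs(d_pk[mask] / data.pk[mask]).max()) if mask.any() else 0.0
        trace["max_dmean"].append(md)
        trace["max_dpair"].append(mp)
        trace["max_dpk_rel"].append(mk)
        trace["iters"] = it
        if verbose and it % 100 == 0:
            print(f"iter {it}: |dmean|={md:.4f} |dpair|={mp:.4f} |dpk|/pk={mk:.3f}")
        big = max(np.abs(h).max(), np.abs(J).max(), np.abs(V).max())
        if big > 1e3:
            raise BMDivergenceError(
                f"BM learning diverged at iteration {it} (|param| = {big:.1f})",
                trace,
            )
        if it >= tail_start:
            avg["h"] += h
            avg["J"] += J
            avg["V"] += V
            avg["k"] += 1
        if md < sched.tol_mean and mp < sched.tol_pair and mk < sched.tol_pk_rel:
            break
    for key in ("max_dmean", "max_dpair", "max_dpk_rel"):
        trace[key] = np.asarray(trace[key])
    if avg["k"] > 1:
        h, J, V = avg["h"] / avg["k"], avg["J"] / avg["k"], avg["V"] / avg["k"]
        V[~mask] = 0.0
        V[0] = 0.0
    model = KPairwiseModel(h, J, V, mask)
    return model, trace
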