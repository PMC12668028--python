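"""Binned +/-1 rasters and the time-averaged statistics constrained by the
maximum-entropy models: per-channel means <sigma_i>, pairwise moments
<sigma_i sigma_j>, covariances C_ij, the synchrony distribution P(K), and
quantities derived from them (firing rates, three-point correlations,
allometric scaling of the total rate)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinnedRaster",
    "MomentSet",
    "AllometryResult",
    "bin_events",
    "compute_moments",
    "three_point",
    "firing_rates",
    "allometric_fit",
    "pair_index",
    "triple_index",
]


@dataclass
class BinnedRaster:
    """Channels x bins matrix of +/-1 spin variables.

    A bin is +1 for a channel when the channel fired at least once during
    the bin.  ``bin_width`` is in units of the event clock (timesteps for
    model data, milliseconds for recordings with a 1 ms clock)."""

    sigma: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.int8)
        if self.sigma.ndim != 2:
            raise ValueError("sigma must be 2-D (channels x bins)")
        if self.sigma.size and not np.all(np.abs(self.sigma) == 1):
            raise ValueError("raster entries must be +/-1")

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sigma.shape[1]


@dataclass
class MomentSet:
    """Constrained statistics of a raster, with blocked standard errors.

    Pairwise entries are stored once, in lexicographic (i<j) order (see
    :func:`pair_index`)."""

    n_channels: int
    n_bins: int
    mean_sigma: np.ndarray       # (N,)
    pair_sigma: np.ndarray       # (N*(N-1)/2,)
    corr: np.ndarray             # (N*(N-1)/2,)  C_ij = <si sj> - <si><sj>
    pk: np.ndarray               # (N+1,)
    se_mean: np.ndarray | None = None
    se_pair: np.ndarray | None = None
    se_pk: np.ndarray | None = None


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of the upper triangle in storage order."""
    return np.triu_indices(n, k=1)


def triple_index(n: int) -> np.ndarray:
    """All unordered triples (i<j<k) in lexicographic order, shape (M, 3)."""
    idx = [(i, j, k) for i in range(n) for j in range(i + 1, n) for k in range(j + 1, n)]
    return np.array(idx, dtype=np.int64).reshape(-1, 3)


def bin_events(events, bin_width: float) -> BinnedRaster:
    """Bin a spike event list into a +/-1 raster.

    A channel is +1 in bin k if it has at least one event with
    ``floor(t / bin_width) == k``; the trailing partial bin is dropped.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be at least one clock unit")
    n_bins = int(events.n_timesteps // bin_width)
    sigma = np.full((events.n_channels, n_bins), -1, dtype=np.int8)
    if n_bins and len(events):
        b = (events.times // bin_width).astype(np.int64)
        keep = b < n_bins
        sigma[events.channels[keep], b[keep]] = 1
    return BinnedRaster(sigma, float(bin_width))


def _blocked_se(values: np.ndarray, axis_blocks: list[np.ndarray]) -> np.ndarray:
    stack = np.stack(axis_blocks)
    nb = stack.shape[0]
    return stack.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.zeros_like(values)


def compute_moments(raster: BinnedRaster, n_blocks: int = 100) -> MomentSet:
    """Means, pairwise moments, covariances and P(K) of a raster.

    Standard errors come from up to ``n_blocks`` contiguous blocks of bins,
    which respects the temporal correlation of the data better than
    per-bin resampling.
    """
    n, nb = raster.n_channels, raster.n_bins
    if nb == 0:
        raise ValueError("raster has no bins")
    s = raster.sigma.astype(np.float64)
    mean = s.mean(axis=1)
    gram = (s @ s.T) / nb
    iu, ju = pair_index(n)
    pair = gram[iu, ju]
    corr = pair - mean[iu] * mean[ju]
    k = ((raster.sigma == 1).sum(axis=0)).astype(np.int64)
    pk = np.bincount(k, minlength=n + 1).astype(np.float64) / nb

    nblk = min(n_blocks, nb)
    bounds = np.linspace(0, nb, nblk + 1).astype(int)
    means_b, pairs_b, pks_b = [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        sb = s[:, a:b]
        means_b.append(sb.mean(axis=1))
        pairs_b.append(((sb @ sb.T) / (b - a))[iu, ju])
        pks_b.append(np.bincount(k[a:b], minlength=n + 1) / (b - a))
    return MomentSet(
        n, nb, mean, pair, corr, pk,
        se_mean=_blocked_se(mean, means_b),
        se_pair=_blocked_se(pair, pairs_b),
        se_pk=_blocked_se(pk, pks_b),
    )


def three_point(raster: BinnedRaster | np.ndarray) -> np.ndarray:
    """Connected three-point correlations T_ijk for all triples i<j<k.

    T_ijk = <(s_i - <s_i>)(s_j - <s_j>)(s_k - <s_k>)>, symmetric under any
    permutation of the indices.  Returns an array aligned with
    :func:`triple_index`; empty for fewer than 3 channels.
    """
    sigma = raster.sigma if isinstance(raster, BinnedRaster) else np.asarray(raster)
    n, nb = sigma.shape
    if n < 3:
        return np.empty(0)
    x = sigma.astype(np.float64)
    x -= x.mean(axis=1, keepdims=True)
    out = []
    for i in range(n - 2):
        y = x[i + 1:] * x[i]           # (n-i-1, nb)
        m = (y @ x[i + 1:].T) / nb     # (n-i-1, n-i-1): <x_i x_j x_k>
        ju, ku = np.triu_indices(n - i - 1, k=1)
        out.append(m[ju, ku])
    return np.concatenate(out)


def firing_rates(raster: BinnedRaster, bin_seconds: float | None = None):
    """Per-channel firing rates r_i = (<sigma_i> + 1) / (2 * dt_b) and their
    total n_a = sum_i r_i.

    With ``bin_seconds`` the rates are in Hz; otherwise per time bin.
    """
    mean = raster.sigma.mean(axis=1, dtype=np.float64) if raster.n_bins else np.full(raster.n_channels, -1.0)
    width = bin_seconds if bin_seconds is not None else 1.0
    r = (mean + 1.0) / (2.0 * width)
    return r, float(r.sum())


@dataclass
class AllometryResult:
    n_values: np.ndarray
    na_values: np.ndarray
    eta: float
    eta_se: float


def allometric_fit(
    n_values, na_values, n_boot: int = 1000, seed: int = 0
) -> AllometryResult:
    """Fit the allometric exponent eta of n_a ~ N**eta on log-log scale.

    The fit is ordinary least squares in (log N, log n_a); the uncertainty
    is bootstrapped over the (N, n_a) points (repeated N values act as
    replicates).
    """
    nv = np.asarray(n_values, dtype=float)
    na = np.asarray(na_values, dtype=float)
    if np.any(na <= 0) or np.any(nv <= 0):
        raise ValueError("allometric fit needs positive N and n_a")
    x, y = np.log(nv), np.log(na)
    eta = float(np.polyfit(x, y, 1)[0])
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.unique(x[idx]).size < 2:
            continue
        slopes.append(np.polyfit(x[idx], y[idx], 1)[0])
    se = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0
    return AllometryResult(nv, na, eta, se)
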