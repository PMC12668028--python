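"""Integrate-and-fire network with short- and long-term plasticity.

The model is a directed, spatially embedded scale-free network of
non-leaky integrate-and-fire units.  A neuron fires when its potential
crosses the threshold ``v_c = 1`` and transmits ``±v_i * u_i * g_ij`` to each
post-synaptic target (minus sign for inhibitory senders).  Firing depletes
the pre-synaptic resource pool ``u_i`` by a factor ``1 - delta_u`` and is
followed by a one-timestep refractory period.  Between avalanches every
resource pool recovers by ``delta_u_rec`` (capped at 1), and a weak external
drive ``delta_v`` is injected into one random neuron per quiescent timestep.
Tuning ``delta_u_rec`` moves the avalanche statistics between subcritical
(exponential), critical (power law with size-dependent cutoff) and
supercritical (excess of system-spanning avalanches) regimes.

Long-term (Hebbian-like) plasticity strengthens each synapse in proportion
to the potential change it causes, and uniformly depresses all synapses at
the end of every avalanche by the mean increment per synapse; strengths are
confined to ``[g_min, 1]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "DynamicsParams",
    "NetworkTopology",
    "NeuronState",
    "AvalancheCatalog",
    "SpikeEventList",
    "RecordingResult",
    "CalibrationResult",
    "DENSITY",
    "DELTA_U_REC_CRIT",
    "build_network",
    "advance_avalanche_step",
    "run_recording",
    "pretrain",
    "calibrate_delta_u_rec",
    "delta_u_rec_for_state",
]

#: neurons per unit volume; fixes the cube side L = (N / DENSITY)**(1/3)
DENSITY = 0.016
#: fraction of inhibitory neurons
P_INHIBITORY = 0.20
#: decay length of the distance-dependent connection probability
R0 = 5.0
#: out-degree exponent, P(k) ~ k**-2
DEGREE_EXPONENT = 2.0

#: resource recovery per avalanche that places an N-neuron network at the
#: critical point, re-derived with :func:`calibrate_delta_u_rec` (one value
#: per system size used in the finite-size analyses).  Off-critical runs use
#: 0.1x (subcritical) and 10x (supercritical) these values.
DELTA_U_REC_CRIT = {
    20: 0.0038,
    40: 0.0051,
    60: 0.0042,
    80: 0.0042,
    100: 0.0032,
}


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the avalanche dynamics (all dimensionless)."""

    delta_u_rec: float
    v_threshold: float = 1.0
    delta_u: float = 0.05
    delta_v: float = 0.1
    beta: float = 0.04
    g_min: float = 1e-5
    pretrain_avalanches: int = 10_000

    def __post_init__(self) -> None:
        for name in ("delta_u_rec", "v_threshold", "delta_u", "delta_v", "beta", "g_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.delta_u >= 1:
            raise ValueError("delta_u must be < 1")


@dataclass
class NetworkTopology:
    """Directed weighted network in CSR (indptr/targets) layout."""

    n_neurons: int
    side: float
    positions: np.ndarray          # (N, 3) in [0, L]^3
    is_inhibitory: np.ndarray      # (N,) bool
    indptr: np.ndarray             # (N+1,) int64; edges of i are indptr[i]:indptr[i+1]
    targets: np.ndarray            # (Ns,) int32
    strengths: np.ndarray          # (Ns,) float64 in [g_min, 1]

    @property
    def n_synapses(self) -> int:
        return int(self.targets.size)

    def out_edges(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Targets and strengths of neuron ``i``."""
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.targets[sl], self.strengths[sl]

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            self.n_neurons, self.side, self.positions.copy(),
            self.is_inhibitory.copy(), self.indptr.copy(),
            self.targets.copy(), self.strengths.copy(),
        )


@dataclass
class NeuronState:
    """Membrane potentials, synaptic resources and refractory flags."""

    v: np.ndarray
    u: np.ndarray
    refractory: np.ndarray

    @classmethod
    def resting(cls, n: int) -> "NeuronState":
        return cls(np.zeros(n), np.ones(n), np.zeros(n, dtype=np.bool_))

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy(), self.refractory.copy())


@dataclass
class AvalancheCatalog:
    """Start time, duration (timesteps) and size (spike count) per avalanche."""

    start: np.ndarray
    duration: np.ndarray
    size: np.ndarray
    participants: list | None = None

    def __len__(self) -> int:
        return int(self.start.size)


@dataclass
class SpikeEventList:
    """Time-ordered (timestep, channel) firing events.

    ``dt_ms`` is the physical duration of one clock tick when the events
    come from a recording; ``None`` for model time."""

    times: np.ndarray
    channels: np.ndarray
    n_channels: int
    n_timesteps: int
    dt_ms: float | None = None

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RecordingResult:
    events: SpikeEventList
    catalog: AvalancheCatalog
    topology: NetworkTopology
    state: NeuronState


def degree_range(n_neurons: int) -> tuple[int, int]:
    return (2, 20) if n_neurons <= 100 else (2, 100)


def build_network(n_neurons: int, params: DynamicsParams, seed: int) -> NetworkTopology:
    """Sample a spatial scale-free topology.

    Neurons are placed uniformly in a cube of side ``L = (N/0.016)^(1/3)``;
    20% (rounded) are inhibitory.  Each neuron draws an out-degree k from
    P(k) ~ k^-2 on [k_min, k_max] and selects k distinct targets with
    probability proportional to exp(-r/5) of the Euclidean distance r.
    Initial strengths are uniform in [0.4, 0.6].
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    kmin, kmax = degree_range(n_neurons)
    if n_neurons - 1 < kmin:
        raise ValueError(
            f"cannot place {kmin} out-edges in a network of {n_neurons} neurons"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    L = (n_neurons / DENSITY) ** (1.0 / 3.0)
    pos = rng.uniform(0.0, L, size=(n_neurons, 3))

    n_inh = int(round(P_INHIBITORY * n_neurons))
    inhibitory = np.zeros(n_neurons, dtype=np.bool_)
    inhibitory[rng.choice(n_neurons, size=n_inh, replace=False)] = True

    ks = np.arange(kmin, kmax + 1)
    pk = ks.astype(float) ** -DEGREE_EXPONENT
    pk /= pk.sum()
    degrees = rng.choice(ks, size=n_neurons, p=pk)
    if np.any(degrees > n_neurons - 1):
        warnings.warn("out-degree truncated to the number of available targets")
        degrees = np.minimum(degrees, n_neurons - 1)

    indptr = np.zeros(n_neurons + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(degrees)
    targets = np.empty(indptr[-1], dtype=np.int32)
    for i in range(n_neurons):
        d = np.linalg.norm(pos - pos[i], axis=1)
        w = np.exp(-d / R0)
        w[i] = 0.0
        # weighted sampling without replacement (exponential-keys trick);
        # zero-weight candidates (the neuron itself) get an infinite key
        keys = np.where(w > 0, rng.exponential(size=n_neurons) / np.maximum(w, 1e-300),
                        np.inf)
        order = np.argsort(keys)[: degrees[i]]
        targets[indptr[i]:indptr[i + 1]] = np.sort(order)
    strengths = rng.uniform(0.4, 0.6, size=targets.size)
    return NetworkTopology(n_neurons, L, pos, inhibitory, indptr, targets, strengths)


# --------------------------------------------------------------------------
# dynamics kernel

_STATUS_STEPS = 0          # timestep budget exhausted
_STATUS_AVALANCHES = 1     # avalanche budget exhausted
_STATUS_EV_FULL = 2        # event buffer full
_STATUS_AV_FULL = 3        # avalanche buffer full
_STATUS_GMIN = 4           # a strength first reached g_min (pre-training stop)
_STATUS_STALL = 5          # no avalanche within the stall window


@njit(cache=True)
def _dynamics_kernel(indptr, targets, g, sign, v, u, refrac,
                     vc, du, durec, dv, beta, gmin,
                     max_steps, max_avalanches, plasticity, record,
                     seed, stall_window,
                     ev_t, ev_id, av_start, av_dur, av_size):  # pragma: no cover
    np.random.seed(seed)
    n = v.size
    ns = g.size
    t = 0
    n_ev = 0
    n_av = 0
    in_av = False
    av_t0 = 0
    last_fire = 0
    count = 0
    sum_dg = 0.0
    last_end = 0
    dv_buf = np.zeros(n)
    fired = np.empty(n, dtype=np.int64)
    while True:
        supra = False
        can_fire = False
        for i in range(n):
            if v[i] >= vc:
                supra = True
                if not refrac[i]:
                    can_fire = True
                    break
        if not supra:
            if in_av:
                # avalanche terminates: log it, recover resources, depress
                av_start[n_av] = av_t0
                av_dur[n_av] = last_fire - av_t0 + 1
                av_size[n_av] = count
                n_av += 1
                for i in range(n):
                    ui = u[i] + durec
                    u[i] = 1.0 if ui > 1.0 else ui
                in_av = False
                last_end = t
                if plasticity:
                    dec = sum_dg / ns
                    hit = False
                    for e in range(ns):
                        ge = g[e] - dec
                        if ge <= gmin:
                            ge = gmin
                            hit = True
                        g[e] = ge
                    if hit:
                        return _STATUS_GMIN, t, n_ev, n_av
                if n_av >= max_avalanches:
                    return _STATUS_AVALANCHES, t, n_ev, n_av
                if n_av >= av_start.size:
                    return _STATUS_AV_FULL, t, n_ev, n_av
            if t >= max_steps:
                return _STATUS_STEPS, t, n_ev, n_av
            if t - last_end > stall_window:
                return _STATUS_STALL, t, n_ev, n_av
            for i in range(n):
                refrac[i] = False
            v[np.random.randint(0, n)] += dv
            t += 1
            continue
        # avalanche step
        if not in_av:
            in_av = True
            av_t0 = t
            count = 0
            sum_dg = 0.0
        if not can_fire:
            # only refractory neurons above threshold: let one step elapse
            for i in range(n):
                refrac[i] = False
            t += 1
            continue
        nf = 0
        for i in range(n):
            dv_buf[i] = 0.0
            if v[i] >= vc and not refrac[i]:
                fired[nf] = i
                nf += 1
        for fi in range(nf):
            i = fired[fi]
            amp = sign[i] * v[i] * u[i]
            for e in range(indptr[i], indptr[i + 1]):
                j = targets[e]
                d = amp * g[e]
                dv_buf[j] += d
                if plasticity:
                    dg = beta * abs(d)
                    ge = g[e] + dg
                    if ge > 1.0:
                        dg = 1.0 - g[e]
                        ge = 1.0
                    g[e] = ge
                    sum_dg += dg
        for i in range(n):
            v[i] += dv_buf[i]
            refrac[i] = False
        for fi in range(nf):
            i = fired[fi]
            v[i] = 0.0
            u[i] *= 1.0 - du
            refrac[i] = True
            if record:
                if n_ev >= ev_t.size:
                    return _STATUS_EV_FULL, t, n_ev, n_av
                ev_t[n_ev] = t
                ev_id[n_ev] = i
                n_ev += 1
        count += nf
        last_fire = t
        t += 1


def _kernel_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def advance_avalanche_step(
    state: NeuronState, topo: NetworkTopology, params: DynamicsParams
) -> tuple[NeuronState, np.ndarray]:
    """One synchronous update: all supra-threshold non-refractory neurons fire.

    Returns the new state and the ids that fired.  Inputs from simultaneous
    firers are summed before any thresholding at the next step; each firer
    is reset to v=0, depleted by ``1 - delta_u`` and made refractory for one
    step, while previous refractory flags are cleared.
    """
    v, u, refrac = state.v, state.u, state.refractory
    firing = (v >= params.v_threshold) & ~refrac
    if not np.any(firing):
        raise ValueError("no non-refractory neuron is above threshold")
    fired = np.flatnonzero(firing)
    dv_buf = np.zeros_like(v)
    sign = np.where(topo.is_inhibitory, -1.0, 1.0)
    for i in fired:
        tg, gg = topo.out_edges(i)
        np.add.at(dv_buf, tg, sign[i] * v[i] * u[i] * gg)
    v_new = v + dv_buf
    u_new = u.copy()
    v_new[fired] = 0.0
    u_new[fired] *= 1.0 - params.delta_u
    refrac_new = np.zeros_like(refrac)
    refrac_new[fired] = True
    return NeuronState(v_new, u_new, refrac_new), fired


def apply_long_term_step(
    strengths: np.ndarray,
    edge_dv: np.ndarray,
    params: DynamicsParams,
    normalize: bool = False,
) -> tuple[np.ndarray, float]:
    """Potentiate the synapses used in one firing event.

    ``edge_dv`` holds the post-synaptic potential change caused by each
    synapse (aligned with ``strengths``); each used synapse gains
    ``beta * |dv|``.  Returns the new strengths and the summed increment; the
    caller subtracts ``sum/Ns`` from every synapse at avalanche end (done
    here when ``normalize`` is set) and clips to ``[g_min, 1]``.
    """
    dg = params.beta * np.abs(edge_dv)
    out = np.clip(strengths + dg, None, 1.0)
    total = float(dg.sum())
    if normalize:
        out = np.clip(out - total / strengths.size, params.g_min, 1.0)
    return out, total


def run_recording(
    topo: NetworkTopology,
    params: DynamicsParams,
    *,
    n_timesteps: int | None = None,
    n_avalanches: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    plasticity_on: bool = False,
    record_events: bool = True,
    record_participants: bool = False,
    state: NeuronState | None = None,
    warmup_avalanches: int = 0,
) -> RecordingResult:
    """Drive the network and record spikes and avalanches.

    Quiescent timesteps inject ``delta_v`` into one uniformly random neuron;
    when any potential crosses threshold an avalanche unfolds (external
    drive suspended) until all potentials drop below threshold, after which
    every resource pool recovers by ``delta_u_rec``.  The clock counts both
    quiescent and avalanche timesteps.  With ``plasticity_on`` the long-term
    rule reshapes the strengths and the run stops early if any strength
    reaches ``g_min``.
    """
    if n_timesteps is None and n_avalanches is None:
        raise ValueError("specify n_timesteps and/or n_avalanches")
    max_steps = int(n_timesteps) if n_timesteps is not None else np.iinfo(np.int64).max // 4
    max_av = int(n_avalanches) if n_avalanches is not None else np.iinfo(np.int64).max // 4
    if max_steps == 0 or max_av == 0:
        empty = SpikeEventList(np.empty(0, np.int64), np.empty(0, np.int32),
                               topo.n_neurons, 0)
        cat = AvalancheCatalog(np.empty(0, np.int64), np.empty(0, np.int64),
                               np.empty(0, np.int64), [] if record_participants else None)
        return RecordingResult(empty, cat, topo, state or NeuronState.resting(topo.n_neurons))

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    if warmup_avalanches > 0:
        # relax v/u to their steady state before the measured stretch
        ss_warm, ss = ss.spawn(2)
        warm = run_recording(topo, params, n_avalanches=int(warmup_avalanches),
                             seed=ss_warm, plasticity_on=plasticity_on,
                             record_events=False, state=state)
        topo = warm.topology
        state = warm.state
    kseed = _kernel_seed(ss)
    topo_out = topo.copy() if plasticity_on else topo
    sign = np.where(topo.is_inhibitory, -1.0, 1.0)
    stall_window = int(2_000 * topo.n_neurons * params.v_threshold / params.delta_v)

    ev_cap = int(min(max_steps * 4 + 1024, 50_000_000)) if record_events else 1
    av_cap = int(min(max_av, max(max_steps, 1024)))
    while True:
        st = (state or NeuronState.resting(topo.n_neurons)).copy()
        g = topo_out.strengths.copy() if plasticity_on else topo_out.strengths
        ev_t = np.empty(ev_cap, np.int64)
        ev_id = np.empty(ev_cap, np.int64)
        av_start = np.empty(av_cap, np.int64)
        av_dur = np.empty(av_cap, np.int64)
        av_size = np.empty(av_cap, np.int64)
        status, t_end, n_ev, n_av = _dynamics_kernel(
            topo_out.indptr, topo_out.targets, g, sign,
            st.v, st.u, st.refractory,
            params.v_threshold, params.delta_u, params.delta_u_rec,
            params.delta_v, params.beta, params.g_min,
            max_steps, max_av, plasticity_on, record_events,
            kseed, stall_window,
            ev_t, ev_id, av_start, av_dur, av_size,
        )
        if status == _STATUS_EV_FULL or status == _STATUS_AV_FULL:
            # deterministic rerun with larger buffers
            ev_cap *= 2
            av_cap *= 2
            continue
        break
    if status == _STATUS_STALL:
        raise RuntimeError(
            "dynamics stalled: no avalanche within the stall window; "
            "delta_u_rec is too small for this drive (delta_v="
            f"{params.delta_v})"
        )
    if plasticity_on:
        topo_out.strengths = g
    events = SpikeEventList(ev_t[:n_ev].copy(), ev_id[:n_ev].astype(np.int32),
                            topo.n_neurons, int(t_end))
    participants = None
    if record_participants and record_events:
        participants = []
        for a in range(n_av):
            lo = np.searchsorted(events.times, av_start[a])
            hi = np.searchsorted(events.times, av_start[a] + av_dur[a])
            participants.append(np.unique(events.channels[lo:hi]))
    catalog = AvalancheCatalog(av_start[:n_av].copy(), av_dur[:n_av].copy(),
                               av_size[:n_av].copy(), participants)
    return RecordingResult(events, catalog, topo_out, st)


def pretrain(
    topo: NetworkTopology, params: DynamicsParams, seed: int | np.random.SeedSequence
) -> NetworkTopology:
    """Shape the strength distribution with long-term plasticity.

    Runs the plastic dynamics for ``params.pretrain_avalanches`` avalanches,
    stopping early the first time a strength reaches ``g_min``.  The
    network is first settled into its stationary activity regime with the
    plasticity off, so that the initial charging transient (one giant
    avalanche from the fully rested state) does not wipe out the strength
    distribution through the end-of-avalanche depression step.
    Measurement runs afterwards keep the plasticity off.
    """
    if params.pretrain_avalanches == 0:
        return topo
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    ss_settle, ss_plastic = ss.spawn(2)
    settled = run_recording(
        topo, params, n_avalanches=500,
        seed=ss_settle, plasticity_on=False, record_events=False,
    )
    res = run_recording(
        topo, params,
        n_avalanches=params.pretrain_avalanches,
        seed=ss_plastic, plasticity_on=True, record_events=False,
        state=settled.state,
    )
    return res.topology


@dataclass
class CalibrationResult:
    estimate: float
    grid: np.ndarray
    labels: list
    n_neurons: int


def delta_u_rec_for_state(n_neurons: int, dyn_state: str,
                          crit_value: float | None = None) -> float:
    """Recovery increment for a named dynamical state at size ``n_neurons``.

    ``crit_value`` overrides the calibrated table ``DELTA_U_REC_CRIT``;
    subcritical and supercritical runs use 0.1x and 10x the critical value.
    """
    if crit_value is None:
        if n_neurons not in DELTA_U_REC_CRIT:
            raise KeyError(
                f"no calibrated delta_u_rec for N={n_neurons}; "
                "run calibrate_delta_u_rec or pass crit_value"
            )
        crit_value = DELTA_U_REC_CRIT[n_neurons]
    factor = {"subcritical": 0.1, "sub": 0.1,
              "critical": 1.0, "crit": 1.0,
              "supercritical": 10.0, "super": 10.0}[dyn_state]
    return crit_value * factor


def calibrate_delta_u_rec(
    n_neurons: int,
    params_like: DynamicsParams | None = None,
    seed: int = 0,
    *,
    grid: Sequence[float] | None = None,
    n_avalanches: int = 3000,
    refine: bool = True,
) -> CalibrationResult:
    """Scan ``delta_u_rec`` for the critical point of the avalanche dynamics.

    Each candidate is pre-trained and then measured for ``n_avalanches``
    avalanches; the avalanche size/duration distributions are classified
    and the geometric midpoint of the critical plateau is returned.  A
    second, finer scan brackets the first estimate.
    """
    from .avalanches import classify_state, distributions

    if grid is None:
        grid = np.geomspace(1e-4, 1e-1, 37)  # 12 points per decade, 3 decades
    grid = np.asarray(grid, dtype=float)
    base = params_like or DynamicsParams(delta_u_rec=grid[0])
    ss = np.random.SeedSequence(int(seed))
    ss_topo, ss_dyn = ss.spawn(2)
    topo0 = build_network(n_neurons, base, _kernel_seed(ss_topo))

    def scan(values: np.ndarray) -> list:
        labels = []
        for val in values:
            p = replace(base, delta_u_rec=float(val))
            topo = pretrain(topo0.copy(), p, ss_dyn)
            res = run_recording(topo, p, n_avalanches=n_avalanches,
                                seed=ss_dyn, record_events=False,
                                warmup_avalanches=500)
            try:
                lab = classify_state(distributions(res.catalog), n_neurons).label
            except ValueError:
                lab = "unstable"
            labels.append(lab)
        return labels

    labels = scan(grid)
    crit = [g for g, lab in zip(grid, labels) if lab == "critical"]
    if not crit:
        detail = ", ".join(f"{g:.2e}:{lab}" for g, lab in zip(grid, labels))
        raise RuntimeError(f"no candidate classified critical ({detail})")
    est = float(np.sqrt(min(crit) * max(crit)))
    if refine:
        fine = np.geomspace(est / 2.0, est * 2.0, 9)
        flabels = scan(fine)
        fcrit = [g for g, lab in zip(fine, flabels) if lab == "critical"]
        if fcrit:
            est = float(np.sqrt(min(fcrit) * max(fcrit)))
        grid = np.concatenate([grid, fine])
        labels = labels + flabels
    return CalibrationResult(est, grid, labels, n_neurons)
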