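"""Synthetic spiking networks with planted triadic motifs.

The generator emulates the statistical structure of dense multielectrode
recordings from cortical cultures that the analysis modules assume:

* lognormal per-neuron baseline rates with mean ~2 Hz (80% below 3 Hz),
* population bursts of 1-10 s separated by ~10 s, shared across neurons,
* sparse directed excitatory coupling (~1% edge density) with known ground
  truth, including planted synergistic triads of chosen motif class.

Dynamics are discrete-time conditionally-Bernoulli at a 1 ms step: neuron i
spikes at step t with probability

    p_i(t) = 1 - exp(-( r_i * g(t) * dt + sum_j w_ji * x_j(t - d_ji) + c * 1{>=2 arrivals} ))

where ``r_i`` is the baseline rate (optionally homeostatically reduced so
realized rates track the drawn targets), ``g(t)`` the shared burst gain
(normalized so its time average is 1, with ramped transitions), ``w_ji``
the hazard increment a presynaptic spike contributes after its edge delay,
and ``c`` an optional supralinear coincidence term.  The exponential-hazard
saturation makes the per-step spike an OR of independent Bernoulli events
(one for the baseline, one for the summed arrivals), so the simulation runs
exactly as an event-driven cascade over the sparse spikes rather than a
dense time loop.  Spike times are placed uniformly within their step.  All
couplings are excitatory, matching what the TE analysis can detect in the
sparse regime.

All randomness flows from a single integer seed through a documented
``numpy`` SeedSequence split: (rates, bursts, baseline spikes, propagation,
within-step placement).
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .raster import SpikeTrain

__all__ = [
    "PlantedTriad",
    "GroundTruthGraph",
    "SimConfig",
    "generate_ground_truth",
    "simulate",
    "write_ground_truth",
    "read_ground_truth",
    "CapacityError",
    "SimConfigError",
]


logger = logging.getLogger(__name__)


class CapacityError(ValueError):
    """Too few neurons for the requested planted triads."""


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class PlantedTriad:
    """Ground-truth synergistic triad: node ids plus its motif signature."""

    sender_a: int
    sender_b: int
    receiver: int
    recurrent_count: int
    feedback_count: int
    chirality: str = "none"


@dataclass
class GroundTruthGraph:
    """Directed coupling matrix with planted triads.

    ``adjacency[j, i]`` is the hazard gain of edge j -> i (0 = no edge).
    No self-edges.
    """

    n_neurons: int
    adjacency: np.ndarray
    planted: tuple[PlantedTriad, ...] = ()

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.float64)
        if adj.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("adjacency shape must be (n_neurons, n_neurons)")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-edges are not allowed")
        if np.any(adj < 0):
            raise ValueError("couplings are excitatory; weights must be >= 0")
        self.adjacency = adj
        self.planted = tuple(self.planted)

    @property
    def density(self) -> float:
        """Realized fraction of possible directed edges."""
        n = self.n_neurons
        return float((self.adjacency > 0).sum() / (n * (n - 1)))

    @property
    def n_edges(self) -> int:
        return int((self.adjacency > 0).sum())

    def edges(self) -> list[tuple[int, int, float]]:
        src, dst = np.nonzero(self.adjacency)
        return [(int(s), int(d), float(self.adjacency[s, d])) for s, d in zip(src, dst)]


def _triad_edges(t: PlantedTriad) -> list[tuple[int, int]]:
    a, b, c = t.sender_a, t.sender_b, t.receiver
    edges = [(a, c), (b, c)]
    if t.recurrent_count >= 1:
        edges.append((a, b))
    if t.recurrent_count == 2:
        edges.append((b, a))
    if t.feedback_count >= 1:
        # parallel: feedback targets the emitter of the recurrent edge (A)
        if t.feedback_count == 1 and t.recurrent_count == 1 and t.chirality == "cross":
            edges.append((c, b))
        else:
            edges.append((c, a))
    if t.feedback_count == 2:
        edges.append((c, b))
    return edges


def generate_ground_truth(
    n_neurons: int,
    background_density: float = 0.0,
    planted: Sequence[tuple[int, int, str | None]] = (),
    weight_range: tuple[float, float] = (0.4, 0.7),
    seed: int | np.random.SeedSequence | None = None,
    recurrent_weight_range: tuple[float, float] | None = None,
) -> GroundTruthGraph:
    """Build a random directed graph with planted triadic motifs.

    Each planted entry is ``(recurrent_count, feedback_count, chirality)``
    (chirality only meaningful for (1,1); None -> 'parallel').  Planted
    triads occupy disjoint node triples (nodes 0-2, 3-5, ...).  Background
    edges are drawn independently at ``background_density`` over all ordered
    pairs outside the planted triads' internal slots, so planted motif
    classes are never perturbed.  Edge weights (hazard gains) are uniform on
    ``weight_range``; sender-sender (recurrent) edges may use their own
    ``recurrent_weight_range``.
    """
    if not 0.0 <= background_density <= 1.0:
        raise ValueError("background_density must be in [0, 1]")
    if n_neurons < 3 * len(planted):
        raise CapacityError(
            f"{n_neurons} neurons cannot host {len(planted)} disjoint triads"
        )
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_neurons, n_neurons))
    triads = []
    for k, (r, f, chi) in enumerate(planted):
        if not (0 <= r <= 2 and 0 <= f <= 2):
            raise ValueError("recurrent/feedback counts must be in 0..2")
        chi = chi or ("parallel" if (r, f) == (1, 1) else "none")
        a, b, c = 3 * k, 3 * k + 1, 3 * k + 2
        triad = PlantedTriad(a, b, c, r, f, chi)
        rec_pairs = {(a, b), (b, a)}
        for s, d in _triad_edges(triad):
            rng_range = (
                recurrent_weight_range
                if recurrent_weight_range is not None and (s, d) in rec_pairs
                else weight_range
            )
            adj[s, d] = rng.uniform(*rng_range)
        triads.append(triad)
    blocked = np.zeros((n_neurons, n_neurons), dtype=bool)
    np.fill_diagonal(blocked, True)
    for t in triads:
        nodes = [t.sender_a, t.sender_b, t.receiver]
        blocked[np.ix_(nodes, nodes)] = True
    if background_density > 0:
        draw = rng.random((n_neurons, n_neurons)) < background_density
        draw &= ~blocked
        adj[draw] = rng.uniform(*weight_range, size=int(draw.sum()))
    return GroundTruthGraph(n_neurons, adj, tuple(triads))


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated recording.

    ``baseline_rate_lognormal = (mu, sigma)`` parametrizes per-neuron rates
    ``exp(N(mu, sigma^2))`` Hz; the defaults give mean 2.1 Hz with ~80% of
    neurons below 3 Hz.  Set sigma = 0 for a constant rate ``exp(mu)``.
    The burst process is an alternating renewal: burst durations uniform on
    ``burst_duration_range_s``, quiet intervals exponential with mean
    ``inter_burst_mean_s``; the gain is ``burst_gain`` inside bursts and is
    rescaled outside so the long-run mean gain is 1 (``burst_gain = 1``
    disables bursting).  ``coupling_delay_ms`` applies to every edge unless
    a per-edge ``delay_matrix_ms`` is given.

    With ``homeostatic_rates`` (the default) the drawn lognormal rates are
    treated as *target* rates: each neuron's baseline hazard is reduced by
    its expected synaptic drive so that total firing rates match the drawn
    distribution regardless of in-degree, mimicking the homeostatic rate
    regulation cultured cortical networks exhibit.  Without it the drawn
    rates are baseline-only and coupled neurons fire above target.

    ``coincidence_gain`` adds supralinear integration: when two or more
    presynaptic spikes arrive at a neuron in the same step, that extra
    hazard is added on top of the summed edge hazards, emulating the
    threshold coincidence detection of real neurons.  Zero (the default)
    keeps the dynamics purely additive.
    """

    duration_ms: float = 600_000.0
    baseline_rate_lognormal: tuple[float, float] = (0.242, 1.0)
    burst_duration_range_s: tuple[float, float] = (1.0, 10.0)
    inter_burst_mean_s: float = 10.0
    burst_gain: float = 2.5
    burst_ramp_ms: float = 100.0
    coupling_delay_ms: float = 1.0
    delay_matrix_ms: np.ndarray | None = None
    step_ms: float = 1.0
    homeostatic_rates: bool = True
    coincidence_gain: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise SimConfigError("duration_ms must be positive")
        if self.step_ms <= 0:
            raise SimConfigError("step_ms must be positive")
        lo, hi = self.burst_duration_range_s
        if not (0 < lo <= hi):
            raise SimConfigError("burst_duration_range_s must be 0 < lo <= hi")
        if self.burst_gain < 1.0:
            raise SimConfigError("burst_gain must be >= 1")


def _burst_gain_series(n_steps: int, step_s: float, cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Shared multiplicative gain; alternating quiet/burst, long-run mean 1."""
    if cfg.burst_gain == 1.0:
        return np.ones(n_steps)
    lo, hi = cfg.burst_duration_range_s
    mean_burst = 0.5 * (lo + hi)
    frac = mean_burst / (mean_burst + cfg.inter_burst_mean_s)
    if cfg.burst_gain * frac >= 1.0:
        raise SimConfigError(
            f"burst_gain {cfg.burst_gain} too large for burst fraction {frac:.3f}; "
            "quiet gain would be negative"
        )
    quiet_gain = (1.0 - frac * cfg.burst_gain) / (1.0 - frac)
    g = np.empty(n_steps)
    t = 0
    in_burst = False
    while t < n_steps:
        if in_burst:
            dur_s = rng.uniform(lo, hi)
            gain = cfg.burst_gain
        else:
            dur_s = rng.exponential(cfg.inter_burst_mean_s)
            gain = quiet_gain
        n = max(1, int(round(dur_s / step_s)))
        g[t : t + n] = gain
        t += n
        in_burst = not in_burst
    # smooth the on/off transitions: population bursts recruit over tens of
    # milliseconds, and instantaneous shared rate steps would create
    # artifactual millisecond-synchronous structure across all neurons
    ramp = int(round(cfg.burst_ramp_ms / 1000.0 / step_s))
    if ramp > 1:
        kernel = np.ones(ramp) / ramp
        pad = np.concatenate([np.full(ramp, g[0]), g, np.full(ramp, g[-1])])
        g = np.convolve(pad, kernel, mode="same")[ramp : ramp + n_steps]
    return g


def _homeostatic_baselines(
    graph: GroundTruthGraph,
    dsteps: np.ndarray,
    targets: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Baseline rates compensating first-order expected synaptic drive.

    The direct term sums, per target, each presynaptic neuron's target rate
    times its transmission probability.  When a coincidence bonus is active,
    chains j -> k -> i whose delays align j's direct arrival with k's
    relayed arrival (d_ji = d_jk + d_ki) contribute a correction replacing
    two independent single arrivals by one joint (bonus-boosted) arrival.
    Baselines are floored at 5% of the target (logged), so strongly driven
    neurons may exceed their targets.
    """
    adj = graph.adjacency
    p_tr = 1.0 - np.exp(-adj)
    induced = p_tr.T @ targets  # events/s arriving and transmitting
    if config.coincidence_gain > 0:
        src, dst = np.nonzero(adj)
        edge_set = set(zip(src.tolist(), dst.tolist()))
        for j, k in edge_set:
            for i in range(graph.n_neurons):
                if (j, i) in edge_set and (k, i) in edge_set:
                    if dsteps[j, i] == dsteps[j, k] + dsteps[k, i]:
                        w_sum = adj[j, i] + adj[k, i] + config.coincidence_gain
                        joint = 1.0 - np.exp(-w_sum)
                        singles = p_tr[j, i] + p_tr[k, i]
                        induced[i] += targets[j] * p_tr[j, k] * (joint - singles)
    floored = np.maximum(targets - induced, 0.05 * targets)
    clipped = np.flatnonzero(targets - induced < 0.05 * targets)
    if clipped.size:
        logger.info("homeostatic baseline floored for neurons %s", clipped.tolist())
    return floored


def simulate(graph: GroundTruthGraph, config: SimConfig) -> list[SpikeTrain]:
    """Run the conditionally-Bernoulli dynamics; returns one train per neuron.

    Deterministic under ``config.seed``.  Raises :class:`SimConfigError`
    when any baseline hazard per step would exceed 1 (reduce ``step_ms``).
    """
    n = graph.n_neurons
    step_s = config.step_ms / 1000.0
    n_steps = int(np.floor(config.duration_ms / config.step_ms + 1e-9))
    if n_steps < 2:
        raise SimConfigError("duration too short for the chosen step")

    ss = np.random.SeedSequence(config.seed)
    rng_rates, rng_burst, rng_base, rng_prop, rng_place = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    # delay in steps per edge
    if config.delay_matrix_ms is not None:
        dmat = np.asarray(config.delay_matrix_ms, dtype=np.float64)
        if dmat.shape != (n, n):
            raise SimConfigError("delay_matrix_ms shape must match adjacency")
    else:
        dmat = np.full((n, n), config.coupling_delay_ms)
    dsteps = np.maximum(1, np.round(dmat / config.step_ms).astype(np.int64))

    mu, sigma = config.baseline_rate_lognormal
    rates = np.exp(rng_rates.normal(mu, sigma, size=n))  # Hz (targets)
    if config.homeostatic_rates and graph.n_edges:
        rates = _homeostatic_baselines(graph, dsteps, rates, config)
    if np.any(rates * config.burst_gain * step_s > 1.0):
        raise SimConfigError(
            "per-step spike probability exceeds 1 for the fastest neuron; "
            f"use a smaller step_ms than {config.step_ms}"
        )

    gain = _burst_gain_series(n_steps, step_s, config, rng_burst)

    out_edges: list[list[tuple[int, int, float]]] = [[] for _ in range(n)]
    for s, d, w in graph.edges():
        out_edges[s].append((d, int(dsteps[s, d]), w))

    # Baseline (non-coupled) spikes, vectorized per neuron.
    spiked = np.zeros((n, n_steps), dtype=bool)
    spikes_at: dict[int, list[int]] = collections.defaultdict(list)
    for i in range(n):
        p0 = 1.0 - np.exp(-rates[i] * step_s * gain)
        hits = np.flatnonzero(rng_base.random(n_steps) < p0)
        spiked[i, hits] = True
        for t in hits:
            spikes_at[int(t)].append(i)

    # Event-driven propagation.  Each realized spike schedules one arrival
    # per out-edge after the edge delay; at every step a target's arrival
    # hazards are summed (plus the coincidence bonus when >= 2 arrive) and a
    # single Bernoulli decides the triggered spike.  Equivalent to the
    # conditional hazard p = 1 - exp(-(baseline + sum w + bonus)).
    if any(out_edges):
        bonus = float(config.coincidence_gain)
        arrivals: dict[int, list[tuple[int, float]]] = collections.defaultdict(list)
        for t in range(n_steps):
            arr = arrivals.pop(t, None)
            if arr is not None:
                agg: dict[int, list[float]] = {}
                for i, w in arr:
                    agg.setdefault(i, []).append(w)
                for i in sorted(agg):
                    if spiked[i, t]:
                        continue
                    h = sum(agg[i]) + (bonus if len(agg[i]) >= 2 else 0.0)
                    if rng_prop.random() < 1.0 - np.exp(-h):
                        spiked[i, t] = True
                        spikes_at[t].append(i)
            if t in spikes_at:
                for j in sorted(spikes_at[t]):
                    for (i, d, w) in out_edges[j]:
                        if t + d < n_steps:
                            arrivals[t + d].append((i, w))

    trains = []
    duration = n_steps * config.step_ms
    for i in range(n):
        bins = np.flatnonzero(spiked[i])
        times = (bins + rng_place.random(bins.size)) * config.step_ms
        times = np.minimum(times, np.nextafter(duration, 0.0))
        trains.append(SpikeTrain(i, times, duration))
    return trains


# ---------------------------------------------------------------------------
# Ground-truth serialization: "src dst weight" edge-list text
# ---------------------------------------------------------------------------


def write_ground_truth(graph: GroundTruthGraph, path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# n_neurons={graph.n_neurons}\n")
        for t in graph.planted:
            fh.write(
                f"# triad {t.sender_a} {t.sender_b} {t.receiver} "
                f"{t.recurrent_count} {t.feedback_count} {t.chirality}\n"
            )
        for s, d, w in graph.edges():
            fh.write(f"{s} {d} {w!r}\n")


def read_ground_truth(path: Union[str, Path]) -> GroundTruthGraph:
    n_neurons = None
    triads = []
    edges = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n_neurons="):
                    n_neurons = int(body.split("=", 1)[1])
                elif body.startswith("triad "):
                    parts = body.split()
                    triads.append(
                        PlantedTriad(
                            int(parts[1]), int(parts[2]), int(parts[3]),
                            int(parts[4]), int(parts[5]), parts[6],
                        )
                    )
                continue
            s, d, w = line.split()
            edges.append((int(s), int(d), float(w)))
    if n_neurons is None:
        n_neurons = 1 + max(max(s, d) for s, d, _ in edges)
    adj = np.zeros((n_neurons, n_neurons))
    for s, d, w in edges:
        adj[s, d] = w
    return GroundTruthGraph(n_neurons, adj, tuple(triads))
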