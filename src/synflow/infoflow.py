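"""Plug-in information estimators on binary series and TE effective networks.

Transfer entropy (TE) from neuron J to neuron I quantifies how well the
present state of I can be predicted from the past state of J beyond what I's
own past provides:

    TE(J -> I) = I(I_t ; J_{t-d} | I_{t-d})

estimated by plugging the empirical joint distribution of
``(I_t, J_{t-d}, I_{t-d})`` into the conditional mutual information.  All
estimators here use binary alphabets and an order-1 target history, which
keeps the joint supports at 8-16 states and matches the sparse-firing regime
the binning in :mod:`synflow.raster` produces.

Edge significance is assessed against interval-jitter surrogates: time is
partitioned into fixed windows of ``2 * jitter_window_ms`` and every source
spike is redrawn uniformly within its own window, then re-binned and TE
recomputed.  Jittering destroys millisecond-precise source-target alignment
while preserving slow structure (rates, population bursts), so the
surrogate distribution is the null of "no fast directed coupling".  Fixed
windows (rather than windows centered on each spike) make the observed
spike train exchangeable with its surrogates under that null, which keeps
the test exactly calibrated.  The p-value uses the add-one convention
``p = (1 + #{null >= observed}) / (1 + n_jitter)`` and an edge is
significant iff ``p < alpha``.

An :class:`EffectiveNetwork` collects, for every ordered neuron pair, raw TE
(bits), TE normalized by the receiver's entropy, the surrogate p-value and
the significance mask at one timescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .raster import SpikeTrain, TimescaleSpec, TS1, bin_spikes, spike_bins

__all__ = [
    "JointDistribution",
    "EffectiveNetwork",
    "JitterResult",
    "entropy",
    "mutual_information",
    "transfer_entropy",
    "multivariate_te",
    "conditional_te",
    "jitter_test",
    "build_network",
    "ConfigError",
]

logger = logging.getLogger(__name__)

_LOG2 = np.log(2.0)


class ConfigError(ValueError):
    """Raised for inconsistent analysis configuration (alpha vs n_jitter, ...)."""


# ---------------------------------------------------------------------------
# Joint distributions and entropy primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JointDistribution:
    """A joint distribution over a few binary variables.

    ``probs`` is an ndarray of shape ``(2,) * n_variables``; axis order
    matches ``variables``.  The convention used throughout the PID machinery
    is ``(target_present, source_a_past, source_b_past, target_past)``.
    """

    variables: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "variables", tuple(self.variables))
        if p.shape != (2,) * len(self.variables):
            raise ValueError(
                f"probs shape {p.shape} does not match {len(self.variables)} binary variables"
            )
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")

    @classmethod
    def from_series(
        cls,
        target: np.ndarray,
        sources: Sequence[np.ndarray],
        delay_bins: int,
        variables: tuple[str, ...] | None = None,
    ) -> "JointDistribution":
        """Empirical joint of ``(target_t, *sources_{t-d}, target_{t-d})``."""
        counts = _lagged_counts(target, sources, delay_bins)
        if variables is None:
            names = ["target_t"]
            names += [f"source{i}_past" for i in range(len(sources))]
            names.append("target_past")
            variables = tuple(names)
        return cls(variables, counts / counts.sum())


def _as_binary(series: np.ndarray, name: str = "series") -> np.ndarray:
    x = np.asarray(series)
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    x = x.astype(np.int64)
    if x.min() < 0 or x.max() > 1:
        raise ValueError(f"{name} must be binary (0/1)")
    return x


def _lagged_counts(
    target: np.ndarray, sources: Sequence[np.ndarray], delay_bins: int
) -> np.ndarray:
    """Joint counts of ``(I_t, S1_{t-d}, ..., Sk_{t-d}, I_{t-d})``.

    Samples run over ``t in [d, T)``.  Returns an array of shape
    ``(2,) * (k + 2)`` with axes ordered target-present, sources, target-past.
    """
    x = _as_binary(target, "target")
    d = int(delay_bins)
    if d < 1:
        raise ValueError("delay_bins must be >= 1")
    T = x.size
    if T <= d:
        raise ValueError(f"series length {T} must exceed delay {d}")
    code = x[d:].copy()
    for s in sources:
        s = _as_binary(s, "source")
        if s.size != T:
            raise ValueError("all series must have equal length")
        code = code * 2 + s[: T - d]
    code = code * 2 + x[: T - d]
    k = len(sources)
    counts = np.bincount(code, minlength=2 ** (k + 2)).astype(np.float64)
    return counts.reshape((2,) * (k + 2))


def _entropy_from_probs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    return float(-xlogy(p, p).sum() / _LOG2)


def entropy(series: np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of a binary series' empirical marginal."""
    x = _as_binary(series)
    p1 = x.mean()
    return _entropy_from_probs(np.array([1.0 - p1, p1]))


def _cmi(probs: np.ndarray, x_axes: tuple, y_axes: tuple, z_axes: tuple) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z) on a joint probability array."""
    axes = set(range(probs.ndim))

    def marg(keep: tuple) -> np.ndarray:
        drop = tuple(sorted(axes - set(keep)))
        return probs.sum(axis=drop) if drop else probs

    h_xz = _entropy_from_probs(marg(x_axes + z_axes))
    h_yz = _entropy_from_probs(marg(y_axes + z_axes))
    h_xyz = _entropy_from_probs(marg(x_axes + y_axes + z_axes))
    h_z = _entropy_from_probs(marg(z_axes)) if z_axes else 0.0
    val = h_xz + h_yz - h_xyz - h_z
    return max(val, 0.0)


def mutual_information(
    a: np.ndarray, b: np.ndarray, normalize: bool = False
) -> float:
    """Plug-in I(A;B) in bits; optionally normalized by min(H(A), H(B)).

    The normalized value lies in [0, 1].  If the smaller marginal entropy is
    zero the normalization is undefined and NaN is returned (not raised).
    """
    xa = _as_binary(a, "a")
    xb = _as_binary(b, "b")
    if xa.size != xb.size:
        raise ValueError("series must have equal length")
    counts = np.bincount(xa * 2 + xb, minlength=4).astype(np.float64).reshape(2, 2)
    p = counts / counts.sum()
    mi = _cmi(p, (0,), (1,), ())
    if not normalize:
        return mi
    h_min = min(_entropy_from_probs(p.sum(1)), _entropy_from_probs(p.sum(0)))
    if h_min == 0.0:
        logger.info("mutual_information: zero-entropy normalizer; returning NaN")
        return float("nan")
    return min(mi / h_min, 1.0)


def _delay(spec: Union[TimescaleSpec, int]) -> int:
    return spec.delay_bins if isinstance(spec, TimescaleSpec) else int(spec)


def transfer_entropy(
    source: np.ndarray, target: np.ndarray, spec: Union[TimescaleSpec, int] = TS1
) -> float:
    """TE(source -> target) = I(I_t ; J_{t-d} | I_{t-d}) in bits (plug-in)."""
    counts = _lagged_counts(target, [source], _delay(spec))
    return _cmi(counts / counts.sum(), (0,), (1,), (2,))


def multivariate_te(
    src_a: np.ndarray,
    src_b: np.ndarray,
    target: np.ndarray,
    spec: Union[TimescaleSpec, int] = TS1,
) -> float:
    """mvTE({A,B} -> target) = I(I_t ; (A_{t-d}, B_{t-d}) | I_{t-d}) in bits."""
    counts = _lagged_counts(target, [src_a, src_b], _delay(spec))
    return _cmi(counts / counts.sum(), (0,), (1, 2), (3,))


def conditional_te(
    source: np.ndarray,
    target: np.ndarray,
    conditioning: np.ndarray,
    spec: Union[TimescaleSpec, int] = TS1,
) -> float:
    """cTE(source -> target | cond) = I(I_t ; J_{t-d} | I_{t-d}, K_{t-d})."""
    counts = _lagged_counts(target, [source, conditioning], _delay(spec))
    return _cmi(counts / counts.sum(), (0,), (1,), (2, 3))


# ---------------------------------------------------------------------------
# Jitter significance
# ---------------------------------------------------------------------------


def _te_from_cell_counts(n_src1: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    """TE in bits from source-conditional cell counts.

    ``n_total[c]`` counts samples in each of the four ``(I_t, I_{t-d})`` cells
    ``c = 2*I_t + I_{t-d}``; ``n_src1[..., c]`` counts the subset with
    ``J_{t-d} = 1``.  Vectorized over leading axes of ``n_src1`` (used to
    score thousands of jitter surrogates at once).
    """
    n_total = np.asarray(n_total, dtype=np.float64)
    n1 = np.asarray(n_src1, dtype=np.float64)
    n0 = n_total - n1
    ns = n_total.sum()
    # stack j=0 / j=1 cell counts: shape (..., 2, 4)
    m = np.stack([n0 + np.zeros_like(n1), n1], axis=-2)
    ip = np.array([0, 1, 0, 1])
    # n(j, ip) = sum over i_t
    n_j_ip = np.stack(
        [m[..., :, ip == 0].sum(-1), m[..., :, ip == 1].sum(-1)], axis=-1
    )  # (..., 2, 2) -> [j, ip]
    n_ip = np.array([n_total[ip == 0].sum(), n_total[ip == 1].sum()])
    # TE = (1/N) sum_{j,c} m log2( m * n(ip) / (n(c) * n(j, ip)) )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m * n_ip[ip] / (n_total * n_j_ip[..., :, ip])
        terms = xlogy(m, ratio)
    te = np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0).sum((-1, -2)) / (
        ns * _LOG2
    )
    return np.maximum(te, 0.0)


@dataclass(frozen=True)
class JitterResult:
    """Outcome of one jitter significance test."""

    te_bits: float
    p_value: float
    significant: bool
    n_jitter: int
    alpha: float


def _check_jitter_config(n_jitter: int, alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    needed = int(np.ceil(1.0 / alpha)) - 1
    if n_jitter < needed:
        raise ConfigError(
            f"n_jitter={n_jitter} cannot resolve alpha={alpha}; "
            f"need at least {needed} jitters"
        )


class _TargetCodes:
    """Per-target precomputation shared across all sources (and all jitters).

    ``codes[t] = 2 * I_t + I_{t-d}`` for ``t >= d``; ``cell_totals`` are the
    four ``(I_t, I_{t-d})`` cell counts over all samples.
    """

    def __init__(self, target_bits: np.ndarray, delay_bins: int):
        x = _as_binary(target_bits, "target")
        d = int(delay_bins)
        if x.size <= d:
            raise ValueError("target series shorter than delay")
        codes = np.zeros(x.size, dtype=np.int64)
        codes[d:] = 2 * x[d:] + x[:-d]
        self.codes = codes
        self.delay = d
        self.n_bins = x.size
        self.cell_totals = np.bincount(codes[d:], minlength=4).astype(np.float64)
        self.entropy = entropy(x)

    def observed_cells(self, src_bins: np.ndarray) -> np.ndarray:
        b = src_bins[(src_bins >= 0) & (src_bins < self.n_bins - self.delay)]
        return np.bincount(self.codes[b + self.delay], minlength=4).astype(np.float64)

    def te_for_source_bins(self, src_bins: np.ndarray) -> float:
        return float(_te_from_cell_counts(self.observed_cells(src_bins), self.cell_totals))


def _null_te(
    spike_times: np.ndarray,
    duration_ms: float,
    bin_width_ms: float,
    tc: _TargetCodes,
    n_jitter: int,
    jitter_window_ms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """TE of n_jitter jitter surrogates of the source against a fixed target."""
    bins0 = np.unique(np.floor(spike_times / bin_width_ms).astype(np.int64))
    bins0 = bins0[(bins0 >= 0) & (bins0 < tc.n_bins)]
    n_spk = bins0.size
    if n_spk == 0:
        return np.zeros(n_jitter)
    # interval jitter on the bin grid: windows of 2 * jitter_window_ms
    # partition the grid; each occupied bin is redrawn uniformly within its
    # window.  Redraws collide occasionally; colliding entries are redrawn
    # so every surrogate keeps one event per bin, matching the binarized
    # observed train (allowing collisions to merge breaks exchangeability
    # between the observed train and its surrogates).
    w_bins = max(1, int(round(2.0 * jitter_window_ms / bin_width_ms)))
    win_start = (bins0 // w_bins) * w_bins
    win_len = np.minimum(win_start + w_bins, tc.n_bins) - win_start
    bins = win_start + np.floor(
        rng.random(size=(n_jitter, n_spk)) * win_len
    ).astype(np.int64)
    for _ in range(30):
        order = np.argsort(bins, axis=1, kind="stable")
        srt = np.take_along_axis(bins, order, axis=1)
        dup = np.zeros_like(bins, dtype=bool)
        dup[:, 1:] = srt[:, 1:] == srt[:, :-1]
        if not dup.any():
            break
        rows, pos = np.nonzero(dup)
        cols = order[rows, pos]
        bins[rows, cols] = win_start[cols] + np.floor(
            rng.random(rows.size) * win_len[cols]
        ).astype(np.int64)
    bins.sort(axis=1)
    valid = np.ones_like(bins, dtype=bool)
    valid[:, 1:] = bins[:, 1:] != bins[:, :-1]  # guard unresolved collisions
    valid &= bins < (tc.n_bins - tc.delay)
    safe = np.where(valid, bins, 0)
    codes = tc.codes[safe + tc.delay]
    rows = np.broadcast_to(np.arange(n_jitter)[:, None], codes.shape)
    flat = (rows * 4 + codes)[valid]
    n1 = np.bincount(flat, minlength=4 * n_jitter).astype(np.float64)
    return _te_from_cell_counts(n1.reshape(n_jitter, 4), tc.cell_totals)


def jitter_test(
    source: SpikeTrain,
    target: SpikeTrain,
    spec: TimescaleSpec = TS1,
    n_jitter: int = 5000,
    alpha: float = 0.001,
    jitter_window_ms: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> JitterResult:
    """Interval-jitter significance test of TE(source -> target).

    Each surrogate redraws every source spike time uniformly within its
    fixed ``2 * jitter_window_ms`` window (so displacements are at most
    comparable to spike-centered jittering by ``+/- jitter_window_ms``),
    re-bins at the spec's bin width, and recomputes TE.
    ``p = (1 + #{null >= observed}) / (1 + n_jitter)``; the edge is
    significant iff ``p < alpha`` (strict).
    """
    _check_jitter_config(n_jitter, alpha)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tc = _TargetCodes(bin_spikes(target, spec), spec.delay_bins)
    te_obs = tc.te_for_source_bins(spike_bins(source, spec))
    null = _null_te(
        source.spike_times,
        source.duration_ms,
        spec.bin_width_ms,
        tc,
        n_jitter,
        jitter_window_ms,
        rng,
    )
    p = (1.0 + int(np.sum(null >= te_obs - 1e-13))) / (1.0 + n_jitter)
    return JitterResult(te_obs, p, bool(p < alpha), n_jitter, alpha)


# ---------------------------------------------------------------------------
# Effective networks
# ---------------------------------------------------------------------------


@dataclass
class EffectiveNetwork:
    """Directed TE network at one timescale.

    ``te_raw`` holds plug-in TE in bits for every ordered pair (row = source,
    column = target); ``te_norm`` divides each column by the receiver's binned
    entropy (NaN where that entropy is zero); ``sig_mask`` marks edges whose
    jitter p-value is below alpha.  Diagonals are zero / False.
    """

    te_raw: np.ndarray
    te_norm: np.ndarray
    pvals: np.ndarray
    sig_mask: np.ndarray
    spec: TimescaleSpec
    neuron_ids: tuple[int, ...]
    alpha: float

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def density(self) -> float:
        """Fraction of possible directed edges that are significant."""
        n = self.n_neurons
        off = ~np.eye(n, dtype=bool)
        return float(self.sig_mask[off].mean()) if n > 1 else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        ids = self.neuron_ids
        for i, src in enumerate(ids):
            for j, dst in enumerate(ids):
                if i == j:
                    continue
                rows.append(
                    {
                        "src": src,
                        "dst": dst,
                        "te_raw": self.te_raw[i, j],
                        "te_norm": self.te_norm[i, j],
                        "pval": self.pvals[i, j],
                        "sig": bool(self.sig_mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def write_edge_list(self, path: Union[str, Path]) -> None:
        df = self.to_dataframe()
        with Path(path).open("w") as fh:
            fh.write(f"# timescale={self.spec.label} bin_width_ms={self.spec.bin_width_ms}"
                     f" delay_bins={self.spec.delay_bins} alpha={self.alpha}\n")
            df.to_csv(fh, sep="\t", index=False)


def build_network(
    trains: Sequence[SpikeTrain],
    spec: TimescaleSpec = TS1,
    n_jitter: int = 5000,
    alpha: float = 0.001,
    jitter_window_ms: float = 10.0,
    seed: int | None = None,
) -> EffectiveNetwork:
    """TE + jitter significance for every ordered pair of neurons.

    Zero-entropy receivers yield NaN normalized TE and non-significant edges;
    they are logged and excluded from downstream normalized aggregates.
    """
    if len(trains) < 2:
        raise ValueError("need at least two spike trains")
    _check_jitter_config(n_jitter, alpha)
    n = len(trains)
    ids = tuple(t.neuron_id for t in trains)
    targets = []
    for t in trains:
        try:
            targets.append(_TargetCodes(bin_spikes(t, spec), spec.delay_bins))
        except ValueError as exc:
            raise ValueError(f"neuron {t.neuron_id} at {spec.label}: {exc}") from exc
    src_bins_all = [spike_bins(t, spec) for t in trains]

    te_raw = np.zeros((n, n))
    te_norm = np.full((n, n), np.nan)
    pvals = np.ones((n, n))
    sig = np.zeros((n, n), dtype=bool)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n * n)
    for i in range(n):  # source
        for j in range(n):  # target
            if i == j:
                continue
            tc = targets[j]
            rng = np.random.default_rng(children[i * n + j])
            try:
                te = tc.te_for_source_bins(src_bins_all[i])
                null = _null_te(
                    trains[i].spike_times,
                    trains[i].duration_ms,
                    spec.bin_width_ms,
                    tc,
                    n_jitter,
                    jitter_window_ms,
                    rng,
                )
            except Exception as exc:  # annotate with pair + spec context
                raise RuntimeError(
                    f"TE estimation failed for pair ({ids[i]} -> {ids[j]}) "
                    f"at {spec.label}: {exc}"
                ) from exc
            p = (1.0 + int(np.sum(null >= te - 1e-13))) / (1.0 + n_jitter)
            te_raw[i, j] = te
            pvals[i, j] = p
            if tc.entropy > 0:
                te_norm[i, j] = min(te / tc.entropy, 1.0)
                sig[i, j] = p < alpha
            else:
                logger.info(
                    "build_network: neuron %s has zero entropy at %s; "
                    "normalized TE undefined",
                    ids[j],
                    spec.label,
                )
    return EffectiveNetwork(te_raw, te_norm, pvals, sig, spec, ids, alpha)
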