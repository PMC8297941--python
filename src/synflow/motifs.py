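"""Synergistic triads and the 10-motif catalog of directed 3-node circuits.

A *synergistic triad* is an unordered pair of transmitter neurons {A, B},
each with a significant TE edge into the same receiver C.  Beyond the two
defining feedforward edges, four optional edges may be present:

* recurrent edges between the transmitters (A->B, B->A), and
* feedback edges from the receiver back to a transmitter (C->A, C->B).

The 16 configurations of these four edges collapse, under exchange of the
two transmitters, into 10 motif classes keyed by
``(recurrent_count, feedback_count, chirality)``.  Chirality distinguishes
the two configurations with exactly one recurrent and one feedback edge:
*parallel* when the feedback edge targets the transmitter that emits the
recurrent edge, *cross* when it targets the other one.  Grouping the two
chiralities gives 9 ``(recurrence, feedback)`` categories.

Because node roles (transmitter vs receiver) are fixed, the two chiral
motifs are kept distinct even though they are conformationally equivalent as
unlabeled graphs.

Under an Erdos-Renyi null in which every directed edge occurs independently
with probability p (the network's edge density), the probability that a
triad known to have both feedforward edges exhibits a given motif's optional
edges is ``p**extra_edges`` (the convention used for expected motif
percentages), and the exact conditional class probability is
``multiplicity * p**e * (1-p)**(4-e)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .infoflow import EffectiveNetwork

__all__ = [
    "MotifClass",
    "Triad",
    "motif_catalog",
    "classify_pattern",
    "classify_triad",
    "enumerate_triads",
    "expected_motif_percentage",
    "expected_class_percentage",
    "observed_motif_percentages",
    "triads_to_dataframe",
    "ConsistencyError",
]


class ConsistencyError(ValueError):
    """Raised when a triad's defining feedforward edges are absent."""


_CHIRALITY_RANK = {"parallel": 0, "cross": 1, "none": 2}


@dataclass(frozen=True)
class MotifClass:
    """One of the 10 synergistic-triad motif classes."""

    motif_id: int
    recurrent_count: int
    feedback_count: int
    chirality: str  # 'parallel' | 'cross' | 'none'

    def __post_init__(self) -> None:
        if not (0 <= self.recurrent_count <= 2 and 0 <= self.feedback_count <= 2):
            raise ValueError("edge counts must be in 0..2")
        is_11 = (self.recurrent_count, self.feedback_count) == (1, 1)
        if is_11 != (self.chirality != "none"):
            raise ValueError("chirality applies exactly to the (1,1) motifs")
        if self.chirality not in _CHIRALITY_RANK:
            raise ValueError(f"unknown chirality {self.chirality!r}")

    @property
    def extra_edges(self) -> int:
        """Optional edges beyond the two defining feedforward edges (0..4)."""
        return self.recurrent_count + self.feedback_count

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.recurrent_count, self.feedback_count, self.chirality)


def _classify_bits(ab: int, ba: int, ca: int, cb: int) -> tuple[int, int, str]:
    r = ab + ba
    f = ca + cb
    if (r, f) != (1, 1):
        return r, f, "none"
    # feedback targets the emitter of the recurrent edge -> parallel
    parallel = (ab and ca) or (ba and cb)
    return r, f, "parallel" if parallel else "cross"


def motif_catalog() -> tuple[MotifClass, ...]:
    """All 10 motif classes in a deterministic canonical order.

    Built by enumerating the 16 configurations of the four optional edges and
    collapsing pairs equivalent under exchanging the two transmitters.
    Ordered by ascending extra edges, then recurrent count, then chirality
    (parallel before cross); ids are assigned 1..10 in that order.
    """
    keys = {_classify_bits(*bits) for bits in product((0, 1), repeat=4)}
    ordered = sorted(
        keys, key=lambda k: (k[0] + k[1], k[0], _CHIRALITY_RANK[k[2]])
    )
    return tuple(
        MotifClass(i + 1, r, f, chi) for i, (r, f, chi) in enumerate(ordered)
    )


_CATALOG = motif_catalog()
_BY_KEY = {m.key: m for m in _CATALOG}


def motif_by_key(recurrent: int, feedback: int, chirality: str = "none") -> MotifClass:
    if (recurrent, feedback) == (1, 1) and chirality == "none":
        raise ValueError("the (1,1) motifs require chirality 'parallel' or 'cross'")
    return _BY_KEY[(recurrent, feedback, chirality)]


@dataclass(frozen=True)
class Triad:
    """One synergistic triad with its motif class and normalized edge weights.

    ``sender_a < sender_b`` by neuron id; weights are normalized TE values of
    the edges present (feedforward always two; recurrent/feedback 0-2).
    ``edge_pattern`` is the significance pattern of the six possible edges in
    the order A->C, B->C, A->B, B->A, C->A, C->B.
    """

    sender_a: int
    sender_b: int
    receiver: int
    motif: MotifClass
    ff_weights: tuple[float, float]
    recurrent_weights: tuple[float, ...]
    feedback_weights: tuple[float, ...]
    edge_pattern: str

    def __post_init__(self) -> None:
        if len({self.sender_a, self.sender_b, self.receiver}) != 3:
            raise ValueError("triad nodes must be distinct")


def classify_pattern(
    ab: bool, ba: bool, ca: bool, cb: bool
) -> MotifClass:
    """Motif class from the presence of the four optional edges."""
    return _BY_KEY[_classify_bits(int(ab), int(ba), int(ca), int(cb))]


def _sig_lookup(net: EffectiveNetwork) -> tuple[dict[int, int], np.ndarray]:
    index = {nid: i for i, nid in enumerate(net.neuron_ids)}
    return index, net.sig_mask


def classify_triad(
    net: EffectiveNetwork, sender_a: int, sender_b: int, receiver: int
) -> MotifClass:
    """Classify one (senderA, senderB, receiver) triad from a network's mask.

    Raises :class:`ConsistencyError` if either feedforward edge is not
    significant.  The class is invariant under exchanging the two senders.
    """
    idx, sig = _sig_lookup(net)
    a, b, c = idx[sender_a], idx[sender_b], idx[receiver]
    if not (sig[a, c] and sig[b, c]):
        raise ConsistencyError(
            f"feedforward edges {sender_a}->{receiver}, {sender_b}->{receiver} "
            "are not both significant"
        )
    return classify_pattern(sig[a, b], sig[b, a], sig[c, a], sig[c, b])


def enumerate_triads(net: EffectiveNetwork) -> list[Triad]:
    """All synergistic triads of a network, classified, without double counting.

    One triad per (unordered significant-sender pair, receiver); senders are
    reported in ascending id order.  Edge weights are normalized TE.
    """
    idx, sig = _sig_lookup(net)
    ids = net.neuron_ids
    w = net.te_norm
    triads: list[Triad] = []
    n = len(ids)
    for c in range(n):
        senders = [i for i in range(n) if i != c and sig[i, c]]
        for a, b in combinations(senders, 2):
            if ids[a] > ids[b]:
                a, b = b, a
            motif = classify_pattern(sig[a, b], sig[b, a], sig[c, a], sig[c, b])
            rec = tuple(
                w[i, j] for (i, j) in ((a, b), (b, a)) if sig[i, j]
            )
            fb = tuple(
                w[c, j] for j in (a, b) if sig[c, j]
            )
            pattern = "".join(
                str(int(sig[i, j]))
                for (i, j) in ((a, c), (b, c), (a, b), (b, a), (c, a), (c, b))
            )
            triads.append(
                Triad(
                    ids[a],
                    ids[b],
                    ids[c],
                    motif,
                    (float(w[a, c]), float(w[b, c])),
                    rec,
                    fb,
                    pattern,
                )
            )
    return triads


def expected_motif_percentage(density: float, motif: MotifClass) -> float:
    """Chance frequency of one motif's optional edges at edge probability p.

    Follows the ``p ** extra_edges`` convention: the probability that all of
    the motif's optional edges are present under independent edges, given
    the defining feedforward pair.  The default motif (no optional edges)
    returns 1.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    return float(density ** motif.extra_edges)


def expected_class_percentage(
    density: float, recurrent: int, feedback: int, exact: bool = False
) -> float:
    """Chance frequency of a (recurrence, feedback) category.

    Sums the ``p**k`` expectation over the motifs in the category (the two
    chiral motifs both contribute for (1,1)).  With ``exact=True`` the exact
    conditional probability ``multiplicity * p**e * (1-p)**(4-e)`` is
    returned instead; summed over all 9 categories the exact form equals 1.
    """
    members = [m for m in _CATALOG if (m.recurrent_count, m.feedback_count) == (recurrent, feedback)]
    if not members:
        raise ValueError(f"no motif class with ({recurrent}, {feedback})")
    mult = {0: 1, 1: 2, 2: 1}
    total = 0.0
    for m in members:
        # number of raw edge configurations mapping to this class
        n_cfg = mult[m.recurrent_count] * mult[m.feedback_count]
        if (m.recurrent_count, m.feedback_count) == (1, 1):
            n_cfg = 2  # 4 raw (1,1) configs split evenly between chiralities
        e = m.extra_edges
        if exact:
            total += n_cfg * density**e * (1 - density) ** (4 - e)
        else:
            total += density**e
    return float(total)


def observed_motif_percentages(triads: Sequence[Triad]) -> dict[int, float]:
    """Fraction of triads in each of the 10 motif classes (sums to 1).

    Returns NaN fractions for an empty triad list rather than raising.
    """
    fractions = {m.motif_id: 0.0 for m in _CATALOG}
    if not triads:
        return {k: float("nan") for k in fractions}
    for t in triads:
        fractions[t.motif.motif_id] += 1.0
    n = float(len(triads))
    return {k: v / n for k, v in fractions.items()}


def triads_to_dataframe(
    triads: Sequence[Triad], network_id: Union[int, str] = 0
) -> pd.DataFrame:
    """Tabular form of a triad list (one row per triad)."""
    rows = []
    for t in triads:
        rows.append(
            {
                "network_id": network_id,
                "sender_a": t.sender_a,
                "sender_b": t.sender_b,
                "receiver": t.receiver,
                "motif_id": t.motif.motif_id,
                "recurrent_count": t.motif.recurrent_count,
                "feedback_count": t.motif.feedback_count,
                "chirality": t.motif.chirality,
                "edge_pattern": t.edge_pattern,
                "ff_weight_mean": float(np.mean(t.ff_weights)),
                "recurrent_weight_mean": (
                    float(np.mean(t.recurrent_weights)) if t.recurrent_weights else 0.0
                ),
                "feedback_weight_mean": (
                    float(np.mean(t.feedback_weights)) if t.feedback_weights else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
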