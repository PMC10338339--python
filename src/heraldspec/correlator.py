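"""Coincidence analyses on time-tag streams.

Implements the cross-correlation histogram between two channels, gated
three-detector counting for the conditional g2(0), and the distribution of
the number of heralds per heralded fluorescence detection.

Gate attribution rule: a tag belongs to the most recent herald whose gate
covers it, so overlapping gates from successive heralds are effectively
truncated at the next herald.  With herald spacings far above the gate
length this is almost always the unique assignment; the rule merely makes
counting deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timetags import DelayHistogram, TagStream, channel_times

__all__ = [
    "GatedCounts",
    "G2Result",
    "HeraldCountDistribution",
    "crosscorrelate",
    "gated_counts",
    "conditional_g2",
    "herald_count_distribution",
]

HERALD_CHANNEL = 1
FLUOR_CHANNELS = (2, 3)


@dataclass(frozen=True)
class GatedCounts:
    """Counts entering the three-detector conditional g2(0).

    N_H heralds opened gates; N_2 / N_3 gates saw at least one tag on
    detector 2 / 3; N_C gates saw both.
    """

    N_H: int
    N_2: int
    N_3: int
    N_C: int
    gate_ps: int

    def __post_init__(self) -> None:
        if min(self.N_H, self.N_2, self.N_3, self.N_C) < 0:
            raise ValueError("counts must be non-negative")
        if self.N_C > min(self.N_2, self.N_3):
            raise ValueError("N_C cannot exceed min(N_2, N_3)")


@dataclass(frozen=True)
class G2Result:
    """Conditional g2(0) with Poisson-propagated standard deviation."""

    value: float
    sd: float
    counts: GatedCounts
    zero_coincidence: bool = False


@dataclass
class HeraldCountDistribution:
    """Empirical P(N): heralds elapsed per heralded fluorescence detection.

    ``counts[N]`` is the number of events recorded with exactly N heralds
    since the previous recorded event (inclusive of the triggering herald);
    the N = 0 bin holds double-fluorescence events (two detections within a
    single herald's gate).
    """

    counts: np.ndarray
    total_heralds: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @classmethod
    def from_counts(cls, counts, total_heralds: int = 0, **meta) -> "HeraldCountDistribution":
        if isinstance(counts, dict):
            size = max(counts) + 1 if counts else 1
            arr = np.zeros(size, dtype=np.int64)
            for n, c in counts.items():
                arr[n] = c
            counts = arr
        return cls(np.asarray(counts), total_heralds, dict(meta))

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        tot = self.total_events
        return self.counts / tot if tot else self.counts.astype(float)

    @property
    def poisson_sd(self) -> np.ndarray:
        """Per-bin Poisson s.d. of P(N): sqrt(counts) / total events."""
        tot = self.total_events
        return np.sqrt(self.counts) / tot if tot else self.counts.astype(float)

    def mean_n(self) -> float:
        """Mean N over events with N >= 1."""
        n = np.arange(self.counts.size)
        tot = self.counts[1:].sum()
        if tot == 0:
            raise ValueError("no events with N >= 1")
        return float((n[1:] * self.counts[1:]).sum() / tot)


# -----------------------------------------------------------------------------


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized expansion of per-row index ranges [lo_i, hi_i).

    Returns (row index, flat index) pairs for every element of every range.
    """
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rows = np.repeat(np.arange(lo.size), counts)
    offsets = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return rows, np.repeat(lo, counts) + offsets


def crosscorrelate(
    heralds: np.ndarray,
    partners: np.ndarray,
    bin_ps: int = 128,
    window_ps: int = 12800,
) -> DelayHistogram:
    """Histogram of delays ``tau = t_partner - t_herald`` for all pairs with
    ``-K*bin <= tau < K*bin`` where ``K = window_ps // bin_ps``.

    Sorted inputs; two-pointer (searchsorted) sweep, O(n log m + pairs),
    identical to the brute-force all-pairs histogram.
    """
    if bin_ps <= 0:
        raise ValueError("bin_ps must be positive")
    if window_ps < bin_ps:
        raise ValueError("window_ps must be at least one bin")
    heralds = np.asarray(heralds, dtype=np.int64)
    partners = np.asarray(partners, dtype=np.int64)
    K = int(window_ps // bin_ps)
    half = K * bin_ps
    edges = np.arange(-K, K + 1, dtype=np.int64) * bin_ps

    lo = np.searchsorted(partners, heralds - half, side="left")
    hi = np.searchsorted(partners, heralds + half, side="left")
    rows, pidx = _expand_ranges(lo, hi)
    delays = partners[pidx] - heralds[rows]
    idx = (delays + half) // bin_ps
    counts = np.bincount(idx, minlength=2 * K).astype(np.int64)
    return DelayHistogram(bin_edges=edges, counts=counts)


def _gate_hits(heralds: np.ndarray, tags: np.ndarray, gate_ps: int, offset_ps: int) -> np.ndarray:
    """Per-herald number of ``tags`` inside [t_h + offset, t_h + offset + gate),
    attributing each tag to the most recent herald whose gate covers it."""
    if heralds.size == 0:
        return np.zeros(0, dtype=np.int64)
    starts = heralds + offset_ps
    pos = np.searchsorted(starts, tags, side="right") - 1
    valid = pos >= 0
    in_gate = np.zeros(tags.shape, dtype=bool)
    in_gate[valid] = tags[valid] < starts[pos[valid]] + gate_ps
    return np.bincount(pos[in_gate], minlength=heralds.size).astype(np.int64)


def gated_counts(
    stream: TagStream,
    gate_ps: int = 10_000,
    offset_ps: int = 0,
) -> GatedCounts:
    """Gated singles and coincidences for the three-detector g2 measurement.

    Each herald (channel 1) opens a gate on detectors 2 and 3; a detector
    contributes one gated single per gate containing >= 1 of its tags, and a
    gate where both detectors fire contributes one coincidence.
    """
    if gate_ps <= 0:
        raise ValueError("gate_ps must be positive")
    heralds = channel_times(stream, HERALD_CHANNEL)
    if heralds.size == 0:
        raise ValueError("stream has no herald tags on channel 1")
    d2 = channel_times(stream, 2)
    d3 = channel_times(stream, 3)
    hits2 = _gate_hits(heralds, d2, gate_ps, offset_ps) > 0
    hits3 = _gate_hits(heralds, d3, gate_ps, offset_ps) > 0
    return GatedCounts(
        N_H=int(heralds.size),
        N_2=int(hits2.sum()),
        N_3=int(hits3.sum()),
        N_C=int((hits2 & hits3).sum()),
        gate_ps=int(gate_ps),
    )


def conditional_g2(gc: GatedCounts) -> G2Result:
    """Conditional g2(0) = (N_H * N_C) / (N_2 * N_3) with Poisson errors.

    The s.d. propagates independent Poisson errors of the four counts:
    ``g2 * sqrt(1/N_C + 1/N_H + 1/N_2 + 1/N_3)``.  When N_C = 0 the value
    is 0 and the s.d. is the one-count bound (N_C -> 1), flagged via
    ``zero_coincidence``.
    """
    if gc.N_2 <= 0 or gc.N_3 <= 0:
        raise ValueError("gated singles must be positive")
    if gc.N_H <= 0:
        raise ValueError("herald count must be positive")
    rel = 1.0 / gc.N_H + 1.0 / gc.N_2 + 1.0 / gc.N_3
    if gc.N_C == 0:
        bound = gc.N_H / (gc.N_2 * gc.N_3)  # one-coincidence bound
        sd = bound * float(np.sqrt(1.0 + rel))
        return G2Result(value=0.0, sd=sd, counts=gc, zero_coincidence=True)
    value = (gc.N_H * gc.N_C) / (gc.N_2 * gc.N_3)
    sd = value * float(np.sqrt(1.0 / gc.N_C + rel))
    return G2Result(value=float(value), sd=sd, counts=gc)


def herald_count_distribution(
    stream: TagStream,
    gate_ps: int = 10_000,
    offset_ps: int = 0,
) -> HeraldCountDistribution:
    """Distribution of the number of heralds per heralded fluorescence photon.

    Heralds are scanned in time order; when a herald's gate contains >= 1
    fluorescence tag (channels 2 and 3 combined) an event is recorded with
    N = number of heralds since the previous recorded event, inclusive of
    the triggering herald.  Each additional fluorescence tag inside the same
    gate (both detectors, or two tags on one) is recorded as an N = 0
    double event — the same events that enter N_C of :func:`gated_counts`.
    """
    if gate_ps <= 0:
        raise ValueError("gate_ps must be positive")
    heralds = channel_times(stream, HERALD_CHANNEL)
    if heralds.size == 0:
        raise ValueError("stream has no herald tags on channel 1")
    fluor = np.sort(np.concatenate([channel_times(stream, c) for c in FLUOR_CHANNELS]))
    hits = _gate_hits(heralds, fluor, gate_ps, offset_ps)
    event_idx = np.nonzero(hits > 0)[0]
    n_doubles = int((hits[event_idx] - 1).sum())
    if event_idx.size:
        gaps = np.diff(event_idx, prepend=-1)  # heralds since previous event
        counts = np.bincount(gaps, minlength=2)
    else:
        counts = np.zeros(2, dtype=np.int64)
    counts = counts.astype(np.int64)
    counts[0] += n_doubles
    return HeraldCountDistribution(
        counts=counts,
        total_heralds=int(heralds.size),
        meta={"gate_ps": int(gate_ps), "offset_ps": int(offset_ps), "n_doubles": n_doubles},
    )
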