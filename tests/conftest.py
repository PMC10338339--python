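"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive O(n*m) / per-event scans so they
stay independent of the sweep-line implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from heraldspec.timetags import TagStream


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_stream(channels, times, duration_s=1.0, **meta) -> TagStream:
    """Build a sorted TagStream from raw (channel, time) values."""
    ch = np.asarray(channels, dtype=np.int16)
    tm = np.asarray(times, dtype=np.int64)
    order = np.lexsort((ch, tm))
    full_meta = {"duration_s": duration_s}
    full_meta.update(meta)
    return TagStream(ch[order], tm[order], full_meta)


def random_stream(rng, n_heralds=30, n2=20, n3=20, t_max=200_000, duration_s=1.0) -> TagStream:
    """Small random three-channel stream for oracle comparisons."""
    ch = np.concatenate(
        [
            np.full(n_heralds, 1),
            np.full(n2, 2),
            np.full(n3, 3),
        ]
    )
    tm = rng.integers(0, t_max, size=ch.size)
    return make_stream(ch, tm, duration_s=duration_s)


# -- oracles ------------------------------------------------------------------


def brute_force_xcorr(heralds, partners, bin_ps, window_ps):
    """All-pairs delay histogram: the O(n*m) reference for crosscorrelate."""
    K = int(window_ps // bin_ps)
    half = K * bin_ps
    counts = np.zeros(2 * K, dtype=np.int64)
    for h in heralds:
        for p in partners:
            d = int(p) - int(h)
            if -half <= d < half:
                counts[(d + half) // bin_ps] += 1
    edges = np.arange(-K, K + 1, dtype=np.int64) * bin_ps
    return edges, counts


def brute_force_gated(heralds, d2, d3, gate_ps, offset_ps=0):
    """Per-herald interval scan for gated singles/coincidences.

    A tag belongs to the most recent herald whose gate covers it, i.e. each
    gate is truncated at the next herald's gate start."""
    heralds = np.sort(np.asarray(heralds, dtype=np.int64))
    N2 = N3 = NC = 0
    for i, h in enumerate(heralds):
        start = h + offset_ps
        end = start + gate_ps
        if i + 1 < heralds.size:
            end = min(end, heralds[i + 1] + offset_ps)
        got2 = any(start <= t < end for t in d2)
        got3 = any(start <= t < end for t in d3)
        N2 += got2
        N3 += got3
        NC += got2 and got3
    return int(heralds.size), N2, N3, NC


def brute_force_pn(heralds, fluor, gate_ps, offset_ps=0):
    """Reference herald-count distribution by explicit counter walking."""
    heralds = np.sort(np.asarray(heralds, dtype=np.int64))
    fluor = np.sort(np.asarray(fluor, dtype=np.int64))
    counts: dict[int, int] = {}
    since = 0
    for i, h in enumerate(heralds):
        since += 1
        start = h + offset_ps
        end = start + gate_ps
        if i + 1 < heralds.size:
            end = min(end, heralds[i + 1] + offset_ps)
        n_tags = int(np.sum((fluor >= start) & (fluor < end)))
        if n_tags >= 1:
            counts[since] = counts.get(since, 0) + 1
            counts[0] = counts.get(0, 0) + (n_tags - 1)
            since = 0
    return counts
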