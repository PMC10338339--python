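"""Data model and I/O for multi-channel photon time-tag streams.

Timestamps are 64-bit integer picoseconds since acquisition start; all
analysis stays integer-exact until histograms are normalized.  The on-disk
format is a tab-separated ``channel<TAB>time`` body preceded by a
``#``-prefixed ``key=value`` metadata header (values JSON-encoded), so that
streams are inspectable and diff-able and round-trip bit-exactly.

Channel conventions: 1 = herald detector (D1), 2 = D2, 3 = D3,
0 = incident-residue monitor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TimeTag",
    "TagStream",
    "DelayHistogram",
    "write_stream",
    "read_stream",
    "stream_rates",
    "channel_times",
]

_MAGIC = "heraldspec-timetags v1"
_DEFAULT_CHANNELS = frozenset({0, 1, 2, 3})

PS_PER_S = 10**12


class TimeTag(NamedTuple):
    """One detection event: a small integer channel label and an integer
    picosecond timestamp."""

    channel: int
    time: int


@dataclass
class TagStream:
    """Time-ordered multi-channel collection of detection events.

    Parameters
    ----------
    channels, times :
        Parallel arrays (any integer dtype; stored as int16/int64).
    meta :
        Mapping with at least ``duration_s``; conventionally also
        ``repetition_rate_hz``, ``channel_roles`` (str channel -> role),
        ``seed`` and, for simulated streams, the generating ``config``.

    Tags must be sorted by time with ties broken by ascending channel.
    """

    channels: np.ndarray
    times: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int16)
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.channels.shape != self.times.shape or self.channels.ndim != 1:
            raise ValueError("channels and times must be parallel 1-D arrays")
        self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_tags(cls, tags: Sequence[TimeTag], meta: Mapping | None = None) -> "TagStream":
        ch = np.fromiter((t.channel for t in tags), dtype=np.int16, count=len(tags))
        tm = np.fromiter((t.time for t in tags), dtype=np.int64, count=len(tags))
        order = np.lexsort((ch, tm))
        return cls(ch[order], tm[order], dict(meta or {}))

    # -- invariants -----------------------------------------------------------

    @property
    def declared_channels(self) -> frozenset[int]:
        roles = self.meta.get("channel_roles")
        if roles:
            return frozenset(int(k) for k in roles)
        return _DEFAULT_CHANNELS

    @property
    def duration_s(self) -> float:
        return float(self.meta.get("duration_s", 0.0))

    def validate(self) -> None:
        if self.times.size:
            if self.times.min() < 0:
                raise ValueError("negative timestamp in stream")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("timestamps not sorted")
            declared = self.declared_channels
            present = set(np.unique(self.channels).tolist())
            unknown = present - declared
            if unknown:
                raise ValueError(f"unknown channel(s) {sorted(unknown)}; declared {sorted(declared)}")
            if self.duration_s > 0 and self.times.max() > self.duration_s * PS_PER_S:
                raise ValueError("timestamp beyond declared acquisition duration")

    # -- sequence protocol ----------------------------------------------------

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[TimeTag]:
        for c, t in zip(self.channels, self.times):
            yield TimeTag(int(c), int(t))

    def __getitem__(self, i: int) -> TimeTag:
        return TimeTag(int(self.channels[i]), int(self.times[i]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagStream):
            return NotImplemented
        return (
            np.array_equal(self.channels, other.channels)
            and np.array_equal(self.times, other.times)
            and self.meta == other.meta
        )


@dataclass
class DelayHistogram:
    """Binned delay/coincidence histogram with uniform picosecond bins.

    ``counts`` are raw non-negative integers when ``normalization == "none"``;
    use :meth:`normalized_counts` for the peak- or area-normalized view
    (raw counts are always retained for fitting).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if widths.size and not np.all(widths == widths[0]):
            raise ValueError("bin edges must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def bin_width(self) -> int:
        return int(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def normalized_counts(self, mode: str = "peak") -> np.ndarray:
        c = self.counts.astype(float)
        if mode == "none":
            return c
        if mode == "peak":
            m = c.max() if c.size else 0.0
            return c / m if m > 0 else c
        if mode == "area":
            s = c.sum() * self.bin_width
            return c / s if s > 0 else c
        raise ValueError(f"unknown normalization {mode!r}")

    def to_table(self) -> str:
        lines = ["# left_edge_ps\tright_edge_ps\tcounts"]
        for lo, hi, n in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
            lines.append(f"{lo}\t{hi}\t{n}")
        return "\n".join(lines) + "\n"


# -- I/O ----------------------------------------------------------------------


def write_stream(stream: TagStream, path: str | Path) -> None:
    """Write a stream to ``path`` in the package's text format.

    The output is self-describing: a ``# key=value`` header (JSON values)
    followed by ``channel<TAB>time`` rows.  :func:`read_stream` inverts it
    bit-exactly.
    """
    stream.validate()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {_MAGIC}\n")
        for key, val in stream.meta.items():
            fh.write(f"# {key}={json.dumps(val)}\n")
        np.savetxt(
            fh,
            np.column_stack([stream.channels.astype(np.int64), stream.times]),
            fmt="%d",
            delimiter="\t",
        )


def read_stream(path: str | Path) -> TagStream:
    """Read a stream written by :func:`write_stream` (or a conforming
    two-column import).

    Unsorted rows are re-sorted with a warning; malformed rows raise a
    ``ValueError`` naming the offending line; unknown channels and negative
    timestamps are rejected by stream validation.
    """
    path = Path(path)
    meta: dict = {}
    channels: list[int] = []
    times: list[int] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body == _MAGIC:
                    continue
                key, sep, val = body.partition("=")
                if sep:
                    try:
                        meta[key.strip()] = json.loads(val)
                    except json.JSONDecodeError:
                        meta[key.strip()] = val
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields")
            try:
                channels.append(int(parts[0]))
                times.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc

    ch = np.asarray(channels, dtype=np.int16)
    tm = np.asarray(times, dtype=np.int64)
    if tm.size and np.any(np.diff(tm) < 0):
        warnings.warn(f"{path}: unsorted time tags; re-sorting", stacklevel=2)
        order = np.lexsort((ch, tm))
        ch, tm = ch[order], tm[order]
    return TagStream(ch, tm, meta)


# -- derived quantities -------------------------------------------------------


def stream_rates(stream: TagStream) -> dict[int, float]:
    """Per-channel tag rate in counts/s over the declared duration.

    Declared-but-empty channels report 0.  Raises on zero duration.
    """
    dur = stream.duration_s
    if dur <= 0:
        raise ValueError("stream duration must be positive to compute rates")
    rates = {ch: 0.0 for ch in sorted(stream.declared_channels)}
    present, counts = np.unique(stream.channels, return_counts=True)
    for ch, n in zip(present, counts):
        rates[int(ch)] = float(n) / dur
    return rates


def channel_times(stream: TagStream, channel: int) -> np.ndarray:
    """Sorted int64 timestamps of one channel."""
    return stream.times[stream.channels == channel]
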