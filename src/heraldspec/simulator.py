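"""Monte Carlo stochastic-trajectory simulator of the heralded single-photon
fluorescence experiment.

Each pump pulse independently creates M photon pairs with single-mode
thermal statistics of mean ``n_p``.  The herald arm is a lossy click
detector (at most one tag per pulse) with a configurable heralding law:

* ``herald_model="per-pulse"`` (default): a pulse with >= 1 pair yields a
  herald click with probability ``eta_herald`` regardless of M, so the
  heralded pulses carry exactly the M >= 1 conditional thermal weights
  ``n_p**(M-1)/(1+n_p)**M`` and the measured conditional g2(0) follows
  ``2*n_p/(1+n_p)``.  This is the counting model behind the analytical
  results being reproduced.
* ``herald_model="per-photon"``: each of the M herald photons is detected
  independently, click probability ``1-(1-eta_herald)**M``.  Physically
  standard for a binary SPCM, but it number-weights the heralded ensemble
  and raises the conditional g2(0) well above ``2*n_p/(1+n_p)``.

Each signal photon independently yields a detected fluorescence photon
with probability ``p_detect_fluor``,
time-tagged at the pulse time plus an exponential emission delay and
Gaussian instrument jitter, and routed 50:50 to detectors 2/3 when the
beamsplitter is in place.  Homogeneous Poisson dark counts are superposed
per detector and an optional non-paralyzable dead time is applied.

Implementation notes
--------------------
* Empty pulses (M = 0, the overwhelming majority at the experimental
  ``n_p``) are skipped exactly by drawing geometric gaps between active
  pulses, so cost scales with the pair rate, not the pulse rate.
* Randomness derives from one root seed via per-block counter-derived
  substreams (fixed block size), so a given (config, seed) is
  bit-reproducible regardless of how execution is chunked.
* Heralds carry no timing jitter: the herald detector is the timing
  reference, so ``irf_sigma`` is both the per-detection jitter of the
  signal-side detectors and the width of any herald-referenced
  cross-correlation (the IRF the lifetime fit must undo).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .correlator import herald_count_distribution, HeraldCountDistribution
from .timetags import PS_PER_S, TagStream

__all__ = [
    "ExperimentConfig",
    "TrajectoryLog",
    "simulate",
    "simulate_pn_experiment",
    "expected_herald_rate",
    "eta_for_herald_rate",
    "expected_e_hf",
]

#: pulses per RNG block; fixed so substreams are chunking-independent
_BLOCK = 1 << 20

# printed-rate defaults: R_h / R_p and R_hf / R_h at the highest pair rate
DEFAULT_R_R = 75.7e6
DEFAULT_N_P = 0.0458
DEFAULT_ETA_HERALD = 9.73e5 / 3.47e6
DEFAULT_E_HF = 1.244e-4


@dataclass
class ExperimentConfig:
    """All physical and instrument parameters of one simulated run.

    ``p_detect_fluor`` lumps every loss from the pair source through the
    sample to the fluorescence detector, so to first order it equals the
    observable heralded-fluorescence channel efficiency e_hf.
    """

    n_p: float = DEFAULT_N_P
    R_r: float = DEFAULT_R_R
    eta_herald: float = DEFAULT_ETA_HERALD
    p_detect_fluor: float = DEFAULT_E_HF
    p_detect_residue: float = 0.0
    tau_fl: float = 1200.0  # ps
    irf_sigma: float = 150.0  # ps
    gate_fluor: int = 10_000  # ps
    gate_incident: int = 6_000  # ps
    dark_rates: dict = field(default_factory=dict)  # channel -> counts/s
    dead_time: float = 0.0  # ps, per detector, non-paralyzable
    splitter: bool = False  # 50:50 routing of detections to channels 2/3
    no_sample: bool = False  # incident-photon variant: no emission delay
    herald_model: str = "per-pulse"  # "per-pulse" | "per-photon", see module docstring
    duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.herald_model not in ("per-pulse", "per-photon"):
            raise ValueError(f"unknown herald_model {self.herald_model!r}")
        for name in ("eta_herald", "p_detect_fluor", "p_detect_residue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_p", "R_r", "tau_fl", "irf_sigma", "dead_time", "duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.R_r <= 0:
            raise ValueError("R_r must be positive")
        if self.gate_fluor <= 0 or self.gate_incident <= 0:
            raise ValueError("gate lengths must be positive")
        if any(r < 0 for r in self.dark_rates.values()):
            raise ValueError("dark rates must be non-negative")

    @property
    def n_pulses(self) -> int:
        return int(self.duration_s * self.R_r)

    @property
    def gate_ps(self) -> int:
        return self.gate_incident if self.no_sample else self.gate_fluor

    def channel_roles(self) -> dict[str, str]:
        roles = {"1": "herald"}
        partner = "incident" if self.no_sample else "fluorescence"
        if self.splitter:
            roles["2"] = f"{partner}-D2"
            roles["3"] = f"{partner}-D3"
        else:
            roles["2"] = partner
        if self.p_detect_residue > 0:
            roles["0"] = "incident-residue"
        for ch in self.dark_rates:
            roles.setdefault(str(ch), "dark-only")
        return roles

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "dark_rates" in d and d["dark_rates"]:
            d["dark_rates"] = {int(k): float(v) for k, v in d["dark_rates"].items()}
        return cls(**d)


@dataclass
class TrajectoryLog:
    """Per-active-pulse diagnostic record of the stochastic trajectories."""

    pulse_index: np.ndarray  # global pulse number k (t_k = k / R_r)
    n_pairs: np.ndarray  # M drawn for the pulse
    herald_click: np.ndarray  # bool
    n_fluor_detected: np.ndarray  # detections before click-collapse
    emission_delays: np.ndarray  # true exponential delays (ps, float)


def expected_herald_rate(config: ExperimentConfig) -> float:
    """Exact herald click rate implied by the config.

    per-pulse model: R_r * eta * n_p/(1+n_p); per-photon model:
    R_r * (1 - pgf(1-eta)) = R_r * n_p*eta / (1 + n_p*eta).
    """
    if config.herald_model == "per-pulse":
        return config.R_r * config.eta_herald * config.n_p / (1.0 + config.n_p)
    x = config.n_p * config.eta_herald
    return config.R_r * x / (1.0 + x)


def eta_for_herald_rate(
    R_h: float,
    n_p: float,
    R_r: float = DEFAULT_R_R,
    herald_model: str = "per-pulse",
) -> float:
    """Herald-arm efficiency that reproduces a target click rate R_h.

    Inverts :func:`expected_herald_rate`; for small occupancies this is
    close to (but slightly above) the naive ratio R_h / (n_p * R_r).
    """
    x = R_h / R_r
    if not 0 <= x < 1:
        raise ValueError("R_h must be below R_r")
    if herald_model == "per-pulse":
        eta = x * (1.0 + n_p) / n_p
    else:
        eta = x / (n_p * (1.0 - x))
    if eta > 1:
        raise ValueError("target herald rate unreachable with eta <= 1")
    return eta


def expected_e_hf(config: ExperimentConfig, max_m: int = 200) -> float:
    """Exact heralded-fluorescence-per-herald ratio implied by the config.

    Equals ``p_detect_fluor`` to first order; the finite-``n_p`` correction
    is ``(1 + n_p)``-sized for the per-pulse herald model.
    """
    M = np.arange(1, max_m + 1)
    p0 = 1.0 / (1.0 + config.n_p)
    pmf = p0 * (1.0 - p0) ** M
    if config.herald_model == "per-pulse":
        w = pmf
    else:
        w = pmf * (1.0 - (1.0 - config.eta_herald) ** M)
    w = w / w.sum()
    return float((w * (1.0 - (1.0 - config.p_detect_fluor) ** M)).sum())


def _active_pulses(rng: np.random.Generator, block_size: int, q: float) -> np.ndarray:
    """Indices (within the block) of pulses with at least one pair.

    Each pulse is active independently with probability q; gaps between
    active pulses are iid Geometric(q), which is sampled directly so cost
    is O(active pulses)."""
    if q <= 0.0:
        return np.empty(0, dtype=np.int64)
    if q >= 0.5:
        return np.nonzero(rng.random(block_size) < q)[0].astype(np.int64)
    chunks = []
    pos = -1
    batch = int(block_size * q + 10.0 * math.sqrt(block_size * q) + 16.0)
    while True:
        gaps = rng.geometric(q, size=batch)
        cum = pos + np.cumsum(gaps)
        inside = cum[cum < block_size]
        chunks.append(inside)
        if inside.size < cum.size:  # crossed the block boundary
            break
        pos = int(cum[-1])
    return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)


def _collapse_clicks(keys: np.ndarray, times: np.ndarray, extra: np.ndarray | None = None):
    """Non-number-resolving click detector: keep the earliest tag per key
    (key encodes pulse and channel)."""
    order = np.lexsort((times, keys))
    keys, times = keys[order], times[order]
    first = np.ones(keys.size, dtype=bool)
    first[1:] = keys[1:] != keys[:-1]
    if extra is not None:
        return times[first], extra[order][first]
    return times[first], None


def _apply_dead_time(times: np.ndarray, dead_ps: float) -> np.ndarray:
    """Non-paralyzable dead time on a sorted single-channel tag sequence."""
    if dead_ps <= 0 or times.size == 0:
        return times
    keep = np.zeros(times.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):  # rare path; dead_time defaults to 0
        if t - last >= dead_ps:
            keep[i] = True
            last = t
    return times[keep]


def simulate(
    config: ExperimentConfig,
    return_log: bool = False,
) -> TagStream | tuple[TagStream, TrajectoryLog]:
    """Run the stochastic-trajectory model and emit a sorted TagStream.

    See the module docstring for the physical model.  The output stream's
    ``meta`` records the generating config and seed.
    """
    if config.n_pulses < 1:
        raise ValueError("duration_s * R_r must cover at least one pulse")
    n_pulses = config.n_pulses
    duration_ps = int(round(config.duration_s * PS_PER_S))
    period_ps = PS_PER_S / config.R_r
    p0 = 1.0 / (1.0 + config.n_p)  # geometric success prob; P(M = 0)
    q = config.n_p * p0  # P(M >= 1)

    ch_parts: list[np.ndarray] = []
    t_parts: list[np.ndarray] = []
    log_parts: list[tuple] = [] if return_log else None

    for block_i, b0 in enumerate(range(0, n_pulses, _BLOCK)):
        bsize = min(_BLOCK, n_pulses - b0)
        rng = np.random.default_rng([int(config.seed), 0x5EED, block_i])
        act = _active_pulses(rng, bsize, q)
        if act.size == 0:
            continue
        M = rng.geometric(p0, size=act.size).astype(np.int64)  # M | M >= 1
        t_pulse = np.round((b0 + act) * period_ps).astype(np.int64)

        # herald arm (see module docstring for the two heralding laws)
        if config.eta_herald >= 1.0:
            click = np.ones(act.size, dtype=bool)
        elif config.eta_herald <= 0.0:
            click = np.zeros(act.size, dtype=bool)
        elif config.herald_model == "per-pulse":
            click = rng.random(act.size) < config.eta_herald
        else:
            p_click = -np.expm1(M * np.log1p(-config.eta_herald))
            click = rng.random(act.size) < p_click
        if click.any():
            ch_parts.append(np.full(int(click.sum()), 1, dtype=np.int16))
            t_parts.append(t_pulse[click])

        # signal arm: per-photon detection, emission delay, jitter, routing
        n_det = rng.binomial(M, config.p_detect_fluor)
        det_pulse = np.repeat(np.arange(act.size), n_det)
        total = det_pulse.size
        delays = np.zeros(total)
        if total:
            if not config.no_sample:
                delays = rng.exponential(config.tau_fl, size=total)
            jitter = rng.normal(0.0, config.irf_sigma, size=total) if config.irf_sigma > 0 else 0.0
            t_det = t_pulse[det_pulse] + np.round(delays + jitter).astype(np.int64)
            if config.splitter:
                route = rng.integers(0, 2, size=total).astype(np.int64)  # 0 -> D2, 1 -> D3
            else:
                route = np.zeros(total, dtype=np.int64)
            key = det_pulse * 2 + route
            t_keep, route_keep = _collapse_clicks(key, t_det, route)
            ch_parts.append((2 + route_keep).astype(np.int16))
            t_parts.append(t_keep)

        # incident-residue monitor (channel 0): click detector at pulse time
        if config.p_detect_residue > 0:
            n_res = rng.binomial(M, config.p_detect_residue)
            has = n_res > 0
            if has.any():
                nr = int(has.sum())
                jit = rng.normal(0.0, config.irf_sigma, size=nr) if config.irf_sigma > 0 else 0.0
                t_res = t_pulse[has] + np.round(jit).astype(np.int64)
                ch_parts.append(np.zeros(nr, dtype=np.int16))
                t_parts.append(t_res)

        if return_log:
            log_parts.append((b0 + act, M, click, n_det, delays))

    # dark counts: homogeneous Poisson per declared dark channel
    for ch, rate in sorted(config.dark_rates.items()):
        if rate <= 0:
            continue
        rng_d = np.random.default_rng([int(config.seed), 0xDA2C, int(ch)])
        n_dark = rng_d.poisson(rate * config.duration_s)
        if n_dark:
            ch_parts.append(np.full(n_dark, ch, dtype=np.int16))
            t_parts.append(rng_d.integers(0, duration_ps, size=n_dark, dtype=np.int64))

    if ch_parts:
        channels = np.concatenate(ch_parts)
        times = np.concatenate(t_parts)
    else:
        channels = np.empty(0, dtype=np.int16)
        times = np.empty(0, dtype=np.int64)

    # clamp to the acquisition window (jitter can push tags past the edges)
    ok = (times >= 0) & (times <= duration_ps)
    channels, times = channels[ok], times[ok]

    if config.dead_time > 0:
        kept_ch, kept_t = [], []
        for ch in np.unique(channels):
            sel = channels == ch
            t_ch = np.sort(times[sel])
            t_ch = _apply_dead_time(t_ch, config.dead_time)
            kept_ch.append(np.full(t_ch.size, ch, dtype=np.int16))
            kept_t.append(t_ch)
        channels = np.concatenate(kept_ch) if kept_ch else channels
        times = np.concatenate(kept_t) if kept_t else times

    order = np.lexsort((channels, times))
    stream = TagStream(
        channels[order],
        times[order],
        meta={
            "repetition_rate_hz": config.R_r,
            "duration_s": config.duration_s,
            "channel_roles": config.channel_roles(),
            "seed": int(config.seed),
            "config": config.to_dict(),
        },
    )
    if return_log:
        log = TrajectoryLog(
            pulse_index=np.concatenate([p[0] for p in log_parts]) if log_parts else np.empty(0, np.int64),
            n_pairs=np.concatenate([p[1] for p in log_parts]) if log_parts else np.empty(0, np.int64),
            herald_click=np.concatenate([p[2] for p in log_parts]) if log_parts else np.empty(0, bool),
            n_fluor_detected=np.concatenate([p[3] for p in log_parts]) if log_parts else np.empty(0, np.int64),
            emission_delays=np.concatenate([p[4] for p in log_parts]) if log_parts else np.empty(0, float),
        )
        return stream, log
    return stream


def simulate_pn_experiment(
    config: ExperimentConfig,
    repeats: int = 1,
) -> HeraldCountDistribution | list[HeraldCountDistribution]:
    """Simulate and reduce to the heralds-per-fluorescence distribution.

    With ``repeats > 1``, runs independent replicas with counter-derived
    sub-seeds (for noise-versus-integration-time studies) and returns a
    list; with ``repeats == 1`` returns the single distribution.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    out = []
    for r in range(repeats):
        cfg = config if repeats == 1 else replace(config, seed=_subseed(config.seed, r))
        stream = simulate(cfg)
        out.append(herald_count_distribution(stream, gate_ps=cfg.gate_ps))
    return out[0] if repeats == 1 else out


def _subseed(root: int, index: int) -> int:
    """Deterministic independent sub-seed derived from (root, index)."""
    ss = np.random.SeedSequence([int(root), 0x9E37, int(index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFF_FFFF_FFFF_FFFF)
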