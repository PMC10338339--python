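"""Closed-form counting-statistics models for a pulsed heralded pair source.

The pair number per pump pulse is modelled as single-mode thermal
(geometric) with mean ``n_p``; conditioning on at least one pair gives the
multi-photon weights ``n_p**(M-1) / (1+n_p)**M``.  The number of heralds per
heralded fluorescence detection is geometric with success probability
``e_hf`` (zero mass at N = 0), which for ``e_hf << 1`` reduces to an
exponential tail ``P(N) ∝ exp(-N*e_hf)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .correlator import HeraldCountDistribution

__all__ = [
    "SourceStats",
    "ChannelEfficiency",
    "GeometricFit",
    "pair_number_pmf",
    "multiphoton_weight",
    "heralded_g2_theory",
    "geometric_pn",
    "exp_tail_approx",
    "fit_geometric",
]


@dataclass(frozen=True)
class SourceStats:
    """Pair-source rate bookkeeping: ``n_p = R_p / R_r``."""

    n_p: float
    R_p: float
    R_r: float

    def __post_init__(self) -> None:
        if self.n_p < 0 or self.R_p < 0 or self.R_r <= 0:
            raise ValueError("rates must be non-negative, R_r positive")
        if not np.isclose(self.n_p, self.R_p / self.R_r, rtol=1e-6):
            raise ValueError("n_p inconsistent with R_p / R_r")

    @classmethod
    def from_rates(cls, R_p: float, R_r: float) -> "SourceStats":
        return cls(n_p=R_p / R_r, R_p=R_p, R_r=R_r)


@dataclass(frozen=True)
class ChannelEfficiency:
    """Heralded-fluorescence channel efficiency: ``e_hf = R_hf / R_h``."""

    e_hf: float
    R_hf: float
    R_h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_hf <= 1.0:
            raise ValueError("e_hf must lie in [0, 1]")

    @classmethod
    def from_rates(cls, R_hf: float, R_h: float) -> "ChannelEfficiency":
        if R_h <= 0:
            raise ValueError("herald rate must be positive")
        return cls(e_hf=R_hf / R_h, R_hf=R_hf, R_h=R_h)


def pair_number_pmf(n_p: float, M) -> np.ndarray | float:
    """P(M pairs in a pulse) for a single-mode thermal source of mean n_p.

    ``P(M) = n_p**M / (1 + n_p)**(M + 1)``, normalized over M >= 0 with
    mean ``n_p``.  Vectorized over ``M``.
    """
    if n_p < 0:
        raise ValueError("n_p must be non-negative")
    M_arr = np.asarray(M)
    if np.any(M_arr < 0) or not np.issubdtype(M_arr.dtype, np.integer):
        raise ValueError("M must be a non-negative integer")
    if n_p == 0:
        out = np.where(M_arr == 0, 1.0, 0.0)
    else:
        # log-space to stay finite for large M
        out = np.exp(M_arr * np.log(n_p) - (M_arr + 1) * np.log1p(n_p))
    return out if out.ndim else float(out)


def multiphoton_weight(n_p: float, M) -> np.ndarray | float:
    """Weight of the M-photon component among heralded pulses (M >= 1).

    ``w(M) = n_p**(M-1) / (1 + n_p)**M``; the weights form a geometric
    series summing to 1 over M >= 1.
    """
    if n_p < 0:
        raise ValueError("n_p must be non-negative")
    M_arr = np.asarray(M)
    if np.any(M_arr < 1) or not np.issubdtype(M_arr.dtype, np.integer):
        raise ValueError("M must be an integer >= 1")
    if n_p == 0:
        out = np.where(M_arr == 1, 1.0, 0.0)
    else:
        out = np.exp((M_arr - 1) * np.log(n_p) - M_arr * np.log1p(n_p))
    return out if out.ndim else float(out)


def heralded_g2_theory(n_p: float) -> float:
    """Theoretical conditional g2(0) for heralded detections: 2*n_p/(1+n_p).

    Zero for an ideal single-photon source, strictly increasing, < 2.
    """
    if n_p < 0:
        raise ValueError("n_p must be non-negative")
    return 2.0 * n_p / (1.0 + n_p)


def geometric_pn(e_hf: float, N) -> np.ndarray | float:
    """Geometric herald-count distribution.

    ``P(N) = e_hf * (1 - e_hf)**(N - 1)`` for N = 1, 2, 3, ... and
    ``P(0) = 0``.  Normalized over N >= 1 with mean ``1/e_hf`` and mode at
    N = 1.
    """
    if not 0.0 < e_hf <= 1.0:
        raise ValueError("e_hf must lie in (0, 1]")
    N_arr = np.asarray(N)
    if np.any(N_arr < 0) or not np.issubdtype(N_arr.dtype, np.integer):
        raise ValueError("N must be a non-negative integer")
    exponent = np.maximum(N_arr - 1, 0)
    out = np.where(N_arr >= 1, e_hf * (1.0 - e_hf) ** exponent, 0.0)
    return out if out.ndim else float(out)


#: warn when the exponential-tail approximation is requested outside its
#: small-efficiency validity regime
_EXP_TAIL_VALIDITY = 1e-2


def exp_tail_approx(e_hf: float, N) -> np.ndarray | float:
    """Small-``e_hf`` exponential-tail approximation to :func:`geometric_pn`.

    Returns ``e_hf * exp(-(N - 1) * e_hf)`` for N >= 1 (zero at N = 0), so
    that ``log P`` is linear in N with slope ``-e_hf``.  The relative
    deviation from the exact geometric law is bounded by ``N * e_hf**2 / 2``
    (so <= 0.51% for ``e_hf <= 1e-3`` over ``N <= 10 / e_hf``; verified
    numerically in the test suite).  Warns outside the validity regime
    ``e_hf <= 1e-2``.
    """
    if not 0.0 < e_hf < 1.0:
        raise ValueError("e_hf must lie in (0, 1)")
    if e_hf > _EXP_TAIL_VALIDITY:
        warnings.warn(
            f"exp_tail_approx valid only for e_hf << 1 (got {e_hf:g})",
            stacklevel=2,
        )
    N_arr = np.asarray(N)
    if np.any(N_arr < 0) or not np.issubdtype(N_arr.dtype, np.integer):
        raise ValueError("N must be a non-negative integer")
    out = np.where(N_arr >= 1, e_hf * np.exp(-(N_arr - 1.0) * e_hf), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GeometricFit:
    """Maximum-likelihood geometric fit of a herald-count distribution."""

    e_hf: float
    se: float
    n_events: int

    def __iter__(self):
        return iter((self.e_hf, self.se))


def fit_geometric(dist: "HeraldCountDistribution") -> GeometricFit:
    """ML estimate of ``e_hf`` from an empirical herald-count distribution.

    The N = 0 bin (double-fluorescence events) carries zero probability
    under the geometric law and is excluded from the likelihood.  For the
    geometric distribution on N >= 1 the MLE is ``1 / mean(N)`` and the
    standard error from the observed Fisher information is
    ``sqrt(e**2 * (1 - e) / n)``.
    """
    counts = np.asarray(dist.counts, dtype=np.int64)
    ns = np.arange(counts.size)
    mask = ns >= 1
    n = int(counts[mask].sum())
    if n < 1:
        raise ValueError("no events with N >= 1 to fit")
    mean_n = float((ns[mask] * counts[mask]).sum()) / n
    e_hat = 1.0 / mean_n
    se = float(np.sqrt(e_hat**2 * (1.0 - e_hat) / n))
    return GeometricFit(e_hf=e_hat, se=se, n_events=n)
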