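"""Movement statistics: visit counts, revisit-tail fits, MSD, density maps.

The headline statistic is the per-trial number of distinct visited
sites.  The shape of the per-site revisit-count distribution is
arbitrated between a discrete power law and a discrete exponential
(geometric) by maximum likelihood and Akaike weights: a power-law tail
is the signature of weak home-range behaviour (a few sites revisited
thousands of times alongside many sites visited once), while the
random-choice control produces an exponential tail.  Mean-squared
displacement from the fixed start position, ⟨R²(t)⟩, distinguishes
confined movement (saturating MSD) from free diffusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .core import VisitLog

__all__ = [
    "RevisitDistribution",
    "TailFitResult",
    "MSDSeries",
    "DensityMap",
    "distinct_visited",
    "revisit_distribution",
    "fit_tail",
    "sample_discrete_power_law",
    "mean_squared_displacement",
    "density_map",
]

_MU_MAX = 50.0  # search bound for the power-law exponent


def distinct_visited(log: VisitLog) -> int:
    """Number of unique sites visited during a trial."""
    return len({sid for _, sid in log.events})


@dataclass
class RevisitDistribution:
    """Per-site visit counts from one trial's visit events."""

    counts: dict[int, int]
    n_data: int

    def values(self) -> np.ndarray:
        return np.array(sorted(self.counts.values()), dtype=int)

    def survival(self) -> pd.DataFrame:
        """Cumulative (survival) form: P(visits >= x) for plotting."""
        v = self.values()
        xs = np.unique(v)
        surv = np.array([(v >= x).mean() for x in xs])
        return pd.DataFrame({"n_visits": xs, "p_ge": surv})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["site_id", "n_visits"]
        )


def revisit_distribution(log: VisitLog) -> RevisitDistribution:
    counts: dict[int, int] = {}
    for _, sid in log.events:
        counts[sid] = counts.get(sid, 0) + 1
    return RevisitDistribution(counts=counts, n_data=len(counts))


# ---------------------------------------------------------------------------
# Tail fitting: discrete power law vs discrete exponential, AIC weights
# ---------------------------------------------------------------------------

@dataclass
class TailFitResult:
    family: str  # "power_law" | "exponential"
    exponent: float  # mu for the power law, rate lambda for the exponential
    log_likelihood: float
    aic: float
    akaike_weight: float
    n_data: int


def _power_law_mle(x: np.ndarray) -> tuple[float, float]:
    """Zeta-normalised discrete power law on x >= 1: p(x) = x^-mu / zeta(mu)."""
    n = len(x)
    slx = np.log(x).sum()

    def nll(mu: float) -> float:
        return mu * slx + n * np.log(zeta(mu))

    res = minimize_scalar(nll, bounds=(1.0 + 1e-9, _MU_MAX), method="bounded")
    return float(res.x), float(-res.fun)


def _exponential_mle(x: np.ndarray) -> tuple[float, float]:
    """Discrete exponential on x >= 1: p(x) = (1 - e^-lam) e^-lam(x-1)."""
    n = len(x)
    m = x.mean()
    if m <= 1.0:  # all counts equal to 1: point mass, lam -> inf
        return np.inf, 0.0
    q = (m - 1.0) / m
    lam = -np.log(q)
    logl = n * np.log(1.0 - q) + (x.sum() - n) * np.log(q)
    return float(lam), float(logl)


def fit_tail(counts: Sequence[int]) -> tuple[TailFitResult, TailFitResult]:
    """Fit power-law and exponential tails to positive-integer counts.

    Both families are one-parameter discrete distributions with support
    x >= 1, fitted by maximum likelihood on the same data; AIC = 2 - 2
    logL and Akaike weights are normalised over the pair.  Returns
    ``(power_law_fit, exponential_fit)``.
    """
    x = np.asarray(counts, dtype=float)
    if len(x) == 0:
        raise ValueError("fit_tail requires a non-empty count vector")
    if np.any(x < 1) or np.any(x != np.round(x)):
        raise ValueError("counts must be positive integers")
    if np.all(x == x[0]):
        warnings.warn("all counts equal: tail fit is degenerate", stacklevel=2)

    mu, logl_p = _power_law_mle(x)
    lam, logl_e = _exponential_mle(x)
    aic_p = 2.0 - 2.0 * logl_p
    aic_e = 2.0 - 2.0 * logl_e
    d = np.array([aic_p, aic_e])
    w = np.exp(-(d - d.min()) / 2.0)
    w /= w.sum()
    n = len(x)
    return (
        TailFitResult("power_law", mu, logl_p, aic_p, float(w[0]), n),
        TailFitResult("exponential", lam, logl_e, aic_e, float(w[1]), n),
    )


def sample_discrete_power_law(
    mu: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the zeta-normalised discrete power law with exponent mu."""
    if mu <= 1.0:
        raise ValueError("mu must exceed 1 for a normalisable zeta law")
    return rng.zipf(mu, size)


# ---------------------------------------------------------------------------
# Mean-squared displacement
# ---------------------------------------------------------------------------

@dataclass
class MSDSeries:
    """Binned ⟨R²(t)⟩ curve paired with t² of the bin midpoints."""

    t: np.ndarray
    t2: np.ndarray
    mean_r2: np.ndarray
    bin_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "t2": self.t2, "mean_R2": self.mean_r2})

    def r2_near(self, t: float) -> float:
        """mean_R2 of the bin whose midpoint is closest to t."""
        return float(self.mean_r2[np.argmin(np.abs(self.t - t))])


def mean_squared_displacement(
    logs: Iterable[VisitLog], bin_size: int = 10
) -> MSDSeries:
    """Trial-averaged squared displacement from the start, binned in time.

    R²(t) is the squared Euclidean distance of the agent from its trial
    start position at step t; it is averaged across trials at each step
    and then over ``bin_size`` consecutive steps, reported at the bin's
    midpoint t (and t²).
    """
    logs = list(logs)
    if not logs:
        raise ValueError("mean_squared_displacement requires at least one log")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_steps = logs[0].n_steps
    if any(l.n_steps != n_steps for l in logs):
        raise ValueError("all logs must share the same number of steps")
    r2 = np.zeros(n_steps)
    for log in logs:
        start = np.asarray(log.start_position, float)
        disp = log.positions[1:] - start
        r2 += (disp**2).sum(axis=1)
    r2 /= len(logs)

    n_bins = n_steps // bin_size
    if n_bins == 0:
        n_bins, bin_size = 1, n_steps
    trimmed = r2[: n_bins * bin_size].reshape(n_bins, bin_size)
    mean_r2 = trimmed.mean(axis=1)
    # steps are 1-indexed; bin k covers steps k*b+1 .. (k+1)*b
    t_mid = np.arange(n_bins) * bin_size + (bin_size + 1) / 2.0
    return MSDSeries(t=t_mid, t2=t_mid**2, mean_r2=mean_r2, bin_size=bin_size)


# ---------------------------------------------------------------------------
# Trajectory density map
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """2-D occupancy histogram of logged positions."""

    counts: np.ndarray  # shape (nx, ny), counts[ix, iy]
    bin_width: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        ix, iy = np.nonzero(self.counts)
        return pd.DataFrame(
            {"ix": ix, "iy": iy, "count": self.counts[ix, iy].astype(int)}
        )


def density_map(
    log: VisitLog,
    bin_width: float = 4.0,
    field_width: float = 100.0,
    field_height: float = 100.0,
) -> DensityMap:
    """Occupancy counts of all logged positions on a square-bin grid.

    Bins are half-open ``[k*w, (k+1)*w)``; positions exactly on the
    upper field boundary fall into the last bin so the total count
    always equals the number of logged positions.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nx = int(np.ceil(field_width / bin_width))
    ny = int(np.ceil(field_height / bin_width))
    ix = np.clip((log.positions[:, 0] // bin_width).astype(int), 0, nx - 1)
    iy = np.clip((log.positions[:, 1] // bin_width).astype(int), 0, ny - 1)
    counts = np.zeros((nx, ny), dtype=np.int64)
    np.add.at(counts, (ix, iy), 1)
    return DensityMap(counts=counts, bin_width=bin_width)
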