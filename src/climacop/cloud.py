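"""Normal cloud model: membership, backward transformation (MBCT-SR), droplets.

A cloud summarizes a qualitative concept over a numeric universe with three
parameters: the expectation Ex (center of the concept), the entropy En
(spread/fuzziness), and the hyper-entropy He (instability of the entropy).
A cloud droplet is one random realization: a per-droplet entropy
Enn ~ N(En, He^2) is drawn first, then the droplet x ~ N(Ex, Enn^2). The
backward transformation estimates (Ex, En, He) from observed samples using
resampled within-group variances: homogeneous group variances force He -> 0,
while spread in the group variances is attributed to hyper-entropy.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

RngLike = int | np.random.Generator | np.random.SeedSequence | None


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Cloud:
    """Cloud parameters (Ex, En, He); En and He are nonnegative standard deviations."""

    ex: float
    en: float
    he: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.ex, self.en, self.he)):
            raise DataError("cloud parameters must be finite")
        if self.en < 0 or self.he < 0:
            raise DataError("En and He must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ex, self.en, self.he)


@dataclass
class BackwardCloudConfig:
    """Resampling plan for the backward transformation.

    ``c`` is the within-group sample size and ``d`` the number of groups
    drawn (with replacement) from the input sample. When ``c`` is None it
    defaults to min(30, round(m/5)) with a floor of 2, so small samples still
    yield a valid plan.
    """

    c: Optional[int] = None
    d: int = 200
    seed: RngLike = None

    def __post_init__(self) -> None:
        if self.c is not None and self.c < 2:
            raise ConfigurationError("within-group size c must be >= 2")
        if self.d < 2:
            raise ConfigurationError("group count d must be >= 2")

    def resolve_c(self, m: int) -> int:
        if self.c is not None:
            return self.c
        return max(2, min(30, round(m / 5)))


@dataclass
class DropletBatch:
    """A batch of droplets realized from one cloud."""

    droplets: np.ndarray
    n: int
    source: Cloud

    def __post_init__(self) -> None:
        self.droplets = np.asarray(self.droplets, dtype=float)
        if self.droplets.shape != (self.n,):
            raise DataError("droplet count mismatch")
        if not np.isfinite(self.droplets).all():
            raise DataError("droplets must be finite")

    @property
    def mean(self) -> float:
        return float(self.droplets.mean())


def membership(x: float, cloud: Cloud, enn: float) -> float:
    """Membership degree of x in the concept, at per-droplet entropy ``enn``.

    exp(-(x - Ex)^2 / (2 enn^2)); equals 1 at x = Ex and decays as a
    Gaussian bell with scale enn.
    """
    if enn <= 0:
        raise DataError("per-droplet entropy enn must be positive")
    return float(np.exp(-((x - cloud.ex) ** 2) / (2.0 * enn**2)))


def backward_cloud(samples: np.ndarray, cfg: BackwardCloudConfig | None = None) -> Cloud:
    """Estimate (Ex, En, He) from samples via multi-group variance resampling.

    Ex is the sample mean. ``d`` groups of size ``c`` are drawn with
    replacement; with t_l^2 the unbiased variance of group l,
    (ET)^2 = mean(t_l^2) and (DT)^2 = unbiased variance of the t_l^2,

        En^2 = (1/2) * sqrt(4 ((ET)^2)^2 - 2 (DT)^2),   He^2 = (ET)^2 - En^2.

    Homogeneous group variances ((DT)^2 = 0) give En^2 = (ET)^2 and He = 0.
    A negative radicand (heavy-tailed group variances) is clamped: En = 0,
    He^2 = (ET)^2, with a warning.
    """
    cfg = cfg or BackwardCloudConfig()
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.isfinite(x).all():
        raise DataError("samples must be finite")
    m = len(x)
    c = cfg.resolve_c(m)
    if m < c:
        raise DataError(f"need at least c={c} samples, got {m}")

    ex = float(x.mean())
    rng = _as_rng(cfg.seed)
    idx = rng.integers(0, m, size=(cfg.d, c))
    t2 = x[idx].var(axis=1, ddof=1)
    et2 = float(t2.mean())
    dt2 = float(t2.var(ddof=1))
    radicand = 4.0 * et2**2 - 2.0 * dt2
    if radicand < 0:
        warnings.warn(
            "backward_cloud: negative radicand (heavy-tailed group variances); "
            "clamping En to 0",
            stacklevel=2,
        )
        en2 = 0.0
    else:
        en2 = 0.5 * math.sqrt(radicand)
    he2 = max(0.0, et2 - en2)
    return Cloud(ex, math.sqrt(en2), math.sqrt(he2))


def forward_cloud(cloud: Cloud, n: int, seed: RngLike = None) -> DropletBatch:
    """Generate ``n`` droplets from a cloud.

    Per droplet: Enn ~ N(En, He^2), with |Enn| taken for non-positive draws;
    then x ~ N(Ex, Enn^2). He = 0 makes Enn = En exactly, and En = He = 0
    makes every droplet equal Ex.
    """
    if n < 1:
        raise DataError("droplet count must be >= 1")
    rng = _as_rng(seed)
    if cloud.he == 0.0:
        enn = np.full(n, cloud.en)
    else:
        enn = rng.normal(cloud.en, cloud.he, size=n)
        enn = np.abs(enn)
    x = rng.normal(cloud.ex, enn)
    return DropletBatch(droplets=x, n=n, source=cloud)
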