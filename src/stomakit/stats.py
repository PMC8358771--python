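"""Statistical analyses for stomatal traits.

Implements the three analyses a density/size phenotyping study needs:

* **Welch's two-sample t-test** (unequal variances, Welch-Satterthwaite
  degrees of freedom) for comparing per-image SD between groups;
* a **resampling power simulation**: repeatedly draw small samples from
  each group, run Welch's test, and tally how often the difference goes
  undetected (p > alpha) — quantifying how sample size and measurement
  noise trade off against statistical power;
* **Pearson's correlation test** for density-size coupling across
  microscopic fields.

The t and correlation statistics are computed from their closed forms
with p-values from the t distribution; they are exact, not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "WelchResult",
    "PearsonResult",
    "NegativeBinomialCounts",
    "PowerSimConfig",
    "PowerSimResult",
    "welch_t",
    "power_simulation",
    "pearson_test",
]


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


class PearsonResult(NamedTuple):
    r: float
    pvalue: float


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Degenerate convention: when both samples have zero variance and
    equal means, t = 0 and p = 1; zero variance with unequal means gives
    an infinite statistic and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(float(np.sign(diff)) * float("inf"),
                           float(a.size + b.size - 2), 0.0)
    sa, sb = va / a.size, vb / b.size
    t = diff / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def _welch_p_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Welch two-sided p-values for (reps, n) sample matrices."""
    na, nb = A.shape[1], B.shape[1]
    va = A.var(axis=1, ddof=1) / na
    vb = B.var(axis=1, ddof=1) / nb
    diff = A.mean(axis=1) - B.mean(axis=1)
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = np.where(
        denom == 0,
        np.where(diff == 0, 1.0, 0.0),
        2.0 * _sps.t.sf(np.abs(t), np.where(denom == 0, 1.0, df)),
    )
    return np.minimum(p, 1.0)


@dataclass(frozen=True)
class NegativeBinomialCounts:
    """Generative per-image count model: mean and dispersion.

    Variance is ``mean + mean^2 / dispersion``; ``dispersion = inf``
    degenerates to Poisson.
    """

    mean: float
    dispersion: float = float("inf")

    def sample(self, rng: np.random.Generator,
               shape: tuple[int, ...]) -> np.ndarray:
        if self.mean < 0 or not self.dispersion > 0:
            raise ValueError("invalid count model parameters")
        if self.mean == 0:
            return np.zeros(shape)
        if np.isinf(self.dispersion):
            return rng.poisson(self.mean, shape).astype(float)
        k = self.dispersion
        return rng.negative_binomial(k, k / (k + self.mean), shape
                                     ).astype(float)


@dataclass
class PowerSimConfig:
    """Configuration of the subsampling power simulation.

    ``group_a``/``group_b`` are either finite datasets of per-image
    values (counts or densities), resampled without replacement within
    each rep, or :class:`NegativeBinomialCounts` generators drawn fresh
    each rep. ``noise_sd`` adds independent Gaussian measurement error to
    every drawn value, emulating automated-count inaccuracy.
    """

    group_a: Sequence[float] | NegativeBinomialCounts
    group_b: Sequence[float] | NegativeBinomialCounts
    sample_size: int = 4
    reps: int = 10_000
    alpha: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sample_size < 2:
            raise ValueError("sample_size must be >= 2 for a t-test")
        for name in ("group_a", "group_b"):
            g = getattr(self, name)
            if not isinstance(g, NegativeBinomialCounts):
                arr = np.asarray(g, dtype=float)
                if arr.ndim != 1 or arr.size < self.sample_size:
                    raise ValueError(
                        f"{name} must be 1-D with >= sample_size values"
                    )


@dataclass(frozen=True)
class PowerSimResult:
    n_nonsignificant: int
    fraction_nonsignificant: int | float
    reps: int

    @property
    def power(self) -> float:
        return 1.0 - self.fraction_nonsignificant


def _draw_group(g, sample_size: int, reps: int,
                rng: np.random.Generator) -> np.ndarray:
    if isinstance(g, NegativeBinomialCounts):
        return g.sample(rng, (reps, sample_size))
    data = np.asarray(g, dtype=float)
    # per-rep sampling without replacement: rank random keys per row
    keys = rng.random((reps, data.size))
    idx = np.argpartition(keys, sample_size - 1, axis=1)[:, :sample_size]
    return data[idx]


def power_simulation(config: PowerSimConfig) -> PowerSimResult:
    """Tally reps where Welch's test misses the group difference.

    Each rep draws ``sample_size`` values per group (without replacement
    when resampling a finite dataset, fresh draws for a generative
    model), applies Welch's t-test, and counts outcomes with
    p > alpha. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    A = _draw_group(config.group_a, config.sample_size, config.reps, rng)
    B = _draw_group(config.group_b, config.sample_size, config.reps, rng)
    if config.noise_sd > 0:
        A = A + rng.normal(0, config.noise_sd, A.shape)
        B = B + rng.normal(0, config.noise_sd, B.shape)
    p = _welch_p_rows(A, B)
    n_ns = int(np.sum(p > config.alpha))
    return PowerSimResult(n_nonsignificant=n_ns,
                          fraction_nonsignificant=n_ns / config.reps,
                          reps=config.reps)


def pearson_test(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero variance in a sample")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    n = x.size
    if abs(r) == 1.0:
        return PearsonResult(r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return PearsonResult(r, float(min(p, 1.0)))
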