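"""Coverage estimation, coverage-based rarefaction, Hill numbers, and the
Chao-Shen entropy estimator.

All diversity values are expressed as Hill numbers ("effective numbers"):
the number of equally abundant features that would produce the observed
value of the underlying index.  Order q tunes sensitivity to rare features
(q=0 richness, q=1 exp(Shannon), q=2 inverse Simpson).  Entropies are in
nats throughout; ``exp(H)`` converts Shannon entropy to effective features.

Rarefaction here is *coverage-based*: samples are compared at equal
estimated sample coverage (the probability that the next read belongs to an
already-observed feature) rather than at equal read count.  The interpolated
diversity and coverage curves are analytic expectations under hypergeometric
subsampling, not Monte-Carlo draws; a seeded multivariate-hypergeometric
subsampler is provided as an oracle and optional mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "AbundanceVector",
    "CoverageEstimate",
    "DiversityResult",
    "good_turing_coverage",
    "expected_coverage_at_size",
    "size_at_coverage",
    "hill_number",
    "inverse_simpson",
    "rarefied_inverse_simpson",
    "rarefy_to_common_coverage",
    "subsample_without_replacement",
    "chao_shen_effective_functions",
]


class DegenerateCoverageWarning(UserWarning):
    """All features are singletons; the Good-Turing estimate is adjusted."""


@dataclass(frozen=True)
class AbundanceVector:
    """Observed counts for a single sample (positive entries only).

    Attributes
    ----------
    counts : ndarray of positive int
        Reads per observed feature.
    sample_id : str
        Identifier carried through to results.
    """

    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("abundance vector must be a non-empty 1-D count array")
        if np.any(c <= 0):
            raise ValueError("abundance vector must hold strictly positive counts")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_counts(
        cls, counts: Sequence[int] | np.ndarray, sample_id: str = ""
    ) -> "AbundanceVector":
        """Build from a full count column, dropping zero-count features."""
        c = np.asarray(counts, dtype=np.int64)
        c = c[c > 0]
        if c.size == 0:
            raise ValueError(f"sample {sample_id!r} has no observed features")
        return cls(c, sample_id=sample_id)

    @property
    def n(self) -> int:
        """Total reads in the sample."""
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        """Number of observed features."""
        return int(self.counts.size)

    def f(self, k: int) -> int:
        """Abundance-frequency count: number of features seen exactly k times."""
        return int(np.count_nonzero(self.counts == k))

    @property
    def f1(self) -> int:
        return self.f(1)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n


@dataclass(frozen=True)
class CoverageEstimate:
    value: float
    method: Literal["good_turing", "chao_jost"]
    at_size: int | Literal["full"] = "full"

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"coverage {self.value} outside [0, 1]")


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    q: float
    estimator: Literal["plugin_hill", "rarefied_q2", "chao_shen_1D"]
    value: float
    rarefied_to: int | None = None
    coverage: float | None = None
    entropy: float | None = None


def _adjusted_f1(v: AbundanceVector) -> int:
    """Good-Turing singleton count with the all-singleton adjustment.

    When every feature is a singleton (f1 = n) the raw estimate C = 0 makes
    the coverage-adjusted estimators degenerate (0/0); the standard practical
    fix substitutes f1 <- n - 1.
    """
    f1 = v.f1
    if f1 == v.n:
        warnings.warn(
            f"sample {v.sample_id!r}: all {v.n} reads are singletons; "
            "substituting f1 = n - 1 for coverage estimation",
            DegenerateCoverageWarning,
            stacklevel=3,
        )
        return v.n - 1
    return f1


def good_turing_coverage(v: AbundanceVector) -> CoverageEstimate:
    """Good-Turing sample coverage C = 1 - f1/n at the full sample size."""
    return CoverageEstimate(1.0 - _adjusted_f1(v) / v.n, "good_turing", "full")


def expected_coverage_at_size(v: AbundanceVector, m: int) -> CoverageEstimate:
    """Expected coverage of a hypergeometric subsample of size m.

        C(m) = 1 - sum_i (X_i/n) * C(n - X_i, m) / C(n - 1, m),  1 <= m <= n-1

    where C(a, b) is the binomial coefficient (zero for a < b).  At
    m = n - 1 this reduces exactly to the Good-Turing estimate 1 - f1/n.
    Binomial ratios are evaluated as log-gamma differences so arbitrarily
    deep samples do not overflow.
    """
    n = v.n
    if not 1 <= m <= n - 1:
        raise ValueError(f"subsample size m={m} outside [1, n-1] = [1, {n - 1}]")
    x = v.counts.astype(np.float64)
    # log C(n - X_i, m) - log C(n - 1, m); terms with n - X_i < m vanish
    keep = (n - v.counts) >= m
    log_ratio = (
        gammaln(n - x[keep] + 1)
        - gammaln(n - x[keep] - m + 1)
        - gammaln(float(n))
        + gammaln(float(n - m))
    )
    total = float(np.sum((x[keep] / n) * np.exp(log_ratio)))
    return CoverageEstimate(min(max(1.0 - total, 0.0), 1.0), "chao_jost", m)


def size_at_coverage(v: AbundanceVector, target_coverage: float) -> int:
    """Smallest subsample size m in [1, n-1] whose expected coverage reaches
    ``target_coverage``.

    Uses bisection on the (non-decreasing) coverage curve followed by a
    linear confirmation step.  Raises if the target exceeds the coverage
    attainable at m = n - 1; the caller must clamp explicitly.
    """
    n = v.n
    if target_coverage < 0:
        raise ValueError("target coverage must be >= 0")
    cmax = expected_coverage_at_size(v, n - 1).value
    if target_coverage > cmax + 1e-12:
        raise ValueError(
            f"sample {v.sample_id!r}: target coverage {target_coverage:.6g} exceeds "
            f"attainable coverage {cmax:.6g} at m = n-1; clamp the target to the "
            "sample's maximum explicitly"
        )
    lo, hi = 1, n - 1  # invariant: C(hi) >= target
    if expected_coverage_at_size(v, lo).value >= target_coverage:
        return 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_coverage_at_size(v, mid).value >= target_coverage:
            hi = mid
        else:
            lo = mid
    assert expected_coverage_at_size(v, hi).value >= target_coverage
    return hi


def hill_number(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill number of order q for a relative-abundance vector.

        qD = (sum_i p_i^q)^(1/(1-q)),   1D = exp(-sum_i p_i ln p_i)

    The q -> 1 limit is taken analytically when |q - 1| < 1e-9.
    """
    p = np.asarray(p, dtype=np.float64)
    if q < 0:
        raise ValueError("diversity order q must be non-negative")
    if np.any(p <= 0):
        raise ValueError("relative abundances must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances sum to {p.sum():.12g}, not 1")
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def inverse_simpson(v: AbundanceVector) -> DiversityResult:
    """Plug-in inverse Simpson index 2D = n^2 / sum X_i^2."""
    x = v.counts.astype(np.float64)
    value = v.n**2 / float(np.sum(x**2))
    return DiversityResult(v.sample_id, 2.0, "plugin_hill", value)


def rarefied_inverse_simpson(v: AbundanceVector, m: int) -> DiversityResult:
    """Expected inverse Simpson of a size-m hypergeometric subsample.

        2D(m) = 1 / [ 1/m + (1 - 1/m) * sum_i X_i (X_i - 1) / (n (n-1)) ]

    At m = n this equals the plug-in inverse Simpson exactly (algebraic
    identity), so interpolation is seamless at the full sample size.
    """
    n = v.n
    if n < 2:
        raise ValueError("rarefied inverse Simpson requires n >= 2")
    if not 1 <= m <= n:
        raise ValueError(f"subsample size m={m} outside [1, n] = [1, {n}]")
    x = v.counts.astype(np.float64)
    pair_match = float(np.sum(x * (x - 1.0))) / (n * (n - 1.0))
    value = 1.0 / (1.0 / m + (1.0 - 1.0 / m) * pair_match)
    return DiversityResult(v.sample_id, 2.0, "rarefied_q2", value, rarefied_to=m)


def subsample_without_replacement(
    v: AbundanceVector, m: int, seed: int | np.random.Generator
) -> AbundanceVector:
    """Multivariate-hypergeometric subsample of m reads, without replacement."""
    if not 1 <= m <= v.n:
        raise ValueError(f"subsample size m={m} outside [1, n] = [1, {v.n}]")
    if m == v.n:
        return v
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(v.counts, m)
    return AbundanceVector.from_counts(drawn, sample_id=v.sample_id)


def rarefy_to_common_coverage(
    samples: Sequence[AbundanceVector],
    mode: Literal["analytic", "montecarlo"] = "analytic",
    reps: int = 1000,
    seed: int | None = None,
) -> list[DiversityResult]:
    """Rarefy all samples to the lowest attainable coverage and report 2D.

    The common target C* is the minimum over samples of the expected
    coverage at m = n - 1 (equivalently 1 - f1/n).  Each sample is
    interpolated down to the smallest m reaching C*; the sample attaining
    the minimum stays at m = n - 1.  In ``montecarlo`` mode the analytic
    interpolation is replaced by the mean plug-in 2D over ``reps`` seeded
    hypergeometric subsamples of the same size.
    """
    if len(samples) < 2:
        raise ValueError("coverage-based rarefaction needs at least 2 samples")
    for v in samples:
        if v.n < 2:
            raise ValueError(f"sample {v.sample_id!r} has n < 2")
    full_cov = [expected_coverage_at_size(v, v.n - 1).value for v in samples]
    for v, c in zip(samples, full_cov):
        if c <= 0.0:
            raise ValueError(
                f"sample {v.sample_id!r} has zero estimated coverage; it cannot "
                "anchor coverage-based rarefaction"
            )
    target = min(full_cov)
    i_min = int(np.argmin(full_cov))
    rng = np.random.default_rng(seed)
    results = []
    for i, v in enumerate(samples):
        m = v.n - 1 if i == i_min else size_at_coverage(v, target)
        if mode == "analytic":
            res = rarefied_inverse_simpson(v, m)
        elif mode == "montecarlo":
            vals = [
                inverse_simpson(subsample_without_replacement(v, m, rng)).value
                for _ in range(reps)
            ]
            res = DiversityResult(
                v.sample_id, 2.0, "rarefied_q2", float(np.mean(vals)), rarefied_to=m
            )
        else:
            raise ValueError(f"unknown rarefaction mode {mode!r}")
        results.append(
            DiversityResult(
                res.sample_id,
                res.q,
                res.estimator,
                res.value,
                rarefied_to=m,
                coverage=target,
            )
        )
    return results


def chao_shen_effective_functions(v: AbundanceVector) -> DiversityResult:
    """Chao-Shen coverage-adjusted Shannon diversity in effective features.

    Coverage-deflated proportions p~_i = C * X_i / n (C the Good-Turing
    coverage) enter a Horvitz-Thompson-corrected Shannon sum,

        H_CS = - sum_i  p~_i ln p~_i / (1 - (1 - p~_i)^n),

    and the result is reported as the effective number 1D = exp(H_CS).
    For functional (GO-term) tables this is the "effective functions"
    diversity of the sample.
    """
    n = v.n
    if n < 2:
        raise ValueError("Chao-Shen estimation requires n >= 2")
    coverage = 1.0 - _adjusted_f1(v) / n
    p_adj = coverage * v.counts / n
    with np.errstate(divide="ignore"):  # p~ = 1 gives log1p(-1) = -inf, detection 1
        detection = -np.expm1(n * np.log1p(-p_adj))  # 1 - (1 - p~)^n, stable
    entropy = float(np.sum(-p_adj * np.log(p_adj) / detection))
    return DiversityResult(
        v.sample_id,
        1.0,
        "chao_shen_1D",
        float(np.exp(entropy)),
        coverage=coverage,
        entropy=entropy,
    )
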