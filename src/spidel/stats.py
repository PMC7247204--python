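"""Mutant-frequency statistics.

A mutant frequency (MF) is one animal's confirmed Spi- mutant count divided
by its rescued plaque-forming units; groups are summarized as mean +/- SD
(n-1 denominator).  Class-specific MFs multiply the group mean MF by the
class ratio among sequenced deletion mutations.  Group comparisons use the
Tukey HSD test on per-animal MFs, with the Tukey-Kramer standard error for
unequal group sizes; tail probabilities come from the studentized range
distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import studentized_range

from .io import AnimalAssay

__all__ = [
    "FrequencyResult",
    "TukeyComparison",
    "mutant_frequency",
    "group_frequencies",
    "specific_mf",
    "fold_change",
    "tukey_hsd",
    "null_familywise_error_rate",
    "pairwise_detection_rate",
    "UndefinedFrequencyError",
    "InsufficientReplicationError",
]


class UndefinedFrequencyError(ZeroDivisionError):
    """MF or fold change with a zero denominator."""


class InsufficientReplicationError(ValueError):
    """A group has fewer than two animals; no within-group variance exists."""


def mutant_frequency(assay: AnimalAssay) -> float:
    """Confirmed mutants per rescued phage (dimensionless; ~1e-6 scale)."""
    if assay.rescued_pfu <= 0:
        raise UndefinedFrequencyError("rescued_pfu must be positive")
    return assay.confirmed_mutants / assay.rescued_pfu


@dataclass(frozen=True)
class FrequencyResult:
    """Per-animal MFs and their mean +/- SD for one group."""

    group: tuple[str, float, str]
    per_animal_mf: tuple[float, ...]

    @property
    def n_animals(self) -> int:
        return len(self.per_animal_mf)

    @property
    def mean_mf(self) -> float:
        return float(np.mean(self.per_animal_mf))

    @property
    def sd_mf(self) -> float:
        if self.n_animals < 2:
            return math.nan
        return float(np.std(self.per_animal_mf, ddof=1))


def group_frequencies(assays: Sequence[AnimalAssay]) -> dict[tuple[str, float, str], FrequencyResult]:
    """Compute per-group MF summaries from per-animal assay counts."""
    buckets: dict[tuple[str, float, str], list[float]] = {}
    for a in assays:
        buckets.setdefault(a.group, []).append(mutant_frequency(a))
    return {
        g: FrequencyResult(group=g, per_animal_mf=tuple(v)) for g, v in buckets.items()
    }


def specific_mf(total_mean_mf: float, class_count: int, total_count: int) -> float:
    """Class-specific MF: total mean MF scaled by the class ratio."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= class_count <= total_count:
        raise ValueError("class_count must lie in [0, total_count]")
    return total_mean_mf * class_count / total_count


def fold_change(post_mf: float, pre_mf: float) -> float:
    """Ratio of post- to pre-treatment MF."""
    if pre_mf <= 0:
        raise UndefinedFrequencyError("pre-treatment MF must be positive for a fold change")
    return post_mf / pre_mf


@dataclass(frozen=True)
class TukeyComparison:
    group_a: tuple
    group_b: tuple
    mean_diff: float
    q_statistic: float
    p_value: float
    significant: bool


def _as_samples(
    groups: Sequence[FrequencyResult] | Mapping[object, Sequence[float]],
) -> list[tuple[object, np.ndarray]]:
    if isinstance(groups, Mapping):
        return [(k, np.asarray(v, dtype=float)) for k, v in groups.items()]
    return [(g.group, np.asarray(g.per_animal_mf, dtype=float)) for g in groups]


def tukey_hsd(
    groups: Sequence[FrequencyResult] | Mapping[object, Sequence[float]],
    alpha: float = 0.05,
) -> list[TukeyComparison]:
    """All-pairs Tukey HSD on per-animal MFs.

    Pools the within-group variance over all groups; unequal group sizes use
    the Tukey-Kramer standard error ``sqrt(MSE/2 * (1/n_i + 1/n_j))``.  The
    p-value is the studentized-range tail probability of ``q = |diff| / SE``
    with ``k`` groups and ``N - k`` error degrees of freedom.
    """
    samples = _as_samples(groups)
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for label, x in samples:
        if x.size < 2:
            raise InsufficientReplicationError(f"group {label!r} has fewer than 2 animals")
    k = len(samples)
    n_total = sum(x.size for _, x in samples)
    df = n_total - k
    mse = sum(((x - x.mean()) ** 2).sum() for _, x in samples) / df
    out: list[TukeyComparison] = []
    for (la, xa), (lb, xb) in itertools.combinations(samples, 2):
        diff = float(xa.mean() - xb.mean())
        se = math.sqrt(mse / 2.0 * (1.0 / xa.size + 1.0 / xb.size))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
        else:
            q = abs(diff) / se
        p = float(studentized_range.sf(q, k, df)) if math.isfinite(q) else 0.0
        p = min(max(p, 0.0), 1.0)
        out.append(
            TukeyComparison(
                group_a=la,
                group_b=lb,
                mean_diff=diff,
                q_statistic=q,
                p_value=p,
                significant=p < alpha,
            )
        )
    return out


def _pairwise_q(x: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Vectorized pairwise q statistics for equal-n replicated designs.

    ``x`` has shape (reps, k, n).  Returns (q[reps, pairs], k, df).
    """
    reps, k, n = x.shape
    means = x.mean(axis=2)
    sse = ((x - means[..., None]) ** 2).sum(axis=(1, 2))
    df = k * (n - 1)
    mse = sse / df
    pairs = list(itertools.combinations(range(k), 2))
    diffs = np.stack([np.abs(means[:, i] - means[:, j]) for i, j in pairs], axis=1)
    se = np.sqrt(mse / n)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(se > 0, diffs / se, np.inf)
    return q, k, df


def null_familywise_error_rate(
    n_groups: int,
    n_per_group: int,
    n_replicates: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte Carlo family-wise error rate of the Tukey test under the null.

    All groups share the same normal distribution; a replicate errs when any
    pair's q exceeds the studentized-range critical value (the decision rule
    of :func:`tukey_hsd` at level ``alpha``).
    """
    rng = rng or np.random.default_rng()
    x = rng.standard_normal((n_replicates, n_groups, n_per_group))
    q, k, df = _pairwise_q(x)
    q_crit = studentized_range.ppf(1.0 - alpha, k, df)
    return float((q.max(axis=1) > q_crit).mean())


def pairwise_detection_rate(
    group_means: Sequence[float],
    sd: float,
    n_per_group: int,
    n_replicates: int,
    pair: tuple[int, int],
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte Carlo power of the Tukey test for one group pair.

    Simulates ``n_replicates`` experiments with the given group means and a
    common normal SD, and reports how often the named pair is declared
    significant.
    """
    rng = rng or np.random.default_rng()
    k = len(group_means)
    x = rng.standard_normal((n_replicates, k, n_per_group)) * sd
    x += np.asarray(group_means, dtype=float)[None, :, None]
    q, k, df = _pairwise_q(x)
    q_crit = studentized_range.ppf(1.0 - alpha, k, df)
    pairs = list(itertools.combinations(range(k), 2))
    idx = pairs.index(tuple(sorted(pair)))
    return float((q[:, idx] > q_crit).mean())
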