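"""Circular descriptive statistics and Watson's two-sample U² test.

Phases live on [0, 1) in all public interfaces (the footfall-phase
convention) and are converted to radians internally. Watson's U² is a
nonparametric, rotation-invariant two-sample test for a difference between
two circular distributions (concentration and/or direction); its p-value is
obtained either by a seeded permutation of the pooled sample labels
(default) or from the asymptotic null series for large samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

__all__ = ["CircularSummary", "U2Result", "PValueMethod",
           "circular_summary", "watson_u2", "U2_CRIT_05"]

#: large-sample 5% critical value for the two-sample U² statistic
U2_CRIT_05 = 0.187


class PValueMethod(str, enum.Enum):
    PERMUTATION = "permutation"
    ASYMPTOTIC = "asymptotic"


@dataclass(frozen=True)
class CircularSummary:
    """First-moment summary of a circular sample on [0, 1)."""

    n: int
    mean_direction: float   # [0, 1); NaN when R == 0 (mean undefined)
    resultant_length: float  # R in [0, 1]
    circular_variance: float  # 1 - R


def circular_summary(phases) -> CircularSummary:
    """Mean direction and resultant length of phases on [0, 1).

    The mean direction is atan2 of the mean sine/cosine of 2π·phase, mapped
    back to [0, 1). When the resultant length is (numerically) zero — e.g. a
    perfectly balanced sample — the mean direction is undefined and reported
    as NaN with R = 0.
    """
    p = np.asarray(phases, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("circular summary of an empty sample")
    ang = 2.0 * np.pi * p
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    r = float(np.hypot(c, s))
    if r < 1e-12:
        mean = float("nan")
        r = 0.0
    else:
        mean = float((np.arctan2(s, c) / (2.0 * np.pi)) % 1.0)
    return CircularSummary(n=int(p.size), mean_direction=mean,
                           resultant_length=r, circular_variance=1.0 - r)


@dataclass(frozen=True)
class U2Result:
    u2: float
    n1: int
    n2: int
    p_value: float
    method: PValueMethod
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"u2": self.u2, "n1": self.n1, "n2": self.n2, "p": self.p_value,
                "method": self.method.value, "seed": self.seed}


def _u2_from_labels(values_sorted: np.ndarray, is_first_sorted: np.ndarray,
                    n1: int, n2: int, block_starts: np.ndarray) -> float:
    """U² from pooled sorted values and sample-membership labels.

    ``d = F − G`` at each ordered pooled point, with every member of a tied
    block taking the block's final cumulative value (the empirical-measure
    evaluation — order-independent and symmetric in the two samples);
    ``U² = (n1·n2/N²)·[Σd² − (Σd)²/N]`` over the N pooled points.
    """
    n = n1 + n2
    f = np.cumsum(is_first_sorted) / n1
    g = np.cumsum(~is_first_sorted) / n2
    d = f - g
    if block_starts.size < n:  # ties present
        counts = np.diff(np.append(block_starts, n))
        block_ends = np.append(block_starts[1:], n) - 1
        d = np.repeat(d[block_ends], counts)
    return float(n1 * n2 / n**2 * (np.sum(d**2) - np.sum(d)**2 / n))


def _asymptotic_p(u2: float, terms: int = 50) -> float:
    """Asymptotic null tail probability: 2·Σ (−1)^{m−1} exp(−2 m² π² U²)."""
    m = np.arange(1, terms + 1, dtype=float)
    p = 2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2(sample1, sample2, method: str | PValueMethod = PValueMethod.PERMUTATION,
              n_permutations: int = 10_000, seed: int | None = None,
              rng: np.random.Generator | None = None) -> U2Result:
    """Watson's two-sample U² test for circular data on [0, 1).

    The statistic is computed from the pooled sort of the two samples: with
    F, G the empirical cumulative fractions of each sample at the N ordered
    pooled points and d = F − G (tied blocks take their final cumulative
    value),
    ``U² = (n1·n2/N²)·[Σd² − (Σd)²/N]``. It is invariant under a common
    rotation of both samples and symmetric in its arguments.

    ``method`` selects the p-value: ``"permutation"`` (default; seeded random
    relabelings of the pooled sample) or ``"asymptotic"`` (large-sample null
    series, adequate for n ≳ 50 per the standard tables).
    """
    x = np.asarray(sample1, dtype=float) % 1.0
    y = np.asarray(sample2, dtype=float) % 1.0
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("watson_u2 requires two non-empty samples")
    method = PValueMethod(method)
    pooled = np.concatenate([x, y])
    labels = np.zeros(n1 + n2, dtype=bool)
    labels[:n1] = True
    order = np.argsort(pooled, kind="mergesort")
    values = pooled[order]
    is_first = labels[order]
    # tie-block starts over the (fixed) sorted pooled values
    block_starts = np.flatnonzero(np.r_[True, np.diff(values) > 0])
    u2 = _u2_from_labels(values, is_first, n1, n2, block_starts)

    if method is PValueMethod.ASYMPTOTIC:
        return U2Result(u2, n1, n2, _asymptotic_p(u2), method)

    if rng is None:
        rng = np.random.default_rng(seed)
    n = n1 + n2
    count = 0
    # permute labels in batches to bound memory; values/tie blocks are fixed
    batch = max(1, min(n_permutations, int(2e7 // max(n, 1))))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        # each row: a random permutation of the label vector
        perm = np.argsort(rng.random((b, n)), axis=1)
        lab = is_first[perm]
        f = np.cumsum(lab, axis=1) / n1
        g = np.cumsum(~lab, axis=1) / n2
        d = f - g
        if block_starts.size < n:
            counts = np.diff(np.append(block_starts, n))
            block_ends = np.append(block_starts[1:], n) - 1
            d = np.repeat(d[:, block_ends], counts, axis=1)
        u2_perm = n1 * n2 / n**2 * (np.sum(d**2, axis=1) - np.sum(d, axis=1)**2 / n)
        count += int(np.sum(u2_perm >= u2 - 1e-12))
        done += b
    p = (count + 1) / (n_permutations + 1)
    return U2Result(u2, n1, n2, float(p), method,
                    n_permutations=n_permutations, seed=seed)
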