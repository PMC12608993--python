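"""Spatial niche overlap between species from per-site abundance.

Pianka's index is the cosine similarity of two species' site-utilisation
vectors,

    O = sum_i p_i q_i / sqrt(sum_i p_i^2 * sum_i q_i^2),

computed here on per-site RAI vectors.  The index is invariant to rescaling
either vector, so raw RAI and proportions give the same value; it is bounded
in [0, 1] by Cauchy-Schwarz, with 1 for proportional utilisation and 0 for
disjoint site use.  Uncertainty comes from a paired site bootstrap: sites are
resampled with replacement, both species' entries travelling together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PiankaResult:
    pair: tuple[str, str]
    index: float
    ci_low: float | None
    ci_high: float | None
    n_sites: int
    stratum: str | None = None
    bootstrap_reps: int = 0


def _validate_pair(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("RAI vectors must be 1-d and share the site index")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("RAI values must be non-negative")
    if not np.any(u > 0) or not np.any(v > 0):
        raise ValueError("Pianka's index is undefined for an all-zero vector")
    return u, v


def pianka(u: np.ndarray, v: np.ndarray) -> float:
    """Pianka's niche-overlap index of two site-indexed RAI vectors."""
    u, v = _validate_pair(u, v)
    num = float(np.dot(u, v))
    den = float(np.sqrt(np.dot(u, u) * np.dot(v, v)))
    return min(max(num / den, 0.0), 1.0)


def pianka_ci(
    u: np.ndarray,
    v: np.ndarray,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    pair: tuple[str, str] = ("a", "b"),
    stratum: str | None = None,
    max_redraws: int = 1000,
) -> PiankaResult:
    """Pianka's index with a percentile 95% CI from a paired site bootstrap.

    Degenerate resamples in which either species' vector is all zero are
    redrawn (their count is logged); after ``max_redraws`` consecutive
    failures the replicate is recorded as NaN and excluded.
    """
    u, v = _validate_pair(u, v)
    n = u.size
    if n < 2:
        raise ValueError("bootstrap CI needs at least 2 sites")
    point = pianka(u, v)
    if reps < 2:
        warnings.warn("fewer than 2 bootstrap reps; CI omitted",
                      RuntimeWarning, stacklevel=2)
        return PiankaResult(pair, point, None, None, n, stratum, 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(reps)
    redraws = 0
    for r in range(reps):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            ub, vb = u[idx], v[idx]
            if np.any(ub > 0) and np.any(vb > 0):
                boots[r] = pianka(ub, vb)
                break
            redraws += 1
        else:
            boots[r] = np.nan
    if redraws:
        logger.info("pianka_ci: %d degenerate resample(s) redrawn", redraws)
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, point), max(hi, point)  # interval brackets the estimate
    return PiankaResult(pair, point,
                        float(min(max(lo, 0.0), 1.0)),
                        float(min(max(hi, 0.0), 1.0)),
                        n, stratum, reps)
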