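"""Hill-number diversity: observed values, asymptotic estimators, bootstrap CIs.

Hill numbers of order q give the effective number of species: q = 0 is
richness (every species counts equally), q = 1 the exponential of Shannon
entropy (individuals count equally), q = 2 the inverse Simpson concentration
(dominant species drive the value).  Observed (plug-in) values underestimate
the community quantity in finite samples, so the headline estimates here are
the standard asymptotic estimators:

* q = 0 — Chao1, using singleton (f1) and doubleton (f2) frequencies,
  ``S_obs + ((n-1)/n) f1^2 / (2 f2)`` (bias-corrected form when f2 = 0);
* q = 1 — exp of the Chao–Jost entropy estimator, a harmonic-sum formula with
  a singleton correction term governed by the mixing constant
  ``A = 2 f2 / ((n-1) f1 + 2 f2)``;
* q = 2 — the minimum-variance unbiased inverse Simpson estimator
  ``n (n-1) / sum xi (xi - 1)``.

Confidence intervals come from a multinomial bootstrap on the observed
proportions: estimate +/- 1.96 x the replicate standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

log = logging.getLogger(__name__)

Counts = Union[Sequence[int], Mapping[str, int], np.ndarray]


class EstimatorUndefined(ArithmeticError):
    """Raised when an estimator has no defined value for the input counts."""


def _as_counts(counts: Counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        counts = list(counts.values())
    x = np.asarray(counts)
    if x.size and not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("abundance counts must be integers")
        x = np.round(x).astype(int)
    if (x < 0).any():
        raise ValueError("abundance counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("need at least one positive count")
    return x


def observed_hill(counts: Counts, q: int) -> float:
    """Plug-in Hill number of order q from abundance counts."""
    x = _as_counts(counts)
    n = x.sum()
    p = x / n
    if q == 0:
        return float(x.size)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p**2).sum())
    raise ValueError(f"order q must be 0, 1 or 2, got {q}")


def _f_counts(x: np.ndarray) -> tuple[int, int, int, int]:
    n = int(x.sum())
    return n, int(x.size), int((x == 1).sum()), int((x == 2).sum())


def chao1_richness(counts: Counts) -> float:
    """Chao1 asymptotic species richness."""
    x = _as_counts(counts)
    n, s_obs, f1, f2 = _f_counts(x)
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        return s_obs + (n - 1) / n * f1 * f1 / (2.0 * f2)
    return s_obs + (n - 1) / n * f1 * (f1 - 1) / 2.0


def asymptotic_shannon(counts: Counts) -> tuple[float, float]:
    """Chao–Jost Shannon entropy estimate and its Hill number exp(H).

    The main term sums, over species with 1 <= xi <= n-1, the harmonic tail
    (xi/n) * sum_{k=xi}^{n-1} 1/k; when singletons are present a correction
    term accounts for undetected species via the mixing constant A.
    """
    x = _as_counts(counts)
    n, _, f1, f2 = _f_counts(x)
    if n < 2:
        raise ValueError("Shannon estimation requires n >= 2")
    # cumulative harmonic tails: tail[x] = sum_{k=x}^{n-1} 1/k
    inv = 1.0 / np.arange(1, n)
    tail = np.concatenate([np.cumsum(inv[::-1])[::-1], [0.0]])  # index 1..n
    h = 0.0
    for xi in x:
        if xi <= n - 1:
            h += xi / n * tail[xi - 1]
    if f1 > 0:
        if f2 > 0:
            a = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
        else:
            a = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
        if a < 1.0:
            r = np.arange(1, n)
            h += (
                f1 / n * (1.0 - a) ** (1 - n)
                * (-math.log(a) - ((1.0 - a) ** r / r).sum())
            )
    return float(h), float(math.exp(h))


def asymptotic_simpson(counts: Counts) -> float:
    """Minimum-variance unbiased inverse Simpson: n(n-1) / sum xi(xi-1)."""
    x = _as_counts(counts)
    n = int(x.sum())
    if n < 2:
        raise ValueError("Simpson estimation requires n >= 2")
    denom = int((x * (x - 1)).sum())
    if denom == 0:
        raise EstimatorUndefined(
            "all species are singletons; unbiased Simpson estimator undefined"
        )
    return n * (n - 1) / denom


def asymptotic_hill(counts: Counts, q: int) -> float:
    """Asymptotic Hill number of order q (dispatch over the three estimators)."""
    if q == 0:
        return chao1_richness(counts)
    if q == 1:
        return asymptotic_shannon(counts)[1]
    if q == 2:
        return asymptotic_simpson(counts)
    raise ValueError(f"order q must be 0, 1 or 2, got {q}")


def bootstrap_ci(
    counts: Counts,
    q: int,
    B: int = 50,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Normal-approximation bootstrap CI for the asymptotic Hill number.

    Draws ``B`` multinomial resamples of size n from the observed proportions,
    recomputes the order-q asymptotic estimator on each, and returns
    estimate +/- 1.96 x replicate SD.  Replicates on which the estimator is
    undefined are dropped with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x = _as_counts(counts)
    n = int(x.sum())
    if rng is None:
        rng = np.random.default_rng(seed)
    point = asymptotic_hill(x, q)
    reps = []
    dropped = 0
    for _ in range(B):
        resample = rng.multinomial(n, x / n)
        try:
            reps.append(asymptotic_hill(resample[resample > 0], q))
        except (EstimatorUndefined, ValueError):
            dropped += 1
    if dropped:
        log.warning("bootstrap: %d of %d replicates dropped (estimator undefined)", dropped, B)
    sd = float(np.std(reps, ddof=0)) if reps else float("nan")
    return point - 1.96 * sd, point + 1.96 * sd


@dataclass(frozen=True)
class DiversityEstimate:
    collection_id: str
    q: int
    observed: float
    asymptotic: float
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    B: int = 0
    seed: Optional[int] = None


def diversity_profile(
    counts: Counts,
    collection_id: str = "",
    qs: Iterable[int] = (0, 1, 2),
    B: int = 50,
    seed: Optional[int] = None,
) -> list[DiversityEstimate]:
    """Observed and asymptotic Hill numbers with bootstrap CIs for each order."""
    out = []
    for q in qs:
        obs = observed_hill(counts, q)
        try:
            asym = asymptotic_hill(counts, q)
        except EstimatorUndefined:
            log.warning("collection %s q=%d: asymptotic estimator undefined", collection_id, q)
            out.append(DiversityEstimate(collection_id, q, obs, float("nan")))
            continue
        lo, hi = (None, None)
        if B > 0:
            lo, hi = bootstrap_ci(counts, q, B=B, seed=seed)
        out.append(DiversityEstimate(collection_id, q, obs, asym, lo, hi, B, seed))
    return out
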