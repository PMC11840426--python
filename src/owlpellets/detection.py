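"""Cumulative probability-of-detection curves and required sampling effort.

If C of N assessed pellets contain a target species, the probability that at
least one of n randomly drawn pellets contains it (draws independent, with
replacement) is ``pn = 1 - (1 - C/N)^n``.  "Confident detection" is the
smallest n with pn strictly above 1 - alpha (default alpha = 0.05, i.e.
pn > 0.95); a species never found (C = 0) is never detectable under the
model and its required effort is reported as absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionQuery:
    """Occurrence of a target species in a pellet collection."""

    C: int  # pellets containing the target species
    N: int  # total pellets assessed
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if not 0 <= self.C <= self.N:
            raise ValidationError("C must satisfy 0 <= C <= N")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")

    @property
    def p1(self) -> float:
        """Detection probability from a single pellet, C/N."""
        return self.C / self.N


def detection_probability(
    query: DetectionQuery, n: Union[int, Sequence[int], np.ndarray]
) -> Union[float, np.ndarray]:
    """Cumulative detection probability pn = 1 - (1 - C/N)^n for n >= 1."""
    n_arr = np.asarray(n)
    if (n_arr < 1).any():
        raise ValidationError("n must be >= 1")
    pn = 1.0 - (1.0 - query.p1) ** n_arr
    return float(pn) if np.isscalar(n) or n_arr.ndim == 0 else pn


def pellets_required(query: DetectionQuery) -> Optional[int]:
    """Smallest n with pn strictly greater than 1 - alpha; None when C = 0.

    Solved in closed form as ceil(ln alpha / ln(1 - C/N)), then nudged to
    honour the strict inequality when the logarithmic solution lands exactly
    on the boundary.
    """
    if query.C == 0:
        log.warning("C = 0: species never detectable under the model")
        return None
    if query.C == query.N:
        return 1
    miss = 1.0 - query.p1
    n = max(1, math.ceil(math.log(query.alpha) / math.log(miss)))
    # strict inequality: pn must exceed 1 - alpha, i.e. miss^n < alpha
    while miss**n >= query.alpha:
        n += 1
    while n > 1 and miss ** (n - 1) < query.alpha:
        n -= 1
    return n


def detection_curve(query: DetectionQuery, n_max: Optional[int] = None) -> pd.DataFrame:
    """pn for n = 1..n_max (default: up to required effort, capped at 1000)."""
    if n_max is None:
        req = pellets_required(query)
        n_max = min(req if req is not None else 1000, 1000)
    ns = np.arange(1, n_max + 1)
    return pd.DataFrame({"n": ns, "pn": detection_probability(query, ns)})


def plot_detection_curves(
    queries: Sequence[tuple[str, DetectionQuery]],
    n_max: int = 160,
    ax=None,
):
    """Plot pn against pellets assessed for several sites on shared axes.

    Curves start at n = 1 (assessing zero pellets is not meaningful in
    application); a horizontal line marks the confident-detection level
    1 - alpha of the first query.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ns = np.arange(1, n_max + 1)
    for label, q in queries:
        ax.plot(ns, detection_probability(q, ns), label=f"{label} (C={q.C}, N={q.N})")
    if queries:
        ax.axhline(1 - queries[0][1].alpha, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("pellets assessed (n)")
    ax.set_ylabel("cumulative probability of detection (pn)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize="small")
    return ax


def detection_report(
    sites: Sequence[tuple[str, Optional[int], int]],
    species: str = "",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Per-site detection effort for one species.

    ``sites`` holds (site label, C, N) triples; sites with unknown C are
    skipped with a warning.  Returns the per-site rows and summary statistics
    of the required pellet numbers across sites where defined.
    """
    rows = []
    for site, c, n_tot in sites:
        if c is None:
            log.warning("site %s: unknown pellet occurrence for %s; skipped", site, species)
            continue
        q = DetectionQuery(C=c, N=n_tot, alpha=alpha)
        rows.append(
            {
                "site": site,
                "species": species,
                "C": c,
                "N": n_tot,
                "p1": q.p1,
                "required_n": pellets_required(q),
                "alpha": alpha,
            }
        )
    df = pd.DataFrame(
        rows, columns=["site", "species", "C", "N", "p1", "required_n", "alpha"]
    )
    if df.empty:
        log.warning("species %s absent from all sites; empty report", species)
        return df, {}
    req = df["required_n"].dropna()
    summary = {
        "species": species,
        "sites": int(len(df)),
        "required_n_min": int(req.min()) if len(req) else None,
        "required_n_max": int(req.max()) if len(req) else None,
        "required_n_mean": float(req.mean()) if len(req) else None,
    }
    return df, summary
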