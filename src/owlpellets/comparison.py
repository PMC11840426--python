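"""Pairwise comparison of per-taxon individual proportions between collections.

Each taxon is compared between two collections with a 2x2 contingency table
(focal-taxon individuals vs all other individuals).  Yates-corrected
chi-squared is used when every expected cell count is at least 5; otherwise
Fisher's exact test.  Within each taxon, the family of pairwise p-values is
adjusted by the Holm step-down procedure, and adjusted p-values are mapped to
the conventional star labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceVector
from .records import UnknownCountError, ValidationError

log = logging.getLogger(__name__)

SIGNIFICANCE_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

#: Relative tolerance for "at most as likely" ties in the two-sided Fisher rule.
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 focal-vs-rest table for one taxon and one collection pair."""

    a: int  # focal individuals in collection A
    b: int  # other individuals in A
    c: int  # focal individuals in B
    d: int  # other individuals in B

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        t = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        r = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        return r * col / t.sum()


@dataclass(frozen=True)
class ComparisonResult:
    taxon: str
    pair: tuple[str, str]
    N: int
    test: str  # "chi_squared_yates" | "fisher_exact"
    statistic: Optional[float]
    df: Optional[int]
    p_raw: float
    p_adj: Optional[float] = None

    @property
    def significance(self) -> str:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        for thresh, stars in SIGNIFICANCE_LEVELS:
            if p <= thresh:
                return stars
        return "ns"


def build_table(x_a: int, n_a: int, x_b: int, n_b: int) -> ContingencyTable:
    """Focal-vs-rest table from per-collection focal counts and totals."""
    if not (0 <= x_a <= n_a and 0 <= x_b <= n_b):
        raise ValidationError("focal count must satisfy 0 <= x <= n")
    return ContingencyTable(x_a, n_a - x_a, x_b, n_b - x_b)


def chi_squared_yates(t: ContingencyTable) -> tuple[float, int, float]:
    """Yates-corrected chi-squared on a 2x2 table: (statistic, df, p)."""
    obs = np.array([[t.a, t.b], [t.c, t.d]])
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError(
            "zero margin: chi-squared undefined, use fisher_exact instead"
        )
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=True)
    return float(chi2), int(df), float(p)


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Conditional on the margins, sums the hypergeometric probabilities of all
    tables at most as likely as the observed one (relative tie tolerance
    ``1e-7``).  Degenerate margins give p = 1.
    """
    r1 = t.a + t.b
    c1 = t.a + t.c
    N = t.N
    if N == 0 or r1 in (0, N) or c1 in (0, N):
        return 1.0
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, c1, r1)
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum())
    return min(p, 1.0)


def choose_test(t: ContingencyTable) -> str:
    """Fisher iff any expected cell count is below 5, else Yates chi-squared."""
    if t.N == 0 or (t.expected() < 5).any():
        return "fisher_exact"
    return "chi_squared_yates"


def compare_pair(
    x_a: int, n_a: int, x_b: int, n_b: int, taxon: str = "", pair: tuple[str, str] = ("A", "B")
) -> ComparisonResult:
    """Test one taxon between two collections with the appropriate test."""
    t = build_table(x_a, n_a, x_b, n_b)
    test = choose_test(t)
    if test == "chi_squared_yates":
        chi2, df, p = chi_squared_yates(t)
        return ComparisonResult(taxon, pair, t.N, test, chi2, df, p)
    return ComparisonResult(taxon, pair, t.N, "fisher_exact", None, None, fisher_exact(t))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def pairwise_compare(
    vectors: Sequence[AbundanceVector],
    taxa: Sequence[str],
) -> list[ComparisonResult]:
    """All unordered collection pairs for each taxon, Holm-adjusted per taxon.

    Pairs in which a collection's count for the taxon is unknown are skipped
    with a warning, never imputed; the Holm family is the set of pairs
    actually tested for that taxon.
    """
    if len(vectors) < 2:
        raise ValidationError("need at least two collections to compare")
    results: list[ComparisonResult] = []
    for taxon in taxa:
        fam: list[ComparisonResult] = []
        for va, vb in itertools.combinations(vectors, 2):
            pair = (va.collection_id, vb.collection_id)
            try:
                xa, xb = va.count(taxon), vb.count(taxon)
                na, nb = va.n, vb.n
            except UnknownCountError:
                xa = xb = None
            if xa is None or xb is None:
                log.warning("skipping %s %s: unknown count", taxon, pair)
                continue
            fam.append(compare_pair(xa, na, xb, nb, taxon=taxon, pair=pair))
        adj = holm_adjust([r.p_raw for r in fam])
        for r, pa in zip(fam, adj):
            results.append(
                ComparisonResult(
                    r.taxon, r.pair, r.N, r.test, r.statistic, r.df, r.p_raw, float(pa)
                )
            )
    return results


def results_frame(results: Sequence[ComparisonResult]):
    """Long-format table of comparison results."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "pair": f"{r.pair[0]} vs {r.pair[1]}",
                "n": r.N,
                "test": r.test,
                "statistic": r.statistic,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significance": r.significance,
            }
            for r in results
        ]
    )
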