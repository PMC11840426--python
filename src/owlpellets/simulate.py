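"""Synthetic pellet-collection generator with known ground truth.

Emulates the statistical structure of a barn-owl pellet series from a
semi-arid rodent boom–bust community: a small set of prey taxa whose
relative abundance shifts across collections (an irruptive rat building up
from a baseline share to plague dominance), a small mean number of
identifiable prey items per pellet (around 1.56 in the motivating series),
a fraction of pellets yielding only unidentifiable postcranial material,
juvenile/adult splits, and per-element recovery loss (an individual whose
mandibles and skull all fail to survive digestion leaves no observable
record while remaining in the ground truth).

Every draw flows from a single integer seed, so identical scenarios produce
bitwise-identical record sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .records import UNIDENTIFIABLE, CollectionMetadata, ElementRecord, ValidationError

_SIDED = ("left_mandible", "right_mandible", "skull")


@dataclass(frozen=True)
class CommunityScenario:
    """Ground-truth community and sampling process for synthetic collections.

    ``proportions`` holds one relative-abundance vector per collection (each
    summing to 1 over ``taxa``); ``mean_items_per_pellet`` is the mean number
    of identifiable prey items in pellets that contain any (the item count is
    zero-truncated Poisson, with its truncated mean matched to this value);
    ``p_unidentifiable_only`` is the chance a pellet yields only
    unidentifiable postcranial material; ``element_recovery`` gives the
    independent survival probability of the left mandible, right mandible and
    skull of each deposited individual.
    """

    taxa: Sequence[str]
    proportions: Sequence[Sequence[float]]
    n_pellets: Sequence[int]
    juvenile_fraction: Mapping[str, float] = field(default_factory=dict)
    mean_items_per_pellet: float = 1.56
    p_unidentifiable_only: float = 0.085
    element_recovery: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValidationError("scenario needs at least one taxon")
        if UNIDENTIFIABLE in self.taxa:
            raise ValidationError("'unidentifiable' is reserved for postcranial-only pellets")
        if len(self.proportions) != len(self.n_pellets):
            raise ValidationError("need one proportions vector per collection")
        for vec in self.proportions:
            if len(vec) != len(self.taxa):
                raise ValidationError("proportions vector length must match taxa")
            if any(p < 0 for p in vec):
                raise ValidationError("proportions must be non-negative")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValidationError("each proportions vector must sum to 1 within 1e-9")
        for n in self.n_pellets:
            if n < 0:
                raise ValidationError("n_pellets must be non-negative")
        if self.mean_items_per_pellet < 1.0:
            raise ValidationError("mean_items_per_pellet must be >= 1 (zero-truncated)")
        probs = [self.p_unidentifiable_only, *self.element_recovery]
        probs += list(self.juvenile_fraction.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """True per-pellet individual counts behind one synthetic collection."""

    collection_id: str
    per_pellet: Dict[str, Dict[tuple[str, str], int]]
    scenario: CommunityScenario

    @property
    def totals(self) -> Dict[tuple[str, str], int]:
        out: Dict[tuple[str, str], int] = {}
        for pellet in self.per_pellet.values():
            for key, c in pellet.items():
                out[key] = out.get(key, 0) + c
        return out

    def group_totals(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for (g, _), c in self.totals.items():
            out[g] = out.get(g, 0) + c
        return out


def _ztp_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals ``mean``."""
    if mean <= 1.0 + 1e-12:
        return 0.0
    f = lambda lam: lam / (1.0 - math.exp(-lam)) - mean
    return brentq(f, 1e-10, 10.0 * mean)


def _draw_ztp(rng: np.random.Generator, lam: float) -> int:
    """Zero-truncated Poisson draw by rejection (lam = 0 degenerates to 1)."""
    if lam == 0.0:
        return 1
    while True:
        k = int(rng.poisson(lam))
        if k >= 1:
            return k


def generate_collection(
    scenario: CommunityScenario, collection_index: int
) -> tuple[list[ElementRecord], SyntheticTruth, CollectionMetadata]:
    """Simulate one collection of the scenario.

    Per pellet: with probability ``p_unidentifiable_only`` emit a single
    unidentifiable-postcranial record; otherwise draw the identifiable item
    count from the zero-truncated Poisson, assign each item a taxon
    (multinomial on the collection's proportions) and an age class, and emit
    left-mandible / right-mandible / skull records according to the element
    recovery probabilities.  The returned truth holds every deposited
    individual, observed or not.
    """
    if not 0 <= collection_index < len(scenario.n_pellets):
        raise ValidationError(f"collection_index {collection_index} out of range")
    rng = np.random.default_rng([scenario.seed, collection_index])
    props = np.asarray(scenario.proportions[collection_index], dtype=float)
    n_pellets = scenario.n_pellets[collection_index]
    lam = _ztp_lambda(scenario.mean_items_per_pellet)
    collection_id = f"synthetic_{collection_index}"

    width = max(1, len(str(max(n_pellets, 1))))
    records: list[ElementRecord] = []
    per_pellet: Dict[str, Dict[tuple[str, str], int]] = {}
    for i in range(n_pellets):
        pellet_id = f"p{i + 1:0{width}d}"
        truth: Dict[tuple[str, str], int] = {}
        if rng.random() < scenario.p_unidentifiable_only:
            truth[(UNIDENTIFIABLE, "unknown")] = 1
            records.append(
                ElementRecord(
                    collection_id, pellet_id, UNIDENTIFIABLE, "unknown",
                    "unidentifiable_postcranial", 1,
                )
            )
        else:
            k = _draw_ztp(rng, lam)
            elem_counts: Dict[tuple[str, str, str], int] = {}
            for taxon_idx in rng.choice(len(props), size=k, p=props):
                taxon = scenario.taxa[int(taxon_idx)]
                jf = scenario.juvenile_fraction.get(taxon)
                if jf is None:
                    age = "unknown"
                else:
                    age = "juvenile" if rng.random() < jf else "adult"
                truth[(taxon, age)] = truth.get((taxon, age), 0) + 1
                for elem, p_rec in zip(_SIDED, scenario.element_recovery):
                    if rng.random() < p_rec:
                        elem_counts[(taxon, age, elem)] = (
                            elem_counts.get((taxon, age, elem), 0) + 1
                        )
            for (taxon, age, elem), c in sorted(elem_counts.items()):
                records.append(
                    ElementRecord(collection_id, pellet_id, taxon, age, elem, c)
                )
        per_pellet[pellet_id] = truth

    meta = CollectionMetadata(
        collection_id=collection_id,
        n_pellets_total=max(n_pellets, 1),
        notes=f"synthetic collection {collection_index} of scenario seed {scenario.seed}",
    )
    truth_obj = SyntheticTruth(collection_id, per_pellet, scenario)
    return records, truth_obj, meta


def generate_all(scenario: CommunityScenario):
    """Generate every collection of the scenario."""
    return [generate_collection(scenario, k) for k in range(len(scenario.n_pellets))]


def plague_trajectory(
    base: Mapping[str, float],
    rat_taxon: str,
    rat_share_by_collection: Sequence[float],
) -> list[Dict[str, float]]:
    """Proportion vectors with the irruptive taxon forced to given shares.

    In collection k the rat taxon takes share ``rat_share_by_collection[k]``
    and all other taxa are rescaled proportionally from ``base``; each output
    vector sums to 1.
    """
    if rat_taxon not in base:
        raise ValidationError(f"rat taxon {rat_taxon!r} absent from base proportions")
    if abs(sum(base.values()) - 1.0) > 1e-9:
        raise ValidationError("base proportions must sum to 1")
    base_rat = base[rat_taxon]
    rest = 1.0 - base_rat
    out = []
    for share in rat_share_by_collection:
        if not 0.0 <= share < 1.0:
            raise ValidationError("rat share must lie in [0, 1)")
        scale = (1.0 - share) / rest if rest > 0 else 0.0
        vec = {t: (share if t == rat_taxon else p * scale) for t, p in base.items()}
        total = sum(vec.values())
        vec = {t: p / total for t, p in vec.items()}
        out.append(vec)
    return out
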