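"""MNI counting and collection-level abundance tables.

The minimum number of individuals (MNI) for a taxon/age class within one
pellet is the largest count among left mandibles, right mandibles and skulls:
two left mandibles and one right mandible imply at least two individuals, and
a skull count can only raise, never lower, that minimum.  Unsided cranial
fragments ("other_cranial") establish presence (MNI >= 1) but cannot raise the
MNI above the sided-element maximum.

Pellet occurrence is tracked at two levels that must not be conflated: the
number of pellets containing a (group, age class) — the shape in which
summary tables are printed — and the number of pellets containing the group
in *any* age class (the union, which feeds the detection formula; per-age
pellet counts cannot be summed into it because one pellet may hold both a
juvenile and an adult).

A pellet whose only content is unidentifiable postcranial material is tallied
as one "unidentifiable" individual, so collection totals count every assessed
pellet's yield.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .records import (
    UNIDENTIFIABLE,
    CollectionMetadata,
    ElementRecord,
    TaxonomyMap,
    UnknownCountError,
    ValidationError,
)
from .taxonomy import IDENTITY_PROFILE, MAMMAL_GROUPS, apply_taxonomy

log = logging.getLogger(__name__)

GroupAge = Tuple[str, str]


def mni_for_group(left: int, right: int, skulls: int) -> int:
    """Minimum number of individuals from sided-mandible and skull counts.

    Returns ``max(left, right, skulls)``: the smallest number of individuals
    consistent with the recovered paired elements, with skulls able to
    corroborate or exceed the mandible-based count.
    """
    for name, v in (("left", left), ("right", right), ("skulls", skulls)):
        if v < 0:
            raise ValidationError(f"{name} count must be >= 0, got {v}")
    return max(left, right, skulls)


@dataclass
class PelletMNI:
    """Per-pellet MNI by (taxon group, age class)."""

    collection_id: str
    pellet_id: str
    mni: Dict[GroupAge, int] = field(default_factory=dict)

    @property
    def has_identifiable(self) -> bool:
        return any(g != UNIDENTIFIABLE and v >= 1 for (g, _), v in self.mni.items())

    @property
    def total(self) -> int:
        return sum(self.mni.values())


@dataclass
class AbundanceVector:
    """Per-taxon individual counts for one collection.

    ``individuals`` and ``pellets_by_age`` map (group, age_class) to counts;
    ``pellets_containing`` maps the group to its union pellet occurrence (the
    C of the detection formula).  A ``None`` anywhere marks a genuinely
    unknown count (partially published data); unknowns are never imputed.
    ``n_total`` overrides the summed total for aggregate-only data whose
    overall size is known even though some per-taxon counts are not.
    """

    collection_id: str
    individuals: Dict[GroupAge, Optional[int]] = field(default_factory=dict)
    pellets_by_age: Dict[GroupAge, Optional[int]] = field(default_factory=dict)
    pellets_containing: Dict[str, Optional[int]] = field(default_factory=dict)
    n_pellets_total: Optional[int] = None
    n_total: Optional[int] = None

    # -- group-level views ------------------------------------------------
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g, _ in self.individuals:
            seen.setdefault(g)
        return list(seen)

    def count(self, group: str) -> Optional[int]:
        """Total individuals of a group across age classes (None if unknown)."""
        vals = [v for (g, _), v in self.individuals.items() if g == group]
        if not vals:
            return 0
        if any(v is None for v in vals):
            return None
        return sum(vals)  # type: ignore[arg-type]

    @property
    def n(self) -> int:
        """Total individuals in the collection (including unidentifiable)."""
        if self.n_total is not None:
            return self.n_total
        total = 0
        for v in self.individuals.values():
            if v is None:
                raise UnknownCountError(
                    f"collection {self.collection_id!r} has unknown counts and no n_total"
                )
            total += v
        return total

    def counts(self, groups: Optional[Sequence[str]] = None) -> Dict[str, int]:
        """Known per-group totals, restricted to ``groups`` when given.

        Raises :class:`UnknownCountError` if any requested group's count is
        unknown — unknowns are never imputed.
        """
        sel = list(groups) if groups is not None else self.groups()
        out: Dict[str, int] = {}
        for g in sel:
            c = self.count(g)
            if c is None:
                raise UnknownCountError(
                    f"count for {g!r} in collection {self.collection_id!r} is unknown"
                )
            out[g] = c
        return out

    def mammal_counts(self, mammal_groups: Sequence[str] = MAMMAL_GROUPS) -> Dict[str, int]:
        """Known counts of mammal groups present in this collection (xi > 0 kept)."""
        present = [g for g in self.groups() if g in mammal_groups]
        counts = self.counts(present)
        return {g: c for g, c in counts.items() if c > 0}


def tabulate(
    records: Iterable[ElementRecord],
    meta: CollectionMetadata,
    taxonomy: TaxonomyMap = IDENTITY_PROFILE,
) -> tuple[list[PelletMNI], AbundanceVector]:
    """Apply the MNI rule per pellet and build the collection abundance vector.

    Returns per-pellet MNI tallies and the collection-level
    :class:`AbundanceVector` (individuals summed over pellets; pellet
    occurrence tracked per age class and as the union over age classes).
    """
    records = apply_taxonomy(records, taxonomy)
    ids = {r.collection_id for r in records}
    if len(ids) > 1:
        raise ValidationError(f"records span multiple collections: {sorted(ids)}")
    if ids and ids != {meta.collection_id}:
        raise ValidationError(
            f"records belong to {ids.pop()!r}, metadata to {meta.collection_id!r}"
        )

    by_pellet: Dict[str, Dict[GroupAge, Dict[str, int]]] = {}
    for r in records:
        slot = by_pellet.setdefault(r.pellet_id, {}).setdefault(
            (r.taxon, r.age_class), {}
        )
        slot[r.element] = slot.get(r.element, 0) + r.count

    if len(by_pellet) > meta.n_pellets_total:
        raise ValidationError(
            f"{len(by_pellet)} distinct pellets exceed n_pellets_total={meta.n_pellets_total}"
        )

    pellets: list[PelletMNI] = []
    individuals: Dict[GroupAge, int] = {}
    occupancy_age: Dict[GroupAge, set] = {}
    occupancy: Dict[str, set] = {}
    for pellet_id in sorted(by_pellet):
        pm = PelletMNI(meta.collection_id, pellet_id)
        groups_here = by_pellet[pellet_id]
        for (group, age), elems in groups_here.items():
            if group == UNIDENTIFIABLE:
                continue
            m = mni_for_group(
                elems.get("left_mandible", 0),
                elems.get("right_mandible", 0),
                elems.get("skull", 0),
            )
            if m == 0 and elems.get("other_cranial", 0) > 0:
                m = 1  # presence established by unsided cranial material
            if m > 0:
                pm.mni[(group, age)] = m
        if not pm.has_identifiable and any(g == UNIDENTIFIABLE for g, _ in groups_here):
            pm.mni[(UNIDENTIFIABLE, "unknown")] = 1
        for (group, age), m in pm.mni.items():
            individuals[(group, age)] = individuals.get((group, age), 0) + m
            occupancy_age.setdefault((group, age), set()).add(pellet_id)
            occupancy.setdefault(group, set()).add(pellet_id)
        pellets.append(pm)

    vec = AbundanceVector(
        collection_id=meta.collection_id,
        individuals=dict(individuals),
        pellets_by_age={k: len(p) for k, p in occupancy_age.items()},
        pellets_containing={g: len(p) for g, p in occupancy.items()},
        n_pellets_total=meta.n_pellets_total,
    )
    return pellets, vec


def pool_abundance(vec: AbundanceVector, taxonomy: TaxonomyMap) -> AbundanceVector:
    """Pool an abundance vector's groups under a taxonomy profile.

    Individual counts of merged groups are summed (unknown + anything =
    unknown).  Pellet-occurrence counts merge only when a single source group
    contributes a known value; otherwise the merged occurrence is unknown,
    because occupied-pellet sets of distinct groups may overlap.
    """
    individuals: Dict[GroupAge, Optional[int]] = {}
    for (g, age), v in vec.individuals.items():
        key = (taxonomy.resolve(g), age)
        if key not in individuals:
            individuals[key] = v
        else:
            prev = individuals[key]
            individuals[key] = None if prev is None or v is None else prev + v

    def _merge_occurrence(items):
        merged: Dict = {}
        contributors: Dict = {}
        for key, new_key, v in items:
            contributors.setdefault(new_key, []).append(v)
        for new_key, vals in contributors.items():
            nonzero = [v for v in vals if v is None or v > 0]
            if len(nonzero) == 0:
                merged[new_key] = 0
            elif len(nonzero) == 1 and nonzero[0] is not None:
                merged[new_key] = nonzero[0]
            else:
                merged[new_key] = None
        return merged

    pellets_by_age = _merge_occurrence(
        (k, (taxonomy.resolve(k[0]), k[1]), v) for k, v in vec.pellets_by_age.items()
    )
    pellets_containing = _merge_occurrence(
        (g, taxonomy.resolve(g), v) for g, v in vec.pellets_containing.items()
    )
    return AbundanceVector(
        collection_id=vec.collection_id,
        individuals=individuals,
        pellets_by_age=pellets_by_age,
        pellets_containing=pellets_containing,
        n_pellets_total=vec.n_pellets_total,
        n_total=vec.n_total,
    )


def richness_inputs(counts: Mapping[str, int]) -> tuple[int, int, int, int]:
    """(n, S_obs, f1, f2) from a per-group count mapping (zeros dropped)."""
    xs = [c for c in counts.values() if c > 0]
    n = sum(xs)
    return n, len(xs), sum(1 for x in xs if x == 1), sum(1 for x in xs if x == 2)


def summarize(
    vec: AbundanceVector,
    meta: CollectionMetadata,
    pellets: Optional[Sequence[PelletMNI]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-(group, age class) summary rows plus collection scalars.

    Rows carry pellets containing the group/age, individuals, and both as
    percentages of pellets assessed / total individuals.  Scalars include
    identifiable individuals, identifiable pellets and their ratio — the
    mean number of prey items per pellet, computed over pellets containing
    identifiable material only.
    """
    n = vec.n
    rows = []
    for (group, age), ind in sorted(vec.individuals.items()):
        pel = vec.pellets_by_age.get((group, age))
        rows.append(
            {
                "collection_id": vec.collection_id,
                "group": group,
                "age_class": age,
                "pellets_containing": pel,
                "pct_pellets": (
                    100.0 * pel / meta.n_pellets_total if pel is not None else math.nan
                ),
                "individuals": ind,
                "pct_individuals": (
                    100.0 * ind / n if ind is not None and n else math.nan
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "collection_id", "group", "age_class", "pellets_containing",
            "pct_pellets", "individuals", "pct_individuals",
        ],
    )

    unid = vec.count(UNIDENTIFIABLE)
    if unid is None:
        raise UnknownCountError(
            f"collection {vec.collection_id!r}: unidentifiable tally unknown; "
            "identifiable totals cannot be derived"
        )
    identifiable_individuals = n - unid
    scalars = {
        "collection_id": vec.collection_id,
        "n_individuals": n,
        "identifiable_individuals": identifiable_individuals,
        "n_pellets_total": meta.n_pellets_total,
    }
    if pellets is not None:
        ident_pellets = sum(1 for p in pellets if p.has_identifiable)
    else:
        unid_pellets = vec.pellets_containing.get(UNIDENTIFIABLE)
        occupied = set()
        for g, p in vec.pellets_containing.items():
            if g != UNIDENTIFIABLE and p:
                occupied.add(g)
        if unid_pellets is not None and meta.n_pellets_total is not None:
            ident_pellets = meta.n_pellets_total - unid_pellets
        else:
            ident_pellets = None
    scalars["identifiable_pellets"] = ident_pellets
    if ident_pellets:
        scalars["mean_items_per_identifiable_pellet"] = (
            identifiable_individuals / ident_pellets
        )
    else:
        log.warning(
            "collection %s: identifiable-pellet count unavailable; mean items per pellet undefined",
            vec.collection_id,
        )
        scalars["mean_items_per_identifiable_pellet"] = None
    return df, scalars


def pooled_mean_items(summaries: Sequence[dict]) -> float:
    """Identifiable individuals per identifiable pellet, pooled over collections."""
    ind = sum(s["identifiable_individuals"] for s in summaries)
    pel = sum(s["identifiable_pellets"] for s in summaries)
    if pel == 0:
        raise ZeroDivisionError("no identifiable pellets in pooled collections")
    return ind / pel


def class_composition(
    vectors: Sequence[AbundanceVector],
    class_groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Percent of individuals per vertebrate class, per collection and pooled.

    Per-collection percentages use the collection's full individual total
    (including one-per-pellet unidentifiable tallies); the pooled row uses the
    identifiable individual total, matching how multi-collection totals are
    conventionally reported.
    """
    rows = []
    pooled: Dict[str, int] = {}
    pooled_ident = 0
    for vec in vectors:
        n = vec.n
        unid = vec.count(UNIDENTIFIABLE) or 0
        pooled_ident += n - unid
        for cls, groups in class_groups.items():
            c = sum(vec.counts([g for g in groups if g in vec.groups()]).values())
            pooled[cls] = pooled.get(cls, 0) + c
            rows.append(
                {
                    "collection_id": vec.collection_id,
                    "class": cls,
                    "individuals": c,
                    "pct_individuals": 100.0 * c / n,
                }
            )
    for cls, c in pooled.items():
        rows.append(
            {
                "collection_id": "pooled",
                "class": cls,
                "individuals": c,
                "pct_individuals": 100.0 * c / pooled_ident,
            }
        )
    return pd.DataFrame(rows)
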