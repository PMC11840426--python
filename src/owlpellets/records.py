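"""Core record types for element-level owl-pellet data.

An owl pellet is dissected into skeletal elements; each identifiable
craniodental element (left/right mandible, skull) is assigned to a taxon
and, where possible, an age class.  These records are the raw observations
that the minimum-number-of-individuals (MNI) counting rule consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

AGE_CLASSES = frozenset({"juvenile", "adult", "unknown"})
ELEMENTS = frozenset(
    {
        "left_mandible",
        "right_mandible",
        "skull",
        "other_cranial",
        "unidentifiable_postcranial",
    }
)

#: Taxon label carried by unidentifiable postcranial material.
UNIDENTIFIABLE = "unidentifiable"


class ValidationError(ValueError):
    """Raised when a record or scenario violates its schema."""


class UnknownCountError(ValueError):
    """Raised when an operation would need a count that is not known.

    Partially published historical datasets carry missing per-taxon counts;
    those are never imputed — any computation touching them refuses.
    """


@dataclass(frozen=True)
class ElementRecord:
    """One observed skeletal-element count within one pellet.

    ``count`` is the number of that element observed for the given taxon and
    age class in the pellet, e.g. two left mandibles of adult *Sminthopsis
    douglasi*.
    """

    collection_id: str
    pellet_id: str
    taxon: str
    age_class: str
    element: str
    count: int

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"age_class {self.age_class!r} not in {sorted(AGE_CLASSES)}"
            )
        if self.element not in ELEMENTS:
            raise ValidationError(
                f"element {self.element!r} not in {sorted(ELEMENTS)}"
            )
        if not isinstance(self.count, int) or self.count < 0:
            raise ValidationError(f"count must be a non-negative integer, got {self.count!r}")
        if self.element == "unidentifiable_postcranial" and self.taxon != UNIDENTIFIABLE:
            raise ValidationError(
                "unidentifiable_postcranial rows must carry taxon 'unidentifiable'"
            )

    @property
    def key(self) -> tuple:
        return (self.collection_id, self.pellet_id, self.taxon, self.age_class, self.element)


@dataclass(frozen=True)
class CollectionMetadata:
    """Collection-level facts: the total number of whole pellets assessed.

    ``n_pellets_total`` is the N of the detection formula — all whole pellets,
    including those that yielded only unidentifiable material.
    """

    collection_id: str
    n_pellets_total: int
    date_range: Optional[str] = None
    notes: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_pellets_total < 1:
            raise ValidationError("n_pellets_total must be a positive integer")


@dataclass(frozen=True)
class TaxonomyMap:
    """Mapping from raw taxon labels to analysis-group labels.

    Cross-study comparisons require a common taxonomy: e.g. bird species
    identified to genus in one study are pooled into Class Aves to match a
    historical dataset that only reported birds as a class.  ``default_group``
    absorbs unmapped labels; when it is ``None`` unmapped labels pass through
    unchanged.  The map must be idempotent: group labels map to themselves.
    """

    profile_name: str
    mapping: Mapping[str, str] = field(default_factory=dict)
    default_group: Optional[str] = None

    def __post_init__(self) -> None:
        for group in self.mapping.values():
            if self.resolve(group) != group:
                raise ValidationError(
                    f"taxonomy map {self.profile_name!r} not idempotent: "
                    f"group {group!r} maps to {self.resolve(group)!r}"
                )

    def resolve(self, taxon: str) -> str:
        """Return the analysis group for a raw taxon label.

        Group labels (mapping targets and the default group) are fixed
        points, which makes resolution idempotent even when a default group
        absorbs unmapped labels.
        """
        if taxon in self.mapping:
            return self.mapping[taxon]
        if taxon == self.default_group or taxon in self.mapping.values():
            return taxon
        if self.default_group is None:
            return taxon
        return self.default_group
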