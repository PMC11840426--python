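"""Taxonomy pooling profiles and their application to element records.

Pooling makes collections comparable across studies that identified prey to
different taxonomic depth.  The bundled ``historic`` profile reproduces the
grouping used when the 2023–2024 Toorak collections are compared with the
1994–2001 historical dataset: bird taxa pool into "Aves spp.", lizard
families into "Squamata", frogs into "Anura"; mammal species and
unidentifiable material pass through unchanged (planigales are already
recorded as *Planigale* spp. because pellet material cannot separate the
candidate species).
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

from .records import ElementRecord, TaxonomyMap

log = logging.getLogger(__name__)

#: Mammal analysis groups (diversity analyses run on mammals only).
MAMMAL_GROUPS = (
    "Sminthopsis douglasi",
    "Sminthopsis macroura",
    "Planigale spp.",
    "Rattus villosissimus",
    "Leggadina forresti",
    "Mus musculus",
)

_BIRDS = (
    "Taeniopygia sp.",
    "Artamus sp.",
    "Mirafra javanica",
    "Melopsittacus undulatus",
    "Anthus australis",
    "Aves spp.",
)

_HISTORIC_MAPPING = {
    **{b: "Aves spp." for b in _BIRDS},
    "Gekkonidae": "Squamata",
    "Agamidae": "Squamata",
    "Squamata": "Squamata",
    "Anura": "Anura",
}

IDENTITY_PROFILE = TaxonomyMap(profile_name="identity")
HISTORIC_PROFILE = TaxonomyMap(profile_name="historic", mapping=_HISTORIC_MAPPING)

PROFILES = {
    "identity": IDENTITY_PROFILE,
    "historic": HISTORIC_PROFILE,
}


def get_profile(name: str) -> TaxonomyMap:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown taxonomy profile {name!r}; available: {sorted(PROFILES)}")


def apply_taxonomy(
    records: Iterable[ElementRecord], taxonomy: TaxonomyMap
) -> list[ElementRecord]:
    """Replace taxon labels by analysis-group labels, merging duplicates.

    Records that collide on (collection, pellet, group, age_class, element)
    after relabelling have their counts summed, so the total element count of
    every element class is conserved.  Absorptions into ``default_group`` are
    logged.
    """
    merged: Counter = Counter()
    order: list[tuple] = []
    for rec in records:
        group = taxonomy.resolve(rec.taxon)
        if group != rec.taxon and rec.taxon not in taxonomy.mapping:
            log.info(
                "taxonomy %s: absorbing unmapped taxon %r into %r",
                taxonomy.profile_name, rec.taxon, group,
            )
        key = (rec.collection_id, rec.pellet_id, group, rec.age_class, rec.element)
        if key not in merged:
            order.append(key)
        merged[key] += rec.count
    return [
        ElementRecord(
            collection_id=k[0], pellet_id=k[1], taxon=k[2], age_class=k[3],
            element=k[4], count=merged[k],
        )
        for k in order
    ]


def is_mammal(group: str, mammal_groups: Sequence[str] = MAMMAL_GROUPS) -> bool:
    return group in mammal_groups
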