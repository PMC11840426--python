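"""Bundled Toorak barn-owl pellet fixtures.

Three present-day collections (Initial, Winter, Summer; 2023–2024) are
bundled as per-taxon/age summary counts, together with the partially
reconstructible Historic collection (1994–2001; total 400 individuals, but
per-taxon counts known only for six groups — the remainder are stored as
unknown and operations touching them refuse rather than impute).

For pipeline testing an element-level representation of each present-day
collection is synthesised deterministically from the summary counts:
individuals are laid out over pellets round-robin so that every per-taxon/age
pellet-occurrence count, every individual count and the number of
identifiable pellets are reproduced exactly.  The within-pellet co-occurrence
structure is synthetic — the true pellet-by-pellet layout is not derivable
from the published summary table.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict

from .abundance import AbundanceVector
from .records import UNIDENTIFIABLE, CollectionMetadata, ElementRecord

PRESENT_DAY = ("Initial", "Winter", "Summer")


def _data_path(name: str):
    return resources.files("owlpellets.data").joinpath(name)


def load_collection_metadata() -> Dict[str, CollectionMetadata]:
    meta: Dict[str, CollectionMetadata] = {}
    with _data_path("toorak_collections.csv").open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            meta[row["collection_id"]] = CollectionMetadata(
                collection_id=row["collection_id"],
                n_pellets_total=int(row["n_pellets_total"]),
                date_range=row["date_range"],
                notes=row["notes"],
            )
    return meta


def _totals() -> Dict[str, int]:
    with _data_path("toorak_collections.csv").open(newline="", encoding="utf-8") as fh:
        return {
            row["collection_id"]: int(row["n_individuals_total"])
            for row in csv.DictReader(fh)
        }


def _load_vectors(filename: str) -> Dict[str, AbundanceVector]:
    from .io import read_abundance_table

    meta = load_collection_metadata()
    return read_abundance_table(
        _data_path(filename),
        n_pellets_total={c: m.n_pellets_total for c, m in meta.items()},
        n_total=_totals(),
    )


def load_present_day() -> Dict[str, AbundanceVector]:
    """Abundance vectors for the Initial, Winter and Summer collections."""
    vecs = _load_vectors("toorak_present_day.csv")
    return {c: vecs[c] for c in PRESENT_DAY}


def load_historic() -> AbundanceVector:
    """The Historic collection: known totals only, unknowns left unknown."""
    return _load_vectors("toorak_historic.csv")["Historic"]


def load_all() -> Dict[str, AbundanceVector]:
    out = load_present_day()
    out["Historic"] = load_historic()
    return out


def element_records(collection_id: str) -> tuple[list[ElementRecord], CollectionMetadata]:
    """Deterministic element-level reconstruction of a present-day collection.

    Identifiable pellets are numbered 1..P (P = pellets assessed minus
    unidentifiable-only pellets).  Each (taxon, age class) with k occupied
    pellets and m individuals is assigned k pellets from a global round-robin
    cursor (so its pellet-occurrence count is exact and all P pellets end up
    occupied), one individual per pellet, with the m - k surplus individuals
    distributed cyclically as additional mandible pairs.  Each individual is
    represented by one left and one right mandible, so the per-pellet MNI
    equals the laid-out individual count.
    """
    if collection_id not in PRESENT_DAY:
        raise KeyError(
            f"element-level fixture only exists for {PRESENT_DAY}, not {collection_id!r}"
        )
    vec = load_present_day()[collection_id]
    meta = load_collection_metadata()[collection_id]
    n_unid = vec.individuals[(UNIDENTIFIABLE, "unknown")]
    p_ident = meta.n_pellets_total - vec.pellets_by_age[(UNIDENTIFIABLE, "unknown")]
    width = len(str(meta.n_pellets_total))

    # per-pellet individual tallies: {pellet index: {(taxon, age): count}}
    layout: Dict[int, Dict[tuple, int]] = {i: {} for i in range(p_ident)}
    cursor = 0
    for (taxon, age), k_pellets in vec.pellets_by_age.items():
        if taxon == UNIDENTIFIABLE or not k_pellets:
            continue
        m_individuals = vec.individuals[(taxon, age)]
        slots = [(cursor + j) % p_ident for j in range(k_pellets)]
        cursor = (cursor + k_pellets) % p_ident
        for j, slot in enumerate(slots):
            layout[slot][(taxon, age)] = 1
        for j in range(m_individuals - k_pellets):
            layout[slots[j % len(slots)]][(taxon, age)] += 1

    records: list[ElementRecord] = []
    for i in range(p_ident):
        pellet_id = f"p{i + 1:0{width}d}"
        for (taxon, age), count in sorted(layout[i].items()):
            for elem in ("left_mandible", "right_mandible"):
                records.append(
                    ElementRecord(collection_id, pellet_id, taxon, age, elem, count)
                )
    for i in range(n_unid):
        records.append(
            ElementRecord(
                collection_id,
                f"u{i + 1:0{width}d}",
                UNIDENTIFIABLE,
                "unknown",
                "unidentifiable_postcranial",
                1,
            )
        )
    return records, meta
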