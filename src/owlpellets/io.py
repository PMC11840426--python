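"""Reading and writing of pellet data and result tables.

Two input levels are supported: element-level records (one row per pellet x
taxon x age class x skeletal element, driving the full MNI pipeline) and
pre-aggregated abundance tables (per-taxon individual counts, enough for the
comparison/diversity/detection stages — the level at which partially
published historical datasets exist).  Files are UTF-8 CSV with a header
row; column names are remappable through a schema so third-party data can be
ingested without editing files.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .abundance import AbundanceVector
from .records import CollectionMetadata, ElementRecord, ValidationError

log = logging.getLogger(__name__)

ELEMENT_COLUMNS = ("collection_id", "pellet_id", "taxon", "age_class", "element", "count")
ABUNDANCE_COLUMNS = ("collection_id", "taxon", "age_class", "individuals", "pellets_containing")


class SchemaError(ValueError):
    """Raised when a required column cannot be resolved in an input file."""


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


def _resolve_columns(
    header: Sequence[str], required: Sequence[str], schema: Optional[Mapping[str, str]]
) -> Dict[str, int]:
    schema = schema or {}
    positions = {}
    for name in required:
        column = schema.get(name, name)
        if column not in header:
            raise SchemaError(f"required column {column!r} (for {name!r}) missing from header")
        positions[name] = header.index(column)
    return positions


def read_element_records(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    n_pellets_total: Optional[Mapping[str, int]] = None,
    strict: bool = False,
) -> tuple[list[ElementRecord], Dict[str, CollectionMetadata], list[RowError]]:
    """Parse an element-record CSV.

    Rows that fail validation (negative or non-integer counts, bad
    vocabulary, duplicate keys) are rejected individually and reported in the
    returned :class:`RowError` list (and logged); with ``strict=True`` any
    row error raises instead.  Collection metadata is built from
    ``n_pellets_total`` when supplied, else from the number of distinct
    pellet ids observed per collection.
    """
    path = Path(path)
    records: list[ElementRecord] = []
    errors: list[RowError] = []
    seen: set = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header row required")
        pos = _resolve_columns(header, ELEMENT_COLUMNS, schema)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                raw_count = row[pos["count"]].strip()
                try:
                    count = int(raw_count)
                except ValueError:
                    raise ValidationError(f"count {raw_count!r} is not an integer")
                rec = ElementRecord(
                    collection_id=row[pos["collection_id"]].strip(),
                    pellet_id=row[pos["pellet_id"]].strip(),
                    taxon=row[pos["taxon"]].strip(),
                    age_class=row[pos["age_class"]].strip(),
                    element=row[pos["element"]].strip(),
                    count=count,
                )
                if rec.key in seen:
                    raise ValidationError(f"duplicate record key {rec.key}")
                seen.add(rec.key)
                records.append(rec)
            except (ValidationError, IndexError) as exc:
                err = RowError(lineno, str(exc))
                errors.append(err)
                log.error("%s:%d: %s", path, lineno, exc)
                if strict:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc

    meta: Dict[str, CollectionMetadata] = {}
    pellets_by_collection: Dict[str, set] = {}
    for rec in records:
        pellets_by_collection.setdefault(rec.collection_id, set()).add(rec.pellet_id)
    for cid, pellets in pellets_by_collection.items():
        total = (n_pellets_total or {}).get(cid, len(pellets))
        if total < len(pellets):
            raise ValidationError(
                f"collection {cid}: n_pellets_total={total} below {len(pellets)} observed pellets"
            )
        meta[cid] = CollectionMetadata(collection_id=cid, n_pellets_total=total)
    return records, meta, errors


def read_abundance_table(
    path: Union[str, Path],
    schema: Optional[Mapping[str, str]] = None,
    n_pellets_total: Optional[Mapping[str, int]] = None,
    n_total: Optional[Mapping[str, int]] = None,
) -> Dict[str, AbundanceVector]:
    """Parse a pre-aggregated abundance CSV into per-collection vectors.

    Empty ``individuals`` or ``pellets_containing`` cells mark unknown
    counts, which downstream operations refuse rather than impute.
    """
    path = Path(path)
    vectors: Dict[str, AbundanceVector] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        pos = _resolve_columns(header, ABUNDANCE_COLUMNS, schema)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            cid = row[pos["collection_id"]].strip()
            taxon = row[pos["taxon"]].strip()
            age = row[pos["age_class"]].strip() or "unknown"
            ind_raw = row[pos["individuals"]].strip()
            pel_raw = row[pos["pellets_containing"]].strip()
            ind = int(ind_raw) if ind_raw else None
            pel = int(pel_raw) if pel_raw else None
            if ind is not None and ind < 0:
                raise ValidationError(f"{path}:{lineno}: negative individuals count")
            vec = vectors.setdefault(
                cid,
                AbundanceVector(
                    collection_id=cid,
                    n_pellets_total=(n_pellets_total or {}).get(cid),
                    n_total=(n_total or {}).get(cid),
                ),
            )
            if (taxon, age) in vec.individuals:
                raise ValidationError(f"{path}:{lineno}: duplicate ({taxon}, {age})")
            vec.individuals[(taxon, age)] = ind
            vec.pellets_by_age[(taxon, age)] = pel
    # The cross-age union pellet occurrence equals the per-age value only for
    # single-age groups; per-age counts of a split group cannot be combined
    # (overlap unknown), so the union is left unknown there.
    for vec in vectors.values():
        for group in vec.groups():
            ages = [k for k in vec.pellets_by_age if k[0] == group]
            if len(ages) == 1:
                vec.pellets_containing[group] = vec.pellets_by_age[ages[0]]
            else:
                vec.pellets_containing[group] = None
    return vectors


def write_element_records(records: Iterable[ElementRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ELEMENT_COLUMNS)
        for r in records:
            writer.writerow([r.collection_id, r.pellet_id, r.taxon, r.age_class, r.element, r.count])


def write_table(
    rows: Union[pd.DataFrame, Sequence[Mapping]],
    path: Union[str, Path],
    fmt: Optional[str] = None,
    precision: int = 2,
    p_value_columns: Sequence[str] = ("p_adj",),
    p_display_floor: float = 0.01,
) -> Path:
    """Write a result table as CSV or JSON with deterministic column order.

    Floating values are rendered with ``precision`` decimals.  For each
    column named in ``p_value_columns`` a display column is added that
    renders values below ``p_display_floor`` as ``"< 0.01"`` (the numeric
    column keeps full precision), matching the conventional presentation of
    heavily-adjusted p-values.
    """
    if rows is None:
        raise ValidationError("rows must not be None")
    df = rows.copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".").lower() or "csv")
    if fmt not in {"csv", "json"}:
        raise ValueError(f"format must be csv or json, got {fmt!r}")

    for col in p_value_columns:
        if col in df.columns:
            df[f"{col}_display"] = [
                "" if pd.isna(v) else (f"< {p_display_floor:g}" if v < p_display_floor else f"{v:.{precision}f}")
                for v in df[col]
            ]

    def _render(v):
        if isinstance(v, float):
            if pd.isna(v):
                return ""
            return f"{v:.{precision}f}"
        return v

    if fmt == "csv":
        out = df.copy()
        for col in out.columns:
            if not col.endswith("_display") and col not in p_value_columns:
                out[col] = out[col].map(_render)
        out.to_csv(path, index=False)
    else:
        payload = df.to_dict(orient="records")
        for rec in payload:
            for k, v in rec.items():
                if isinstance(v, float) and not k.endswith("_display") and k not in p_value_columns:
                    rec[k] = None if pd.isna(v) else round(v, precision)
        path.write_text(json.dumps(payload, indent=2, default=str), encoding="utf-8")
    return path
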