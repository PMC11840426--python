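"""End-to-end orchestration: ingest -> taxonomy -> abundance -> summaries ->
comparisons -> diversity -> detection, from a single run configuration.

Stages are individually skippable: aggregate-only inputs cannot run the
abundance stage, and the detection stage runs only when focal species are
configured.  The manifest records the configuration, seed, package version,
per-stage row counts and a content hash of every output file, so identical
configurations are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import yaml

from . import __version__
from .abundance import AbundanceVector, pool_abundance, summarize, tabulate
from .comparison import pairwise_compare, results_frame
from .detection import detection_report
from .diversity import diversity_profile
from .io import read_abundance_table, read_element_records, write_table
from .records import UnknownCountError, ValidationError
from .taxonomy import get_profile

log = logging.getLogger(__name__)

#: Default taxa compared between collections (long-format comparison table).
DEFAULT_COMPARISON_TAXA = (
    "Sminthopsis douglasi",
    "Sminthopsis macroura",
    "Planigale spp.",
    "Rattus villosissimus",
    "Leggadina forresti",
    "Mus musculus",
    "Aves spp.",
    "Squamata",
    "Anura",
    "unidentifiable",
)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    element_files: Sequence[str] = field(default_factory=list)
    abundance_files: Sequence[str] = field(default_factory=list)
    use_bundled_fixtures: bool = False
    taxonomy_profile: str = "identity"
    comparison_taxa: Sequence[str] = field(default_factory=lambda: list(DEFAULT_COMPARISON_TAXA))
    diversity_q: Sequence[int] = (0, 1, 2)
    bootstrap_replicates: int = 50
    seed: Optional[int] = None
    detection_species: Sequence[str] = field(default_factory=list)
    alpha: float = 0.05
    output_dir: str = "results"
    n_pellets_total: Dict[str, int] = field(default_factory=dict)
    n_total: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.element_files or self.abundance_files or self.use_bundled_fixtures):
            raise ValidationError("config needs at least one input source")
        if self.bootstrap_replicates > 0 and self.seed is None:
            raise ValidationError("seed is required when bootstrap_replicates > 0")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every applicable stage and write the result bundle.

    Returns the manifest (also written as ``manifest.json``); any stage
    failure aborts with the stage named and partial outputs removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxonomy = get_profile(config.taxonomy_profile)
    written: list[Path] = []
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    stage = "ingest"
    try:
        vectors: Dict[str, AbundanceVector] = {}
        pellet_sets: Dict[str, list] = {}
        metas: Dict[str, object] = {}
        for f in config.element_files:
            recs, meta_map, errors = read_element_records(
                f, n_pellets_total=config.n_pellets_total
            )
            for cid, meta in meta_map.items():
                stage = "abundance"
                cid_records = [r for r in recs if r.collection_id == cid]
                pellets, vec = tabulate(cid_records, meta, taxonomy)
                vectors[cid] = vec
                pellet_sets[cid] = pellets
                metas[cid] = meta
        stage = "ingest"
        for f in config.abundance_files:
            for cid, vec in read_abundance_table(
                f, n_pellets_total=config.n_pellets_total, n_total=config.n_total
            ).items():
                vectors[cid] = vec
        if config.use_bundled_fixtures:
            from . import fixtures

            for cid, vec in fixtures.load_all().items():
                vectors.setdefault(cid, vec)
                metas.setdefault(cid, fixtures.load_collection_metadata()[cid])
        if not vectors:
            raise ValidationError("no collections ingested")
        manifest["stages"]["ingest"] = {"collections": sorted(vectors)}

        stage = "summaries"
        summary_frames = []
        scalar_rows = []
        for cid, vec in vectors.items():
            meta = metas.get(cid)
            if meta is None:
                from .records import CollectionMetadata

                if vec.n_pellets_total is None:
                    log.info("collection %s: no pellet total; summary skipped", cid)
                    continue
                meta = CollectionMetadata(cid, vec.n_pellets_total)
            try:
                df, scalars = summarize(vec, meta, pellet_sets.get(cid))
            except UnknownCountError:
                log.warning("collection %s: unknown counts; summary skipped", cid)
                continue
            summary_frames.append(df)
            scalar_rows.append(scalars)
        if summary_frames:
            import pandas as pd

            written.append(
                write_table(pd.concat(summary_frames, ignore_index=True), outdir / "summary.csv")
            )
            written.append(write_table(scalar_rows, outdir / "collection_scalars.json"))
        manifest["stages"]["summaries"] = {"rows": sum(len(f) for f in summary_frames)}

        stage = "comparisons"
        comparison_rows = 0
        if len(vectors) >= 2:
            pooled = [pool_abundance(v, taxonomy) for v in vectors.values()]
            results = pairwise_compare(pooled, config.comparison_taxa)
            cmp_df = results_frame(results)
            comparison_rows = len(cmp_df)
            written.append(write_table(cmp_df, outdir / "comparisons.csv", precision=4))
        manifest["stages"]["comparisons"] = {"rows": comparison_rows}

        stage = "diversity"
        div_rows = []
        for cid, vec in vectors.items():
            try:
                counts = vec.mammal_counts()
            except UnknownCountError:
                log.warning("collection %s: mammal counts incomplete; diversity skipped", cid)
                continue
            for est in diversity_profile(
                counts,
                collection_id=cid,
                qs=config.diversity_q,
                B=config.bootstrap_replicates,
                seed=config.seed,
            ):
                div_rows.append(asdict(est))
        if div_rows:
            written.append(write_table(div_rows, outdir / "diversity.csv", precision=4))
        manifest["stages"]["diversity"] = {"rows": len(div_rows)}

        stage = "detection"
        det_rows = 0
        for species in config.detection_species:
            sites = [
                (cid, vec.pellets_containing.get(species), vec.n_pellets_total)
                for cid, vec in vectors.items()
                if vec.n_pellets_total is not None
            ]
            df, _ = detection_report(sites, species=species, alpha=config.alpha)
            if not df.empty:
                det_rows += len(df)
                safe = species.replace(" ", "_").replace(".", "")
                written.append(
                    write_table(df, outdir / f"detection_{safe}.csv", precision=4)
                )
        manifest["stages"]["detection"] = {"rows": det_rows}
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {str(p.name): _sha256(p) for p in written}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    return manifest
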