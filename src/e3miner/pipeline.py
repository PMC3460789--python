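"""End-to-end orchestration: mine → homology → rate → stage → report.

A run is described by a YAML config (paths plus rating/stage/homology
parameters).  Any prefix of the stage chain may be configured; each stage
that has its inputs runs and contributes its artifacts to the report bundle:
the catalogue TSV, the homology summary, ratings and the family × level
cross-tab, stage groups and the group × level cross-tab, Venn-style counts,
a per-tissue long-format level summary, and a manifest with a content hash
so identical runs are provably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import ARRAY, EST_COUNTS, StageDataset, read_expression_dataset, read_matrix
from .domain_mining import (
    E3Catalog,
    classify_families,
    filter_hits,
    parse_domtblout,
    read_gene_map,
)
from .homology import enrichment_test, map_homologs, parse_homologene, read_gene_set
from .stage_grouping import (
    StageConfig,
    assign_groups,
    group_ballot_all,
    stage_cross_tab,
)
from .tissue_rating import (
    RatingConfig,
    RatingMatrix,
    level_cross_tab,
    rate_all,
)

log = logging.getLogger("e3miner")


@dataclass
class RunConfig:
    """Validated run description (see ``from_yaml``)."""

    out_dir: Path
    tissue: str = "testis"
    domtbl: Path | None = None
    gene_map: Path | None = None
    e_max: float = 0.1
    homology_table: Path | None = None
    set_a: Path | None = None
    taxon_a: str = "10090"
    set_b: Path | None = None
    taxon_b: str = "9606"
    background_p0: float | None = None
    datasets: list[dict] = field(default_factory=list)
    stage_datasets: list[dict] = field(default_factory=list)
    rating: RatingConfig = field(default_factory=RatingConfig)
    stage: StageConfig = field(default_factory=StageConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "e3miner_out")),
            tissue=raw.get("tissue", "testis"),
            domtbl=_opt_path(raw.get("domtbl")),
            gene_map=_opt_path(raw.get("gene_map")),
            e_max=float(raw.get("e_max", 0.1)),
            homology_table=_opt_path(raw.get("homology_table")),
            set_a=_opt_path(raw.get("set_a")),
            taxon_a=str(raw.get("taxon_a", "10090")),
            set_b=_opt_path(raw.get("set_b")),
            taxon_b=str(raw.get("taxon_b", "9606")),
            background_p0=raw.get("background_p0"),
            datasets=raw.get("datasets", []),
            stage_datasets=raw.get("stage_datasets", []),
            rating=RatingConfig(**raw.get("rating", {})),
            stage=StageConfig(**raw.get("stage", {})),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("domtbl", "gene_map", "homology_table", "set_a", "set_b"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for spec in self.datasets + self.stage_datasets:
            if not Path(spec["path"]).exists():
                raise FileNotFoundError(f"dataset file {spec['path']} does not exist")


def _opt_path(value) -> Path | None:
    return Path(value) if value else None


@dataclass
class ReportBundle:
    out_dir: Path
    catalog: E3Catalog | None = None
    homology_summary: dict | None = None
    ratings: RatingMatrix | None = None
    level_table: pd.DataFrame | None = None
    stage_groups: pd.DataFrame | None = None
    stage_table: pd.DataFrame | None = None
    headline: dict | None = None
    manifest: dict | None = None


def summarize_testis_classes(cross_tab: pd.DataFrame) -> dict[str, int]:
    """Headline counts from a family × level cross-tab.

    ``expressed`` = P + HP + MS + SP total; ``high_or_specific`` = HP + MS + SP.
    """
    totals = cross_tab.loc["total"]
    expressed = int(totals[["SP", "MS", "HP", "P"]].sum())
    high_or_specific = int(totals[["SP", "MS", "HP"]].sum())
    return {"expressed": expressed, "high_or_specific": high_or_specific}


def per_tissue_level_counts(ratings: RatingMatrix, genes=None) -> pd.DataFrame:
    """Long-format (tissue, level, count) table across all tissues."""
    final = ratings.final if genes is None else ratings.final.loc[
        ratings.final.index.intersection(list(genes))
    ]
    rows = []
    for tissue in final.columns:
        counts = final[tissue].value_counts()
        for level, count in counts.items():
            rows.append((tissue, level, int(count)))
    return pd.DataFrame(rows, columns=["tissue", "level", "count"])


def summarize_bundle(out_dir: Path) -> dict:
    """Recompute summary.json from an existing bundle's own artifacts.

    Idempotent: applied to a bundle the pipeline just wrote, it reproduces
    the identical summary file.
    """
    out_dir = Path(out_dir)
    summary: dict = {"headline": None}
    tab_path = out_dir / "level_cross_tab.tsv"
    if tab_path.exists():
        table = pd.read_csv(tab_path, sep="\t", index_col=0)
        summary["headline"] = summarize_testis_classes(table)
    cat_path = out_dir / "catalog.tsv"
    if cat_path.exists():
        catalog = pd.read_csv(cat_path, sep="\t")
        summary["family_counts"] = {
            fam: int((catalog["family"] == fam).sum())
            for fam in ("RING", "HECT", "U-box")
        }
        summary["catalog_size"] = int(len(catalog))
    hom_path = out_dir / "homology_summary.json"
    if hom_path.exists():
        hom = json.loads(hom_path.read_text())
        summary["venn"] = {
            "set_a": hom["n_a"],
            "set_b": hom["n_b"],
            "intersection": hom["n_shared"],
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _load_expression(spec: dict):
    kind = spec.get("kind", ARRAY)
    return read_expression_dataset(
        spec["path"],
        name=spec.get("name"),
        kind=kind,
        require_calls=kind == ARRAY and spec.get("require_calls", True),
    )


def _load_stage(spec: dict) -> StageDataset:
    values = read_matrix(spec["path"])
    return StageDataset(
        name=spec.get("name", Path(spec["path"]).stem),
        values=values,
        phases=list(spec["phases"]),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every configured stage and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    written: list[Path] = []

    if config.domtbl is not None:
        log.info("mining catalogue from %s", config.domtbl)
        if config.gene_map is None:
            raise ValueError("domain mining needs a protein→gene map (gene_map)")
        hits = filter_hits(parse_domtblout(config.domtbl), config.e_max)
        bundle.catalog = classify_families(
            hits,
            read_gene_map(config.gene_map),
            provenance=f"{config.domtbl} (E <= {config.e_max})",
        )
        path = out / "catalog.tsv"
        bundle.catalog.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)

    if config.homology_table is not None and config.set_a and config.set_b:
        log.info("mapping homologs from %s", config.homology_table)
        table = parse_homologene(config.homology_table)
        summary = map_homologs(
            read_gene_set(config.set_a),
            config.taxon_a,
            read_gene_set(config.set_b),
            config.taxon_b,
            table,
        )
        bundle.homology_summary = {
            "n_a": summary.n_a,
            "n_b": summary.n_b,
            "n_shared": summary.n_shared,
            "union": summary.union,
            "fraction": summary.fraction,
            "fraction_pct": round(100 * summary.fraction, 1),
        }
        if config.background_p0 is not None:
            bundle.homology_summary["enrichment_p"] = enrichment_test(
                summary.n_shared, summary.union, float(config.background_p0)
            )
        path = out / "homology_summary.json"
        path.write_text(json.dumps(bundle.homology_summary, indent=2, sort_keys=True))
        written.append(path)

    if config.datasets:
        log.info("rating %d expression voters", len(config.datasets))
        voters = [_load_expression(spec) for spec in config.datasets]
        shared = set.intersection(*(set(v.genes) for v in voters))
        if not shared:
            sizes = {v.name: len(v.genes) for v in voters}
            log.warning("no gene shared by all voters (sizes: %s)", sizes)
        bundle.ratings = rate_all(voters, config.rating)
        path = out / "ratings.tsv"
        flat = bundle.ratings.final.copy()
        flat.to_csv(path, sep="\t", index_label="gene_id")
        written.append(path)
        tissue_counts = per_tissue_level_counts(
            bundle.ratings,
            genes=bundle.catalog.genes() if bundle.catalog else None,
        )
        path = out / "per_tissue_levels.tsv"
        tissue_counts.to_csv(path, sep="\t", index=False)
        written.append(path)
        if bundle.catalog is not None:
            bundle.level_table = level_cross_tab(
                bundle.catalog, bundle.ratings, config.tissue
            )
            path = out / "level_cross_tab.tsv"
            bundle.level_table.to_csv(path, sep="\t", index_label="family")
            written.append(path)
            bundle.headline = summarize_testis_classes(bundle.level_table)

    if config.stage_datasets:
        log.info("grouping %d stage voters", len(config.stage_datasets))
        courses = [_load_stage(spec) for spec in config.stage_datasets]
        per_ds = [assign_groups(ds, config.stage) for ds in courses]
        bundle.stage_groups = group_ballot_all(per_ds, config.stage)
        path = out / "stage_groups.tsv"
        bundle.stage_groups.to_csv(path, sep="\t")
        written.append(path)
        if bundle.ratings is not None:
            bundle.stage_table = stage_cross_tab(
                bundle.stage_groups["final"], bundle.ratings, config.tissue
            )
            path = out / "stage_cross_tab.tsv"
            bundle.stage_table.to_csv(path, sep="\t", index_label="group")
            written.append(path)

    summary = {"headline": bundle.headline}
    if bundle.catalog is not None:
        summary["family_counts"] = bundle.catalog.family_counts()
        summary["catalog_size"] = len(bundle.catalog)
    if bundle.homology_summary is not None:
        summary["venn"] = {
            "set_a": bundle.homology_summary["n_a"],
            "set_b": bundle.homology_summary["n_b"],
            "intersection": bundle.homology_summary["n_shared"],
        }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(path)

    digest = hashlib.sha256()
    for p in sorted(written):
        digest.update(p.name.encode())
        digest.update(p.read_bytes())
    bundle.manifest = {
        "version": __version__,
        "seed": config.seed,
        "tissue": config.tissue,
        "outputs": sorted(p.name for p in written),
        "bundle_sha256": digest.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return bundle
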