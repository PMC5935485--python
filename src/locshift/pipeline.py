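"""End-to-end orchestration: cells -> profiles -> z-scores -> clusters.

The pipeline profiles every screen's single-cell table, detects localization
changes of each screen against the designated reference, concatenates the
per-screen change profiles, applies the strong-signal filter, clusters the
survivors and writes every intermediate plus a provenance manifest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cluster as cl
from . import detect, formats, profiles

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every numeric setting of the analysis in one place."""

    reference_screen_id: str
    screen_order: list[str]
    k_neighbors: int = 50
    trim: float = 0.05
    min_cells_per_bin: int = 1
    min_neighbors: int = 10
    min_strong: int = 3
    z_thresh: float = 5.0
    min_present: float = 0.8
    cut_height: float = 0.8
    min_cluster_size: int = 2
    transcript_min_count: int = 2
    transcript_thresh: float = 2.0
    abundance_min_count: int = 2
    abundance_thresh: float = 50.0
    loc_min_count: int = 8
    loc_thresh: float = 5.0
    n_perm: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.reference_screen_id not in self.screen_order:
            raise ValueError("reference screen must appear in screen_order")
        if len(set(self.screen_order)) != len(self.screen_order):
            raise ValueError("duplicate screens in screen_order")
        for name in ("trim", "z_thresh", "min_present", "transcript_thresh",
                     "abundance_thresh", "loc_thresh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PipelineResult:
    profiles: dict[str, pd.DataFrame]
    counts: dict[str, pd.DataFrame]
    change: dict[str, pd.DataFrame]
    concatenated: pd.DataFrame
    filtered: pd.DataFrame
    tree: cl.Dendrogram | None
    clusters: cl.ClusterSet | None
    manifest: dict


def run_full_pipeline(
    config: PipelineConfig,
    cell_tables: dict[str, pd.DataFrame],
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run profiling, change detection, integration and clustering.

    ``cell_tables`` maps screen id to a validated single-cell table.  When
    ``outdir`` is given, all intermediates (profile matrices, z matrices,
    concatenated/filtered matrices, CDT/GTR, cluster table) and a manifest
    are written there.  Deterministic for fixed inputs/config.
    """
    missing = [s for s in config.screen_order if s not in cell_tables]
    if missing:
        raise ValueError(f"screens in config but not in inputs: {missing}")

    prof: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.DataFrame] = {}
    for s in config.screen_order:
        try:
            vals, cnts = profiles.build_screen_profiles(cell_tables[s], trim=config.trim)
        except Exception as exc:  # pragma: no cover - stage tagging
            raise RuntimeError(f"[profile:{s}] {exc}") from exc
        keep = cnts[(cnts >= config.min_cells_per_bin).all(axis=1)].index
        dropped = len(vals) - len(keep)
        if dropped:
            logger.info("screen %s: %d proteins fail the cell-count filter", s, dropped)
        prof[s] = vals.loc[keep]
        counts[s] = cnts.loc[keep]

    ref = config.reference_screen_id
    change: dict[str, pd.DataFrame] = {}
    for s in config.screen_order:
        if s == ref:
            continue
        try:
            change[s] = detect.change_profiles(
                prof[ref], prof[s],
                k=config.k_neighbors, min_neighbors=config.min_neighbors,
                reference_screen_id=ref, target_screen_id=s,
            )
        except Exception as exc:
            raise RuntimeError(f"[detect:{s}] {exc}") from exc

    non_ref = [s for s in config.screen_order if s != ref]
    concat = cl.concatenate(change, non_ref)
    filtered = cl.strong_signal_filter(
        concat, config.min_strong, config.z_thresh, config.min_present
    )
    tree = clusters = None
    if len(filtered) >= 2:
        tree = cl.average_linkage_tree(filtered)
        clusters = cl.extract_clusters(
            tree, config.cut_height, min_size=config.min_cluster_size,
            concat_z=filtered, screen_order=non_ref,
        )

    manifest: dict = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = {}
        for s in config.screen_order:
            p = outdir / f"profiles_{s}.tsv"
            formats.write_matrix(prof[s], p)
            outputs[f"profiles_{s}"] = str(p)
        for s, z in change.items():
            p = outdir / f"change_{s}.tsv"
            formats.write_matrix(z, p)
            outputs[f"change_{s}"] = str(p)
        formats.write_matrix(concat, outdir / "concatenated.tsv")
        formats.write_matrix(filtered, outdir / "filtered.tsv")
        outputs["concatenated"] = str(outdir / "concatenated.tsv")
        outputs["filtered"] = str(outdir / "filtered.tsv")
        if tree is not None:
            cl.export_clustered_heatmap(filtered, tree, str(outdir / "heatmap"))
            outputs["heatmap"] = str(outdir / "heatmap.cdt")
            rows = [
                {"cluster": name, "protein_id": p2, "screens": ";".join(clusters.implicated_screens.get(name, []))}
                for name, members in clusters
                for p2 in members
            ]
            pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            outputs["clusters"] = str(outdir / "clusters.tsv")
        manifest = formats.write_manifest(
            outdir / "manifest.json", asdict(config), outputs, config.seed
        )
    return PipelineResult(prof, counts, change, concat, filtered, tree, clusters, manifest)
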