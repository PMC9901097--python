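"""End-to-end orchestration: curation -> aggregation -> DE -> patterns -> enrichment.

`run_pipeline` consumes a :class:`RunConfig` naming the input files and
thresholds, executes the stages in order, writes every result table as TSV
under the output directory, and records a manifest (config hash, seed,
package version, per-stage feature counts) from which the run can be
reproduced.  The pipeline itself is deterministic; the seed is carried for
provenance and for the synthetic-data generator upstream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._util import ConfigurationError, parse_sample_names
from .curate import curate_transcripts
from .diffexp import cpm, deg_between_segments, deo_between_species, tmm_factors
from .enrichment import GODag, elim_go, fisher_go, pca_loadings, top_loading_sets
from .orthogroups import (
    Annotation,
    aggregate_expression,
    parse_orthogroup_table,
    shared_orthogroups,
    transfer_annotation,
)
from .patterns import (
    classify_sink_source,
    heatmap_matrix,
    mean_cpm_profiles,
    pathway_deo_percentages,
    pattern_conservation,
    zscore_profile,
)

logger = logging.getLogger(__name__)

STAGES = ("curate", "aggregate", "de", "patterns", "enrich")


@dataclass
class RunConfig:
    """Paths, thresholds and species settings for one pipeline run."""

    counts: str
    tpm: str
    fasta: str
    orthogroups: str
    annotations: str
    go_edges: str
    pathways: str
    outdir: str
    focal_species: str
    priority: tuple[str, ...]
    markers: str | None = None
    alpha: float = 0.01
    fc_threshold: float = 1.0
    min_cpm: float = 1.0
    min_libraries: int = 3
    identity_threshold: float = 0.95
    orf_min_len: int = 100
    r_conserved: float = 0.8
    loading_fraction: float = 0.05
    n_components: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.fc_threshold < 0:
            raise ConfigurationError("fc_threshold must be >= 0")
        if not 0 < self.identity_threshold <= 1:
            raise ConfigurationError("identity_threshold must be in (0, 1]")
        if not -1 <= self.r_conserved <= 1:
            raise ConfigurationError("r_conserved must be in [-1, 1]")
        if not 0 < self.loading_fraction < 0.5:
            raise ConfigurationError("loading_fraction must be in (0, 0.5)")
        if not self.priority:
            raise ConfigurationError("priority species list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["priority"] = tuple(d["priority"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["priority"] = list(self.priority)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["priority"] = list(self.priority)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    """In-memory handles to the tables a run produced."""

    curation: pd.DataFrame
    og_counts: pd.DataFrame
    annotations: pd.DataFrame
    shared_og: list[str]
    deg: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    deo: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    deg_summary: pd.DataFrame | None = None
    deo_summary: pd.DataFrame | None = None
    conservation: pd.DataFrame | None = None
    pathway_deo: pd.DataFrame | None = None
    heatmaps: dict[str, pd.DataFrame] = field(default_factory=dict)
    sink_source: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    pca_variance: pd.DataFrame | None = None
    pca_enrichment: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _read_ref_annotations(path) -> dict[str, dict[str, Annotation]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, dict[str, Annotation]] = {}
    for row in df.itertuples(index=False):
        go_ids = tuple(t for t in str(row.go_ids).split(",") if t)
        out.setdefault(row.species, {})[row.transcript_id] = Annotation(
            row.species, row.description, go_ids, str(row.is_tf) in ("1", "True", "true")
        )
    return out


def run_pipeline(config: RunConfig, through_stage: str = "enrich") -> ResultBundle:
    """Execute the pipeline up to and including ``through_stage``."""
    if through_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {through_stage!r}; choose from {STAGES}")
    last = STAGES.index(through_stage)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts = io.read_matrix(config.counts)
    tpm = io.read_matrix(config.tpm)
    records = io.read_fasta(config.fasta)
    og_map = parse_orthogroup_table(config.orthogroups)
    ref_ann = _read_ref_annotations(config.annotations)
    meta = parse_sample_names(counts.columns)
    species = sorted(meta["species"].unique())
    segments = sorted(meta["segment"].unique())

    # ---- stage: curate -----------------------------------------------------
    cur_rows = []
    kept: set[str] = set()
    for sp in species:
        sp_records = [r for r in records if r.species == sp]
        sp_samples = list(meta.index[meta["species"] == sp])
        mean_tpm = tpm.loc[[r.transcript_id for r in sp_records], sp_samples].mean(axis=1)
        report = curate_transcripts(
            sp_records,
            mean_tpm.to_dict(),
            counts[sp_samples],
            identity_threshold=config.identity_threshold,
            orf_min_len=config.orf_min_len,
            min_cpm=config.min_cpm,
            min_libraries=config.min_libraries,
        )
        kept |= set(report.kept)
        frame = report.as_frame()
        frame.insert(0, "species", sp)
        cur_rows.append(frame)
        logger.info("curation %s: %s", sp, dict(zip(frame["stage"], frame["n_transcripts"])))
    curation = pd.concat(cur_rows, ignore_index=True)
    io.write_pairs(curation, outdir / "curation_report.tsv")

    # ---- stage: aggregate --------------------------------------------------
    og_map = og_map.restrict_members(kept)
    og_map = transfer_annotation(og_map, ref_ann, config.priority)
    og_expr = aggregate_expression(counts, og_map, meta, strict=True)
    shared = shared_orthogroups(og_map, species, expressed=kept)
    ann_rows = [
        {
            "og": og,
            "source_species": a.source_species,
            "description": a.description,
            "go_ids": ",".join(a.go_ids),
            "is_tf": int(a.is_tf),
        }
        for og, a in sorted(og_map.annotation.items())
    ]
    annotations = pd.DataFrame(ann_rows, columns=["og", "source_species", "description", "go_ids", "is_tf"])
    io.write_matrix(og_expr.matrix, outdir / "og_counts.tsv", index_label="og_id")
    io.write_pairs(annotations, outdir / "og_annotations.tsv")
    (outdir / "shared_og.txt").write_text("\n".join(shared) + "\n")
    logger.info("aggregation: %d OG, %d shared across %s", len(og_map.og_ids), len(shared), species)

    bundle = ResultBundle(
        curation=curation,
        og_counts=og_expr.matrix,
        annotations=annotations,
        shared_og=shared,
    )
    tf_flags = pd.Series(
        {og: bool(og_map.annotation[og].is_tf) for og in og_map.annotation}
    ).reindex(shared).fillna(False)
    shared_counts = og_expr.matrix.loc[shared]

    if last >= STAGES.index("de"):
        _stage_de(config, bundle, shared_counts, meta, species, segments, tf_flags, outdir)
    if last >= STAGES.index("patterns"):
        _stage_patterns(config, bundle, shared_counts, meta, species, segments, outdir)
    if last >= STAGES.index("enrich"):
        _stage_enrich(config, bundle, og_map, shared_counts, meta, outdir)

    bundle.manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "through_stage": through_stage,
        "n_samples": int(meta.shape[0]),
        "species": species,
        "segments": segments,
        "n_transcripts_input": int(curation.loc[curation["stage"] == "input", "n_transcripts"].sum()),
        "n_transcripts_kept": int(curation.loc[curation["stage"] == "expression_filter", "n_transcripts"].sum()),
        "n_og": len(og_map.og_ids),
        "n_shared_og": len(shared),
    }
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    return bundle


def _consecutive(segments: list[str]) -> list[tuple[str, str]]:
    return list(zip(segments[:-1], segments[1:]))


def _stage_de(config, bundle, shared_counts, meta, species, segments, tf_flags, outdir) -> None:
    deg_rows = []
    for sp in species:
        for seg_a, seg_b in _consecutive(segments):
            res = deg_between_segments(
                shared_counts, meta, sp, (seg_a, seg_b), config.alpha, config.fc_threshold
            )
            bundle.deg[(sp, seg_a, seg_b)] = res
            io.write_matrix(res, outdir / f"deg_{sp}_{seg_a}-{seg_b}.tsv", index_label="og_id")
            deg_rows.append(
                {
                    "species": sp,
                    "transition": f"{seg_a}-{seg_b}",
                    "n_deg": int(res["significant"].sum()),
                    "n_up_late": int((res["direction"] == "up_in_B").sum()),
                    "n_up_early": int((res["direction"] == "up_in_A").sum()),
                }
            )
    bundle.deg_summary = pd.DataFrame(deg_rows)
    io.write_pairs(bundle.deg_summary, outdir / "deg_summary.tsv")

    deo_rows = []
    for sp_a, sp_b in itertools.combinations(species, 2):
        for seg in segments:
            res, tf = deo_between_species(
                shared_counts, meta, (sp_a, sp_b), seg, config.alpha,
                config.fc_threshold, tf_flags=tf_flags,
            )
            bundle.deo[(sp_a, sp_b, seg)] = res
            io.write_matrix(res, outdir / f"deo_{sp_a}-{sp_b}_{seg}.tsv", index_label="og_id")
            deo_rows.append(
                {
                    "species_pair": f"{sp_a}-{sp_b}",
                    "segment": seg,
                    "n_tested": int(res.shape[0]),
                    "n_deo": tf.n_deo,
                    "n_tf": tf.n_tf,
                    "tf_pct": tf.percent,
                }
            )
    bundle.deo_summary = pd.DataFrame(deo_rows)
    io.write_pairs(bundle.deo_summary, outdir / "deo_summary.tsv")
    logger.info("DE stage: %d DEG tables, %d DEO tables", len(bundle.deg), len(bundle.deo))


def _stage_patterns(config, bundle, shared_counts, meta, species, segments, outdir) -> None:
    profiles = mean_cpm_profiles(shared_counts, meta, segments)
    cons_rows = []
    for og in shared_counts.index:
        z = {sp: zscore_profile(profiles[sp].loc[og].to_numpy()) for sp in species}
        call = pattern_conservation(z, config.r_conserved, focal_species=config.focal_species)
        row = {"og": og, "conserved": call.conserved}
        for (sa, sb), r in sorted(call.pair_r.items()):
            row[f"r_{sa}-{sb}"] = r
        cons_rows.append(row)
    bundle.conservation = pd.DataFrame(cons_rows)
    io.write_pairs(bundle.conservation.round(6), outdir / "conservation.tsv")

    pathways = io.read_pathways(config.pathways)
    pw_tables = []
    for (sp_a, sp_b, seg), res in sorted(bundle.deo.items()):
        pw_tables.append(pathway_deo_percentages(res, pathways, (sp_a, sp_b), seg))
    bundle.pathway_deo = (
        pd.concat(pw_tables, ignore_index=True) if pw_tables else pd.DataFrame()
    )
    io.write_pairs(bundle.pathway_deo, outdir / "pathway_deo.tsv")

    for pw, og_list in pathways.items():
        present = [og for og in og_list if og in shared_counts.index]
        if not present:
            continue
        hm = heatmap_matrix(profiles, present)
        hm.columns = [f"{sp}_{seg}" for sp, seg in hm.columns]
        io.write_matrix(hm.round(6), outdir / f"heatmap_{pw}.tsv", index_label="og_id")
        bundle.heatmaps[pw] = hm

    if config.markers:
        markers = io.read_pairs(config.markers, ("og", "role"))
        rows = []
        for sp in species:
            prof = profiles[sp]
            marker_profiles = {
                og: prof.loc[og].to_numpy() for og in markers["og"] if og in prof.index
            }
            roles = dict(zip(markers["og"], markers["role"]))
            call = classify_sink_source(marker_profiles, roles, segments)
            rows += [{"species": sp, "segment": seg, "zone": call[seg]} for seg in segments]
        bundle.sink_source = pd.DataFrame(rows)
        io.write_pairs(bundle.sink_source, outdir / "sink_source.tsv")
    logger.info("patterns stage: %d conserved of %d shared OG",
                int(bundle.conservation["conserved"].sum()), len(bundle.conservation))


def _stage_enrich(config, bundle, og_map, shared_counts, meta, outdir) -> None:
    edges = io.read_pairs(config.go_edges, ("child", "parent"))
    og_terms = {
        og: list(og_map.annotation[og].go_ids)
        for og in bundle.shared_og
        if og in og_map.annotation
    }
    dag = GODag(list(edges.itertuples(index=False)), og_terms)
    universe = set(og_terms)

    enr_rows = []
    for (sp_a, sp_b, seg), res in sorted(bundle.deo.items()):
        study = set(res.index[res["significant"]]) & universe
        if not study:
            continue
        classic = fisher_go(dag, study, universe)
        adjusted = elim_go(dag, study, universe, alpha=config.alpha)
        for term in adjusted.index:
            enr_rows.append(
                {
                    "comparison": f"{sp_a}-{sp_b}_{seg}",
                    "term": term,
                    "p_classic": classic.get(term, np.nan),
                    "p_elim": adjusted[term],
                    "significant": adjusted[term] < config.alpha,
                }
            )
    bundle.enrichment = pd.DataFrame(enr_rows)
    io.write_pairs(bundle.enrichment, outdir / "go_enrichment.tsv")

    norm = tmm_factors(shared_counts)
    logcpm = np.log2(cpm(shared_counts, norm.effective_lib_sizes) + 1)
    n_comp = min(config.n_components, min(logcpm.shape))
    pca = pca_loadings(logcpm, n_comp)
    io.write_matrix(pca.scores.round(6), outdir / "pca_scores.tsv", index_label="sample")
    io.write_matrix(pca.loadings.round(6), outdir / "pca_loadings.tsv", index_label="og_id")
    bundle.pca_variance = pd.DataFrame(
        {"component": pca.loadings.columns, "variance_explained": pca.variance_explained}
    )
    io.write_pairs(bundle.pca_variance.round(6), outdir / "pca_variance.tsv")

    pca_rows = []
    for comp in pca.loadings.columns[:2]:
        top, bottom = top_loading_sets(pca.loadings[comp], config.loading_fraction)
        for side, feats in (("top", top), ("bottom", bottom)):
            study = set(feats) & universe
            if not study:
                continue
            adjusted = elim_go(dag, study, universe, alpha=config.alpha)
            for term in adjusted.index:
                pca_rows.append(
                    {
                        "component": comp,
                        "side": side,
                        "term": term,
                        "p_elim": adjusted[term],
                        "significant": adjusted[term] < config.alpha,
                    }
                )
    bundle.pca_enrichment = pd.DataFrame(pca_rows)
    io.write_pairs(bundle.pca_enrichment, outdir / "pca_enrichment.tsv")
    logger.info("enrichment stage: %d GO rows, PCA variance %s",
                len(bundle.enrichment), np.round(pca.variance_explained, 3).tolist())


def write_dataset(ds, outdir) -> None:
    """Write a :class:`~leafdeo.simulate.SimulatedDataset` as pipeline inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.transcripts, outdir / "transcripts.fasta")
    io.write_matrix(ds.counts, outdir / "counts.tsv", index_label="transcript_id")
    io.write_matrix(ds.tpm.round(4), outdir / "tpm.tsv", index_label="transcript_id")
    from .orthogroups import write_orthogroup_table

    write_orthogroup_table(ds.og_map, outdir / "orthogroups.tsv")
    ann_rows = [
        {
            "transcript_id": tid,
            "species": sp,
            "description": a.description,
            "go_ids": ",".join(a.go_ids),
            "is_tf": int(a.is_tf),
        }
        for sp in sorted(ds.ref_annotations)
        for tid, a in sorted(ds.ref_annotations[sp].items())
    ]
    io.write_pairs(
        pd.DataFrame(ann_rows, columns=["transcript_id", "species", "description", "go_ids", "is_tf"]),
        outdir / "annotations.tsv",
    )
    io.write_pairs(ds.go_annotations, outdir / "go_annotations.tsv")
    io.write_pairs(ds.go_dag_edges, outdir / "go_dag.tsv")
    io.write_pairs(
        pd.DataFrame(
            [(pw, og) for pw, members in sorted(ds.pathways.items()) for og in members],
            columns=["pathway", "og"],
        ),
        outdir / "pathways.tsv",
    )
    io.write_pairs(ds.markers, outdir / "markers.tsv")
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    io.write_pairs(ds.truth.og_effects, truth_dir / "og_effects.tsv")
    io.write_pairs(ds.truth.pattern_class, truth_dir / "pattern_class.tsv")
    io.write_pairs(ds.truth.pathway_membership, truth_dir / "pathway_membership.tsv")
    io.write_pairs(ds.truth.transcript_labels, truth_dir / "transcript_labels.tsv")
    tf = ds.truth.tf_flags.copy()
    tf["is_tf"] = tf["is_tf"].astype(int)
    io.write_pairs(tf, truth_dir / "tf_flags.tsv")
    io.sim_config_to_yaml(ds.config, outdir / "sim_config.yaml")


def default_run_config(data_dir, outdir, ds=None, **overrides) -> RunConfig:
    """A RunConfig pointing at a `write_dataset` directory."""
    data_dir = Path(data_dir)
    species = list(ds.config.species) if ds is not None else ["C3", "PK", "C4"]
    defaults = dict(
        counts=str(data_dir / "counts.tsv"),
        tpm=str(data_dir / "tpm.tsv"),
        fasta=str(data_dir / "transcripts.fasta"),
        orthogroups=str(data_dir / "orthogroups.tsv"),
        annotations=str(data_dir / "annotations.tsv"),
        go_edges=str(data_dir / "go_dag.tsv"),
        pathways=str(data_dir / "pathways.tsv"),
        markers=str(data_dir / "markers.tsv"),
        outdir=str(outdir),
        focal_species=species[-1],
        priority=tuple(species),
    )
    defaults.update(overrides)
    return RunConfig(**defaults)
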