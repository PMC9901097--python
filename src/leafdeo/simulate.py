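"""Synthetic leaf-gradient transcriptome datasets with planted ground truth.

The generator emulates the study design the analysis assumes: three grass
species (C3, Proto-Kranz, C4), four leaf segments sampled along the
developmental gradient (S1 base .. S7 tip), three pooled replicates per
segment, orthogroups with variable copy number (including species-absent
orthogroups), negative-binomial counts with gene-wise dispersion,
segment-profile classes (ascending / descending / peaked / flat), planted
species-by-segment differential-expression effects on pathway orthogroups,
planted transcription-factor labels, low-expression junk transcripts,
redundant truncated isoforms, and non-coding (short-ORF) transcripts.

Counts are drawn NB(mean, phi) with variance mu + phi * mu^2, the same
dispersion convention as the differential-expression engine.  A single
global seed is split into per-stage substreams so each stage is
individually reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._util import ConfigurationError, InputError, sample_name
from .curate import TranscriptRecord, find_best_orf
from .orthogroups import Annotation, OrthogroupMap

GO_ROOT = "GO:0008150"

_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in {"TAA", "TAG", "TGA"}
]

#: log2 expression offsets across segments for each profile class
DIVERGENT_CLASS = {
    "ascending": "descending",
    "descending": "ascending",
    "peaked": "flat",
    "flat": "peaked",
}


class PlantedEffect(NamedTuple):
    """A planted cross-species effect: every orthogroup of ``pathway`` gains
    ``log2fc`` in ``species`` at ``segment``."""

    pathway: str
    species: str
    segment: str
    log2fc: float


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic dataset; defaults mirror the study design."""

    seed: int = 0
    n_og: int = 500
    species: tuple[str, ...] = ("C3", "PK", "C4")
    segments: tuple[str, ...] = ("S1", "S3", "S5", "S7")
    n_reps: int = 3
    copy_number_probs: tuple[float, ...] = (0.0, 0.75, 0.18, 0.07)  # copies 0..3
    frac_species_absent: float = 0.10
    baseline_logmean_range: tuple[float, float] = (0.0, 8.0)
    dispersion_range: tuple[float, float] = (0.05, 0.2)
    profile_classes: tuple[tuple[str, float], ...] = (
        ("ascending", 0.40),
        ("descending", 0.25),
        ("peaked", 0.20),
        ("flat", 0.15),
    )
    frac_pattern_divergent: float = 0.0
    n_pathways: int = 3
    pathway_size: int = 20
    planted_deo: tuple[PlantedEffect, ...] = (
        PlantedEffect("pw01", "C4", "S5", 2.0),
        PlantedEffect("pw01", "C4", "S7", 2.0),
    )
    frac_junk: float = 0.15
    frac_noncoding: float = 0.08
    isoform_rate: float = 0.5
    library_size_range: tuple[float, float] = (8e5, 1.6e6)
    tf_fraction: float = 0.063
    orf_min_len: int = 100

    def __post_init__(self) -> None:
        for name in ("frac_species_absent", "frac_junk", "frac_noncoding", "tf_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_reps < 2:
            raise ConfigurationError(f"n_reps must be >= 2, got {self.n_reps}")
        if len(self.copy_number_probs) != 4 or any(p < 0 for p in self.copy_number_probs):
            raise ConfigurationError("copy_number_probs must be 4 non-negative weights over 0..3 copies")
        if abs(sum(self.copy_number_probs) - 1) > 1e-9:
            raise ConfigurationError("copy_number_probs must sum to 1")
        weights = [w for _, w in self.profile_classes]
        if any(w < 0 for w in weights) or abs(sum(weights) - 1) > 1e-9:
            raise ConfigurationError("profile_classes weights must be non-negative and sum to 1")
        known = set(DIVERGENT_CLASS)
        bad = {c for c, _ in self.profile_classes} - known
        if bad:
            raise ConfigurationError(f"profile_classes contains unknown classes {sorted(bad)}")
        if not 0 <= self.frac_pattern_divergent <= 1:
            raise ConfigurationError("frac_pattern_divergent must be in [0, 1]")
        if self.isoform_rate < 0:
            raise ConfigurationError(f"isoform_rate must be >= 0, got {self.isoform_rate}")
        for name in ("baseline_logmean_range", "dispersion_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be (low, high) with low <= high")
        if self.dispersion_range[0] < 0:
            raise ConfigurationError("dispersion_range must be non-negative")
        for eff in self.planted_deo:
            if eff.species not in self.species:
                raise ConfigurationError(f"planted_deo references unknown species {eff.species!r}")
            if eff.segment not in self.segments:
                raise ConfigurationError(f"planted_deo references unknown segment {eff.segment!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the data tables."""

    og_effects: pd.DataFrame  # og, species, segment, log2fc
    pattern_class: pd.DataFrame  # og, species, profile_class
    pathway_membership: pd.DataFrame  # pathway, og
    transcript_labels: pd.DataFrame  # transcript_id, label
    tf_flags: pd.DataFrame  # og, is_tf


@dataclass
class SimulatedDataset:
    config: SimConfig
    transcripts: list[TranscriptRecord]
    counts: pd.DataFrame  # transcripts x samples (zeros outside own species)
    tpm: pd.DataFrame
    og_map: OrthogroupMap
    ref_annotations: dict[str, dict[str, Annotation]]
    go_annotations: pd.DataFrame  # transcript_id, go_id
    go_dag_edges: pd.DataFrame  # child, parent
    pathways: dict[str, list[str]]
    markers: pd.DataFrame  # marker og, role in {sink, source}
    truth: SyntheticTruth
    lib_sizes: pd.Series
    sample_meta: pd.DataFrame


def profile_shape(cls: str, n_segments: int, amplitude: float = 1.5) -> np.ndarray:
    """Per-segment log2 offsets for a profile class."""
    x = np.linspace(-amplitude, amplitude, n_segments)
    if cls == "ascending":
        return x
    if cls == "descending":
        return x[::-1]
    if cls == "flat":
        return np.zeros(n_segments)
    if cls == "peaked":
        # maximum just after the leaf base, declining toward the tip
        pos = np.linspace(0, 1, n_segments)
        bump = np.exp(-(((pos - 0.35) / 0.28) ** 2))
        return amplitude * (2 * bump - 1)
    raise ConfigurationError(f"unknown profile class {cls!r}")


def simulate_counts(
    mean_matrix: np.ndarray | pd.DataFrame,
    dispersion: float | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray | pd.DataFrame:
    """Independent NB draws with variance mu + phi mu^2; phi = 0 is Poisson."""
    mu = np.asarray(mean_matrix, dtype=float)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float).reshape(-1, 1) if np.ndim(dispersion) == 1 else np.asarray(dispersion, dtype=float), mu.shape)
    if (mu < 0).any():
        raise InputError("negative mean in simulate_counts")
    if (phi < 0).any():
        raise InputError("negative dispersion in simulate_counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    if isinstance(mean_matrix, pd.DataFrame):
        return pd.DataFrame(out, index=mean_matrix.index, columns=mean_matrix.columns)
    return out


def _random_coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    utr5 = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 90)))
    utr3 = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 120)))
    body = "".join(np.asarray(_SENSE_CODONS)[rng.integers(0, len(_SENSE_CODONS), size=n_codons)])
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return utr5 + "ATG" + body + stop + utr3


def _random_noncoding_sequence(rng: np.random.Generator, min_orf: int) -> str:
    for _ in range(500):
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(120, 250)))
        if find_best_orf(seq, min_len_nt=min_orf) is None:
            return seq
    raise RuntimeError("failed to draw a non-coding sequence")  # pragma: no cover


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full dataset plus truth tables from ``config``.

    Identical config (including seed) yields byte-identical outputs.
    """
    rng_struct = np.random.default_rng([config.seed, 1])
    rng_seq = np.random.default_rng([config.seed, 2])
    rng_expr = np.random.default_rng([config.seed, 3])
    rng_counts = np.random.default_rng([config.seed, 4])

    ogs = [f"OG{i:04d}" for i in range(1, config.n_og + 1)]
    n_seg = len(config.segments)

    # --- orthogroup structure: copy numbers, absent species -----------------
    n_absent = int(round(config.frac_species_absent * config.n_og))
    absent_ogs = sorted(rng_struct.choice(ogs, size=n_absent, replace=False))
    absent_species = {
        og: config.species[rng_struct.integers(0, len(config.species))] for og in absent_ogs
    }
    probs = np.asarray(config.copy_number_probs, dtype=float)
    present = probs.copy()
    present[0] = 0.0
    if present.sum() == 0:
        raise ConfigurationError("copy_number_probs gives zero mass to >= 1 copies")
    present /= present.sum()
    copy_number: dict[tuple[str, str], int] = {}
    for og in ogs:
        for sp in config.species:
            if absent_species.get(og) == sp:
                copy_number[(og, sp)] = 0
            else:
                copy_number[(og, sp)] = int(rng_struct.choice([0, 1, 2, 3], p=present))

    # --- pathways over fully shared orthogroups ----------------------------
    shared = [og for og in ogs if og not in absent_species]
    need = config.n_pathways * config.pathway_size
    if need > len(shared):
        raise ConfigurationError(
            f"n_pathways*pathway_size={need} exceeds the {len(shared)} fully shared orthogroups"
        )
    chosen = list(rng_struct.choice(shared, size=need, replace=False))
    pathways = {
        f"pw{k + 1:02d}": sorted(chosen[k * config.pathway_size : (k + 1) * config.pathway_size])
        for k in range(config.n_pathways)
    }
    for eff in config.planted_deo:
        if eff.pathway not in pathways:
            raise ConfigurationError(f"planted_deo references unknown pathway {eff.pathway!r}")

    # --- per-OG attributes --------------------------------------------------
    classes = [c for c, _ in config.profile_classes]
    weights = np.asarray([w for _, w in config.profile_classes])
    base_class = {og: classes[int(rng_struct.choice(len(classes), p=weights))] for og in ogs}
    n_div = int(round(config.frac_pattern_divergent * config.n_og))
    divergent = set(rng_struct.choice(ogs, size=n_div, replace=False)) if n_div else set()
    og_class = {
        (og, sp): (
            DIVERGENT_CLASS[base_class[og]]
            if og in divergent and sp == config.species[-1]
            else base_class[og]
        )
        for og in ogs
        for sp in config.species
    }
    lo, hi = config.baseline_logmean_range
    base_logmean = {og: rng_expr.uniform(lo, hi) for og in ogs}
    # per-copy offsets are drawn once per OG and shared across species, so
    # species with matching copy numbers have identical expected expression
    # (a true cross-species null unless an effect is planted)
    copy_offset = {og: rng_expr.uniform(-0.5, 0.5, size=3) for og in ogs}
    tf_flag = {og: bool(rng_struct.random() < config.tf_fraction) for og in ogs}

    effect_log2fc: dict[tuple[str, str, str], float] = {}
    for eff in config.planted_deo:
        for og in pathways[eff.pathway]:
            key = (og, eff.species, eff.segment)
            effect_log2fc[key] = effect_log2fc.get(key, 0.0) + eff.log2fc

    shapes = {c: profile_shape(c, n_seg) for c in classes + [DIVERGENT_CLASS[c] for c in classes]}

    # --- transcripts --------------------------------------------------------
    transcripts: list[TranscriptRecord] = []
    labels: list[tuple[str, str]] = []
    # per transcript: (id, species, og or None, weight multiplier, parent weight)
    tx_og: dict[str, str] = {}
    tx_base_weight: dict[str, float] = {}
    top_members: dict[tuple[str, str], list[str]] = {}

    n_signal_genes = sum(copy_number.values())
    pool_frac = 1.0 - config.frac_junk - config.frac_noncoding
    if pool_frac <= 0:
        raise ConfigurationError("frac_junk + frac_noncoding must be < 1")

    for sp in config.species:
        for og in ogs:
            members = []
            for copy in range(copy_number[(og, sp)]):
                gene = f"{sp}_{og}_g{copy + 1}"
                tid = f"{gene}_t1"
                seq = _random_coding_sequence(rng_seq, int(rng_seq.integers(40, 300)))
                transcripts.append(TranscriptRecord(tid, gene, sp, seq))
                labels.append((tid, "signal"))
                members.append(tid)
                w = base_logmean[og] + copy_offset[og][copy]
                tx_base_weight[tid] = float(2.0 ** w)
                tx_og[tid] = og
                # truncated extra isoforms, strictly less expressed than t1
                for iso in range(rng_struct.poisson(config.isoform_rate)):
                    itid = f"{gene}_t{iso + 2}"
                    frac = rng_seq.uniform(0.4, 0.8)
                    iseq = seq[: max(60, int(len(seq) * frac))]
                    transcripts.append(TranscriptRecord(itid, gene, sp, iseq))
                    labels.append((itid, "redundant-isoform"))
                    # count weight scales with length so the isoform's TPM is
                    # a strict fraction (< 0.4) of its gene's top isoform
                    rel_tpm = float(rng_expr.uniform(0.05, 0.4))
                    tx_base_weight[itid] = (
                        tx_base_weight[tid] * rel_tpm * len(iseq) / len(seq)
                    )
                    tx_og[itid] = og
            top_members[(og, sp)] = members

    # junk and non-coding pools, sized as fractions of the final transcript pool
    n_genes_sp = {sp: sum(copy_number[(og, sp)] for og in ogs) for sp in config.species}
    for sp in config.species:
        n_pool = int(round(n_genes_sp[sp] / max(pool_frac, 1e-9)))
        n_junk = int(round(config.frac_junk * n_pool))
        n_nc = int(round(config.frac_noncoding * n_pool))
        for j in range(n_junk):
            tid = f"{sp}_junk{j + 1:04d}_t1"
            seq = _random_coding_sequence(rng_seq, int(rng_seq.integers(40, 150)))
            transcripts.append(TranscriptRecord(tid, f"{sp}_junk{j + 1:04d}", sp, seq))
            labels.append((tid, "junk"))
        for j in range(n_nc):
            tid = f"{sp}_nc{j + 1:04d}_t1"
            seq = _random_noncoding_sequence(rng_seq, config.orf_min_len)
            transcripts.append(TranscriptRecord(tid, f"{sp}_nc{j + 1:04d}", sp, seq))
            labels.append((tid, "noncoding"))
            tx_base_weight[tid] = float(2.0 ** rng_expr.uniform(0.0, 4.0))

    junk_cpm = {
        r.transcript_id: float(_loguniform(rng_expr, 0.01, 0.3))
        for r in transcripts
        if r.transcript_id.split("_")[1].startswith("junk")
    }

    # --- samples and expected counts ---------------------------------------
    samples = [
        sample_name(sp, seg, r + 1)
        for sp in config.species
        for seg in config.segments
        for r in range(config.n_reps)
    ]
    sample_meta = pd.DataFrame(
        {
            "species": [s.split("_")[0] for s in samples],
            "segment": [s.split("_")[1] for s in samples],
            "replicate": [int(s.split("_")[2][1:]) for s in samples],
        },
        index=samples,
    )
    lib_lo, lib_hi = config.library_size_range
    lib_sizes = pd.Series(_loguniform(rng_expr, lib_lo, lib_hi, size=len(samples)), index=samples)

    tids = [r.transcript_id for r in transcripts]
    tid_index = {t: i for i, t in enumerate(tids)}
    mean = np.zeros((len(tids), len(samples)))
    d_lo, d_hi = config.dispersion_range
    if d_lo == d_hi:
        phi = np.full(len(tids), d_lo)
    elif d_lo > 0:
        phi = _loguniform(rng_counts, d_lo, d_hi, size=len(tids))
    else:
        phi = rng_counts.uniform(d_lo, d_hi, size=len(tids))

    seg_index = {seg: k for k, seg in enumerate(config.segments)}
    for sj, samp in enumerate(samples):
        sp = sample_meta.loc[samp, "species"]
        seg = sample_meta.loc[samp, "segment"]
        k = seg_index[seg]
        w_vec = np.zeros(len(tids))
        junk_rows = []
        for r in transcripts:
            if r.species != sp:
                continue
            i = tid_index[r.transcript_id]
            if r.transcript_id in junk_cpm:
                junk_rows.append(i)
                continue
            base = tx_base_weight.get(r.transcript_id)
            if base is None:
                continue
            og = tx_og.get(r.transcript_id)
            f = base
            if og is not None:
                f *= 2.0 ** shapes[og_class[(og, sp)]][k]
                f *= 2.0 ** effect_log2fc.get((og, sp, seg), 0.0)
            w_vec[i] = f
        signal_total = w_vec.sum()
        total_junk_cpm = sum(junk_cpm[tids[i]] for i in junk_rows)
        # calibrated so the expected cpm of each junk transcript equals its
        # drawn target (< 1 by construction), exercising the expression filter
        for i in junk_rows:
            w_vec[i] = junk_cpm[tids[i]] / 1e6 * signal_total / (1 - total_junk_cpm / 1e6)
        mean[:, sj] = lib_sizes.iloc[sj] * w_vec / w_vec.sum()

    counts = pd.DataFrame(
        simulate_counts(mean, phi, rng_counts), index=tids, columns=samples
    )

    lengths = np.array([r.length for r in transcripts], dtype=float)
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    col_tot = rate.sum(axis=0)
    col_tot[col_tot == 0] = 1.0
    tpm = pd.DataFrame(rate / col_tot * 1e6, index=tids, columns=samples)

    # --- orthogroup map and annotations ------------------------------------
    membership = {
        og: {sp: list(top_members[(og, sp)]) for sp in config.species} for og in ogs
    }
    og_map = OrthogroupMap(membership, list(config.species))

    go_dag_edges, leaf_terms = _go_dag()
    og_terms: dict[str, list[str]] = {og: [] for og in ogs}
    for k, (pw, members) in enumerate(sorted(pathways.items())):
        term = leaf_terms[k % len(leaf_terms)]
        for og in members:
            og_terms[og].append(term)
    for og in ogs:
        extra = rng_struct.integers(0, 3)
        for t in rng_struct.choice(leaf_terms, size=extra, replace=False):
            if t not in og_terms[og]:
                og_terms[og].append(t)

    ref_annotations: dict[str, dict[str, Annotation]] = {sp: {} for sp in config.species}
    go_rows = []
    for og in ogs:
        for sp in config.species:
            for tid in top_members[(og, sp)]:
                ann = Annotation(
                    source_species=sp,
                    description=f"{og} {base_class[og]}-profile protein",
                    go_ids=tuple(og_terms[og]),
                    is_tf=tf_flag[og],
                )
                ref_annotations[sp][tid] = ann
                for term in og_terms[og]:
                    go_rows.append((tid, term))
    go_annotations = pd.DataFrame(go_rows, columns=["transcript_id", "go_id"])

    # sink/source marker orthogroups: descending profiles mark the immature
    # sink zone (cell-cycle-like), ascending mark the mature source zone
    marker_rows = []
    for cls, role in (("descending", "sink"), ("ascending", "source")):
        cand = [og for og in shared if base_class[og] == cls and og not in divergent][:3]
        marker_rows += [(og, role) for og in cand]
    markers = pd.DataFrame(marker_rows, columns=["og", "role"])

    # --- truth tables -------------------------------------------------------
    og_effects = pd.DataFrame(
        [(og, sp, seg, fc) for (og, sp, seg), fc in sorted(effect_log2fc.items())],
        columns=["og", "species", "segment", "log2fc"],
    )
    pattern_class = pd.DataFrame(
        [(og, sp, og_class[(og, sp)]) for og in ogs for sp in config.species],
        columns=["og", "species", "profile_class"],
    )
    pathway_membership = pd.DataFrame(
        [(pw, og) for pw, members in sorted(pathways.items()) for og in members],
        columns=["pathway", "og"],
    )
    transcript_labels = pd.DataFrame(labels, columns=["transcript_id", "label"])
    tf_flags = pd.DataFrame(
        [(og, tf_flag[og]) for og in ogs], columns=["og", "is_tf"]
    )
    truth = SyntheticTruth(
        og_effects, pattern_class, pathway_membership, transcript_labels, tf_flags
    )

    return SimulatedDataset(
        config=config,
        transcripts=transcripts,
        counts=counts,
        tpm=tpm,
        og_map=og_map,
        ref_annotations=ref_annotations,
        go_annotations=go_annotations,
        go_dag_edges=go_dag_edges,
        pathways=pathways,
        markers=markers,
        truth=truth,
        lib_sizes=lib_sizes,
        sample_meta=sample_meta,
    )


def _go_dag() -> tuple[pd.DataFrame, list[str]]:
    """A small fixed biological-process-style DAG: root -> 4 branches -> 12 leaves."""
    edges = []
    leaves = []
    for b in range(4):
        branch = f"GO:00091{b:02d}"
        edges.append((branch, GO_ROOT))
        for l in range(3):
            leaf = f"GO:00101{b}{l}"
            edges.append((leaf, branch))
            leaves.append(leaf)
    return pd.DataFrame(edges, columns=["child", "parent"]), leaves
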