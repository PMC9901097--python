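"""Readers and writers for the plain-text interchange formats.

All tables are TSV with header rows; expression matrices have feature rows
and sample columns named ``species_segment_rep``.  Sequences travel as
FASTA.  Simulation and run configurations are YAML mappings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import FormatError
from .curate import TranscriptRecord
from .simulate import PlantedEffect, SimConfig


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate feature IDs in {path}")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence), id=r.transcript_id, description=f"gene={r.gene_id} species={r.species}"
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts; gene and species are recovered from the description
    (``gene=... species=...``), falling back to the ID's leading fields."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        parts = rec.id.split("_")
        gene = fields.get("gene", "_".join(parts[:-1]) if len(parts) > 1 else rec.id)
        species = fields.get("species", parts[0])
        out.append(TranscriptRecord(rec.id, gene, species, str(rec.seq).upper()))
    return out


def read_pairs(path, columns: tuple[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != list(columns):
        raise FormatError(f"{path}: expected columns {columns}, got {tuple(df.columns)}")
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pathways(path) -> dict[str, list[str]]:
    df = read_pairs(path, ("pathway", "og"))
    out: dict[str, list[str]] = {}
    for pw, og in df.itertuples(index=False):
        out.setdefault(pw, []).append(og)
    return {pw: sorted(dict.fromkeys(v)) for pw, v in sorted(out.items())}


def sim_config_to_yaml(config: SimConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["planted_deo"] = [list(e) for e in config.planted_deo]
    # order matters for reproducibility of the class draw: keep it
    d["profile_classes"] = [[c, w] for c, w in config.profile_classes]
    for key in ("species", "segments", "copy_number_probs", "baseline_logmean_range",
                "dispersion_range", "library_size_range"):
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def sim_config_from_yaml(path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["planted_deo"] = tuple(
        PlantedEffect(str(p), str(sp), str(seg), float(fc)) for p, sp, seg, fc in d.get("planted_deo", [])
    )
    d["profile_classes"] = tuple((str(c), float(w)) for c, w in d["profile_classes"])
    for key in ("species", "segments", "copy_number_probs", "baseline_logmean_range",
                "dispersion_range", "library_size_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
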