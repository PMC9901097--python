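"""Orthogroup-level expression aggregation and annotation transfer.

Orthogroups (OG) are the unit of cross-species comparison: sets of genes
across species descended from a single ancestral gene.  Multicopy OG are
quantified as the sum of their member transcripts' raw counts, which keeps
negative-binomial count semantics for the downstream exact test.
Annotations are transferred from a prioritized list of reference species:
the highest-priority species with at least one member in the OG supplies
the annotation (no merging across references).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import pandas as pd

from ._util import FormatError, InputError

logger = logging.getLogger(__name__)


class Annotation(NamedTuple):
    source_species: str
    description: str
    go_ids: tuple[str, ...]
    is_tf: bool


@dataclass
class OrthogroupMap:
    """og_id -> species -> member transcript IDs, plus transferred annotation."""

    membership: dict[str, dict[str, list[str]]]
    species: list[str]
    annotation: dict[str, Annotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og in self.membership:
            for sp in self.species:
                members = self.membership[og].setdefault(sp, [])
                for t in members:
                    if t in seen and seen[t] != og:
                        raise FormatError(
                            f"transcript {t!r} assigned to both {seen[t]} and {og}"
                        )
                    seen[t] = og

    @property
    def og_ids(self) -> list[str]:
        return sorted(self.membership)

    def copy_number(self, og: str, species: str) -> int:
        return len(self.membership[og][species])

    def members(self, og: str) -> list[str]:
        return [t for sp in self.species for t in self.membership[og][sp]]

    def restrict_members(self, kept: set[str]) -> "OrthogroupMap":
        """A new map keeping only member transcripts in ``kept`` (OG rows stay)."""
        membership = {
            og: {sp: [t for t in self.membership[og][sp] if t in kept] for sp in self.species}
            for og in self.membership
        }
        return OrthogroupMap(membership, list(self.species), dict(self.annotation))


def parse_orthogroup_table(path) -> OrthogroupMap:
    """Read an orthogroup table: og_id column + one comma-separated member
    column per species, header row naming the species."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("orthogroup table is empty")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError("orthogroup table needs an og_id column plus >= 1 species column")
    species = header[1:]
    membership: dict[str, dict[str, list[str]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"orthogroup table line {lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        og = fields[0]
        if og in membership:
            raise FormatError(f"duplicate orthogroup row {og!r}")
        membership[og] = {}
        for sp, cell in zip(species, fields[1:]):
            members = [m.strip() for m in cell.split(",") if m.strip()]
            membership[og][sp] = sorted(dict.fromkeys(members))  # dedupe
    return OrthogroupMap(membership, species)


def write_orthogroup_table(og_map: OrthogroupMap, path) -> None:
    rows = []
    for og in og_map.og_ids:
        rows.append(
            [og] + [",".join(og_map.membership[og][sp]) for sp in og_map.species]
        )
    pd.DataFrame(rows, columns=["og_id"] + list(og_map.species)).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class OGExpression:
    """OG x sample matrix with the member transcripts each row summed over."""

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    provenance: dict[str, list[str]]


def aggregate_expression(
    counts: pd.DataFrame,
    og_map: OrthogroupMap,
    sample_meta: pd.DataFrame,
    strict: bool = True,
) -> OGExpression:
    """Sum member-transcript rows per orthogroup.

    Single-copy OG rows equal the member row unchanged; per-sample totals
    over the OG matrix equal the totals of the member transcripts exactly.
    In permissive mode missing members are logged and treated as zero.
    """
    index = counts.index
    have = set(index)
    rows = {}
    provenance = {}
    for og in og_map.og_ids:
        members = og_map.members(og)
        missing = [t for t in members if t not in have]
        if missing:
            if strict:
                raise InputError(
                    f"orthogroup {og} member(s) missing from counts: {missing[:5]}"
                )
            logger.warning("OG %s: %d member(s) missing, treated as zero", og, len(missing))
        present = [t for t in members if t in have]
        rows[og] = counts.loc[present].sum(axis=0) if present else pd.Series(0.0, index=counts.columns)
        provenance[og] = present
    matrix = pd.DataFrame(rows).T
    matrix.index.name = "og_id"
    return OGExpression(matrix, sample_meta, provenance)


def transfer_annotation(
    og_map: OrthogroupMap,
    ref_annotations: Mapping[str, Mapping[str, Annotation]],
    priority: Sequence[str],
) -> OrthogroupMap:
    """Annotate each OG from the highest-priority reference with a member.

    Within the chosen reference species, the member with the
    lexicographically smallest transcript ID supplies the annotation.
    OG with no annotated reference member stay unannotated.
    """
    if not priority:
        raise InputError("priority list must be non-empty")
    annotation: dict[str, Annotation] = {}
    for og in og_map.og_ids:
        for sp in priority:
            members = sorted(
                t
                for t in og_map.membership[og].get(sp, [])
                if t in ref_annotations.get(sp, {})
            )
            if members:
                ann = ref_annotations[sp][members[0]]
                annotation[og] = Annotation(sp, ann.description, tuple(ann.go_ids), ann.is_tf)
                break
    out = OrthogroupMap(
        {og: {sp: list(v) for sp, v in m.items()} for og, m in og_map.membership.items()},
        list(og_map.species),
    )
    out.annotation = annotation
    return out


def shared_orthogroups(
    og_map: OrthogroupMap,
    species: Sequence[str],
    expressed: set[str] | None = None,
) -> list[str]:
    """Sorted OG with >= 1 member in every listed species.

    If ``expressed`` is given, member lists are first intersected with it
    (the shared set is defined after expression filtering).
    """
    unknown = [sp for sp in species if sp not in og_map.species]
    if unknown:
        raise InputError(f"unknown species {unknown} not in orthogroup map")
    out = []
    for og in og_map.og_ids:
        ok = True
        for sp in species:
            members = og_map.membership[og][sp]
            if expressed is not None:
                members = [t for t in members if t in expressed]
            if not members:
                ok = False
                break
        if ok:
            out.append(og)
    return out
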