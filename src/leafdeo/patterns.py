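"""Segment-profile analytics: z-scores, conservation, pathway DEO tables,
heatmap matrices, sink/source classification.

Expression profiles are mean TMM-normalized cpm per leaf segment (averaged
over replicates).  Cross-species pattern conservation is called on
z-score-normalized profiles: a species pair is conserved when the Pearson
correlation of their z-profiles reaches ``r_threshold`` (default 0.8);
constant profiles are never conserved.  The z-score step makes the calls
invariant to per-species affine rescaling of expression level, so they
compare the *shape* of the developmental gradient, not its magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import InputError, percentage1
from .diffexp import cpm, tmm_factors

logger = logging.getLogger(__name__)


def zscore_profile(segment_means: Sequence[float]) -> np.ndarray:
    """(x - mean) / sd with sample sd (n-1); constant input -> zero vector."""
    x = np.asarray(segment_means, dtype=float)
    if x.size < 2:
        raise InputError("zscore_profile needs at least 2 segments")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(x.size)
    return (x - x.mean()) / sd


def mean_cpm_profiles(
    og_counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    segments: Sequence[str],
    lib_sizes: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Per species: OG x segment mean TMM-normalized cpm.

    TMM factors are computed within each species across all of its samples.
    """
    out: dict[str, pd.DataFrame] = {}
    for sp in sorted(sample_meta["species"].unique()):
        cols = list(sample_meta.index[sample_meta["species"] == sp])
        sub = og_counts[cols]
        libs = None if lib_sizes is None else pd.Series(lib_sizes)[cols]
        norm = tmm_factors(sub, lib_sizes=libs)
        mat = cpm(sub, norm.effective_lib_sizes)
        prof = pd.DataFrame(index=og_counts.index, columns=list(segments), dtype=float)
        for seg in segments:
            seg_cols = [c for c in cols if sample_meta.loc[c, "segment"] == seg]
            prof[seg] = mat[seg_cols].mean(axis=1)
        out[sp] = prof
    return out


@dataclass
class ConservationCall:
    """Pairwise and overall conservation of one OG's expression pattern."""

    pair_conserved: dict[tuple[str, str], bool]
    pair_r: dict[tuple[str, str], float]
    conserved: bool


def pattern_conservation(
    z_profiles: Mapping[str, Sequence[float]],
    r_threshold: float = 0.8,
    focal_species: str | None = None,
) -> ConservationCall:
    """Call pattern conservation across species from z-profiles.

    A pair is conserved iff Pearson r >= ``r_threshold``; a constant
    profile is conserved with nothing.  Overall the OG is conserved iff
    every pair involving ``focal_species`` is conserved (all pairs when no
    focal species is designated).
    """
    species = sorted(z_profiles)
    lengths = {len(np.asarray(z_profiles[sp], dtype=float)) for sp in species}
    if len(lengths) != 1:
        raise InputError("z-profiles must cover the same ordered segments")
    if focal_species is not None and focal_species not in species:
        raise InputError(f"focal species {focal_species!r} has no profile")
    pair_conserved: dict[tuple[str, str], bool] = {}
    pair_r: dict[tuple[str, str], float] = {}
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            za = np.asarray(z_profiles[sa], dtype=float)
            zb = np.asarray(z_profiles[sb], dtype=float)
            if za.std() == 0 or zb.std() == 0:
                r = np.nan
                ok = False
            else:
                r = float(np.corrcoef(za, zb)[0, 1])
                ok = r >= r_threshold
            pair_conserved[(sa, sb)] = ok
            pair_r[(sa, sb)] = r
    relevant = [
        ok
        for (sa, sb), ok in pair_conserved.items()
        if focal_species is None or focal_species in (sa, sb)
    ]
    return ConservationCall(pair_conserved, pair_r, bool(relevant) and all(relevant))


def pathway_deo_percentages(
    deo_results: pd.DataFrame,
    pathway_lists: Mapping[str, Sequence[str]],
    species_pair: tuple[str, str],
    segment: str,
) -> pd.DataFrame:
    """Per pathway: DEO counts and percentages by direction.

    ``deo_results`` is a `two_group_test` frame where group A / B are the
    first / second species of the pair.  Pathway members absent from the
    tested set are excluded with a warning.  Percentages are
    100 * count / n_pathway_og rounded half-to-even to one decimal.
    """
    tested = set(deo_results.index)
    rows = []
    for pathway in sorted(pathway_lists):
        members = list(dict.fromkeys(pathway_lists[pathway]))
        missing = [og for og in members if og not in tested]
        if missing:
            logger.warning(
                "pathway %s: %d orthogroup(s) not in the tested set, excluded",
                pathway,
                len(missing),
            )
        members = [og for og in members if og in tested]
        sub = deo_results.loc[members]
        n_up_a = int((sub["direction"] == "up_in_A").sum())
        n_up_b = int((sub["direction"] == "up_in_B").sum())
        rows.append(
            {
                "pathway": pathway,
                "species_pair": f"{species_pair[0]}-{species_pair[1]}",
                "segment": segment,
                "n_pathway_og": len(members),
                "n_up_in_A": n_up_a,
                "n_up_in_B": n_up_b,
                "pct_up_in_A": percentage1(n_up_a, len(members)),
                "pct_up_in_B": percentage1(n_up_b, len(members)),
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(
    profiles: Mapping[str, pd.DataFrame], og_list: Sequence[str]
) -> pd.DataFrame:
    """OG x (species, segment) relative expression, min-max scaled per row.

    ``profiles`` maps species -> OG x segment mean expression.  Each OG row
    is scaled to [0, 1] across all species and segments jointly; constant
    rows map to 0.5 everywhere.
    """
    if len(og_list) == 0:
        raise InputError("heatmap_matrix needs a non-empty og_list")
    species = sorted(profiles)
    blocks = []
    for sp in species:
        prof = profiles[sp]
        missing = [og for og in og_list if og not in prof.index]
        if missing:
            raise InputError(f"orthogroups missing from {sp} profiles: {missing[:5]}")
        block = prof.loc[list(og_list)].copy()
        block.columns = pd.MultiIndex.from_product([[sp], block.columns])
        blocks.append(block)
    mat = pd.concat(blocks, axis=1)
    lo = mat.min(axis=1)
    hi = mat.max(axis=1)
    span = hi - lo
    scaled = mat.sub(lo, axis=0).div(span.where(span > 0, 1.0), axis=0)
    scaled[span == 0] = 0.5
    return scaled


def classify_sink_source(
    marker_profiles: Mapping[str, Sequence[float]],
    marker_roles: Mapping[str, str],
    segments: Sequence[str],
) -> dict[str, str]:
    """Label each segment sink or source from marker expression profiles.

    Sink markers (cell-cycle/sucrose-synthase-like genes) peak in the
    immature leaf base; source markers (sucrose transporters, nitrate
    reductase) peak in the mature blade.  Each marker profile is z-scored;
    a segment is labeled ``sink`` iff the mean z of sink markers exceeds
    the mean z of source markers there.
    """
    roles = {m: r for m, r in marker_roles.items() if m in marker_profiles}
    for role in ("sink", "source"):
        if role not in roles.values():
            raise InputError(f"need at least one {role!r} marker")
    z = {m: zscore_profile(marker_profiles[m]) for m in roles}
    sink_z = np.mean([z[m] for m, r in roles.items() if r == "sink"], axis=0)
    source_z = np.mean([z[m] for m, r in roles.items() if r == "source"], axis=0)
    return {
        seg: ("sink" if sink_z[k] > source_z[k] else "source")
        for k, seg in enumerate(segments)
    }
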