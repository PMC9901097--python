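"""Curation of a raw de novo transcript set into a high-confidence coding set.

The curation mirrors the standard post-assembly workflow for short-read de
novo transcriptomes: (1) keep the most expressed isoform per gene, (2)
collapse redundant sequences at 95% identity, (3) keep transcripts whose
single best open reading frame is at least 100 nt, (4) keep transcripts
expressed at >= 1 cpm in at least 3 libraries.  Each stage returns a subset
of its input and is idempotent on its own output.

Coordinates are 0-based, half-open on the reported strand; ORF spans
include the stop codon, so a span length is a multiple of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigurationError, InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class Orf:
    """An open reading frame on one strand of a transcript.

    ``start``/``end`` are 0-based half-open on the given strand (i.e. on the
    reverse-complemented sequence when ``strand == '-'``); the span includes
    the stop codon.
    """

    start: int
    end: int
    strand: str
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptRecord:
    """One assembled transcript with its isoform grouping and coding call."""

    transcript_id: str
    gene_id: str
    species: str
    sequence: str
    orf: Orf | None = None
    coding: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    mean_length: float
    n50: int


@dataclass
class CurationReport:
    """Per-stage survivor counts and the final kept transcript IDs."""

    n_input: int = 0
    n_after_isoform: int = 0
    n_after_redundancy: int = 0
    n_after_orf: int = 0
    n_after_expression: int = 0
    kept: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "input",
                    "top_isoform",
                    "redundancy_collapse",
                    "orf_filter",
                    "expression_filter",
                ],
                "n_transcripts": [
                    self.n_input,
                    self.n_after_isoform,
                    self.n_after_redundancy,
                    self.n_after_orf,
                    self.n_after_expression,
                ],
            }
        )


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def find_best_orf(
    sequence: str, min_len_nt: int = 100, require_start: bool = True
) -> Orf | None:
    """Scan all six frames for the longest complete ORF.

    An ORF runs from a start codon (ATG) to the first in-frame stop; the
    stop codon is included in the span.  Codons containing N are treated as
    sense codons (neither start nor stop).  Returns the longest ORF whose
    span is at least ``min_len_nt``, or ``None``.  Ties are broken by
    forward strand first, then lower frame, then lower start.
    """
    seq = sequence.upper()
    if not _VALID.issuperset(seq):
        bad = sorted(set(seq) - _VALID)
        raise InputError(f"non-nucleotide characters in sequence: {bad}")
    if not require_start:
        raise NotImplementedError("partial (start-less) ORFs are not supported")

    best: Orf | None = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        n = len(s)
        for frame in range(3):
            orf_start = -1
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if orf_start >= 0:
                        cand = Orf(orf_start, pos + 3, strand, frame)
                        if _better(cand, best):
                            best = cand
                        orf_start = -1
                elif orf_start < 0 and codon == START_CODON:
                    orf_start = pos
            # an ORF without an in-frame stop is incomplete: dropped
    if best is not None and best.length >= min_len_nt:
        return best
    return None


def _better(cand: Orf, best: Orf | None) -> bool:
    if best is None:
        return True
    key = lambda o: (-o.length, o.strand != "+", o.frame, o.start)  # noqa: E731
    return key(cand) < key(best)


def select_top_isoform(
    expression: Mapping[str, float], grouping: Mapping[str, str]
) -> list[str]:
    """Keep, per gene, the isoform with maximal mean TPM.

    Ties are broken by taking the lexicographically smallest transcript ID.
    Every transcript in ``expression`` must appear in ``grouping``.
    """
    best: dict[str, tuple[float, str]] = {}
    for tid in expression:
        if tid not in grouping:
            raise InputError(f"transcript {tid!r} missing from the isoform grouping")
    for tid, tpm in expression.items():
        gene = grouping[tid]
        cur = best.get(gene)
        # higher TPM wins; on an exact tie the smaller transcript_id wins
        if cur is None or (-tpm, tid) < (-cur[0], cur[1]):
            best[gene] = (tpm, tid)
    return sorted(tid for _, tid in best.values())


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def collapse_redundant(
    sequences: Mapping[str, str], identity_threshold: float = 0.95, k: int = 11
) -> list[str]:
    """Greedy longest-first redundancy collapse at a k-mer containment identity.

    A candidate is absorbed by an already-retained representative when it is
    an exact duplicate, an exact substring, or when the fraction of its
    k-mers found in the representative reaches ``identity_threshold``.
    Returns the sorted representative IDs.  Empty input yields empty output.
    """
    if not 0 < identity_threshold <= 1:
        raise ConfigurationError("identity_threshold must be in (0, 1]")
    order = sorted(sequences, key=lambda t: (-len(sequences[t]), t))
    reps: list[str] = []
    postings: dict[str, list[int]] = {}  # kmer -> indices into reps
    rep_seqs: list[str] = []
    for tid in order:
        seq = sequences[tid].upper()
        cand_kmers = _kmers(seq, k)
        absorbed = False
        if cand_kmers:
            # exact duplicates and substrings have containment identity 1.0,
            # so the k-mer rule subsumes them for sequences of length >= k
            hits: dict[int, int] = {}
            for km in cand_kmers:
                for ri in postings.get(km, ()):
                    hits[ri] = hits.get(ri, 0) + 1
            if hits:
                best_shared = max(hits.values())
                absorbed = best_shared / len(cand_kmers) >= identity_threshold
        else:  # shorter than k: fall back to direct substring scan
            absorbed = any(seq in r for r in rep_seqs)
        if not absorbed:
            ri = len(reps)
            reps.append(tid)
            rep_seqs.append(seq)
            for km in cand_kmers:
                postings.setdefault(km, []).append(ri)
    return sorted(reps)


def cpm_raw(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (un-normalized) library sizes."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = pd.Series(lib_sizes, index=counts.columns, dtype=float)
    if (lib_sizes <= 0).any():
        raise InputError("library sizes must be positive")
    return counts.div(lib_sizes, axis=1) * 1e6


def filter_by_expression(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_libraries: int = 3,
    lib_sizes: pd.Series | None = None,
) -> list[str]:
    """Keep features with cpm >= ``min_cpm`` in at least ``min_libraries`` samples.

    The cpm is computed on raw library sizes (this filter precedes TMM
    normalization in the workflow).
    """
    if min_libraries > counts.shape[1]:
        raise ConfigurationError(
            f"min_libraries={min_libraries} exceeds the {counts.shape[1]} available samples"
        )
    cpm = cpm_raw(counts, lib_sizes)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    return list(counts.index[keep])


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N50 and mean length of an assembly from its transcript lengths.

    N50 is the largest length L such that transcripts of length >= L hold at
    least half of the total assembled bases (descending sort + accumulate).
    """
    if len(lengths) == 0:
        raise InputError("assembly_stats requires a non-empty length list")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise InputError("transcript lengths must be positive")
    srt = np.sort(arr)[::-1]
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(srt), half))
    return AssemblyStats(len(arr), float(arr.mean()), int(srt[idx]))


def curate_transcripts(
    records: Iterable[TranscriptRecord],
    mean_tpm: Mapping[str, float],
    counts: pd.DataFrame,
    identity_threshold: float = 0.95,
    orf_min_len: int = 100,
    min_cpm: float = 1.0,
    min_libraries: int = 3,
) -> CurationReport:
    """Run the full curation for one species' transcriptome.

    ``counts`` must contain only that species' libraries; raw library sizes
    are taken as the column sums over the *input* transcript set so that the
    cpm filter sees the sequencing depth, not the post-filter depth.
    """
    recs = {r.transcript_id: r for r in records}
    report = CurationReport(n_input=len(recs))

    kept = select_top_isoform(
        {t: mean_tpm[t] for t in recs}, {t: recs[t].gene_id for t in recs}
    )
    report.n_after_isoform = len(kept)

    kept = collapse_redundant({t: recs[t].sequence for t in kept}, identity_threshold)
    report.n_after_redundancy = len(kept)

    coding = []
    for t in kept:
        orf = find_best_orf(recs[t].sequence, min_len_nt=orf_min_len)
        if orf is not None:
            recs[t].orf = orf
            recs[t].coding = True
            coding.append(t)
    report.n_after_orf = len(coding)

    lib_sizes = counts.loc[list(recs)].sum(axis=0)
    expressed = set(
        filter_by_expression(
            counts.loc[coding], min_cpm=min_cpm, min_libraries=min_libraries,
            lib_sizes=lib_sizes,
        )
    )
    report.kept = [t for t in coding if t in expressed]
    report.n_after_expression = len(report.kept)
    return report
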