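"""Candidate-SNP calling from EST contig alignments.

A consensus column yields a candidate SNP when all of the following hold
(the "stringent filters" of in-silico EST SNP mining):

1. informative depth at the column (reads showing A/C/G/T) is at least
   ``min_depth`` (default 7);
2. the ``flank_len`` (default 4) columns on each side of the site are
   exactly conserved: every read that spans a side without N/gap matches
   the consensus there, and at least one such read exists per side;
3. the minor base is seen in at least ``min_minor`` reads (default 3);
4. columns where the consensus itself is not a plain base are skipped;
5. reads contributing N or ``-`` at a column are excluded from its counts
   (and from the flank-conservation check where the N/gap falls in the
   flank window).

Sites with three or more observed bases are rejected (candidates are
biallelic); ties for the major base break alphabetically.  Sites whose
flank window runs off the contig edge are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import ContigAlignment
from .popgen_stats import FreqStats, freq_stats

__all__ = [
    "SnpCandidate",
    "RejectedSite",
    "call_candidate_snps",
    "sequence_stats",
    "contig_snp_distribution",
    "SNPS_PER_CONTIG_BINS",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_BASES = "ACGT"

SNPS_PER_CONTIG_BINS = tuple(str(i) for i in range(1, 11)) + (">10",)


@dataclass(frozen=True)
class SnpCandidate:
    """A biallelic candidate site on a contig, with depth-based stats."""

    contig_id: str
    position: int  # 0-based consensus coordinate
    major_base: str
    minor_base: str
    base_counts: dict[str, int]
    depth: int
    left_flank: str
    right_flank: str
    stats: FreqStats

    @property
    def snp_id(self) -> str:
        return f"snp_{self.contig_id}_{self.position}"


@dataclass(frozen=True)
class RejectedSite:
    """An audited polymorphic column that failed a filter."""

    contig_id: str
    position: int
    reason: str


def sequence_stats(counts: dict[str, int]) -> FreqStats:
    """Direct-count frequency statistics from per-base read depths.

    Exactly two bases must carry positive counts; ``p`` is the major
    sequence frequency (alphabetical tie-break).
    """
    positive = {b: int(n) for b, n in counts.items() if n > 0}
    if len(positive) != 2:
        raise ValueError(
            f"need exactly two observed bases, got {sorted(positive)}"
        )
    (b1, n1), (b2, n2) = sorted(positive.items())
    major = n1 if n1 >= n2 else n2
    return freq_stats(major / (n1 + n2))


def _encode(aln: ContigAlignment) -> tuple[np.ndarray, np.ndarray]:
    cons = np.frombuffer(aln.consensus.encode(), dtype=np.uint8)
    lut = np.full(128, 255, dtype=np.uint8)
    for ch, code in _CODE.items():
        lut[ord(ch)] = code
    cons_codes = lut[cons]
    if aln.reads:
        reads = np.vstack(
            [lut[np.frombuffer(seq.encode(), dtype=np.uint8)] for _, seq in aln.reads]
        )
    else:
        reads = np.empty((0, len(aln.consensus)), dtype=np.uint8)
    return cons_codes, reads


def call_candidate_snps(
    aln: ContigAlignment,
    min_depth: int = 7,
    min_minor: int = 3,
    flank_len: int = 4,
    audit: bool = False,
) -> list[SnpCandidate] | tuple[list[SnpCandidate], list[RejectedSite]]:
    """Apply the stringent discovery filters to one contig alignment.

    Returns the candidate list, or ``(candidates, rejected)`` with per-site
    rejection reasons when ``audit`` is set (only columns showing at least
    two distinct bases are audited).
    """
    aln.validate()
    cons, reads = _encode(aln)
    n_reads, length = reads.shape
    candidates: list[SnpCandidate] = []
    rejected: list[RejectedSite] = []

    if n_reads == 0 or length == 0:
        return (candidates, rejected) if audit else candidates

    informative = reads < 4  # A/C/G/T only (filter 5)
    counts = np.stack([(reads == b).sum(axis=0) for b in range(4)])  # (4, L)
    depth = counts.sum(axis=0)
    n_distinct = (counts > 0).sum(axis=0)

    # flank conservation bookkeeping (filter 2): per read x column,
    # "blocked" = N/gap (excluded from the check), "mismatch" = informative
    # base differing from consensus.  Prefix sums give window counts.
    blocked = ~informative
    mismatch = informative & (reads != cons[None, :])
    blk = np.zeros((n_reads, length + 1), dtype=np.int32)
    mis = np.zeros((n_reads, length + 1), dtype=np.int32)
    np.cumsum(blocked, axis=1, out=blk[:, 1:])
    np.cumsum(mismatch, axis=1, out=mis[:, 1:])

    consensus_ok = cons < 4  # filter 4: skip padded/ambiguous consensus columns
    polymorphic = np.flatnonzero((n_distinct >= 2) & consensus_ok)

    for j in polymorphic:
        col = counts[:, j]
        if n_distinct[j] > 2:
            if audit:
                rejected.append(RejectedSite(aln.contig_id, int(j), "multiallelic"))
            continue
        if depth[j] < min_depth:
            if audit:
                rejected.append(RejectedSite(aln.contig_id, int(j), "low_depth"))
            continue
        order = np.argsort(col, kind="stable")
        minor_b, major_b = order[-2], order[-1]
        if col[major_b] == col[minor_b] and major_b > minor_b:
            # tie for major base breaks alphabetically
            major_b, minor_b = minor_b, major_b
        if col[minor_b] < min_minor:
            if audit:
                rejected.append(RejectedSite(aln.contig_id, int(j), "low_minor"))
            continue
        if j - flank_len < 0 or j + flank_len >= length:
            if audit:
                rejected.append(RejectedSite(aln.contig_id, int(j), "edge"))
            continue
        ok = True
        for lo, hi in ((j - flank_len, j), (j + 1, j + 1 + flank_len)):
            eligible = (blk[:, hi] - blk[:, lo]) == 0
            clean = eligible & ((mis[:, hi] - mis[:, lo]) == 0)
            if not eligible.any() or not (eligible == clean).all():
                ok = False
                break
        if not ok:
            if audit:
                rejected.append(
                    RejectedSite(aln.contig_id, int(j), "flank_not_conserved")
                )
            continue
        base_counts = {
            _BASES[b]: int(col[b]) for b in (major_b, minor_b)
        }
        candidates.append(
            SnpCandidate(
                contig_id=aln.contig_id,
                position=int(j),
                major_base=_BASES[major_b],
                minor_base=_BASES[minor_b],
                base_counts=base_counts,
                depth=int(depth[j]),
                left_flank=aln.consensus[j - flank_len : j],
                right_flank=aln.consensus[j + 1 : j + 1 + flank_len],
                stats=sequence_stats(base_counts),
            )
        )
    return (candidates, rejected) if audit else candidates


def contig_snp_distribution(candidates: Iterable[SnpCandidate]) -> pd.Series:
    """Count contigs by their number of candidate SNPs (bins 1..10, >10)."""
    per_contig: dict[str, int] = {}
    for c in candidates:
        per_contig[c.contig_id] = per_contig.get(c.contig_id, 0) + 1
    table = pd.Series(0, index=list(SNPS_PER_CONTIG_BINS), dtype=int)
    for n in per_contig.values():
        table[str(n) if n <= 10 else ">10"] += 1
    table.index.name = "snps_per_contig"
    table.name = "n_contigs"
    return table
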