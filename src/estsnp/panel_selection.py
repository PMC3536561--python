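"""Validation-panel filters for candidate SNPs.

Assay design for multiplexed genotyping platforms constrains which
candidate SNPs are worth validating.  Five filters are applied, each a
pure predicate evaluated on the *pre-filter* candidate set (so the
outcome does not depend on application order):

* ``spacing``            — a candidate with another candidate closer than
  ``min_gap`` nucleotides (default 60) on the same contig is removed;
  both members of a close pair go (optionally keep the better-scored one);
* ``flank_length``       — at least ``min_flank`` (default 100) nt of
  contig sequence required on each side of the site;
* ``genomic_contiguity`` — the full flanking sequence (both flanks plus
  the site, with either allele) must occur contiguously in a supplied
  genomic reference on either strand; guards against probes spanning
  exon-intron junctions.  Skipped with a warning when no reference is
  given;
* ``design_score``       — a pluggable flank-sequence scorer in [0,1]
  must return at least ``min_score`` (default 0.6).  The built-in proxy
  starts at 1 and subtracts 0.3 for flank GC outside [0.30, 0.70], 0.3
  for a homopolymer run of 6+ nt within 60 nt of the site, 0.5 for any N
  in the flanks, and 0.2 when another candidate lies within 60 nt
  (computed on the pre-filter set), floored at 0;
* ``similarity``         — candidates whose flanking windows share an
  exact 31-mer with a candidate on a *different* contig are removed (a
  proxy for cross-candidate similarity and repetitive sequence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .snp_discovery import SnpCandidate

__all__ = [
    "PanelFilterReport",
    "PanelConfig",
    "spacing_filter",
    "flank_length_filter",
    "genomic_contiguity_filter",
    "design_score_filter",
    "similarity_filter",
    "proxy_design_score",
    "candidate_flank_window",
    "select_panel",
]

FILTER_ORDER = (
    "spacing",
    "flank_length",
    "genomic_contiguity",
    "design_score",
    "similarity",
)


@dataclass
class PanelConfig:
    min_gap: int = 60
    min_flank: int = 100
    min_score: float = 0.6
    kmer: int = 31
    keep_better_of_close_pair: bool = False
    max_panel_size: Optional[int] = None


@dataclass
class PanelFilterReport:
    """Per-candidate outcome: kept iff no filter failed."""

    candidates: list[SnpCandidate]
    failed_filters: list[list[str]]
    warnings: list[str] = field(default_factory=list)

    @property
    def kept(self) -> list[SnpCandidate]:
        return [c for c, f in zip(self.candidates, self.failed_filters) if not f]

    def kept_mask(self) -> list[bool]:
        return [not f for f in self.failed_filters]


def _key(c: SnpCandidate) -> tuple[str, int]:
    return (c.contig_id, c.position)


def spacing_filter(
    candidates: Sequence[SnpCandidate],
    min_gap: int = 60,
    keep_better: bool = False,
    scorer: Optional[Callable[[SnpCandidate], float]] = None,
) -> set[tuple[str, int]]:
    """Keys of candidates with no neighbour closer than ``min_gap`` nt.

    By default both members of a close pair are removed; with
    ``keep_better`` the higher-scoring member of each close pair survives
    (ties keep the leftmost).
    """
    by_contig: dict[str, list[SnpCandidate]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c)
    kept: set[tuple[str, int]] = set()
    for contig, group in by_contig.items():
        group.sort(key=lambda c: c.position)
        close = [False] * len(group)
        for i in range(len(group) - 1):
            if group[i + 1].position - group[i].position < min_gap:
                close[i] = close[i + 1] = True
        if keep_better and scorer is not None:
            for i, c in enumerate(group):
                if not close[i]:
                    kept.add(_key(c))
                    continue
                neighbours = [
                    o
                    for o in group
                    if o is not c and abs(o.position - c.position) < min_gap
                ]
                if all(
                    scorer(c) > scorer(o)
                    or (scorer(c) == scorer(o) and c.position < o.position)
                    for o in neighbours
                ):
                    kept.add(_key(c))
        else:
            kept.update(_key(c) for i, c in enumerate(group) if not close[i])
    return kept


def flank_length_filter(
    candidates: Sequence[SnpCandidate],
    contig_lengths: Mapping[str, int],
    min_flank: int = 100,
) -> set[tuple[str, int]]:
    """Keys of candidates with >= ``min_flank`` nt of contig on each side."""
    kept = set()
    for c in candidates:
        length = contig_lengths[c.contig_id]
        if c.position >= min_flank and (length - 1 - c.position) >= min_flank:
            kept.add(_key(c))
    return kept


def candidate_flank_window(
    c: SnpCandidate, consensus: str, min_flank: int, allele: Optional[str] = None
) -> Optional[str]:
    """Flanks + site string (``min_flank`` nt each side); None near edges."""
    lo = c.position - min_flank
    hi = c.position + 1 + min_flank
    if lo < 0 or hi > len(consensus):
        return None
    site = allele if allele is not None else consensus[c.position]
    return consensus[lo : c.position] + site + consensus[c.position + 1 : hi]


def genomic_contiguity_filter(
    candidates: Sequence[SnpCandidate],
    contigs: Mapping[str, str],
    reference: Optional[Mapping[str, str]],
    min_flank: int = 100,
) -> tuple[set[tuple[str, int]], Optional[str]]:
    """Keys whose full flanking window occurs contiguously in the reference.

    Either allele is accepted at the site, on either strand.  When
    ``reference`` is None the filter is skipped: all candidates pass and a
    warning string is returned.
    """
    if reference is None:
        msg = "no genomic reference supplied: contiguity filter skipped"
        warnings.warn(msg, stacklevel=2)
        return {_key(c) for c in candidates}, msg
    haystack = "\n".join(reference.values())
    haystack = haystack + "\n" + str(Seq(haystack).reverse_complement())
    kept = set()
    for c in candidates:
        consensus = contigs[c.contig_id]
        for allele in (c.major_base, c.minor_base):
            window = candidate_flank_window(c, consensus, min_flank, allele)
            if window is not None and window in haystack:
                kept.add(_key(c))
                break
    return kept, None


def proxy_design_score(
    c: SnpCandidate,
    consensus: str,
    neighbour_positions: Mapping[str, Sequence[int]],
    min_flank: int = 100,
    proximity: int = 60,
) -> float:
    """Built-in stand-in for a platform assay-design score, in [0,1]."""
    window = candidate_flank_window(c, consensus, min_flank)
    if window is None:
        # fall back to whatever flank exists; short flanks are the
        # flank_length filter's business, not the scorer's
        lo = max(0, c.position - min_flank)
        hi = min(len(consensus), c.position + 1 + min_flank)
        window = consensus[lo:hi]
    flanks = window[: len(window) // 2] + window[len(window) // 2 + 1 :]
    penalty = 0.0
    gc = (flanks.count("G") + flanks.count("C")) / max(1, len(flanks))
    if not 0.30 <= gc <= 0.70:
        penalty += 0.3
    if _has_homopolymer_near(consensus, c.position, run=6, within=proximity):
        penalty += 0.3
    if "N" in flanks:
        penalty += 0.5
    others = neighbour_positions.get(c.contig_id, ())
    if any(p != c.position and abs(p - c.position) <= proximity for p in others):
        penalty += 0.2
    return max(0.0, 1.0 - penalty)


def _has_homopolymer_near(seq: str, pos: int, run: int, within: int) -> bool:
    lo = max(0, pos - within)
    hi = min(len(seq), pos + 1 + within)
    region = seq[lo:hi]
    current = 1
    for i in range(1, len(region)):
        if region[i] == region[i - 1]:
            current += 1
            if current >= run:
                return True
        else:
            current = 1
    return False


def design_score_filter(
    candidates: Sequence[SnpCandidate],
    scorer: Callable[[SnpCandidate], float],
    min_score: float = 0.6,
) -> set[tuple[str, int]]:
    """Keys of candidates whose design score reaches ``min_score``."""
    kept = set()
    for c in candidates:
        score = scorer(c)
        if not 0 <= score <= 1:
            raise ValueError(
                f"design scorer returned {score} for {c.snp_id}: must be in [0,1]"
            )
        if score >= min_score:
            kept.add(_key(c))
    return kept


def similarity_filter(
    candidates: Sequence[SnpCandidate],
    contigs: Mapping[str, str],
    min_flank: int = 100,
    kmer: int = 31,
) -> set[tuple[str, int]]:
    """Keys of candidates sharing no exact k-mer with another contig's candidate."""
    windows: list[tuple[SnpCandidate, set[str]]] = []
    for c in candidates:
        window = candidate_flank_window(c, contigs[c.contig_id], min_flank)
        if window is None:
            lo = max(0, c.position - min_flank)
            hi = min(len(contigs[c.contig_id]), c.position + 1 + min_flank)
            window = contigs[c.contig_id][lo:hi]
        kmers = {window[i : i + kmer] for i in range(max(0, len(window) - kmer + 1))}
        windows.append((c, kmers))
    owners: dict[str, set[str]] = {}
    for c, kmers in windows:
        for k in kmers:
            owners.setdefault(k, set()).add(c.contig_id)
    kept = set()
    for c, kmers in windows:
        if all(owners[k] <= {c.contig_id} for k in kmers):
            kept.add(_key(c))
    return kept


def select_panel(
    candidates: Sequence[SnpCandidate],
    contigs: Mapping[str, str],
    reference: Optional[Mapping[str, str]] = None,
    config: Optional[PanelConfig] = None,
    scorer: Optional[Callable[[SnpCandidate], float]] = None,
) -> PanelFilterReport:
    """Run all panel filters, recording every failure per candidate.

    Each filter is evaluated as a predicate on the full input set
    (proximity-dependent terms use pre-filter neighbours), so the report
    is independent of filter order.  ``config.max_panel_size`` optionally
    caps the survivors to the best-scoring N.
    """
    cfg = config or PanelConfig()
    candidates = list(candidates)
    contig_lengths = {cid: len(seq) for cid, seq in contigs.items()}
    neighbour_positions: dict[str, list[int]] = {}
    for c in candidates:
        neighbour_positions.setdefault(c.contig_id, []).append(c.position)

    if scorer is None:
        def scorer(c: SnpCandidate) -> float:  # noqa: F811 - deliberate default
            return proxy_design_score(
                c, contigs[c.contig_id], neighbour_positions, cfg.min_flank
            )

    passed: dict[str, set[tuple[str, int]]] = {}
    passed["spacing"] = spacing_filter(
        candidates, cfg.min_gap, cfg.keep_better_of_close_pair, scorer
    )
    passed["flank_length"] = flank_length_filter(
        candidates, contig_lengths, cfg.min_flank
    )
    contiguity, warning = genomic_contiguity_filter(
        candidates, contigs, reference, cfg.min_flank
    )
    passed["genomic_contiguity"] = contiguity
    passed["design_score"] = design_score_filter(candidates, scorer, cfg.min_score)
    passed["similarity"] = similarity_filter(
        candidates, contigs, cfg.min_flank, cfg.kmer
    )

    failed = [
        [name for name in FILTER_ORDER if _key(c) not in passed[name]]
        for c in candidates
    ]
    report = PanelFilterReport(
        candidates=candidates,
        failed_filters=failed,
        warnings=[warning] if warning else [],
    )
    if cfg.max_panel_size is not None:
        survivors = sorted(
            (i for i, f in enumerate(failed) if not f),
            key=lambda i: (-scorer(candidates[i]), _key(candidates[i])),
        )
        for i in survivors[cfg.max_panel_size :]:
            failed[i].append("panel_cap")
    return report
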