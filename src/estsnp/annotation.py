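"""Homology-hit filtering and synonymous/non-synonymous SNP calling.

Protein-homology searches (e.g. blastx against a model-species peptide
set) are consumed as tabular hit files — never executed here.  Hit
filtering collapses alternative-splicing protein ids to gene ids, keeps
the minimal e-value per query, and breaks residual ties by the HSP
product (% identity x alignment length).

Effect calling translates the hit-defined window of the contig under
both SNP alleles and compares peptides directly: identical peptides that
match the reference window are synonymous; exactly one amino-acid
difference between the two allele peptides is non-synonymous (stop-gain
counts, recorded as ``*``); anything else is unresolved.  A SNP whose
own best hit names a different gene than its contig's best hit is
``discordant_hit`` and excluded from effect calling; a missing hit is
``no_hit``.  Standard genetic code throughout; N in a codon gives
``unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .io_formats import HomologyHit

__all__ = [
    "AnnotationRecord",
    "BestHit",
    "filter_best_hits",
    "build_peptide_window",
    "classify_substitution",
    "EFFECTS",
]

EFFECTS = ("synonymous", "nonsynonymous", "no_hit", "discordant_hit", "unresolved")


@dataclass
class AnnotationRecord:
    snp_id: str
    gene_id: str
    effect: str  # one of EFFECTS
    ref_aa: str = ""
    alt_aa: str = ""
    codon_index: int = -1  # 0-based within the matched peptide window
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.effect == "nonsynonymous" and self.ref_aa == self.alt_aa:
            raise ValueError("nonsynonymous record with identical amino acids")
        if self.effect == "no_hit" and self.gene_id:
            raise ValueError("no_hit record must carry an empty gene_id")


@dataclass
class BestHit:
    """Best hit for one query after e-value / HSP-product filtering."""

    hit: HomologyHit
    gene_id: str
    ambiguous: bool = False
    tied: list[HomologyHit] = field(default_factory=list)


def filter_best_hits(
    hits: Sequence[HomologyHit],
    protein_to_gene: Optional[Mapping[str, str]] = None,
    evalue_max: float = 1e-5,
) -> dict[str, BestHit]:
    """Reduce raw homology hits to one best gene hit per query.

    Steps: drop hits above ``evalue_max``; map protein ids to gene ids
    (identity when no mapping is given); per query keep the minimal
    e-value; break residual ties by maximal % identity x alignment
    length; exact ties across *different* genes leave the query flagged
    ambiguous with all tied hits retained.
    """
    def gene_of(h: HomologyHit) -> str:
        if h.subject_gene_id:
            return h.subject_gene_id
        if protein_to_gene is None:
            return h.subject_protein_id
        return protein_to_gene.get(h.subject_protein_id, h.subject_protein_id)

    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.evalue <= evalue_max:
            by_query.setdefault(h.query_id, []).append(h)

    out: dict[str, BestHit] = {}
    for query, group in by_query.items():
        best_e = min(h.evalue for h in group)
        group = [h for h in group if h.evalue == best_e]
        best_prod = max(h.hsp_score for h in group)
        group = [h for h in group if h.hsp_score == best_prod]
        genes = {gene_of(h) for h in group}
        winner = group[0]
        out[query] = BestHit(
            hit=winner,
            gene_id=gene_of(winner),
            ambiguous=len(genes) > 1,
            tied=group if len(genes) > 1 else [],
        )
    return out


def build_peptide_window(
    contig_seq: str, hit: HomologyHit
) -> tuple[str, bool]:
    """Translate the hit-defined window of a contig sequence.

    Extracts the 1-based inclusive [qstart, qend] window (order-free:
    minus-frame hits may store qstart > qend), reverse-complements when
    the frame is negative, translates with the standard genetic code and
    drops a trailing partial codon.  An internal stop truncates the
    peptide; the second return value flags that truncation.
    """
    lo, hi = hit.window()
    if not (0 <= lo < hi <= len(contig_seq)):
        raise ValueError(
            f"hit window [{lo + 1}, {hi}] outside contig of length {len(contig_seq)}"
        )
    if hi - lo < 3:
        raise ValueError("hit window shorter than one codon")
    window = contig_seq[lo:hi]
    if hit.frame < 0:
        window = str(Seq(window).reverse_complement())
    usable = len(window) - len(window) % 3
    peptide = str(Seq(window[:usable]).translate())
    truncated = "*" in peptide
    if truncated:
        peptide = peptide.split("*", 1)[0]
    return peptide, truncated


def _translate_window(window: str) -> str:
    usable = len(window) - len(window) % 3
    return str(Seq(window[:usable]).translate())


def classify_substitution(
    snp_id: str,
    contig_seq: str,
    snp_pos: int,
    allele_a: str,
    allele_b: str,
    contig_hit: Optional[BestHit],
    snp_hit: Optional[BestHit],
) -> AnnotationRecord:
    """Call the coding effect of one SNP from its contig's best hit.

    ``snp_pos`` is 0-based on the contig; alleles are given in contig
    orientation.  Requires a concordant SNP-level hit (same gene as the
    contig-level hit); the comparison itself runs in the contig hit's
    window and frame.
    """
    if contig_hit is None or snp_hit is None:
        return AnnotationRecord(snp_id=snp_id, gene_id="", effect="no_hit")
    if snp_hit.gene_id != contig_hit.gene_id:
        return AnnotationRecord(
            snp_id=snp_id,
            gene_id=contig_hit.gene_id,
            effect="discordant_hit",
            notes=[f"snp_hit_gene={snp_hit.gene_id}"],
        )
    hit = contig_hit.hit
    lo, hi = hit.window()
    record = AnnotationRecord(
        snp_id=snp_id, gene_id=contig_hit.gene_id, effect="unresolved"
    )
    if not (lo <= snp_pos < hi):
        record.notes.append("snp_outside_hit_window")
        return record
    if hi - lo < 3:
        record.notes.append("window_shorter_than_codon")
        return record

    def windowed(allele: str) -> tuple[str, int]:
        seq = contig_seq[lo:snp_pos] + allele + contig_seq[snp_pos + 1 : hi]
        offset = snp_pos - lo
        if hit.frame < 0:
            seq = str(Seq(seq).reverse_complement())
            offset = (hi - lo) - 1 - offset
        return seq, offset

    ref_window, _ = windowed(contig_seq[snp_pos])
    win_a, offset = windowed(allele_a)
    win_b, _ = windowed(allele_b)
    codon_index = offset // 3
    if 3 * (codon_index + 1) > len(win_a) - len(win_a) % 3:
        record.notes.append("snp_in_trailing_partial_codon")
        return record
    codon_a = win_a[3 * codon_index : 3 * codon_index + 3]
    codon_b = win_b[3 * codon_index : 3 * codon_index + 3]
    if set(codon_a + codon_b) - set("ACGT"):
        record.notes.append("ambiguous_base_in_codon")
        return record

    pep_ref = _translate_window(ref_window)
    pep_a = _translate_window(win_a)
    pep_b = _translate_window(win_b)
    diffs = [i for i, (x, y) in enumerate(zip(pep_a, pep_b)) if x != y]
    if not diffs:
        if pep_a == pep_ref:
            record.effect = "synonymous"
            record.codon_index = codon_index
        else:
            record.notes.append("alleles_agree_but_differ_from_reference")
        return record
    if len(diffs) == 1 and diffs[0] == codon_index:
        ref_allele = contig_seq[snp_pos]
        if ref_allele == allele_a:
            ref_aa, alt_aa = pep_a[codon_index], pep_b[codon_index]
        elif ref_allele == allele_b:
            ref_aa, alt_aa = pep_b[codon_index], pep_a[codon_index]
        else:
            record.notes.append("neither_allele_matches_contig")
            return record
        record.effect = "nonsynonymous"
        record.ref_aa = ref_aa
        record.alt_aa = alt_aa
        record.codon_index = codon_index
        return record
    record.notes.append("multiple_amino_acid_differences")
    return record
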