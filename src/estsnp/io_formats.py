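"""Readers and writers for the pipeline's on-disk formats.

Formats handled
---------------
* gapped FASTA, one file (or handle) per contig: the first record is the
  assembly consensus, followed by the aligned reads in consensus
  coordinates (``-`` for gaps, ``N`` for ambiguous calls);
* a genotype-matrix CSV in a GenomeStudio-export-like dialect (defined
  below, since array software exports vary): header
  ``snp_id,gentrain,allele_a,allele_b,<sample...>`` and per-sample cells
  ``CALL:gencall`` with ``CALL`` one of AA/AB/BB/NC;
* a three-column sample manifest TSV (``sample_id``, ``population``,
  ``ploidy_class``);
* BLAST tabular (outfmt-6-compatible) homology-hit tables, with an
  optional 13th ``frame`` column;
* plain (peptide / genomic reference) FASTA.

Coordinates are 1-based inclusive on disk (BLAST convention) and 0-based
half-open in memory.  Readers validate invariants and reject rather than
repair, unless an explicit ``lenient`` flag is passed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]

__all__ = [
    "FormatError",
    "ContigAlignment",
    "GenotypeMatrix",
    "SampleManifest",
    "HomologyHit",
    "CALL_LABELS",
    "CALL_AA",
    "CALL_AB",
    "CALL_BB",
    "CALL_NC",
    "read_contig_alignment",
    "write_contig_alignment",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_sample_manifest",
    "write_sample_manifest",
    "read_homology_table",
    "write_homology_table",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """A file violates the format contract (wrong token, bad length...)."""


# genotype call encoding shared across the package
CALL_LABELS = ("AA", "AB", "BB", "NC")
CALL_AA, CALL_AB, CALL_BB, CALL_NC = 0, 1, 2, 3
_CALL_CODE = {label: code for code, label in enumerate(CALL_LABELS)}

_CONSENSUS_ALPHABET = set("ACGTN")
_READ_ALPHABET = set("ACGTN-")


@dataclass
class ContigAlignment:
    """A consensus sequence plus gapped reads in consensus coordinates."""

    contig_id: str
    consensus: str
    reads: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> "ContigAlignment":
        if not self.contig_id:
            raise FormatError("contig_id must be non-empty")
        if not set(self.consensus) <= _CONSENSUS_ALPHABET:
            bad = set(self.consensus) - _CONSENSUS_ALPHABET
            raise FormatError(
                f"contig {self.contig_id}: consensus contains {sorted(bad)!r} "
                "(allowed: A,C,G,T,N; no gaps)"
            )
        n = len(self.consensus)
        for read_id, seq in self.reads:
            if len(seq) != n:
                raise FormatError(
                    f"contig {self.contig_id}: read {read_id!r} has length "
                    f"{len(seq)}, consensus has {n}"
                )
            if not set(seq) <= _READ_ALPHABET:
                bad = set(seq) - _READ_ALPHABET
                raise FormatError(
                    f"contig {self.contig_id}: read {read_id!r} contains "
                    f"{sorted(bad)!r}"
                )
        return self

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass
class GenotypeMatrix:
    """Per-SNP x per-sample genotype calls with platform quality scores.

    ``calls`` holds the integer codes ``CALL_AA..CALL_NC``; genotypes are
    unordered (AB is the single heterozygous class).  No-calls (NC) carry
    a GenCall score of 0.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray  # (n_snps, n_samples) int8
    gencall: np.ndarray  # (n_snps, n_samples) float
    gentrain: np.ndarray  # (n_snps,) float
    alleles: list[tuple[str, str]]  # per-snp (allele_A, allele_B)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> "GenotypeMatrix":
        shape = (self.n_snps, self.n_samples)
        if self.calls.shape != shape or self.gencall.shape != shape:
            raise FormatError(
                f"grid shape mismatch: calls {self.calls.shape}, "
                f"gencall {self.gencall.shape}, expected {shape}"
            )
        if self.gentrain.shape != (self.n_snps,):
            raise FormatError("gentrain must be one score per SNP")
        if len(self.alleles) != self.n_snps:
            raise FormatError("alleles must be one pair per SNP")
        if len(set(self.snp_ids)) != self.n_snps:
            raise FormatError("duplicate snp_id")
        if len(set(self.sample_ids)) != self.n_samples:
            raise FormatError("duplicate sample_id")
        if self.calls.min(initial=0) < 0 or self.calls.max(initial=0) > 3:
            raise FormatError("calls must be codes 0..3 (AA,AB,BB,NC)")
        if ((self.gencall < 0) | (self.gencall > 1)).any():
            raise FormatError("gencall scores must lie in [0,1]")
        if ((self.gentrain < 0) | (self.gentrain > 1)).any():
            raise FormatError("gentrain scores must lie in [0,1]")
        nc = self.calls == CALL_NC
        if (self.gencall[nc] != 0).any():
            raise FormatError("NC calls must carry gencall 0")
        for snp_id, (a, b) in zip(self.snp_ids, self.alleles):
            if a == b or a not in "ACGT" or b not in "ACGT":
                raise FormatError(f"SNP {snp_id}: invalid allele pair ({a},{b})")
        return self


@dataclass
class SampleManifest:
    """Sample ids with population label and ploidy class (DH or diploid)."""

    sample_ids: list[str]
    populations: list[str]
    ploidy_classes: list[str]  # each "DH" or "diploid"

    def validate(self) -> "SampleManifest":
        n = len(self.sample_ids)
        if len(self.populations) != n or len(self.ploidy_classes) != n:
            raise FormatError("manifest columns must have equal length")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample_id in manifest")
        bad = set(self.ploidy_classes) - {"DH", "diploid"}
        if bad:
            raise FormatError(f"invalid ploidy_class values: {sorted(bad)}")
        if n == 0 or not set(self.populations):
            raise FormatError("manifest must contain at least one population")
        return self

    def is_dh(self) -> np.ndarray:
        return np.array([p == "DH" for p in self.ploidy_classes], dtype=bool)

    def population_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def samples_in(self, population: str) -> np.ndarray:
        return np.array([p == population for p in self.populations], dtype=bool)


@dataclass
class HomologyHit:
    """One row of a BLAST-tabular homology search (consumed, not run)."""

    query_id: str
    subject_protein_id: str
    pct_identity: float
    aln_len: int
    qstart: int  # 1-based inclusive
    qend: int  # 1-based inclusive
    evalue: float
    bitscore: float = 0.0
    frame: int = 1
    subject_gene_id: str = ""  # empty until protein->gene mapping applied

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise FormatError(f"negative e-value for query {self.query_id}")
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise FormatError(f"invalid frame {self.frame} for {self.query_id}")
        if self.frame > 0 and self.qstart > self.qend:
            raise FormatError(
                f"{self.query_id}: qstart > qend with positive frame"
            )

    @property
    def hsp_score(self) -> float:
        """Tie-break score: percent identity times alignment length."""
        return self.pct_identity * self.aln_len

    def window(self) -> tuple[int, int]:
        """Query window as a 0-based half-open interval."""
        lo, hi = sorted((self.qstart, self.qend))
        return lo - 1, hi


# ---------------------------------------------------------------------------
# contig alignments (gapped FASTA)
# ---------------------------------------------------------------------------


def read_contig_alignment(path: Union[PathLike, TextIO]) -> ContigAlignment:
    """Read one contig alignment from a gapped FASTA file.

    The consensus is the record whose id ends in ``.consensus`` or, failing
    that, the first record.  Sequences are uppercased.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"empty alignment file: {path}")
    cons_idx = 0
    for i, rec in enumerate(records):
        if rec.id.endswith(".consensus"):
            cons_idx = i
            break
    cons = records.pop(cons_idx)
    contig_id = cons.id.removesuffix(".consensus")
    aln = ContigAlignment(
        contig_id=contig_id,
        consensus=str(cons.seq).upper(),
        reads=[(r.id, str(r.seq).upper()) for r in records],
    )
    return aln.validate()


def write_contig_alignment(aln: ContigAlignment, path: Union[PathLike, TextIO]) -> None:
    aln.validate()
    records = [
        SeqRecord(Seq(aln.consensus), id=f"{aln.contig_id}.consensus", description="")
    ]
    records += [
        SeqRecord(Seq(seq), id=read_id, description="") for read_id, seq in aln.reads
    ]
    SeqIO.write(records, path, "fasta-2line")


# ---------------------------------------------------------------------------
# genotype matrix CSV
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["snp_id", "gentrain", "allele_a", "allele_b"]


def read_genotype_matrix(
    path: Union[PathLike, TextIO], lenient: bool = False
) -> GenotypeMatrix:
    """Read a genotype matrix CSV (dialect documented in the module docstring).

    With ``lenient=True`` unparseable cells become NC with gencall 0;
    otherwise they raise :class:`FormatError`.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"empty genotype matrix: {path}") from None
        if header[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
            raise FormatError(
                f"genotype matrix header must start with {_FIXED_COLUMNS}, "
                f"got {header[:4]}"
            )
        sample_ids = header[len(_FIXED_COLUMNS):]
        snp_ids: list[str] = []
        alleles: list[tuple[str, str]] = []
        gentrain: list[float] = []
        calls_rows: list[list[int]] = []
        gc_rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            snp_id = row[0]
            if snp_id in seen:
                raise FormatError(f"duplicate snp_id {snp_id!r} (line {lineno})")
            seen.add(snp_id)
            snp_ids.append(snp_id)
            try:
                gentrain.append(float(row[1]))
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric gentrain {row[1]!r}"
                ) from None
            alleles.append((row[2], row[3]))
            calls_row: list[int] = []
            gc_row: list[float] = []
            for cell in row[len(_FIXED_COLUMNS):]:
                call, score = _parse_cell(cell, snp_id, lenient)
                calls_row.append(call)
                gc_row.append(score)
            calls_rows.append(calls_row)
            gc_rows.append(gc_row)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    m = GenotypeMatrix(
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        calls=np.array(calls_rows, dtype=np.int8).reshape(len(snp_ids), len(sample_ids)),
        gencall=np.array(gc_rows, dtype=float).reshape(len(snp_ids), len(sample_ids)),
        gentrain=np.array(gentrain, dtype=float),
        alleles=alleles,
    )
    return m.validate()


def _parse_cell(cell: str, snp_id: str, lenient: bool) -> tuple[int, float]:
    try:
        call_tok, score_tok = cell.split(":")
        call = _CALL_CODE[call_tok]
        score = float(score_tok)
        if not 0 <= score <= 1:
            raise ValueError
        if call == CALL_NC and score != 0:
            raise ValueError
    except (ValueError, KeyError):
        if lenient:
            return CALL_NC, 0.0
        raise FormatError(f"SNP {snp_id}: unparseable cell {cell!r}") from None
    return call, score


def write_genotype_matrix(m: GenotypeMatrix, path: Union[PathLike, TextIO]) -> None:
    m.validate()
    handle = open(path, "w", newline="") if isinstance(path, (str, Path)) else path
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(_FIXED_COLUMNS + list(m.sample_ids))
        for i, snp_id in enumerate(m.snp_ids):
            a, b = m.alleles[i]
            row = [snp_id, _fmt(m.gentrain[i]), a, b]
            for j in range(m.n_samples):
                call = CALL_LABELS[m.calls[i, j]]
                row.append(f"{call}:{_fmt(m.gencall[i, j])}")
            writer.writerow(row)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


def _fmt(x: float) -> str:
    # shortest repr round-trips floats exactly; integers print bare
    return str(int(x)) if float(x) == int(x) else repr(float(x))


# ---------------------------------------------------------------------------
# sample manifest TSV
# ---------------------------------------------------------------------------


def read_sample_manifest(path: Union[PathLike, TextIO]) -> SampleManifest:
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"empty manifest: {path}") from None
        if header != ["sample_id", "population", "ploidy_class"]:
            raise FormatError(
                "manifest header must be sample_id<TAB>population<TAB>ploidy_class"
            )
        ids, pops, ploidy = [], [], []
        for row in reader:
            if not row:
                continue
            if len(row) != 3:
                raise FormatError(f"manifest row has {len(row)} fields: {row!r}")
            ids.append(row[0])
            pops.append(row[1])
            ploidy.append(row[2])
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return SampleManifest(ids, pops, ploidy).validate()


def write_sample_manifest(man: SampleManifest, path: Union[PathLike, TextIO]) -> None:
    man.validate()
    handle = open(path, "w", newline="") if isinstance(path, (str, Path)) else path
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "population", "ploidy_class"])
        for rec in zip(man.sample_ids, man.populations, man.ploidy_classes):
            writer.writerow(rec)
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


# ---------------------------------------------------------------------------
# homology-hit table (BLAST tabular)
# ---------------------------------------------------------------------------


def read_homology_table(path: Union[PathLike, TextIO]) -> list[HomologyHit]:
    """Parse a 12(+frame)-column BLAST-tabular TSV into HomologyHit records.

    Column order: query, subject, %identity, aln_len, mismatches, gapopen,
    qstart, qend, sstart, send, evalue, bitscore[, frame].  A missing frame
    column defaults to +1, except that rows with qstart > qend are taken as
    minus-strand (-1).
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    hits: list[HomologyHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"line {lineno}: expected >=12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                pct = float(parts[2])
                aln_len = int(parts[3])
                qstart = int(parts[6])
                qend = int(parts[7])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if len(parts) >= 13 and parts[12] != "":
                frame = int(parts[12])
            else:
                frame = -1 if qstart > qend else 1
            hits.append(
                HomologyHit(
                    query_id=parts[0],
                    subject_protein_id=parts[1],
                    pct_identity=pct,
                    aln_len=aln_len,
                    qstart=qstart,
                    qend=qend,
                    evalue=evalue,
                    bitscore=bitscore,
                    frame=frame,
                )
            )
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return hits


def write_homology_table(
    hits: Iterable[HomologyHit], path: Union[PathLike, TextIO]
) -> None:
    handle = open(path, "w", newline="") if isinstance(path, (str, Path)) else path
    try:
        for h in hits:
            fields = [
                h.query_id,
                h.subject_protein_id,
                _fmt(h.pct_identity),
                str(h.aln_len),
                "0",
                "0",
                str(h.qstart),
                str(h.qend),
                "1",
                str(h.aln_len),
                repr(h.evalue),
                _fmt(h.bitscore),
                str(h.frame),
            ]
            handle.write("\t".join(fields) + "\n")
    finally:
        if isinstance(path, (str, Path)):
            handle.close()


# ---------------------------------------------------------------------------
# plain FASTA (reference genome / peptides)
# ---------------------------------------------------------------------------


def read_fasta(path: Union[PathLike, TextIO]) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: Mapping[str, str], path: Union[PathLike, TextIO]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, path, "fasta-2line")
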