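"""Quality thresholding and SNP-status classification from a genotype panel.

Assayed SNPs are partitioned into four mutually exclusive statuses:

* ``failed``      — the assay itself is unusable: cluster-quality
  (GenTrain) score below 0.25, or fewer than 80% of samples yield a
  valid call after masking low-confidence (GenCall < 0.25) genotypes;
* ``monomorphic`` — every valid call is the same homozygous genotype;
  in EST-mined panels these are mostly sequencing-error pseudo-SNPs (or
  rare alleles absent from the genotyped samples);
* ``psv``         — every valid call is heterozygous, including doubled
  haploid (DH) individuals, whose genomes are fully homozygous: the
  assay is reading a fixed difference between two paralogous loci
  superimposed by cross-hybridisation (a paralogous sequence variant, a
  false-positive SNP);
* ``true``        — at least two genotype classes observed.

A ``true`` SNP is additionally flagged as a multisite-variant (MSV)
candidate when its DH calls mix heterozygotes with at most one
homozygous class — the signature of a duplicated locus pair with one
paralog fixed and the other segregating.  The flag is a screening
heuristic (MSV confirmation requires linkage mapping, outside this
package's scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    CALL_NC,
    GenotypeMatrix,
    SampleManifest,
)
from .popgen_stats import MAF_BIN_LABELS, allele_frequencies, maf_bin
from .snp_discovery import SNPS_PER_CONTIG_BINS

__all__ = [
    "SnpClassification",
    "apply_quality_thresholds",
    "classify_snp",
    "classify_matrix",
    "classification_summary",
    "STATUSES",
]

STATUSES = ("failed", "monomorphic", "psv", "true")


@dataclass
class SnpClassification:
    snp_id: str
    status: str  # one of STATUSES
    msv_candidate: bool
    call_rate: float
    n_valid_dh: int
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.msv_candidate and self.status != "true":
            raise ValueError("msv_candidate only applies to true SNPs")


def apply_quality_thresholds(
    m: GenotypeMatrix,
    gencall_min: float = 0.25,
    gentrain_min: float = 0.25,
    min_call_rate: float = 0.80,
) -> tuple[np.ndarray, set[str]]:
    """Mask low-confidence calls and mark unusable SNPs as failed.

    Returns ``(valid_mask, failed_snp_ids)``: ``valid_mask[i, j]`` is True
    when sample j's call at SNP i is a genotype (not NC) with GenCall >=
    ``gencall_min``.  A SNP fails when its GenTrain score is below
    ``gentrain_min`` or its valid-call rate is below ``min_call_rate``.
    """
    valid = (m.calls != CALL_NC) & (m.gencall >= gencall_min)
    call_rate = valid.mean(axis=1) if m.n_samples else np.zeros(m.n_snps)
    failed_mask = (m.gentrain < gentrain_min) | (call_rate < min_call_rate)
    failed = {sid for sid, f in zip(m.snp_ids, failed_mask) if f}
    return valid, failed


def classify_snp(
    calls: np.ndarray,
    valid: np.ndarray,
    manifest: SampleManifest,
    snp_id: str = "",
) -> SnpClassification:
    """Classify one non-failed SNP from its per-sample calls.

    ``calls`` and ``valid`` are per-sample arrays aligned with the
    manifest.  Raises ``ValueError`` when no valid call exists (such a
    SNP should already have been marked failed).
    """
    calls = np.asarray(calls)
    valid = np.asarray(valid, dtype=bool)
    if valid.size != calls.size or calls.size != len(manifest.sample_ids):
        raise ValueError("calls/valid/manifest lengths differ")
    v = calls[valid]
    if v.size == 0:
        raise ValueError(
            f"SNP {snp_id or '<unnamed>'} has zero valid calls; "
            "it should have been marked failed by the quality thresholds"
        )
    is_dh = manifest.is_dh()
    dh_calls = calls[valid & is_dh]
    n_aa = int((v == CALL_AA).sum())
    n_ab = int((v == CALL_AB).sum())
    n_bb = int((v == CALL_BB).sum())
    notes: list[str] = []
    msv = False
    if n_ab == v.size:
        status = "psv"
        if dh_calls.size == 0:
            notes.append("psv_without_dh_support")
    elif (n_aa == v.size) or (n_bb == v.size):
        status = "monomorphic"
    else:
        status = "true"
        dh_ab = int((dh_calls == CALL_AB).sum())
        dh_homo_classes = int((dh_calls == CALL_AA).any()) + int(
            (dh_calls == CALL_BB).any()
        )
        if dh_ab >= 1 and dh_homo_classes <= 1:
            msv = True
            notes.append("dh_mixed_homo_het")
    return SnpClassification(
        snp_id=snp_id,
        status=status,
        msv_candidate=msv,
        call_rate=float(valid.mean()),
        n_valid_dh=int((valid & is_dh).sum()),
        notes=notes,
    )


def classify_matrix(
    m: GenotypeMatrix,
    manifest: SampleManifest,
    gencall_min: float = 0.25,
    gentrain_min: float = 0.25,
    min_call_rate: float = 0.80,
    sample_mask: Optional[np.ndarray] = None,
) -> list[SnpClassification]:
    """Threshold and classify every SNP of a genotype matrix.

    ``sample_mask`` restricts the analysis to a subset of samples (used
    for per-population summaries); thresholds, call rates and statuses
    are then computed within that subset.
    """
    if list(manifest.sample_ids) != list(m.sample_ids):
        raise ValueError("manifest and matrix sample ids differ")
    if sample_mask is not None:
        cols = np.flatnonzero(np.asarray(sample_mask, dtype=bool))
        sub = GenotypeMatrix(
            snp_ids=m.snp_ids,
            sample_ids=[m.sample_ids[j] for j in cols],
            calls=m.calls[:, cols],
            gencall=m.gencall[:, cols],
            gentrain=m.gentrain,
            alleles=m.alleles,
        )
        sub_manifest = SampleManifest(
            [manifest.sample_ids[j] for j in cols],
            [manifest.populations[j] for j in cols],
            [manifest.ploidy_classes[j] for j in cols],
        )
        return classify_matrix(
            sub, sub_manifest, gencall_min, gentrain_min, min_call_rate
        )

    valid, failed = apply_quality_thresholds(
        m, gencall_min, gentrain_min, min_call_rate
    )
    out: list[SnpClassification] = []
    for i, snp_id in enumerate(m.snp_ids):
        if snp_id in failed:
            out.append(
                SnpClassification(
                    snp_id=snp_id,
                    status="failed",
                    msv_candidate=False,
                    call_rate=float(valid[i].mean()),
                    n_valid_dh=int((valid[i] & manifest.is_dh()).sum()),
                )
            )
        else:
            out.append(classify_snp(m.calls[i], valid[i], manifest, snp_id))
    return out


def classification_summary(
    m: GenotypeMatrix,
    manifest: SampleManifest,
    classifications: Optional[Sequence[SnpClassification]] = None,
    snp_contigs: Optional[Mapping[str, str]] = None,
    gencall_min: float = 0.25,
    gentrain_min: float = 0.25,
    min_call_rate: float = 0.80,
) -> dict[str, pd.DataFrame]:
    """Summarise a classified panel the way validation studies report it.

    Returns a dict of tables:

    * ``status_counts``       — pooled counts per status (+ total);
    * ``per_population``      — status counts re-classified within each
      population subset (DH samples included in every subset so the PSV
      signature stays detectable) and pooled;
    * ``maf_bins``            — true-SNP counts per MAF bin per subset;
    * ``contig_distribution`` — status by snps-per-contig bin, when a
      ``snp_id -> contig`` mapping is supplied.
    """
    if classifications is None:
        classifications = classify_matrix(
            m, manifest, gencall_min, gentrain_min, min_call_rate
        )
    by_id = {c.snp_id: c for c in classifications}

    status_counts = pd.Series(
        {s: sum(c.status == s for c in classifications) for s in STATUSES},
        name="n_snps",
    )
    status_counts["total"] = len(classifications)

    is_dh = manifest.is_dh()
    subsets: dict[str, np.ndarray] = {}
    for pop in manifest.population_names():
        mask = manifest.samples_in(pop)
        if pop != "DH":
            mask = mask | is_dh  # keep the duplication detector in view
        subsets[pop] = mask
    subsets["all"] = np.ones(len(manifest.sample_ids), dtype=bool)

    per_pop = {}
    maf_rows = {}
    valid_all, _ = apply_quality_thresholds(m, gencall_min, gentrain_min, 0.0)
    for name, mask in subsets.items():
        cls = classify_matrix(
            m, manifest, gencall_min, gentrain_min, min_call_rate, sample_mask=mask
        )
        per_pop[name] = {s: sum(c.status == s for c in cls) for s in STATUSES}
        bins = dict.fromkeys(MAF_BIN_LABELS, 0)
        pop_only = mask & ~is_dh if name not in ("DH", "all") else mask
        for i, c in enumerate(cls):
            if c.status != "true":
                continue
            sel = valid_all[i] & (pop_only if pop_only.any() else mask)
            if not sel.any():
                continue
            stats = allele_frequencies(m.calls[i][sel])
            bins[maf_bin(stats.maf)] += 1
        maf_rows[name] = bins
    per_population = pd.DataFrame(per_pop).reindex(list(STATUSES))
    per_population.loc["total"] = per_population.sum()
    maf_bins = pd.DataFrame(maf_rows).reindex(list(MAF_BIN_LABELS))

    tables = {
        "status_counts": status_counts.to_frame(),
        "per_population": per_population,
        "maf_bins": maf_bins,
    }

    if snp_contigs is not None:
        per_contig: dict[str, int] = {}
        for snp_id in m.snp_ids:
            contig = snp_contigs[snp_id]
            per_contig[contig] = per_contig.get(contig, 0) + 1
        rows = {
            b: dict.fromkeys(STATUSES + ("assayed",), 0)
            for b in SNPS_PER_CONTIG_BINS
        }
        for snp_id in m.snp_ids:
            n = per_contig[snp_contigs[snp_id]]
            b = str(n) if n <= 10 else ">10"
            rows[b]["assayed"] += 1
            rows[b][by_id[snp_id].status] += 1
        tables["contig_distribution"] = pd.DataFrame(rows).T
    return tables
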