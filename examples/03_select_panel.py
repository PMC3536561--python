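"""Filter discovered candidates into a genotyping validation panel.

Assay design needs isolated SNPs (>= 60 nt apart), long flanks
(>= 100 nt), probes that do not span exon-intron junctions (checked by
contiguous match against a genomic reference), an adequate design score
and no cross-candidate flank similarity.  Here the "genome" is built
from the simulated contigs, with an intron spliced into some of them so
the contiguity filter has junctions to catch.
"""

from collections import Counter

import numpy as np

from estsnp import SimConfig, call_candidate_snps, select_panel
from estsnp import simulate_est_alignments, simulate_gene_set

config = SimConfig(n_loci=300, locus_len=400, seed=42)
truth = simulate_gene_set(config)
alignments, _ = simulate_est_alignments(truth)
contigs = {a.contig_id: a.consensus for a in alignments}
candidates = [c for a in alignments for c in call_candidate_snps(a)]

# genomic reference: every contig verbatim, but every third one gets an
# 80-nt intron inserted mid-sequence (an exon-intron junction)
rng = np.random.default_rng(0)
reference = {}
for i, (cid, seq) in enumerate(contigs.items()):
    if i % 3 == 0:
        cut = len(seq) // 2
        intron = "".join(rng.choice(list("ACGT"), size=80))
        reference[cid] = seq[:cut] + intron + seq[cut:]
    else:
        reference[cid] = seq

report = select_panel(candidates, contigs, reference)
failures = Counter(f for fl in report.failed_filters for f in fl)
print(f"candidates in: {len(candidates)}, kept for the panel: {len(report.kept)}")
print("failures by filter (a candidate can fail several):", dict(failures))
print("(spacing = neighbour < 60 nt; flank_length = < 100 nt to a contig end;")
print(" genomic_contiguity = probe window interrupted in the genome;")
print(" design_score = assay-design proxy < 0.6; similarity = shared 31-mer)")
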