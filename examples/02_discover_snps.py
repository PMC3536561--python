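"""Mine candidate SNPs from EST contig alignments.

Applies the stringent in-silico filters (depth >= 7 informative reads,
minor base in >= 3 reads, 4-base flanks exactly conserved, N/gaps
excluded) and compares the calls with the simulator's truth labels.
"""

from collections import Counter

from estsnp import SimConfig, call_candidate_snps, contig_snp_distribution
from estsnp import simulate_est_alignments, simulate_gene_set

config = SimConfig(n_loci=300, seed=42)
truth = simulate_gene_set(config)
alignments, _ = simulate_est_alignments(truth)

candidates = [c for aln in alignments for c in call_candidate_snps(aln)]
classes = Counter(truth.site_class(c.contig_id, c.position) for c in candidates)

print(f"{len(candidates)} candidate SNPs from {len(alignments)} contigs")
print("truth classes of the calls:", dict(classes))
print("(psv calls come from co-assembled paralog pairs; pseudo_snp calls")
print(" are clustered sequencing errors — both look like SNPs in ESTs)")

c = candidates[0]
print(f"\nexample candidate {c.snp_id}: {c.major_base}/{c.minor_base} "
      f"counts {c.base_counts}, depth {c.depth}")
print(f"  sequence-frequency stats: p={c.stats.p:.3f} He={c.stats.he:.3f} "
      f"PIC={c.stats.pic:.3f}  (He=2pq, PIC=He-2p^2q^2)")

dist = contig_snp_distribution(candidates)
print("\ncontigs by number of candidate SNPs:")
print(dist[dist > 0].to_string())
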