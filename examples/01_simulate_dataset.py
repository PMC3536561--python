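"""Generate a labelled pseudo-tetraploid study set.

Builds the default study conditions (2,000 loci would be the full run;
300 here keeps the example quick), simulates the gene set, the EST
contig alignments and the genotyping panel, and prints what was made.
"""

from collections import Counter

from estsnp import SimConfig, simulate_est_alignments, simulate_gene_set, simulate_genotype_panel

config = SimConfig(n_loci=300, seed=42)
truth = simulate_gene_set(config)
alignments, site_labels = simulate_est_alignments(truth)
matrix, manifest, truth_table = simulate_genotype_panel(truth)

n_dup = sum(l.duplicated for l in truth.loci)
print(f"loci: {config.n_loci}, duplicated: {n_dup} "
      f"({100 * n_dup / config.n_loci:.0f}% — residual genome duplication)")
depths = [len(a.reads) for a in alignments]
print(f"EST depth per contig: mean {sum(depths) / len(depths):.1f}, "
      f"range {min(depths)}-{max(depths)}")
print(f"genotyping panel: {matrix.n_snps} assayed SNPs x {matrix.n_samples} samples "
      f"({manifest.is_dh().sum()} doubled haploids)")
print("assayed-site truth classes:", dict(Counter(truth_table["class"])))
print("(true_snp = real segregating site; pseudo_snp = sequencing-error artifact;")
print(" psv = fixed paralog difference; msv = one paralog fixed, one segregating)")
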