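# Methods

This note records the models, parameter choices and numerical conventions
behind `estsnp`, and what the synthetic data do and do not establish.

## Discovery model

Candidate SNPs are called per consensus column of an EST contig alignment.
A column is a candidate iff: the consensus base is a plain A/C/G/T (padded
or ambiguous consensus columns are skipped); exactly two distinct bases are
observed among reads, after excluding reads showing N or a gap at the
column; informative depth ≥ `min_depth` (default 7); the minor base is
carried by ≥ `min_minor` reads (default 3); and the `flank_len` (default 4)
columns on each side are exactly conserved. Conservation is checked against
the **consensus**, per side: reads with an N/gap anywhere in a side's window
are excluded from that side's check, every remaining read must match the
consensus there, and at least one remaining read is required per side (an
all-excluded side rejects the site — the conservative reading). Sites with
three or more observed bases are rejected outright: the pipeline's markers
are biallelic and multi-allelic columns in EST data are overwhelmingly
error-driven. Ties for the major base break alphabetically; sites whose
flank window runs off the contig edge are rejected (panel design needs
100-nt flanks anyway, so nothing usable is lost).

Sequence-frequency statistics use direct counts of read depth per base:
p = major/(major+minor), He = 2pq, PIC = He − 2p²q².

## Panel-selection filters

Each filter is a pure predicate evaluated on the *pre-filter* candidate
set, so the surviving set is independent of application order; the report
records every failed filter per candidate.

* **spacing** (default 60 nt): *both* members of a close pair are removed —
  the conservative choice when a rule says close neighbours "were removed"
  without naming a survivor; `keep_better_of_close_pair` retains the
  higher-scoring member instead.
* **flank_length** (default 100 nt per side): closed form — positions in
  [100, L−101] survive.
* **genomic_contiguity**: the 201-nt probe window (both flanks + site,
  either allele) must occur contiguously in the supplied reference, either
  strand, by exact substring match. This replaces alignment-based screens
  against BAC-end/model-genome sequences: with a faithful reference, an
  interrupted exact match is precisely an exon–intron junction or a
  mismatch-bearing region, both of which the screen is meant to catch. A
  candidate whose window cannot be built (too close to a contig edge) fails
  the filter — contiguity cannot be verified. Without a reference the
  filter is skipped with a recorded warning.
* **design_score** (threshold 0.6): platform design scores are proprietary,
  so the scorer is pluggable; the built-in proxy starts at 1.0 and
  subtracts 0.3 for flank GC outside [0.30, 0.70], 0.3 for a homopolymer
  run ≥ 6 nt within 60 nt of the site, 0.5 for any N in the flanks and 0.2
  for another candidate within 60 nt, floored at 0. The penalties mirror
  the known failure modes of bead-array oligo design; the threshold keeps
  the conventional 0.6 gate.
* **similarity**: exact 31-mer sharing between the probe windows of
  candidates on *different* contigs (same-contig overlap is trivially
  shared sequence, not repetitiveness). 31 was chosen as the smallest odd
  k at which random 201-nt windows essentially never collide (4³¹ ≫ any
  panel) while genuine repeats and cross-assembled paralog flanks do.

## Quality thresholding and classification

Calls with GenCall < 0.25 are masked; SNPs with GenTrain < 0.25 or a
valid-call rate < 80% are **failed**. The 0.25 score cutoffs are the
standard stringent choice for bead-array data; the 80% call-rate floor is
this package's operationalisation of "did not cluster well / failed to
amplify" — no numeric rule is standard, so it is a configurable default.

Non-failed SNPs classify from their valid calls:

* **monomorphic** — a single homozygous genotype class;
* **psv** — every valid call heterozygous. Strict by default (tolerance
  knob exposed, default 0). With zero valid DH calls the status is still
  psv, with a low-confidence note: the all-heterozygous pattern has no
  other plausible generator, but only DH calls make it conclusive;
* **true** — two or more genotype classes.

**MSV-candidate flag** (true SNPs only): valid DH calls contain AB and at
most one homozygous class. This is a screening heuristic of this package
(MSV confirmation belongs to linkage mapping, out of scope here). The rule
deliberately does *not* require a homozygous DH class to be present: under
the assay model an MSV whose segregating paralog is near-fixed in the DH
panel yields all-AB DH calls while diploids still split, and requiring the
homozygous class would leave a heterozygous-DH "true" SNP unflagged —
breaking the invariant that every unflagged true SNP is DH-homozygous.
With the relaxed rule that invariant holds by construction.

Per-population summary tables re-classify within each population subset
with the DH samples retained in every subset (without them the PSV
signature is undetectable); MAF bins for true SNPs use the population's
diploid calls.

## The simulator

`synthetic_data` emulates an EST-derived SNP study in a genome descending
from a whole-genome duplication. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 2000 | loci (contigs) simulated |
| `locus_len` | 300 nt | contig length (EST contigs are longer; 300 keeps runs fast and leaves room for 100-nt flanks in panel tests at `locus_len=400`) |
| `dup_fraction` | 0.5 | loci retaining a diverged paralog |
| `mean_depth` / range | 12.7 / [7, 466] | reads per contig, truncated log-normal (σ = 0.6 on the log scale), location solved numerically so the truncated mean equals 12.7 |
| `per_base_error_rate` | 0.003 | i.i.d. read error |
| `pseudo_snp_rate` | 0.7 | clustered-error sites per locus *at* error rate 0.003; scales linearly with the error rate |
| `paralog_divergence` | 0.02 | per-base fixed differences between paralogs |
| `co_assembly_prob` | 0.8 | duplicated pair assembles into one contig |
| `true_snp_rate` | 1.3 | segregating sites per single-copy locus (Poisson) |
| `msv_fraction` | 0.1 | duplicated loci with one segregating paralog |
| populations | 3 × Fst 0.10 + DH group | Balding–Nichols frequencies around a Uniform ancestral draw |
| panel | 47 DH + 20/20/44 diploids | genotyped samples |
| `ts_prob` | 0.74 | transition share among real substitutions (matches the transition excess typical of transcriptome SNPs) |
| `assay_fail_rate` | 0.17 | SNPs injected as failed assays |
| `genotype_error` | 0.005 | per-call miscall probability |

Modelling choices that matter:

* **Pseudo-SNPs are planned clustered errors.** At depth ~12.7, i.i.d.
  errors at 0.3% essentially never put the same wrong base on ≥ 3 reads,
  yet real EST panels are ~a third monomorphic. The generator therefore
  plans pseudo-SNP sites per locus and realises them as a same-base error
  cluster in 3 … 45% of reads (systematic RT/library artifacts behave this
  way); i.i.d. background error is injected on top. The planned-site rate
  scales linearly with `per_base_error_rate` — pseudo-SNP incidence *is*
  sequencing error — so more error means both more error-born candidates
  and more flank-conservation rejections of real ones.
* **One PSV per duplicated locus on the assay panel.** Divergence 0.02 ×
  300 nt gives ~6 fixed differences per duplicated contig; all appear in
  the alignments (and in discovery), but a real validation panel admits
  only a few sites per contig, so the panel generator assays one
  representative PSV per locus. The default assay mixture then lands near
  one third monomorphic, one quarter PSV and one third true + MSV.
* **Miscalls score badly.** Assay miscalls are modelled as cluster
  outliers: they become no-calls or carry GenCall below the 0.25 validity
  cutoff, so the quality threshold absorbs them. This reflects how
  cluster-based callers behave and is what makes the strict (tolerance-0)
  classification rules coherent; raw-intensity miscalls that score *well*
  are not modelled.
* **The assay superposes paralogs.** PSV sites call AB in everyone; MSV
  sites call AB whenever the segregating paralog carries a B allele, else
  AA (never BB); single-copy sites are Mendelian with DH samples
  homozygous (a DH is one haplotype doubled).
* **Co-assembly is all-or-nothing** per pair, read split Binomial(d, ½);
  reads are full-length, no indels, no partial coverage. A
  non-co-assembled duplicated pair contributes only the focal paralog's
  contig (its sibling assembly is outside the assayed coordinate system).
* Consensus is the per-column majority (ties to the alphabetically first
  base). Determinism: all draws come from one generator seeded from
  `seed` (gene set), `[seed, 1]` (alignments) and `[seed, 2]` (panel);
  identical configs give byte-identical written outputs. Scores are
  quantised to 4 decimals so the CSV round-trips exactly.

What the simulator does **not** capture — and hence what passing tests do
not show about real data: overlap-layout assembly and chimeric contigs,
indel polymorphism, partial read coverage (local depth ≡ contig depth),
quality-value-aware error profiles, linked loci/recombination, assay
chemistry beyond the superposition model, and miscalls with confident
scores. Recovery rates on synthetic panels are therefore upper bounds; the
pipeline's value on real data rests on the filters and rules themselves,
which are implemented exactly as specified above.

## Annotation

Homology hits come from tabular (outfmt-6-like) files; the searches are
never executed in-package. Best-hit filtering: e-value ≤ 1e−5, protein ids
collapsed to gene ids (splicing isoforms), minimal e-value per query, ties
by maximal %identity × alignment length, residual cross-gene ties flagged
ambiguous. Effect calling translates the contig hit window ([qstart,
qend], 1-based inclusive; reverse-complemented for negative frames;
standard genetic code; trailing partial codon dropped) under both alleles:
both peptides identical to the reference window ⇒ synonymous; exactly one
amino-acid difference ⇒ non-synonymous (stop-gain counts, recorded as
`*`); N in the SNP codon, a SNP outside the window, or multiple
differences ⇒ unresolved. A SNP whose own best hit names a different gene
than its contig is discordant and excluded from effect calling. Replacing
a second homology round with direct translation comparison is exact for
the perfect-match / one-mismatch decision rule. Multi-HSP queries use the
single best HSP.

## Numerical conventions

Coordinates are 1-based inclusive on disk (BLAST convention), 0-based
half-open in memory. Ts/Tv ratios round half-away-from-zero to 2 decimals;
percentages to 1 decimal; a transversion-free set reports an infinite
ratio. MAF bins are half-open with a closed top bin (MAF cannot exceed
0.5). Genotypes are unordered (AB ≡ BA). The genotype-matrix CSV dialect
(`snp_id,gentrain,allele_a,allele_b,<samples…>` with `CALL:gencall` cells)
is this package's own definition — array-software exports vary, and
readers validate strictly unless a lenient flag is passed.

## Problem sizes in the checks

The acceptance script and test suite run the classification study at
2,000 loci (≈ 3,700 assayed SNPs × 131 samples), brute-force discovery
equivalence at 500 contigs, and effect-calling truth at 500 coding SNPs;
unit tests use 300-locus fixtures. These sizes give per-class counts in
the hundreds-to-thousands, enough that the 0.95 precision/recall and 0.90
MSV-recall checks are meaningful, while a full run stays under a few
seconds on one CPU.
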