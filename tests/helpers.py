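"""Independent oracles used by the test suite.

These re-implement pipeline rules with plain Python loops, deliberately
sharing no code with the package, so they can serve as brute-force
cross-checks.
"""

from __future__ import annotations

from estsnp.io_formats import ContigAlignment


def brute_force_candidates(
    aln: ContigAlignment,
    min_depth: int = 7,
    min_minor: int = 3,
    flank: int = 4,
) -> list[tuple[str, int, str, str, int, int]]:
    """Enumerate every consensus column and re-apply the discovery filters.

    Returns tuples (contig_id, position, major, minor, major_count,
    minor_count) for each passing site.
    """
    cons = aln.consensus
    out = []
    for j in range(len(cons)):
        if cons[j] not in "ACGT":
            continue
        bases = [seq[j] for _, seq in aln.reads if seq[j] in "ACGT"]
        uniq = sorted(set(bases))
        if len(uniq) != 2:
            continue
        c0, c1 = bases.count(uniq[0]), bases.count(uniq[1])
        if c0 + c1 < min_depth:
            continue
        if min(c0, c1) < min_minor:
            continue
        if j - flank < 0 or j + flank >= len(cons):
            continue
        conserved = True
        for lo, hi in ((j - flank, j), (j + 1, j + 1 + flank)):
            eligible = []
            for _, seq in aln.reads:
                w = seq[lo:hi]
                if "N" in w or "-" in w:
                    continue
                eligible.append(w)
            if not eligible or any(w != cons[lo:hi] for w in eligible):
                conserved = False
                break
        if not conserved:
            continue
        if c0 >= c1:  # alphabetical tie-break: uniq is sorted
            major, minor, cmaj, cmin = uniq[0], uniq[1], c0, c1
        else:
            major, minor, cmaj, cmin = uniq[1], uniq[0], c1, c0
        out.append((aln.contig_id, j, major, minor, cmaj, cmin))
    return out


def make_alignment(
    consensus: str, reads: list[str], contig_id: str = "ctg1"
) -> ContigAlignment:
    return ContigAlignment(
        contig_id=contig_id,
        consensus=consensus,
        reads=[(f"r{i + 1}", seq) for i, seq in enumerate(reads)],
    ).validate()
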