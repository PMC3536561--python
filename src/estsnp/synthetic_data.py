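"""Ground-truth-labelled simulator for a partially duplicated gene set.

Salmonid genomes descend from a whole-genome duplication and remain
semi-tetraploid: roughly half of all loci still carry a diverged paralog
pair.  EST-mined SNP panels in such genomes mix four site classes, and
this module generates all of them with known labels:

* ``true_snp``   — a segregating site at a single-copy locus;
* ``pseudo_snp`` — an apparent SNP created by EST sequencing error; the
  genotyped population is monomorphic there;
* ``psv``        — a fixed difference between two co-hybridising
  paralogs (paralogous sequence variant): every individual, including
  fully homozygous doubled haploids (DH), types heterozygous;
* ``msv``        — a multisite variant: one paralog fixed, the other
  segregating, so DH individuals split between a homozygous class and
  heterozygotes and the BB class never appears.

Three differentiated diploid populations (Balding–Nichols draws around
an ancestral frequency) plus a DH panel are genotyped through an assay
model that superimposes both paralogs of a duplicated locus.  EST contig
alignments are emitted with i.i.d. per-base error plus planned clustered
errors realising discoverable pseudo-SNPs, and paralog pairs co-assemble
into a single contig with configurable probability.

Everything is deterministic given the config seed; outputs round-trip
byte-identically through :mod:`estsnp.io_formats`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .io_formats import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    CALL_NC,
    ContigAlignment,
    GenotypeMatrix,
    HomologyHit,
    SampleManifest,
)

__all__ = [
    "SimConfig",
    "SimSite",
    "SimLocus",
    "SimTruth",
    "simulate_gene_set",
    "simulate_est_alignments",
    "simulate_genotype_panel",
    "CodingSnpCase",
    "simulate_coding_snps",
    "CODON_TABLE",
]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": "CT",
    "C": "AG",
    "G": "CT",
    "T": "AG",
}
SITE_CLASSES = ("true_snp", "pseudo_snp", "psv", "msv")


@dataclass
class SimConfig:
    """Study conditions for the simulator (all rates per the defaults below).

    Defaults emulate an EST-mined validation panel in a semi-tetraploid
    genome: half the loci duplicated, mean read depth 12.7 per contig in
    [7, 466], three diploid populations (20/20/44 individuals) plus 47
    doubled haploids, and a site mixture giving roughly a third each of
    monomorphic / duplicated / true assays.
    """

    n_loci: int = 2000
    locus_len: int = 300
    dup_fraction: float = 0.5
    mean_depth: float = 12.7
    depth_min: int = 7
    depth_max: int = 466
    depth_sigma: float = 0.6  # log-scale spread of the truncated log-normal
    per_base_error_rate: float = 0.003
    paralog_divergence: float = 0.02
    co_assembly_prob: float = 0.8
    populations: tuple[tuple[str, float], ...] = (
        ("INRA-SP", 0.10),
        ("INRA-SY", 0.10),
        ("NCCCWA", 0.10),
    )
    dh_fst: float = 0.10
    n_dh: int = 47
    diploids_per_pop: tuple[int, ...] = (20, 20, 44)
    true_snp_rate: float = 1.3  # mean segregating sites per single-copy locus
    # mean clustered-error (pseudo-SNP) sites per locus at the default
    # per-base error rate; scales linearly with per_base_error_rate, since
    # pseudo-SNP incidence is an expression of sequencing error
    pseudo_snp_rate: float = 0.7
    pseudo_rate_ref_error: float = 0.003
    msv_fraction: float = 0.1
    ts_prob: float = 0.74  # transition share among real substitutions
    assay_fail_rate: float = 0.17
    genotype_error: float = 0.005
    edge_margin: int = 10  # planned sites stay this far from contig ends
    seed: int = 0

    DH_LABEL = "DH"

    def validate(self) -> "SimConfig":
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")
        if not self.depth_min < self.mean_depth < self.depth_max:
            raise ValueError("mean_depth must lie strictly inside the depth range")
        for name in (
            "dup_fraction",
            "per_base_error_rate",
            "paralog_divergence",
            "co_assembly_prob",
            "msv_fraction",
            "ts_prob",
            "assay_fail_rate",
            "genotype_error",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        for label, fst in self.populations:
            if not 0 <= fst < 1:
                raise ValueError(f"fst for {label} outside [0,1)")
        if not 0 <= self.dh_fst < 1:
            raise ValueError("dh_fst outside [0,1)")
        if len(self.diploids_per_pop) != len(self.populations):
            raise ValueError("diploids_per_pop must match populations")
        return self

    # --- YAML round-trip -------------------------------------------------
    def to_yaml(self, path: Union[str, Path]) -> None:
        data = dataclasses.asdict(self)
        data["populations"] = [
            {"label": l, "fst": f} for l, f in self.populations
        ]
        data["diploids_per_pop"] = list(self.diploids_per_pop)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "populations" in data:
            data["populations"] = tuple(
                (d["label"], float(d["fst"])) for d in data["populations"]
            )
        if "diploids_per_pop" in data:
            data["diploids_per_pop"] = tuple(data["diploids_per_pop"])
        return cls(**data).validate()

    def group_labels(self) -> list[str]:
        return [self.DH_LABEL] + [label for label, _ in self.populations]

    def group_fst(self) -> dict[str, float]:
        out = {self.DH_LABEL: self.dh_fst}
        out.update({label: fst for label, fst in self.populations})
        return out


@dataclass
class SimSite:
    """One labelled site; ``q`` values are the allele-B frequency."""

    locus_id: str
    pos: int
    klass: str  # one of SITE_CLASSES
    allele_a: str
    allele_b: str
    ancestral_q: float
    pop_q: dict[str, float] = field(default_factory=dict)
    assayed: bool = False

    @property
    def snp_id(self) -> str:
        return f"snp_{self.locus_id}_{self.pos}"


@dataclass
class SimLocus:
    locus_id: str
    duplicated: bool
    co_assembled: bool
    seq: np.ndarray  # paralog 1, uint8 codes 0..3
    seq2: Optional[np.ndarray]  # paralog 2 or None
    sites: list[SimSite] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate_gene_set`."""

    config: SimConfig
    manifest: SampleManifest
    loci: list[SimLocus]
    # per assayed SNP: allele-B dose per sample on the segregating paralog
    # (paralog 1 for true_snp, paralog 2 for msv); absent for psv/pseudo
    doses: dict[str, np.ndarray] = field(default_factory=dict)

    def assayed_sites(self) -> list[SimSite]:
        return [s for locus in self.loci for s in locus.sites if s.assayed]

    def all_sites(self) -> list[SimSite]:
        return [s for locus in self.loci for s in locus.sites]

    def site_class(self, locus_id: str, pos: int) -> str:
        """Truth class of a (contig, position); unplanned sites showing
        variation can only be sequencing-error artifacts (pseudo_snp)."""
        return self._index().get((locus_id, pos), "pseudo_snp")

    def _index(self) -> dict[tuple[str, int], str]:
        if not hasattr(self, "_site_index"):
            self._site_index = {
                (s.locus_id, s.pos): s.klass for s in self.all_sites()
            }
        return self._site_index

    def site_label_table(self) -> pd.DataFrame:
        rows = [
            {
                "contig_id": s.locus_id,
                "pos": s.pos,
                "class": s.klass,
                "assayed": s.assayed,
            }
            for s in self.all_sites()
        ]
        return pd.DataFrame(
            rows, columns=["contig_id", "pos", "class", "assayed"]
        )


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def _mutate(base: str, rng: np.random.Generator, ts_prob: float) -> str:
    """Substitute a base, transition with probability ``ts_prob``."""
    if rng.random() < ts_prob:
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def _balding_nichols(
    q0: float, fst: float, rng: np.random.Generator
) -> float:
    """Population frequency around ancestral q0 at differentiation fst."""
    if fst == 0:
        return q0
    a = q0 * (1 - fst) / fst
    b = (1 - q0) * (1 - fst) / fst
    return float(rng.beta(a, b))


def _build_manifest(config: SimConfig) -> SampleManifest:
    ids, pops, ploidy = [], [], []
    for i in range(config.n_dh):
        ids.append(f"DH_{i + 1:03d}")
        pops.append(config.DH_LABEL)
        ploidy.append("DH")
    for (label, _), n in zip(config.populations, config.diploids_per_pop):
        for i in range(n):
            ids.append(f"{label}_{i + 1:03d}")
            pops.append(label)
            ploidy.append("diploid")
    return SampleManifest(ids, pops, ploidy).validate()


def simulate_gene_set(config: SimConfig) -> SimTruth:
    """Draw loci, duplication status, labelled sites and true genotypes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = _build_manifest(config)
    groups = config.group_labels()
    fsts = config.group_fst()
    sample_group = np.array(manifest.populations)
    is_dh = manifest.is_dh()
    L = config.locus_len
    margin = config.edge_margin
    interior = np.arange(margin, L - margin)

    loci: list[SimLocus] = []
    doses: dict[str, np.ndarray] = {}
    width = len(str(config.n_loci))
    for i in range(config.n_loci):
        locus_id = f"CTG{i + 1:0{width}d}"
        seq = rng.integers(0, 4, L, dtype=np.uint8)
        duplicated = bool(rng.random() < config.dup_fraction)
        co_assembled = duplicated and bool(rng.random() < config.co_assembly_prob)
        seq2 = None
        psv_positions: np.ndarray = np.empty(0, dtype=int)
        if duplicated:
            seq2 = seq.copy()
            div_mask = rng.random(L) < config.paralog_divergence
            psv_positions = np.flatnonzero(div_mask)
            for p in psv_positions:
                seq2[p] = _BASES.index(
                    _mutate(_BASES[seq[p]], rng, config.ts_prob)
                )
        used = set(psv_positions.tolist())
        sites: list[SimSite] = []

        def pick_position() -> Optional[int]:
            free = [p for p in interior if p not in used]
            if not free:
                return None
            p = int(free[rng.integers(len(free))])
            used.add(p)
            return p

        if duplicated:
            # one representative PSV goes on the assay panel; a real panel
            # admits few sites per contig, and fixed differences are dense
            inter_psv = [p for p in psv_positions if margin <= p < L - margin]
            if inter_psv:
                p = int(inter_psv[rng.integers(len(inter_psv))])
                sites.append(
                    SimSite(
                        locus_id,
                        p,
                        "psv",
                        _BASES[seq[p]],
                        _BASES[seq2[p]],
                        1.0,
                        {g: 1.0 for g in groups},
                        assayed=True,
                    )
                )
            for p in psv_positions:
                if not any(s.pos == p for s in sites):
                    sites.append(
                        SimSite(
                            locus_id,
                            int(p),
                            "psv",
                            _BASES[seq[p]],
                            _BASES[seq2[p]],
                            1.0,
                            {g: 1.0 for g in groups},
                            assayed=False,
                        )
                    )
            if rng.random() < config.msv_fraction:
                p = pick_position()
                if p is not None:
                    ref = _BASES[seq[p]]
                    alt = _mutate(ref, rng, config.ts_prob)
                    q0 = float(rng.uniform(0.2, 0.8))
                    pop_q = {g: _balding_nichols(q0, fsts[g], rng) for g in groups}
                    site = SimSite(
                        locus_id, p, "msv", ref, alt, q0, pop_q, assayed=True
                    )
                    sites.append(site)
                    doses[site.snp_id] = _draw_doses(
                        pop_q, sample_group, is_dh, rng
                    )
        else:
            for _ in range(rng.poisson(config.true_snp_rate)):
                p = pick_position()
                if p is None:
                    break
                ref = _BASES[seq[p]]
                alt = _mutate(ref, rng, config.ts_prob)
                q0 = float(rng.uniform(0.1, 0.9))
                pop_q = {g: _balding_nichols(q0, fsts[g], rng) for g in groups}
                site = SimSite(
                    locus_id, p, "true_snp", ref, alt, q0, pop_q, assayed=True
                )
                sites.append(site)
                doses[site.snp_id] = _draw_doses(pop_q, sample_group, is_dh, rng)

        pseudo_rate = config.pseudo_snp_rate * (
            config.per_base_error_rate / config.pseudo_rate_ref_error
        )
        for _ in range(rng.poisson(pseudo_rate)):
            p = pick_position()
            if p is None:
                break
            ref = _BASES[seq[p]]
            alt = _BASES[(seq[p] + 1 + rng.integers(3)) % 4]  # errors unbiased
            sites.append(
                SimSite(
                    locus_id,
                    p,
                    "pseudo_snp",
                    ref,
                    alt,
                    0.0,
                    {g: 0.0 for g in groups},
                    assayed=True,
                )
            )
        sites.sort(key=lambda s: s.pos)
        loci.append(SimLocus(locus_id, duplicated, co_assembled, seq, seq2, sites))
    return SimTruth(config=config, manifest=manifest, loci=loci, doses=doses)


def _draw_doses(
    pop_q: dict[str, float],
    sample_group: np.ndarray,
    is_dh: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele-B dose per sample; DH individuals are doubled single draws."""
    n = len(sample_group)
    q = np.array([pop_q[g] for g in sample_group])
    doses = np.empty(n, dtype=np.int8)
    dh = is_dh
    doses[dh] = 2 * (rng.random(dh.sum()) < q[dh]).astype(np.int8)
    doses[~dh] = rng.binomial(2, q[~dh]).astype(np.int8)
    return doses


# ---------------------------------------------------------------------------
# depth model: log-normal truncated to [depth_min, depth_max], mean matched
# ---------------------------------------------------------------------------


def _truncated_lognormal_mean(mu: float, sigma: float, a: float, b: float) -> float:
    alpha = (np.log(a) - mu) / sigma
    beta = (np.log(b) - mu) / sigma
    mass = norm.cdf(beta) - norm.cdf(alpha)
    return float(
        np.exp(mu + sigma**2 / 2)
        * (norm.cdf(beta - sigma) - norm.cdf(alpha - sigma))
        / mass
    )


def _solve_depth_mu(config: SimConfig) -> float:
    sigma, a, b = config.depth_sigma, config.depth_min, config.depth_max
    target = config.mean_depth

    def f(mu: float) -> float:
        return _truncated_lognormal_mean(mu, sigma, a, b) - target

    return float(brentq(f, np.log(a) - 5 * sigma, np.log(b) + 5 * sigma))


def _draw_depths(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = _solve_depth_mu(config)
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(mu, config.depth_sigma, size=2 * (n - filled)))
        keep = draw[(draw >= config.depth_min) & (draw <= config.depth_max)]
        take = keep[: n - filled]
        out[filled : filled + take.size] = np.rint(take).astype(int)
        filled += take.size
    return np.clip(out, config.depth_min, config.depth_max)


# ---------------------------------------------------------------------------
# EST contig alignments
# ---------------------------------------------------------------------------


def simulate_est_alignments(
    truth: SimTruth, config: Optional[SimConfig] = None
) -> tuple[list[ContigAlignment], pd.DataFrame]:
    """Emit one contig alignment per locus plus the site-label table.

    Reads are full-length haplotype copies of a paralog.  A co-assembled
    duplicated pair interleaves reads from both paralogs (binomial
    half-half split), so fixed inter-paralog differences surface as
    ~50%-frequency "alleles" and a single-paralog segregating site as an
    attenuated-frequency variant.  Planned pseudo-SNP sites receive a
    clustered same-base error in >= 3 reads; independent background
    errors hit every base at ``per_base_error_rate``.  A non-co-assembled
    duplicated pair contributes only the focal paralog's reads (the
    second assembly is not part of the assayed coordinate system).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 1])
    depths = _draw_depths(len(truth.loci), config, rng)
    alignments: list[ContigAlignment] = []
    for locus, d in zip(truth.loci, depths):
        L = config.locus_len
        if locus.co_assembled:
            n2 = int(rng.binomial(d, 0.5))
        else:
            n2 = 0
        n1 = int(d) - n2
        reads = np.empty((d, L), dtype=np.uint8)
        reads[:n1] = locus.seq
        if n2:
            reads[n1:] = locus.seq2
        from_paralog2 = np.zeros(d, dtype=bool)
        from_paralog2[n1:] = True

        for site in locus.sites:
            if site.klass == "true_snp":
                carrier = ~from_paralog2
            elif site.klass == "msv":
                carrier = from_paralog2
            else:
                continue
            if not carrier.any():
                continue
            alt = rng.random(d) < site.ancestral_q
            rows = carrier & alt
            reads[rows, site.pos] = _BASES.index(site.allele_b)

        for site in locus.sites:
            if site.klass != "pseudo_snp":
                continue
            k = int(min(max(3, round(d * rng.uniform(0.20, 0.45))), d // 2))
            rows = rng.choice(d, size=k, replace=False)
            reads[rows, site.pos] = _BASES.index(site.allele_b)

        # background error: shifts drawn unconditionally so that at a fixed
        # seed a larger error rate yields a superset of error positions
        shift = rng.integers(1, 4, size=(d, L), dtype=np.uint8)
        err = rng.random((d, L)) < config.per_base_error_rate
        reads[err] = (reads[err] + shift[err]) % 4

        one_hot = np.stack([(reads == b).sum(axis=0) for b in range(4)])
        consensus = one_hot.argmax(axis=0).astype(np.uint8)  # ties: lowest code
        alignments.append(
            ContigAlignment(
                contig_id=locus.locus_id,
                consensus=_decode(consensus),
                reads=[
                    (f"{locus.locus_id}_r{j + 1}", _decode(reads[j]))
                    for j in range(d)
                ],
            ).validate()
        )
    return alignments, truth.site_label_table()


# ---------------------------------------------------------------------------
# genotyping panel
# ---------------------------------------------------------------------------


def simulate_genotype_panel(
    truth: SimTruth, config: Optional[SimConfig] = None
) -> tuple[GenotypeMatrix, SampleManifest, pd.DataFrame]:
    """Assay every planned site through the paralog-superposition model.

    The assay reads both paralogs of a duplicated locus at once: a PSV
    site types AB in every sample; an MSV site types AB whenever the
    segregating paralog carries at least one B allele, else AA (so BB
    never occurs and DH samples split AA/AB); a single-copy true SNP
    yields Mendelian genotypes with DH samples homozygous; a pseudo-SNP
    site is monomorphic AA.  Scores: valid calls draw GenCall in
    [0.60, 0.99]; miscalls (rate ``genotype_error``) become no-calls or
    carry GenCall below the 0.25 validity cutoff — a deviant intensity
    point sits off its genotype cluster and scores poorly.  A fraction
    ``assay_fail_rate`` of SNPs is injected as failed, either by a low
    GenTrain score or by a no-call rate far above the 20% tolerance.

    Returns the matrix, the manifest and a truth table (snp_id, locus,
    class, alleles, per-population allele-B frequency, injected_fail).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 2])
    manifest = truth.manifest
    n_samples = len(manifest.sample_ids)
    sites = truth.assayed_sites()
    n = len(sites)

    calls = np.empty((n, n_samples), dtype=np.int8)
    for i, site in enumerate(sites):
        if site.klass == "pseudo_snp":
            calls[i] = CALL_AA
        elif site.klass == "psv":
            calls[i] = CALL_AB
        elif site.klass == "true_snp":
            dose = truth.doses[site.snp_id]
            calls[i] = np.where(
                dose == 0, CALL_AA, np.where(dose == 1, CALL_AB, CALL_BB)
            )
        elif site.klass == "msv":
            dose = truth.doses[site.snp_id]
            calls[i] = np.where(dose == 0, CALL_AA, CALL_AB)
        else:  # pragma: no cover - exhaustive over SITE_CLASSES
            raise AssertionError(site.klass)

    gencall = np.round(rng.uniform(0.60, 0.99, size=(n, n_samples)), 4)
    gentrain = np.round(rng.uniform(0.55, 0.95, size=n), 4)

    # per-call miscalls: no-call, or an off-cluster genotype scoring < 0.25
    err = rng.random((n, n_samples)) < config.genotype_error
    to_nc = err & (rng.random((n, n_samples)) < 0.6)
    to_wrong = err & ~to_nc
    wrong = (calls + 1 + rng.integers(0, 2, size=(n, n_samples))) % 3
    calls = np.where(to_wrong, wrong, calls).astype(np.int8)
    gencall = np.where(
        to_wrong, np.round(rng.uniform(0.02, 0.22, size=(n, n_samples)), 4), gencall
    )
    calls[to_nc] = CALL_NC

    # injected assay failures
    fail = rng.random(n) < config.assay_fail_rate
    fail_by_gentrain = rng.random(n) < 0.5
    low_gt = np.round(rng.uniform(0.05, 0.24, size=n), 4)
    gentrain = np.where(fail & fail_by_gentrain, low_gt, gentrain)
    nc_prob = rng.uniform(0.40, 0.65, size=n)
    drop = rng.random((n, n_samples)) < nc_prob[:, None]
    drop &= (fail & ~fail_by_gentrain)[:, None]
    calls[drop] = CALL_NC
    gencall[calls == CALL_NC] = 0.0

    matrix = GenotypeMatrix(
        snp_ids=[s.snp_id for s in sites],
        sample_ids=list(manifest.sample_ids),
        calls=calls,
        gencall=gencall,
        gentrain=gentrain,
        alleles=[(s.allele_a, s.allele_b) for s in sites],
    ).validate()

    groups = config.group_labels()
    truth_rows = []
    locus_by_id = {locus.locus_id: locus for locus in truth.loci}
    for i, site in enumerate(sites):
        row = {
            "snp_id": site.snp_id,
            "locus_id": site.locus_id,
            "pos": site.pos,
            "class": site.klass,
            "allele_a": site.allele_a,
            "allele_b": site.allele_b,
            "duplicated": locus_by_id[site.locus_id].duplicated,
            "ancestral_q": site.ancestral_q,
            "injected_fail": bool(fail[i]),
        }
        for g in groups:
            row[f"q_{g}"] = site.pop_q.get(g, np.nan)
        truth_rows.append(row)
    truth_table = pd.DataFrame(truth_rows)
    return matrix, manifest, truth_table


# ---------------------------------------------------------------------------
# coding-SNP cases for annotation testing
# ---------------------------------------------------------------------------

# literal standard genetic code (kept independent of any translation library
# so annotation's translation route can be cross-checked against it)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CodingSnpCase:
    """A simulated coding SNP with known codon context and truth effect."""

    snp_id: str
    contig_id: str
    contig_seq: str
    snp_pos: int  # 0-based on the contig
    allele_a: str  # contig (reference) allele, in contig orientation
    allele_b: str
    contig_hit: HomologyHit
    snp_hit: HomologyHit
    effect: str  # "synonymous" or "nonsynonymous"
    ref_aa: str
    alt_aa: str
    codon_index: int


def simulate_coding_snps(
    n: int, seed: int = 0, n_codons: int = 20
) -> list[CodingSnpCase]:
    """Generate coding SNPs embedded in contigs with homology hits.

    Each case places a CDS of ``n_codons`` sense codons between random
    UTRs, on the plus or minus strand of the contig, substitutes one base
    of one codon, and records the truth effect from the literal codon
    table.  The accompanying hits carry the CDS window coordinates and
    frame, mimicking a protein-homology search result.
    """
    rng = np.random.default_rng(seed)
    cases: list[CodingSnpCase] = []
    for i in range(n):
        contig_id = f"CDSCTG{i + 1:04d}"
        codons = [
            _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons)
        ]
        cds = "".join(codons)
        utr5 = _decode(rng.integers(0, 4, int(rng.integers(5, 31)), dtype=np.uint8))
        utr3 = _decode(rng.integers(0, 4, int(rng.integers(5, 31)), dtype=np.uint8))
        plus = utr5 + cds + utr3
        ci = int(rng.integers(n_codons))
        cj = int(rng.integers(3))
        ref_codon = codons[ci]
        ref_base = ref_codon[cj]
        alt_base = _BASES[(_BASES.index(ref_base) + 1 + rng.integers(3)) % 4]
        alt_codon = ref_codon[:cj] + alt_base + ref_codon[cj + 1 :]
        ref_aa = CODON_TABLE[ref_codon]
        alt_aa = CODON_TABLE[alt_codon]
        effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"

        minus = bool(rng.random() < 0.5)
        cds_lo = len(utr5)  # 0-based half-open on the plus layout
        cds_hi = cds_lo + 3 * n_codons
        pos_plus = cds_lo + 3 * ci + cj
        if not minus:
            contig_seq = plus
            qstart, qend, frame = cds_lo + 1, cds_hi, 1
            snp_pos = pos_plus
            a_contig, b_contig = ref_base, alt_base
        else:
            contig_seq = _revcomp(plus)
            lo = len(plus) - cds_hi  # 0-based half-open on the contig
            hi = len(plus) - cds_lo
            qstart, qend, frame = hi, lo + 1, -1  # qstart > qend on minus
            snp_pos = len(plus) - 1 - pos_plus
            a_contig = ref_base.translate(_COMPLEMENT)
            b_contig = alt_base.translate(_COMPLEMENT)

        gene = f"gene_{i + 1:04d}"
        protein = f"prot_{i + 1:04d}"
        contig_hit = HomologyHit(
            query_id=contig_id,
            subject_protein_id=protein,
            pct_identity=98.0,
            aln_len=n_codons,
            qstart=qstart,
            qend=qend,
            evalue=1e-30,
            bitscore=200.0,
            frame=frame,
            subject_gene_id=gene,
        )
        snp_id = f"snp_{contig_id}_{snp_pos}"
        snp_hit = dataclasses.replace(contig_hit, query_id=snp_id)
        cases.append(
            CodingSnpCase(
                snp_id=snp_id,
                contig_id=contig_id,
                contig_seq=contig_seq,
                snp_pos=snp_pos,
                allele_a=a_contig,
                allele_b=b_contig,
                contig_hit=contig_hit,
                snp_hit=snp_hit,
                effect=effect,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                codon_index=ci,
            )
        )
    return cases
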