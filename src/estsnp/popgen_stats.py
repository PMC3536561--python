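"""Allele-frequency summaries for biallelic markers.

For a biallelic locus with allele frequencies p and q = 1 - p:

* expected heterozygosity  He  = 2pq              (max 0.5 at p = 0.5)
* polymorphism information content
                           PIC = He - 2 p^2 q^2   (max 0.375 at p = 0.5)
* minor allele frequency   MAF = min(p, q)

Frequencies are obtained by direct count — of sequence depth per base at
the discovery stage, or of genotype calls at the validation stage
(p = (2 n_AA + n_AB) / 2 n_valid).

Substitution types: A<->G and C<->T are transitions, the four remaining
unordered pairs transversions; the Ts/Tv ratio of a marker set is the
transition count over the transversion count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import CALL_AA, CALL_AB, CALL_BB

__all__ = [
    "FreqStats",
    "MutationType",
    "freq_stats",
    "allele_frequencies",
    "maf_bin",
    "MAF_BIN_LABELS",
    "mutation_type",
    "ts_tv_table",
    "TRANSITIONS",
    "TRANSVERSIONS",
    "round_half_away",
    "percentage",
]

TRANSITIONS = ("AG", "CT")
TRANSVERSIONS = ("AC", "AT", "CG", "GT")
ALL_PAIRS = TRANSITIONS + TRANSVERSIONS

MAF_BIN_LABELS = (
    "<0.05",
    "0.05-0.10",
    "0.10-0.20",
    "0.20-0.30",
    "0.30-0.40",
    "0.40-0.50",
)
_MAF_EDGES = (0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass(frozen=True)
class FreqStats:
    """Frequency statistics for one biallelic site."""

    p: float  # frequency of the reference/major allele
    q: float
    maf: float
    he: float
    pic: float

    def __post_init__(self) -> None:
        if not math.isclose(self.p + self.q, 1.0, abs_tol=1e-9):
            raise ValueError("p + q must equal 1")
        if not 0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError("maf must lie in [0, 0.5]")


def freq_stats(p: float) -> FreqStats:
    """Build FreqStats from the frequency of one allele."""
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency {p} outside [0,1]")
    q = 1.0 - p
    he = 2.0 * p * q
    return FreqStats(p=p, q=q, maf=min(p, q), he=he, pic=he - 2.0 * p * p * q * q)


def allele_frequencies(
    calls: Union[np.ndarray, Sequence[int], Mapping[str, int]],
) -> FreqStats:
    """Direct-count allele frequencies from genotype calls at one SNP.

    ``calls`` is either a sequence of call codes (NC entries are ignored)
    or a mapping like ``{"AA": 5, "AB": 4, "BB": 3}``.  ``p`` is the
    frequency of allele A: (2 n_AA + n_AB) / (2 n_valid).
    """
    if isinstance(calls, Mapping):
        n_aa = int(calls.get("AA", 0))
        n_ab = int(calls.get("AB", 0))
        n_bb = int(calls.get("BB", 0))
    else:
        arr = np.asarray(calls)
        n_aa = int((arr == CALL_AA).sum())
        n_ab = int((arr == CALL_AB).sum())
        n_bb = int((arr == CALL_BB).sum())
    n_valid = n_aa + n_ab + n_bb
    if n_valid == 0:
        raise ValueError("no valid calls: allele frequency undefined")
    p = (2 * n_aa + n_ab) / (2 * n_valid)
    return freq_stats(p)


def maf_bin(maf: float) -> str:
    """Assign a minor allele frequency to its half-open summary bin.

    Bins: [0,0.05), [0.05,0.10), [0.10,0.20), [0.20,0.30), [0.30,0.40),
    [0.40,0.50] — the top bin is closed because MAF cannot exceed 0.5.
    """
    if not 0 <= maf <= 0.5 + 1e-12:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    for label, hi in zip(MAF_BIN_LABELS, _MAF_EDGES):
        if maf < hi:
            return label
    return MAF_BIN_LABELS[-1]


@dataclass(frozen=True)
class MutationType:
    """Canonical unordered allele pair plus its substitution class."""

    pair: str  # alphabetically ordered, e.g. "AG"
    klass: str  # "transition" or "transversion"


def mutation_type(allele_a: str, allele_b: str) -> MutationType:
    a, b = allele_a.upper(), allele_b.upper()
    if a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"alleles must be A/C/G/T, got ({allele_a},{allele_b})")
    if a == b:
        raise ValueError("alleles must differ")
    pair = "".join(sorted((a, b)))
    klass = "transition" if pair in TRANSITIONS else "transversion"
    return MutationType(pair=pair, klass=klass)


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (2.865 -> 2.87), unlike bankers' rounding."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percentage(part: float, total: float, ndigits: int = 1) -> float:
    """Share of ``part`` in ``total`` as a percent, rounded half away from zero."""
    if total == 0:
        raise ValueError("total must be non-zero")
    return round_half_away(100.0 * part / total, ndigits)


def ts_tv_table(
    snp_sets: Mapping[str, Union[Iterable[tuple[str, str]], Mapping[str, int]]],
) -> pd.DataFrame:
    """Tabulate substitution-type counts, percentages and Ts/Tv ratios.

    ``snp_sets`` maps a set name to either an iterable of allele pairs or
    a precomputed ``pair -> count`` mapping.  The result has one row per
    canonical pair plus ``TOTAL``, ``pct_transition`` (share of the two
    transition pairs in the set, 1 decimal) and ``ts_tv_ratio`` (2
    decimals, rounded half away from zero; infinite when the set has no
    transversions).  Per-pair percentage columns (``<set> %``) use the
    set's total as denominator.
    """
    columns: dict[str, dict[str, float]] = {}
    for name, pairs in snp_sets.items():
        counts = dict.fromkeys(ALL_PAIRS, 0)
        if isinstance(pairs, Mapping):
            for pair, n in pairs.items():
                key = "".join(sorted(pair.upper()))
                if key not in counts:
                    raise ValueError(f"unknown allele pair {pair!r}")
                counts[key] += int(n)
        else:
            for a, b in pairs:
                counts[mutation_type(a, b).pair] += 1
        total = sum(counts.values())
        ts = sum(counts[p] for p in TRANSITIONS)
        tv = sum(counts[p] for p in TRANSVERSIONS)
        col: dict[str, float] = dict(counts)
        col["TOTAL"] = total
        col["pct_transition"] = percentage(ts, total) if total else float("nan")
        col["ts_tv_ratio"] = (
            round_half_away(ts / tv, 2) if tv else float("inf")
        )
        columns[name] = col
        columns[f"{name} %"] = {
            pair: percentage(counts[pair], total) if total else float("nan")
            for pair in ALL_PAIRS
        }
    index = list(ALL_PAIRS) + ["TOTAL", "pct_transition", "ts_tv_ratio"]
    return pd.DataFrame(columns).reindex(index)
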