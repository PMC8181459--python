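"""Forensic summary statistics for Y-STR data.

Per-locus statistics
    allele frequencies and gene diversity GD = n/(n-1) * (1 - sum p_i^2),
    the Y-chromosome analogue of expected heterozygosity (alleles at one
    locus are the units).

Haplotype-level statistics, all functions of the occurrence spectrum
(the map multiplicity -> number of distinct haplotypes seen that often):
    MP  (match probability)        = sum of squared haplotype frequencies
    HD  (haplotype diversity)      = n/(n-1) * (1 - MP)
    DC  (discrimination capacity)  = distinct haplotypes / sample size
    FUH (unique-haplotype fraction)= singletons / distinct haplotypes

Frequencies are kept as exact rationals internally and converted to float
only on output, so integer identities like DC * n = k hold exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import pandas as pd

from .alleles import AlleleValue
from .errors import (
    EmptyLocusError,
    EmptyTableError,
    InvalidParameterError,
    UndefinedDiversityError,
)
from .haplotypes import HaplotypeTable, haplotype_key

AlleleKey = AlleleValue | tuple[AlleleValue, ...]


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Observed allele frequencies at one locus.

    For multi-copy loci the default unit is the canonical sorted allele
    combination (the single-locus DYS385a/b treatment); ``mode="values"``
    instead counts each allele copy separately.
    """

    locus: str
    freqs: Mapping[AlleleKey, Fraction]
    n: int
    mode: str = "combination"

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class OccurrenceSpectrum:
    """How many distinct haplotypes were seen once, twice, ... m times."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise InvalidParameterError("occurrence spectrum cannot be empty")
        for m, c in self.counts.items():
            if m < 1 or c < 1:
                raise InvalidParameterError(f"invalid spectrum entry {m}:{c}")
        object.__setattr__(self, "counts", dict(sorted(self.counts.items())))

    @property
    def n(self) -> int:
        """Sample size."""
        return sum(m * c for m, c in self.counts.items())

    @property
    def k(self) -> int:
        """Number of distinct haplotypes."""
        return sum(self.counts.values())

    @property
    def singletons(self) -> int:
        return self.counts.get(1, 0)


def allele_frequencies(
    table: HaplotypeTable, locus: str, mode: str = "combination"
) -> AlleleFrequencySet:
    """Allele frequencies at one locus over non-missing calls.

    ``mode="combination"`` (default) treats a multi-copy call as one unit
    (the sorted pair); ``mode="values"`` counts individual allele copies.
    Single-copy loci are identical under both modes.
    """
    if locus not in table.panel.loci:
        raise InvalidParameterError(f"unknown locus {locus!r}")
    if mode not in ("combination", "values"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    counter: Counter[AlleleKey] = Counter()
    for h in table:
        call = h.calls[locus]
        if call.missing:
            continue
        if table.panel.is_multicopy(locus):
            if mode == "combination":
                counter[call.alleles] += 1
            else:
                counter.update(call.alleles)
        else:
            counter[call.alleles[0]] += 1
    n = sum(counter.values())
    if n == 0:
        raise EmptyLocusError(f"all calls missing at {locus}")
    freqs = {a: Fraction(c, n) for a, c in counter.items()}
    return AlleleFrequencySet(locus, freqs, n, mode)


def gene_diversity(freqs: AlleleFrequencySet) -> float:
    """Unbiased gene diversity n/(n-1) * (1 - sum p_i^2)."""
    if freqs.n < 2:
        raise UndefinedDiversityError(f"{freqs.locus}: gene diversity needs n >= 2")
    sum_p2 = sum(p * p for p in freqs.freqs.values())
    return float(Fraction(freqs.n, freqs.n - 1) * (1 - sum_p2))


def haplotype_spectrum(table: HaplotypeTable) -> OccurrenceSpectrum:
    """Occurrence spectrum of complete haplotypes, grouped by canonical key."""
    complete = table.complete_haplotypes()
    if not complete:
        raise EmptyTableError("no haplotype with complete calls")
    key_counts = Counter(haplotype_key(h, table.panel) for h in complete)
    spectrum: Counter[int] = Counter(key_counts.values())
    return OccurrenceSpectrum(dict(spectrum))


def _mp_fraction(s: OccurrenceSpectrum) -> Fraction:
    n = s.n
    return sum((Fraction(c) * m * m for m, c in s.counts.items()), Fraction(0)) / (n * n)


def match_probability(s: OccurrenceSpectrum) -> float:
    """MP = sum over haplotypes of (frequency)^2; chance of a random match."""
    return float(_mp_fraction(s))


def haplotype_diversity(s: OccurrenceSpectrum) -> float:
    """HD = n/(n-1) * (1 - MP)."""
    n = s.n
    if n < 2:
        raise UndefinedDiversityError("haplotype diversity needs n >= 2")
    return float(Fraction(n, n - 1) * (1 - _mp_fraction(s)))


def discrimination_capacity(s: OccurrenceSpectrum) -> float:
    """DC = distinct haplotypes / sample size."""
    return float(Fraction(s.k, s.n))


def unique_haplotype_fraction(s: OccurrenceSpectrum) -> float:
    """FUH = fraction of distinct haplotypes observed exactly once."""
    return float(Fraction(s.singletons, s.k))


@dataclass
class ForensicReport:
    """Per-locus and haplotype-level statistics for every population."""

    per_locus: pd.DataFrame
    summary: pd.DataFrame
    spectra: dict[str, OccurrenceSpectrum] = field(default_factory=dict)


def forensic_report(table: HaplotypeTable) -> ForensicReport:
    """Compute the full forensic characterization, one block per population.

    ``per_locus`` has columns population, locus, n_calls, n_alleles
    (canonical combinations for multi-copy loci), n_allele_values
    (individual values; equals n_alleles at single-copy loci) and
    gene_diversity.  ``summary`` has n, n_complete, k_distinct, fuh, hd,
    dc, mp.  Rows are deterministic and invariant to input row order.
    """
    locus_rows = []
    summary_rows = []
    spectra: dict[str, OccurrenceSpectrum] = {}
    for pop in sorted(table.populations):
        sub = table.subset([pop])
        for locus in table.panel.loci:
            try:
                fs = allele_frequencies(sub, locus)
            except EmptyLocusError:
                continue
            if table.panel.is_multicopy(locus):
                n_values = allele_frequencies(sub, locus, mode="values").n_alleles
            else:
                n_values = fs.n_alleles
            locus_rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "n_calls": fs.n,
                    "n_alleles": fs.n_alleles,
                    "n_allele_values": n_values,
                    "gene_diversity": gene_diversity(fs) if fs.n >= 2 else float("nan"),
                }
            )
        s = haplotype_spectrum(sub)
        spectra[pop] = s
        summary_rows.append(
            {
                "population": pop,
                "n": len(sub),
                "n_complete": s.n,
                "k_distinct": s.k,
                "fuh": unique_haplotype_fraction(s),
                "hd": haplotype_diversity(s) if s.n >= 2 else float("nan"),
                "dc": discrimination_capacity(s),
                "mp": match_probability(s),
            }
        )
    return ForensicReport(
        per_locus=pd.DataFrame(locus_rows),
        summary=pd.DataFrame(summary_rows),
        spectra=spectra,
    )
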