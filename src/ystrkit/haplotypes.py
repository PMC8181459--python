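"""Haplotype data model: locus calls, haplotypes, and haplotype tables.

A haplotype is one male's joint allele profile across the panel loci; the
Y chromosome is inherited as a block, so the whole profile is the unit of
identity.  Multi-copy loci (DYS385a/b) carry an unordered allele multiset
stored sorted ascending, so (17,13) and (13,17) are the same call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alleles import AlleleValue
from .errors import (
    DuplicateSampleError,
    InvalidParameterError,
    MissingDataError,
)
from .panel import PanelConfig


@dataclass(frozen=True)
class LocusCall:
    """Alleles observed at one locus, or a missing flag."""

    locus: str
    alleles: tuple[AlleleValue, ...] = ()
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            if self.alleles:
                raise InvalidParameterError(f"{self.locus}: missing call cannot carry alleles")
            return
        if not self.alleles:
            raise InvalidParameterError(f"{self.locus}: non-missing call needs >=1 allele")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    def __str__(self) -> str:
        if self.missing:
            return ""
        return "-".join(str(a) for a in self.alleles)


@dataclass(frozen=True)
class Haplotype:
    """One sample's calls at every panel locus, with its population label."""

    sample_id: str
    population: str
    calls: Mapping[str, LocusCall]

    def call(self, locus: str) -> LocusCall:
        return self.calls[locus]

    def is_complete(self, panel: PanelConfig) -> bool:
        return all(not self.calls[l].missing for l in panel.loci)


def validate_haplotype(h: Haplotype, panel: PanelConfig) -> None:
    """Check a haplotype conforms to the panel; raise on violation."""
    if set(h.calls) != set(panel.loci):
        extra = set(h.calls) - set(panel.loci)
        lacking = set(panel.loci) - set(h.calls)
        raise InvalidParameterError(
            f"sample {h.sample_id}: calls do not cover the panel "
            f"(extra={sorted(extra)}, missing={sorted(lacking)})"
        )
    for locus in panel.loci:
        call = h.calls[locus]
        if call.missing:
            continue
        if not panel.is_multicopy(locus) and len(call.alleles) != 1:
            raise InvalidParameterError(
                f"sample {h.sample_id}: single-copy locus {locus} has "
                f"{len(call.alleles)} alleles"
            )


@dataclass
class HaplotypeTable:
    """A collection of haplotypes on a shared panel."""

    panel: PanelConfig
    haplotypes: list[Haplotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for h in self.haplotypes:
            if h.sample_id in seen:
                raise DuplicateSampleError(f"duplicate sample_id {h.sample_id!r}")
            seen.add(h.sample_id)
            if not h.population:
                raise InvalidParameterError(f"sample {h.sample_id}: empty population label")
            validate_haplotype(h, self.panel)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def populations(self) -> tuple[str, ...]:
        """Population labels in first-appearance order."""
        out: list[str] = []
        for h in self.haplotypes:
            if h.population not in out:
                out.append(h.population)
        return tuple(out)

    def subset(self, populations: Iterable[str]) -> "HaplotypeTable":
        keep = set(populations)
        return HaplotypeTable(self.panel, [h for h in self.haplotypes if h.population in keep])

    def complete_haplotypes(self) -> list[Haplotype]:
        """Haplotypes with no missing call (the unit for haplotype-level stats)."""
        return [h for h in self.haplotypes if h.is_complete(self.panel)]


def haplotype_key(h: Haplotype, panel: PanelConfig) -> str:
    """Canonical identity string of a haplotype.

    Two haplotypes get the same key iff every locus carries the same allele
    multiset; multi-copy order is ignored (calls are stored sorted) and
    microvariants are distinct alleles (19 != 19.1).  Raises
    :class:`MissingDataError` on any missing call, since identity is
    undefined for partial profiles.
    """
    parts: list[str] = []
    for locus in panel.loci:
        call = h.calls[locus]
        if call.missing:
            raise MissingDataError(f"sample {h.sample_id}: missing call at {locus}")
        parts.append(",".join(str(a) for a in call.alleles))
    return "|".join(parts)


def haplotype_from_alleles(
    sample_id: str,
    population: str,
    alleles: Mapping[str, Iterable[AlleleValue] | AlleleValue | None],
    panel: PanelConfig,
) -> Haplotype:
    """Convenience constructor from a locus -> allele(s) mapping.

    ``None`` marks a missing call; a bare :class:`AlleleValue` is a
    single-copy call.
    """
    calls: dict[str, LocusCall] = {}
    for locus in panel.loci:
        val = alleles[locus]
        if val is None:
            calls[locus] = LocusCall(locus, missing=True)
        elif isinstance(val, AlleleValue):
            calls[locus] = LocusCall(locus, (val,))
        else:
            calls[locus] = LocusCall(locus, tuple(val))
    return Haplotype(sample_id, population, calls)
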