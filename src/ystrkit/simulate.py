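"""Synthetic Y-STR data under the stepwise mutation model (SMM).

Three generators cover everything the statistics need:

* :func:`simulate_smm_populations` — populations diverging from a star
  ancestor.  Each population founder evolves from the ancestral haplotype
  for ``divergence_generations``; each individual then evolves from its
  founder for ``within_generations``.  Per generation and locus a mutation
  occurs with probability ``mu`` and shifts the repeat count by +-1 with
  equal probability, reflecting at allele 1 (a downward step from 1 goes
  to 2), so alleles stay positive.  Under this model the expected squared
  allele-size difference between two populations at divergence t is
  2*t*mu (sum of two independent walks of variance t*mu).

* :func:`generate_spectrum_table` — a table realizing an exact haplotype
  occurrence spectrum, e.g. the published per-population spectra, making
  every haplotype-level statistic checkable without the source genotypes.

* :func:`generate_reference_panel` — haplogroup-labeled references plus
  held-out queries with truth labels: founders pairwise separated by at
  least a requested squared repeat distance, members SMM-perturbed around
  them with Poisson(mu*t) mutations per locus.

All randomness flows from the explicit seed through one
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt
from typing import Sequence

import numpy as np

from .alleles import AlleleValue
from .errors import ConstructiveFailureError, InvalidParameterError
from .forensic import OccurrenceSpectrum
from .haplogroup import ReferencePanel
from .haplotypes import Haplotype, HaplotypeTable, LocusCall
from .panel import DEFAULT_PANEL, PanelConfig


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the star-phylogeny SMM simulation."""

    seed: int
    n_populations: int = 2
    sample_sizes: tuple[int, ...] | int = 50
    panel: PanelConfig = DEFAULT_PANEL
    mu: float = 0.002  # per locus per generation
    divergence_generations: tuple[int, ...] | int = 1000
    within_generations: int = 50
    ancestral_allele: int = 14

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise InvalidParameterError("mu must be in [0, 1]")
        if self.n_populations < 1:
            raise InvalidParameterError("need >=1 population")
        sizes = self.sizes
        if any(s < 1 for s in sizes):
            raise InvalidParameterError("sample sizes must be >= 1")
        if any(t < 0 for t in self.divergences):
            raise InvalidParameterError("divergence must be >= 0")
        if self.within_generations < 0:
            raise InvalidParameterError("within_generations must be >= 0")
        if self.ancestral_allele < 1:
            raise InvalidParameterError("ancestral allele must be >= 1")

    @property
    def sizes(self) -> tuple[int, ...]:
        if isinstance(self.sample_sizes, int):
            return (self.sample_sizes,) * self.n_populations
        if len(self.sample_sizes) != self.n_populations:
            raise InvalidParameterError("one sample size per population required")
        return tuple(self.sample_sizes)

    @property
    def divergences(self) -> tuple[int, ...]:
        if isinstance(self.divergence_generations, int):
            return (self.divergence_generations,) * self.n_populations
        if len(self.divergence_generations) != self.n_populations:
            raise InvalidParameterError("one divergence per population required")
        return tuple(self.divergence_generations)


@dataclass
class SimTruth:
    """Sidecar record of the generating process."""

    config: SimConfig
    ancestor: dict[str, tuple[int, ...]]
    founders: dict[str, dict[str, tuple[int, ...]]] = field(default_factory=dict)


def _apply_mutations(values: np.ndarray, n_mut: np.ndarray, rng: np.random.Generator) -> None:
    """Apply counted +-1 SMM steps in place, reflecting at allele 1."""
    remaining = n_mut.astype(np.int64).copy()
    while True:
        mask = remaining > 0
        if not mask.any():
            break
        steps = rng.choice((-1, 1), size=int(mask.sum()))
        values[mask] += steps
        values[values == 0] = 2  # reflect: a down-step from 1 lands on 2
        remaining[mask] -= 1


def smm_evolve(
    values: np.ndarray, generations: int, mu: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an integer repeat-count array for ``generations`` under SMM.

    Mutation counts are Binomial(generations, mu) per entry — exactly the
    per-generation Bernoulli model, since step order within a lineage does
    not change the distribution of the endpoint.
    """
    out = values.astype(np.int64).copy()
    if generations > 0 and mu > 0:
        n_mut = rng.binomial(generations, mu, size=out.shape)
        _apply_mutations(out, n_mut, rng)
    return out


def _copies_per_locus(panel: PanelConfig) -> list[int]:
    return [2 if panel.is_multicopy(l) else 1 for l in panel.loci]


def _vector_to_haplotype(
    vec: np.ndarray, sample_id: str, population: str, panel: PanelConfig
) -> Haplotype:
    calls: dict[str, LocusCall] = {}
    pos = 0
    for locus, ncopy in zip(panel.loci, _copies_per_locus(panel)):
        alleles = tuple(AlleleValue.from_repeats(int(v)) for v in vec[pos : pos + ncopy])
        calls[locus] = LocusCall(locus, alleles)
        pos += ncopy
    return Haplotype(sample_id, population, calls)


def simulate_smm_populations(cfg: SimConfig) -> tuple[HaplotypeTable, SimTruth]:
    """Simulate diverged populations; returns the table plus a truth record."""
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel
    n_values = sum(_copies_per_locus(panel))
    ancestor = np.full(n_values, cfg.ancestral_allele, dtype=np.int64)
    truth = SimTruth(cfg, ancestor={"ancestor": tuple(int(v) for v in ancestor)})
    haplotypes: list[Haplotype] = []
    for p, (size, div) in enumerate(zip(cfg.sizes, cfg.divergences), start=1):
        pop = f"POP{p}"
        founder = smm_evolve(ancestor, div, cfg.mu, rng)
        truth.founders[pop] = {"founder": tuple(int(v) for v in founder)}
        for i in range(1, size + 1):
            vec = smm_evolve(founder, cfg.within_generations, cfg.mu, rng)
            haplotypes.append(
                _vector_to_haplotype(vec, f"{pop}_S{i:04d}", pop, panel)
            )
    return HaplotypeTable(panel, haplotypes), truth


def generate_spectrum_table(
    spectrum: OccurrenceSpectrum,
    panel: PanelConfig | None = None,
    seed: int = 0,
    population: str = "POP1",
) -> HaplotypeTable:
    """Build a table whose haplotype occurrence spectrum is exactly ``spectrum``.

    Distinct haplotypes are guaranteed distinct by construction: each one
    encodes its index in base-10 digits spread over the single-copy loci
    on top of seeded random base alleles, so up to 10^(#single loci)
    haplotypes are available.  The seed varies the base alleles, not the
    spectrum.
    """
    panel = panel or DEFAULT_PANEL
    rng = np.random.default_rng(seed)
    single = panel.single_copy_loci
    k = spectrum.k
    if k > 10 ** len(single):
        raise ConstructiveFailureError(
            f"cannot encode {k} distinct haplotypes on {len(single)} single-copy loci"
        )
    base = {l: int(rng.integers(10, 18)) for l in panel.loci}
    haplotypes: list[Haplotype] = []
    idx = 0
    sample = 0
    for multiplicity, count in spectrum.counts.items():
        for _ in range(count):
            digits = []
            v = idx
            for _ in single:
                digits.append(v % 10)
                v //= 10
            calls: dict[str, LocusCall] = {}
            digit_iter = iter(digits)
            for locus in panel.loci:
                if panel.is_multicopy(locus):
                    a = AlleleValue.from_repeats(base[locus])
                    calls[locus] = LocusCall(locus, (a, a))
                else:
                    a = AlleleValue.from_repeats(base[locus] + next(digit_iter) - 4)
                    calls[locus] = LocusCall(locus, (a,))
            for _ in range(multiplicity):
                sample += 1
                haplotypes.append(
                    Haplotype(f"S{sample:04d}", population, dict(calls))
                )
            idx += 1
    return HaplotypeTable(panel, haplotypes)


def generate_reference_panel(
    n_haplogroups: int = 6,
    founders_min_separation: float = 8.0,
    within_noise_mu_t: float = 0.05,
    sizes: Sequence[int] | int = 80,
    n_queries: int = 0,
    seed: int = 0,
    panel: PanelConfig | None = None,
) -> tuple[ReferencePanel, list[Haplotype], dict[str, str]]:
    """Labeled reference panel plus held-out queries with truth labels.

    Founder haplotypes are pairwise at least ``founders_min_separation``
    apart in summed squared repeat distance (each founder shifts one
    dedicated single-copy locus by ceil(sqrt(sep/2)) repeats).  Members and
    queries carry Poisson(``within_noise_mu_t``) SMM mutations per locus
    around their founder.  Returns ``(panel, queries, truth_labels)``.
    """
    if founders_min_separation <= 0:
        raise InvalidParameterError("separation must be > 0")
    panel = panel or DEFAULT_PANEL
    single = panel.single_copy_loci
    if n_haplogroups > len(single):
        raise ConstructiveFailureError(
            f"{n_haplogroups} haplogroups need {n_haplogroups} single-copy loci, "
            f"panel has {len(single)}"
        )
    if isinstance(sizes, int):
        sizes = (sizes,) * n_haplogroups
    if len(sizes) != n_haplogroups or any(s < 1 for s in sizes):
        raise InvalidParameterError("one positive size per haplogroup required")
    rng = np.random.default_rng(seed)
    delta = ceil(sqrt(founders_min_separation / 2.0))
    n_values = sum(_copies_per_locus(panel))
    base = rng.integers(12, 18, size=n_values).astype(np.int64)
    # map single-copy locus -> flat index
    flat_idx = {}
    pos = 0
    for locus, ncopy in zip(panel.loci, _copies_per_locus(panel)):
        if ncopy == 1:
            flat_idx[locus] = pos
        pos += ncopy

    def noisy(vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        n_mut = rng.poisson(within_noise_mu_t, size=out.shape)
        _apply_mutations(out, n_mut, rng)
        return out

    founders = []
    hg_names = [f"HG{g + 1:02d}" for g in range(n_haplogroups)]
    for g in range(n_haplogroups):
        f = base.copy()
        f[flat_idx[single[g]]] += delta
        founders.append(f)

    refs: list[Haplotype] = []
    labels: dict[str, str] = {}
    for g, (hg, size) in enumerate(zip(hg_names, sizes)):
        for i in range(1, size + 1):
            sid = f"{hg}_R{i:04d}"
            refs.append(_vector_to_haplotype(noisy(founders[g]), sid, "REF", panel))
            labels[sid] = hg
    queries: list[Haplotype] = []
    truth: dict[str, str] = {}
    for i in range(1, n_queries + 1):
        g = int(rng.integers(0, n_haplogroups))
        sid = f"Q{i:04d}"
        queries.append(_vector_to_haplotype(noisy(founders[g]), sid, "QUERY", panel))
        truth[sid] = hg_names[g]
    ref_panel = ReferencePanel(HaplotypeTable(panel, refs), labels)
    return ref_panel, queries, truth
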