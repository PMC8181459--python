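"""Repeat-count distances, one-level AMOVA, and R_ST with permutation tests.

R_ST is the microsatellite-specific analogue of F_ST: the Phi-statistic of
an analysis of molecular variance whose inter-individual distances are
squared repeat-count differences summed over loci (the distance implied by
the stepwise mutation model).  Sums of squares follow the standard
distance-form AMOVA:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within

with df_among = G-1, df_within = N-G, sigma2_w = MS_within and
sigma2_a = (MS_among - MS_within) / n0, n0 = (N - sum n_g^2 / N) / (G-1).
R_ST = sigma2_a / (sigma2_a + sigma2_w).

Permutation p-values shuffle individuals between the two populations and
use the add-one estimator p = (1 + #{perm >= obs}) / (1 + B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import (
    DegenerateGroupError,
    InvalidParameterError,
    UndefinedRstError,
)
from .haplotypes import Haplotype, HaplotypeTable
from .panel import PanelConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RstResult:
    """AMOVA sums of squares, variance components, R_ST, and optional p."""

    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    rst: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def _locus_values(h: Haplotype, locus: str, microvariants: str) -> tuple[float, ...]:
    call = h.calls[locus]
    if microvariants == "face":
        return tuple(a.numeric for a in call.alleles)
    return tuple(float(a.integer_repeats) for a in call.alleles)


def repeat_distance_sq(
    h1: Haplotype,
    h2: Haplotype,
    panel: PanelConfig,
    microvariants: str = "face",
) -> float:
    """Sum of squared repeat differences over the panel's distance loci.

    Loci missing in either haplotype are skipped (pairwise deletion; the
    skip is counted at DEBUG level).  Multi-copy loci included in
    ``distance_loci`` are compared sorted-elementwise and skipped when the
    copy numbers differ.  ``microvariants`` is ``"face"`` (19.1 - 19 = 0.1,
    default) or ``"truncate"`` (integer repeats only).
    """
    if microvariants not in ("face", "truncate"):
        raise InvalidParameterError(f"unknown microvariant convention {microvariants!r}")
    total = 0.0
    skipped = 0
    for locus in panel.distance_loci:
        c1, c2 = h1.calls[locus], h2.calls[locus]
        if c1.missing or c2.missing:
            skipped += 1
            continue
        v1 = _locus_values(h1, locus, microvariants)
        v2 = _locus_values(h2, locus, microvariants)
        if len(v1) != len(v2):
            skipped += 1
            continue
        total += sum((a - b) ** 2 for a, b in zip(v1, v2))
    if skipped:
        logger.debug(
            "distance %s-%s: %d locus pair(s) skipped by pairwise deletion",
            h1.sample_id,
            h2.sample_id,
            skipped,
        )
    return total


def squared_distance_matrix(
    table: HaplotypeTable, microvariants: str = "face"
) -> np.ndarray:
    """Dense matrix of pairwise squared repeat distances (the AMOVA input)."""
    hs = table.haplotypes
    n = len(hs)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d2[i, j] = d2[j, i] = repeat_distance_sq(hs[i], hs[j], table.panel, microvariants)
    return d2


def _amova_components(d2: np.ndarray, groups: list[np.ndarray]):
    """SS, variance components and Phi from a squared-distance matrix."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        if len(g) > 1:
            sub = d2[np.ix_(g, g)]
            ss_within += sub[np.triu_indices(len(g), 1)].sum() / len(g)
    ss_among = ss_total - ss_within
    n_groups = len(groups)
    df_among = n_groups - 1
    df_within = n - n_groups
    sizes = np.array([len(g) for g in groups], dtype=float)
    n0 = (n - (sizes**2).sum() / n) / df_among
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    denom = var_among + var_within
    phi = var_among / denom if denom != 0 else np.nan
    return ss_among, ss_within, var_among, var_within, phi


def amova_rst(
    table: HaplotypeTable,
    grouping: dict[str, str] | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
    microvariants: str = "face",
) -> RstResult:
    """One-level AMOVA of a table; groups default to population labels.

    ``grouping`` optionally maps sample_id -> group label.  With
    ``n_permutations > 0`` a permutation p-value is attached (individuals
    shuffled across groups, add-one estimator).
    """
    complete = table.complete_haplotypes()
    labels = [
        grouping[h.sample_id] if grouping is not None else h.population for h in complete
    ]
    group_names = sorted(set(labels))
    if len(group_names) < 2:
        raise InvalidParameterError("AMOVA needs at least two groups")
    if len(complete) < 3:
        raise InvalidParameterError("AMOVA needs at least three haplotypes")
    for g in group_names:
        if labels.count(g) < 1:
            raise DegenerateGroupError(f"group {g!r} has no usable haplotype")
    sub = HaplotypeTable(table.panel, complete)
    d2 = squared_distance_matrix(sub, microvariants)
    idx = {g: np.array([i for i, l in enumerate(labels) if l == g]) for g in group_names}
    groups = [idx[g] for g in group_names]
    ss_a, ss_w, var_a, var_w, phi = _amova_components(d2, groups)
    if np.isnan(phi):
        raise UndefinedRstError("both variance components are zero (identical data)")
    p_value = None
    if n_permutations > 0:
        if seed is None:
            raise InvalidParameterError("permutation test needs a seed")
        sizes = [len(g) for g in groups]
        rng = np.random.default_rng(seed)
        p_value = _permutation_p(d2, sizes, phi, n_permutations, rng)
    return RstResult(ss_a, ss_w, var_a, var_w, float(phi), p_value, n_permutations, seed)


def _permutation_p(
    d2: np.ndarray, sizes: list[int], observed: float, n_permutations: int, rng
) -> float:
    n = d2.shape[0]
    bounds = np.cumsum([0, *sizes])
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        groups = [perm[bounds[k] : bounds[k + 1]] for k in range(len(sizes))]
        phi = _amova_components(d2, groups)[4]
        if not np.isnan(phi) and phi >= observed - 1e-12:
            ge += 1
    return (1 + ge) / (1 + n_permutations)


@dataclass
class PairwiseRst:
    """Pairwise R_ST between populations with permutation p-values.

    ``distances`` floors negative estimates at 0 (usable as NJ/MDS input);
    ``raw`` keeps the signed estimates; ``p_values`` is NaN on the diagonal.
    """

    distances: DistanceMatrix
    raw: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    seed: int


def pairwise_rst(
    table: HaplotypeTable,
    n_permutations: int = 9999,
    seed: int | None = None,
    microvariants: str = "face",
) -> PairwiseRst:
    """Population-pairwise R_ST matrix and permutation p-values."""
    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    if seed is None:
        raise InvalidParameterError("pairwise_rst needs a seed")
    pops = sorted(table.populations)
    if len(pops) < 2:
        raise InvalidParameterError("need at least two populations")
    k = len(pops)
    raw = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for a in range(k):
        for b in range(a + 1, k):
            pair = table.subset([pops[a], pops[b]])
            res = amova_rst(
                pair,
                n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31)),
                microvariants=microvariants,
            )
            raw[a, b] = raw[b, a] = res.rst
            pmat[a, b] = pmat[b, a] = res.p_value
    floored = np.maximum(raw, 0.0)
    np.fill_diagonal(floored, 0.0)
    return PairwiseRst(
        distances=DistanceMatrix(floored, pops),
        raw=pd.DataFrame(raw, index=pops, columns=pops),
        p_values=pd.DataFrame(pmat, index=pops, columns=pops),
        n_permutations=n_permutations,
        seed=seed,
    )
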