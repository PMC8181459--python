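"""Ordination of populations from allele-frequency profiles.

Populations are the unit: each row of the frequency matrix is one
population, each column one (locus, allele) pair over the union of
observed alleles, zero-filled where an allele was never seen.  PCA is a
column-centered singular value decomposition of that matrix (no variance
scaling; frequencies already share a scale).  Classical (Torgerson) MDS
double-centers -1/2 d^2 and embeds with the top non-negative eigenpairs;
any negative-eigenvalue mass (possible for non-Euclidean metrics such as
Manhattan) is reported, never silently dropped.

Axis signs follow a fixed convention - the largest-magnitude loading
(PCA) or coordinate (MDS) on each axis is positive - so outputs are
stable across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import InvalidParameterError, PanelMismatchError
from .forensic import AlleleFrequencySet, allele_frequencies
from .haplotypes import HaplotypeTable


@dataclass
class Ordination:
    """Low-dimensional coordinates with per-axis explained shares."""

    coordinates: pd.DataFrame  # populations x axes
    explained: np.ndarray  # variance fractions (PCA) / eigenvalue shares (MDS)
    method: str
    metric: str | None = None
    negative_eigenvalue_mass: float = 0.0


def _allele_sort_key(key) -> tuple:
    if isinstance(key, tuple):
        return tuple(a.tenths for a in key)
    return (key.tenths,)


def _allele_label(key) -> str:
    if isinstance(key, tuple):
        return "-".join(str(a) for a in key)
    return str(key)


def build_frequency_matrix(
    tables: Sequence[HaplotypeTable] | Mapping[str, Mapping[str, AlleleFrequencySet]],
) -> pd.DataFrame:
    """Population x (locus, allele) frequency matrix, zero-filled.

    Accepts haplotype tables (populations are taken from their labels) or
    a prebuilt mapping population -> locus -> AlleleFrequencySet.  Columns
    are ordered by panel locus, then allele ascending.
    """
    freq_sets: dict[str, dict[str, AlleleFrequencySet]] = {}
    if isinstance(tables, Mapping):
        freq_sets = {p: dict(v) for p, v in tables.items()}
        loci_order = None
    else:
        tables = list(tables)
        if not tables:
            raise InvalidParameterError("no input tables")
        panel = tables[0].panel
        for t in tables:
            if t.panel.loci != panel.loci:
                raise PanelMismatchError("tables do not share a locus panel")
        loci_order = panel.loci
        for t in tables:
            for pop in t.populations:
                sub = t.subset([pop])
                freq_sets[pop] = {
                    locus: allele_frequencies(sub, locus) for locus in panel.loci
                }
    pops = sorted(freq_sets)
    if len(pops) < 2:
        raise InvalidParameterError("need at least two populations")
    if loci_order is None:
        loci_order = tuple(
            dict.fromkeys(l for p in pops for l in freq_sets[p])
        )
    columns: list[tuple[str, str]] = []
    col_keys: dict[str, list] = {}
    for locus in loci_order:
        union = set()
        for pop in pops:
            fs = freq_sets[pop].get(locus)
            if fs is not None:
                union.update(fs.freqs)
        ordered = sorted(union, key=_allele_sort_key)
        col_keys[locus] = ordered
        columns.extend((locus, _allele_label(k)) for k in ordered)
    data = np.zeros((len(pops), len(columns)))
    col_index = {c: i for i, c in enumerate(columns)}
    for r, pop in enumerate(pops):
        for locus in loci_order:
            fs = freq_sets[pop].get(locus)
            if fs is None:
                continue
            for key, frac in fs.freqs.items():
                data[r, col_index[(locus, _allele_label(key))]] = float(frac)
    return pd.DataFrame(
        data, index=pops, columns=pd.MultiIndex.from_tuples(columns, names=["locus", "allele"])
    )


def _fix_signs(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip axes so the largest-|reference| entry per axis is positive."""
    for j in range(coords.shape[1]):
        col = reference[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, j] *= -1
            reference[:, j] *= -1
    return coords


def pca(m: pd.DataFrame, k: int = 2) -> Ordination:
    """Principal component analysis of a frequency matrix.

    Columns are centered (not scaled); coordinates are the projections of
    the centered rows; explained fractions are squared singular values
    over the total variance.
    """
    n_rows, n_cols = m.shape
    if n_rows < 2:
        raise InvalidParameterError("PCA needs at least two rows")
    if not 1 <= k <= min(n_rows - 1, n_cols):
        raise InvalidParameterError(f"axis count k={k} out of range")
    x = m.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T.copy()
    coords = _fix_signs(coords, loadings)
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=m.index, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained=explained,
        method="pca",
    )


def population_distance(m: pd.DataFrame, metric: str = "euclidean") -> DistanceMatrix:
    """L2 or L1 distances between frequency-matrix rows."""
    if metric not in ("euclidean", "manhattan"):
        raise InvalidParameterError(f"unknown metric {metric!r}")
    if m.shape[0] < 2:
        raise InvalidParameterError("need at least two rows")
    scipy_metric = "cityblock" if metric == "manhattan" else "euclidean"
    d = squareform(pdist(m.to_numpy(dtype=float), metric=scipy_metric))
    return DistanceMatrix(d, list(m.index))


def classical_mds(d: DistanceMatrix, k: int = 2) -> Ordination:
    """Torgerson principal-coordinates embedding of a distance matrix.

    Double-centers -1/2 d^2, keeps the top-k non-negative eigenpairs
    (axes beyond the positive spectrum are zero), and reports the total
    magnitude of any negative eigenvalues.
    """
    n = len(d.ids)
    if not 1 <= k <= n - 1:
        raise InvalidParameterError(f"axis count k={k} out of range")
    d2 = d.data.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    neg_mass = float(np.abs(eigvals[eigvals < 0]).sum())
    pos = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(pos)
    coords = _fix_signs(coords, coords.copy())
    pos_total = float(eigvals[eigvals > 0].sum())
    explained = pos / pos_total if pos_total > 0 else np.zeros(k)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"Dim{i + 1}" for i in range(k)]
        ),
        explained=explained,
        method="classical_mds",
        negative_eigenvalue_mass=neg_mass,
    )


def mds_from_frequencies(
    m: pd.DataFrame, metric: str = "euclidean", k: int = 2
) -> Ordination:
    """Convenience: classical MDS of row distances of a frequency matrix."""
    ord_ = classical_mds(population_distance(m, metric), k)
    ord_.metric = metric
    return ord_
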