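"""Y-haplogroup prediction by nearest-neighbor matching.

A haplogroup is a Y-chromosome lineage defined by SNP markers (O2-M122,
O1a-M119, ...).  Because Y-STR haplotypes are strongly associated with
haplogroup background, a query STR profile can be assigned the haplogroup
of its closest matches in a labeled reference panel.  The classifier here
is k-nearest neighbors on the squared repeat-count distance: the k
closest references vote; the majority label wins with confidence = vote
fraction; below ``min_confidence`` the query is reported "unassigned".
Ties are broken by smaller mean distance, then lexicographic label, so
predictions are deterministic and independent of panel row order.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .amova import repeat_distance_sq
from .errors import EmptyPanelError, InvalidParameterError
from .haplotypes import Haplotype, HaplotypeTable

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReferencePanel:
    """Haplogroup-labeled reference haplotypes."""

    table: HaplotypeTable
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        unlabeled = [h.sample_id for h in self.table if h.sample_id not in self.labels]
        if unlabeled:
            raise InvalidParameterError(f"unlabeled reference sample(s): {unlabeled[:5]}")

    @property
    def haplogroups(self) -> tuple[str, ...]:
        return tuple(sorted({self.labels[h.sample_id] for h in self.table}))


@dataclass(frozen=True)
class Prediction:
    sample_id: str
    haplogroup: str
    confidence: float
    mean_distance: float


def predict_haplogroup(
    query: Haplotype,
    panel: ReferencePanel,
    k: int = 5,
    min_confidence: float = 0.6,
) -> Prediction:
    """Classify one query haplotype against the reference panel."""
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    refs = sorted(panel.table.haplotypes, key=lambda h: h.sample_id)
    if not refs:
        raise EmptyPanelError("reference panel is empty")
    pcfg = panel.table.panel
    scored = sorted(
        ((repeat_distance_sq(query, ref, pcfg), ref.sample_id) for ref in refs),
        key=lambda t: (t[0], t[1]),
    )[: min(k, len(refs))]
    votes: dict[str, list[float]] = defaultdict(list)
    for dist, sid in scored:
        votes[panel.labels[sid]].append(dist)
    # most votes; ties -> smaller mean distance; then lexicographic label
    best = min(
        votes.items(), key=lambda kv: (-len(kv[1]), sum(kv[1]) / len(kv[1]), kv[0])
    )
    label, dists = best
    confidence = len(dists) / len(scored)
    mean_dist = sum(dists) / len(dists)
    if confidence < min_confidence:
        label = UNASSIGNED
    return Prediction(query.sample_id, label, confidence, mean_dist)


def predict_table(
    queries: HaplotypeTable | Iterable[Haplotype],
    panel: ReferencePanel,
    k: int = 5,
    min_confidence: float = 0.6,
) -> list[Prediction]:
    return [predict_haplogroup(q, panel, k, min_confidence) for q in queries]


@dataclass(frozen=True)
class HaplogroupSpectrum:
    """Predicted haplogroup percentages over assigned samples."""

    percentages: Mapping[str, float]  # sums to 100 over assigned
    n_assigned: int
    n_unassigned: int

    @property
    def assignment_rate(self) -> float:
        total = self.n_assigned + self.n_unassigned
        return 100.0 * self.n_assigned / total if total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.percentages.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["haplogroup", "percent"])


def haplogroup_spectrum(predictions: Iterable[Prediction]) -> HaplogroupSpectrum:
    """Percentage breakdown of predicted haplogroups.

    Percentages are over assigned samples only and sum to 100; the
    unassigned count is reported separately.
    """
    preds = list(predictions)
    if not preds:
        raise InvalidParameterError("no predictions given")
    assigned = [p for p in preds if p.haplogroup != UNASSIGNED]
    counts: dict[str, int] = defaultdict(int)
    for p in assigned:
        counts[p.haplogroup] += 1
    n = len(assigned)
    percentages = {hg: 100.0 * c / n for hg, c in counts.items()} if n else {}
    return HaplogroupSpectrum(percentages, n, len(preds) - n)
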