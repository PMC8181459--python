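"""Locus-panel configuration.

A panel names the ordered Y-STR loci of a typing kit, flags which of them
are multi-copy (reported as an unordered allele multiset in one column),
and which enter repeat-count distances.  The default is the PowerPlex Y23
panel: the 17 Yfiler Y-STRs (DYS385a/b reported in a single column) plus
six further discriminating loci.

Panels can be loaded from a small TOML file with three keys::

    loci = ["DYS19", "DYS385a/b", ...]   # required, ordered
    multicopy = ["DYS385a/b"]            # optional, default []
    distance = ["DYS19", ...]            # optional, default loci - multicopy
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidParameterError

#: Column loci of the PowerPlex Y23 system, Yfiler core first.  DYS385a/b
#: is one column holding an unordered pair, so 22 columns carry 23 Y-STRs.
POWERPLEX_Y23_LOCI: tuple[str, ...] = (
    "DYS19",
    "DYS385a/b",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "Y_GATA_H4",
    "DYS481",
    "DYS533",
    "DYS549",
    "DYS570",
    "DYS576",
    "DYS643",
)


@dataclass(frozen=True)
class PanelConfig:
    """Ordered loci plus the multi-copy and distance-locus subsets."""

    loci: tuple[str, ...] = POWERPLEX_Y23_LOCI
    multicopy_loci: frozenset[str] = frozenset({"DYS385a/b"})
    distance_loci: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise InvalidParameterError("panel loci must be unique")
        if not set(self.multicopy_loci) <= set(self.loci):
            raise InvalidParameterError("multicopy_loci must be a subset of loci")
        if self.distance_loci is None:
            object.__setattr__(
                self,
                "distance_loci",
                tuple(l for l in self.loci if l not in self.multicopy_loci),
            )
        if not set(self.distance_loci) <= set(self.loci):
            raise InvalidParameterError("distance_loci must be a subset of loci")

    def is_multicopy(self, locus: str) -> bool:
        return locus in self.multicopy_loci

    @property
    def single_copy_loci(self) -> tuple[str, ...]:
        return tuple(l for l in self.loci if l not in self.multicopy_loci)

    def with_distance_loci(self, loci: tuple[str, ...]) -> "PanelConfig":
        return PanelConfig(self.loci, self.multicopy_loci, tuple(loci))

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "loci" not in raw:
            raise InvalidParameterError(f"panel file {path} lacks a 'loci' key")
        loci = tuple(raw["loci"])
        multicopy = frozenset(raw.get("multicopy", ()))
        distance = tuple(raw["distance"]) if "distance" in raw else None
        return cls(loci, multicopy, distance)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        def toml_list(items) -> str:
            return "[" + ", ".join(f'"{i}"' for i in items) + "]"

        text = (
            f"loci = {toml_list(self.loci)}\n"
            f"multicopy = {toml_list(sorted(self.multicopy_loci))}\n"
            f"distance = {toml_list(self.distance_loci)}\n"
        )
        Path(path).write_text(text)


DEFAULT_PANEL = PanelConfig()
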