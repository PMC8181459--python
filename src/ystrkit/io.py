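"""Reading and writing haplotype tables and distance matrices.

Haplotype tables are flat delimited text in the style of YHRD submission
sheets: a header row with ``SampleID``, ``Population`` and one column per
panel locus (any column order), one row per male.  Multi-copy loci such as
DYS385a/b hold hyphen- or comma-joined values ("13-17").  Missing calls
are blank or "0".  The delimiter (tab or comma) is sniffed from the header.

Distance matrices are read/written either as square tab-delimited text
with header labels (scikit-bio's lsmat format) or as square PHYLIP.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import IO, Iterable

import numpy as np
from skbio import DistanceMatrix

from .alleles import AlleleValue
from .errors import (
    AlleleParseError,
    InvalidMatrixError,
    TableFormatError,
)
from .haplotypes import Haplotype, HaplotypeTable, LocusCall
from .panel import DEFAULT_PANEL, PanelConfig

MISSING_TOKENS = {"", "0"}


def _open_text(source: str | Path | IO[str], mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, newline=""), True
    return source, False


def _parse_cell(token: str, locus: str, row: int) -> LocusCall:
    token = token.strip()
    if token in MISSING_TOKENS:
        return LocusCall(locus, missing=True)
    sep = "-" if "-" in token else ","
    try:
        alleles = tuple(AlleleValue.parse(t) for t in token.split(sep))
    except AlleleParseError as exc:
        raise AlleleParseError(f"row {row}, locus {locus}: {exc}") from exc
    return LocusCall(locus, alleles)


def read_haplotype_table(
    source: str | Path | IO[str], panel: PanelConfig | None = None
) -> HaplotypeTable:
    """Parse a delimited haplotype table.

    Raises :class:`TableFormatError` for header problems,
    :class:`AlleleParseError` for bad tokens, and
    :class:`DuplicateSampleError` for repeated SampleIDs.
    """
    panel = panel or DEFAULT_PANEL
    fh, owned = _open_text(source)
    try:
        first = fh.readline()
        if not first:
            raise TableFormatError("empty input: no header row")
        delim = "\t" if "\t" in first else ","
        reader = csv.reader(_chain_lines(first, fh), delimiter=delim)
        header = [c.strip() for c in next(reader)]
        required = ["SampleID", "Population", *panel.loci]
        lacking = [c for c in required if c not in header]
        if lacking:
            raise TableFormatError(f"missing column(s): {lacking}")
        unknown = [c for c in header if c not in required]
        if unknown:
            raise TableFormatError(f"unknown column(s): {unknown}")
        idx = {c: header.index(c) for c in required}
        haplotypes: list[Haplotype] = []
        for rownum, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise TableFormatError(f"row {rownum}: expected {len(header)} fields, got {len(row)}")
            calls = {
                locus: _parse_cell(row[idx[locus]], locus, rownum) for locus in panel.loci
            }
            haplotypes.append(
                Haplotype(row[idx["SampleID"]].strip(), row[idx["Population"]].strip(), calls)
            )
        return HaplotypeTable(panel, haplotypes)
    finally:
        if owned:
            fh.close()


def _chain_lines(first: str, rest: IO[str]) -> Iterable[str]:
    yield first
    yield from rest


def write_haplotype_table(table: HaplotypeTable, sink: str | Path | IO[str]) -> None:
    """Write a table as tab-delimited text; an exact inverse of reading.

    Multi-copy calls are hyphen-joined; missing calls are blank; the
    designation strings are exact, so 19.1 survives the round trip.
    """
    fh, owned = _open_text(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["SampleID", "Population", *table.panel.loci])
        for h in table.haplotypes:
            writer.writerow(
                [h.sample_id, h.population, *(str(h.calls[l]) for l in table.panel.loci)]
            )
    finally:
        if owned:
            fh.close()


def read_reference_panel(
    source: str | Path | IO[str], panel: PanelConfig | None = None
):
    """Read a haplotype table that carries an extra ``Haplogroup`` column.

    Returns a :class:`ystrkit.haplogroup.ReferencePanel`.
    """
    from .haplogroup import ReferencePanel  # local import: avoid cycle

    panel = panel or DEFAULT_PANEL
    fh, owned = _open_text(source)
    try:
        text = fh.read()
    finally:
        if owned:
            fh.close()
    first = text.splitlines()[0] if text else ""
    delim = "\t" if "\t" in first else ","
    rows = list(csv.reader(_io.StringIO(text), delimiter=delim))
    if not rows:
        raise TableFormatError("empty input: no header row")
    header = [c.strip() for c in rows[0]]
    if "Haplogroup" not in header:
        raise TableFormatError("reference panel needs a 'Haplogroup' column")
    hg_idx = header.index("Haplogroup")
    labels: dict[str, str] = {}
    stripped_rows = []
    for row in rows[1:]:
        if not any(c.strip() for c in row):
            continue
        stripped_rows.append([c for i, c in enumerate(row) if i != hg_idx])
    table_text = _io.StringIO()
    writer = csv.writer(table_text, delimiter=delim, lineterminator="\n")
    writer.writerow([c for i, c in enumerate(header) if i != hg_idx])
    writer.writerows(stripped_rows)
    table = read_haplotype_table(_io.StringIO(table_text.getvalue()), panel)
    sid_idx = header.index("SampleID")
    for row in rows[1:]:
        if any(c.strip() for c in row):
            labels[row[sid_idx].strip()] = row[hg_idx].strip()
    return ReferencePanel(table, labels)


def write_reference_panel(ref, sink: str | Path | IO[str]) -> None:
    fh, owned = _open_text(sink, "w")
    try:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["SampleID", "Population", "Haplogroup", *ref.table.panel.loci])
        for h in ref.table.haplotypes:
            writer.writerow(
                [
                    h.sample_id,
                    h.population,
                    ref.labels[h.sample_id],
                    *(str(h.calls[l]) for l in ref.table.panel.loci),
                ]
            )
    finally:
        if owned:
            fh.close()


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(dm: DistanceMatrix, sink: str | Path | IO[str]) -> None:
    """Square tab-delimited matrix with header labels (lsmat)."""
    fh, owned = _open_text(sink, "w")
    try:
        dm.write(fh, format="lsmat")
    finally:
        if owned:
            fh.close()


def read_distance_matrix(source: str | Path | IO[str]) -> DistanceMatrix:
    fh, owned = _open_text(source)
    try:
        try:
            return DistanceMatrix.read(fh, format="lsmat")
        except Exception as exc:  # skbio raises its own hierarchy
            raise InvalidMatrixError(str(exc)) from exc
    finally:
        if owned:
            fh.close()


def write_phylip_matrix(dm: DistanceMatrix, sink: str | Path | IO[str]) -> None:
    """Square PHYLIP distance format: count line, then label + row."""
    fh, owned = _open_text(sink, "w")
    try:
        fh.write(f"{len(dm.ids)}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
    finally:
        if owned:
            fh.close()


def read_phylip_matrix(source: str | Path | IO[str]) -> DistanceMatrix:
    fh, owned = _open_text(source)
    try:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    finally:
        if owned:
            fh.close()
    if not lines:
        raise InvalidMatrixError("empty PHYLIP matrix")
    try:
        n = int(lines[0].split()[0])
    except ValueError as exc:
        raise InvalidMatrixError("first PHYLIP line must be the taxon count") from exc
    if len(lines) - 1 != n:
        raise InvalidMatrixError(f"expected {n} rows, found {len(lines) - 1}")
    labels, data = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        data.append([float(v) for v in parts[1:]])
    arr = np.asarray(data, dtype=float)
    if arr.shape != (n, n):
        raise InvalidMatrixError("PHYLIP matrix is not square")
    if not np.allclose(arr, arr.T):
        raise InvalidMatrixError("PHYLIP matrix is not symmetric")
    return DistanceMatrix(arr, labels)
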