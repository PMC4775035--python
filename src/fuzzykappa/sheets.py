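"""Readers and writers for the coding-sheet layouts.

Three delimited-text layouts, all spreadsheet exports in practice:

* ``one_to_one`` — unit id plus one integer level code per first-tier
  dimension (0 = not present);
* ``one_to_many`` — unit id plus ranked category codes ``Cat1..CatK``,
  trailing blanks allowed;
* ``membership`` — unit id plus one numeric grade column per category.

Readers reject malformed input (never coerce) and report line numbers.
The delimiter defaults to comma with tab auto-detection.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .coding import (
    CategorySet,
    CodingError,
    CrispSheet,
    DimensionScheme,
    MembershipTable,
    RankedSheet,
    membership_table,
)

__all__ = [
    "SheetFormat",
    "SheetParseError",
    "read_crisp_sheet",
    "write_crisp_sheet",
    "read_ranked_sheet",
    "write_ranked_sheet",
    "read_membership_sheet",
    "write_membership_sheet",
    "read_categories",
    "write_categories",
    "read_scheme",
    "write_scheme",
    "write_report",
]


class SheetParseError(CodingError):
    """Malformed sheet content; the message carries the line number."""


@dataclass(frozen=True)
class SheetFormat:
    """Layout and dialect of a delimited coding sheet.

    ``delimiter=None`` sniffs between tab and comma from the first line.
    ``not_present`` is the integer code of the "not present" level in
    one-to-one sheets. ``max_ranked`` caps the ``Cat1..CatK`` columns
    written for one-to-many sheets.
    """

    layout: str = "one_to_many"
    delimiter: str | None = None
    header: bool = True
    not_present: int = 0
    max_ranked: int = 4

    def __post_init__(self):
        if self.layout not in ("one_to_one", "one_to_many", "membership"):
            raise CodingError(f"unknown sheet layout {self.layout!r}")


def _sniff(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if "\t" in first_line else ","


def _rows(path: str | Path, fmt: SheetFormat) -> Iterator[tuple[int, list[str]]]:
    text = Path(path).read_text()
    if not text.strip():
        raise SheetParseError(f"{path}: file is empty")
    delim = _sniff(text.splitlines()[0], fmt.delimiter)
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    for lineno, row in enumerate(reader, start=1):
        if not any(cell.strip() for cell in row):
            continue  # blank line
        yield lineno, [cell.strip() for cell in row]


def _split_header(rows, fmt: SheetFormat, path):
    rows = list(rows)
    if fmt.header:
        if not rows:
            raise SheetParseError(f"{path}: no header line")
        header = rows[0][1]
        rows = rows[1:]
    else:
        header = None
    if not rows:
        raise SheetParseError(f"{path}: no data lines")
    return header, rows


def read_crisp_sheet(path: str | Path, scheme: DimensionScheme,
                     fmt: SheetFormat = SheetFormat("one_to_one")) -> CrispSheet:
    """Parse a one-to-one two-tier sheet and validate codes against the scheme."""
    header, rows = _split_header(_rows(path, fmt), fmt, path)
    if header is not None:
        names = tuple(header[1:])
        if names != scheme.names:
            raise SheetParseError(
                f"{path}: header dimensions {names} do not match "
                f"scheme {scheme.names}")
    d = scheme.n_dimensions
    ids: list[str] = []
    codes: list[list[int]] = []
    seen: set[str] = set()
    for lineno, row in rows:
        if len(row) != d + 1:
            raise SheetParseError(
                f"{path}:{lineno}: expected {d + 1} columns, got {len(row)}")
        uid = row[0]
        if uid in seen:
            raise SheetParseError(f"{path}:{lineno}: duplicate unit id {uid!r}")
        seen.add(uid)
        line_codes = []
        for col, cell in enumerate(row[1:]):
            try:
                code = int(cell)
            except ValueError:
                raise SheetParseError(
                    f"{path}:{lineno}: non-integer code {cell!r} "
                    f"in dimension {scheme.names[col]!r}") from None
            if not 0 <= code < scheme.n_levels(col):
                raise SheetParseError(
                    f"{path}:{lineno}: code {code} outside "
                    f"0..{scheme.n_levels(col) - 1} "
                    f"for dimension {scheme.names[col]!r}")
            line_codes.append(code)
        ids.append(uid)
        codes.append(line_codes)
    return CrispSheet(ids, np.asarray(codes, dtype=int))


def write_crisp_sheet(path: str | Path, sheet: CrispSheet,
                      scheme: DimensionScheme,
                      fmt: SheetFormat = SheetFormat("one_to_one")) -> None:
    delim = fmt.delimiter or ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if fmt.header:
            writer.writerow(("ID",) + scheme.names)
        for uid, row in zip(sheet.unit_ids, sheet.codes):
            writer.writerow([uid, *map(int, row)])


def read_ranked_sheet(path: str | Path, categories: CategorySet,
                      fmt: SheetFormat = SheetFormat("one_to_many")
                      ) -> RankedSheet:
    """Parse a one-to-many sheet; non-empty cell order is rank order."""
    _, rows = _split_header(_rows(path, fmt), fmt, path)
    ids: list[str] = []
    sels: list[tuple[str, ...]] = []
    seen: set[str] = set()
    for lineno, row in rows:
        uid = row[0]
        if uid in seen:
            raise SheetParseError(f"{path}:{lineno}: duplicate unit id {uid!r}")
        seen.add(uid)
        cells = row[1:]
        while cells and not cells[-1]:
            cells.pop()  # trailing blanks
        if not cells:
            raise SheetParseError(
                f"{path}:{lineno}: unit {uid!r} has no selections")
        labels: list[str] = []
        for rank, cell in enumerate(cells, start=1):
            if not cell:
                raise SheetParseError(
                    f"{path}:{lineno}: blank cell at rank {rank} before a "
                    "non-blank one")
            if cell not in categories:
                raise SheetParseError(
                    f"{path}:{lineno}: unknown category code {cell!r}")
            if cell in labels:
                raise SheetParseError(
                    f"{path}:{lineno}: category {cell!r} repeated")
            labels.append(cell)
        ids.append(uid)
        sels.append(tuple(labels))
    return RankedSheet(ids, sels)


def write_ranked_sheet(path: str | Path, sheet: RankedSheet,
                       fmt: SheetFormat = SheetFormat("one_to_many")) -> None:
    delim = fmt.delimiter or ","
    k = max(fmt.max_ranked, sheet.max_selections)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if fmt.header:
            writer.writerow(["ID"] + [f"Cat{i + 1}" for i in range(k)])
        for uid, row in zip(sheet.unit_ids, sheet.selections):
            writer.writerow([uid, *row] + [""] * (k - len(row)))


def read_membership_sheet(path: str | Path,
                          categories: CategorySet | None = None,
                          fmt: SheetFormat = SheetFormat("membership")
                          ) -> MembershipTable:
    """Parse pre-weighted membership grades; header names the categories.

    Row sums are not enforced (a warning is recorded when a row exceeds
    1), matching the pass-through builder.
    """
    header, rows = _split_header(_rows(path, fmt), fmt, path)
    if header is not None:
        file_cats = CategorySet(header[1:])
        if categories is None:
            categories = file_cats
        elif categories != file_cats:
            raise SheetParseError(
                f"{path}: header categories do not match the supplied set")
    elif categories is None:
        raise SheetParseError(
            f"{path}: a category set is required when the sheet has no header")
    nc = len(categories)
    ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for lineno, row in rows:
        if len(row) != nc + 1:
            raise SheetParseError(
                f"{path}:{lineno}: expected {nc + 1} columns, got {len(row)}")
        uid = row[0]
        if uid in seen:
            raise SheetParseError(f"{path}:{lineno}: duplicate unit id {uid!r}")
        seen.add(uid)
        try:
            grades = [float(cell) for cell in row[1:]]
        except ValueError:
            raise SheetParseError(
                f"{path}:{lineno}: non-numeric membership grade") from None
        if any(g < 0 or g > 1 for g in grades):
            raise SheetParseError(
                f"{path}:{lineno}: membership grade outside [0, 1]")
        ids.append(uid)
        values.append(grades)
    return membership_table(ids, categories, np.asarray(values))


def write_membership_sheet(path: str | Path, table: MembershipTable,
                           fmt: SheetFormat = SheetFormat("membership")
                           ) -> None:
    delim = fmt.delimiter or ","
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if fmt.header:
            writer.writerow(("ID",) + table.categories.labels)
        for uid, row in zip(table.unit_ids, table.values):
            writer.writerow([uid, *(format(v, ".17g") for v in row)])


def read_categories(path: str | Path) -> CategorySet:
    """Category list file: one case-sensitive label per line."""
    labels = [line.strip() for line in Path(path).read_text().splitlines()
              if line.strip()]
    if not labels:
        raise SheetParseError(f"{path}: no category labels found")
    return CategorySet(labels)


def write_categories(path: str | Path, categories: CategorySet) -> None:
    Path(path).write_text("\n".join(categories.labels) + "\n")


def read_scheme(path: str | Path) -> DimensionScheme:
    """Two-tier scheme from YAML: list of {name, levels | n_levels}."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list) or not doc:
        raise SheetParseError(
            f"{path}: scheme file must hold a non-empty list of dimensions")
    dims = []
    for entry in doc:
        if not isinstance(entry, dict) or "name" not in entry:
            raise SheetParseError(f"{path}: each dimension needs a 'name'")
        name = str(entry["name"])
        if "levels" in entry:
            levels = [str(v) for v in entry["levels"]]
        elif "n_levels" in entry:
            levels = [str(i) for i in range(int(entry["n_levels"]))]
        else:
            raise SheetParseError(
                f"{path}: dimension {name!r} needs 'levels' or 'n_levels'")
        dims.append((name, levels))
    return DimensionScheme(dims)


def write_scheme(path: str | Path, scheme: DimensionScheme) -> None:
    doc = [{"name": name, "levels": list(levels)}
           for name, levels in scheme.dimensions]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def write_report(report: dict, path: str | Path, fmt: str = "yaml") -> None:
    """Serialize a structured analysis report as YAML or JSON."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(report, indent=2) + "\n")
    elif fmt == "yaml":
        path.write_text(yaml.safe_dump(report, sort_keys=False))
    else:
        raise CodingError(f"unknown report format {fmt!r}")
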