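"""Readers and writers for the flat tab-separated exchange formats.

All inputs are plain TSV with ``#`` comment lines and blank lines ignored.
Identifiers are treated as opaque strings; no organism-specific parsing is
performed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator


class ParseError(ValueError):
    """Raised for a malformed input line; carries the file and line number."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _rows(path: str | Path, min_cols: int) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(path, line_no, f"expected >= {min_cols} tab-separated fields, got {len(fields)}")
            yield line_no, fields


def read_pair_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column undirected pair list (PPI edges or DDI pairs)."""
    pairs = []
    for line_no, fields in _rows(path, 2):
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(path, line_no, "empty identifier")
        pairs.append((a, b))
    return pairs


read_ppi = read_pair_list
read_ddi = read_pair_list


def read_domains(path: str | Path) -> dict[str, list[str]]:
    """Read the domain annotation: one (protein, domain) row per slot occurrence.

    Row order is preserved; a domain listed twice for one protein yields two
    distinct binding slots.
    """
    slots: dict[str, list[str]] = {}
    for line_no, fields in _rows(path, 2):
        protein, domain = fields[0].strip(), fields[1].strip()
        if not protein or not domain:
            raise ParseError(path, line_no, "empty identifier")
        slots.setdefault(protein, []).append(domain)
    return slots


def read_abundance(path: str | Path) -> dict[str, float]:
    """Read protein abundances (copies per cell)."""
    abundance: dict[str, float] = {}
    for line_no, fields in _rows(path, 2):
        protein = fields[0].strip()
        try:
            value = float(fields[1])
        except ValueError as exc:
            raise ParseError(path, line_no, f"abundance is not a number: {fields[1]!r}") from exc
        if value < 0:
            raise ParseError(path, line_no, f"negative abundance: {value}")
        abundance[protein] = value
    return abundance


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read functional annotation: one (protein, term) row per assignment."""
    terms: dict[str, set[str]] = {}
    for line_no, fields in _rows(path, 2):
        protein, term = fields[0].strip(), fields[1].strip()
        if not protein or not term:
            raise ParseError(path, line_no, "empty identifier")
        terms.setdefault(protein, set()).add(term)
    return terms


def read_reference_complexes(path: str | Path) -> list[frozenset[str]]:
    """Read a reference complex set: one complex per line, tab-separated members."""
    complexes = []
    for line_no, fields in _rows(path, 1):
        members = frozenset(f.strip() for f in fields if f.strip())
        if not members:
            raise ParseError(path, line_no, "complex with no members")
        complexes.append(members)
    return complexes


def read_drug_targets(path: str | Path) -> dict[str, set[str]]:
    """Read a drug-target list: (drug_id, target_protein) rows."""
    targets: dict[str, set[str]] = {}
    for line_no, fields in _rows(path, 2):
        drug, protein = fields[0].strip(), fields[1].strip()
        if not drug or not protein:
            raise ParseError(path, line_no, "empty identifier")
        targets.setdefault(drug, set()).add(protein)
    return targets


def write_tsv(path: str | Path, rows: Iterable[Iterable], header: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if header:
            handle.write("# " + "\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_json(path: str | Path, payload) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
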