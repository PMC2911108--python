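"""Strain/barcode catalog: data model, TSV I/O, and duplicate-barcode handling.

A pooled deletion library is described by a five-column catalog mapping each
strain (systematic gene id) to its plate well, a position flag, and up to two
20-nt molecular barcodes: the *uptag* upstream and the *dntag* downstream of
the deletion cassette.  Barcodes used by more than one (strain, tag-class)
pair cannot be attributed to a single strain at counting time and are set
aside as *ambiguous*; reads matching them are discarded, never assigned.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "StrainRecord",
    "Catalog",
    "CatalogError",
    "read_catalog",
    "write_catalog",
    "find_ambiguous",
    "catalog_summary",
    "write_ambiguity_report",
]

POSITION_FLAGS = {"OK", "W", "M", "C"}
TAG_ALPHABET = frozenset("ACGT")
TAG_LENGTH = 20


class CatalogError(ValueError):
    """Malformed catalog content; carries the offending line number when known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class StrainRecord:
    """One deletion strain: gene id, well, position flag, and its barcode tags.

    ``position_flag`` is one of ``OK`` (as expected), ``W`` (wrongly placed),
    ``M`` (present in multiple wells), ``C`` (contaminated).  Flags are
    annotation only; they never affect counting or scoring.
    """

    gene_id: str
    well_position: str
    position_flag: str = "OK"
    uptag: Optional[str] = None
    dntag: Optional[str] = None

    def __post_init__(self):
        if self.uptag is None and self.dntag is None:
            raise CatalogError(f"{self.gene_id}: record has neither uptag nor dntag")
        if self.position_flag not in POSITION_FLAGS:
            raise CatalogError(
                f"{self.gene_id}: unknown position flag {self.position_flag!r}"
            )
        for cls, tag in (("uptag", self.uptag), ("dntag", self.dntag)):
            if tag is None:
                continue
            if len(tag) != TAG_LENGTH or not TAG_ALPHABET.issuperset(tag):
                raise CatalogError(
                    f"{self.gene_id}: {cls} {tag!r} is not a 20-nt ACGT sequence"
                )

    def tags(self) -> Iterable[tuple[str, str]]:
        """Yield (tag_class, sequence) for each present tag."""
        if self.uptag is not None:
            yield "up", self.uptag
        if self.dntag is not None:
            yield "dn", self.dntag


@dataclass
class Catalog:
    """Validated strain records plus the barcode -> strain lookup.

    ``lookup`` maps each unambiguous barcode to its unique
    ``(gene_id, tag_class)``; ``ambiguous`` holds barcodes claimed by more
    than one (strain, tag-class) pair, which are excluded from counting.
    The two key sets are disjoint by construction.
    """

    records: list[StrainRecord] = field(default_factory=list)
    lookup: dict[str, tuple[str, str]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    @classmethod
    def from_records(cls, records: list[StrainRecord]) -> "Catalog":
        dupes = find_ambiguous(records)
        lookup: dict[str, tuple[str, str]] = {}
        for rec in records:
            for tag_class, seq in rec.tags():
                if seq not in dupes:
                    lookup[seq] = (rec.gene_id, tag_class)
        return cls(records=list(records), lookup=lookup, ambiguous=set(dupes))

    def __len__(self) -> int:
        return len(self.records)

    def usable_tags(self, gene_id: str) -> set[str]:
        """Tag classes of ``gene_id`` that survive ambiguity exclusion."""
        classes = set()
        for rec in self.records:
            if rec.gene_id != gene_id:
                continue
            for tag_class, seq in rec.tags():
                if seq in self.lookup:
                    classes.add(tag_class)
        return classes


def find_ambiguous(
    records: list[StrainRecord],
) -> dict[str, list[tuple[str, str]]]:
    """Barcodes associated with more than one (strain, tag-class) pair.

    A sequence serving as uptag of one gene and dntag of another counts as
    ambiguous, as does a single strain reusing one sequence for both tags:
    the barcode alone cannot resolve the association at counting time.
    Output is ordered by barcode, associations by gene id then tag class.
    """
    uses: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for rec in records:
        for tag_class, seq in rec.tags():
            uses[seq].append((rec.gene_id, tag_class))
    return {
        seq: sorted(assoc)
        for seq, assoc in sorted(uses.items())
        if len(assoc) >= 2
    }


def catalog_summary(catalog: Catalog) -> tuple[int, int]:
    """(strains with >=1 usable tag, strains with both tags usable), after
    ambiguity exclusion."""
    n_any = n_both = 0
    for rec in catalog.records:
        usable = {cls for cls, seq in rec.tags() if seq in catalog.lookup}
        if usable:
            n_any += 1
        if usable == {"up", "dn"}:
            n_both += 1
    return n_any, n_both


def _parse_tag(cell: str, line_no: int, what: str) -> Optional[str]:
    cell = cell.strip().upper()
    if not cell:
        return None
    if len(cell) != TAG_LENGTH or not TAG_ALPHABET.issuperset(cell):
        raise CatalogError(f"{what} {cell!r} is not a 20-nt ACGT sequence", line_no)
    return cell


def read_catalog(path) -> Catalog:
    """Read a 5-column TSV (gene id, well, flag, uptag, dntag) into a Catalog.

    A header row is detected by a non-ACGT fourth/fifth column of the first
    line; '#'-prefixed lines are comments; empty tag cells mean the tag is
    absent.  Tags are parsed case-insensitively and stored uppercase.
    """
    path = Path(path)
    records: list[StrainRecord] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise CatalogError(f"cannot read catalog {path}: {exc}") from exc
    first_data_line = True
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 5:
            cols += [""] * (5 - len(cols))
        gene_id, well, flag, up_cell, dn_cell = (c.strip() for c in cols[:5])
        if first_data_line:
            first_data_line = False
            tagish = (up_cell or dn_cell).upper()
            if tagish and not TAG_ALPHABET.issuperset(tagish):
                continue  # header row
        try:
            records.append(
                StrainRecord(
                    gene_id=gene_id,
                    well_position=well,
                    position_flag=flag or "OK",
                    uptag=_parse_tag(up_cell, line_no, "uptag"),
                    dntag=_parse_tag(dn_cell, line_no, "dntag"),
                )
            )
        except CatalogError as exc:
            if exc.line is None:
                raise CatalogError(str(exc), line_no) from None
            raise
    return Catalog.from_records(records)


def write_catalog(catalog: Catalog, path) -> None:
    """Write the catalog back as the same 5-column TSV (header included)."""
    lines = ["gene_id\twell_position\tposition_flag\tuptag\tdntag"]
    for rec in catalog.records:
        lines.append(
            "\t".join(
                [
                    rec.gene_id,
                    rec.well_position,
                    rec.position_flag,
                    rec.uptag or "",
                    rec.dntag or "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ambiguity_report(records: list[StrainRecord], path) -> None:
    """TSV report of duplicated barcodes: barcode, n_associations, gene list."""
    dupes = find_ambiguous(records)
    lines = ["barcode\tn_associations\tgenes"]
    for seq, assoc in dupes.items():
        genes = ",".join(f"{g}:{c}" for g, c in assoc)
        lines.append(f"{seq}\t{len(assoc)}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")
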