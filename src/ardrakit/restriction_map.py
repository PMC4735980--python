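"""Assembly of the taxa x enzymes matrix of observable band patterns.

Taxa whose sets of distinct gene-copy sequences are string-identical are
collapsed into a single entry first: such strains cannot be told apart by any
restriction pattern (nor by sequencing the same marker), so they enter the
scheme as one unit and the identification result simply lists all member
names.

Each matrix cell is the pooled lane of the entry's copies under one enzyme:
every distinct copy is digested, converted to observable bands, and the lanes
are pooled with the same co-migration rule.  Full band-length lists are kept
(not just counts) so one build serves both the count-only and the
count-and-length scheme modes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .digestion import (
    DEFAULT_MERGE_DELTA,
    DEFAULT_MIN_FRAGMENT,
    BandPattern,
    RestrictionEnzyme,
    digest_linear,
    pool_bands,
    to_band_pattern,
)
from .errors import ParseError, ValidationError
from .seq_io import NucleotideSequence


@dataclass(frozen=True)
class TaxonEntry:
    """One row of the restriction map: possibly several strains whose marker
    sequences are indistinguishable."""

    entry_id: str
    member_names: tuple[str, ...]
    copy_sequences: tuple[NucleotideSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_names", tuple(self.member_names))
        object.__setattr__(self, "copy_sequences", tuple(self.copy_sequences))
        if not self.member_names:
            raise ValidationError(f"entry {self.entry_id!r} has no members")
        strings = [c.residues for c in self.copy_sequences]
        if len(set(strings)) != len(strings):
            raise ValidationError(
                f"entry {self.entry_id!r}: copy sequences must be pairwise distinct")


@dataclass(frozen=True)
class RestrictionMap:
    """Band patterns for every entry x enzyme pair, plus the gel thresholds
    used to compute them."""

    entries: tuple[TaxonEntry, ...]
    enzymes: tuple[RestrictionEnzyme, ...]
    patterns: dict[tuple[str, str], BandPattern]
    min_fragment: int = DEFAULT_MIN_FRAGMENT
    merge_delta: int = DEFAULT_MERGE_DELTA

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        for e in self.entries:
            for z in self.enzymes:
                if (e.entry_id, z.name) not in self.patterns:
                    raise ValidationError(
                        f"pattern missing for entry {e.entry_id!r} x "
                        f"enzyme {z.name!r}")

    @property
    def entry_ids(self) -> list[str]:
        return [e.entry_id for e in self.entries]

    @property
    def enzyme_names(self) -> list[str]:
        return [z.name for z in self.enzymes]

    def members_of(self, entry_id: str) -> tuple[str, ...]:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e.member_names
        raise KeyError(entry_id)

    def pattern(self, entry_id: str, enzyme_name: str) -> BandPattern:
        return self.patterns[(entry_id, enzyme_name)]


def collapse_identical(
    taxa: Sequence[tuple[str, Sequence[NucleotideSequence]]]
) -> list[TaxonEntry]:
    """Merge taxa with string-identical sets of distinct copy sequences.

    The key is the sorted set of distinct copy strings, so copy order and
    copy-number redundancy (two copies with the same sequence) do not split
    entries.  Each entry is named after its first member, keeps all member
    names in input order, and carries the distinct copy variants.
    """
    order: list[tuple[str, ...]] = []
    groups: dict[tuple[str, ...], list[str]] = {}
    reps: dict[tuple[str, ...], tuple[NucleotideSequence, ...]] = {}
    for name, copies in taxa:
        if not copies:
            raise ValidationError(f"taxon {name!r} has no copy sequences")
        distinct: dict[str, NucleotideSequence] = {}
        for c in copies:
            distinct.setdefault(c.residues, c)
        key = tuple(sorted(distinct))
        if key not in groups:
            order.append(key)
            groups[key] = []
            reps[key] = tuple(distinct[s] for s in sorted(distinct))
        groups[key].append(name)
    return [TaxonEntry(groups[k][0], tuple(groups[k]), reps[k]) for k in order]


def build_restriction_map(entries: Sequence[TaxonEntry],
                          enzymes: Sequence[RestrictionEnzyme],
                          min_fragment: int = DEFAULT_MIN_FRAGMENT,
                          merge_delta: int = DEFAULT_MERGE_DELTA) -> RestrictionMap:
    """Digest every entry's distinct copies with every enzyme and pool lanes."""
    if not entries:
        raise ValidationError("restriction map needs at least one entry")
    if not enzymes:
        raise ValidationError("restriction map needs at least one enzyme")
    patterns: dict[tuple[str, str], BandPattern] = {}
    for entry in entries:
        if not entry.copy_sequences:
            raise ValidationError(
                f"entry {entry.entry_id!r} has no copy sequences to digest")
        for enz in enzymes:
            lanes = [
                to_band_pattern(digest_linear(c, enz).raw_fragments,
                                min_fragment, merge_delta)
                for c in entry.copy_sequences
            ]
            patterns[(entry.entry_id, enz.name)] = pool_bands(lanes, merge_delta)
    return RestrictionMap(tuple(entries), tuple(enzymes), patterns,
                          min_fragment, merge_delta)


_MAP_HEADER_FIXED = ["entry_id", "members", "copy_sequences"]


def export_map(rmap: RestrictionMap, path: "str | Path") -> None:
    """Write a restriction map as CSV.

    Leading ``#`` lines carry the enzyme definitions and gel thresholds so the
    file is self-contained; then one row per entry with the member names,
    the copy sequences, and per enzyme a band count and the semicolon-joined
    band lengths.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"#params\tmin_fragment={rmap.min_fragment}\t"
                 f"merge_delta={rmap.merge_delta}\n")
        for z in rmap.enzymes:
            fh.write(f"#enzyme\t{z.name}\t{z.caret_site}\n")
        writer = csv.writer(fh)
        header = list(_MAP_HEADER_FIXED)
        for z in rmap.enzymes:
            header += [f"{z.name}:count", f"{z.name}:bands"]
        writer.writerow(header)
        for e in rmap.entries:
            row = [e.entry_id, "|".join(e.member_names),
                   ";".join(f"{c.id}={c.residues}" for c in e.copy_sequences)]
            for z in rmap.enzymes:
                pat = rmap.patterns[(e.entry_id, z.name)]
                row += [str(pat.count), ";".join(map(str, pat.bands))]
            writer.writerow(row)


def import_map(path: "str | Path") -> RestrictionMap:
    """Read a restriction map CSV written by :func:`export_map`."""
    path = Path(path)
    min_fragment, merge_delta = DEFAULT_MIN_FRAGMENT, DEFAULT_MERGE_DELTA
    enzymes: list[RestrictionEnzyme] = []
    data_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#params"):
                for part in line.split("\t")[1:]:
                    k, _, v = part.partition("=")
                    if k == "min_fragment":
                        min_fragment = int(v)
                    elif k == "merge_delta":
                        merge_delta = int(v)
            elif line.startswith("#enzyme"):
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}: line {lineno}: bad enzyme line")
                enzymes.append(RestrictionEnzyme.from_caret(parts[1], parts[2]))
            elif line.startswith("#"):
                continue
            else:
                data_lines.append((lineno, line))
    if not data_lines:
        raise ParseError(f"{path}: no data rows")
    rows = list(csv.reader(ln for _, ln in data_lines))
    linenos = [n for n, _ in data_lines]
    header = rows[0]
    if header[:3] != _MAP_HEADER_FIXED:
        raise ParseError(f"{path}: line {linenos[0]}: unexpected header {header[:3]}")
    enz_names = [z.name for z in enzymes]
    expected = _MAP_HEADER_FIXED + [c for z in enz_names
                                    for c in (f"{z}:count", f"{z}:bands")]
    if header != expected:
        raise ParseError(f"{path}: line {linenos[0]}: header does not match "
                         f"declared enzymes {enz_names}")
    entries: list[TaxonEntry] = []
    patterns: dict[tuple[str, str], BandPattern] = {}
    for lineno, row in zip(linenos[1:], rows[1:]):
        if len(row) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected "
                             f"{len(header)} fields, got {len(row)}")
        try:
            entry_id = row[0]
            members = tuple(row[1].split("|"))
            copies = tuple(
                NucleotideSequence(*field.split("=", 1))
                for field in row[2].split(";") if field
            )
            entry = TaxonEntry(entry_id, members, copies)
            for j, zname in enumerate(enz_names):
                count = int(row[3 + 2 * j])
                bands_field = row[4 + 2 * j]
                bands = tuple(int(b) for b in bands_field.split(";") if b)
                if len(bands) != count:
                    raise ValueError(
                        f"band count {count} does not match bands {bands}")
                patterns[(entry_id, zname)] = BandPattern(bands)
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        entries.append(entry)
    return RestrictionMap(tuple(entries), tuple(enzymes), patterns,
                          min_fragment, merge_delta)
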