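"""Restriction-site search, linear digestion, and virtual gel band calling.

A digest of a linear fragment with k cut positions yields k+1 raw fragments
whose lengths sum to the sequence length.  Raw fragments are then turned into
what an agarose gel would actually show:

* fragments shorter than ``min_fragment`` (default 30 bp) run off the gel and
  are dropped;
* fragments whose lengths differ by less than ``merge_delta`` (default 10 bp)
  co-migrate and are read as a single band (exact duplicates are the trivial
  case of this rule).

Only the top-strand cut coordinate defines fragment length: sticky-end
overhangs of a few nucleotides are invisible at gel resolution, so end
chemistry is deliberately not modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError
from .seq_io import NucleotideSequence, _validate_residues, reverse_complement
from .amplify import scan_iupac

MIN_SITE_LENGTH = 4

DEFAULT_MIN_FRAGMENT = 30
DEFAULT_MERGE_DELTA = 10


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A Type II restriction enzyme cutting inside its recognition site.

    ``cut_offset`` is the number of site bases 5' of the top-strand cut, so
    HinfI = G^ANTC has site ``GANTC`` and offset 1.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", self.site.upper())
        _validate_residues(self.site, f"enzyme {self.name!r} site")
        if len(self.site) < MIN_SITE_LENGTH:
            raise ValidationError(
                f"enzyme {self.name!r}: site {self.site!r} shorter than "
                f"{MIN_SITE_LENGTH} bp")
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValidationError(
                f"enzyme {self.name!r}: cut offset {self.cut_offset} outside "
                f"site of length {len(self.site)}")

    @classmethod
    def from_caret(cls, name: str, caret_site: str) -> "RestrictionEnzyme":
        """Parse REBASE-style caret notation, e.g. ``G^ANTC``."""
        if caret_site.count("^") != 1:
            raise ParseError(
                f"enzyme {name!r}: expected exactly one '^' in {caret_site!r}")
        offset = caret_site.index("^")
        return cls(name, caret_site.replace("^", ""), offset)

    @property
    def caret_site(self) -> str:
        return self.site[:self.cut_offset] + "^" + self.site[self.cut_offset:]

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.site) == self.site


@dataclass(frozen=True)
class DigestResult:
    """Cut positions (1-based; the top strand is severed after each) and the
    raw fragment lengths they imply, left to right."""

    cut_positions: tuple[int, ...]
    raw_fragments: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.raw_fragments) != len(self.cut_positions) + 1:
            raise ValidationError("fragment count must be cut count + 1")


@dataclass(frozen=True)
class BandPattern:
    """Observable gel bands: strictly descending lengths, well separated."""

    bands: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if any(a <= b for a, b in zip(self.bands, self.bands[1:])):
            raise ValidationError(f"bands must be strictly descending: {self.bands}")

    @property
    def count(self) -> int:
        return len(self.bands)


def find_sites(seq: "NucleotideSequence | str",
               enzyme: RestrictionEnzyme) -> tuple[int, ...]:
    """All top-strand cut positions of an enzyme on a linear sequence.

    Both strands are scanned: a site window starting at ``w`` (1-based) cuts
    after position ``w + offset - 1``; a window matching only the site's
    reverse complement is a site on the minus strand, whose top-strand cut
    falls at the mirrored offset ``w + (|site| - offset) - 1``.  A window
    matching in both orientations (any palindromic site) is a single
    double-stranded site and contributes the plus-strand cut once — the
    mirrored coordinate there is the *bottom*-strand nick, which does not
    change fragment lengths.  Overlapping windows all count; cuts falling on
    a sequence boundary split nothing and are discarded.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n = len(residues)
    plus = set(scan_iupac(residues, enzyme.site))
    minus = set(scan_iupac(residues, reverse_complement(enzyme.site)))
    cuts = {w + enzyme.cut_offset - 1 for w in plus}
    cuts |= {w + (len(enzyme.site) - enzyme.cut_offset) - 1
             for w in minus if w not in plus}
    return tuple(sorted(c for c in cuts if 1 <= c <= n - 1))


def digest_linear(seq: "NucleotideSequence | str",
                  enzyme: RestrictionEnzyme) -> DigestResult:
    """Digest a linear sequence: fragments are the runs between cuts."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if not residues:
        raise ValidationError("cannot digest an empty sequence")
    cuts = find_sites(residues, enzyme)
    bounds = (0,) + cuts + (len(residues),)
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(cuts, frags)


def _merge_descending(lengths: Sequence[int], merge_delta: int) -> tuple[int, ...]:
    """Single-linkage clustering of sorted lengths; one band per cluster.

    Consecutive lengths differing by less than ``merge_delta`` join the same
    cluster; the cluster maximum represents it (co-migrating fragments read
    at the slower, larger position).
    """
    if not lengths:
        return ()
    ordered = sorted(lengths, reverse=True)
    bands = [ordered[0]]
    prev = ordered[0]
    for length in ordered[1:]:
        # equal lengths are one band by definition, whatever merge_delta is
        if length < prev and prev - length >= merge_delta:
            bands.append(length)
        prev = length
    return tuple(bands)


def to_band_pattern(raw_fragments: Iterable[int],
                    min_fragment: int = DEFAULT_MIN_FRAGMENT,
                    merge_delta: int = DEFAULT_MERGE_DELTA) -> BandPattern:
    """Convert raw fragment lengths to the bands a gel would show."""
    if min_fragment < 1:
        raise ValidationError(f"min_fragment must be >= 1, got {min_fragment}")
    if merge_delta < 0:
        raise ValidationError(f"merge_delta must be >= 0, got {merge_delta}")
    frags = list(raw_fragments)
    if any(f <= 0 for f in frags):
        raise ValidationError("raw fragment lengths must be positive")
    visible = [f for f in frags if f >= min_fragment]
    return BandPattern(_merge_descending(visible, merge_delta))


def pool_bands(patterns: Sequence[BandPattern],
               merge_delta: int = DEFAULT_MERGE_DELTA) -> BandPattern:
    """Pool the lanes of all gene copies of one genome into one lane.

    All copies of a multi-copy gene are amplified and digested together in
    the lab, so fragments of (nearly) equal length across copies fall into
    the same band.  The pooled lane is the union of all band lengths followed
    by the same co-migration merge used within a single digest.
    """
    all_bands: list[int] = []
    for p in patterns:
        all_bands.extend(p.bands)
    return BandPattern(_merge_descending(all_bands, merge_delta))


def read_enzyme_table(path: "str | Path") -> list[RestrictionEnzyme]:
    """Read an enzyme TSV.

    Two layouts are accepted per row: ``name<TAB>site-with-caret`` or
    ``name<TAB>site<TAB>cut_offset``.
    """
    enzymes = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            try:
                if len(parts) >= 3 and parts[2]:
                    enz = RestrictionEnzyme(parts[0], parts[1], int(parts[2]))
                elif len(parts) >= 2:
                    enz = RestrictionEnzyme.from_caret(parts[0], parts[1])
                else:
                    raise ParseError("expected name<TAB>site")
            except (ParseError, ValidationError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if enz.name in names:
                raise ParseError(f"{path}: line {lineno}: duplicate enzyme "
                                 f"name {enz.name!r}")
            names.add(enz.name)
            enzymes.append(enz)
    return enzymes


def default_enzymes() -> dict[str, RestrictionEnzyme]:
    """The bundled enzyme panel (13 common 4-6-cutters incl. HinfI, TfiI)."""
    with resources.as_file(resources.files("ardrakit.data") / "enzymes.tsv") as p:
        return {e.name: e for e in read_enzyme_table(p)}
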