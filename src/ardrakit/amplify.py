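"""IUPAC-degenerate primer matching and in-silico PCR.

Matching is exact (zero mismatches): a primer letter matches a template base
iff the template base's set is a subset of the primer letter's set.  Ambiguity
codes in the *template* therefore never match — deposited genomes with runs of
``N`` must not create phantom amplicons.

The amplicon *interior* is the sequence strictly between the two
primer-binding windows; the primer regions themselves are excluded, matching
the usual practice of trimming primers before downstream restriction analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParseError, ValidationError
from .seq_io import IUPAC_SETS, NucleotideSequence, reverse_complement

MIN_PRIMER_LENGTH = 10


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3', possibly degenerate."""

    name: str
    sequence: NucleotideSequence

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_PRIMER_LENGTH:
            raise ValidationError(
                f"primer {self.name!r} is {len(self.sequence)} nt; "
                f"minimum is {MIN_PRIMER_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product.

    ``interior`` excludes both primer-binding windows.  ``fwd_match_start``
    and ``rev_match_start`` are 1-based leftmost coordinates of the two
    matched windows on the template as given (for products found on the
    minus strand the coordinates are mapped back to the original template,
    and ``strand`` is ``'-'``).
    """

    interior: NucleotideSequence
    fwd_match_start: int
    rev_match_start: int
    source_id: str
    strand: str = "+"


def iupac_matches(pattern_base: str, target_base: str) -> bool:
    """True iff ``target_base``'s base set is a subset of ``pattern_base``'s.

    With a concrete A/C/G/T target this is ordinary degenerate matching
    (W matches A or T; N matches anything).  An ambiguous target only matches
    a pattern letter that covers every base it could be.
    """
    try:
        p = IUPAC_SETS[pattern_base.upper()]
        t = IUPAC_SETS[target_base.upper()]
    except KeyError as exc:
        raise ValidationError(f"invalid IUPAC code: {exc.args[0]!r}") from exc
    return t <= p


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a regex over concrete bases only."""
    parts = []
    for ch in pattern.upper():
        try:
            bases = sorted(IUPAC_SETS[ch])
        except KeyError as exc:
            raise ValidationError(f"invalid IUPAC code: {ch!r}") from exc
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(parts)


def scan_iupac(residues: str, pattern: str) -> list[int]:
    """All 1-based start positions where ``pattern`` matches, overlapping included."""
    rx = re.compile("(?=" + iupac_regex(pattern) + ")")
    return [m.start() + 1 for m in rx.finditer(residues)]


def find_primer_sites(seq: "NucleotideSequence | str",
                      primer: Primer) -> tuple[list[int], list[int]]:
    """Locate every exact degenerate match of a primer on both strands.

    Returns ``(plus_strand_starts, minus_strand_starts)``: plus-strand hits
    are matches of the primer itself, minus-strand hits are matches of its
    reverse complement; both are 1-based leftmost coordinates of the matched
    window on the given sequence, ascending.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    pat = primer.sequence.residues
    return scan_iupac(residues, pat), scan_iupac(residues, reverse_complement(pat))


def _pair_hits(residues: str, fwd: Primer, rev: Primer, max_product: int,
               source_id: str, strand: str, total_len: int) -> list[Amplicon]:
    """One-orientation PCR: pair each forward hit with the nearest downstream
    reverse-complemented reverse-primer hit within ``max_product``."""
    fwd_hits = scan_iupac(residues, fwd.sequence.residues)
    rev_hits = scan_iupac(residues, reverse_complement(rev.sequence.residues))
    out = []
    j = 0
    for f in fwd_hits:
        # nearest rev window starting at or after the forward window's end
        lo = f + len(fwd)
        while j < len(rev_hits) and rev_hits[j] < lo:
            j += 1
        k = j
        amp = None
        while k < len(rev_hits):
            r = rev_hits[k]
            span = r + len(rev) - f
            if span > max_product:
                break
            amp = (f, r)
            break
        if amp is None:
            continue
        f_pos, r_pos = amp
        interior = residues[f_pos + len(fwd) - 1:r_pos - 1]
        if strand == "+":
            f_orig, r_orig = f_pos, r_pos
        else:
            # map window starts on the reverse complement back to the template
            f_orig = total_len - (f_pos + len(fwd) - 1) + 1
            r_orig = total_len - (r_pos + len(rev) - 1) + 1
        out.append(Amplicon(
            NucleotideSequence(f"{source_id}:amp{f_orig}", interior),
            f_orig, r_orig, source_id, strand))
    return out


def in_silico_pcr(template: NucleotideSequence, fwd: Primer, rev: Primer,
                  max_product: int = 3000) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Both orientations of the template are searched, so the strand on which a
    gene cassette was deposited never matters.  Each forward hit yields at
    most one product (the nearest compatible reverse hit), which keeps
    multi-copy genomes from exploding combinatorially: one rRNA operon, one
    amplicon.  The default ``max_product`` of 3000 bp comfortably covers
    full-length 16S rRNA / HSP60 amplicons (~1.5-1.6 kb).
    """
    if max_product <= 0:
        raise ValidationError(f"max_product must be positive, got {max_product}")
    if max_product <= len(fwd) + len(rev):
        raise ValidationError(
            f"max_product ({max_product}) must exceed combined primer length "
            f"({len(fwd) + len(rev)})"
        )
    n = len(template)
    amps = _pair_hits(template.residues, fwd, rev, max_product,
                      template.id, "+", n)
    amps += _pair_hits(reverse_complement(template.residues), fwd, rev,
                       max_product, template.id, "-", n)
    # a palindromic product could be found in both orientations: deduplicate
    # on the unordered pair of window coordinates
    seen = set()
    unique = []
    for a in amps:
        key = tuple(sorted((a.fwd_match_start, a.rev_match_start)))
        if key in seen:
            continue
        seen.add(key)
        unique.append(a)
    unique.sort(key=lambda a: min(a.fwd_match_start, a.rev_match_start))
    return unique


def read_primer_table(path: "str | Path") -> list[Primer]:
    """Read a primer TSV: ``name<TAB>sequence[<TAB>gene[<TAB>reference]]``.

    Blank lines and ``#`` comments are skipped; whitespace inside the
    sequence field is removed (typeset tables often break oligos across
    spaces).
    """
    primers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected at least "
                                 f"name<TAB>sequence, got {line!r}")
            name = parts[0].strip()
            seq = re.sub(r"\s+", "", parts[1])
            primers.append(Primer(name, NucleotideSequence(name, seq)))
    return primers


def default_primers() -> dict[str, Primer]:
    """The bundled 16S rRNA / HSP60 primer panel, keyed by name.

    Includes the 8F/1541R universal 16S pair and the degenerate HSP60-F/-R
    pair alongside other published 16S primers.
    """
    with resources.as_file(resources.files("ardrakit.data") / "primers.tsv") as p:
        return {pr.name: pr for pr in read_primer_table(p)}
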