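"""Sequence and annotation I/O: FASTA, GenBank flat files, marker-gene extraction.

Coordinates are 1-based inclusive throughout, the GenBank convention; the
half-open arithmetic used by Biopython internally is converted at the parsing
boundary and never leaks out.  Genomes are treated as linear even when the
source record declares a circular topology, so features or recognition sites
spanning the replication origin are not modelled.

Lowercase residues and RNA-style ``U`` are accepted on input and normalised to
uppercase ``T``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

#: The 15 IUPAC nucleotide codes (4 bases + 11 ambiguity codes).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: IUPAC code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Ambiguity-aware complement table: R(AG)<->Y(CT), K(GT)<->M(AC),
# B(CGT)<->V(ACG), D(AGT)<->H(ACT); S, W and N are self-complementary.
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def _validate_residues(residues: str, context: str = "sequence") -> None:
    bad = set(residues) - IUPAC_ALPHABET
    if bad:
        raise ValidationError(
            f"{context} contains non-IUPAC characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over the IUPAC alphabet.

    Residues are normalised (uppercase, U -> T) and validated on construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize(self.residues))
        _validate_residues(self.residues, f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class FeatureAnnotation:
    """A feature location on a genome, 1-based inclusive, stranded."""

    feature_type: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid feature span {self.start}..{self.end} (need 1 <= start <= end)"
            )

    @property
    def span(self) -> int:
        """Feature length under inclusive coordinates: end - start + 1."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeRecord:
    """A genome (or contig) with its feature annotations."""

    accession: str
    sequence: NucleotideSequence
    features: tuple[FeatureAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        object.__setattr__(self, "features", tuple(self.features))
        for f in self.features:
            if f.end > self.sequence.length:
                raise ValidationError(
                    f"feature {f.feature_type} {f.start}..{f.end} exceeds "
                    f"genome length {self.sequence.length}"
                )


def reverse_complement(seq: "NucleotideSequence | str"):
    """Ambiguity-aware reverse complement; an involution.

    Accepts a raw string or a :class:`NucleotideSequence` and returns the same
    type (a ``NucleotideSequence`` keeps its id).
    """
    if isinstance(seq, NucleotideSequence):
        return NucleotideSequence(seq.id, reverse_complement(seq.residues))
    _validate_residues(_normalize(seq))
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


def read_fasta(path: "str | Path") -> list[NucleotideSequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    first_content = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if first_content is None:
        raise ParseError(f"{path}: empty file, no FASTA records")
    if not lines[first_content].startswith(">"):
        raise ParseError(
            f"{path}: line {first_content + 1}: expected '>' header, "
            f"got {lines[first_content][:30]!r}"
        )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[NucleotideSequence], path: "str | Path",
                width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_genbank(path: "str | Path") -> GenomeRecord:
    """Read a GenBank flat file into a :class:`GenomeRecord`.

    Locations are converted to 1-based inclusive coordinates.  A
    ``complement(a..b)`` (or any compound location on the minus strand) is
    represented with strand ``'-'`` over the overall a..b extent; fuzzy and
    origin-spanning locations are out of scope.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a parseable GenBank record: {exc}") from exc
    try:
        residues = str(rec.seq)
    except Exception as exc:  # undefined sequence: no ORIGIN block
        raise ParseError(f"{path}: missing ORIGIN sequence block") from exc
    if not residues:
        raise ParseError(f"{path}: missing or empty ORIGIN sequence block")

    features = []
    for f in rec.features:
        if f.type == "source":
            continue
        start = int(f.location.start) + 1
        end = int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        product = f.qualifiers.get("product", [""])[0]
        features.append(FeatureAnnotation(f.type, start, end, strand, product))
    return GenomeRecord(rec.id or rec.name, NucleotideSequence(rec.id or rec.name, residues),
                        tuple(features))


def write_genbank(genome: GenomeRecord, path: "str | Path") -> None:
    """Write a minimal GenBank flat file (LOCUS/FEATURES/ORIGIN)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation

    rec = SeqRecord(
        Seq(genome.sequence.residues),
        id=genome.accession,
        name=genome.accession[:16],
        description="",
        # fixed date keeps output byte-stable across runs
        annotations={"molecule_type": "DNA", "date": "01-JAN-2015",
                     "topology": "linear"},
    )
    for f in genome.features:
        loc = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        qualifiers = {"product": [f.product]} if f.product else {}
        rec.features.append(SeqFeature(loc, type=f.feature_type, qualifiers=qualifiers))
    SeqIO.write([rec], str(path), "genbank")


def extract_features(genome: GenomeRecord, feature_type: str,
                     product_filter: "str | None" = None) -> list[NucleotideSequence]:
    """Extract the sequences of matching features, strand-corrected.

    Minus-strand features are reverse-complemented so the returned sequence is
    always the gene read 5'->3' (multi-copy rRNA operons commonly sit on both
    strands of a genome).  Ids carry accession and 1-based coordinates.
    Returns an empty list when nothing matches; the caller decides whether
    that is an error.
    """
    out = []
    for f in genome.features:
        if f.feature_type != feature_type:
            continue
        if product_filter is not None and product_filter.lower() not in f.product.lower():
            continue
        sub = genome.sequence.residues[f.start - 1:f.end]
        if f.strand == "-":
            sub = reverse_complement(sub)
        out.append(NucleotideSequence(
            f"{genome.accession}:{f.start}-{f.end}({f.strand})", sub))
    return out
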