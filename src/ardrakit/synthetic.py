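"""Synthetic bacterial populations with known ground truth.

The generator emulates the structure that drives marker-gene ribotyping:
genomes carrying several copies of a marker gene (a 16S rRNA-like cassette:
forward-primer site, gene body, reverse-complemented reverse-primer site),
with some copies on the minus strand, copy variants differing by point
mutations, a controlled number of recognition sites per enzyme planted in
each copy, and a subset of taxa sharing sequence-identical copy sets (strains
no marker-based method can separate).

Gene bodies are rejection-screened so they contain *exactly* the planted
recognition sites for every enzyme in the spec and no primer-binding sites:
the planted bookkeeping is therefore an exact oracle for site counts,
amplicon recovery, and map collapse, which is what makes every pipeline
stage testable without downloading a single genome.

Everything is driven by one ``random.Random(seed)``; the same spec always
produces byte-identical fixtures.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .amplify import Primer, default_primers, in_silico_pcr, iupac_regex
from .digestion import RestrictionEnzyme, default_enzymes
from .errors import GenerationError, ValidationError
from .seq_io import (
    IUPAC_SETS,
    FeatureAnnotation,
    GenomeRecord,
    NucleotideSequence,
    reverse_complement,
    write_fasta,
    write_genbank,
)

_BASES = "ACGT"
_EDGE_MARGIN = 8   # planted sites keep clear of body ends
_SITE_PAD = 3      # min gap between planted windows
_MAX_TRIES = 60


@dataclass
class PopulationSpec:
    """Parameters of a synthetic marker-gene population.

    Defaults mirror a typical lactic-acid-bacteria 16S study: 33 taxa of
    which 9 duplicate another taxon's sequences (24 distinguishable entries),
    4-9 gene copies per genome, ~1.5 kb gene bodies amplified by the 8F/1541R
    universal pair, and a handful of recognition sites per copy for common
    4-5 bp cutters.  ``planted_sites`` values may be an ``int`` (every copy),
    a 2-tuple ``(lo, hi)`` (drawn per copy), or a list with one count per
    copy.
    """

    n_taxa: int = 33
    copies_per_taxon: "int | tuple[int, int]" = (4, 9)
    n_duplicates: int = 9
    gene_length: int = 1513
    fwd_primer: "Primer | None" = None    # default: bundled 8F
    rev_primer: "Primer | None" = None    # default: bundled 1541R
    planted_sites: Mapping[str, object] = field(default_factory=lambda: {
        "HinfI": (2, 6), "MseI": (1, 5), "AluI": (2, 6), "RsaI": (1, 5)})
    point_mutation_rate: float = 0.005
    seed: int = 0

    def resolved_primers(self) -> tuple[Primer, Primer]:
        if self.fwd_primer is not None and self.rev_primer is not None:
            return self.fwd_primer, self.rev_primer
        bundled = default_primers()
        return (self.fwd_primer or bundled["8F"],
                self.rev_primer or bundled["1541R"])

    def resolved_enzymes(self) -> dict[str, RestrictionEnzyme]:
        bundled = default_enzymes()
        out = {}
        for name in self.planted_sites:
            if name not in bundled:
                raise ValidationError(f"unknown enzyme {name!r} in planted_sites")
            out[name] = bundled[name]
        return out

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        if not (0 <= self.n_duplicates < self.n_taxa):
            raise ValidationError("need 0 <= n_duplicates < n_taxa")
        fwd, rev = self.resolved_primers()
        if self.gene_length <= len(fwd) + len(rev) + 50:
            raise ValidationError(
                f"gene_length {self.gene_length} too short for primers "
                f"({len(fwd)}+{len(rev)} nt) plus 50 bp")
        if not (0.0 <= self.point_mutation_rate < 1.0):
            raise ValidationError("point_mutation_rate must be in [0, 1)")
        enzymes = self.resolved_enzymes()
        # planted counts can only be exact when no instance of one enzyme's
        # site can satisfy another planted enzyme's pattern (e.g. every
        # TfiI site GAWTC is also a HinfI site GANTC: such a pair is
        # infeasible to plant with independent exact counts)
        pool = list(enzymes.values())
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                for x, y in ((a, b), (b, a)):
                    if len(x.site) == len(y.site) and all(
                            IUPAC_SETS[p] & IUPAC_SETS[q]
                            for p, q in zip(x.site, y.site)):
                        raise GenerationError(
                            f"planted enzymes {a.name} and {b.name} have "
                            f"overlapping specificities; exact per-enzyme "
                            f"site counts are infeasible")
        worst = sum(
            _max_count(v) * (len(enzymes[name].site) + _SITE_PAD)
            for name, v in self.planted_sites.items())
        if worst + 2 * _EDGE_MARGIN >= self.gene_length:
            raise GenerationError(
                f"planted sites need up to {worst} bp but gene bodies are "
                f"only {self.gene_length} bp")


@dataclass
class TaxonTruth:
    """Ground truth for one taxon: its genome accession, planted copy
    sequences, per-copy site counts, feature table, and whether it clones
    another taxon's sequence set."""

    name: str
    accession: str
    copy_sequences: list[str]
    site_counts: dict[str, list[int]]
    features: list[FeatureAnnotation]
    duplicate_of: "str | None" = None


@dataclass
class PopulationTruth:
    taxa: dict[str, TaxonTruth]

    @property
    def expected_entries(self) -> int:
        """Number of distinguishable entries after collapsing duplicates."""
        return sum(1 for t in self.taxa.values() if t.duplicate_of is None)


def _max_count(value: object) -> int:
    if isinstance(value, int):
        return value
    if isinstance(value, tuple) and len(value) == 2:
        return int(value[1])
    if isinstance(value, (list,)):
        return max(int(v) for v in value) if value else 0
    raise ValidationError(f"bad planted_sites value {value!r}")


def _count_for_copy(value: object, copy_index: int, n_copies: int,
                    rng: random.Random) -> int:
    if isinstance(value, int):
        return value
    if isinstance(value, tuple) and len(value) == 2:
        return rng.randint(int(value[0]), int(value[1]))
    if isinstance(value, list):
        if len(value) != n_copies:
            raise ValidationError(
                f"planted_sites list {value} does not match {n_copies} copies")
        return int(value[copy_index])
    raise ValidationError(f"bad planted_sites value {value!r}")


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _concretize(pattern: str, rng: random.Random) -> str:
    return "".join(rng.choice(sorted(IUPAC_SETS[ch])) for ch in pattern)


def _forbidden_patterns(enzymes: Sequence[RestrictionEnzyme],
                        primers: Sequence[Primer]) -> list[re.Pattern]:
    pats: set[str] = set()
    for z in enzymes:
        pats.add(z.site)
        pats.add(reverse_complement(z.site))
    for p in primers:
        pats.add(p.sequence.residues)
        pats.add(reverse_complement(p.sequence.residues))
    return [re.compile("(?=" + iupac_regex(p) + ")") for p in sorted(pats)]


def _scrub(seq: str, forbidden: Sequence[re.Pattern],
           rng: random.Random) -> str:
    """Point-mutate matches of forbidden patterns away until none remain."""
    chars = list(seq)
    for _ in range(20 * len(forbidden) + 200):
        hit = None
        text = "".join(chars)
        for rx in forbidden:
            m = rx.search(text)
            if m is not None and (hit is None or m.start() < hit[0]):
                # window length: regex is a lookahead, recover from pattern
                hit = (m.start(), rx)
        if hit is None:
            return text
        pos = hit[0] + rng.randrange(4)  # mutate inside the first 4 window bases
        pos = min(pos, len(chars) - 1)
        chars[pos] = rng.choice([b for b in _BASES if b != chars[pos]])
    raise GenerationError("could not scrub forbidden motifs from sequence")


def _site_windows(body: str, enzyme: RestrictionEnzyme) -> set[int]:
    """Distinct 1-based window starts where the recognition site occurs on
    either strand."""
    from .amplify import scan_iupac
    hits = set(scan_iupac(body, enzyme.site))
    hits.update(scan_iupac(body, reverse_complement(enzyme.site)))
    return hits


def _verify_body(body: str, counts: Mapping[str, int],
                 enzymes: Mapping[str, RestrictionEnzyme],
                 primers: Sequence[Primer]) -> bool:
    """Exact planted site counts and no primer-binding motif, by rescan."""
    if any(len(_site_windows(body, enzymes[n])) != counts[n] for n in counts):
        return False
    for p in primers:
        for pat in (p.sequence.residues,
                    reverse_complement(p.sequence.residues)):
            if re.search("(?=" + iupac_regex(pat) + ")", body):
                return False
    return True


def _make_body(rng: random.Random, length: int,
               counts: dict[str, int],
               enzymes: Mapping[str, RestrictionEnzyme],
               forbidden: Sequence[re.Pattern],
               primers: Sequence[Primer]) -> str:
    """One gene-body variant with exactly the requested site counts.

    Starts from a background scrubbed clean of every planted motif, then
    overwrites non-overlapping windows with concrete instances of each
    enzyme's site; verified by independent rescan, resampled on any accident.
    """
    for _ in range(_MAX_TRIES):
        bg = _scrub(_random_seq(rng, length), forbidden, rng)
        # choose non-overlapping windows for all planted sites jointly
        taken: list[tuple[int, int]] = []  # 0-based [start, end) with pad
        chars = list(bg)
        ok = True
        for name in sorted(counts):
            site = enzymes[name].site
            for _ in range(counts[name]):
                placed = False
                for _ in range(200):
                    s = rng.randrange(_EDGE_MARGIN,
                                      length - _EDGE_MARGIN - len(site))
                    if all(s + len(site) + _SITE_PAD <= a
                           or s >= b + _SITE_PAD for a, b in taken):
                        taken.append((s, s + len(site)))
                        chars[s:s + len(site)] = _concretize(site, rng)
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        body = "".join(chars)
        if _verify_body(body, counts, enzymes, primers):
            return body
    raise GenerationError("failed to build a gene body with the planted "
                          f"site counts {counts}")


def _mutate_preserving(rng: random.Random, base: str, rate: float,
                       counts: Mapping[str, int],
                       enzymes: Mapping[str, RestrictionEnzyme],
                       primers: Sequence[Primer]) -> str:
    """A point-mutated variant of ``base`` with the same site counts.

    Positions inside recognition windows are protected; mutations elsewhere
    that happen to create a new site (or a primer motif) are caught by the
    rescan and the variant is redrawn.  A rate of 0 returns ``base`` itself
    (mutation-free clone copies)."""
    if rate == 0.0:
        return base
    protected = set()
    for name in counts:
        site_len = len(enzymes[name].site)
        for w in _site_windows(base, enzymes[name]):
            protected.update(range(w - 1, w - 1 + site_len))
    for _ in range(_MAX_TRIES):
        chars = list(base)
        for i in range(len(chars)):
            if i not in protected and rng.random() < rate:
                chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
        body = "".join(chars)
        if _verify_body(body, counts, enzymes, primers):
            return body
    raise GenerationError("mutated copy variants kept creating accidental "
                          "recognition or primer sites")


def _assemble_genome(rng: random.Random, accession: str, bodies: Sequence[str],
                     fwd: Primer, rev: Primer,
                     primer_forbidden: Sequence[re.Pattern]
                     ) -> tuple[GenomeRecord, list[FeatureAnnotation]]:
    """Place one cassette per body at random non-overlapping positions,
    at least one on the minus strand."""
    fwd_inst = _concretize(fwd.sequence.residues, rng)
    rev_inst = _concretize(rev.sequence.residues, rng)
    for _ in range(_MAX_TRIES):
        minus = [rng.random() < 0.4 for _ in bodies]
        if len(bodies) > 1 and not any(minus):
            minus[rng.randrange(len(bodies))] = True
        elif len(bodies) == 1:
            minus = [rng.random() < 0.5]
        parts: list[str] = []
        features: list[FeatureAnnotation] = []
        pos = 0
        for body, on_minus in zip(bodies, minus):
            spacer = _scrub(_random_seq(rng, rng.randint(100, 300)),
                            primer_forbidden, rng)
            parts.append(spacer)
            pos += len(spacer)
            cassette = fwd_inst + body + reverse_complement(rev_inst)
            if on_minus:
                cassette = reverse_complement(cassette)
                start = pos + len(rev_inst) + 1
                strand = "-"
            else:
                start = pos + len(fwd_inst) + 1
                strand = "+"
            features.append(FeatureAnnotation(
                "rRNA", start, start + len(body) - 1, strand,
                "16S ribosomal RNA"))
            parts.append(cassette)
            pos += len(cassette)
        tail = _scrub(_random_seq(rng, rng.randint(100, 300)),
                      primer_forbidden, rng)
        parts.append(tail)
        genome = GenomeRecord(accession,
                              NucleotideSequence(accession, "".join(parts)),
                              tuple(features))
        # verification: PCR recovers exactly the planted bodies
        amps = in_silico_pcr(genome.sequence, fwd, rev)
        if len(amps) == len(bodies) and \
                sorted(a.interior.residues for a in amps) == sorted(bodies):
            return genome, features
    raise GenerationError(f"could not assemble genome {accession} cleanly")


def generate_population(spec: PopulationSpec
                        ) -> tuple[list[GenomeRecord], PopulationTruth]:
    """Generate the genomes and exact ground truth for a population spec."""
    spec.validate()
    rng = random.Random(spec.seed)
    fwd, rev = spec.resolved_primers()
    enzymes = spec.resolved_enzymes()
    body_forbidden = _forbidden_patterns(list(enzymes.values()), [fwd, rev])
    primer_forbidden = _forbidden_patterns([], [fwd, rev])

    n_unique = spec.n_taxa - spec.n_duplicates
    width = max(3, len(str(spec.n_taxa)))
    names = [f"TAX{i + 1:0{width}d}" for i in range(spec.n_taxa)]
    duplicate_of = {}
    for i in range(n_unique, spec.n_taxa):
        duplicate_of[names[i]] = names[rng.randrange(n_unique)]

    genomes: list[GenomeRecord] = []
    taxa: dict[str, TaxonTruth] = {}
    for i, name in enumerate(names):
        accession = f"SYN{i + 1:0{width}d}"
        source = duplicate_of.get(name)
        if source is None:
            if isinstance(spec.copies_per_taxon, int):
                n_copies = spec.copies_per_taxon
            else:
                n_copies = rng.randint(*spec.copies_per_taxon)
            bodies: list[str] = []
            counts_per_copy: list[dict[str, int]] = []
            base: "str | None" = None
            base_counts: dict[str, int] = {}
            for c in range(n_copies):
                if base is not None and spec.point_mutation_rate == 0.0:
                    # no mutations: every copy is an exact operon clone
                    counts = dict(base_counts)
                else:
                    counts = {z: _count_for_copy(v, c, n_copies, rng)
                              for z, v in spec.planted_sites.items()}
                if base is not None and counts == base_counts:
                    # same site structure: a point-mutated variant of the
                    # first copy (or an exact clone at rate 0)
                    body = _mutate_preserving(
                        rng, base, spec.point_mutation_rate, counts,
                        enzymes, [fwd, rev])
                else:
                    body = _make_body(rng, spec.gene_length, counts,
                                      enzymes, body_forbidden, [fwd, rev])
                if base is None:
                    base, base_counts = body, counts
                bodies.append(body)
                counts_per_copy.append(counts)
        else:
            bodies = list(taxa[source].copy_sequences)
            counts_per_copy = [
                {z: taxa[source].site_counts[z][c] for z in spec.planted_sites}
                for c in range(len(bodies))]
        genome, features = _assemble_genome(rng, accession, bodies, fwd, rev,
                                            primer_forbidden)
        genomes.append(genome)
        taxa[name] = TaxonTruth(
            name=name, accession=accession, copy_sequences=bodies,
            site_counts={z: [cc[z] for cc in counts_per_copy]
                         for z in spec.planted_sites},
            features=features, duplicate_of=source)
    return genomes, PopulationTruth(taxa)


def write_fixture(genomes: Sequence[GenomeRecord], truth: PopulationTruth,
                  spec: PopulationSpec, directory: "str | Path") -> None:
    """Write a fixture directory: genomes/*.fasta + *.gbk, truth.csv,
    spec.yaml.  Regenerating with the same seed is byte-identical."""
    directory = Path(directory)
    gdir = directory / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        write_fasta([g.sequence], gdir / f"{g.accession}.fasta")
        write_genbank(g, gdir / f"{g.accession}.gbk")

    enzyme_names = sorted(spec.planted_sites)
    with open(directory / "truth.csv", "w") as fh:
        header = ["taxon", "accession", "duplicate_of", "copy_index",
                  "start", "end", "strand"]
        header += [f"sites_{z}" for z in enzyme_names]
        header.append("sequence")
        fh.write(",".join(header) + "\n")
        for name in sorted(truth.taxa):
            t = truth.taxa[name]
            for c, (body, feat) in enumerate(zip(t.copy_sequences, t.features)):
                row = [t.name, t.accession, t.duplicate_of or "", str(c),
                       str(feat.start), str(feat.end), feat.strand]
                row += [str(t.site_counts[z][c]) for z in enzyme_names]
                row.append(body)
                fh.write(",".join(row) + "\n")

    fwd, rev = spec.resolved_primers()
    doc = {
        "n_taxa": spec.n_taxa,
        "copies_per_taxon": list(spec.copies_per_taxon)
        if isinstance(spec.copies_per_taxon, tuple) else spec.copies_per_taxon,
        "n_duplicates": spec.n_duplicates,
        "gene_length": spec.gene_length,
        "fwd_primer": {"name": fwd.name, "sequence": fwd.sequence.residues},
        "rev_primer": {"name": rev.name, "sequence": rev.sequence.residues},
        "planted_sites": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in spec.planted_sites.items()},
        "point_mutation_rate": spec.point_mutation_rate,
        "seed": spec.seed,
    }
    with open(directory / "spec.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
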