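# Methods

## Model

The package models ARDRA-style identification of bacterial isolates from a
marker gene (16S rRNA by default, HSP60 or any amplifiable marker in
general). The physical chain it simulates is:

    genome --PCR--> marker copies --digest--> raw fragments --gel--> bands

and the statistic it exploits is the *discriminativeness* of an enzyme on a
group of taxa: the number of distinct observation classes the enzyme's
digest induces. In count-only mode the observation is the number of bands;
in count-and-length mode it is the pair (band count, band-length profile).
An enzyme under which every taxon shows a different observation identifies
the whole group in one digest; one under which all taxa look alike carries
no information. The scheme builder is a greedy recursive partitioner over
this statistic; the identifier replays the resulting tree against observed
patterns.

### Assumptions

- Genomes are linear; features or recognition sites spanning a circular
  origin are not modelled.
- Primer matching is exact and degenerate (IUPAC subset semantics), with
  zero mismatch tolerance: screening is presence/absence, and mismatch
  tolerance would silently change copy counts. Ambiguity codes in the
  *template* never match, so `N` runs in deposited genomes cannot create
  phantom amplicons.
- Digestion is complete (no partials), insensitive to methylation, and only
  Type II enzymes cutting within their recognition site are supported.
- Fragment length is defined by the top-strand cut coordinate. Sticky-end
  overhangs (≤ 5 nt) are invisible at gel resolution; a consequence is that
  reading the same molecule from the other strand can shift fragment
  lengths by up to the overhang, which is below the co-migration threshold
  and therefore harmless.
- A window matching the recognition site in both orientations (every
  palindromic site) is a single double-stranded site contributing one
  top-strand cut. A window matching only in reverse-complement orientation
  is a minus-strand site cut at the mirrored offset. Without the
  first rule a palindromic digest would report two cuts per site,
  contradicting the defining identity *fragments = sites + 1*.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_fragment` | 30 | bp | fragments shorter than this run off a standard agarose gel |
| `merge_delta` | 10 | bp | bands closer than this co-migrate and are read as one |
| `max_product` | 3000 | bp | upper bound for a plausible PCR product; covers 16S/HSP60 (~1.5–1.6 kb) with margin |
| `mode` | `count_only` | — | what a gel read yields quickly; `count_and_length` uses sizes too |

All are configuration (CLI flags or YAML), not constants: the defaults
reproduce standard gel observability but other labs may resolve differently.

### Numerical and tie-break choices

- Band merging is single-linkage on descending lengths: consecutive sorted
  lengths differing by less than `merge_delta` join one band; the cluster
  *maximum* represents the band (co-migrating fragments are read at the
  slower, larger position; any fixed choice is admissible since differences
  are below resolution). Exact duplicates merge at any `merge_delta`,
  including 0. The same rule applies within one digest and when pooling the
  lanes of a genome's gene copies — one equivalence, consistent with the
  physics of a single lane.
- Enzyme-selection ties are broken by lexicographic enzyme name. The
  greedy makes no optimality promise; determinism is what matters, and the
  same map and mode always serialize to byte-identical schemes.
- In count-and-length mode, profile equality is positional: two profiles
  match when counts agree and every matched pair of lengths differs by less
  than `merge_delta`. Near-equality is not transitive, so partition classes
  are seeded greedily in sorted entry order (deterministic). The same
  tolerance is used during identification — a gel cannot resolve at lookup
  what it could not resolve in a lane. Folding lengths into enzyme
  *selection* (not merely into tie-breaking at stuck nodes) is the design
  choice that lets fewer enzymes suffice in count-and-length mode.
- Groups that no remaining enzyme can split become explicit
  `indistinguishable` leaves; identification then reports the candidate
  set. Taxa with string-identical marker sequence sets are collapsed before
  map building for the same reason — they are indistinguishable by any
  method that reads this marker, sequencing included.
- Coordinates are 1-based inclusive throughout (GenBank convention). Gene
  length is `end − start + 1`; a span like 125,303..126,858 is reported as
  1556 bp even where source annotations round differently.
- Degenerate sites mean "no site present" is a stronger statement than it
  looks: GACTC *is* a HinfI site (G ANTC with N = C).

## Identification of unknown isolates

An unknown can be identified from measured band patterns (a mapping enzyme →
lengths), interactively enzyme by enzyme, or in silico from sequence. For a
multi-copy marker the lab digests all copies of an isolate together, so the
in-silico provider pools the per-copy lanes into one pattern before
traversal — the exact counterpart of how map cells are built. An observation
matching no branch at some node fails explicitly: the isolate is not in the
scheme's population (distinct exit code 3 in the CLI).

## The synthetic population generator

The generator emulates the structural features that drive marker-gene
ribotyping, with exact bookkeeping so every pipeline stage is testable
without downloads:

- multi-copy marker cassettes (forward-primer site, gene body,
  reverse-complemented reverse-primer site) at random non-overlapping
  genome positions, at least one per genome on the minus strand;
- per-copy planted recognition-site counts; gene bodies are built from
  backgrounds scrubbed of every planted motif, then verified by independent
  rescan to contain *exactly* the planted counts and no primer-binding
  motif (accidents are resampled);
- copy variants: copies sharing the first copy's site counts are
  point-mutated variants of it (sites protected; a mutation rate of 0
  yields exact operon clones), while copies with different counts are
  independent bodies;
- planted duplicates: a configurable number of taxa clone another taxon's
  sequence set exactly, exercising the collapse step;
- full determinism: one `random.Random(seed)` drives everything, and
  regenerated fixtures are byte-identical (FASTA, minimal GenBank with a
  pinned LOCUS date, truth CSV, spec YAML).

Defaults mirror a typical lactic-acid-bacteria 16S study: 33 taxa, 9
duplicates (24 distinguishable entries), 4–9 copies per genome, ~1.5 kb
bodies amplified by 8F/1541R, and 1–6 sites per copy for four common
4–5 bp cutters (HinfI, MseI, AluI, RsaI).

Planted enzymes must have non-overlapping specificities: every TfiI site
(`GAWTC`) is also a HinfI site (`GANTC`), so exact independent per-enzyme
counts cannot be planted for such a pair and the spec is rejected upfront.
TfiI remains in the bundled digestion panel; the restriction is only on
what the generator will *plant*.

### What the generator does not emulate

Real 16S evolution: no indels, no phylogenetic correlation between taxa
(bodies are independent random sequences), no intra-operon secondary
structure, and band patterns of distinct taxa are far better separated than
in a real genus. Passing the round-trip tests therefore demonstrates the
*correctness of the machinery* (amplification, digestion, band calling,
tree construction and traversal are mutually consistent and deterministic),
not that any particular real genus is separable with a given enzyme panel —
that depends on the actual sequence divergence of the population and must
be assessed on real maps. `scripts/accession_checks.py` provides spot
checks against four real *Lactobacillus* genomes when network access is
available.

## Problem sizes

The shipped test suite and the acceptance script run populations of 33 taxa
(the default study scale) with ~1.5 kb genes; smaller fixtures (6–8 taxa,
300–400 bp genes) cover the same code paths where scale adds nothing. The
acceptance script's identification round trip covers all 24 entries of a
33-taxon population in both modes.

## Known limitations

- No mismatch-tolerant primer matching or melting-temperature modelling.
- No Type IIS (cut outside the site), two-site, or methylation-sensitive
  digestion behaviour.
- GenBank parsing covers simple and `complement(a..b)` locations; fuzzy
  (`<`/`>`) and origin-spanning `join` locations are out of scope.
- The greedy scheme is not guaranteed minimal in enzymes or depth; enzyme
  counts can shift with tie-break order and pool composition.
- Band-length profiles compare positionally; an insertion-like shift that
  changes counts is handled, but a profile differing by one band in the
  middle simply fails to match (by design: so would the gel read).
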