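import random

import pytest

from ardrakit import (
    BandPattern,
    NucleotideSequence,
    PopulationSpec,
    RestrictionEnzyme,
    RestrictionMap,
    TaxonEntry,
    default_enzymes,
    generate_population,
)


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def hinfi(enzymes):
    return enzymes["HinfI"]


@pytest.fixture(scope="session")
def tfii(enzymes):
    return enzymes["TfiI"]


@pytest.fixture(scope="session")
def small_population():
    """8 taxa, 2 of which duplicate another's sequence set -> 6 entries."""
    spec = PopulationSpec(n_taxa=8, n_duplicates=2, copies_per_taxon=(2, 4),
                          gene_length=400, seed=42)
    genomes, truth = generate_population(spec)
    return spec, genomes, truth


def random_band_pattern(rng: random.Random, max_bands: int = 6) -> BandPattern:
    """A valid gel lane: descending lengths separated by >= 10 bp."""
    n = rng.randint(1, max_bands)
    lengths = rng.sample(range(3, 160), n)  # multiples of 10 via scaling
    return BandPattern(tuple(sorted((x * 10 for x in lengths), reverse=True)))


def random_restriction_map(rng: random.Random, n_entries: int = 8,
                           n_enzymes: int = 5) -> RestrictionMap:
    """A synthetic map with arbitrary (but valid) band patterns per cell."""
    entries = tuple(
        TaxonEntry(f"T{i:02d}", (f"T{i:02d}",),
                   (NucleotideSequence(f"T{i:02d}/c1", "ACGTACGT"),))
        for i in range(n_entries))
    pool = tuple(RestrictionEnzyme(f"Z{j}", "AACGTT", 2)
                 for j in range(n_enzymes))
    patterns = {(e.entry_id, z.name): random_band_pattern(rng)
                for e in entries for z in pool}
    return RestrictionMap(entries, pool, patterns)


# derandomized hypothesis: identical example sequences on every run
from hypothesis import settings as _settings

_settings.register_profile("deterministic", derandomize=True)
_settings.load_profile("deterministic")
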