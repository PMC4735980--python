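#!/usr/bin/env python
"""Optional verification against real GenBank genomes (requires network).

Downloads four Lactobacillus genomes from NCBI and checks the pipeline's
behaviour on real data:

* CP000233 (L. salivarius UCC118): leftmost 8F hit on the genome at 74,520,
  amplicon interior starting at 74,540;
* CP002764 (L. kefiranofaciens ZW3): exactly 4 amplicons with 8F/1541R;
* CP000416 (L. brevis ATCC 367): pooled HinfI lane of the 16S amplicons,
  expected 7 bands (976/891/379/243/136/117/86 bp);
* CP000156 (L. delbrueckii subsp. bulgaricus 2038): HinfI observable band
  count 4 for the multi-site 16S copy.

These are reported, not asserted: annotation revisions at NCBI since the
source datasets were frozen can legitimately shift the numbers.

Usage:  python scripts/accession_checks.py --email you@example.org
"""

import argparse
import sys
import tempfile
from pathlib import Path

from Bio import Entrez

from ardrakit import (
    build_restriction_map,
    collapse_identical,
    default_enzymes,
    default_primers,
    find_primer_sites,
    in_silico_pcr,
    read_genbank,
)


def fetch(accession: str, workdir: Path) -> Path:
    path = workdir / f"{accession}.gbk"
    if not path.exists():
        with Entrez.efetch(db="nucleotide", id=accession, rettype="gbwithparts",
                           retmode="text") as handle:
            path.write_text(handle.read())
    return path


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True,
                        help="contact email for NCBI Entrez")
    parser.add_argument("--workdir", type=Path,
                        default=Path(tempfile.gettempdir()) / "ardrakit_gbk")
    args = parser.parse_args()
    Entrez.email = args.email
    args.workdir.mkdir(parents=True, exist_ok=True)

    primers = default_primers()
    fwd, rev = primers["8F"], primers["1541R"]
    hinfi = default_enzymes()["HinfI"]

    ucc118 = read_genbank(fetch("CP000233", args.workdir))
    plus, _ = find_primer_sites(ucc118.sequence, fwd)
    amps = in_silico_pcr(ucc118.sequence, fwd, rev)
    first = min(amps, key=lambda a: a.fwd_match_start)
    print(f"CP000233 leftmost 8F hit: {min(plus)} (expected 74520)")
    print(f"CP000233 first interior start: "
          f"{first.fwd_match_start + len(fwd)} (expected 74540)")

    zw3 = read_genbank(fetch("CP002764", args.workdir))
    amps = in_silico_pcr(zw3.sequence, fwd, rev)
    print(f"CP002764 amplicons with 8F/1541R: {len(amps)} (expected 4)")

    brevis = read_genbank(fetch("CP000416", args.workdir))
    amps = in_silico_pcr(brevis.sequence, fwd, rev)
    entries = collapse_identical([("brevis", [a.interior for a in amps])])
    rmap = build_restriction_map(entries, [hinfi])
    lane = rmap.pattern("brevis", "HinfI")
    print(f"CP000416 pooled HinfI lane: {lane.count} bands {lane.bands} "
          f"(expected 7: 976/891/379/243/136/117/86)")

    delb = read_genbank(fetch("CP000156", args.workdir))
    amps = in_silico_pcr(delb.sequence, fwd, rev)
    entries = collapse_identical([("delb", [a.interior for a in amps])])
    rmap = build_restriction_map(entries, [hinfi])
    lane = rmap.pattern("delb", "HinfI")
    print(f"CP000156 pooled HinfI band count: {lane.count} "
          f"(in-text per-copy observable count was 4)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
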