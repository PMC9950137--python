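#!/usr/bin/env python
"""Extended consistency checks against the study's deposited data.

These checks need files that must be downloaded first (they are not bundled
and the package never fetches anything):

- a FASTA with the deposited ancestor proteins (GenBank OP381052-OP381055),
  with ids containing "tAncFMO1-5", "tAncFMO5", "tAncFMO1-4", "tAncFMO1-3";
- the study's supplementary 536-sequence alignment FASTA.

Usage:
    python scripts/extended_checks.py --ancestors ancestors.fasta \
        --msa supplementary_msa.fasta
"""

from __future__ import annotations

import argparse
import sys

from paleofmo.formats import read_fasta

EXPECTED_LENGTH = 532
EXPECTED_BRANCH_SUBSTITUTIONS = 45
EXPECTED_MSA_SEQUENCES = 536
EXPECTED_MSA_COLUMNS = 537


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def check_ancestors(path: str) -> bool:
    records = {}
    aln = read_fasta(path)
    for sid in aln.ids:
        for tag in ("tAncFMO1-5", "tAncFMO1-4", "tAncFMO1-3", "tAncFMO5"):
            if tag in sid.replace("–", "-"):
                records[tag] = aln.row(sid).replace("-", "")
    ok = True
    for tag, seq in sorted(records.items()):
        status = "OK" if len(seq) == EXPECTED_LENGTH else "MISMATCH"
        ok &= len(seq) == EXPECTED_LENGTH
        print(f"{tag}: length {len(seq)} (expected {EXPECTED_LENGTH}) {status}")
    if "tAncFMO1-5" in records and "tAncFMO1-4" in records:
        d = hamming(records["tAncFMO1-5"], records["tAncFMO1-4"])
        status = "OK" if d == EXPECTED_BRANCH_SUBSTITUTIONS else "MISMATCH"
        ok &= d == EXPECTED_BRANCH_SUBSTITUTIONS
        print(
            f"tAncFMO1-5 vs tAncFMO1-4: {d} substitutions "
            f"(expected {EXPECTED_BRANCH_SUBSTITUTIONS}) {status}"
        )
    else:
        print("could not find both branch endpoints in the ancestors FASTA")
        ok = False
    return ok


def check_msa(path: str) -> bool:
    aln = read_fasta(path)
    ok = (aln.n_seqs == EXPECTED_MSA_SEQUENCES
          and aln.n_sites == EXPECTED_MSA_COLUMNS)
    print(
        f"MSA: {aln.n_seqs} sequences x {aln.n_sites} columns "
        f"(expected {EXPECTED_MSA_SEQUENCES} x {EXPECTED_MSA_COLUMNS}) "
        f"{'OK' if ok else 'MISMATCH'}"
    )
    return ok


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--ancestors", help="FASTA of deposited ancestors")
    parser.add_argument("--msa", help="supplementary alignment FASTA")
    args = parser.parse_args()
    if not args.ancestors and not args.msa:
        parser.error("give --ancestors and/or --msa")
    ok = True
    if args.ancestors:
        ok &= check_ancestors(args.ancestors)
    if args.msa:
        ok &= check_msa(args.msa)
    sys.exit(0 if ok else 1)


if __name__ == "__main__":
    main()
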