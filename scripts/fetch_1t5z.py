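#!/usr/bin/env python
"""Optional, network-dependent check of the native-pair count on PDB 1T5Z.

Downloads the AR-LBD/DHT crystal structure from RCSB, identifies every
heavy-atom pair within 0.45 nm across the 34 channel residue pairs, and
prints the resulting pair count m (the production contact definition).
Not part of the offline test suite.

Usage:
    python scripts/fetch_1t5z.py [--cutoff 0.45] [--pdb path/to/1T5Z.pdb]
"""

import argparse
import urllib.request
from pathlib import Path

from funnelmd.colvars import AR_CHANNEL_RESIDUE_PAIRS, identify_native_pairs
from funnelmd.io import read_structure

URL = "https://files.rcsb.org/download/1T5Z.pdb"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cutoff", type=float, default=0.45, help="nm")
    ap.add_argument("--pdb", type=Path, default=Path("scratch/1T5Z.pdb"))
    args = ap.parse_args()

    if not args.pdb.exists():
        args.pdb.parent.mkdir(parents=True, exist_ok=True)
        print(f"downloading {URL} ...")
        urllib.request.urlretrieve(URL, args.pdb)

    ref = read_structure(args.pdb)
    cdef = identify_native_pairs(ref, AR_CHANNEL_RESIDUE_PAIRS,
                                 cutoff=args.cutoff)
    print(f"m = {cdef.m} native heavy-atom pairs at cutoff "
          f"{args.cutoff:.2f} nm across {len(AR_CHANNEL_RESIDUE_PAIRS)} "
          "residue pairs")


if __name__ == "__main__":
    main()
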