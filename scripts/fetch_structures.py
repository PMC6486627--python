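"""Explicit, opt-in download of the deposited coordinate entries into the
local cache used by `helicore.structure.read_structure` accession lookup.

    python scripts/fetch_structures.py [--cache pdb_cache]

Fetches the Prp22/Prp43 entries analyzed by the pipeline (the two apo
Prp22 forms, the Prp22-RNA complex, the motif V serine mutants, and the
nucleotide-bound reference structures).  Requires network access; the
analysis code itself never touches the network.
"""

import argparse

from helicore.cli import fetch

ENTRIES = ["6i3o", "6i3p", "6qic", "6qid", "6qie", "5lta", "5ltj", "6fa5"]

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--cache", default="pdb_cache")
    args = ap.parse_args()
    fetch.callback(ENTRIES, args.cache)
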