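#!/usr/bin/env python
"""Fetch the public COI records used by the printed-distance checks.

Downloads the GenBank nucleotide records listed below (NCBI E-utilities,
plain FASTA) into ``data/genbank_coi.fasta``. This is the only place in
the repository that performs network I/O; the library itself never does.
Run it once, online, before the optional accession-based acceptance
checks:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import time
import urllib.request
from pathlib import Path

#: accession -> species label
ACCESSIONS = {
    "OP700782": "Lymantria dispar asiatica",
    "OP700785": "Lymantria apicebrunnea",
    "HM775840": "Lymantria schaeferi",
    "HM775854": "Lymantria umbrosa",
    "HM418030": "Lymantria dispar dispar",
    "KY923061": "Lymantria dispar japonica",
    "LC406184": "Lymantria albescens",
    "LC406195": "Lymantria postalba",
    "MW085568": "Lymantria xylina",
}

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nucleotide&id={acc}&rettype=fasta&retmode=text"
)


def main() -> int:
    out_path = Path(__file__).resolve().parents[1] / "data" / "genbank_coi.fasta"
    out_path.parent.mkdir(exist_ok=True)
    chunks = []
    for acc in ACCESSIONS:
        url = EFETCH.format(acc=acc)
        sys.stderr.write(f"fetching {acc}...\n")
        with urllib.request.urlopen(url, timeout=60) as response:
            text = response.read().decode()
        if not text.startswith(">"):
            sys.stderr.write(f"unexpected response for {acc}\n")
            return 1
        chunks.append(text.strip() + "\n")
        time.sleep(0.4)  # NCBI rate courtesy
    out_path.write_text("".join(chunks))
    sys.stderr.write(f"wrote {len(ACCESSIONS)} records to {out_path}\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
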