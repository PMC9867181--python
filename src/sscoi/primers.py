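"""Published primer sequences used throughout tests and examples.

All sequences are written 5'->3'. SPONGY_MOTH_FWD/REV are the
species-specific diagnostic pair for the Asian spongy moth; the other two
pairs are universal COI barcode/fragment primers (degenerate IUPAC codes
in the universal fragment pair).
"""

#: Species-specific diagnostic pair (ASMF / ASMR).
SPONGY_MOTH_FWD = "CCTTCTACTTTTATCTTTACCTGTT"
SPONGY_MOTH_REV = "ATTGTAGCAGAGGTAAAG"

#: Universal barcode pair (LCO1490 / HCO2198).
BARCODE_FWD = "GGTCAACAAATCATAAAGATATTGG"
BARCODE_REV = "TAAACTTCAGGGTGACCAAAAAATCA"

#: Universal COI fragment pair with degenerate positions (C1-J1709 / C1-N2776).
COI_FRAGMENT_FWD = "AATTGGWGGWTTYGGAAAYTG"
COI_FRAGMENT_REV = "GGTAATCAGAGTATCGWCGNGG"
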