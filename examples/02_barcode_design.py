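"""Design a 72-plex variable-length barcode set and its adapter oligos.

Builds a decodable set of 4-8 nt barcodes, validates it against the
AvaII cut-site remnant, and prints the adapter oligo pair for the first
sample.
"""

from ggrs.barcodes import build_adapter, design_barcode_set, validate_barcode_set

bset = design_barcode_set(n=72, seed=0)
report = validate_barcode_set(bset)

lengths = sorted({len(s) for s in bset.sequences})
print(f"designed {len(bset)} barcodes, lengths {lengths}")
print(f"decodable against remnant GWC: {report['valid']}")

first = bset.barcodes[0]
pair = build_adapter(first)
print(f"\nsample {first.sample_id}, barcode {first.sequence}")
print(f"plus strand : 5'-{pair.plus_strand}-3'")
print(f"minus strand: 5'-{pair.minus_strand}-3'")

# 'valid' means no read prefix can parse as barcode+remnant under two
# different barcodes, so demultiplexing the pooled lane is unambiguous.
# The minus strand starts with the GWC overhang that ligates into the
# AvaII cut, followed by the reverse complement of the barcode.
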