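"""Design a reduced-representation experiment by in-silico digestion.

Digests a simulated 100 kb reference with AvaII (GGWCC, cutting G^GWCC),
applies the 200-300 bp size window, and prints the coverage and yield
statistics an experimenter would use to pick an enzyme and window.
"""

from ggrs.digest import EnzymeSpec, SizeWindow, digest_genome, summarize_digest
from ggrs.simulate import SimConfig, simulate_reference

config = SimConfig(seed=1, genome_length=100_000, n_individuals=1)
genome, truth = simulate_reference(config)

enzyme = EnzymeSpec()  # AvaII: GGWCC, cut offsets 1/4, overhang GWC
fragments = digest_genome(genome, enzyme)
summary = summarize_digest(
    fragments, SizeWindow(200, 300), genome.total_length, read_len=100, genome=genome
)

print(f"enzyme {enzyme.name}: motif {enzyme.recognition}, overhang {enzyme.overhang}")
print(f"cut sites:            {summary.n_sites}")
print(f"fragments:            {summary.n_fragments_total}")
print(f"selected (200-300bp): {summary.n_fragments_selected}")
print(f"coverage fraction:    {summary.coverage_fraction:.4f}")
print(f"2x100 yield (bases):  {summary.expected_sequenced_bases}")

# The coverage fraction is the genome share sequencing will concentrate on;
# the yield is the number of genomic bases a 2x100 paired-end run reads per
# library copy of each selected fragment.
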