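"""Enumerate the 3F zinc-finger library and its target-site statistics.

Sixteen finger modules, one per 5'-GNN-3' triplet, combine into 16^3
ordered three-finger arrays; each array is predicted to bind one 9-bp
site.  The expected frequency of such a site in random DNA sets the scale
of a genome-interrogation screen.
"""

from zfscreen import (
    compile_pattern,
    enumerate_fingers,
    enumerate_library,
    expected_genome_occurrences,
    expected_site_spacing,
)

fingers = enumerate_fingers()
print(f"finger modules: {len(fingers)} ({fingers[0].triplet} .. {fingers[-1].triplet})")

library = enumerate_library()
subpool = enumerate_library(founder="GAG")
print(f"full library: {len(library)} 3F arrays; GAG-founder subpool: {len(subpool)}")

# the recognition site of one screen isolate
pattern = compile_pattern("GGTGATGGA")
spacing = expected_site_spacing(pattern)
occurrences = expected_genome_occurrences(pattern, 1.3e8)
print(f"exact site {pattern.site}: one hit per {spacing:,.0f} bp (both strands)")
print(f"expected occurrences in a 1.3e8-bp genome: {occurrences:,.0f}")
# ~131,072 bp spacing and ~992 genome-wide occurrences: each library member
# addresses on the order of a thousand loci in an Arabidopsis-sized genome.
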