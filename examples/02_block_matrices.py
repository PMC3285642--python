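"""Sector-block density and reciprocity change tables.

Computes within/between-sector tie densities (union counting: a tie counts
whichever member reported it) and directional reciprocation shares for both
waves, then renders the change tables in the conventional
"delta (early-late)" whole-percent format.
"""

from sectornet import (
    GeneratorConfig,
    block_change,
    block_density,
    block_reciprocity,
    format_block_change,
    generate_dataset,
)

ds = generate_dataset(GeneratorConfig(), seed=7)
roster = ds.roster

density_change = block_change(
    block_density(ds.waves.year4, roster),
    block_density(ds.waves.inception, roster),
)
print("Density change by sector block, % (inception-year4):")
print(format_block_change(density_change, layout="upper").to_string())

reciprocity_change = block_change(
    block_reciprocity(ds.waves.year4, roster),
    block_reciprocity(ds.waves.inception, roster),
)
print("\nReciprocity change by sector block, % (columns = reporting sector):")
print(format_block_change(reciprocity_change, layout="full", nan_as="0").to_string())

# A cell like "16 (19-35)" reads: the block's level rose 16 points, from 19%
# to 35%.  "n/a" marks blocks with no within-group pairs (singleton sectors).
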