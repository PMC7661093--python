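"""Mint stable, content-derived taxon identifiers.

The taxonID is <dataset shortname>:taxon:<32-hex digest of the scientific
name>. Because the digest depends only on the name, identifiers survive row
insertion, deletion and reordering across checklist releases.
"""

from dwcforge.mapping import mint_taxon_id

for name in ("Acanthus mollis L.", "Acanthus spinosus L.", "Fallopia japonica (Houtt.) Ronse Decr."):
    print(f"{name:42s} -> {mint_taxon_id(name, 'Plantae', 'alien-plants-belgium')}")

a = mint_taxon_id("Acanthus mollis L.", "Plantae", "alien-plants-belgium")
b = mint_taxon_id("Acanthus mollis L.", "Plantae", "alien-plants-belgium")
print(f"\ndeterministic: {a == b}")
# The first two identifiers are the published reference values for the
# Belgian alien-plants checklist: any compatible pipeline must mint exactly
# these digests for these names.
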