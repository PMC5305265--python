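"""The exhaustive complexity atlas of the octagon sequence space.

All 5040 sequences of 8 distinct vertices from a fixed origin are scored
with their complexity K and with resource flags (does reaching K require
the point symmetry P? nested repetitions?).  768 sequences are
incompressible: their shortest description is the plain list of their
transitions (K = 16).
"""

import json

from geomlang import ComplexityAtlas

atlas = ComplexityAtlas.build(origin=0)
print(json.dumps(atlas.stats(), indent=1))

rec = atlas.lookup((0, 2, 4, 6, 1, 3, 5, 7))
print("2squares record:", rec.K, rec.witness_texts(),
      "uses_P:", rec.uses_P, "uses_nesting:", rec.uses_nesting)

# Histogram runs from K=5 (the two plain progressions) to K=16 (768
# incompressible sequences).  The 2squares record shows uses_nesting=True:
# its cost-8 witness nests a repetition inside the variation figure, and
# without nesting its best description costs more.
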