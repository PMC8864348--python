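"""From occurrence records to the complementary sample.

Builds a toy occurrence table for four cactus genera plus relatives,
derives the taxonomic tree, takes three genera as taxa of interest,
and computes the complementary taxa (the rest of the family) and the
per-cell three-state complementary response y^c used to identify the
sampling-effort process.
"""

import numpy as np
import pandas as pd

from pojsdm import (
    build_grid_lattice, build_tree, complementary_taxa,
    complementary_response, presence_response, records_to_cells,
)

rng = np.random.default_rng(0)

# a 6x6 degree grid and 120 occurrence records of six genera
lattice = build_grid_lattice((-110.0, 20.0, -104.0, 26.0), 1.0)
genera = ["Mammillaria", "Coryphantha", "Echinocactus",
          "Opuntia", "Ferocactus", "Ariocarpus"]
records = pd.DataFrame({
    "family": "Cactaceae",
    "genus": rng.choice(genera, size=120),
    "decimalLongitude": rng.uniform(-110, -104, size=120),
    "decimalLatitude": rng.uniform(20, 26, size=120),
})

tree = build_tree(records, ranks=("family", "genus"))
print("taxonomic tree (newick):")
print(" ", tree.to_newick())

toi = ["Mammillaria", "Coryphantha", "Echinocactus"]
spec = complementary_taxa(tree, toi)
print(f"taxa of interest: {toi}")
print(f"lowest common ancestor: {spec.lca[-1]}")
print("complementary taxa (informed background):",
      [t[-1] for t in spec.complement_taxa])

cells = records_to_cells(records, lattice)
y_c = complementary_response(tree, spec, cells, lattice,
                             missing_policy="no-information-missing")
print(f"complementary response over {lattice.n_cells} cells: "
      f"{y_c.n_present} presences, {y_c.n_absent} pseudo-absences, "
      f"{y_c.n_missing} missing")
print("  (presence = a relative was recorded there; pseudo-absence = only")
print("   a focal taxon was; missing = no record of anything at all)")

y0 = presence_response(tree, "Mammillaria", cells, lattice)
print(f"Mammillaria occupies {y0.n_present} cells")
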