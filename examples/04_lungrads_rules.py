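"""Assign Lung-RADS categories from the shipped rule table.

Texture picks the branch, margin refines it for subsolid nodules, and size
picks the category; the table is YAML data validated for totality and
determinism, so a revision of the standard is a config edit, not code.
"""

from lungreport import (
    MarginLabel,
    TextureLabel,
    assign_category,
    default_rule_table,
    enumerate_truth_table,
)

table = default_rule_table()
print(f"rule table version: {table.version} ({len(table.rules)} rules)")

cases = [
    (TextureLabel.SOLID, MarginLabel.LOBULATED, 5.0),
    (TextureLabel.SOLID, MarginLabel.SPICULATED, 16.0),
    (TextureLabel.PURE_GGO, MarginLabel.SHARP_CIRCUMSCRIBED, 31.0),
    (TextureLabel.SUBSOLID, MarginLabel.LOBULATED, 7.0),
    (TextureLabel.SUBSOLID, MarginLabel.SPICULATED, 9.0),
]
for texture, margin, size in cases:
    category = assign_category(texture, margin, size, table)
    print(f"  ({texture.value:8s}, {margin.value:18s}, {size:4.1f} mm) "
          f"-> Lung-RADS {category.value}")

rows = enumerate_truth_table(table, [1, 7, 10, 20, 40])
print(f"truth table over a 5-size grid: {len(rows)} rows "
      f"(3 textures x 4 margins x 5 sizes)")
# Higher categories mean more suspicious findings: a 16 mm solid spiculated
# nodule is 4B, while a 31 mm pure ground-glass nodule is only category 3.
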