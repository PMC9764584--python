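"""Render the 3x3 PMC surface of one strong and one weak policy.

The first nine primary scores are arranged column-major into a 3x3 matrix and
drawn as a 3-D surface with the z-axis fixed to [0, 1]; depressions mark the
evaluation dimensions where the policy text falls short.
"""

import pmcindex as pmc

schema = pmc.default_schema()
table, _ = pmc.load_sichuan_fixture()
scores = {s.policy_id: s for s in pmc.score_policies(table, schema)}

for pid in ("P7", "P33"):
    mat = pmc.surface_matrix(scores[pid])
    out = pmc.render_surface(mat, f"surface_{pid}.png")
    lowest = mat.cells.min()
    print(f"{pid} (grade {mat.grade}): cells =")
    print(mat.cells)
    print(f"  deepest cell {lowest:.3f} -> wrote {out}")
# P7's only dents are X4 (incentives) and X8 (issuing agency); P33 sags
# everywhere and scores zero on X4, which is why it grades D.
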