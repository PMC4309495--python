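"""Measure oligodendrocyte territory diameters on synthetic culture fields.

Emulates the five-field coverslip sampling: five 1 mm^2 fields of branched
cells whose territory diameters come from a compact/arborized mixture (28%
above the 70 um cutoff, the control-culture regime). Each field is
segmented, each cell's minimal enclosing circle is measured, and the cells
are classified at 70 um.
"""

from oligono import (
    ArborFieldSpec,
    classify_and_summarize,
    generate_arbor_field,
    measure_territories,
    select_fields,
)

print("five-field positions on a 13 mm coverslip (mm from center):")
print(" ", select_fields(coverslip_diameter=13.0, field_side=1.0))

territories = []
for i in range(5):
    field, truth = generate_arbor_field(ArborFieldSpec(n_cells=40, frac_large=0.28, seed=i))
    territories += measure_territories(field, threshold=50.0)

summary = classify_and_summarize(territories, cutoff=70.0, include_border=True)
print(f"cells measured: {summary.n_cells}")
print(f"% of cells with territory diameter > {summary.cutoff:.0f} um: "
      f"{summary.pct_above_cutoff:.1f}%")
print(f"mean diameter of those arborized cells: "
      f"{summary.mean_diameter_above_cutoff:.1f} um")
# The recovered percentage tracks the generator's sampled fraction to within
# binomial sampling error; diameters are exact to ~1 pixel (2 um here).
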