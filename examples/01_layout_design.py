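"""Design a screening array layout and write it as a GAL file.

Builds the reference sub-array (108 x 36 spots of 200 um at 500 um pitch,
16 printing pins), places a 492-gene x 2-construct siRNA library plus 5%
negative controls, and reports the geometry and reagent economics.
"""

import csma

layout = csma.build_layout(108, 36, pitch_um=500, diameter_um=200, n_wells=1, n_pins=16)
sheet = csma.SampleSheet.from_gene_list([f"GPCR{i:03d}" for i in range(492)], constructs_per_gene=2)
layout = csma.assign_samples(layout, sheet, control_fraction=0.05, seed=0)

df = layout.to_frame()
n_ctrl = (df.sample_id == csma.CONTROL_ID).sum()
print(f"spots per sub-array : {layout.n_spots}")
print(f"lattice extent      : {df.x_um.max()/1000:.1f} x {df.y_um.max()/1000:.1f} mm")
print(f"targets / controls  : {len(sheet.targets)} / {n_ctrl}")
print(f"siRNA fold saving   : {csma.reagent_ratio(10e-9, 50e-12):.0f}x (10 ng/well vs 50 pg/spot)")

csma.write_gal(layout, "gpcr_subarray.gal")
print("layout written to gpcr_subarray.gal")
# The 3,888-spot lattice fits the 18 x 54 mm printable area; four such
# sub-arrays give 15,552 spots on one microplate-sized vessel.
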