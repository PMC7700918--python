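"""Generate a synthetic breast phantom and inspect its structures.

The phantom stands in for a planning CT with approved contours: a
half-cylindrical thorax, a breast bulge (the PTV), lungs, heart,
contralateral breast and the anterior midline tattoo used to pin the
tangent fields.
"""

from tangentplan import PhantomConfig, generate_phantom

patient = generate_phantom(PhantomConfig(seed=1, laterality="left"))

print(f"grid {patient.shape} at {patient.spacing} cm, laterality {patient.laterality}")
print(f"tattoo (anterior midline skin): {patient.tattoo.round(2)} cm")
vol = patient.spacing**3
for name, mask in patient.structures.items():
    print(f"  {name:22s} {mask.sum():8d} voxels  ({mask.sum() * vol:7.1f} cm^3)")

# The planning PTV is the whole-breast PTV retracted 5 mm from the skin,
# keeping the optimizer out of the surface build-up region.
ptv = patient.structures["PTV_Breast"].sum()
ptvp = patient.structures["PTV_planning"].sum()
print(f"skin retraction removed {100 * (1 - ptvp / ptv):.1f}% of PTV voxels")
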