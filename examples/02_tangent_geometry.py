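"""Build the tangential beam geometry for a phantom.

The posterior field edge is a line through the midline tattoo, rotated
until the planning target (plus margin) is covered with the least body
tissue in the field.  Its intersections with the skin at the PTV
mid-plane are the medial and posterior borders, from which the gantry
angles (simple arctangent rules), the isocenter (mid-separation on the
nondivergent posterior edge, snapped to whole-cm shifts from the tattoo)
and the energy selection (mixed 6/18 MV beyond 25 cm separation) follow.
"""

from tangentplan import PhantomConfig, build_tangent_geometry, generate_phantom

for laterality in ("left", "right"):
    patient = generate_phantom(PhantomConfig(seed=1, laterality=laterality))
    geom = build_tangent_geometry(patient)
    b = geom.borders
    print(f"{laterality}-sided patient:")
    print(f"  medial border    ({b.x_m:6.2f}, {b.y_m:6.2f}) cm")
    print(f"  posterior border ({b.x_p:6.2f}, {b.y_p:6.2f}) cm")
    print(f"  separation       {b.separation:5.1f} cm -> energies {geom.energies} MV")
    print(f"  gantry angles    medial {geom.theta_medial:.0f} deg, lateral {geom.theta_lateral:.0f} deg")
    print(f"  isocenter        {geom.isocenter.round(2)} cm (posterior jaw 0.0)")
    tips = geom.beams[0].leaf_tips
    print(f"  aperture         {len(tips)} leaf rows, max tip {tips.max():.1f} cm (2 cm flash)")
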