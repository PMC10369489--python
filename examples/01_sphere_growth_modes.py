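"""Classify sphere-model dimers by their polymerization angles.

Builds idealized two-sphere dimers at a few (theta_pol, phi_pol) pairs,
propagates each into a 32-monomer chain and prints the growth verdict.
"""

from dimergrow import build_sphere_dimer, classify_sphere_growth, propagate_chain

CASES = [
    (81.0, 160.0),   # an open, gently zigzagging chain
    (123.0, 16.0),   # a wide helix
    (38.0, 24.0),    # folds straight back onto itself
    (78.0, 20.0),    # closes into a ring
    (180.0, 0.0),    # perfectly straight
]

print(f"{'theta':>6} {'phi':>6} {'mode':>10} {'subtype':>9} "
      f"{'min dist':>9} {'omega':>7} {'pitch':>7}")
for theta, phi in CASES:
    cls = classify_sphere_growth(theta, phi, n=32)
    print(
        f"{theta:6.1f} {phi:6.1f} {cls.mode:>10} {cls.subtype:>9} "
        f"{cls.min_nonadjacent_distance:9.2f} {cls.screw_angle:7.1f} "
        f"{cls.screw_pitch:7.2f}"
    )

# "min dist" is the closest approach of non-adjacent unit spheres along the
# chain: below 2*(1-0.05) the chain collides with itself (limited growth).
# omega/pitch are the per-step screw rotation (deg) and axial advance.

chain = propagate_chain(build_sphere_dimer(81.0, 160.0), 32)
print(f"\n(81, 160) chain end-to-end length: "
      f"{((chain.centers[-1] - chain.centers[0]) ** 2).sum() ** 0.5:.1f} "
      f"sphere radii over 32 monomers (an extended, unlimited chain)")
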