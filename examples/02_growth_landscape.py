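"""Scan the (theta_pol, phi_pol) growth landscape and fit its boundary.

Classifies every cell of the 5-degree grid with 32-monomer sphere chains,
fits the limited/unlimited transition with a three-parameter exponential
and classifies a few query points against the fitted boundary.
"""

from dimergrow import classify_region, scan_landscape

landscape = scan_landscape(step=5.0, n=32, delta=0.05)

a, b, c = landscape.fit_params
print(f"grid: {len(landscape.thetas)} x {len(landscape.phis)} cells")
print(f"smallest theta with any unlimited dihedral: "
      f"{landscape.smallest_unlimited_theta():.0f} deg")
print(f"boundary fit: theta*(phi) = {a:.1f} * exp({b:.4f} * phi) + {c:.1f}")
print(f"fit residual RMS: {landscape.fit_residual_rms:.2f} deg "
      f"(below the 5-degree grid step)")

# the transition is steep at small dihedrals (near-planar chains close into
# rings up to high theta) and flattens to a ~55-degree plateau where the
# head-to-head fold-back alone limits growth
for phi in (0.0, 30.0, 90.0, 180.0):
    print(f"  theta*({phi:5.1f}) = {float(landscape.theta_star(phi)):6.1f} deg")

print("\nregion lookups (limited / uncertain / unlimited):")
for theta, phi in [(30.0, 40.0), (60.0, 90.0), (123.0, 16.0), (170.0, 90.0)]:
    print(f"  ({theta:5.1f}, {phi:5.1f}) -> {classify_region(landscape, theta, phi)}")

# uncomment to export the landscape:
# landscape.to_frame().to_csv("landscape.tsv", sep="\t", index=False)
# from dimergrow.landscape import plot_landscape; plot_landscape(landscape, "landscape.png")
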