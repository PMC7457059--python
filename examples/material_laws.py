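"""Evaluate the three constitutive laws and the Mooney-Rivlin joint fit.

Prints the derived bone moduli, ligament stiffness/force at a few strains,
the sacrocaudal joint tangent modulus and stress, and the fitted 3-parameter
Mooney-Rivlin coefficients with their worst relative residual.
"""

from sijstrain import JointLaw, LigamentLaw, derive_isotropic, fit_mooney_rivlin

bone = derive_isotropic(1.7e10, 0.3)
print(f"bone: E = {bone.E:.3e} Pa, nu = {bone.nu}")
print(f"  bulk modulus  K = {bone.K:.4e} Pa")
print(f"  shear modulus G = {bone.G:.4e} Pa")

lig = LigamentLaw()
print("\nligament (tension-only piecewise stiffness):")
for strain in (0.01, 0.03, 0.07, 0.12, -0.05):
    print(
        f"  strain {strain:+.2f}: stiffness {lig.stiffness(strain):6.1f} N/mm, "
        f"force at L0=10 mm {lig.force(strain, 10.0):7.3f} N"
    )

joint = JointLaw()
print("\nsacrocaudal joint (compression-only):")
for eps in (0.05, 0.10, 0.20):
    print(
        f"  compressive strain {eps:.2f}: tangent modulus "
        f"{joint.tangent_modulus(eps):6.3f} MPa, stress {joint.stress(eps):7.4f} MPa"
    )

mr = fit_mooney_rivlin(joint)
print("\n3-parameter Mooney-Rivlin fit to the joint stress curve:")
print(f"  c10 = {mr.c10:+.4f} MPa, c01 = {mr.c01:+.4f} MPa, c11 = {mr.c11:+.4f} MPa")
print(f"  fitted over compressive strain {mr.fit_range}, "
      f"max relative error {mr.max_rel_error:.2%}")
print("A residual under 2% means the hyperelastic surrogate can stand in for")
print("the polynomial joint law across the working compression range.")
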