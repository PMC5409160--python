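"""Expected shear wave speeds of the study materials.

For a nearly incompressible elastic solid the shear wave speed is
c_T = sqrt(E / (2 rho (1 + nu))).  The four phantom materials (background
and three lesions) land on round speeds, which is why they were chosen.
"""

from shearwave import MaterialSpec, shear_wave_speed, shear_impedance, reflection_coefficient

background = MaterialSpec(E=3.0, rho=1.0, nu=0.495)
print("material   E (kPa)   c_T (m/s)   Z (g/cm^3 * m/s)")
for name, e_kpa in [("background", 3.0), ("lesion A", 6.0), ("lesion B", 12.0), ("lesion C", 18.75)]:
    m = MaterialSpec(E=e_kpa, rho=1.0, nu=0.495)
    print(f"{name:<10} {e_kpa:7.2f}   {shear_wave_speed(m):9.3f}   {shear_impedance(m):7.3f}")

print()
for e_kpa in (6.0, 12.0, 18.75):
    r = reflection_coefficient(background, MaterialSpec(E=e_kpa))
    print(f"reflection coefficient background -> {e_kpa} kPa lesion: R = {r:+.3f}")
print("\nLarger impedance mismatch -> stronger reflected wave -> stronger "
      "reflection artifact in the speed image.")
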