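"""Unit system: Å, kcal/mol, ps, amu, Kelvin (the Amber convention).

Velocities are in Å/ps.  ``ACCEL_FACTOR`` converts a force in
kcal mol⁻¹ Å⁻¹ acting on a mass in amu into an acceleration in Å ps⁻²;
its inverse converts m·v² into kcal/mol for kinetic energies.
"""

#: Boltzmann constant, kcal mol⁻¹ K⁻¹.
KB = 0.0019872041

#: (kcal mol⁻¹ Å⁻¹ / amu) → Å ps⁻².  1 kcal/mol = 4184 J/mol.
ACCEL_FACTOR = 418.4

#: amu (Å/ps)² → kcal/mol, for kinetic energy.
KE_FACTOR = 1.0 / ACCEL_FACTOR
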