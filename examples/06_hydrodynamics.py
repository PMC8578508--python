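"""Sedimentation-velocity utilities: s20,w correction and shape analysis."""

import phosdim as P

# correct an observed s to standard conditions (water, 20 C)
buffer = P.SolventConditions(density=1.008, viscosity=0.0105, label="Tris/NaCl")
s_obs = 5.1
s_std = P.s20w(s_obs, buffer)
print(f"s_obs = {s_obs:.2f} S in {buffer.label} -> s20,w = {s_std:.2f} S")

# shape of a dimer: frictional ratio at the measured s
mass_dimer = 2 * 82415.3  # Da
ratio = P.frictional_ratio(mass_dimer, s_std)
s_sphere = P.sphere_s(mass_dimer)
print(f"dimer of {mass_dimer:,.0f} Da: sphere limit {s_sphere:.2f} S, "
      f"measured {s_std:.2f} S -> f/f0 = {ratio:.2f}")
print("f/f0 = 1 is a compact anhydrous sphere; larger values indicate an "
      "elongated or expanded conformation (vbar = 0.73 cm^3/g).")
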