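"""EX1 kinetics detection from isotopic envelopes.

The demo system contains a segment (residues 41-52) that unfolds
cooperatively in the unphosphorylated state.  Peptides covering it show
bimodal envelopes whose light component decays with time; the classifier
flags them EX1 so the differential analysis treats them as "no difference".
"""

import phosdim as P

construct, model = P.demo_system(seed=1)
protocol = P.LabelingProtocol(seed=1)
pmap = P.generate_peptide_map(construct, seed=1)

for pep in pmap.peptides:
    if pep.start >= 40 and pep.end <= 53:  # inside the EX1 segment
        for state in model.states:
            envs = P.simulate_envelopes(model, pep, protocol, state)
            label, fits = P.classify_kinetics(envs)
            ws = ", ".join(
                f"t={e.exposure:g}min w_low={f.w_low:.2f}"
                for e, f in zip(envs[1:], fits) if f.mode == "two"
            )
            print(f"peptide {pep.start}-{pep.end} [{state}]: {label}"
                  + (f"  ({ws})" if ws else ""))

print("\nw_low is the closed-population weight exp(-k_op t): its monotone decay"
      "\nacross consecutive bimodal timepoints is the EX1 signature; the"
      "\nphosphorylated state (no cooperative opening) stays EX2.")
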