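# phosdim

Quantitative analyses for phosphorylation-dependent dimerization studies of
BET-family proteins (BRD4 in particular), built around differential
hydrogen–deuterium exchange mass spectrometry (HDX-MS) and the orthogonal
measurements that typically accompany it: EX1/EX2 kinetic classification
from isotopic envelopes, cross-linking MS (XL-MS) contact topology,
construct mass and motif annotation, NanoBRET dose–response quantification,
and analytical-ultracentrifugation utilities.

The package is aimed at structural biophysicists who have peptide-level
HDX-MS uptake tables (DynamX-cluster-style CSV), cross-link lists, or plate
readings, and want the downstream arithmetic — significance filtering,
residue-level projection, region calling, classification, fitting — to be
scripted, seeded, and testable. A built-in Linderstrøm-Lang exchange
simulator generates realistic synthetic data so every stage can be verified
against known ground truth.

## The core computations

**Differential HDX-MS.** Deuterium uptake of a peptide is the centroid mass
minus the undeuterated centroid, `D(t) = m(t) − m(0)`; no back-exchange
correction is applied. For two states A and B measured in triplicate, a
peptide/timepoint difference `Δ = D̄_A − D̄_B` is significant only when

```
|Δ| > 0.5 Da   and   |Δ| > 2.3 × SD,      SD = sqrt(sd_A² + sd_B²)
```

Per-peptide differences (non-significant timepoints contributing 0, and
EX1-flagged peptides forced to 0) are projected onto residues by averaging
over the N overlapping peptides that contain residue j as an exchanging
position:

```
res_j = (1/N) Σ_i  pep_i / amide_i
```

where `amide_i` counts a peptide's exchanging residues (all but the first,
prolines excluded). Runs of consistently protected residues are then called
as regions.

**EX1 detection.** Envelopes are fit as a single binomial deuteration
distribution and as a two-binomial mixture (each convolved with the fixed
averagine natural envelope). A peptide is EX1 when the mixture is preferred
at ≥2 consecutive timepoints, the modes are ≥2 Da apart, and the
light-population weight `w_low ≈ exp(−k_op t)` decays monotonically.

**XL-MS.** Cross-links unique to the monomer-enriched fraction are
intra-molecular, those unique to the dimer fraction inter-molecular;
self-links (identical residue numbers, e.g. K519–K519) are necessarily
inter-molecular. Allowed chemistry: K–K, K–S, K–T, K–Y.

**NanoBRET.** `mBU = 1000·A610/D450`; one-site total binding
`Y = Bmax·X/(Kd+X) + NS·X` and variable-slope four-parameter logistics
`Y = Bottom + (Top−Bottom)/(1 + 10^((LogX50−X)·Hill))` for EC50/IC50.

**Hydrodynamics.** `s20,w` buffer correction and the Svedberg/frictional
relations `f = M(1−v̄ρ)/(N_A s)`, `f₀ = 6πη(3Mv̄/4πN_A)^{1/3}`, with
v̄ = 0.73 cm³/g.

## Worked example

```python
import pandas as pd, phosdim as P

construct, model = P.demo_system(seed=1, ex1_interval=None)
protocol = P.LabelingProtocol(seed=1)          # 3 s / 0.5 / 50 / 180 min, n=3
pmap = P.generate_peptide_map(construct, seed=1)
table = pd.concat([P.simulate_uptake(model, pmap, protocol, s)
                   for s in model.states], ignore_index=True)
diff = P.differential(table, "unphos", "phos")
profile = P.residue_projection(diff, construct)
print(P.call_protected_regions(profile))
```

prints `[(100, 124, 1)]`: the pipeline recovers the simulated 22-residue
protected segment (truth 101–122) with positive sign, i.e. less exchange in
the phosphorylated state. Running `python examples/02_simulate_and_analyze_hdx.py`
additionally reports `significant peptide-timepoints: 20/184` and a peak
per-residue differential uptake of `0.127 Da at residue 114`. The other
`examples/*.py` scripts demonstrate each capability in the same style, and
the same workflows are scriptable from the shell via the `phosdim` CLI
(`simulate`, `analyze-hdx`, `detect-ex1`, `xl-map`, `bret-fit`, `construct`,
`report`).

## Packaged reference sequence

`phosdim.load_brd4()` returns BRD4 residues 1–722 with domain annotations
(BD1, BD2, NPS, motif B, BID, ET, CPS, PDD). The packaged FASTA is a
literature-validated reconstruction of the UniProt O60885 N-terminal
sequence, not a database download (see the FASTA header): its C-terminal
segments reproduce the published inter-construct mass differences to 0.1 Da
and all motif landmarks (WPF shelves, K519, the 7 NPS and 6 CPS consensus
serines) are at their canonical positions, but the disordered BD1–BD2
linker composition could not be verified offline, so absolute intact masses
computed from it carry that caveat.

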