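# Methods

This note records the models implemented in `phosdim`, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Exchange model (synthetic module)

Backbone amide exchange follows the Linderstrøm-Lang two-process picture.
Each non-proline residue `j` after a peptide's first position exchanges with
observed rate `k_int_j / P_j`, where `P_j ≥ 1` is a state-dependent
protection factor, giving expected per-site uptake
`(1−b)·f_D·(1−exp(−k_int_j t / P_j))` (EX2 limit: refolding much faster
than exchange). Segments assigned EX1 kinetics instead open cooperatively
and irreversibly with rate `k_op`; their residues exchange only through the
opening event, so the closed population carries no deuterium from those
sites and peptide envelopes become two-component mixtures with closed
weight `exp(−k_op t)`.

Defaults, with rationale:

- **Deuterium fraction `f_D = 0.862`** — the labelling dilution emulated
  (5 µl protein into 50 µl of 94.8% D₂O buffer: 50/55 × 0.948).
- **Exposures 0.05, 0.5, 50, 180 min; triplicates** — the emulated
  experimental schedule (0.05 min is the 3-s on-ice pulse).
- **Back-exchange `b = 0`** — results are relative deuterium levels with no
  back-exchange correction; nonzero `b` is available to test robustness.
- **Centroid noise SD 0.05 Da** — a typical replicate-level centroid
  precision for peptide-level HDX-MS.
- **Intrinsic rates: lognormal, median 50 min⁻¹, log-SD 1; baseline
  protection 100** — observed rates then straddle the four-decade exposure
  window, so uptake curves are informative at every timepoint. The
  sequence-dependent intrinsic-rate tables are deliberately *not*
  implemented: the analysis never consumes intrinsic rates, only centroids,
  so a seeded lognormal exercises the pipeline equally well. This is the
  main idealization of the generator.
- **Protected segment: 22 residues, protection ×20 in the second state** —
  the motif-B-analogue study condition used by the recovery tests.
- **EX1 `k_op = 0.007 min⁻¹`** — puts the closed-population weight at
  ≈0.70/0.28 over the last two exposures, the bimodal pattern the
  classifier is designed to catch.

The generator does **not** emulate: sequence-dependent intrinsic rates,
peptide ionization/intensity effects, spectral overlap or mis-assignment,
back-exchange gradients across a run, carryover, or EX1 segments that
re-close. Passing tests therefore demonstrate the correctness of the
analysis arithmetic and the detectability of the modelled effects, not
robustness to every instrument artifact of real data.

Envelopes live on an integer isotope grid treated as exactly 1 Da per
channel (deuterium mass increments and isotope spacings are unified), which
makes envelope centroids and centroid-difference uptake exactly
commensurable; natural envelopes use an averagine one-neutron Poisson rate
of 5.36 × 10⁻⁴ per Da of monoisotopic mass (two-neutron isotopes ignored).
The EX2 deuteration distribution is a binomial at the mean site
probability — the exact distribution is Poisson-binomial, but the mean
(hence every centroid-level quantity) is identical, and the binomial is the
standard single-envelope description.

## Differential analysis

Uptake is the centroid minus the mean undeuterated centroid per
peptide/state. Significance of a state difference per peptide/timepoint
uses the two-part rule (absolute threshold 0.5 Da AND 2.3× the SD of the
difference). Decisions that were genuinely open, and how they were fixed:

- **SD definition** — default is per peptide/timepoint, propagated from the
  replicate SDs as `sqrt(sd_A² + sd_B²)`; a pooled mode (RMS of those SDs
  across all peptide/timepoints) is provided for low-replicate tables. The
  per-peptide form is the default because it is the quantity the replicate
  design actually measures.
- **Summary across timepoints** — the per-peptide difference fed to the
  projection is the mean over timepoints with non-significant timepoints
  contributing 0. Averaging only significant timepoints would bias summary
  magnitudes upward for peptides significant at a single timepoint.
- **Non-significant and EX1 peptides contribute 0 rather than being
  dropped**, so covered-but-unchanged regions read 0 instead of appearing
  as coverage gaps; EX1 centroids are not meaningful EX2 averages, hence
  the forced zero.
- **Containment = exchanging position**: a residue belongs to a peptide for
  projection and coverage purposes only if it can carry deuterium there
  (not the first residue, not proline).
- **Timepoints are matched exactly** (tolerance 10⁻⁹ min).

Protected regions are maximal runs of ≥ `min_run` consecutive covered
residues with `|res_j| ≥ min_abs` and uniform sign; gaps break runs.
Defaults `min_abs = 0.05` Da/residue and `min_run = 5`: with the study
conditions above, residues inside a protected segment project to roughly
0.1 Da/residue while boundary smear from straddling peptides stays below
~0.05, so the defaults sit between signal and smear; both are exposed as
parameters.

## EX1 classification

Each envelope is fit by least squares as natural ⊛ Binomial(n, p) (one
parameter) and as a two-binomial mixture (p_low, p_high, w; three
parameters), selected by the information criterion
`K·log(RSS/K) + penalty·k` with penalty 2 (AIC-like) and an RSS floor of
10⁻¹² to keep noiseless fits finite. Optimization: a 41-point grid then
bounded refinement for the single fit; four fixed multi-starts of L-BFGS-B
for the mixture, with canonical ordering p_low < p_high. A peptide is EX1
only if the mixture wins at ≥2 consecutive timepoints with mode separation
≥2 Da and non-increasing `w_low` (tolerance 0.05) — the one-way population
transfer that distinguishes true EX1 from fit instabilities. Mixture
weights within 0.02 of 0 or 1 are treated as unimodal. Flat envelopes are
ambiguous. These thresholds are configurable (`Ex1Config`).

## Cross-links

Link identity is the canonicalized `(min(pos), max(pos))` pair; scores are
metadata. The fraction logic (monomer-unique → intra, dimer-unique → inter,
intersection → shared) is a set partition and is tested as such. `shared`
handling is an extension beyond the strict unique-set picture. Chemistry
filtering accepts the amine-reactive pairs K-K, K-S, K-T, K-Y. No 3-D
distance filtering is performed (no structure is involved). Concordance
with HDX-protected regions counts links with ≥1 endpoint within `w`
residues of any protected interval, and is monotone in `w` by construction.

## Binding curves

One-site total and 4PL fits use `scipy.optimize.curve_fit` with
initialization from data extrema (Top/Bottom), the half-range crossing
(LogX50), the median positive dose (Kd), and a positivity bound on Kd.
The 4PL canonical form puts Bottom at the low-dose asymptote with positive
HillSlope; the (Top, Bottom, −Hill) reflection is the same curve. Recovery
studies use quadruplicate 3-fold serial-dilution designs (the layout of the
emulated cell assay); with a 15-point linear dose grid instead, Kd at 5%
noise is identifiable only to ~±40%, which is a property of the design, not
the fitter.

## Hydrodynamics

Standard conditions are water at 20 °C (ρ = 0.998234 g/cm³,
η = 0.0100194 P). f₀ uses the anhydrous sphere (hydration ignored), the
convention under which sedimentation-velocity software reports f/f₀.
Experimental sedimentation quantities from the motivating study are *not*
reproduced here — they require raw instrument data and buffer details — so
this module provides exact algebraic relations (tested as round trips to
10⁻⁹ relative) rather than refits.

## Packaged reference sequence

UniProt could not be reached from the build environment, so
`data/brd4_1_722.synthetic.fasta` is a reconstruction of BRD4 residues
1–722 assembled from well-characterized landmarks. Everything checkable
offline checks out: segments 531–579 and 580–722 reproduce the published
inter-construct theoretical-mass differences to 0.1 Da; the CK2 scanner
finds exactly 7 NPS and 6 CPS consensus serines (matching the 7A/6A mutant
mass deltas of −112.0 and −96.0 Da); K519, both WPF shelves, and the
conserved bromodomain asparagines sit at their canonical positions; and
506–527 contains three heptad repeats with hydrophobic a/d positions.
The published mass difference between the 1–722 and Δ506–530 constructs
(2,067.4 Da) additionally pins the deletion construct's 12-residue
glycine–serine linker to the composition 9 Gly + 3 Ser — realized here as
(GGGS)₃ — and reproduces to 0.1 Da against the packaged 506–530 segment,
a further independent validation of that segment. The
composition of the disordered BD1–BD2 linker (~residues 170–350) could not
be validated against any offline checksum, and absolute intact masses of
constructs spanning it disagree with the published theoretical column by a
constant ≈1.85 kDa — attributable either to reconstruction error in that
linker or to vector-derived residues in the published values (the purified
constructs carry an uncleaved His₆-TEV leader, and insect-cell rows sit
exactly one glycine above bacterial rows). The five absolute-mass
assertions in the acceptance tests are therefore expected to fail until a
verified database sequence is substituted; all difference-based mass checks
pass.

## Known limitations

- Intrinsic exchange rates are not sequence-dependent (see above).
- EX1 opening is irreversible; EX1/EX2 mixtures within one segment are not
  generated, so classifier performance on partially-reclosing systems is
  untested.
- The peptide map generator aims at mean redundancy, not at reproducing
  pepsin cleavage specificity.
- Coiled-coil annotation is a heptad hydrophobicity score, not a
  statistical coiled-coil predictor; it ranks registers, it does not assign
  oligomeric state.
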