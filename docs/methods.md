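# Methods

This note records the models, conventions and numerical choices behind
`fretscreen`, in the order the pipeline uses them.

## Mass arithmetic

All masses derive from elemental compositions and a fixed monoisotopic
element table (H 1.0078250319, C 12 exactly, N 14.0030740052,
O 15.9949146221, S 31.97207069; proton 1.00727646688 Da). Residues are
stored as compositions of the residue (amino acid − water), never as bare
masses, so modifications compose by formula arithmetic: nitration of
tyrosine is +NO₂ −H, the Abz fluorophore is a +C₇H₅NO acyl on a side-chain
or N-terminal amine, a C-terminal amide replaces −OH with −NH₂ (−O +N +H),
and the Dpa quencher residue is diaminopropionic acid with a
2,4-dinitrophenyl substitution on the side-chain amine (C₉H₈N₄O₅ total).
A peptide's neutral mass is Σ residue masses + H₂O plus any terminal
deltas; ions are (M − losses + z·proton)/z.

Library peptides released by base hydrolysis carry a free-acid C-terminus,
so that is the default; `-NH2` must be written explicitly. The noncanonical
building blocks are registered as O = ornithine (C₅H₁₀N₂O),
B = 2,4-diaminobutyric acid (C₄H₈N₂O), U = 2,3-diaminopropionic acid
(C₃H₆N₂O), J = β-cyclopropyl-alanine (C₆H₉NO), Z = 4-thiazolyl-alanine
(C₆H₆N₂OS) and X = 4-hydroxyproline (C₅H₇NO₂). The registry is a YAML file
and user-extensible.

Nitro-tyrosine-containing peptides are observed in MALDI as an
[M − O + H]⁺ species as well as [M + H]⁺. We interpret "− O" as the loss of
one oxygen atom (−15.99491 Da): computed this way, the decoded hit's
precursor agrees with its published value to ~1 ppm, whereas any other
reading (e.g. loss of an ornithine residue) is off by tens of mDa. The
decoder therefore tries [M + H]⁺ first and [M − O + H]⁺ second, and reports
which interpretation admitted each candidate.

## Fragmentation and matching

MALDI CID of these peptides yields predominantly singly charged b and y
ions, so the default ion model is b/y at charge 1; b ions carry the
N-terminal acyl, y ions the C-terminal amide, and side-chain modifications
travel with their residue. The complementarity identity
mz(bᵢ) + mz(y₍ₙ₋ᵢ₎) = M + 2·proton holds to numerical precision and is
property-tested.

Peak matching is greedy nearest-first: all (ion, peak) pairs within the ppm
tolerance are sorted by |ppm error| and accepted one-to-one, which is
deterministic and independent of input peak order. Defaults are 10 ppm for
fragments, 5 ppm for precursors, and 0.01 Da for ladder reading —
FT-ICR-grade figures chosen as engineering defaults (the source instrument's
tolerances are not published); all are parameters. Ladder reading reports
every alphabet residue within tolerance of a peak-pair mass difference and
flags multi-candidate steps ambiguous (K vs Q separate at 0.01 Da but not at
0.05 Da). Reading a complete single-series ladder recovers only the internal
sequence: the two terminal residues never appear as differences.

## Library model and decoding

A positional library is an ordered list of residue-token option sets with a
scissile-bond index; its size is the product of option counts and
enumeration is position-major (last position fastest) for reproducibility.
Precursor-constrained candidate generation is depth-first branch-and-bound
on partial residue-mass sums with per-depth attainable-mass intervals; it is
contractually identical to brute-force filtering and tested for equivalence
against it.

The packaged ADAMTS-5 design fixes the quencher (P5), fluorophore (P4'),
scissile-bond pair E(P1)/S(P1'), solubilizing lysines (P6, P9') and the
C-terminal glycine (P10'), and varies nine positions with conservative
natural swaps plus the unnatural residues at the positions where they were
used (O/B at P2', J at P5'/P7', U at P8'). The full per-position sets are
figure-only content in the source and were transcribed under the published
constraints: the option-count product must be exactly 12288 and the library
parent and every published hit sequence must be members. The loader enforces
both and refuses the design otherwise.

Candidate scoring is Σ over matched theoretical ions of (1 + I_peak/I_max):
each match counts 1 and intense peaks add up to 1 more. This is the simplest
function of "number of matching fragment ion peaks and their intensity"; the
weight is pluggable so alternatives (e.g. log-intensity) can be benchmarked.
The score is invariant to uniform intensity rescaling, and an all-zero
intensity spectrum degrades to 1 per match. Candidates are ranked by score
with exact ties sharing a rank; a candidate within 1% relative score of a
neighbor — or with zero score — is flagged ambiguous. The 1% threshold
exposes rather than hides the library's genuine isobaric degeneracy: several
position pairs (S+E/T+D, E+G/D+A, Y/F transpositions) are exactly isobaric
and can only be separated by the few fragments between them, so at partial
fragment coverage a correct decoder must sometimes return a flagged tie.
This mirrors the screening reality in which only a subset of picked beads
can be conclusively identified.

## Kinetics

Calibration is ordinary least squares of RFU against fluorophore
concentration; the gradient (RFU μM⁻¹) converts rates. Initial rates take
the longest leading window of ≥ 5 points with r² ≥ 0.995, falling back to
the first 5 points with a quality warning; both knobs are parameters, since
"the linear part of the curve" has no published operational definition.
Per-enzyme rates are rate / [E] / gradient.

Inner-filter correction follows the spiked-fluorophore protocol: at each
substrate concentration the net fluorophore signal is (reading with spiked
Abz − reading without), blank-corrected; the correction factor is that
signal normalized to the 0 μM value, clipped to ≤ 1. Dividing raw rates by
their factors undoes the quench, so corrected rates are never smaller.

Michaelis–Menten fitting is nonlinear least squares (lmfit) of
v = V_max·[S]/(K_m+[S]) with nonnegative bounds, starting from
V_max = 1.2·max(v), K_m = median(S), with five seeded random restarts on
failure; k_cat = V_max/[E] and k_cat/K_m (μM → M) carry first-order
propagated standard errors. Note that a published table computed from
unrounded fits can disagree with the quotient of its own rounded k_cat and
K_m by a few percent; this package always reports its own quotient.

Tight-binding titrations are fitted to the Morrison equation
a = 100·(E − I − K_i + √((I + K_i − E)² + 4·K_i·E))/(2E) (a = percent
activity, all concentrations in nM). The active-site concentration is
additionally read out graphically — a straight line through points with
20% ≤ a ≤ 80% extrapolated to the abscissa — because that is how such
titrations are reported in practice; with K_i(app) ≪ [E] the curve is nearly
linear in that band and the intercept sits within ~0.5 nM of the true
active concentration (the residual curvature of the Morrison form biases it
slightly high). The 20–80% band is a parameter.

Selectivity tables report fold = rate(reference)/rate(other) and percent of
reference; a rate below the detection bound is reported as a "> x-fold"
bound rather than an infinite number. Detection calls compare
ΔRFU(t) = RFU(t) − RFU(0) with a threshold over a horizon and interpolate
the first crossing linearly. Bead arithmetic is
ΔFI(t) = (FI(t) − BG(t)) − (FI(0) − BG(0)).

## Substrate profiling

P-positions follow Schechter–Berger: P1 immediately N-terminal of the
scissile bond, P1' immediately C-terminal. Frequencies are percentages per
position over the records that cover that position; substrates too short for
a position are excluded from that position's denominator (the source figure
does not state its convention; exclusion-per-position is ours, and the
denominators are reported so the choice is visible). Consensus is the
per-position argmax with ties reported jointly.

## Synthetic data

Every generator is a pure function of its config, seed included. Spectra:
theoretical b/y ions subsampled to a coverage fraction, Gaussian ppm mass
error, log-normal intensities, uniform-m/z chemical noise peaks at reduced
intensity, precursor with or without the −O loss — these reproduce the
decodability structure of MALDI CID peak lists (partial ladders, near-isobar
confusions, intensity spread) but none of the instrument physics (isotope
envelopes, matrix adducts, detector saturation), so passing recovery tests
demonstrate the decoder's statistical behavior, not instrument robustness.
Progress curves integrate dS/dt = −k_cat·E·S/(K_m+S) (stiff-safe RK with
tight tolerances) and read out RFU = gradient · product · inner-filter
factor (exp(−αS₀)) + Gaussian noise. Titrations come from the Morrison
expression plus noise. Substrate tables draw residues independently per
position from given distributions.

Default simulated study conditions follow the published assay design: eight
2-fold substrate dilutions from 200 μM, enzyme 0.03 μM, 20 s plate reads,
calibration gradient 50 RFU μM⁻¹ (a typical Abz value); titrations use
inhibitor 1.25–160 nM against 27 nM active enzyme with K_i(app) = 0.1 nM.
Decoder recovery uses fragment coverage 0.7, 5 ppm mass-error s.d. and 20
noise peaks. Test and acceptance problem sizes (tens of seeds for property
loops, 200 spectra for the recovery rate, ≤ 60 s simulated assay windows
with 1–2 s reads) were chosen as the smallest sizes at which the checked
statistics are stable.

## Known limitations

* Singly charged b/y ions only; no a/internal/neutral-loss fragment series,
  no isotope envelopes, no deisotoping — adequate for library-constrained
  decoding, not for open de novo sequencing.
* The intensity weight in the score is a reasonable reconstruction, not a
  published formula; only ranking behavior (not absolute scores) should be
  compared across implementations.
* The packaged library's variable option sets are constrained, not
  published, content (see above); any analysis that depends on the identity
  of *non-hit* members should treat them as representative, not factual.
* Initial-rate estimation from discretized, depleting progress curves
  carries a small downward bias (~1–3% under the default windows), which
  propagates into closure tests run through full progress-curve simulation;
  fits on rate panels themselves are exact to solver precision.
* Graphical active-site read-out inherits the slight convexity bias of the
  Morrison curve; the nonlinear fit's [E] is also reported and is exact on
  noiseless data.
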