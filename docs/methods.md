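# Methods

This note documents the models, conventions and numerical choices
behind each module, what the synthetic generators do and do not
emulate, and the known limitations.

## Structure I/O

PDB text is read from the fixed columns (serial 7–11, name 13–16,
residue 18–20/23–26, coordinates 31–54 in Å) with MODEL/ENDMDL blocks
counted; a file without MODEL records is a single-model structure.
Alternate locations other than blank/'A' are dropped so each model is
one conformer. Hydrogens are retained but every default selection
("sidechain", "heavy") uses heavy atoms only, because the geometric
metrics are heavy-atom quantities. The lowest-energy member of an NMR
ensemble is taken as MODEL 1 by convention; callers can pass any model
index. Writing uses the 8.3 coordinate field and raises on overflow;
round-trips preserve coordinates to 3 decimals (the format's own
precision). Multi-chain files need an explicit chain id; insertion
codes and mmCIF are out of scope.

## Pharmacophore model and matching

Feature placement follows standard pharmacophore conventions, since a
residue list alone does not fix atom sets: hydrophobic features sit at
sidechain heavy-atom centroids, the aromatic feature at the Phe ring
centroid, the positive feature at the Arg guanidinium (NH1/NH2/CZ)
centroid, the negative feature at the Asp carboxylate (OD1/OD2/CG)
centroid, the donor on the Ala backbone amide nitrogen and the
acceptor on the Tyr hydroxyl oxygen. All placements are overridable
through the feature spec.

The composition rule defaults to: at least 4 matched points, of which
≥ 3 hydrophobic and ≥ 1 aromatic; a 5-point match must additionally
contain one donor/acceptor/positive/negative point. Whether a 4-point
match may omit the aromatic point is genuinely ambiguous, so the rule
object is fully configurable; the default keeps the aromatic
requirement at every size. A46 contributes a single donor feature by
default (a second acceptor feature is one spec entry away).

Matching enumerates injective, kind-compatible correspondences by
backtracking with distance-geometry pruning: two pairs are compatible
only if the model-side and ligand-side inter-feature distances agree
within 2·tolerance. The bound is sound — if a rigid transform places
both ligand features within `tol` of their model partners, the
triangle inequality bounds the distance disagreement by 2·tol — so no
alignable mapping is pruned (property-tested against exhaustive
enumeration). Each surviving candidate is rigidly superposed (Kabsch)
and accepted if every post-alignment paired distance is within the
tolerance; the winner maximises `fit_score = n_matched − rmsd/tol`
(equivalently most points, then lowest RMSD, then the lexicographically
smallest mapping — deterministic). The default tolerance is 2.0 Å, a
typical matching radius. The score is our own definition and is not
comparable to any proprietary screening score. Aromatic ligand
features match hydrophobic model features only when an explicit flag
enables cross-typing (default off: strict typing is testable).

## Chemical-shift perturbation

CSP is implemented literally as `½·√(Δδ²_H + (Δδ_N/5)²)` in ppm, with
the nitrogen scale (1/5) and overall scale (1/2) as explicit
parameters; the alternative root-mean-square convention
`√((Δδ²_H + (Δδ_N/5)²)/2)` is available behind a flag because both
appear in the literature. Significance thresholds are the mean plus
0.5 or 1 sample standard deviations (ddof = 1) of the CSPs over
assigned residues; residues missing from either list (prolines,
overlapped or unassigned peaks) are classed `absent` and excluded from
the statistics. Classification is scale-equivariant by construction.
Region tables (helix/loop ranges) are user-supplied configuration, not
hard-coded.

## Ensemble metrics

Kabsch superposition uses the SVD with the determinant sign correction
so the rotation is always proper; collinear point sets (second
singular value below 1e-9 of the first) fall back to translation-only
and are flagged. Correctness is cross-checked against an independent
quaternion-eigenvalue (Horn) oracle to 1e-8 Å.

RMSF superposes every frame onto the frame-average once, recomputes
the mean and reports per-atom root-mean-square displacement about it
(Cα per residue by default). This single-iteration mean-structure
convention is standard and deterministic. A consequence worth knowing:
the rigid fit partially absorbs the motion of a strongly fluctuating
residue, so planted-amplitude recovery on the toy fold runs ~3–4%
below the σ√3 ideal; recovery checks therefore use the median over
seeds. ΔRMSF is the element-wise relative change (bound − apo)/apo;
the apo profile is conventionally the average over apo replicates, and
replicate averaging is left to the caller.

The canonical-site area sums two Heron triangles over the Cα atoms of
K189, V91, T85, M79 (decomposition sharing the K189–T85 edge);
vertices are configurable `AtomSelection`s since the residue list does
not pin the atoms. Numerically negative Heron radicands (degenerate
triangles) clamp to zero. Replicate aggregation is the mean of
per-ensemble means, never frame pooling.

## Assay models

*One-site binding*: `response = B_max·[L]/(K_D + [L]) + baseline`,
least squares with deterministic starts (K_D at the half-max
concentration, B_max at the response range) and K_D boxed to
[1e-3, 1e7] nM; a fit pinned at a box edge or with no dynamic range is
flagged and not reported as converged. The fitter is cross-checked
against a grid search with the linear subproblem solved exactly.

*Constrained 4PL*: `bottom + (top − bottom)/(1 + (x/IC50)^h)` with the
plateaus fixed from the saturated and probe-only controls; only IC50
and the Hill slope are free. Curves traversing < 10% of the anchor
window are flagged unidentifiable.

*Melt curves*: signal is rescaled so the 25 °C anchor maps to 100% and
the 74 °C anchor to 0%, then fit with the two-state Boltzmann
`100/(1 + exp((T − Tm)/k))`; Tm is the inflection. ΔTm = Tm_control −
Tm_treated, so a destabilising ligand gives a positive number. Because
the sigmoid is not exactly zero at the hot anchor, anchor rescaling
leaves a small systematic residual (~0.02 °C at Tm 62 °C, k 2 °C) —
negligible against the 0.5 °C recovery tolerance but visible in
noiseless self-consistency checks.

*Bliss synergy* is computed from the independence formula
`E = f_A + f_B − f_A·f_B` using the observed zero-dose marginals; the
score is observed − expected per cell and its mean over interior
(both-doses-positive) cells. No surface smoothing or weighting is
applied; scores are formula-exact and labelled as such.

*SEC quantification* follows the printed fraction windows: monomer
(C6/2 + C7 + C8 + C9), dimer (C3 + C4 + C5 + C6/2), oligomer
(C2 + C1 + B1 + B2, optional), each over the total reported intensity;
the straddling C6 fraction splits half/half. Windows are keyed by
fraction label; the label→volume map (0.5-ml fractions) is
configuration. Molecular-weight calibration fits log10(MW) linearly in
elution volume and flags extrapolation.

*Depolarization*: trapezoidal AUC per trace;
`% = 100·(AUC_DMSO − AUC_sample)/(AUC_DMSO − AUC_CCCP)`. Values
outside [0, 100] are flagged, never clipped. The statistic is
invariant to any common affine gain/offset on all traces.

## Synthetic data

All generators draw from one `numpy` Generator seeded explicitly; a
given parameter set (seed included) reproduces output exactly, and
each generator returns a truth record used by the recovery tests.
Noise models: additive Gaussian in ppm for chemical shifts, isotropic
Gaussian in Å for coordinates, multiplicative Gaussian for plate and
fluorescence signals — the dominant error source for each readout.

The toy fold is a deterministic helical hairpin (~66 residues sparsely
numbered 20–190) carrying the real residue identities needed at the
named positions (e.g. Lys21 with an NZ, Arg145 with an NE, Phe176 with
a six-ring), so every selection exercised by the metrics exists
without any external structure. It is a geometric stand-in: its
distances and areas are internally consistent but not those of BAX.

Planted effects are chosen to mirror the study conditions: isotherms
default to 12 log-spaced points spanning ±1.5 decades around K_D with
3% multiplicative noise; melt pairs sample the 8-temperature CETSA
gradient plus the 25 °C anchor with 2% noise, control Tm 62 °C and
slope 2 °C; the area generator drifts the four vertex Cα linearly
(scale √(1 + δ) about the vertex centroid, δ ramping 0 → 2·target) so
the mean area change equals the target exactly in expectation; decoy
conformers keep the feature-kind multiset of an active but are
re-placed at random and verified by correspondence enumeration to
admit no minimum-size mapping.

What passing these tests shows — and does not: the pipeline recovers
planted parameters under the stated noise models at desk scale. Real
spectra, trajectories and plates add peak overlap, correlated and
anharmonic motions, plate effects and baseline drift that these
generators deliberately omit; recovery here validates the analysis
code, not instrument-level robustness.

## Problem sizes

Default test/report sizes were chosen to make the statistics stable at
interactive cost: 100 seeds for all recovery medians, 2000 frames for
fluctuation/area recovery, 10⁴ random triangles and 10³ random
matcher instances for the oracle equivalences, and toy screening
libraries of tens of conformers.

## Known limitations

- No molecular dynamics is run; ensembles are analysed as supplied.
- No conformer generation from chemical structures; libraries are
  typed feature-point tables.
- Pharmacophore scoring is not calibrated against any commercial
  screening score; ranks are comparable only within a run.
- CSP analysis stops at per-residue classification; titration-series
  K_D estimation from CSPs is out of scope.
- The Bliss implementation omits the smoothing some GUI tools apply
  before rendering heatmaps.
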