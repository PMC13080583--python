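# Methods

## Binding model

The FP readout is modelled as a linear map of the bound-probe fraction θ:
FP = F_min + (F_max − F_min)·θ, with θ the exact solution of 1:1 binding
under ligand depletion,

θ = (([P_T]+[L_T]+K_D) − √(([P_T]+[L_T]+K_D)² − 4[P_T][L_T])) / (2[L_T]).

Implementation notes:

* θ is evaluated in the algebraically equivalent form
  2[P_T]/(S + √(S²−4[P_T][L_T])) with S = [P_T]+[L_T]+K_D, which avoids
  catastrophic cancellation at high titrant; at [L_T] = 0 the analytic
  limit θ = [P_T]/([P_T]+K_D) is used.
* The fit is unweighted least squares (lmfit/`leastsq`) over
  (K_D, F_min, F_max). K_D is bounded to (10⁻³, 10⁹) nM purely as a
  numerical guard; the determinability rule, not the bound, handles
  unresolvable affinities. Initial guesses: F_min = min(FP),
  F_max = max(FP), K_D = the lowest titrant at which the signal crosses
  half-span — robust for monotone curves.
* Replicates are fit independently; the reported K_D is the replicate mean
  and `kd_sd` the sample SD (ddof = 1), matching the replicate-SD
  convention of triplicate FP experiments. For a single curve `kd_sd`
  falls back to the asymptotic standard error, and `kd_sd_kind` records
  which definition applies.
* "Too weak to be determined" is a three-way rule: no convergence, fitted
  K_D above the top titrant concentration (the estimate would be pure
  extrapolation), or fitted span (F_max−F_min) < 3× residual RMS (no
  resolvable signal). The triggering reasons are kept in the result.

Units: concentrations nM, polarization mP.

## Unfolding model

FirbY-W(x) = (D·e^{(mx−ΔG)/RT} + N)/(e^{(mx−ΔG)/RT} + 1), with
R = 1.987×10⁻³ kcal/(mol·K) and T defaulting to 295 K (the assay
temperature). ΔG is the unfolding free energy at zero denaturant
(kcal/mol), m the urea m-value (kcal/mol/M), N and D the native and
denatured baselines of the ratio. The transition midpoint is C_m = ΔG/m.

The spectral band is the four-parameter asymmetric log-normal used in
protein fluorescence work — amplitude A (value at the mode), peak position
p (nm), FWHM w (nm), asymmetry ρ > 1 — written in wavelength with a finite
blue-side support edge b = p − wρ/(ρ²−1):

I(λ) = A·exp(−(ln2/ln²ρ)·ln²((λ−b)/(p−b))) for λ > b, exactly 0 otherwise.

Its closed-form area A(p−b)√(π/k)·e^{1/4k}, k = ln2/ln²ρ, backs the
area-mode ratio and a quadrature cross-check in the tests.

Deconvolution fits two such bands by least squares with the Tyr peak
constrained to 295–312 nm and the Trp peak to 325–360 nm; the physical
windows both prevent band swapping and enforce the tyr-before-trp ordering,
so permuted initial guesses converge to the identical solution. FirbY-W is
the Tyr/Trp *peak-intensity* ratio by default; an integrated-area mode is
available (`compute_firby_ratio(..., mode="area")`) since either convention
appears in the literature.

The two-state fit is multi-start least squares over (ΔG, m, N, D), with ΔG
started from a small fixed grid (−2 … 5 kcal/mol). The multi-start matters
for destabilised constructs (ΔG < 0): the folded baseline then lies outside
the sampled urea range and a single poor start can stall in a flat region.
A series whose fitted span is below 3× the residual RMS — or whose raw span
is zero — carries no transition and is flagged non-identifiable rather than
reported.

## Interaction census

Default geometric criteria (all configurable via `GeometryConfig`):

| interaction | criterion | default |
|---|---|---|
| salt bridge | donor side-chain N (Arg NE/NH1/NH2, Lys NZ) to acceptor side-chain O (Asp OD1/OD2, Glu OE1/OE2, SEP O1P/O2P/O3P/OG) distance | ≤ 4.0 Å |
| hydrogen bond | donor–acceptor heavy-atom distance; D–H···A angle | ≤ 3.5 Å; ≥ 135° |
| stacking | plane-centroid distance; angle between group planes | ≤ 4.5 Å; ≤ 20° |

Salt bridges and stacks are counted at residue-pair granularity: one event
per residue pair per frame, keeping the minimal distance (a Trp counts once
per partner even when both of its rings qualify). Residue pairs already
counted as salt bridges are excluded from hydrogen bonds to avoid double
counting. The stacking angle is taken between the two group planes (folded
to [0°, 90°]) because the cation-cation (Arg–Arg) case is symmetric and a
normal-to-centroid-vector definition would be ambiguous there; planes are
fitted by SVD, and collinear "planar" groups raise a geometry error.
Stacking partners are aromatic rings (Phe, Tyr, His, both Trp rings) and
the Arg guanidinium plane; cation-π is restricted to Arg. Hydrogen-bond
donors require an explicit hydrogen within 1.35 Å of the donor heavy atom;
a structure with no hydrogens at all raises a capability error unless
`infer_hydrogens` is set, which places the hydrogen on the donor–acceptor
line (equivalent to a distance-only criterion). Backbone amide donors and
carbonyl acceptors are included by default (`include_backbone_hbonds`).

Census summaries report mean counts per frame by (kind × span) over a
trailing time window; 150 ns at the 150 ps snapshot interval is exactly
1000 frames. Per-residue salt-bridge profiles credit every participating
residue on the profiled chain (an intrachain event within the chain counts
for both partners); the overall mean across residues is the dashed-line
average of a per-residue bar plot. Replicate aggregation is mean ± sample
SD (ddof = 1) across per-replicate frame summaries. Backbone RMSD uses
Kabsch superposition (numpy SVD with the determinant correction); the
equilibration flag requires the best-fit linear slope of RMSD over the
trailing half of the trajectory to stay below 0.002 Å/ns by default.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions used throughout the tests:
titrations at probe 10 nM with 2-fold dilutions from 8000 nM and
homoscedastic Gaussian mP noise (plain replicate SDs are the reported
uncertainty, so no variance model is imposed); spectra on the 280–400 nm
grid whose deconvoluted Tyr/Trp ratio equals the two-state curve exactly;
RS-repeat sequences in three flavors — pure RS, RS with sparse RR doublets,
and a basic-acidic dipeptide pattern interleaving RS with RE/RD and
consecutive-R motifs — with net charge computed as Arg/Lys +1, Asp/Glu −1,
phosphoserine −2. At equal repeat counts the flavor net charges order
bad1-like > u2af1-like > srsf1-like, and the flavor-complex fixture plants
interchain salt bridges in proportion to the partner's net positive charge
(net_charge // 3, arginines onto phosphoserines), which is what makes the
interchain-total ranking a *constructed* property of the synthetic data:
the rank tests validate the census bookkeeping, not binding physics.

Coordinate fixtures use simplified residues — a compact backbone cluster
(N, H, CA, C, O) plus one idealized functional group per side chain (exact
ring polygons with well-defined planes, charged-group atoms, donor
hydrogens) — rather than rotamer libraries, because the detectors operate
on functional-group geometry and the ground truth must be provable.
Non-planted residues sit on a 32 Å grid (non-planted atom pairs stay
≥ ~7 Å apart, far outside every cutoff); each planted pair is placed at its
own grid point satisfying its criterion with margin (salt bridge at 3.0 Å,
H-bond at 2.9 Å/180°, stacks at 3.8 Å/0° with pendant atoms of the two
planes oriented apart). Per-frame Gaussian jitter is clipped to 0.15 Å per
atom; the worst-case effect on any planted or non-planted quantity
(distances ≤ 0.3 Å, D–H···A bend ≤ ~20°, ring-normal tilt ≤ ~12° combined)
stays inside every margin, so detector labels cannot flip and the recorded
ground truth is exact on every frame. Two structural constraints keep the
ground truth provable: a residue may take part in at most one planted
interaction, and a planted H-bond pair may neither be salt-bridge-compatible
(it would be detected and excluded as a salt bridge) nor join two
plane-capable residues (which could stack accidentally); violations raise
generation errors.

What passing these tests shows: the detectors, partitioning, windowing and
aggregation are exactly correct on geometry whose truth is known. What it
does not show: anything about real conformational ensembles — the fixtures
have no excluded volume, no realistic backbone connectivity, no force-field
sampling, and interaction counts planted by construction. Likewise the
titration and spectra generators share their functional form with the
fitters, so recovery tests demonstrate estimator correctness and
calibration (median |bias| ≤ 5% across the panel under triplicate 5 mP
noise), not robustness to model misspecification.

The exact residue-level sequences of the study's RS regions are not
machine-readable from the source text, so the flavors are pattern-matched
stand-ins; `PlantedComplexSpec` accepts arbitrary user-supplied sequences
(e.g. true UniProt ranges) wherever a real sequence is available.

## Problem sizes and numerical choices

Round-trip and calibration tests use the study design directly (14–15
titration points, 15 urea points, 200 simulated triplicate experiments per
affinity). Census tests use 50 dense random frames for oracle equivalence,
20 random planted specs with 2–4 frames each, flavor fixtures of 36
dipeptide units per chain with 3 frames × 3 replicates, and one
1000–1100-frame miniature trajectory for the window accounting; these sizes
keep the full suite around ten seconds while exercising every code path.
Fits run lmfit's Levenberg–Marquardt with default tolerances; the
deconvolution bounds and the unfolding multi-start grid are stated above.
Ties and degenerate inputs: constant titrations and constant ratio series
are flagged rather than fit; zero-Trp-amplitude ratios raise; empty
analysis windows and missing chains raise.

## Known limitations

* No competitive/displacement binding, anisotropy conversion, or global
  multi-curve fits.
* No three-state or sloped-baseline unfolding models; no thermal melts.
* Trajectories are multi-model PDB only (no DCD/XTC); no MD engine, force
  fields or free-energy estimates.
* Hydrogen inference is deliberately crude (distance-only equivalent); use
  protonated models when angles matter.
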