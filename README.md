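# rsdomain

Quantitative analysis of phosphorylation-dependent interactions between
arginine/serine-repeat (RS) domains of splicing factors, packaged as a
tested, reusable pipeline. The biological setting is the interaction
network around the spliceosomal factors U2AF1 and SRSF1: phosphorylated RS
domains bind unphosphorylated ones, affinities are measured by fluorescence
polarization, construct stability by urea denaturation, and the atomic
drivers of binding (salt bridges between phosphoserine and arginine,
hydrogen bonds, stacking) are counted in molecular-dynamics-style coordinate
ensembles.

The package is for structural-bioinformatics and biophysics practitioners
who need any of these three measurement models with exact, testable
semantics — plus a synthetic-data generator that produces every input with
known ground truth, so the whole pipeline is verifiable without instrument
data or trajectories.

## The three models

**Ligand-depletion FP binding isotherm.** A fluorescent probe at total
concentration [L_T] (10 nM in the study design) is titrated with total
titrant [P_T]; because [L_T] is not negligible against K_D, the bound
fraction is the exact quadratic root, not the hyperbola:

    FP = F_min + (F_max − F_min) · ( ([P_T]+[L_T]+K_D) − √(([P_T]+[L_T]+K_D)² − 4[P_T][L_T]) ) / (2[L_T])

`rsdomain.binding` evaluates and fits this with free (K_D, F_min, F_max)
and classifies non-determinable affinities ("too weak to be determined"):
no convergence, fitted K_D above the top titrant concentration, or signal
span under 3× the residual RMS.

**FirbY-W two-state unfolding.** Tyr/Trp emission spectra (280–400 nm) are
deconvoluted into two asymmetric log-normal bands; the Tyr/Trp
peak-intensity ratio FirbY-W follows the two-state model in urea
concentration x:

    FirbY-W(x) = ( D·e^{(mx−ΔG)/RT} + N ) / ( e^{(mx−ΔG)/RT} + 1 )

with native/denatured baselines N, D, m-value m, unfolding free energy ΔG,
R = 1.987×10⁻³ kcal/(mol·K), T = 295 K by default; midpoint C_m = ΔG/m.
`rsdomain.unfolding` implements band evaluation, deconvolution, the ratio
and the four-parameter fit.

**Geometric interaction census.** `rsdomain.contacts` reads multi-model PDB
ensembles (phosphoserine as SEP), detects salt bridges (Arg/Lys side-chain N
to Asp/Glu/SEP side-chain O ≤ 4.0 Å, one event per residue pair), hydrogen
bonds (D–A ≤ 3.5 Å, D–H···A ≥ 135°, salt-bridge pairs excluded) and planar
stacking (centroid distance ≤ 4.5 Å, inter-plane angle ≤ 20°, classified
π-π / cation-π / cation-cation with the Arg guanidinium as the cation
plane), partitions events into intra- and interchain, and aggregates
per-frame means, per-residue salt-bridge profiles, replicate mean ± SD and
backbone-RMSD equilibration checks.

`rsdomain.simulate` generates titrations, spectra, RS-repeat sequences
(with a chosen fraction of serines phosphorylated) and coordinate ensembles
with *planted*, exactly counted interactions, all bit-reproducible under a
seed.

## Worked example

```python
import numpy as np
from rsdomain import *
from rsdomain.simulate import GenConfig

# 1. binding: simulate a noiseless titration at Kd = 200 nM and refit it
curve = generate_titration(kd=200, probe_lt=10, fmin=50, fmax=250,
                           top=8000, n_points=14, gen=GenConfig(seed=1))[0]
fit = fit_isotherm(curve)
print(round(fit.kd, 2), fit.determinable)       # 200.0 True

# 2. stability: spectra -> deconvolution -> FirbY-W -> two-state fit
spectra = generate_spectra_series(dg=1.91, m_value=1.0, n_base=0.5, d_base=1.5,
                                  urea_grid=np.arange(0, 7.5, 0.5),
                                  gen=GenConfig(seed=1))
ratios = []
for s in spectra:
    d = deconvolute_spectrum(s)
    ratios.append(compute_firby_ratio(d.tyr_band, d.trp_band))
ufit = fit_unfolding(UnfoldingSeries(urea=[s.urea for s in spectra], ratio=ratios))
print(round(ufit.dg, 3), round(ufit.m_value, 3))  # 1.91 1.0

# 3. contacts: a two-chain ensemble with three planted interchain salt bridges
spec = PlantedComplexSpec(chain_a_seq="R S R S R S", chain_b_seq="D E sep S S S",
                          planted_salt_bridges=[("A",1,"B",1), ("A",3,"B",2), ("A",5,"B",3)],
                          n_frames=10)
built = build_planted_complex(spec, GenConfig(seed=1, noise_sd=0.05))
summary = summarize_frames(built.trajectory)
print(summary.mean_counts[("salt_bridge", "inter")])  # 1.0 per planted bridge -> 3.0
```

The first block prints `200.0 True`: the fit recovers the generating
affinity exactly and calls it determinable. The second prints `1.91 1.0`
— the unfolding free energy (kcal/mol) and m-value (kcal/mol/M) recovered
through the full spectral route. The third prints `3.0`: the census finds
exactly the planted interchain salt bridges in every frame.

## Analysis scripts

The `analysis/` drivers run the full study-shaped workflow and write their
tables under `results/` (bulky intermediates go to `scratch/`):

```
python analysis/01_simulate_inputs.py    # titration panel, spectra, planted ensemble
python analysis/02_fit_binding.py        # affinity table incl. the too-weak call
python analysis/03_fit_unfolding.py      # recovered dG for wildtype / destabilised
python analysis/04_contact_census.py     # census, replicate SD, rank check, profiles
```

A `rsdomain` console script exposes the same stages
(`simulate-titration`, `fit-binding`, `fit-unfolding`, `analyze-contacts`,
`run --config config.yaml`).

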