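#!/usr/bin/env python
"""Generate every synthetic input used by the downstream analyses.

Writes, under results/data/:
  * one noiseless + one noisy-triplicate FP titration TSV per affinity in
    the construct panel (probe 10 nM, 2-fold dilutions from 8000 nM);
  * noiseless emission-spectra series (280-400 nm, urea 0-7 M) for the
    wildtype and zinc-finger-deletion stabilities;
  * a two-chain planted coordinate ensemble with its ground-truth JSON.
"""

from pathlib import Path

from rsdomain.binding import write_titration_tsv
from rsdomain.simulate import (
    GenConfig,
    PlantedComplexSpec,
    build_planted_complex,
    generate_spectra_series,
    generate_titration,
    write_ground_truth_json,
    write_trajectory_pdb,
)
from rsdomain.unfolding import write_spectra_tsv

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
OUT.mkdir(parents=True, exist_ok=True)

KD_PANEL = {  # nM, the affinity panel of the construct comparison
    "U2AF1_vs_piSRSF1": 200.0,
    "RSU2AF1_vs_piSRSF1": 9.0,
    "U2AF1_vs_piRS_SRSF1": 780.0,
    "RSU2AF1_vs_piRS_SRSF1": 60.0,
    "refolded_U2AF1_vs_U2AF2pep": 400.0,
    "dRS_U2AF1_vs_U2AF2pep": 50.0,
    "SRSF1_vs_piSRSF1": 25.0,
}

for label, kd in KD_PANEL.items():
    clean = generate_titration(kd, 10.0, 50.0, 250.0, 8000.0, 14, GenConfig(seed=100))
    write_titration_tsv(clean, OUT / f"titration_{label}_noiseless.tsv")
    noisy = generate_titration(
        kd, 10.0, 50.0, 250.0, 8000.0, 14,
        GenConfig(seed=100, noise_sd=5.0, n_replicates=3),
    )
    write_titration_tsv(noisy, OUT / f"titration_{label}_triplicate.tsv")
print(f"wrote {2 * len(KD_PANEL)} titration files")

for label, dg in (("wildtype", 1.91), ("zf_deletion", -0.44)):
    urea = [0.5 * i for i in range(15)]
    spectra = generate_spectra_series(dg, 1.0, 0.5, 1.5, urea, GenConfig(seed=200))
    write_spectra_tsv(spectra, OUT / f"spectra_{label}.tsv",
                      header_comment=f"generating dG={dg} kcal/mol, m=1.0, N=0.5, D=1.5")
print("wrote 2 spectra series (15 urea points each)")

spec = PlantedComplexSpec(
    chain_a_seq="R S R sep D F Y R K",
    chain_b_seq="R sep E S K Y W H T",
    planted_salt_bridges=[("A", 1, "B", 2), ("A", 9, "A", 5)],
    planted_hbonds=[("B", 4, "B", 3)],
    planted_stacks=[("A", 6, "B", 6), ("A", 8, "B", 7)],
    n_frames=20,
)
built = build_planted_complex(spec, GenConfig(seed=300, noise_sd=0.05))
write_trajectory_pdb(built.trajectory, OUT / "planted_complex.pdb")
write_ground_truth_json(built, OUT / "planted_complex_truth.json")
print(f"wrote planted complex: {len(built.trajectory)} frames, "
      f"ground truth {built.counts_by_kind()}")
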