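"""Synthetic inputs for every pipeline stage.

Four generators, all deterministic under a seed:

* FP titrations drawn from the exact ligand-depletion isotherm
  (2-fold dilution series from a top titrant concentration, Gaussian mP
  noise);
* Tyr+Trp emission-spectrum series whose deconvoluted peak-intensity ratio
  follows the two-state unfolding model across a urea grid;
* RS-repeat peptide sequences in three flavors (pure RS repeats, RS with
  occasional RR doublets, and a basic-acidic dipeptide pattern that
  interleaves RS with RE/RD and consecutive-R motifs) with a chosen
  fraction of serines phosphorylated;
* multi-frame one- or two-chain coordinate ensembles with *planted*,
  exactly counted salt bridges, hydrogen bonds and stacking interactions.

The coordinate fixtures use simplified residues: a compact backbone cluster
(N, H, CA, C, O) plus the side-chain functional group the detectors key on
(charged-group atoms, ring atoms forming an exact plane, donor hydrogens).
Residues that do not take part in a planted interaction sit on a coarse 3D
grid (32 A spacing) so that every non-planted residue pair violates all
detector criteria by a wide margin; each planted pair is placed at its own
grid point with the planted geometry satisfied well inside the thresholds
(>= 0.5 A distance margin, parallel planes, linear D-H...A).  Per-frame
Gaussian jitter is clipped to 0.15 A per atom, small enough that no label
can flip, so the recorded ground truth is exact for every frame.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from rsdomain.binding import TitrationCurve, eval_isotherm
from rsdomain.contacts import (
    AtomRecord,
    Frame,
    Trajectory,
)
from rsdomain.unfolding import (
    DEFAULT_TEMPERATURE,
    EmissionSpectrum,
    LogNormalBand,
    eval_lognormal_band,
    eval_unfolding_ratio,
)

__all__ = [
    "GenConfig",
    "PlantedComplexSpec",
    "PlantedComplex",
    "ParameterError",
    "GenerationError",
    "generate_titration",
    "generate_spectra_series",
    "generate_rs_sequence",
    "build_planted_complex",
    "build_flavor_complex",
    "net_charge",
    "parse_sequence",
    "write_trajectory_pdb",
    "write_ground_truth_json",
    "DEFAULT_TYR_BAND",
    "DEFAULT_TRP_BAND",
]


class ParameterError(ValueError):
    """Invalid generator parameters."""


class GenerationError(ValueError):
    """A fixture cannot be constructed as specified."""


@dataclass
class GenConfig:
    """Shared generator knobs.

    ``noise_sd`` is in the units of the generated quantity: mP for
    titrations, intensity units for spectra, Angstrom for coordinate
    jitter.  Identical seed + parameters give bit-identical output;
    ``noise_sd = 0`` gives noiseless output.
    """

    seed: int = 0
    noise_sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + offset)


# ---------------------------------------------------------------------------
# FP titrations


def generate_titration(
    kd: float,
    probe_lt: float,
    fmin: float,
    fmax: float,
    top: float,
    n_points: int,
    gen: GenConfig,
) -> list[TitrationCurve]:
    """Simulate FP titration replicates from the ligand-depletion isotherm.

    The titrant series is a 2-fold dilution from ``top`` (nM) downward over
    ``n_points`` concentrations; polarization is the exact isotherm value
    plus homoscedastic Gaussian noise of SD ``gen.noise_sd`` (mP).  Returns
    one curve per replicate.
    """
    if kd <= 0 or probe_lt <= 0 or top <= 0:
        raise ParameterError("kd, probe_lt and top must all be > 0")
    if n_points < 6:
        raise ParameterError("need at least 6 titration points")
    pt = top / np.power(2.0, np.arange(n_points))
    true = {"kd": kd, "probe_lt": probe_lt, "fmin": fmin, "fmax": fmax, "top": top}
    curves = []
    for rep in range(gen.n_replicates):
        rng = gen.rng(offset=rep)
        fp = eval_isotherm(pt, probe_lt, kd, fmin, fmax)
        if gen.noise_sd > 0:
            fp = fp + rng.normal(0.0, gen.noise_sd, size=fp.shape)
        curves.append(
            TitrationCurve(
                titrant_total=pt.copy(),
                polarization=np.asarray(fp, dtype=float),
                probe_total=probe_lt,
                replicate_id=rep,
                true_params=dict(true),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# emission spectra

DEFAULT_TYR_BAND = LogNormalBand(amplitude=1.0, peak_position=303.0, width=30.0, asymmetry=1.3)
DEFAULT_TRP_BAND = LogNormalBand(amplitude=100.0, peak_position=340.0, width=55.0, asymmetry=1.4)
WAVELENGTH_GRID = np.arange(280.0, 400.0 + 1e-9, 1.0)


def generate_spectra_series(
    dg: float,
    m_value: float,
    n_base: float,
    d_base: float,
    urea_grid: Sequence[float],
    gen: GenConfig,
    tyr_band: LogNormalBand = DEFAULT_TYR_BAND,
    trp_band: LogNormalBand = DEFAULT_TRP_BAND,
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[EmissionSpectrum]:
    """Two-band emission spectra (280-400 nm, 1 nm grid) across a urea series.

    The Trp band keeps the amplitude of ``trp_band``; the Tyr band amplitude
    is set to ``ratio(x) * trp_amplitude`` where ratio(x) is the two-state
    FirbY-W value at urea x, so deconvolution recovers exactly the generating
    unfolding curve.  ``tyr_band.amplitude`` is ignored (shape parameters are
    used).  Gaussian intensity noise of SD ``gen.noise_sd`` is added.
    """
    urea = np.asarray(urea_grid, dtype=float)
    if np.any(urea < 0) or np.any(urea > 8):
        raise ParameterError("urea grid must lie within [0, 8] M")
    if trp_band.amplitude <= 0:
        raise ParameterError("Trp band amplitude must be > 0 (ratio undefined otherwise)")
    rng = gen.rng()
    spectra = []
    for x in urea:
        ratio = eval_unfolding_ratio(float(x), dg, m_value, n_base, d_base, temperature)
        tyr = LogNormalBand(
            amplitude=ratio * trp_band.amplitude,
            peak_position=tyr_band.peak_position,
            width=tyr_band.width,
            asymmetry=tyr_band.asymmetry,
        )
        intensity = eval_lognormal_band(tyr, WAVELENGTH_GRID) + eval_lognormal_band(
            trp_band, WAVELENGTH_GRID
        )
        if gen.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, gen.noise_sd, size=intensity.shape)
        spectra.append(
            EmissionSpectrum(
                wavelength=WAVELENGTH_GRID.copy(), intensity=intensity, urea=float(x)
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# RS-repeat sequences

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "sep": "SEP",
}

RESIDUE_CHARGE = {"R": 1, "K": 1, "D": -1, "E": -1, "sep": -2}

# dipeptide-unit cycles; at equal repeat counts the net charge per unit
# orders bad1-like (+7/6) > u2af1-like (+9/8) > srsf1-like (+1)
FLAVOR_CYCLES = {
    "srsf1-like": [("R", "S")],
    "u2af1-like": [
        ("R", "S"), ("R", "S"), ("R", "S"), ("R", "R"),
        ("R", "S"), ("R", "S"), ("R", "S"), ("R", "S"),
    ],
    "bad1-like": [
        ("R", "R"), ("R", "S"), ("R", "E"), ("R", "R"), ("R", "D"), ("R", "R"),
    ],
}


def parse_sequence(seq: str | Sequence[str]) -> list[str]:
    """Split a residue-token string ('R sep R S ...') into a token list."""
    tokens = seq.split() if isinstance(seq, str) else list(seq)
    for t in tokens:
        if t not in ONE_TO_THREE:
            raise ParameterError(f"unknown residue code {t!r}")
    return tokens


def generate_rs_sequence(
    n_repeats: int,
    phospho_fraction: float,
    flavor: str,
    gen: GenConfig,
) -> str:
    """Emit an RS-repeat residue-token string.

    ``n_repeats`` dipeptide units are drawn cyclically from the flavor
    pattern; ``phospho_fraction`` of the serines (rounded) are replaced by
    the phosphoserine token 'sep', chosen reproducibly under the seed.
    """
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    if not 0.0 <= phospho_fraction <= 1.0:
        raise ParameterError("phospho_fraction must lie in [0, 1]")
    if flavor not in FLAVOR_CYCLES:
        raise ParameterError(f"unknown flavor {flavor!r}")
    cycle = FLAVOR_CYCLES[flavor]
    tokens: list[str] = []
    for i in range(n_repeats):
        tokens.extend(cycle[i % len(cycle)])
    ser_positions = [i for i, t in enumerate(tokens) if t == "S"]
    k = int(round(phospho_fraction * len(ser_positions)))
    if k:
        rng = gen.rng()
        chosen = rng.choice(len(ser_positions), size=k, replace=False)
        for j in chosen:
            tokens[ser_positions[int(j)]] = "sep"
    return " ".join(tokens)


def net_charge(seq: str | Sequence[str]) -> int:
    """Net charge at neutral pH: Arg/Lys +1, Asp/Glu -1, phosphoserine -2."""
    return sum(RESIDUE_CHARGE.get(t, 0) for t in parse_sequence(seq))


# ---------------------------------------------------------------------------
# planted coordinate ensembles

# local residue templates: (atom name, offset) with the side-chain cluster
# near the origin and the backbone cluster displaced to x ~ -8 A
_BACKBONE = [
    ("N", (-9.4, 0.0, 0.0)),
    ("H", (-9.4, 0.0, 1.0)),
    ("CA", (-8.0, 0.0, 0.0)),
    ("C", (-6.6, 0.0, 0.0)),
    ("O", (-6.0, 1.0, 0.0)),
]

_SIDECHAINS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "ARG": [
        ("NH1", (0.0, 0.0, 0.0)),
        ("HH11", (1.0, 0.0, 0.0)),
        ("CZ", (-1.33, 0.0, 0.0)),
        ("NE", (-2.0, 1.15, 0.0)),
        ("HE", (-3.0, 1.3, 0.0)),
        ("NH2", (-2.0, -1.15, 0.0)),
        ("HH21", (-2.6, -1.95, 0.0)),
    ],
    "LYS": [
        ("NZ", (0.0, 0.0, 0.0)),
        ("HZ1", (1.0, 0.0, 0.0)),
        ("CE", (-1.5, 0.0, 0.0)),
    ],
    "ASP": [
        ("OD1", (0.0, 0.0, 0.0)),
        ("CG", (-1.25, 0.0, 0.0)),
        ("OD2", (-1.9, -1.05, 0.0)),
        ("CB", (-2.0, 1.0, 0.0)),
    ],
    "GLU": [
        ("OE1", (0.0, 0.0, 0.0)),
        ("CD", (-1.25, 0.0, 0.0)),
        ("OE2", (-1.9, -1.05, 0.0)),
        ("CG", (-2.0, 1.0, 0.0)),
    ],
    "SEP": [
        ("O1P", (0.0, 0.0, 0.0)),
        ("P", (-1.5, 0.0, 0.0)),
        ("O2P", (-2.25, 1.2, 0.0)),
        ("O3P", (-2.25, -1.2, 0.0)),
        ("OG", (-1.5, 0.0, 1.45)),
    ],
    "SER": [
        ("OG", (0.0, 0.0, 0.0)),
        ("HG", (1.0, 0.0, 0.0)),
        ("CB", (-1.4, 0.0, 0.0)),
    ],
    "THR": [
        ("OG1", (0.0, 0.0, 0.0)),
        ("HG1", (1.0, 0.0, 0.0)),
        ("CB", (-1.4, 0.0, 0.0)),
    ],
    "ASN": [
        ("ND2", (0.0, 0.0, 0.0)),
        ("HD21", (1.0, 0.0, 0.0)),
        ("CG", (-1.3, 0.0, 0.0)),
        ("OD1", (-1.95, -1.05, 0.0)),
    ],
    "GLN": [
        ("NE2", (0.0, 0.0, 0.0)),
        ("HE21", (1.0, 0.0, 0.0)),
        ("CD", (-1.3, 0.0, 0.0)),
        ("OE1", (-1.95, -1.05, 0.0)),
    ],
    "PHE": [
        ("CG", (1.39, 0.0, 0.0)),
        ("CD1", (0.695, 1.204, 0.0)),
        ("CD2", (0.695, -1.204, 0.0)),
        ("CE1", (-0.695, 1.204, 0.0)),
        ("CE2", (-0.695, -1.204, 0.0)),
        ("CZ", (-1.39, 0.0, 0.0)),
    ],
    "TYR": [
        ("OH", (0.0, 0.0, 0.0)),
        ("HH", (1.0, 0.0, 0.0)),
        ("CZ", (-1.38, 0.0, 0.0)),
        ("CE1", (-2.075, 1.204, 0.0)),
        ("CE2", (-2.075, -1.204, 0.0)),
        ("CD1", (-3.465, 1.204, 0.0)),
        ("CD2", (-3.465, -1.204, 0.0)),
        ("CG", (-4.16, 0.0, 0.0)),
    ],
    "TRP": [
        ("CE2", (1.39, 0.0, 0.0)),
        ("CZ2", (0.695, 1.204, 0.0)),
        ("CH2", (-0.695, 1.204, 0.0)),
        ("CZ3", (-1.39, 0.0, 0.0)),
        ("CE3", (-0.695, -1.204, 0.0)),
        ("CD2", (0.695, -1.204, 0.0)),
        ("CG", (1.3, -2.35, 0.0)),
        ("CD1", (2.65, -2.15, 0.0)),
        ("NE1", (3.0, -0.95, 0.0)),
        ("HE1", (3.95, -0.7, 0.0)),
    ],
    "HIS": [
        ("CG", (1.19, 0.0, 0.0)),
        ("ND1", (0.368, 1.132, 0.0)),
        ("HD1", (0.7, 2.0, 0.0)),
        ("CE1", (-0.963, 0.7, 0.0)),
        ("NE2", (-0.963, -0.7, 0.0)),
        ("HE2", (-1.73, -1.26, 0.0)),
        ("CD2", (0.368, -1.132, 0.0)),
    ],
}

# role anchors within the templates (all templates are oriented so the
# partner sits toward +x from the anchor, and planar groups lie in z=0)
_SB_DONOR_ANCHOR = {"ARG": "NH1", "LYS": "NZ"}
_SB_ACCEPTOR_ANCHOR = {"ASP": "OD1", "GLU": "OE1", "SEP": "O1P"}
_HB_DONOR_ANCHOR = {
    "SER": "OG", "THR": "OG1", "TYR": "OH", "ASN": "ND2", "GLN": "NE2",
    "ARG": "NH1", "LYS": "NZ",
}
_HB_ACCEPTOR_ANCHOR = {"SER": "OG", "THR": "OG1", "ASP": "OD1", "GLU": "OE1", "SEP": "O1P"}
_PLANE_CAPABLE = {"PHE", "TYR", "TRP", "HIS", "ARG"}

_GRID_SPACING = 32.0  # A between placement units
_JITTER_CLIP = 0.15  # A, max per-atom displacement; keeps every label stable

# planted separations (A) vs detector defaults (4.0 / 3.5 / 4.5)
_SB_SEP = 3.0
_HB_SEP = 2.9
_STACK_SEP = 3.8


@dataclass
class PlantedComplexSpec:
    """Ground-truth recipe for a coordinate ensemble.

    Planted interaction entries are ``(chain, resindex, chain, resindex)``
    with 1-based residue indices and chain ids 'A'/'B'.  ``chain_b_seq``
    may be empty for a single-chain system.
    """

    chain_a_seq: str
    chain_b_seq: str = ""
    planted_salt_bridges: list[tuple] = field(default_factory=list)
    planted_hbonds: list[tuple] = field(default_factory=list)
    planted_stacks: list[tuple] = field(default_factory=list)
    n_frames: int = 10

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")


@dataclass
class PlantedComplex:
    """A built fixture: the trajectory plus its exact ground truth."""

    trajectory: Trajectory
    ground_truth_counts: dict  # (kind, span) -> count, constant across frames
    events: list  # (kind, (chain, res), (chain, res), span)

    def counts_by_kind(self) -> dict:
        out: dict[str, int] = {}
        for (kind, _), v in self.ground_truth_counts.items():
            out[kind] = out.get(kind, 0) + v
        return out


def _stack_kind(resname_a: str, resname_b: str) -> str:
    if resname_a == "ARG" and resname_b == "ARG":
        return "cation_cation"
    if resname_a == "ARG" or resname_b == "ARG":
        return "cation_pi"
    return "pi_pi"


def _plane_centroid(resname: str) -> np.ndarray:
    from rsdomain.contacts import PLANE_GROUPS

    names = PLANE_GROUPS[resname][0] if resname != "TRP" else PLANE_GROUPS["TRP"][1]
    coords = {n: np.array(o) for n, o in _SIDECHAINS[resname]}
    return np.mean([coords[n] for n in names], axis=0)


def _validate_spec(spec: PlantedComplexSpec) -> tuple[dict, list]:
    """Chain tables + normalized planted list [(kind, key_a, key_b, resnames)]."""
    chains: dict[str, list[str]] = {}
    chains["A"] = [ONE_TO_THREE[t] for t in parse_sequence(spec.chain_a_seq)]
    if spec.chain_b_seq:
        chains["B"] = [ONE_TO_THREE[t] for t in parse_sequence(spec.chain_b_seq)]

    def resolve(entry: tuple) -> tuple:
        ca, ra, cb, rb = entry
        for c, r in ((ca, ra), (cb, rb)):
            if c not in chains:
                raise GenerationError(f"planted pair references missing chain {c!r}")
            if not 1 <= r <= len(chains[c]):
                raise GenerationError(f"planted pair references residue {c}{r} out of range")
        if (ca, ra) == (cb, rb):
            raise GenerationError("planted pair references the same residue twice")
        return (ca, ra, chains[ca][ra - 1]), (cb, rb, chains[cb][rb - 1])

    used: set[tuple[str, int]] = set()
    normalized = []

    def claim(a, b):
        for c, r, _ in (a, b):
            if (c, r) in used:
                raise GenerationError(
                    f"residue {c}{r} takes part in more than one planted interaction"
                )
            used.add((c, r))

    for entry in spec.planted_salt_bridges:
        a, b = resolve(entry)
        if a[2] in _SB_DONOR_ANCHOR and b[2] in _SB_ACCEPTOR_ANCHOR:
            donor, acceptor = a, b
        elif b[2] in _SB_DONOR_ANCHOR and a[2] in _SB_ACCEPTOR_ANCHOR:
            donor, acceptor = b, a
        else:
            raise GenerationError(
                f"salt bridge requires an Arg/Lys donor and Asp/Glu/SEP acceptor, got "
                f"{a[2]}-{b[2]}"
            )
        claim(donor, acceptor)
        normalized.append(("salt_bridge", donor, acceptor))

    for entry in spec.planted_hbonds:
        a, b = resolve(entry)
        if a[2] in _HB_DONOR_ANCHOR and b[2] in _HB_ACCEPTOR_ANCHOR:
            donor, acceptor = a, b
        elif b[2] in _HB_DONOR_ANCHOR and a[2] in _HB_ACCEPTOR_ANCHOR:
            donor, acceptor = b, a
        else:
            raise GenerationError(f"cannot plant an H-bond between {a[2]} and {b[2]}")
        if donor[2] in _SB_DONOR_ANCHOR and acceptor[2] in _SB_ACCEPTOR_ANCHOR:
            raise GenerationError(
                f"{donor[2]}-{acceptor[2]} would be detected as a salt bridge, "
                "not an H-bond; plant a salt bridge instead"
            )
        if donor[2] in _PLANE_CAPABLE and acceptor[2] in _PLANE_CAPABLE:
            raise GenerationError(
                "planted H-bond between two plane-capable residues could create "
                "an accidental stacking event"
            )
        claim(donor, acceptor)
        normalized.append(("hbond", donor, acceptor))

    for entry in spec.planted_stacks:
        a, b = resolve(entry)
        if a[2] not in _PLANE_CAPABLE or b[2] not in _PLANE_CAPABLE:
            raise GenerationError(
                f"stacking requires two planar residues (aromatic or Arg), got "
                f"{a[2]}-{b[2]}"
            )
        claim(a, b)
        normalized.append((_stack_kind(a[2], b[2]), a, b))

    return chains, normalized


# rotations used when placing the two partners of a planted pair:
# side A keeps the template frame (for point contacts) and side B is turned
# 180 deg about z so its anchor faces back toward A; stacking maps the
# template plane normal (z) onto the +/-x separation axis with the in-plane
# x axis sent to opposite y directions so pendant atoms (e.g. Tyr OH) of the
# two rings point away from each other.
_R_IDENTITY = np.eye(3)
_R_FLIP = np.diag([-1.0, -1.0, 1.0])
_R_STACK_A = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
_R_STACK_B = np.array([[0.0, 0.0, -1.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def _residue_atoms(resname: str) -> list[tuple[str, np.ndarray]]:
    atoms = [(n, np.array(o)) for n, o in _BACKBONE]
    atoms += [(n, np.array(o)) for n, o in _SIDECHAINS.get(resname, [])]
    return atoms


def _anchor_offset(resname: str, kind: str, role: str) -> np.ndarray:
    if kind == "salt_bridge":
        name = (_SB_DONOR_ANCHOR if role == "donor" else _SB_ACCEPTOR_ANCHOR)[resname]
    elif kind == "hbond":
        name = (_HB_DONOR_ANCHOR if role == "donor" else _HB_ACCEPTOR_ANCHOR)[resname]
    else:
        return _plane_centroid(resname)
    for n, o in _SIDECHAINS[resname]:
        if n == name:
            return np.array(o)
    raise KeyError(name)


def build_planted_complex(spec: PlantedComplexSpec, gen: GenConfig) -> PlantedComplex:
    """Build an idealized multi-frame ensemble realising the spec exactly.

    Every planted interaction satisfies its detector criterion with margin;
    every non-planted residue pair is separated by >= 12 A.  Per-frame
    jitter is Gaussian (SD ``gen.noise_sd`` A) clipped to 0.15 A per atom.
    Frame interval is 150 ps.
    """
    chains, planted = _validate_spec(spec)

    # placement units: planted pairs first, then remaining singleton residues
    placed: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}  # -> (R, t)
    units: list[list[tuple[tuple[str, int, str], np.ndarray, np.ndarray]]] = []

    for kind, donor, acceptor in planted:
        sep = {"salt_bridge": _SB_SEP, "hbond": _HB_SEP}.get(kind, _STACK_SEP)
        if kind in ("salt_bridge", "hbond"):
            r_a, r_b = _R_IDENTITY, _R_FLIP
        else:
            r_a, r_b = _R_STACK_A, _R_STACK_B
        half = 0.5 * sep
        anchor_a = _anchor_offset(donor[2], kind, "donor")
        anchor_b = _anchor_offset(acceptor[2], kind, "acceptor")
        # translations chosen so R @ anchor + t lands at -half/+half on x
        t_a = np.array([-half, 0.0, 0.0]) - r_a @ anchor_a
        t_b = np.array([half, 0.0, 0.0]) - r_b @ anchor_b
        units.append([(donor, r_a, t_a), (acceptor, r_b, t_b)])

    in_pairs = {(c, r) for unit in units for (c, r, _), _, _ in unit}
    for chain_id, seq in chains.items():
        for idx, resname in enumerate(seq, start=1):
            if (chain_id, idx) not in in_pairs:
                units.append([((chain_id, idx, resname), _R_IDENTITY, np.zeros(3))])

    # coarse grid, one unit per point
    n_side = max(2, math.ceil(len(units) ** (1.0 / 3.0)))
    grid_points = [
        np.array(p, dtype=float) * _GRID_SPACING
        for p in itertools.product(range(n_side), repeat=3)
    ]
    if len(grid_points) < len(units):
        raise GenerationError("could not place all residues on the grid")

    base: dict[tuple[str, int], list[tuple[str, str, np.ndarray]]] = {}
    for unit, origin in zip(units, grid_points):
        for (chain_id, idx, resname), rot, trans in unit:
            atoms = [
                (name, resname, rot @ offset + trans + origin)
                for name, offset in _residue_atoms(resname)
            ]
            base[(chain_id, idx)] = atoms

    # assemble frames in chain/residue order with clipped per-frame jitter
    ordered_keys = [
        (chain_id, idx)
        for chain_id in sorted(chains)
        for idx in range(1, len(chains[chain_id]) + 1)
    ]
    rng = gen.rng()
    frames = []
    for _ in range(spec.n_frames):
        records = []
        for chain_id, idx in ordered_keys:
            for name, resname, xyz in base[(chain_id, idx)]:
                if gen.noise_sd > 0:
                    disp = rng.normal(0.0, gen.noise_sd, size=3)
                    norm = float(np.linalg.norm(disp))
                    if norm > _JITTER_CLIP:
                        disp *= _JITTER_CLIP / norm
                    xyz = xyz + disp
                records.append(
                    AtomRecord(
                        name=name,
                        residue_name=resname,
                        residue_index=idx,
                        chain_id=chain_id,
                        xyz=np.asarray(xyz, dtype=float),
                    )
                )
        frames.append(Frame(records))

    counts: dict[tuple[str, str], int] = {}
    events = []
    for kind, a, b in planted:
        span = "inter" if a[0] != b[0] else "intra"
        counts[(kind, span)] = counts.get((kind, span), 0) + 1
        events.append((kind, (a[0], a[1]), (b[0], b[1]), span))

    trajectory = Trajectory(frames=frames, frame_interval=150.0)
    return PlantedComplex(
        trajectory=trajectory, ground_truth_counts=counts, events=events
    )


def build_flavor_complex(
    flavor: str,
    n_repeats: int,
    gen: GenConfig,
    n_frames: int = 5,
) -> PlantedComplex:
    """Two-chain fixture mimicking an unphosphorylated RS partner (chain A,
    the given flavor) bound to a fully phosphorylated RS chain (chain B).

    The number of planted interchain salt bridges scales with the partner's
    net positive charge (net_charge // 3, Arg donors onto phosphoserine
    acceptors), so across flavors the interchain totals rank
    bad1-like > u2af1-like > srsf1-like by construction.  One interchain
    H-bond and one interchain Arg-Arg stack are planted identically in every
    flavor so the ordering is carried by the salt bridges.
    """
    partner = parse_sequence(generate_rs_sequence(n_repeats, 0.0, flavor, gen))
    pi_chain = parse_sequence(
        generate_rs_sequence(n_repeats, 1.0, "srsf1-like", gen)
    )
    k = max(1, net_charge(partner) // 3)
    arg_positions = [i + 1 for i, t in enumerate(partner) if t == "R"]
    sep_positions = [i + 1 for i, t in enumerate(pi_chain) if t == "sep"]
    ser_positions = [i + 1 for i, t in enumerate(partner) if t == "S"]
    if k + 1 > len(sep_positions) or k + 1 > len(arg_positions) or not ser_positions:
        raise GenerationError(
            f"flavor fixture needs more repeats: {k} salt bridges requested with "
            f"{len(sep_positions)} phosphoserines / {len(arg_positions)} arginines"
        )
    salt_bridges = [
        ("A", arg_positions[i], "B", sep_positions[i]) for i in range(k)
    ]
    hbonds = [("A", ser_positions[-1], "B", sep_positions[k])]
    # chain B odd positions are Arg in the srsf1-like pattern
    stacks = [("A", arg_positions[-1], "B", sep_positions[k] - 1)]
    spec = PlantedComplexSpec(
        chain_a_seq=" ".join(partner),
        chain_b_seq=" ".join(pi_chain),
        planted_salt_bridges=salt_bridges,
        planted_hbonds=hbonds,
        planted_stacks=stacks,
        n_frames=n_frames,
    )
    return build_planted_complex(spec, gen)


# ---------------------------------------------------------------------------
# serialization

_ELEMENTS = {"N": "N", "C": "C", "O": "O", "H": "H", "P": "P", "S": "S"}


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int, xyz: np.ndarray
) -> str:
    pdb_name = name if len(name) >= 4 else f" {name:<3s}"
    element = _ELEMENTS.get(name[0], name[0])
    return (
        f"ATOM  {serial:5d} {pdb_name:<4s} {resname:>3s} {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_trajectory_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame, occupancy 1.00,
    B-factor 0.00) with a REMARK recording the frame interval."""
    lines = [f"REMARK 250 frame_interval_ps {trajectory.frame_interval:g}"]
    for m, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL {m:8d}")
        serial = 0
        prev_chain = None
        for a in frame.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            prev_chain = a.chain_id
            serial += 1
            lines.append(
                _pdb_atom_line(
                    serial, a.name, a.residue_name, a.chain_id, a.residue_index, a.xyz
                )
            )
        lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ground_truth_json(complex_: PlantedComplex, path: str | Path) -> None:
    payload = {
        "counts": {f"{k}|{s}": v for (k, s), v in complex_.ground_truth_counts.items()},
        "events": [
            {"kind": kind, "a": list(a), "b": list(b), "span": span}
            for kind, a, b, span in complex_.events
        ],
        "n_frames": len(complex_.trajectory),
        "frame_interval_ps": complex_.trajectory.frame_interval,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
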