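"""Geometric interaction census over coordinate ensembles.

Implements the interaction analysis applied to RS-peptide ensembles:
salt bridges (Arg/Lys side-chain N donors against Asp/Glu/phosphoserine
side-chain O acceptors), hydrogen bonds (heavy-atom distance plus D-H...A
linearity), and planar stacking (pi-pi between aromatic rings, cation-pi
between an Arg guanidinium plane and an aromatic ring, cation-cation
between two guanidinium planes), each partitioned into intrachain and
interchain events.  Downstream summaries give per-frame mean counts by
kind and span, per-residue salt-bridge profiles, replicate mean +/- SD,
and backbone-RMSD equilibration checks.

Trajectories are multi-model PDB files (MODEL/ENDMDL blocks, chains A/B,
residue name SEP for phosphoserine); parsing goes through Biopython.

Default geometric criteria (all configurable):

* salt bridge: donor N to acceptor O distance <= 4.0 A, counted once per
  residue pair per frame;
* hydrogen bond: donor-acceptor heavy-atom distance <= 3.5 A and
  D-H...A angle >= 135 deg, pairs already counted as salt bridges excluded;
* stacking: plane-centroid distance <= 4.5 A and inter-plane angle
  <= 20 deg.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "GeometryConfig",
    "InteractionEvent",
    "FrameSummary",
    "ReplicateSummary",
    "ResidueSaltBridgeProfile",
    "RmsdResult",
    "INTERACTION_KINDS",
    "read_multimodel_pdb",
    "detect_salt_bridges",
    "detect_hbonds",
    "detect_stacking",
    "detect_all",
    "summarize_frames",
    "per_residue_profile",
    "aggregate_replicates",
    "backbone_rmsd_series",
    "write_events_tsv",
]

INTERACTION_KINDS = ("salt_bridge", "hbond", "pi_pi", "cation_pi", "cation_cation")
SPANS = ("intra", "inter")

SALT_BRIDGE_DONOR_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}
SALT_BRIDGE_ACCEPTOR_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SEP": ("O1P", "O2P", "O3P", "OG"),
}

# side-chain hydrogen-bond donors (heavy atoms carrying a polar H)
HBOND_DONOR_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "CYS": ("SG",),
    "SEP": (),
}
HBOND_ACCEPTOR_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "SEP": ("O1P", "O2P", "O3P", "OG"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
}

# planar groups used for stacking; Trp contributes both rings but is counted
# once per residue pair
PLANE_GROUPS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "ARG": (("CZ", "NE", "NH1", "NH2"),),
}
AROMATIC_RESIDUES = {"PHE", "TYR", "TRP", "HIS"}

KNOWN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "SEP", "THR", "TRP", "TYR",
    "VAL",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("xyz must be a finite length-3 vector")


class Frame:
    """One snapshot: column-oriented atom table with residue lookup."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = list(atoms)
        self.names = np.array([a.name for a in self.atoms])
        self.resnames = np.array([a.residue_name for a in self.atoms])
        self.resindex = np.array([a.residue_index for a in self.atoms])
        self.chains = np.array([a.chain_id for a in self.atoms])
        self.coords = (
            np.array([a.xyz for a in self.atoms])
            if self.atoms
            else np.zeros((0, 3))
        )
        self._by_residue: dict[tuple[str, int], list[int]] = defaultdict(list)
        for i, a in enumerate(self.atoms):
            self._by_residue[(a.chain_id, a.residue_index)].append(i)
        unknown = {
            rn for rn in set(self.resnames) if rn not in KNOWN_RESIDUES
        }
        if unknown:
            warnings.warn(
                f"unknown residue name(s) {sorted(unknown)}: side-chain sites skipped",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """(chain, residue_index, residue_name) in first-appearance order."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), a.residue_name)
        return [(c, i, n) for (c, i), n in seen.items()]

    def residue_atoms(self, chain: str, resindex: int) -> list[int]:
        return self._by_residue.get((chain, resindex), [])

    def atom_xyz(self, chain: str, resindex: int, name: str) -> np.ndarray | None:
        for i in self.residue_atoms(chain, resindex):
            if self.names[i] == name:
                return self.coords[i]
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Rigidly moved copy (for invariance checks and fixtures)."""
        new = [
            AtomRecord(a.name, a.residue_name, a.residue_index, a.chain_id,
                       rotation @ a.xyz + translation)
            for a in self.atoms
        ]
        return Frame(new)


@dataclass
class Trajectory:
    frames: list[Frame]
    frame_interval: float = 150.0  # ps between snapshots
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.frames and not self.chain_ids:
            self.chain_ids = tuple(sorted(set(self.frames[0].chains)))
        counts = {len(f) for f in self.frames}
        if len(counts) > 1:
            raise ValueError("atom count varies across frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class GeometryConfig:
    """Detector thresholds; distances in Angstrom, angles in degrees.

    ``hbond_angle_cutoff`` is the allowed deviation from linearity: the
    D-H...A angle must be >= 180 - cutoff.  ``stack_angle_cutoff`` is the
    maximum angle between the two group planes.
    """

    saltbridge_cutoff: float = 4.0
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 45.0
    stack_dist_cutoff: float = 4.5
    stack_angle_cutoff: float = 20.0
    infer_hydrogens: bool = False
    include_backbone_hbonds: bool = True

    def __post_init__(self) -> None:
        for name in ("saltbridge_cutoff", "hbond_dist_cutoff", "stack_dist_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_angle_cutoff", "stack_angle_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 90:
                raise ValueError(f"{name} must lie in (0, 90]")


@dataclass(frozen=True)
class InteractionEvent:
    kind: str
    partner_a: tuple[str, int]
    partner_b: tuple[str, int]
    span: str
    frame_index: int
    distance: float
    angle: float | None = None


@dataclass
class FrameSummary:
    """Per-frame mean interaction counts by (kind, span) over a window."""

    mean_counts: dict[tuple[str, str], float]
    n_frames: int

    def total(self, kind: str) -> float:
        return self.mean_counts.get((kind, "intra"), 0.0) + self.mean_counts.get(
            (kind, "inter"), 0.0
        )


@dataclass
class ReplicateSummary:
    mean: dict[tuple[str, str], float]
    sd: dict[tuple[str, str], float]
    n_replicates: int


@dataclass
class ResidueSaltBridgeProfile:
    chain: str
    per_residue: dict[int, float]  # residue index -> mean salt bridges / frame
    overall_mean: float
    n_frames: int


@dataclass
class RmsdResult:
    series: np.ndarray  # A, one value per frame
    equilibrated: bool
    trailing_slope: float  # A / ns
    reference_frame: int


# ---------------------------------------------------------------------------
# PDB input / output helpers


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory` via Biopython.

    Models become frames in file order.  SEP residues are kept with their
    phosphate oxygens so they act as salt-bridge/H-bond acceptors.  A
    ``REMARK frame_interval_ps`` line written by the simulator is honoured;
    otherwise the interval defaults to 150 ps.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    interval = 150.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK") and "frame_interval_ps" in line:
                interval = float(line.rsplit(None, 1)[1])
            if line.startswith(("MODEL", "ATOM", "HETATM")):
                break

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames: list[Frame] = []
    for model in structure:
        records = []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                for atom in residue:
                    records.append(
                        AtomRecord(
                            name=atom.get_name(),
                            residue_name=resname,
                            residue_index=residue.get_id()[1],
                            chain_id=chain.get_id(),
                            xyz=atom.get_coord().astype(float),
                        )
                    )
        frames.append(Frame(records))
    if not frames:
        raise ValueError(f"no models found in {path}")
    counts = {len(f) for f in frames}
    if len(counts) > 1:
        raise ValueError(f"inconsistent atom counts across models in {path}: {sorted(counts)}")
    return Trajectory(frames=frames, frame_interval=interval)


def write_events_tsv(events: Iterable[InteractionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "frame\tkind\tspan\tchainA\tresA\tchainB\tresB\tdistance_A\tangle_deg\n"
        )
        for e in events:
            angle = f"{e.angle:.2f}" if e.angle is not None else ""
            fh.write(
                f"{e.frame_index}\t{e.kind}\t{e.span}\t{e.partner_a[0]}\t{e.partner_a[1]}"
                f"\t{e.partner_b[0]}\t{e.partner_b[1]}\t{e.distance:.3f}\t{angle}\n"
            )


# ---------------------------------------------------------------------------
# detectors


def _span(a: tuple[str, int], b: tuple[str, int]) -> str:
    return "inter" if a[0] != b[0] else "intra"


def _ordered(a: tuple[str, int], b: tuple[str, int]) -> tuple[tuple[str, int], tuple[str, int]]:
    return (a, b) if a <= b else (b, a)


def _collect_sites(frame: Frame, table: dict[str, tuple[str, ...]]):
    """(residue key, atom index) pairs for every site atom named in table."""
    sites = []
    for chain, resindex, resname in frame.residues:
        wanted = table.get(resname)
        if not wanted:
            continue
        for i in frame.residue_atoms(chain, resindex):
            if frame.names[i] in wanted:
                sites.append(((chain, resindex), i))
    return sites


def detect_salt_bridges(
    frame: Frame, config: GeometryConfig | None = None, frame_index: int = 0
) -> list[InteractionEvent]:
    """Salt bridges: any donor-N within ``saltbridge_cutoff`` of an
    acceptor-O, deduplicated to one event per residue pair (minimum
    distance kept)."""
    config = config or GeometryConfig()
    donors = _collect_sites(frame, SALT_BRIDGE_DONOR_ATOMS)
    acceptors = _collect_sites(frame, SALT_BRIDGE_ACCEPTOR_ATOMS)
    best: dict[tuple, float] = {}
    for di_pos, dres, ai_pos, ares, d in _close_site_pairs(
        frame, donors, acceptors, config.saltbridge_cutoff
    ):
        key = _ordered(dres, ares)
        if d < best.get(key, math.inf):
            best[key] = d
    return [
        InteractionEvent(
            kind="salt_bridge",
            partner_a=a,
            partner_b=b,
            span=_span(a, b),
            frame_index=frame_index,
            distance=d,
        )
        for (a, b), d in sorted(best.items())
    ]


def _close_site_pairs(frame: Frame, donors, acceptors, cutoff: float):
    """Yield (donor_idx, donor_res, acceptor_idx, acceptor_res, distance)
    for all cross-residue site pairs within cutoff (vectorized distances)."""
    if not donors or not acceptors:
        return
    from scipy.spatial.distance import cdist

    d_idx = np.array([i for _, i in donors])
    a_idx = np.array([i for _, i in acceptors])
    dist = cdist(frame.coords[d_idx], frame.coords[a_idx])
    for r, c in np.argwhere(dist <= cutoff):
        dres = donors[r][0]
        ares = acceptors[c][0]
        if dres == ares:
            continue
        yield donors[r][1], dres, acceptors[c][1], ares, float(dist[r, c])


def _donor_hydrogens(frame: Frame, res_key: tuple[str, int], donor_idx: int) -> list[np.ndarray]:
    """Positions of hydrogens bonded to the donor heavy atom (<= 1.35 A)."""
    hs = []
    for i in frame.residue_atoms(*res_key):
        if frame.names[i].startswith("H"):
            if np.linalg.norm(frame.coords[i] - frame.coords[donor_idx]) <= 1.35:
                hs.append(frame.coords[i])
    return hs


def detect_hbonds(
    frame: Frame,
    config: GeometryConfig | None = None,
    frame_index: int = 0,
    salt_bridge_pairs: set[tuple] | None = None,
) -> list[InteractionEvent]:
    """Hydrogen bonds by heavy-atom distance plus D-H...A linearity.

    Residue pairs already counted as salt bridges in the same frame are
    excluded (pass their pair keys, or they are recomputed here).  Donors
    without an explicit hydrogen raise a capability error unless
    ``config.infer_hydrogens`` is set, in which case the hydrogen is placed
    on the donor-acceptor line (the angle criterion then always passes,
    i.e. a distance-only call).
    """
    config = config or GeometryConfig()
    if salt_bridge_pairs is None:
        salt_bridge_pairs = {
            _ordered(e.partner_a, e.partner_b)
            for e in detect_salt_bridges(frame, config, frame_index)
        }
    donor_table = dict(HBOND_DONOR_ATOMS)
    acceptor_table = dict(HBOND_ACCEPTOR_ATOMS)
    if config.include_backbone_hbonds:
        for rn in KNOWN_RESIDUES:
            donor_table[rn] = tuple(donor_table.get(rn, ())) + ("N",)
            acceptor_table[rn] = tuple(acceptor_table.get(rn, ())) + ("O",)

    donors = _collect_sites(frame, donor_table)
    acceptors = _collect_sites(frame, acceptor_table)
    min_angle = 180.0 - config.hbond_angle_cutoff
    frame_has_hydrogens = any(n.startswith("H") for n in frame.names)

    best: dict[tuple, tuple[float, float]] = {}
    for di, dres, ai, ares, dist in _close_site_pairs(
        frame, donors, acceptors, config.hbond_dist_cutoff
    ):
        if dist == 0.0:
            continue
        key = _ordered(dres, ares)
        if key in salt_bridge_pairs:
            continue
        d_xyz = frame.coords[di]
        a_xyz = frame.coords[ai]
        hs = _donor_hydrogens(frame, dres, di)
        if not hs:
            if config.infer_hydrogens:
                hs = [d_xyz + (a_xyz - d_xyz) / dist * 1.0]
            elif not frame_has_hydrogens:
                raise RuntimeError(
                    "structure carries no explicit hydrogens and hydrogen "
                    "inference is disabled (GeometryConfig.infer_hydrogens)"
                )
            else:
                # protonated model, but this site has no proton to donate
                continue
        angle = max(_angle_deg(d_xyz, h, a_xyz) for h in hs)
        if angle >= min_angle:
            if dist < best.get(key, (math.inf, 0.0))[0]:
                best[key] = (dist, angle)
    return [
        InteractionEvent(
            kind="hbond",
            partner_a=a,
            partner_b=b,
            span=_span(a, b),
            frame_index=frame_index,
            distance=d,
            angle=ang,
        )
        for (a, b), (d, ang) in sorted(best.items())
    ]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a near-planar atom group via SVD.

    Raises on degenerate (collinear) geometry where no plane is defined.
    """
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    if len(s) < 3 or s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("degenerate planar group: atoms are collinear")
    return centroid, vt[2]


def _plane_groups(frame: Frame):
    """All resolvable planar groups: (residue key, resname, centroid, normal)."""
    groups = []
    for chain, resindex, resname in frame.residues:
        for atom_names in PLANE_GROUPS.get(resname, ()):
            coords = []
            for name in atom_names:
                xyz = frame.atom_xyz(chain, resindex, name)
                if xyz is not None:
                    coords.append(xyz)
            if len(coords) < 3:
                continue
            centroid, normal = _plane_fit(np.array(coords))
            groups.append(((chain, resindex), resname, centroid, normal))
    return groups


def _stack_kind(resname_a: str, resname_b: str) -> str:
    a_arg = resname_a == "ARG"
    b_arg = resname_b == "ARG"
    if a_arg and b_arg:
        return "cation_cation"
    if a_arg or b_arg:
        return "cation_pi"
    return "pi_pi"


def plane_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two planes from their unit normals, folded to [0, 90]."""
    c = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    return math.degrees(math.acos(c))


def detect_stacking(
    frame: Frame, config: GeometryConfig | None = None, frame_index: int = 0
) -> list[InteractionEvent]:
    """Planar stacking: centroid distance <= cutoff and inter-plane angle
    <= cutoff, classified pi-pi / cation-pi / cation-cation; one event per
    residue pair even when both Trp rings qualify."""
    config = config or GeometryConfig()
    groups = _plane_groups(frame)
    best: dict[tuple, tuple[float, float, str]] = {}
    for i in range(len(groups)):
        res_i, name_i, c_i, n_i = groups[i]
        for j in range(i + 1, len(groups)):
            res_j, name_j, c_j, n_j = groups[j]
            if res_i == res_j:
                continue
            dist = float(np.linalg.norm(c_i - c_j))
            if dist > config.stack_dist_cutoff:
                continue
            angle = plane_angle_deg(n_i, n_j)
            if angle > config.stack_angle_cutoff:
                continue
            key = _ordered(res_i, res_j)
            if dist < best.get(key, (math.inf, 0.0, ""))[0]:
                best[key] = (dist, angle, _stack_kind(name_i, name_j))
    return [
        InteractionEvent(
            kind=kind,
            partner_a=a,
            partner_b=b,
            span=_span(a, b),
            frame_index=frame_index,
            distance=d,
            angle=ang,
        )
        for (a, b), (d, ang, kind) in sorted(best.items())
    ]


def detect_all(
    frame: Frame, config: GeometryConfig | None = None, frame_index: int = 0
) -> list[InteractionEvent]:
    """All detectors on one frame, with the salt-bridge/H-bond exclusion
    applied consistently."""
    config = config or GeometryConfig()
    sb = detect_salt_bridges(frame, config, frame_index)
    sb_pairs = {_ordered(e.partner_a, e.partner_b) for e in sb}
    hb = detect_hbonds(frame, config, frame_index, salt_bridge_pairs=sb_pairs)
    st = detect_stacking(frame, config, frame_index)
    return sb + hb + st


# ---------------------------------------------------------------------------
# summaries


def _window_frames(trajectory: Trajectory, window_ns: float | None) -> list[int]:
    n_total = len(trajectory)
    if n_total == 0:
        raise ValueError("empty trajectory")
    if window_ns is None:
        return list(range(n_total))
    n = int(round(window_ns * 1000.0 / trajectory.frame_interval))
    if n <= 0:
        raise ValueError("analysis window contains no frames")
    if n > n_total:
        raise ValueError(
            f"window of {n} frames exceeds trajectory length {n_total}"
        )
    return list(range(n_total - n, n_total))


def summarize_frames(
    trajectory: Trajectory,
    config: GeometryConfig | None = None,
    window_ns: float | None = None,
) -> FrameSummary:
    """Mean interaction counts per frame by (kind, span) over the trailing
    ``window_ns`` nanoseconds (all frames when None).  A 150 ns window at
    the 150 ps snapshot interval covers exactly 1000 frames."""
    config = config or GeometryConfig()
    indices = _window_frames(trajectory, window_ns)
    totals: dict[tuple[str, str], float] = {
        (k, s): 0.0 for k in INTERACTION_KINDS for s in SPANS
    }
    for idx in indices:
        for e in detect_all(trajectory.frames[idx], config, idx):
            totals[(e.kind, e.span)] += 1.0
    n = len(indices)
    return FrameSummary(
        mean_counts={k: v / n for k, v in totals.items()}, n_frames=n
    )


def per_residue_profile(
    trajectory: Trajectory,
    chain: str,
    config: GeometryConfig | None = None,
    window_ns: float | None = None,
) -> ResidueSaltBridgeProfile:
    """Mean salt bridges per frame for each residue of ``chain``.

    Every salt-bridge event increments each of its participants that lies
    on the profiled chain (an intrachain event within the chain counts for
    both residues).  The overall mean across residues is the horizontal
    reference line of a per-residue bar plot.
    """
    config = config or GeometryConfig()
    indices = _window_frames(trajectory, window_ns)
    residues = [
        (c, i) for c, i, _ in trajectory.frames[indices[0]].residues if c == chain
    ]
    if not residues:
        raise ValueError(f"chain {chain!r} not present")
    counts = {i: 0.0 for _, i in residues}
    for idx in indices:
        for e in detect_salt_bridges(trajectory.frames[idx], config, idx):
            for partner in (e.partner_a, e.partner_b):
                if partner[0] == chain:
                    counts[partner[1]] += 1.0
    n = len(indices)
    per_residue = {i: v / n for i, v in counts.items()}
    return ResidueSaltBridgeProfile(
        chain=chain,
        per_residue=per_residue,
        overall_mean=float(np.mean(list(per_residue.values()))),
        n_frames=n,
    )


def aggregate_replicates(summaries: Sequence[FrameSummary]) -> ReplicateSummary:
    """Mean +/- SD of per-frame mean counts across replicate trajectories
    (sample SD, ddof=1)."""
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicate summaries")
    keys = set(summaries[0].mean_counts)
    for s in summaries[1:]:
        if set(s.mean_counts) != keys:
            raise ValueError("replicate summaries have mismatched (kind, span) keys")
    mean = {}
    sd = {}
    for k in keys:
        vals = np.array([s.mean_counts[k] for s in summaries])
        mean[k] = float(vals.mean())
        sd[k] = float(vals.std(ddof=1))
    return ReplicateSummary(mean=mean, sd=sd, n_replicates=len(summaries))


# ---------------------------------------------------------------------------
# backbone RMSD / equilibration


def _backbone_coords(frame: Frame) -> np.ndarray:
    mask = np.isin(frame.names, BACKBONE_ATOMS)
    coords = frame.coords[mask]
    if len(coords) < 3:
        raise ValueError("fewer than 3 backbone atoms; cannot superpose")
    return coords


def kabsch_rmsd(mobile: np.ndarray, reference: np.ndarray, superpose: bool = True) -> float:
    """RMSD between matched coordinate sets, after optimal (Kabsch)
    superposition unless ``superpose=False``."""
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets differ in shape")
    if superpose:
        mc = mobile - mobile.mean(axis=0)
        rc = reference - reference.mean(axis=0)
        h = mc.T @ rc
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        corr = np.diag([1.0, 1.0, d])
        rot = vt.T @ corr @ u.T
        diff = (rot @ mc.T).T - rc
    else:
        diff = mobile - reference
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def backbone_rmsd_series(
    trajectory: Trajectory,
    reference_frame: int = 0,
    trailing_fraction: float = 0.5,
    slope_threshold: float = 0.002,
    superpose: bool = True,
) -> RmsdResult:
    """Backbone RMSD of every frame against a reference frame.

    The system is flagged equilibrated when the magnitude of the best-fit
    linear slope of RMSD versus time over the trailing ``trailing_fraction``
    of the trajectory is below ``slope_threshold`` (A/ns).
    """
    ref = _backbone_coords(trajectory.frames[reference_frame])
    series = np.array(
        [
            kabsch_rmsd(_backbone_coords(f), ref, superpose=superpose)
            for f in trajectory.frames
        ]
    )
    n_tail = max(2, int(len(series) * trailing_fraction))
    tail = series[-n_tail:]
    t_ns = np.arange(len(series))[-n_tail:] * trajectory.frame_interval / 1000.0
    slope = float(np.polyfit(t_ns, tail, 1)[0]) if len(tail) >= 2 else 0.0
    return RmsdResult(
        series=series,
        equilibrated=abs(slope) < slope_threshold,
        trailing_slope=slope,
        reference_frame=reference_frame,
    )
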