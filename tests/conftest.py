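"""Shared fixtures: random rigid frames and random planted-complex specs.

The random-frame builder places simplified residue templates at random
positions and orientations in a small box, producing dense frames with many
genuine interactions for oracle-equivalence tests.  Placement is rigid
(no atom-level jitter) so planar groups stay exactly planar and any
plane-fitting convention gives the same normal.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rsdomain.contacts import AtomRecord, Frame
from rsdomain.simulate import ONE_TO_THREE, PlantedComplexSpec, _residue_atoms

# residue pools for random fixtures
SB_DONORS = ["R", "K"]
SB_ACCEPTORS = ["D", "E", "sep"]
SAFE_HB_DONORS = ["S", "T", "N", "Q"]  # never salt-bridge donors, never planar
SAFE_HB_ACCEPTORS = ["S", "T", "D", "E", "sep"]
PLANAR = ["F", "Y", "W", "H", "R"]
FILLERS = ["A", "G"]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def build_random_frame(rng: np.random.Generator, n_residues: int = 12, box: float = 9.0) -> Frame:
    """Dense random frame of rigidly placed residue templates (2 chains)."""
    pool = SB_DONORS + SB_ACCEPTORS + SAFE_HB_DONORS + PLANAR + FILLERS
    records = []
    counters = {"A": 0, "B": 0}
    for _ in range(n_residues):
        token = pool[rng.integers(len(pool))]
        resname = ONE_TO_THREE[token]
        chain = "A" if rng.random() < 0.5 else "B"
        counters[chain] += 1
        rot = random_rotation(rng)
        origin = rng.uniform(0, box, size=3)
        for name, offset in _residue_atoms(resname):
            records.append(
                AtomRecord(
                    name=name,
                    residue_name=resname,
                    residue_index=counters[chain],
                    chain_id=chain,
                    xyz=rot @ offset + origin,
                )
            )
    return Frame(records)


def random_planted_spec(rng: np.random.Generator) -> PlantedComplexSpec:
    """Random two-chain spec with compatible planted interactions."""

    def random_chain(n: int) -> list[str]:
        pool = SB_DONORS + SB_ACCEPTORS + SAFE_HB_DONORS + PLANAR + FILLERS
        return [pool[rng.integers(len(pool))] for _ in range(n)]

    chain_a = random_chain(int(rng.integers(8, 14)))
    chain_b = random_chain(int(rng.integers(8, 14)))
    chains = {"A": chain_a, "B": chain_b}
    free = {(c, i + 1) for c in chains for i in range(len(chains[c]))}

    def pick(tokens: list[str]) -> tuple[str, int] | None:
        candidates = [
            (c, i + 1)
            for c in chains
            for i, t in enumerate(chains[c])
            if t in tokens and (c, i + 1) in free
        ]
        if not candidates:
            return None
        choice = candidates[rng.integers(len(candidates))]
        free.discard(choice)
        return choice

    sbs, hbs, stacks = [], [], []
    for _ in range(int(rng.integers(1, 4))):
        d = pick(SB_DONORS)
        a = pick(SB_ACCEPTORS)
        if d and a:
            sbs.append((d[0], d[1], a[0], a[1]))
    for _ in range(int(rng.integers(0, 3))):
        d = pick(SAFE_HB_DONORS)
        a = pick(SAFE_HB_ACCEPTORS)
        if d and a:
            hbs.append((d[0], d[1], a[0], a[1]))
    for _ in range(int(rng.integers(0, 3))):
        p = pick(PLANAR)
        q = pick(PLANAR)
        if p and q:
            stacks.append((p[0], p[1], q[0], q[1]))

    return PlantedComplexSpec(
        chain_a_seq=" ".join(chain_a),
        chain_b_seq=" ".join(chain_b),
        planted_salt_bridges=sbs,
        planted_hbonds=hbs,
        planted_stacks=stacks,
        n_frames=int(rng.integers(2, 5)),
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (pure python, all-pairs)

from rsdomain.contacts import (  # noqa: E402
    HBOND_ACCEPTOR_ATOMS,
    HBOND_DONOR_ATOMS,
    PLANE_GROUPS,
    SALT_BRIDGE_ACCEPTOR_ATOMS,
    SALT_BRIDGE_DONOR_ATOMS,
)


def _dist(a, b) -> float:
    return math.dist(tuple(a), tuple(b))


def _reskey(atom: AtomRecord) -> tuple[str, int]:
    return (atom.chain_id, atom.residue_index)


def brute_salt_bridge_pairs(frame: Frame, cutoff: float = 4.0) -> set:
    pairs = set()
    for a1 in frame.atoms:
        names = SALT_BRIDGE_DONOR_ATOMS.get(a1.residue_name, ())
        if a1.name not in names:
            continue
        for a2 in frame.atoms:
            if _reskey(a1) == _reskey(a2):
                continue
            if a2.name not in SALT_BRIDGE_ACCEPTOR_ATOMS.get(a2.residue_name, ()):
                continue
            if _dist(a1.xyz, a2.xyz) <= cutoff:
                pairs.add(tuple(sorted((_reskey(a1), _reskey(a2)))))
    return pairs


def brute_hbond_pairs(
    frame: Frame,
    dist_cutoff: float = 3.5,
    min_angle: float = 135.0,
    exclude: set | None = None,
    include_backbone: bool = True,
) -> set:
    exclude = exclude if exclude is not None else brute_salt_bridge_pairs(frame)
    pairs = set()
    for d in frame.atoms:
        donor_names = list(HBOND_DONOR_ATOMS.get(d.residue_name, ()))
        if include_backbone:
            donor_names.append("N")
        if d.name not in donor_names:
            continue
        hydrogens = [
            h.xyz
            for h in frame.atoms
            if h.name.startswith("H")
            and _reskey(h) == _reskey(d)
            and _dist(h.xyz, d.xyz) <= 1.35
        ]
        if not hydrogens:
            continue
        for a in frame.atoms:
            if _reskey(a) == _reskey(d):
                continue
            acceptor_names = list(HBOND_ACCEPTOR_ATOMS.get(a.residue_name, ()))
            if include_backbone:
                acceptor_names.append("O")
            if a.name not in acceptor_names:
                continue
            key = tuple(sorted((_reskey(d), _reskey(a))))
            if key in exclude:
                continue
            dda = _dist(d.xyz, a.xyz)
            if dda > dist_cutoff or dda == 0:
                continue
            for h in hydrogens:
                v1 = np.asarray(d.xyz) - np.asarray(h)
                v2 = np.asarray(a.xyz) - np.asarray(h)
                cosang = float(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                )
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle >= min_angle:
                    pairs.add(key)
                    break
    return pairs


def brute_stack_pairs(
    frame: Frame, dist_cutoff: float = 4.5, angle_cutoff: float = 20.0
) -> dict:
    """Residue-pair -> kind via cross-product plane normals (exact planes)."""
    groups = []
    for chain, idx, resname in frame.residues:
        for atom_names in PLANE_GROUPS.get(resname, ()):
            coords = []
            for n in atom_names:
                xyz = frame.atom_xyz(chain, idx, n)
                if xyz is not None:
                    coords.append(np.asarray(xyz))
            if len(coords) < 3:
                continue
            centroid = np.mean(coords, axis=0)
            normal = np.cross(coords[1] - coords[0], coords[2] - coords[0])
            normal = normal / np.linalg.norm(normal)
            groups.append(((chain, idx), resname, centroid, normal))
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            (ra, na, ca, va), (rb, nb, cb, vb) = groups[i], groups[j]
            if ra == rb:
                continue
            if _dist(ca, cb) > dist_cutoff:
                continue
            cosang = abs(float(np.dot(va, vb)))
            angle = math.degrees(math.acos(min(1.0, cosang)))
            if angle > angle_cutoff:
                continue
            if na == "ARG" and nb == "ARG":
                kind = "cation_cation"
            elif na == "ARG" or nb == "ARG":
                kind = "cation_pi"
            else:
                kind = "pi_pi"
            key = tuple(sorted((ra, rb)))
            out.setdefault(key, kind)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
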