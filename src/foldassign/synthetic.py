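"""Synthetic structure fixtures with recorded ground truth.

Everything the pipeline consumes can be generated here: ideal
secondary-structure geometry (helices, strands, sheets), compact and
deliberately non-globular domains, confidence profiles, perturbed homolog
pairs, fragmented long proteins with hit tables, and prediction records.
Generators are seed-deterministic: the same spec and seed reproduce the
fixture byte for byte.

Backbones are built in internal coordinates (standard bond lengths/angles,
chosen phi/psi) so that ideal helices genuinely satisfy the i->i+4
hydrogen-bond pattern and paired strands form ladders. Side chains are
approximated by an ideal C-beta only; loops between packed elements are
geometric interpolations, not physically valid conformations — tests on the
secondary-structure assigner therefore only assert element cores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .model_io import (DomainHit, FragmentSet, ResidueRecord, StructureModel)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "make_chain",
    "make_ideal_helix",
    "make_ideal_strand",
    "make_sheet",
    "make_bundle",
    "make_decoy",
    "make_concatenated",
    "perturb",
    "inject_plddt",
    "make_fragmented_protein",
    "make_assignment_benchmark",
    "HELIX_PHI_PSI",
    "STRAND_PHI_PSI",
]

# canonical backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


@dataclass
class FixtureSpec:
    kind: str  # helix | strand | bundle | sheet | concatenated | coil
    n_residues: int
    noise_sigma: float = 0.0
    plddt_profile: float | Sequence[float] = 90.0
    seed: int = 0


@dataclass
class GroundTruth:
    """What the generator planted, for asserting recovered behaviour."""

    fixture_id: str
    planted_qc_violations: list[str] = field(default_factory=list)
    homolog_of: str = ""
    true_superfamily: str = ""

    def to_json(self) -> dict:
        return asdict(self)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle: float, dihedral: float) -> np.ndarray:
    """Position a fourth atom D from A-B-C by bond length C-D, angle B-C-D
    and dihedral A-B-C-D (the standard internal-coordinate construction)."""
    ang = np.deg2rad(angle)
    dih = np.deg2rad(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(dih),
        length * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_chain(phi_psi: Sequence[tuple[float, float]], sequence: str | None = None,
               plddt: float | Sequence[float] = 90.0,
               protein_id: str = "synth", start_index: int = 1,
               with_cb: bool = True) -> StructureModel:
    """Build a backbone (N, CA, C, O, optionally CB) from phi/psi angles.

    ``phi_psi[i]`` gives residue i's torsions; phi of the first residue and
    psi of the last are still used (psi places the final carbonyl oxygen).
    """
    n = len(phi_psi)
    if n < 1:
        raise ValueError("need at least one residue")
    if sequence is None:
        sequence = ("LA" * n)[:n]  # alternating Leu/Ala: hydrophobic-rich
    if len(sequence) != n:
        raise ValueError("sequence length mismatch")
    plddt_arr = np.broadcast_to(np.asarray(plddt, dtype=float), (n,))
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # seed frame for residue 0
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = phi_psi[i - 1][1]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           _B_CA_C, _A_N_CA_C, phi_psi[i][0])
    residues: list[ResidueRecord] = []
    for i in range(n):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        if i + 1 < n:
            atoms["O"] = _place_atom(N[i + 1], CA[i], C[i],
                                     _B_C_O, _A_CA_C_O, 180.0)
        else:
            atoms["O"] = _place_atom(N[i], CA[i], C[i],
                                     _B_C_O, _A_CA_C_O, phi_psi[i][1] + 180.0)
        if with_cb and sequence[i] != "G":
            atoms["CB"] = _place_atom(C[i], N[i], CA[i],
                                      _B_CA_CB, 110.4, 122.6)
        residues.append(ResidueRecord(start_index + i, sequence[i], atoms,
                                      float(plddt_arr[i])))
    return StructureModel(protein_id, residues)


def make_ideal_helix(n: int, seed: int = 0, plddt: float = 90.0,
                     protein_id: str = "helix") -> StructureModel:
    """Canonical alpha-helix (~1.5 A rise, ~100 deg turn per residue)."""
    if n < 5:
        raise ValueError("helix needs >= 5 residues")
    return make_chain([HELIX_PHI_PSI] * n, plddt=plddt, protein_id=protein_id)


def make_ideal_strand(n: int, seed: int = 0, plddt: float = 90.0,
                      protein_id: str = "strand") -> StructureModel:
    """Single extended beta strand; in isolation it has no ladder partner,
    so the secondary-structure assigner leaves it coil."""
    if n < 3:
        raise ValueError("strand needs >= 3 residues")
    return make_chain([STRAND_PHI_PSI] * n, plddt=plddt, protein_id=protein_id)


def _rigid(model_coords: np.ndarray, rotation: np.ndarray,
           translation: np.ndarray) -> np.ndarray:
    return model_coords @ rotation.T + translation


def _transform_model(model: StructureModel, rotation: np.ndarray,
                     translation: np.ndarray) -> StructureModel:
    residues = []
    for r in model.residues:
        atoms = {k: rotation @ v + translation for k, v in r.atoms.items()}
        residues.append(ResidueRecord(r.seq_index, r.aa, atoms, r.plddt))
    return StructureModel(model.protein_id, residues, model.fragment_index)


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[1, 0, 0],
                     [0, np.cos(t), -np.sin(t)],
                     [0, np.sin(t), np.cos(t)]])


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0],
                     [0, 0, 1]])


def _principal_axis_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation taking the point cloud's principal axis to +z, and centroid."""
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # rotation aligning `axis` with z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else _rot_x(180.0)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    return rot, centroid


def _loop_phi_psi(k: int) -> list[tuple[float, float]]:
    """Irregular torsions for a connecting loop (no repeating pattern)."""
    table = [(-80.0, 90.0), (60.0, 40.0), (-100.0, 150.0), (-70.0, -20.0)]
    return [table[i % len(table)] for i in range(k)]


def make_bundle(n_helices: int = 3, helix_len: int = 18,
                packing_distance: float = 10.0, seed: int = 0,
                plddt: float = 90.0, loop_len: int = 4,
                protein_id: str = "bundle") -> StructureModel:
    """Up-down helix bundle: axes on a regular polygon of side
    ``packing_distance``, alternating direction, joined by interpolated
    coil loops.

    At side <= ~10 A the result is a compact, QC-passing domain; spreading
    the helices (>= ~25 A) produces a planted packing-density failure.
    """
    if n_helices < 2:
        raise ValueError("bundle needs >= 2 helices")
    if packing_distance < 4.0:
        raise ValueError("helices would clash: separation < 4 A")
    # polygon vertex positions for the helix axes
    if n_helices == 2:
        centers = [np.array([0.0, 0.0]), np.array([packing_distance, 0.0])]
    else:
        circum = packing_distance / (2 * np.sin(np.pi / n_helices))
        centers = [circum * np.array([np.cos(2 * np.pi * k / n_helices),
                                      np.sin(2 * np.pi * k / n_helices)])
                   for k in range(n_helices)]
    torsions: list[tuple[float, float]] = []
    spans: list[tuple[int, int]] = []  # residue index ranges of each helix
    pos = 0
    for k in range(n_helices):
        spans.append((pos, pos + helix_len - 1))
        torsions.extend([HELIX_PHI_PSI] * helix_len)
        pos += helix_len
        if k < n_helices - 1:
            torsions.extend(_loop_phi_psi(loop_len))
            pos += loop_len
    chain = make_chain(torsions, plddt=plddt, protein_id=protein_id)
    # rigidly re-place each helix on its polygon vertex (alternating up/down),
    # then rebuild loops as straight interpolations between flanking anchors
    coords_res = [dict(r.atoms) for r in chain.residues]
    for k, (a, b) in enumerate(spans):
        helix_atoms = np.array([xyz for i in range(a, b + 1)
                                for xyz in coords_res[i].values()])
        rot, centroid = _principal_axis_frame(
            np.array([coords_res[i]["CA"] for i in range(a, b + 1)]))
        flip = _rot_x(180.0) if k % 2 else np.eye(3)
        target = np.array([centers[k][0], centers[k][1], 0.0])
        for i in range(a, b + 1):
            for name, xyz in coords_res[i].items():
                coords_res[i][name] = flip @ (rot @ (xyz - centroid)) + target
    # interpolate loop residues between helix ends
    for k in range(n_helices - 1):
        start = spans[k][1]
        end = spans[k + 1][0]
        p0 = coords_res[start]["C"]
        p1 = coords_res[end]["N"]
        gap = end - start - 1
        for g, i in enumerate(range(start + 1, end), start=1):
            t = g / (gap + 1)
            anchor = (1 - t) * p0 + t * p1
            ca0 = coords_res[i]["CA"]
            for name, xyz in coords_res[i].items():
                coords_res[i][name] = xyz - ca0 + anchor
    residues = [ResidueRecord(r.seq_index, r.aa, coords_res[i], r.plddt)
                for i, r in enumerate(chain.residues)]
    return StructureModel(protein_id, residues)


def make_sheet(n_strands: int = 2, strand_len: int = 8, spacing: float = 4.5,
               seed: int = 0, plddt: float = 90.0,
               protein_id: str = "sheet") -> StructureModel:
    """Antiparallel beta sheet built from rigidly paired ideal strands.

    Strands alternate direction at ``spacing`` A separation. Registry (the
    axial offset of each strand against its predecessor) is chosen by a
    deterministic scan maximising the inter-strand backbone H-bond count, so
    the fixture genuinely satisfies the ladder pattern and the assigner
    reports one E element per strand. Strands are joined into one chain with
    short interpolated turns.
    """
    from . import quality  # deferred: quality imports nothing from here

    if n_strands < 2:
        raise ValueError("sheet needs >= 2 strands")
    turn_len = 2
    torsions: list[tuple[float, float]] = []
    spans = []
    pos = 0
    for k in range(n_strands):
        spans.append((pos, pos + strand_len - 1))
        torsions.extend([STRAND_PHI_PSI] * strand_len)
        pos += strand_len
        if k < n_strands - 1:
            torsions.extend(_loop_phi_psi(turn_len))
            pos += turn_len
    chain = make_chain(torsions, plddt=plddt, protein_id=protein_id)
    coords_res = [dict(r.atoms) for r in chain.residues]
    flip_y = np.diag([-1.0, 1.0, -1.0])  # reverse strand direction in place

    def place(k: int, zshift: float) -> None:
        a, b = spans[k]
        cas = np.array([coords_res[i]["CA"] for i in range(a, b + 1)])
        rot, centroid = _principal_axis_frame(cas)
        flip = flip_y if k % 2 else np.eye(3)
        target = np.array([0.0, k * spacing, zshift])
        for i in range(a, b + 1):
            for name, xyz in coords_res[i].items():
                coords_res[i][name] = flip @ (rot @ (xyz - centroid)) + target

    def inter_hbonds(k: int) -> int:
        a0, b0 = spans[k - 1]
        a1, b1 = spans[k]
        sub = [coords_res[i] for i in range(a0, b0 + 1)]
        sub += [coords_res[i] for i in range(a1, b1 + 1)]
        residues = [ResidueRecord(i + 1, "A", dict(atoms), 90.0)
                    for i, atoms in enumerate(sub)]
        hb = quality._hbond_matrix(StructureModel("pair", residues))
        n0 = b0 - a0 + 1
        return int(sum(hb[i, j] for i in range(len(sub))
                       for j in range(len(sub)) if (i < n0) != (j < n0)))

    snapshots = [dict(d) for d in coords_res]
    place(0, 0.0)
    for k in range(1, n_strands):
        best = None
        for zshift in np.arange(-3.5, 3.51, 0.25):
            for i in range(spans[k][0], spans[k][1] + 1):
                coords_res[i] = dict(snapshots[i])
            place(k, float(zshift))
            count = inter_hbonds(k)
            if best is None or count > best[0]:
                best = (count, float(zshift))
        for i in range(spans[k][0], spans[k][1] + 1):
            coords_res[i] = dict(snapshots[i])
        place(k, best[1])
    for k in range(n_strands - 1):
        start, end = spans[k][1], spans[k + 1][0]
        p0, p1 = coords_res[start]["C"], coords_res[end]["N"]
        gap = end - start - 1
        for g, i in enumerate(range(start + 1, end), start=1):
            t = g / (gap + 1)
            anchor = (1 - t) * p0 + t * p1
            ca0 = coords_res[i]["CA"]
            for name, xyz in coords_res[i].items():
                coords_res[i][name] = xyz - ca0 + anchor
    residues = [ResidueRecord(r.seq_index, r.aa, coords_res[i], r.plddt)
                for i, r in enumerate(chain.residues)]
    return StructureModel(protein_id, residues)


def make_mixed_fold(n_strands: int = 4, strand_len: int = 10,
                    n_helices: int = 2, helix_len: int = 14,
                    lift: float = 10.0, seed: int = 0, plddt: float = 90.0,
                    protein_id: str = "mixedfold") -> StructureModel:
    """Two-layer alpha/beta fold: helices packed above an antiparallel sheet.

    The sheet comes from :func:`make_sheet`; helices are laid parallel to
    the strand axis at ``lift`` A above the sheet plane. A geometry class
    distinct from pure bundles and pure sheets, for novel-fold fixtures.
    """
    sheet = make_sheet(n_strands, strand_len, plddt=plddt,
                       protein_id=protein_id)
    helix = make_ideal_helix(helix_len, plddt=plddt, protein_id=protein_id)
    h_cas = helix.ca_coords()
    rot, cen = _principal_axis_frame(h_cas)
    sheet_width = (n_strands - 1) * 4.5
    pieces = [[dict(r.atoms) for r in sheet.residues]]
    for k in range(n_helices):
        flip = _rot_x(180.0) if k % 2 else np.eye(3)
        target = np.array([lift,
                           sheet_width * (k + 1) / (n_helices + 1), 0.0])
        placed = []
        for r in helix.residues:
            placed.append({name: flip @ (rot @ (xyz - cen)) + target
                           for name, xyz in r.atoms.items()})
        pieces.append(placed)
    # stitch pieces into one chain with 3-residue interpolated linkers
    chain_atoms: list[dict[str, np.ndarray]] = []
    seq_parts: list[str] = [sheet.sequence]
    for k, piece in enumerate(pieces):
        if k > 0:
            p0 = chain_atoms[-1]["C"]
            p1 = piece[0]["N"]
            for g in range(1, 4):
                t = g / 4.0
                anchor = (1 - t) * p0 + t * p1
                offset = np.array([0.0, 0.0, 1.5]) * (1 if g % 2 else -1)
                chain_atoms.append({
                    "N": anchor + offset + np.array([-0.6, 0.0, 0.0]),
                    "CA": anchor + offset,
                    "C": anchor + offset + np.array([0.6, 0.0, 0.0]),
                    "O": anchor + offset + np.array([0.6, 1.2, 0.0]),
                })
            seq_parts.append("GGG")
            seq_parts.append(("LA" * helix_len)[:helix_len])
        chain_atoms.extend(piece)
    sequence = "".join(seq_parts)
    residues = [ResidueRecord(i + 1, sequence[i], atoms, plddt)
                for i, (atoms) in enumerate(chain_atoms)]
    return StructureModel(protein_id, residues)


def make_collapsed(model: StructureModel, factor: float = 0.7,
                   protein_id: str | None = None) -> StructureModel:
    """Scale all coordinates toward the centroid.

    Over-compacted residues pile neighbours into the 5 A shell: a planted
    packing-density violation that leaves the fold's topology (and its
    secondary-structure H-bond pattern, at moderate factors) intact.
    """
    if not (0.0 < factor < 1.0):
        raise ValueError("factor must be in (0, 1)")
    coords = np.array([v for r in model.residues for v in r.atoms.values()])
    cen = coords.mean(axis=0)
    residues = [
        ResidueRecord(r.seq_index, r.aa,
                      {k: cen + factor * (v - cen) for k, v in r.atoms.items()},
                      r.plddt)
        for r in model.residues
    ]
    return StructureModel(protein_id or model.protein_id, residues,
                          model.fragment_index)


def make_decoy(n: int, seed: int, plddt: float = 90.0,
               protein_id: str | None = None) -> StructureModel:
    """A compact random fold: torsions sampled from broad allowed regions.

    Independent seeds give structurally unrelated chains — the negative
    pairs for comparator and cascade benchmarks.
    """
    rng = np.random.default_rng(seed)
    basins = [(-60.0, -45.0), (-120.0, 130.0), (-90.0, 0.0), (55.0, 45.0)]
    torsions = []
    i = 0
    while len(torsions) < n:
        phi0, psi0 = basins[rng.integers(len(basins))]
        run = int(rng.integers(3, 9))
        for _ in range(min(run, n - len(torsions))):
            torsions.append((phi0 + rng.uniform(-15, 15),
                             psi0 + rng.uniform(-15, 15)))
        i += 1
    return make_chain(torsions, plddt=plddt,
                      protein_id=protein_id or f"decoy{seed}")


def make_concatenated(a: StructureModel, b: StructureModel,
                      gap: float = 6.0,
                      protein_id: str = "concat") -> StructureModel:
    """Join two folds end to end (B translated past A's bounding box).

    Emulates a region spanning two domains — the multidomain triage case.
    """
    coords_a = np.array([xyz for r in a.residues for xyz in r.atoms.values()])
    coords_b = np.array([xyz for r in b.residues for xyz in r.atoms.values()])
    shift = np.array([coords_a[:, 0].max() - coords_b[:, 0].min() + gap, 0, 0])
    residues = [ResidueRecord(r.seq_index, r.aa, dict(r.atoms), r.plddt)
                for r in a.residues]
    offset = a.residues[-1].seq_index
    for r in b.residues:
        atoms = {k: v + shift for k, v in r.atoms.items()}
        residues.append(ResidueRecord(offset + r.seq_index, r.aa, atoms, r.plddt))
    return StructureModel(protein_id, residues)


def perturb(model: StructureModel, sigma: float, seed: int = 0) -> StructureModel:
    """Isotropic Gaussian coordinate noise (sigma per coordinate, A)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return StructureModel(model.protein_id,
                              [ResidueRecord(r.seq_index, r.aa, dict(r.atoms),
                                             r.plddt) for r in model.residues],
                              model.fragment_index)
    rng = np.random.default_rng(seed)
    residues = []
    for r in model.residues:
        atoms = {k: v + rng.normal(0.0, sigma, 3) for k, v in r.atoms.items()}
        residues.append(ResidueRecord(r.seq_index, r.aa, atoms, r.plddt))
    return StructureModel(model.protein_id, residues, model.fragment_index)


def inject_plddt(model: StructureModel,
                 profile: float | Sequence[float]) -> StructureModel:
    """Overwrite per-residue confidences (drives LUR / mean-pLDDT tests)."""
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 1 and arr.shape[0] != model.n_residues:
        raise ValueError(
            f"profile length {arr.shape[0]} != {model.n_residues} residues")
    values = np.broadcast_to(arr, (model.n_residues,))
    residues = [ResidueRecord(r.seq_index, r.aa, dict(r.atoms), float(v))
                for r, v in zip(model.residues, values)]
    return StructureModel(model.protein_id, residues, model.fragment_index)


def _renumber(model: StructureModel, start: int,
              protein_id: str | None = None,
              fragment_index: int = 1) -> StructureModel:
    residues = [ResidueRecord(start + i, r.aa, dict(r.atoms), r.plddt)
                for i, r in enumerate(model.residues)]
    return StructureModel(protein_id or model.protein_id, residues,
                          fragment_index)


def make_fragmented_protein(
    length: int,
    domain_layout: Sequence[tuple[int, int, str, str, float]],
    seed: int = 0,
    fragment_length: int = 1400,
    step: int = 200,
    protein_id: str = "longprot",
) -> tuple[FragmentSet, list[StructureModel], list[DomainHit], dict]:
    """A long protein split into overlapping fragment models, plus hits.

    ``domain_layout`` rows are ``(start, stop, family_id, source, score)``.
    Fragment models keep protein (global) numbering so chopped domains carry
    their UniProt-style indices. Ground truth records, per planted domain,
    which fragment fully contains it (or None when none does).
    """
    fragset = FragmentSet.for_length(protein_id, length, fragment_length, step)
    full = make_decoy(length, seed=seed, protein_id=protein_id)
    models = []
    for idx, first, last in fragset.fragments:
        sub = StructureModel(
            protein_id,
            [ResidueRecord(r.seq_index, r.aa, dict(r.atoms), r.plddt)
             for r in full.residues[first - 1:last]],
            fragment_index=idx,
        )
        models.append(sub)
    hits = []
    truth: dict[str, int | None] = {}
    for start, stop, family, source, score in domain_layout:
        hits.append(DomainHit(protein_id, source, family,
                              [(start, stop)], score))
        containing = [
            (idx, first, last) for idx, first, last in fragset.fragments
            if first <= start and stop <= last
        ]
        if not containing:
            truth[f"{start}-{stop}"] = None
        else:
            centre = (start + stop) / 2
            best = min(containing,
                       key=lambda f: (abs((f[1] + f[2]) / 2 - centre), f[0]))
            truth[f"{start}-{stop}"] = best[0]
    return fragset, models, hits, truth


def make_assignment_benchmark(
    n_superfamilies: int = 10,
    n_representatives: int = 3,
    n_queries: int = 30,
    n_decoys: int = 10,
    domain_len: int = 60,
    sigma: float = 0.5,
    seed: int = 0,
) -> dict:
    """Library + queries + decoys with ground truth for cascade benchmarks.

    Each superfamily is seeded by an independent random fold; its
    representatives and the queries drawn from it are coordinate-noise
    copies (queries at ``sigma`` A). Decoys are further independent folds.
    Superfamily codes cycle through classes 1-3 with distinct topologies so
    the cascade's widening stages are exercised.
    """
    rng = np.random.default_rng(seed)
    library = []  # (domain_id, superfamily, model)
    sf_templates = {}
    for s in range(n_superfamilies):
        code = f"{s % 3 + 1}.{10 + s}.{s + 1}.{s + 1}"
        template = make_decoy(domain_len, seed=int(rng.integers(2 ** 31)),
                              protein_id=f"sf{s}_template")
        sf_templates[code] = template
        for rep in range(n_representatives):
            m = perturb(template, 0.3, seed=int(rng.integers(2 ** 31)))
            library.append((f"sf{s}_rep{rep}", code,
                            StructureModel(f"sf{s}_rep{rep}", m.residues)))
    codes = list(sf_templates)
    queries = []  # (query_id, model, true_superfamily)
    for q in range(n_queries):
        code = codes[q % len(codes)]
        m = perturb(sf_templates[code], sigma, seed=int(rng.integers(2 ** 31)))
        queries.append((f"query{q}", StructureModel(f"query{q}", m.residues),
                        code))
    from .assignment import align_structures

    decoys = []
    templates = list(sf_templates.values())
    for d in range(n_decoys):
        # screened negatives: verified unrelated to every superfamily
        # template, so the unassigned label holds by construction
        base = int(rng.integers(2 ** 30))
        for attempt in range(50):
            cand = make_decoy(domain_len, seed=base + attempt + 7_000_000,
                              protein_id=f"neg{d}")
            if all(align_structures(cand, t).score < 0.35
                   for t in templates):
                break
        else:
            raise RuntimeError("could not generate an unrelated decoy")
        decoys.append((f"neg{d}", cand))
    return {"library": library, "queries": queries, "decoys": decoys,
            "superfamilies": codes}


def make_reference_battery(seed: int = 0) -> list[StructureModel]:
    """Reference set of ordered, compact domains for threshold calibration.

    Mimics a curated classified-domain set: helix bundles, sheets and mixed
    alpha/beta folds across a spread of sizes and packing geometries, plus
    mildly noised copies. Feed the QC reports of these to
    :func:`foldassign.quality.calibrate_thresholds`.
    """
    models: list[StructureModel] = []
    bundle_params = [(3, 14, 8.0), (3, 16, 8.2), (3, 18, 8.5), (3, 20, 9.0),
                     (3, 18, 10.0), (3, 22, 8.5), (4, 16, 8.5), (4, 18, 9.0),
                     (4, 20, 9.5), (5, 14, 9.0), (5, 18, 9.5), (4, 14, 8.2)]
    for i, (nh, ln, sep) in enumerate(bundle_params):
        models.append(make_bundle(nh, ln, sep, protein_id=f"ref_b{i}"))
    sheet_params = [(3, 10), (4, 8), (4, 10), (5, 8), (5, 10), (4, 12)]
    for i, (ns, ln) in enumerate(sheet_params):
        models.append(make_sheet(ns, ln, protein_id=f"ref_s{i}"))
    mixed_params = [(4, 10, 2, 14), (3, 9, 2, 12), (4, 8, 2, 12)]
    for i, (ns, ln, nh, hl) in enumerate(mixed_params):
        models.append(make_mixed_fold(ns, ln, nh, hl,
                                      protein_id=f"ref_m{i}"))
    rng = np.random.default_rng(seed)
    noised = [perturb(m, 0.3, seed=int(rng.integers(2 ** 31)))
              for m in models[::3]]
    for i, m in enumerate(noised):
        models.append(StructureModel(f"ref_n{i}", m.residues))
    return models


def make_qc_passing_decoy(n: int, seed: int,
                          distinct_from: Sequence[StructureModel] = (),
                          max_tm: float = 0.40,
                          thresholds=None,
                          protein_id: str | None = None) -> StructureModel:
    """First decoy at or after ``seed`` that genuinely passes the QC battery.

    Scans seeds deterministically; each candidate is checked with the real
    QC verdict (and, when ``distinct_from`` templates are given, with the
    real comparator at ``max_tm``), so the returned fixture's planted
    properties hold by construction. Used for novel-fold fixtures that must
    survive filtering yet match nothing.
    """
    from . import quality
    from .assignment import align_structures

    for attempt in range(seed, seed + 200):
        decoy = make_decoy(n, attempt, protein_id=protein_id or f"novel{seed}")
        report = quality.qc_verdict(decoy, thresholds)
        if report.verdict != "pass":
            continue
        if any(align_structures(decoy, t).score > max_tm
               or align_structures(t, decoy).score > max_tm
               for t in distinct_from):
            continue
        return decoy
    raise RuntimeError(f"no QC-passing decoy found near seed {seed}")


def assemble_protein(protein_id: str, parts: Sequence[StructureModel],
                     linker_len: int = 8, pad: int = 5,
                     linker_plddt: float = 50.0
                     ) -> tuple[StructureModel, list[tuple[int, int]]]:
    """Concatenate folded parts into one numbered protein chain.

    Parts are translated apart along x and joined by geometrically naive
    extended linkers (confidence ``linker_plddt``, like a disordered
    region); ``pad`` coil residues flank the termini. Returns the assembled
    model and the residue range each part occupies.
    """
    placed: list[dict[str, np.ndarray]] = []
    plddts: list[float] = []
    seqs: list[str] = []
    ranges: list[tuple[int, int]] = []

    def linker(n_res: int, p0: np.ndarray, p1: np.ndarray) -> None:
        for g in range(n_res):
            t = (g + 1) / (n_res + 1)
            anchor = (1 - t) * p0 + t * p1
            wob = np.array([0.0, 1.5 * (1 if g % 2 else -1), 0.0])
            placed.append({
                "N": anchor + wob + np.array([-0.6, 0.0, 0.0]),
                "CA": anchor + wob,
                "C": anchor + wob + np.array([0.6, 0.0, 0.0]),
                "O": anchor + wob + np.array([0.6, 1.2, 0.0]),
            })
            plddts.append(linker_plddt)
            seqs.append("G")

    cursor = np.zeros(3)
    if pad:
        linker(pad, cursor + np.array([-3.5 * pad, 0, 0]), cursor)
    for k, part in enumerate(parts):
        coords = np.array([v for r in part.residues
                           for v in r.atoms.values()])
        shift = cursor - coords.min(axis=0) + np.array([6.0, 0.0, 0.0])
        start = len(placed) + 1
        for r in part.residues:
            placed.append({n: v + shift for n, v in r.atoms.items()})
            plddts.append(r.plddt)
            seqs.append(r.aa)
        ranges.append((start, len(placed)))
        cursor = np.array([coords.max(axis=0)[0] + shift[0], 0.0, 0.0])
        if k < len(parts) - 1:
            linker(linker_len, cursor,
                   cursor + np.array([3.5 * linker_len, 0, 0]))
            cursor = cursor + np.array([3.5 * linker_len, 0, 0])
    if pad:
        linker(pad, cursor, cursor + np.array([3.5 * pad, 0, 0]))
    residues = [ResidueRecord(i + 1, seqs[i], placed[i], plddts[i])
                for i in range(len(placed))]
    return StructureModel(protein_id, residues), ranges


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([t.to_json() for t in truths], indent=1) + "\n")
    return path


def make_qc_battery(thresholds=None, seed: int = 0
                    ) -> list[tuple[StructureModel, GroundTruth, str | None]]:
    """Fixtures with planted single-rule QC violations (plus clean passes).

    Returns ``(model, ground_truth, external_ss)`` triples;
    ``ground_truth.planted_qc_violations`` names the one rule each fixture
    violates (empty for the passes). The unordered-fraction and SSE-count
    faults are planted through an externally supplied secondary-structure
    string on an otherwise clean compact domain, so no second rule trips.
    Evaluate with thresholds calibrated on :func:`make_reference_battery`.
    """
    out: list[tuple[StructureModel, GroundTruth, str | None]] = []
    compact = make_bundle(3, 18, 8.5, protein_id="qc_pass_bundle")
    out.append((compact, GroundTruth("qc_pass_bundle"), None))
    out.append((make_sheet(4, 10, protein_id="qc_pass_sheet"),
                GroundTruth("qc_pass_sheet"), None))
    n = compact.n_residues
    # mean pLDDT below 70 without any 5-run under 70 (so no LUR fault)
    tile = [55.0] * 4 + [95.0] * 2
    profile = (tile * (n // 6 + 1))[:n]
    out.append((inject_plddt(
        StructureModel("qc_low_plddt", compact.residues), profile),
        GroundTruth("qc_low_plddt",
                    planted_qc_violations=["min_mean_plddt"]), None))
    # one LUR covering >30% of the domain, mean still >= 70
    dip = [90.0] * n
    for i in range(20, 42):
        dip[i] = 60.0
    out.append((inject_plddt(
        StructureModel("qc_single_lur", compact.residues), dip),
        GroundTruth("qc_single_lur",
                    planted_qc_violations=["max_single_lur_fraction"]), None))
    # >65% unordered by external annotation, but still 3 elements
    ss_unord = "C" * 10 + "H" * 4 + "C" * 16 + "H" * 4 + "C" * 16 + "H" * 12
    out.append((StructureModel("qc_unordered", compact.residues),
                GroundTruth("qc_unordered",
                            planted_qc_violations=["max_unordered_fraction"]),
                ss_unord))
    # under 40 residues, otherwise clean
    out.append((make_bundle(3, 9, 8.5, loop_len=6, protein_id="qc_small"),
                GroundTruth("qc_small",
                            planted_qc_violations=["min_residues"]), None))
    # only two elements by external annotation
    ss_two = "H" * 18 + "C" * 8 + "H" * 18 + "C" * 18
    out.append((StructureModel("qc_two_sses", compact.residues),
                GroundTruth("qc_two_sses",
                            planted_qc_violations=["min_sses"]), ss_two))
    # over-compacted: packing density blows past the calibrated cut
    out.append((make_collapsed(compact, 0.7, protein_id="qc_collapsed"),
                GroundTruth("qc_collapsed",
                            planted_qc_violations=["max_packing_density"]),
                None))
    # well-formed helices spread far apart: high surface-to-volume
    out.append((make_bundle(3, 18, 28.0, protein_id="qc_spread"),
                GroundTruth("qc_spread",
                            planted_qc_violations=["max_ses_per_volume"]),
                None))
    return out


def _screened_instance(template: StructureModel, sigma: float, rng,
                       thresholds, protein_id: str) -> StructureModel:
    """Perturbed copy verified to pass QC (deterministic seed scan)."""
    from . import quality

    base = int(rng.integers(2 ** 31))
    for attempt in range(60):
        inst = perturb(template, sigma, seed=(base + attempt) % (2 ** 31))
        inst = StructureModel(protein_id, inst.residues)
        if quality.qc_verdict(inst, thresholds).verdict == "pass":
            return inst
    raise RuntimeError(f"no QC-passing perturbation of {template.protein_id}")


def make_end_to_end_inputs(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete synthetic input set for a pipeline run.

    Produces a models directory (including one sliding-window fragmented
    protein), a hit table, a prediction table, reference-library and
    unclassified-structure libraries, calibrated thresholds and a ground
    truth manifest. Every planted domain's fate (QC verdict, assignment,
    cluster, triage) is guaranteed by construction: instances are screened
    with the package's own QC and comparator at generation time.

    Returns the manifest dict (also written as ``truth.json``).
    """
    from . import quality
    from .model_io import write_model, write_hits, DomainHit
    from dataclasses import asdict as dc_asdict

    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "library").mkdir(exist_ok=True)
    (out / "pdb_unclassified").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    reports = [quality.qc_verdict(m) for m in make_reference_battery(seed)]
    thresholds = quality.calibrate_thresholds(reports)
    (out / "thresholds.json").write_text(json.dumps(
        dc_asdict(thresholds), indent=1, sort_keys=True) + "\n")

    templates = {
        "1.10.8.10": (make_bundle(3, 18, 8.5, protein_id="tmplA"), 0.15),
        "1.20.5.100": (make_bundle(5, 14, 9.0, protein_id="tmplE"), 0.15),
        "2.40.20.10": (make_sheet(4, 10, protein_id="tmplC"), 0.05),
    }
    lib_rows = []
    for sf, (tmpl, _) in sorted(templates.items()):
        for rep in range(2):
            m = perturb(tmpl, 0.3, seed=int(rng.integers(2 ** 31)))
            did = f"lib_{sf.replace('.', '_')}_r{rep}"
            write_model(StructureModel(did, m.residues),
                        out / "library" / f"{did}.pdb")
            lib_rows.append((did, sf, f"library/{did}.pdb"))
    (out / "library.tsv").write_text(
        "\n".join("\t".join(r) for r in lib_rows) + "\n")

    lib_templates = [t for t, _ in templates.values()]
    novel1 = make_qc_passing_decoy(60, seed * 7 + 11, lib_templates,
                                   thresholds=thresholds, protein_id="novel1")
    novel2 = make_qc_passing_decoy(70, seed * 7 + 101, lib_templates + [novel1],
                                   thresholds=thresholds, protein_id="novel2")
    unclass = make_qc_passing_decoy(64, seed * 7 + 201,
                                    lib_templates + [novel1, novel2],
                                    thresholds=thresholds, protein_id="uncl")
    write_model(unclass, out / "pdb_unclassified" / "uncl0.pdb")
    (out / "pdb_unclassified.tsv").write_text(
        "uncl0\t-\tpdb_unclassified/uncl0.pdb\n")

    hits: list[DomainHit] = []
    predictions: list[tuple[str, str, float]] = []
    truth: dict = {"domains": {}, "proteins": [], "seed": seed}

    def plant(pid: str, parts, part_meta, fragment_scheme=None):
        """parts: folded pieces; part_meta: per-part dicts describing the hit
        and expectations. Writes model file(s), appends hits/predictions."""
        model, ranges = assemble_protein(pid, parts)
        if fragment_scheme:
            flen, step = fragment_scheme
            fragset = FragmentSet.for_length(pid, model.n_residues, flen, step)
            for idx, first, last in fragset.fragments:
                sub = StructureModel(
                    pid, model.residues[first - 1:last], fragment_index=idx)
                write_model(sub, out / "models" / f"{pid}-F{idx}.pdb")
        else:
            write_model(model, out / "models" / f"{pid}.pdb")
        truth["proteins"].append(pid)
        for (start, stop), meta in zip(ranges, part_meta):
            if meta.get("skip"):
                continue  # structural filler, not a planted domain
            family = meta.get("family", "-")
            hits.append(DomainHit(pid, meta["source"],
                                  "" if family == "-" else family,
                                  [(start, stop)], meta.get("score", 250.0)))
            did = f"{pid}_{start}-{stop}"
            if "prediction" in meta:
                predictions.append((did, *meta["prediction"]))
            truth["domains"][did] = {
                "qc": meta.get("qc", "pass"),
                "qc_rule": meta.get("qc_rule", ""),
                "superfamily": meta.get("superfamily", ""),
                "cluster_group": meta.get("cluster_group", ""),
                "triage": meta.get("triage", ""),
            }

    sf_codes = sorted(templates)
    # assignable domains matched by HMM (two per superfamily)
    k = 0
    for sf in sf_codes:
        tmpl, sigma = templates[sf]
        for _ in range(2):
            inst = _screened_instance(tmpl, sigma, rng, thresholds,
                                      f"af_H{k:02d}")
            plant(f"af_H{k:02d}", [inst],
                  [{"source": "CATH-HMM", "family": sf, "superfamily": sf}])
            k += 1
    # embedding-predicted domains: confident, and below the probability cut
    instP = _screened_instance(*templates["1.10.8.10"][:2], rng, thresholds,
                               "af_P00")
    plant("af_P00", [instP], [{"source": "Pfam", "family": "PF00010",
                               "prediction": ("1.10.8.10", 0.9),
                               "superfamily": "1.10.8.10"}])
    instQ = _screened_instance(*templates["1.20.5.100"][:2], rng, thresholds,
                               "af_P01")
    plant("af_P01", [instQ], [{"source": "Pfam", "family": "PF00011",
                               "prediction": ("1.20.5.100", 0.2),
                               "superfamily": "1.20.5.100"}])
    instN = _screened_instance(*templates["2.40.20.10"][:2], rng, thresholds,
                               "af_N00")
    plant("af_N00", [instN], [{"source": "NewFam",
                               "superfamily": "2.40.20.10"}])
    # novel-fold domains: cluster together, match nothing
    for i in range(3):
        inst = _screened_instance(novel1, 0.1, rng, thresholds, f"af_V1{i}")
        plant(f"af_V1{i}", [inst], [{"source": "NewFam",
                                     "cluster_group": "novel1",
                                     "triage": "putative_new"}])
    for i in range(2):
        inst = _screened_instance(novel2, 0.1, rng, thresholds, f"af_V2{i}")
        plant(f"af_V2{i}", [inst], [{"source": "NewFam",
                                     "cluster_group": "novel2",
                                     "triage": "putative_new"}])
    # unassigned but present (unclassified) in the structure archive
    for i in range(2):
        inst = _screened_instance(unclass, 0.1, rng, thresholds, f"af_U0{i}")
        plant(f"af_U0{i}", [inst], [{"source": "NewFam",
                                     "cluster_group": "uncl",
                                     "triage": "pdb_unclassified_match"}])
    # a region spanning two domains: unassignable, triaged as multidomain
    con = make_concatenated(templates["1.10.8.10"][0],
                            templates["2.40.20.10"][0], protein_id="af_M00")
    plant("af_M00", [con], [{"source": "NewFam",
                             "cluster_group": "concat",
                             "triage": "multidomain"}])
    # planted QC failures
    low_bundle = make_bundle(3, 18, 8.5, protein_id="af_F00")
    low = inject_plddt(low_bundle, (([55.0] * 4 + [95.0] * 2)
                                    * 11)[:low_bundle.n_residues])
    plant("af_F00", [low], [{"source": "CATH-HMM", "family": "1.10.8.10",
                             "qc": "fail", "qc_rule": "min_mean_plddt"}])
    lur_prof = [90.0] * 62
    for i in range(20, 42):
        lur_prof[i] = 60.0
    lur = inject_plddt(make_bundle(3, 18, 8.5, protein_id="af_F01"), lur_prof)
    plant("af_F01", [lur], [{"source": "NewFam", "qc": "fail",
                             "qc_rule": "max_single_lur_fraction"}])
    plant("af_F02", [make_bundle(3, 18, 28.0, protein_id="af_F02")],
          [{"source": "NewFam", "qc": "fail",
            "qc_rule": "max_ses_per_volume"}])
    # one long protein split into overlapping window fragments
    padA = _screened_instance(*templates["1.10.8.10"][:2], rng, thresholds,
                              "af_L00")
    padE = _screened_instance(*templates["1.20.5.100"][:2], rng, thresholds,
                              "af_L00")
    filler = make_chain([(-120.0, 130.0)] * 1500, plddt=50.0,
                        protein_id="af_L00")
    plant("af_L00", [padA, filler, padE],
          [{"source": "CATH-HMM", "family": "1.10.8.10",
            "superfamily": "1.10.8.10"},
           {"skip": True},
           {"source": "CATH-HMM", "family": "1.20.5.100",
            "superfamily": "1.20.5.100"}],
          fragment_scheme=(1400, 200))
    # an overlapping lower-scoring hit that resolution must reject
    first = next(h for h in hits if h.protein_id == "af_H00")
    hits.append(DomainHit("af_H00", "Pfam", "PF09999",
                          [(first.start + 5, first.stop + 5)],
                          first.score / 2))
    write_hits(hits, out / "hits.tsv")
    (out / "predictions.tsv").write_text("".join(
        f"{did}\t{sf}\t{p}\n" for did, sf, p in predictions))
    (out / "truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return truth
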