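"""Backbone frames, SE(3)-invariant features, and structure-space losses.

The residue frame convention is the rigid-body convention popularised by
structure-prediction networks: the frame origin sits on CA, the x-axis points
toward C, and N lies in the xy-plane with positive y.  The frame-aligned point
error (FAPE) and the flat-bottom violation loss defined here are the
reconstruction losses of the tokenizer; the invariant single/pair features are
the encoder input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import (
    BackboneStructure,
    DegenerateGeometryError,
    ValidationError,
    require_same_length,
)

# Ideal backbone stereochemistry (Angstrom / degrees).  The synthetic
# generator builds chains with exactly these values, so ideal structures sit
# in the flat bottom of every violation term.
IDEAL_BONDS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.229}
IDEAL_ANGLES = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7,
                "CA-C-O": 120.8, "O-C-N": 123.0}
BOND_TOLERANCE = 0.1      # Angstrom of slack before a bond term activates
ANGLE_TOLERANCE = 5.0     # degrees of slack before an angle term activates
CLASH_DISTANCE = 3.0      # CA pairs (|i-j| >= 2) closer than this are clashes

DISTANCE_BIN_START = 3.25
DISTANCE_BIN_STOP = 50.75
DISTANCE_BIN_WIDTH = 1.25
N_DISTANCE_BINS = int(round((DISTANCE_BIN_STOP - DISTANCE_BIN_START) / DISTANCE_BIN_WIDTH)) + 1
MAX_SEQSEP = 8

#: Feature dimensions produced by :func:`invariant_features`.
SINGLE_DIM = 9
PAIR_DIM = N_DISTANCE_BINS + (2 * MAX_SEQSEP + 1)


@dataclass
class ResidueFrameSet:
    """One rigid frame per residue: ``x_global = R @ x_local + t``."""

    rotations: np.ndarray     # (n_res, 3, 3)
    translations: np.ndarray  # (n_res, 3)

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=np.float64)
        self.translations = np.asarray(self.translations, dtype=np.float64)
        if self.rotations.shape[1:] != (3, 3) or self.translations.shape[1:] != (3,):
            raise ValidationError("frame arrays have wrong shapes")

    @property
    def n_res(self) -> int:
        return self.rotations.shape[0]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express global ``points`` (..., 3) in every frame: (n_res, ..., 3)."""
        rel = points[None, ...] - self.translations.reshape(
            (self.n_res,) + (1,) * (points.ndim - 1) + (3,)
        )
        return np.einsum("rji,r...j->r...i", self.rotations, rel)


@dataclass
class ResidueFeatureSet:
    """SE(3)-invariant encoder input features."""

    single: np.ndarray  # (n_res, SINGLE_DIM)
    pair: np.ndarray    # (n_res, n_res, PAIR_DIM)


def frames_from_backbone(structure: BackboneStructure, eps: float = 1e-8) -> ResidueFrameSet:
    """Gram–Schmidt residue frames from the N, CA, C atoms.

    Raises
    ------
    DegenerateGeometryError
        If N, CA, C of some residue are (near-)collinear, which leaves the
        y-axis undefined.
    """
    n = structure.atom("N")
    ca = structure.atom("CA")
    c = structure.atom("C")

    v1 = c - ca
    n1 = np.linalg.norm(v1, axis=1)
    v2 = n - ca
    bad = np.flatnonzero(n1 < eps)
    if bad.size:
        raise DegenerateGeometryError(f"zero CA-C bond at residue {bad[0]}")
    e1 = v1 / n1[:, None]
    v2p = v2 - (v2 * e1).sum(axis=1, keepdims=True) * e1
    n2 = np.linalg.norm(v2p, axis=1)
    bad = np.flatnonzero(n2 < eps)
    if bad.size:
        raise DegenerateGeometryError(
            f"collinear N/CA/C triple at residue {bad[0]} (degenerate frame)"
        )
    e2 = v2p / n2[:, None]
    e3 = np.cross(e1, e2)
    rot = np.stack([e1, e2, e3], axis=2)  # columns are the local axes
    return ResidueFrameSet(rotations=rot, translations=ca.copy())


def fape(
    pred: BackboneStructure,
    true: BackboneStructure,
    clamp: float = 10.0,
    length_scale: float = 10.0,
) -> float:
    """Frame-aligned point error between two equal-length backbones.

    For every residue frame index i and backbone atom j, the atoms of each
    structure are expressed in that structure's own frame i and the two local
    positions are compared: ``d_ij = |T_i(pred)^-1 x_j(pred) -
    T_i(true)^-1 x_j(true)|``, clamped at ``clamp`` and divided by
    ``length_scale``, averaged over all (i, j).  Zero iff the two structures
    differ only by a global rigid motion; symmetric in its arguments.
    """
    require_same_length(pred, true)
    local_pred = frames_from_backbone(pred).to_local(pred.coords.reshape(-1, 3))
    local_true = frames_from_backbone(true).to_local(true.coords.reshape(-1, 3))
    d = np.sqrt(((local_pred - local_true) ** 2).sum(axis=-1))
    return float(np.minimum(d, clamp).mean() / length_scale)


def _angles_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at vertex b (degrees) for stacked point triples."""
    u = a - b
    v = c - b
    cosang = (u * v).sum(axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def violation_loss(structure: BackboneStructure) -> float:
    """Flat-bottom stereochemistry penalty.

    Three term families, each averaged then summed: bond lengths (Angstrom
    excess beyond :data:`BOND_TOLERANCE`), bond angles (radian excess beyond
    :data:`ANGLE_TOLERANCE`), and non-bonded CA clashes (Angstrom of
    penetration below :data:`CLASH_DISTANCE`).  Inter-residue terms spanning a
    chain break are skipped.  Zero on idealized geometry.
    """
    n_at, ca, c, o = (structure.atom(x) for x in ("N", "CA", "C", "O"))
    not_break = ~structure.chain_break_mask()

    def excess(values: np.ndarray, target: float, tol: float) -> np.ndarray:
        return np.maximum(np.abs(values - target) - tol, 0.0)

    bond_terms = [
        excess(np.linalg.norm(n_at - ca, axis=1), IDEAL_BONDS["N-CA"], BOND_TOLERANCE),
        excess(np.linalg.norm(ca - c, axis=1), IDEAL_BONDS["CA-C"], BOND_TOLERANCE),
        excess(np.linalg.norm(c - o, axis=1), IDEAL_BONDS["C-O"], BOND_TOLERANCE),
        excess(
            np.linalg.norm(n_at[1:] - c[:-1], axis=1), IDEAL_BONDS["C-N"], BOND_TOLERANCE
        )[not_break],
    ]
    tol_rad = np.radians(ANGLE_TOLERANCE)

    def angle_excess(vals_deg: np.ndarray, target_deg: float) -> np.ndarray:
        return np.maximum(np.abs(np.radians(vals_deg - target_deg)) - tol_rad, 0.0)

    angle_terms = [
        angle_excess(_angles_deg(n_at, ca, c), IDEAL_ANGLES["N-CA-C"]),
        angle_excess(_angles_deg(ca, c, o), IDEAL_ANGLES["CA-C-O"]),
        angle_excess(_angles_deg(ca[:-1], c[:-1], n_at[1:]), IDEAL_ANGLES["CA-C-N"])[not_break],
        angle_excess(_angles_deg(o[:-1], c[:-1], n_at[1:]), IDEAL_ANGLES["O-C-N"])[not_break],
        angle_excess(_angles_deg(c[:-1], n_at[1:], ca[1:]), IDEAL_ANGLES["C-N-CA"])[not_break],
    ]

    dmat = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    i, j = np.triu_indices(structure.n_res, k=2)
    clash = np.maximum(CLASH_DISTANCE - dmat[i, j], 0.0)

    loss = 0.0
    for fam in (np.concatenate(bond_terms), np.concatenate(angle_terms), clash):
        if fam.size:
            loss += float(fam.mean())
    return loss


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed dihedral angle (radians, IUPAC sign) for stacked point quads."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = p3 - p2
    v = b0 - (b0 * b1).sum(axis=-1, keepdims=True) * b1
    w = b2 - (b2 * b1).sum(axis=-1, keepdims=True) * b1
    x = (v * w).sum(axis=-1)
    y = (np.cross(b1, v) * w).sum(axis=-1)
    return np.arctan2(y, x)


def backbone_dihedrals(structure: BackboneStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (phi, psi, omega) and validity flags.

    phi_i uses C_{i-1}; psi_i and omega_i use atoms of residue i+1, where
    omega_i is the torsion of the peptide bond following residue i.  Undefined
    angles (chain termini, chain breaks) have value 0 and flag 0.
    """
    n_res = structure.n_res
    n_at, ca, c = (structure.atom(x) for x in ("N", "CA", "C"))
    angles = np.zeros((n_res, 3))
    valid = np.zeros((n_res, 3), dtype=bool)
    brk = structure.chain_break_mask()

    angles[1:, 0] = dihedral(c[:-1], n_at[1:], ca[1:], c[1:])
    valid[1:, 0] = ~brk
    angles[:-1, 1] = dihedral(n_at[:-1], ca[:-1], c[:-1], n_at[1:])
    valid[:-1, 1] = ~brk
    angles[:-1, 2] = dihedral(ca[:-1], c[:-1], n_at[1:], ca[1:])
    valid[:-1, 2] = ~brk
    angles[~valid] = 0.0
    return angles, valid


def distance_bin_onehot(distances: np.ndarray) -> np.ndarray:
    """Radial one-hot binning of CA distances (over-range bin last)."""
    idx = np.floor((distances - DISTANCE_BIN_START) / DISTANCE_BIN_WIDTH).astype(int)
    idx = np.clip(idx, 0, N_DISTANCE_BINS - 1)
    onehot = np.zeros(distances.shape + (N_DISTANCE_BINS,))
    np.put_along_axis(onehot, idx[..., None], 1.0, axis=-1)
    return onehot


def invariant_features(structure: BackboneStructure) -> ResidueFeatureSet:
    """SE(3)-invariant single and pair features.

    Single: ``[sin, cos, valid]`` for each of phi, psi, omega (zeros where the
    angle is undefined).  Pair: one-hot binned CA-CA distance plus one-hot
    signed relative sequence separation clipped to ``[-8, 8]``.
    """
    angles, valid = backbone_dihedrals(structure)
    v = valid.astype(float)
    single = np.stack(
        [
            np.sin(angles[:, 0]) * v[:, 0], np.cos(angles[:, 0]) * v[:, 0], v[:, 0],
            np.sin(angles[:, 1]) * v[:, 1], np.cos(angles[:, 1]) * v[:, 1], v[:, 1],
            np.sin(angles[:, 2]) * v[:, 2], np.cos(angles[:, 2]) * v[:, 2], v[:, 2],
        ],
        axis=1,
    )

    ca = structure.ca
    dmat = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    dist_oh = distance_bin_onehot(dmat)

    idx = np.arange(structure.n_res)
    sep = np.clip(idx[None, :] - idx[:, None], -MAX_SEQSEP, MAX_SEQSEP) + MAX_SEQSEP
    sep_oh = np.eye(2 * MAX_SEQSEP + 1)[sep]

    pair = np.concatenate([dist_oh, sep_oh], axis=-1)
    return ResidueFeatureSet(single=single, pair=pair)
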