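"""Synthetic backbone generator.

Builds ideal-stereochemistry backbones (helices, strands, bundles, mixed
topologies, coils) from internal coordinates, same-basin perturbations that
emulate intra-basin structural fluctuations, hinge-motion conformational
pairs, and training corpora with an optional planted sequence-structure
coupling.  Every other module trains and tests against this generator, so no
structure database is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import IDEAL_ANGLES, IDEAL_BONDS
from .structure import AMINO_ACIDS, BackboneStructure, ValidationError

FOLD_CLASSES = ("helix", "strand", "helix-bundle", "mixed", "coil")

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-119.0, 113.0)

#: Amino acids enriched in the planted helix / strand classes.
PLANTED_CLASSES = {"H": "AELK", "S": "VIFY"}

_MIN_FOLDED_LENGTH = 10
_CLASH_CA = 3.0
_MAX_RETRIES = 100


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic backbone."""

    fold_class: str = "helix"
    length: int = 60
    perturb_sigma: float = 0.0
    seed: int = 0
    planted_class: str | None = None

    def __post_init__(self) -> None:
        if self.fold_class not in FOLD_CLASSES:
            raise ValidationError(f"unknown fold class {self.fold_class!r}")
        if self.fold_class != "coil" and self.length < _MIN_FOLDED_LENGTH:
            raise ValidationError(
                f"folded classes need length >= {_MIN_FOLDED_LENGTH}, got {self.length}"
            )
        if self.length < 2:
            raise ValidationError("length must be >= 2")
        if self.perturb_sigma < 0:
            raise ValidationError("perturb_sigma must be >= 0")
        if self.planted_class is not None and self.planted_class not in PLANTED_CLASSES:
            raise ValidationError(f"unknown planted class {self.planted_class!r}")


def _place_atom(a, b, c, bond, angle_deg, torsion_rad):
    """Internal-coordinate (NeRF) placement of the atom bonded to ``c``."""
    theta = np.radians(angle_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    d = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(torsion_rad), np.sin(theta) * np.sin(torsion_rad)]
    )
    return c + m @ d


def backbone_from_dihedrals(
    phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | None = None
) -> BackboneStructure:
    """Build an ideal-geometry backbone from per-residue torsions (degrees).

    ``phi[0]`` and the last ``psi``/``omega`` entries are ignored (undefined
    at the termini).  Carbonyl O atoms are placed anti to the following N.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = phi.shape[0]
    if psi.shape[0] != n_res:
        raise ValidationError("phi and psi must have equal length")
    omega = np.full(n_res, 180.0) if omega is None else np.asarray(omega, dtype=float)

    b = IDEAL_BONDS
    ang = IDEAL_ANGLES
    coords = np.zeros((n_res, 4, 3))

    # canonical first residue in the xy-plane
    coords[0, 0] = np.array([0.0, 0.0, 0.0])
    coords[0, 1] = np.array([b["N-CA"], 0.0, 0.0])
    th = np.radians(ang["N-CA-C"])
    coords[0, 2] = coords[0, 1] + b["CA-C"] * np.array([-np.cos(th), np.sin(th), 0.0])

    for i in range(n_res - 1):
        n_atom, ca, c = coords[i, 0], coords[i, 1], coords[i, 2]
        n_next = _place_atom(n_atom, ca, c, b["C-N"], ang["CA-C-N"], np.radians(psi[i]))
        ca_next = _place_atom(ca, c, n_next, b["N-CA"], ang["C-N-CA"], np.radians(omega[i]))
        c_next = _place_atom(c, n_next, ca_next, b["CA-C"], ang["N-CA-C"], np.radians(phi[i + 1]))
        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = n_next, ca_next, c_next
        # O_i anti to the next N (torsion psi_i + 180 about CA_i-C_i)
        coords[i, 3] = _place_atom(
            n_atom, ca, c, b["C-O"], ang["CA-C-O"], np.radians(psi[i] + 180.0)
        )
    i = n_res - 1
    coords[i, 3] = _place_atom(
        coords[i, 0], coords[i, 1], coords[i, 2], b["C-O"], ang["CA-C-O"], np.radians(135.0 + 180.0)
    )
    return BackboneStructure(coords)


def _segment_torsions(rng: np.random.Generator, length: int, fold_class: str):
    """(phi, psi) arrays for one segment of the requested class."""
    if fold_class == "helix":
        return (np.full(length, HELIX_PHI_PSI[0]), np.full(length, HELIX_PHI_PSI[1]))
    if fold_class == "strand":
        return (np.full(length, STRAND_PHI_PSI[0]), np.full(length, STRAND_PHI_PSI[1]))
    # coil / loop: broad, mostly extended-compatible torsion pool
    return (rng.uniform(-160.0, -50.0, length), rng.uniform(-70.0, 170.0, length))


def _compose_segments(rng: np.random.Generator, length: int, classes: list[str],
                      seg_len: dict[str, tuple[int, int]]):
    phis, psis = [], []
    remaining = length
    k = 0
    while remaining > 0:
        cls = classes[k % len(classes)] if classes else "coil"
        lo, hi = seg_len.get(cls, (3, 5))
        n = min(int(rng.integers(lo, hi + 1)), remaining)
        p, s = _segment_torsions(rng, n, cls)
        phis.append(p)
        psis.append(s)
        remaining -= n
        k += 1
    return np.concatenate(phis), np.concatenate(psis)


def _has_clash(structure: BackboneStructure) -> bool:
    ca = structure.ca
    d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    i, j = np.triu_indices(structure.n_res, k=2)
    return bool((d[i, j] < _CLASH_CA).any())


def gen_backbone(spec: SyntheticSpec) -> BackboneStructure:
    """Deterministically generate one backbone for ``spec``.

    Bundle/mixed topologies are assembled from secondary-structure segments
    joined by random loop linkers, rejecting clashing draws (up to
    ``_MAX_RETRIES``, then the stream is re-seeded).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    for attempt in range(_MAX_RETRIES + 1):
        if attempt == _MAX_RETRIES:
            rng = np.random.default_rng(spec.seed + 1_000_003)
        if spec.fold_class == "helix":
            phi, psi = _segment_torsions(rng, n, "helix")
        elif spec.fold_class == "strand":
            phi, psi = _segment_torsions(rng, n, "strand")
        elif spec.fold_class == "coil":
            phi, psi = _segment_torsions(rng, n, "coil")
        elif spec.fold_class == "helix-bundle":
            phi, psi = _compose_segments(
                rng, n, ["helix", "coil", "helix", "coil", "helix"],
                {"helix": (10, 18), "coil": (3, 5)},
            )
        else:  # mixed
            order = ["helix", "coil", "strand", "coil"]
            phi, psi = _compose_segments(
                rng, n, order, {"helix": (8, 15), "strand": (5, 10), "coil": (3, 5)}
            )
        structure = backbone_from_dihedrals(phi, psi)
        if spec.fold_class in ("helix", "strand") or not _has_clash(structure):
            break
    return structure


def regularize_bonds(structure: BackboneStructure, n_sweeps: int = 5) -> BackboneStructure:
    """Project covalent bond lengths back to their ideal values.

    A SHAKE-like sweep: each bonded atom pair is moved symmetrically along
    the bond to restore the ideal length; angles are left untouched.
    """
    coords = structure.coords.copy()
    b = IDEAL_BONDS
    bonds = [((0,), (1,), b["N-CA"]), ((1,), (2,), b["CA-C"]), ((2,), (3,), b["C-O"])]
    for _ in range(n_sweeps):
        for (ai,), (bi,), target in bonds:
            v = coords[:, bi] - coords[:, ai]
            d = np.linalg.norm(v, axis=1, keepdims=True)
            corr = 0.5 * (1.0 - target / d) * v
            coords[:, ai] += corr
            coords[:, bi] -= corr
        # peptide bond C_i - N_{i+1}
        v = coords[1:, 0] - coords[:-1, 2]
        d = np.linalg.norm(v, axis=1, keepdims=True)
        corr = 0.5 * (1.0 - b["C-N"] / d) * v
        coords[:-1, 2] += corr
        coords[1:, 0] -= corr
    return BackboneStructure(coords, residue_names=structure.residue_names,
                             chain_id=structure.chain_id)


def _jitter_torsions(structure: BackboneStructure, rng: np.random.Generator,
                     amplitude_deg: float, fraction: float = 0.1) -> BackboneStructure:
    """Rotate a random subset of phi/psi torsions by small angles."""
    coords = structure.coords.copy()
    n = structure.n_res
    flat = coords.reshape(-1, 3)
    # torsion axes: phi_i about N_i-CA_i (moves atoms after CA_i),
    # psi_i about CA_i-C_i (moves atoms after C_i)
    axes = []
    for i in range(1, n):
        axes.append((4 * i + 0, 4 * i + 1, 4 * i + 2))   # phi: rotate from C_i on
    for i in range(0, n - 1):
        axes.append((4 * i + 1, 4 * i + 2, 4 * i + 3))   # psi: rotate from O_i on
    n_pick = max(1, int(round(fraction * len(axes))))
    picks = rng.choice(len(axes), size=n_pick, replace=False)
    for k in sorted(picks):
        a_idx, b_idx, start = axes[k]
        angle = np.radians(rng.uniform(-amplitude_deg, amplitude_deg))
        axis = flat[b_idx] - flat[a_idx]
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        flat[start:] = (flat[start:] - flat[b_idx]) @ R.T + flat[b_idx]
    return BackboneStructure(flat.reshape(n, 4, 3), residue_names=structure.residue_names,
                             chain_id=structure.chain_id)


def perturb(structure: BackboneStructure, sigma: float, seed: int) -> BackboneStructure:
    """Same-basin perturbation emulating intra-basin fluctuations.

    Small torsion jitter (amplitude scaled with ``sigma``, capped at 5
    degrees), per-atom Gaussian noise of standard deviation ``sigma``
    Angstrom, then five bond-projection sweeps.  ``sigma = 0`` is the
    identity.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return structure.copy()
    rng = np.random.default_rng(seed)
    amplitude = min(5.0, 1.0 * sigma / 0.3)
    out = _jitter_torsions(structure, rng, amplitude)
    out = BackboneStructure(
        out.coords + rng.normal(0.0, sigma, out.coords.shape),
        residue_names=structure.residue_names, chain_id=structure.chain_id,
    )
    return regularize_bonds(out)


def gen_conformational_pair(
    spec: SyntheticSpec, hinge_angle_deg: float = 60.0
) -> tuple[BackboneStructure, BackboneStructure]:
    """Two conformations of one chain related by a hinge rotation.

    The second conformation rigidly rotates the C-terminal half about a
    random axis through the hinge CA; each half therefore superimposes
    exactly on its counterpart.
    """
    base = gen_backbone(spec)
    rng = np.random.default_rng(spec.seed + 7919)
    hinge = base.n_res // 2
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(hinge_angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    pivot = base.ca[hinge]
    coords = base.coords.copy()
    coords[hinge:] = (coords[hinge:] - pivot) @ R.T + pivot
    return base, BackboneStructure(coords, residue_names=base.residue_names,
                                   chain_id=base.chain_id)


@dataclass
class CorpusConfig:
    """Study conditions for a synthetic training corpus."""

    length_range: tuple[int, int] = (60, 80)
    fold_classes: tuple[str, ...] = ("helix", "strand", "helix-bundle", "mixed")
    enrichment: float = 3.0        # planted-class frequency ratio vs background
    planted_coupling: bool = True
    seed: int = 0


def _class_distribution(fold_class: str, enrichment: float) -> np.ndarray:
    """Amino-acid distribution; planted classes multiply their background mass."""
    p = np.full(20, 1.0 / 20)
    key = {"helix": "H", "helix-bundle": "H", "strand": "S"}.get(fold_class)
    if key is not None:
        members = [AMINO_ACIDS.index(a) for a in PLANTED_CLASSES[key]]
        target = enrichment * len(members) / 20.0
        if target >= 1.0:
            raise ValidationError(f"enrichment {enrichment} infeasible for class {key}")
        p[:] = (1.0 - target) / (20 - len(members))
        p[members] = target / len(members)
    return p


def gen_training_corpus(
    n: int, config: CorpusConfig | None = None
) -> list[tuple[BackboneStructure, str]]:
    """Generate ``n`` (structure, sequence) pairs.

    Fold classes cycle through ``config.fold_classes``; with planted coupling
    enabled, helical folds draw sequences enriched (by ``config.enrichment``
    in frequency ratio) in the class-H amino acids and strand folds in the
    class-S set, giving conditional-generation tests a recoverable signal.
    """
    config = config or CorpusConfig()
    rng = np.random.default_rng(config.seed)
    corpus: list[tuple[BackboneStructure, str]] = []
    for k in range(n):
        fold = config.fold_classes[k % len(config.fold_classes)]
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        structure = gen_backbone(
            SyntheticSpec(fold_class=fold, length=length, seed=int(rng.integers(2**31)))
        )
        dist = _class_distribution(fold if config.planted_coupling else "coil",
                                   config.enrichment)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=dist))
        structure.residue_names = list(seq)
        structure.__post_init__()
        corpus.append((structure, seq))
    return corpus


def helix_likeness(structure: BackboneStructure) -> float:
    """Mean CA(i)->CA(i+3) distance; near 5 Angstrom for an alpha helix."""
    ca = structure.ca
    return float(np.linalg.norm(ca[3:] - ca[:-3], axis=1).mean())
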