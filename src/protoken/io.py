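"""File formats: PDB backbones, FASTA sequences, token text, matrices,
checkpoints.

PDB reading and writing go through biotite; only the four backbone heavy
atoms are kept, residues missing any of them are dropped with a warning, and
altloc conflicts resolve to the highest occupancy (ties by altloc letter).
Token sequences use a FASTA-like text format (``.ptk``): a header line
``>name length=N codebook=ID`` followed by whitespace-separated integer
indices.  Checkpoints are ``.npz`` archives with a format-version field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as pdb_io
import biotite.sequence.io.fasta as fasta_io

from .structure import (
    BACKBONE_ATOMS,
    BackboneStructure,
    FormatError,
    ONE_TO_THREE,
    THREE_TO_ONE,
    UNKNOWN_AA,
    ValidationError,
)
from .tokenizer import (
    Codebook,
    StructureDecoder,
    StructureEncoder,
    TokenSequence,
    TokenizerConfig,
    TokenizerParams,
)
from .diffusion import DenoiserConfig, DenoiserParams, DiTNetwork

logger = logging.getLogger("protoken")

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------
def read_pdb(path: str | Path, chain: str | None = None) -> BackboneStructure:
    """Read one chain's backbone from a PDB file.

    ``chain = None`` selects the first chain.  Altloc conflicts resolve by
    occupancy (ties by altloc letter); residues missing any of N/CA/C/O are
    dropped with a logged warning.
    """
    try:
        pdb_file = pdb_io.PDBFile.read(str(path))
        atoms = pdb_io.get_structure(pdb_file, model=1, altloc="occupancy",
                                     extra_fields=["occupancy"])
    except Exception as err:
        raise FormatError(f"{path}: not a parsable PDB file ({err})") from err
    atoms = atoms[bst.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise FormatError(f"{path}: no parsable protein residues")
    chains = np.unique(atoms.chain_id)
    chain_id = chain if chain is not None else str(chains[0])
    if chain_id not in chains:
        raise FormatError(f"{path}: chain {chain_id!r} not present (has {list(chains)})")
    atoms = atoms[atoms.chain_id == chain_id]

    coords, names, dropped = [], [], 0
    missing_types: set[str] = set()
    for res in bst.residue_iter(atoms):
        block = np.full((4, 3), np.nan)
        for k, atom_name in enumerate(BACKBONE_ATOMS):
            hit = res[res.atom_name == atom_name]
            if hit.array_length():
                block[k] = hit.coord[0]
        if np.isnan(block).any():
            dropped += 1
            missing_types |= {BACKBONE_ATOMS[k] for k in range(4)
                              if np.isnan(block[k]).any()}
            continue
        coords.append(block)
        names.append(THREE_TO_ONE.get(str(res.res_name[0]), UNKNOWN_AA))
    if dropped:
        logger.warning("%s: dropped %d residue(s) missing backbone atoms", path, dropped)
    if len(coords) < 2:
        raise FormatError(
            f"{path}: fewer than 2 complete backbone residues "
            f"(missing atom types: {sorted(missing_types)})"
        )
    return BackboneStructure(np.array(coords), residue_names=names, chain_id=chain_id)


def write_pdb(structure: BackboneStructure, path: str | Path) -> None:
    """Write a backbone as a single-chain PDB file (serials regenerated)."""
    n = structure.n_res
    array = bst.AtomArray(4 * n)
    array.coord = structure.coords.reshape(-1, 3)
    array.chain_id = np.full(4 * n, structure.chain_id)
    array.res_id = np.repeat(np.arange(1, n + 1), 4)
    names = structure.residue_names or [UNKNOWN_AA] * n
    array.res_name = np.repeat([ONE_TO_THREE.get(r, "UNK") for r in names], 4)
    array.atom_name = np.tile(np.array(BACKBONE_ATOMS), n)
    array.element = np.tile(np.array(["N", "C", "C", "O"]), n)
    array.hetero = np.zeros(4 * n, bool)
    pdb_file = pdb_io.PDBFile()
    pdb_io.set_structure(pdb_file, array)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------
def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences; lowercase letters are upper-cased with a warning."""
    records = dict(fasta_io.FastaFile.read(str(path)).items())
    out = {}
    for name, seq in records.items():
        if any(c.islower() for c in seq):
            logger.warning("%s: sequence %r contains lowercase letters; upper-casing",
                           path, name)
        out[name] = seq.upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    f = fasta_io.FastaFile()
    for name, seq in sequences.items():
        f[name] = seq
    f.write(str(path))


# ---------------------------------------------------------------------------
# token text format (.ptk)
# ---------------------------------------------------------------------------
def write_ptk(tokens: TokenSequence, path: str | Path) -> None:
    header = f">{tokens.name} length={len(tokens)}"
    if tokens.codebook_id is not None:
        header += f" codebook={tokens.codebook_id}"
    lines = [header]
    idx = tokens.indices
    for start in range(0, len(idx), 20):
        lines.append(" ".join(str(i) for i in idx[start:start + 20]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ptk(path: str | Path, codebook: Codebook | None = None) -> TokenSequence:
    """Parse a token text file, optionally validating against a codebook."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise FormatError(f"{path}: missing '>' header line")
    fields = lines[0][1:].split()
    name = fields[0] if fields else "protein"
    meta = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
    indices: list[int] = []
    for ln, line in enumerate(lines[1:], start=2):
        for token in line.split():
            try:
                indices.append(int(token))
            except ValueError as err:
                raise FormatError(f"{path}:{ln}: not an integer token: {token!r}") from err
    if "length" in meta and int(meta["length"]) != len(indices):
        raise FormatError(
            f"{path}: header says length={meta['length']} but found {len(indices)} tokens"
        )
    ts = TokenSequence(np.array(indices, dtype=np.int64), name=name,
                       codebook_id=meta.get("codebook"))
    if codebook is not None:
        if (ts.indices >= codebook.n_codes).any():
            bad_line = None
            count = 0
            for ln, line in enumerate(lines[1:], start=2):
                for token in line.split():
                    if int(token) >= codebook.n_codes:
                        bad_line = (ln, token)
                        break
                if bad_line:
                    break
            raise ValidationError(
                f"{path}:{bad_line[0]}: token {bad_line[1]} >= codebook size "
                f"{codebook.n_codes}"
            )
        ts.validate_against(codebook)
    return ts


# ---------------------------------------------------------------------------
# matrices (TSV)
# ---------------------------------------------------------------------------
def write_matrix_tsv(matrix: np.ndarray, path: str | Path) -> None:
    """Square matrix with code-index headers, BLOSUM-file-like layout."""
    n = matrix.shape[0]
    lines = ["\t" + "\t".join(str(j) for j in range(n))]
    for i in range(n):
        lines.append(str(i) + "\t" + "\t".join(f"{v:g}" for v in matrix[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_tsv(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text().strip().splitlines()
    rows = [list(map(float, line.split("\t")[1:])) for line in lines[1:]]
    m = np.array(rows)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: not a square matrix")
    return m


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------
def save_tokenizer(params: TokenizerParams, path: str | Path) -> None:
    state = {f"enc/{k}": v for k, v in params.encoder.state_dict().items()}
    state |= {f"dec/{k}": v for k, v in params.decoder.state_dict().items()}
    np.savez(
        str(path),
        format_version=CHECKPOINT_FORMAT_VERSION,
        kind="tokenizer",
        config=json.dumps(dataclasses.asdict(params.config)),
        codebook_codes=params.codebook.codes,
        codebook_counts=params.codebook.ema_counts,
        codebook_sums=params.codebook.ema_sums,
        **state,
    )


def load_tokenizer(path: str | Path) -> TokenizerParams:
    with np.load(str(path), allow_pickle=False) as data:
        _check_version(data, "tokenizer", path)
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["sandwich"] = tuple(cfg_dict["sandwich"])
        cfg = TokenizerConfig(**cfg_dict)
        rng = np.random.default_rng(cfg.seed)
        encoder = StructureEncoder(cfg, rng)
        decoder = StructureDecoder(cfg, rng)
        encoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("enc/")}
        )
        decoder.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("dec/")}
        )
        codebook = Codebook(
            codes=data["codebook_codes"],
            ema_counts=data["codebook_counts"],
            ema_sums=data["codebook_sums"],
            eps=cfg.ema_eps,
        )
    return TokenizerParams(encoder=encoder, decoder=decoder, codebook=codebook, config=cfg)


def save_denoiser(params: DenoiserParams, path: str | Path) -> None:
    state = {f"net/{k}": v for k, v in params.network.state_dict().items()}
    np.savez(
        str(path),
        format_version=CHECKPOINT_FORMAT_VERSION,
        kind="denoiser",
        config=json.dumps(dataclasses.asdict(params.config)),
        channel_mean=params.channel_mean,
        channel_std=params.channel_std,
        **state,
    )


def load_denoiser(path: str | Path) -> DenoiserParams:
    with np.load(str(path), allow_pickle=False) as data:
        _check_version(data, "denoiser", path)
        cfg = DenoiserConfig(**json.loads(str(data["config"])))
        params = DenoiserParams.initialize(cfg)
        params.network.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("net/")}
        )
        params.channel_mean = data["channel_mean"]
        params.channel_std = data["channel_std"]
    return params


def _check_version(data, kind: str, path) -> None:
    if int(data["format_version"]) != CHECKPOINT_FORMAT_VERSION:
        raise FormatError(
            f"{path}: checkpoint format {int(data['format_version'])} unsupported"
        )
    if str(data["kind"]) != kind:
        raise FormatError(f"{path}: checkpoint is a {data['kind']}, expected {kind}")
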