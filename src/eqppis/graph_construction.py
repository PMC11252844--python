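"""Residue contact-graph construction from structures and profile features.

A protein chain becomes an undirected graph: one node per residue positioned
at its side-chain centroid, an edge whenever two centroids lie closer than a
distance cutoff (14 Å by default), and a 62-column node feature matrix
concatenating five blocks:

* PSSM  (20) — PSI-BLAST position-specific scoring matrix,
* HMM   (20) — HHblits profile-HMM match-emission probabilities,
* DSSP  (14) — secondary-structure one-hot (9 states), relative solvent
  accessibility, and sine/cosine of the backbone torsions phi and psi,
* AF     (7) — per-residue means of seven atomic characteristics,
* PEF    (1) — centered radial position of the residue in the chain.

Readers for the standard PSI-BLAST ASCII, HHblits HHM and classic DSSP
output dialects are provided; running those programs is out of scope.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .elements import (
    BACKBONE_ATOMS,
    ELEMENT_PROPERTIES,
    MAX_ASA,
    atom_h_count,
    atom_in_ring,
)

FEATURE_GROUPS = ("pssm", "hmm", "dssp", "af", "pef")
GROUP_WIDTHS = {"pssm": 20, "hmm": 20, "dssp": 14, "af": 7, "pef": 1}
DEFAULT_CUTOFF = 14.0

#: DSSP secondary-structure states, in one-hot column order ('-' = coil/none)
DSSP_STATES = "HBEGITSP-"

PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
HMM_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


class FileFormatError(ValueError):
    """Raised when a feature or structure file does not parse."""


@dataclass
class Atom:
    element: str
    name: str
    coords: np.ndarray  # (3,) in Å
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite values")


@dataclass
class ResidueRecord:
    """One residue of a chain with its heavy (and possibly H) atoms."""

    chain_id: str
    residue_index: int
    residue_name: str
    atoms: list[Atom] = field(default_factory=list)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def sidechain_heavy_atoms(self) -> list[Atom]:
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_ATOMS]


@dataclass
class FeatureBundle:
    """The five per-residue feature blocks, all with L rows."""

    pssm: np.ndarray
    hmm: np.ndarray
    dssp: np.ndarray
    af: np.ndarray
    pef: np.ndarray

    def __post_init__(self):
        for name in FEATURE_GROUPS:
            block = np.asarray(getattr(self, name), dtype=np.float64)
            if block.ndim != 2:
                raise ValueError(f"{name} block must be 2-D")
            if not np.all(np.isfinite(block)):
                raise ValueError(f"{name} block contains non-finite entries")
            setattr(self, name, block)
        lengths = {name: getattr(self, name).shape[0] for name in FEATURE_GROUPS}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"feature blocks disagree on residue count: {lengths}")

    @property
    def n_residues(self) -> int:
        return self.pssm.shape[0]


@dataclass
class ProteinGraph:
    """A protein chain as a residue graph."""

    coords: np.ndarray  # (L, 3) side-chain centroids, Å
    features: np.ndarray  # (L, D)
    adjacency: np.ndarray  # (L, L) binary, symmetric, zero diagonal
    labels: np.ndarray | None = None  # (L,) binary interface labels
    ids: list[tuple[str, int]] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.adjacency = np.asarray(self.adjacency)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        L = self.coords.shape[0]
        if L < 1:
            raise ValueError("graph must contain at least one residue")
        if self.coords.shape != (L, 3):
            raise ValueError("coords must be (L, 3)")
        if self.features.shape[0] != L:
            raise ValueError("features row count must match coords")
        if self.adjacency.shape != (L, L):
            raise ValueError("adjacency must be (L, L)")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.labels is not None and self.labels.shape != (L,):
            raise ValueError("labels must be a length-L vector")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def compute_sc_centroids(residues: Sequence[ResidueRecord]) -> np.ndarray:
    """Side-chain centroid of each residue: the unweighted mean coordinate of
    its side-chain heavy atoms; glycine (no side-chain heavy atom) falls back
    to the CA position."""
    if len(residues) == 0:
        raise ValueError("empty residue list")
    out = np.empty((len(residues), 3), dtype=np.float64)
    for i, res in enumerate(residues):
        heavy = res.heavy_atoms()
        if not heavy:
            raise ValueError(
                f"residue {res.residue_name} {res.chain_id}:{res.residue_index} "
                "has no heavy atoms"
            )
        side = res.sidechain_heavy_atoms()
        if side:
            out[i] = np.mean([a.coords for a in side], axis=0)
        else:
            ca = [a for a in heavy if a.name == "CA"]
            if not ca:
                raise ValueError(
                    f"residue {res.residue_name} {res.chain_id}:{res.residue_index} "
                    "has neither side-chain heavy atoms nor CA"
                )
            out[i] = ca[0].coords
    return out


def build_adjacency(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Binary contact map: an edge wherever the inter-centroid Euclidean
    distance is strictly below `cutoff`."""
    coords = np.asarray(coords, dtype=np.float64)
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (L, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    dist = cdist(coords, coords)
    adj = (dist < cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def aggregate_atom_features(residues: Sequence[ResidueRecord]) -> np.ndarray:
    """Seven atomic characteristics averaged over each residue's heavy atoms.

    Columns: atomic mass, B factor, side-chain flag, electron count,
    bonded-hydrogen count, ring-membership flag, van der Waals radius.
    """
    if len(residues) == 0:
        raise ValueError("empty residue list")
    out = np.empty((len(residues), 7), dtype=np.float64)
    for i, res in enumerate(residues):
        heavy = res.heavy_atoms()
        if not heavy:
            raise ValueError(
                f"residue {res.residue_name} {res.chain_id}:{res.residue_index} "
                "has no heavy atoms"
            )
        rows = []
        for a in heavy:
            key = a.element.upper()
            if key not in ELEMENT_PROPERTIES:
                raise ValueError(f"unknown element symbol {a.element!r}")
            mass, electrons, vdw = ELEMENT_PROPERTIES[key]
            rows.append([
                mass,
                a.b_factor,
                0.0 if a.name in BACKBONE_ATOMS else 1.0,
                float(electrons),
                float(atom_h_count(res.residue_name, a.name)),
                1.0 if atom_in_ring(res.residue_name, a.name) else 0.0,
                vdw,
            ])
        out[i] = np.mean(rows, axis=0)
    return out


def position_embedding(coords: np.ndarray) -> np.ndarray:
    """Translation-invariant positional scalar per residue: the distance from
    the residue's side-chain centroid to the chain's centroid, after centering."""
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    centered = coords - coords.mean(axis=0, keepdims=True)
    return np.linalg.norm(centered, axis=1, keepdims=True)


def assemble_features(
    bundle: FeatureBundle, groups: Iterable[str] = FEATURE_GROUPS
) -> np.ndarray:
    """Concatenate the requested feature blocks in the fixed order
    PSSM, HMM, DSSP, AF, PEF. With all five groups the result has 62 columns."""
    requested = {g.lower() for g in groups}
    unknown = requested - set(FEATURE_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature group(s): {sorted(unknown)}")
    if not requested:
        raise ValueError("at least one feature group is required")
    blocks = [getattr(bundle, g) for g in FEATURE_GROUPS if g in requested]
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_pdb_chain(path: str | Path, chain_id: str) -> list[ResidueRecord]:
    """Parse one chain of a PDB file into residue records (hydrogens dropped,
    heteroatoms and waters skipped). Residues are numbered 0..L-1 in file order."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("chain", str(path))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise FileFormatError(f"chain {chain_id!r} not found in {path}")
    records: list[ResidueRecord] = []
    for res in model[chain_id]:
        if res.id[0] != " ":
            continue  # skip waters / heteroatoms
        atoms = [
            Atom(
                element=atom.element if atom.element else atom.get_name()[0],
                name=atom.get_name(),
                coords=np.asarray(atom.get_coord(), dtype=np.float64),
                b_factor=float(atom.get_bfactor()),
                occupancy=float(atom.get_occupancy() or 1.0),
            )
            for atom in res
            if (atom.element or atom.get_name()[0]).upper() not in ("H", "D")
        ]
        if not atoms:
            continue
        records.append(
            ResidueRecord(
                chain_id=chain_id,
                residue_index=len(records),
                residue_name=res.get_resname(),
                atoms=atoms,
            )
        )
    if not records:
        raise FileFormatError(f"chain {chain_id!r} in {path} contains no residues")
    return records


def read_pssm(path: str | Path) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into the L×20 log-odds score matrix
    (columns in the standard A R N D C Q E G H I L K M F P S T W Y V order)."""
    rows: list[list[float]] = []
    in_table = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not in_table:
                # header line listing the 20 amino acids (twice in full files)
                if len(tokens) >= 20 and all(
                    len(t) == 1 and t in PSSM_AA_ORDER for t in tokens[:20]
                ):
                    in_table = True
                continue
            if not tokens:
                break  # blank line ends the table
            if len(tokens) < 22 or not tokens[0].isdigit():
                raise FileFormatError(f"{path}: malformed PSSM row at line {lineno}")
            try:
                rows.append([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise FileFormatError(
                    f"{path}: non-numeric PSSM score at line {lineno}"
                ) from exc
    if not rows:
        raise FileFormatError(f"{path}: no PSSM table found")
    return np.asarray(rows, dtype=np.float64)


def _hhm_scores_to_probs(scores: np.ndarray) -> np.ndarray:
    """HHM integer scores -1000*log2(p) to probabilities; negative encodes '*' (p=0)."""
    with np.errstate(over="ignore"):
        probs = 2.0 ** (-scores.astype(np.float64) / 1000.0)
    return np.where(scores < 0, 0.0, probs)


def read_hhm(path: str | Path) -> np.ndarray:
    """Read an HHblits HHM profile into the L×20 match-emission probability
    matrix (columns in the HHM A C D E F G H I K L M N P Q R S T V W Y order).

    Scores s are stored as -1000·log2(p); '*' denotes probability zero.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("HMM "))
    except StopIteration:
        raise FileFormatError(f"{path}: no HMM block found") from None
    rows: list[list[float]] = []
    i = start + 3  # skip the transition-label line and the begin-state line
    while i < len(lines):
        line = lines[i]
        if line.startswith("//"):
            break
        tokens = line.split()
        if len(tokens) < 22:
            raise FileFormatError(f"{path}: malformed HHM match line at line {i + 1}")
        try:
            rows.append([-1 if t == "*" else int(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise FileFormatError(f"{path}: bad HHM score at line {i + 1}") from exc
        i += 2  # each residue block is a match line plus a transition line
    if not rows:
        raise FileFormatError(f"{path}: no residue rows in HHM block")
    return _hhm_scores_to_probs(np.asarray(rows, dtype=np.int64))


def dssp_row_features(
    aa: str, ss: str, acc: float, phi: float, psi: float
) -> np.ndarray:
    """The 14 DSSP-derived features for one residue: one-hot secondary
    structure over H B E G I T S P and coil, relative solvent accessibility,
    and sin/cos of phi and psi (degrees)."""
    onehot = np.zeros(len(DSSP_STATES))
    state = ss if ss in DSSP_STATES else "-"
    onehot[DSSP_STATES.index(state)] = 1.0
    max_asa = MAX_ASA.get(aa, 200.0)
    rsa = min(acc / max_asa, 1.0)
    rad_phi, rad_psi = math.radians(phi), math.radians(psi)
    return np.concatenate([
        onehot,
        [rsa, math.sin(rad_phi), math.cos(rad_phi), math.sin(rad_psi), math.cos(rad_psi)],
    ])


def read_dssp(path: str | Path) -> np.ndarray:
    """Read classic DSSP output into the L×14 feature matrix (one-hot
    secondary structure, RSA, torsion sines/cosines). Chain-break rows
    ('!') are skipped."""
    from .elements import ONE_TO_THREE

    rows: list[np.ndarray] = []
    in_table = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table:
                continue
            if len(line) < 115:
                raise FileFormatError(f"{path}: truncated DSSP row at line {lineno}")
            aa_one = line[13]
            if aa_one == "!":
                continue
            ss = line[16]
            try:
                acc = float(line[34:38])
                phi = float(line[103:109])
                psi = float(line[109:115])
            except ValueError as exc:
                raise FileFormatError(
                    f"{path}: non-numeric DSSP field at line {lineno}"
                ) from exc
            aa_three = ONE_TO_THREE.get(aa_one.upper(), "UNK")
            rows.append(dssp_row_features(aa_three, ss, acc, phi, psi))
    if not rows:
        raise FileFormatError(f"{path}: no DSSP table found")
    return np.asarray(rows, dtype=np.float64)


# ---------------------------------------------------------------------------
# assembly and the on-disk graph container
# ---------------------------------------------------------------------------

def build_graph(
    residues: Sequence[ResidueRecord],
    pssm: np.ndarray,
    hmm: np.ndarray,
    dssp: np.ndarray,
    labels: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    groups: Iterable[str] = FEATURE_GROUPS,
) -> ProteinGraph:
    """Assemble a ProteinGraph from parsed structure and feature blocks;
    the AF and PEF blocks are derived from the structure itself."""
    L = len(residues)
    for name, block in (("pssm", pssm), ("hmm", hmm), ("dssp", dssp)):
        if np.asarray(block).shape[0] != L:
            raise ValueError(
                f"{name} has {np.asarray(block).shape[0]} rows for a {L}-residue chain"
            )
    coords = compute_sc_centroids(residues)
    bundle = FeatureBundle(
        pssm=pssm,
        hmm=hmm,
        dssp=dssp,
        af=aggregate_atom_features(residues),
        pef=position_embedding(coords),
    )
    return ProteinGraph(
        coords=coords,
        features=assemble_features(bundle, groups),
        adjacency=build_adjacency(coords, cutoff),
        labels=labels,
        ids=[(r.chain_id, r.residue_index) for r in residues],
    )


def save_graph(graph: ProteinGraph, path: str | Path) -> None:
    """Write a graph to the JSON container (edge list, features, coords, labels)."""
    iu, ju = np.where(np.triu(graph.adjacency, k=1))
    payload = {
        "ids": [list(t) for t in (graph.ids or [])],
        "coords": graph.coords.tolist(),
        "features": graph.features.tolist(),
        "edges": np.stack([iu, ju], axis=1).tolist() if iu.size else [],
        "labels": None if graph.labels is None else graph.labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_graph(path: str | Path) -> ProteinGraph:
    payload = json.loads(Path(path).read_text())
    coords = np.asarray(payload["coords"], dtype=np.float64)
    L = coords.shape[0]
    adj = np.zeros((L, L), dtype=np.int8)
    for i, j in payload["edges"]:
        adj[i, j] = adj[j, i] = 1
    labels = payload.get("labels")
    return ProteinGraph(
        coords=coords,
        features=np.asarray(payload["features"], dtype=np.float64),
        adjacency=adj,
        labels=None if labels is None else np.asarray(labels, dtype=np.int64),
        ids=[tuple(t) for t in payload.get("ids", [])] or None,
    )
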