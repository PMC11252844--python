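"""Self-contained protein-like fixtures with planted interface signal.

A synthetic chain is a seeded self-avoiding random walk in 3D with the
3.8 Å consecutive spacing of real CA traces. Each walk point is the
side-chain position of one residue (a CB-like atom sits exactly on the walk
point, with a small backbone built around it), so side-chain centroids
reproduce the walk exactly. Interface labels are planted geometrically:
residues within `radius` of a probe point (the position of one randomly
chosen residue, standing in for a binding partner's contact point) are
positive, optionally corrupted by independent label flips.

Feature blocks mimic the real 62-column layout. Class signal is injected as
a mean shift on a per-dataset random subset of PSSM/HMM columns, so that no
single feature block is trivially sufficient; DSSP, atomic and positional
features carry no planted signal. PSSM values live on the integer grid of
PSI-BLAST ASCII output and HMM probabilities on the 2^(-s/1000) grid of
HHblits HHM files, so writing the fixture files and re-reading them with
the standard-format readers reproduces the in-memory matrices exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .elements import MAX_ASA, ONE_TO_THREE, THREE_TO_ONE
from .graph_construction import (
    Atom,
    FeatureBundle,
    ProteinGraph,
    ResidueRecord,
    assemble_features,
    aggregate_atom_features,
    build_adjacency,
    compute_sc_centroids,
    dssp_row_features,
    _hhm_scores_to_probs,
    position_embedding,
    DEFAULT_CUTOFF,
    HMM_AA_ORDER,
    PSSM_AA_ORDER,
)

logger = logging.getLogger(__name__)

#: secondary-structure states and sampling weights for synthetic DSSP rows
_SS_STATES = np.array(list("HET-SGBIP"))
_SS_WEIGHTS = np.array([0.33, 0.22, 0.11, 0.20, 0.06, 0.04, 0.02, 0.01, 0.01])

#: number of PSSM+HMM columns eligible for the class-conditional shift
_N_SHIFTABLE = 40
_N_SHIFT_DEFAULT = 12


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic chain."""

    n_residues: int = 60
    step: float = 3.8  # consecutive-residue spacing, Å
    feature_noise: float = 1.0  # scales the PSSM noise standard deviation
    probe: np.ndarray | None = None  # interface probe point; random residue if None
    radius: float = 10.0  # interface rule: positive within this distance, Å
    label_noise: float = 0.0
    feature_shift: float = 2.0  # class-conditional mean shift magnitude
    shift_columns: tuple[int, ...] | None = None  # indices into the 40 PSSM+HMM cols
    cutoff: float = DEFAULT_CUTOFF
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")


@dataclass
class SyntheticChain:
    """A generated chain: graph plus everything needed to write fixture files."""

    graph: ProteinGraph
    residues: list[ResidueRecord]
    bundle: FeatureBundle
    probe: np.ndarray
    spec: SyntheticSpec
    sequence: str  # one-letter
    pssm_raw: np.ndarray  # (L, 20) integers on the PSI-BLAST grid
    hmm_scores: np.ndarray  # (L, 20) integer HHM scores, -1 encodes '*'
    dssp_rows: list[tuple[str, str, int, float, float]]  # (aa3, ss, acc, phi, psi)
    name: str = "synthetic"


@dataclass
class SyntheticDataset:
    train_chains: list[SyntheticChain]
    test_chains: list[SyntheticChain]
    shift_columns: tuple[int, ...]
    positive_fraction: float

    @property
    def train(self) -> list[ProteinGraph]:
        return [c.graph for c in self.train_chains]

    @property
    def test(self) -> list[ProteinGraph]:
        return [c.graph for c in self.test_chains]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _self_avoiding_walk(
    rng: np.random.Generator,
    n: int,
    step: float,
    min_separation: float = 3.4,
    max_tries: int = 100,
    max_restarts: int = 50,
) -> np.ndarray:
    """A 3D walk with exact step length; non-consecutive points keep at
    least `min_separation` apart."""
    for _ in range(max_restarts):
        pts = np.empty((n, 3))
        pts[0] = 0.0
        ok = True
        for i in range(1, n):
            for _ in range(max_tries):
                cand = pts[i - 1] + step * _random_unit(rng)
                if i < 2:
                    break
                d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
                if np.all(d >= min_separation):
                    break
            else:
                ok = False
                break
            pts[i] = cand
        if ok:
            return pts
    raise RuntimeError("self-avoiding walk failed after bounded restarts")


def _build_residues(
    rng: np.random.Generator, walk: np.ndarray, names: list[str]
) -> list[ResidueRecord]:
    """Place a minimal backbone + one side-chain atom per residue so the
    side-chain centroid equals the walk point exactly (for glycine the CA
    itself sits on the walk point)."""
    residues = []
    for i, (name, pt) in enumerate(zip(names, walk)):
        b = lambda: round(float(rng.uniform(10, 50)), 2)
        off = lambda r: r * _random_unit(rng)
        if name == "GLY":
            atoms = [
                Atom("N", "N", pt + off(1.46), b()),
                Atom("C", "CA", pt, b()),
                Atom("C", "C", pt + off(1.52), b()),
                Atom("O", "O", pt + off(2.4), b()),
            ]
        else:
            ca = pt + off(1.53)
            atoms = [
                Atom("N", "N", ca + off(1.46), b()),
                Atom("C", "CA", ca, b()),
                Atom("C", "C", ca + off(1.52), b()),
                Atom("O", "O", ca + off(2.4), b()),
                Atom("C", "CB", pt, b()),
            ]
        residues.append(ResidueRecord("A", i, name, atoms))
    return residues


# ---------------------------------------------------------------------------
# chain generation
# ---------------------------------------------------------------------------

def generate_chain(spec: SyntheticSpec, name: str = "synthetic") -> SyntheticChain:
    """Generate one labelled synthetic chain (deterministic in spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    L = spec.n_residues
    walk = _self_avoiding_walk(rng, L, spec.step)

    aa_three = list(ONE_TO_THREE.values())
    names = [aa_three[i] for i in rng.integers(0, 20, size=L)]
    sequence = "".join(THREE_TO_ONE[n] for n in names)
    residues = _build_residues(rng, walk, names)
    coords = compute_sc_centroids(residues)

    probe = (
        coords[int(rng.integers(L))].copy() if spec.probe is None
        else np.asarray(spec.probe, dtype=np.float64)
    )
    labels = (np.linalg.norm(coords - probe, axis=1) <= spec.radius).astype(np.int64)
    if spec.label_noise > 0:
        flips = rng.random(L) < spec.label_noise
        labels = labels ^ flips.astype(np.int64)

    shift_cols = (
        np.asarray(spec.shift_columns, dtype=int)
        if spec.shift_columns is not None
        else rng.choice(_N_SHIFTABLE, size=_N_SHIFT_DEFAULT, replace=False)
    )
    pssm_cols = shift_cols[shift_cols < 20]
    hmm_cols = shift_cols[shift_cols >= 20] - 20
    pos = labels == 1

    # PSSM: integer log-odds grid, class shift added before rounding
    pssm = rng.normal(0.0, 2.0 * spec.feature_noise, size=(L, 20))
    if spec.feature_shift:
        pssm[np.ix_(pos, pssm_cols)] += spec.feature_shift
    pssm_raw = np.clip(np.rint(pssm), -12, 12).astype(np.int64)

    # HMM: integer scores s, probability 2^(-s/1000); the class shift lowers
    # the score (raises the emission probability) on the selected columns
    hmm_scores = rng.integers(1500, 4500, size=(L, 20))
    if spec.feature_shift:
        shifted = hmm_scores[np.ix_(pos, hmm_cols)] - int(round(1000 * spec.feature_shift))
        hmm_scores[np.ix_(pos, hmm_cols)] = np.clip(shifted, 0, None)
    hmm = _hhm_scores_to_probs(hmm_scores)

    # DSSP: random plausible rows on the file grid (no planted signal)
    dssp_rows: list[tuple[str, str, int, float, float]] = []
    ss_choices = rng.choice(len(_SS_STATES), size=L, p=_SS_WEIGHTS / _SS_WEIGHTS.sum())
    for i in range(L):
        acc = int(rng.integers(0, int(MAX_ASA[names[i]]) + 1))
        phi = float(rng.integers(-1800, 1800)) / 10.0
        psi = float(rng.integers(-1800, 1800)) / 10.0
        dssp_rows.append((names[i], str(_SS_STATES[ss_choices[i]]), acc, phi, psi))
    dssp = np.asarray([dssp_row_features(*row) for row in dssp_rows])

    bundle = FeatureBundle(
        pssm=pssm_raw.astype(np.float64),
        hmm=hmm,
        dssp=dssp,
        af=aggregate_atom_features(residues),
        pef=position_embedding(coords),
    )
    graph = ProteinGraph(
        coords=coords,
        features=assemble_features(bundle),
        adjacency=build_adjacency(coords, spec.cutoff),
        labels=labels,
        ids=[(r.chain_id, r.residue_index) for r in residues],
    )
    return SyntheticChain(
        graph=graph,
        residues=residues,
        bundle=bundle,
        probe=probe,
        spec=spec,
        sequence=sequence,
        pssm_raw=pssm_raw,
        hmm_scores=hmm_scores,
        dssp_rows=dssp_rows,
        name=name,
    )


def generate_dataset(
    n_chains: int,
    template: SyntheticSpec | None = None,
    seed: int = 0,
    test_fraction: float = 0.25,
    residue_range: tuple[int, int] = (40, 80),
) -> SyntheticDataset:
    """Generate a train/test collection of chains with disjoint per-chain
    seeds and one dataset-wide set of class-shifted feature columns."""
    if n_chains < 2:
        raise ValueError("need at least two chains")
    template = template or SyntheticSpec()
    rng = np.random.default_rng(seed)
    shift_columns = tuple(
        int(c) for c in rng.choice(_N_SHIFTABLE, size=_N_SHIFT_DEFAULT, replace=False)
    )
    chains = []
    for ci in range(n_chains):
        spec = replace(
            template,
            n_residues=int(rng.integers(residue_range[0], residue_range[1] + 1)),
            shift_columns=shift_columns,
            seed=int(rng.integers(0, 2**31)),
        )
        chains.append(generate_chain(spec, name=f"chain{ci:03d}"))
    n_test = max(1, int(round(test_fraction * n_chains)))
    test_chains = chains[n_chains - n_test:]
    train_chains = chains[: n_chains - n_test]
    n_pos = sum(int(c.graph.labels.sum()) for c in chains)
    n_all = sum(c.graph.n_residues for c in chains)
    frac = n_pos / n_all
    logger.info(
        "generated %d chains (%d residues, positive fraction %.3f)",
        n_chains, n_all, frac,
    )
    return SyntheticDataset(
        train_chains=train_chains,
        test_chains=test_chains,
        shift_columns=shift_columns,
        positive_fraction=frac,
    )


# ---------------------------------------------------------------------------
# fixture-file writers (dialects of the standard tool outputs)
# ---------------------------------------------------------------------------

def write_pdb(chain: SyntheticChain, path: str | Path) -> None:
    """Standard ATOM records (coordinates at the 0.001 Å PDB precision)."""
    lines = []
    serial = 1
    for res in chain.residues:
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.residue_name:>3s} "
                f"{res.chain_id}{res.residue_index + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pssm(chain: SyntheticChain, path: str | Path) -> None:
    """PSI-BLAST ASCII PSSM dialect (log-odds scores; percentages zeroed)."""
    header = "  ".join(PSSM_AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {header}  {header}",
    ]
    for i, (aa, row) in enumerate(zip(chain.sequence, chain.pssm_raw), start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        pcts = " ".join(f"{0:3d}" for _ in row)
        lines.append(f"{i:5d} {aa}  {scores}  {pcts}  0.00 0.00")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def write_hhm(chain: SyntheticChain, path: str | Path) -> None:
    """HHblits HHM dialect (match-emission scores; s = -1000 log2 p)."""
    L = len(chain.sequence)
    lines = [
        "HHsearch 1.5",
        f"NAME  {chain.name}",
        f"LENG  {L} match states, {L} columns in multiple alignment",
        "#",
        "NULL   3706 5728 4211 4064 4839 3729 4763 4308 4069 3323 "
        "5509 4640 4464 4937 4285 4423 3815 3783 6325 4665",
        "HMM    " + "\t".join(HMM_AA_ORDER),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t*\t*\t*\t*\t*\t*\t*",
    ]
    for i, (aa, row) in enumerate(zip(chain.sequence, chain.hmm_scores), start=1):
        scores = "\t".join("*" if s < 0 else str(int(s)) for s in row)
        lines.append(f"{aa} {i}\t{scores}\t{i}")
        lines.append("       0\t*\t*\t*\t*\t*\t*\t1000\t0\t0")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dssp(chain: SyntheticChain, path: str | Path) -> None:
    """Classic DSSP output dialect (fixed-column layout)."""
    lines = [
        "==== Secondary Structure Definition, synthetic fixture ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    for i, (aa3, ss, acc, phi, psi) in enumerate(chain.dssp_rows):
        row = [" "] * 130
        row[0:5] = f"{i + 1:5d}"
        row[5:10] = f"{i + 1:5d}"
        row[11] = "A"
        row[13] = THREE_TO_ONE[aa3]
        row[16] = ss
        row[34:38] = f"{acc:4d}"
        row[103:109] = f"{phi:6.1f}"
        row[109:115] = f"{psi:6.1f}"
        lines.append("".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_labels(chain: SyntheticChain, path: str | Path) -> None:
    """One binary interface label per line, in residue order."""
    Path(path).write_text(
        "\n".join(str(int(v)) for v in chain.graph.labels) + "\n"
    )


def write_fixture_files(chain: SyntheticChain, out_dir: str | Path) -> dict[str, Path]:
    """Emit all reader-testable files for one chain; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": out / f"{chain.name}.pdb",
        "pssm": out / f"{chain.name}.pssm",
        "hhm": out / f"{chain.name}.hhm",
        "dssp": out / f"{chain.name}.dssp",
        "labels": out / f"{chain.name}.labels",
    }
    write_pdb(chain, paths["pdb"])
    write_pssm(chain, paths["pssm"])
    write_hhm(chain, paths["hhm"])
    write_dssp(chain, paths["dssp"])
    write_labels(chain, paths["labels"])
    return paths
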