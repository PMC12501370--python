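"""Synthetic complexes, mock predictors, and state-series generators.

Everything downstream of structure prediction is testable without GPUs or
downloads: this module builds toy protein-ligand complexes with a known
binding site, emulates the two caricature predictor behaviours the
adversarial methodology distinguishes, and simulates bound/unbound RMSD
series with a stated stationary bound probability.

Toy proteins are geometric residue arrangements with correct atom names,
not folded chains: site residues ring the ligand with their side-chain tip
at a chosen pocket radius, scaffold residues sit well outside any plausible
detection cutoff. Every criterion the pipeline scores is local and
geometric, so this is sufficient for end-to-end testing.

The two mock predictors embody the qualitative contrast under study:

* ``memorizer`` keeps the ligand at the wild-type pose no matter how the
  binding site or ligand was perturbed (the pattern-recall failure mode);
* ``physics`` keeps the wild-type pose only when the pocket is intact and
  otherwise expels the ligand by a configurable displacement (the
  physically expected response). Whether the glycine-removal challenge
  retains binding is configurable, since backbone contacts alone can keep
  a ligand partially bound.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._aminoacids import SIDE_CHAIN_ATOMS, element_of
from .challenge import ChallengeSpec
from .core_structures import (
    Atom,
    LigandGraph,
    PredictedStructure,
    ProteinLigandComplex,
    Residue,
    write_complex,
)
from .ligand_challenges import ATP_SMILES, GLUCOSE_SMILES
from .pose_evaluation import conservation_stats, evaluate_prediction
from .site_challenges import build_suite

__all__ = [
    "ToyComplexParams",
    "MockPredictorConfig",
    "make_toy_complex",
    "mock_predict",
    "simulate_state_series",
    "run_benchmark",
    "cdk2_pocket_mimic",
    "mek1_pocket_mimic",
]

LIGAND_TEMPLATES = {
    "atp_like": ATP_SMILES,
    "glucose_like": GLUCOSE_SMILES,
    "generic": "c1ccc(cc1)C(=O)NC2CC2",
}

_DEFAULT_SITE_CODES = ["ILE", "THR", "VAL", "ALA", "LYS", "ASP", "GLN", "ASN"]
_SCAFFOLD_CODES = ["SER", "LEU", "GLU", "LYS", "ALA", "VAL", "THR", "ASN"]


@dataclass
class ToyComplexParams:
    """Recipe for a toy pocket: residue identities, geometry, ligand, seed."""

    n_site_residues: int = 8
    site_residue_codes: Optional[list[str]] = None
    site_residue_numbers: Optional[list[int]] = None
    pocket_radius: float = 3.2
    n_scaffold_residues: int = 20
    scaffold_margin: float = 6.0
    ligand_template: str = "atp_like"
    chain_id: str = "A"
    source_id: str = "TOY"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_site_residues < 0:
            raise ValueError("n_site_residues must be >= 0")
        if self.pocket_radius <= 0.5:
            raise ValueError(
                f"geometrically infeasible pocket_radius {self.pocket_radius}"
            )
        if self.site_residue_codes is None:
            self.site_residue_codes = [
                _DEFAULT_SITE_CODES[i % len(_DEFAULT_SITE_CODES)]
                for i in range(self.n_site_residues)
            ]
        if len(self.site_residue_codes) != self.n_site_residues:
            raise ValueError("site_residue_codes length != n_site_residues")
        for code in self.site_residue_codes:
            if code not in SIDE_CHAIN_ATOMS:
                raise ValueError(f"unknown residue code {code!r}")
            if not SIDE_CHAIN_ATOMS[code]:
                raise ValueError(
                    f"{code} has no side-chain heavy atoms and can never be "
                    "detected as a site residue"
                )
        if self.site_residue_numbers is None:
            self.site_residue_numbers = list(
                range(10, 10 + self.n_site_residues)
            )
        if len(self.site_residue_numbers) != self.n_site_residues:
            raise ValueError("site_residue_numbers length != n_site_residues")


def _fibonacci_directions(n: int, offset: float = 0.0) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    if n == 0:
        return np.zeros((0, 3))
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i + offset
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _embed_ligand(template: str, seed: int) -> LigandGraph:
    smiles = LIGAND_TEMPLATES.get(template)
    if smiles is None:
        raise ValueError(f"unknown ligand template {template!r}")
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"3D embedding failed for template {template!r}")
    mol = Chem.RemoveHs(mol)
    graph = LigandGraph.from_rdkit(mol)
    centered = graph.coords - graph.coords.mean(axis=0)
    return graph.with_coords(np.round(centered, 3))


def _perpendicular(d: np.ndarray) -> np.ndarray:
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, trial)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = np.cross(d, trial)
    return perp / np.linalg.norm(perp)


def _build_residue(
    chain_id: str,
    number: int,
    code3: str,
    tip_pos: np.ndarray,
    direction_out: np.ndarray,
) -> Residue:
    """Residue with its side-chain tip at ``tip_pos`` and the backbone laid
    outward along ``direction_out`` (1.45 Å steps, slight zigzag)."""
    side_names = SIDE_CHAIN_ATOMS[code3]
    perp = _perpendicular(direction_out)
    atoms = []
    m = len(side_names)
    for j, name in enumerate(side_names):
        pos = tip_pos + direction_out * 1.45 * (m - 1 - j)
        if j < m - 1:  # keep the tip exactly at tip_pos
            pos = pos + perp * 0.25 * (-1.0) ** j
        atoms.append(Atom(name=name, element=element_of(name), coords=pos))
    cb_pos = atoms[0].coords if atoms else tip_pos
    ca = cb_pos + direction_out * 1.52
    atoms.insert(0, Atom(name="CA", element="C", coords=ca))
    atoms.insert(0, Atom(name="N", element="N", coords=ca + direction_out * 1.2 + perp * 0.9))
    atoms.append(Atom(name="C", element="C", coords=ca + direction_out * 1.2 - perp * 0.9))
    atoms.append(Atom(name="O", element="O", coords=ca + direction_out * 2.4 - perp * 0.9))
    return Residue(
        chain_id=chain_id, number=number, insertion_code="", code3=code3, atoms=atoms
    )


def make_toy_complex(
    params: ToyComplexParams, out_path: Optional[str | Path] = None
) -> ProteinLigandComplex:
    """Build a toy complex; optionally write it as PDB.

    Site residues are guaranteed to have their side-chain tip at exactly
    ``pocket_radius`` from the nearest ligand heavy atom; scaffold residues
    sit at least ``pocket_radius + scaffold_margin`` away. Deterministic
    under ``seed``.
    """
    ligand = _embed_ligand(params.ligand_template, params.seed)
    lig_xyz = ligand.coords
    centroid = lig_xyz.mean(axis=0)

    residues: list[Residue] = []
    directions = _fibonacci_directions(params.n_site_residues)
    for i in range(params.n_site_residues):
        d = directions[i]
        # anchor: ligand atom with the largest projection along d, so the
        # tip is exactly pocket_radius from its nearest ligand atom
        proj = (lig_xyz - centroid) @ d
        anchor = lig_xyz[int(np.argmax(proj))]
        tip = anchor + d * params.pocket_radius
        residues.append(
            _build_residue(
                params.chain_id,
                params.site_residue_numbers[i],
                params.site_residue_codes[i],
                tip,
                d,
            )
        )

    scaffold_dirs = _fibonacci_directions(params.n_scaffold_residues, offset=1.234)
    taken = set(params.site_residue_numbers)
    number = 1000
    for i in range(params.n_scaffold_residues):
        d = scaffold_dirs[i]
        proj = (lig_xyz - centroid) @ d
        anchor = lig_xyz[int(np.argmax(proj))]
        tip = anchor + d * (params.pocket_radius + params.scaffold_margin)
        while number in taken:
            number += 1
        taken.add(number)
        residues.append(
            _build_residue(
                params.chain_id,
                number,
                _SCAFFOLD_CODES[i % len(_SCAFFOLD_CODES)],
                tip,
                d,
            )
        )
        number += 1

    residues.sort(key=lambda r: r.number)
    cplx = ProteinLigandComplex(
        chains={params.chain_id: residues},
        ligand=ligand,
        ligand_code="LIG",
        source_id=params.source_id,
    )
    if out_path is not None:
        write_complex(cplx, out_path)
    return cplx


def cdk2_pocket_mimic(seed: int = 0) -> ProteinLigandComplex:
    """Synthetic stand-in for the CDK2/ATP pocket (crystal structure 1B38).

    Reproduces the published 11 contact-residue identities and author
    numbers (I10, T14, V18, A31, K33, D86, K129, Q131, N132, L134, D145)
    around an ATP-like ligand; the geometry is synthetic, not the crystal's.
    """
    return make_toy_complex(
        ToyComplexParams(
            n_site_residues=11,
            site_residue_codes=[
                "ILE", "THR", "VAL", "ALA", "LYS", "ASP",
                "LYS", "GLN", "ASN", "LEU", "ASP",
            ],
            site_residue_numbers=[10, 14, 18, 31, 33, 86, 129, 131, 132, 134, 145],
            ligand_template="atp_like",
            source_id="SYN-CDK2",
            seed=seed,
        )
    )


def mek1_pocket_mimic(seed: int = 0) -> ProteinLigandComplex:
    """Synthetic stand-in for the MEK1 inhibitor pocket (crystal 7XLP).

    Reproduces the published 7 contact-residue identities and numbers
    (A40, A59, I105, E108, M110, S158, F173); geometry is synthetic.
    """
    return make_toy_complex(
        ToyComplexParams(
            n_site_residues=7,
            site_residue_codes=["ALA", "ALA", "ILE", "GLU", "MET", "SER", "PHE"],
            site_residue_numbers=[40, 59, 105, 108, 110, 158, 173],
            ligand_template="generic",
            source_id="SYN-MEK1",
            seed=seed,
        )
    )


# --------------------------------------------------------------------------
# mock predictors
# --------------------------------------------------------------------------

@dataclass
class MockPredictorConfig:
    """Caricature predictor behaviour for pipeline testing."""

    mode: str = "memorizer"
    displacement: float = 8.0
    coordinate_noise: float = 0.0
    seed: int = 0
    removal_conserved: bool = True

    def __post_init__(self) -> None:
        if self.mode not in {"memorizer", "physics"}:
            raise ValueError(f"unknown mock mode {self.mode!r}")
        if self.coordinate_noise < 0:
            raise ValueError("coordinate_noise must be >= 0")
        if self.mode == "physics" and self.displacement < 2.0:
            raise ValueError(
                "physics-mode displacement must be >= the 2 Å conservation "
                "threshold, otherwise the mock cannot break conservation"
            )


def _rebuild_side_chain(res: Residue, new_code: str, toward: np.ndarray) -> None:
    """Replace a residue's side chain with the new identity's atoms, laid
    from CA toward ``toward`` in 1.45 Å steps."""
    ca = res.atom("CA")
    backbone = [a for a in res.atoms if a.name in {"N", "CA", "C", "O", "OXT"}]
    res.code3 = new_code
    res.atoms = backbone
    if ca is None:
        return
    d = toward - ca.coords
    norm = np.linalg.norm(d)
    d = d / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    perp = _perpendicular(d)
    for j, name in enumerate(SIDE_CHAIN_ATOMS[new_code]):
        pos = ca.coords + d * 1.45 * (j + 1) + perp * 0.25 * ((-1.0) ** j)
        res.atoms.append(Atom(name=name, element=element_of(name), coords=pos))


def mock_predict(
    cplx: ProteinLigandComplex,
    spec: ChallengeSpec,
    config: MockPredictorConfig,
) -> PredictedStructure:
    """Emulate a co-folding prediction for one challenge spec.

    Mutated residues are rebuilt with the new identity's atoms. The ligand
    is either kept at the wild-type pose (memorizer; physics on an intact
    pocket) or translated out of the pocket by ``displacement`` (physics on
    a disrupted pocket). Per-atom confidence values are synthesized in
    [0, 100]: high for retained poses, low for expelled ones.
    """
    if spec.parent != cplx.source_id:
        raise ValueError(
            f"spec parent {spec.parent!r} does not match complex {cplx.source_id!r}"
        )
    rng = np.random.default_rng(config.seed)
    pred = cplx.copy()
    lig_centroid = cplx.ligand.coords.mean(axis=0)
    for m in spec.mutations:
        res = pred.residue(m.chain, m.number, m.insertion_code)
        if res.code3 != m.wt:
            raise ValueError(f"mutation {m.label}: residue is {res.code3}, not {m.wt}")
        _rebuild_side_chain(res, m.new, lig_centroid)

    graph = spec.modified_ligand if spec.modified_ligand is not None else cplx.ligand
    xyz = graph.coords.copy()

    displaced = False
    if config.mode == "physics" and spec.is_perturbation():
        displaced = not (spec.kind == "removal" and config.removal_conserved)
    if displaced:
        protein_xyz = np.array([a.coords for _, a in pred.protein_atoms()])
        direction = lig_centroid - protein_xyz.mean(axis=0)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
        xyz = xyz + direction * config.displacement
    if config.coordinate_noise > 0:
        xyz = xyz + rng.normal(0.0, config.coordinate_noise, xyz.shape)

    pred.ligand = graph.with_coords(xyz)
    if spec.modified_ligand is not None:
        pred.ligand_code = "MOD"

    lo, hi = (40.0, 70.0) if displaced else (85.0, 98.0)
    confidence = rng.uniform(lo, hi, len(pred.ligand.atoms))
    return PredictedStructure(
        complex=pred,
        per_atom_confidence=confidence.tolist(),
        complex_confidence=float(confidence.mean()),
    )


# --------------------------------------------------------------------------
# state-series simulation
# --------------------------------------------------------------------------

def simulate_state_series(
    p_bound: float,
    n_frames: int,
    dwell: float = 20.0,
    seed: int = 0,
    threshold: float = 2.0,
) -> np.ndarray:
    """Two-state correlated RMSD series with stationary bound fraction
    ``p_bound``; bound frames sample RMSD < threshold, unbound frames above.

    The hidden state follows a two-state Markov chain with mean dwell
    ``dwell`` frames (leave probabilities (1−p)/dwell and p/dwell), whose
    stationary distribution is exactly (p_bound, 1−p_bound).
    """
    if not 0.0 <= p_bound <= 1.0:
        raise ValueError(f"p_bound {p_bound} outside [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dwell < 1.0:
        raise ValueError("dwell must be >= 1 frame")
    rng = np.random.default_rng(seed)
    leave_bound = (1.0 - p_bound) / dwell
    leave_unbound = p_bound / dwell
    state = rng.random() < p_bound  # stationary start
    rmsd = np.empty(n_frames)
    for i in range(n_frames):
        if state:
            rmsd[i] = rng.uniform(0.15 * threshold, 0.95 * threshold)
            if rng.random() < leave_bound:
                state = False
        else:
            rmsd[i] = rng.uniform(1.25 * threshold, 4.5 * threshold)
            if rng.random() < leave_unbound:
                state = True
    return rmsd


# --------------------------------------------------------------------------
# end-to-end benchmark
# --------------------------------------------------------------------------

def run_benchmark(
    seed: int = 0,
    displacement: float = 8.0,
    coordinate_noise: float = 0.05,
    removal_conserved: bool = True,
    cutoff: float = 3.5,
) -> dict:
    """Full pipeline on the synthetic benchmark: build a toy complex,
    derive the four-challenge suite, run both mock predictors, score every
    prediction, and summarize pose conservation per challenge.

    Returns ``{"memorizer": {...fractions...}, "physics": {...},
    "records": {...}}`` with challenge kinds as keys.
    """
    cplx = make_toy_complex(ToyComplexParams(seed=seed))
    suite = build_suite(cplx, cutoff=cutoff)
    out: dict = {"records": {}}
    for mode in ("memorizer", "physics"):
        config = MockPredictorConfig(
            mode=mode,
            displacement=displacement,
            coordinate_noise=coordinate_noise,
            seed=seed,
            removal_conserved=removal_conserved,
        )
        records = [
            evaluate_prediction(mock_predict(cplx, spec, config), cplx, spec)
            for spec in suite
        ]
        summary = conservation_stats(records)
        out[mode] = {kind: summary.fractions[kind] for kind in summary.fractions}
        out["records"][mode] = records
    return out
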