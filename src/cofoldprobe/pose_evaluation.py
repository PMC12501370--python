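"""Scoring of predicted complexes against references.

The frame convention follows docking practice: the predicted protein is
rigidly superposed onto the reference over shared Cα atoms, and the ligand
RMSD is then computed in that common frame over corresponding heavy atoms —
never after a ligand-only refit. A pose is *conserved* when its ligand RMSD
is strictly below the threshold (default 2.0 Å).

For chemically modified ligands the correspondence covers the shared
substructure: methyl additions are excluded from the RMSD, while
charge-replacement groups are mapped onto the excised phosphate positions
by chain topology where a correspondence exists. Symmetry-aware RMSD takes
the minimum over graph automorphisms of the reference ligand.

Steric clashes are non-bonded protein/ligand heavy-atom pairs closer than
the sum of van der Waals radii minus a tolerance (default 0.4 Å).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .challenge import ChallengeSpec, LIGAND_KINDS
from .core_structures import LigandGraph, PredictedStructure, ProteinLigandComplex

__all__ = [
    "AtomMapping",
    "EvaluationRecord",
    "ConservationSummary",
    "RigidTransform",
    "Clash",
    "ClashReport",
    "VDW_RADII",
    "superpose_calpha",
    "map_common_heavy_atoms",
    "ligand_rmsd",
    "detect_clashes",
    "evaluate_prediction",
    "conservation_stats",
]

#: Bondi van der Waals radii (Å) for elements seen in protein/ligand work
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: cap on automorphism enumeration before falling back to the naive mapping
AUTOMORPHISM_CAP = 10_000

CONSERVATION_THRESHOLD = 2.0


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """x -> R @ x + t"""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _shared_calpha(
    a: ProteinLigandComplex, b: ProteinLigandComplex
) -> tuple[np.ndarray, np.ndarray]:
    coords_a, coords_b = [], []
    b_index = {
        res.identity: res for res in b.iter_residues()
    }
    for res in a.iter_residues():
        other = b_index.get(res.identity)
        if other is None:
            continue
        ca_a, ca_b = res.atom("CA"), other.atom("CA")
        if ca_a is not None and ca_b is not None:
            coords_a.append(ca_a.coords)
            coords_b.append(ca_b.coords)
    return np.array(coords_a), np.array(coords_b)


def superpose_calpha(
    predicted: ProteinLigandComplex, reference: ProteinLigandComplex
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of predicted onto reference over
    shared Cα atoms (matched by chain + author number + insertion code).

    Returns the transform taking predicted coordinates into the reference
    frame, and the Cα RMSD after superposition.
    """
    pred_xyz, ref_xyz = _shared_calpha(predicted, reference)
    if len(pred_xyz) < 3:
        raise ValueError(
            f"only {len(pred_xyz)} shared Cα atoms; need at least 3 to superpose"
        )
    pred_c = pred_xyz.mean(axis=0)
    ref_c = ref_xyz.mean(axis=0)
    rot, rssd = Rotation.align_vectors(ref_xyz - ref_c, pred_xyz - pred_c)
    R = rot.as_matrix()
    t = ref_c - R @ pred_c
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(pred_xyz)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1))))
    return transform, rmsd


# --------------------------------------------------------------------------
# atom correspondence
# --------------------------------------------------------------------------

@dataclass
class AtomMapping:
    """Injective heavy-atom correspondence reference -> predicted."""

    pairs: list[tuple[int, int]]
    coverage: float

    def __post_init__(self) -> None:
        refs = [r for r, _ in self.pairs]
        preds = [p for _, p in self.pairs]
        if len(set(refs)) != len(refs) or len(set(preds)) != len(preds):
            raise ValueError("atom mapping must be injective both ways")


def _extend_along_chains(
    ref_mol: Chem.Mol,
    pred_mol: Chem.Mol,
    pairs: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Pair unmapped atoms reachable through matching linear chains.

    From every mapped anchor, while both sides have exactly one unmapped
    heavy neighbour, pair them and walk on. This maps replacement-group
    atoms onto excised-group positions by topology and stops at branches.
    """
    mapped_ref = {r for r, _ in pairs}
    mapped_pred = {p for _, p in pairs}
    out = list(pairs)
    frontier = list(pairs)
    while frontier:
        r_idx, p_idx = frontier.pop()
        while True:
            r_next = [
                a.GetIdx()
                for a in ref_mol.GetAtomWithIdx(r_idx).GetNeighbors()
                if a.GetIdx() not in mapped_ref
            ]
            p_next = [
                a.GetIdx()
                for a in pred_mol.GetAtomWithIdx(p_idx).GetNeighbors()
                if a.GetIdx() not in mapped_pred
            ]
            if len(r_next) != 1 or len(p_next) != 1:
                break
            r_idx, p_idx = r_next[0], p_next[0]
            mapped_ref.add(r_idx)
            mapped_pred.add(p_idx)
            out.append((r_idx, p_idx))
    return out


def map_common_heavy_atoms(
    reference_ligand: LigandGraph,
    predicted_ligand: LigandGraph,
    mode: str = "identical",
    min_coverage: float = 0.5,
) -> AtomMapping:
    """Heavy-atom correspondence between reference and predicted ligands.

    ``identical`` requires a full graph bijection (same molecule). In
    ``modified`` mode the maximum common substructure anchors the mapping —
    covering all parent atoms for methyl additions — and linear-chain
    extension then maps replacement groups onto excised-group positions.
    Coverage below ``min_coverage`` of the reference heavy atoms raises.
    """
    ref_mol = reference_ligand.to_rdkit(with_coords=False)
    pred_mol = predicted_ligand.to_rdkit(with_coords=False)

    if mode == "identical":
        if ref_mol.GetNumAtoms() != pred_mol.GetNumAtoms():
            raise ValueError("ligands not comparable: different atom counts")
        match = pred_mol.GetSubstructMatch(ref_mol)
        if len(match) != ref_mol.GetNumAtoms():
            raise ValueError("ligands not comparable: graphs are not identical")
        pairs = [(i, match[i]) for i in range(len(match))]
        return AtomMapping(pairs=pairs, coverage=1.0)

    if mode != "modified":
        raise ValueError(f"unknown mapping mode {mode!r}")

    mcs = rdFMCS.FindMCS(
        [ref_mol, pred_mol],
        timeout=10,
        bondCompare=rdFMCS.BondCompare.CompareAny,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        matchValences=False,
        ringMatchesRingOnly=True,
    )
    core = Chem.MolFromSmarts(mcs.smartsString)
    if core is None or core.GetNumAtoms() == 0:
        raise ValueError("ligands not comparable: no common substructure")
    ref_match = ref_mol.GetSubstructMatch(core)
    pred_match = pred_mol.GetSubstructMatch(core)
    pairs = list(zip(ref_match, pred_match))
    pairs = _extend_along_chains(ref_mol, pred_mol, pairs)
    coverage = len({r for r, _ in pairs}) / max(reference_ligand.heavy_atom_count, 1)
    if coverage < min_coverage:
        raise ValueError(
            f"ligands not comparable: mapping covers {coverage:.0%} "
            f"of reference heavy atoms (< {min_coverage:.0%})"
        )
    return AtomMapping(pairs=pairs, coverage=coverage)


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------

def _reference_automorphisms(ref: LigandGraph, cap: int = AUTOMORPHISM_CAP):
    mol = ref.to_rdkit(with_coords=False)
    matches = mol.GetSubstructMatches(
        mol, uniquify=False, useChirality=False, maxMatches=cap + 1
    )
    if len(matches) > cap:
        warnings.warn(
            f"more than {cap} ligand automorphisms; falling back to the naive mapping"
        )
        return [tuple(range(mol.GetNumAtoms()))]
    return matches


def ligand_rmsd(
    predicted: LigandGraph,
    reference: LigandGraph,
    mapping: AtomMapping,
    symmetry: bool = True,
) -> float:
    """RMSD over mapped heavy-atom pairs, both ligands already in a common
    frame (after Cα superposition; no ligand-only refit).

    With ``symmetry`` the result is the minimum over reference-graph
    automorphisms consistent with the mapped atom set.
    """
    if not mapping.pairs:
        raise ValueError("empty atom mapping")
    ref_xyz = reference.coords
    pred_xyz = predicted.coords
    ref_idx = np.array([r for r, _ in mapping.pairs])
    pred_idx = np.array([p for _, p in mapping.pairs])

    def rmsd_for(ref_order: np.ndarray) -> float:
        d = ref_xyz[ref_order] - pred_xyz[pred_idx]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    best = rmsd_for(ref_idx)
    if symmetry:
        mapped_set = set(ref_idx.tolist())
        for perm in _reference_automorphisms(reference):
            order = np.array([perm[r] for r in ref_idx])
            if not set(order.tolist()) <= mapped_set:
                continue
            best = min(best, rmsd_for(order))
    return best


# --------------------------------------------------------------------------
# clashes
# --------------------------------------------------------------------------

@dataclass
class Clash:
    residue: tuple[str, int, str]
    protein_atom: str
    ligand_atom_index: int
    distance: float
    overlap: float


@dataclass
class ClashReport:
    clashes: list[Clash]

    @property
    def count(self) -> int:
        return len(self.clashes)

    @property
    def worst_overlap(self) -> float:
        return max((c.overlap for c in self.clashes), default=0.0)


def detect_clashes(
    cplx: ProteinLigandComplex, tolerance: float = 0.4
) -> ClashReport:
    """Protein/ligand heavy-atom pairs with distance < vdW_i + vdW_j − tol."""
    lig_xyz = cplx.ligand.coords
    if len(lig_xyz) == 0:
        return ClashReport(clashes=[])
    lig_radii = np.array(
        [VDW_RADII.get(a.element.upper(), DEFAULT_VDW) for a in cplx.ligand.atoms]
    )
    tree = cKDTree(lig_xyz)
    max_cut = float(lig_radii.max() + max(VDW_RADII.values()) - tolerance)
    clashes = []
    for res in cplx.iter_residues():
        for atom in res.atoms:
            r_p = VDW_RADII.get(atom.element.upper(), DEFAULT_VDW)
            for j in tree.query_ball_point(atom.coords, max_cut):
                dist = float(np.linalg.norm(atom.coords - lig_xyz[j]))
                limit = r_p + lig_radii[j] - tolerance
                if dist < limit:
                    clashes.append(
                        Clash(
                            residue=res.identity,
                            protein_atom=atom.name,
                            ligand_atom_index=j,
                            distance=dist,
                            overlap=float(limit - dist),
                        )
                    )
    return ClashReport(clashes=clashes)


# --------------------------------------------------------------------------
# per-prediction evaluation and dataset statistics
# --------------------------------------------------------------------------

@dataclass
class EvaluationRecord:
    spec_id: str
    kind: str
    ligand_rmsd: float
    conserved: bool
    n_clashes: int
    calpha_rmsd: Optional[float] = None
    ligand_confidence: Optional[float] = None


def evaluate_prediction(
    predicted: PredictedStructure,
    reference: ProteinLigandComplex,
    spec: ChallengeSpec,
    threshold: float = CONSERVATION_THRESHOLD,
    symmetry: bool = True,
) -> EvaluationRecord:
    """Score one prediction: superpose on Cα, map ligand atoms, compute
    RMSD/conservation, count clashes, summarize confidence."""
    transform, calpha = superpose_calpha(predicted.complex, reference)
    pred_ligand = predicted.complex.ligand.with_coords(
        transform.apply(predicted.complex.ligand.coords)
    )
    mode = "modified" if spec.kind in LIGAND_KINDS else "identical"
    mapping = map_common_heavy_atoms(reference.ligand, pred_ligand, mode=mode)
    rmsd = ligand_rmsd(pred_ligand, reference.ligand, mapping, symmetry=symmetry)
    clash_report = detect_clashes(predicted.complex)
    confidence = None
    if predicted.per_atom_confidence is not None:
        vals = np.asarray(predicted.per_atom_confidence, dtype=float)
        confidence = float(np.mean(vals[[p for _, p in mapping.pairs]]))
    return EvaluationRecord(
        spec_id=spec.spec_id,
        kind=spec.kind,
        ligand_rmsd=rmsd,
        conserved=bool(rmsd < threshold),
        n_clashes=clash_report.count,
        calpha_rmsd=calpha,
        ligand_confidence=confidence,
    )


@dataclass
class ConservationSummary:
    """Per-challenge pose-conservation fractions (and optional confidence
    stratification at a stated cutoff)."""

    fractions: dict[str, float]
    counts: dict[str, tuple[int, int]]  # kind -> (conserved, total)
    confidence_cutoff: Optional[float] = None
    stratified_fractions: dict[str, float] = field(default_factory=dict)
    stratified_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def conservation_stats(
    records: Sequence[EvaluationRecord],
    confidence_cutoff: Optional[float] = None,
) -> ConservationSummary:
    """Fraction of predictions with conserved pose, per challenge kind.

    With ``confidence_cutoff``, fractions are additionally computed over the
    records whose ligand confidence exceeds the cutoff.
    """
    if not records:
        raise ValueError("no evaluation records")

    def tally(subset: Iterable[EvaluationRecord]):
        counts: dict[str, list[int]] = {}
        for rec in subset:
            c = counts.setdefault(rec.kind, [0, 0])
            c[0] += int(rec.conserved)
            c[1] += 1
        fractions = {k: c[0] / c[1] for k, c in counts.items()}
        return fractions, {k: (c[0], c[1]) for k, c in counts.items()}

    fractions, counts = tally(records)
    summary = ConservationSummary(
        fractions=fractions, counts=counts, confidence_cutoff=confidence_cutoff
    )
    if confidence_cutoff is not None:
        high = [
            r
            for r in records
            if r.ligand_confidence is not None
            and r.ligand_confidence > confidence_cutoff
        ]
        if high:
            summary.stratified_fractions, summary.stratified_counts = tally(high)
    return summary
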