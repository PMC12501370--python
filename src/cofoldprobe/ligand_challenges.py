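"""Ligand-level adversarial modifications.

Two chemistry-editing schemes probe whether a co-folding model responds to
changes in the ligand itself:

* **progressive methylation** — hydroxyl groups of a sugar-like ligand are
  converted, one by one, into methyl ethers. Each step removes one
  hydrogen-bond donor and adds one heavy atom, eroding the polar contacts
  that drive sugar recognition while adding steric bulk.
* **triphosphate replacement** — the triphosphate tail of an ATP-like
  ligand (net charge −3 under the deprotonation convention used here) is
  excised at the O5' bridge and replaced by k neutral tert-butyl units or
  k positively charged choline-like quaternary-amine units, producing
  analogs with net formal charge 0 or +k that keep the adenosine core and
  a topologically similar tail.

Tanimoto similarity against the unmodified parent is tracked with a Morgan
(circular) fingerprint, radius 2 over 2048 bits.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .challenge import ChallengeSpec
from .core_structures import LigandGraph

__all__ = [
    "GLUCOSE_SMILES",
    "ATP_SMILES",
    "FINGERPRINT_RADIUS",
    "FINGERPRINT_BITS",
    "enumerate_hydroxyls",
    "methylate",
    "replace_triphosphate",
    "net_formal_charge",
    "tanimoto_similarity",
    "methylation_spec",
    "charge_spec",
]

#: beta-D-glucopyranose (five alcohol groups)
GLUCOSE_SMILES = "OC[C@H]1O[C@@H](O)[C@H](O)[C@@H](O)[C@@H]1O"

#: ATP with one protonated gamma-phosphate oxygen, giving net charge -3
ATP_SMILES = (
    "Nc1ncnc2n(cnc12)[C@@H]1O[C@H](COP(=O)([O-])OP(=O)([O-])OP(=O)(O)[O-])"
    "[C@@H](O)[C@H]1O"
)

FINGERPRINT_RADIUS = 2
FINGERPRINT_BITS = 2048


# --------------------------------------------------------------------------
# hydroxyl enumeration
# --------------------------------------------------------------------------

def _sugar_locants(mol: Chem.Mol) -> Optional[dict[int, int]]:
    """Carbon locants for a single-ring sugar-like molecule.

    The anomeric carbon (the ring-oxygen neighbour bearing an exocyclic
    hydroxyl) is C1; numbering proceeds around the ring away from the ring
    oxygen, and exocyclic carbons extend their parent's locant (e.g. C6 on
    C5 of a pyranose). Returns None when no unique single-oxygen ring exists.
    """
    ri = mol.GetRingInfo()
    sugar_rings = []
    for ring in ri.AtomRings():
        oxygens = [i for i in ring if mol.GetAtomWithIdx(i).GetSymbol() == "O"]
        if len(oxygens) == 1:
            sugar_rings.append((ring, oxygens[0]))
    if len(sugar_rings) != 1:
        return None
    ring, ring_o = sugar_rings[0]
    ring_set = set(ring)
    neighbors = [
        a.GetIdx()
        for a in mol.GetAtomWithIdx(ring_o).GetNeighbors()
        if a.GetIdx() in ring_set
    ]

    def has_exocyclic_oh(idx: int) -> bool:
        atom = mol.GetAtomWithIdx(idx)
        for nb in atom.GetNeighbors():
            if nb.GetIdx() in ring_set or nb.GetSymbol() != "O":
                continue
            if nb.GetTotalNumHs() >= 1 and nb.GetDegree() == 1:
                return True
        return False

    anomeric = next((i for i in neighbors if has_exocyclic_oh(i)), neighbors[0])

    # walk the ring from the anomeric carbon away from the ring oxygen
    locants: dict[int, int] = {}
    prev, cur, loc = ring_o, anomeric, 1
    while cur != ring_o:
        locants[cur] = loc
        nxt = next(
            a.GetIdx()
            for a in mol.GetAtomWithIdx(cur).GetNeighbors()
            if a.GetIdx() in ring_set and a.GetIdx() not in (prev, ring_o)
        ) if loc < len(ring) - 1 else ring_o
        prev, cur, loc = cur, nxt, loc + 1

    # exocyclic carbons inherit parent locant + 1 (C6 from C5 etc.)
    for idx, loc in sorted(locants.items(), key=lambda kv: kv[1]):
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            if nb.GetSymbol() == "C" and nb.GetIdx() not in locants:
                locants[nb.GetIdx()] = loc + 1
    return locants


def enumerate_hydroxyls(ligand: LigandGraph) -> list[int]:
    """Indices of hydroxyl oxygens, ordered by the locant of their carbon.

    A hydroxyl oxygen is bonded to exactly one heavy atom (a carbon) and
    carries at least one hydrogen. For sugar-like single-ring molecules the
    order follows carbon locants with the anomeric position first; otherwise
    canonical atom ranking of the attached carbon is used.
    """
    mol = ligand.to_rdkit(with_coords=False)
    hydroxyls = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "O" or atom.GetDegree() != 1:
            continue
        if atom.GetTotalNumHs() < 1 or atom.GetFormalCharge() != 0:
            continue
        carbon = atom.GetNeighbors()[0]
        if carbon.GetSymbol() == "C":
            hydroxyls.append((atom.GetIdx(), carbon.GetIdx()))

    locants = _sugar_locants(mol)
    if locants is None:
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        key = lambda pair: ranks[pair[1]]
    else:
        ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
        key = lambda pair: (locants.get(pair[1], 10_000), ranks[pair[1]])
    return [o for o, _ in sorted(hydroxyls, key=key)]


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------

def _place_new_atom(mol: Chem.Mol, anchor_idx: int) -> Optional[np.ndarray]:
    """Crude deterministic position for an atom appended at ``anchor_idx``:
    1.45 Å outward from the molecular centroid through the anchor."""
    if mol.GetNumConformers() == 0:
        return None
    conf = mol.GetConformer()
    xyz = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    anchor = xyz[anchor_idx]
    direction = anchor - xyz.mean(axis=0)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    return anchor + 1.45 * direction


def methylate(ligand: LigandGraph, n: int) -> LigandGraph:
    """Convert the first ``n`` hydroxyls (enumeration order) to methyl ethers.

    Adds exactly ``n`` heavy atoms and removes exactly ``n`` hydrogen-bond
    donors; formal charge is unchanged. Base-atom indices are preserved, so
    the methylation series is nested under the identity mapping.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        import copy

        return copy.deepcopy(ligand)
    positions = enumerate_hydroxyls(ligand)
    if n > len(positions):
        raise ValueError(
            f"requested {n} methylations but only {len(positions)} hydroxyls "
            "are available"
        )
    mol = ligand.to_rdkit()
    rw = Chem.RWMol(mol)
    conf = rw.GetConformer() if rw.GetNumConformers() else None
    for o_idx in positions[:n]:
        c_idx = rw.AddAtom(Chem.Atom("C"))
        rw.AddBond(o_idx, c_idx, Chem.BondType.SINGLE)
        if conf is not None:
            pos = _place_new_atom(mol, o_idx)
            conf.SetAtomPosition(c_idx, pos.tolist())
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    result = LigandGraph.from_rdkit(out)
    result.coords_present = ligand.coords_present
    return result


# --------------------------------------------------------------------------
# triphosphate replacement
# --------------------------------------------------------------------------

def _find_triphosphate(mol: Chem.Mol) -> tuple[list[int], int]:
    """Locate the phosphate tail: returns (atoms to delete, anchor O index).

    The anchor is the carbon-bonded bridging oxygen (O5' in ATP); deleted
    atoms are all phosphorus atoms plus every oxygen bonded only to
    phosphorus.
    """
    p_atoms = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "P"]
    if not p_atoms:
        raise ValueError("no phosphate chain found in ligand")
    doomed = set(p_atoms)
    anchor = None
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "O":
            continue
        heavy_nbrs = [nb for nb in atom.GetNeighbors()]
        symbols = {nb.GetSymbol() for nb in heavy_nbrs}
        if symbols <= {"P"}:
            doomed.add(atom.GetIdx())
        elif "P" in symbols and "C" in symbols:
            anchor = atom.GetIdx()
    if anchor is None:
        raise ValueError("phosphate chain has no carbon-bonded bridge oxygen")
    return sorted(doomed), anchor


def replace_triphosphate(
    ligand: LigandGraph, replacement: str, k: int
) -> LigandGraph:
    """Swap the phosphate tail for ``k`` replacement units.

    ``quaternary_amine`` attaches choline-like units
    (-CH2-CH2-N+(CH3)2-)... with a trimethylated terminal nitrogen, one +1
    charge per unit; ``tert_butyl`` attaches branched neutral C4 units with
    matching topology. The nucleoside core is untouched.
    """
    if replacement not in {"tert_butyl", "quaternary_amine"}:
        raise ValueError(f"unsupported replacement {replacement!r}")
    if not 1 <= k <= 3:
        raise ValueError(f"unsupported k={k}; expected 1..3")

    mol = ligand.to_rdkit()
    doomed, anchor = _find_triphosphate(mol)
    rw = Chem.RWMol(mol)
    keep_coords = rw.GetNumConformers() > 0

    # deleting atoms reindexes; delete in descending order and track anchor
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
        if idx < anchor:
            anchor -= 1

    def add_atom(symbol: str, bond_to: int, charge: int = 0) -> int:
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        idx = rw.AddAtom(a)
        rw.AddBond(bond_to, idx, Chem.BondType.SINGLE)
        if keep_coords:
            pos = _place_new_atom(rw.GetMol(), bond_to)
            rw.GetConformer().SetAtomPosition(idx, pos.tolist())
        return idx

    prev = anchor
    for unit in range(1, k + 1):
        terminal = unit == k
        if replacement == "quaternary_amine":
            c1 = add_atom("C", prev)
            c2 = add_atom("C", c1)
            nq = add_atom("N", c2, charge=+1)
            n_methyls = 3 if terminal else 2
            for _ in range(n_methyls):
                add_atom("C", nq)
            prev = nq
        else:  # tert_butyl
            cq = add_atom("C", prev)
            n_methyls = 3 if terminal else 2
            for _ in range(n_methyls):
                add_atom("C", cq)
            if not terminal:
                prev = add_atom("C", cq)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    result = LigandGraph.from_rdkit(out)
    result.coords_present = ligand.coords_present
    return result


def net_formal_charge(ligand: LigandGraph) -> int:
    """Sum of atomic formal charges."""
    return ligand.net_formal_charge


# --------------------------------------------------------------------------
# similarity
# --------------------------------------------------------------------------

def _fingerprint(ligand: LigandGraph):
    if not ligand.atoms:
        raise ValueError("empty ligand graph")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_BITS
    )
    return gen.GetFingerprint(ligand.to_rdkit(with_coords=False))


def tanimoto_similarity(a: LigandGraph, b: LigandGraph) -> float:
    """Morgan-fingerprint Tanimoto coefficient in [0, 1]."""
    return float(DataStructs.TanimotoSimilarity(_fingerprint(a), _fingerprint(b)))


# --------------------------------------------------------------------------
# spec builders
# --------------------------------------------------------------------------

def methylation_spec(
    base: LigandGraph, n: int, parent: str,
    wild_sequences: Optional[dict[str, str]] = None,
) -> ChallengeSpec:
    """ChallengeSpec for the n-methyl member of the methylation series."""
    modified = methylate(base, n)
    return ChallengeSpec(
        kind="methylation",
        parent=parent,
        mutated_sequence=dict(wild_sequences or {}),
        modified_ligand=modified,
        params={
            "n_methyls": n,
            "net_charge": modified.net_formal_charge,
            "tanimoto_to_base": round(tanimoto_similarity(base, modified), 4),
        },
    )


def charge_spec(
    base: LigandGraph, replacement: str, k: int, parent: str,
    wild_sequences: Optional[dict[str, str]] = None,
) -> ChallengeSpec:
    """ChallengeSpec for one member of the charge-replacement series."""
    modified = replace_triphosphate(base, replacement, k)
    return ChallengeSpec(
        kind="charge",
        parent=parent,
        mutated_sequence=dict(wild_sequences or {}),
        modified_ligand=modified,
        params={
            "replacement": replacement,
            "k_groups": k,
            "net_charge": modified.net_formal_charge,
            "tanimoto_to_base": round(tanimoto_similarity(base, modified), 4),
        },
    )
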