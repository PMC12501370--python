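"""Domain model and I/O for protein-ligand complexes.

This module carries the package's central containers — :class:`Atom`,
:class:`Residue`, :class:`LigandGraph`, :class:`ProteinLigandComplex`,
:class:`PredictedStructure` — together with structure reading/writing
(PDB/mmCIF via gemmi), sequence extraction, and emission of tool-agnostic
prediction-job bundles (FASTA + SDF + SMILES + JSON manifest) that external
co-folding tools consume.

Conventions: hydrogens are dropped on read (all downstream criteria are
stated on heavy atoms); alternate locations are resolved to the highest
occupancy (tie broken by file order); waters and monoatomic ions are
stripped. Residues are identified by author numbering plus insertion code
plus chain id throughout.
"""

from __future__ import annotations

import copy as _copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ._aminoacids import BACKBONE_ATOMS, STANDARD_CODES, one_letter

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

__all__ = [
    "Atom",
    "Residue",
    "LigandGraph",
    "ProteinLigandComplex",
    "PredictedStructure",
    "read_complex",
    "write_complex",
    "extract_sequence",
    "emit_jobs",
    "read_job",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """A heavy atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"unknown element symbol {self.element!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue, identified by author numbering within its chain."""

    chain_id: str
    number: int
    insertion_code: str
    code3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.code3 in STANDARD_CODES

    @property
    def identity(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def side_chain_atoms(self) -> list[Atom]:
        """Heavy atoms excluding the N/CA/C/O(/OXT) backbone."""
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        return f"{one_letter(self.code3)}{self.number}{self.insertion_code.strip()}"


_BOND_TYPES = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    1.5: Chem.BondType.AROMATIC,
}


@dataclass
class LigandGraph:
    """Molecular graph of a small molecule (heavy atoms only).

    Bond orders are stored kekulized; ``canonical_string`` is the canonical
    SMILES when the graph sanitizes, otherwise empty.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    canonical_string: str = ""
    coords_present: bool = True

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond indices ({i}, {j}) for {n} atoms")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "LigandGraph":
        mol = Chem.RemoveHs(mol)
        canonical = Chem.MolToSmiles(mol)
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        conf = mol.GetConformer() if mol.GetNumConformers() else None
        atoms = []
        for at in mol.GetAtoms():
            xyz = (
                np.array(conf.GetAtomPosition(at.GetIdx()))
                if conf is not None
                else np.zeros(3)
            )
            info = at.GetPDBResidueInfo()
            name = info.GetName().strip() if info else f"{at.GetSymbol()}{at.GetIdx() + 1}"
            atoms.append(
                Atom(
                    name=name,
                    element=at.GetSymbol(),
                    coords=xyz,
                    formal_charge=at.GetFormalCharge(),
                )
            )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in kek.GetBonds()
        ]
        return cls(
            atoms=atoms,
            bonds=bonds,
            canonical_string=canonical,
            coords_present=conf is not None,
        )

    @classmethod
    def from_smiles(cls, smiles: str) -> "LigandGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smiles!r}")
        return cls.from_rdkit(mol)

    @classmethod
    def from_sdf(cls, path: str | Path) -> "LigandGraph":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        mols = [m for m in supplier if m is not None]
        if not mols:
            raise ValueError(f"no parsable molecule in {path}")
        return cls.from_rdkit(mols[0])

    # -- conversions -------------------------------------------------------
    def to_rdkit(self, sanitize: bool = True, with_coords: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.formal_charge)
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            rw.AddBond(int(i), int(j), _BOND_TYPES.get(order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        if with_coords and self.coords_present:
            conf = Chem.Conformer(len(self.atoms))
            for idx, atom in enumerate(self.atoms):
                conf.SetAtomPosition(idx, atom.coords.tolist())
            mol.AddConformer(conf, assignId=True)
        return mol

    def to_dict(self) -> dict:
        return {
            "atoms": [
                [a.name, a.element, [round(float(x), 4) for x in a.coords], a.formal_charge]
                for a in self.atoms
            ],
            "bonds": [[int(i), int(j), float(o)] for i, j, o in self.bonds],
            "canonical_string": self.canonical_string,
            "coords_present": self.coords_present,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LigandGraph":
        atoms = [
            Atom(name=n, element=e, coords=np.array(xyz), formal_charge=int(q))
            for n, e, xyz, q in payload["atoms"]
        ]
        bonds = [(int(i), int(j), float(o)) for i, j, o in payload["bonds"]]
        return cls(
            atoms=atoms,
            bonds=bonds,
            canonical_string=payload.get("canonical_string", ""),
            coords_present=bool(payload.get("coords_present", True)),
        )

    def write_sdf(self, path: str | Path) -> None:
        mol = self.to_rdkit()
        if not self.coords_present:
            AllChem.Compute2DCoords(mol)
        writer = Chem.SDWriter(str(path))
        writer.write(mol)
        writer.close()

    # -- properties --------------------------------------------------------
    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def net_formal_charge(self) -> int:
        return int(sum(a.formal_charge for a in self.atoms))

    def with_coords(self, xyz: np.ndarray) -> "LigandGraph":
        """Copy of the graph with replacement coordinates."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        out = _copy.deepcopy(self)
        for atom, row in zip(out.atoms, xyz):
            atom.coords = np.asarray(row, dtype=float)
        out.coords_present = True
        return out

    def validate(self) -> None:
        """Valence sanity via sanitization plus canonical round-trip."""
        self.to_rdkit(sanitize=True, with_coords=False)
        if self.canonical_string:
            mol = Chem.MolFromSmiles(self.canonical_string)
            if mol is None or Chem.MolToSmiles(mol) != self.canonical_string:
                raise ValueError("canonical string does not round-trip")

    def is_connected(self) -> bool:
        frags = Chem.GetMolFrags(self.to_rdkit(sanitize=False, with_coords=False))
        return len(frags) == 1


@dataclass
class ProteinLigandComplex:
    """Protein chains plus one designated ligand (and untouched cofactors)."""

    chains: dict[str, list[Residue]]
    ligand: LigandGraph
    ligand_code: str
    source_id: str
    cofactors: list[LigandGraph] = field(default_factory=list)

    def iter_residues(self) -> Iterator[Residue]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def residue(self, chain_id: str, number: int, insertion_code: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.number == number and res.insertion_code == insertion_code:
                return res
        raise KeyError(f"residue {chain_id}/{number}{insertion_code} not found")

    def protein_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(res, a) for res in self.iter_residues() for a in res.atoms]

    def copy(self) -> "ProteinLigandComplex":
        return _copy.deepcopy(self)


@dataclass
class PredictedStructure:
    """A predictor's output for one challenge job.

    Confidence values (e.g. per-atom pLDDT) are consumed as given numbers on
    a 0-100 scale; this package never produces them itself.
    """

    complex: ProteinLigandComplex
    per_atom_confidence: Optional[list[float]] = None
    complex_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.per_atom_confidence is not None:
            vals = np.asarray(self.per_atom_confidence, dtype=float)
            if vals.size != len(self.complex.ligand.atoms):
                raise ValueError("per-atom confidence length != ligand atom count")
            if np.any((vals < 0) | (vals > 100)):
                raise ValueError("confidence values must lie in [0, 100]")
        if self.complex_confidence is not None and not (
            0 <= self.complex_confidence <= 100
        ):
            raise ValueError("complex confidence must lie in [0, 100]")


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties keep file order."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        key = at.name
        if key not in best:
            best[key] = at
            order.append(key)
        elif at.occ > best[key].occ:
            best[key] = at
    return [best[k] for k in order]


def _ligand_graph_from_gemmi(
    res: gemmi.Residue, template_smiles: Optional[str] = None
) -> LigandGraph:
    """Build a ligand graph from a structure residue.

    Bond orders come from a template SMILES when supplied; otherwise
    connectivity is perceived from interatomic distances (single bonds).
    """
    picked = [a for a in _pick_altlocs(res) if a.element.name != "H"]
    xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in picked])
    rw = Chem.RWMol()
    for a in picked:
        atom = Chem.Atom(a.element.name)
        atom.SetNoImplicit(True)
        info = Chem.AtomPDBResidueInfo()
        info.SetName(f" {a.name:<3s}"[:4])
        atom.SetPDBResidueInfo(info)
        rw.AddAtom(atom)
    conf = Chem.Conformer(len(picked))
    for idx, row in enumerate(xyz):
        conf.SetAtomPosition(idx, row.tolist())
    mol = rw.GetMol()
    mol.AddConformer(conf)
    from rdkit.Chem import rdDetermineBonds

    try:
        rdDetermineBonds.DetermineConnectivity(mol)
    except Exception:
        pass
    if template_smiles:
        template = Chem.MolFromSmiles(template_smiles)
        if template is None:
            raise ValueError(f"unparsable template SMILES {template_smiles!r}")
        try:
            mol = AllChem.AssignBondOrdersFromTemplate(template, mol)
        except Exception:
            warnings.warn(
                f"template assignment failed for {res.name}; keeping perceived bonds"
            )
    try:
        Chem.SanitizeMol(mol)
        return LigandGraph.from_rdkit(mol)
    except Exception:
        # fall back to an order-less graph that still carries names/coords
        atoms = [
            Atom(name=a.name, element=a.element.name, coords=row, occupancy=a.occ)
            for a, row in zip(picked, xyz)
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), 1.0) for b in mol.GetBonds()
        ]
        return LigandGraph(atoms=atoms, bonds=bonds, canonical_string="")


def read_complex(
    path: str | Path,
    ligand_code: str,
    chain_filter: Optional[str] = None,
    ligand_template: Optional[str] = None,
    source_id: Optional[str] = None,
) -> ProteinLigandComplex:
    """Read a PDB/mmCIF file and extract protein chains plus one ligand.

    Waters and monoatomic ions are discarded; other hetero components are
    retained as cofactors. ``ligand_code`` must resolve to exactly one copy
    after applying ``chain_filter``; otherwise a descriptive error is raised.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_hydrogens()
    model = st[0]

    chains: dict[str, list[Residue]] = {}
    ligand_hits: list[tuple[str, gemmi.Residue]] = []
    cofactors: list[LigandGraph] = []

    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            if name in WATER_NAMES:
                continue
            tab = gemmi.find_tabulated_residue(res.name)
            is_amino = name in STANDARD_CODES or (
                tab is not None and tab.is_amino_acid()
            )
            if is_amino:
                picked = [a for a in _pick_altlocs(res) if a.element.name != "H"]
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=min(max(a.occ, 0.0), 1.0),
                    )
                    for a in picked
                ]
                chains.setdefault(chain.name, []).append(
                    Residue(
                        chain_id=chain.name,
                        number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        code3=name,
                        atoms=atoms,
                    )
                )
                continue
            if name == ligand_code.upper():
                if chain_filter is None or chain.name == chain_filter:
                    ligand_hits.append((chain.name, res))
                continue
            heavy = [a for a in res if a.element.name != "H"]
            if len(heavy) <= 1:
                continue  # monoatomic ion
            cofactors.append(_ligand_graph_from_gemmi(res))

    if not ligand_hits:
        raise ValueError(f"ligand not found: {ligand_code!r} in {path.name}")
    if len(ligand_hits) > 1:
        where = ", ".join(f"{c}/{r.seqid.num}" for c, r in ligand_hits)
        raise ValueError(
            f"ambiguous ligand {ligand_code!r}: candidates {where}; pass chain_filter"
        )

    lig_chain, lig_res = ligand_hits[0]
    ligand = _ligand_graph_from_gemmi(lig_res, template_smiles=ligand_template)
    sid = source_id or (st.name.strip() if st.name.strip() else path.stem)
    return ProteinLigandComplex(
        chains=chains,
        ligand=ligand,
        ligand_code=ligand_code.upper(),
        source_id=sid,
        cofactors=cofactors,
    )


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def write_complex(cplx: ProteinLigandComplex, path: str | Path) -> None:
    """Write a complex to PDB (default) or mmCIF (``.cif`` suffix)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = cplx.source_id
    model = gemmi.Model("1")

    for chain_id, residues in cplx.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.code3
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coords)
                gat.occ = atom.occupancy
                gres.add_atom(gat)
            chain.add_residue(gres)
        model.add_chain(chain)

    lig_chain = gemmi.Chain("X")
    for seq, (code, graph) in enumerate(
        [(cplx.ligand_code, cplx.ligand)]
        + [("UNL", g) for g in cplx.cofactors],
        start=1,
    ):
        gres = gemmi.Residue()
        gres.name = code
        gres.seqid = gemmi.SeqId(seq, " ")
        gres.het_flag = "H"
        for atom in graph.atoms:
            gat = gemmi.Atom()
            gat.name = atom.name[:4]
            gat.element = gemmi.Element(atom.element)
            gat.pos = gemmi.Position(*atom.coords)
            gat.occ = 1.0
            gres.add_atom(gat)
        lig_chain.add_residue(gres)
    model.add_chain(lig_chain)

    st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

def extract_sequence(
    cplx: ProteinLigandComplex, chain_id: str
) -> tuple[str, dict[int, tuple[int, str]]]:
    """One-letter sequence of a chain plus a 1-based index -> author-number map.

    Nonstandard residues are emitted as ``X`` with a warning. The map is a
    bijection between sequence position and (author number, insertion code)
    in order of appearance.
    """
    if not chain_id:
        raise ValueError("empty chain id")
    if chain_id not in cplx.chains:
        raise KeyError(f"unknown chain {chain_id!r}")
    letters = []
    index_map: dict[int, tuple[int, str]] = {}
    for pos, res in enumerate(cplx.chains[chain_id], start=1):
        if not res.is_standard:
            warnings.warn(
                f"nonstandard residue {res.code3} at {chain_id}/{res.number}; using X"
            )
        letters.append(one_letter(res.code3))
        index_map[pos] = (res.number, res.insertion_code)
    return "".join(letters), index_map


# --------------------------------------------------------------------------
# job emission
# --------------------------------------------------------------------------

def emit_jobs(
    suite: Sequence,
    out_dir: str | Path,
    ligand: Optional[LigandGraph] = None,
) -> list[Path]:
    """Write one prediction-job directory per challenge spec.

    Each directory holds ``job.fasta`` (per-chain mutated sequences),
    ``ligand.sdf`` and ``ligand.smi`` (the modified ligand, or the supplied
    base ligand when the spec leaves the ligand untouched), and
    ``manifest.json`` from which the spec round-trips losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in suite:
        if (
            spec.kind != "wild_type"
            and not spec.mutations
            and spec.modified_ligand is None
        ):
            raise ValueError(
                f"spec {spec.spec_id}: no sequence or ligand change and not wild-type"
            )
        if not spec.mutated_sequence:
            raise ValueError(f"spec {spec.spec_id}: missing sequence")
        job_dir = out_dir / spec.spec_id
        job_dir.mkdir(parents=True, exist_ok=True)

        with open(job_dir / "job.fasta", "w") as fh:
            for chain_id in sorted(spec.mutated_sequence):
                fh.write(f">{spec.parent}_{chain_id}_{spec.kind}\n")
                fh.write(spec.mutated_sequence[chain_id] + "\n")

        job_ligand = spec.modified_ligand or ligand
        manifest = {
            "spec": spec.to_dict(),
            "challenge": spec.kind,
            "parent": spec.parent,
            "ligand_net_charge": (
                job_ligand.net_formal_charge if job_ligand else None
            ),
        }
        if job_ligand is not None:
            job_ligand.write_sdf(job_dir / "ligand.sdf")
            (job_dir / "ligand.smi").write_text(
                (job_ligand.canonical_string or "") + "\n"
            )
        (job_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        paths.append(job_dir)
    return paths


def read_job(job_dir: str | Path):
    """Reconstruct the :class:`~cofoldprobe.challenge.ChallengeSpec` of a job."""
    from .challenge import ChallengeSpec

    manifest = json.loads((Path(job_dir) / "manifest.json").read_text())
    return ChallengeSpec.from_dict(manifest["spec"])
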