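"""Binding-site detection and sequence-level adversarial challenges.

Three perturbation schemes are applied to the residues whose side-chain
heavy atoms contact the ligand:

* **removal** — every site residue becomes glycine, deleting the side-chain
  interactions that drive recognition;
* **packing** — every site residue becomes phenylalanine, crowding the
  pocket with bulk;
* **inversion** — every site residue is replaced by the standard
  maximally-dissimilar partner under the Miyata amino-acid distance, which
  combines normalized polarity and volume differences:

  .. math:: d_{ij} = \\sqrt{(\\Delta p_{ij}/\\sigma_p)^2
                            + (\\Delta v_{ij}/\\sigma_v)^2}

The default property table uses the Grantham (1974) polarity and volume
scales underlying Miyata et al. (1979), with :math:`\\sigma_p` and
:math:`\\sigma_v` the population standard deviations of the property
differences over the 190 unordered amino-acid pairs. This normalization
reproduces the published pairwise distances of the dissimilarity assignment
to two decimals; tables that fail that check are refused by
:func:`MiyataPropertyTable.validated`.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from ._aminoacids import SIDE_CHAIN_ATOMS, STANDARD_CODES
from .challenge import ChallengeSpec, Mutation
from .core_structures import ProteinLigandComplex, extract_sequence

__all__ = [
    "MiyataPropertyTable",
    "BindingSite",
    "ChallengeSpec",
    "Mutation",
    "DISSIMILAR_MAP",
    "REFERENCE_DISTANCES",
    "detect_binding_site",
    "miyata_distance",
    "assign_dissimilar",
    "apply_site_challenge",
    "build_suite",
]

# Grantham (1974) polarity scale
_POLARITY = {
    "ALA": 8.1, "ARG": 10.5, "ASN": 11.6, "ASP": 13.0, "CYS": 5.5,
    "GLN": 10.5, "GLU": 12.3, "GLY": 9.0, "HIS": 10.4, "ILE": 5.2,
    "LEU": 4.9, "LYS": 11.3, "MET": 5.7, "PHE": 5.2, "PRO": 8.0,
    "SER": 9.2, "THR": 8.6, "TRP": 5.4, "TYR": 6.2, "VAL": 5.9,
}
# Grantham (1974) side-chain volume scale
_VOLUME = {
    "ALA": 31.0, "ARG": 124.0, "ASN": 56.0, "ASP": 54.0, "CYS": 55.0,
    "GLN": 85.0, "GLU": 83.0, "GLY": 3.0, "HIS": 96.0, "ILE": 111.0,
    "LEU": 111.0, "LYS": 119.0, "MET": 105.0, "PHE": 132.0, "PRO": 32.5,
    "SER": 32.0, "THR": 61.0, "TRP": 170.0, "TYR": 136.0, "VAL": 84.0,
}

#: fixed dissimilar-residue assignment (large/apolar <-> small/polar swaps)
DISSIMILAR_MAP = {
    "TYR": "GLY", "TRP": "GLY", "LYS": "GLY", "ARG": "GLY",
    "VAL": "ASP", "LEU": "ASP", "ILE": "ASP", "MET": "ASP", "PHE": "ASP",
    "ALA": "TRP", "GLY": "TRP", "PRO": "TRP", "HIS": "TRP", "ASP": "TRP",
    "GLU": "TRP", "CYS": "TRP", "ASN": "TRP", "GLN": "TRP", "THR": "TRP",
    "SER": "TRP",
}

#: published Miyata distances for each assignment pair (2 decimals)
REFERENCE_DISTANCES = {
    ("TYR", "GLY"): 4.08, ("TRP", "GLY"): 5.13, ("LYS", "GLY"): 3.54,
    ("ARG", "GLY"): 3.58, ("VAL", "ASP"): 3.40, ("LEU", "ASP"): 4.10,
    ("ILE", "ASP"): 3.98, ("MET", "ASP"): 3.69, ("PHE", "ASP"): 4.27,
    ("ALA", "TRP"): 4.23, ("GLY", "TRP"): 5.13, ("PRO", "TRP"): 4.17,
    ("HIS", "TRP"): 3.16, ("ASP", "TRP"): 4.88, ("GLU", "TRP"): 4.08,
    ("CYS", "TRP"): 3.34, ("ASN", "TRP"): 4.39, ("GLN", "TRP"): 3.42,
    ("THR", "TRP"): 3.50, ("SER", "TRP"): 4.38,
}


@dataclass(frozen=True)
class MiyataPropertyTable:
    """Per-amino-acid polarity/volume plus the normalizing deviations."""

    polarity: dict[str, float]
    volume: dict[str, float]
    sigma_p: float
    sigma_v: float

    def __post_init__(self) -> None:
        missing = STANDARD_CODES - set(self.polarity) | STANDARD_CODES - set(self.volume)
        if missing:
            raise ValueError(f"property table missing amino acids: {sorted(missing)}")
        if self.sigma_p <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_p and sigma_v must be positive")

    @classmethod
    def from_properties(
        cls,
        polarity: dict[str, float],
        volume: dict[str, float],
        sigma_p: Optional[float] = None,
        sigma_v: Optional[float] = None,
    ) -> "MiyataPropertyTable":
        """Build a table; missing sigmas are the population standard
        deviations of |Δp| and |Δv| over the 190 unordered pairs."""
        pairs = list(itertools.combinations(sorted(STANDARD_CODES), 2))
        if sigma_p is None:
            sigma_p = float(np.std([abs(polarity[a] - polarity[b]) for a, b in pairs]))
        if sigma_v is None:
            sigma_v = float(np.std([abs(volume[a] - volume[b]) for a, b in pairs]))
        return cls(polarity=dict(polarity), volume=dict(volume),
                   sigma_p=sigma_p, sigma_v=sigma_v)

    @classmethod
    def default(cls) -> "MiyataPropertyTable":
        return cls.from_properties(_POLARITY, _VOLUME)

    def check(self) -> bool:
        """True iff the table reproduces all published assignment distances
        at two decimals."""
        return all(
            round(miyata_distance(a, b, self), 2) == d
            for (a, b), d in REFERENCE_DISTANCES.items()
        )

    @classmethod
    def validated(cls, table: Optional["MiyataPropertyTable"] = None) -> "MiyataPropertyTable":
        """Return a table guaranteed to match the published distances;
        refuses (raises) any property set that fails the check."""
        table = table or cls.default()
        if not table.check():
            raise ValueError(
                "property table does not reproduce the published Miyata "
                "dissimilarity distances at 2 decimals; refusing it"
            )
        return table


def miyata_distance(
    aa_i: str, aa_j: str, table: Optional[MiyataPropertyTable] = None
) -> float:
    """Miyata distance d_ij between two amino acids (3-letter codes)."""
    if table is None:
        table = MiyataPropertyTable.default()
    aa_i, aa_j = aa_i.upper(), aa_j.upper()
    for aa in (aa_i, aa_j):
        if aa not in STANDARD_CODES:
            raise ValueError(f"unknown amino-acid code {aa!r}")
        if aa not in table.polarity or aa not in table.volume:
            raise ValueError(f"amino acid {aa!r} missing from property table")
    dp = (table.polarity[aa_i] - table.polarity[aa_j]) / table.sigma_p
    dv = (table.volume[aa_i] - table.volume[aa_j]) / table.sigma_v
    return math.sqrt(dp * dp + dv * dv)


def assign_dissimilar(aa: str) -> str:
    """Fixed dissimilar-partner assignment for the inversion challenge."""
    aa = aa.upper()
    if aa not in STANDARD_CODES:
        raise ValueError(f"unknown amino-acid code {aa!r}")
    return DISSIMILAR_MAP[aa]


# --------------------------------------------------------------------------
# binding-site detection
# --------------------------------------------------------------------------

@dataclass
class BindingSite:
    """Residues whose side-chain heavy atoms contact the ligand."""

    residues: list[tuple[str, int, str, str]]  # (chain, number, icode, code3)
    cutoff: float = 3.5
    ligand_code: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def identities(self) -> list[tuple[str, int, str]]:
        return [(c, n, i) for c, n, i, _ in self.residues]

    @property
    def labels(self) -> list[str]:
        from ._aminoacids import one_letter

        return [f"{one_letter(code)}{num}{ic.strip()}" for _, num, ic, code in self.residues]


def detect_binding_site(
    cplx: ProteinLigandComplex,
    cutoff: float = 3.5,
    inclusive: bool = True,
) -> BindingSite:
    """Select residues with >=1 side-chain heavy atom within ``cutoff`` Å of
    any ligand heavy atom.

    Glycine can never qualify: it has no side-chain heavy atoms. Residues
    with partially missing side chains are evaluated on the atoms present
    (with a warning). The comparison is inclusive (<=) by default.
    """
    if not cplx.ligand.coords_present or not cplx.ligand.atoms:
        raise ValueError("ligand has no coordinates; cannot detect binding site")
    tree = cKDTree(cplx.ligand.coords)
    hits = []
    for res in cplx.iter_residues():
        side = res.side_chain_atoms
        if res.is_standard and len(side) < len(SIDE_CHAIN_ATOMS.get(res.code3, [])):
            warnings.warn(
                f"residue {res.chain_id}/{res.number} {res.code3}: "
                f"{len(side)}/{len(SIDE_CHAIN_ATOMS[res.code3])} side-chain atoms "
                "present; evaluating on the atoms present"
            )
        if not side:
            continue
        dmin = min(tree.query(a.coords)[0] for a in side)
        if (dmin <= cutoff) if inclusive else (dmin < cutoff):
            hits.append((res.chain_id, res.number, res.insertion_code, res.code3))
    hits.sort(key=lambda t: (t[0], t[1], t[2]))
    return BindingSite(residues=hits, cutoff=cutoff, ligand_code=cplx.ligand_code)


# --------------------------------------------------------------------------
# challenge application
# --------------------------------------------------------------------------

_SITE_TARGET = {
    "removal": lambda aa: "GLY",
    "packing": lambda aa: "PHE",
    "inversion": assign_dissimilar,
}


def apply_site_challenge(
    cplx: ProteinLigandComplex,
    site: BindingSite,
    kind: str,
) -> ChallengeSpec:
    """Mutate every site residue per the challenge scheme; nothing else.

    Sequence length is always preserved (substitutions only).
    """
    if kind not in _SITE_TARGET:
        raise ValueError(f"unknown site challenge kind {kind!r}")
    if not site.residues:
        raise ValueError("empty binding site")

    mutations = []
    for chain_id, number, icode, code3 in site.residues:
        try:
            res = cplx.residue(chain_id, number, icode)
        except KeyError:
            raise ValueError(
                f"site residue {chain_id}/{number}{icode} missing from complex"
            ) from None
        target = _SITE_TARGET[kind](res.code3)
        mutations.append(Mutation(chain_id, number, icode, res.code3, target))

    mutated_sequence = {}
    for chain_id in cplx.chains:
        seq, index_map = extract_sequence(cplx, chain_id)
        rev = {v: k for k, v in index_map.items()}
        letters = list(seq)
        for m in mutations:
            if m.chain == chain_id:
                from ._aminoacids import one_letter

                letters[rev[(m.number, m.insertion_code)] - 1] = one_letter(m.new)
        mutated_sequence[chain_id] = "".join(letters)

    return ChallengeSpec(
        kind=kind,
        parent=cplx.source_id,
        mutations=mutations,
        mutated_sequence=mutated_sequence,
    )


def build_suite(cplx: ProteinLigandComplex, cutoff: float = 3.5) -> list[ChallengeSpec]:
    """Ordered challenge suite: wild-type, removal, packing, inversion.

    A complex whose detected site is empty yields the wild-type spec only
    (with a warning).
    """
    site = detect_binding_site(cplx, cutoff=cutoff)
    wild_sequences = {c: extract_sequence(cplx, c)[0] for c in cplx.chains}
    suite = [
        ChallengeSpec(kind="wild_type", parent=cplx.source_id,
                      mutated_sequence=wild_sequences)
    ]
    if not site.residues:
        warnings.warn(f"{cplx.source_id}: empty binding site; wild-type suite only")
        return suite
    for kind in ("removal", "packing", "inversion"):
        spec = apply_site_challenge(cplx, site, kind)
        spec.params["site"] = site.labels
        suite.append(spec)
    return suite
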