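"""Challenge specifications: one adversarial perturbation of a complex.

A :class:`ChallengeSpec` bundles either a set of binding-site point mutations
(sequence-level challenge) or a chemically modified ligand (ligand-level
challenge), together with everything a downstream co-folding job needs:
the mutated per-chain sequences, the modified ligand graph, and bookkeeping
identifiers. Wild-type specs carry neither change and act as controls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from ._aminoacids import STANDARD_CODES, one_letter
from .core_structures import LigandGraph

SITE_KINDS = ("removal", "packing", "inversion")
LIGAND_KINDS = ("methylation", "charge")
ALL_KINDS = ("wild_type",) + SITE_KINDS + LIGAND_KINDS


class Mutation(NamedTuple):
    """A single point mutation identified by author residue numbering."""

    chain: str
    number: int
    insertion_code: str
    wt: str   # 3-letter wild-type code
    new: str  # 3-letter replacement code

    @property
    def label(self) -> str:
        """Compact 'I10D'-style label (1-letter codes, author number)."""
        return f"{one_letter(self.wt)}{self.number}{self.insertion_code.strip()}{one_letter(self.new)}"


@dataclass
class ChallengeSpec:
    """One adversarial perturbation plus the derived sequence/ligand."""

    kind: str
    parent: str
    mutations: list[Mutation] = field(default_factory=list)
    mutated_sequence: dict[str, str] = field(default_factory=dict)
    modified_ligand: Optional[LigandGraph] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown challenge kind {self.kind!r}")
        if self.kind == "wild_type" and self.mutations:
            raise ValueError("wild-type spec must carry no mutations")
        if self.kind in LIGAND_KINDS and self.mutations:
            raise ValueError("ligand challenges must not mutate the sequence")
        for m in self.mutations:
            if m.wt not in STANDARD_CODES or m.new not in STANDARD_CODES:
                raise ValueError(f"non-standard residue code in mutation {m}")

    @property
    def spec_id(self) -> str:
        suffix = ""
        if self.kind == "methylation":
            suffix = f"_{self.params.get('n_methyls', 0)}"
        elif self.kind == "charge":
            suffix = f"_{self.params.get('replacement', '')}_{self.params.get('k_groups', 0)}"
        return f"{self.parent}_{self.kind}{suffix}"

    @property
    def mutation_string(self) -> str:
        """'I10D, T14W, ...' summary in site order."""
        return ", ".join(m.label for m in self.mutations)

    def is_perturbation(self) -> bool:
        return bool(self.mutations) or self.modified_ligand is not None

    # -- lossless (de)serialization used by the job emitter ---------------
    def to_dict(self) -> dict:
        return {
            "spec_id": self.spec_id,
            "kind": self.kind,
            "parent": self.parent,
            "mutations": [list(m) for m in self.mutations],
            "mutated_sequence": dict(self.mutated_sequence),
            "modified_ligand": (
                self.modified_ligand.to_dict() if self.modified_ligand else None
            ),
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ChallengeSpec":
        ligand = payload.get("modified_ligand")
        return cls(
            kind=payload["kind"],
            parent=payload["parent"],
            mutations=[Mutation(*m) for m in payload["mutations"]],
            mutated_sequence=dict(payload["mutated_sequence"]),
            modified_ligand=LigandGraph.from_dict(ligand) if ligand else None,
            params=dict(payload["params"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ChallengeSpec":
        return cls.from_dict(json.loads(text))
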