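"""Mapping configuration: binds chains/residue numbers to quarter sites.

The modelled dimer complexes carry no canonical numbering, so instead of
guessing, every analysis takes an explicit mapping that states which
protein chain reads which quarter site, which chains hold the two DNA
strands, the residue numbers of the monitored side chains, and where the
response element registers on the reference strand.

DNA numbering convention: each strand is numbered 1..n_bp in its own
5'->3' direction, so reference-strand residue ``c`` pairs with
complementary-strand residue ``n_bp + 1 - c``.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .ensemble_io import NUCLEOTIDE_NAMES, Ensemble, SelectionSpec, select
from .errors import LabelError, MappingError, RegistrationError
from .re_model import QUARTER_IDS, ResponseElement

#: Residue numbers of the monitored p53 core-domain positions.
DEFAULT_RESIDUES: Mapping[str, int] = {
    "lys120": 120,
    "arg248": 248,
    "ser269": 269,
    "arg273": 273,
    "arg280": 280,
    "glu281": 281,
    "gly112": 112,
}


@dataclass
class MappingConfig:
    """Chain/residue bindings for one complex."""

    ref_chain: str
    comp_chain: str
    n_bp: int
    re_offset: int  # reference-strand residue number of position 1 of the first quarter
    quarters: Mapping[str, str]  # quarter id -> protein chain id
    residues: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_RESIDUES))
    position0_offset: int = 1  # bp 5'-adjacent to position 1 (configurable anchoring)
    re_name: str = ""

    def __post_init__(self):
        for q in self.quarters:
            if q not in QUARTER_IDS:
                raise LabelError(f"unknown quarter site {q!r} in mapping")
        if not self.quarters:
            raise MappingError("mapping must bind at least one quarter site")

    @property
    def base_quarter_index(self) -> int:
        """1-based index of the first quarter present (1 for Q1/Q2, 3 for Q3/Q4)."""
        return min(QUARTER_IDS.index(q) + 1 for q in self.quarters)

    # -- DNA coordinate arithmetic -----------------------------------------

    def column(self, quarter: str, position: int) -> int:
        """Reference-strand residue number of ``quarter``'s local ``position``.

        Position 0 resolves ``position0_offset`` base pairs 5' of position 1
        in the quarter's local orientation.
        """
        if quarter not in self.quarters:
            raise MappingError(f"quarter {quarter!r} is not bound in this mapping")
        j = QUARTER_IDS.index(quarter) + 1 - (self.base_quarter_index - 1)
        half = (j - 1) // 2
        p = position if position != 0 else 1 - self.position0_offset
        if j % 2 == 1:
            return self.re_offset + 10 * half + p - 1
        return self.re_offset + 10 * half + 10 - p

    def dna_residue(self, quarter: str, position: int, primed: bool) -> tuple:
        """(chain_id, res_id) of the base at a quarter's local position.

        Unprimed addresses the quarter's sense strand, primed its partner.
        """
        col = self.column(quarter, position)
        if not 1 <= col <= self.n_bp:
            raise MappingError(
                f"{quarter} position {position} maps to column {col}, outside 1..{self.n_bp}"
            )
        sense_is_ref = quarter in ("Q1", "Q3")
        on_ref = sense_is_ref != primed
        if on_ref:
            return self.ref_chain, col
        return self.comp_chain, self.n_bp + 1 - col

    def protein_chain(self, quarter: str) -> str:
        try:
            return self.quarters[quarter]
        except KeyError:
            raise MappingError(f"quarter {quarter!r} is not bound in this mapping") from None

    def protein_atom(self, quarter: str, residue_key: str, atom_name) -> SelectionSpec:
        return SelectionSpec(
            chain_id=self.protein_chain(quarter),
            res_id=self.residues[residue_key],
            atom_name=atom_name,
        )

    # -- serialization ------------------------------------------------------

    def to_toml(self, path) -> None:
        lines = ["[dna]"]
        lines.append(f'ref_chain = "{self.ref_chain}"')
        lines.append(f'comp_chain = "{self.comp_chain}"')
        lines.append(f"n_bp = {self.n_bp}")
        lines.append(f"re_offset = {self.re_offset}")
        lines.append("")
        for q in sorted(self.quarters):
            lines.append(f"[protein.{q}]")
            lines.append(f'chain = "{self.quarters[q]}"')
            lines.append("")
        lines.append("[residues]")
        for key in sorted(self.residues):
            lines.append(f"{key} = {self.residues[key]}")
        lines.append("")
        lines.append("[options]")
        lines.append(f"position0_offset = {self.position0_offset}")
        lines.append(f're_name = "{self.re_name}"')
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path) -> "MappingConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        dna = data["dna"]
        options = data.get("options", {})
        return cls(
            ref_chain=dna["ref_chain"],
            comp_chain=dna["comp_chain"],
            n_bp=int(dna["n_bp"]),
            re_offset=int(dna["re_offset"]),
            quarters={q: spec["chain"] for q, spec in data.get("protein", {}).items()},
            residues={k: int(v) for k, v in data.get("residues", DEFAULT_RESIDUES).items()},
            position0_offset=int(options.get("position0_offset", 1)),
            re_name=str(options.get("re_name", "")),
        )


def dna_base(ens: Ensemble, chain_id: str, res_id: int) -> str:
    """Single-letter base identity of a DNA residue, from its residue name."""
    idx = select(ens, SelectionSpec(chain_id=chain_id, res_id=res_id))
    if len(idx) == 0:
        raise MappingError(f"no atoms for DNA residue {chain_id}:{res_id}")
    res_name = ens.topology.res_name[idx[0]]
    try:
        return NUCLEOTIDE_NAMES[res_name]
    except KeyError:
        raise MappingError(
            f"residue {chain_id}:{res_id} has non-nucleotide name {res_name!r}"
        ) from None


def dna_atom_indices(
    ens: Ensemble,
    mapping: MappingConfig,
    quarter: str,
    position: int,
    primed: bool,
    atom_names,
):
    chain, resid = mapping.dna_residue(quarter, position, primed)
    return select(ens, SelectionSpec(chain_id=chain, res_id=resid, atom_name=atom_names))


def verify_registration(
    ens: Ensemble, re: ResponseElement, mapping: MappingConfig
) -> None:
    """Check that the topology's bases spell the response element.

    Quarter sense sequences derived from residue names must match the RE;
    a disagreement means the mapping registration (or the sequence) is wrong.
    """
    for quarter in mapping.quarters:
        expected = re.sense_sequence(quarter)
        for pos in range(1, 6):
            chain, resid = mapping.dna_residue(quarter, pos, primed=False)
            observed = dna_base(ens, chain, resid)
            if observed != expected[pos - 1]:
                raise RegistrationError(
                    f"{quarter} position {pos}: topology base {observed} at "
                    f"{chain}:{resid} but response element {re.name!r} expects "
                    f"{expected[pos - 1]}"
                )
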