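"""p53 response-element sequence model.

A p53 response element (RE) is a 20-bp site made of two 10-bp half sites,
each half site two 5-bp quarter sites (Q1..Q4).  One p53 core-domain monomer
reads one quarter site.  Each half site degenerately matches the consensus

    5'-Pu Pu Pu C (A/T) (A/T) G Py Py Py-3'

(Pu = purine A/G, Py = pyrimidine C/T, W = A/T), which is its own reverse
complement under the class mapping Pu<->Py, C<->G, W<->W.

Position labels follow the quarter-site convention: Q1/Q3 columns are
labelled 1..5 on the reference strand; Q2/Q4 columns are labelled 5'..1'
because there the monomer's consensus-oriented ("sense") strand is the
complementary chain.  Label 0 denotes the base pair immediately 5' of
position 1 in the quarter's local orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

from .errors import LabelError, SequenceError

BASES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Membership sets for the degenerate consensus classes.
CLASS_MEMBERS: Mapping[str, frozenset] = {
    "Pu": frozenset("AG"),
    "Py": frozenset("CT"),
    "W": frozenset("AT"),
    "C": frozenset("C"),
    "G": frozenset("G"),
}

#: Class mapping under Watson-Crick complementation.
CLASS_COMPLEMENT = {"Pu": "Py", "Py": "Pu", "W": "W", "C": "G", "G": "C"}

#: One half site, read on the reference strand.
CONSENSUS_HALF_SITE = ("Pu", "Pu", "Pu", "C", "W", "W", "G", "Py", "Py", "Py")

QUARTER_IDS = ("Q1", "Q2", "Q3", "Q4")

#: Column labels per quarter, left to right on the reference strand.
QUARTER_LABELS = {
    "Q1": ("1", "2", "3", "4", "5"),
    "Q2": ("5'", "4'", "3'", "2'", "1'"),
    "Q3": ("1", "2", "3", "4", "5"),
    "Q4": ("5'", "4'", "3'", "2'", "1'"),
}

#: The six naturally occurring response elements studied with this package,
#: two each from cell-cycle arrest, DNA repair and apoptosis programs.
KNOWN_RESPONSE_ELEMENTS: Mapping[str, Mapping[str, str]] = {
    "14-3-3sigma": {"sequence": "AGGCATGTGCCACCATGCCC", "function": "cell cycle arrest"},
    "GADD45": {"sequence": "GAACATGTCTAAGCATGCTG", "function": "DNA repair"},
    "Noxa": {"sequence": "AGGCTTGCCCCGGCAAGTTG", "function": "apoptosis"},
    "p21-5'": {"sequence": "GAACATGCCCCAACATGTTG", "function": "cell cycle arrest"},
    "p53R2": {"sequence": "TGACATGCCCAGGCATGTCT", "function": "DNA repair"},
    "Puma": {"sequence": "CTGCAAGTCCTGACTTGTCC", "function": "apoptosis"},
}


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    seq = sequence.upper()
    for i, b in enumerate(seq):
        if b not in BASES:
            raise SequenceError(f"invalid base {sequence[i]!r} at index {i}")
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ConsensusMotif:
    """Degenerate consensus for a full 20-bp site (two half sites)."""

    half_site: Sequence[str] = CONSENSUS_HALF_SITE

    def __post_init__(self):
        if len(self.half_site) != 10:
            raise SequenceError(
                f"half-site motif must have 10 positions, got {len(self.half_site)}"
            )
        for cls in self.half_site:
            if cls not in CLASS_MEMBERS:
                raise SequenceError(f"unknown consensus class {cls!r}")

    @property
    def full_site(self) -> tuple:
        return tuple(self.half_site) + tuple(self.half_site)

    def is_palindromic(self) -> bool:
        """True when the half site equals its reverse complement under class mapping."""
        rc = tuple(CLASS_COMPLEMENT[c] for c in reversed(self.half_site))
        return rc == tuple(self.half_site)

    def matches(self, base: str, position: int) -> bool:
        """Test ``base`` against the full-site class at 0-based ``position``."""
        return base.upper() in CLASS_MEMBERS[self.full_site[position]]


@dataclass(frozen=True)
class ResponseElement:
    """A 20-bp response element on its reference strand.

    ``flank5``/``flank3`` optionally carry flanking sequence so that
    position-0 lookups at the element boundary can resolve.
    """

    name: str
    sequence: str
    display_sequence: str = ""
    flank5: str = ""
    flank3: str = ""

    @property
    def half_sites(self) -> tuple:
        return self.sequence[:10], self.sequence[10:]

    @property
    def quarter_sites(self) -> Mapping[str, str]:
        s = self.sequence
        return {"Q1": s[0:5], "Q2": s[5:10], "Q3": s[10:15], "Q4": s[15:20]}

    def quarter(self, quarter: str) -> str:
        try:
            return self.quarter_sites[quarter]
        except KeyError:
            raise LabelError(f"unknown quarter site {quarter!r}") from None

    def sense_sequence(self, quarter: str) -> str:
        """Quarter-site sequence on the monomer-local sense strand (RRRCW order)."""
        q = self.quarter(quarter)
        return q if quarter in ("Q1", "Q3") else reverse_complement(q)


def parse_re(name: str, sequence: str, flank5: str = "", flank3: str = "") -> ResponseElement:
    """Tokenize a 20-base response-element string.

    Case is preserved for display (the lowercase-mismatch print convention)
    but ignored semantically.
    """
    raw = sequence.strip()
    seq = raw.upper()
    if len(seq) != 20:
        raise SequenceError(
            f"response element {name!r}: expected 20 bases, got {len(seq)}"
        )
    for i, b in enumerate(seq):
        if b not in BASES:
            raise SequenceError(
                f"response element {name!r}: invalid base {raw[i]!r} at index {i}"
            )
    for fl in (flank5, flank3):
        for b in fl.upper():
            if b not in BASES:
                raise SequenceError(f"invalid flank base {b!r}")
    return ResponseElement(
        name=name,
        sequence=seq,
        display_sequence=raw,
        flank5=flank5.upper(),
        flank3=flank3.upper(),
    )


def parse_re_fasta(path) -> ResponseElement:
    """Read a single-record FASTA file as a response element."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SequenceError(f"expected a single FASTA record, got {len(records)}")
    rec = records[0]
    return parse_re(rec.id, str(rec.seq))


@dataclass(frozen=True)
class PositionScore:
    quarter: str
    label: str
    base: str
    expected_class: str
    match: bool


@dataclass(frozen=True)
class MismatchReport:
    """Per-position consensus match flags for one response element."""

    name: str
    rows: Sequence[PositionScore]

    @property
    def flags(self) -> tuple:
        return tuple(r.match for r in self.rows)

    @property
    def mismatch_count(self) -> int:
        return sum(1 for r in self.rows if not r.match)

    @property
    def mismatches(self) -> list:
        return [
            (r.quarter, r.label, r.base, r.expected_class)
            for r in self.rows
            if not r.match
        ]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "quarter": r.quarter,
                    "label": r.label,
                    "base": r.base,
                    "expected_class": r.expected_class,
                    "match": r.match,
                }
                for r in self.rows
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        payload = {
            "name": self.name,
            "mismatch_count": self.mismatch_count,
            "positions": [
                {
                    "quarter": r.quarter,
                    "label": r.label,
                    "base": r.base,
                    "expected_class": r.expected_class,
                    "match": r.match,
                }
                for r in self.rows
            ],
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return payload


def score_half_site(half: str, motif: ConsensusMotif = ConsensusMotif()) -> list:
    """Match flags of a 10-base half site against the half-site motif."""
    seq = half.upper()
    if len(seq) != 10:
        raise SequenceError(f"half site must have 10 bases, got {len(seq)}")
    return [seq[i] in CLASS_MEMBERS[motif.half_site[i]] for i in range(10)]


def score_consensus(
    re: ResponseElement, motif: ConsensusMotif = ConsensusMotif()
) -> MismatchReport:
    """Score all 20 positions of an element against the consensus motif."""
    rows = []
    for qi, quarter in enumerate(QUARTER_IDS):
        qseq = re.quarter(quarter)
        labels = QUARTER_LABELS[quarter]
        for ci in range(5):
            col = qi * 5 + ci
            base = qseq[ci]
            cls = motif.full_site[col]
            rows.append(
                PositionScore(
                    quarter=quarter,
                    label=labels[ci],
                    base=base,
                    expected_class=cls,
                    match=base in CLASS_MEMBERS[cls],
                )
            )
    return MismatchReport(name=re.name, rows=tuple(rows))


def parse_label(label: Union[int, str]) -> tuple:
    """Normalize a position label to ``(position, primed)``.

    Accepts integers 0..5 (unprimed) and strings ``"1"``..``"5"``,
    ``"1'"``..``"5'"`` (ASCII apostrophe or prime mark).
    """
    primed = False
    if isinstance(label, str):
        text = label.strip().replace("′", "'")
        if text.endswith("'"):
            primed = True
            text = text[:-1]
        try:
            pos = int(text)
        except ValueError:
            raise LabelError(f"unknown position label {label!r}") from None
    else:
        pos = int(label)
    if primed and not 1 <= pos <= 5:
        raise LabelError(f"primed label out of range: {label!r}")
    if not primed and not 0 <= pos <= 5:
        raise LabelError(f"position label out of range: {label!r}")
    return pos, primed


def quarter_column(quarter: str, position: int, offset: int = 1) -> int:
    """Reference-strand column (1-based) of a quarter's local position.

    ``offset`` is the column of Q1 position 1.  Q2/Q4 run antiparallel, so
    their local positions count down the reference strand; position 0 is the
    base pair 5'-adjacent to position 1 in the local orientation.
    """
    if quarter not in QUARTER_IDS:
        raise LabelError(f"unknown quarter site {quarter!r}")
    j = QUARTER_IDS.index(quarter) + 1
    half = (j - 1) // 2  # 0 for Q1/Q2, 1 for Q3/Q4
    if j % 2 == 1:  # sense strand is the reference strand
        return offset + 10 * half + position - 1
    return offset + 10 * half + 10 - position


def contact_partner(
    re: ResponseElement, quarter: str, label: Union[int, str]
) -> tuple:
    """Strand and base whose major-groove face a residue approaches.

    Returns ``(strand, base)`` in the monomer-local frame: ``"reference"``
    is the quarter's consensus-oriented sense strand, ``"complementary"``
    its Watson-Crick partner.  Unprimed labels address the sense strand,
    primed labels the partner base in the same column.
    """
    pos, primed = parse_label(label)
    col = quarter_column(quarter, pos)  # 1-based within the 20-mer
    idx = col - 1
    if idx < 0:
        if len(re.flank5) >= -idx:
            ref_base = re.flank5[idx]
        else:
            raise LabelError(
                f"position {label} of {quarter} lies 5' of the element; "
                "supply flanking sequence"
            )
    elif idx >= 20:
        over = idx - 20
        if len(re.flank3) > over:
            ref_base = re.flank3[over]
        else:
            raise LabelError(
                f"position {label} of {quarter} lies 3' of the element; "
                "supply flanking sequence"
            )
    else:
        ref_base = re.sequence[idx]
    sense = ref_base if quarter in ("Q1", "Q3") else COMPLEMENT[ref_base]
    if primed:
        return "complementary", COMPLEMENT[sense]
    return "reference", sense
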