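"""Hydrogen-bond and salt-bridge distance series, occupancies and bond modes.

A contact is a set of donor heavy atoms against a set of acceptor heavy
atoms; its per-frame distance is the minimum over all donor-acceptor pairs
and it counts as formed when that distance is within a 3.5 Å heavy-atom
cutoff.  Occupancy is the percentage of window frames in which the contact
is formed.  No donor-H-acceptor angle enters the criterion by default (the
bond is defined purely by the distance cutoff); an optional angle filter
is out of scope here.

The boundary rule is <= cutoff (a distance exactly at the cutoff counts as
bonded); it is configurable because prose and footnote conventions differ
on whether the boundary itself is in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .ensemble_io import (
    OCCUPANCY_WINDOW,
    Ensemble,
    FrameWindow,
    SelectionSpec,
    resolve_window,
    select,
)
from .errors import MappingError
from .mapping import MappingConfig, dna_base, verify_registration
from .re_model import ResponseElement

DEFAULT_CUTOFF = 3.5  # Å, donor-acceptor heavy atoms

#: Major-groove hydrogen-bond acceptor atoms by base identity.  Cytosine
#: exposes no major-groove acceptor, so a lysine cannot bond it directly.
MAJOR_GROOVE_ACCEPTORS: Mapping[str, tuple] = {
    "G": ("O6", "N7"),
    "A": ("N7",),
    "T": ("O4",),
    "C": (),
}

#: DNA backbone atoms used for salt bridges / minor-groove anchoring.
DEFAULT_BACKBONE_ATOMS = ("O1P", "O2P")


@dataclass
class ContactDefinition:
    """Named donor-set/acceptor-set contact with a distance cutoff."""

    label: str
    donors: Union[SelectionSpec, Sequence[SelectionSpec]]
    acceptors: Union[SelectionSpec, Sequence[SelectionSpec]]
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


@dataclass
class DistanceSeries:
    """Per-frame minimum donor-acceptor distance for one contact."""

    label: str
    frames: np.ndarray
    values: np.ndarray  # Å

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise ValueError("frames and values must have equal length")

    def __len__(self):
        return len(self.values)


@dataclass
class OccupancyRow:
    label: str
    occupancy: float  # percent of window frames
    n_frames: int
    note: str = ""


@dataclass
class OccupancyTable:
    """Rows of (contact label, occupancy %) over one frame window."""

    rows: Sequence[OccupancyRow]
    window: tuple = (0, 0)

    def __getitem__(self, label: str) -> OccupancyRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    @property
    def labels(self):
        return [r.label for r in self.rows]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "occupancy": r.occupancy,
                    "n_frames": r.n_frames,
                    "note": r.note,
                }
                for r in self.rows
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")


class HBondMode(enum.Enum):
    """Hydrogen-bond geometry of a donor against one base."""

    THREE_CENTERED = "three_centered"
    TWO_CENTERED = "two_centered"
    NONE = "none"


def _resolve_specs(ens: Ensemble, specs, what: str, label: str) -> np.ndarray:
    if isinstance(specs, SelectionSpec):
        specs = [specs]
    indices = []
    for spec in specs:
        indices.extend(select(ens, spec).tolist())
    # stable order, unique
    seen = set()
    out = [i for i in indices if not (i in seen or seen.add(i))]
    if not out:
        raise MappingError(f"contact {label!r}: {what} selection resolved to no atoms")
    return np.asarray(out, dtype=int)


def distance_series(
    ens: Ensemble,
    contact: ContactDefinition,
    window: FrameWindow = OCCUPANCY_WINDOW,
) -> DistanceSeries:
    """Per-frame minimum Euclidean distance over all donor-acceptor pairs."""
    don = _resolve_specs(ens, contact.donors, "donor", contact.label)
    acc = _resolve_specs(ens, contact.acceptors, "acceptor", contact.label)
    start, end = resolve_window(ens, window)
    crd = ens.coords[start:end]
    diff = crd[:, don, None, :] - crd[:, None, acc, :]
    dists = np.sqrt((diff ** 2).sum(axis=3))
    return DistanceSeries(
        label=contact.label,
        frames=np.arange(start, end),
        values=dists.reshape(len(crd), -1).min(axis=1),
    )


def occupancy(
    series: DistanceSeries,
    cutoff: float = DEFAULT_CUTOFF,
    boundary: str = "le",
) -> float:
    """Percentage of frames with distance within the cutoff, in [0, 100]."""
    if len(series) == 0:
        raise ValueError(f"empty distance series for {series.label!r}")
    if boundary == "le":
        bonded = series.values <= cutoff
    elif boundary == "lt":
        bonded = series.values < cutoff
    else:
        raise ValueError("boundary must be 'le' or 'lt'")
    return float(100.0 * bonded.mean())


def classify_mode(
    distances: Mapping[str, float],
    base: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> HBondMode:
    """Bond mode of one donor against one base in a single frame.

    A guanine with both O6 and N7 within the cutoff forms a three-centered
    bond; a single acceptor within the cutoff (any base) is two-centered.
    """
    base = base.upper()
    if base not in MAJOR_GROOVE_ACCEPTORS:
        raise ValueError(f"unknown base {base!r}")
    names = MAJOR_GROOVE_ACCEPTORS[base]
    within = [a for a in names if a in distances and distances[a] <= cutoff]
    if base == "G" and len(within) == 2:
        return HBondMode.THREE_CENTERED
    if within:
        return HBondMode.TWO_CENTERED
    return HBondMode.NONE


# ---------------------------------------------------------------------------
# Residue-specific fingerprints


def _lys_contact(
    ens, mapping, quarter, position, primed, cutoff
) -> tuple:
    """(ContactDefinition | None, base, note) for one fingerprint row."""
    chain, resid = mapping.dna_residue(quarter, position, primed)
    base = dna_base(ens, chain, resid)
    acceptors = MAJOR_GROOVE_ACCEPTORS[base]
    suffix = "b" if primed else "a"
    label = f"{quarter}:{position}{suffix}"
    if not acceptors:
        return None, base, "C has no major-groove acceptor"
    contact = ContactDefinition(
        label=label,
        donors=mapping.protein_atom(quarter, "lys120", "NZ"),
        acceptors=SelectionSpec(chain_id=chain, res_id=resid, atom_name=acceptors),
        cutoff=cutoff,
    )
    return contact, base, ""


def lys120_fingerprint(
    ens: Ensemble,
    re: ResponseElement,
    mapping: MappingConfig,
    window: FrameWindow = OCCUPANCY_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    quarters: Optional[Sequence[str]] = None,
) -> OccupancyTable:
    """Lys120 hydrogen-bond occupancies at positions 1-3 of each quarter site.

    Six rows per quarter: positions 1-3 by the two strands (1a/1b .. 3a/3b;
    'a' is the sense-strand base, 'b' its Watson-Crick partner).  A base
    without a major-groove acceptor yields a structural 0 with a note.
    """
    verify_registration(ens, re, mapping)
    rows = []
    start_end = resolve_window(ens, window)
    for quarter in quarters or sorted(mapping.quarters):
        for position in (1, 2, 3):
            for primed in (False, True):
                contact, base, note = _lys_contact(
                    ens, mapping, quarter, position, primed, cutoff
                )
                suffix = "b" if primed else "a"
                label = f"{quarter}:{position}{suffix}"
                if contact is None:
                    rows.append(
                        OccupancyRow(
                            label=label,
                            occupancy=0.0,
                            n_frames=start_end[1] - start_end[0],
                            note=f"{base}: {note}",
                        )
                    )
                    continue
                series = distance_series(ens, contact, window)
                rows.append(
                    OccupancyRow(
                        label=label,
                        occupancy=occupancy(series, cutoff),
                        n_frames=len(series),
                        note=base,
                    )
                )
    return OccupancyTable(rows=rows, window=start_end)


def arg280_contact(
    ens: Ensemble,
    re: ResponseElement,
    mapping: MappingConfig,
    quarter: str,
    window: FrameWindow = OCCUPANCY_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple:
    """Arg280 guanidinium contact with the (largely conserved) G at position 4'.

    Returns ``(OccupancyTable, series)`` where ``series`` maps
    ``"NH1-O6"``, ``"NH2-N7"``, ``"min"`` and ``"mean"`` to
    :class:`DistanceSeries`; occupancy rows cover the three distance
    definitions (per-pair and min-aggregate).
    """
    verify_registration(ens, re, mapping)
    chain, resid = mapping.dna_residue(quarter, 4, primed=True)
    base = dna_base(ens, chain, resid)
    acceptors = MAJOR_GROOVE_ACCEPTORS[base]
    if not acceptors:
        raise MappingError(
            f"{quarter}: position 4' base {base} has no major-groove acceptor"
        )
    series = {}
    pair_defs = []
    if base == "G":
        pair_defs = [("NH1-O6", "NH1", "O6"), ("NH2-N7", "NH2", "N7")]
    else:
        pair_defs = [(f"NH1-{acceptors[0]}", "NH1", acceptors[0])]
    for label, don_name, acc_name in pair_defs:
        contact = ContactDefinition(
            label=f"{quarter}:R280:{label}",
            donors=mapping.protein_atom(quarter, "arg280", don_name),
            acceptors=SelectionSpec(chain_id=chain, res_id=resid, atom_name=acc_name),
            cutoff=cutoff,
        )
        series[label] = distance_series(ens, contact, window)
    agg = ContactDefinition(
        label=f"{quarter}:R280:min",
        donors=mapping.protein_atom(quarter, "arg280", ("NH1", "NH2")),
        acceptors=SelectionSpec(chain_id=chain, res_id=resid, atom_name=acceptors),
        cutoff=cutoff,
    )
    series["min"] = distance_series(ens, agg, window)
    values = np.mean([series[lbl].values for lbl, _, _ in pair_defs], axis=0)
    series["mean"] = DistanceSeries(
        label=f"{quarter}:R280:mean", frames=series["min"].frames, values=values
    )
    rows = [
        OccupancyRow(
            label=s.label, occupancy=occupancy(s, cutoff), n_frames=len(s)
        )
        for key, s in series.items()
        if key != "mean"
    ]
    table = OccupancyTable(rows=rows, window=resolve_window(ens, window))
    return table, series


@dataclass
class SaltBridgeOccupancy:
    """Occupancies of the four-bridge network stabilizing one quarter site.

    A: DNA-R280 (the specific base contact), B: R280-E281, C: E281-R273,
    D: R273-DNA backbone.
    """

    quarter: str
    a: float
    b: float
    c: float
    d: float

    def as_tuple(self):
        return (self.a, self.b, self.c, self.d)


def saltbridge_contacts(
    ens: Ensemble,
    mapping: MappingConfig,
    quarter: str,
    cutoff: float = DEFAULT_CUTOFF,
    backbone_atoms: Sequence[str] = DEFAULT_BACKBONE_ATOMS,
) -> Mapping[str, ContactDefinition]:
    """The four contact definitions of the A-D network for one quarter."""
    chain4, resid4 = mapping.dna_residue(quarter, 4, primed=True)
    base4 = dna_base(ens, chain4, resid4)
    acceptors4 = MAJOR_GROOVE_ACCEPTORS[base4] or ("N3",)  # degenerate fallback
    phosphate_specs = []
    for position in range(1, 6):
        chain, resid = mapping.dna_residue(quarter, position, primed=False)
        phosphate_specs.append(
            SelectionSpec(chain_id=chain, res_id=resid, atom_name=backbone_atoms)
        )
    r280 = mapping.protein_atom(quarter, "arg280", ("NH1", "NH2"))
    r273 = mapping.protein_atom(quarter, "arg273", ("NH1", "NH2"))
    e281 = mapping.protein_atom(quarter, "glu281", ("OE1", "OE2"))
    return {
        "A": ContactDefinition(
            label=f"{quarter}:A:DNA-R280",
            donors=r280,
            acceptors=SelectionSpec(
                chain_id=chain4, res_id=resid4, atom_name=acceptors4
            ),
            cutoff=cutoff,
        ),
        "B": ContactDefinition(
            label=f"{quarter}:B:R280-E281", donors=r280, acceptors=e281, cutoff=cutoff
        ),
        "C": ContactDefinition(
            label=f"{quarter}:C:E281-R273", donors=r273, acceptors=e281, cutoff=cutoff
        ),
        "D": ContactDefinition(
            label=f"{quarter}:D:R273-DNA",
            donors=r273,
            acceptors=phosphate_specs,
            cutoff=cutoff,
        ),
    }


def saltbridge_network(
    ens: Ensemble,
    mapping: MappingConfig,
    window: FrameWindow = OCCUPANCY_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    quarters: Optional[Sequence[str]] = None,
    backbone_atoms: Sequence[str] = DEFAULT_BACKBONE_ATOMS,
) -> Mapping[str, SaltBridgeOccupancy]:
    """Percent formation of bridges A-D per quarter site (min-pair rule)."""
    out = {}
    for quarter in quarters or sorted(mapping.quarters):
        contacts = saltbridge_contacts(ens, mapping, quarter, cutoff, backbone_atoms)
        occ = {
            key: occupancy(distance_series(ens, c, window), cutoff)
            for key, c in contacts.items()
        }
        out[quarter] = SaltBridgeOccupancy(
            quarter=quarter, a=occ["A"], b=occ["B"], c=occ["C"], d=occ["D"]
        )
    return out


def arg248_distances(
    ens: Ensemble,
    mapping: MappingConfig,
    quarter: str,
    window: FrameWindow = OCCUPANCY_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    backbone_atoms: Sequence[str] = DEFAULT_BACKBONE_ATOMS,
) -> tuple:
    """Two monitored Arg248-backbone distance series (positions 4 and 5).

    Arg248 approaches from the minor groove; when it is ejected it docks on
    the backbone from the outside, which these distances track.
    """
    donors = mapping.protein_atom(quarter, "arg248", ("NH1", "NH2"))
    out = []
    for position in (4, 5):
        chain, resid = mapping.dna_residue(quarter, position, primed=False)
        contact = ContactDefinition(
            label=f"{quarter}:R248:p{position}",
            donors=donors,
            acceptors=SelectionSpec(
                chain_id=chain, res_id=resid, atom_name=backbone_atoms
            ),
            cutoff=cutoff,
        )
        out.append(distance_series(ens, contact, window))
    return tuple(out)


def cooccupancy_correlation(
    a: DistanceSeries,
    b: DistanceSeries,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple:
    """Pearson r of two distance series plus their co-disruption fraction.

    The co-disruption fraction is the fraction of frames in which both
    distances exceed the cutoff (both bonds broken at once).  For a
    zero-variance series the correlation is undefined and reported as NaN;
    the fraction is still computed.
    """
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    co_fraction = float(np.mean((a.values > cutoff) & (b.values > cutoff)))
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        return float("nan"), co_fraction
    from scipy import stats

    r = float(stats.pearsonr(a.values, b.values)[0])
    return r, co_fraction
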