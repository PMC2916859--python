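"""Synthetic p53-DNA-like ensembles with planted, recorded ground truth.

Real trajectories of these complexes are not deposited, and explicit-solvent
MD is far out of desk scale.  This module therefore generates minimal
complexes whose *statistics* are known by construction, so every analysis
stage can be validated against recorded truth:

* a template: ideal B-DNA for one 10-bp half site plus the capping
  sequences 5'-ATAATT-3' / 5'-ATTAA-3', with pseudo-protein anchor atoms
  (Lys120 NZ, Arg280/Arg273 NH1/NH2, Glu281 OE1/OE2, Arg248 NH1/NH2, Cα
  anchors) placed at crystal-like contact distances, one monomer per
  quarter site;
* per-frame Bernoulli bonding for each monitored contact, with bonded /
  unbonded donor-acceptor distances drawn from truncated normals chosen so
  the 3.5 Å cutoff separates the two states with negligible leakage;
* isotropic Gaussian positional jitter, a planted DNA bend (rigid rotation
  of the second half about a roll axis at the midpoint), and one planted
  (anti-)correlated atom pair.

There is no force field and no sterics: the ensembles are statistical
objects, not physical ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .dna_geometry import B_DNA_RISE, B_DNA_TWIST, ideal_bdna
from .ensemble_io import (
    Ensemble,
    SelectionSpec,
    Topology,
    select,
    write_multimodel_pdb,
)
from .errors import MappingError, SequenceError
from .geom_descriptors import place_by_internal_coordinates
from .interface_contacts import MAJOR_GROOVE_ACCEPTORS
from .mapping import DEFAULT_RESIDUES, MappingConfig
from .re_model import ResponseElement, parse_re

CAP5 = "ATAATT"
CAP3 = "ATTAA"

#: Protein residue names for the pseudo-monomer atoms.
_RES_NAMES = {112: "GLY", 120: "LYS", 248: "ARG", 269: "SER",
              273: "ARG", 280: "ARG", 281: "GLU"}

#: Extra Cα-only residues so fluctuation/covariance profiles have a spine.
_EXTRA_CA_RESIDUES = (96, 100, 105, 110, 115, 125, 130, 135, 175, 180, 185, 225, 244)

_CONTACT_KINDS = ("lys120", "A", "B", "C", "D", "arg248_p4", "arg248_p5")


@dataclass(frozen=True)
class ContactPlant:
    """One planted contact probability."""

    quarter: str
    kind: str  # one of _CONTACT_KINDS
    probability: float
    position: int = 2  # lys120 only: quarter-site position 1-3

    def __post_init__(self):
        if self.kind not in _CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability out of [0,1]: {self.probability}")
        if self.kind == "lys120" and self.position not in (1, 2, 3):
            raise ValueError(f"lys120 position must be 1-3, got {self.position}")

    @property
    def key(self) -> str:
        if self.kind == "lys120":
            return f"{self.quarter}:lys120:p{self.position}"
        return f"{self.quarter}:{self.kind}"


@dataclass
class PlantedTruth:
    """Generator parameters: the recorded ground truth of one ensemble.

    Distance distributions follow the package's separation design: bonded
    ~ N(2.9, 0.15) Å truncated below 2.4; unbonded ~ N(5.5, 0.5) truncated
    below cutoff + 0.2, so the 3.5 Å rule recovers the drawn state.
    """

    contacts: Sequence[ContactPlant] = field(default_factory=list)
    n_frames: int = 2000
    bonded_mean: float = 2.9
    bonded_std: float = 0.15
    bonded_min: float = 2.4
    unbonded_mean: float = 5.5
    unbonded_std: float = 0.5
    cutoff: float = 3.5
    fluct_sigma: float = 0.3  # Å, isotropic per coordinate
    sigma_overrides: Mapping[str, float] = field(default_factory=dict)  # "chain:resid:atom"
    bend_deg: float = 0.0
    corr_pair: Optional[Sequence[str]] = None  # two "chain:resid:atom" keys
    corr_sign: int = -1
    corr_amplitude: float = 2.0  # Å

    def __post_init__(self):
        if self.fluct_sigma < 0:
            raise ValueError("fluct_sigma must be >= 0")
        if not self.bonded_mean < self.cutoff < self.unbonded_mean:
            raise ValueError("need bonded mean < cutoff < unbonded mean")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.corr_pair is not None and len(self.corr_pair) != 2:
            raise ValueError("corr_pair must name exactly two atoms")
        if self.corr_sign not in (-1, 1):
            raise ValueError("corr_sign must be -1 or +1")

    def to_json(self, path=None, extra: Optional[dict] = None):
        payload = {
            "contacts": [asdict(c) for c in self.contacts],
            "n_frames": self.n_frames,
            "bonded_mean": self.bonded_mean,
            "bonded_std": self.bonded_std,
            "bonded_min": self.bonded_min,
            "unbonded_mean": self.unbonded_mean,
            "unbonded_std": self.unbonded_std,
            "cutoff": self.cutoff,
            "fluct_sigma": self.fluct_sigma,
            "sigma_overrides": dict(self.sigma_overrides),
            "bend_deg": self.bend_deg,
            "corr_pair": list(self.corr_pair) if self.corr_pair else None,
            "corr_sign": self.corr_sign,
            "corr_amplitude": self.corr_amplitude,
        }
        if extra:
            payload.update(extra)
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return payload

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        data = json.loads(Path(path).read_text())
        contacts = [ContactPlant(**c) for c in data.pop("contacts", [])]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {k: v for k, v in data.items() if k in known and k != "contacts"}
        if kwargs.get("corr_pair"):
            kwargs["corr_pair"] = tuple(kwargs["corr_pair"])
        return cls(contacts=contacts, **kwargs)


def default_truth(n_frames: int = 2000) -> PlantedTruth:
    """The default stated world: the 14-3-3σ first half site.

    Dominant Lys120 occupancies per quarter (position 2 at 87 % in Q1,
    position 1 at 91 % in Q2), the published salt-bridge network values for
    that element's Q1/Q2 (A-D = 100/0/96/91 and 0/100/70/0), a 18.80°
    planted bend, and an anti-correlated Cα pair bridging the Lys120 loop
    region and the dimerization-interface region (residues 120 vs 180).
    Arg248 backbone-contact levels (85 %/55 %) are plausible
    ejected-then-docked values; no table reports them.
    """
    contacts = [
        ContactPlant("Q1", "lys120", 0.87, position=2),
        ContactPlant("Q1", "A", 1.00),
        ContactPlant("Q1", "B", 0.00),
        ContactPlant("Q1", "C", 0.96),
        ContactPlant("Q1", "D", 0.91),
        ContactPlant("Q1", "arg248_p4", 0.85),
        ContactPlant("Q1", "arg248_p5", 0.55),
        ContactPlant("Q2", "lys120", 0.91, position=1),
        ContactPlant("Q2", "A", 0.00),
        ContactPlant("Q2", "B", 1.00),
        ContactPlant("Q2", "C", 0.70),
        ContactPlant("Q2", "D", 0.00),
        ContactPlant("Q2", "arg248_p4", 0.85),
        ContactPlant("Q2", "arg248_p5", 0.55),
    ]
    return PlantedTruth(
        contacts=contacts,
        n_frames=n_frames,
        bend_deg=18.80,
        corr_pair=("A:120:CA", "A:180:CA"),
        corr_sign=-1,
        corr_amplitude=2.0,
    )


# ---------------------------------------------------------------------------
# Template construction


@dataclass
class _Placement:
    """Donor atom placed at a drawn distance from an anchor atom."""

    donor: int
    anchor: int


@dataclass
class _LysTarget:
    position: int
    primary: int  # acceptor atom the NZ is placed against
    direction: np.ndarray  # straight-template placement direction


@dataclass
class TemplateComplex:
    """Minimal half-site complex: topology, initial coordinates, mapping."""

    ensemble: Ensemble
    mapping: MappingConfig
    re: ResponseElement
    placements: Mapping[str, Sequence[_Placement]] = field(default_factory=dict)
    followers: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    lys_donor: Mapping[str, int] = field(default_factory=dict)
    lys_targets: Mapping[str, Mapping[int, _LysTarget]] = field(default_factory=dict)
    rotated_chains: Sequence[str] = ()

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        idx = select(
            self.ensemble,
            SelectionSpec(chain_id=chain, res_id=res_id, atom_name=atom_name),
        )
        if len(idx) != 1:
            raise MappingError(
                f"template atom {chain}:{res_id}:{atom_name} resolved to {len(idx)}"
            )
        return int(idx[0])

    def atom_key_index(self, key: str) -> int:
        chain, resid, name = key.split(":")
        return self.atom_index(chain, int(resid), name)


def _radial(point: np.ndarray) -> np.ndarray:
    """Unit vector pointing away from the (z-axis) helix axis at the point's height."""
    v = np.array([point[0], point[1], 0.0])
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _direction_grid(n: int = 1024) -> np.ndarray:
    """Deterministic Fibonacci-sphere direction grid."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


_GRID = _direction_grid()


def _clearance_direction(
    primary: np.ndarray,
    competitors: Sequence[np.ndarray],
    radial: np.ndarray,
    distances=(2.9, 5.2),
) -> np.ndarray:
    """Placement direction from ``primary`` maximizing clearance.

    The donor will sit at drawn distances (bonded ~2.9 Å, unbonded ~5.5 Å)
    from ``primary`` along the returned unit vector; among directions with
    an outward (major-groove) component, pick the one maximizing the
    minimum distance to every competing acceptor atom at both regimes, so
    neighbouring-base contact rows stay clean.
    """
    if not competitors:
        return radial
    comp = np.asarray(competitors)  # (m, 3)
    dots = _GRID @ radial
    candidates = _GRID[dots >= 0.25]
    if len(candidates) == 0:
        candidates = _GRID
    total = np.full(len(candidates), np.inf)
    for d in distances:
        pts = primary[None, :] + d * candidates  # (k, 3)
        dist = np.linalg.norm(pts[:, None, :] - comp[None, :, :], axis=2)
        total = np.minimum(total, dist.min(axis=1))
    return candidates[int(np.argmax(total))]


def build_template(
    half_site: Union[str, ResponseElement],
    half: int = 1,
    name: str = "synthetic",
) -> TemplateComplex:
    """Build the minimal complex for one 10-bp half site.

    ``half_site`` is either a 10-base string or a full 20-bp response
    element, in which case ``half`` picks the half site (1 or 2).  The DNA
    is ideal B-DNA for cap + half site + cap (21 bp); two pseudo-monomers
    (chains A and B) carry the monitored side-chain atoms, placed so every
    specific contact starts formed at 2.9 Å and the organizational angle
    starts near the middle of the published range (~105°).
    """
    if isinstance(half_site, ResponseElement):
        re = half_site
        hs = re.half_sites[half - 1]
        quarters = ("Q1", "Q2") if half == 1 else ("Q3", "Q4")
    else:
        hs = half_site.upper()
        if len(hs) != 10:
            raise SequenceError(f"half site must have 10 bases, got {len(hs)}")
        re = parse_re(name, hs + hs)
        quarters = ("Q1", "Q2")

    dna_seq = CAP5 + hs + CAP3
    dna = ideal_bdna(dna_seq)
    n_bp = len(dna_seq)
    mapping = MappingConfig(
        ref_chain="E",
        comp_chain="F",
        n_bp=n_bp,
        re_offset=len(CAP5) + 1,
        quarters={quarters[0]: "A", quarters[1]: "B"},
        residues=dict(DEFAULT_RESIDUES),
        re_name=re.name,
    )

    dna_coords = dna.coords[0]
    dna_top = dna.topology

    def dna_idx(chain, resid, atom_name):
        idx = select(dna, SelectionSpec(chain_id=chain, res_id=resid, atom_name=atom_name))
        if len(idx) != 1:
            raise MappingError(f"DNA atom {chain}:{resid}:{atom_name} missing")
        return int(idx[0])

    def base_of(chain, resid):
        from .mapping import dna_base

        return dna_base(dna, chain, resid)

    protein_records = []  # (chain, resid, atom_name, res_name, element, xyz)

    def add_atom(chain, resid, atom_name, xyz):
        res_name = _RES_NAMES.get(resid, "ALA")
        protein_records.append(
            (chain, resid, atom_name, res_name, atom_name[0], np.asarray(xyz, float))
        )

    placement_keys = {}  # (quarter, kind) -> list of (donor_key, anchor_key)
    lys_meta = {}

    for quarter in quarters:
        chain = mapping.protein_chain(quarter)

        def site(position, primed, names):
            dchain, dresid = mapping.dna_residue(quarter, position, primed)
            base = base_of(dchain, dresid)
            if isinstance(names, str):
                names = (names,)
            return dchain, dresid, base

        # --- Lys120: NZ over the major groove at position 2 -----------------
        # Gather contactable acceptors at positions 1-3 (both strands), then
        # choose, per position, a placement direction keeping the NZ clear of
        # every *other* position's acceptors in both the bonded and unbonded
        # regime — so a planted occupancy at one position does not bleed into
        # the neighbouring rows.
        position_acceptors = {}  # position -> (primary_idx, row_atom_indices)
        all_acceptors = {}  # position -> atom indices on both strands
        for position in (1, 2, 3):
            atoms = []
            primary = None
            for primed in (False, True):
                dchain, dresid = mapping.dna_residue(quarter, position, primed)
                base = base_of(dchain, dresid)
                names = MAJOR_GROOVE_ACCEPTORS[base]
                idxs = [dna_idx(dchain, dresid, nm) for nm in names]
                atoms.extend(idxs)
                if idxs and primary is None:
                    primary = idxs[0]
            all_acceptors[position] = atoms
            if primary is not None:
                position_acceptors[position] = primary
        lys_meta[quarter] = {}
        for position, primary in position_acceptors.items():
            competitors = [
                dna_coords[i]
                for other, atoms in all_acceptors.items()
                if other != position
                for i in atoms
            ]
            point = dna_coords[primary]
            direction = _clearance_direction(point, competitors, _radial(point))
            lys_meta[quarter][position] = (primary, direction)
        anchor2, dir2 = lys_meta[quarter].get(
            2, next(iter(lys_meta[quarter].values()))
        )
        nz = dna_coords[anchor2] + 2.9 * dir2
        add_atom(chain, 120, "NZ", nz)
        add_atom(chain, 120, "CA", nz + 3.2 * _radial(nz))

        # --- Arg280 against the G at position 4' ---------------------------
        g_chain, g_resid, g_base = site(4, True, ())
        g_acc = MAJOR_GROOVE_ACCEPTORS[g_base] or ("N3",)
        acc1 = dna_idx(g_chain, g_resid, g_acc[0])
        acc2 = dna_idx(g_chain, g_resid, g_acc[-1])
        p1 = dna_coords[acc1]
        p2 = dna_coords[acc2]
        nh1 = p1 + 2.9 * _radial(p1)
        nh2 = p2 + 2.9 * _radial(p2)
        if np.allclose(nh1, nh2):
            nh2 = nh1 + np.array([0.0, 0.0, 1.8])
        add_atom(chain, 280, "NH1", nh1)
        add_atom(chain, 280, "NH2", nh2)
        add_atom(chain, 280, "CA", (nh1 + nh2) / 2 + 3.0 * _radial(nh1))
        placement_keys[(quarter, "A")] = [
            ((chain, 280, "NH1"), ("dna", acc1)),
            ((chain, 280, "NH2"), ("dna", acc2)),
        ]

        # --- Glu281 bridging Arg280 ---------------------------------------
        oe1 = nh1 + 2.9 * _radial(nh1)
        oe2 = oe1 + np.array([0.0, 0.0, 1.8])
        add_atom(chain, 281, "OE1", oe1)
        add_atom(chain, 281, "OE2", oe2)
        add_atom(chain, 281, "CA", oe1 + 3.0 * _radial(oe1))
        placement_keys[(quarter, "B")] = [((chain, 281, "OE1"), (chain, 280, "NH1"))]
        placement_keys.setdefault(("followers", quarter), []).append(
            ((chain, 281, "OE2"), (chain, 281, "OE1"), oe2 - oe1)
        )

        # --- Arg273: one arm on Glu281, one on the backbone ----------------
        ph_chain, ph_resid = mapping.dna_residue(quarter, 5, primed=False)
        ph_d = dna_idx(ph_chain, ph_resid, "O2P")
        php = dna_coords[ph_d]
        r273_nh2 = oe2 + 2.9 * _radial(oe2)
        r273_nh1 = php + 2.9 * _radial(php)
        add_atom(chain, 273, "NH1", r273_nh1)
        add_atom(chain, 273, "NH2", r273_nh2)
        add_atom(chain, 273, "CA", (r273_nh1 + r273_nh2) / 2 + 3.0 * _radial(r273_nh1))
        placement_keys[(quarter, "C")] = [((chain, 273, "NH2"), (chain, 281, "OE2"))]
        placement_keys[(quarter, "D")] = [((chain, 273, "NH1"), ("dna", ph_d))]

        # --- Arg248 on the backbone at positions 4-5 (minor-groove side) ---
        for pos, arm, kind in ((4, "NH1", "arg248_p4"), (5, "NH2", "arg248_p5")):
            bchain, bresid = mapping.dna_residue(quarter, pos, primed=False)
            bidx = dna_idx(bchain, bresid, "O1P")
            bp = dna_coords[bidx]
            add_atom(chain, 248, arm, bp + 2.9 * _radial(bp))
            placement_keys[(quarter, kind)] = [((chain, 248, arm), ("dna", bidx))]
        nh1_248 = protein_records[-2][5]
        add_atom(chain, 248, "CA", nh1_248 + 3.0 * _radial(nh1_248))

        # --- organizational anchors: Cα(Gly112), Cα(Ser269) ----------------
        c30 = dna_coords[dna_idx(*mapping.dna_residue(quarter, 0, False), "C3'")]
        c4p = dna_coords[dna_idx(*mapping.dna_residue(quarter, 4, True), "C3'")]
        ca112 = c30 + 12.0 * _radial(c30)
        ca269 = place_by_internal_coordinates(ca112, c30, c4p, 14.0, 105.0, 25.0)
        add_atom(chain, 112, "CA", ca112)
        add_atom(chain, 269, "CA", ca269)

        # --- Cα spine for fluctuation/covariance profiles ------------------
        centre = ca112
        zhat = np.array([0.0, 0.0, 1.0])
        e1 = _radial(centre)
        e2 = np.cross(zhat, e1)
        for resid in _EXTRA_CA_RESIDUES:
            phi = 2 * np.pi * ((resid * 37) % 100) / 100.0
            zoff = float((resid * 17) % 7 - 3)
            pos = centre + 6.0 * (np.cos(phi) * e1 + np.sin(phi) * e2) + zoff * zhat
            add_atom(chain, resid, "CA", pos)

    # --- assemble topology: protein chains then DNA ------------------------
    protein_records.sort(key=lambda r: (r[0], r[1], r[2]))
    records = []
    coords = []
    serial = 1
    atom_lookup = {}
    for chain, resid, atom_name, res_name, element, xyz in protein_records:
        records.append((serial, atom_name, res_name, resid, chain, element))
        atom_lookup[(chain, resid, atom_name)] = serial - 1
        coords.append(xyz)
        serial += 1
    dna_offset = len(records)
    for i in range(dna_top.n_atoms):
        records.append(
            (
                serial,
                dna_top.atom_name[i],
                dna_top.res_name[i],
                int(dna_top.res_id[i]),
                dna_top.chain_id[i],
                dna_top.element[i],
            )
        )
        coords.append(dna_coords[i])
        serial += 1

    ensemble = Ensemble(
        topology=Topology.from_records(records), coords=np.asarray(coords)[None]
    )

    def to_index(ref):
        if ref[0] == "dna":
            return dna_offset + ref[1]
        return atom_lookup[ref]

    placements = {}
    followers = {}
    for key, plist in placement_keys.items():
        if key[0] == "followers":
            quarter = key[1]
            followers[quarter] = [
                (to_index(a), to_index(p), np.asarray(off, float))
                for a, p, off in plist
            ]
            continue
        quarter, kind = key
        placements[f"{quarter}:{kind}"] = [
            _Placement(donor=to_index(d), anchor=to_index(a)) for d, a in plist
        ]

    lys_donor = {}
    lys_targets = {}
    for quarter in quarters:
        chain = mapping.protein_chain(quarter)
        lys_donor[quarter] = atom_lookup[(chain, 120, "NZ")]
        targets = {}
        for position, (prim, direction) in lys_meta[quarter].items():
            targets[position] = _LysTarget(
                position=position,
                primary=dna_offset + prim,
                direction=direction,
            )
        lys_targets[quarter] = targets

    # quarters whose DNA columns lie wholly in the rotated (bent) half
    mid_col = (n_bp + 1) // 2
    rotated = []
    for quarter in quarters:
        cols = [mapping.column(quarter, p) for p in range(1, 6)]
        if min(cols) > mid_col:
            rotated.append(mapping.protein_chain(quarter))

    return TemplateComplex(
        ensemble=ensemble,
        mapping=mapping,
        re=re,
        placements=placements,
        followers=followers,
        lys_donor=lys_donor,
        lys_targets=lys_targets,
        rotated_chains=tuple(rotated),
    )


# ---------------------------------------------------------------------------
# Ensemble generation


@dataclass
class GenerationRecord:
    """What the generator actually drew: the oracle for recovery tests."""

    truth: PlantedTruth
    seed: int
    states: Mapping[str, np.ndarray]  # contact key -> per-frame bonded flags

    def planted_occupancy(self, key: str) -> float:
        """Realized (drawn) bonded fraction for a contact, percent."""
        return float(100.0 * np.mean(self.states[key]))


def _bend_transform(template: TemplateComplex, bend_deg: float):
    """Rotation applied to the second DNA half (and its monomer) for a planted bend."""
    ens = template.ensemble
    top = ens.topology
    n_bp = template.mapping.n_bp
    mid_col = (n_bp + 1) // 2
    ref = template.mapping.ref_chain
    comp = template.mapping.comp_chain
    cols = np.zeros(top.n_atoms, dtype=int)
    is_ref = top.chain_id == ref
    is_comp = top.chain_id == comp
    cols[is_ref] = top.res_id[is_ref]
    cols[is_comp] = n_bp + 1 - top.res_id[is_comp]
    mask = (is_ref | is_comp) & (cols > mid_col)
    for chain in template.rotated_chains:
        mask |= top.chain_id == chain
    pivot = np.array([0.0, 0.0, B_DNA_RISE * (mid_col - 1)])
    axis = Rotation.from_euler("z", B_DNA_TWIST * (mid_col - 1), degrees=True).apply(
        [1.0, 0.0, 0.0]
    )
    rot = Rotation.from_rotvec(np.deg2rad(bend_deg) * axis)
    return mask, rot, pivot


def _bent_template_coords(template: TemplateComplex, bend_deg: float):
    coords = template.ensemble.coords[0].copy()
    if bend_deg == 0.0:
        return coords, None
    mask, rot, pivot = _bend_transform(template, bend_deg)
    coords[mask] = rot.apply(coords[mask] - pivot) + pivot
    return coords, (mask, rot, pivot)


def _draw_distances(rng, truth: PlantedTruth, bonded: np.ndarray) -> np.ndarray:
    n = len(bonded)
    out = np.empty(n)
    nb = int(bonded.sum())
    if nb:
        a = (truth.bonded_min - truth.bonded_mean) / truth.bonded_std
        out[bonded] = truncnorm.rvs(
            a, np.inf, loc=truth.bonded_mean, scale=truth.bonded_std,
            size=nb, random_state=rng,
        )
    nu = n - nb
    if nu:
        lo = truth.cutoff + 0.2
        a = (lo - truth.unbonded_mean) / truth.unbonded_std
        out[~bonded] = truncnorm.rvs(
            a, np.inf, loc=truth.unbonded_mean, scale=truth.unbonded_std,
            size=nu, random_state=rng,
        )
    return out


def _sigma_array(template: TemplateComplex, truth: PlantedTruth) -> np.ndarray:
    top = template.ensemble.topology
    sig = np.full(top.n_atoms, float(truth.fluct_sigma))
    for key, value in truth.sigma_overrides.items():
        idx = template.atom_key_index(key)
        sig[idx] = float(value)
    return sig


def _trilaterate(anchors: np.ndarray, targets: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Least-squares point at given distances from anchor points (Gauss-Newton)."""
    x = start.astype(float).copy()
    for _ in range(25):
        diff = x[None, :] - anchors
        dist = np.linalg.norm(diff, axis=1)
        dist = np.where(dist < 1e-9, 1e-9, dist)
        resid = dist - targets
        jac = diff / dist[:, None]
        try:
            step, *_ = np.linalg.lstsq(jac, resid, rcond=None)
        except np.linalg.LinAlgError:
            break
        x = x - step
        if np.linalg.norm(step) < 1e-10:
            break
    return x


def generate(
    template: TemplateComplex,
    truth: Optional[PlantedTruth] = None,
    seed: int = 0,
    states_override: Optional[Mapping[str, np.ndarray]] = None,
) -> tuple:
    """Generate an ensemble realizing a planted truth; fully seed-reproducible.

    Returns ``(Ensemble, GenerationRecord)``.  ``states_override`` replaces
    the Bernoulli draw for named contacts with explicit per-frame bonded
    flags (used by the coupled-disruption scenario).
    """
    if truth is None:
        truth = default_truth()
    rng = np.random.default_rng(seed)
    n = truth.n_frames
    base, _ = _bent_template_coords(template, truth.bend_deg)
    sig = _sigma_array(template, truth)
    coords = base[None] + rng.standard_normal((n,) + base.shape) * sig[None, :, None]

    # planted (anti-)correlated pair: shared scalar mode along a fixed direction
    if truth.corr_pair is not None:
        i = template.atom_key_index(truth.corr_pair[0])
        j = template.atom_key_index(truth.corr_pair[1])
        direction = np.array([1.0, 0.0, 0.0])
        mode = rng.standard_normal(n) * truth.corr_amplitude
        coords[:, i, :] += mode[:, None] * direction
        coords[:, j, :] += truth.corr_sign * mode[:, None] * direction

    states = {}
    # group lys120 plants per quarter, keep other contacts in canonical order
    lys_plants = {}
    other_plants = []
    for plant in truth.contacts:
        if plant.kind == "lys120":
            lys_plants.setdefault(plant.quarter, []).append(plant)
        else:
            other_plants.append(plant)

    def draw_states(plant):
        if states_override and plant.key in states_override:
            flags = np.asarray(states_override[plant.key], dtype=bool)
            if flags.shape != (n,):
                raise ValueError(f"states override for {plant.key} has wrong length")
            return flags
        return rng.random(n) < plant.probability

    # Lys120: one donor, possibly several planted positions
    for quarter in sorted(set(list(lys_plants) + [q for q in template.lys_targets])):
        plants = sorted(lys_plants.get(quarter, []), key=lambda p: p.position)
        if not plants:
            continue
        donor = template.lys_donor[quarter]
        rotated = (
            template.mapping.protein_chain(quarter) in template.rotated_chains
            and truth.bend_deg != 0.0
        )
        if rotated:
            _, rot, _ = _bend_transform(template, truth.bend_deg)
        flag_matrix = []
        dist_matrix = []
        targets = []
        for plant in plants:
            if plant.position not in template.lys_targets[quarter]:
                raise MappingError(
                    f"{quarter}: no contactable base at position {plant.position}"
                )
            flags = draw_states(plant)
            states[plant.key] = flags
            flag_matrix.append(flags)
            dist_matrix.append(_draw_distances(rng, truth, flags))
            target = template.lys_targets[quarter][plant.position]
            direction = target.direction
            if rotated:
                direction = rot.apply(direction)
            targets.append((target.primary, direction))
        flag_matrix = np.array(flag_matrix)  # (k, n)
        dist_matrix = np.array(dist_matrix)
        n_bonded = flag_matrix.sum(axis=0)
        # simple frames: at most one bonded position
        for f in range(n):
            bonded_idx = np.nonzero(flag_matrix[:, f])[0]
            if len(bonded_idx) == 0:
                k = 0  # park the lysine away from the first planted position
            elif len(bonded_idx) == 1:
                k = int(bonded_idx[0])
            else:
                anchors = np.array(
                    [coords[f, targets[int(kk)][0]] for kk in bonded_idx]
                )
                tgt = dist_matrix[bonded_idx, f]
                start = anchors.mean(axis=0) + 2.0 * targets[int(bonded_idx[0])][1]
                coords[f, donor] = _trilaterate(anchors, tgt, start)
                continue
            anchor_idx, direction = targets[k]
            coords[f, donor] = (
                coords[f, anchor_idx] + dist_matrix[k, f] * direction
            )

    # other contacts: vectorized anchored placement, then followers
    for plant in sorted(other_plants, key=lambda p: (p.quarter, _CONTACT_KINDS.index(p.kind))):
        key = f"{plant.quarter}:{plant.kind}"
        if key not in template.placements:
            raise MappingError(f"template has no placement rule for {key}")
        flags = draw_states(plant)
        states[plant.key] = flags
        dists = _draw_distances(rng, truth, flags)
        for rule in template.placements[key]:
            direction = base[rule.donor] - base[rule.anchor]
            direction = direction / np.linalg.norm(direction)
            coords[:, rule.donor, :] = (
                coords[:, rule.anchor, :] + dists[:, None] * direction[None, :]
            )
        for atom, parent, offset in template.followers.get(plant.quarter, []):
            # follower offsets are defined in bent-template frame already
            coords[:, atom, :] = coords[:, parent, :] + offset[None, :]

    ens = Ensemble(topology=template.ensemble.topology, coords=coords)
    record = GenerationRecord(truth=truth, seed=seed, states=states)
    return ens, record


def coupled_disruption_scenario(
    template: TemplateComplex,
    p_joint: float,
    p_solo: float = 0.0,
    n_frames: int = 2000,
    seed: int = 0,
    quarter: str = "Q1",
) -> tuple:
    """Ensemble in which Lys120 and Arg280 bonds break *together*.

    With probability ``p_joint`` a frame is a joint-disruption frame (both
    the Lys120 and the Arg280 contact broken); otherwise each contact
    breaks independently with probability ``p_solo``.  All other contacts
    stay formed.  Returns ``(Ensemble, GenerationRecord)``.
    """
    if not 0.0 <= p_joint <= 1.0:
        raise ValueError(f"p_joint out of [0,1]: {p_joint}")
    if not 0.0 <= p_solo <= 1.0:
        raise ValueError(f"p_solo out of [0,1]: {p_solo}")
    rng = np.random.default_rng(seed + 101)
    joint = rng.random(n_frames) < p_joint
    lys_broken = joint | (rng.random(n_frames) < p_solo)
    arg_broken = joint | (rng.random(n_frames) < p_solo)
    position = 2 if 2 in template.lys_targets[quarter] else min(template.lys_targets[quarter])
    contacts = [
        ContactPlant(quarter, "lys120", 0.5, position=position),
        ContactPlant(quarter, "A", 0.5),
    ]
    truth = PlantedTruth(
        contacts=contacts,
        n_frames=n_frames,
        bend_deg=0.0,
        corr_pair=None,
    )
    overrides = {
        contacts[0].key: ~lys_broken,
        contacts[1].key: ~arg_broken,
    }
    return generate(template, truth, seed=seed, states_override=overrides)


# ---------------------------------------------------------------------------
# Bundle I/O


def write_bundle(out_dir, ens: Ensemble, template: TemplateComplex,
                 record: GenerationRecord) -> Mapping[str, Path]:
    """Emit ensemble + mapping + truth side by side (PDB / TOML / JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ensemble": out_dir / "ensemble.pdb",
        "mapping": out_dir / "mapping.toml",
        "truth": out_dir / "truth.json",
    }
    write_multimodel_pdb(ens, paths["ensemble"])
    template.mapping.to_toml(paths["mapping"])
    realized = {
        key: round(record.planted_occupancy(key), 6) for key in sorted(record.states)
    }
    record.truth.to_json(
        paths["truth"],
        extra={
            "seed": record.seed,
            "re_name": template.re.name,
            "re_sequence": template.re.sequence,
            "realized_occupancy": realized,
        },
    )
    return paths


def file_checksum(path) -> str:
    """SHA-256 of a file, for determinism checks and run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
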