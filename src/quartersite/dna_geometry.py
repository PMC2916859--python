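"""Idealized B-DNA construction, base-pair frames and bend angles.

Bases are built from the standard reference-frame coordinates used by
modern helical-parameter software (base-pair centre at the origin, x-axis
toward the major groove, z-axis along the 5'->3' direction of strand I).
The complementary base of a Watson-Crick pair is the standard geometry of
its type rotated 180 deg about x (y -> -y, z -> -z), which reproduces the
canonical hydrogen-bonding distances to ~0.1 Å.

The bend metric here is deliberately *not* the Curves curvilinear axis:
straight axes are fitted (principal axis of base-pair origins) to the two
terminal thirds of a segment and the bend is the angle between them,
oriented 5'->3'.  It is transparent, exactly testable on planted kinks,
and sufficient for ensemble-relative comparisons, but its absolute values
are not comparable with Curves output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble_io import Ensemble, SelectionSpec, Topology, select
from .errors import MappingError, SequenceError
from .re_model import BASES, COMPLEMENT

#: Standard reference-frame base coordinates (heavy atoms, Å).
STANDARD_BASES = {
    "A": {
        "N9": (-1.291, 4.498, 0.000), "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000), "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000), "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000), "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000), "C4": (-1.267, 3.124, 0.000),
        "C1'": (-2.479, 5.346, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000), "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000), "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000), "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000), "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001), "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
        "C1'": (-2.477, 5.399, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000), "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001), "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000), "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000), "C6": (-0.023, 5.068, 0.000),
        "C1'": (-2.477, 5.402, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000), "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000), "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000), "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000), "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
        "C1'": (-2.481, 5.354, 0.000),
    },
}

#: Ring atoms used for least-squares base-frame fitting.
RING_ATOMS = {
    "A": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "G": ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Approximate sugar/phosphate pseudo-backbone in the base frame (strand I).
#: Radii are B-DNA-like (C1' ~5.9 Å, C3' ~7.7 Å, P ~8.6 Å from the axis);
#: only plausibility matters here — backbone atoms serve distance plumbing
#: (salt bridges, minor-groove anchors) and C3' descriptor anchors.
BACKBONE_TEMPLATE = {
    "C3'": (-3.55, 6.80, 1.55),
    "P": (-4.25, 7.50, -2.17),
    "O1P": (-5.35, 8.40, -2.62),
    "O2P": (-4.05, 8.80, -2.87),
}

RES_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

B_DNA_RISE = 3.38  # Å per bp
B_DNA_TWIST = 36.0  # deg per bp

_FLIP = np.diag([1.0, -1.0, -1.0])  # strand II: rotate 180 deg about x


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def ideal_bdna(
    sequence: str,
    ref_chain: str = "E",
    comp_chain: str = "F",
    rise: float = B_DNA_RISE,
    twist: float = B_DNA_TWIST,
) -> Ensemble:
    """Build an ideal straight B-form duplex for ``sequence`` (reference strand).

    Both strands are emitted with correct Watson-Crick pairing.  Residues
    are numbered 1..n on each strand in its own 5'->3' direction, so
    reference residue ``c`` pairs with complementary residue ``n + 1 - c``.
    The helix axis is the global z-axis through the origin.
    """
    seq = sequence.upper()
    for i, b in enumerate(seq):
        if b not in BASES:
            raise SequenceError(f"invalid base {sequence[i]!r} at index {i}")
    n = len(seq)
    records = []
    coords = []
    serial = 1

    def emit(base, chain, resid, local_coords, flip):
        nonlocal serial
        col = resid if chain == ref_chain else n + 1 - resid
        rot = _rot_z(twist * (col - 1))
        shift = np.array([0.0, 0.0, rise * (col - 1)])
        for name, xyz in local_coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if flip:
                xyz = _FLIP @ xyz
            coords.append(rot @ xyz + shift)
            records.append(
                (serial, name, RES_NAMES[base], resid, chain, name[0])
            )
            serial += 1

    # strand I (reference), 5'->3' = increasing residue/column
    for c, base in enumerate(seq, start=1):
        local = dict(STANDARD_BASES[base])
        local.update(BACKBONE_TEMPLATE)
        emit(base, ref_chain, c, local, flip=False)
    # strand II (complementary), antiparallel
    for j in range(1, n + 1):
        col = n + 1 - j
        base = COMPLEMENT[seq[col - 1]]
        local = dict(STANDARD_BASES[base])
        local.update(BACKBONE_TEMPLATE)
        emit(base, comp_chain, j, local, flip=True)

    topology = Topology.from_records(records)
    return Ensemble(topology=topology, coords=np.asarray(coords)[None])


@dataclass
class BasePairFrame:
    """Origin and orthonormal triad of one base pair."""

    origin: np.ndarray
    triad: np.ndarray  # columns are the x, y, z axes

    def __post_init__(self):
        if not np.allclose(self.triad @ self.triad.T, np.eye(3), atol=1e-6):
            raise MappingError("base-pair triad is not orthonormal")


def _fit_base_frame(obs: np.ndarray, base: str, atom_names, flipped: bool):
    """Rotation/origin of one base by fitting its standard geometry."""
    from .geom_descriptors import kabsch

    std = np.array([STANDARD_BASES[base][a] for a in atom_names])
    if flipped:
        std = std @ _FLIP.T
    sp = kabsch(std, obs)
    return sp.rotation, sp.translation


def base_pair_frame(
    ens: Ensemble,
    ref: tuple,
    comp: tuple,
    frame_index: int = 0,
) -> BasePairFrame:
    """Least-squares base-pair frame from the two paired bases' ring atoms.

    ``ref``/``comp`` are (chain_id, res_id) of the reference- and
    complementary-strand nucleotides of the pair.
    """
    from .mapping import dna_base

    coords = ens.coords[frame_index]
    rotations = []
    origins = []
    for (chain, resid), flipped in ((ref, False), (comp, True)):
        base = dna_base(ens, chain, resid)
        names = RING_ATOMS[base]
        idx = select(ens, SelectionSpec(chain_id=chain, res_id=resid, atom_name=names))
        if len(idx) != len(names):
            raise MappingError(
                f"ring atoms missing for {chain}:{resid} ({len(idx)}/{len(names)})"
            )
        # order by requested names
        order = {ens.topology.atom_name[i]: i for i in idx}
        idx = [order[a] for a in names]
        rot, orig = _fit_base_frame(coords[idx], base, names, flipped)
        rotations.append(rot)
        origins.append(orig)
    mean_rot = (rotations[0] + rotations[1]) / 2
    u, _, vt = np.linalg.svd(mean_rot)
    triad = u @ vt
    if np.linalg.det(triad) < 0:
        u[:, -1] *= -1
        triad = u @ vt
    return BasePairFrame(origin=(origins[0] + origins[1]) / 2, triad=triad)


def base_pair_frames(
    ens: Ensemble,
    pairs: Sequence[tuple],
    frame_index: int = 0,
) -> list:
    """Frames for a list of ((ref_chain, ref_resid), (comp_chain, comp_resid)) pairs."""
    return [base_pair_frame(ens, r, c, frame_index) for r, c in pairs]


def duplex_pairs(ref_chain: str, comp_chain: str, n_bp: int, columns=None) -> list:
    """Pairing registration for a 1..n numbered duplex (both strands 5'->3')."""
    if columns is None:
        columns = range(1, n_bp + 1)
    return [((ref_chain, c), (comp_chain, n_bp + 1 - c)) for c in columns]


def helical_twist(frames: Sequence[BasePairFrame]) -> np.ndarray:
    """Rotation angle (deg) between successive base-pair triads."""
    out = []
    for a, b in zip(frames[:-1], frames[1:]):
        rel = a.triad.T @ b.triad
        cos = (np.trace(rel) - 1) / 2
        out.append(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return np.asarray(out)


def wc_acceptor_spacing(ens: Ensemble, ref: tuple, comp: tuple,
                        frame_index: int = 0) -> float:
    """Distance between the two major-groove acceptor atoms of one base pair.

    For an A·T (or T·A) pair this is the purine N7 to thymine O4 distance —
    the reason a lysine amine can hydrogen-bond one base of the pair but not
    both.  For a G·C pair the two acceptors (O6, N7) sit on the guanine
    itself and the intra-base distance is returned.
    """
    from .mapping import dna_base

    coords = ens.coords[frame_index]
    bases = {}
    for chain, resid in (ref, comp):
        bases[(chain, resid)] = dna_base(ens, chain, resid)
    kinds = set(bases.values())
    if kinds == {"A", "T"}:
        targets = {"A": "N7", "T": "O4"}
    elif kinds == {"G", "C"}:
        g = next(k for k, v in bases.items() if v == "G")
        pts = []
        for name in ("O6", "N7"):
            idx = select(ens, SelectionSpec(chain_id=g[0], res_id=g[1], atom_name=name))
            if len(idx) != 1:
                raise MappingError(f"missing atom {name} on {g}")
            pts.append(coords[idx[0]])
        return float(np.linalg.norm(pts[0] - pts[1]))
    else:
        raise MappingError(f"not a Watson-Crick pair: {bases}")
    pts = []
    for key, base in bases.items():
        name = targets[base]
        idx = select(ens, SelectionSpec(chain_id=key[0], res_id=key[1], atom_name=name))
        if len(idx) != 1:
            raise MappingError(f"missing atom {name} on {key}")
        pts.append(coords[idx[0]])
    return float(np.linalg.norm(pts[0] - pts[1]))


@dataclass
class BendResult:
    """Angle between straight axes fitted to the two ends of a DNA segment."""

    angle_deg: float
    axis_first: np.ndarray
    axis_last: np.ndarray
    degenerate: bool = False


def _principal_axis(points: np.ndarray) -> Optional[np.ndarray]:
    centred = points - points.mean(axis=0)
    if np.allclose(centred, 0, atol=1e-9):
        return None
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # orient 5'->3' (first point toward last point)
    direction = points[-1] - points[0]
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis


def bend_angle(
    origins_or_frames,
    terminal: Optional[int] = None,
) -> BendResult:
    """Bend of a bp segment: angle between terminal-segment principal axes.

    ``origins_or_frames`` is an ordered 5'->3' sequence of base-pair origins
    (n, 3) or of :class:`BasePairFrame` objects, at least 8 base pairs.
    ``terminal`` overrides the terminal segment length (default ceil(n/3)).
    """
    if len(origins_or_frames) and isinstance(origins_or_frames[0], BasePairFrame):
        origins = np.array([f.origin for f in origins_or_frames])
    else:
        origins = np.asarray(origins_or_frames, dtype=float)
    n = len(origins)
    if n < 8:
        raise MappingError(f"bend angle needs >= 8 base pairs, got {n}")
    k = int(terminal) if terminal is not None else int(np.ceil(n / 3))
    if not 2 <= k <= n // 2:
        raise MappingError(f"terminal segment length {k} invalid for {n} bp")
    axis_first = _principal_axis(origins[:k])
    axis_last = _principal_axis(origins[-k:])
    if axis_first is None or axis_last is None:
        return BendResult(
            angle_deg=0.0,
            axis_first=np.zeros(3),
            axis_last=np.zeros(3),
            degenerate=True,
        )
    cos = np.clip(np.dot(axis_first, axis_last), -1.0, 1.0)
    return BendResult(
        angle_deg=float(np.degrees(np.arccos(cos))),
        axis_first=axis_first,
        axis_last=axis_last,
    )
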