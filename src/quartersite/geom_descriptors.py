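"""Superposition, RMSD/RMSF, average structures and organizational geometry.

The organizational angle/dihedral descriptors track how a p53 core domain
sits on its quarter site: the angle between Cα(Ser269), Cα(Gly112) and the
DNA C3' atom at quarter-site position 0, and the dihedral formed by adding
the C3' atom at position 4'.  The two protein atoms sit at the centres of
the well-structured β-sheets, the two DNA atoms flank the contacted
quarter site, so the descriptors move when the monomer re-orients with
respect to the DNA even if neither partner deforms internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .ensemble_io import (
    FLUCTUATION_WINDOW,
    Ensemble,
    FrameWindow,
    SelectionSpec,
    resolve_window,
    select,
)
from .errors import MappingError, SuperpositionError
from .mapping import MappingConfig


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray  # 3x3, proper (det +1)
    translation: np.ndarray  # Å
    rmsd: float  # Å, after the transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Least-squares optimal rotation + translation (SVD / Kabsch).

    Requires at least three non-collinear atom pairs.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise SuperpositionError("mobile and reference must both be (n, 3)")
    n = mob.shape[0]
    if n < 3:
        raise SuperpositionError(f"superposition needs >= 3 atoms, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise SuperpositionError("invalid weights")
    wsum = w.sum()
    mob_c = mob - (w[:, None] * mob).sum(0) / wsum
    ref_c = ref - (w[:, None] * ref).sum(0) / wsum
    # collinearity check on the reference geometry
    if np.linalg.matrix_rank(ref_c - ref_c.mean(0), tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) reference geometry")
    h = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    ref_mean = (w[:, None] * ref).sum(0) / wsum
    mob_mean = (w[:, None] * mob).sum(0) / wsum
    trans = ref_mean - rot @ mob_mean
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt((w * ((moved - ref) ** 2).sum(1)).sum() / wsum))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _indices(ens: Ensemble, sel) -> np.ndarray:
    if isinstance(sel, SelectionSpec):
        idx = select(ens, sel)
    else:
        idx = np.asarray(sel, dtype=int)
    if len(idx) == 0:
        raise MappingError("selection resolved to no atoms")
    return idx


def rmsd_series(
    ens: Ensemble,
    fit_sel,
    measure_sel,
    reference: Union[int, np.ndarray] = 0,
) -> np.ndarray:
    """Per-frame RMSD over ``measure_sel`` after superposing on ``fit_sel``.

    ``reference`` is a frame index or an explicit (n_atoms, 3) coordinate
    array congruent with the topology.  Un-weighted, as in per-residue
    deviation profiles fitted on the monomer backbone.
    """
    fit_idx = _indices(ens, fit_sel)
    meas_idx = _indices(ens, measure_sel)
    if isinstance(reference, (int, np.integer)):
        ref_coords = ens.coords[int(reference)]
    else:
        ref_coords = np.asarray(reference, dtype=float)
        if ref_coords.shape != (ens.n_atoms, 3):
            raise SuperpositionError("reference coordinates not congruent with topology")
    out = np.empty(ens.n_frames)
    for f in range(ens.n_frames):
        sp = kabsch(ens.coords[f][fit_idx], ref_coords[fit_idx])
        moved = sp.apply(ens.coords[f][meas_idx])
        out[f] = np.sqrt(((moved - ref_coords[meas_idx]) ** 2).sum(1).mean())
    return out


def average_structure(
    ens: Ensemble,
    window: FrameWindow = FLUCTUATION_WINDOW,
    fit_sel: Optional[object] = None,
) -> np.ndarray:
    """Mean coordinates over a window after superposing each frame.

    Frames are superposed onto the first window frame via ``fit_sel``
    (all atoms when omitted); returns an (n_atoms, 3) array.
    """
    start, end = resolve_window(ens, window)
    fit_idx = (
        np.arange(ens.n_atoms) if fit_sel is None else _indices(ens, fit_sel)
    )
    ref = ens.coords[start]
    acc = np.zeros((ens.n_atoms, 3))
    for f in range(start, end):
        sp = kabsch(ens.coords[f][fit_idx], ref[fit_idx])
        acc += sp.apply(ens.coords[f])
    return acc / (end - start)


def superposed_window(ens, window, fit_sel=None):
    """Window coordinates superposed onto the window-average structure.

    Two-pass: frames are first aligned to the first window frame, averaged,
    then re-aligned to that mean.  Returns (coords (m, n, 3), (start, end)).
    """
    start, end = resolve_window(ens, window)
    fit_idx = (
        np.arange(ens.n_atoms) if fit_sel is None else _indices(ens, fit_sel)
    )
    mean = average_structure(ens, window, fit_sel if fit_sel is not None else None)
    out = np.empty((end - start, ens.n_atoms, 3))
    for k, f in enumerate(range(start, end)):
        sp = kabsch(ens.coords[f][fit_idx], mean[fit_idx])
        out[k] = sp.apply(ens.coords[f])
    return out, (start, end)


@dataclass
class RmsfProfile:
    """Per-residue (and per-atom) fluctuation amplitudes over a window."""

    res_keys: Sequence[tuple]  # (chain_id, res_id), one per residue
    values: np.ndarray  # per-residue RMSF, Å
    atom_indices: np.ndarray
    atom_values: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain_id": [k[0] for k in self.res_keys],
                "res_id": [k[1] for k in self.res_keys],
                "rmsf": self.values,
            }
        )


def rmsf(
    ens: Ensemble,
    sel,
    window: FrameWindow = FLUCTUATION_WINDOW,
    fit_sel: Optional[object] = None,
    reference: str = "mean",
) -> RmsfProfile:
    """Root-mean-square fluctuation per atom, reported per residue.

    Displacements are taken about the windowed mean structure after
    per-frame superposition (``reference="mean"``, the standard RMSF);
    ``reference="initial"`` instead measures deviations from the first
    window frame, the alternative reading of deviation-profile figures.
    """
    if reference not in ("mean", "initial"):
        raise ValueError("reference must be 'mean' or 'initial'")
    idx = _indices(ens, sel)
    coords, (start, end) = superposed_window(ens, window, fit_sel)
    if reference == "mean":
        ref = coords.mean(axis=0)
    else:
        ref = coords[0]
    disp = coords[:, idx, :] - ref[idx]
    atom_values = np.sqrt((disp ** 2).sum(axis=2).mean(axis=0))
    top = ens.topology
    res_keys = []
    values = []
    seen = {}
    for j, a in enumerate(idx):
        key = (top.chain_id[a], int(top.res_id[a]))
        seen.setdefault(key, []).append(j)
    for key, members in seen.items():
        res_keys.append(key)
        values.append(float(atom_values[members].mean()))
    return RmsfProfile(
        res_keys=res_keys,
        values=np.asarray(values),
        atom_indices=idx,
        atom_values=atom_values,
    )


# ---------------------------------------------------------------------------
# Angles and dihedrals


def angle(p1, p2, p3) -> float:
    """Angle at vertex p2, degrees in [0, 180]."""
    v1 = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    v2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion p1-p2-p3-p4, degrees in (-180, 180], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_by_internal_coordinates(b, c, d, r, theta_deg, phi_deg) -> np.ndarray:
    """Place point ``a`` with |a-b| = r, angle(a,b,c) = theta, dihedral(a,b,c,d) = phi."""
    b, c, d = (np.asarray(p, dtype=float) for p in (b, c, d))
    e1 = (c - b) / np.linalg.norm(c - b)
    u = d - c
    u = u - np.dot(u, e1) * e1
    if np.linalg.norm(u) < 1e-9:
        raise SuperpositionError("degenerate internal-coordinate frame (collinear)")
    e2 = u / np.linalg.norm(u)
    e3 = np.cross(e1, e2)
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(phi_deg)
    direction = (
        np.cos(theta) * e1
        + np.sin(theta) * (np.cos(phi) * e2 - np.sin(phi) * e3)
    )
    return b + r * direction


@dataclass
class OrgGeometry:
    """Per-frame organizational angle/dihedral plus window summaries.

    ``avg_structure_angle``/``avg_structure_dihedral`` are evaluated on the
    window-average structure (the table convention for reporting these
    descriptors); ``mean_angle``/``mean_dihedral`` are per-frame means over
    the window.  Both are carried because the two conventions differ on
    fluctuating ensembles.
    """

    quarter: str
    frames: np.ndarray
    angles: np.ndarray  # deg, [0, 180]
    dihedrals: np.ndarray  # deg, (-180, 180]
    mean_angle: float
    mean_dihedral: float
    avg_structure_angle: float
    avg_structure_dihedral: float


def org_geometry(
    ens: Ensemble,
    mapping: MappingConfig,
    quarter: str,
    window: FrameWindow = FLUCTUATION_WINDOW,
    fit_sel: Optional[object] = None,
) -> OrgGeometry:
    """Organizational angle/dihedral of one monomer against its quarter site.

    Anchors: Cα(Ser269) and Cα(Gly112) of the quarter's protein chain and
    the DNA C3' atoms at quarter positions 0 (sense strand) and 4'
    (partner strand).
    """
    from .mapping import dna_atom_indices

    anchors = []
    for key in ("ser269", "gly112"):
        idx = select(ens, mapping.protein_atom(quarter, key, "CA"))
        if len(idx) != 1:
            raise MappingError(
                f"{quarter}: anchor CA of {key} resolved to {len(idx)} atoms"
            )
        anchors.append(idx[0])
    for position, primed in ((0, False), (4, True)):
        idx = dna_atom_indices(ens, mapping, quarter, position, primed, "C3'")
        if len(idx) != 1:
            raise MappingError(
                f"{quarter}: C3' anchor at position {position}{'prime' if primed else ''} "
                f"resolved to {len(idx)} atoms"
            )
        anchors.append(idx[0])
    a269, a112, c0, c4p = anchors
    start, end = resolve_window(ens, window)
    frames = np.arange(start, end)
    angles = np.empty(len(frames))
    dihedrals = np.empty(len(frames))
    for k, f in enumerate(frames):
        crd = ens.coords[f]
        angles[k] = angle(crd[a269], crd[a112], crd[c0])
        dihedrals[k] = dihedral(crd[a269], crd[a112], crd[c0], crd[c4p])
    avg = average_structure(ens, window, fit_sel)
    return OrgGeometry(
        quarter=quarter,
        frames=frames,
        angles=angles,
        dihedrals=dihedrals,
        mean_angle=float(angles.mean()),
        mean_dihedral=float(dihedrals.mean()),
        avg_structure_angle=angle(avg[a269], avg[a112], avg[c0]),
        avg_structure_dihedral=dihedral(avg[a269], avg[a112], avg[c0], avg[c4p]),
    )
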