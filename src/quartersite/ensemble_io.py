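"""Structural ensembles: topology + ordered coordinate frames.

The trajectory container is deliberately a multi-model PDB file — text,
diffable, self-contained — rather than a binary trajectory dialect.
Parsing and writing of the fixed-column format are delegated to biotite;
this module adds the congruence checks (every model must repeat the same
atoms in the same order) and the selection/window plumbing the analysis
stages consume.

Coordinates are Å throughout.  Frame "time" is optional metadata: every
window is resolved in frame counts, so nanosecond conventions (a "last 20
ns" of 30) map to frame fractions of whatever ensemble is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import FormatError, WindowError

#: DNA residue-name dialects accepted when reading nucleotide identity.
NUCLEOTIDE_NAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}


def normalize_atom_name(name: str) -> str:
    """Fold prime-mark dialects: C3′ / C3' / C3* all compare equal."""
    return name.strip().replace("′", "'").replace("*", "'")


@dataclass
class Topology:
    """Ordered atom records as parallel arrays."""

    serial: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray

    def __post_init__(self):
        n = len(self.serial)
        for attr in ("atom_name", "res_name", "res_id", "chain_id", "element"):
            if len(getattr(self, attr)) != n:
                raise FormatError(f"topology field {attr} has wrong length")
        if len(np.unique(self.serial)) != n:
            raise FormatError("atom serial numbers are not unique")
        self.atom_name = np.asarray(
            [normalize_atom_name(a) for a in self.atom_name], dtype="U6"
        )

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Topology":
        """Build from (serial, atom_name, res_name, res_id, chain_id, element) tuples."""
        cols = list(zip(*records))
        return cls(
            serial=np.asarray(cols[0], dtype=int),
            atom_name=np.asarray(cols[1], dtype="U6"),
            res_name=np.asarray(cols[2], dtype="U4"),
            res_id=np.asarray(cols[3], dtype=int),
            chain_id=np.asarray(cols[4], dtype="U2"),
            element=np.asarray(cols[5], dtype="U2"),
        )


@dataclass
class Ensemble:
    """Topology plus an ordered stack of coordinate frames (n_frames, n_atoms, 3)."""

    topology: Topology
    coords: np.ndarray
    times: Optional[np.ndarray] = None  # ns, optional metadata

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise FormatError("an ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"coordinate count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, index: int) -> np.ndarray:
        return self.coords[index]


@dataclass(frozen=True)
class SelectionSpec:
    """Conjunction of atom predicates; ``None`` fields are unconstrained.

    Each field accepts a scalar or a sequence of admissible values.
    """

    chain_id: Union[str, Sequence[str], None] = None
    res_id: Union[int, Sequence[int], None] = None
    res_name: Union[str, Sequence[str], None] = None
    atom_name: Union[str, Sequence[str], None] = None


def _as_set(value, transform=lambda x: x):
    if value is None:
        return None
    if isinstance(value, (str, int, np.integer)):
        return {transform(value)}
    return {transform(v) for v in value}


def select(ens: Ensemble, spec: SelectionSpec) -> np.ndarray:
    """Indices (topology order) of atoms matching all stated predicates."""
    top = ens.topology
    mask = np.ones(top.n_atoms, dtype=bool)
    chains = _as_set(spec.chain_id, str)
    if chains is not None:
        mask &= np.isin(top.chain_id, list(chains))
    res_ids = _as_set(spec.res_id, int)
    if res_ids is not None:
        mask &= np.isin(top.res_id, list(res_ids))
    res_names = _as_set(spec.res_name, str)
    if res_names is not None:
        mask &= np.isin(top.res_name, list(res_names))
    atom_names = _as_set(spec.atom_name, normalize_atom_name)
    if atom_names is not None:
        mask &= np.isin(top.atom_name, list(atom_names))
    return np.nonzero(mask)[0]


@dataclass(frozen=True)
class FrameWindow:
    """Either a tail fraction of the trajectory or an explicit [start, end) range."""

    fraction: Optional[float] = None
    start: Optional[int] = None
    end: Optional[int] = None

    @classmethod
    def tail(cls, fraction: float) -> "FrameWindow":
        if not 0 < fraction <= 1:
            raise WindowError(f"tail fraction must be in (0, 1], got {fraction}")
        return cls(fraction=fraction)

    @classmethod
    def frame_range(cls, start: int, end: int) -> "FrameWindow":
        return cls(start=start, end=end)


#: Default windows: occupancies over the final 2/3 of a run (the "last 20 ns"
#: of a 30 ns trajectory); fluctuation analyses over the final 1/6 ("final 5 ns").
OCCUPANCY_WINDOW = FrameWindow.tail(2 / 3)
FLUCTUATION_WINDOW = FrameWindow.tail(1 / 6)
FULL_WINDOW = FrameWindow.tail(1.0)


def resolve_window(ens: Ensemble, window: FrameWindow) -> tuple:
    """Resolve to a half-open frame index range [start, end)."""
    n = ens.n_frames
    if window.fraction is not None:
        # ceil keeps "last 2/3 of 30" at [10, 30); the clamp keeps a tail
        # window non-empty on very short ensembles (a 1-frame ensemble is
        # its own tail)
        # epsilon guards the exact-fraction case ((1 - 2/3)*30 must ceil to 10)
        start = min(int(np.ceil((1 - window.fraction) * n - 1e-9)), n - 1)
        end = n
    else:
        start = int(window.start if window.start is not None else 0)
        end = int(window.end if window.end is not None else n)
    if start < 0 or end > n or start >= end:
        raise WindowError(
            f"window resolved to empty or out-of-bounds range [{start}, {end}) "
            f"for {n} frames"
        )
    return start, end


# ---------------------------------------------------------------------------
# Multi-model PDB I/O


def _scan_models(path) -> list:
    """Per-model atom identity keys, for congruence errors biotite cannot name."""
    models = []
    current = []
    in_model = False
    seen_model_record = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                seen_model_record = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
            elif rec in ("ATOM  ", "HETATM"):
                key = (line[12:16].strip(), line[17:20].strip(),
                       line[21], line[22:26].strip())
                current.append(key)
    if not seen_model_record:
        models = [current]
    elif in_model:
        # MODEL without ENDMDL: accept the trailing block
        models.append(current)
    return [m for m in models if m]


def read_multimodel_pdb(path) -> Ensemble:
    """Read a (possibly single-model) PDB file as an ensemble.

    The topology comes from the first model; atom order and identity are
    verified identical across models before coordinates are accepted.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    models = _scan_models(path)
    if not models:
        raise FormatError(f"{path}: no atom records found")
    ref = models[0]
    for i, model in enumerate(models[1:], start=2):
        if len(model) != len(ref):
            raise FormatError(
                f"{path}: model {i} has {len(model)} atoms, expected {len(ref)}"
            )
        if model != ref:
            j = next(k for k, (a, b) in enumerate(zip(ref, model)) if a != b)
            raise FormatError(
                f"{path}: model {i} atom {j + 1} is {model[j]}, expected {ref[j]}"
            )
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"{path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    element = stack.element
    if np.all(element == ""):
        element = np.asarray([n[:1] for n in stack.atom_name], dtype="U2")
    topology = Topology(
        serial=np.asarray(stack.atom_id, dtype=int),
        atom_name=np.asarray(stack.atom_name, dtype="U6"),
        res_name=np.asarray(stack.res_name, dtype="U4"),
        res_id=np.asarray(stack.res_id, dtype=int),
        chain_id=np.asarray(stack.chain_id, dtype="U2"),
        element=np.asarray(element, dtype="U2"),
    )
    return Ensemble(topology=topology, coords=np.asarray(stack.coord, dtype=float))


def write_multimodel_pdb(ens: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB, MODEL records numbered from 1."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    top = ens.topology
    n = top.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    stack.coord = np.asarray(ens.coords, dtype=np.float32)
    stack.chain_id = top.chain_id.astype("U4")
    stack.res_id = top.res_id.copy()
    stack.res_name = top.res_name.astype("U5")
    stack.atom_name = top.atom_name.astype("U6")
    stack.element = top.element.astype("U2")
    stack.hetero = np.zeros(n, dtype=bool)
    stack.set_annotation("atom_id", top.serial.copy())
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
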