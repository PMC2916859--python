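"""Cα dynamic cross-correlation (covariance) maps.

The map reported here is the normalized cross-correlation of atomic
displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

with displacements taken about the windowed mean structure after per-frame
superposition on a fit selection (the same convention as the RMSF module).
Entries lie in [-1, 1], the diagonal is exactly 1, and anti-correlated
motions (e.g. the loop around the DNA-reading lysine moving against the
dimerization interface) appear as negative blocks.  The raw 3n x 3n
covariance is available behind a flag for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ensemble_io import FULL_WINDOW, Ensemble, FrameWindow
from .errors import MappingError
from .geom_descriptors import _indices, superposed_window


@dataclass
class CovarianceMap:
    """Normalized cross-correlation matrix with atom labels.

    Square and symmetric when produced by :func:`covariance_map`;
    rectangular after an asymmetric :func:`submap` extraction, in which
    case ``col_labels`` names the columns.  Zero-variance atoms carry NaN
    in their row/column (undefined, not 0).
    """

    labels: Sequence[tuple]  # (chain_id, res_id) per row atom
    matrix: np.ndarray
    col_labels: Optional[Sequence[tuple]] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        ncols = len(self.col_labels) if self.col_labels is not None else len(self.labels)
        if self.matrix.shape != (len(self.labels), ncols):
            raise ValueError("matrix shape does not match labels")

    def to_dataframe(self):
        import pandas as pd

        rows = [f"{c}:{r}" for c, r in self.labels]
        cols = [
            f"{c}:{r}" for c, r in (self.col_labels or self.labels)
        ]
        return pd.DataFrame(self.matrix, index=rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")


def covariance_map(
    ens: Ensemble,
    sel,
    fit_sel: Optional[object] = None,
    window: FrameWindow = FULL_WINDOW,
    raw: bool = False,
) -> CovarianceMap:
    """Normalized dynamic cross-correlation of the selected atoms.

    With ``raw=True`` the un-normalized 3x3-block trace covariance
    <dr_i . dr_j> is returned instead.
    """
    idx = _indices(ens, sel)
    start, end = None, None
    coords, (start, end) = superposed_window(ens, window, fit_sel)
    if end - start < 2:
        raise MappingError("covariance needs at least 2 frames in the window")
    sub = coords[:, idx, :]
    disp = sub - sub.mean(axis=0)
    m, n, _ = disp.shape
    flat = disp.reshape(m, -1)
    # <dr_i . dr_j> as a block-trace of the full covariance
    dots = np.einsum("mik,mjk->ij", disp, disp) / m
    top = ens.topology
    labels = [(top.chain_id[i], int(top.res_id[i])) for i in idx]
    if raw:
        return CovarianceMap(labels=labels, matrix=dots)
    var = np.diag(dots).copy()
    # numerically zero variance (superposition float noise is ~1e-30 Å^2)
    zero = var <= 1e-18
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.sqrt(np.outer(var, var))
        matrix = np.where(norm > 0, dots / np.where(norm > 0, norm, 1.0), np.nan)
    matrix[zero, :] = np.nan
    matrix[:, zero] = np.nan
    np.fill_diagonal(matrix, np.where(zero, np.nan, 1.0))
    return CovarianceMap(labels=labels, matrix=matrix)


def submap(cmap: CovarianceMap, row_range: tuple, col_range: Optional[tuple] = None) -> CovarianceMap:
    """Extract the sub-matrix for residue-number ranges (inclusive bounds).

    ``row_range``/``col_range`` are (lo, hi) residue-number pairs; when
    ``col_range`` is omitted the row range applies to both axes and a square
    symmetric submap is returned.
    """
    if col_range is None:
        col_range = row_range
    res = np.asarray([r for _, r in cmap.labels])

    def pick(rng):
        lo, hi = rng
        if lo > hi:
            raise ValueError(f"empty residue range {rng}")
        mask = (res >= lo) & (res <= hi)
        if not mask.any():
            raise KeyError(f"no residues in range {rng}")
        return np.nonzero(mask)[0]

    rows = pick(row_range)
    cols = pick(col_range)
    sub = cmap.matrix[np.ix_(rows, cols)]
    if np.array_equal(rows, cols):
        return CovarianceMap(labels=[cmap.labels[i] for i in rows], matrix=sub)
    return CovarianceMap(
        labels=[cmap.labels[i] for i in rows],
        matrix=sub,
        col_labels=[cmap.labels[j] for j in cols],
    )
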