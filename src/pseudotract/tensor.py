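"""Per-voxel diffusion tensor fitting and scalar metric maps.

The tensor D is estimated by ordinary (unweighted) log-linear least
squares of the Stejskal-Tanner relation

    ln S_k = ln S0 - b_k g_k^T D g_k

which is exact on noise-free signals and deterministic. S0 is the fitted
intercept, so all volumes (not only the b=0 ones) inform it. From the
sorted eigenvalues l1 >= l2 >= l3 the four scalar metrics are

    MD = (l1 + l2 + l3) / 3          mean diffusivity, mm^2/s
    L1 = l1                          axial diffusivity
    RD = (l2 + l3) / 2               radial diffusivity ("L2 and 3")
    FA = sqrt(3/2) * ||l - MD|| / ||l||

Negative eigenvalues (noise) are clamped to zero before metrics are
computed and counted for QC; the FA of an all-zero tensor is defined as
0 so background voxels never produce NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DwiVolume, GradientTable, ScalarMap

__all__ = ["TensorField", "fit_tensor", "scalar_maps", "eigensystem", "metrics_from_eigenvalues"]

_SIGNAL_FLOOR = 1e-12


@dataclass
class TensorField:
    """Voxel-wise symmetric tensors as 6 components (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz)."""

    tensors: np.ndarray  # (x, y, z, 6), mm^2/s
    s0: np.ndarray  # (x, y, z)
    mask: np.ndarray  # (x, y, z) bool, True where fitted
    affine: np.ndarray
    qc: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Full (x, y, z, 3, 3) symmetric matrices."""
        t = self.tensors
        m = np.empty(t.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = t[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 2]
        m[..., 1, 1] = t[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 4]
        m[..., 2, 2] = t[..., 5]
        return m


def tensor_to_components(D: np.ndarray) -> np.ndarray:
    """3x3 symmetric tensor(s) -> 6-component representation."""
    D = np.asarray(D, float)
    return np.stack(
        [D[..., 0, 0], D[..., 0, 1], D[..., 0, 2], D[..., 1, 1], D[..., 1, 2], D[..., 2, 2]],
        axis=-1,
    )


def fit_tensor(dwi: DwiVolume, mask: ScalarMap | None = None) -> TensorField:
    """Ordinary log-linear least-squares tensor fit.

    Exact (to float precision) on noise-free Stejskal-Tanner signals.
    Voxels outside ``mask`` are left unfitted (zero tensor, mask False).
    """
    gtab: GradientTable = dwi.gtab
    if not np.any(gtab.bvals > 0):
        raise ValueError("all-b0 gradient table: tensor fit impossible")
    X = gtab.design_matrix()
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("degenerate design matrix: need >= 6 independent directions + b0")
    pinv = np.linalg.pinv(X)

    shape = dwi.shape
    if mask is not None:
        m = np.asarray(mask.data, bool)
        if m.shape != shape:
            raise ValueError("mask shape does not match DWI grid")
    else:
        m = np.ones(shape, dtype=bool)

    signals = dwi.data[m]  # (n_vox, k)
    signals = np.maximum(signals, _SIGNAL_FLOOR)
    beta = np.log(signals) @ pinv.T  # (n_vox, 7)

    tensors = np.zeros(shape + (6,), dtype=float)
    s0 = np.zeros(shape, dtype=float)
    tensors[m] = beta[:, :6]
    s0[m] = np.exp(beta[:, 6])
    return TensorField(tensors=tensors, s0=s0, mask=m, affine=dwi.affine.copy())


def eigensystem(field: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Sorted eigenvalues (desc) and matching eigenvectors of every voxel.

    Returns ``(evals, evecs)`` with shapes (x,y,z,3) and (x,y,z,3,3);
    ``evecs[..., :, i]`` is the eigenvector of ``evals[..., i]``.
    """
    w, v = np.linalg.eigh(field.as_matrices())  # ascending
    return w[..., ::-1], v[..., :, ::-1]


def metrics_from_eigenvalues(evals: np.ndarray) -> dict[str, np.ndarray]:
    """FA/MD/L1/RD from eigenvalues (last axis length 3, any leading shape).

    Negative eigenvalues are clamped to 0 first; FA of an all-zero tensor
    is 0 by definition.
    """
    ev = np.maximum(np.asarray(evals, float), 0.0)
    ev = np.sort(ev, axis=-1)[..., ::-1]
    md = ev.mean(axis=-1)
    l1 = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    num = np.sqrt(((ev - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    return {"FA": fa, "MD": md, "L1": l1, "RD": rd}


def scalar_maps(field: TensorField) -> dict[str, ScalarMap]:
    """Derive the four scalar maps analysed in the study from a fitted field."""
    evals, _ = eigensystem(field)
    n_negative = int(np.sum((evals < 0) & field.mask[..., None]))
    field.qc["negative_eigenvalues_clamped"] = n_negative
    metrics = metrics_from_eigenvalues(evals)
    out = {}
    for kind in ("FA", "MD", "L1", "RD"):
        data = np.where(field.mask, metrics[kind], 0.0)
        out[kind] = ScalarMap(data=data, affine=field.affine.copy(), kind=kind)
    return out
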