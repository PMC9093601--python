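"""Domain containers and file IO for the tractography pipeline.

Conventions used throughout the package:

* voxel indices are 0-based;
* world space is RAS+ millimetres (``+x`` right, ``+y`` anterior,
  ``+z`` superior);
* streamline points are stored in world millimetres, which makes tract
  selection independent of the acquisition grid.

Volumes are NIfTI-1 (via :mod:`nibabel`), gradient tables are FSL-style
``bval``/``bvec`` text files, and tractograms are TrackVis ``.trk``
containers with a JSON fallback for debugging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DwiVolume",
    "ScalarMap",
    "Tractogram",
    "read_dwi",
    "write_dwi",
    "write_scalar_map",
    "read_scalar_map",
    "write_tractogram",
    "read_tractogram",
    "write_tractogram_json",
    "voxel_to_world",
    "world_to_voxel",
]

SCALAR_KINDS = ("FA", "MD", "L1", "RD", "S0", "T1like", "mask")


class GradientTableError(ValueError):
    """Raised when a bval/bvec table cannot support a tensor fit."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or 3 not in bvecs.shape:
            raise GradientTableError("bvecs must be an N x 3 (or 3 x N) array")
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        if bvecs.shape[0] != bvals.size:
            raise GradientTableError(
                f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(norms - 1.0)))
            raise GradientTableError(
                f"diffusion-weighted bvec {bad} has norm {norms[bad]:.4f}, expected 1"
            )
        # re-normalize tiny deviations so downstream design matrices are exact
        if dwi.any():
            bvecs = bvecs.copy()
            bvecs[dwi] /= norms[:, None]
        if int(np.sum(~dwi)) < 1:
            raise GradientTableError("gradient table needs at least one b=0 entry")
        if int(np.sum(dwi)) < 6 or _design_rank(bvals, bvecs) < 6:
            raise GradientTableError(
                "gradient table needs >= 6 non-collinear b>0 directions "
                "(tensor fit underdetermined)"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Design matrix X with ln(S_k) = X @ (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz, lnS0)."""
        return _design_matrix(self.bvals, self.bvecs)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    b = np.asarray(bvals, float)[:, None]
    g = np.asarray(bvecs, float)
    cols = np.stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ],
        axis=1,
    )
    return np.hstack([-b * cols, np.ones((len(g), 1))])


def _design_rank(bvals: np.ndarray, bvecs: np.ndarray) -> int:
    dwi = bvals > 0
    if not dwi.any():
        return 0
    X = _design_matrix(bvals[dwi], bvecs[dwi])[:, :6]
    return int(np.linalg.matrix_rank(X))


@dataclass
class DwiVolume:
    """4D diffusion-weighted signal with its grid affine and gradient table."""

    data: np.ndarray
    affine: np.ndarray
    gtab: GradientTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, k)")
        if self.data.shape[3] != len(self.gtab):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) does not match "
                f"gradient table length ({len(self.gtab)})"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if np.any(self.data < 0):
            raise ValueError("DWI signals must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ScalarMap:
    """3D scalar volume (FA, MD, L1, RD, S0, T1-like, or a binary mask)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str = "FA"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ScalarMap data must be 3D")
        if self.kind not in SCALAR_KINDS:
            raise ValueError(f"unknown scalar kind {self.kind!r}; one of {SCALAR_KINDS}")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class Tractogram:
    """Set of streamlines in world (RAS+ mm) coordinates with provenance."""

    streamlines: list
    space: str = "world-RAS-mm"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) array")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


# ---------------------------------------------------------------------------
# coordinate helpers


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(np.asarray(ijk, float))
    return ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(np.asarray(affine))
    xyz = np.atleast_2d(np.asarray(xyz, float))
    return xyz @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# NIfTI + bval/bvec


def _read_fsl_vector_file(path: Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().strip().splitlines():
        line = line.strip()
        if line:
            rows.append([float(tok) for tok in line.split()])
    return np.asarray(rows, dtype=float)


def read_dwi(nifti_path, bval_path, bvec_path) -> DwiVolume:
    """Load a 4D NIfTI plus FSL-dialect bval/bvec files.

    bvec layout (3 x N vs N x 3) is auto-detected from shape; both occur
    in the wild.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    bvals = _read_fsl_vector_file(Path(bval_path)).ravel()
    bvecs = _read_fsl_vector_file(Path(bvec_path))
    gtab = GradientTable(bvals, bvecs)
    return DwiVolume(data=data, affine=np.asarray(img.affine), gtab=gtab)


def write_dwi(dwi: DwiVolume, nifti_path, bval_path, bvec_path) -> None:
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine), str(nifti_path))
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in dwi.gtab.bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in dwi.gtab.bvecs[:, ax]) for ax in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def write_scalar_map(smap: ScalarMap, path) -> Path:
    """Write a scalar map as NIfTI-1; NaN background survives the round trip."""
    path = Path(path)
    nib.save(nib.Nifti1Image(smap.data.astype(np.float32), smap.affine), str(path))
    return path


def read_scalar_map(path, kind: str = "FA") -> ScalarMap:
    img = nib.load(str(path))
    return ScalarMap(np.asarray(img.get_fdata(), float), np.asarray(img.affine), kind)


# ---------------------------------------------------------------------------
# tractograms


def write_tractogram(tractogram: Tractogram, path) -> Path:
    """Write a TrackVis .trk file (world RAS+ mm points)."""
    path = Path(path)
    sl = nib.streamlines.Tractogram(
        streamlines=[s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    trk = nib.streamlines.TrkFile(sl)
    trk.save(str(path))
    return path


def read_tractogram(path, provenance: dict | None = None) -> Tractogram:
    try:
        trk = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed header / unknown format
        raise IOError(f"cannot read tractogram {path}: {exc}") from exc
    streamlines = [np.asarray(s, float) for s in trk.tractogram.streamlines]
    return Tractogram(streamlines=streamlines, provenance=provenance or {})


def write_tractogram_json(tractogram: Tractogram, path) -> Path:
    """Debug-friendly JSON fallback writer."""
    path = Path(path)
    payload = {
        "space": tractogram.space,
        "provenance": tractogram.provenance,
        "streamlines": [s.tolist() for s in tractogram.streamlines],
    }
    path.write_text(json.dumps(payload))
    return path
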