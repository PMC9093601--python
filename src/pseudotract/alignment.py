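"""Spatial normalization: ACPC alignment, affine registration, ROI
propagation and atlas-label metric extraction.

The cohort-specific ("pseudo-atlas") workflow registers the template
subject's FA map to every other subject and pushes the template's
resolved ROI gates through the recovered transform; the comparator
workflow warps a user-supplied label volume (a standard white-matter
atlas is such a volume) onto each subject and averages the scalar maps
inside each label.

Registration is a 12-parameter affine minimizing the mean squared
intensity difference, optimized with a deterministic gradient-free
pattern search over three resolution levels: no random restarts, no
seed, identical output for identical input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import ScalarMap
from .recipes import ResolvedGate

__all__ = [
    "RigidOrAffineTransform",
    "AtlasLabels",
    "acpc_align",
    "register_affine",
    "propagate_rois",
    "extract_label_metrics",
]


@dataclass
class RigidOrAffineTransform:
    """4x4 world-to-world (mm) transform with provenance."""

    matrix: np.ndarray
    kind: str  # rigid | affine
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (4, 4) or abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform matrix must be invertible 4x4")
        if self.kind == "rigid":
            R = self.matrix[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
                raise ValueError("rigid transform needs an orthonormal rotation block (det +1)")

    def inverse(self) -> "RigidOrAffineTransform":
        return RigidOrAffineTransform(np.linalg.inv(self.matrix), self.kind, dict(self.provenance))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def compose(self, other: "RigidOrAffineTransform") -> "RigidOrAffineTransform":
        """self o other: apply ``other`` first."""
        kind = "rigid" if self.kind == other.kind == "rigid" else "affine"
        return RigidOrAffineTransform(self.matrix @ other.matrix, kind)


@dataclass
class AtlasLabels:
    """Integer label volume + id->tract-name table (a white-matter atlas)."""

    labels: np.ndarray
    affine: np.ndarray
    table: dict  # label id -> tract name

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} missing from the atlas table")

    @property
    def coverage(self) -> set:
        present = set(np.unique(self.labels)) - {0}
        return {self.table[i] for i in present}


# ---------------------------------------------------------------------------
# ACPC


def acpc_align(landmarks: dict, volume: ScalarMap | None = None) -> RigidOrAffineTransform:
    """Rigid transform placing AC at the origin, AC->PC along -y, and the
    midsagittal plane at x = 0.

    ``landmarks`` maps ``AC``, ``PC`` and ``midsagittal`` (a third point
    on the midsagittal plane) to world-mm positions. ``volume`` is only
    carried into provenance.
    """
    ac = np.asarray(landmarks["AC"], float)
    pc = np.asarray(landmarks["PC"], float)
    ms = np.asarray(landmarks["midsagittal"], float)

    y_axis = ac - pc  # PC sits posterior: AC->PC direction becomes -y
    ny = np.linalg.norm(y_axis)
    in_plane = ms - ac
    x_axis = np.cross(y_axis, in_plane)
    nx = np.linalg.norm(x_axis)
    if ny < 1e-9 or nx < 1e-9 * max(ny, 1.0):
        raise ValueError("ACPC landmarks are collinear; cannot define the midsagittal plane")
    y_axis = y_axis / ny
    x_axis = x_axis / nx
    if x_axis[0] < 0:  # keep subject-right mapping to +x
        x_axis = -x_axis
    z_axis = np.cross(x_axis, y_axis)

    R = np.vstack([x_axis, y_axis, z_axis])  # world -> aligned rotation
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = -R @ ac
    return RigidOrAffineTransform(M, kind="rigid", provenance={"landmarks": {k: list(map(float, v)) for k, v in landmarks.items()}})


# ---------------------------------------------------------------------------
# affine registration (deterministic multiresolution pattern search)


def _params_to_matrix(p: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4: translation mm, rotation deg, scale, shear."""
    tx, ty, tz, rx, ry, rz, sx, sy, sz, kxy, kxz, kyz = p
    rx, ry, rz = np.deg2rad([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, np.cos(rx), -np.sin(rx)], [0, np.sin(rx), np.cos(rx)]])
    Ry = np.array([[np.cos(ry), 0, np.sin(ry)], [0, 1, 0], [-np.sin(ry), 0, np.cos(ry)]])
    Rz = np.array([[np.cos(rz), -np.sin(rz), 0], [np.sin(rz), np.cos(rz), 0], [0, 0, 1]])
    S = np.diag([sx, sy, sz])
    K = np.array([[1, kxy, kxz], [0, 1, kyz], [0, 0, 1]])
    M = np.eye(4)
    M[:3, :3] = Rz @ Ry @ Rx @ K @ S
    M[:3, 3] = [tx, ty, tz]
    return M


def _resample_to(moving: ScalarMap, fixed_shape, fixed_affine, matrix: np.ndarray, order=1) -> np.ndarray:
    """Pull ``moving`` onto the fixed grid under world map M: moving->fixed."""
    # fixed voxel -> fixed world -> (M^-1) moving world -> moving voxel
    A = np.linalg.inv(np.asarray(moving.affine)) @ np.linalg.inv(matrix) @ np.asarray(fixed_affine)
    return ndimage.affine_transform(
        np.asarray(moving.data, float),
        A[:3, :3],
        offset=A[:3, 3],
        output_shape=tuple(fixed_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )


def _level_maps(smap: ScalarMap, factor: int) -> ScalarMap:
    if factor == 1:
        return smap
    sm = ndimage.gaussian_filter(np.asarray(smap.data, float), sigma=factor / 2.0)
    down = sm[::factor, ::factor, ::factor]
    aff = np.asarray(smap.affine).copy()
    aff[:3, :3] *= factor
    return ScalarMap(down, aff, smap.kind)


def _msd(moving: ScalarMap, fixed: ScalarMap, matrix: np.ndarray) -> float:
    resampled = _resample_to(moving, fixed.data.shape, fixed.affine, matrix)
    f = np.asarray(fixed.data, float)
    support = (f > 0) | (resampled > 0)
    if not support.any():
        return np.inf
    return float(((resampled - f) ** 2)[support].mean())


def register_affine(
    moving: ScalarMap,
    fixed: ScalarMap,
    kind: str = "affine",
    levels: tuple = (4, 2, 1),
) -> RigidOrAffineTransform:
    """12-parameter affine (or 6-parameter rigid) minimizing mean squared
    difference, multiresolution, deterministic.

    Returns the world-to-world transform mapping moving-space mm to
    fixed-space mm.
    """
    p = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0], float)
    n_active = 6 if kind == "rigid" else 12
    init_steps = np.array([8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05])
    min_steps = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.002, 0.002, 0.002, 0.002, 0.002, 0.002])

    overlap = _msd(moving, fixed, _params_to_matrix(p))
    if not np.isfinite(overlap):
        raise ValueError("registration fields of view do not overlap at initialization")

    level_costs = []
    for factor in levels:
        mv = _level_maps(moving, factor)
        fx = _level_maps(fixed, factor)
        steps = init_steps * (1.0 if factor == max(levels) else 0.5 ** levels.index(factor))
        cost = _msd(mv, fx, _params_to_matrix(p))
        while np.any(steps[:n_active] > min_steps[:n_active]):
            improved = False
            for i in range(n_active):
                for sign in (+1, -1):
                    q = p.copy()
                    q[i] += sign * steps[i]
                    c = _msd(mv, fx, _params_to_matrix(q))
                    if c < cost - 1e-15:
                        p, cost = q, c
                        improved = True
            if not improved:
                steps = np.maximum(steps / 2.0, min_steps)
                if np.all(steps[:n_active] <= min_steps[:n_active]):
                    break
        full_cost = float(_msd(moving, fixed, _params_to_matrix(p)))
        if level_costs and full_cost > level_costs[-1]:
            # a coarse level may overfit its own grid; never let the full-
            # resolution cost regress between levels
            p, full_cost = prev_p, level_costs[-1]
        level_costs.append(full_cost)
        prev_p = p.copy()

    matrix = _params_to_matrix(p)
    prov = {"cost": level_costs[-1], "level_costs": level_costs, "params": p.tolist()}
    return RigidOrAffineTransform(matrix, kind="affine" if kind != "rigid" else "rigid", provenance=prov)


# ---------------------------------------------------------------------------
# ROI propagation and atlas extraction


def propagate_rois(
    template_gates: list[ResolvedGate],
    transform: RigidOrAffineTransform,
    subject_affine: np.ndarray,
    subject_shape: tuple,
) -> list[ResolvedGate]:
    """Map resolved gate masks from template space into a subject grid.

    ``transform`` maps template world to subject world; masks are pulled
    with nearest-neighbour resampling so they stay binary. An empty
    mapped mask is kept (polarity preserved) and flagged in ``note``;
    downstream selection then reports the tract as missing, mirroring
    how out-of-field ROIs produce missing data.
    """
    out = []
    subject_affine = np.asarray(subject_affine, float)
    for gate in template_gates:
        A = np.linalg.inv(np.asarray(gate.affine)) @ np.linalg.inv(transform.matrix) @ subject_affine
        mapped = ndimage.affine_transform(
            gate.mask.astype(np.float32),
            A[:3, :3],
            offset=A[:3, 3],
            output_shape=tuple(subject_shape),
            order=0,
            mode="constant",
            cval=0.0,
        ).astype(bool)
        note = gate.note
        if gate.mask.any() and not mapped.any():
            note = (note + " [mapped outside subject field of view]").strip()
        out.append(ResolvedGate(mask=mapped, polarity=gate.polarity, affine=subject_affine, note=note))
    return out


def extract_label_metrics(
    maps: dict,
    atlas: AtlasLabels,
    transform: RigidOrAffineTransform,
) -> pd.DataFrame:
    """Mean FA/MD/L1/RD per atlas label after warping labels onto the subject.

    ``transform`` maps atlas world to subject world. Labels mapping to
    zero voxels yield missing (NaN) metric entries, not zeros. Partial
    atlases (covering only a subset of the study tracts) are supported.
    """
    ref = next(iter(maps.values()))
    subject_affine = np.asarray(ref.affine)
    A = np.linalg.inv(np.asarray(atlas.affine)) @ np.linalg.inv(transform.matrix) @ subject_affine
    warped = ndimage.affine_transform(
        atlas.labels.astype(np.int32),
        A[:3, :3],
        offset=A[:3, 3],
        output_shape=ref.data.shape,
        order=0,
        mode="constant",
        cval=0,
    )
    rows = []
    for label_id in sorted(set(np.unique(atlas.labels)) - {0}):
        tract = atlas.table[label_id]
        sel = warped == label_id
        row = {"label": int(label_id), "tract": tract, "n_voxels": int(sel.sum())}
        for name, smap in maps.items():
            row[name] = float(np.asarray(smap.data)[sel].mean()) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
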