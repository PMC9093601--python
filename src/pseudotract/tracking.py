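"""Whole-brain deterministic streamline tractography.

Streamlines follow the principal eigenvector of the diffusion tensor
with fixed-step Euler integration (FACT-style). The direction at an
off-grid point is the FA-weighted trilinear blend of the surrounding
voxels' principal eigenvectors, each sign-aligned to the incoming
direction before blending (eigenvectors are axes, not vectors).
Integration runs bidirectionally from every seed; a streamline stops
when interpolated FA drops below ``fa_threshold``, the per-step turning
angle exceeds ``angle_threshold``, it leaves the volume, or it reaches
``max_length``. Streamlines shorter than ``min_length`` are discarded.
Seeds sit on a fixed subvoxel grid, so the output is fully
deterministic and independent of seed ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import ScalarMap, Tractogram, voxel_to_world
from .tensor import TensorField, eigensystem

__all__ = ["TrackingParams", "track_whole_brain"]


@dataclass(frozen=True)
class TrackingParams:
    step_size: float = 1.35  # mm; default 0.5 x the 2.7 mm voxel
    fa_threshold: float = 0.2
    angle_threshold: float = 45.0  # degrees per step
    seed_density: int = 1  # seeds per voxel (subvoxel grid when > 1)
    min_length: float = 10.0  # mm
    max_length: float = 300.0  # mm

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not (0 <= self.fa_threshold < 1):
            raise ValueError("fa_threshold must lie in [0, 1)")
        if not (0 < self.angle_threshold <= 90):
            raise ValueError("angle_threshold must lie in (0, 90] degrees")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be < max_length")


def _trilinear_weights(coords: np.ndarray, shape: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Corner indices (n,8,3) and weights (n,8) for voxel-space points."""
    base = np.floor(coords).astype(int)
    frac = coords - base
    corners = np.zeros((len(coords), 8, 3), dtype=int)
    weights = np.ones((len(coords), 8))
    for c in range(8):
        bits = np.array([(c >> 2) & 1, (c >> 1) & 1, c & 1])
        corners[:, c, :] = base + bits
        w = np.where(bits[None, :] == 1, frac, 1.0 - frac)
        weights[:, c] = w.prod(axis=1)
    np.clip(corners, 0, np.asarray(shape) - 1, out=corners)
    return corners, weights


def _interp_scalar(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    corners, weights = _trilinear_weights(coords, volume.shape)
    vals = volume[corners[..., 0], corners[..., 1], corners[..., 2]]
    return (vals * weights).sum(axis=1)


def _interp_direction(
    evecs: np.ndarray, fa: np.ndarray, coords: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """FA-weighted, sign-aligned trilinear blend of principal eigenvectors."""
    corners, weights = _trilinear_weights(coords, fa.shape)
    vecs = evecs[corners[..., 0], corners[..., 1], corners[..., 2]]  # (n, 8, 3)
    favals = fa[corners[..., 0], corners[..., 1], corners[..., 2]]  # (n, 8)
    dots = np.einsum("ncj,nj->nc", vecs, reference)
    vecs = vecs * np.sign(np.where(dots == 0, 1.0, dots))[..., None]
    blended = np.einsum("ncj,nc->nj", vecs, weights * favals)
    norms = np.linalg.norm(blended, axis=1)
    ok = norms > 1e-12
    blended[ok] /= norms[ok, None]
    return np.where(ok[:, None], blended, 0.0)


def track_whole_brain(
    field: TensorField,
    fa: ScalarMap,
    params: TrackingParams = TrackingParams(),
    seed_mask: np.ndarray | None = None,
    seeds_vox: np.ndarray | None = None,
) -> Tractogram:
    """Deterministic whole-brain tractography over a fitted tensor field."""
    if field.shape != fa.data.shape:
        raise ValueError("tensor field and FA map must share the grid")
    if not np.allclose(field.affine, fa.affine):
        raise ValueError("tensor field and FA map must share the affine")
    if np.any(~np.isfinite(field.tensors[field.mask])):
        raise ValueError("NaN/inf tensor components inside the mask")

    fa_grid = np.nan_to_num(np.asarray(fa.data, float))
    evals, evecs_full = eigensystem(field)
    e1 = evecs_full[..., :, 0]  # principal eigenvector per voxel
    e1 = np.where(field.mask[..., None], e1, 0.0)

    affine = np.asarray(field.affine, float)
    inv_affine = np.linalg.inv(affine)

    if seeds_vox is None:
        if seed_mask is None:
            seed_mask = fa_grid > params.fa_threshold
        seed_vox = np.argwhere(seed_mask)
        if len(seed_vox) == 0:
            return Tractogram(streamlines=[], provenance={"params": asdict(params), "n_seeds": 0})
        m = max(1, round(params.seed_density ** (1.0 / 3.0)))
        offsets = (np.arange(m) + 0.5) / m - 0.5
        sub = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), -1).reshape(-1, 3)
        seeds_vox = (seed_vox[:, None, :] + sub[None, :, :]).reshape(-1, 3)
    else:
        seeds_vox = np.atleast_2d(np.asarray(seeds_vox, float))
        if len(seeds_vox) == 0:
            return Tractogram(streamlines=[], provenance={"params": asdict(params), "n_seeds": 0})
    seeds_world = voxel_to_world(affine, seeds_vox)

    shape = fa_grid.shape
    seed_dirs = _interp_direction(
        e1, fa_grid, seeds_vox, reference=np.ones((len(seeds_vox), 3)) / np.sqrt(3)
    )
    valid = np.linalg.norm(seed_dirs, axis=1) > 0.5
    seeds_world = seeds_world[valid]
    seed_dirs = seed_dirs[valid]
    n = len(seeds_world)

    def propagate(start: np.ndarray, first_dir: np.ndarray) -> list:
        """March all streamlines one direction; returns per-seed point lists."""
        pts: list[list[np.ndarray]] = [[] for _ in range(n)]
        pos = start.copy()
        direction = first_dir.copy()
        lengths = np.zeros(n)
        active = np.ones(n, bool)
        max_steps = int(np.ceil(params.max_length / params.step_size)) + 1
        cos_thresh = np.cos(np.deg2rad(params.angle_threshold))
        for _ in range(max_steps):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            nxt = pos[idx] + params.step_size * direction[idx]
            vox = nxt @ inv_affine[:3, :3].T + inv_affine[:3, 3]
            inb = np.all((vox >= 0) & (vox <= np.asarray(shape) - 1), axis=1)
            fa_next = np.zeros(idx.size)
            fa_next[inb] = _interp_scalar(fa_grid, vox[inb])
            ok = inb & (fa_next >= params.fa_threshold) & (lengths[idx] + params.step_size <= params.max_length)
            stopped = idx[~ok]
            active[stopped] = False
            keep = idx[ok]
            if keep.size == 0:
                continue
            nxt_ok = nxt[ok]
            for i, k in enumerate(keep):
                pts[k].append(nxt_ok[i])
            pos[keep] = nxt_ok
            lengths[keep] += params.step_size
            new_dir = _interp_direction(e1, fa_grid, vox[ok], reference=direction[keep])
            norms = np.linalg.norm(new_dir, axis=1)
            cosang = np.einsum("nj,nj->n", new_dir, direction[keep])
            good = (norms > 0.5) & (cosang >= cos_thresh - 1e-12)
            active[keep[~good]] = False
            direction[keep[good]] = new_dir[good]
        return pts

    forward = propagate(seeds_world, seed_dirs)
    backward = propagate(seeds_world, -seed_dirs)

    streamlines = []
    for i in range(n):
        points = backward[i][::-1] + [seeds_world[i]] + forward[i]
        if len(points) < 2:
            continue
        arr = np.asarray(points)
        length = np.linalg.norm(np.diff(arr, axis=0), axis=1).sum()
        if length >= params.min_length:
            streamlines.append(arr)

    provenance = {"params": asdict(params), "n_seeds": int(n)}
    return Tractogram(streamlines=streamlines, provenance=provenance)
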