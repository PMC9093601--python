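"""Synthetic DWI phantom cohorts with complete ground truth.

A phantom subject is a brain-like volume built from geometric primitives
in a canonical (template) frame whose origin is the anterior commissure
(AC), with RAS+ axes and the posterior commissure (PC) on the -y axis:

* an inner-skull ellipsoid filled with isotropic "tissue" diffusion;
* paired lateral ventricles (ellipsoid bodies with frontal-horn
  protrusions anterior to the AC) filled with CSF-like isotropic
  diffusion, optionally enlarged per subject;
* white-matter bundles (tubes around straight segments or circular
  arcs) carrying a prescribed-eigenvalue tensor whose principal axis
  follows the local centerline tangent: by default a midline
  corpus-callosum-like arch, a vertical bilateral bundle lateral to the
  ventricles (internal-capsule-like) and a long anterior-posterior
  bilateral bundle (fronto-occipital-like);
* box-shaped landmark regions (thalamus, pons, brainstem, cingulum,
  lobes, ...) that the tract-recipe resolver can reference.

Each subject receives an independent rigid pose (rotation + translation
drawn inside ``pose_jitter``); the image grid stays axis-aligned while
the anatomy is rendered rotated inside it, emulating a non-ACPC-aligned
acquisition. DWI signals follow the Stejskal-Tanner equation from the
posed tensor field, with optional Rician noise. Everything needed for
oracles (masks, pose, landmarks, analytic per-bundle metrics) is
recorded in the truth structure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .io import DwiVolume, GradientTable, ScalarMap
from .tensor import TensorField, metrics_from_eigenvalues, tensor_to_components

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "PhantomSubject",
    "default_gradient_table",
    "default_phantom_spec",
    "generate_subject",
    "generate_cohort",
]

CSF_DIFFUSIVITY = 3.0e-3  # mm^2/s, free-water-like
TISSUE_DIFFUSIVITY = 0.9e-3  # mm^2/s, isotropic background (grey-matter-like MD)
DEFAULT_S0 = 1000.0


@dataclass(frozen=True)
class BundleSpec:
    """A tube of prescribed-eigenvalue tensors around a parametric centerline.

    ``centerline`` is one of
      {"type": "straight", "start": (3,), "end": (3,)}
      {"type": "arc", "center": (3,), "radius": float, "u": (3,), "v": (3,),
       "theta": (theta0, theta1) radians}   (circle c + R(cos t * u + sin t * v))
      {"type": "polyline", "points": (n, 3)}
    all coordinates in template-frame mm.
    """

    name: str
    centerline: dict
    radius: float  # tube radius, mm
    eigenvalues: tuple  # (l1, l2, l3), mm^2/s
    laterality: str = "midline"  # midline | left | right

    def __post_init__(self):
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(f"bundle {self.name}: need l1 >= l2 >= l3 > 0")
        if self.radius <= 0:
            raise ValueError(f"bundle {self.name}: radius must be positive")

    def analytic_metrics(self) -> dict[str, float]:
        m = metrics_from_eigenvalues(np.asarray(self.eigenvalues, float))
        return {k: float(v) for k, v in m.items()}

    def distance_and_tangent(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(inside, distance-to-centerline, tangent) for template-frame points."""
        c = self.centerline
        if c["type"] == "straight":
            return _straight_geometry(pts, np.asarray(c["start"], float), np.asarray(c["end"], float), self.radius)
        if c["type"] == "arc":
            return _arc_geometry(
                pts,
                np.asarray(c["center"], float),
                float(c["radius"]),
                np.asarray(c["u"], float),
                np.asarray(c["v"], float),
                float(c["theta"][0]),
                float(c["theta"][1]),
                self.radius,
            )
        if c["type"] == "polyline":
            points = np.asarray(c["points"], float)
            best_inside = np.zeros(len(pts), bool)
            best_dist = np.full(len(pts), np.inf)
            best_tan = np.zeros((len(pts), 3))
            for a, b in zip(points[:-1], points[1:]):
                inside, dist, tan = _straight_geometry(pts, a, b, self.radius)
                closer = dist < best_dist
                best_dist = np.where(closer, dist, best_dist)
                best_tan[closer] = tan[closer]
                best_inside |= inside
            return best_inside, best_dist, best_tan
        raise ValueError(f"unknown centerline type {c['type']!r}")

    def arc_length(self) -> float:
        c = self.centerline
        if c["type"] == "straight":
            return float(np.linalg.norm(np.asarray(c["end"], float) - np.asarray(c["start"], float)))
        if c["type"] == "arc":
            return float(c["radius"]) * abs(float(c["theta"][1]) - float(c["theta"][0]))
        pts = np.asarray(c["points"], float)
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _straight_geometry(pts, a, b, radius):
    ab = b - a
    length = np.linalg.norm(ab)
    u = ab / length
    rel = pts - a
    proj = rel @ u
    perp = rel - proj[:, None] * u
    dist = np.linalg.norm(perp, axis=1)
    inside = (proj >= 0) & (proj <= length) & (dist <= radius)
    tangent = np.broadcast_to(u, pts.shape)
    return inside, dist, tangent


def _arc_geometry(pts, center, arc_radius, u, v, theta0, theta1, radius):
    u = u / np.linalg.norm(u)
    v = v - (v @ u) * u
    v = v / np.linalg.norm(v)
    rel = pts - center
    x = rel @ u
    y = rel @ v
    w = rel - x[:, None] * u - y[:, None] * v
    theta = np.arctan2(y, x)
    in_range = (theta >= theta0) & (theta <= theta1)
    ring = np.sqrt((np.hypot(x, y) - arc_radius) ** 2 + (w**2).sum(axis=1))
    inside = in_range & (ring <= radius)
    tangent = -np.sin(theta)[:, None] * u + np.cos(theta)[:, None] * v
    return inside, ring, tangent


# ---------------------------------------------------------------------------
# template geometry (canonical, AC at origin, mm)

AC_T = np.array([0.0, 0.0, 0.0])
PC_T = np.array([0.0, -25.0, 0.0])
MIDSAGITTAL_T = np.array([0.0, 0.0, 40.0])

SKULL_CENTER = np.array([0.0, -5.0, 5.0])
SKULL_SEMIAXES = np.array([65.0, 75.0, 60.0])

# per-side ventricle: ellipsoid body + frontal-horn protrusion (anterior of AC)
VENT_BODY_CENTER = np.array([11.0, -5.0, 8.0])  # x mirrored per side
VENT_BODY_SEMIAXES = np.array([7.0, 25.0, 8.0])
VENT_HORN_CENTER = np.array([14.0, 14.0, 8.0])
VENT_HORN_SEMIAXES = np.array([6.0, 8.0, 6.0])

LANDMARK_BOXES = {
    # name -> (lo, hi) template-frame mm; {side} boxes are mirrored in x
    "thalamus_right": ([6.0, -28.0, -2.0], [20.0, -8.0, 12.0]),
    "thalamus_left": ([-20.0, -28.0, -2.0], [-6.0, -8.0, 12.0]),
    "pons": ([-10.0, -32.0, -40.0], [10.0, -18.0, -24.0]),
    "brainstem": ([-10.0, -32.0, -50.0], [10.0, -14.0, -20.0]),
    "cingulum": ([-5.0, -46.0, 46.0], [5.0, 18.0, 53.0]),
    "occipital_lobe": ([-45.0, -70.0, -25.0], [45.0, -44.0, 35.0]),
    "temporal_lobe_right": ([25.0, -20.0, -40.0], [50.0, 32.0, -10.0]),
    "temporal_lobe_left": ([-50.0, -20.0, -40.0], [-25.0, 32.0, -10.0]),
    "frontal_lobe": ([-45.0, 30.0, -20.0], [45.0, 65.0, 40.0]),
    "parieto_occipital_sulcus": ([-45.0, -48.0, 0.0], [45.0, -44.0, 40.0]),
}


def default_gradient_table(n_directions: int = 41, n_b0: int = 5, b_value: float = 1000.0) -> GradientTable:
    """41 directions at b=1,000 s/mm^2 plus 5 b=0 volumes, evenly spread.

    Directions come from a deterministic golden-ratio spiral on the
    hemisphere (electrostatic-repulsion-style spread).
    """
    k = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    z = (k + 0.5) / n_directions  # hemisphere
    phi = 2 * np.pi * k / golden
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)


def default_bundles() -> list[BundleSpec]:
    """CC-like midline arch, PLIC-like vertical pair, IFO-like A-P pair."""
    bundles = [
        BundleSpec(
            name="cc",
            centerline={
                "type": "arc",
                "center": [0.0, -5.0, 15.0],
                "radius": 30.0,
                "u": [0.0, 1.0, 0.0],
                "v": [0.0, 0.0, 1.0],
                "theta": (0.0, np.pi),
            },
            radius=6.0,
            eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3),
            laterality="midline",
        )
    ]
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        bundles.append(
            BundleSpec(
                name=f"plic_{side}",
                centerline={"type": "straight", "start": [sgn * 26.0, -8.0, -15.0], "end": [sgn * 26.0, -8.0, 25.0]},
                radius=4.0,
                eigenvalues=(1.6e-3, 0.35e-3, 0.35e-3),
                laterality=side,
            )
        )
        bundles.append(
            BundleSpec(
                name=f"ifo_{side}",
                centerline={"type": "straight", "start": [sgn * 34.0, -48.0, -22.0], "end": [sgn * 34.0, 48.0, -22.0]},
                radius=4.5,
                eigenvalues=(1.5e-3, 0.4e-3, 0.4e-3),
                laterality=side,
            )
        )
    return bundles


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic cohort."""

    shape: tuple = (64, 64, 64)
    voxel_size: float = 2.7  # mm, isotropic (mirrors the acquisition emulated)
    bundles: list = field(default_factory=default_bundles)
    ventricle_scale: float = 1.0  # multiplies ventricle semi-axes (graded enlargement)
    gtab: GradientTable = field(default_factory=default_gradient_table)
    noise_sigma: float = 0.02  # Rician sigma relative to S0 (SNR 50)
    pose_jitter_deg: float = 10.0  # max rigid rotation
    pose_jitter_mm: float = 5.0  # max translation
    seed: int = 0
    s0: float = DEFAULT_S0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        half = np.asarray(self.shape) * self.voxel_size / 2.0
        for b in self.bundles:
            if b.radius <= self.voxel_size:
                raise ValueError(f"bundle {b.name}: radius must exceed the voxel size")
            # crude containment check on centerline endpoints
            c = b.centerline
            if c["type"] == "straight":
                pts = np.array([c["start"], c["end"]], float)
            elif c["type"] == "arc":
                t = np.linspace(c["theta"][0], c["theta"][1], 32)
                u = np.asarray(c["u"], float)
                v = np.asarray(c["v"], float)
                pts = np.asarray(c["center"], float) + c["radius"] * (
                    np.cos(t)[:, None] * u + np.sin(t)[:, None] * v
                )
            else:
                pts = np.asarray(c["points"], float)
            if np.any(np.abs(pts) > half - b.radius):
                raise ValueError(f"bundle {b.name} does not fit inside the grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) * self.voxel_size / 2.0
        return aff


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The default study conditions: 64^3 grid at 2.7 mm, 41x b=1000 + 5 b0,
    Rician sigma 0.02, pose jitter up to 10 deg / 5 mm."""
    return PhantomSpec(**overrides)


@dataclass
class PhantomTruth:
    """Everything an oracle needs about one generated subject."""

    tensor_field: TensorField
    structures: dict  # name -> bool array on the subject grid
    landmarks: dict  # AC / PC / midsagittal, world mm (posed)
    pose: np.ndarray  # 4x4 world transform: subject_world = pose @ template_coord
    bundle_metrics: dict  # bundle name -> analytic FA/MD/L1/RD
    overlap_mask: np.ndarray
    analytic: dict  # analytic widths etc.

    def structure_map(self, name: str, affine: np.ndarray) -> ScalarMap:
        return ScalarMap(self.structures[name].astype(float), affine, kind="mask")


@dataclass
class PhantomSubject:
    subject_id: str
    dwi: DwiVolume
    truth: PhantomTruth


def _rigid_pose(rng: np.random.Generator, max_deg: float, max_mm: float) -> np.ndarray:
    pose = np.eye(4)
    if max_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(-max_deg, max_deg))
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        pose[:3, :3] = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    if max_mm > 0:
        pose[:3, 3] = rng.uniform(-max_mm, max_mm, size=3)
    return pose


def _ellipsoid(pts: np.ndarray, center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    return (((pts - center) / semiaxes) ** 2).sum(axis=1) <= 1.0


def _box(pts: np.ndarray, lo, hi) -> np.ndarray:
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    return np.all((pts >= lo) & (pts <= hi), axis=1)


def _orthonormal_frame(tangent: np.ndarray) -> np.ndarray:
    """(n, 3, 3) rotation whose first column is the unit tangent."""
    t = tangent / np.linalg.norm(tangent, axis=1, keepdims=True)
    helper = np.where(np.abs(t[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    e2 = np.cross(t, helper)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(t, e2)
    return np.stack([t, e2, e3], axis=2)


def generate_subject(spec: PhantomSpec, subject_seed: int, subject_id: str | None = None) -> PhantomSubject:
    """Render one posed subject: DWI volume plus full ground truth."""
    rng = np.random.default_rng(subject_seed)
    pose = _rigid_pose(rng, spec.pose_jitter_deg, spec.pose_jitter_mm)
    R, tau = pose[:3, :3], pose[:3, 3]

    affine = spec.affine
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    tmpl = (world - tau) @ R  # pose^-1: template-frame coordinates of every voxel

    n_vox = len(tmpl)
    skull = _ellipsoid(tmpl, SKULL_CENTER, SKULL_SEMIAXES)

    vent_sides = {}
    horns = np.zeros(n_vox, bool)
    vs = spec.ventricle_scale
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        mirror = np.array([sgn, 1.0, 1.0])
        body = _ellipsoid(tmpl, VENT_BODY_CENTER * mirror, VENT_BODY_SEMIAXES * vs)
        horn = _ellipsoid(tmpl, VENT_HORN_CENTER * mirror, VENT_HORN_SEMIAXES * vs)
        vent_sides[side] = body | horn
        horns |= horn
    ventricles = vent_sides["left"] | vent_sides["right"]

    # tensor field in the template frame
    tensors_t = np.zeros((n_vox, 3, 3))
    tensors_t[skull] = TISSUE_DIFFUSIVITY * np.eye(3)
    tensors_t[ventricles] = CSF_DIFFUSIVITY * np.eye(3)

    bundle_masks = {}
    claimed = np.zeros(n_vox, bool)
    overlap = np.zeros(n_vox, bool)
    for bundle in spec.bundles:
        inside, _, tangent = bundle.distance_and_tangent(tmpl)
        bundle_masks[bundle.name] = inside
        overlap |= inside & claimed  # later bundle wins on overlap, flagged
        claimed |= inside
        idx = np.flatnonzero(inside)
        frame = _orthonormal_frame(tangent[idx])
        lam = np.diag(np.asarray(bundle.eigenvalues, float))
        tensors_t[idx] = np.einsum("nij,jk,nlk->nil", frame, lam, frame)

    # pose the tensors into the subject (scanner) frame
    tensors_w = np.einsum("ij,njk,lk->nil", R, tensors_t, R)

    s0 = np.where(skull, spec.s0, 0.0)
    comps = tensor_to_components(tensors_w)
    X6 = spec.gtab.design_matrix()[:, :6]
    signals = s0[:, None] * np.exp(comps @ X6.T)

    if spec.noise_sigma > 0:
        sig = spec.noise_sigma * spec.s0
        e1 = rng.normal(0.0, sig, signals.shape)
        e2 = rng.normal(0.0, sig, signals.shape)
        signals = np.sqrt((signals + e1) ** 2 + e2**2)

    grid = lambda a: a.reshape(spec.shape)
    dwi = DwiVolume(data=signals.reshape(spec.shape + (len(spec.gtab),)), affine=affine, gtab=spec.gtab)

    structures = {name: grid(mask) for name, mask in bundle_masks.items()}
    structures["corpus_callosum"] = structures.get("cc", grid(np.zeros(n_vox, bool)))
    for side in ("left", "right"):
        if f"plic_{side}" in structures:
            structures[f"corticospinal_tract_{side}"] = structures[f"plic_{side}"]
        structures[f"ventricle_{side}"] = grid(vent_sides[side])
    structures["ventricles"] = grid(ventricles)
    structures["frontal_horns"] = grid(horns)
    structures["skull_inner"] = grid(skull)
    for name, (lo, hi) in LANDMARK_BOXES.items():
        structures[name] = grid(_box(tmpl, lo, hi))
    structures["thalamus"] = structures["thalamus_left"] | structures["thalamus_right"]

    truth_field = TensorField(
        tensors=tensor_to_components(tensors_w).reshape(spec.shape + (6,)),
        s0=s0.reshape(spec.shape),
        mask=grid(skull),
        affine=affine,
    )
    landmarks = {
        "AC": R @ AC_T + tau,
        "PC": R @ PC_T + tau,
        "midsagittal": R @ MIDSAGITTAL_T + tau,
    }
    analytic = {
        "frontal_horn_width_mm": 2 * (VENT_HORN_CENTER[0] + VENT_HORN_SEMIAXES[0] * vs),
        "cranial_width_mm": 2 * SKULL_SEMIAXES[0],
        "ventricle_scale": vs,
    }
    truth = PhantomTruth(
        tensor_field=truth_field,
        structures=structures,
        landmarks=landmarks,
        pose=pose,
        bundle_metrics={b.name: b.analytic_metrics() for b in spec.bundles},
        overlap_mask=grid(overlap),
        analytic=analytic,
    )
    return PhantomSubject(subject_id=subject_id or f"sub-{subject_seed}", dwi=dwi, truth=truth)


def apply_cohort_shift(spec: PhantomSpec, cohort_shift: dict | None) -> PhantomSpec:
    """Return a spec whose bundle eigenvalues are offset per bundle name.

    ``cohort_shift`` maps bundle name (or a prefix such as ``"plic"``)
    to a 3-vector of eigenvalue offsets (mm^2/s); used to emulate
    CN / EMCI / AD-like cohort-level metric shifts.
    """
    if not cohort_shift:
        return spec
    new_bundles = []
    for b in spec.bundles:
        offset = None
        for key, val in cohort_shift.items():
            if b.name == key or b.name.startswith(key + "_"):
                offset = np.asarray(val, float)
        if offset is None:
            new_bundles.append(b)
        else:
            ev = tuple(np.asarray(b.eigenvalues, float) + offset)
            new_bundles.append(replace(b, eigenvalues=ev))
    out = copy.copy(spec)
    out.bundles = new_bundles
    return out


def generate_cohort(
    spec: PhantomSpec,
    n: int,
    cohort_shift: dict | None = None,
    seed: int | None = None,
) -> list[PhantomSubject]:
    """n independent subjects (pose + noise) from one spec, deterministic in seed."""
    if n < 2:
        raise ValueError("a cohort needs n >= 2 subjects")
    spec = apply_cohort_shift(spec, cohort_shift)
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]
    return [
        generate_subject(spec, child_seeds[i], subject_id=f"sub-{i:03d}")
        for i in range(n)
    ]
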