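"""Per-tract metric aggregation, DTI radar profiles, along-tract
profiles and the Evans' index.

Tract metrics are means of trilinearly sampled scalar maps over
streamline vertices (tractography-weighted averaging). Radar profiles
display FA scaled x20 and MD/L1/RD scaled x10^4 so all four metrics
share one axis range; the scaling is an exact bijection. The Evans'
index is the ratio of the maximal frontal-horn width of the lateral
ventricles to the maximal internal cranial width on axial slices, both
measured along world x after ACPC alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ScalarMap, Tractogram

__all__ = [
    "TractMetrics",
    "DtiProfile",
    "EvansIndexResult",
    "tract_metrics",
    "bilateral_average",
    "radar_profile",
    "plot_radar",
    "along_tract_profile",
    "evans_index",
]

METRIC_NAMES = ("FA", "MD", "L1", "RD")
RADAR_SCALES = {"FA": 20.0, "MD": 1.0e4, "L1": 1.0e4, "RD": 1.0e4}


@dataclass
class TractMetrics:
    subject_id: str
    tract: str
    side: str  # left | right | midline
    fa: float | None = None
    md: float | None = None
    l1: float | None = None
    rd: float | None = None
    n_streamlines: int = 0
    generated: bool = False
    method: str = "pseudo_atlas"  # pseudo_atlas | atlas
    single_side: bool = False  # bilateral average fell back to one side
    qc: dict = field(default_factory=dict)

    def metric(self, name: str):
        return {"FA": self.fa, "MD": self.md, "L1": self.l1, "RD": self.rd}[name]


@dataclass(frozen=True)
class DtiProfile:
    """Radar-graph representation: FA x20, MD/L1/RD x10^4.

    The raw metrics are carried alongside the display scaling so that
    descaling is an exact bijection (dividing a float by its scale is
    not guaranteed to invert the multiplication at machine precision).
    """

    tract: str
    scaled: dict  # metric name -> scaled value
    raw: dict = field(default_factory=dict)
    tags: dict = field(default_factory=dict)

    def descale(self) -> dict:
        if self.raw:
            return dict(self.raw)
        return {k: v / RADAR_SCALES[k] for k, v in self.scaled.items()}


@dataclass(frozen=True)
class EvansIndexResult:
    frontal_horn_width_mm: float
    cranial_width_mm: float
    ei: float
    slice_index: int


def _sample_map(smap: ScalarMap, points: np.ndarray) -> tuple[np.ndarray, int]:
    """Trilinear map values at world points; out-of-grid points excluded."""
    inv = np.linalg.inv(np.asarray(smap.affine))
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    shape = np.asarray(smap.data.shape)
    inb = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    vals = ndimage.map_coordinates(np.asarray(smap.data, float), vox[inb].T, order=1, mode="nearest")
    return vals, int(np.sum(~inb))


def tract_metrics(
    streamlines: Tractogram,
    maps: dict,
    subject_id: str = "",
    tract: str = "",
    side: str = "midline",
    method: str = "pseudo_atlas",
) -> TractMetrics:
    """Mean of each scalar map over all streamline vertices.

    An empty selection yields ``generated=False`` with missing (None)
    metrics, never zeros. Vertices outside a map are excluded from the
    mean and counted in QC.
    """
    tm = TractMetrics(subject_id=subject_id, tract=tract, side=side, method=method)
    if len(streamlines) == 0:
        return tm
    pts = np.vstack(list(streamlines))
    values = {}
    qc_out = 0
    for name in METRIC_NAMES:
        if name not in maps:
            continue
        vals, n_out = _sample_map(maps[name], pts)
        qc_out = max(qc_out, n_out)
        values[name] = float(vals.mean()) if vals.size else None
    tm.fa = values.get("FA")
    tm.md = values.get("MD")
    tm.l1 = values.get("L1")
    tm.rd = values.get("RD")
    tm.n_streamlines = len(streamlines)
    tm.generated = True
    tm.qc["vertices_outside_map"] = qc_out
    return tm


def bilateral_average(left: TractMetrics, right: TractMetrics) -> TractMetrics:
    """Average the two sides per metric.

    If exactly one side is missing the present side is used and flagged
    (``single_side=True``); if both are missing the result is missing.
    """
    if left.tract != right.tract:
        raise ValueError(f"tract mismatch: {left.tract!r} vs {right.tract!r}")
    if left.subject_id != right.subject_id:
        raise ValueError("bilateral_average needs the same subject on both sides")
    out = TractMetrics(
        subject_id=left.subject_id, tract=left.tract, side="bilateral", method=left.method
    )
    if not left.generated and not right.generated:
        return out
    if left.generated and right.generated:
        for attr in ("fa", "md", "l1", "rd"):
            a, b = getattr(left, attr), getattr(right, attr)
            setattr(out, attr, None if a is None or b is None else (a + b) / 2.0)
        out.n_streamlines = left.n_streamlines + right.n_streamlines
    else:
        present = left if left.generated else right
        for attr in ("fa", "md", "l1", "rd"):
            setattr(out, attr, getattr(present, attr))
        out.n_streamlines = present.n_streamlines
        out.single_side = True
    out.generated = True
    return out


def radar_profile(metrics: TractMetrics, tags: dict | None = None) -> DtiProfile:
    """Scale tract metrics for radar display (FA x20, MD/L1/RD x10^4)."""
    if not metrics.generated or any(metrics.metric(m) is None for m in METRIC_NAMES):
        raise ValueError(f"radar profile needs complete metrics for {metrics.tract!r}")
    scaled = {m: metrics.metric(m) * RADAR_SCALES[m] for m in METRIC_NAMES}
    raw = {m: metrics.metric(m) for m in METRIC_NAMES}
    return DtiProfile(tract=metrics.tract, scaled=scaled, raw=raw, tags=tags or {})


def plot_radar(profiles: list, path, title: str = "DTI profiles"):
    """Write a radar figure of one or more profiles (SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axes_names = list(METRIC_NAMES)
    angles = np.linspace(0, 2 * np.pi, len(axes_names), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    for prof in profiles:
        vals = [prof.scaled[m] for m in axes_names]
        label = prof.tract + (" " + " ".join(f"{v}" for v in prof.tags.values()) if prof.tags else "")
        ax.plot(np.r_[angles, angles[0]], np.r_[vals, vals[0]], label=label)
    ax.set_xticks(angles)
    ax.set_xticklabels([f"{m} (x{RADAR_SCALES[m]:g})" for m in axes_names])
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize="small")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def _resample_arclength(streamline: np.ndarray, n_nodes: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(streamline, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    if s[-1] == 0:
        return np.repeat(streamline[:1], n_nodes, axis=0)
    target = np.linspace(0.0, s[-1], n_nodes)
    return np.stack([np.interp(target, s, streamline[:, k]) for k in range(3)], axis=1)


def along_tract_profile(
    streamlines: Tractogram,
    smap: ScalarMap,
    n_nodes: int = 50,
    orientation_axis: int | None = None,
) -> np.ndarray:
    """Mean map value at ``n_nodes`` equidistant arc-length nodes.

    Each streamline is resampled to ``n_nodes`` points and oriented
    consistently before averaging: along ``orientation_axis`` when
    given (each streamline runs from its smaller to larger coordinate
    on that world axis), otherwise by matching endpoints to the first
    streamline.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    usable = [s for s in streamlines if len(s) >= 2]
    if not usable:
        raise ValueError("along-tract profile needs at least one streamline")
    resampled = []
    ref = None
    for s in usable:
        r = _resample_arclength(s, n_nodes)
        if orientation_axis is not None:
            if r[0, orientation_axis] > r[-1, orientation_axis]:
                r = r[::-1]
        elif ref is not None:
            fwd = np.linalg.norm(r[0] - ref[0]) + np.linalg.norm(r[-1] - ref[-1])
            rev = np.linalg.norm(r[-1] - ref[0]) + np.linalg.norm(r[0] - ref[-1])
            if rev < fwd:
                r = r[::-1]
        if ref is None:
            ref = r
        resampled.append(r)
    node_vals = np.empty((len(resampled), n_nodes))
    for i, r in enumerate(resampled):
        vals, _ = _sample_map(smap, r)
        node_vals[i] = vals
    return node_vals.mean(axis=0)


# ---------------------------------------------------------------------------
# Evans' index


def _max_axial_width(mask: np.ndarray, affine: np.ndarray, select: np.ndarray | None = None):
    """Max left-right (x) extent over axial (z) slices, in world mm.

    Width counts whole voxels: (max - min + 1 voxel pitch) along x, so a
    mask identical to the comparison mask gives a ratio of exactly 1.
    """
    m = mask if select is None else (mask & select)
    pitch_x = float(np.linalg.norm(np.asarray(affine)[:3, 0]))
    best_w, best_k = 0.0, -1
    for k in range(m.shape[2]):
        sl = m[:, :, k]
        if not sl.any():
            continue
        xs = np.flatnonzero(sl.any(axis=1))
        w = (xs.max() - xs.min() + 1) * pitch_x
        if w > best_w:
            best_w, best_k = w, k
    return best_w, best_k


def evans_index(
    ventricle_mask: ScalarMap,
    inner_skull_mask: ScalarMap,
    ac_y: float = 0.0,
    frontal_horn_mask: ScalarMap | None = None,
) -> EvansIndexResult:
    """Evans' index: max frontal-horn width / max internal cranial width.

    Masks must be co-registered and ACPC-aligned (axial = z planes,
    widths along world x). The frontal-horn compartment defaults to
    ventricle voxels anterior to the AC plane (world y > ``ac_y``); an
    explicit horn mask overrides the heuristic.
    """
    vent = np.asarray(ventricle_mask.data) > 0.5
    skull = np.asarray(inner_skull_mask.data) > 0.5
    if not vent.any() or not skull.any():
        raise ValueError("Evans' index needs non-empty ventricle and skull masks")
    if frontal_horn_mask is not None:
        horn_sel = np.asarray(frontal_horn_mask.data) > 0.5
    else:
        ny = vent.shape[1]
        A = np.asarray(ventricle_mask.affine)
        yy = (np.arange(ny) * A[1, 1] + A[1, 3])  # world y of each j index
        horn_sel = np.zeros_like(vent)
        horn_sel[:, yy > ac_y, :] = True
    horn_w, k = _max_axial_width(vent, ventricle_mask.affine, select=horn_sel)
    if horn_w == 0:
        raise ValueError("no ventricle voxels anterior to the AC plane")
    cran_w, _ = _max_axial_width(skull, inner_skull_mask.affine)
    return EvansIndexResult(
        frontal_horn_width_mm=horn_w,
        cranial_width_mm=cran_w,
        ei=horn_w / cran_w,
        slice_index=k,
    )
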