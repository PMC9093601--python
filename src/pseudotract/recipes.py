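"""Declarative ROI recipes and AND/NOT gate selection of streamlines.

Each white-matter tract is isolated from a whole-brain tractogram by an
ordered list of ROI gates. An AND gate keeps only streamlines that pass
through its voxel mask; a NOT gate removes streamlines that touch its
mask. Gate placements are anatomical rules resolved against named
landmark masks (a "reference geometry"), never hard-coded slice
indices, so the same recipe file works in template space, subject
space, or phantom space.

Placement vocabulary (all positions in world mm):

``fraction``           slab over a fractional range of a structure's
                       bounding extent along an axis, measured from a
                       named edge (e.g. anterior 1/6 of the corpus
                       callosum);
``edge_slice``         one-voxel-thick slice at a structure's bounding
                       edge, with a signed offset in mm (positive =
                       beyond the edge);
``center_slice``       slice through the centre of a structure's extent;
``max_area_slice``     slice where the structure's in-plane area is
                       largest;
``lateral_edge_slice`` parasagittal slice at (or beyond) the lateral
                       edge of a structure, per side;
``midsagittal``        the central sagittal slice.

The in-plane ``extent`` of a gate is the entire slice, the named
structure's footprint, or the slice minus the structure (complement).

Anterior-posterior is measured along world +y (RAS+): "anterior 1/6"
means the sixth of the bounding extent with the largest y. This
convention matters for every fractional rule and is fixed package-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .io import Tractogram

__all__ = [
    "RoiGate",
    "TractRecipe",
    "ResolvedGate",
    "ReferenceGeometry",
    "load_recipes",
    "default_recipe_path",
    "expand_instances",
    "resolve_gates",
    "select_tract",
]

TRACT_NAMES = ("gCC", "bCC", "ATR", "IFO", "ILF", "PLIC", "PTR", "UF")
_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0, "parasagittal": 0}
_EDGE_AXIS_SIGN = {
    "anterior": (1, +1),
    "posterior": (1, -1),
    "superior": (2, +1),
    "inferior": (2, -1),
    "left": (0, -1),
    "right": (0, +1),
}


class RecipeError(ValueError):
    """Recipe file fails schema or semantic validation."""


@dataclass(frozen=True)
class RoiGate:
    polarity: str  # AND | NOT
    plane: str  # axial | coronal | sagittal | parasagittal
    placement: dict
    extent: dict = field(default_factory=lambda: {"mode": "entire"})
    side: str = "n/a"  # left | right | both | n/a (parasagittal gates need one)
    note: str = ""

    def __post_init__(self):
        if self.polarity not in ("AND", "NOT"):
            raise RecipeError(f"gate polarity must be AND or NOT, got {self.polarity!r}")
        if self.plane not in _PLANE_AXIS:
            raise RecipeError(f"unknown plane {self.plane!r}")
        if self.plane == "parasagittal" and self.side not in ("left", "right", "both", "instance"):
            raise RecipeError(
                "parasagittal gates must carry a side (left/right/both, or "
                "'instance' to follow the bilateral instance being resolved)"
            )
        if "type" not in self.placement:
            raise RecipeError("gate placement needs a 'type'")


@dataclass(frozen=True)
class TractRecipe:
    tract: str
    laterality: str  # midline | bilateral
    gates: tuple

    def __post_init__(self):
        if self.tract not in TRACT_NAMES:
            raise RecipeError(f"unknown tract {self.tract!r}; one of {TRACT_NAMES}")
        if self.laterality not in ("midline", "bilateral"):
            raise RecipeError(f"{self.tract}: laterality must be midline or bilateral")
        if not any(g.polarity == "AND" for g in self.gates):
            raise RecipeError(f"{self.tract}: recipe needs at least one AND gate")

    @property
    def n_instances(self) -> int:
        return 1 if self.laterality == "midline" else 2


def default_recipe_path() -> Path:
    return Path(resources.files("pseudotract") / "data" / "tract_recipes.yaml")


def _parse_fraction(val) -> float:
    if isinstance(val, str) and "/" in val:
        num, den = val.split("/")
        return float(num) / float(den)
    return float(val)


def load_recipes(path=None) -> list[TractRecipe]:
    """Load tract recipes; with no path, the shipped 8-tract encoding."""
    path = Path(path) if path is not None else default_recipe_path()
    doc = yaml.safe_load(path.read_text())
    recipes = []
    for entry in doc["tracts"]:
        if "laterality" not in entry:
            raise RecipeError(f"recipe {entry.get('tract', '?')}: missing laterality")
        gates = []
        for g in entry.get("gates", []):
            placement = dict(g.get("placement", {}))
            for key in ("lo", "hi"):
                if key in placement:
                    placement[key] = _parse_fraction(placement[key])
            gates.append(
                RoiGate(
                    polarity=g["polarity"],
                    plane=g["plane"],
                    placement=placement,
                    extent=dict(g.get("extent", {"mode": "entire"})),
                    side=g.get("side", "n/a"),
                    note=g.get("note", ""),
                )
            )
        recipes.append(TractRecipe(tract=entry["tract"], laterality=entry["laterality"], gates=tuple(gates)))
    return recipes


def expand_instances(recipes) -> list[tuple[TractRecipe, str]]:
    """Per-subject tract instances: midline once, bilateral left + right."""
    out = []
    for r in recipes:
        if r.laterality == "midline":
            out.append((r, "midline"))
        else:
            out.append((r, "left"))
            out.append((r, "right"))
    return out


# ---------------------------------------------------------------------------
# gate resolution against a reference geometry


@dataclass
class ReferenceGeometry:
    """Named landmark masks on one grid (phantom truth or user-segmented)."""

    masks: dict  # name -> 3D bool array
    affine: np.ndarray

    _world: np.ndarray | None = None

    def shape(self):
        return next(iter(self.masks.values())).shape

    def world_coords(self) -> np.ndarray:
        """(x, y, z, 3) world mm coordinate of every voxel centre (cached)."""
        if self._world is None:
            shp = self.shape()
            ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shp], indexing="ij")
            vox = np.stack([ii, jj, kk], axis=-1).astype(float)
            A = np.asarray(self.affine)
            self._world = vox @ A[:3, :3].T + A[:3, 3]
        return self._world

    def structure(self, name: str, side: str | None = None) -> np.ndarray:
        if side in ("left", "right") and f"{name}_{side}" in self.masks:
            return self.masks[f"{name}_{side}"]
        if name in self.masks:
            return self.masks[name]
        raise RecipeError(f"reference geometry has no structure named {name!r}")

    def pitch(self, axis: int) -> float:
        return float(np.linalg.norm(np.asarray(self.affine)[:3, axis]))


@dataclass
class ResolvedGate:
    mask: np.ndarray  # bool, on the reference grid
    polarity: str
    affine: np.ndarray
    note: str = ""


def _bbox(world: np.ndarray, mask: np.ndarray, axis: int) -> tuple[float, float]:
    coords = world[..., axis][mask]
    if coords.size == 0:
        raise RecipeError("placement references an empty structure mask")
    return float(coords.min()), float(coords.max())


def _slab(world: np.ndarray, axis: int, lo: float, hi: float) -> np.ndarray:
    c = world[..., axis]
    return (c >= lo) & (c <= hi)


def _resolve_placement(gate: RoiGate, ref: ReferenceGeometry, side: str | None) -> np.ndarray:
    p = gate.placement
    axis = _PLANE_AXIS[gate.plane]
    world = ref.world_coords()
    t = ref.pitch(axis)  # slice thickness: one voxel pitch
    kind = p["type"]

    if kind == "midsagittal":
        return _slab(world, 0, -t / 2, t / 2)

    if kind == "lateral_edge_slice":
        offset = float(p.get("offset_mm", 0.0))
        if gate.side == "both":
            sides = ("left", "right")
        elif gate.side in ("left", "right"):
            sides = (gate.side,)
        else:  # 'instance': follow the bilateral instance under resolution
            if side not in ("left", "right"):
                raise RecipeError("lateral gate with side='instance' needs a resolution side")
            sides = (side,)
        out = np.zeros(ref.shape(), bool)
        for s in sides:
            struct = ref.structure(p["structure"], s)
            mn, mx = _bbox(world, struct, 0)
            pos = mn - offset if s == "left" else mx + offset
            out |= _slab(world, 0, pos - t / 2, pos + t / 2)
        return out

    struct = ref.structure(p["structure"], side)
    if kind == "fraction":
        frac_axis = {"x": 0, "y": 1, "z": 2}[p.get("axis", "xyz"[axis])]
        mn, mx = _bbox(world, struct, frac_axis)
        length = mx - mn
        lo_f, hi_f = float(p["lo"]), float(p["hi"])
        _, sign = _EDGE_AXIS_SIGN[p.get("from_edge", "posterior")]
        if sign > 0:  # measured from the max-coordinate edge inward
            lo, hi = mx - hi_f * length, mx - lo_f * length
        else:
            lo, hi = mn + lo_f * length, mn + hi_f * length
        if hi - lo < t:  # degenerate range (a "slice at fraction f"): one voxel thick
            centre = (lo + hi) / 2
            lo, hi = centre - t / 2, centre + t / 2
        return _slab(world, frac_axis, lo, hi)
    if kind == "edge_slice":
        edge_axis, sign = _EDGE_AXIS_SIGN[p["edge"]]
        mn, mx = _bbox(world, struct, edge_axis)
        pos = (mx if sign > 0 else mn) + sign * float(p.get("offset_mm", 0.0))
        return _slab(world, edge_axis, pos - t / 2, pos + t / 2)
    if kind == "center_slice":
        mn, mx = _bbox(world, struct, axis)
        pos = (mn + mx) / 2 + float(p.get("offset_mm", 0.0))
        return _slab(world, axis, pos - t / 2, pos + t / 2)
    if kind == "max_area_slice":
        coords = world[..., axis][struct]
        mn, mx = coords.min(), coords.max()
        edges = np.arange(mn - t / 2, mx + t, t)
        counts, _ = np.histogram(coords, bins=edges)
        b = int(np.argmax(counts))
        return _slab(world, axis, edges[b], edges[b + 1])
    raise RecipeError(f"unknown placement type {kind!r}")


def resolve_gates(recipe: TractRecipe, reference: ReferenceGeometry, side: str | None = None) -> list[ResolvedGate]:
    """Turn one tract instance's anatomical rules into voxel masks.

    ``side`` selects the instance of a bilateral recipe; side-specific
    structures resolve to ``<name>_<side>`` when present.
    """
    if recipe.laterality == "bilateral" and side not in ("left", "right"):
        raise RecipeError(f"{recipe.tract}: bilateral recipe needs side='left' or 'right'")
    resolved = []
    for gate in recipe.gates:
        mask = _resolve_placement(gate, reference, side)
        mode = gate.extent.get("mode", "entire")
        if mode in ("structure", "complement"):
            name = gate.extent.get("structure", gate.placement.get("structure"))
            struct = reference.structure(name, side)
            mask = (mask & struct) if mode == "structure" else (mask & ~struct)
        resolved.append(ResolvedGate(mask=mask, polarity=gate.polarity, affine=np.asarray(reference.affine), note=gate.note or gate.plane))
    return resolved


# ---------------------------------------------------------------------------
# streamline selection


def _streamline_hits(streamline: np.ndarray, mask: np.ndarray, inv_affine: np.ndarray) -> bool:
    vox = streamline @ inv_affine[:3, :3].T + inv_affine[:3, 3]
    idx = np.rint(vox).astype(int)
    inb = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    if not inb.any():
        return False
    i = idx[inb]
    return bool(mask[i[:, 0], i[:, 1], i[:, 2]].any())


def select_tract(tractogram: Tractogram, gates: list[ResolvedGate]) -> tuple[Tractogram, bool]:
    """Keep streamlines passing every AND mask and no NOT mask.

    Membership is tested at streamline vertices (step <= half a voxel
    rules out tunnelling at default tracking parameters). Returns the
    selected tractogram and ``generated`` = whether anything was kept.
    """
    if not gates:
        raise RecipeError("select_tract needs at least one resolved gate")
    inv = {id(g): np.linalg.inv(np.asarray(g.affine)) for g in gates}
    kept = []
    for s in tractogram.streamlines:
        ok = True
        for g in gates:
            hit = _streamline_hits(s, g.mask, inv[id(g)])
            if (g.polarity == "AND" and not hit) or (g.polarity == "NOT" and hit):
                ok = False
                break
        if ok:
            kept.append(s)
    out = Tractogram(streamlines=kept, provenance=dict(tractogram.provenance))
    return out, len(kept) >= 1
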