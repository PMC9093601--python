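"""End-to-end study drivers over synthetic cohorts.

These functions assemble the building blocks into the two competing
workflows:

* **pseudo-atlas extraction** — resolve the tract recipes once on a
  template subject, propagate the gate masks to every other subject
  (identity, landmark-ACPC, or FA-registration transforms), run
  whole-brain tractography per subject and select each tract instance;
* **atlas-based extraction** — warp a label volume onto each subject
  and average the scalar maps inside each label. A deliberately
  mismatched atlas (dilated and shifted bundle labels) emulates a
  population template that does not quite fit any cohort member.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alignment import (
    AtlasLabels,
    RigidOrAffineTransform,
    acpc_align,
    extract_label_metrics,
    propagate_rois,
    register_affine,
)
from .io import ScalarMap
from .phantom import PhantomSpec, PhantomSubject, generate_subject
from .profiles import evans_index, tract_metrics
from .recipes import ReferenceGeometry, expand_instances, load_recipes, resolve_gates, select_tract
from .stats import attempted_count, success_rate
from .tensor import fit_tensor, scalar_maps
from .tracking import TrackingParams, track_whole_brain

__all__ = [
    "SubjectDerived",
    "derive_subject",
    "truth_reference",
    "pseudo_atlas_study",
    "mismatched_atlas",
    "atlas_study",
    "ventriculomegaly_cohort",
    "subject_evans_index",
    "metrics_to_frame",
]


@dataclass
class SubjectDerived:
    """Fitted maps and tractogram for one subject."""

    subject: PhantomSubject
    maps: dict  # FA/MD/L1/RD ScalarMaps
    tractogram: object
    acpc: RigidOrAffineTransform


def truth_reference(subject: PhantomSubject) -> ReferenceGeometry:
    return ReferenceGeometry(masks=subject.truth.structures, affine=subject.dwi.affine)


def derive_subject(subject: PhantomSubject, params: TrackingParams | None = None) -> SubjectDerived:
    """Fit tensors, derive scalar maps, track whole brain, compute ACPC."""
    mask = ScalarMap(
        subject.truth.structures["skull_inner"].astype(float), subject.dwi.affine, kind="mask"
    )
    field_ = fit_tensor(subject.dwi, mask=mask)
    maps = scalar_maps(field_)
    if params is None:
        params = TrackingParams(step_size=0.5 * float(np.cbrt(abs(np.linalg.det(subject.dwi.affine[:3, :3])))))
    tractogram = track_whole_brain(field_, maps["FA"], params)
    acpc = acpc_align(subject.truth.landmarks)
    return SubjectDerived(subject=subject, maps=maps, tractogram=tractogram, acpc=acpc)


def _template_to_subject(
    template: SubjectDerived, subject: SubjectDerived, mode: str
) -> RigidOrAffineTransform:
    if mode == "identity":
        return RigidOrAffineTransform(np.eye(4), kind="rigid")
    if mode == "acpc":
        # template world -> ACPC world -> subject world
        return subject.acpc.inverse().compose(template.acpc)
    if mode == "register":
        return register_affine(template.maps["FA"], subject.maps["FA"])
    raise ValueError(f"unknown propagation mode {mode!r}")


def pseudo_atlas_study(
    derived: list[SubjectDerived],
    recipes=None,
    template_index: int = 0,
    propagation: str = "acpc",
) -> pd.DataFrame:
    """Method-1-style extraction: template ROIs propagated to the cohort.

    Returns a long DataFrame with one row per (subject, tract instance)
    carrying FA/MD/L1/RD, the streamline count and the generated flag.
    """
    recipes = recipes if recipes is not None else load_recipes()
    template = derived[template_index]
    reference = truth_reference(template.subject)
    instances = expand_instances(recipes)
    template_gates = {
        (r.tract, side): resolve_gates(r, reference, side=None if side == "midline" else side)
        for r, side in instances
    }

    rows = []
    for subj in derived:
        transform = _template_to_subject(template, subj, propagation)
        aff = subj.subject.dwi.affine
        shape = subj.subject.dwi.shape
        for (tract, side), gates in template_gates.items():
            gates_s = propagate_rois(gates, transform, aff, shape)
            selected, generated = select_tract(subj.tractogram, gates_s)
            tm = tract_metrics(
                selected,
                subj.maps,
                subject_id=subj.subject.subject_id,
                tract=tract,
                side=side,
                method="pseudo_atlas",
            )
            rows.append(
                {
                    "subject": tm.subject_id,
                    "tract": tract,
                    "side": side,
                    "FA": tm.fa,
                    "MD": tm.md,
                    "L1": tm.l1,
                    "RD": tm.rd,
                    "n_streamlines": tm.n_streamlines,
                    "generated": generated,
                    "method": "pseudo_atlas",
                }
            )
    return pd.DataFrame(rows)


def study_success_rate(table: pd.DataFrame, recipes=None) -> float:
    recipes = recipes if recipes is not None else load_recipes()
    n_subjects = table["subject"].nunique()
    attempted = attempted_count(recipes, n_subjects)
    return success_rate(int(table["generated"].sum()), attempted)


# ---------------------------------------------------------------------------
# atlas comparator


_ATLAS_SLABS = {  # tract -> (bundle structure, y-fraction range from anterior) on the CC
    "gCC": ("corpus_callosum", (0.0, 1.0 / 6.0)),
    "bCC": ("corpus_callosum", (1.0 / 6.0, 3.0 / 4.0)),
}


def mismatched_atlas(
    template: PhantomSubject,
    shift_mm: tuple = (4.0, -4.0, 0.0),
    dilate: int = 2,
    tracts: tuple = ("gCC", "bCC", "PLIC", "IFO"),
) -> AtlasLabels:
    """Label volume built from template bundle masks, dilated and shifted.

    Emulates a population atlas whose labels overspill the cohort's
    true bundles into surrounding tissue and CSF. Bilateral tracts are
    a single label covering both sides.
    """
    from scipy import ndimage

    structures = template.truth.structures
    affine = template.dwi.affine
    shape = next(iter(structures.values())).shape

    # world y per voxel (template assumed near-axis-aligned for slab splits)
    jj = np.arange(shape[1])
    ys = jj * affine[1, 1] + affine[1, 3]

    labels = np.zeros(shape, dtype=np.int32)
    table = {}
    shift_vox = np.round(np.asarray(shift_mm) / np.diag(affine)[:3]).astype(int)
    for i, tract in enumerate(tracts, start=1):
        if tract in _ATLAS_SLABS:
            struct_name, (lo, hi) = _ATLAS_SLABS[tract]
            base = structures[struct_name]
            yy = np.nonzero(base)[1]
            y_lo, y_hi = ys[yy.min()], ys[yy.max()]
            length = y_hi - y_lo
            sel = (ys >= y_hi - hi * length) & (ys <= y_hi - lo * length)
            mask = base & sel[None, :, None]
        else:
            key = tract.lower()
            mask = structures[f"{key}_left"] | structures[f"{key}_right"]
        if dilate > 0:
            mask = ndimage.binary_dilation(mask, iterations=dilate)
        mask = np.roll(mask, shift_vox, axis=(0, 1, 2))
        labels[mask] = i
        table[i] = tract
    return AtlasLabels(labels=labels, affine=affine, table=table)


def atlas_study(
    derived: list[SubjectDerived],
    atlas: AtlasLabels,
    template_index: int = 0,
    propagation: str = "acpc",
) -> pd.DataFrame:
    """Method-2/3-style extraction: warp labels onto each subject, average maps."""
    template = derived[template_index]
    rows = []
    for subj in derived:
        transform = _template_to_subject(template, subj, propagation)
        tab = extract_label_metrics(subj.maps, atlas, transform)
        for _, rec in tab.iterrows():
            rows.append(
                {
                    "subject": subj.subject.subject_id,
                    "tract": rec["tract"],
                    "side": "atlas",
                    "FA": rec["FA"],
                    "MD": rec["MD"],
                    "L1": rec.get("L1", np.nan),
                    "RD": rec.get("RD", np.nan),
                    "n_streamlines": 0,
                    "generated": bool(rec["n_voxels"] > 0),
                    "method": "atlas",
                }
            )
    return pd.DataFrame(rows)


def metrics_to_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Bilaterally average the long per-instance table to per-(subject, tract).

    Follows the single-side fallback policy: if one side of a bilateral
    tract is missing, the present side is used.
    """
    out = []
    for (subject, tract), grp in table.groupby(["subject", "tract"]):
        vals = {}
        for metric in ("FA", "MD", "L1", "RD"):
            present = grp.loc[grp["generated"].astype(bool), metric].dropna()
            vals[metric] = float(present.mean()) if len(present) else np.nan
        out.append({"subject": subject, "tract": tract, **vals})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# graded-ventriculomegaly cohort


def ventriculomegaly_cohort(
    base_spec: PhantomSpec,
    n: int = 8,
    seed: int = 0,
    scale_range: tuple = (0.9, 1.5),
    plic_coupling: tuple = (0.25e-3, -0.05e-3),
) -> list[PhantomSubject]:
    """Cohort with graded ventricular enlargement compressing the
    internal-capsule-like bundle.

    Subject i gets ventricle semi-axes scaled by s_i (linear over
    ``scale_range``) and PLIC eigenvalues shifted by ``plic_coupling``
    = (axial offset, radial offset) per unit of (s_i - 1): enlargement
    raises the axial and lowers the radial diffusivity (higher FA,
    slightly higher MD), the compression pattern of periventricular
    tracts.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]
    scales = np.linspace(scale_range[0], scale_range[1], n)
    subjects = []
    d_ax, d_rad = plic_coupling
    for i, s in enumerate(scales):
        bundles = []
        for b in base_spec.bundles:
            if b.name.startswith("plic"):
                l1, l2, l3 = b.eigenvalues
                bundles.append(
                    replace(
                        b,
                        eigenvalues=(
                            l1 + d_ax * (s - 1.0),
                            l2 + d_rad * (s - 1.0),
                            l3 + d_rad * (s - 1.0),
                        ),
                    )
                )
            else:
                bundles.append(b)
        spec_i = replace_spec(base_spec, bundles=bundles, ventricle_scale=float(s))
        subjects.append(generate_subject(spec_i, child[i], subject_id=f"sub-{i:03d}"))
    return subjects


def replace_spec(spec: PhantomSpec, **kwargs) -> PhantomSpec:
    import copy

    out = copy.copy(spec)
    for k, v in kwargs.items():
        setattr(out, k, v)
    return out


def subject_evans_index(subject: PhantomSubject) -> float:
    """Evans' index from the subject's ventricle and inner-skull masks."""
    aff = subject.dwi.affine
    vent = subject.truth.structure_map("ventricles", aff)
    skull = subject.truth.structure_map("skull_inner", aff)
    ac_y = float(subject.truth.landmarks["AC"][1])
    return evans_index(vent, skull, ac_y=ac_y).ei
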