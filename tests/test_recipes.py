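import numpy as np
import pytest
import yaml

from pseudotract.io import Tractogram
from pseudotract.recipes import (
    RecipeError,
    ReferenceGeometry,
    RoiGate,
    TractRecipe,
    expand_instances,
    load_recipes,
    resolve_gates,
    select_tract,
)

EXPECTED_GATE_COUNTS = {"gCC": 2, "bCC": 2, "ATR": 4, "IFO": 3, "ILF": 4, "PLIC": 3, "PTR": 4, "UF": 4}


class TestShippedRecipes:
    def test_eight_tracts_fourteen_instances(self):
        recipes = load_recipes()
        assert len(recipes) == 8
        assert len({r.tract for r in recipes}) == 8
        assert len(expand_instances(recipes)) == 14
        midline = {r.tract for r in recipes if r.laterality == "midline"}
        assert midline == {"gCC", "bCC"}

    def test_gate_counts_per_tract(self):
        for r in load_recipes():
            assert len(r.gates) == EXPECTED_GATE_COUNTS[r.tract], r.tract

    def test_bcc_carries_axial_not_beneath_body(self):
        bcc = next(r for r in load_recipes() if r.tract == "bCC")
        axial_nots = [g for g in bcc.gates if g.polarity == "NOT" and g.plane == "axial"]
        assert len(axial_nots) == 1
        g = axial_nots[0]
        assert g.placement["type"] == "edge_slice"
        assert g.placement["edge"] == "inferior"
        assert g.extent["mode"] == "entire"

    def test_every_recipe_has_an_and_gate(self):
        for r in load_recipes():
            assert any(g.polarity == "AND" for g in r.gates)

    def test_missing_laterality_rejected(self, tmp_path):
        doc = {"tracts": [{"tract": "gCC", "gates": [
            {"polarity": "AND", "plane": "sagittal", "placement": {"type": "midsagittal"}}]}]}
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(RecipeError, match="laterality"):
            load_recipes(p)

    def test_recipe_without_and_gate_rejected(self):
        with pytest.raises(RecipeError, match="AND"):
            TractRecipe("gCC", "midline", (RoiGate("NOT", "sagittal", {"type": "midsagittal"}),))

    def test_parasagittal_gate_requires_side(self):
        with pytest.raises(RecipeError, match="side"):
            RoiGate("AND", "parasagittal", {"type": "midsagittal"})


def cc_slab_reference(ny=61):
    """Corpus-callosum mask spanning y in [0, 60] mm on a unit grid."""
    shape = (21, ny + 4, 21)
    cc = np.zeros(shape, bool)
    cc[9:12, 0:ny, 9:12] = True  # y voxel j has world y = j
    masks = {"corpus_callosum": cc}
    return ReferenceGeometry(masks=masks, affine=np.eye(4)), cc


class TestGateResolution:
    def test_anterior_sixth_resolves_to_top_slab(self):
        ref, cc = cc_slab_reference()
        recipe = TractRecipe("gCC", "midline", (
            RoiGate("AND", "sagittal",
                    {"type": "fraction", "structure": "corpus_callosum", "axis": "y",
                     "from_edge": "anterior", "lo": 0.0, "hi": 1.0 / 6.0},
                    extent={"mode": "structure"}),
        ))
        [gate] = resolve_gates(recipe, ref)
        ys = ref.world_coords()[..., 1][gate.mask]
        assert ys.min() >= 50.0 - 1e-9 and ys.max() <= 60.0 + 1e-9
        # it covers exactly the structure voxels inside the slab
        expected = cc & (ref.world_coords()[..., 1] >= 50.0)
        assert np.array_equal(gate.mask, expected)

    def test_posterior_quarter_is_complementary_slab(self):
        ref, cc = cc_slab_reference()
        recipe = TractRecipe("bCC", "midline", (
            RoiGate("AND", "sagittal",
                    {"type": "fraction", "structure": "corpus_callosum", "axis": "y",
                     "from_edge": "posterior", "lo": 0.0, "hi": 0.25},
                    extent={"mode": "structure"}),
        ))
        [gate] = resolve_gates(recipe, ref)
        ys = ref.world_coords()[..., 1][gate.mask]
        assert ys.min() >= 0.0 - 1e-9 and ys.max() <= 15.0 + 1e-9

    def test_midsagittal_gate_spans_full_inplane_extent(self):
        ref, cc = cc_slab_reference()
        recipe = TractRecipe("gCC", "midline", (
            RoiGate("AND", "sagittal", {"type": "midsagittal"}),
        ))
        [gate] = resolve_gates(recipe, ref)
        xs = ref.world_coords()[..., 0][gate.mask]
        assert np.abs(xs).max() <= 0.5 + 1e-9
        # full y-z extent at the midline plane
        assert gate.mask.sum() == gate.mask.shape[1] * gate.mask.shape[2]

    def test_missing_structure_error_names_it(self):
        ref, _ = cc_slab_reference()
        recipe = TractRecipe("ATR", "bilateral", (
            RoiGate("AND", "coronal", {"type": "edge_slice", "structure": "pons", "edge": "anterior"}),
        ))
        with pytest.raises(RecipeError, match="pons"):
            resolve_gates(recipe, ref, side="left")


def random_tractogram(rng, n_streamlines=30, box=20.0):
    sls = []
    for _ in range(n_streamlines):
        n = rng.integers(2, 12)
        start = rng.uniform(0, box, 3)
        steps = rng.normal(0, 1.0, size=(n - 1, 3))
        sls.append(np.vstack([start, start + np.cumsum(steps, axis=0)]))
    return Tractogram(sls)


def random_gate(rng, shape=(21, 21, 21)):
    from pseudotract.recipes import ResolvedGate

    mask = np.zeros(shape, bool)
    n_blobs = rng.integers(1, 4)
    for _ in range(n_blobs):
        c = rng.integers(0, np.array(shape) - 4)
        sz = rng.integers(1, 5, 3)
        mask[c[0]:c[0] + sz[0], c[1]:c[1] + sz[1], c[2]:c[2] + sz[2]] = True
    polarity = "AND" if rng.random() < 0.6 else "NOT"
    return ResolvedGate(mask=mask, polarity=polarity, affine=np.eye(4))


def brute_force_select(tractogram, gates):
    """Independent oracle: per-gate membership sets combined by set logic."""
    member_sets = []
    for g in gates:
        inv = np.linalg.inv(g.affine)
        members = set()
        for i, s in enumerate(tractogram.streamlines):
            idx = np.rint(s @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            ok = np.all((idx >= 0) & (idx < np.asarray(g.mask.shape)), axis=1)
            if ok.any() and g.mask[idx[ok][:, 0], idx[ok][:, 1], idx[ok][:, 2]].any():
                members.add(i)
        member_sets.append((g.polarity, members))
    keep = set(range(len(tractogram)))
    for pol, members in member_sets:
        keep = keep & members if pol == "AND" else keep - members
    return keep


class TestSelection:
    def test_and_mask_at_one_midpoint_keeps_exactly_that_streamline(self):
        from pseudotract.recipes import ResolvedGate

        sls = [np.array([[1.0, 1, 1], [5, 5, 5], [9, 9, 9]]),
               np.array([[1.0, 9, 1], [9, 1, 9]]),
               np.array([[0.0, 0, 9], [9, 0, 0]])]
        t = Tractogram(sls)
        mask = np.zeros((11, 11, 11), bool)
        mask[5, 5, 5] = True
        sel, gen = select_tract(t, [ResolvedGate(mask, "AND", np.eye(4))])
        assert gen and len(sel) == 1
        assert np.array_equal(sel.streamlines[0], sls[0])

    def test_not_covering_volume_annihilates(self):
        from pseudotract.recipes import ResolvedGate

        rng = np.random.default_rng(0)
        t = random_tractogram(rng)
        all_mask = np.ones((21, 21, 21), bool)
        sel, gen = select_tract(t, [ResolvedGate(all_mask, "AND", np.eye(4)),
                                    ResolvedGate(all_mask, "NOT", np.eye(4))])
        assert not gen and len(sel) == 0

    def test_and_covering_volume_keeps_everything(self):
        from pseudotract.recipes import ResolvedGate

        rng = np.random.default_rng(1)
        t = random_tractogram(rng)
        sel, gen = select_tract(t, [ResolvedGate(np.ones((21, 21, 21), bool), "AND", np.eye(4))])
        assert gen and len(sel) == len(t)

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            t = random_tractogram(rng, n_streamlines=int(rng.integers(1, 25)))
            gates = [random_gate(rng) for _ in range(int(rng.integers(1, 5)))]
            if not any(g.polarity == "AND" for g in gates):
                gates[0].polarity = "AND"
            sel, _ = select_tract(t, gates)
            expected = brute_force_select(t, gates)
            got = {i for i, s in enumerate(t.streamlines)
                   if any(s is k for k in sel.streamlines)}
            assert got == expected

    def test_adding_gates_never_increases_kept_count(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            t = random_tractogram(rng)
            gates = [random_gate(rng)]
            gates[0].polarity = "AND"
            prev = len(select_tract(t, gates)[0])
            for _ in range(4):
                gates.append(random_gate(rng))
                now = len(select_tract(t, gates)[0])
                assert now <= prev
                prev = now


class TestPhantomFidelity:
    def test_cc_and_plic_recipes_capture_their_bundles_without_decoys(self, clean_subject, clean_derived):
        """Recipe gates select >= 95% of bundle streamlines and no decoys."""
        from pseudotract.pipeline import truth_reference

        sub, d = clean_subject, clean_derived
        ref = truth_reference(sub)
        recipes = {r.tract: r for r in load_recipes()}
        inv = np.linalg.inv(sub.dwi.affine)
        names = ("cc", "plic_left", "plic_right", "ifo_left", "ifo_right")

        def label(s):
            idx = np.rint(s @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            idx = idx[np.all((idx >= 0) & (idx < np.array(sub.dwi.shape)), axis=1)]
            counts = {n: sub.truth.structures[n][idx[:, 0], idx[:, 1], idx[:, 2]].sum() for n in names}
            return max(counts, key=counts.get)

        labels = [label(s) for s in d.tractogram]

        def selected_indices(tract, side=None):
            gates = resolve_gates(recipes[tract], ref, side=side)
            sel, _ = select_tract(d.tractogram, gates)
            chosen = {id(s) for s in sel.streamlines}
            return {i for i, s in enumerate(d.tractogram.streamlines) if id(s) in chosen}

        cc_idx = {i for i, l in enumerate(labels) if l == "cc"}
        cc_sel = selected_indices("gCC") | selected_indices("bCC")
        assert len(cc_sel & cc_idx) / len(cc_idx) >= 0.95
        assert not (cc_sel - cc_idx)  # no decoy contamination

        for side in ("left", "right"):
            plic_idx = {i for i, l in enumerate(labels) if l == f"plic_{side}"}
            plic_sel = selected_indices("PLIC", side)
            assert len(plic_sel & plic_idx) / len(plic_idx) >= 0.95
            assert not (plic_sel - plic_idx)
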