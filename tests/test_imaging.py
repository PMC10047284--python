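"""3D nucleus segmentation, intensity/puncta quantification, radial
profiles and the hierarchical mixed-model comparison."""

import numpy as np
import pandas as pd
import pytest

from linc_chromatin.imaging import (
    NucleusImage,
    NucleusQuant,
    compare_groups,
    cytoplasm_reference,
    quantify_cohort,
    quantify_nucleus,
    radial_distribution,
    segment_nuclei,
    segment_puncta,
)
from linc_chromatin.synthetic import (
    SynthNucleiSpec,
    gen_nuclei_cohort,
    quants_from_truth,
)


def _sphere_stack(radius_um=5.0, voxel=0.25, shape=64, value=100.0, background=0.0):
    z = (np.arange(shape) + 0.5) * voxel
    c = shape * voxel / 2
    d2 = (
        (z[:, None, None] - c) ** 2
        + (z[None, :, None] - c) ** 2
        + (z[None, None, :] - c) ** 2
    )
    mask = d2 <= radius_um**2
    dna = np.where(mask, value, background).astype(np.float32)
    return (
        NucleusImage(dna=dna, mark=dna.copy(), voxel_size=(voxel,) * 3),
        mask,
    )


class TestSegmentation:
    def test_sphere_volume_recovered(self):
        stack, _ = _sphere_stack(radius_um=5.0)
        masks = segment_nuclei(stack)
        assert len(masks) == 1
        vol = masks[0].sum() * stack.voxel_volume
        expected = 4 / 3 * np.pi * 125
        assert abs(vol - expected) / expected < 0.05

    def test_blank_stack_yields_nothing(self):
        im = NucleusImage(
            dna=np.zeros((16, 16, 16), np.float32),
            mark=np.zeros((16, 16, 16), np.float32),
            voxel_size=(0.25,) * 3,
        )
        assert segment_nuclei(im) == []

    def test_two_spheres_found_separately(self):
        shape, voxel, r = 96, 0.25, 2.5
        z = (np.arange(shape) + 0.5) * voxel
        dna = np.zeros((shape,) * 3, np.float32)
        for cx in (30 * voxel, 66 * voxel):
            c = shape * voxel / 2
            d2 = (
                (z[:, None, None] - c) ** 2
                + (z[None, :, None] - c) ** 2
                + (z[None, None, :] - cx) ** 2
            )
            dna[d2 <= r**2] = 100.0
        im = NucleusImage(dna=dna, mark=dna, voxel_size=(voxel,) * 3)
        masks = segment_nuclei(im)
        assert len(masks) == 2
        expected = 4 / 3 * np.pi * r**3
        for m in masks:
            assert abs(m.sum() * im.voxel_volume - expected) / expected < 0.1

    def test_small_and_boundary_components_discarded(self):
        stack, _ = _sphere_stack(radius_um=1.5)  # ~14 um^3 < 20 um^3 floor
        with pytest.warns(UserWarning):
            assert segment_nuclei(stack) == []


class TestQuantify:
    def test_uniform_mark_mean_exact(self):
        stack, mask = _sphere_stack()
        stack.mark[:] = 0
        stack.mark[mask] = 42.0
        seg = segment_nuclei(stack)[0]
        q = quantify_nucleus(seg, stack)
        assert q.mean_mark_intensity == pytest.approx(42.0)

    def test_volume_scales_with_voxel_size(self):
        stack, _ = _sphere_stack()
        seg = segment_nuclei(stack)[0]
        q1 = quantify_nucleus(seg, stack)
        big = NucleusImage(
            dna=stack.dna, mark=stack.mark, voxel_size=(0.5, 0.5, 0.5)
        )
        q2 = quantify_nucleus(seg, big)
        assert q2.volume == pytest.approx(8 * q1.volume)

    def test_cytoplasmic_halo_cannot_leak_into_mean(self):
        stack, mask = _sphere_stack()
        seg = segment_nuclei(stack)[0]
        base = quantify_nucleus(seg, stack).mean_mark_intensity
        halo = stack.mark.copy()
        halo[~mask] = 500.0  # bright cytoplasm outside the nucleus
        stack2 = NucleusImage(dna=stack.dna, mark=halo, voxel_size=stack.voxel_size)
        assert quantify_nucleus(seg, stack2).mean_mark_intensity == pytest.approx(
            base
        )

    def test_empty_mask_rejected(self):
        stack, _ = _sphere_stack()
        with pytest.raises(ValueError):
            quantify_nucleus(np.zeros_like(stack.dna, bool), stack)


def _puncta_stack(volumes_um3, voxel=0.1, shape=64, base=50.0, contrast=200.0):
    """Nucleus-sized mask with hard spherical puncta of known volume."""
    z = (np.arange(shape) + 0.5) * voxel
    c = shape * voxel / 2
    d2 = (
        (z[:, None, None] - c) ** 2
        + (z[None, :, None] - c) ** 2
        + (z[None, None, :] - c) ** 2
    )
    mask = d2 <= (shape * voxel * 0.45) ** 2
    mark = np.full((shape,) * 3, base, np.float32)
    centers = [
        (c + 1.2 * np.cos(2 * np.pi * k / len(volumes_um3)),
         c + 1.2 * np.sin(2 * np.pi * k / len(volumes_um3)), c)
        for k in range(len(volumes_um3))
    ]
    for (cx, cy, cz), v in zip(centers, volumes_um3):
        r = (3 * v / (4 * np.pi)) ** (1 / 3)
        dd = (
            (z[:, None, None] - cx) ** 2
            + (z[None, :, None] - cy) ** 2
            + (z[None, None, :] - cz) ** 2
        )
        mark[dd <= r**2] = base + contrast
    return mask, mark, (voxel,) * 3


class TestPuncta:
    def test_five_supra_threshold_puncta_counted(self):
        mask, mark, vox = _puncta_stack([0.05] * 5)
        puncta = segment_puncta(mask, mark, vox)
        assert len(puncta) == 5
        for p in puncta:
            assert abs(p.volume - 0.05) / 0.05 < 0.2

    def test_sub_threshold_blob_filtered_out(self):
        mask, mark, vox = _puncta_stack([0.005], voxel=0.05)
        assert segment_puncta(mask, mark, vox) == []

    def test_mixed_volumes_exact_supra_count(self):
        mask, mark, vox = _puncta_stack([0.05, 0.004, 0.08, 0.006], voxel=0.05)
        puncta = segment_puncta(mask, mark, vox)
        assert len(puncta) == 2  # only the 0.05 and 0.08 um^3 puncta survive

    def test_flat_nucleus_has_no_puncta(self):
        mask, mark, vox = _puncta_stack([])
        assert segment_puncta(mask, mark, vox) == []

    def test_no_voxel_in_two_puncta(self):
        mask, mark, vox = _puncta_stack([0.05] * 5)
        # reconstruct label map the same way and check disjointness via
        # total volume <= mask volume
        puncta = segment_puncta(mask, mark, vox)
        total = sum(p.volume for p in puncta)
        assert total <= mask.sum() * np.prod(vox)


class TestRadialProfile:
    def test_uniform_intensity_flat_profile(self):
        stack, mask = _sphere_stack(value=80.0, background=80.0)
        seg = segment_nuclei(NucleusImage(
            dna=np.where(mask, 100.0, 0.0).astype(np.float32),
            mark=stack.mark, voxel_size=stack.voxel_size))[0]
        ref = cytoplasm_reference(seg)
        prof = radial_distribution(seg, stack.mark, stack.voxel_size, 5, ref)
        np.testing.assert_allclose(prof, 1.0, atol=0.01)

    def test_peripheral_rim_enriches_first_shell(self):
        spec = SynthNucleiSpec(
            n_larvae=2, muscles_per_larva=1, nuclei_per_muscle=1,
            peripheral_bias=2.0, noise_sd_frac=0.0, puncta_count_mean=0.0,
        )
        imgs, _ = gen_nuclei_cohort(spec, seed=0)
        im = imgs[0]
        seg = segment_nuclei(im)[0]
        ref = cytoplasm_reference(seg)
        prof = radial_distribution(seg, im.dna, im.voxel_size, 5, ref)
        assert prof[0] > prof[-1]

    def test_scale_invariance_of_ratio(self):
        stack, mask = _sphere_stack(value=80.0, background=80.0)
        dna = np.where(mask, 100.0, 0.0).astype(np.float32)
        seg = segment_nuclei(NucleusImage(dna=dna, mark=stack.mark,
                                          voxel_size=stack.voxel_size))[0]
        ref = cytoplasm_reference(seg)
        a = radial_distribution(seg, stack.mark, stack.voxel_size, 4, ref)
        b = radial_distribution(seg, 3.7 * stack.mark, stack.voxel_size, 4, ref)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_empty_reference_rejected(self):
        stack, _ = _sphere_stack()
        seg = segment_nuclei(stack)[0]
        with pytest.raises(ValueError):
            radial_distribution(seg, stack.mark, stack.voxel_size, 5,
                                np.zeros_like(seg))


class TestCompareGroups:
    def _quants(self, effect=0.0, seed=0, **kw):
        spec = SynthNucleiSpec(genotype_effect=effect, **kw)
        _, truth = gen_nuclei_cohort(spec, seed, render=False)
        return quants_from_truth(truth)

    def test_identical_groups_null_result(self):
        q = self._quants(effect=0.0, seed=1, larva_sd=0.0, muscle_sd=0.0,
                         nucleus_sd=0.0)
        res = compare_groups(q)
        assert res.effect_pct == pytest.approx(0.0, abs=1e-6)
        assert res.p_value > 0.9

    def test_fifty_percent_effect_recovered(self):
        """Injected +50% multiplicative effect is recovered within
        [40, 60] in >= 90% of seeds."""
        hits = 0
        n_seeds = 60
        for s in range(n_seeds):
            q = self._quants(
                effect=50.0, seed=s, n_larvae=8, larva_sd=0.05, muscle_sd=0.05
            )
            est = compare_groups(q).effect_pct
            hits += 40.0 <= est <= 60.0
        assert hits / n_seeds >= 0.9

    def test_permuted_labels_kill_the_effect(self, rng):
        q = self._quants(effect=50.0, seed=3)
        df = pd.DataFrame(
            {
                "genotype": [x.genotype for x in q],
                "larva_id": [x.larva_id for x in q],
                "muscle_id": [x.muscle_id for x in q],
                "volume": [x.volume for x in q],
                "mean_mark_intensity": [x.mean_mark_intensity for x in q],
                "total_dna_intensity": [x.total_dna_intensity for x in q],
                "mean_punctum_volume": np.nan,
                "n_puncta": 0,
                "nucleus_id": "",
            }
        )
        true_effect = compare_groups(df).effect_pct
        perm_effects = []
        for _ in range(5):
            shuffled = df.copy()
            # permute genotype at the larva level, preserving the hierarchy
            larvae = shuffled["larva_id"].unique()
            geno = rng.permutation(
                [df[df.larva_id == l]["genotype"].iloc[0] for l in larvae]
            )
            mapping = dict(zip(larvae, geno))
            shuffled["genotype"] = shuffled["larva_id"].map(mapping)
            try:
                perm_effects.append(abs(compare_groups(shuffled).effect_pct))
            except ValueError:
                continue  # a permutation may put <2 larvae in a genotype
        assert perm_effects
        assert np.median(perm_effects) < abs(true_effect)

    def test_volume_covariate_fit(self):
        q = self._quants(effect=30.0, seed=5)
        res = compare_groups(q, log_volume_covariate=True)
        assert res.p_value < 0.05
        assert 15 < res.effect_pct < 45

    def test_needs_two_genotypes(self):
        q = self._quants(effect=0.0, seed=0)
        only_ctrl = [x for x in q if x.genotype == "control"]
        with pytest.raises(ValueError):
            compare_groups(only_ctrl)


def test_cohort_pipeline_metadata_propagation():
    spec = SynthNucleiSpec(n_larvae=2, muscles_per_larva=1, nuclei_per_muscle=2)
    imgs, truth = gen_nuclei_cohort(spec, seed=4)
    quants = quantify_cohort(imgs)
    assert len(quants) == len(truth)
    assert {q.genotype for q in quants} == {"control", "mutant"}
    assert all(q.larva_id and q.muscle_id for q in quants)
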