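"""Skeleton-graph analysis, classification filter and per-cell metrics."""

import numpy as np
import pytest

from mitomorph.images import BinaryMask
from mitomorph.morphology import (
    MitoNetworkAnalyzer,
    analyze_skeleton,
    cell_morphometrics,
    classify_objects,
    label_components,
    mitochondrial_footprint,
    skeletonize_mask,
)
from mitomorph.synth import SceneSpec, generate_scene
from conftest import flood_fill_label, neighbor_counts, random_masks

PPM = 23.4
NOISELESS = dict(gaussian_sd=0.0, poisson_scale=0.0)


def mask_of(arr, ppm=1.0):
    return BinaryMask(np.asarray(arr, dtype=bool), pixels_per_micron=ppm)


class TestComponents:
    def test_counts_two_disjoint_blobs(self):
        a = np.zeros((12, 12), bool)
        a[1:2, 1:6] = True  # 5 px line
        a[8, 3:8] = True  # 5 px line
        comps = label_components(mask_of(a))
        assert comps.n_components == 2
        assert sorted(comps.props["area_px"]) == [5, 5]

    def test_area_unit_conversion_at_default_calibration(self):
        a = np.zeros((40, 40), bool)
        a.ravel()[:1000] = True
        comps = label_components(mask_of(a, ppm=PPM))
        assert mitochondrial_footprint(comps) == pytest.approx(1000 / PPM**2)
        assert mitochondrial_footprint(comps) == pytest.approx(1.826, abs=2e-3)

    def test_labels_match_flood_fill_oracle(self):
        for mask in random_masks(100, shape=(32, 32), seed=5):
            comps = label_components(mask_of(mask))
            oracle = flood_fill_label(mask)
            assert comps.n_components == oracle.max()
            # identical partitions up to relabeling
            pairs = set(zip(comps.labels.ravel(), oracle.ravel()))
            assert len(pairs) == oracle.max() + 1

    def test_empty_mask_gives_empty_set_and_zero_footprint(self):
        comps = label_components(mask_of(np.zeros((10, 10))))
        assert comps.n_components == 0
        assert mitochondrial_footprint(comps) == 0.0

    def test_footprint_is_additive(self):
        import pandas as pd
        from mitomorph.morphology import ComponentSet

        props = pd.DataFrame({"component_id": [1, 2, 3],
                              "area_um2": [1.2, 0.6, 0.2]})
        cs = ComponentSet(labels=np.zeros((2, 2), int), props=props,
                          pixels_per_micron=PPM)
        assert mitochondrial_footprint(cs) == pytest.approx(2.0)


class TestSkeletonize:
    def test_solid_bar_thins_to_single_line(self):
        a = np.zeros((9, 26), bool)
        a[3:6, 3:23] = True  # 20x3 bar
        skel = skeletonize_mask(mask_of(a))
        g = list(analyze_skeleton(skel))[0]
        assert g.branch_count == 1
        assert g.junction_count == 0
        assert 15 <= g.branches[0].length_px <= 20

    def test_filled_disk_degenerates_without_junctions(self):
        from skimage.morphology import disk as disk_fp

        a = np.pad(disk_fp(6).astype(bool), 3)
        skel = skeletonize_mask(mask_of(a))
        g = list(analyze_skeleton(skel))[0]
        assert g.junction_count == 0
        assert skel.pixels.sum() <= 5

    def test_component_count_preserved_and_skeleton_subset(self):
        for mask in random_masks(100, shape=(32, 32), seed=17):
            m = mask_of(mask)
            skel = skeletonize_mask(m)
            assert (skel.pixels & ~m.pixels).sum() == 0
            assert flood_fill_label(m.pixels).max() == flood_fill_label(skel.pixels).max()


class TestAnalyzeSkeleton:
    def test_straight_line_single_branch(self):
        a = np.zeros((5, 14), bool)
        a[2, 2:12] = True
        g = list(analyze_skeleton(mask_of(a, ppm=2.0)))[0]
        assert (g.branch_count, g.junction_count, g.endpoint_count) == (1, 0, 2)
        assert g.branches[0].length_px == pytest.approx(9.0)
        assert g.branches[0].length_um == pytest.approx(4.5)

    def test_diagonal_line_uses_sqrt2_metric(self):
        a = np.zeros((14, 14), bool)
        for i in range(10):
            a[2 + i, 2 + i] = True
        g = list(analyze_skeleton(mask_of(a)))[0]
        assert g.branches[0].length_px == pytest.approx(9 * np.sqrt(2))

    def test_t_shape_three_branches_one_junction(self):
        a = np.zeros((10, 11), bool)
        a[2, 2:9] = True  # 7-px bar
        a[3:7, 5] = True  # 4-px stem from its center
        # brute-force oracle on the printed pixel set
        counts = neighbor_counts(a)
        assert (counts[a] > 2).sum() >= 1  # junction pixels exist
        assert (counts[a] == 1).sum() == 3  # three tips
        g = list(analyze_skeleton(mask_of(a)))[0]
        assert (g.branch_count, g.junction_count, g.endpoint_count) == (3, 1, 3)

    def test_junction_and_endpoint_pixels_match_neighbor_count_oracle(self):
        for mask in random_masks(100, shape=(32, 32), seed=23):
            skel = skeletonize_mask(mask_of(mask)).pixels
            counts = neighbor_counts(skel)
            graph = analyze_skeleton(mask_of(skel))
            junction_px = {p for g in graph for n in g.nodes if n.kind == "junction" for p in n.pixels}
            endpoint_px = {p for g in graph for n in g.nodes if n.kind == "endpoint" for p in n.pixels}
            oracle_junctions = {tuple(p) for p in np.argwhere(skel & (counts > 2))}
            oracle_endpoints = {tuple(p) for p in np.argwhere(skel & (counts == 1))}
            assert junction_px == oracle_junctions
            assert endpoint_px == oracle_endpoints

    def test_closed_ring_has_no_nodes_one_closed_branch(self):
        # diamond ring: a clean 8-connected cycle
        a = np.zeros((9, 9), bool)
        for i in range(4):
            a[i, 4 - i] = a[i, 4 + i] = True
            a[8 - i, 4 - i] = a[8 - i, 4 + i] = True
        a[4, 0] = a[4, 8] = True
        g = list(analyze_skeleton(mask_of(a)))[0]
        assert (g.junction_count, g.endpoint_count) == (0, 0)
        assert g.branch_count == 1
        assert g.branches[0].closed

    def test_solid_block_rejected(self):
        a = np.zeros((6, 6), bool)
        a[1:4, 1:4] = True
        with pytest.raises(ValueError, match="skeleton"):
            analyze_skeleton(mask_of(a))


class TestClassification:
    def _objects(self, arr):
        m = mask_of(arr)
        comps = label_components(m)
        graph = analyze_skeleton(skeletonize_mask(m), comps)
        return classify_objects(graph, comps)

    def test_single_open_branch_is_individual(self):
        a = np.zeros((5, 12), bool)
        a[2, 2:10] = True
        (obj,) = self._objects(a)
        assert obj.mito_class == "individual"
        assert (obj.branch_count, obj.junction_count) == (1, 0)

    def test_branched_component_is_network(self):
        a = np.zeros((10, 11), bool)
        a[2, 2:9] = True
        a[3:7, 5] = True
        (obj,) = self._objects(a)
        assert obj.mito_class == "network"
        assert obj.branch_count == 3 and obj.junction_count == 1

    def test_ring_is_unclassified_loop(self):
        a = np.zeros((9, 9), bool)
        for i in range(4):
            a[i, 4 - i] = a[i, 4 + i] = True
            a[8 - i, 4 - i] = a[8 - i, 4 + i] = True
        a[4, 0] = a[4, 8] = True
        (obj,) = self._objects(a)
        assert obj.mito_class == "unclassified"
        assert obj.reason == "loop"

    def test_isolated_pixel_is_flagged_individual(self):
        a = np.zeros((5, 5), bool)
        a[2, 2] = True
        (obj,) = self._objects(a)
        assert obj.mito_class == "individual"
        assert obj.degenerate

    def test_partition_is_exhaustive_and_exclusive(self):
        for mask in random_masks(30, shape=(48, 48), seed=31):
            objs = self._objects(mask)
            n_comp = label_components(mask_of(mask)).n_components
            assert len(objs) == n_comp
            counts = {"network": 0, "individual": 0, "unclassified": 0}
            for o in objs:
                counts[o.mito_class] += 1
            assert sum(counts.values()) == n_comp

    def test_mismatched_components_error(self):
        a = np.zeros((5, 12), bool)
        a[2, 2:10] = True
        m = mask_of(a)
        comps = label_components(m)
        graph = analyze_skeleton(skeletonize_mask(m), comps)
        comps2 = label_components(mask_of(np.zeros((5, 12))))
        with pytest.raises(ValueError, match="component"):
            classify_objects(graph, comps2)


class TestCellMorphometrics:
    def _fake_objects(self):
        from mitomorph.morphology import MitoObject

        nets = [
            MitoObject(1, "network", 5, 20, 6, [1.0, 2.0, 3.0], 4.0, 2.0),
            MitoObject(2, "network", 4, 16, 5, [2.0, 4.0], 3.0, 2.5),
        ]
        inds = [
            MitoObject(10 + i, "individual", 1, 0, 2, [float(i + 1)], 0.5, 3.0)
            for i in range(6)
        ]
        return nets + inds

    def test_count_ratio_and_connectivity(self):
        m = cell_morphometrics(self._fake_objects(), footprint_um2=12.0)
        assert m.individual_to_network_ratio == pytest.approx(3.0)
        assert m.mean_junctions_per_network == pytest.approx(18.0)
        assert m.median_network_branch_len_um == pytest.approx(2.0)
        assert m.median_individual_len_um == pytest.approx(3.5)
        assert m.n_networks == 2 and m.n_individuals == 6

    def test_missing_values_propagate_not_zero(self):
        m = cell_morphometrics([], footprint_um2=0.0)
        assert np.isnan(m.individual_to_network_ratio)
        assert np.isnan(m.median_network_branch_len_um)
        assert np.isnan(m.median_individual_len_um)

    def test_fields_match_independent_ground_truth_aggregation(self):
        # full pipeline on noise-free truth masks vs direct aggregation of
        # the generator's records
        for seed in range(20):
            spec = SceneSpec(
                image_size=(300, 300), n_networks=1, n_individuals=4,
                seed=seed, **NOISELESS,
            )
            _, truth_mask, truth = generate_scene(spec)
            res = MitoNetworkAnalyzer().analyze(truth_mask)
            m = res.morphometrics
            nets = truth.by_class("network")
            inds = truth.by_class("individual")
            assert m.n_networks == len(nets)
            assert m.n_individuals == len(inds)
            assert m.individual_to_network_ratio == pytest.approx(
                len(inds) / len(nets)
            )
            exp_ratio_med = float(
                np.median([l for o in nets for l in o.true_branch_lengths_um])
            )
            assert m.median_network_branch_len_um == pytest.approx(
                exp_ratio_med, abs=3.0 / spec.pixels_per_micron
            )
            exp_ind_med = float(
                np.median([o.true_branch_lengths_um[0] for o in inds])
            )
            assert m.median_individual_len_um == pytest.approx(
                exp_ind_med, abs=3.0 / spec.pixels_per_micron
            )
            assert m.footprint_um2 == pytest.approx(
                sum(o.true_area_px for o in truth.objects) / spec.pixels_per_micron**2
            )


class TestShapeMetrics:
    def test_sphere_aspect_near_one_rod_elongated(self):
        spec = SceneSpec(
            image_size=(300, 300), n_networks=0, n_individuals=3, n_spheres=3,
            seed=12,
        )
        img, truth_mask, truth = generate_scene(spec)
        from mitomorph.preprocess import preprocess_micrograph

        res = MitoNetworkAnalyzer().analyze(preprocess_micrograph(img))
        labels = res.components.labels
        aspects = {int(r.component_id): float(r.aspect_ratio)
                   for r in res.components.props.itertuples()}
        for obj in truth.objects:
            rr, cc = zip(*obj.centerline_pixels)
            lab = labels[np.array(rr), np.array(cc)]
            lab = lab[lab > 0]
            assert len(lab) > 0
            a = aspects[int(np.bincount(lab).argmax())]
            if obj.shape == "sphere":
                assert a < 1.5
            else:
                assert a > 1.5

    def test_individuals_shorter_than_network_branches_when_generated_so(self):
        spec = SceneSpec(
            image_size=(420, 420), n_networks=2, n_individuals=4,
            branch_length_range=(2.0, 3.0), seed=3, **NOISELESS,
        )
        _, net_mask, _ = generate_scene(spec)
        spec_short = SceneSpec(
            image_size=(420, 420), n_networks=0, n_individuals=4,
            branch_length_range=(0.5, 1.0), seed=4, **NOISELESS,
        )
        _, ind_mask, _ = generate_scene(spec_short)
        analyzer = MitoNetworkAnalyzer()
        m_net = analyzer.analyze(net_mask).morphometrics
        m_ind = analyzer.analyze(ind_mask).morphometrics
        assert m_ind.median_individual_len_um < m_net.median_network_branch_len_um
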