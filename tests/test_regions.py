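"""Nine-region partitioning, implant segmentation and coverage."""

import numpy as np
import pytest

from orbitqc.phantom import WALL_REGIONS
from orbitqc.regions import (ImplantMask, implant_coverage, label_walls,
                             segment_implant, split_thirds, transition_zone_mask)


class TestPartition:
    def test_every_vertex_exactly_one_label(self, mirror_setup):
        labeling = mirror_setup["labeling"]
        assert len(labeling.labels) == mirror_setup["template"].n_vertices
        allowed = set(WALL_REGIONS) | {"roof", "rim", "unassigned"}
        assert set(np.unique(labeling.labels)) <= allowed

    def test_nine_wall_regions_nonempty(self, mirror_setup):
        present = set(np.unique(mirror_setup["labeling"].labels))
        assert set(WALL_REGIONS) <= present

    def test_lowest_vertices_are_floor(self, mirror_setup):
        template = mirror_setup["template"]
        labels = mirror_setup["labeling"].labels
        lowest = np.argsort(template.vertices[:, 2])[:50]
        walls = {str(l).split("_")[0] for l in labels[lowest]}
        assert walls == {"floor"}

    def test_wall_agreement_with_truth(self, mirror_setup):
        """>= 90% of wall vertices get the generator's wall label."""
        truth = mirror_setup["truth"]
        template = mirror_setup["template"]
        labels = mirror_setup["labeling"].labels
        tl = truth.label_points(template.vertices, "right")
        walls_pl = np.array([str(l).split("_")[0] for l in labels])
        walls_tr = np.array([str(l).split("_")[0] for l in tl])
        sel = np.isin(walls_tr, ("medial", "floor", "lateral"))
        agreement = (walls_pl[sel] == walls_tr[sel]).mean()
        assert agreement >= 0.90

    def test_thirds_agreement_with_truth(self, mirror_setup):
        """>= 95% depth-third agreement on wall vertices."""
        truth = mirror_setup["truth"]
        template = mirror_setup["template"]
        labels = mirror_setup["labeling"].labels
        tl = truth.label_points(template.vertices, "right")
        both_walls = (np.char.count(labels.astype(str), "_") > 0) \
            & (np.char.count(tl.astype(str), "_") > 0)
        thirds_pl = np.array([str(l).split("_")[-1] for l in labels])
        thirds_tr = np.array([str(l).split("_")[-1] for l in tl])
        agreement = (thirds_pl[both_walls] == thirds_tr[both_walls]).mean()
        assert agreement >= 0.95

    def test_boundary_vertex_goes_to_deeper_third(self, mirror_setup):
        """d exactly 1/3 classifies as central (right-closed boundary)."""
        labeling = mirror_setup["labeling"]
        walls = label_walls(mirror_setup["template"], mirror_setup["truth"].landmarks,
                            mirror_setup["plane"], "right")
        walls.depth_norm = np.full(len(walls.labels), 1.0 / 3.0)
        out = split_thirds(walls)
        on_walls = np.char.count(out.labels.astype(str), "_") > 0
        assert np.all(np.char.endswith(out.labels[on_walls].astype(str), "central"))
        del labeling

    def test_area_conservation(self, mirror_setup):
        template = mirror_setup["template"]
        labeling = mirror_setup["labeling"]
        areas = template.vertex_areas()
        total = sum(areas[labeling.labels == r].sum()
                    for r in np.unique(labeling.labels))
        assert total == pytest.approx(areas.sum(), rel=1e-6)

    def test_transition_zone_band(self, mirror_setup):
        labeling = mirror_setup["labeling"]
        band = transition_zone_mask(labeling, band_mm=2.0)
        assert band.any()
        walls = {str(l).split("_")[0] for l in labeling.labels[band]}
        assert walls <= {"medial", "floor", "rim"}


class TestSegmentImplant:
    def test_exact_recovery_on_phantom(self, default_phantom):
        truth = default_phantom["truth"]
        rec = default_phantom["reconstructed"]
        # CBCT profile: implant at 3000 * 0.6 = 1800, bone at 720
        imp = segment_implant(rec, implant_threshold=1200.0)
        got = set(map(tuple, np.argwhere(imp.mask)))
        expected = set(map(tuple, truth.implant_indices))
        # noise may flip a handful of voxels near the threshold
        assert len(got ^ expected) <= 0.01 * len(expected)

    def test_preoperative_volume_warns_empty(self, default_phantom):
        with pytest.warns(UserWarning, match="no implant"):
            imp = segment_implant(default_phantom["affected"],
                                  implant_threshold=5000.0)
        assert imp.voxel_count == 0

    def test_low_threshold_leaks_into_bone(self, default_phantom):
        rec = default_phantom["reconstructed"]
        imp_good = segment_implant(rec, implant_threshold=1200.0)
        imp_bad = segment_implant(rec, implant_threshold=500.0)
        # leaking into the bone shell inflates the largest component hugely
        assert imp_bad.component_sizes[0] > 5 * imp_good.voxel_count


@pytest.fixture(scope="session")
def coverage(noiseless_phantom, mirror_setup):
    from orbitqc.deviation import signed_distance

    rec = noiseless_phantom["reconstructed"]
    imp = segment_implant(rec, implant_threshold=1200.0)
    # coverage is measured at the template's foot points on the
    # reconstructed surface — where the implant actually sits
    _, foot = signed_distance(mirror_setup["template"], mirror_setup["target"],
                              return_closest=True)
    return implant_coverage(mirror_setup["labeling"], mirror_setup["template"],
                            imp, surface_points=foot)


class TestImplantCoverage:
    def test_empty_implant_gives_zero_everywhere(self, mirror_setup):
        imp = ImplantMask(mask=np.zeros((4, 4, 4), dtype=bool),
                          spacing=(0.5,) * 3, origin=(0, 0, 0))
        cov = implant_coverage(mirror_setup["labeling"], mirror_setup["template"],
                               imp).set_index("region")
        assert (cov["coverage_fraction"] == 0.0).all()

    def test_full_floor_implant_covers_floor(self, coverage):
        cov = coverage.set_index("region")["coverage_fraction"]
        for region in ("floor_anterior", "floor_central", "floor_posterior"):
            assert cov[region] > 0.85
        for region in ("medial_central", "lateral_central", "roof"):
            assert cov[region] < 0.25

    def test_coverage_in_unit_interval(self, coverage):
        assert ((coverage["coverage_fraction"] >= 0)
                & (coverage["coverage_fraction"] <= 1)).all()

    def test_coverage_monotone_in_projection_distance(self, default_phantom,
                                                      mirror_setup):
        rec = default_phantom["reconstructed"]
        imp = segment_implant(rec, implant_threshold=1200.0)
        labeling = mirror_setup["labeling"]
        template = mirror_setup["template"]
        c1 = implant_coverage(labeling, template, imp, projection_distance_mm=1.0)
        c3 = implant_coverage(labeling, template, imp, projection_distance_mm=3.0)
        assert (c3["coverage_fraction"] >= c1["coverage_fraction"] - 1e-12).all()
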