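"""Rendering and image quantification: segmentation, classification,
well measurement, transfection efficiency."""

import dataclasses

import numpy as np
import pytest

import hcsprotect as h
from hcsprotect.imaging import (LABEL_DYING, LABEL_HEALTHY, ClassifierParams,
                                ClassifierThresholds, NucleusRecord,
                                fit_thresholds)
from hcsprotect.render import render_from_positions

from conftest import match_centroids


def _grid_positions(n, size, spacing, margin=25):
    per_row = int((size - 2 * margin) // spacing) + 1
    pos = [(margin + spacing * (i // per_row), margin + spacing * (i % per_row))
           for i in range(n)]
    assert max(p[0] for p in pos) < size - margin
    return np.array(pos, dtype=float)


class TestRenderer:
    def test_zero_nuclei_gives_background_only(self, neutral_truth,
                                               imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=0)
        well = h.render_well_image(None, True, neutral_truth, params, seed=0)
        assert well.nuclei == []
        assert well.image.mean() < 3 * params.background_level

    def test_planted_label_counts_by_construction(self, imaging_params):
        pos = _grid_positions(100, imaging_params.image_size, 24)
        dying = np.zeros(100, bool)
        dying[:20] = True
        well = render_from_positions(pos, dying, imaging_params, seed=1)
        assert len(well.nuclei) == 100
        assert well.n_dying == 20

    def test_template_invariants_enforced(self, imaging_params):
        with pytest.raises(ValueError, match="brighter"):
            dataclasses.replace(imaging_params, dying_intensity_mult=0.9).validate()
        with pytest.raises(ValueError, match="smaller"):
            dataclasses.replace(imaging_params, dying_sigma_mult=1.2).validate()

    def test_overpacked_well_rejected_with_diagnostic(self, neutral_truth,
                                                      imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=2000)
        with pytest.raises(ValueError, match="overlap"):
            h.render_well_image(None, True, neutral_truth, params, seed=0)

    def test_same_seed_identical_images(self, neutral_truth, imaging_params):
        a = h.render_well_image("x", True,
                                h.GroundTruth({"x": 0.6}, seed=0),
                                imaging_params, seed=5)
        b = h.render_well_image("x", True,
                                h.GroundTruth({"x": 0.6}, seed=0),
                                imaging_params, seed=5)
        assert np.array_equal(a.image, b.image)
        assert a.labels == b.labels


class TestSegmentation:
    def test_background_only_image_yields_no_records(self, neutral_truth,
                                                     imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=0)
        well = h.render_well_image(None, True, neutral_truth, params, seed=2)
        assert h.segment_nuclei(well.image) == []

    def test_constant_image_warns_not_raises(self):
        with pytest.warns(UserWarning, match="constant"):
            assert h.segment_nuclei(np.full((64, 64), 500, np.uint16)) == []

    def test_nonimage_input_rejected(self):
        with pytest.raises(ValueError):
            h.segment_nuclei(np.zeros((4, 4, 3)))

    def test_planted_nuclei_recovered_with_subpixel_centroids(
            self, neutral_truth, imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=50)
        well = h.render_well_image(None, True, neutral_truth, params, seed=8)
        records = h.segment_nuclei(well.image)
        assert len(records) == 50
        n_matched, pairs = match_centroids(
            [n.center for n in well.nuclei],
            [r.centroid for r in records], tol=2.0)
        assert n_matched == 50  # every centroid within 2 px

    def test_touching_nuclei_split_by_watershed(self, imaging_params):
        # Two healthy nuclei one radius (~10 px) apart must yield 2 objects.
        size = imaging_params.image_size
        pos = np.array([[size / 2, size / 2 - 5], [size / 2, size / 2 + 5.0]])
        well = render_from_positions(pos, np.zeros(2, bool), imaging_params,
                                     seed=3)
        records = h.segment_nuclei(well.image)
        assert len(records) == 2


class TestClassifier:
    def _record(self, intensity, area, nid=0):
        return NucleusRecord(nucleus_id=nid, centroid=(0.0, 0.0), area=area,
                             mean_intensity=intensity,
                             integrated_intensity=intensity * area,
                             circularity=0.9, intensity_dispersion=0.1)

    def test_homogeneous_healthy_population_all_healthy(
            self, imaging_params, dark_reference_records):
        pos = _grid_positions(80, imaging_params.image_size, 24)
        well = render_from_positions(pos, np.zeros(80, bool), imaging_params,
                                     seed=21)
        records = h.segment_nuclei(well.image)
        labelled = h.classify_nuclei(records,
                                     reference=dark_reference_records)
        assert all(r.label == LABEL_HEALTHY for r in labelled)

    def test_fitted_rule_forces_bright_small_nucleus_dying(self):
        rng = np.random.default_rng(0)
        ref = [self._record(1000 + 50 * rng.standard_normal(),
                            130 + 10 * rng.standard_normal(), i)
               for i in range(200)]
        thr = fit_thresholds(ref, k=3.0)
        # +4 robust-z intensity, -3 robust-z area relative to the reference.
        probe = self._record(thr.intensity_center + 4 * thr.intensity_scale,
                             thr.area_center - 3 * thr.area_scale)
        (labelled,) = h.classify_nuclei([probe],
                                        ClassifierParams(thresholds=thr))
        assert labelled.label == LABEL_DYING
        # A nucleus matching the reference template stays healthy.
        (ok,) = h.classify_nuclei(
            [self._record(thr.intensity_center, thr.area_center)],
            ClassifierParams(thresholds=thr))
        assert ok.label == LABEL_HEALTHY

    def test_planted_dying_fraction_recovered(self, imaging_params,
                                              dark_reference_records):
        thr = fit_thresholds(dark_reference_records)
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=120)
        truth = h.GroundTruth({"x": 0.5}, seed=0)  # 20% dying under light
        fracs = []
        for s in range(5):
            well = h.render_well_image("x", True, truth, params, seed=40 + s)
            records = h.classify_nuclei(h.segment_nuclei(well.image),
                                        ClassifierParams(thresholds=thr))
            est = np.mean([r.label == LABEL_DYING for r in records])
            fracs.append(est - well.n_dying / len(well.nuclei))
        assert np.max(np.abs(fracs)) < 0.03  # within 3 percentage points

    def test_raising_intensity_cut_never_adds_dying_calls(
            self, dark_reference_records):
        thr = fit_thresholds(dark_reference_records)
        counts = []
        for bump in (0.0, 50.0, 200.0, 1000.0):
            t = dataclasses.replace(thr,
                                    intensity_high=thr.intensity_high + bump)
            labelled = h.classify_nuclei(dark_reference_records,
                                         ClassifierParams(thresholds=t))
            counts.append(sum(r.label == LABEL_DYING for r in labelled))
        assert counts == sorted(counts, reverse=True)

    def test_fit_without_reference_rejected(self):
        with pytest.raises(ValueError, match="control"):
            h.classify_nuclei([self._record(1.0, 1.0)])
        with pytest.raises(ValueError):
            fit_thresholds([])

    def test_cluster_mode_separates_planted_populations(self, imaging_params):
        pos = _grid_positions(100, imaging_params.image_size, 24)
        dying = np.zeros(100, bool)
        dying[:30] = True
        well = render_from_positions(pos, dying, imaging_params, seed=9)
        records = h.segment_nuclei(well.image)
        labelled = h.classify_nuclei(records, ClassifierParams(mode="cluster"))
        frac = np.mean([r.label == LABEL_DYING for r in labelled])
        assert abs(frac - 0.3) < 0.05


class TestWellMeasurement:
    def _records(self, n_healthy, n_dying):
        recs = []
        for i in range(n_healthy + n_dying):
            recs.append(NucleusRecord(
                nucleus_id=i, centroid=(0, 0), area=100, mean_intensity=1,
                integrated_intensity=100, circularity=1.0,
                intensity_dispersion=0.1,
                label=LABEL_DYING if i < n_dying else LABEL_HEALTHY))
        return recs

    @pytest.mark.parametrize("n_healthy,n_dying,expected", [
        (100, 0, 0.0),
        (60, 20, 25.0),
        (0, 50, 100.0),
    ])
    def test_percent_dying_arithmetic(self, n_healthy, n_dying, expected):
        m = h.measure_well(self._records(n_healthy, n_dying), plate_id="P",
                           well="A01", role="sample", min_nuclei=10)
        assert m.percent_dying == expected
        assert m.valid

    def test_sparse_well_flagged_invalid(self):
        m = h.measure_well(self._records(10, 5), plate_id="P", well="A01",
                           role="sample", min_nuclei=50)
        assert not m.valid
        empty = h.measure_well([], plate_id="P", well="A02", role="sample")
        assert not empty.valid and np.isnan(empty.percent_dying)

    def test_unclassified_records_rejected(self):
        rec = NucleusRecord(nucleus_id=0, centroid=(0, 0), area=100,
                            mean_intensity=1, integrated_intensity=1,
                            circularity=1.0, intensity_dispersion=0.1)
        with pytest.raises(ValueError, match="unclassified"):
            h.measure_well([rec], plate_id="P", well="A01", role="sample")

    def test_record_order_never_changes_measurement(self):
        recs = self._records(40, 20)
        a = h.measure_well(recs, plate_id="P", well="A01", role="sample")
        b = h.measure_well(list(reversed(recs)), plate_id="P", well="A01",
                           role="sample")
        assert a == b


class TestTransfectionEfficiency:
    def test_background_red_channel_gives_zero(self, neutral_truth,
                                               imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=60,
                                     transfected_fraction=0.0)
        well = h.render_well_image(None, True, neutral_truth, params, seed=12,
                                   with_red=True)
        assert h.estimate_transfection_efficiency(well.image,
                                                  well.red_image) == 0.0

    def test_saturating_transfection_gives_one(self, neutral_truth,
                                               imaging_params):
        params = dataclasses.replace(imaging_params, nuclei_count_fixed=60,
                                     transfected_fraction=1.0)
        well = h.render_well_image(None, True, neutral_truth, params, seed=13,
                                   with_red=True)
        assert h.estimate_transfection_efficiency(well.image,
                                                  well.red_image) == 1.0

    def test_half_transfected_recovered(self, neutral_truth, imaging_params):
        ests, truths = [], []
        for s in range(6):
            well = h.render_well_image(None, True, neutral_truth,
                                       imaging_params, seed=60 + s,
                                       with_red=True)
            ests.append(h.estimate_transfection_efficiency(well.image,
                                                           well.red_image))
            truths.append(np.mean([n.transfected for n in well.nuclei]))
        assert abs(np.mean(ests) - 0.5) < 0.05
        assert abs(np.mean(ests) - np.mean(truths)) < 0.03

    def test_missing_or_misregistered_red_channel_rejected(self, neutral_truth,
                                                           imaging_params):
        well = h.render_well_image(None, True, neutral_truth, imaging_params,
                                   seed=14)
        with pytest.raises(ValueError):
            h.estimate_transfection_efficiency(well.image, None)
        with pytest.raises(ValueError, match="registered"):
            h.estimate_transfection_efficiency(well.image,
                                               np.zeros((10, 10)))
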