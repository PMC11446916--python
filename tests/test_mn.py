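"""Micronucleus detection, classification, counting, and stratification."""

import numpy as np
import pytest

from emdmn import (
    PhantomParams,
    StratificationCutoffs,
    classify_mn,
    classify_phenotype,
    detect_mn,
    generate_field,
    ne_reference,
    quantify_field,
    segment_nuclei,
    stratify,
    summarize_field,
)
from emdmn.pipeline import match_mn
from emdmn.segcore import DegenerateImageError, LabelMask


def paint_disk(img, cx, cy, r, value):
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value


class TestSegmentNuclei:
    def test_noiseless_phantom_counts(self, small_phantom):
        params, (field, truth) = small_phantom
        nuclei = segment_nuclei(field.channels["dapi"], pixel_size_um=params.pixel_size_um)
        assert nuclei.n_labels == len(truth.nuclei) == 5

    def test_blank_field_raises_degenerate(self):
        with pytest.raises(DegenerateImageError):
            segment_nuclei(np.zeros((64, 64)))

    def test_noisy_blank_field_has_zero_labels(self, rng):
        # pure noise: foreground specks are below the nucleus area gate
        noise = rng.normal(10, 2, (128, 128)).clip(0)
        assert segment_nuclei(noise, pixel_size_um=0.3).n_labels == 0

    def test_planted_count_recovered_across_seeds(self):
        hits = 0
        for seed in range(1, 21):
            params = PhantomParams(seed=seed)
            field, truth = generate_field(params)
            nuclei = segment_nuclei(
                field.channels["dapi"], pixel_size_um=params.pixel_size_um
            )
            hits += nuclei.n_labels == len(truth.nuclei)
        assert hits >= 19


class TestNeReference:
    def test_phantom_rim_recovered(self, small_phantom):
        params, (field, truth) = small_phantom
        nuclei = segment_nuclei(field.channels["dapi"], pixel_size_um=params.pixel_size_um)
        refs = ne_reference(
            field.channels["emerin"], nuclei, pixel_size_um=params.pixel_size_um
        )
        for r in refs.values():
            if not r["truncated"]:
                assert 90 <= r["mean"] <= 110

    def test_uniform_channel_gives_constant_reference(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[10:30, 10:30] = 1
        labels[40:60, 40:60] = 2
        refs = ne_reference(np.full((64, 64), 37.0), LabelMask(labels, 2))
        assert refs[1]["mean"] == pytest.approx(37.0)
        assert refs[2]["mean"] == pytest.approx(37.0)

    def test_empty_mask_empty_result(self):
        refs = ne_reference(np.ones((16, 16)), LabelMask(np.zeros((16, 16), int), 0))
        assert refs == {}

    def test_border_nucleus_flagged_truncated(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[0:12, 0:12] = 1
        refs = ne_reference(np.ones((40, 40)), LabelMask(labels, 1))
        assert refs[1]["truncated"]


class TestDetectMN:
    def test_size_gate(self):
        """0.1 um^2 rejected, 5 um^2 kept, 15 um^2 rejected at 0.3 um/px."""
        ps = 0.3
        em = np.full((200, 200), 5.0)
        nuclei = LabelMask(np.zeros((200, 200), int), 0)
        paint_disk(em, 30, 30, 1, 200.0)        # ~0.1-0.3 um^2... radius 1 px
        paint_disk(em, 100, 100, np.sqrt(5 / np.pi) / ps, 200.0)   # ~5 um^2
        paint_disk(em, 170, 170, np.sqrt(15 / np.pi) / ps, 200.0)  # ~15 um^2
        found = detect_mn(em, nuclei, pixel_size_um=ps, size_gate_um2=(0.5, 12.0))
        centroids = sorted(p.centroid_xy for p in found)
        assert len(found) == 1
        assert centroids[0] == pytest.approx((100, 100), abs=1)

    def test_particle_overlapping_nucleus_excluded(self):
        em = np.full((100, 100), 5.0)
        labels = np.zeros((100, 100), dtype=int)
        labels[40:60, 40:60] = 1
        paint_disk(em, 62, 50, 4, 200.0)   # pokes >= 1 px into the nucleus
        paint_disk(em, 20, 20, 4, 200.0)   # clear of it
        found = detect_mn(em, LabelMask(labels, 1), pixel_size_um=0.3)
        assert len(found) == 1
        assert found[0].centroid_xy == pytest.approx((20, 20), abs=1)

    def test_phantom_default_recall(self):
        recalls = []
        for seed in range(1, 11):
            params = PhantomParams(seed=seed)
            field, truth = generate_field(params)
            _, records, _ = quantify_field(field)
            recalls.append(match_mn(truth, records, params.pixel_size_um)["recall"])
        assert np.mean(recalls) >= 0.95


class TestClassifyMN:
    def test_ratio_thresholding(self, small_phantom):
        params, (field, truth) = small_phantom
        summary, records, _ = quantify_field(field)
        for r in records:
            if r.emerin_ratio_to_ne >= 1.2:
                assert r.mn_class == "rich"
            else:
                assert r.mn_class == "ne_level"

    def test_confusion_matrix_diagonal(self, small_phantom):
        params, (field, truth) = small_phantom
        _, records, _ = quantify_field(field)
        m = match_mn(truth, records, params.pixel_size_um)
        assert m["n_matched"] == len(truth.mn)
        assert m["class_accuracy"] == 1.0

    def test_conservation_of_candidates(self, default_phantom):
        params, (field, truth) = default_phantom
        nuclei = segment_nuclei(field.channels["dapi"], pixel_size_um=params.pixel_size_um)
        refs = ne_reference(field.channels["emerin"], nuclei, pixel_size_um=params.pixel_size_um)
        cands = detect_mn(field.channels["emerin"], nuclei, pixel_size_um=params.pixel_size_um)
        records, dropped = classify_mn(cands, refs, nuclei, pixel_size_um=params.pixel_size_um)
        n_rich = sum(r.mn_class == "rich" for r in records)
        n_ne = sum(r.mn_class == "ne_level" for r in records)
        assert n_rich + n_ne + dropped == len(cands)

    def test_raising_rich_ratio_never_increases_rich_count(self, default_phantom):
        params, (field, _) = default_phantom
        nuclei = segment_nuclei(field.channels["dapi"], pixel_size_um=params.pixel_size_um)
        refs = ne_reference(field.channels["emerin"], nuclei, pixel_size_um=params.pixel_size_um)
        cands = detect_mn(field.channels["emerin"], nuclei, pixel_size_um=params.pixel_size_um)
        counts = []
        for rr in (0.8, 1.0, 1.2, 1.5, 2.5):
            records, _ = classify_mn(
                cands, refs, nuclei, rich_ratio=rr, pixel_size_um=params.pixel_size_um
            )
            counts.append(sum(r.mn_class == "rich" for r in records))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_far_candidates_dropped(self):
        em = np.full((300, 300), 5.0)
        labels = np.zeros((300, 300), dtype=int)
        labels[10:40, 10:40] = 1
        paint_disk(em, 250, 250, 4, 200.0)  # ~90 um from the nucleus at 0.3 um/px
        cands = detect_mn(em, LabelMask(labels, 1), pixel_size_um=0.3)
        refs = {1: {"mean": 100.0, "ring_px": 1, "truncated": False}}
        records, dropped = classify_mn(cands, refs, LabelMask(labels, 1), pixel_size_um=0.3)
        assert records == [] and dropped == 1


class TestSummaries:
    def test_zero_mn(self):
        s = summarize_field([], 10)
        assert s.rich_per_nucleus == 0.0

    def test_ratio_value(self, small_phantom):
        params, (field, truth) = small_phantom
        summary, _, _ = quantify_field(field)
        planted_rich = sum(m.mn_class == "rich" for m in truth.mn)
        assert summary.n_rich == planted_rich
        assert summary.rich_per_nucleus == pytest.approx(planted_rich / 5)

    def test_zero_nuclei_error(self):
        with pytest.raises(ValueError, match="undefined"):
            summarize_field([], 0)


class TestStratify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.05, "<p25"),
            (0.10, "p25-median"),
            (0.1280, "median-p75"),  # boundary goes to the upper stratum
            (0.15, "median-p75"),
            (0.1861, ">=p75"),
            (0.20, ">=p75"),
        ],
    )
    def test_fixed_cutoffs(self, value, expected):
        assert stratify([value])[0] == expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            stratify([-0.1])

    def test_data_driven_quartiles(self):
        vals = np.linspace(0, 1, 101)
        strata = stratify(vals, mode="data_driven")
        counts = {s: strata.count(s) for s in set(strata)}
        assert all(20 <= c <= 30 for c in counts.values())

    def test_default_cutoff_constants(self):
        c = StratificationCutoffs()
        assert (c.p25, c.median, c.p75) == (0.07538, 0.1280, 0.1861)
        assert c.neg_cell_fraction == 0.85


class TestClassifyPhenotype:
    @pytest.mark.parametrize(
        "frac,ratio,expected",
        [
            (0.90, 0.05, "pauperized"),  # mostly Emerin-negative cells
            (0.10, 0.05, "normal"),
            (0.10, 0.19, "pauperized"),  # >= upper-quartile MN burden
            (0.10, 0.1861, "pauperized"),
            (0.85, 0.05, "normal"),      # strictly greater than 0.85 required
        ],
    )
    def test_rule(self, frac, ratio, expected):
        assert classify_phenotype(frac, ratio) == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            classify_phenotype(1.2, 0.0)


def test_noise_never_improves_concordance():
    """Mean detection recall is non-increasing along a noise ladder."""
    ladder = [0.0, 4.0, 16.0, 40.0]
    means = []
    for sd in ladder:
        recs = []
        for seed in range(10):
            params = PhantomParams(
                field_size_px=(256, 256), n_nuclei=6, n_mn_rich=2, n_mn_ne=2,
                noise_sd=sd, seed=100 + seed,
            )
            field, truth = generate_field(params)
            try:
                _, records, _ = quantify_field(field)
            except (ValueError, DegenerateImageError):
                recs.append(0.0)
                continue
            recs.append(match_mn(truth, records, params.pixel_size_um)["recall"])
        means.append(np.mean(recs))
    for a, b in zip(means, means[1:]):
        assert b <= a + 0.02  # non-increasing up to replicate noise
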