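import numpy as np
import pytest

import readernet as rn
from readernet.labels import ClassLabel, N_CLASSES
from readernet.panel_sim import (
    AnnotationRecord,
    Phase,
    Provenance,
    ReaderProfile,
    ReaderRole,
    age_adjusted_row,
    age_factor,
    arbitrate,
    class_prior,
    heterogeneous_profiles,
    sample_reader_label,
    site_adjusted_priors,
    split_by_patient,
    synth_image,
)

from oracles import two_class_arbitration_accuracy


class TestClassPrior:
    def test_default_matches_study_prevalence(self):
        np.testing.assert_allclose(class_prior(), (0.15, 0.24, 0.11, 0.40, 0.10))

    def test_sums_to_one(self):
        assert class_prior().sum() == pytest.approx(1.0)

    def test_override_returned_verbatim(self):
        np.testing.assert_allclose(class_prior([0.2] * 5), [0.2] * 5)

    @pytest.mark.parametrize(
        "bad",
        [[1, 0, 0, 0, 0.1], [0.5, 0.6, 0, 0, -0.1], [0.5, 0.5], [0.2, 0.2, 0.2, 0.2, 0.1]],
    )
    def test_invalid_prior_rejected(self, bad):
        with pytest.raises(ValueError):
            class_prior(bad)


class TestSynthImage:
    def test_seed_determinism(self):
        a = synth_image(ClassLabel.NORMAL, 64, 1)
        b = synth_image(ClassLabel.NORMAL, 64, 1)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self):
        a = synth_image(ClassLabel.NORMAL, 64, 1)
        b = synth_image(ClassLabel.NORMAL, 64, 2)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            synth_image(ClassLabel.NORMAL, 31, 0)

    def test_pixels_bounded_unit_interval(self):
        for c in ClassLabel:
            im = synth_image(c, 48, 5)
            assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0
            assert im.pixels.shape == (48, 48)

    def test_consolidation_blob_brighter_than_lung_field(self):
        im = synth_image(ClassLabel.CONSOLIDATION, 64, 7)
        assert im.blob_mask.sum() > 0
        inside = im.pixels[im.blob_mask].mean()
        rest = im.pixels[im.lung_mask & ~im.blob_mask].mean()
        assert inside > rest

    def test_uninterpretable_flatter_than_normal(self):
        n = synth_image(ClassLabel.NORMAL, 64, 3)
        u = synth_image(ClassLabel.UNINTERPRETABLE, 64, 3)
        assert u.pixels.var() < n.pixels.var()

    def test_both_has_blob_and_texture(self):
        im = synth_image(ClassLabel.BOTH, 64, 9)
        assert im.blob_mask.sum() > 0
        norm = synth_image(ClassLabel.NORMAL, 64, 9)
        lung_rest = im.lung_mask & ~im.blob_mask
        # infiltrate texture raises variance within the lung fields
        assert im.pixels[lung_rest].var() > norm.pixels[norm.lung_mask].var()

    def test_normal_has_no_blob(self):
        assert synth_image(ClassLabel.NORMAL, 64, 2).blob_mask.sum() == 0


class TestReaderBehaviour:
    def test_age_factor_monotone_and_floored(self):
        fs = [age_factor(1.0, a) for a in (0, 12, 36, 60, 240)]
        assert all(a >= b for a, b in zip(fs, fs[1:]))
        assert fs[-1] == pytest.approx(0.3)
        assert age_factor(0.0, 59) == 1.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_factor(1.0, -1)

    @pytest.mark.parametrize("age", [0.0, 7.5, 30.0, 59.0, 240.0])
    def test_age_adjusted_rows_remain_stochastic(self, age, rng):
        prof = heterogeneous_profiles(2, 2, rng)[0]
        for t in ClassLabel:
            row = age_adjusted_row(prof, t, age)
            assert row.sum() == pytest.approx(1.0, abs=1e-9)
            assert row.min() >= 0

    def test_age_adjustment_increases_diagonal(self):
        prof = heterogeneous_profiles(2, 2, 3)[0]
        young = age_adjusted_row(prof, ClassLabel.NORMAL, 2.0)
        old = age_adjusted_row(prof, ClassLabel.NORMAL, 59.0)
        assert old[ClassLabel.NORMAL] > young[ClassLabel.NORMAL]

    def test_identity_reader_always_correct(self, identity_profile, rng):
        prof = identity_profile()
        for t in ClassLabel:
            assert sample_reader_label(prof, t, 24.0, rng) == t

    def test_degenerate_row_forces_label(self, rng):
        conf = np.eye(5)
        conf[0] = [0, 0, 0, 1, 0]  # consolidation always read as normal
        prof = ReaderProfile("R", ReaderRole.INITIAL, conf, age_noise_slope=0.0)
        draws = {sample_reader_label(prof, ClassLabel.CONSOLIDATION, 10.0, rng) for _ in range(20)}
        assert draws == {ClassLabel.NORMAL}

    def test_sampled_frequencies_match_row(self, rng):
        conf = np.eye(5)
        conf[0] = [0.7, 0.1, 0.1, 0.05, 0.05]
        prof = ReaderProfile("R", ReaderRole.INITIAL, conf, age_noise_slope=0.0)
        n = 10_000
        counts = np.zeros(5)
        for _ in range(n):
            counts[sample_reader_label(prof, ClassLabel.CONSOLIDATION, 24.0, rng)] += 1
        np.testing.assert_allclose(counts / n, conf[0], atol=0.02)

    def test_invalid_confusion_rejected(self):
        bad = np.full((5, 5), 0.2)
        bad[0, 0] = 0.5  # row 0 sums to 1.3
        with pytest.raises(ValueError):
            ReaderProfile("R", ReaderRole.INITIAL, bad)


def _recs(image_id, labels):
    return [
        AnnotationRecord(image_id, f"I{k + 1:02d}", ClassLabel(lab), Phase.INITIAL)
        for k, lab in enumerate(labels)
    ]


class TestArbitrate:
    def test_concordant_reads_stand(self, identity_profile, rng):
        arbs = [identity_profile(f"A{k}", ReaderRole.ARBITRATOR) for k in range(2)]
        img = synth_image(ClassLabel.NORMAL, 32, 0)
        final, extra = arbitrate(_recs("img", [3, 3]), arbs, img, rng, qc_fraction=0.0)
        assert final.label is ClassLabel.NORMAL
        assert final.provenance is Provenance.INITIAL_CONCORDANT
        assert extra == []

    def test_qc_records_appear_at_expected_rate_and_do_not_alter(self, identity_profile, rng):
        arbs = [identity_profile(f"A{k}", ReaderRole.ARBITRATOR) for k in range(2)]
        img = synth_image(ClassLabel.NORMAL, 32, 0)
        n_qc = 0
        for _ in range(2000):
            final, extra = arbitrate(_recs("img", [3, 3]), arbs, img, rng)
            assert final.label is ClassLabel.NORMAL
            if extra:
                assert all(r.phase is Phase.QC for r in extra)
                n_qc += 1
        assert 0.10 * 2000 == pytest.approx(n_qc, abs=3 * np.sqrt(2000 * 0.1 * 0.9))

    def test_perfect_arbitrators_recover_truth(self, identity_profile, rng):
        arbs = [identity_profile(f"A{k}", ReaderRole.ARBITRATOR) for k in range(2)]
        img = synth_image(ClassLabel.CONSOLIDATION, 32, 1)
        final, extra = arbitrate(_recs("img", [0, 3]), arbs, img, rng)
        assert final.label is ClassLabel.CONSOLIDATION
        assert final.provenance is Provenance.ARBITRATOR_CONCORDANT
        assert [r.phase for r in extra] == [Phase.ARBITRATION, Phase.ARBITRATION]

    def test_requires_two_initial_and_two_arbitrators(self, identity_profile, rng):
        arbs = [identity_profile("A0", ReaderRole.ARBITRATOR)]
        img = synth_image(ClassLabel.NORMAL, 32, 0)
        with pytest.raises(ValueError):
            arbitrate(_recs("img", [0, 3]), arbs, img, rng)
        with pytest.raises(ValueError):
            arbitrate(_recs("img", [0]), arbs * 2, img, rng)

    def test_two_class_toy_matches_enumeration(self):
        """Monte-Carlo protocol accuracy vs brute-force tree enumeration."""
        p, q = 0.8, 0.9

        def two_class_profile(acc, rid, role):
            conf = np.eye(5)
            conf[0] = [acc, 0, 0, 1 - acc, 0]
            conf[3] = [1 - acc, 0, 0, acc, 0]
            return ReaderProfile(rid, role, conf, age_noise_slope=0.0)

        initial = [two_class_profile(p, f"I{k}", ReaderRole.INITIAL) for k in range(2)]
        arbs = [two_class_profile(q, f"A{k}", ReaderRole.ARBITRATOR) for k in range(2)]
        rng = np.random.default_rng(2024)
        n = 20_000
        truths = rng.choice([0, 3], size=n)
        correct = 0
        img_cache = {
            t: synth_image(ClassLabel(t), 32, 0) for t in (0, 3)
        }  # pixels irrelevant to arbitration
        for t in truths:
            recs = [
                AnnotationRecord(
                    "img", prof.reader_id,
                    sample_reader_label(prof, ClassLabel(int(t)), 24.0, rng), Phase.INITIAL,
                )
                for prof in initial
            ]
            final, _ = arbitrate(recs, arbs, img_cache[int(t)], rng, qc_fraction=0.0)
            correct += int(final.label) == int(t)
        expected = two_class_arbitration_accuracy(p, q)
        assert correct / n == pytest.approx(expected, abs=0.01)


class TestBuildPanel:
    def test_counts(self):
        data = rn.build_panel_dataset(
            n_patients=10, images_per_patient_dist={1: 1.0}, seed=0, image_size=32
        )
        assert len(data.finals) == 10
        initial = [r for r in data.annotations if r.phase is Phase.INITIAL]
        assert len(initial) == 20

    def test_noiseless_panel_recovers_truth(self, identity_profile):
        profiles = [identity_profile(f"I{k + 1:02d}") for k in range(2)] + [
            identity_profile(f"A{k + 1:02d}", ReaderRole.ARBITRATOR) for k in range(2)
        ]
        data = rn.build_panel_dataset(
            n_patients=40, images_per_patient_dist={1: 1.0}, n_initial_readers=2,
            n_arbitrators=2, profiles=profiles, seed=4, image_size=32,
        )
        for im in data.images:
            assert data.final_by_id(im.image_id).label == im.true_class

    def test_seed_determinism(self):
        a = rn.build_panel_dataset(n_patients=25, seed=9, image_size=32)
        b = rn.build_panel_dataset(n_patients=25, seed=9, image_size=32)
        assert a.manifest_frame().equals(b.manifest_frame())
        assert a.finals_frame().equals(b.finals_frame())
        assert all(
            np.array_equal(x.pixels, y.pixels) for x, y in zip(a.images, b.images)
        )

    def test_annotation_key_uniqueness(self, small_panel):
        keys = [(r.image_id, r.reader_id, r.phase) for r in small_panel.annotations]
        assert len(keys) == len(set(keys))

    def test_every_image_has_two_initial_records(self, small_panel):
        counts = {}
        for r in small_panel.annotations:
            if r.phase is Phase.INITIAL:
                counts[r.image_id] = counts.get(r.image_id, 0) + 1
        assert set(counts.values()) == {2}
        assert len(counts) == len(small_panel.images)

    def test_profile_mismatch_rejected(self, identity_profile):
        with pytest.raises(ValueError):
            rn.build_panel_dataset(
                n_patients=5, n_initial_readers=4, n_arbitrators=2,
                profiles=[identity_profile("I01")], seed=0, image_size=32,
            )

    def test_inter_reader_concordance_matches_closed_form(self):
        profiles = heterogeneous_profiles(2, 2, 5, age_noise_slope=0.0)
        data = rn.build_panel_dataset(
            n_patients=20_000, images_per_patient_dist={1: 1.0}, n_initial_readers=2,
            n_arbitrators=2, profiles=profiles, seed=6, image_size=32,
            site_prior_adjust=False, qc_fraction=0.0,
        )
        r1, r2 = profiles[0].confusion, profiles[1].confusion
        pi = class_prior()
        expected = float(sum(pi[t] * (r1[t] @ r2[t]) for t in range(N_CLASSES)))
        by_image = {}
        for r in data.annotations:
            if r.phase is Phase.INITIAL:
                by_image.setdefault(r.image_id, []).append(int(r.label))
        observed = np.mean([a == b for a, b in by_image.values()])
        assert observed == pytest.approx(expected, abs=0.01)

    def test_final_accuracy_at_least_single_reader(self):
        """Arbitrated finals beat a lone initial reader when arbitrators
        are at least as accurate (two-class toy, Monte-Carlo vs oracle)."""
        p, q = 0.75, 0.85
        expected = two_class_arbitration_accuracy(p, q)
        assert expected >= p

    def test_low_normal_sites_get_lower_normal_share(self):
        priors = site_adjusted_priors(class_prior(), ("KEN", "SAF", "ZAM"))
        assert priors["SAF"][ClassLabel.NORMAL] < priors["KEN"][ClassLabel.NORMAL]
        for pvec in priors.values():
            assert pvec.sum() == pytest.approx(1.0)


class TestSplit:
    def _images(self, n_patients, two_image_every=0):
        out = []
        for k in range(n_patients):
            pid = f"P{k}"
            out.append(synth_image(ClassLabel.NORMAL, 32, k, image_id=f"{pid}_1", patient_id=pid))
            if two_image_every and k % two_image_every == 0:
                out.append(
                    synth_image(ClassLabel.NORMAL, 32, k + 1, image_id=f"{pid}_2", patient_id=pid)
                )
        return out

    def test_twenty_percent_of_4008_patients_is_802(self):
        split = split_by_patient(self._images(4008), 0.2, 0)
        assert len(split.test_patients) == 802

    def test_partition_properties(self):
        images = self._images(50, two_image_every=5)
        split = split_by_patient(images, 0.2, 3)
        assert not (split.train_patients & split.test_patients)
        assert split.train_patients | split.test_patients == {im.patient_id for im in images}

    def test_multi_image_patients_stay_together(self):
        images = self._images(50, two_image_every=3)
        split = split_by_patient(images, 0.3, 1)
        by_patient: dict = {}
        for im in images:
            by_patient.setdefault(im.patient_id, []).append(
                im.patient_id in split.test_patients
            )
        assert all(len(set(sides)) == 1 for sides in by_patient.values())
        assert any(len(sides) == 2 for sides in by_patient.values())

    def test_determinism_and_seed_sensitivity(self):
        images = self._images(100)
        assert split_by_patient(images, 0.2, 7) == split_by_patient(images, 0.2, 7)
        assert split_by_patient(images, 0.2, 7) != split_by_patient(images, 0.2, 8)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_invalid_fraction(self, bad):
        with pytest.raises(ValueError):
            split_by_patient(self._images(10), bad, 0)

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_by_patient(self._images(1), 0.2, 0)
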