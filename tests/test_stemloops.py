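"""Stem-loop derivation: metaprofiles, M detection, arm delineation, folding."""

import numpy as np
import pytest

from duplexatlas.reference import TranscriptInterval
from duplexatlas.simulate import simulate_stemloop_study
from duplexatlas.stemloops import (
    CLUSTER_REGION,
    FLANK,
    PeakProfile,
    build_metaprofile,
    cluster_peak_profiles,
    delineate_arms,
    derive_duplex,
    detect_m_shape,
    extract_peak_profile,
    run_derivation,
)


def profile(vec, peak_id="p", tx="T", start=100):
    w = np.full(201, np.nan)
    w[: len(vec)] = vec
    return PeakProfile(peak_id, tx, start, np.asarray(w, dtype=float))


def full_profile(vec, **kw):
    assert len(vec) == 201
    return PeakProfile(kw.get("peak_id", "p"), kw.get("tx", "T"), kw.get("start", 100),
                       np.asarray(vec, dtype=float))


def gaussian_bump(center, width, height, n=201):
    x = np.arange(n)
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestMetaprofile:
    def test_identical_profiles(self):
        p = full_profile(np.full(201, 0.4))
        mean, sem = build_metaprofile([p, p, p])
        assert np.allclose(mean, 0.4) and np.allclose(sem, 0)

    def test_mean_and_sem_of_two_extremes(self):
        zero = full_profile(np.zeros(201))
        one = full_profile(np.ones(201))
        mean, sem = build_metaprofile([zero, one])
        assert np.allclose(mean, 0.5) and np.allclose(sem, 0.5)

    def test_nan_ignored_per_position(self):
        a = np.full(201, 0.2)
        b = np.full(201, 0.8)
        c = np.full(201, 0.8)
        c[50] = np.nan
        mean, _ = build_metaprofile([full_profile(a), full_profile(b), full_profile(c)])
        assert mean[50] == pytest.approx(0.5)
        assert mean[51] == pytest.approx(0.6)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_metaprofile([])


class TestMShape:
    def test_two_bumps_with_dip(self):
        x = np.arange(66)
        v = (
            0.8 * np.exp(-0.5 * ((x - 10) / 5) ** 2)
            + 0.8 * np.exp(-0.5 * ((x - 35) / 5) ** 2)
        )
        assert detect_m_shape(v)

    def test_flat_profile(self):
        assert not detect_m_shape(np.full(66, 0.5))

    def test_single_bump(self):
        x = np.arange(66)
        assert not detect_m_shape(0.9 * np.exp(-0.5 * ((x - 30) / 8) ** 2))

    def test_shallow_undulation_below_prominence(self):
        x = np.arange(66)
        v = 0.5 + 0.03 * np.sin(x / 5)
        assert not detect_m_shape(v)


class TestDelineation:
    def test_constructed_m_recovers_known_regions(self):
        # bumps over +5..+25 and +30..+46 -> arms approximately (1,25), (26,46)
        x = np.arange(101)
        down = np.zeros(101)
        down[5:26] = 0.9
        down[30:47] = 0.9
        meta = np.full(201, np.nan)
        meta[FLANK:] = np.convolve(
            np.pad(down, 2, mode="edge"), np.ones(5) / 5, mode="valid"
        )
        (p0, p1), (d0, d1) = delineate_arms(meta, pad=0)
        assert abs(p0 - 1) <= 3
        assert abs(p1 - 27) <= 3
        assert d0 == p1 + 1
        assert abs(d1 - 48) <= 3

    def test_flat_profile_rejected(self):
        meta = np.full(201, 0.5)
        with pytest.raises(ValueError):
            delineate_arms(meta)


class TestClusterProfiles:
    def _planted_groups(self, rng, n_per=40):
        profiles = []
        x = np.arange(201)
        for i in range(n_per):  # flat-low group
            v = 0.25 + 0.05 * rng.standard_normal(201)
            profiles.append(full_profile(np.clip(v, 0, 1), peak_id=f"flat{i}"))
        for i in range(n_per):  # M-shaped group
            v = (
                0.25
                + gaussian_bump(FLANK + 18, 6, 0.7)
                + gaussian_bump(FLANK + 45, 6, 0.7)
                + 0.05 * rng.standard_normal(201)
            )
            profiles.append(full_profile(np.clip(v, 0, 1), peak_id=f"m{i}"))
        return profiles

    def test_two_planted_groups_recovered(self, rng):
        profiles = self._planted_groups(rng)
        out = cluster_peak_profiles(profiles, rng=rng)
        assert out.chosen_k == 2
        m_cluster = {out.assignments[f"m{i}"] for i in range(40)}
        flat_cluster = {out.assignments[f"flat{i}"] for i in range(40)}
        assert len(m_cluster) == 1 and len(flat_cluster) == 1
        assert m_cluster != flat_cluster
        mc, fc = m_cluster.pop(), flat_cluster.pop()
        assert out.m_shaped[mc] and not out.m_shaped[fc]

    def test_identical_profiles_force_single_cluster(self):
        p = [full_profile(np.full(201, 0.4), peak_id=f"p{i}") for i in range(10)]
        out = cluster_peak_profiles(p, rng=np.random.default_rng(0))
        assert out.chosen_k == 1
        assert set(out.assignments.values()) == {0}

    def test_shifted_m_groups_separate(self, rng):
        profiles = []
        for shift_idx, shift in enumerate((0, 8, 16)):
            for i in range(30):
                v = (
                    0.2
                    + gaussian_bump(FLANK + 14 + shift, 5, 0.75)
                    + gaussian_bump(FLANK + 38 + shift, 5, 0.75)
                    + 0.04 * rng.standard_normal(201)
                )
                profiles.append(
                    full_profile(np.clip(v, 0, 1), peak_id=f"s{shift_idx}_{i}")
                )
        out = cluster_peak_profiles(profiles, rng=rng)
        assert out.chosen_k == 3
        for shift_idx in range(3):
            labels = {out.assignments[f"s{shift_idx}_{i}"] for i in range(30)}
            assert len(labels) == 1

    def test_high_nan_profiles_dropped(self, rng):
        good = [full_profile(np.full(201, 0.5), peak_id=f"g{i}") for i in range(5)]
        v = np.full(201, np.nan)
        bad = full_profile(v, peak_id="bad")
        out = cluster_peak_profiles(good + [bad], rng=rng)
        assert "bad" not in out.assignments


class TestDeriveDuplex:
    def test_planted_hairpin_recovered_with_exact_loop(self, rng):
        flank1 = "".join(rng.choice(list("AT"), size=30))
        stem = "GGCAGGCGGCAG"
        loop = "ACACAA"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = flank1 + stem + loop + "".join(comp[c] for c in reversed(stem)) + "".join(
            rng.choice(list("AT"), size=30)
        )
        peak = PeakProfile("p", "T", 25, np.full(201, np.nan))
        dd = derive_duplex(peak, (0, 20), (21, 45), seq)
        assert dd is not None
        assert dd.passes_filter
        assert dd.loop_length == len(loop)
        assert dd.proximal.start == 30 and dd.proximal.end == 42
        assert dd.distal.start == 48 and dd.distal.end == 60

    def test_short_stem_fails_filter(self, rng):
        stem = "GCGCG"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = (
            "".join(rng.choice(list("AT"), size=25))
            + stem + "ACACA" + "".join(comp[c] for c in reversed(stem))
            + "".join(rng.choice(list("AT"), size=25))
        )
        peak = PeakProfile("p", "T", 20, np.full(201, np.nan))
        dd = derive_duplex(peak, (0, 15), (16, 35), seq)
        if dd is not None:
            assert not dd.passes_filter

    def test_unstructured_sequence_gives_no_duplex(self):
        seq = "A" * 80
        peak = PeakProfile("p", "T", 20, np.full(201, np.nan))
        assert derive_duplex(peak, (0, 20), (21, 40), seq) is None

    def test_empty_region_after_clipping(self):
        peak = PeakProfile("p", "T", 5, np.full(201, np.nan))
        assert derive_duplex(peak, (-30, -10), (0, 10), "GCGCGCGC") is None


class TestRunDerivation:
    def test_small_study_end_to_end(self):
        rng = np.random.default_rng(11)
        study = simulate_stemloop_study(n_utrs=60, rng=rng)
        res = run_derivation(
            study.peaks, study.records, n_control_shuffles=3, rng=rng
        )
        passing = {d.peak_id for d in res.duplexes if d.passes_filter}
        hp = study.hairpin_peaks
        assert len(passing & hp) >= 0.8 * len(hp)
        # derived arms always start at or downstream of the peak
        for d in res.duplexes:
            peak_start = dict((p, s) for p, t, s in study.peaks)[d.peak_id]
            assert d.proximal.start >= peak_start
            assert d.distal.start >= d.proximal.end
        # the shuffled-control metaprofile shows no stem-loop signature
        ctrl_region = res.control_metaprofile[
            FLANK + CLUSTER_REGION[0] : FLANK + CLUSTER_REGION[1] + 1
        ]
        assert not detect_m_shape(ctrl_region)

    def test_zero_peaks(self):
        rng = np.random.default_rng(2)
        study = simulate_stemloop_study(n_utrs=5, rng=rng)
        res = run_derivation([], study.records, rng=rng)
        assert res.duplexes == [] and res.clustering is None

    def test_unknown_transcript_peaks_skipped(self):
        rng = np.random.default_rng(3)
        study = simulate_stemloop_study(n_utrs=5, rng=rng)
        peaks = [("pX", "MISSING", 50)] + study.peaks
        res = run_derivation(peaks, study.records, n_control_shuffles=2, rng=rng)
        assert res.counts["skipped_not_representative"] == 1
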