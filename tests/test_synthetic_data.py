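"""Generator tests: cohort, schedule, signal structure, reproducibility."""

import numpy as np
import pytest
from scipy import stats

import ethoclass as ec
from ethoclass.synthetic_data import (
    ConfigurationError, DURATION_BOUNDS_S, SimulationConfig,
    _subject_stream, default_behaviour_specs, sample_bout_schedule,
    stationary_distribution, _default_transition_matrix,
)

from _bruteforce import decompose_bruteforce


def _config(**kw):
    kw.setdefault("n_subjects", 12)
    kw.setdefault("seed", 1)
    return SimulationConfig(**kw)


class TestCohort:
    def test_cardinality_and_uniqueness(self):
        profiles = ec.generate_cohort(_config())
        assert len(profiles) == 12
        assert len({p.subject_id for p in profiles}) == 12

    def test_seeded_determinism(self):
        a = ec.generate_cohort(_config())
        b = ec.generate_cohort(_config())
        assert a == b

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError, match="leave-two-out"):
            ec.generate_cohort(_config(n_subjects=2))

    def test_diversity_guarantees(self):
        profiles = ec.generate_cohort(_config(n_subjects=4))
        assert {p.attachment for p in profiles} == {"harness", "tape"}
        assert len({p.species for p in profiles}) >= 2
        # attachment reflects species: harness iff sea lion
        for p in profiles:
            assert (p.attachment == "harness") == (p.species == "ASL")

    def test_profile_validation(self):
        with pytest.raises(ConfigurationError):
            ec.SubjectProfile("X", "ASL", "female", 5, mass=10.0, attachment="harness")
        with pytest.raises(ConfigurationError):
            ec.SubjectProfile("X", "walrus", "female", 5, mass=50.0, attachment="tape")


class TestBehaviourSpecs:
    def test_ethogram_is_complete(self):
        specs = default_behaviour_specs()
        assert len(specs) == 26
        assert {s.behaviour_name for s in specs} == set(ec.BEHAVIOUR_TO_CATEGORY)

    def test_gravity_vectors_are_unit(self):
        for spec in default_behaviour_specs():
            assert np.linalg.norm(spec.gravity) == pytest.approx(1.0)

    def test_resting_specs_are_near_static(self):
        for spec in default_behaviour_specs():
            if spec.category == "resting":
                assert all(o.amplitude < spec.noise_sd for o in spec.oscillators)

    def test_session_must_cover_maximal_bout(self):
        with pytest.raises(ConfigurationError):
            _config(session_length=100.0)


class TestSchedule:
    def test_durations_within_bounds(self):
        rng = np.random.default_rng(3)
        sched = sample_bout_schedule(default_behaviour_specs(), _config(),
                                     rng, n_bouts=2000)
        rate = 25.0
        lo, hi = DURATION_BOUNDS_S
        for spec, m in sched:
            assert round(lo * rate) <= m <= round(hi * rate)

    def test_category_frequencies_match_stationary_law(self):
        """Bout-category frequencies over 1e5 schedule draws agree with the
        transition matrix's stationary distribution (chi-square GOF not
        rejected at alpha = 0.01)."""
        specs = default_behaviour_specs()
        config = _config()
        rng = np.random.default_rng(11)
        sched = sample_bout_schedule(specs, config, rng, n_bouts=100_000)
        categories = [c for c in ec.CATEGORIES
                      if any(sp.category == c for sp in specs)]
        tm = _default_transition_matrix(categories)
        stat = stationary_distribution(tm)
        counts = np.array([sum(1 for sp, _ in sched if sp.category == c)
                           for c in categories])
        res = stats.chisquare(counts, f_exp=stat * counts.sum())
        assert res.pvalue > 0.01

    def test_bad_transition_matrix_rejected(self):
        tm = np.full((5, 5), 0.1)   # rows sum to 0.5
        with pytest.raises(ConfigurationError, match="sum to 1"):
            ec.simulate_session(ec.generate_cohort(_config())[0],
                                default_behaviour_specs(),
                                _config(transition_matrix=tm))

    def test_empty_specs_rejected(self):
        with pytest.raises(ConfigurationError, match="non-empty"):
            ec.simulate_session(ec.generate_cohort(_config())[0], [], _config())


class TestSession:
    def test_length_arithmetic(self):
        profile = ec.generate_cohort(_config())[0]
        trace, labels = ec.simulate_session(profile, default_behaviour_specs(),
                                            _config(session_length=240.0))
        assert len(trace) == 240 * 25
        assert len(labels) == len(trace)

    def test_every_sample_labelled_and_mapped(self):
        profile = ec.generate_cohort(_config())[0]
        trace, labels = ec.simulate_session(profile, default_behaviour_specs(),
                                            _config(session_length=240.0))
        assert not labels["behaviour"].isna().any()
        mapped = labels["behaviour"].map(ec.BEHAVIOUR_TO_CATEGORY)
        assert (mapped == labels["category"]).all()

    def test_bit_identical_reproducibility(self):
        profile = ec.generate_cohort(_config())[0]
        specs = default_behaviour_specs()
        t1, l1 = ec.simulate_session(profile, specs, _config(session_length=240.0))
        t2, l2 = ec.simulate_session(profile, specs, _config(session_length=240.0))
        np.testing.assert_array_equal(t1.xyz, t2.xyz)
        assert (l1["behaviour"] == l2["behaviour"]).all()

    def test_clipped_to_logger_range(self):
        profile = ec.generate_cohort(_config())[0]
        trace, _ = ec.simulate_session(profile, default_behaviour_specs(),
                                       _config(session_length=240.0))
        assert np.abs(trace.xyz).max() <= 8.0

    def test_static_only_signal(self):
        """A spec with no oscillators and zero noise gives a pure 1 g
        gravity signal: dynamic component identically 0."""
        spec = ec.BehaviourSpec("Still", 0.0, 0.0, (), 0.0,
                                (np.log(60), 0.1), "surface")
        profile = ec.generate_cohort(_config())[0]
        trace, labels = ec.simulate_session(profile, [spec],
                                            _config(transition_matrix=np.array([[1.0]]),
                                                    session_length=240.0))
        q = np.sqrt((trace.xyz ** 2).sum(axis=1))
        np.testing.assert_allclose(q, 1.0, atol=1e-12)
        assert (labels["behaviour"] == "Still").all()

    def test_gravity_recovery_from_running_mean(self):
        """A 3 s running mean over a constant-orientation bout recovers the
        gravity vector within 3 * noise_sd / sqrt(75) per axis."""
        spec = ec.BehaviourSpec("Sitting", 0.9, 0.0, (), 0.03,
                                (np.log(120), 0.1), "land")
        profile = ec.generate_cohort(_config())[0]
        config = _config(transition_matrix=np.array([[1.0]]), session_length=240.0)
        trace, _ = ec.simulate_session(profile, [spec], config)
        dec = ec.decompose(trace)
        interior = slice(75, len(trace) - 75)
        tol = 3 * spec.noise_sd / np.sqrt(75)
        err = np.abs(dec.static[interior] - spec.gravity[None, :])
        assert np.quantile(err, 0.99) < tol

    def test_separability_scales_class_contrast_not_schedule(self):
        """Lowering separability keeps the bout schedule bit-identical and
        shrinks the between-class mean-ODBA gap (ODBA recomputed by brute
        force, independent of the package decomposition)."""
        profile = ec.generate_cohort(_config())[0]
        specs = default_behaviour_specs()
        hi_t, hi_l = ec.simulate_session(profile, specs,
                                         _config(session_length=240.0, separability=1.0))
        lo_t, lo_l = ec.simulate_session(profile, specs,
                                         _config(session_length=240.0, separability=0.1))
        assert (hi_l["behaviour"] == lo_l["behaviour"]).all()

        def class_gap(trace, labels):
            odba = np.array(decompose_bruteforce(trace.xyz.tolist(), 25.0)["odba"])
            cats = labels["category"].to_numpy()
            means = {}
            for c in ("resting", "travelling"):
                sel = cats == c
                if sel.any():
                    means[c] = odba[sel].mean()
            return means.get("travelling", 0) - means.get("resting", 0)

        assert class_gap(hi_t, hi_l) > 2 * class_gap(lo_t, lo_l)

    def test_mass_scaling_shifts_dominant_frequency(self):
        """Heavier subjects oscillate slower: (mass/60)^(-1/3) frequency
        scaling is visible in the lag-1 autocorrelation of a pure bout."""
        spec = ec.BehaviourSpec("Swimming", 0.0, 0.0,
                                (ec.Oscillator(0, 0.5, 2.0, 0.0),), 0.0,
                                (np.log(120), 0.1), "underwater")
        config = _config(transition_matrix=np.array([[1.0]]), session_length=240.0)
        light = ec.SubjectProfile("L", "SFS", "male", 4, 28.0, "tape")
        heavy = ec.SubjectProfile("H", "AFS", "male", 16, 226.8, "tape")
        ar1 = {}
        for p in (light, heavy):
            trace, _ = ec.simulate_session(p, [spec], config)
            x = trace.xyz[:, 0]
            ar1[p.subject_id] = np.corrcoef(x[:-1], x[1:])[0, 1]
        # slower oscillation (heavy) -> higher lag-1 autocorrelation
        assert ar1["H"] > ar1["L"]

    def test_subject_streams_are_independent(self):
        a = _subject_stream(1, "S01", 1).uniform(size=4)
        b = _subject_stream(1, "S02", 1).uniform(size=4)
        assert not np.allclose(a, b)


class TestWriters:
    def test_cohort_csv_roundtrip(self, tmp_path):
        profiles = ec.generate_cohort(_config())
        path = tmp_path / "cohort.csv"
        ec.synthetic_data.write_cohort_csv(profiles, path)
        back = ec.synthetic_data.read_cohort_csv(path)
        assert back == profiles
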