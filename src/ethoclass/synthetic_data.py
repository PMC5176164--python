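"""Synthetic multi-subject accelerometer sessions with behaviour labels.

Emulates captive fur-seal / sea-lion deployments: a back-mounted tri-axial
logger sampling at 25 Hz with a +-8 g range, while the animal moves through
bouts of 26 behaviours grouped into five categories (foraging, grooming,
resting, travelling, other).

Each behaviour has a signature: a unit gravity vector set by body pitch and
roll, a sum of sinusoidal oscillators (axis, amplitude, frequency,
phase-jitter) for the dynamic component, and white Gaussian sensor/muscle
noise. Bouts follow a semi-Markov schedule: the category comes from a
row-stochastic transition matrix, the behaviour is drawn uniformly within
the category, and the bout duration is log-normal, truncated to
[0.25 s, 210 s] — the span from a single body shake to a long continuous
swim.

Two knobs shape the learning problem:

* ``separability`` in (0, 1] pulls every behaviour's dynamic signal power
  toward the grand mean (rescaling oscillator amplitudes and noise
  together), collapsing between-class contrast at low values without
  touching the bout schedule (schedule and signal use independent seeded
  streams).
* subject mass scales oscillator frequency by ``(mass / 60 kg)^(-1/3)``
  (larger animals move with slower limb beats), which is what makes the
  subject covariates genuinely informative to a classifier.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import BEHAVIOUR_TO_CATEGORY, CATEGORIES, category_of
from .signal_features import AccelerometerTrace

DURATION_BOUNDS_S = (0.25, 210.0)
SPECIES = ("AFS", "NZFS", "SFS", "ASL")
FUR_SEAL_SPECIES = ("AFS", "NZFS", "SFS")
REFERENCE_MASS_KG = 60.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectProfile:
    """Per-animal metadata; drives both simulation and model covariates."""

    subject_id: str
    species: str          # AFS / NZFS / SFS (fur seals) or ASL (sea lion)
    sex: str              # male / female
    age: int              # years
    mass: float           # kg
    attachment: str       # harness (sea lions) or tape (fur seals)

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ConfigurationError(f"unknown species {self.species!r}")
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.age < 0:
            raise ConfigurationError("age must be >= 0")
        if not 20.0 <= self.mass <= 250.0:
            raise ConfigurationError("mass outside the plausible otariid range [20, 250] kg")
        if self.attachment not in ("harness", "tape"):
            raise ConfigurationError(f"unknown attachment {self.attachment!r}")


@dataclass(frozen=True)
class Oscillator:
    axis: int             # 0=x (surge), 1=y (sway), 2=z (heave)
    amplitude: float      # g
    frequency: float      # Hz
    phase_jitter_sd: float = 0.0   # radians per sample (random-walk phase)


@dataclass(frozen=True)
class BehaviourSpec:
    """Signal signature of one behaviour."""

    behaviour_name: str
    pitch: float                   # radians, body pitch setting the gravity vector
    roll: float
    oscillators: tuple[Oscillator, ...]
    noise_sd: float                # g
    duration_lognorm: tuple[float, float]   # (mu, sigma) of log seconds
    place: str                     # surface / underwater / land
    #: optional per-species multiplier on oscillator frequency, modelling
    #: species-specific movement styles (e.g. fur seals and sea lions use
    #: different gaits and prey-processing tactics)
    species_frequency_scale: dict | None = None
    #: sd of a log-normal per-bout multiplier on all oscillator frequencies
    #: (one draw per bout, harmonic structure preserved): no two swimming
    #: bouts share exactly the same beat
    bout_frequency_jitter_sd: float = 0.0
    #: per-sample log-frequency random-walk step: the beat wanders
    #: continuously within a bout (an irregular gait) instead of holding
    #: one tone
    freq_drift_sd: float = 0.0
    #: behaviours whose tempo is set by the task rather than the body
    #: (e.g. processing a prey item) do not follow the allometric
    #: mass-frequency scaling
    mass_scaling_exempt: bool = False

    @property
    def category(self) -> str:
        return category_of(self.behaviour_name)

    @property
    def gravity(self) -> np.ndarray:
        """Unit gravity vector implied by pitch and roll (|g| = 1)."""
        p, r = self.pitch, self.roll
        return np.array([np.sin(p), -np.sin(r) * np.cos(p), np.cos(r) * np.cos(p)])


@dataclass
class SimulationConfig:
    n_subjects: int = 12
    sampling_rate: float = 25.0
    session_length: float = 400.0          # seconds per subject-session
    transition_matrix: np.ndarray | None = None   # over categories present in specs
    seed: int = 0
    separability: float = 1.0              # (0, 1]; 1 = full between-class contrast
    mass_frequency_scaling: bool = True

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.session_length < DURATION_BOUNDS_S[1]:
            raise ConfigurationError(
                f"session_length must cover one maximal bout ({DURATION_BOUNDS_S[1]} s)"
            )
        if not 0 < self.separability <= 1:
            raise ConfigurationError("separability must be in (0, 1]")


# ---------------------------------------------------------------------------
# default behaviour signatures
# ---------------------------------------------------------------------------

def _osc(axis: int, amp: float, freq: float, jit: float = 0.05) -> Oscillator:
    return Oscillator(axis=axis, amplitude=amp, frequency=freq, phase_jitter_sd=jit)


def default_behaviour_specs() -> list[BehaviourSpec]:
    """Signatures for the 26-behaviour ethogram.

    Amplitudes, frequencies and orientations are free model choices (no
    published per-behaviour signal parameters exist); they are set so that
    the class structure the analysis assumes emerges: resting is
    near-static, grooming is mid-amplitude and fast, travelling and foraging
    are high-amplitude and share overlapping frequency bands, so per-class
    mean ODBA orders resting < grooming < travelling ~= foraging.
    """
    s: list[BehaviourSpec] = []
    # --- travelling: rhythmic locomotion, 1.0-2.2 Hz band
    s += [
        BehaviourSpec("Walking", 0.1, 0.0,
                      (_osc(0, 0.35, 1.2), _osc(2, 0.45, 1.2), _osc(1, 0.15, 2.4)),
                      0.06, (np.log(20), 0.6), "land"),
        BehaviourSpec("Surface swimming", 0.0, 0.0,
                      (_osc(0, 0.45, 1.4), _osc(1, 0.55, 1.4), _osc(2, 0.25, 2.8)),
                      0.07, (np.log(35), 0.7), "surface"),
        BehaviourSpec("Swimming", -0.15, 0.0,
                      (_osc(0, 0.50, 1.6), _osc(1, 0.60, 1.6), _osc(2, 0.30, 1.6)),
                      0.07, (np.log(40), 0.7), "underwater"),
        BehaviourSpec("Fast", -0.2, 0.0,
                      (_osc(0, 0.80, 2.2), _osc(1, 0.90, 2.2), _osc(2, 0.45, 2.2)),
                      0.09, (np.log(8), 0.5), "underwater"),
        BehaviourSpec("Porpoising", 0.3, 0.0,
                      (_osc(0, 0.85, 1.8), _osc(2, 0.95, 1.8), _osc(1, 0.40, 3.6)),
                      0.10, (np.log(6), 0.4), "surface"),
    ]
    # --- foraging: overlapping frequency band with travelling, head-dominated
    #     axes mix and an extra fast strike component
    s += [
        BehaviourSpec("Chewing", 0.5, 0.0,
                      (_osc(0, 0.55, 1.5), _osc(2, 0.65, 3.0), _osc(1, 0.20, 1.5)),
                      0.08, (np.log(10), 0.6), "surface"),
        BehaviourSpec("Searching", -0.4, 0.0,
                      (_osc(0, 0.45, 1.3), _osc(2, 0.70, 2.6), _osc(1, 0.30, 1.3)),
                      0.08, (np.log(25), 0.6), "underwater"),
        BehaviourSpec("Thrash", 0.2, 0.3,
                      (_osc(0, 0.95, 1.9), _osc(1, 0.60, 3.8), _osc(2, 0.85, 1.9)),
                      0.12, (np.log(4), 0.5), "surface"),
        BehaviourSpec("Manipulation", 0.4, 0.1,
                      (_osc(0, 0.60, 1.7), _osc(2, 0.80, 3.4), _osc(1, 0.35, 1.7)),
                      0.10, (np.log(15), 0.6), "surface"),
        BehaviourSpec("Hold and tear", 0.45, 0.2,
                      (_osc(0, 0.75, 1.4), _osc(2, 0.90, 2.8), _osc(1, 0.40, 1.4)),
                      0.11, (np.log(12), 0.5), "surface"),
    ]
    # --- resting: near-static, amplitudes below the noise floor
    s += [
        BehaviourSpec("Lying", 0.0, np.pi / 2,
                      (_osc(0, 0.01, 0.3, 0.0),), 0.02, (np.log(90), 0.7), "land"),
        BehaviourSpec("Sitting", 0.9, 0.0,
                      (_osc(2, 0.01, 0.4, 0.0),), 0.02, (np.log(60), 0.7), "land"),
        BehaviourSpec("Still", 0.0, 0.0,
                      (_osc(1, 0.01, 0.2, 0.0),), 0.02, (np.log(45), 0.7), "surface"),
    ]
    # --- grooming: mid-amplitude, fast scratch/rub band 3-5 Hz
    s += [
        BehaviourSpec("Scratch", 0.2, 0.5,
                      (_osc(1, 0.30, 4.5), _osc(2, 0.20, 4.5)),
                      0.05, (np.log(5), 0.5), "land"),
        BehaviourSpec("Rubbing", 0.1, 0.6,
                      (_osc(0, 0.25, 3.2), _osc(1, 0.28, 3.2)),
                      0.05, (np.log(6), 0.5), "surface"),
        BehaviourSpec("Sailing", 0.0, np.pi / 2.5,
                      (_osc(1, 0.12, 0.8), _osc(2, 0.10, 0.8)),
                      0.04, (np.log(30), 0.6), "surface"),
        BehaviourSpec("Jugging", 0.6, 0.0,
                      (_osc(2, 0.15, 0.9), _osc(0, 0.10, 0.9)),
                      0.04, (np.log(25), 0.6), "surface"),
        BehaviourSpec("Face rub", 0.4, 0.3,
                      (_osc(0, 0.28, 3.8), _osc(2, 0.22, 3.8)),
                      0.05, (np.log(4), 0.4), "surface"),
        BehaviourSpec("Shake", 0.1, 0.0,
                      (_osc(1, 0.55, 5.0), _osc(0, 0.35, 5.0)),
                      0.08, (np.log(0.8), 0.4), "surface"),
        BehaviourSpec("Rolling", 0.0, 0.8,
                      (_osc(1, 0.35, 1.0), _osc(2, 0.30, 1.0), _osc(0, 0.15, 2.0)),
                      0.06, (np.log(8), 0.5), "surface"),
    ]
    # --- other: husbandry / out of sight; generated but excluded downstream
    s += [
        BehaviourSpec("Hand feeding", 0.5, 0.0,
                      (_osc(0, 0.40, 1.1), _osc(2, 0.30, 2.2)),
                      0.08, (np.log(10), 0.5), "surface"),
        BehaviourSpec("Out of sight", 0.0, 0.0,
                      (_osc(0, 0.20, 1.0), _osc(1, 0.20, 1.5)),
                      0.10, (np.log(20), 0.8), "surface"),
        BehaviourSpec("Pool transit", 0.2, 0.0,
                      (_osc(0, 0.30, 1.3), _osc(2, 0.35, 1.3)),
                      0.07, (np.log(8), 0.5), "land"),
        BehaviourSpec("Station", 0.7, 0.0,
                      (_osc(2, 0.05, 0.5),), 0.03, (np.log(15), 0.5), "land"),
        BehaviourSpec("Playing", 0.0, 0.2,
                      (_osc(0, 0.60, 2.5), _osc(1, 0.50, 3.0), _osc(2, 0.40, 2.0)),
                      0.10, (np.log(12), 0.6), "underwater"),
        BehaviourSpec("Haul out", 0.3, 0.1,
                      (_osc(0, 0.45, 1.0), _osc(2, 0.50, 1.0)),
                      0.08, (np.log(5), 0.4), "land"),
    ]
    assert len(s) == len(BEHAVIOUR_TO_CATEGORY)
    return s


def overlapping_travel_forage_specs() -> list[BehaviourSpec]:
    """Variant ethogram in which travelling signatures overlap foraging's.

    Each travelling behaviour shares a foraging behaviour's signature
    centre (orientation, place, noise, axes mix, amplitudes, frequency),
    but travelling bouts carry a broad per-bout frequency jitter while
    foraging bouts stay tightly on-band: travelling is the noisy, variable
    gait, foraging the distinctive burst. Wherever a travelling bout lands
    on the shared band, concentrated foraging examples dominate it, so
    classifiers absorb travelling into foraging — making travelling the
    hardest category, the confusion structure reported for real seals —
    while travelling's off-band tails stay recognisable. Pair this
    ethogram with ``feeding_session_transition_matrix()`` so foraging
    examples are plentiful enough to dominate the shared band."""
    base = {sp.behaviour_name: sp for sp in default_behaviour_specs()}
    donors = {
        "Walking": "Chewing",
        "Surface swimming": "Manipulation",
        "Swimming": "Searching",
        "Fast": "Thrash",
        "Porpoising": "Hold and tear",
    }
    specs = []
    for name, spec in base.items():
        if name in donors:
            donor = base[donors[name]]
            # travelling: same signature centre as its foraging donor, but
            # a noisy wandering gait (wide per-bout jitter + within-bout
            # drift) sweeping across the whole shared band
            specs.append(dataclasses.replace(
                spec, pitch=donor.pitch, roll=donor.roll,
                oscillators=donor.oscillators, noise_sd=donor.noise_sd,
                place=donor.place, bout_frequency_jitter_sd=0.40,
                mass_scaling_exempt=True))
        elif spec.category == "foraging":
            # foraging: many short, tightly on-band capture/manipulation
            # bursts, so every animal's band is densely sampled in training;
            # the tempo is prey-determined, hence mass-exempt like the
            # travelling mimics above
            specs.append(dataclasses.replace(
                spec, duration_lognorm=(np.log(5.0), 0.5),
                bout_frequency_jitter_sd=0.22, mass_scaling_exempt=True))
        else:
            specs.append(spec)
    return specs


def feeding_session_transition_matrix() -> np.ndarray:
    """Transition matrix for feeding-trial sessions: most bouts are short
    prey captures and manipulations, with little sustained travelling.
    Because the schedule is semi-Markov, the bout-level weights are set so
    that the duration-weighted epoch shares of foraging and travelling
    come out roughly equal. Used by the travelling/foraging overlap
    experiment."""
    weights = {"foraging": 0.55, "grooming": 0.10, "resting": 0.15,
               "travelling": 0.10, "other": 0.10}
    w = np.array([weights[c] for c in CATEGORIES])
    w = w / w.sum()
    return np.tile(w, (len(CATEGORIES), 1))


def mass_confounded_specs() -> list[BehaviourSpec]:
    """Variant ethogram for the mass-scaled covariate experiment.

    Travelling and foraging share orientation, place, axes mix, amplitudes
    and noise, and differ only in oscillator frequency. Within any one
    animal, foraging beats 2.6x faster than travelling; fur seals, whose
    gait and prey processing differ from sea lions', run every beat 2.6x
    slower (species_frequency_scale). Because the species slowdown equals
    the within-animal foraging/travelling ratio, a fur seal's foraging
    band coincides with a sea lion's travelling band. On top sit the
    continuous mass scaling (mass/60)^(-1/3) and a per-bout log-normal
    frequency jitter, which smear every band into a continuum. An observed
    beat is therefore ambiguous between the two categories without the
    subject covariates, while with them the rule "faster beat means
    foraging, with a species-specific threshold" becomes expressible by
    every model family, linear ones included. Resting and grooming keep
    their default signatures.
    """
    # fur-seal slowdown == within-animal foraging/travelling band ratio
    style = {"AFS": 1 / 2.6, "NZFS": 1 / 2.6, "SFS": 1 / 2.6}
    travel_freq = {"Walking": 1.20, "Surface swimming": 1.28,
                   "Swimming": 1.36, "Fast": 1.52, "Porpoising": 1.44}
    forage_freq = {"Chewing": 3.12, "Searching": 3.54, "Thrash": 3.95,
                   "Manipulation": 3.74, "Hold and tear": 3.33}
    specs = []
    for spec in default_behaviour_specs():
        if spec.behaviour_name in travel_freq:
            f = travel_freq[spec.behaviour_name]
        elif spec.behaviour_name in forage_freq:
            f = forage_freq[spec.behaviour_name]
        else:
            specs.append(spec)
            continue
        # harmonic at 1.3x keeps the fastest foraging beat clear of the
        # 12.5 Hz Nyquist limit even for the lightest animal
        osc = (_osc(0, 0.50, f, 0.02), _osc(1, 0.55, f, 0.02),
               _osc(2, 0.30, 1.3 * f, 0.02))
        specs.append(dataclasses.replace(
            spec, pitch=0.0, roll=0.0, oscillators=osc,
            noise_sd=0.08, place="underwater",
            species_frequency_scale=style,
            bout_frequency_jitter_sd=0.12))
    return specs


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: (low, high) mass ranges in kg per (species, sex), loosely following the
#: published captive cohort (sea-lion males and adult fur-seal males heavy,
#: subantarctic fur seals small)
_MASS_RANGES = {
    ("ASL", "female"): (44.0, 74.0),
    ("ASL", "male"): (108.0, 162.0),
    ("AFS", "female"): (69.0, 79.0),
    ("AFS", "male"): (175.0, 242.0),
    ("NZFS", "female"): (40.0, 60.0),
    ("NZFS", "male"): (47.0, 154.0),
    ("SFS", "female"): (25.0, 35.0),
    ("SFS", "male"): (28.0, 30.0),
}


def _subject_stream(seed: int, subject_id: str, salt: int) -> np.random.Generator:
    """Independent seeded stream per (seed, subject, purpose)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode()), salt])


def generate_cohort(config: SimulationConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    The first four subjects cycle through ASL-female, AFS-male, NZFS-male,
    SFS-male so that any cohort of >= 4 contains both attachment methods,
    >= 2 species, and the female-sea-lion / male-fur-seal pair the default
    held-out split looks for; remaining subjects are drawn at random.
    Deterministic given ``config.seed``.
    """
    if config.n_subjects < 3:
        raise ConfigurationError(
            "need at least 3 subjects: leave-two-out evaluation requires "
            "two held-out animals plus at least one training animal"
        )
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xC047])
    anchors = [("ASL", "female"), ("AFS", "male"), ("NZFS", "male"), ("SFS", "male")]
    # species mix of the captive study population: half sea lions, the
    # rest mostly New Zealand and Australian fur seals
    species_p = {"ASL": 0.50, "NZFS": 0.25, "AFS": 0.17, "SFS": 0.08}
    profiles = []
    for i in range(config.n_subjects):
        if i < len(anchors):
            species, sex = anchors[i]
        else:
            species = rng.choice(SPECIES, p=[species_p[s] for s in SPECIES])
            sex = ("male", "female")[rng.integers(2)]
        lo, hi = _MASS_RANGES[(species, sex)]
        mass = float(np.round(rng.uniform(lo, hi), 1))
        age = int(rng.integers(4, 18))
        attachment = "harness" if species == "ASL" else "tape"
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}", species=species, sex=sex,
            age=age, mass=mass, attachment=attachment,
        ))
    return profiles


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _default_transition_matrix(categories: list[str]) -> np.ndarray:
    """i.i.d. category draws weighted toward travelling, mirroring the real
    ethogram's bout counts (travelling ~40% of analysed bouts)."""
    weights = {"travelling": 0.34, "foraging": 0.24, "resting": 0.14,
               "grooming": 0.14, "other": 0.14}
    w = np.array([weights.get(c, 0.1) for c in categories])
    w = w / w.sum()
    return np.tile(w, (len(categories), 1))


def _dynamic_power(spec: BehaviourSpec) -> float:
    """Expected dynamic signal power: sinusoid power a^2/2 per oscillator
    plus noise variance on all three axes."""
    return (sum(o.amplitude ** 2 / 2.0 for o in spec.oscillators)
            + 3.0 * spec.noise_sd ** 2)


def _power_scales(specs: list[BehaviourSpec], separability: float) -> dict[str, float]:
    """Per-spec scale factor on amplitudes and noise so that each spec's
    dynamic power moves from its own value (separability = 1) toward the
    grand mean power (separability -> 0), collapsing between-class
    amplitude contrast."""
    powers = {sp.behaviour_name: _dynamic_power(sp) for sp in specs}
    mean_p = float(np.mean(list(powers.values())))
    scales = {}
    for name, p in powers.items():
        target = mean_p + separability * (p - mean_p)
        scales[name] = float(np.sqrt(target / p)) if p > 0 else 1.0
    return scales


def _resolve_transition(specs: list[BehaviourSpec], config: SimulationConfig):
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    categories = [c for c in CATEGORIES if any(sp.category == c for sp in specs)]
    tm = config.transition_matrix
    if tm is None:
        tm = _default_transition_matrix(categories)
    tm = np.asarray(tm, dtype=float)
    if tm.shape != (len(categories), len(categories)):
        raise ConfigurationError(
            f"transition matrix shape {tm.shape} does not match the "
            f"{len(categories)} categories present in specs: {categories}"
        )
    if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigurationError("transition matrix rows must sum to 1")
    return categories, tm


def stationary_distribution(tm: np.ndarray) -> np.ndarray:
    """Stationary law of a row-stochastic matrix (left eigenvector at 1)."""
    evals, evecs = np.linalg.eig(np.asarray(tm, dtype=float).T)
    stat = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    return np.abs(stat) / np.abs(stat).sum()


def sample_bout_schedule(
    specs: list[BehaviourSpec],
    config: SimulationConfig,
    rng: np.random.Generator,
    n_samples: int | None = None,
    n_bouts: int | None = None,
) -> list[tuple[BehaviourSpec, int]]:
    """Draw the semi-Markov bout sequence: category from the transition
    matrix (initialised at its stationary law), behaviour uniform within
    the category, duration log-normal truncated to the bout bounds.

    Returns (spec, bout length in samples) pairs; with ``n_samples`` the
    last bout is cut at the session end, with ``n_bouts`` exactly that many
    bouts are drawn untruncated.
    """
    if (n_samples is None) == (n_bouts is None):
        raise ValueError("give exactly one of n_samples / n_bouts")
    categories, tm = _resolve_transition(specs, config)
    by_cat = {c: [sp for sp in specs if sp.category == c] for c in categories}
    rate = config.sampling_rate
    stat = stationary_distribution(tm)

    schedule: list[tuple[BehaviourSpec, int]] = []
    pos = 0
    cat_idx = rng.choice(len(categories), p=stat)
    while True:
        if n_bouts is not None and len(schedule) >= n_bouts:
            break
        if n_samples is not None and pos >= n_samples:
            break
        cat = categories[cat_idx]
        spec = by_cat[cat][rng.integers(len(by_cat[cat]))]
        mu, sigma = spec.duration_lognorm
        dur = float(np.clip(rng.lognormal(mu, sigma), *DURATION_BOUNDS_S))
        m = max(int(round(dur * rate)), 1)
        if n_samples is not None:
            m = min(m, n_samples - pos)
        schedule.append((spec, m))
        pos += m
        cat_idx = rng.choice(len(categories), p=tm[cat_idx])
    return schedule


def simulate_session(
    profile: SubjectProfile,
    specs: list[BehaviourSpec],
    config: SimulationConfig,
) -> tuple[AccelerometerTrace, pd.DataFrame]:
    """Simulate one subject-session.

    Returns the trace and a per-sample label frame with columns
    ``behaviour``, ``category``, ``place`` of the same length. Bit-identical
    for identical (profile, specs, config). The bout schedule and the signal
    noise use independent random streams, so ``separability`` (which only
    rescales signal power) changes the signal but never the schedule.
    """
    n = int(round(config.session_length * config.sampling_rate))
    rate = config.sampling_rate

    rng_sched = _subject_stream(config.seed, profile.subject_id, 1)
    rng_sig = _subject_stream(config.seed, profile.subject_id, 2)
    schedule = sample_bout_schedule(specs, config, rng_sched, n_samples=n)

    scales = _power_scales(specs, config.separability)
    freq_scale = (
        (profile.mass / REFERENCE_MASS_KG) ** (-1.0 / 3.0)
        if config.mass_frequency_scaling else 1.0
    )

    xyz = np.empty((n, 3))
    behaviour = np.empty(n, dtype=object)
    place = np.empty(n, dtype=object)

    pos = 0
    for spec, m in schedule:
        f_scale = 1.0 if spec.mass_scaling_exempt else freq_scale
        if spec.species_frequency_scale is not None:
            f_scale *= spec.species_frequency_scale.get(profile.species, 1.0)
        if spec.bout_frequency_jitter_sd > 0:
            f_scale *= float(np.exp(rng_sig.normal(0, spec.bout_frequency_jitter_sd)))
        _render_bout(xyz[pos:pos + m], spec, rng_sig, rate,
                     scales[spec.behaviour_name], f_scale)
        behaviour[pos:pos + m] = spec.behaviour_name
        place[pos:pos + m] = spec.place
        pos += m

    np.clip(xyz, -8.0, 8.0, out=xyz)
    trace = AccelerometerTrace(xyz=xyz, sampling_rate=rate, place=place,
                               subject_id=profile.subject_id)
    labels = pd.DataFrame({
        "behaviour": behaviour,
        "category": [category_of(b) for b in behaviour],
        "place": place,
    })
    return trace, labels


def _render_bout(
    out: np.ndarray,
    spec: BehaviourSpec,
    rng: np.random.Generator,
    rate: float,
    power_scale: float,
    freq_scale: float,
) -> None:
    m = len(out)
    out[:] = spec.gravity[None, :]
    t = np.arange(m) / rate
    drift = None
    if spec.freq_drift_sd > 0:
        drift = np.exp(np.cumsum(rng.normal(0, spec.freq_drift_sd, m)))
    for osc in spec.oscillators:
        phase0 = rng.uniform(0, 2 * np.pi)
        f = osc.frequency * freq_scale
        if drift is not None:
            phase = 2 * np.pi * np.cumsum(f * drift) / rate + phase0
        else:
            phase = 2 * np.pi * f * t + phase0
        if osc.phase_jitter_sd > 0:
            phase = phase + np.cumsum(rng.normal(0, osc.phase_jitter_sd, m))
        out[:, osc.axis] += power_scale * osc.amplitude * np.sin(phase)
    if spec.noise_sd > 0:
        out += rng.normal(0, power_scale * spec.noise_sd, (m, 3))


# ---------------------------------------------------------------------------
# cohort-level convenience + file output
# ---------------------------------------------------------------------------

def simulate_cohort_sessions(
    config: SimulationConfig,
    specs: list[BehaviourSpec] | None = None,
    profiles: list[SubjectProfile] | None = None,
) -> tuple[list[SubjectProfile], dict[str, tuple[AccelerometerTrace, pd.DataFrame]]]:
    """Generate profiles (unless given) and one session per subject."""
    if specs is None:
        specs = default_behaviour_specs()
    if profiles is None:
        profiles = generate_cohort(config)
    sessions = {p.subject_id: simulate_session(p, specs, config) for p in profiles}
    return profiles, sessions


def write_session_csv(trace: AccelerometerTrace, labels: pd.DataFrame, path) -> None:
    n = len(trace)
    df = pd.DataFrame({
        "timestamp_s": np.arange(n) / trace.sampling_rate,
        "x": trace.xyz[:, 0], "y": trace.xyz[:, 1], "z": trace.xyz[:, 2],
        "behaviour": labels["behaviour"].to_numpy(),
        "category": labels["category"].to_numpy(),
        "place": labels["place"].to_numpy(),
    })
    df.to_csv(path, index=False)


def write_cohort_csv(profiles: list[SubjectProfile], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectProfile]:
    df = pd.read_csv(path)
    return [SubjectProfile(subject_id=str(r.subject_id), species=r.species,
                           sex=r.sex, age=int(r.age), mass=float(r.mass),
                           attachment=r.attachment)
            for r in df.itertuples()]


def write_config_json(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    if d["transition_matrix"] is not None:
        d["transition_matrix"] = np.asarray(d["transition_matrix"]).tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
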