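"""From labelled feature tables to training / held-out datasets.

Covers the four data-preparation steps of the protocol: labelling each
epoch with a behaviour category (majority vote with a precedence rule for
ties, 'other' epochs dropped), attaching subject-level covariates, a
subject-wise train / held-out split (two animals held out entirely), and
random under-sampling of over-represented classes in the training data
only — the held-out data is never balanced, so it keeps the skewed class
mix a wild deployment would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import CATEGORY_PRECEDENCE, MODEL_CATEGORIES, category_of
from .synthetic_data import FUR_SEAL_SPECIES, SPECIES, SubjectProfile

log = logging.getLogger(__name__)

PLACES = ("surface", "underwater", "land")
SEXES = ("male", "female")
ATTACHMENTS = ("harness", "tape")


@dataclass
class SplitPlan:
    """Subject-wise split: two animals held out, the rest train."""

    holdout_size: int = 2
    inner_train_fraction: float = 0.70
    n_folds: int = 10
    seed: int = 0
    stratified: bool = True   # prefer one female sea lion + one male fur seal


@dataclass
class BalancePolicy:
    method: str = "undersample"      # or "none"
    class_cap: int = 3000
    seed: int = 0


# ---------------------------------------------------------------------------
# epoch labelling
# ---------------------------------------------------------------------------

def label_epochs(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    epoch_len: int = 13,
) -> pd.DataFrame:
    """Label each epoch with the majority behaviour category of its samples.

    ``labels`` is the per-sample frame (column ``category`` or
    ``behaviour``) covering the session the features came from; epochs are
    located by their ``epoch_start`` column. Exact majority ties are broken
    by precedence: foraging > grooming > travelling > resting > other
    (grooming and foraging take precedence over travelling and resting;
    foraging wins a direct tie with grooming). Epochs whose assigned
    category is 'other' are dropped; the dropped count is logged and stored
    in ``table.attrs['n_dropped_other']``.
    """
    if "category" in labels.columns:
        cat = labels["category"].to_numpy(dtype=object)
    elif "behaviour" in labels.columns:
        cat = np.array([category_of(b) for b in labels["behaviour"]], dtype=object)
    else:
        raise ValueError("label frame needs a 'category' or 'behaviour' column")

    if pd.isna(cat).any():
        bad_sample = int(np.flatnonzero(pd.isna(cat))[0])
        raise ValueError(
            f"unlabelled sample {bad_sample}; first affected epoch starts at "
            f"or before this sample"
        )

    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    cat_codes = np.array([rank[c] for c in cat])
    starts = features["epoch_start"].to_numpy(dtype=int)
    if starts.max(initial=0) + epoch_len > len(cat):
        raise ValueError(
            f"label track ({len(cat)} samples) does not cover epoch starting "
            f"at sample {starts.max()}"
        )

    n_cat = len(CATEGORY_PRECEDENCE)
    counts = np.zeros((len(starts), n_cat), dtype=int)
    for j in range(n_cat):
        csum = np.concatenate(([0], np.cumsum(cat_codes == j)))
        counts[:, j] = csum[starts + epoch_len] - csum[starts]
    # argmax over counts; ties resolved by precedence order = column order
    winner = counts.argmax(axis=1)
    out = features.copy()
    out["category"] = np.array(CATEGORY_PRECEDENCE, dtype=object)[winner]

    keep = out["category"] != "other"
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d epochs labelled 'other'", n_dropped)
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped_other"] = n_dropped
    return out


# ---------------------------------------------------------------------------
# subject covariates
# ---------------------------------------------------------------------------

def _one_hot(values: pd.Series, levels: tuple[str, ...], prefix: str) -> pd.DataFrame:
    return pd.DataFrame(
        {f"{prefix}_{lv}": (values == lv).astype(float).to_numpy() for lv in levels}
    )


def attach_subject_features(
    features: pd.DataFrame,
    profiles: dict[str, SubjectProfile] | list[SubjectProfile],
    enabled: bool = True,
) -> pd.DataFrame:
    """Attach place indicators (always) and, when ``enabled``, the five
    subject covariates: attachment method, age, mass, sex, species.
    Categorical covariates are one-hot encoded; column order is fixed.
    """
    if not isinstance(profiles, dict):
        profiles = {p.subject_id: p for p in profiles}
    missing = set(features["subject_id"].astype(str)) - set(profiles)
    if missing:
        raise KeyError(f"no profile for subject(s): {sorted(missing)}")

    out = features.copy().reset_index(drop=True)
    place = out["place"].astype(str)
    unknown = set(place.unique()) - set(PLACES)
    if unknown:
        raise ValueError(f"unknown place value(s): {sorted(unknown)}")
    blocks = [_one_hot(place, PLACES, "place")]

    if enabled:
        prof = out["subject_id"].astype(str).map(profiles)
        attach = prof.map(lambda p: p.attachment)
        sex = prof.map(lambda p: p.sex)
        species = prof.map(lambda p: p.species)
        blocks.append(_one_hot(attach, ATTACHMENTS, "attachment"))
        blocks.append(pd.DataFrame({
            "subj_age": prof.map(lambda p: float(p.age)).to_numpy(),
            "subj_mass": prof.map(lambda p: float(p.mass)).to_numpy(),
        }))
        blocks.append(_one_hot(sex, SEXES, "sex"))
        blocks.append(_one_hot(species, SPECIES, "species"))

    return pd.concat([out] + blocks, axis=1)


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """The model inputs: the 52 movement statistics plus any covariate
    columns, in table order; metadata and label columns excluded."""
    meta = {"subject_id", "epoch_index", "epoch_start", "place", "behaviour", "category"}
    return [c for c in table.columns if c not in meta]


# ---------------------------------------------------------------------------
# subject-wise split
# ---------------------------------------------------------------------------

def split_subjects(
    features: pd.DataFrame,
    profiles: dict[str, SubjectProfile] | list[SubjectProfile],
    plan: SplitPlan | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Partition epochs by subject into train and held-out tables.

    The default stratified holdout picks one female sea lion (ASL) and one
    male fur seal when such animals exist — spanning the cohort's range of
    body plans — otherwise a seeded random pair. Returns
    (train, holdout, manifest); the manifest records the subject lists and
    seed. No subject ever appears on both sides.
    """
    plan = plan or SplitPlan()
    if not isinstance(profiles, dict):
        profiles = {p.subject_id: p for p in profiles}
    subjects = sorted(set(features["subject_id"].astype(str)))
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects for a leave-two-out split")

    rng = np.random.default_rng(plan.seed & 0x7FFFFFFF)
    holdout: list[str] = []
    if plan.stratified:
        asl_f = [s for s in subjects
                 if profiles[s].species == "ASL" and profiles[s].sex == "female"]
        fur_m = [s for s in subjects
                 if profiles[s].species in FUR_SEAL_SPECIES and profiles[s].sex == "male"]
        if asl_f and fur_m:
            holdout = [asl_f[rng.integers(len(asl_f))]]
            fur_m = [s for s in fur_m if s not in holdout]
            holdout.append(fur_m[rng.integers(len(fur_m))])
    if len(holdout) != plan.holdout_size:
        holdout = list(rng.choice(subjects, size=plan.holdout_size, replace=False))

    holdout_set = set(holdout)
    train_subjects = [s for s in subjects if s not in holdout_set]
    in_holdout = features["subject_id"].astype(str).isin(holdout_set)
    train = features.loc[~in_holdout].reset_index(drop=True)
    hold = features.loc[in_holdout].reset_index(drop=True)
    manifest = {
        "train_subjects": train_subjects,
        "holdout_subjects": sorted(holdout),
        "seed": plan.seed,
        "stratified": plan.stratified,
    }
    return train, hold, manifest


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------

def undersample(train: pd.DataFrame, policy: BalancePolicy | None = None) -> pd.DataFrame:
    """Cap every class at ``policy.class_cap`` epochs by seeded uniform
    sampling without replacement; classes at or below the cap are untouched.
    Applied to training data only — never to held-out data. Row order is
    shuffled deterministically.
    """
    policy = policy or BalancePolicy()
    if policy.method == "none":
        return train.reset_index(drop=True)
    if policy.method != "undersample":
        raise ValueError(f"unknown balance method {policy.method!r}")
    if policy.class_cap <= 0:
        raise ValueError("class_cap must be positive")

    rng = np.random.default_rng(policy.seed & 0x7FFFFFFF)
    keep_idx: list[np.ndarray] = []
    # iterate in fixed category order so the seeded draw is reproducible
    for cat in MODEL_CATEGORIES:
        idx = np.flatnonzero((train["category"] == cat).to_numpy())
        if len(idx) > policy.class_cap:
            idx = np.sort(rng.choice(idx, size=policy.class_cap, replace=False))
        keep_idx.append(idx)
    extra = np.flatnonzero(~train["category"].isin(MODEL_CATEGORIES).to_numpy())
    if len(extra):
        raise ValueError(
            f"training table contains non-model categories: "
            f"{sorted(train['category'].iloc[extra].unique())}"
        )
    keep = np.concatenate(keep_idx)
    keep = keep[rng.permutation(len(keep))]
    return train.iloc[keep].reset_index(drop=True)
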