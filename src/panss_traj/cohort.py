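"""Synthetic trial-cohort generator.

Emulates a 6-week, seven-arm randomised antipsychotic trial in which each
patient belongs to one of two latent response classes ("high" responders and
"low" responders). Follow-up PANSS totals are generated by *inverting* the
corrected percent-reduction formula,

    total_w = baseline - r_w / 100 * (baseline - 30),

where ``r_w`` is the patient's class mean percent reduction at week ``w`` plus
Gaussian noise. Because clustering downstream operates in reduction-rate
space, generating in that space makes the configured class curves exact there
(up to integer rounding of scores).

Subscale scores (positive, negative, general psychopathology) are apportioned
from the total by a fixed per-patient proportional split with bounded integer
jitter; dropout is monotone (once a patient leaves, all later visits are
missing) and isolated cell missingness is MCAR on follow-up visits only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

ARMS: tuple[str, ...] = (
    "risperidone",
    "olanzapine",
    "quetiapine",
    "aripiprazole",
    "ziprasidone",
    "perphenazine",
    "haloperidol",
)
ATYPICAL_ARMS: tuple[str, ...] = ARMS[:5]
TYPICAL_ARMS: tuple[str, ...] = ARMS[5:]

WEEKS: tuple[int, ...] = (0, 2, 4, 6)
FOLLOWUP_WEEKS: tuple[int, ...] = (2, 4, 6)

#: PANSS scale bounds: (floor, ceiling) per scale.
SCALE_BOUNDS: dict[str, tuple[int, int]] = {
    "total": (30, 210),
    "positive": (7, 49),
    "negative": (7, 49),
    "general": (16, 112),
}
SUBSCALES: tuple[str, ...] = ("positive", "negative", "general")

SCORE_COLUMNS: tuple[str, ...] = tuple(
    f"panss_{scale}_w{w}" for scale in ("total",) + SUBSCALES for w in WEEKS
)


@dataclass(frozen=True)
class CohortConfig:
    """All generator parameters.

    Defaults reproduce the trial design this package analyses: 3010 patients
    randomised 1:1:1:1:1:0.5:0.5 across seven arms, two latent response
    classes (48.9% high / 51.1% low) whose mean percent-reduction curves at
    weeks 2/4/6 are 35.84/60.51/73.58 (high) and 15.16/28.10/31.99 (low), and
    12.62% monotone dropout.
    """

    n_patients: int = 3010
    arm_weights: tuple[float, ...] = (1, 1, 1, 1, 1, 0.5, 0.5)
    class_names: tuple[str, ...] = ("high", "low")
    class_proportions: tuple[float, ...] = (0.489, 0.511)
    class_mean_curves: tuple[tuple[float, ...], ...] = (
        (35.84, 60.51, 73.58),
        (15.16, 28.10, 31.99),
    )
    #: Percent-reduction noise SD per follow-up visit (percentage points).
    within_class_sd: float = 8.0
    baseline_total_mean: float = 90.0
    baseline_total_sd: float = 15.0
    #: Baseline totals are clipped here; the floor stays above 30 so the
    #: percent-change denominator is always positive.
    baseline_total_range: tuple[int, int] = (60, 150)
    dropout_rate: float = 0.1262
    missing_rate: float = 0.02
    first_episode_prop: float = 0.55
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        w = np.asarray(self.arm_weights, dtype=float)
        if len(w) != len(ARMS):
            raise ConfigurationError(
                f"arm_weights must have {len(ARMS)} entries, got {len(w)}"
            )
        if (w < 0).any() or not (w > 0).any():
            raise ConfigurationError(
                "arm_weights must be non-negative with at least one positive"
            )
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) != len(self.class_names) or len(p) != len(self.class_mean_curves):
            raise ConfigurationError(
                "class_names, class_proportions and class_mean_curves must align"
            )
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        lo, hi = SCALE_BOUNDS["total"]
        if not (lo <= self.baseline_total_mean <= hi):
            raise ConfigurationError(
                f"baseline_total_mean must lie in the PANSS total range [{lo}, {hi}]"
            )
        if not (lo < self.baseline_total_range[0] <= self.baseline_total_range[1] <= hi):
            raise ConfigurationError(
                "baseline_total_range must lie within (30, 210]"
            )
        for rate, name in (
            (self.dropout_rate, "dropout_rate"),
            (self.missing_rate, "missing_rate"),
            (self.first_episode_prop, "first_episode_prop"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {rate}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        kwargs = dict(d)
        for key in (
            "arm_weights",
            "class_names",
            "class_proportions",
            "baseline_total_range",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "class_mean_curves" in kwargs:
            kwargs["class_mean_curves"] = tuple(
                tuple(c) for c in kwargs["class_mean_curves"]
            )
        return cls(**kwargs)


def assign_arms(n: int, weights, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` arm labels independently with probability weight / sum(weights).

    ``seed`` may be an integer or an already-constructed Generator; the same
    integer seed always yields the identical label sequence.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(ARMS) or (w < 0).any() or not (w > 0).any():
        raise ConfigurationError(
            "weights must be seven non-negative values with at least one positive"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(ARMS), size=n, p=w / w.sum())
    return np.asarray(ARMS, dtype=object)[idx]


def _partition_total(
    total: int, props: np.ndarray, rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
) -> np.ndarray:
    """Split a PANSS total into (positive, negative, general) integers.

    Largest-remainder apportionment of ``total * props`` followed by clipping
    to the subscale bounds and slack-directed redistribution so the parts sum
    exactly to ``total``. Feasible for every total in [30, 210] because the
    subscale floors sum to 30 and the ceilings to 210.
    """
    lows = np.array([SCALE_BOUNDS[s][0] for s in SUBSCALES])
    highs = np.array([SCALE_BOUNDS[s][1] for s in SUBSCALES])
    p = np.asarray(props, dtype=float)
    if rng is not None and jitter_sd > 0:
        p = np.clip(p + rng.normal(0.0, jitter_sd, size=3), 0.05, None)
    p = p / p.sum()
    x = np.floor(total * p).astype(int)
    rem = total * p - x
    for i in np.argsort(-rem)[: total - x.sum()]:
        x[i] += 1
    x = np.clip(x, lows, highs)
    diff = int(total - x.sum())
    while diff != 0:
        if diff > 0:
            slack = highs - x
            i = int(np.argmax(slack))
            step = min(diff, int(slack[i]))
        else:
            slack = x - lows
            i = int(np.argmax(slack))
            step = -min(-diff, int(slack[i]))
        if step == 0:  # pragma: no cover - unreachable for totals in [30, 210]
            raise ConfigurationError(f"cannot partition total {total} into subscales")
        x[i] += step
        diff -= step
    return x


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a wide-format cohort table, one row per patient.

    Columns: ``patient_id, arm, first_episode, latent_class, age_at_onset,
    illness_duration, dose_risperidone_equiv`` and ``panss_<scale>_w<week>``
    for the four scales at weeks 0/2/4/6. Follow-up cells may be NaN after
    dropout/missingness; baseline cells never are. ``latent_class`` is
    simulation ground truth and is excluded from written files by default
    (see :func:`write_cohort`).
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)
    # Independent child streams so each mechanism is reproducible in isolation.
    s_arm, s_class, s_scores, s_covar, s_drop, s_miss = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(6)
    )

    arms = assign_arms(n, config.arm_weights, s_arm)
    class_idx = s_class.choice(
        len(config.class_names), size=n, p=np.asarray(config.class_proportions, float)
    )
    latent = np.asarray(config.class_names, dtype=object)[class_idx]

    lo, hi = config.baseline_total_range
    baseline = np.rint(
        s_scores.normal(config.baseline_total_mean, config.baseline_total_sd, size=n)
    ).astype(int)
    baseline = np.clip(baseline, lo, hi)

    curves = np.asarray(config.class_mean_curves, dtype=float)  # (n_class, 3)
    target_pct = curves[class_idx] + s_scores.normal(
        0.0, config.within_class_sd, size=(n, len(FOLLOWUP_WEEKS))
    )
    followup = np.rint(
        baseline[:, None] - target_pct / 100.0 * (baseline[:, None] - 30)
    ).astype(int)
    t_lo, t_hi = SCALE_BOUNDS["total"]
    followup = np.clip(followup, t_lo, t_hi)

    # Per-patient subscale mix: symptom profile is stable within a patient, so
    # the baseline split (with jitter around a typical profile) is reused at
    # every visit with only small additional jitter.
    base_props = np.array([0.26, 0.25, 0.49])
    props = np.clip(
        base_props + s_scores.normal(0.0, 0.03, size=(n, 3)), 0.05, None
    )
    props /= props.sum(axis=1, keepdims=True)

    totals = np.column_stack([baseline, followup])  # (n, 4) weeks 0,2,4,6
    sub = np.empty((n, len(WEEKS), 3), dtype=int)
    for i in range(n):
        for j in range(len(WEEKS)):
            jitter = 0.0 if j == 0 else 0.01
            sub[i, j] = _partition_total(int(totals[i, j]), props[i], s_scores, jitter)

    first_episode = s_covar.random(n) < config.first_episode_prop
    age_at_onset = np.clip(s_covar.normal(26.0, 7.0, size=n), 13.0, 60.0).round(1)
    illness_duration = np.where(
        first_episode,
        s_covar.exponential(1.0, size=n),
        1.0 + s_covar.exponential(7.0, size=n),
    ).round(1)
    dose = np.clip(s_covar.lognormal(np.log(4.0), 0.35, size=n), 0.5, 16.0).round(2)

    width = len(str(n))
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
            "arm": arms,
            "first_episode": first_episode,
            "latent_class": latent,
            "age_at_onset": age_at_onset,
            "illness_duration": illness_duration,
            "dose_risperidone_equiv": dose,
        }
    )
    for j, w in enumerate(WEEKS):
        df[f"panss_total_w{w}"] = totals[:, j].astype(float)
        for k, scale in enumerate(SUBSCALES):
            df[f"panss_{scale}_w{w}"] = sub[:, j, k].astype(float)

    df = apply_dropout(df, config.dropout_rate, s_drop)
    if config.missing_rate > 0:
        followup_cols = [
            f"panss_{scale}_w{w}"
            for scale in ("total",) + SUBSCALES
            for w in FOLLOWUP_WEEKS
        ]
        mask = s_miss.random((n, len(followup_cols))) < config.missing_rate
        for c, col in enumerate(followup_cols):
            df.loc[mask[:, c], col] = np.nan
    return df


def apply_dropout(
    records: pd.DataFrame,
    dropout_rate: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Monotone dropout: selected patients lose all visits from a uniformly
    chosen follow-up week onward. Baseline is never touched."""
    if not 0.0 <= dropout_rate <= 1.0:
        raise ConfigurationError(f"dropout_rate must lie in [0, 1], got {dropout_rate}")
    rng = (
        np.random.default_rng(seed)
        if not isinstance(seed, np.random.Generator)
        else seed
    )
    out = records.copy()
    n = len(out)
    dropped = rng.random(n) < dropout_rate
    cut_idx = rng.integers(0, len(FOLLOWUP_WEEKS), size=n)
    for i in np.flatnonzero(dropped):
        for w in FOLLOWUP_WEEKS[cut_idx[i]:]:
            for scale in ("total",) + SUBSCALES:
                out.iloc[i, out.columns.get_loc(f"panss_{scale}_w{w}")] = np.nan
    return out


def write_cohort(
    df: pd.DataFrame,
    path,
    include_latent: bool = False,
    long_path=None,
    config: CohortConfig | None = None,
    sidecar_path=None,
) -> None:
    """Write the wide-format CSV (and optionally a long-format CSV and a JSON
    sidecar recording the full generating config, seed included).

    ``latent_class`` is dropped unless ``include_latent`` — the analysis
    stages must never see the simulation ground truth by default.
    """
    out = df if include_latent else df.drop(columns=["latent_class"], errors="ignore")
    out.to_csv(path, index=False, float_format="%.10g")
    if long_path is not None:
        long = df.melt(
            id_vars=["patient_id"],
            value_vars=[c for c in df.columns if c.startswith("panss_")],
            var_name="measure",
            value_name="score",
        )
        parts = long["measure"].str.extract(r"panss_(\w+)_w(\d+)")
        long["scale"], long["week"] = parts[0], parts[1].astype(int)
        long[["patient_id", "week", "scale", "score"]].to_csv(
            long_path, index=False, float_format="%.10g"
        )
    if sidecar_path is not None and config is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_cohort(path) -> pd.DataFrame:
    """Read a wide-format cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    if "first_episode" in df.columns:
        df["first_episode"] = df["first_episode"].astype(bool)
    return df
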