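"""Percent-reduction trajectories from raw PANSS scores.

The corrected percent change of the PANSS *total* subtracts the scale floor
of 30 from the denominator,

    100 * (baseline - followup) / (baseline - 30),

so that 100% corresponds to complete remission (a score of exactly 30) rather
than an unattainable score of zero. Subscale percent change uses the plain
baseline denominator without the floor.

Outliers are winsorized by the Tukey fence rule (beyond quartile +/- 1.5 IQR)
with replacement at the 0.01 / 0.99 quantiles of the original values, and
missing follow-up scores are completed by chained-equation imputation with
predictive-mean-matching draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import FOLLOWUP_WEEKS
from .errors import (
    ImputationError,
    InsufficientDataError,
    UndefinedDenominatorError,
)

logger = logging.getLogger(__name__)

PANSS_TOTAL_FLOOR = 30


def percent_change_total(baseline, followup):
    """Corrected percent reduction of the PANSS total score.

    Accepts scalars or arrays; raises :class:`UndefinedDenominatorError` when
    any baseline is at or below the 30-point scale floor.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if np.any(b <= PANSS_TOTAL_FLOOR):
        raise UndefinedDenominatorError(
            "baseline PANSS total must exceed the scale floor of 30"
        )
    out = 100.0 * (b - f) / (b - PANSS_TOTAL_FLOOR)
    return out if out.ndim else float(out)


def percent_change_subscale(baseline, followup):
    """Percent reduction of a PANSS subscale (no floor correction)."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if np.any(b <= 0):
        raise UndefinedDenominatorError("subscale baseline must be positive")
    out = 100.0 * (b - f) / b
    return out if out.ndim else float(out)


def winsorize_iqr(
    values,
    quantile_method: str = "linear",
    with_mask: bool = False,
    fences: tuple[float, float] | None = None,
    replacements: tuple[float, float] | None = None,
):
    """Replace out-of-fence values by the 0.01 / 0.99 quantiles.

    Fences are ``Q1 - 1.5*IQR`` and ``Q3 + 1.5*IQR`` computed from the finite
    values of the input; values above the upper fence become the 0.99 quantile
    of the *original* values, values below the lower fence the 0.01 quantile.
    NaN cells pass through untouched. ``quantile_method`` is any method name
    accepted by :func:`numpy.quantile` (default: linear interpolation).

    Pass ``fences=(lo, hi)`` and ``replacements=(lo_rep, hi_rep)`` to reuse
    bounds stored from an earlier pass (this makes the operation idempotent:
    re-applying with the original fences is the identity).
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 4:
        raise InsufficientDataError(
            f"winsorization needs >= 4 finite values, got {int(finite.sum())}"
        )
    obs = x[finite]
    if fences is None:
        q1, q3 = np.quantile(obs, [0.25, 0.75], method=quantile_method)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        lo_fence, hi_fence = fences
    if replacements is None:
        lo_rep, hi_rep = np.quantile(obs, [0.01, 0.99], method=quantile_method)
    else:
        lo_rep, hi_rep = replacements
    low = finite & (x < lo_fence)
    high = finite & (x > hi_fence)
    x[low] = lo_rep
    x[high] = hi_rep
    if with_mask:
        return x, (low | high)
    return x


def impute_chained(
    table: pd.DataFrame,
    n_imputations: int = 5,
    n_iterations: int = 20,
    seed: int = 0,
    donor_pool: int = 5,
) -> list[pd.DataFrame]:
    """Multiple imputation by chained equations with predictive mean matching.

    ``table`` is a wide numeric table (rows = patients, columns = visit
    scores); the first column set is assumed to include a complete baseline.
    Each incomplete column is regressed (OLS with intercept) on all other
    columns, and every missing cell receives the *observed* value of a donor
    drawn uniformly from the ``donor_pool`` rows whose predicted values are
    nearest the missing row's prediction. The cycle over columns is repeated
    ``n_iterations`` times per imputation.

    Returns ``n_imputations`` completed copies. Observed cells are never
    altered, and every imputed value equals some observed value of its column.
    """
    if n_imputations < 1 or n_iterations < 1:
        raise ImputationError("n_imputations and n_iterations must be >= 1")
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    for j, col in enumerate(table.columns):
        n_obs = n - int(miss[:, j].sum())
        if n_obs == 0:
            raise ImputationError(f"column {col!r} has no observed values")
        if n_obs < n / 2:
            raise ImputationError(
                f"column {col!r} has fewer than 50% observed values"
            )
    if not miss.any():
        return [table.copy() for _ in range(n_imputations)]

    incomplete = [j for j in range(p) if miss[:, j].any()]
    results = []
    for child in np.random.SeedSequence(seed).spawn(n_imputations):
        rng = np.random.default_rng(child)
        Xc = X.copy()
        # Initial fill: random draws from each column's observed values.
        for j in incomplete:
            obs_vals = X[~miss[:, j], j]
            Xc[miss[:, j], j] = rng.choice(obs_vals, size=int(miss[:, j].sum()))
        for _ in range(n_iterations):
            for j in incomplete:
                obs = ~miss[:, j]
                others = [c for c in range(p) if c != j]
                A = np.column_stack([np.ones(n), Xc[:, others]])
                beta, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
                pred = A @ beta
                obs_idx = np.flatnonzero(obs)
                obs_pred = pred[obs_idx]
                for i in np.flatnonzero(miss[:, j]):
                    d = np.abs(obs_pred - pred[i])
                    k = min(donor_pool, len(obs_idx))
                    donors = obs_idx[np.argpartition(d, k - 1)[:k]]
                    Xc[i, j] = X[rng.choice(donors), j]
        results.append(pd.DataFrame(Xc, index=table.index, columns=table.columns))
    return results


@dataclass
class TrajectoryMatrix:
    """Per-patient percent-reduction vectors over the follow-up weeks."""

    patient_ids: np.ndarray
    weeks: tuple[int, ...]
    values: np.ndarray  # (n_patients, n_weeks) percent reductions
    observed: np.ndarray | None = None  # True where the raw score was observed

    def __post_init__(self):
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.weeks)):
            raise ValueError("values shape must be (n_patients, n_weeks)")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient_ids must be unique")
        if any(b <= a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"pct_w{w}" for w in self.weeks]
        )
        df.insert(0, "patient_id", self.patient_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TrajectoryMatrix":
        df = pd.read_csv(path)
        weeks = tuple(
            int(c.removeprefix("pct_w")) for c in df.columns if c.startswith("pct_w")
        )
        return cls(
            patient_ids=df["patient_id"].to_numpy(dtype=object),
            weeks=weeks,
            values=df[[f"pct_w{w}" for w in weeks]].to_numpy(dtype=float),
        )


def build_trajectories(
    records: pd.DataFrame,
    imputed: pd.DataFrame,
    weeks: tuple[int, ...] = FOLLOWUP_WEEKS,
) -> TrajectoryMatrix:
    """Assemble the clustering input: corrected percent reductions per visit.

    ``imputed`` is a completed wide table of PANSS totals whose columns are
    ``panss_total_w<week>`` for week 0 and each follow-up week, row-aligned
    with ``records``. Baselines are never imputed: a missing baseline is a
    hard error.
    """
    base = imputed["panss_total_w0"].to_numpy(dtype=float)
    if np.isnan(base).any():
        raise UndefinedDenominatorError("baseline totals must be complete")
    cols = [f"panss_total_w{w}" for w in weeks]
    follow = imputed[cols].to_numpy(dtype=float)
    if np.isnan(follow).any():
        raise ImputationError("follow-up totals must be complete after imputation")
    values = percent_change_total(base[:, None], follow)
    observed = ~records[cols].isna().to_numpy()
    return TrajectoryMatrix(
        patient_ids=records["patient_id"].to_numpy(dtype=object),
        weeks=tuple(weeks),
        values=values,
        observed=observed,
    )


@dataclass
class PreprocessResult:
    trajectories: TrajectoryMatrix
    completed: pd.DataFrame  # completed raw totals (first imputation by default)
    all_imputations: list[pd.DataFrame]
    winsorized_cells: dict[str, int] = field(default_factory=dict)
    imputed_cells: dict[str, int] = field(default_factory=dict)
    dropped_patients: list[str] = field(default_factory=list)


def preprocess(
    records: pd.DataFrame,
    weeks: tuple[int, ...] = FOLLOWUP_WEEKS,
    winsorize: bool = True,
    quantile_method: str = "linear",
    n_imputations: int = 5,
    n_iterations: int = 20,
    seed: int = 0,
    dataset_index: int = 0,
) -> PreprocessResult:
    """Full preprocessing stage: winsorize -> impute -> percent change.

    Winsorization is applied per visit column on raw total scores across
    patients (outlier *scores*, not outlier ratios, are treated as the
    measurement artifact), then missing follow-ups are completed by chained
    PMM imputation, and finally corrected percent reductions are computed.
    Patients whose baseline total is at or below the scale floor of 30 are
    dropped with a logged warning — the denominator is undefined for them.
    Downstream stages consume imputation ``dataset_index`` (single-dataset
    mode); all completed datasets are returned for spread analyses.
    """
    cols = ["panss_total_w0"] + [f"panss_total_w{w}" for w in weeks]
    recs = records.reset_index(drop=True)
    floor_mask = recs["panss_total_w0"] <= PANSS_TOTAL_FLOOR
    dropped = recs.loc[floor_mask, "patient_id"].tolist()
    if dropped:
        logger.warning(
            "dropping %d patient(s) with baseline total <= 30 (undefined "
            "percent change): %s", len(dropped), ", ".join(map(str, dropped))
        )
        recs = recs.loc[~floor_mask].reset_index(drop=True)

    wide = recs[cols].astype(float).copy()
    winsorized_cells: dict[str, int] = {}
    if winsorize:
        for col in cols:
            new, mask = winsorize_iqr(
                wide[col].to_numpy(), quantile_method=quantile_method, with_mask=True
            )
            wide[col] = new
            winsorized_cells[col] = int(mask.sum())

    imputed_cells = {col: int(wide[col].isna().sum()) for col in cols}
    completed_sets = impute_chained(
        wide, n_imputations=n_imputations, n_iterations=n_iterations, seed=seed
    )
    completed = completed_sets[dataset_index]
    traj = build_trajectories(recs, completed, weeks=weeks)
    return PreprocessResult(
        trajectories=traj,
        completed=completed,
        all_imputations=completed_sets,
        winsorized_cells=winsorized_cells,
        imputed_cells=imputed_cells,
        dropped_patients=dropped,
    )
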