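"""Trajectory-based versus 50%-reduction responder classification.

The dichotomous rule calls a patient a responder when the week-6 corrected
percent reduction reaches the cutoff (default 50%, boundary inclusive). This
module cross-classifies that rule against trajectory membership, tests the
composition ratio of the two methods, and breaks the classifications down by
drug arm and by episode status with FDR-adjusted pairwise comparisons.

A note on the composition test: the two classifications of the *same*
patients are compared as if they were independent samples (a 2x2 table with
grand total 2n: methods as rows, good/poor response as columns). That is the
unpaired construction used for the published composition ratio; the
statistically conventional paired alternative (McNemar on the discordant
cells) is exposed separately as :func:`mcnemar_paired`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ARMS, TYPICAL_ARMS
from .errors import AlignmentError, ConfigurationError, DegenerateTableError


@dataclass
class CrossTab:
    """A labelled contingency table of non-negative integer counts."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise AlignmentError("counts shape must match labels")
        if (self.counts < 0).any():
            raise DegenerateTableError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
        }


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str
    adjusted_p: float | None = None
    odds_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": None if self.statistic is None else float(self.statistic),
            "df": self.df,
            "p_value": float(self.p_value),
            "method": self.method,
            "adjusted_p": None if self.adjusted_p is None else float(self.adjusted_p),
            "odds_ratio": None
            if self.odds_ratio is None or not np.isfinite(self.odds_ratio)
            else float(self.odds_ratio),
        }


def classify_threshold(week6_pct, cutoff: float = 50.0, strict: bool = False):
    """Responder flag from the week-6 percent reduction.

    ``strict=False`` (default) counts the boundary as response
    (``pct >= cutoff``); ``strict=True`` requires ``pct > cutoff``.
    """
    x = np.asarray(week6_pct, dtype=float)
    out = x > cutoff if strict else x >= cutoff
    return out if out.ndim else bool(out)


def _check_aligned(*vectors):
    n = len(vectors[0])
    for v in vectors[1:]:
        if len(v) != n:
            raise AlignmentError(
                f"per-patient vectors have mismatched lengths ({n} vs {len(v)})"
            )


def paired_crosstab(traj_labels, resp_flags) -> CrossTab:
    """2x2 cross-classification of the same patients: trajectory group (rows
    high/low) against threshold responder status (columns)."""
    traj = np.asarray(traj_labels, dtype=object)
    resp = np.asarray(resp_flags, dtype=bool)
    _check_aligned(traj, resp)
    counts = np.array(
        [
            [(traj == "high")[resp].sum(), (traj == "high")[~resp].sum()],
            [(traj == "low")[resp].sum(), (traj == "low")[~resp].sum()],
        ]
    )
    return CrossTab(("high", "low"), ("responder", "non_responder"), counts)


def discordant_count(crosstab: CrossTab) -> int:
    """Patients the two methods classify differently (off-diagonal sum)."""
    c = crosstab.counts
    return int(c.sum() - np.trace(c))


def composition_table(traj_labels, resp_flags) -> CrossTab:
    """Composition-ratio table: one row per classification method, columns
    good/poor response. The grand total is 2n — each patient is counted once
    per method — matching the unpaired composition comparison."""
    traj = np.asarray(traj_labels, dtype=object)
    resp = np.asarray(resp_flags, dtype=bool)
    _check_aligned(traj, resp)
    counts = np.array(
        [
            [(traj == "high").sum(), (traj == "low").sum()],
            [resp.sum(), (~resp).sum()],
        ]
    )
    return CrossTab(("trajectory", "threshold"), ("good", "poor"), counts)


def _expected(counts: np.ndarray) -> np.ndarray:
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()


def pearson_chi2(table: CrossTab) -> TestResult:
    """Pearson chi-squared without continuity correction."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "zero expected count; consider Fisher's exact test"
        )
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(stat), int(dof), float(p), "pearson_chi2")


def fisher_exact_2x2(table: CrossTab) -> TestResult:
    """Two-sided Fisher's exact test (probability-ordering definition) with
    the sample odds ratio as point estimate."""
    counts = table.counts
    if counts.shape != (2, 2):
        raise DegenerateTableError("Fisher's exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return TestResult(
        statistic=float(odds), df=None, p_value=float(p),
        method="fisher_exact", odds_ratio=float(odds),
    )


def mcnemar_paired(paired: CrossTab) -> TestResult:
    """McNemar chi-squared on the discordant cells of the paired table —
    the conventional paired counterpart to :func:`pearson_chi2` on the
    composition table."""
    c = paired.counts
    if c.shape != (2, 2):
        raise DegenerateTableError("McNemar requires a 2x2 paired table")
    b, cc = int(c[0, 1]), int(c[1, 0])
    if b + cc == 0:
        return TestResult(0.0, 1, 1.0, "mcnemar")
    stat = (b - cc) ** 2 / (b + cc)
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(float(stat), 1, p, "mcnemar")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def omnibus_test(
    table: CrossTab,
    expected_threshold: float = 5.0,
    seed: int = 0,
    n_mc: int = 10000,
) -> TestResult:
    """Chi-squared omnibus test with an exact/Monte-Carlo fallback.

    When any expected count falls below ``expected_threshold`` the chi-squared
    approximation is unreliable: a 2x2 table falls back to Fisher's exact
    test, and a larger table to a seeded Monte-Carlo permutation test
    conditioning on the observed margins (chi-squared statistic as the
    discrepancy measure).
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero margin")
    expected = _expected(counts)
    if (expected >= expected_threshold).all():
        return pearson_chi2(table)
    if counts.shape == (2, 2):
        return fisher_exact_2x2(table)
    # Permutation of the column variable over the pooled sample keeps both
    # margins fixed in expectation; p = (1 + #{T_perm >= T_obs}) / (B + 1).
    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(counts.shape[0]), counts.sum(axis=1))
    cols = np.repeat(np.arange(counts.shape[1]), counts.sum(axis=0))
    obs = float(stats.chi2_contingency(counts, correction=False)[0])
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(cols)
        t = np.zeros_like(counts)
        np.add.at(t, (rows, perm), 1)
        e = _expected(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(e > 0, (t - e) ** 2 / e, 0.0).sum()
        if s >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_mc)
    return TestResult(obs, None, float(p), "mc_permutation_chi2")


def _crosstab_by(groups, flags, group_order, col_labels) -> CrossTab:
    g = np.asarray(groups, dtype=object)
    f = np.asarray(flags, dtype=bool)
    counts = np.array(
        [[(g == a)[f].sum(), (g == a)[~f].sum()] for a in group_order]
    )
    return CrossTab(tuple(group_order), col_labels, counts)


@dataclass
class ArmBreakdown:
    trajectory_table: CrossTab
    threshold_table: CrossTab
    omnibus_trajectory: TestResult
    omnibus_threshold: TestResult
    pairwise: pd.DataFrame  # arm_a, arm_b, odds_ratio, p_value, p_adjusted
    pairwise_on: str

    def to_dict(self) -> dict:
        return {
            "trajectory_table": self.trajectory_table.to_dict(),
            "threshold_table": self.threshold_table.to_dict(),
            "omnibus_trajectory": self.omnibus_trajectory.to_dict(),
            "omnibus_threshold": self.omnibus_threshold.to_dict(),
            "pairwise": self.pairwise.to_dict(orient="records"),
            "pairwise_on": self.pairwise_on,
        }


def per_arm_breakdown(
    traj_labels,
    arms,
    resp_flags,
    seed: int = 0,
    pairwise_on: str = "threshold",
) -> ArmBreakdown:
    """Per-drug 7x2 tables by trajectory and by threshold, omnibus tests, and
    all pairwise 2x2 Fisher comparisons with BH adjustment.

    Pairwise comparisons default to the threshold (responder) table; set
    ``pairwise_on="trajectory"`` to compare high/low membership instead.
    Arms with zero patients are dropped with a warning.
    """
    traj = np.asarray(traj_labels, dtype=object)
    arm_v = np.asarray(arms, dtype=object)
    resp = np.asarray(resp_flags, dtype=bool)
    _check_aligned(traj, arm_v, resp)
    present = [a for a in ARMS if (arm_v == a).any()]
    if len(present) < 2:
        raise ConfigurationError("per-arm breakdown needs >= 2 arms present")
    if len(present) < len(ARMS):
        warnings.warn(
            f"dropping empty arm(s): {sorted(set(ARMS) - set(present))}",
            stacklevel=2,
        )
    high = traj == "high"
    traj_table = _crosstab_by(arm_v, high, present, ("high", "low"))
    thresh_table = _crosstab_by(arm_v, resp, present, ("responder", "non_responder"))

    flags = resp if pairwise_on == "threshold" else high
    base = thresh_table if pairwise_on == "threshold" else traj_table
    rows = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            sub = CrossTab(
                (present[i], present[j]),
                base.col_labels,
                base.counts[[i, j]],
            )
            res = fisher_exact_2x2(sub)
            rows.append(
                {
                    "arm_a": present[i],
                    "arm_b": present[j],
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                }
            )
    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = bh_fdr(pairwise["p_value"].to_numpy())
    return ArmBreakdown(
        trajectory_table=traj_table,
        threshold_table=thresh_table,
        omnibus_trajectory=omnibus_test(traj_table, seed=seed),
        omnibus_threshold=omnibus_test(thresh_table, seed=seed),
        pairwise=pairwise,
        pairwise_on=pairwise_on,
    )


def episode_split(
    traj_labels,
    arms,
    first_episode,
    typical_arm_set: Sequence[str] = TYPICAL_ARMS,
    seed: int = 0,
) -> dict[str, tuple[CrossTab, TestResult]]:
    """Within the typical-drug and atypical-drug strata separately, a 2x2
    table of episode status (first-episode / relapse) against trajectory
    (high / low) and its chi-squared result. Empty strata are skipped with a
    warning."""
    traj = np.asarray(traj_labels, dtype=object)
    arm_v = np.asarray(arms, dtype=object)
    fe = np.asarray(first_episode, dtype=bool)
    _check_aligned(traj, arm_v, fe)
    typical = set(typical_arm_set)
    unknown = typical - set(ARMS)
    if unknown:
        raise ConfigurationError(f"unknown arm(s) in typical_arm_set: {sorted(unknown)}")
    in_typical = np.isin(arm_v, sorted(typical))
    out: dict[str, tuple[CrossTab, TestResult]] = {}
    for name, mask in (("typical", in_typical), ("atypical", ~in_typical)):
        if not mask.any():
            warnings.warn(f"empty stratum {name!r}; skipped", stacklevel=2)
            continue
        high = traj[mask] == "high"
        counts = np.array(
            [
                [(high & fe[mask]).sum(), (~high & fe[mask]).sum()],
                [(high & ~fe[mask]).sum(), (~high & ~fe[mask]).sum()],
            ]
        )
        tab = CrossTab(("first_episode", "relapse"), ("high", "low"), counts)
        out[name] = (tab, omnibus_test(tab, seed=seed))
    return out
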