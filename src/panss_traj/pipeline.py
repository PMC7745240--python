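"""End-to-end pipeline: simulate -> preprocess -> cluster -> compare -> report.

Every stage writes plain-text artifacts (CSV/JSON) plus a provenance block
recording the seeds and options in force, so a re-run from the same config
produces byte-identical output bundles. No timestamps are embedded for that
reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    TYPICAL_ARMS,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .cluster import ModelSelection, assignment_labels, select_k
from .compare import (
    classify_threshold,
    composition_table,
    discordant_count,
    episode_split,
    mcnemar_paired,
    paired_crosstab,
    pearson_chi2,
    per_arm_breakdown,
)
from .errors import ConfigurationError
from .metrics import TrajectoryMatrix, preprocess

logger = logging.getLogger(__name__)

PROVENANCE_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Single configuration object driving every stage."""

    outdir: str = "results/run"
    input_csv: str | None = None  # when set, simulate is skipped
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    weeks: tuple[int, ...] = (2, 4, 6)
    winsorize: bool = True
    quantile_method: str = "linear"
    n_imputations: int = 5
    n_iterations: int = 20
    # clustering
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 20
    # comparison
    cutoff: float = 50.0
    strict_cutoff: bool = False
    typical_arm_set: tuple[str, ...] = TYPICAL_ARMS
    # subset filters
    first_episode_only: bool = False
    arm: str | None = None
    per_arm_fits: bool = False
    # master seed; stage seeds are derived deterministically from it
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)
        self.weeks = tuple(self.weeks)
        self.typical_arm_set = tuple(self.typical_arm_set)

    def stage_seed(self, stage: str) -> int:
        # crc32 keeps the derivation stable across processes (str hash is not)
        tag = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
        ss = np.random.SeedSequence((self.seed, tag))
        return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        if "cohort" in kwargs and isinstance(kwargs["cohort"], dict):
            kwargs["cohort"] = CohortConfig.from_dict(kwargs["cohort"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _provenance(stage: str, config: RunConfig, **extra) -> dict:
    return {
        "schema_version": PROVENANCE_SCHEMA_VERSION,
        "package_version": __version__,
        "stage": stage,
        "master_seed": config.seed,
        "stage_seed": config.stage_seed(stage),
        **extra,
    }


def cmd_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort CSV plus its provenance sidecar."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("simulate"))
    df = generate_cohort(cohort_cfg)
    path = outdir / "cohort.csv"
    write_cohort(
        df,
        path,
        include_latent=False,
        config=cohort_cfg,
        sidecar_path=outdir / "cohort_config.json",
    )
    # Ground-truth labels go to a separate file for recovery analyses only.
    df[["patient_id", "latent_class"]].to_csv(outdir / "latent_classes.csv", index=False)
    _write_json(
        _provenance("simulate", config, n_patients=len(df), cohort=cohort_cfg.to_dict()),
        outdir / "provenance_simulate.json",
    )
    logger.info("simulate: wrote %d patients to %s", len(df), path)
    return path


def _load_records(config: RunConfig) -> pd.DataFrame:
    path = (
        Path(config.input_csv)
        if config.input_csv
        else Path(config.outdir) / "cohort.csv"
    )
    if not path.exists():
        raise ConfigurationError(f"input cohort not found: {path}")
    df = read_cohort(path)
    if config.first_episode_only:
        df = df[df["first_episode"]].reset_index(drop=True)
    if config.arm is not None:
        df = df[df["arm"] == config.arm].reset_index(drop=True)
    if df.empty:
        raise ConfigurationError("subset filters left an empty cohort")
    return df


def cmd_preprocess(config: RunConfig) -> TrajectoryMatrix:
    """Winsorize, impute, and write the percent-reduction trajectory matrix."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _load_records(config)
    result = preprocess(
        records,
        weeks=config.weeks,
        winsorize=config.winsorize,
        quantile_method=config.quantile_method,
        n_imputations=config.n_imputations,
        n_iterations=config.n_iterations,
        seed=config.stage_seed("impute"),
    )
    result.trajectories.to_csv(outdir / "trajectories.csv")
    _write_json(
        _provenance(
            "preprocess",
            config,
            winsorized_cells=result.winsorized_cells,
            imputed_cells=result.imputed_cells,
            dropped_patients=result.dropped_patients,
            n_imputations=config.n_imputations,
            quantile_method=config.quantile_method,
        ),
        outdir / "provenance_preprocess.json",
    )
    logger.info(
        "preprocess: %d patients; winsorized %d cells; imputed %d cells; dropped %d",
        result.trajectories.n_patients,
        sum(result.winsorized_cells.values()),
        sum(result.imputed_cells.values()),
        len(result.dropped_patients),
    )
    return result.trajectories


def cmd_cluster(config: RunConfig) -> ModelSelection:
    """Fit k = k_min..k_max with multi-restart k-means and pick the CH argmax."""
    outdir = Path(config.outdir)
    traj = TrajectoryMatrix.from_csv(outdir / "trajectories.csv")
    selection = select_k(
        traj,
        k_range=range(config.k_min, config.k_max + 1),
        n_restarts=config.n_restarts,
        seed=config.stage_seed("cluster"),
    )
    model = selection.selected
    labels = assignment_labels(model)
    pd.DataFrame(
        {
            "patient_id": traj.patient_ids,
            "cluster": model.assignments,
            "label": labels,
        }
    ).to_csv(outdir / "assignments.csv", index=False)
    _write_json(selection.to_dict(), outdir / "cluster_model.json")
    _write_json(
        _provenance(
            "cluster",
            config,
            k_range=[config.k_min, config.k_max],
            n_restarts=config.n_restarts,
            selected_k=selection.selected_k,
        ),
        outdir / "provenance_cluster.json",
    )
    logger.info("cluster: selected k=%d (CH=%.3f)", selection.selected_k,
                model.ch_index)
    return selection


def cmd_compare(config: RunConfig) -> dict:
    """Cross-classify trajectory membership against the threshold rule and
    run the arm / episode breakdowns; write a results JSON."""
    outdir = Path(config.outdir)
    records = _load_records(config)
    traj = TrajectoryMatrix.from_csv(outdir / "trajectories.csv")
    assign = pd.read_csv(outdir / "assignments.csv")
    merged = records.merge(assign, on="patient_id", validate="one_to_one")
    order = {pid: i for i, pid in enumerate(traj.patient_ids)}
    merged = merged.sort_values("patient_id", key=lambda s: s.map(order))

    week6 = traj.values[:, traj.weeks.index(config.weeks[-1])]
    resp = classify_threshold(week6, cutoff=config.cutoff, strict=config.strict_cutoff)
    labels = merged["label"].to_numpy(dtype=object)

    results: dict = {
        "decisions": {
            "cutoff": config.cutoff,
            "strict_cutoff": config.strict_cutoff,
            "composition_test": "unpaired_2n",
        },
        "n_patients": int(len(labels)),
    }
    two_group = set(np.unique(labels)) == {"high", "low"}
    if two_group:
        paired = paired_crosstab(labels, resp)
        comp = composition_table(labels, resp)
        results["paired_crosstab"] = paired.to_dict()
        results["discordant_count"] = discordant_count(paired)
        results["composition_table"] = comp.to_dict()
        results["composition_chi2"] = pearson_chi2(comp).to_dict()
        results["mcnemar_paired"] = mcnemar_paired(paired).to_dict()
        if config.arm is None and merged["arm"].nunique() >= 2:
            breakdown = per_arm_breakdown(
                labels, merged["arm"].to_numpy(dtype=object), resp,
                seed=config.stage_seed("compare"),
            )
            results["per_arm"] = breakdown.to_dict()
            strata = episode_split(
                labels,
                merged["arm"].to_numpy(dtype=object),
                merged["first_episode"].to_numpy(dtype=bool),
                typical_arm_set=config.typical_arm_set,
                seed=config.stage_seed("compare"),
            )
            results["episode_split"] = {
                name: {"table": tab.to_dict(), "test": res.to_dict()}
                for name, (tab, res) in strata.items()
            }
    else:
        results["note"] = "selected model is not two-group; threshold comparison limited"
        results["responder_count"] = int(np.asarray(resp).sum())
    _write_json(results, outdir / "comparison.json")
    _write_json(_provenance("compare", config), outdir / "provenance_compare.json")
    return results


def cmd_run_all(config: RunConfig) -> dict:
    """Execute every stage in order; optionally repeat the trajectory fit
    separately per drug arm."""
    stages = [
        ("simulate", lambda: cmd_simulate(config) if config.input_csv is None else None),
        ("preprocess", lambda: cmd_preprocess(config)),
        ("cluster", lambda: cmd_cluster(config)),
        ("compare", lambda: cmd_compare(config)),
    ]
    results = None
    for name, fn in stages:
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "compare":
            results = out
    if config.per_arm_fits:
        records = _load_records(config)
        for arm_name in sorted(records["arm"].unique()):
            sub_cfg = dataclasses.replace(
                config,
                outdir=str(Path(config.outdir) / f"arm_{arm_name}"),
                input_csv=str(
                    Path(config.input_csv)
                    if config.input_csv
                    else Path(config.outdir) / "cohort.csv"
                ),
                arm=arm_name,
                per_arm_fits=False,
            )
            for fn in (cmd_preprocess, cmd_cluster, cmd_compare):
                fn(sub_cfg)
    assert results is not None
    return results


def cmd_report(outdir) -> str:
    """Render a plain-text summary of a completed bundle."""
    outdir = Path(outdir)
    needed = ["cluster_model.json", "assignments.csv", "comparison.json"]
    for name in needed:
        if not (outdir / name).exists():
            raise ConfigurationError(f"bundle incomplete: missing {name}")
    with open(outdir / "cluster_model.json") as fh:
        model = json.load(fh)
    with open(outdir / "comparison.json") as fh:
        comp = json.load(fh)
    assign = pd.read_csv(outdir / "assignments.csv")
    traj = TrajectoryMatrix.from_csv(outdir / "trajectories.csv")

    lines = []
    k = model["selected_k"]
    lines.append("Trajectory analysis report")
    lines.append("==========================")
    lines.append(f"Selected number of trajectories: k = {k}")
    best = model["candidates"][str(k)]
    lines.append(
        "Calinski-Harabasz by k: "
        + ", ".join(
            f"{kk}: {model['candidates'][kk]['ch_index']:.2f}"
            for kk in sorted(model["candidates"], key=int)
        )
    )
    n = len(assign)
    lines.append("")
    lines.append("Cluster sizes:")
    label_series = assign["label"]
    for label, cnt in label_series.value_counts().sort_index().items():
        lines.append(f"  {label}: {cnt} ({100.0 * cnt / n:.2f}%)")
    lines.append("")
    lines.append("Mean percent reduction per cluster per week:")
    df = traj.to_frame().merge(assign, on="patient_id")
    for label, grp in df.groupby("label"):
        means = ", ".join(
            f"w{w}: {grp[f'pct_w{w}'].mean():.2f}%" for w in traj.weeks
        )
        lines.append(f"  {label}: {means}")
    if "discordant_count" in comp:
        lines.append("")
        lines.append(f"Discordant patients (trajectory vs threshold): {comp['discordant_count']}")
        chi = comp["composition_chi2"]
        lines.append(
            f"Composition chi-squared: {chi['statistic']:.2f} "
            f"(df={chi['df']}, p={chi['p_value']:.3g})"
        )
        mc = comp["mcnemar_paired"]
        lines.append(
            f"McNemar (paired alternative): {mc['statistic']:.2f} (p={mc['p_value']:.3g})"
        )
    if "per_arm" in comp:
        omni = comp["per_arm"]["omnibus_trajectory"]
        lines.append(
            f"Per-drug omnibus (trajectory): {omni['statistic']:.2f} "
            f"(p={omni['p_value']:.3g})"
        )
        omni_t = comp["per_arm"]["omnibus_threshold"]
        lines.append(
            f"Per-drug omnibus (threshold): {omni_t['statistic']:.2f} "
            f"(p={omni_t['p_value']:.3g})"
        )
    if "episode_split" in comp:
        for name, block in sorted(comp["episode_split"].items()):
            t = block["test"]
            lines.append(
                f"Episode split ({name} arms): {t['statistic']:.2f} "
                f"(p={t['p_value']:.3g})"
            )
    lines.append("")
    lines.append(f"Decisions in force: {json.dumps(comp['decisions'], sort_keys=True)}")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text
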