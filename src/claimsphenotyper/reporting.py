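"""Pipeline orchestration and table rendering.

``run_pipeline`` executes generate (optional) -> build-cohorts -> match ->
outcomes -> reports from a single :class:`PipelineConfig`, writing delimited
tables, a plain-text log and a JSON run manifest stamped with the config hash
and per-stage seeds. Reruns with the same config are byte-identical: all
randomness flows from ``config.seed`` through one seed-derivation rule per
stage and no artifact embeds a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cohort_builder, matching, outcomes, synthetic_claims
from .code_catalog import load_catalog, load_fixture_catalog
from .dataset import read_dataset, write_dataset
from .errors import ClaimsPhenotyperError, ConfigurationError
from .outcomes import round_half_away

POPULATIONS = ("critically_ill_newborn", "pediatric")


def pct(numerator: float, denominator: float) -> float:
    """Exact ratio rendered as a one-decimal percent; NaN for zero denominators."""
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, 1)


def prevalence_report(counts: list[dict]) -> pd.DataFrame:
    """Prevalence table from per-group counts.

    Each entry needs population, cohort, n_case, n_control; optional
    n_excluded_from_population widens the eligible denominator (e.g. patients
    with qualifying codes but no NICU stay, moved out of the newborn
    population), and optional nicu_universe yields the share of the
    NICU-exposed population.
    """
    rows = []
    for entry in counts:
        n_case = int(entry["n_case"])
        n_control = int(entry["n_control"])
        n_extra = int(entry.get("n_excluded_from_population", 0))
        if min(n_case, n_control, n_extra) < 0:
            raise ValueError("prevalence counts must be >= 0")
        n_eligible = n_case + n_control + n_extra
        row = {"population": entry.get("population", ""),
               "cohort": entry.get("cohort", ""),
               "n_case": n_case, "n_control": n_control,
               "n_eligible": n_eligible,
               "prevalence_pct": pct(n_case, n_eligible)}
        if "nicu_universe" in entry:
            row["nicu_universe_n"] = int(entry["nicu_universe"])
            row["nicu_share_pct"] = pct(n_case, row["nicu_universe_n"])
        rows.append(row)
    return pd.DataFrame(rows)


def combined_transition_pct(possible_to_definite_pct: float,
                            probable_to_definite_pct: float) -> float:
    """Fraction moving from a possible-or-probable index to a definite primary
    diagnosis: the sum of the two component fractions (shared denominator)."""
    return round_half_away(possible_to_definite_pct + probable_to_definite_pct, 1)


class PipelineConfig(BaseModel):
    """End-to-end run configuration; see docs/methods.md for the knobs."""

    out_dir: str
    catalog: Optional[str] = None       # None -> bundled fixture catalog
    data_dir: Optional[str] = None      # None -> generate synthetic data
    seed: int = 0
    generator: dict = Field(default_factory=dict)
    cohorts: list[str] = Field(
        default_factory=lambda: ["broad", "mca_id_dd_e", "conservative"])
    populations: list[str] = Field(default_factory=lambda: list(POPULATIONS))
    n_cost_bins: int = 24
    enrollment_gap_bridge: int = 0
    nicu_gap_threshold: int = 1
    require_enrollment: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls(**(yaml.safe_load(handle) or {}))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    entropy = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(entropy.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure aborts with the stage name and cause.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(message: str) -> None:
        log_lines.append(message)

    def run_stage(name: str, func):
        try:
            result = func()
        except Exception as exc:
            raise ClaimsPhenotyperError(f"stage {name!r} failed: {exc}") from exc
        log(f"stage {name}: ok")
        return result

    # -- configuration validation happens before any computation
    if config.catalog is not None and not Path(config.catalog).exists():
        raise ConfigurationError(f"catalog path does not exist: {config.catalog}")
    if config.data_dir is not None and not Path(config.data_dir).exists():
        raise ConfigurationError(f"data directory does not exist: {config.data_dir}")
    unknown = set(config.cohorts) - set(cohort_builder.COHORTS)
    if unknown:
        raise ConfigurationError(f"unknown cohorts in config: {sorted(unknown)}")

    catalog = run_stage("load-catalog", lambda: (
        load_fixture_catalog() if config.catalog is None
        else load_catalog(config.catalog)))

    if config.data_dir is None:
        def generate():
            gen_config = synthetic_claims.GeneratorConfig(
                **{"seed": stage_seed(config.seed, "generate"), **config.generator})
            dataset, truth = synthetic_claims.generate_population(gen_config, catalog)
            data_dir = out_dir / "data"
            write_dataset(dataset, data_dir)
            truth.to_csv(data_dir / "ground_truth.csv", index=False)
            return dataset
        dataset = run_stage("generate", generate)
    else:
        dataset = run_stage("read-data", lambda: read_dataset(config.data_dir))

    def build():
        assignments, attrition = cohort_builder.assign_cohorts(
            dataset, catalog, require_enrollment=config.require_enrollment,
            gap_bridge=config.enrollment_gap_bridge)
        assignments.to_csv(out_dir / "cohorts.csv", index=False)
        attrition.to_frame().to_csv(out_dir / "attrition.csv", index=False)
        return assignments, attrition
    assignments, attrition = run_stage("build-cohorts", build)

    exclusion_counts = assignments.loc[
        assignments["population"] == "excluded", "exclusion_reason"] \
        .value_counts().to_dict()
    n_cases = int((assignments["population"].isin(POPULATIONS)).sum())
    n_controls = int((assignments["population"] == "control").sum())
    log(f"accounting: cases={n_cases} controls={n_controls} "
        f"excluded_by_reason={json.dumps(exclusion_counts, sort_keys=True)}")

    controls = cohort_builder.cohort_index_frame(assignments, "control")
    control_cov = matching.covariate_frame(controls, dataset.patients)

    match_frames, utilization_rows, transition_rows = {}, [], []
    cost_frames, demographic_frames, prevalence_counts = [], [], []
    nicu_universe = int(assignments.loc[
        assignments["population"].isin(("critically_ill_newborn", "control")),
        "has_nicu_stay"].sum())

    for population in config.populations:
        for cohort in config.cohorts:
            tag = f"{population}_{cohort}"
            cases = cohort_builder.cohort_index_frame(assignments, cohort,
                                                      population)
            prevalence_counts.append({
                "population": population, "cohort": cohort,
                "n_case": len(cases), "n_control": n_controls,
                **({"nicu_universe": nicu_universe}
                   if population == "critically_ill_newborn" else {})})
            if cases.empty or controls.empty:
                log(f"matching {tag}: skipped (empty group)")
                continue

            def match(cases=cases, population=population, tag=tag):
                scheme = matching.CoarseningScheme.default(
                    pediatric=(population == "pediatric"))
                case_cov = matching.covariate_frame(cases, dataset.patients)
                result = matching.cem_match_k2k(
                    case_cov, control_cov, scheme,
                    seed=stage_seed(config.seed, f"match-{tag}"))
                result.to_frame().to_csv(out_dir / f"matches_{tag}.csv",
                                         index=False)
                log(f"matching {tag}: pairs={result.n_pairs} "
                    f"pruned={len(result.pruned_cases)} "
                    f"pre_l1={result.pre_l1:.4f} post_l1={result.post_l1}")
                return result
            match_result = run_stage(f"match-{tag}", match)
            match_frames[tag] = match_result

            def compute_outcomes(cases=cases, match_result=match_result,
                                 population=population, cohort=cohort, tag=tag):
                summary = outcomes.utilization_summary(cases, dataset, catalog)
                utilization_rows.append({"population": population,
                                         "cohort": cohort, **summary.to_dict()})
                transitions = outcomes.diagnostic_transitions(cases, dataset,
                                                              catalog)
                transition_rows.append({"population": population,
                                        "cohort": cohort,
                                        **transitions.to_dict()})
                matched_controls = controls[controls["patient_id"].isin(
                    [c for _, c in match_result.pairs])]
                for group, frame in (("case", cases),
                                     ("matched_control", matched_controls)):
                    series = outcomes.cost_accrual_30d(frame, dataset,
                                                       config.n_cost_bins)
                    table = series.table.copy()
                    table.insert(0, "group", group)
                    table.insert(0, "cohort", cohort)
                    table.insert(0, "population", population)
                    cost_frames.append(table)
                if len(cases) >= 2 and len(matched_controls) >= 2:
                    case_cov = matching.covariate_frame(cases, dataset.patients)
                    ctrl_cov = matching.covariate_frame(matched_controls,
                                                        dataset.patients)
                    demo = outcomes.compare_demographics(
                        case_cov, ctrl_cov,
                        continuous=("age_years",),
                        binary={"male": ("sex", "M"),
                                "white": ("race_ethnicity", "white")})
                    demo.insert(0, "cohort", cohort)
                    demo.insert(0, "population", population)
                    demographic_frames.append(demo)
            run_stage(f"outcomes-{tag}", compute_outcomes)

    def report():
        prevalence_report(prevalence_counts).to_csv(out_dir / "prevalence.csv",
                                                    index=False)
        if utilization_rows:
            pd.DataFrame(utilization_rows).to_csv(out_dir / "utilization.csv",
                                                  index=False)
        if transition_rows:
            pd.DataFrame(transition_rows).to_csv(out_dir / "transitions.csv",
                                                 index=False)
        if cost_frames:
            pd.concat(cost_frames, ignore_index=True).to_csv(
                out_dir / "cost_bins.csv", index=False)
        if demographic_frames:
            pd.concat(demographic_frames, ignore_index=True).to_csv(
                out_dir / "demographics.csv", index=False)
    run_stage("report", report)

    manifest = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "stage_seeds": {name: stage_seed(config.seed, name)
                        for name in ["generate"]
                        + [f"match-{p}_{c}" for p in config.populations
                           for c in config.cohorts]},
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir


def plot_cost_curves(cost_bins: pd.DataFrame, path: str | Path) -> None:
    """Simple per-cohort monthly cost curves (cases vs matched controls)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    populations = sorted(cost_bins["population"].unique())
    fig, axes = plt.subplots(1, max(len(populations), 1),
                             figsize=(6 * max(len(populations), 1), 4),
                             squeeze=False)
    for ax, population in zip(axes[0], populations):
        subset = cost_bins[cost_bins["population"] == population]
        for (cohort, group), frame in subset.groupby(["cohort", "group"]):
            style = "-" if group == "case" else "--"
            ax.plot(frame["bin"], frame["total_mean"], style,
                    label=f"{cohort} ({group})")
        ax.set_title(population)
        ax.set_xlabel("30-day bin from index")
        ax.set_ylabel("mean allowed cost per enrolled patient")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
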