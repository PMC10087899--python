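"""End-to-end orchestration: generate -> preprocess -> descriptives ->
ISM / CoDA / LPA -> report bundle, driven by one configuration with full
seed control.

Every run writes CSV tables, figures, an exclusion log, and a JSON manifest
recording the seed and the stages executed, so a run is reproducible
byte-for-byte from config + seed (timestamps live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coda, composition, ism, lpa, preprocess, synthetic
from .composition import PARTS, PivotBasis, pivot_ilr_matrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age_group", "female", "white", "bmi", "education",
                      "cesd", "good_health"]


@dataclass
class RunConfig:
    """One pipeline run: where data come from, which methods run, seeds."""

    input_mode: str = "synthetic"          # synthetic | csv
    daily_csv: str | None = None
    persons_csv: str | None = None
    cohort: synthetic.CohortConfig = field(
        default_factory=synthetic.CohortConfig)
    covariates: list[str] = field(
        default_factory=lambda: list(DEFAULT_COVARIATES))
    outcome: str = "outcome"
    run_ism: bool = True
    run_coda: bool = True
    run_lpa: bool = True
    delta_minutes: float = 30.0
    lpa_k_range: tuple[int, ...] = (2, 3, 4, 5)
    lpa_k_final: int = 4
    lpa_n_starts: int = 40
    lpa_bootstrap_reps: int = 0            # 0 disables the bootstrap LRT
    zero_strategy: str = "fail"
    ci_level: float = 0.95
    seed: int = 0
    outdir: str = "hac24_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = raw.pop("cohort", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "cohort"})
        if cohort:
            cfg.cohort = synthetic.config_from_dict(cohort)
        if "lpa_k_range" in raw:
            cfg.lpa_k_range = tuple(raw["lpa_k_range"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cohort"] = synthetic.config_to_dict(self.cohort)
        d["lpa_k_range"] = list(self.lpa_k_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def run_descriptives(person_table: pd.DataFrame,
                     by: str | None = None,
                     james_seed: int = 0) -> dict:
    """Cohort descriptive summary plus compositional statistics.

    Returns a dict with a univariate summary table, total-time median [IQR],
    the compositional mean and variation matrix (overall and, when `by` is
    given, per subgroup with a James test on the ilr coordinates).
    """
    out: dict = {}
    rows = []
    for col in person_table.columns:
        if col in ("person_id",):
            continue
        s = person_table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or \
                s.dropna().isin([0, 1]).all():
            for level, cnt in s.value_counts(dropna=False).items():
                rows.append((col, str(level), int(cnt),
                             100.0 * cnt / len(s), np.nan, np.nan))
        else:
            sd = float(s.std()) if s.notna().sum() > 1 else np.nan
            rows.append((col, "", int(s.notna().sum()), np.nan,
                         float(s.mean()), sd))
    out["summary"] = pd.DataFrame(
        rows, columns=["variable", "level", "n", "percent", "mean", "sd"])

    if "day_length_minutes" in person_table:
        t = person_table["day_length_minutes"]
        out["total_time"] = {"median": float(t.median()),
                             "iqr": [float(t.quantile(0.25)),
                                     float(t.quantile(0.75))]}
    X = person_table[list(PARTS)].to_numpy(dtype=float)
    if np.all(X > 0):
        comps = X / X.sum(axis=1, keepdims=True)
        out["compositional_mean"] = composition.compositional_mean(
            comps, labels=PARTS).as_dict()
        if len(comps) >= 2:
            out["variation_matrix"] = pd.DataFrame(
                composition.variation_matrix(comps), index=PARTS,
                columns=PARTS)
        if by is not None:
            groups = {}
            basis = PivotBasis.for_pivot("sit")
            ilr_groups = []
            for level, sub in person_table.groupby(by, observed=True):
                Xi = sub[list(PARTS)].to_numpy(dtype=float)
                ci = Xi / Xi.sum(axis=1, keepdims=True)
                groups[str(level)] = composition.compositional_mean(
                    ci, labels=PARTS).as_dict()
                ilr_groups.append(pivot_ilr_matrix(ci, basis))
            out["compositional_mean_by"] = groups
            if len(ilr_groups) >= 2 and all(g.shape[0] > 3 for g in ilr_groups):
                stat, p = composition.james_test(ilr_groups, seed=james_seed)
                out["james_test"] = {"statistic": stat, "p_value": p}
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages and write the report bundle to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {},
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    results: dict = {}

    def run_stage(name, fn):
        try:
            t0 = time.perf_counter()
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3)}
        except Exception as err:
            manifest["stages"][name] = {"status": "failed",
                                        "error": str(err)}
            _write_manifest(outdir, manifest)
            raise RuntimeError(f"stage {name!r} failed: {err}") from err

    # ---- data -------------------------------------------------------------
    def _data():
        if config.input_mode == "synthetic":
            cohort = dataclasses.replace(config.cohort, seed=config.seed)
            daily, persons, classes, truth = synthetic.generate_cohort(cohort)
            results["truth"] = truth
        elif config.input_mode == "csv":
            daily = pd.read_csv(config.daily_csv)
            persons = pd.read_csv(config.persons_csv)
        else:
            raise ValueError(f"unknown input_mode {config.input_mode!r}")
        flags = preprocess.flag_valid_days(daily)
        table = preprocess.aggregate_persons(daily, flags, persons)
        n_dropped = persons["person_id"].nunique() - len(table)
        with open(outdir / "exclusions.log", "w") as fh:
            fh.write(f"persons dropped for < {preprocess.MIN_VALID_DAYS} "
                     f"valid days: {n_dropped}\n")
            fh.write(f"analysis persons: {len(table)}\n")
        if (table[list(PARTS)].to_numpy() == 0).any():
            table = preprocess.impute_zeros(table, config.zero_strategy)
        results["person_table"] = table

    run_stage("data", _data)
    table = results["person_table"]

    def _desc():
        desc = run_descriptives(table, james_seed=config.seed)
        desc["summary"].to_csv(outdir / "table1_summary.csv", index=False)
        if "variation_matrix" in desc:
            desc["variation_matrix"].to_csv(outdir / "variation_matrix.csv")
        results["descriptives"] = desc
        composition.ternary_plot(
            table[list(PARTS)].to_numpy(dtype=float) /
            table[list(PARTS)].to_numpy(dtype=float).sum(axis=1, keepdims=True),
            labels=PARTS, color=table[config.outcome].to_numpy(),
            path=str(outdir / "fig1_ternary.png"))

    run_stage("descriptives", _desc)

    if config.run_ism:
        def _ism():
            fits = ism.fit_all_isms(table, config.covariates,
                                    outcome=config.outcome)
            tab = ism.substitution_table(fits, config.delta_minutes,
                                         ci_level=config.ci_level)
            tab.to_frame().to_csv(outdir / "table2_ism.csv", index=False)
            results["ism_table"] = tab

        run_stage("ism", _ism)

    if config.run_coda:
        def _coda():
            fits = coda.fit_all_pivots(table, config.covariates,
                                       outcome=config.outcome)
            summary = coda.pivot_summary(fits, ci_level=config.ci_level)
            summary.to_csv(outdir / "table3_coda.csv", index=False)
            results["coda_summary"] = summary
            results["coda_fits"] = fits
            curves = {p: coda.one_vs_remaining_curve(fits[p],
                                                     ci_level=config.ci_level)
                      for p in PARTS}
            coda.plot_curves(curves, path=str(outdir / "fig2_one_vs_rest.png"))
            pair_curves = {}
            ref = fits[PARTS[0]]
            for a in PARTS:
                for b in PARTS:
                    if a != b:
                        pair_curves[f"{a} -> {b}"] = coda.pairwise_curve(
                            ref, a, b, ci_level=config.ci_level)
            coda.plot_curves(pair_curves,
                             path=str(outdir / "fig3_pairwise.png"), ncols=4)
            pd.concat([cv.to_frame().assign(reallocation=k)
                       for k, cv in pair_curves.items()]) \
                .to_csv(outdir / "coda_pairwise_curves.csv", index=False)
            results["coda_pairwise"] = pair_curves

        run_stage("coda", _coda)

    if config.run_lpa:
        def _lpa():
            indicators = table[["sit", "stand", "step"]]
            fits = {k: lpa.fit_lpa(indicators, k,
                                   n_starts=config.lpa_n_starts,
                                   seed=config.seed)
                    for k in config.lpa_k_range}
            sel = lpa.selection_table(fits)
            sel.to_csv(outdir / "lpa_model_selection.csv", index=False)
            final = fits[config.lpa_k_final]
            assign = lpa.modal_assign(final)
            D = lpa.classification_matrix(final, assign)
            pd.DataFrame(D).to_csv(outdir / "lpa_classification_matrix.csv",
                                   index=False)
            if config.lpa_bootstrap_reps:
                blrt = lpa.bootstrap_lrt(indicators, config.lpa_k_final,
                                         reps=config.lpa_bootstrap_reps,
                                         seed=config.seed,
                                         n_starts=max(2, config.lpa_n_starts // 10))
                manifest["stages"].setdefault("lpa_extras", {})[
                    "bootstrap_lrt_p"] = blrt["p_value"]
            desc4 = table.assign(profile=assign + 1) \
                .groupby("profile")[list(PARTS) + [config.outcome]] \
                .agg(["median", "mean", "std"])
            desc4.to_csv(outdir / "table4_profiles.csv")
            y = table[config.outcome].to_numpy()
            ref = int(np.argmax(final.weights))   # largest profile as reference
            naive = lpa.distal_naive(assign, y, table, config.covariates,
                                     K=final.K, reference=ref)
            bch = lpa.distal_bch(final, assign, D, y, table, config.covariates,
                                 reference=ref)
            comparison = pd.concat([
                naive.summary().add_prefix("naive_"),
                bch.summary().add_prefix("bch_")], axis=1)
            comparison.to_csv(outdir / "table5_distal.csv")
            lpa.profile_boxplot(table[list(PARTS)], assign,
                                path=str(outdir / "fig4_profiles.png"))
            results.update(lpa_fits=fits, lpa_final=final, lpa_assign=assign,
                           lpa_D=D, distal_naive=naive, distal_bch=bch)

        run_stage("lpa", _lpa)

    if config.run_ism and config.run_coda:
        def _compare():
            comp_rows = []
            baseline = results["coda_fits"][PARTS[0]].baseline
            for a in PARTS:
                for b in PARTS:
                    if a == b:
                        continue
                    ism_est = results["ism_table"].estimate.loc[a, b]
                    cv = results["coda_pairwise"][f"{a} -> {b}"]
                    k = int(np.argmin(np.abs(cv.delta_minutes
                                             - config.delta_minutes)))
                    comp_rows.append((a, b, float(ism_est),
                                      float(cv.estimate[k])))
            cmp_df = pd.DataFrame(comp_rows, columns=[
                "from", "to", "ism_estimate", "coda_estimate"])
            cmp_df.to_csv(outdir / "comparison_ism_coda.csv", index=False)
            results["comparison"] = cmp_df

        run_stage("comparison", _compare)

    for name, enabled in (("ism", config.run_ism), ("coda", config.run_coda),
                          ("lpa", config.run_lpa)):
        if not enabled:
            manifest["stages"][name] = {"status": "skipped"}
    _write_manifest(outdir, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
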