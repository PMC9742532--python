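"""Cohort file I/O, structured logging, and the end-to-end pipeline.

Cohort tables travel as plain CSV with a documented header (see
:data:`MANDATORY_COLUMNS`); unknown columns are preserved and lab columns
bind late — a table without ``fpg`` loads fine and only fails when a
cascade actually needs it. Numeric round-trips are value-exact because
floats are written with shortest-roundtrip repr.

``run_pipeline`` executes the whole study on synthetic data: generate a
calibrated cohort, split 60/40 into development and testing sets, inject
and impute missingness, streamline a boosted-tree classifier to its
top-k features, run the screening cascades against a questionnaire
score, and write the per-strategy economics and matched comparisons,
together with a manifest recording seeds and a config hash so any run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cascade import CascadeSpec, DiagnosticThresholds, run_cascade, tally
from .economics import CostSchedule, summarize
from .metrics import compare_at_matched, confusion_metrics, roc
from .riskmodels import impute, load_score_table, streamline
from .synthpop import default_config, inject_missingness, sample_population, split_dev_test

__all__ = [
    "MANDATORY_COLUMNS",
    "PopulationIOError",
    "read_population",
    "write_population",
    "log_event",
    "RunConfig",
    "run_pipeline",
    "descriptive_table",
]

#: columns every population CSV must carry
MANDATORY_COLUMNS = ("person_id",)

#: columns parsed as numeric when present
NUMERIC_COLUMNS = ("age", "rpr", "sbp", "dbp", "weight", "height", "wc", "hc",
                   "bmi", "whr", "whtr", "sleep_duration", "cellphone_years",
                   "fpg", "p2hpg", "hba1c")

log = logging.getLogger("dmscreen")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter(
        "%(asctime)s | %(levelname)s | %(name)s | %(stage)s | %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class PopulationIOError(ValueError):
    pass


def log_event(level: str, stage: str, message: str) -> None:
    """Structured log line: timestamp | level | run id | stage | message."""
    log.log(getattr(logging, level.upper()), message, extra={"stage": stage})


def read_population(path: str | Path) -> pd.DataFrame:
    """Load a cohort CSV; validates mandatory columns and numeric parsing."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise PopulationIOError(f"{path}: missing mandatory columns {missing}")
    bad_rows: dict[str, list[int]] = {}
    for col in NUMERIC_COLUMNS:
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            newly_bad = coerced.isna() & df[col].notna()
            if newly_bad.any():
                bad_rows[col] = list(np.flatnonzero(newly_bad)[:10])
            df[col] = coerced
    if bad_rows:
        raise PopulationIOError(
            f"{path}: malformed numeric values (column -> first bad rows): {bad_rows}")
    if "dm_status" in df.columns:
        df["dm_status"] = df["dm_status"].astype(bool)
    return df


def write_population(pop: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV; floats use shortest-roundtrip repr (lossless)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in pop.columns]
    if missing:
        raise PopulationIOError(f"refusing to write table without {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # shortest-roundtrip float repr keeps numeric round-trips value-exact
    pop.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def descriptive_table(pop: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) by diabetes status for numeric features, n (%) for
    categoricals, with Kruskal–Wallis / chi-square group comparisons."""
    if "dm_status" not in pop.columns:
        raise PopulationIOError("descriptive table needs a dm_status column")
    dm = pop[pop["dm_status"]]
    non = pop[~pop["dm_status"]]
    rows = []
    for col in pop.columns:
        if col in ("person_id", "dm_status", "subtype"):
            continue
        if pd.api.types.is_numeric_dtype(pop[col]):
            stat, p = stats.kruskal(non[col].dropna(), dm[col].dropna())
            rows.append({
                "feature": col, "kind": "continuous",
                "non_dm": f"{non[col].median():.2f} "
                          f"({non[col].quantile(.25):.2f}-{non[col].quantile(.75):.2f})",
                "dm": f"{dm[col].median():.2f} "
                      f"({dm[col].quantile(.25):.2f}-{dm[col].quantile(.75):.2f})",
                "p_value": float(p),
            })
        else:
            tab = pd.crosstab(pop[col], pop["dm_status"])
            p = stats.chi2_contingency(tab)[1] if tab.shape[0] > 1 else np.nan
            rows.append({
                "feature": col, "kind": "categorical",
                "non_dm": "; ".join(f"{k}: {v} ({100 * v / len(non):.1f}%)"
                                    for k, v in tab[False].items()),
                "dm": "; ".join(f"{k}: {v} ({100 * v / len(dm):.1f}%)"
                                for k, v in tab[True].items()),
                "p_value": float(p),
            })
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything one end-to-end synthetic run depends on."""

    n_participants: int = 8425
    seed: int = 20221128
    dev_fraction: float = 0.6
    missingness_rate: float = 0.05
    learner_kind: str = "GRADIENT_BOOSTED_TREES"
    ks: tuple[int, ...] = (5, 10, 15, 20, 25)
    streamline_tolerance: float = 0.005
    score_table: str = "ncdrs_placeholder"
    horizons: tuple[int, ...] = (5, 10, 15, 20, 25)
    matched_sensitivity: float = 0.72
    output_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise PopulationIOError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ks", "horizons"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Generate → split → impute → streamline → cascades → economics → compare.

    Writes a manifest, the descriptive summary, the streamlining table,
    per-strategy economic summaries and matched-comparison tables under
    ``config.output_dir``; returns the same artefacts in memory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_event("INFO", "start", f"seed={config.seed} config_hash={config.config_hash()}")

    gen = default_config(n_participants=config.n_participants, seed=config.seed)
    pop = sample_population(gen)
    if config.missingness_rate > 0:
        pop = inject_missingness(pop, config.missingness_rate, seed=config.seed + 1)
    write_population(pop, out / "cohort.csv")
    log_event("INFO", "simulate", f"cohort n={len(pop)} "
              f"prevalence={pop['dm_status'].mean():.4f}")

    dev, test = split_dev_test(pop, config.dev_fraction, seed=config.seed + 2)
    dev, test = impute(dev, test, seed=config.seed + 3)
    log_event("INFO", "split", f"dev={len(dev)} test={len(test)}")

    desc = descriptive_table(pop.dropna(subset=[c for c in NUMERIC_COLUMNS
                                                if c in pop.columns]))
    desc.to_csv(out / "descriptive_table.csv", index=False)

    chosen_k, model, ktable = streamline(
        dev, learner_kind=config.learner_kind, ks=config.ks,
        tolerance=config.streamline_tolerance, seed=config.seed + 4)
    ktable.to_csv(out / "streamline.csv", index=False)
    log_event("INFO", "train", f"chosen k={chosen_k} features={model.feature_list}")

    table = load_score_table(config.score_table)
    scores = model.predict_risk(test)
    labels = test["dm_status"].to_numpy(dtype=bool)
    curve = roc(scores, labels, n_boot=500, seed=config.seed + 5)
    log_event("INFO", "evaluate", f"test AUC={curve.auc:.3f} auPR={curve.aupr:.3f}")

    schedule = CostSchedule.default()
    thr = DiagnosticThresholds()
    from .metrics import threshold_for_sensitivity
    cut = threshold_for_sensitivity(scores, labels, config.matched_sensitivity)
    strategies = {
        "ml": CascadeSpec("ml", model, decision_threshold=cut),
        "score_table": CascadeSpec("score_table", table),
        "ml+fpg": CascadeSpec("ml+fpg", model, screening_lab="FPG",
                              decision_threshold=cut),
        "ml+p2hpg": CascadeSpec("ml+p2hpg", model, screening_lab="P2HPG",
                                decision_threshold=cut),
        "ml+hba1c": CascadeSpec("ml+hba1c", model, screening_lab="HBA1C",
                                decision_threshold=cut),
    }
    econ_rows = []
    for name, spec in strategies.items():
        records = run_cascade(test, spec, thr)
        counts = tally(records)
        cm = confusion_metrics(counts)
        summ = summarize(records, schedule, config.horizons)
        row = {"strategy": name, "n": summ.n,
               "sensitivity": cm.sensitivity, "specificity": cm.specificity,
               "prop_confirmatory": summ.prop_confirmatory,
               "avg_detection_cost": summ.avg_detection_cost,
               "fn_count": summ.fn_count}
        for h, (lo, hi) in summ.complication_cost_range.items():
            row[f"complication_low_{h}y"] = lo
            row[f"complication_high_{h}y"] = hi
        econ_rows.append(row)
    econ = pd.DataFrame(econ_rows)
    econ.to_csv(out / "economics.csv", index=False)

    comparison = compare_at_matched(
        test, strategies["score_table"], strategies["ml"], schedule,
        match="SENSITIVITY", horizons=(15,), thresholds=thr)
    comparison.table.to_csv(out / "matched_comparison.csv", index=False)
    comparison.reductions.to_csv(out / "matched_reductions.csv", index=False)
    for name, c in comparison.curves.items():
        c.to_csv(out / f"curve_{name}.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": {**config.__dict__},
        "config_hash": config.config_hash(),
        "n_dev": len(dev), "n_test": len(test),
        "chosen_k": chosen_k,
        "test_auc": curve.auc, "test_aupr": curve.aupr,
        "auc_ci95": list(curve.ci95.get("auc", ())),
        "delong_vs_score_table": list(comparison.delong or ()),
        "elapsed_s": round(time.time() - t0, 2),
    }
    _write_json(out / "manifest.json", manifest)
    log_event("INFO", "done", f"outputs in {out}")
    return {"population": pop, "dev": dev, "test": test, "model": model,
            "chosen_k": chosen_k, "streamline_table": ktable, "economics": econ,
            "comparison": comparison, "manifest": manifest, "descriptive": desc}
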