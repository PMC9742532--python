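"""Seeded synthetic cohort generator for the screening analyses.

The generator emulates a middle-aged community cohort of the kind used to
evaluate diabetes screening strategies in China: ~12% undiagnosed
diabetes prevalence, marked discordance between fasting and post-load
glucose (about 41% of diabetics have seemingly normal FPG, 28% a
seemingly normal 2hPG, and only 31% have both analytes in the diagnostic
range), and modest shifts of anthropometric and lifestyle features
between diabetic and non-diabetic strata.

Model
-----
One standard-normal latent risk ``z`` per person drives everything:

* each continuous feature is ``median + loading * z + noise``, with the
  noise SD derived from the feature's interquartile range (IQR / 1.349);
* log FPG and log 2hPG are bivariate normal conditional on ``z``: each
  log-analyte carries a ``z`` loading plus a correlated residual, so the
  marginal pair is bivariate lognormal with a closed-form correlation;
* HbA1c is linear in the two glucose values plus Gaussian noise,
  truncated below at 3.5%;
* categorical features are generated by thresholding a normal latent
  (partially loaded on ``z``) at the quantiles of the category
  frequencies, so weak associations with risk are possible;
* diabetes status and glycemic subtype are *derived* from the generated
  glucose pair via the diagnostic rule, never sampled directly.

Because the marginal log-glucose pair is bivariate normal, the generator
can be calibrated analytically: the two diagnostic-threshold margins fix
the log-scale SDs through probit quantiles, and the target prevalence
fixes the total correlation through the bivariate normal CDF
(:func:`calibrate_generator`).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .cascade import DiagnosticThresholds, diagnose, subtype

__all__ = [
    "GeneratorConfig",
    "GlucoseModel",
    "HbA1cModel",
    "ConfigError",
    "CalibrationError",
    "default_config",
    "sample_population",
    "calibrate_generator",
    "inject_missingness",
    "split_dev_test",
]

#: scale factor between an IQR and the SD of a normal distribution
IQR_TO_SD = 2.0 * norm.ppf(0.75)  # ~1.349

#: columns that are never masked by inject_missingness and never imputed
PROTECTED_COLUMNS = ("person_id", "fpg", "p2hpg", "hba1c", "dm_status", "subtype")


class ConfigError(ValueError):
    """A generator configuration field violates its invariants."""


class CalibrationError(RuntimeError):
    """Calibration could not reach the requested population targets."""


@dataclass
class GlucoseModel:
    """Marginal bivariate-lognormal model of (FPG, 2hPG) with a shared latent.

    ``log_median_*`` and ``log_sd_*`` are the marginal log-scale location
    and scale; ``z_share_*`` is the correlation between the log-analyte
    and the latent risk z (the z loading is ``z_share * log_sd``);
    ``residual_rho`` is the correlation of the residuals after removing z.
    """

    log_median_fpg: float
    log_median_p2hpg: float
    log_sd_fpg: float
    log_sd_p2hpg: float
    z_share_fpg: float = 0.6
    z_share_p2hpg: float = 0.6
    residual_rho: float = 0.0

    @property
    def total_rho(self) -> float:
        """Marginal correlation of (log FPG, log 2hPG)."""
        a = self.z_share_fpg * self.z_share_p2hpg
        return a + self.residual_rho * math.sqrt(
            (1 - self.z_share_fpg**2) * (1 - self.z_share_p2hpg**2))

    def validate(self) -> None:
        if self.log_sd_fpg <= 0 or self.log_sd_p2hpg <= 0:
            raise ConfigError("glucose_model: log-scale SDs must be > 0")
        for name in ("z_share_fpg", "z_share_p2hpg", "residual_rho"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigError(f"glucose_model.{name} must lie in (-1, 1), got {v}")


@dataclass
class HbA1cModel:
    """HbA1c (%) as a linear function of the two glucose values plus noise."""

    intercept: float = 4.27
    slope_fpg: float = 0.15
    slope_p2hpg: float = 0.055
    noise_sd: float = 0.30
    floor: float = 3.5

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("hba1c_model.noise_sd must be > 0")


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort draw."""

    n_participants: int
    seed: int
    target_prevalence: float
    #: (isolated_postload, isolated_fasting, combined) fractions among diabetics
    target_subtype_fractions: tuple[float, float, float]
    #: feature -> (median, IQR) in natural units
    feature_baselines: dict[str, tuple[float, float]]
    #: feature -> shift per SD of latent risk, natural units
    latent_loading_per_feature: dict[str, float]
    glucose_model: GlucoseModel
    hba1c_model: HbA1cModel = field(default_factory=HbA1cModel)
    #: feature -> (category labels, frequencies, z coefficient of the latent)
    categorical_features: dict[str, tuple[tuple[str, ...], tuple[float, ...], float]] = field(
        default_factory=dict)
    missingness_rate: float = 0.0
    thresholds: DiagnosticThresholds = field(default_factory=DiagnosticThresholds)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence must lie in (0, 1)")
        fr = self.target_subtype_fractions
        if len(fr) != 3 or any(f < 0 for f in fr):
            raise ConfigError("target_subtype_fractions must be three non-negative proportions")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigError(
                f"target_subtype_fractions must sum to 1 (got {sum(fr):.12f})")
        if not 0.0 <= self.missingness_rate < 0.2:
            raise ConfigError("missingness_rate must lie in [0, 0.2): features with "
                              "20% or more missing data are excluded, not imputed")
        for feat, (med, iqr) in self.feature_baselines.items():
            if iqr <= 0:
                raise ConfigError(f"feature_baselines[{feat!r}]: IQR must be > 0")
        for feat in self.latent_loading_per_feature:
            if feat not in self.feature_baselines:
                raise ConfigError(f"latent loading given for unknown feature {feat!r}")
        for feat, (cats, probs, _) in self.categorical_features.items():
            if len(cats) != len(probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"categorical_features[{feat!r}]: frequencies must "
                                  "match categories and sum to 1")
        self.glucose_model.validate()
        self.hba1c_model.validate()


# Baselines: medians and IQRs of a middle-aged, predominantly female
# community cohort; loadings are per-SD-of-latent shifts sized so the
# diabetic/non-diabetic contrasts match the typical reported gaps
# (diabetics ~3 y older, ~6 bpm higher resting pulse, ~7 mmHg higher SBP,
# slightly heavier and more centrally obese; height unshifted).
_CONTINUOUS_BASELINES: dict[str, tuple[float, float]] = {
    "age": (54.0, 13.0),
    "rpr": (80.0, 15.7),
    "sbp": (135.0, 28.2),
    "dbp": (79.0, 16.0),
    "weight": (57.0, 12.3),
    "height": (1.56, 0.10),
    "wc": (78.0, 12.0),
    "hc": (90.0, 9.0),
    "sleep_duration": (7.5, 2.0),
    "cellphone_years": (8.0, 6.0),
}

_CONTINUOUS_LOADINGS: dict[str, float] = {
    "age": 2.6,
    "rpr": 5.1,
    "sbp": 6.0,
    "dbp": 2.8,
    "weight": 1.7,
    "height": 0.0,
    "wc": 2.4,
    "hc": 0.9,
    "sleep_duration": -0.15,
    "cellphone_years": 0.4,
}

#: strictly positive floors applied after the linear-Gaussian draw
_FEATURE_FLOOR: dict[str, float] = {
    "age": 18.0, "rpr": 35.0, "sbp": 70.0, "dbp": 40.0, "weight": 30.0,
    "height": 1.30, "wc": 50.0, "hc": 60.0, "sleep_duration": 2.0,
    "cellphone_years": 0.0,
}

_CATEGORICAL_FEATURES: dict[str, tuple[tuple[str, ...], tuple[float, ...], float]] = {
    "sex": (("male", "female"), (0.355, 0.645), 0.0),
    "smoke": (("current", "past", "never"), (0.192, 0.042, 0.766), 0.0),
    "drink": (("current", "past", "never"), (0.129, 0.024, 0.847), -0.05),
    "physical_activity": (("active", "inactive"), (0.099, 0.901), -0.08),
    "work_status": (("employed", "retired", "other"), (0.45, 0.40, 0.15), 0.03),
    "education": (("primary", "secondary", "tertiary"), (0.40, 0.45, 0.15), -0.02),
}


def default_config(n_participants: int = 8425, seed: int = 20221128,
                   missingness_rate: float = 0.0) -> GeneratorConfig:
    """The shipped default cohort: calibrated to 12.4% prevalence and
    41/28/31% glycemic subtype fractions among diabetics."""
    cfg = GeneratorConfig(
        n_participants=n_participants,
        seed=seed,
        target_prevalence=0.124,
        target_subtype_fractions=(0.41, 0.28, 0.31),
        feature_baselines=dict(_CONTINUOUS_BASELINES),
        latent_loading_per_feature=dict(_CONTINUOUS_LOADINGS),
        glucose_model=GlucoseModel(
            log_median_fpg=math.log(5.7), log_median_p2hpg=math.log(6.9),
            log_sd_fpg=0.14, log_sd_p2hpg=0.35),
        categorical_features=dict(_CATEGORICAL_FEATURES),
        missingness_rate=missingness_rate,
    )
    return calibrate_generator(cfg, verify=False)


def _draw_categorical(rng: np.random.Generator, z: np.ndarray,
                      cats: tuple[str, ...], probs: tuple[float, ...],
                      z_coef: float) -> np.ndarray:
    """Ordinal-latent draw: threshold a unit normal (partially z) at the
    normal quantiles of the cumulative category frequencies."""
    resid = math.sqrt(max(1.0 - z_coef**2, 0.0))
    latent = z_coef * z + resid * rng.standard_normal(len(z))
    edges = norm.ppf(np.cumsum(probs)[:-1])
    idx = np.searchsorted(edges, latent)
    return np.asarray(cats, dtype=object)[idx]


def sample_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one cohort. Same config (incl. seed) gives a bit-identical table."""
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {"person_id": np.arange(n, dtype=np.int64)}

    z = rng.standard_normal(n)
    for feat in sorted(config.feature_baselines):
        med, iqr = config.feature_baselines[feat]
        loading = config.latent_loading_per_feature.get(feat, 0.0)
        vals = med + loading * z + rng.normal(0.0, iqr / IQR_TO_SD, size=n)
        floor = _FEATURE_FLOOR.get(feat)
        if floor is not None:
            vals = np.maximum(vals, floor)
        cols[feat] = vals

    for feat in sorted(config.categorical_features):
        cats, probs, z_coef = config.categorical_features[feat]
        cols[feat] = _draw_categorical(rng, z, cats, probs, z_coef)

    g = config.glucose_model
    e1 = rng.standard_normal(n)
    e2 = g.residual_rho * e1 + math.sqrt(1.0 - g.residual_rho**2) * rng.standard_normal(n)
    log_fpg = (g.log_median_fpg + g.log_sd_fpg *
               (g.z_share_fpg * z + math.sqrt(1 - g.z_share_fpg**2) * e1))
    log_p2hpg = (g.log_median_p2hpg + g.log_sd_p2hpg *
                 (g.z_share_p2hpg * z + math.sqrt(1 - g.z_share_p2hpg**2) * e2))
    fpg = np.exp(log_fpg)
    p2hpg = np.exp(log_p2hpg)
    cols["fpg"] = fpg
    cols["p2hpg"] = p2hpg

    h = config.hba1c_model
    hba1c = (h.intercept + h.slope_fpg * fpg + h.slope_p2hpg * p2hpg
             + rng.normal(0.0, h.noise_sd, size=n))
    cols["hba1c"] = np.maximum(hba1c, h.floor)

    pop = pd.DataFrame(cols)
    # anthropometric identities hold row-wise by construction
    if {"weight", "height"} <= set(pop.columns):
        pop["bmi"] = pop["weight"] / pop["height"] ** 2
    if {"wc", "hc"} <= set(pop.columns):
        pop["whr"] = pop["wc"] / pop["hc"]
    if {"wc", "height"} <= set(pop.columns):
        pop["whtr"] = pop["wc"] / (pop["height"] * 100.0)

    if n == 0:
        pop["dm_status"] = np.array([], dtype=bool)
        pop["subtype"] = np.array([], dtype=object)
    else:
        pop["dm_status"] = diagnose(fpg, p2hpg, config.thresholds)
        pop["subtype"] = subtype(fpg, p2hpg, config.thresholds)

    if config.missingness_rate > 0 and n > 0:
        pop = inject_missingness(pop, config.missingness_rate,
                                 seed=int(rng.integers(2**31)))
    return pop


def calibrate_generator(config: GeneratorConfig,
                        targets: dict | None = None,
                        n_calibration: int = 50_000,
                        seed: int = 0,
                        verify: bool = True,
                        prevalence_tol: float = 0.01,
                        subtype_tol: float = 0.03) -> GeneratorConfig:
    """Tune the glucose model so the cohort hits prevalence and subtype targets.

    The marginal (log FPG, log 2hPG) pair is bivariate normal, so the
    targets determine the model in closed form: the probability of each
    analyte being below its diagnostic threshold fixes that analyte's
    log-scale SD through a probit quantile (holding the log-median at its
    configured value), and the joint probability of both being below —
    one minus the prevalence — fixes the total correlation through a
    root-find on the bivariate normal CDF. The residual correlation after
    removing the latent-risk share follows algebraically.

    When ``verify`` is true, a cohort of ``n_calibration`` is sampled with
    ``seed`` and the realized prevalence / subtype fractions are checked
    against the targets (±``prevalence_tol`` / ±``subtype_tol`` absolute);
    failure raises :class:`CalibrationError` reporting achieved vs target.
    """
    config.validate()
    targets = targets or {}
    prev = float(targets.get("prevalence", config.target_prevalence))
    fr = tuple(targets.get("subtype_fractions", config.target_subtype_fractions))
    if not 0.0 < prev < 1.0:
        raise ConfigError("target prevalence must lie in (0, 1)")
    if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9:
        raise ConfigError("subtype fractions must be three proportions summing to 1")
    f_postload, f_fasting, f_combined = fr

    out = copy.deepcopy(config)
    out.target_prevalence = prev
    out.target_subtype_fractions = fr
    g = out.glucose_model
    thr = out.thresholds

    # margins: P(FPG < fpg_dm) and P(2hPG < p2hpg_dm)
    p_fpg_lt = 1.0 - prev * (f_fasting + f_combined)
    p_p2_lt = 1.0 - prev * (f_postload + f_combined)
    q1, q2 = norm.ppf(p_fpg_lt), norm.ppf(p_p2_lt)
    for name, q, logthr, logmed in (("fpg", q1, math.log(thr.fpg_dm), g.log_median_fpg),
                                    ("p2hpg", q2, math.log(thr.p2hpg_dm), g.log_median_p2hpg)):
        if q <= 0 or logthr <= logmed:
            raise CalibrationError(
                f"cannot calibrate {name}: requires the diagnostic threshold above the "
                f"log-median and a below-threshold probability above 0.5")
    g.log_sd_fpg = (math.log(thr.fpg_dm) - g.log_median_fpg) / q1
    g.log_sd_p2hpg = (math.log(thr.p2hpg_dm) - g.log_median_p2hpg) / q2

    # joint: P(both below) = 1 - prevalence fixes the total correlation
    def joint(r: float) -> float:
        return multivariate_normal.cdf([q1, q2], mean=[0.0, 0.0],
                                       cov=[[1.0, r], [r, 1.0]]) - (1.0 - prev)

    lo, hi = -0.9999, 0.9999
    if joint(lo) * joint(hi) > 0:
        raise CalibrationError(
            f"prevalence {prev:.4f} unattainable with these margins: the joint "
            f"below-threshold probability ranges over "
            f"[{joint(lo) + 1 - prev:.4f}, {joint(hi) + 1 - prev:.4f}]")
    r_total = brentq(joint, lo, hi, xtol=1e-12)

    a = g.z_share_fpg * g.z_share_p2hpg
    denom = math.sqrt((1 - g.z_share_fpg**2) * (1 - g.z_share_p2hpg**2))
    residual_rho = (r_total - a) / denom
    if not -1.0 < residual_rho < 1.0:
        raise CalibrationError(
            f"required total log-glucose correlation {r_total:.4f} is infeasible with "
            f"z shares ({g.z_share_fpg}, {g.z_share_p2hpg}): residual correlation "
            f"would be {residual_rho:.4f}")
    g.residual_rho = residual_rho

    if verify:
        check = copy.deepcopy(out)
        check.n_participants = max(n_calibration, 1)
        check.seed = seed
        check.missingness_rate = 0.0
        pop = sample_population(check)
        achieved_prev = float(pop["dm_status"].mean())
        dm = pop[pop["dm_status"]]
        achieved = tuple(
            float((dm["subtype"] == s).mean())
            for s in ("ISOLATED_POSTLOAD", "ISOLATED_FASTING", "COMBINED"))
        errs = []
        if abs(achieved_prev - prev) > prevalence_tol:
            errs.append(f"prevalence achieved {achieved_prev:.4f} vs target {prev:.4f}")
        for name, got, want in zip(("isolated_postload", "isolated_fasting", "combined"),
                                   achieved, fr):
            if abs(got - want) > subtype_tol:
                errs.append(f"{name} achieved {got:.4f} vs target {want:.4f}")
        if errs:
            raise CalibrationError("calibration verification failed: " + "; ".join(errs))
    return out


def inject_missingness(pop: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask non-lab feature cells independently (MCAR) at the given rate.

    Labs, outcome columns and the id are never masked. Rates of 20% or
    more are rejected, mirroring the exclusion of features with that much
    missing data from any analysis.
    """
    if not 0.0 <= rate < 0.2:
        raise ConfigError(
            f"missingness rate {rate} out of range: features with more than 20% "
            "missing data are excluded from analysis, so rates of 0.2+ are not generated")
    out = pop.copy()
    if rate == 0.0 or len(pop) == 0:
        return out
    rng = np.random.default_rng(seed)
    maskable = [c for c in out.columns if c not in PROTECTED_COLUMNS]
    for col in maskable:
        mask = rng.random(len(out)) < rate
        if out[col].dtype == object:
            out.loc[mask, col] = None
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


def split_dev_test(pop: pd.DataFrame, dev_fraction: float = 0.6,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random split into development and testing sets.

    The development set has ``round(n * dev_fraction)`` rows, the test
    set the remainder; the partition is disjoint and exhaustive and fully
    determined by the seed.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ConfigError("dev_fraction must lie strictly between 0 and 1")
    n = len(pop)
    if n < 2:
        raise ConfigError("need at least two rows to split")
    n_dev = int(round(n * dev_fraction))
    n_dev = min(max(n_dev, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    dev_idx = np.sort(perm[:n_dev])
    test_idx = np.sort(perm[n_dev:])
    return (pop.iloc[dev_idx].reset_index(drop=True),
            pop.iloc[test_idx].reset_index(drop=True))
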