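"""Synthetic cohorts of diabetic pregnancies with ultrasound biometry.

The generator emulates a pregestational-diabetes delivery cohort in which
maternal glycemia (HbA1c) drives fetal overgrowth.  The construction is a
probit latent-growth model:

1. covariates (age, BMI, race/ethnicity, parity, diabetes type, GA at scan
   and delivery) are drawn from the configured marginals;
2. HbA1c is drawn from a truncated normal and set missing completely at
   random with the configured probability (a missing value still drives
   growth, it is only blanked in the output column);
3. the latent growth score is ``s = effect*(HbA1c - mean) + eps + delta``
   with ``eps ~ N(0,1)`` and ``delta`` calibrated by root finding so the
   expected LGA fraction equals ``lga_prevalence_target``;
4. the birth-weight percentile is ``Phi(s)`` on the sex-specific reference
   at the completed delivery week, so LGA at birth is exactly ``s >= z90``;
5. the observed EFW sits at z-score ``s + N(0, biometry_noise_sd)`` on the
   reference EFW chart at the scan GA, and biometry (BPD, FL at GA-typical
   values, AC solved exactly) is constructed so Hadlock-C reproduces that
   EFW.

Because the same latent score places both the EFW percentile and the birth
weight, classification against the generating ("truth") chart with zero
biometry noise reproduces the birth outcome exactly, and measurement noise
degrades it smoothly.

Truncated draws are moment-matched: the underlying normal (or, for BMI, a
skew normal, which also hits the obesity fraction P(BMI >= 30)) is solved so
the *truncated* distribution has exactly the configured mean and SD.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import cumulative_trapezoid
from scipy.stats import norm, skewnorm, truncnorm

from .charts import BirthweightReference, GrowthChart
from .efw import (
    GA_SCAN_MAX_WEEKS,
    GA_SCAN_MIN_WEEKS,
    HADLOCK_C_COEF,
    BiometryRecord,
    hadlock_c_log10_efw,
)

__all__ = [
    "SimulationConfig",
    "CohortRecord",
    "SimulationError",
    "simulate_cohort",
    "simulate_cohort_df",
    "records_to_df",
    "write_cohort_csv",
    "read_cohort_csv",
    "truth_efw_chart",
    "synthetic_chart_suite",
    "synthetic_birthweight_reference",
    "solve_ac_for_log10_efw",
    "RACE_ETH_LEVELS",
    "COHORT_COLUMNS",
]

RACE_ETH_LEVELS = ("NH-white", "NH-black", "Hispanic", "NH-Asian/PI")

#: Flat cohort-CSV column order (biometry flattened into its four columns).
COHORT_COLUMNS = [
    "subject_id", "age_years", "bmi", "race_eth", "parity", "diabetes_type",
    "hba1c_pct", "ga_hba1c_weeks", "ga_weeks", "bpd_cm", "ac_cm", "fl_cm",
    "ga_delivery_weeks", "infant_sex", "birth_weight_g",
]

# log10-scale SD of the synthetic EFW chart and birth-weight reference
# (~12% proportional spread, the order used by common references).
SIGMA_LOG10_EFW = 0.05
SIGMA_LOG10_BW = 0.05

_Z90 = float(norm.ppf(0.90))


class SimulationError(ValueError):
    """Invalid simulation configuration or failed calibration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults reproduce the study cohort's marginals.

    ``hba1c_effect`` is the shift in the latent growth z-score per 1% HbA1c;
    ``biometry_noise_sd`` is ultrasound measurement error expressed on the
    chart's z-scale.  All ``*_frac`` values are fractions in [0, 1].
    """

    n_subjects: int = 358
    seed: int = 0
    lga_prevalence_target: float = 0.41
    hba1c_mean: float = 6.4
    hba1c_sd: float = 1.2
    hba1c_missing_frac: float = 52.0 / 358.0
    hba1c_effect: float = 0.4
    biometry_noise_sd: float = 0.9
    ga_scan_mean: float = 31.6
    ga_scan_sd: float = 1.5
    ga_delivery_mean: float = 37.2
    ga_delivery_sd: float = 2.0
    obesity_frac: float = 0.69
    race_eth_probs: tuple = (0.529, 0.280, 0.059, 0.132)
    type1_frac: float = 0.336
    # secondary marginals
    bmi_mean: float = 35.4
    bmi_sd: float = 9.5
    age_mean: float = 31.7
    age_sd: float = 6.3
    nulliparous_frac: float = 0.369
    male_frac: float = 0.512
    ga_hba1c_mean: float = 31.1
    ga_hba1c_sd: float = 3.8
    # truncation bounds keeping draws physiologic
    hba1c_bounds: tuple = (3.5, 20.0)
    ga_scan_bounds: tuple = (GA_SCAN_MIN_WEEKS, GA_SCAN_MAX_WEEKS)
    bmi_bounds: tuple = (15.0, 70.0)
    age_bounds: tuple = (16.0, 50.0)
    ga_delivery_max: float = 42.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, (tuple, list)) else (v,)
            if not all(math.isfinite(float(x)) for x in vals):
                raise SimulationError(f"{f.name} must be finite, got {v!r}")
        if self.n_subjects < 1:
            raise SimulationError("n_subjects must be >= 1")
        for name in ("lga_prevalence_target", "hba1c_missing_frac", "obesity_frac",
                     "type1_frac", "nulliparous_frac", "male_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        probs = np.asarray(self.race_eth_probs, dtype=float)
        if probs.size != len(RACE_ETH_LEVELS) or np.any(probs < 0):
            raise SimulationError("race_eth_probs must be 4 non-negative fractions")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise SimulationError(f"race_eth_probs must sum to 1, got {probs.sum()!r}")
        object.__setattr__(self, "race_eth_probs", tuple(float(p) for p in probs))
        for name in ("hba1c_sd", "ga_scan_sd", "ga_delivery_sd", "bmi_sd",
                     "age_sd", "ga_hba1c_sd"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        if self.biometry_noise_sd < 0:
            raise SimulationError("biometry_noise_sd must be >= 0")
        lo, hi = self.ga_scan_bounds
        if lo < GA_SCAN_MIN_WEEKS - 1e-9 or hi > GA_SCAN_MAX_WEEKS + 1e-9 or lo >= hi:
            raise SimulationError(
                f"ga_scan_bounds must lie within the study window "
                f"[{GA_SCAN_MIN_WEEKS}, {GA_SCAN_MAX_WEEKS:.4f}], got {self.ga_scan_bounds}"
            )

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SimulationConfig":
        """Load from a JSON document (path or string); unknown keys rejected."""
        text = source
        try:
            p = Path(str(source))
            if p.exists():
                text = p.read_text()
        except OSError:
            pass  # not a path: treat as a JSON string
        doc = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        for key, val in doc.items():
            if isinstance(val, list):
                doc[key] = tuple(val)
        return cls(**doc)


@dataclass(frozen=True)
class CohortRecord:
    """One pregnancy: exposures, covariates and the birth outcome."""

    subject_id: str
    age_years: float
    bmi: float
    race_eth: str
    parity: str             # nulliparous | parous
    diabetes_type: str      # T1 | T2
    hba1c_pct: float | None
    ga_hba1c_weeks: float | None
    biometry: BiometryRecord
    ga_delivery_weeks: float
    infant_sex: str         # M | F
    birth_weight_g: float


# ---------------------------------------------------------------------------
# Moment-matched truncated draws
# ---------------------------------------------------------------------------

def _truncnorm_ppf(u, mean, sd, lo, hi):
    """Inverse-CDF transform of uniforms to a truncated normal (array bounds ok)."""
    a = (np.asarray(lo, dtype=float) - mean) / sd
    b = (np.asarray(hi, dtype=float) - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


@lru_cache(maxsize=64)
def _matched_truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the given moments."""

    def resid(p):
        mu, lsig = p
        sig = math.exp(lsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.least_squares(resid, x0=[mean, math.log(sd)],
                                 xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.max(np.abs(sol.fun)) > 1e-8:
        raise SimulationError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _matched_truncnorm_draw(u, mean, sd, lo, hi):
    mu, sig = _matched_truncnorm_params(float(mean), float(sd), float(lo), float(hi))
    return _truncnorm_ppf(u, mu, sig, lo, hi)


@lru_cache(maxsize=16)
def _bmi_grid(mean: float, sd: float, obese_frac: float, lo: float, hi: float,
              threshold: float = 30.0):
    """Inverse-CDF grid of a truncated skew normal matching mean, SD and
    P(BMI >= threshold) = obese_frac simultaneously."""
    x = np.linspace(lo, hi, 6001)

    def profile(p):
        a, loc, lscale = p
        pdf = skewnorm.pdf(x, a, loc=loc, scale=math.exp(lscale))
        z = np.trapezoid(pdf, x)
        if not np.isfinite(z) or z <= 0:
            return None
        pdf = pdf / z
        cdf = cumulative_trapezoid(pdf, x, initial=0.0)
        cdf = cdf / cdf[-1]
        m = np.trapezoid(x * pdf, x)
        s = math.sqrt(np.trapezoid((x - m) ** 2 * pdf, x))
        p_ge = 1.0 - float(np.interp(threshold, x, cdf))
        return pdf, cdf, m, s, p_ge

    def resid(p):
        prof = profile(p)
        if prof is None:
            return [1e3, 1e3, 1e3]
        _, _, m, s, p_ge = prof
        return [m - mean, s - sd, p_ge - obese_frac]

    sol = optimize.least_squares(
        resid, x0=[1.5, mean - 0.7 * sd, math.log(sd * 1.1)],
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if np.max(np.abs(sol.fun)) > 1e-6:
        raise SimulationError(
            f"cannot realize BMI marginal mean={mean}, sd={sd} with "
            f"obesity_frac={obese_frac} on [{lo}, {hi}]"
        )
    _, cdf, *_ = profile(sol.x)
    return x, cdf


def _bmi_draw(u, mean, sd, obese_frac, lo, hi):
    x, cdf = _bmi_grid(float(mean), float(sd), float(obese_frac), float(lo), float(hi))
    return np.interp(u, cdf, x)


# ---------------------------------------------------------------------------
# Synthetic reference standards (truth chart, chart suite, natality table)
# ---------------------------------------------------------------------------

def _log10_median_efw(ga_weeks):
    """Smooth synthetic median EFW curve (grams), log10 scale.

    Quadratic-in-GA on the log scale; ~1210 g at 28 w, ~1950 g at 32 w,
    ~3600 g at 40 w — textbook third-trimester values.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    return (0.578 + 0.332 * ga - 0.00354 * ga ** 2) / math.log(10.0)


def truth_efw_chart(name: str = "truth_efw_synthetic") -> GrowthChart:
    """The generating EFW chart: log10-normal around the synthetic median."""
    ga = np.arange(27.0, 38.51, 0.5)
    return GrowthChart(
        name=name, dialect="mean_sd_log", ga_weeks=ga,
        mean=_log10_median_efw(ga), sd=np.full(ga.size, SIGMA_LOG10_EFW),
    )


#: Per-stratum z-offsets of the misaligned stratified demo chart.
NICHD_LIKE_OFFSETS = {
    "NH-white": -0.65, "NH-black": 0.85, "Hispanic": 0.45, "NH-Asian/PI": 1.0,
}


def synthetic_chart_suite() -> dict[str, GrowthChart]:
    """Three synthetic reference charts, one per dialect.

    * ``fmf_synthetic`` — the truth chart (log-scale mean/SD): best aligned.
    * ``hadlock_synthetic`` — linear median + proportional SD with the median
      shifted +4%: flags fewer fetuses (higher specificity, lower sensitivity).
    * ``nichd_synthetic`` — stratified quantile table whose per-stratum
      offsets average out (similar screen-positive rate) but misalign the
      threshold within strata (lower discrimination).
    """
    truth = truth_efw_chart("fmf_synthetic")
    ga = truth.ga_weeks
    med = 10.0 ** _log10_median_efw(ga)

    med_lin = med * 1.04
    hadlock_like = GrowthChart(
        name="hadlock_synthetic", dialect="mean_sd_linear", ga_weeks=ga,
        mean=med_lin, sd=0.127 * med_lin,
    )

    pct = np.asarray([1, 5, 10, 25, 50, 75, 90, 95, 99], dtype=float)
    zgrid = norm.ppf(pct / 100.0)
    tables = {
        stratum: 10.0 ** (
            _log10_median_efw(ga)[:, None]
            + SIGMA_LOG10_EFW * (off + zgrid)[None, :]
        )
        for stratum, off in NICHD_LIKE_OFFSETS.items()
    }
    nichd_like = GrowthChart(
        name="nichd_synthetic", dialect="quantile_table", ga_weeks=ga,
        percentiles=pct, tables=tables,
    )
    return {"fmf": truth, "hadlock": hadlock_like, "nichd": nichd_like}


def synthetic_birthweight_reference(name: str = "bw_reference_synthetic") -> BirthweightReference:
    """Sex-specific synthetic natality-style reference, weeks 28-42.

    Median follows the synthetic growth curve at mid-week; males run ~1.5%
    heavier.  ``p90_g`` is the 90th percentile of the log10-normal spread.
    """
    weeks = np.arange(28, 43)
    rows = []
    for sex, factor in (("M", 1.015), ("F", 0.985)):
        med = factor * 10.0 ** _log10_median_efw(weeks + 0.5)
        p90 = med * 10.0 ** (SIGMA_LOG10_BW * _Z90)
        for w, m, c in zip(weeks, med, p90):
            rows.append({"sex": sex, "ga_week": int(w), "p50_g": m, "p90_g": c,
                         "sigma_log10": SIGMA_LOG10_BW})
    return BirthweightReference(name=name, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Biometry back-solve
# ---------------------------------------------------------------------------

def typical_bpd_cm(ga_weeks):
    """GA-typical biparietal diameter (cm), linear over the study window."""
    return 7.1 + 0.225 * (np.asarray(ga_weeks, dtype=float) - 28.0)


def typical_fl_cm(ga_weeks):
    """GA-typical femur length (cm), linear over the study window."""
    return 5.3 + 0.2 * (np.asarray(ga_weeks, dtype=float) - 28.0)


def solve_ac_for_log10_efw(log10_efw, bpd_cm, fl_cm):
    """AC (cm) making Hadlock-C hit the target log10 EFW at fixed BPD, FL.

    At fixed BPD and FL the formula is affine in AC with positive slope
    0.0457 - 0.0034*FL (all physiologic FL < 13.4 cm), so the solution is
    unique and exact.
    """
    c = HADLOCK_C_COEF
    fl = np.asarray(fl_cm, dtype=float)
    slope = c["ac"] + c["ac_fl"] * fl
    if np.any(slope <= 0):
        raise SimulationError("FL too large: Hadlock-C not increasing in AC")
    base = c["intercept"] + c["bpd"] * np.asarray(bpd_cm, dtype=float) + c["fl"] * fl
    return (np.asarray(log10_efw, dtype=float) - base) / slope


# ---------------------------------------------------------------------------
# The generator
# ---------------------------------------------------------------------------

def _calibrate_delta(linear_term: np.ndarray, target: float) -> float:
    """Shift delta so the expected LGA fraction equals the target.

    Each subject's LGA probability, integrating over the unit-variance
    residual, is Phi(linear + delta - z90); the mean is monotone in delta.
    """
    if not 0.0 < target < 1.0:
        raise SimulationError(
            f"lga_prevalence_target must be strictly inside (0, 1), got {target}"
        )

    def g(delta):
        return float(np.mean(norm.cdf(linear_term + delta - _Z90))) - target

    try:
        return float(optimize.brentq(g, -40.0, 40.0, xtol=1e-12))
    except ValueError as exc:  # pragma: no cover - unreachable for valid targets
        raise SimulationError(
            f"calibration failed for lga_prevalence_target={target}: {exc}"
        ) from exc


def simulate_cohort(config: SimulationConfig) -> list[CohortRecord]:
    """Draw a seed-reproducible cohort; same (seed, config) => identical output."""
    cfg = config
    n = cfg.n_subjects
    rng = np.random.default_rng(cfg.seed)

    age = _truncnorm_ppf(rng.uniform(size=n), cfg.age_mean, cfg.age_sd, *cfg.age_bounds)
    race = rng.choice(len(RACE_ETH_LEVELS), size=n, p=cfg.race_eth_probs)
    race = np.asarray(RACE_ETH_LEVELS)[race]
    parity = np.where(rng.uniform(size=n) < cfg.nulliparous_frac, "nulliparous", "parous")
    dtype = np.where(rng.uniform(size=n) < cfg.type1_frac, "T1", "T2")
    sex = np.where(rng.uniform(size=n) < cfg.male_frac, "M", "F")
    bmi = _bmi_draw(rng.uniform(size=n), cfg.bmi_mean, cfg.bmi_sd,
                    cfg.obesity_frac, *cfg.bmi_bounds)
    ga_scan = _matched_truncnorm_draw(rng.uniform(size=n), cfg.ga_scan_mean,
                                      cfg.ga_scan_sd, *cfg.ga_scan_bounds)
    ga_delivery = _truncnorm_ppf(rng.uniform(size=n), cfg.ga_delivery_mean,
                                 cfg.ga_delivery_sd, ga_scan + 1.0 / 7.0,
                                 cfg.ga_delivery_max)

    hba1c = _matched_truncnorm_draw(rng.uniform(size=n), cfg.hba1c_mean,
                                    cfg.hba1c_sd, *cfg.hba1c_bounds)
    missing = rng.uniform(size=n) < cfg.hba1c_missing_frac
    ga_hba1c = _truncnorm_ppf(rng.uniform(size=n), cfg.ga_hba1c_mean,
                              cfg.ga_hba1c_sd, 20.0 + 1.0 / 7.0, ga_delivery)

    # latent growth score; delta calibrated in expectation over the residual
    linear = cfg.hba1c_effect * (hba1c - cfg.hba1c_mean)
    delta = _calibrate_delta(linear, cfg.lga_prevalence_target)
    score = linear + rng.standard_normal(n) + delta

    # birth weight on the reference at the completed delivery week
    bw_ref = synthetic_birthweight_reference()
    week = np.floor(ga_delivery).astype(int)
    p50_lut = {(s, w): m for s, w, m in zip(bw_ref.table["sex"],
                                            bw_ref.table["ga_week"],
                                            bw_ref.table["p50_g"])}
    med = np.array([p50_lut[(s, w)] for s, w in zip(sex, week)])
    bw = med * 10.0 ** (SIGMA_LOG10_BW * score)

    # observed EFW at the scan: latent score plus measurement noise, placed
    # on the truth chart exactly as the downstream percentile engine reads it
    z_obs = score + cfg.biometry_noise_sd * rng.standard_normal(n)
    chart = truth_efw_chart()
    ga_arr = np.asarray(ga_scan)
    mean_ga = np.interp(ga_arr, chart.ga_weeks, chart.mean)
    sd_ga = np.interp(ga_arr, chart.ga_weeks, chart.sd)
    log10_efw = mean_ga + sd_ga * z_obs

    bpd = typical_bpd_cm(ga_scan)
    fl = typical_fl_cm(ga_scan)
    ac = solve_ac_for_log10_efw(log10_efw, bpd, fl)
    if np.any(ac <= 0) or np.any(ac >= 80):
        raise SimulationError("back-solved AC left the physiologic range; "
                              "check biometry_noise_sd")
    assert np.allclose(hadlock_c_log10_efw(bpd, ac, fl), log10_efw, atol=1e-12)

    records = []
    for i in range(n):
        records.append(CohortRecord(
            subject_id=f"S{i:05d}",
            age_years=float(age[i]),
            bmi=float(bmi[i]),
            race_eth=str(race[i]),
            parity=str(parity[i]),
            diabetes_type=str(dtype[i]),
            hba1c_pct=None if missing[i] else float(hba1c[i]),
            ga_hba1c_weeks=None if missing[i] else float(ga_hba1c[i]),
            biometry=BiometryRecord(
                ga_weeks=float(ga_scan[i]), bpd_cm=float(bpd[i]),
                ac_cm=float(ac[i]), fl_cm=float(fl[i]),
            ),
            ga_delivery_weeks=float(ga_delivery[i]),
            infant_sex=str(sex[i]),
            birth_weight_g=float(bw[i]),
        ))
    return records


def records_to_df(records: list[CohortRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        bio = d.pop("biometry")
        d.update(bio)
        rows.append(d)
    df = pd.DataFrame(rows)
    return df[COHORT_COLUMNS]


def simulate_cohort_df(config: SimulationConfig) -> pd.DataFrame:
    return records_to_df(simulate_cohort(config))


def write_cohort_csv(cohort, path) -> None:
    """Write a cohort (records or DataFrame) to CSV; missing HbA1c is empty."""
    df = cohort if isinstance(cohort, pd.DataFrame) else records_to_df(cohort)
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SimulationError(f"cohort file {path}: missing columns {missing}")
    return df[COHORT_COLUMNS]
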