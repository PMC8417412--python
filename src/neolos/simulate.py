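"""Synthetic neonatal LOS case-control cohort generator.

Real patient-level data from the source study were never deposited, so the
whole analysis pipeline is exercised on simulated cohorts whose *marginal*
structure is calibrated to the published development-cohort frequencies:
per-group marker exceedance probabilities, group medians for CRP and NLR,
the 3-level appearance-score multinomial, and the blood-culture
time-to-positivity distribution (log-normal, median 25.9 h, IQR
18.7-37.3 h).

Dependence between markers is induced by a single per-patient latent
severity variable: each marker channel is a Gaussian-copula mixture
``x_m = sqrt(rho) * z + sqrt(1 - rho) * eps_m`` with one shared standard
normal ``z``, so ``latent_correlation`` (rho) is the pairwise tetrachoric
correlation between any two channels.  Continuous labs (CRP, NLR) are
produced by pushing the channel's uniform through an inverse CDF whose
threshold quantile sits exactly at the clinical cutoff, so re-deriving the
binary marker from the generated raw value reproduces the intended draw
exactly, and empirical exceedance converges to the configured probability.

Raw CBC / vitals values are drawn inside or outside their normal ranges
according to the intended marker flag; only window summaries are
generated, not trajectories.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, HealthScore, PatientRecord, Sex

__all__ = [
    "CalibrationError",
    "SyntheticConfig",
    "default_config",
    "validation_config",
    "sample_time_to_positivity",
    "generate_cohort",
    "lognormal_sigma_from_iqr",
]

_NORM = sps.norm()
_Q75 = float(_NORM.ppf(0.75))  # 0.6745, the unit-normal upper quartile


class CalibrationError(ValueError):
    """A configured continuous distribution cannot achieve the requested
    threshold-exceedance probability."""


# Fixed channel order: one latent-coupled Gaussian channel per row, drawn in
# this order so cohorts are bit-reproducible for a given seed.
_BINARY_CHANNELS = (
    "lymphopenia",
    "abnormal_neutrophils",
    "abnormal_wbc",
    "thrombocytopenia",
    "hyperglycemia",
    "abnormal_temperature",
    "tachycardia",
    "central_line",
    "parenteral_nutrition",
)


@dataclass
class SyntheticConfig:
    """Calibration targets for one simulated cohort.

    ``marker_probs`` maps a marker (or line/nutrition covariate) to
    ``(P(marker | sepsis), P(marker | control))``.  ``crp_dist`` /
    ``nlr_dist`` give per-group value distributions (log-normal median,
    optional ``sigma``; the control CRP additionally carries a detection
    floor as ``floor_mass`` / ``floor_value``, since a quarter of control
    CRPs sit at the assay floor).  ``sick_score_probs`` are per-group
    (healthy, equivocal, sick) multinomials over the worst-in-window
    appearance grade.
    """

    n_total: int = 105
    prevalence: float = 33 / 105
    marker_probs: dict[str, tuple[float, float]] = field(default_factory=dict)
    crp_dist: dict[str, dict[str, float]] = field(default_factory=dict)
    nlr_dist: dict[str, dict[str, float]] = field(default_factory=dict)
    ttp_dist: dict[str, object] = field(
        default_factory=lambda: {"median": 25.9, "iqr": (18.7, 37.3)}
    )
    sick_score_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    latent_correlation: float = 0.3
    cohort: str = "development"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.latent_correlation < 1:
            raise ValueError("latent_correlation must lie in [0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name, (ps, pc) in self.marker_probs.items():
            if not (0 <= ps <= 1 and 0 <= pc <= 1):
                raise ValueError(f"marker_probs[{name!r}] outside [0, 1]")
        for grp, probs in self.sick_score_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"sick_score_probs[{grp!r}] must sum to 1")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["marker_probs"] = {k: tuple(v) for k, v in raw.get("marker_probs", {}).items()}
        raw["sick_score_probs"] = {
            k: tuple(v) for k, v in raw.get("sick_score_probs", {}).items()
        }
        if "iqr" in raw.get("ttp_dist", {}):
            raw["ttp_dist"]["iqr"] = tuple(raw["ttp_dist"]["iqr"])
        return cls(**raw)


def default_config(seed: int = 0) -> SyntheticConfig:
    """Development-cohort configuration calibrated to the published
    frequencies: n = 105 with 33 sepsis cases / 72 controls, and every
    marker probability equal to the printed count ratio."""
    return SyntheticConfig(
        n_total=105,
        prevalence=33 / 105,
        marker_probs={
            "crp_high": (30 / 33, 10 / 72),
            "nlr_high": (33 / 33, 17 / 72),
            # the printed union row pins the CRP-NLR dependence beyond the
            # shared severity latent (see generate_cohort)
            "crp_or_nlr": (33 / 33, 18 / 72),
            "lymphopenia": (22 / 33, 6 / 72),
            "abnormal_neutrophils": (30 / 33, 29 / 72),
            "abnormal_wbc": (14 / 33, 13 / 72),
            "thrombocytopenia": (17 / 33, 4 / 72),
            "hyperglycemia": (22 / 33, 23 / 72),
            "abnormal_temperature": (10 / 33, 20 / 72),
            "tachycardia": (27 / 33, 61 / 72),
            "central_line": (16 / 33, 12 / 72),
            "parenteral_nutrition": (28 / 33, 19 / 72),
        },
        crp_dist={
            "sepsis": {"median": 7.0},
            "control": {"median": 0.01, "floor_mass": 0.25, "floor_value": 0.0},
        },
        nlr_dist={
            # sepsis exceedance is 33/33; sigma 0.5 keeps the untruncated
            # P(NLR > 1.5) above 0.995 before tail conditioning
            "sepsis": {"median": 6.0, "sigma": 0.5},
            "control": {"median": 0.7},
        },
        ttp_dist={"median": 25.9, "iqr": (18.7, 37.3)},
        sick_score_probs={
            "sepsis": (2 / 33, 17 / 33, 14 / 33),
            "control": (49 / 72, 21 / 72, 2 / 72),
        },
        covariates={
            "corrected_ga_weeks": {
                "mean_sepsis": 31.5, "sd_sepsis": 4.7,
                "mean_control": 32.7, "sd_control": 2.6,
                "low": 23.0, "high": 42.0,
            },
            "birthweight_g": {
                "mean_sepsis": 1343.0, "sd_sepsis": 831.0,
                "mean_control": 1484.0, "sd_control": 566.0,
                "low": 400.0, "high": 4500.0,
            },
            "female_fraction": {"value": 0.486},
        },
        cohort="development",
        seed=seed,
    )


def validation_config(base: SyntheticConfig) -> SyntheticConfig:
    """Temporal-validation twin of ``base``: same calibration, n = 60 with
    20 cases / 40 controls, an independent seed stream, no drift model."""
    return dataclasses.replace(
        base,
        n_total=60,
        prevalence=20 / 60,
        cohort="validation",
        seed=base.seed + 1_000_003,
    )


# ---------------------------------------------------------------------------
# Distribution calibration
# ---------------------------------------------------------------------------

def lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-normal scale implied by an interquartile range."""
    if not 0 < q1 < q3:
        raise ValueError("need 0 < q1 < q3")
    return (math.log(q3) - math.log(q1)) / (2.0 * _Q75)


def _sigma_from_exceedance(median: float, cutoff: float, p: float) -> float:
    """Log-normal scale with the given median and P(X > cutoff) = p."""
    z = float(_NORM.ppf(1.0 - p))
    num = math.log(cutoff) - math.log(median)
    if z == 0.0 or num == 0.0 or (num > 0) != (z > 0):
        raise CalibrationError(
            f"log-normal with median {median} cannot have P(>{cutoff}) = {p:.4g}"
        )
    return num / z


def _mixture_params(median: float, floor_mass: float, cutoff: float, p: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal tail of a floor-inflated mixture with
    the given overall median and P(X > cutoff) = p."""
    if not 0 <= floor_mass < 0.5:
        raise CalibrationError("floor_mass must lie in [0, 0.5)")
    q_med = (0.5 - floor_mass) / (1.0 - floor_mass)
    q_cut = (1.0 - p - floor_mass) / (1.0 - floor_mass)
    if not 0 < q_med < q_cut < 1:
        raise CalibrationError(
            f"floor-inflated log-normal infeasible: median {median}, "
            f"floor mass {floor_mass}, P(>{cutoff}) = {p:.4g}"
        )
    z_med = float(_NORM.ppf(q_med))
    z_cut = float(_NORM.ppf(q_cut))
    sigma = (math.log(cutoff) - math.log(median)) / (z_cut - z_med)
    if sigma <= 0:
        raise CalibrationError("floor-inflated log-normal needs cutoff above the median")
    mu = math.log(median) - sigma * z_med
    return mu, sigma


def _value_transform(dist: dict[str, float], cutoff: float, p: float):
    """Return Q(u) mapping a uniform to a lab value with P(value > cutoff)
    exactly p (tail-conditioned when p is 0 or 1)."""
    median = float(dist["median"])
    mu = math.log(median)
    if "floor_mass" in dist:
        fm = float(dist["floor_mass"])
        fv = float(dist.get("floor_value", 0.0))
        mu_t, sigma_t = _mixture_params(median, fm, cutoff, p)

        def q(u: np.ndarray) -> np.ndarray:
            out = np.full_like(u, fv, dtype=float)
            tail = u > fm
            inner = (u[tail] - fm) / (1.0 - fm)
            out[tail] = np.exp(mu_t + sigma_t * _NORM.ppf(inner))
            return out

        return q
    if p >= 1.0 or p <= 0.0:
        sigma = float(dist.get("sigma", 0.0))
        if sigma <= 0:
            raise CalibrationError(
                f"degenerate exceedance P = {p} requires an explicit positive sigma"
            )
        f_cut = float(_NORM.cdf((math.log(cutoff) - mu) / sigma))
        if p >= 1.0:
            # conditioned on exceeding the cutoff
            def q(u: np.ndarray) -> np.ndarray:
                return np.exp(mu + sigma * _NORM.ppf(f_cut + u * (1.0 - f_cut)))
        else:
            def q(u: np.ndarray) -> np.ndarray:
                return np.exp(mu + sigma * _NORM.ppf(u * f_cut))
        return q
    sigma = float(dist["sigma"]) if "sigma" in dist else _sigma_from_exceedance(median, cutoff, p)
    achieved = float(_NORM.sf((math.log(cutoff) - mu) / sigma))
    if abs(achieved - p) > 0.02:
        raise CalibrationError(
            f"configured sigma {sigma:.3g} gives P(>{cutoff}) = {achieved:.3g}, "
            f"target {p:.3g}"
        )

    def q(u: np.ndarray) -> np.ndarray:
        return np.exp(mu + sigma * _NORM.ppf(u))

    return q


def sample_time_to_positivity(dist: dict, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Sample blood-culture times to positivity (hours).

    ``dist`` carries a log-normal ``median`` plus either ``iqr`` (quartile
    pair, from which the scale is fitted) or an explicit ``sigma``; a zero
    scale degenerates to the median exactly.
    """
    median = float(dist["median"])
    if median <= 0:
        raise ValueError("median time to positivity must be positive")
    if "sigma" in dist:
        sigma = float(dist["sigma"])
    else:
        q1, q3 = dist["iqr"]
        sigma = lognormal_sigma_from_iqr(float(q1), float(q3))
    if sigma == 0.0:
        return np.full(size, median)
    return np.exp(math.log(median) + sigma * rng.standard_normal(size))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _channel(rng: np.random.Generator, z: np.ndarray, rho: float) -> np.ndarray:
    """One latent-coupled uniform channel."""
    x = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * rng.standard_normal(z.size)
    return _NORM.cdf(x)


def _binorm_orthant(z_a: float, z_b: float, r: float) -> float:
    """P(X > z_a, Y > z_b) for standard bivariate normal with corr r."""
    cov = [[1.0, r], [r, 1.0]]
    return float(sps.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-z_a, -z_b]))


def _pair_extra_corr(p_a: float, p_b: float, p_union: float, rho: float) -> float:
    """Extra common-factor loading for two marker channels so their joint
    exceedance matches a target union probability.

    The total channel correlation r solves the bivariate-normal orthant
    equation P(both) = p_a + p_b - p_union; the returned s satisfies
    rho + (1 - rho) * s = r.  Degenerate marginals (p in {0, 1}) leave the
    pair unconstrained and return 0.
    """
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return 0.0
    p_both = p_a + p_b - p_union
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not lo - 1e-9 <= p_both <= hi + 1e-9:
        raise CalibrationError(
            f"union probability {p_union:.4g} violates Frechet bounds for "
            f"marginals {p_a:.4g}, {p_b:.4g}"
        )
    z_a = float(_NORM.ppf(1.0 - p_a))
    z_b = float(_NORM.ppf(1.0 - p_b))
    from scipy.optimize import brentq

    r = brentq(lambda r_: _binorm_orthant(z_a, z_b, r_) - p_both, -0.995, 0.995,
               xtol=1e-10)
    s = (r - rho) / (1.0 - rho)
    if not 0.0 <= s < 1.0:
        raise CalibrationError(
            f"union calibration needs pair correlation {r:.3f}, outside what "
            f"latent_correlation {rho} admits"
        )
    return s


def _truncnorm(rng, mean, sd, low, high, size) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    u = rng.random(size)
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_cohort(config: SyntheticConfig) -> list[PatientRecord]:
    """Generate one case-control cohort under ``config``.

    Case/control counts are fixed margins (``round(n_total * prevalence)``
    cases), as in a matched case-control design.  Sepsis cases are
    culture-positive with a time to positivity from ``ttp_dist``; controls
    are always culture-negative.  Binary markers are *not* stored: raw lab
    values are generated to realise the intended flags, and downstream
    code re-derives the panel through :func:`neolos.cohort.derive_markers`.
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_total)
    n_cases = int(round(n * config.prevalence))
    if not 0 < n_cases < n:
        raise ValueError("prevalence and n_total must yield both groups")
    s = np.zeros(n, dtype=bool)
    s[:n_cases] = True
    rho = config.latent_correlation

    z = rng.standard_normal(n)  # latent severity

    def group_prob(name: str) -> np.ndarray:
        ps, pc = config.marker_probs[name]
        return np.where(s, ps, pc)

    # appearance score: ordinal threshold on its own channel
    u_score = _channel(rng, z, rho)
    p_sick = np.where(s, config.sick_score_probs["sepsis"][2], config.sick_score_probs["control"][2])
    p_equiv = np.where(s, config.sick_score_probs["sepsis"][1], config.sick_score_probs["control"][1])
    worst_sev = np.where(u_score > 1.0 - p_sick, 2, np.where(u_score > 1.0 - p_sick - p_equiv, 1, 0))

    # continuous labs via exceedance-calibrated inverse CDFs; the CRP/NLR
    # pair carries an extra common factor per group so the union frequency
    # P(crp_high OR nlr_high) matches its configured value
    if "crp_or_nlr" in config.marker_probs:
        s_extra = np.where(
            s,
            _pair_extra_corr(
                config.marker_probs["crp_high"][0],
                config.marker_probs["nlr_high"][0],
                config.marker_probs["crp_or_nlr"][0],
                rho,
            ),
            _pair_extra_corr(
                config.marker_probs["crp_high"][1],
                config.marker_probs["nlr_high"][1],
                config.marker_probs["crp_or_nlr"][1],
                rho,
            ),
        )
    else:
        s_extra = np.zeros(n)
    g_pair = rng.standard_normal(n)
    e_crp = rng.standard_normal(n)
    e_nlr = rng.standard_normal(n)
    inner_crp = np.sqrt(s_extra) * g_pair + np.sqrt(1.0 - s_extra) * e_crp
    inner_nlr = np.sqrt(s_extra) * g_pair + np.sqrt(1.0 - s_extra) * e_nlr
    u_crp = _NORM.cdf(math.sqrt(rho) * z + math.sqrt(1.0 - rho) * inner_crp)
    u_nlr = _NORM.cdf(math.sqrt(rho) * z + math.sqrt(1.0 - rho) * inner_nlr)
    crp = np.empty(n)
    nlr = np.empty(n)
    for grp, mask in (("sepsis", s), ("control", ~s)):
        idx = 0 if grp == "sepsis" else 1
        q_crp = _value_transform(config.crp_dist[grp], 0.75, config.marker_probs["crp_high"][idx])
        q_nlr = _value_transform(config.nlr_dist[grp], 1.5, config.marker_probs["nlr_high"][idx])
        crp[mask] = q_crp(u_crp[mask])
        nlr[mask] = q_nlr(u_nlr[mask])
    # physiologic ceiling; far above the 0.75 mg/dl cutoff, so neither the
    # group median nor the calibrated exceedance is affected
    np.minimum(crp, 60.0, out=crp)

    flags = {name: _channel(rng, z, rho) > 1.0 - group_prob(name) for name in _BINARY_CHANNELS}

    # time to positivity: shorter for sicker infants (quantile at 1 - u)
    u_ttp = _channel(rng, z, rho)
    ttp_median = float(config.ttp_dist["median"])
    if "sigma" in config.ttp_dist:
        ttp_sigma = float(config.ttp_dist["sigma"])
    else:
        q1, q3 = config.ttp_dist["iqr"]
        ttp_sigma = lognormal_sigma_from_iqr(float(q1), float(q3))
    ttp = np.exp(math.log(ttp_median) + ttp_sigma * _NORM.ppf(1.0 - u_ttp))

    # raw vitals/CBC realising the intended flags
    f = flags["lymphopenia"]
    lymph_min = np.where(f, rng.uniform(200, 1950, n), rng.uniform(2000, 6000, n))
    f = flags["thrombocytopenia"]
    platelets_min = np.where(f, rng.uniform(20e3, 149e3, n), rng.uniform(150e3, 450e3, n))
    f = flags["hyperglycemia"]
    glucose_max = np.where(f, rng.uniform(109, 250, n), rng.uniform(60, 108, n))
    f = flags["tachycardia"]
    hr_max = np.where(f, rng.uniform(187, 220, n), rng.uniform(120, 186, n))

    f = flags["abnormal_temperature"]
    high_side = rng.random(n) < 0.6
    t_a = rng.uniform(36.1, 37.4, n)
    t_b = rng.uniform(36.1, 37.4, n)
    temp_min = np.minimum(t_a, t_b)
    temp_max = np.maximum(t_a, t_b)
    temp_min = np.where(f & high_side, rng.uniform(36.2, 37.2, n), temp_min)
    temp_max = np.where(f & high_side, rng.uniform(37.6, 39.5, n), temp_max)
    temp_min = np.where(f & ~high_side, rng.uniform(34.5, 35.9, n), temp_min)
    temp_max = np.where(f & ~high_side, rng.uniform(36.0, 37.4, n), temp_max)

    f = flags["abnormal_wbc"]
    low_side = rng.random(n) < 0.5
    w_a = rng.uniform(5000, 20000, n)
    w_b = rng.uniform(5000, 20000, n)
    wbc_min = np.minimum(w_a, w_b)
    wbc_max = np.maximum(w_a, w_b)
    wbc_min = np.where(f & low_side, rng.uniform(1000, 4900, n), wbc_min)
    wbc_max = np.where(f & low_side, rng.uniform(5000, 18000, n), wbc_max)
    wbc_min = np.where(f & ~low_side, rng.uniform(6000, 15000, n), wbc_min)
    wbc_max = np.where(f & ~low_side, rng.uniform(20100, 40000, n), wbc_max)

    f = flags["abnormal_neutrophils"]
    low_side = rng.random(n) < 0.5
    a_a = rng.uniform(1800, 5400, n)
    a_b = rng.uniform(1800, 5400, n)
    anc_min = np.minimum(a_a, a_b)
    anc_max = np.maximum(a_a, a_b)
    anc_min = np.where(f & low_side, rng.uniform(200, 1750, n), anc_min)
    anc_max = np.where(f & low_side, rng.uniform(1800, 5400, n), anc_max)
    anc_min = np.where(f & ~low_side, rng.uniform(1800, 5400, n), anc_min)
    anc_max = np.where(f & ~low_side, rng.uniform(5500, 12000, n), anc_max)

    # demographics
    cov = config.covariates
    ga_cov = cov["corrected_ga_weeks"]
    corrected_ga = np.where(
        s,
        _truncnorm(rng, ga_cov["mean_sepsis"], ga_cov["sd_sepsis"], ga_cov["low"], ga_cov["high"], n),
        0.0,
    )
    corrected_ga = np.where(
        ~s,
        _truncnorm(rng, ga_cov["mean_control"], ga_cov["sd_control"], ga_cov["low"], ga_cov["high"], n),
        corrected_ga,
    )
    bw_cov = cov["birthweight_g"]
    birthweight = np.where(
        s,
        _truncnorm(rng, bw_cov["mean_sepsis"], bw_cov["sd_sepsis"], bw_cov["low"], bw_cov["high"], n),
        0.0,
    )
    birthweight = np.where(
        ~s,
        _truncnorm(rng, bw_cov["mean_control"], bw_cov["sd_control"], bw_cov["low"], bw_cov["high"], n),
        birthweight,
    )
    day_of_life = rng.integers(4, 61, n)
    gestational_age = np.clip(corrected_ga - day_of_life / 7.0, 22.0, 44.0)
    female = rng.random(n) < cov["female_fraction"]["value"]

    extra_sev = np.empty(n, dtype=int)
    for grp, mask in (("sepsis", s), ("control", ~s)):
        probs = np.asarray(config.sick_score_probs[grp])
        extra_sev[mask] = rng.choice(3, size=int(mask.sum()), p=probs / probs.sum())
    sev_0h = np.minimum(worst_sev, extra_sev)
    score_levels = (HealthScore.HEALTHY, HealthScore.EQUIVOCAL, HealthScore.SICK)

    order = rng.permutation(n)
    prefix = "dev" if config.cohort == "development" else "val"
    records: list[PatientRecord] = []
    for rank, j in enumerate(order, start=1):
        is_case = bool(s[j])
        records.append(
            PatientRecord(
                patient_id=f"{prefix}-{rank:05d}",
                cohort=Cohort(config.cohort),
                gestational_age_weeks=round(float(gestational_age[j]), 1),
                corrected_ga_weeks=round(float(corrected_ga[j]), 1),
                birthweight_g=round(float(birthweight[j])),
                sex=Sex.F if female[j] else Sex.M,
                day_of_life=int(day_of_life[j]),
                central_line=bool(flags["central_line"][j]),
                parenteral_nutrition=bool(flags["parenteral_nutrition"][j]),
                temp_min_c=round(float(temp_min[j]), 1),
                temp_max_c=round(float(temp_max[j]), 1),
                hr_max_bpm=round(float(hr_max[j])),
                glucose_max_mgdl=round(float(glucose_max[j])),
                wbc_min=round(float(wbc_min[j])),
                wbc_max=round(float(wbc_max[j])),
                anc_min=round(float(anc_min[j])),
                anc_max=round(float(anc_max[j])),
                lymph_min=round(float(lymph_min[j])),
                platelets_min=round(float(platelets_min[j])),
                crp_max_mgdl=round(float(crp[j]), 3),
                nlr_max=round(float(nlr[j]), 3),
                health_score_0h=score_levels[int(sev_0h[j])],
                health_score_24h=score_levels[int(worst_sev[j])],
                culture_positive=is_case,
                time_to_positivity_h=round(float(ttp[j]), 1) if is_case else None,
                sepsis=is_case,
            )
        )
    return records
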