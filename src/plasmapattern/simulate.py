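"""Synthetic cohort and binary-proteome generator with known ground truth.

The generator emulates a 104-subject study split into five BMI groups
(NORM/OW/OB1/OB2/OB3). Group BMI is drawn from a range-truncated normal
whose parameters are calibrated so the *truncated* mean and SD match the
published group moments; height and age are plain normals, sex is Bernoulli
with the observed female fraction, and weight is derived as
``BMI * (height/100)^2`` so anthropometrics are internally consistent.

Protein occurrence follows a logistic model on standardised BMI,

    P(protein j present in sample i) = logistic(a_j + b_j * z_i),
    z_i = (BMI_i - 30) / 6,

with fixed centring constants so effect sizes mean the same thing for any
cohort. ``b_j != 0`` marks an informative protein (returned as the ground
truth); noise proteins have ``b_j = 0`` with baselines drawn uniformly;
"ubiquitous" columns (presence probability >= 0.999) and "singleton-ish"
columns (expected occurrence about one sample) exercise the catalogue
filters downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import truncnorm

from .errors import CalibrationError, DataError
from .io import GROUPS, CohortTable, PresenceMatrix, Sample, assign_group

#: Centring constants of the logistic occurrence link (kg/m^2).
BMI_CENTER = 30.0
BMI_SCALE = 6.0

#: Baseline-logit range for uninformative noise proteins (occurrence
#: frequencies roughly 12-88%).
NOISE_LOGIT_RANGE = (-2.0, 2.0)

_CALIBRATION_TOL = 1e-6


@dataclass(frozen=True)
class GroupSpec:
    """Sampling targets for one BMI group (moments on the truncated scale)."""

    group: str
    n: int
    bmi_mean: float
    bmi_sd: float
    bmi_range: tuple[float, float]
    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    sex_ratio: float  # fraction female

    def validate(self) -> None:
        if self.n < 0 or self.bmi_sd < 0 or self.age_sd < 0 or self.height_sd < 0:
            raise DataError(f"group {self.group}: negative count or sd")
        lo, hi = self.bmi_range
        if not lo < hi:
            raise DataError(f"group {self.group}: empty BMI range {self.bmi_range}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise DataError(f"group {self.group}: sex_ratio outside [0,1]")


@dataclass(frozen=True)
class EffectSpec:
    """Logistic occurrence model for one protein: logit = a + b*z."""

    protein_id: str
    baseline_logit: float
    bmi_slope: float

    def validate(self) -> None:
        if not (math.isfinite(self.baseline_logit) and math.isfinite(self.bmi_slope)):
            raise DataError(f"effect {self.protein_id}: non-finite parameters")


# Published five-group cohort characteristics (sex ratios are f/(f+m)).
_TABLE1 = {
    "NORM": dict(n=22, bmi_mean=21.73, bmi_sd=1.90, bmi_range=(18.5, 25.0),
                 age_mean=30.54, age_sd=5.34, height_mean=172.65, height_sd=7.31,
                 sex_ratio=13 / 22),
    "OW": dict(n=21, bmi_mean=27.52, bmi_sd=1.35, bmi_range=(25.0, 30.0),
               age_mean=32.90, age_sd=6.66, height_mean=171.99, height_sd=11.81,
               sex_ratio=10 / 21),
    "OB1": dict(n=19, bmi_mean=32.51, bmi_sd=1.69, bmi_range=(30.0, 35.0),
                age_mean=29.89, age_sd=8.16, height_mean=170.15, height_sd=11.99,
                sex_ratio=10 / 19),
    "OB2": dict(n=21, bmi_mean=36.81, bmi_sd=1.39, bmi_range=(35.0, 40.0),
                age_mean=32.62, age_sd=7.92, height_mean=172.26, height_sd=9.74,
                sex_ratio=10 / 21),
    "OB3": dict(n=21, bmi_mean=46.99, bmi_sd=5.81, bmi_range=(40.0, math.inf),
                age_mean=34.05, age_sd=6.64, height_mean=172.08, height_sd=9.72,
                sex_ratio=11 / 21),
}

#: Default clinical panel: (name, intercept at BMI 30, slope per BMI unit,
#: residual SD). A few deliberately BMI-independent parameters are included
#: so the group-difference screen has true nulls to control.
DEFAULT_CLINICAL_PARAMS: tuple[tuple[str, float, float, float], ...] = (
    ("glucose_mmol_l", 5.0, 0.03, 0.50),
    ("triglycerides_mmol_l", 1.2, 0.05, 0.35),
    ("hdl_mmol_l", 1.55, -0.02, 0.20),
    ("ldl_mmol_l", 3.0, 0.04, 0.60),
    ("cholesterol_mmol_l", 4.8, 0.05, 0.70),
    ("alt_u_l", 22.0, 0.8, 8.0),
    ("ast_u_l", 22.0, 0.4, 6.0),
    ("ggt_u_l", 25.0, 0.9, 10.0),
    ("uric_acid_umol_l", 300.0, 3.5, 50.0),
    ("crp_mg_l", 1.5, 0.25, 1.20),
    ("hemoglobin_g_l", 140.0, 0.0, 10.0),
    ("creatinine_umol_l", 75.0, 0.0, 10.0),
)


@dataclass
class SimConfig:
    """Full simulator configuration (cohort + proteome + clinical panel)."""

    groups: list[GroupSpec]
    effects: list[EffectSpec]
    n_noise_proteins: int = 95
    n_ubiquitous: int = 36
    n_singletonish: int = 8
    clinical_params: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_CLINICAL_PARAMS)
    )
    seed: int = 0

    def validate(self) -> None:
        for g in self.groups:
            g.validate()
        ids = [e.protein_id for e in self.effects]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate protein ids among effects")
        for e in self.effects:
            e.validate()
        if min(self.n_noise_proteins, self.n_ubiquitous, self.n_singletonish) < 0:
            raise DataError("protein counts must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "n_noise_proteins": self.n_noise_proteins,
            "n_ubiquitous": self.n_ubiquitous,
            "n_singletonish": self.n_singletonish,
            "clinical_params": [list(p) for p in self.clinical_params],
            "groups": [
                {**asdict(g), "bmi_range": [g.bmi_range[0],
                                            None if math.isinf(g.bmi_range[1]) else g.bmi_range[1]]}
                for g in self.groups
            ],
            "effects": [asdict(e) for e in self.effects],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        groups = []
        for g in doc["groups"]:
            lo, hi = g.pop("bmi_range")
            groups.append(GroupSpec(bmi_range=(lo, math.inf if hi is None else hi), **g))
        effects = [EffectSpec(**e) for e in doc.get("effects", [])]
        cfg = cls(
            groups=groups,
            effects=effects,
            n_noise_proteins=doc.get("n_noise_proteins", 0),
            n_ubiquitous=doc.get("n_ubiquitous", 0),
            n_singletonish=doc.get("n_singletonish", 0),
            clinical_params=[tuple(p) for p in doc.get("clinical_params", [])],
            seed=doc.get("seed", 0),
        )
        cfg.validate()
        return cfg


def default_group_specs() -> list[GroupSpec]:
    """The published five-group cohort layout (n = 22/21/19/21/21)."""
    return [GroupSpec(group=g, **_TABLE1[g]) for g in GROUPS]


def default_effects(
    n_informative: int = 15,
    slope_range: tuple[float, float] = (1.0, 3.0),
    start_index: int = 1,
) -> list[EffectSpec]:
    """Deterministic informative panel: slopes of alternating sign with
    magnitudes evenly spread over ``slope_range``, baselines 0."""
    lo, hi = slope_range
    mags = np.linspace(lo, hi, n_informative) if n_informative > 1 else np.array([hi])
    effects = []
    for k in range(n_informative):
        slope = float(mags[k]) * (1 if k % 2 == 0 else -1)
        effects.append(
            EffectSpec(protein_id=_accession(start_index + k), baseline_logit=0.0,
                       bmi_slope=slope)
        )
    return effects


def default_sim_config(seed: int = 0) -> SimConfig:
    """Default study conditions: the five-group 104-sample cohort, a
    15-protein informative panel, 95 noise, 36 ubiquitous and 8
    singleton-ish proteins (154 columns before filtering)."""
    return SimConfig(groups=default_group_specs(), effects=default_effects(), seed=seed)


def _accession(i: int) -> str:
    """Synthetic UniProt-shaped accession (P-prefixed, zero-padded)."""
    return f"P{i:05d}"


def _trunc_params(mu: float, sigma: float, lo: float, hi: float):
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma if math.isfinite(hi) else math.inf
    return a, b


def _trunc_moments(mu: float, sigma: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = _trunc_params(mu, sigma, lo, hi)
    m, v = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(math.sqrt(v))


def _mu_matching_mean(target_mean: float, sigma: float, lo: float, hi: float) -> float:
    """Solve for mu such that the truncated mean equals target_mean.

    The truncated mean is strictly increasing in mu and spans (lo, hi), so a
    bracketing root always exists for a target strictly inside the range.
    """
    def f(mu: float) -> float:
        return _trunc_moments(mu, sigma, lo, hi)[0] - target_mean

    lo_b = (lo if math.isfinite(lo) else target_mean) - 5.0 * sigma
    hi_b = (hi if math.isfinite(hi) else target_mean) + 5.0 * sigma
    flo, fhi = f(lo_b), f(hi_b)
    k = 0
    while flo > 0 and k < 30:
        lo_b -= 5.0 * sigma
        flo = f(lo_b)
        k += 1
    k = 0
    while fhi < 0 and k < 30:
        hi_b += 5.0 * sigma
        fhi = f(hi_b)
        k += 1
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"cannot bracket mu for mean {target_mean} on [{lo}, {hi}) at sigma={sigma}"
        )
    return float(brentq(f, lo_b, hi_b, xtol=1e-12))


@lru_cache(maxsize=256)
def calibrate_truncated_normal(
    target_mean: float,
    target_sd: float,
    bmi_range: tuple[float, float],
    strict: bool = True,
) -> tuple[float, float]:
    """Normal parameters whose range-truncation has the target moments.

    Matches the mean exactly (1-D root in mu at each sigma) and minimises
    the SD residual over sigma. On a bounded interval the family's SD is
    capped by the uniform limit ``width/sqrt(12)``; a target above the cap
    is infeasible. ``strict=True`` raises :class:`CalibrationError` when the
    best residual exceeds 1e-6, ``strict=False`` returns the closest
    attainable parameters.
    """
    lo, hi = bmi_range
    if not math.isfinite(lo) and not math.isfinite(hi):
        return (target_mean, target_sd)
    if not (lo < target_mean) or (math.isfinite(hi) and not (target_mean < hi)):
        raise CalibrationError(
            f"target mean {target_mean} not inside range [{lo}, {hi})"
        )
    if target_sd <= 0:
        raise CalibrationError("target sd must be positive")

    width = (hi - lo) if math.isfinite(hi) else math.inf

    def sd_at(sigma: float) -> float:
        try:
            mu = _mu_matching_mean(target_mean, sigma, lo, hi)
            return _trunc_moments(mu, sigma, lo, hi)[1]
        except CalibrationError:
            return math.nan  # extreme-tail regime; skipped by the scan

    # sd(sigma) with the mean held matched is not monotone on bounded
    # ranges: it climbs toward the uniform limit and then decays toward a
    # truncated-exponential shape. Scan a sigma grid, root-find on the
    # first bracket containing the target, and fall back to the best grid
    # neighbourhood (closest attainable sd) when no bracket exists.
    span_hi = 50.0 * (width if math.isfinite(width) else target_sd * 10)
    span_lo = max(target_sd / 50.0, 1e-6)
    sigmas = np.geomspace(span_lo, span_hi, 60)
    resid = np.array([sd_at(s) - target_sd for s in sigmas])
    sigma = None
    for a, b, ra, rb in zip(sigmas[:-1], sigmas[1:], resid[:-1], resid[1:]):
        if np.isfinite(ra) and np.isfinite(rb) and ra * rb <= 0:
            sigma = float(brentq(lambda s: sd_at(s) - target_sd, a, b, xtol=1e-12))
            break
    if sigma is None:
        best = int(np.nanargmin(np.abs(resid)))
        bracket = (
            math.log(sigmas[max(best - 1, 0)]),
            math.log(sigmas[min(best + 1, len(sigmas) - 1)]),
        )
        res = minimize_scalar(
            lambda ls: (sd_at(math.exp(ls)) - target_sd) ** 2,
            bounds=bracket, method="bounded", options={"xatol": 1e-12},
        )
        sigma = math.exp(float(res.x))
    mu = _mu_matching_mean(target_mean, sigma, lo, hi)
    achieved_mean, achieved_sd = _trunc_moments(mu, sigma, lo, hi)
    err = max(abs(achieved_mean - target_mean), abs(achieved_sd - target_sd))
    if strict and err > _CALIBRATION_TOL:
        raise CalibrationError(
            f"targets (mean={target_mean}, sd={target_sd}) infeasible on "
            f"[{lo}, {hi}): best achievable sd {achieved_sd:.4f}"
            + (f" (uniform limit {width / math.sqrt(12):.4f})" if math.isfinite(width) else "")
        )
    return (mu, sigma)


def _draw_group_bmi(spec: GroupSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = calibrate_truncated_normal(
        spec.bmi_mean, spec.bmi_sd, spec.bmi_range, strict=False
    )
    lo, hi = spec.bmi_range
    a, b = _trunc_params(mu, sigma, lo, hi)
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def simulate_cohort(config: SimConfig, seed: int | None = None) -> CohortTable:
    """Draw a synthetic cohort from the configured group specs.

    Per group: BMI ~ calibrated range-truncated normal, height and age ~
    normal, sex ~ Bernoulli(female fraction); weight is derived from BMI and
    height so anthropometrics are exactly consistent. Clinical parameter k
    is ``intercept_k + slope_k * (BMI - 30) + N(0, sd_k)``. Fully
    reproducible from the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples: list[Sample] = []
    for spec in config.groups:
        bmi = _draw_group_bmi(spec, spec.n, rng)
        height = rng.normal(spec.height_mean, spec.height_sd, size=spec.n)
        height = np.clip(height, 120.0, 230.0)  # physiological guard, ~never active
        age = rng.normal(spec.age_mean, spec.age_sd, size=spec.n)
        female = rng.random(spec.n) < spec.sex_ratio
        weight = bmi * (height / 100.0) ** 2
        noise = {
            name: rng.normal(0.0, sd, size=spec.n)
            for (name, _, _, sd) in config.clinical_params
        }
        for i in range(spec.n):
            clinical = {
                name: intercept + slope * (bmi[i] - BMI_CENTER) + noise[name][i]
                for (name, intercept, slope, _) in config.clinical_params
            }
            samples.append(
                Sample(
                    sample_id=f"{spec.group}_{i + 1:03d}",
                    group=spec.group,
                    sex="f" if female[i] else "m",
                    age=float(age[i]),
                    height=float(height[i]),
                    weight=float(weight[i]),
                    bmi=float(bmi[i]),
                    clinical=clinical,
                )
            )
    return CohortTable(samples, [p[0] for p in config.clinical_params])


def simulate_proteome(
    cohort: CohortTable, config: SimConfig, seed: int | None = None
) -> tuple[PresenceMatrix, set[str]]:
    """Draw the binary proteome for an existing cohort.

    Returns the presence matrix (columns in lexicographic accession order,
    matching :func:`plasmapattern.io.build_presence_matrix`) and the ground-
    truth set of informative protein ids (nonzero BMI slope).
    """
    if len(cohort) == 0:
        raise DataError("cohort is empty")
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = len(cohort)
    z = (cohort.bmi - BMI_CENTER) / BMI_SCALE

    ids: list[str] = []
    baselines: list[float] = []
    slopes: list[float] = []
    for e in config.effects:
        ids.append(e.protein_id)
        baselines.append(e.baseline_logit)
        slopes.append(e.bmi_slope)
    next_idx = len(config.effects) + 1
    lo, hi = NOISE_LOGIT_RANGE
    for _ in range(config.n_noise_proteins):
        ids.append(_accession(next_idx))
        baselines.append(float(rng.uniform(lo, hi)))
        slopes.append(0.0)
        next_idx += 1
    for _ in range(config.n_ubiquitous):
        ids.append(_accession(next_idx))
        baselines.append(10.0)  # logistic(10) > 0.9999
        slopes.append(0.0)
        next_idx += 1
    p_single = 1.0 / n
    for _ in range(config.n_singletonish):
        ids.append(_accession(next_idx))
        baselines.append(float(math.log(p_single / (1.0 - p_single))))
        slopes.append(0.0)
        next_idx += 1

    a = np.asarray(baselines)
    b = np.asarray(slopes)
    logits = a[None, :] + z[:, None] * b[None, :]
    prob = 1.0 / (1.0 + np.exp(-logits))
    draws = (rng.random(prob.shape) < prob).astype(np.int8)

    order = np.argsort(ids)
    matrix = PresenceMatrix(
        cohort.sample_ids, [ids[j] for j in order], draws[:, order]
    )
    truth = {e.protein_id for e in config.effects if e.bmi_slope != 0.0}
    return matrix, truth
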