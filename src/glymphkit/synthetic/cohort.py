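"""Synthetic cohort tables with planted group effects and mediation structure.

Each table has one row per subject across three groups — healthy controls
(HC), small-vessel-disease patients without cognitive impairment
(CSVD-NCI) and with mild cognitive impairment (CSVD-MCI) — carrying
demographics, vascular risk factors, imaging covariates, raw cognitive
scores, the ALPS index and regional perivascular-space volume fractions.

The exposure -> mediator -> outcome chain is planted as a linear
structural model with X = putamen PVS volume fraction (%), M = ALPS
index, Y = MoCA:

    M = alpha_M(group) + a*X + w_M.cov + eps_M
    Y = alpha_Y(group) + c'*X + b*M + w_Y.cov + eps_Y

Group intercepts are solved so that expected group means of M and Y hit
the targets in the effect model, letting planted mediation coexist with
planted group differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MediationModel", "CovariateModel", "CohortSpec", "make_cohort", "GROUPS"]

GROUPS = ("HC", "CSVD-NCI", "CSVD-MCI")

# regions carrying a PVS volume-fraction column (percent of GM+WM volume)
_PVS_REGIONS = (
    "caudate",
    "putamen",
    "pallidum",
    "amygdala",
    "thalamus",
    "hippocampus",
)


@dataclass
class MediationModel:
    """Structural coefficients of the planted X -> M -> Y chain."""

    a: float = -0.08       # ALPS units per % putamen PVS VF
    b: float = 8.0         # MoCA points per ALPS unit
    c_prime: float = -1.5  # MoCA points per % putamen PVS VF, direct
    sd_m: float = 0.11     # residual SD of the ALPS index
    sd_y: float = 2.5      # residual SD of MoCA

    def __post_init__(self) -> None:
        if self.sd_m < 0 or self.sd_y < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CovariateModel:
    """Distributions of the covariates (per group where they differ) and
    their regression weights into the mediator and outcome."""

    age: dict = field(
        default_factory=lambda: {
            "HC": (60.18, 4.57),
            "CSVD-NCI": (62.38, 6.96),
            "CSVD-MCI": (64.69, 6.62),
        }
    )
    education: dict = field(
        default_factory=lambda: {
            "HC": (9.43, 4.10),
            "CSVD-NCI": (9.09, 3.85),
            "CSVD-MCI": (8.10, 3.80),
        }
    )
    bmi: dict = field(
        default_factory=lambda: {
            "HC": (23.77, 2.28),
            "CSVD-NCI": (23.78, 2.55),
            "CSVD-MCI": (23.89, 3.02),
        }
    )
    # Bernoulli rates per group (male=1 coding for sex)
    sex: dict = field(
        default_factory=lambda: {"HC": 0.475, "CSVD-NCI": 0.5385, "CSVD-MCI": 0.4853}
    )
    hypertension: dict = field(
        default_factory=lambda: {"HC": 0.35, "CSVD-NCI": 0.6346, "CSVD-MCI": 0.6618}
    )
    diabetes: dict = field(
        default_factory=lambda: {"HC": 0.15, "CSVD-NCI": 0.1731, "CSVD-MCI": 0.1765}
    )
    hypercholesterolemia: dict = field(
        default_factory=lambda: {"HC": 0.25, "CSVD-NCI": 0.2885, "CSVD-MCI": 0.2794}
    )
    smoking: dict = field(
        default_factory=lambda: {"HC": 0.125, "CSVD-NCI": 0.3077, "CSVD-MCI": 0.3088}
    )
    lacunes: dict = field(
        default_factory=lambda: {"HC": 0.0, "CSVD-NCI": 0.2692, "CSVD-MCI": 0.2353}
    )
    cmbs: dict = field(
        default_factory=lambda: {"HC": 0.0, "CSVD-NCI": 0.4231, "CSVD-MCI": 0.4853}
    )
    bg_epvs_grade: dict = field(
        default_factory=lambda: {"HC": 0.0, "CSVD-NCI": 0.4808, "CSVD-MCI": 0.7059}
    )
    # ordinal white-matter-hyperintensity grade, rounded clipped normal 0..6
    fazekas: dict = field(
        default_factory=lambda: {
            "HC": (1.0, 1.0),
            "CSVD-NCI": (4.0, 1.2),
            "CSVD-MCI": (5.0, 1.2),
        }
    )
    # regression weights into mediator (ALPS) and outcome (MoCA)
    weights_m: dict = field(default_factory=lambda: {"age": -0.004})
    weights_y: dict = field(default_factory=lambda: {"age": -0.08, "education": 0.15})


def _default_effect_model() -> dict:
    """Per-group target means (and SDs for exogenous variables)."""
    return {
        # target group means of the mediator / outcome (residual SDs live in
        # the mediation model)
        "alps": {"HC": 1.39, "CSVD-NCI": 1.29, "CSVD-MCI": 1.23},
        "moca": {"HC": 25.98, "CSVD-NCI": 25.25, "CSVD-MCI": 19.82},
        # regional PVS VF percent: (mean, sd) per group
        "pvs_vf_putamen": {
            "HC": (1.20, 0.35),
            "CSVD-NCI": (1.55, 0.40),
            "CSVD-MCI": (1.65, 0.40),
        },
        "pvs_vf_caudate": {
            "HC": (0.90, 0.30),
            "CSVD-NCI": (1.20, 0.35),
            "CSVD-MCI": (1.30, 0.35),
        },
        "pvs_vf_pallidum": {
            "HC": (0.60, 0.20),
            "CSVD-NCI": (0.62, 0.20),
            "CSVD-MCI": (0.63, 0.20),
        },
        "pvs_vf_amygdala": {
            "HC": (0.50, 0.20),
            "CSVD-NCI": (0.52, 0.20),
            "CSVD-MCI": (0.52, 0.20),
        },
        "pvs_vf_thalamus": {
            "HC": (0.80, 0.25),
            "CSVD-NCI": (0.82, 0.25),
            "CSVD-MCI": (0.83, 0.25),
        },
        "pvs_vf_hippocampus": {
            "HC": (0.70, 0.25),
            "CSVD-NCI": (0.75, 0.25),
            "CSVD-MCI": (0.95, 0.30),
        },
        # raw cognitive tests: HC (mean, sd) and per-group shift in HC-SD units
        # (times-based tests shift upward = worse)
        "avlt": {"hc": (45.0, 8.0), "shift": {"HC": 0.0, "CSVD-NCI": -0.21, "CSVD-MCI": -1.16}},
        "tmt_b": {"hc": (120.0, 40.0), "shift": {"HC": 0.0, "CSVD-NCI": 0.59, "CSVD-MCI": 2.33}},
        "tmt_a": {"hc": (50.0, 15.0), "shift": {"HC": 0.0, "CSVD-NCI": 0.34, "CSVD-MCI": 1.54}},
        "cdt10": {"hc": (8.5, 1.2), "shift": {"HC": 0.0, "CSVD-NCI": -0.29, "CSVD-MCI": -4.19}},
        "bnt": {"hc": (24.0, 2.5), "shift": {"HC": 0.0, "CSVD-NCI": -0.09, "CSVD-MCI": -2.37}},
    }


@dataclass
class CohortSpec:
    """Specification of a synthetic three-group cohort.

    ``effect_model=None`` disables group effects entirely (zero intercepts,
    standard-normal exposure); ``covariate_model=None`` drops covariate
    columns and covariate terms from the structural model.  The defaults
    emulate the scale of a 40/52/68 HC / CSVD-NCI / CSVD-MCI cohort.
    """

    n_hc: int = 40
    n_nci: int = 52
    n_mci: int = 68
    mediation: MediationModel = field(default_factory=MediationModel)
    covariates: CovariateModel | None = field(default_factory=CovariateModel)
    effect_model: dict | None = field(default_factory=_default_effect_model)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_nci, self.n_mci) <= 0:
            raise ValueError("group counts must be positive")


def _draw_covariates(
    spec: CohortSpec, group: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    cm = spec.covariates
    n = len(group)
    cols: dict[str, np.ndarray] = {}
    for name in ("age", "education", "bmi"):
        params = getattr(cm, name)
        mean = np.array([params[g][0] for g in group])
        sd = np.array([params[g][1] for g in group])
        cols[name] = rng.normal(mean, sd)
    cols["education"] = np.clip(cols["education"], 0.0, None)
    for name in (
        "sex",
        "hypertension",
        "diabetes",
        "hypercholesterolemia",
        "smoking",
        "lacunes",
        "cmbs",
        "bg_epvs_grade",
    ):
        rates = getattr(cm, name)
        p = np.array([rates[g] for g in group])
        cols[name] = (rng.random(n) < p).astype(int)
    fz = cm.fazekas
    mean = np.array([fz[g][0] for g in group])
    sd = np.array([fz[g][1] for g in group])
    cols["fazekas"] = np.clip(np.round(rng.normal(mean, sd)), 0, 6).astype(int)
    return pd.DataFrame(cols)


def _cov_term(cov: pd.DataFrame, weights: dict) -> np.ndarray:
    out = np.zeros(len(cov))
    for name, w in weights.items():
        out = out + w * cov[name].to_numpy(dtype=float)
    return out


def _expected_cov_term(spec: CohortSpec, group: str, weights: dict) -> float:
    """Expected covariate contribution for intercept solving."""
    cm = spec.covariates
    total = 0.0
    for name, w in weights.items():
        params = getattr(cm, name)
        val = params[group]
        mean = val[0] if isinstance(val, tuple) else val
        total += w * mean
    return total


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate the cohort table and a dictionary of the planted truth.

    Bit-reproducible for a fixed spec (single seeded generator, fixed draw
    order).
    """
    rng = np.random.default_rng(spec.seed)
    group = np.array(
        ["HC"] * spec.n_hc + ["CSVD-NCI"] * spec.n_nci + ["CSVD-MCI"] * spec.n_mci
    )
    n = len(group)
    med = spec.mediation
    em = spec.effect_model or {}

    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)], "group": group})
    df["cdr"] = np.where(group == "CSVD-MCI", 0.5, 0.0)

    if spec.covariates is not None:
        cov = _draw_covariates(spec, group, rng)
        df = pd.concat([df, cov], axis=1)
    else:
        cov = None

    # exposure: putamen PVS VF (X); other regional VFs drawn independently
    def _draw_region(name: str) -> np.ndarray:
        if name in em:
            mean = np.array([em[name][g][0] for g in group])
            sd = np.array([em[name][g][1] for g in group])
            return np.clip(rng.normal(mean, sd), 0.0, None)
        return rng.normal(0.0, 1.0, n)

    vf = {r: _draw_region(f"pvs_vf_{r}") for r in _PVS_REGIONS}
    x = vf["putamen"]

    # mediator and outcome via the structural model
    wm = spec.covariates.weights_m if spec.covariates is not None else {}
    wy = spec.covariates.weights_y if spec.covariates is not None else {}
    cov_m = _cov_term(cov, wm) if cov is not None else np.zeros(n)
    cov_y = _cov_term(cov, wy) if cov is not None else np.zeros(n)

    alpha_m = np.zeros(n)
    alpha_y = np.zeros(n)
    if "alps" in em or "moca" in em:
        for g in GROUPS:
            gm = group == g
            ex_x = em[f"pvs_vf_putamen"][g][0] if "pvs_vf_putamen" in em else 0.0
            e_cov_m = _expected_cov_term(spec, g, wm) if cov is not None else 0.0
            e_cov_y = _expected_cov_term(spec, g, wy) if cov is not None else 0.0
            if "alps" in em:
                target_m = em["alps"][g]
                alpha_m[gm] = target_m - med.a * ex_x - e_cov_m
            if "moca" in em:
                target_y = em["moca"][g]
                e_m = em["alps"][g] if "alps" in em else med.a * ex_x + e_cov_m
                alpha_y[gm] = target_y - med.c_prime * ex_x - med.b * e_m - e_cov_y

    eps_m = rng.normal(0.0, med.sd_m, n) if med.sd_m > 0 else np.zeros(n)
    eps_y = rng.normal(0.0, med.sd_y, n) if med.sd_y > 0 else np.zeros(n)
    m = alpha_m + med.a * x + cov_m + eps_m
    y = alpha_y + med.c_prime * x + med.b * m + cov_y + eps_y

    df["alps"] = m
    df["moca"] = y if "moca" not in em else np.clip(y, 0.0, 30.0)

    # raw cognitive tests with group shifts in HC-SD units
    for test in ("avlt", "tmt_a", "tmt_b", "cdt10", "bnt"):
        if test in em:
            hc_mean, hc_sd = em[test]["hc"]
            shift = np.array([em[test]["shift"][g] for g in group])
            vals = rng.normal(hc_mean + shift * hc_sd, hc_sd)
            df[test] = np.clip(vals, 0.0, None)

    # regional VF columns; BG aggregate is the sum of its subdivisions,
    # hemispheric split with a mild left lateralization in patients
    for r in _PVS_REGIONS:
        df[f"pvs_vf_{r}"] = vf[r]
    bg = sum(vf[r] for r in ("caudate", "putamen", "pallidum", "amygdala"))
    df["pvs_vf_bg"] = bg
    lateral = np.where(group == "HC", 0.50, 0.54)
    frac = np.clip(rng.normal(lateral, 0.02), 0.0, 1.0)
    df["pvs_vf_putamen_left"] = vf["putamen"] * frac
    df["pvs_vf_putamen_right"] = vf["putamen"] * (1.0 - frac)
    df["pvs_vf_bg_left"] = bg * frac
    df["pvs_vf_bg_right"] = bg * (1.0 - frac)

    truth = {
        "a": med.a,
        "b": med.b,
        "c_prime": med.c_prime,
        "indirect": med.a * med.b,
        "sd_m": med.sd_m,
        "sd_y": med.sd_y,
        "exposure": "pvs_vf_putamen",
        "mediator": "alps",
        "outcome": "moca",
        "seed": spec.seed,
        "n_per_group": {"HC": spec.n_hc, "CSVD-NCI": spec.n_nci, "CSVD-MCI": spec.n_mci},
    }
    return df, truth
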