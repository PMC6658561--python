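"""Synthetic cohorts with the statistical structure the pipeline assumes.

No raw data accompany the study this pipeline serves, so every downstream
analysis is exercised on simulated cohorts built here:

* a 2x2 animal design (prenatal stress x adult trauma induction) whose
  five-test behavioral battery is driven by a single latent susceptibility
  factor — the shared factor is what makes extremes co-occur across tests
  and lets the 3-of-5 classifier exceed its independence null (~5.8%);
* a four-gene amygdalar expression panel (GILZ, FKBP51, GR, CRF) with
  per-cell means and Gaussian residuals, plus promoter CpG methylation
  coupled to GILZ expression through a Gaussian copula;
* a knockdown experiment (bilateral infection areas -> 1-5 rubric ->
  PTSD-like score rising with total infection);
* a human-style candidate-gene table (trauma-event counts, sex-specific
  expression slopes, male-only methylation coupling, nuisance covariates).

One global seed is split into fixed per-stream sub-seeds, so adding a new
stream never perturbs the draws of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiler import DEFAULT_BATTERY
from .quant import infection_score

__all__ = [
    "CohortParams",
    "PanelParams",
    "KDParams",
    "HumanTableParams",
    "simulate_behavior_cohort",
    "simulate_expression_panel",
    "simulate_kd_experiment",
    "simulate_human_table",
]

# fixed stream ids: appending here never changes earlier streams
_STREAMS = {"cohort": 11, "panel": 23, "kd": 37, "human": 53}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


# ---------------------------------------------------------------------------
# Behavioral cohort
# ---------------------------------------------------------------------------

def _default_cells() -> dict[tuple[str, str], int]:
    # trauma cells sized like the phenotyping cohort (35 control / 46
    # prenatally stressed); no-trauma cells sized like the expression panel
    return {
        ("control", "trauma"): 35,
        ("PNS", "trauma"): 46,
        ("control", "no_trauma"): 8,
        ("PNS", "no_trauma"): 8,
    }


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for the behavioral cohort.

    ``latent_effect`` shifts the latent susceptibility of prenatally
    stressed (PNS) animals; ``test_loadings`` map the latent score onto
    each battery metric (sign-flipped for low-direction tests so that
    higher susceptibility is always more extreme).  The defaults were
    calibrated once, by Monte-Carlo sweep, so that the 3-of-5 classifier
    with pooled 20% cutoffs reproduces the target prevalences of roughly
    8.6% (control) and 26.1% (stressed) in the trauma-exposed cells.
    """

    n_per_group: dict[tuple[str, str], int] = field(default_factory=_default_cells)
    latent_effect: float = 0.75
    test_loadings: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_sd: tuple[float, ...] | float = 0.65
    target_prevalences: dict[str, float] = field(
        default_factory=lambda: {"control": 3 / 35, "PNS": 12 / 46}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one design cell")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("every design cell needs n >= 1")
        sds = self.noise_sds
        if any(s <= 0 for s in sds):
            raise ValueError("noise_sd must be positive")
        if len(self.test_loadings) != len(DEFAULT_BATTERY.tests):
            raise ValueError("one loading per battery test required")
        if any(not 0 <= p <= 1 for p in self.target_prevalences.values()):
            raise ValueError("target prevalences must lie in [0, 1]")

    @property
    def noise_sds(self) -> tuple[float, ...]:
        if np.isscalar(self.noise_sd):
            return (float(self.noise_sd),) * len(self.test_loadings)
        return tuple(float(s) for s in self.noise_sd)


#: plausible raw-metric location/scale per battery test, applied as an
#: affine transform of the standardized simulated metric (does not affect
#: percentile-based classification)
_METRIC_SCALE = {
    "risk_assessment_time": (45.0, 12.0),
    "startle_peak_latency": (38.0, 9.0),
    "ppi_percent": (55.0, 14.0),
    "dark_phase_activity": (320.0, 70.0),
    "marbles_buried_percent": (40.0, 15.0),
}


def simulate_behavior_cohort(params: CohortParams) -> pd.DataFrame:
    """One row per animal: design labels plus the five battery metrics.

    Each animal draws a latent susceptibility z ~ N(0, 1), shifted by
    ``latent_effect`` for PNS animals; metric j is
    ``direction_sign_j * loading_j * z + noise`` mapped onto a realistic
    raw scale.  Deterministic given ``params.seed``.
    """
    rng = _rng(params.seed, "cohort")
    rows = []
    animal = 0
    for (prenatal, adult), n in sorted(params.n_per_group.items()):
        shift = params.latent_effect if prenatal == "PNS" else 0.0
        z = rng.normal(shift, 1.0, size=n)
        metrics = {}
        for j, spec in enumerate(DEFAULT_BATTERY.tests):
            sign = -1.0 if spec.direction == "low" else 1.0
            raw = sign * params.test_loadings[j] * z + rng.normal(
                0.0, params.noise_sds[j], size=n
            )
            loc, scale = _METRIC_SCALE[spec.column]
            metrics[spec.column] = loc + scale * raw
        for i in range(n):
            rows.append(
                {
                    "animal_id": f"A{animal + i:04d}",
                    "prenatal": prenatal,
                    "adult_exposure": adult,
                    "sex": "M",
                    **{c: metrics[c][i] for c in metrics},
                }
            )
        animal += n
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expression / methylation panel
# ---------------------------------------------------------------------------

def _default_cell_means() -> pd.DataFrame:
    # relative expression (fold vs control/no-trauma) chosen to mirror the
    # qualitative effect pattern: GILZ hit by both exposures additively;
    # FKBP51 up and GR/CRF down with adult trauma mainly on the stressed
    # background (interaction-flavored)
    cells = ["control|no_trauma", "PNS|no_trauma", "control|trauma", "PNS|trauma"]
    data = {
        "GILZ": [1.00, 0.75, 0.72, 0.47],
        "FKBP51": [1.00, 1.00, 1.05, 1.45],
        "GR": [1.00, 1.00, 0.92, 0.62],
        "CRF": [1.00, 1.05, 1.00, 0.70],
    }
    return pd.DataFrame(data, index=cells).T


@dataclass(frozen=True)
class PanelParams:
    """Generative parameters for the molecular panel."""

    cell_means: pd.DataFrame = field(default_factory=_default_cell_means)
    residual_sd: float = 0.15
    meth_coupling_r: float = -0.6
    meth_mean_percent: float = 30.0
    meth_spread: float = 0.5  # logit-scale sd of the methylation latent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if abs(self.meth_coupling_r) > 1:
            raise ValueError("|meth_coupling_r| must be <= 1")

    @property
    def gene_names(self) -> list[str]:
        return list(self.cell_means.index)


def simulate_expression_panel(design: pd.DataFrame, params: PanelParams) -> pd.DataFrame:
    """Gene-wise relative expression plus coupled CpG methylation.

    Long format: one row per animal x gene with the design labels, the
    expression value (cell mean + Gaussian residual) and, on each row, the
    animal's promoter %CpG methylation.  Methylation is built by a
    Gaussian copula against the standardized GILZ expression — latent =
    r * z_GILZ + sqrt(1 - r^2) * w — then squashed through a logistic onto
    (0, 100)% so betas stay in range while the target Pearson coupling is
    preserved to first order.
    """
    required = {"animal_id", "prenatal", "adult_exposure"}
    if not required <= set(design.columns):
        raise KeyError(f"design table missing columns: {sorted(required - set(design.columns))}")
    cells = design["prenatal"].astype(str) + "|" + design["adult_exposure"].astype(str)
    unknown = set(cells) - set(params.cell_means.columns)
    if unknown:
        raise ValueError(f"design cells without specified means: {sorted(unknown)}")

    rng = _rng(params.seed, "panel")
    n = len(design)
    expr = {}
    for gene in params.gene_names:
        mu = params.cell_means.loc[gene, cells].to_numpy(dtype=float)
        expr[gene] = mu + rng.normal(0.0, params.residual_sd, size=n)

    gilz = expr.get("GILZ", expr[params.gene_names[0]])
    sd = gilz.std(ddof=0)
    z = (gilz - gilz.mean()) / sd if sd > 0 else np.zeros(n)
    r = params.meth_coupling_r
    latent = r * z + np.sqrt(max(1.0 - r**2, 0.0)) * rng.normal(0.0, 1.0, size=n)
    logit0 = np.log(params.meth_mean_percent / (100.0 - params.meth_mean_percent))
    meth = 100.0 / (1.0 + np.exp(-(logit0 + params.meth_spread * latent)))

    frames = []
    for gene in params.gene_names:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": design["animal_id"].to_numpy(),
                    "prenatal": design["prenatal"].to_numpy(),
                    "adult_exposure": design["adult_exposure"].to_numpy(),
                    "gene": gene,
                    "expression": expr[gene],
                    "percent_methylation": meth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Knockdown experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KDParams:
    """Defaults calibrated once so that thresholding the PTSD-like score at
    >= 3 reproduces prevalences near 6/9 (knockdown) and 1/10 (control
    virus)."""

    kd_intercept: float = 0.45
    cv_mean: float = 2.30
    score_noise_sd: float = 0.55
    area_log_mean: float = 3.1  # per-side infection areas ~ lognormal, mm^2
    area_log_sd: float = 0.75


def simulate_kd_experiment(
    n_kd: int = 9,
    n_cv: int = 10,
    score_slope: float = 0.42,
    seed: int = 0,
    params: KDParams = KDParams(),
) -> pd.DataFrame:
    """Knockdown vs control-virus animals with infection scoring.

    Knockdown animals draw bilateral infection areas (lognormal mm^2),
    scored by the 1-5 rubric per side; their PTSD-like score rises with
    the total infection score at ``score_slope`` plus Gaussian noise.
    Control-virus animals sit at a baseline score.  Scores below 0 are
    clipped; labels use the 3-of-5 battery threshold (score >= 3).
    """
    if n_kd < 1 or n_cv < 1:
        raise ValueError("group sizes must be >= 1")
    rng = _rng(seed, "kd")
    rows = []
    for i in range(n_kd):
        left = float(rng.lognormal(params.area_log_mean, params.area_log_sd))
        right = float(rng.lognormal(params.area_log_mean, params.area_log_sd))
        sc = infection_score(left, right)
        score = params.kd_intercept + score_slope * sc.total + rng.normal(
            0.0, params.score_noise_sd
        )
        score = float(np.clip(score, 0.0, 5.0))
        rows.append(
            dict(animal_id=f"KD{i:02d}", group="KD",
                 left_area_mm2=left, right_area_mm2=right,
                 infection_total=sc.total, ptsd_score=score)
        )
    for i in range(n_cv):
        score = float(np.clip(params.cv_mean + rng.normal(0.0, params.score_noise_sd), 0.0, 5.0))
        rows.append(
            dict(animal_id=f"CV{i:02d}", group="CV",
                 left_area_mm2=np.nan, right_area_mm2=np.nan,
                 infection_total=np.nan, ptsd_score=score)
        )
    df = pd.DataFrame(rows)
    df["label"] = np.where(df["ptsd_score"] >= 3.0, "PTSD-like", "resilient")
    return df


# ---------------------------------------------------------------------------
# Human-style candidate-gene table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HumanTableParams:
    """Generative parameters for the human candidate-gene table.

    Sample sizes and the male-only negative expression-trauma-load slope
    mirror a sex-stratified civilian trauma cohort (~105 male / ~316
    female); trauma-event counts are Poisson, expression is on a log2
    microarray-like scale, and CpG beta values are a clamped-logistic
    function of a latent coupled to expression in males only.
    """

    n_subjects: int = 421
    sex_ratio: float = 105 / 421  # fraction male
    tei_mean: float = 3.0  # Poisson mean of trauma-event counts
    expr_tei_slope_male: float = -0.15
    expr_tei_slope_female: float = 0.0
    meth_expr_slope_male: float = -0.6
    expr_intercept: float = 8.0
    expr_noise_sd: float = 0.6
    meth_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 8:  # covariates + 2
            raise ValueError("n_subjects too small for the covariate model")
        if not 0 < self.sex_ratio < 1:
            raise ValueError("sex_ratio must lie in (0, 1)")
        if self.tei_mean < 0:
            raise ValueError("tei_mean must be >= 0")


def simulate_human_table(params: HumanTableParams) -> pd.DataFrame:
    """Per-subject trauma load, expression, CpG beta and covariates.

    Expression carries a sex-specific slope on the trauma-event count;
    the CpG beta is coupled (through a logistic squash, so betas stay in
    [0, 1]) to standardized expression in males only.  Deterministic given
    ``params.seed``.
    """
    rng = _rng(params.seed, "human")
    n = params.n_subjects
    n_male = int(round(params.sex_ratio * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    tei = rng.poisson(params.tei_mean, size=n).astype(float)
    slope = np.where(sex == "M", params.expr_tei_slope_male, params.expr_tei_slope_female)
    age = np.clip(rng.normal(40.0, 12.0, size=n), 18.0, 75.0)
    substance = rng.binomial(1, 0.4, size=n).astype(float)
    treatment = rng.binomial(1, 0.3, size=n).astype(float)
    ancestry = rng.choice(["anc1", "anc2", "anc3"], size=n, p=[0.6, 0.3, 0.1])
    expr = (
        params.expr_intercept
        + slope * tei
        - 0.005 * (age - 40.0)
        + rng.normal(0.0, params.expr_noise_sd, size=n)
    )
    z = (expr - expr.mean()) / expr.std(ddof=0)
    meth_latent = np.where(
        sex == "M", params.meth_expr_slope_male * z, 0.0
    ) + rng.normal(0.0, params.meth_noise_sd, size=n)
    beta = 1.0 / (1.0 + np.exp(-(np.log(0.25 / 0.75) + 0.7 * meth_latent)))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "tei": tei,
            "expression": expr,
            "cpg_beta": beta,
            "age": age,
            "ancestry": ancestry,
            "substance_use": substance,
            "treatment": treatment,
        }
    )
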