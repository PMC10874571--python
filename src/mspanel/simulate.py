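"""Synthetic clinical-cohort generator.

Emulates the statistical structure of a paired CSF/serum biomarker
discovery cohort: two groups (MS cases and non-MS neurological
controls) with different age and sex distributions, log-normally
distributed analyte concentrations with a configurable correlation
structure and multiplicative group fold-changes, limit-of-detection
censoring, completely-at-random missingness, CSF total-protein
variation, and clinical outcomes (relapse times, an EDSS trajectory
with a first-passage time to sustained EDSS 6, disease-modifying
therapy initiation and administrative censoring) whose hazards depend
log-linearly on latent standardized biomarker levels.

The generator returns the planted ground truth alongside the cohort so
recovery tests can check that the downstream selection machinery finds
what was planted.  Everything is driven by one ``numpy`` Generator:
identical config + seed gives a bit-identical cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import MS, CONTROL, CSF, SERUM, CohortData, Subject
import pandas as pd


@dataclass(frozen=True)
class AnalyteSpec:
    """Distributional parameters for one (analyte, compartment) pair.

    ``ms_fold`` is the multiplicative shift of the MS group's median
    concentration relative to controls (1.0 = no group effect); it
    enters the log-normal model as an additive log(ms_fold) shift.
    """

    name: str
    compartment: str
    log_mean: float
    log_sd: float
    ms_fold: float = 1.0
    lod: float = 0.0


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults mirror the study structure the pipeline is designed for:
    80 controls vs 77 MS cases, control ages 33.2 (SD 10.2) vs MS
    41.9 (SD 12.4) years, 90% vs 60% female, ~7.9 (SD 3.5) years of
    follow-up, 20 CSF + 24 serum analytes with the largest planted CSF
    fold-changes at 4.1 / 3.4 / 2.6 and serum at 1.6 / 1.54.
    """

    n_control: int = 80
    n_ms: int = 77
    control_age_mean: float = 33.2
    control_age_sd: float = 10.2
    ms_age_mean: float = 41.9
    ms_age_sd: float = 12.4
    control_female_frac: float = 0.90
    ms_female_frac: float = 0.60
    analytes: list[AnalyteSpec] = field(default_factory=list)
    correlation: str = "exchangeable"      # "exchangeable" | "block"
    rho: float = 0.2
    block_size: int = 4
    missing_rate: float = 0.05
    # age/sex effects on analyte levels, in Z units per year / per male
    age_slope: float = 0.0
    sex_effect: float = 0.0
    relapse_betas: dict[tuple[str, str], float] = field(default_factory=dict)
    edss6_betas: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_relapse_rate: float = 0.18    # events / year
    baseline_edss6_rate: float = 0.045     # events / year
    dmt_probability: float = 0.6
    dmt_time_mean: float = 2.0             # years, exponential
    followup_mean: float = 7.9
    followup_sd: float = 3.5
    admin_censor_years: float = 15.0
    baseline_edss6_frac: float = 4 / 77
    csf_protein_log_mean: float = float(np.log(0.35))   # mg/mL
    csf_protein_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.analytes:
            self.analytes = default_analytes()
        for p in (self.control_female_frac, self.ms_female_frac,
                  self.missing_rate, self.dmt_probability, self.baseline_edss6_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion {p} outside [0, 1]")
        for a in self.analytes:
            if a.log_sd <= 0:
                raise ValueError(f"{a.name}/{a.compartment}: log_sd must be > 0")
            if a.lod < 0:
                raise ValueError(f"{a.name}/{a.compartment}: negative LOD")
        if self.control_age_sd <= 0 or self.ms_age_sd <= 0:
            raise ValueError("age SDs must be > 0")
        if self.baseline_relapse_rate < 0 or self.baseline_edss6_rate < 0:
            raise ValueError("baseline hazard rates must be non-negative")

    # -- canned scenarios --------------------------------------------------

    @classmethod
    def paper_like(cls, seed: int = 0) -> "SimConfig":
        """The default study-structured scenario (44 analytes, planted folds)."""
        cfg = cls(seed=seed)
        cfg.relapse_betas = {("NfL", CSF): 0.45, ("VDBP", CSF): 0.35}
        cfg.edss6_betas = {("NfL", CSF): 0.8, ("C1inh-C1s", SERUM): 0.5}
        return cfg

    @classmethod
    def null_scenario(cls, seed: int = 0) -> "SimConfig":
        """No group effects, no outcome effects, independent analytes.

        Used for calibration checks: with everything planted at zero the
        per-analyte tests should reject at their nominal level and every
        model metric should sit at chance.
        """
        analytes = [AnalyteSpec(a.name, a.compartment, a.log_mean, a.log_sd,
                                1.0, a.lod) for a in default_analytes()]
        return cls(analytes=analytes, rho=0.0, seed=seed)

    @classmethod
    def recovery_scenario(cls, seed: int = 0) -> "SimConfig":
        """Planted-signal scenario for procedure-recovery tests.

        Ten independent CSF markers: two diagnostic markers with a
        2.0-fold MS shift at log-SD 0.5 (≈1.4 SD each, so each addition
        clears the Δ=0.01 AUC gain over the age+sex baseline), one
        relapse marker with log-hazard 1.0 per Z unit, seven pure noise.
        """
        analytes = [
            AnalyteSpec(f"M{i:02d}", CSF, 3.0 + 0.3 * i, 0.5,
                        2.0 if i in (0, 1) else 1.0, 0.0)
            for i in range(10)
        ]
        cfg = cls(analytes=analytes, rho=0.0, missing_rate=0.0, seed=seed)
        cfg.relapse_betas = {("M02", CSF): 1.0}
        cfg.edss6_betas = {}
        return cfg

    def informative_sets(self):
        diag = {(a.name, a.compartment) for a in self.analytes
                if abs(np.log(a.ms_fold)) > 1e-12}
        return diag, dict(self.relapse_betas), dict(self.edss6_betas)


@dataclass
class PlantedTruth:
    """What was planted: the targets recovery tests must find."""

    informative_diagnostic: set[tuple[str, str]]
    informative_relapse: dict[tuple[str, str], float]
    informative_edss6: dict[tuple[str, str], float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_diagnostic": sorted(map(list, self.informative_diagnostic)),
            "informative_relapse": {f"{a}@{c}": b for (a, c), b in self.informative_relapse.items()},
            "informative_edss6": {f"{a}@{c}": b for (a, c), b in self.informative_edss6.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


_CSF_NAMES = [
    "Ch3L1", "sCD27", "NfL", "osteopontin", "C5", "iC3b", "C9", "TCC",
    "TNFR1", "MCP1", "CXCL12", "IL8", "VDBP", "C3", "fH", "fB", "fI",
    "C1inh-C1s", "CRP", "IL4",
]
_SERUM_NAMES = [
    "Ch3L1", "sCD27", "NfL", "osteopontin", "C5", "iC3b", "C9", "TCC",
    "TNFR1", "MCP1", "CXCL12", "VDBP", "C3", "fH", "fB", "fI",
    "C1inh-C1s", "CRP", "IL4", "GFAP", "BDNF", "CCL27", "CXCL13", "IL18",
]
_CSF_FOLDS = {"sCD27": 4.1, "NfL": 3.4, "iC3b": 2.6, "Ch3L1": 1.8,
              "osteopontin": 1.5, "TNFR1": 1.6, "C9": 1.4, "TCC": 1.5,
              "C5": 1.3, "MCP1": 0.8}
_SERUM_FOLDS = {"NfL": 1.6, "osteopontin": 1.54, "iC3b": 1.3, "C5": 1.2,
                "fB": 1.3, "VDBP": 1.25, "CRP": 1.4, "MCP1": 0.85}


def default_analytes() -> list[AnalyteSpec]:
    """20 CSF + 24 serum analytes with study-like planted fold-changes.

    Log-means are spread over a realistic pg/mL-to-µg/mL span; the LOD
    sits 1.8 log-SDs below the control log-mean, leaving a few percent
    of control measurements below detection.
    """
    specs: list[AnalyteSpec] = []
    for i, name in enumerate(_CSF_NAMES):
        mu, sd = 2.0 + 0.35 * i, 0.6
        specs.append(AnalyteSpec(name, CSF, mu, sd, _CSF_FOLDS.get(name, 1.0),
                                 lod=float(np.exp(mu - 1.8 * sd))))
    for i, name in enumerate(_SERUM_NAMES):
        mu, sd = 3.0 + 0.3 * i, 0.55
        specs.append(AnalyteSpec(name, SERUM, mu, sd, _SERUM_FOLDS.get(name, 1.0),
                                 lod=float(np.exp(mu - 1.8 * sd))))
    return specs


# ---------------------------------------------------------------------------
# Generation


def _correlation_matrix(config: SimConfig) -> np.ndarray:
    m = len(config.analytes)
    rho = config.rho
    if config.correlation == "exchangeable":
        corr = np.full((m, m), rho)
    elif config.correlation == "block":
        corr = np.zeros((m, m))
        for start in range(0, m, config.block_size):
            stop = min(start + config.block_size, m)
            corr[start:stop, start:stop] = rho
    else:
        raise ValueError(f"unknown correlation structure {config.correlation!r}")
    np.fill_diagonal(corr, 1.0)
    # cheap positive-definiteness check before Cholesky
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        raise ValueError(f"rho={rho} does not yield a valid correlation matrix")
    return corr


def _truncated_normal(rng, mean, sd, low, size):
    """Draws truncated to (low, inf) whose MEAN equals ``mean``.

    The location parameter is recentred (fixed-point on the truncated-
    normal mean formula) so truncation does not bias the group mean
    away from the configured value.
    """
    from scipy import stats as _st
    mu = mean
    for _ in range(50):
        alpha = (low - mu) / sd
        tail = _st.norm.sf(alpha)
        shift = sd * _st.norm.pdf(alpha) / tail
        new_mu = mean - shift
        if abs(new_mu - mu) < 1e-10:
            break
        mu = new_mu
    out = rng.normal(mu, sd, size=size)
    while True:
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))


def generate_cohort(config: SimConfig, seed: int | None = None
                    ) -> tuple[CohortData, PlantedTruth]:
    """Draw one synthetic cohort plus its planted ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_control + config.n_ms
    is_ms = np.concatenate([np.zeros(config.n_control, bool),
                            np.ones(config.n_ms, bool)])

    ages = np.where(
        is_ms,
        _truncated_normal(rng, config.ms_age_mean, config.ms_age_sd, 18.0, n),
        _truncated_normal(rng, config.control_age_mean, config.control_age_sd, 18.0, n),
    )
    female = np.where(
        is_ms,
        rng.random(n) < config.ms_female_frac,
        rng.random(n) < config.control_female_frac,
    )

    corr = _correlation_matrix(config)
    chol = np.linalg.cholesky(corr)
    z_latent = rng.standard_normal((n, len(config.analytes))) @ chol.T
    if config.age_slope or config.sex_effect:
        z_latent = z_latent + np.outer(
            config.age_slope * (ages - 40.0) + config.sex_effect * (~female),
            np.ones(len(config.analytes)))

    log_conc = np.empty_like(z_latent)
    for j, a in enumerate(config.analytes):
        shift = np.log(a.ms_fold) * is_ms
        log_conc[:, j] = a.log_mean + shift + a.log_sd * z_latent[:, j]
    conc = np.exp(log_conc)

    below = np.zeros_like(conc, dtype=bool)
    for j, a in enumerate(config.analytes):
        below[:, j] = conc[:, j] < a.lod
    missing = rng.random(conc.shape) < config.missing_rate

    subject_ids = [f"S{i:04d}" for i in range(n)]
    protein = np.exp(rng.normal(config.csf_protein_log_mean,
                                config.csf_protein_log_sd, size=n))

    subjects = [
        Subject(subject_id=subject_ids[i],
                group=MS if is_ms[i] else CONTROL,
                age_at_sampling=float(ages[i]),
                sex="F" if female[i] else "M")
        for i in range(n)
    ]

    z_frame = pd.DataFrame(
        z_latent, index=subject_ids,
        columns=pd.MultiIndex.from_tuples(
            [(a.name, a.compartment) for a in config.analytes]),
    )
    generate_outcomes(subjects, z_frame, config, rng)

    records = []
    for i, sid in enumerate(subject_ids):
        for j, a in enumerate(config.analytes):
            if missing[i, j]:
                records.append((sid, a.name, a.compartment, np.nan, False, False))
            elif below[i, j]:
                records.append((sid, a.name, a.compartment, np.nan, True, False))
            else:
                records.append((sid, a.name, a.compartment, float(conc[i, j]), False, False))
    panel = pd.DataFrame(records, columns=["subject_id", "analyte", "compartment",
                                           "concentration", "below_lod", "imputed"])

    cohort = CohortData(
        subjects=subjects, panel=panel,
        csf_total_protein={sid: float(p) for sid, p in zip(subject_ids, protein)},
    )
    diag, relapse, edss6 = config.informative_sets()
    return cohort, PlantedTruth(diag, relapse, edss6)


def generate_outcomes(subjects: list[Subject], z_latent: pd.DataFrame,
                      config: SimConfig, rng: np.random.Generator) -> None:
    """Fill clinical outcome fields on MS subjects in place.

    Relapses follow a Poisson process with per-subject rate
    ``baseline_relapse_rate * exp(sum(beta * Z))``; the first-passage
    time to sustained EDSS 6 is exponential with the analogous rate.
    Follow-up is truncated-normal, capped at ``admin_censor_years``.
    DMT starts with probability ``dmt_probability`` at an exponential
    time.  A configured fraction of MS subjects starts at EDSS >= 6.
    Controls get a follow-up duration and nothing else.
    """
    def linpred(betas: dict[tuple[str, str], float], sid: str) -> float:
        total = 0.0
        for key, beta in betas.items():
            if key not in z_latent.columns:
                raise KeyError(f"outcome beta refers to unknown analyte {key}")
            total += beta * float(z_latent.loc[sid, key])
        return total

    ms_subjects = [s for s in subjects if s.is_ms]
    n_baseline_high = int(round(config.baseline_edss6_frac * len(ms_subjects)))
    high_idx = set(rng.choice(len(ms_subjects), size=n_baseline_high,
                              replace=False)) if n_baseline_high else set()

    for s in subjects:
        fu = float(np.clip(rng.normal(config.followup_mean, config.followup_sd),
                           0.5, config.admin_censor_years))
        s.followup_years = round(fu, 6)
        if not s.is_ms:
            continue

    for k, s in enumerate(ms_subjects):
        fu = s.followup_years

        # relapses: homogeneous Poisson process at the subject's rate
        rate = config.baseline_relapse_rate * float(
            np.exp(linpred(config.relapse_betas, s.subject_id)))
        if rate < 0:
            raise ValueError("negative relapse rate")
        t, times = 0.0, []
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t >= fu:
                break
            times.append(round(t, 6))
        s.relapse_times = times

        # DMT initiation
        if rng.random() < config.dmt_probability:
            dmt = rng.exponential(config.dmt_time_mean)
            if dmt < fu:
                s.dmt_start_years = round(float(dmt), 6)
                s.dmt_ever = True

        # EDSS: baseline score, then a first passage to sustained >= 6
        if k in high_idx:
            base = float(rng.choice([6.0, 6.5, 7.0, 7.5]))
            t6 = 0.0
        else:
            base = float(rng.choice([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]))
            rate6 = config.baseline_edss6_rate * float(
                np.exp(linpred(config.edss6_betas, s.subject_id)))
            if rate6 < 0:
                raise ValueError("negative EDSS-6 rate")
            t6 = rng.exponential(1.0 / rate6) if rate6 > 0 else np.inf
        s.baseline_edss = base

        visits = []
        score = base
        for vt in np.arange(1.0, fu, 1.0):
            if vt >= t6:
                score = max(6.0, score)
                score = min(9.5, score + float(rng.choice([0.0, 0.0, 0.5])))
            else:
                score = float(np.clip(score + rng.choice([-0.5, 0.0, 0.0, 0.5]),
                                      0.0, 5.5))
            visits.append((round(float(vt), 6), score))
        s.edss_visits = visits
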