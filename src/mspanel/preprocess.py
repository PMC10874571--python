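"""Panel preprocessing: detectability filtering, half-LOD imputation,
CSF total-protein adjustment, Z-standardisation and control-anchored
age/sex residualisation.

The pipeline order is fixed and enforced through the cohort's
``processing`` history::

    filter_detectable -> impute_below_lod -> adjust_csf_total_protein
        -> zscore_panel -> residualize_on_controls

Each operation records itself and refuses to run out of order (or, for
the protein adjustment, twice).  The total-protein step divides every
CSF concentration by the subject's CSF total protein, normalising for
differences in blood-brain-barrier permeability between groups; it can
be skipped entirely, in which case Z-scoring accepts the unadjusted
cohort when told so explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CSF, CohortData, Subject

logger = logging.getLogger(__name__)

FILTER = "filter_detectable"
IMPUTE = "impute_below_lod"
ADJUST = "adjust_csf_total_protein"


class PipelineOrderError(RuntimeError):
    """A preprocessing step was applied out of the mandated order."""


@dataclass
class AnalyteProvenance:
    mean: float
    sd: float
    n_valid: int
    n_imputed: int
    adjusted_for_protein: bool = False
    residualised: bool = False
    # control-cohort age/sex model, populated by residualisation
    age_slope: float | None = None
    age_slope_se: float | None = None
    sex_effect: float | None = None
    sex_effect_se: float | None = None


@dataclass
class StandardizedPanel:
    """Z-scored feature matrix: subjects x (analyte, compartment).

    ``features`` is a wide DataFrame indexed by subject_id with a
    (analyte, compartment) column MultiIndex; NaN marks missing.
    """

    features: pd.DataFrame
    provenance: dict[tuple[str, str], AnalyteProvenance]
    dropped_analytes: list[tuple[str, str, str]] = field(default_factory=list)

    def markers(self) -> list[tuple[str, str]]:
        return list(self.features.columns)

    def column(self, analyte: str, compartment: str) -> pd.Series:
        return self.features[(analyte, compartment)]

    def to_long(self) -> pd.DataFrame:
        long = self.features.stack(["analyte", "compartment"], future_stack=True)
        long = long.rename("z").reset_index()
        long.columns = ["subject_id", "analyte", "compartment", "z"]
        return long.dropna(subset=["z"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "StandardizedPanel":
        wide = long.pivot_table(index="subject_id",
                                columns=["analyte", "compartment"],
                                values="z", aggfunc="first", dropna=False)
        prov = {key: AnalyteProvenance(np.nan, np.nan,
                                       int(wide[key].notna().sum()), 0)
                for key in wide.columns}
        return cls(features=wide, provenance=prov)


def _require(cohort: CohortData, *steps: str) -> None:
    for step in steps:
        if step not in cohort.processing:
            raise PipelineOrderError(
                f"step requires {step!r} to have been applied first "
                f"(history: {cohort.processing})")


def filter_detectable(cohort: CohortData, min_detect_frac: float = 0.5
                      ) -> tuple[CohortData, list[tuple[str, str, str]]]:
    """Drop analyte/compartment pairs detectable in too few samples.

    A pair is kept when the fraction of its measurements that are
    non-missing and above the LOD is at least ``min_detect_frac``
    (default 0.5: detectable in at least half the samples).  Dropping
    is per compartment, so an analyte undetectable in CSF can survive
    in serum.
    """
    if not 0.0 < min_detect_frac <= 1.0:
        raise ValueError("min_detect_frac must be in (0, 1]")
    out = cohort.copy()
    dropped: list[tuple[str, str, str]] = []
    keep_mask = pd.Series(True, index=out.panel.index)
    for (analyte, compartment), grp in out.panel.groupby(["analyte", "compartment"],
                                                         sort=False):
        detected = ((~grp["below_lod"]) & grp["concentration"].notna()).sum()
        if detected / len(grp) < min_detect_frac:
            dropped.append((analyte, compartment, "undetectable"))
            keep_mask[grp.index] = False
    out.panel = out.panel[keep_mask].reset_index(drop=True)
    out.processing.append(FILTER)
    return out, dropped


def impute_below_lod(cohort: CohortData,
                     lods: dict[tuple[str, str], float] | None = None) -> CohortData:
    """Impute below-LOD cells at half the minimum detectable value.

    The minimum detectable value defaults to the smallest observed
    above-LOD concentration for that analyte/compartment in this
    cohort; an explicit assay LOD supplied in ``lods`` takes
    precedence.  Detected values are untouched.
    """
    _require(cohort, FILTER)
    out = cohort.copy()
    panel = out.panel
    for (analyte, compartment), grp in panel.groupby(["analyte", "compartment"],
                                                     sort=False):
        below_idx = grp.index[grp["below_lod"] & ~grp["imputed"]]
        if len(below_idx) == 0:
            continue
        if lods and (analyte, compartment) in lods:
            floor = lods[(analyte, compartment)]
        else:
            observed = grp.loc[(~grp["below_lod"]) & grp["concentration"].notna(),
                               "concentration"]
            if observed.empty:
                raise ValueError(
                    f"{analyte}/{compartment}: no above-LOD values to impute from "
                    "(should have been filtered)")
            floor = float(observed.min())
        panel.loc[below_idx, "concentration"] = 0.5 * floor
        panel.loc[below_idx, "imputed"] = True
    out.processing.append(IMPUTE)
    return out


def adjust_csf_total_protein(cohort: CohortData) -> CohortData:
    """Divide CSF concentrations by the subject's CSF total protein.

    Normalises CSF analyte levels to per-mg-total-protein units so
    group differences in blood-brain-barrier permeability do not
    masquerade as analyte differences.  Serum is untouched.  Subjects
    missing a total-protein value have their CSF cells set missing
    (logged); the operation refuses to run twice.
    """
    _require(cohort, IMPUTE)
    if ADJUST in cohort.processing:
        raise PipelineOrderError("CSF total-protein adjustment already applied")
    out = cohort.copy()
    panel = out.panel
    csf_rows = panel["compartment"] == CSF
    for sid in panel.loc[csf_rows, "subject_id"].unique():
        tp = out.csf_total_protein.get(sid)
        rows = csf_rows & (panel["subject_id"] == sid)
        if tp is None:
            logger.warning("subject %s has CSF measurements but no total protein; "
                           "setting CSF cells missing", sid)
            panel.loc[rows, "concentration"] = np.nan
            panel.loc[rows, ["below_lod", "imputed"]] = False
            continue
        if tp <= 0:
            raise ValueError(f"subject {sid}: non-positive CSF total protein {tp}")
        panel.loc[rows, "concentration"] = panel.loc[rows, "concentration"] / tp
    out.processing.append(ADJUST)
    return out


def zscore_panel(cohort: CohortData, require_adjusted: bool = True
                 ) -> StandardizedPanel:
    """Standardize each analyte to zero mean, unit SD over valid data.

    The mean and sample SD (n-1 denominator) pool all non-missing
    values across both groups.  Constant analytes are dropped with
    reason "constant" rather than silently kept.  Pass
    ``require_adjusted=False`` when the total-protein step was
    deliberately skipped.
    """
    _require(cohort, FILTER, IMPUTE)
    if require_adjusted:
        _require(cohort, ADJUST)
    wide = cohort.wide()
    features = {}
    provenance: dict[tuple[str, str], AnalyteProvenance] = {}
    dropped: list[tuple[str, str, str]] = []
    n_imputed = cohort.panel[cohort.panel["imputed"]].groupby(
        ["analyte", "compartment"]).size()
    for key in wide.columns:
        col = wide[key]
        valid = col.dropna()
        mean = float(valid.mean())
        sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0:
            dropped.append((key[0], key[1], "constant"))
            continue
        features[key] = (col - mean) / sd
        provenance[key] = AnalyteProvenance(
            mean=mean, sd=sd, n_valid=int(len(valid)),
            n_imputed=int(n_imputed.get(key, 0)),
            adjusted_for_protein=ADJUST in cohort.processing,
        )
    frame = pd.DataFrame(features, index=wide.index)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["analyte", "compartment"])
    return StandardizedPanel(features=frame, provenance=provenance,
                             dropped_analytes=dropped)


def residualize_on_controls(panel: StandardizedPanel, subjects: list[Subject]
                            ) -> StandardizedPanel:
    """Remove the physiological age/sex signal estimated in controls.

    Per analyte, fits OLS ``Z ~ intercept + age + sex`` on control
    subjects only (sex coded F=0, M=1), then subtracts the fitted
    values from every subject's Z so that only disease-related
    variation remains.  The fitted slopes and their standard errors are
    stored in provenance.
    """
    info = pd.DataFrame({
        "age": [s.age_at_sampling for s in subjects],
        "male": [1.0 if s.sex == "M" else 0.0 for s in subjects],
        "is_control": [not s.is_ms for s in subjects],
    }, index=[s.subject_id for s in subjects])
    info = info.reindex(panel.features.index)

    out = panel.features.copy()
    provenance = {k: AnalyteProvenance(**vars(v)) for k, v in panel.provenance.items()}
    design_all = sm.add_constant(info[["age", "male"]].astype(float), has_constant="add")
    for key in panel.features.columns:
        z = panel.features[key]
        mask = info["is_control"].fillna(False).astype(bool) & z.notna()
        if int(mask.sum()) < 3:
            raise ValueError(f"{key}: fewer than 3 control subjects with data")
        X = design_all[mask.to_numpy()]
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"{key}: rank-deficient age/sex design in controls "
                             "(e.g. single-sex control cohort)")
        fit = sm.OLS(z[mask.to_numpy()].astype(float), X).fit()
        predicted = design_all.to_numpy() @ fit.params.to_numpy()
        out[key] = z - predicted
        rec = provenance[key]
        rec.residualised = True
        rec.age_slope = float(fit.params["age"])
        rec.age_slope_se = float(fit.bse["age"])
        rec.sex_effect = float(fit.params["male"])
        rec.sex_effect_se = float(fit.bse["male"])
    return StandardizedPanel(features=out, provenance=provenance,
                             dropped_analytes=list(panel.dropped_analytes))


def standardize_cohort(cohort: CohortData, min_detect_frac: float = 0.5,
                       adjust_protein: bool = True, residualize: bool = False,
                       lods: dict[tuple[str, str], float] | None = None,
                       ) -> tuple[CohortData, StandardizedPanel]:
    """Run the full preprocessing pipeline in its mandated order.

    Returns the processed cohort (post-imputation/adjustment
    concentrations, as used for fold changes) and the standardized
    panel used by all downstream models.
    """
    filtered, dropped = filter_detectable(cohort, min_detect_frac)
    imputed = impute_below_lod(filtered, lods=lods)
    adjusted = adjust_csf_total_protein(imputed) if adjust_protein else imputed
    panel = zscore_panel(adjusted, require_adjusted=adjust_protein)
    panel.dropped_analytes = dropped + panel.dropped_analytes
    if residualize:
        panel = residualize_on_controls(panel, cohort.subjects)
    return adjusted, panel
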