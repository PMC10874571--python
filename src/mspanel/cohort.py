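"""Cohort domain types and tabular I/O.

A cohort couples subject-level clinical records (group, demographics,
relapse history, EDSS trajectory, disease-modifying-therapy exposure)
with a long-format panel of per-analyte, per-compartment concentration
measurements.  Below-LOD and missing are distinct states and are carried
as separate flags on every measurement; times are years since sampling.

On disk a cohort is a directory of three UTF-8 comma-separated files:

``subjects.csv``
    subject_id, group, age, sex, followup_years, baseline_edss,
    dmt_start_years, dmt_ever, relapse_times (semicolon-separated),
    csf_total_protein
``edss.csv``
    subject_id, time_years, edss
``panel.csv``
    subject_id, analyte, compartment, value (numeric, "<LOD" or empty),
    below_lod, imputed

The explicit flag columns in ``panel.csv`` make the round trip lossless
even after imputation has assigned numeric values to below-LOD cells;
files without them (bare "<LOD" / empty encoding) load equally well.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MS = "MS"
CONTROL = "CONTROL"
CSF = "CSF"
SERUM = "SERUM"

LOD_TOKEN = "<LOD"

SUBJECT_COLUMNS = [
    "subject_id", "group", "age", "sex", "followup_years", "baseline_edss",
    "dmt_start_years", "dmt_ever", "relapse_times", "csf_total_protein",
]
PANEL_COLUMNS = ["subject_id", "analyte", "compartment", "value", "below_lod", "imputed"]
EDSS_COLUMNS = ["subject_id", "time_years", "edss"]


class CohortError(ValueError):
    """Malformed cohort file or invalid cohort content."""


@dataclass
class Subject:
    """One participant: demographics plus (for MS cases) clinical outcomes."""

    subject_id: str
    group: str                       # MS | CONTROL
    age_at_sampling: float           # years
    sex: str                         # F | M
    followup_years: float = 0.0
    baseline_edss: float | None = None
    dmt_start_years: float | None = None
    dmt_ever: bool = False
    relapse_times: list[float] = field(default_factory=list)
    edss_visits: list[tuple[float, float]] = field(default_factory=list)

    @property
    def is_ms(self) -> bool:
        return self.group == MS


@dataclass
class CohortData:
    """Subjects plus the long-format measurement panel.

    ``panel`` columns: subject_id, analyte, compartment, concentration
    (float, NaN when absent), below_lod (bool), imputed (bool).
    ``processing`` records preprocessing steps already applied, in order;
    the preprocessing operations use it to enforce their pipeline order.
    """

    subjects: list[Subject]
    panel: pd.DataFrame
    csf_total_protein: dict[str, float] = field(default_factory=dict)
    processing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in ["subject_id", "analyte", "compartment",
                               "concentration", "below_lod", "imputed"]
                   if c not in self.panel.columns]
        if missing:
            raise CohortError(f"panel missing columns: {missing}")

    # -- convenience views -------------------------------------------------

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subjects_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age_at_sampling,
                "sex": s.sex,
                "followup_years": s.followup_years,
                "baseline_edss": s.baseline_edss,
                "dmt_start_years": s.dmt_start_years,
                "dmt_ever": s.dmt_ever,
            })
        return pd.DataFrame(rows)

    def wide(self) -> pd.DataFrame:
        """Subjects x (analyte, compartment) concentration matrix."""
        wide = self.panel.pivot(
            index="subject_id", columns=["analyte", "compartment"],
            values="concentration",
        ).reindex([s.subject_id for s in self.subjects])
        return wide.sort_index(axis=1)

    def analyte_pairs(self) -> list[tuple[str, str]]:
        pairs = self.panel[["analyte", "compartment"]].drop_duplicates()
        return [tuple(r) for r in pairs.itertuples(index=False)]

    def copy(self) -> "CohortData":
        return CohortData(
            subjects=[replace(s, relapse_times=list(s.relapse_times),
                              edss_visits=list(s.edss_visits))
                      for s in self.subjects],
            panel=self.panel.copy(),
            csf_total_protein=dict(self.csf_total_protein),
            processing=list(self.processing),
        )


# ---------------------------------------------------------------------------
# I/O


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float) and np.isnan(x):
        return ""
    return repr(float(x))


def _parse_float(tok: str, where: str) -> float | None:
    tok = tok.strip()
    if tok == "":
        return None
    try:
        return float(tok)
    except ValueError:
        raise CohortError(f"{where}: cannot parse {tok!r} as a number") from None


def write_cohort(cohort: CohortData, path: str | Path) -> Path:
    """Write a cohort directory in the documented CSV dialect.

    Missing values are written as empty cells, never as 0; below-LOD
    cells without an imputed value are written as the "<LOD" token.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    buf = io.StringIO()
    buf.write(",".join(SUBJECT_COLUMNS) + "\n")
    for s in cohort.subjects:
        tp = cohort.csf_total_protein.get(s.subject_id)
        buf.write(",".join([
            s.subject_id, s.group, _fmt(s.age_at_sampling), s.sex,
            _fmt(s.followup_years), _fmt(s.baseline_edss),
            _fmt(s.dmt_start_years), str(bool(s.dmt_ever)),
            ";".join(_fmt(t) for t in s.relapse_times), _fmt(tp),
        ]) + "\n")
    (path / "subjects.csv").write_text(buf.getvalue(), encoding="utf-8")

    buf = io.StringIO()
    buf.write(",".join(EDSS_COLUMNS) + "\n")
    for s in cohort.subjects:
        for t, e in s.edss_visits:
            buf.write(f"{s.subject_id},{_fmt(t)},{_fmt(e)}\n")
    (path / "edss.csv").write_text(buf.getvalue(), encoding="utf-8")

    buf = io.StringIO()
    buf.write(",".join(PANEL_COLUMNS) + "\n")
    for row in cohort.panel.itertuples(index=False):
        conc = row.concentration
        if row.below_lod and not row.imputed:
            value = LOD_TOKEN
        elif conc is None or (isinstance(conc, float) and np.isnan(conc)):
            value = ""
        else:
            value = repr(float(conc))
        buf.write(f"{row.subject_id},{row.analyte},{row.compartment},"
                  f"{value},{bool(row.below_lod)},{bool(row.imputed)}\n")
    (path / "panel.csv").write_text(buf.getvalue(), encoding="utf-8")
    return path


def load_cohort(path: str | Path) -> CohortData:
    """Load a cohort directory written by :func:`write_cohort`.

    "<LOD" cells parse to below_lod=True with an absent concentration;
    empty cells parse to missing.  Neither is ever coerced to 0.
    """
    path = Path(path)
    for name in ("subjects.csv", "panel.csv"):
        if not (path / name).exists():
            raise CohortError(f"missing cohort file: {path / name}")

    sub_df = pd.read_csv(path / "subjects.csv", dtype=str, keep_default_na=False)
    for col in SUBJECT_COLUMNS:
        if col not in sub_df.columns:
            raise CohortError(f"subjects.csv missing column {col!r}")

    edss_path = path / "edss.csv"
    visits: dict[str, list[tuple[float, float]]] = {}
    if edss_path.exists():
        edss_df = pd.read_csv(edss_path, dtype=str, keep_default_na=False)
        for col in EDSS_COLUMNS:
            if col not in edss_df.columns:
                raise CohortError(f"edss.csv missing column {col!r}")
        for i, row in enumerate(edss_df.itertuples(index=False), start=2):
            t = _parse_float(row.time_years, f"edss.csv row {i} col time_years")
            e = _parse_float(row.edss, f"edss.csv row {i} col edss")
            if t is None or e is None:
                raise CohortError(f"edss.csv row {i}: empty time or score")
            visits.setdefault(row.subject_id, []).append((t, e))

    subjects: list[Subject] = []
    protein: dict[str, float] = {}
    seen_ids: set[str] = set()
    for i, row in enumerate(sub_df.itertuples(index=False), start=2):
        where = f"subjects.csv row {i}"
        sid = row.subject_id.strip()
        if not sid:
            raise CohortError(f"{where}: empty subject_id")
        if sid in seen_ids:
            raise CohortError(f"{where}: duplicate subject_id {sid!r}")
        seen_ids.add(sid)
        if row.group not in (MS, CONTROL):
            raise CohortError(f"{where} col group: {row.group!r} not in {{MS, CONTROL}}")
        if row.sex not in ("F", "M"):
            raise CohortError(f"{where} col sex: {row.sex!r} not in {{F, M}}")
        age = _parse_float(row.age, f"{where} col age")
        if age is None:
            raise CohortError(f"{where} col age: required")
        relapses = [t for t in (
            _parse_float(tok, f"{where} col relapse_times")
            for tok in row.relapse_times.split(";") if tok.strip() != ""
        ) if t is not None]
        subjects.append(Subject(
            subject_id=sid,
            group=row.group,
            age_at_sampling=age,
            sex=row.sex,
            followup_years=_parse_float(row.followup_years, f"{where} col followup_years") or 0.0,
            baseline_edss=_parse_float(row.baseline_edss, f"{where} col baseline_edss"),
            dmt_start_years=_parse_float(row.dmt_start_years, f"{where} col dmt_start_years"),
            dmt_ever=row.dmt_ever.strip().lower() in ("true", "1", "yes"),
            relapse_times=relapses,
            edss_visits=sorted(visits.get(sid, [])),
        ))
        tp = _parse_float(row.csf_total_protein, f"{where} col csf_total_protein")
        if tp is not None:
            protein[sid] = tp

    panel_df = pd.read_csv(path / "panel.csv", dtype=str, keep_default_na=False)
    for col in ("subject_id", "analyte", "compartment", "value"):
        if col not in panel_df.columns:
            raise CohortError(f"panel.csv missing column {col!r}")
    has_flags = "below_lod" in panel_df.columns

    records = []
    seen_keys: set[tuple[str, str, str]] = set()
    for i, row in enumerate(panel_df.itertuples(index=False), start=2):
        where = f"panel.csv row {i}"
        key = (row.subject_id, row.analyte, row.compartment)
        if key in seen_keys:
            raise CohortError(f"{where}: duplicate measurement key {key}")
        seen_keys.add(key)
        if row.compartment not in (CSF, SERUM):
            raise CohortError(f"{where} col compartment: {row.compartment!r}")
        value = row.value.strip()
        if value == LOD_TOKEN:
            conc, below, imputed = np.nan, True, False
        elif value == "":
            conc, below, imputed = np.nan, False, False
        else:
            conc = _parse_float(value, f"{where} col value")
            below = has_flags and row.below_lod.strip().lower() == "true"
            imputed = has_flags and row.imputed.strip().lower() == "true"
        records.append((row.subject_id, row.analyte, row.compartment, conc, below, imputed))

    panel = pd.DataFrame(records, columns=["subject_id", "analyte", "compartment",
                                           "concentration", "below_lod", "imputed"])
    cohort = CohortData(subjects=subjects, panel=panel, csf_total_protein=protein)
    report = validate_cohort(cohort)
    if report:
        raise CohortError("invalid cohort:\n" + "\n".join(report))
    return cohort


# ---------------------------------------------------------------------------
# Validation


def validate_cohort(cohort: CohortData) -> list[str]:
    """Check every structural invariant; an empty report means valid."""
    report: list[str] = []
    ids = {s.subject_id for s in cohort.subjects}

    for s in cohort.subjects:
        if s.age_at_sampling <= 0:
            report.append(f"{s.subject_id}: non-positive age {s.age_at_sampling}")
        if s.followup_years < 0:
            report.append(f"{s.subject_id}: negative follow-up {s.followup_years}")
        if any(t2 <= t1 for t1, t2 in zip(s.relapse_times, s.relapse_times[1:])):
            report.append(f"{s.subject_id}: relapse times not strictly increasing")
        if any(t > s.followup_years + 1e-12 for t in s.relapse_times):
            report.append(f"{s.subject_id}: relapse after end of follow-up")
        times = [t for t, _ in s.edss_visits]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            report.append(f"{s.subject_id}: EDSS visit times decrease")
        if s.dmt_start_years is not None and s.dmt_start_years > s.followup_years + 1e-12:
            report.append(f"{s.subject_id}: DMT start after end of follow-up")
        if s.baseline_edss is not None and not _valid_edss(s.baseline_edss):
            report.append(f"{s.subject_id}: baseline EDSS {s.baseline_edss} not on the 0-10 half-point scale")
        if not s.is_ms and (s.relapse_times or s.dmt_ever or s.dmt_start_years is not None
                            or s.baseline_edss is not None or s.edss_visits):
            report.append(f"{s.subject_id}: control with MS outcome fields populated")

    orphans = set(cohort.panel["subject_id"]) - ids
    for sid in sorted(orphans):
        report.append(f"measurement references unknown subject {sid!r}")

    dup = cohort.panel.duplicated(subset=["subject_id", "analyte", "compartment"])
    for _, row in cohort.panel[dup].iterrows():
        report.append(f"duplicate measurement key ({row.subject_id}, {row.analyte}, {row.compartment})")

    bad_lod = cohort.panel[(cohort.panel["below_lod"]) & (~cohort.panel["imputed"])
                           & cohort.panel["concentration"].notna()]
    for _, row in bad_lod.iterrows():
        report.append(f"({row.subject_id}, {row.analyte}, {row.compartment}): "
                      "below-LOD cell carries a concentration but is not flagged imputed")

    neg = cohort.panel[cohort.panel["concentration"] < 0]
    for _, row in neg.iterrows():
        report.append(f"({row.subject_id}, {row.analyte}, {row.compartment}): negative concentration")

    for sid, tp in cohort.csf_total_protein.items():
        if sid not in ids:
            report.append(f"csf_total_protein for unknown subject {sid!r}")
        elif tp <= 0:
            report.append(f"{sid}: non-positive CSF total protein {tp}")
    return report


def _valid_edss(x: float) -> bool:
    return 0.0 <= x <= 10.0 and abs(x * 2 - round(x * 2)) < 1e-9
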