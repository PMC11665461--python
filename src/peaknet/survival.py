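"""Survival association of the axis partition.

Kaplan-Meier curves with a two-group log-rank test compare overall survival
(OS) or progression-free survival (PFS) between samples inside and outside
the axis-distance border. Cox proportional-hazards models quantify the
effect: univariable on the partition indicator alone (outside = 1), and
multivariable with clinical covariates (tumor stage, age, gender and the
T/N/M factors). Ties are handled with the Efron approximation; ordered
categorical covariates are collapsed to numeric ranks by default, which is
the only numerically sane coding at the small cohort sizes this analysis
targets (a dummy coding is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .axis import AxisPartition
from .io import ClinicalRecord, clinical_index

logger = logging.getLogger(__name__)

ENDPOINTS = {"OS": ("os_time", "os_event"), "PFS": ("pfs_time", "pfs_event")}

#: default multivariable covariate set
DEFAULT_COVARIATES = ("stage", "age", "gender", "t_factor", "n_factor", "m_factor")

_ORDERED_CATEGORICALS = ("stage", "t_factor", "n_factor", "m_factor")


class CoxFitError(RuntimeError):
    """Structured Cox failure naming the offending covariate when known."""


@dataclass
class CoxCovariate:
    name: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class SurvivalFit:
    endpoint: str
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_per_group: dict[str, int] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    cox_univariable: CoxCovariate | None = None
    cox_multivariable: list[CoxCovariate] | None = None


def _endpoint_frame(
    partition: AxisPartition, clinical: Sequence[ClinicalRecord], endpoint: str
) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}, got {endpoint!r}")
    tcol, ecol = ENDPOINTS[endpoint]
    by_sample = clinical_index(clinical)
    rows, missing = [], 0
    for s in partition.sample_ids:
        rec = by_sample.get(s)
        if rec is None or getattr(rec, tcol) is None or getattr(rec, ecol) is None:
            missing += 1
            continue
        rows.append(
            {
                "sample_id": s,
                "time": float(getattr(rec, tcol)),
                "event": bool(getattr(rec, ecol)),
                "outside": int(s in partition.outside),
            }
        )
    if missing:
        logger.warning("%d samples lack %s endpoint data and were dropped", missing, endpoint)
    if not rows:
        raise ValueError(f"no samples carry {endpoint} endpoint columns")
    return pd.DataFrame(rows).set_index("sample_id")


def km_logrank(
    partition: AxisPartition, clinical: Sequence[ClinicalRecord], endpoint: str
) -> SurvivalFit:
    """Product-limit curves per partition group and the two-group log-rank test."""
    df = _endpoint_frame(partition, clinical, endpoint)
    fit = SurvivalFit(endpoint=endpoint)
    groups = {"inside": df[df.outside == 0], "outside": df[df.outside == 1]}
    for name, g in groups.items():
        fit.n_per_group[name] = len(g)
        if len(g) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(g.time, g.event, label=name)
        table = kmf.event_table
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[name].to_numpy(),
                "at_risk": table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        fit.km_curves[name] = curve
    if all(len(g) > 0 for g in groups.values()):
        if df.event.sum() == 0:
            raise ValueError("log-rank needs at least one event overall")
        res = logrank_test(
            groups["outside"].time,
            groups["inside"].time,
            event_observed_A=groups["outside"].event,
            event_observed_B=groups["inside"].event,
        )
        fit.logrank_statistic = float(res.test_statistic)
        fit.logrank_p = float(res.p_value)
    else:
        raise ValueError("both partition groups must be non-empty for the log-rank test")
    return fit


def _encode_covariates(
    clinical: Sequence[ClinicalRecord],
    sample_ids: Sequence[str],
    covariates: Sequence[str],
    categorical: str,
) -> pd.DataFrame:
    by_sample = clinical_index(clinical)
    raw = pd.DataFrame(
        {
            cov: [getattr(by_sample[s], cov, None) for s in sample_ids]
            for cov in covariates
        },
        index=list(sample_ids),
    )
    out = pd.DataFrame(index=raw.index)
    for cov in covariates:
        col = raw[cov]
        if cov == "age":
            out[cov] = pd.to_numeric(col, errors="coerce")
        elif cov in _ORDERED_CATEGORICALS:
            cats = sorted({v for v in col.dropna()})
            codes = pd.Categorical(col, categories=cats, ordered=True).codes.astype(float)
            codes[codes < 0] = np.nan
            if categorical == "rank":
                out[cov] = codes
            elif categorical == "dummy":
                for c in cats[1:]:
                    out[f"{cov}_{c}"] = (col == c).astype(float)
            else:
                raise ValueError("categorical must be 'rank' or 'dummy'")
        else:  # gender and other unordered labels -> dummy against first level
            cats = sorted({v for v in col.dropna()})
            for c in cats[1:]:
                out[f"{cov}_{c}"] = (col == c).astype(float)
            if len(cats) == 1:
                raise CoxFitError(f"covariate {cov!r} is constant across samples")
    return out


def cox_fit(
    partition: AxisPartition,
    clinical: Sequence[ClinicalRecord],
    endpoint: str,
    covariates: Sequence[str] = (),
    categorical: str = "rank",
) -> SurvivalFit:
    """Cox proportional-hazards fit with the partition indicator as exposure.

    With an empty ``covariates`` list this is the univariable fit on the
    outside-vs-inside indicator; otherwise the indicator plus the encoded
    covariates enter a multivariable fit. The fit is refused when the event
    count is below the number of coefficients, and flagged with a warning
    when events are fewer than ten per coefficient (as in very small
    cohorts, e.g. n = 22).
    """
    df = _endpoint_frame(partition, clinical, endpoint)
    design = df[["time", "event", "outside"]].copy()
    if covariates:
        enc = _encode_covariates(clinical, df.index, covariates, categorical)
        design = design.join(enc)
        n0 = len(design)
        design = design.dropna()
        if len(design) < n0:
            logger.warning("dropped %d samples with missing covariates", n0 - len(design))
    coef_cols = [c for c in design.columns if c not in ("time", "event")]
    for c in coef_cols:
        if design[c].nunique() <= 1:
            raise CoxFitError(f"covariate {c!r} is constant across samples")
    events = int(design.event.sum())
    if events < len(coef_cols):
        raise CoxFitError(
            f"{events} events cannot support {len(coef_cols)} coefficients; fit refused"
        )
    if events < 10 * len(coef_cols):
        logger.warning(
            "small-sample Cox fit: %d events for %d coefficients (n=%d); "
            "estimates will be unstable", events, len(coef_cols), len(design)
        )
    cph = CoxPHFitter()  # lifelines handles ties with the Efron approximation
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise CoxFitError(f"Cox fit did not converge: {err}") from err
    summary = cph.summary
    results = [
        CoxCovariate(
            name=name,
            hazard_ratio=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p_value=float(row["p"]),
        )
        for name, row in summary.iterrows()
    ]
    fit = SurvivalFit(endpoint=endpoint)
    fit.n_per_group = {
        "inside": int((design.outside == 0).sum()),
        "outside": int((design.outside == 1).sum()),
    }
    by_name = {r.name: r for r in results}
    if covariates:
        fit.cox_multivariable = results
        fit.cox_univariable = by_name.get("outside")
    else:
        fit.cox_univariable = by_name["outside"]
    return fit
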