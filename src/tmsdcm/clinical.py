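"""Clinical scales: reductions, response/remission, longitudinal tests.

Bookkeeping for the outcome layer of an accelerated-iTBS trial: percent
reductions of scale scores, response (reduction >= 50%, boundary
inclusive) and scale-specific remission rules, mean-imputation of a
missing visit, repeated-measures ANOVA / paired t tests over timepoints,
and (partial) correlations between connectivity estimates and score
changes.

Scores live in long-format tables with columns ``subject_id``, ``scale``,
``timepoint``, ``value``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "round_half_up",
    "ScaleDefinition",
    "SCALES",
    "percent_reduction",
    "classify",
    "impute_missing",
    "summarize_rates",
    "longitudinal_tests",
    "correlate",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """Response/remission rules for one clinical scale.

    ``response_threshold`` is the fractional reduction defining response
    (inclusive). Remission is a score threshold (strictly below
    ``remission_score``), optionally combined with the response-level
    reduction (``remission_needs_reduction``, as for the suicidal-ideation
    scale where remission = reduction >= 50% AND score < 6).
    """

    name: str
    response_threshold: float | None = 0.5
    remission_score: float | None = None
    remission_needs_reduction: bool = False


SCALES: dict[str, ScaleDefinition] = {
    "BSI-CV": ScaleDefinition("BSI-CV", 0.5, remission_score=6.0, remission_needs_reduction=True),
    "HAMD-17": ScaleDefinition("HAMD-17", 0.5, remission_score=8.0),
    "MADRS": ScaleDefinition("MADRS", 0.5, remission_score=11.0),
    "HAMD-6": ScaleDefinition("HAMD-6", 0.5, remission_score=5.0),
    "BDI": ScaleDefinition("BDI", 0.5, remission_score=13.0),
    # neurocognitive scales: tracked, no response/remission rule
    "PDQ-D": ScaleDefinition("PDQ-D", None),
    "DST": ScaleDefinition("DST", None),
    "DSST": ScaleDefinition("DSST", None),
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (reporting convention for percentages)."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def percent_reduction(baseline: float, follow: float) -> float:
    """Fractional reduction (baseline - follow) / baseline.

    May be negative (worsening). Reported percentages are this fraction
    times 100, rounded only at the reporting layer.
    """
    if baseline <= 0:
        raise ValueError("baseline score must be positive")
    return (baseline - follow) / baseline


def classify(scale: ScaleDefinition | str, baseline: float, follow: float) -> tuple[bool, bool]:
    """(response, remission) flags for one subject and scale.

    Response iff reduction >= threshold (inclusive at the boundary);
    remission per the scale's rule. Unknown scale names raise.
    """
    if isinstance(scale, str):
        try:
            scale = SCALES[scale]
        except KeyError:
            raise ValueError(f"unknown scale {scale!r}") from None
    red = percent_reduction(baseline, follow)
    if scale.response_threshold is None:
        return False, False
    response = red >= scale.response_threshold
    remission = False
    if scale.remission_score is not None:
        remission = follow < scale.remission_score
        if scale.remission_needs_reduction:
            remission = remission and response
    return response, remission


def impute_missing(scores: pd.DataFrame, timepoint: str, max_missing: int = 1):
    """Replace missing values at a timepoint by the observed mean.

    Returns ``(completed scores, audit log)``; the audit log lists one row
    per imputed value (subject, scale, imputed value). Observed values are
    never modified. More than ``max_missing`` missing values per scale
    raise a warning but are still imputed; a scale with no observed value
    at the timepoint raises an error.
    """
    import warnings as _w

    out = scores.copy()
    audit = []
    sel = out["timepoint"] == timepoint
    for scale, grp in out[sel].groupby("scale"):
        missing = grp[grp["value"].isna()]
        if missing.empty:
            continue
        observed = grp["value"].dropna()
        if observed.empty:
            raise ValueError(f"all values missing for {scale} at {timepoint}")
        if len(missing) > max_missing:
            _w.warn(f"{len(missing)} missing values for {scale} at {timepoint}", stacklevel=2)
        fill = observed.mean()
        out.loc[missing.index, "value"] = fill
        for _, row in missing.iterrows():
            audit.append({"subject_id": row.get("subject_id"), "scale": scale,
                          "timepoint": timepoint, "imputed_value": fill})
    return out, audit


def summarize_rates(scores: pd.DataFrame, scale: str, timepoint: str) -> dict:
    """Response/remission counts and percentages at a timepoint.

    ``scores`` is long-format with a ``baseline`` row per subject.
    Percentages are reported to 2 decimals and recompute exactly from the
    returned counts.
    """
    sd = SCALES[scale] if isinstance(scale, str) else scale
    wide = scores[scores["scale"] == (sd.name)].pivot_table(
        index="subject_id", columns="timepoint", values="value"
    )
    if "baseline" not in wide.columns or timepoint not in wide.columns:
        raise ValueError(f"scores lack baseline or {timepoint} for {sd.name}")
    wide = wide.dropna(subset=["baseline", timepoint])
    if wide.empty:
        raise ValueError("no subjects with complete data")
    flags = [classify(sd, b, f) for b, f in zip(wide["baseline"], wide[timepoint])]
    n = len(flags)
    n_resp = sum(f[0] for f in flags)
    n_rem = sum(f[1] for f in flags)
    return {
        "scale": sd.name, "timepoint": timepoint, "n": n,
        "response_n": n_resp, "response_pct": round_half_up(100.0 * n_resp / n),
        "remission_n": n_rem, "remission_pct": round_half_up(100.0 * n_rem / n),
    }


def longitudinal_tests(wide_scores: pd.DataFrame, correction: str = "gg") -> dict:
    """Within-subject test of a timepoint effect.

    ``wide_scores``: subjects x timepoints (complete, post-imputation).
    With exactly two timepoints a paired t test is run (and the returned F
    equals t**2); with more, a one-way repeated-measures ANOVA with
    optional Greenhouse–Geisser correction of the degrees of freedom, plus
    Bonferroni-corrected pairwise paired t tests against baseline.
    """
    X = np.asarray(wide_scores, float)
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    if np.isnan(X).any():
        raise ValueError("scores must be complete (impute first)")
    if k == 2:
        t, p = stats.ttest_rel(X[:, 0], X[:, 1])
        return {"test": "paired_t", "t": float(t), "F": float(t**2),
                "df": (1.0, float(n - 1)), "p": float(p)}
    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "time": np.tile(np.asarray(wide_scores.columns if hasattr(wide_scores, "columns") else range(k)), n),
        "value": X.ravel(),
    })
    aov = pg.rm_anova(data=long, dv="value", within="time", subject="subject", correction=True)
    row = aov.iloc[0]
    use_gg = correction == "gg" and "p_GG_corr" in aov.columns and not pd.isna(row.get("p_GG_corr", np.nan))
    eps = float(row["eps"]) if "eps" in aov.columns else 1.0
    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    if use_gg:
        df1, df2, p = df1 * eps, df2 * eps, float(row["p_GG_corr"])
    else:
        p = float(row["p_unc"])
    cols = list(wide_scores.columns) if hasattr(wide_scores, "columns") else list(range(k))
    pairwise = []
    m = k - 1
    for j in range(1, k):
        t, praw = stats.ttest_rel(X[:, 0], X[:, j])
        pairwise.append({"baseline_vs": cols[j], "t": float(t),
                         "p_bonferroni": float(min(praw * m, 1.0))})
    return {"test": "rm_anova", "F": float(row["F"]), "df": (df1, df2), "p": p,
            "eps": eps, "pairwise": pairwise}


def correlate(
    conn_estimates: np.ndarray,
    score_changes: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """(Partial) Pearson correlation between connectivity and score change.

    With covariates, both variables are regressed on [1, covariates] and
    the residuals are correlated (partial correlation); p values are
    two-sided with degrees of freedom reduced by the number of covariates.
    No multiple-testing correction is applied here.
    """
    x = np.asarray(conn_estimates, float)
    y = np.asarray(score_changes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be aligned 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    ncov = 0
    if covariates is not None:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        ncov = Z.shape[1]
        D = np.column_stack([np.ones(n), Z])
        x = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
        y = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    scale = max(np.abs(x).max(), np.abs(y).max(), 1e-30)
    if np.std(x) <= 1e-12 * scale or np.std(y) <= 1e-12 * scale:
        raise ValueError("zero-variance variable in correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - ncov
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p
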