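"""Construct-validity report tables from a CDI table plus covariates.

Mirrors the validation workflow of the method: height-adjusted CDI and its
follow-up-minus-baseline change, stratified by radiographic severity
(JSN / KL grade) with linear-trend p-values, progressor versus
non-progressor contrasts with SRMs and t-tests, and Spearman correlations
with joint space width and static alignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cdi import REGIONS
from .errors import UndefinedStatisticError, ValidationError
from .stats import group_summary, linear_trend, spearman, srm, two_sample_t


def change_table(cdi_table: pd.DataFrame, adjusted: bool = True) -> pd.DataFrame:
    """Wide per-knee frame of baseline CDI and change, per region.

    Expects the tidy table from :func:`kneecdi.io.results_table` covering
    both timepoints; change = followup - baseline on the height-adjusted
    scale (raw when ``adjusted`` is False).
    """
    col = "cdi_height_adjusted" if adjusted else "cdi_mm3"
    if col not in cdi_table:
        raise ValidationError(f"CDI table lacks column {col!r}")
    wide = cdi_table.pivot_table(
        index="knee_id", columns=["region", "timepoint"], values=col
    )
    out = pd.DataFrame(index=wide.index)
    for region in REGIONS:
        if (region, "baseline") not in wide.columns:
            raise ValidationError(f"no baseline rows for region {region!r}")
        out[f"{region}_baseline"] = wide[(region, "baseline")]
        if (region, "followup") in wide.columns:
            out[f"{region}_change"] = (
                wide[(region, "followup")] - wide[(region, "baseline")]
            )
    return out.reset_index()


def severity_table(
    per_knee: pd.DataFrame, covariates: pd.DataFrame, grade_col: str
) -> pd.DataFrame:
    """Stratified baseline and change summaries with trend p-values.

    One row per (measure, stratum); the ``p_trend`` column repeats the
    linear-trend p of that measure across grades.
    """
    df = per_knee.merge(covariates, on="knee_id", validate="one_to_one")
    rows = []
    for region in REGIONS:
        for kind in ("baseline", "change"):
            col = f"{region}_{kind}"
            if col not in df:
                continue
            summ = group_summary(df, grade_col, col)
            trend = summ.attrs["trend"]
            for _, r in summ.iterrows():
                rows.append(
                    {
                        "measure": col,
                        grade_col: r[grade_col],
                        "n": int(r["n"]),
                        "mean": r["mean"],
                        "sd": r["sd"],
                        "p_trend": trend.p if trend is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def progression_table(
    per_knee: pd.DataFrame,
    covariates: pd.DataFrame,
    flag_col: str,
    ttest_variant: str = "welch",
) -> pd.DataFrame:
    """Change in CDI among knees with and without structural progression.

    Per region: n / mean / sd / SRM in each progression group plus the
    independent-samples t-test p-value for the group difference.
    """
    df = per_knee.merge(covariates, on="knee_id", validate="one_to_one")
    if flag_col not in df:
        raise ValidationError(f"covariates lack column {flag_col!r}")
    rows = []
    for region in REGIONS:
        col = f"{region}_change"
        if col not in df:
            raise ValidationError(f"no change scores for region {region!r}")
        groups = {}
        for label, flag in (("no_progression", False), ("progression", True)):
            vals = df.loc[df[flag_col] == flag, col].dropna().to_numpy()
            groups[label] = vals
        if len(groups["no_progression"]) >= 2 and len(groups["progression"]) >= 2:
            _, p = two_sample_t(
                groups["no_progression"], groups["progression"],
                variant=ttest_variant,  # type: ignore[arg-type]
            )
        else:
            p = np.nan
        for label, vals in groups.items():
            try:
                s = srm(vals) if len(vals) >= 2 else np.nan
            except UndefinedStatisticError:
                s = np.nan
            rows.append(
                {
                    "measure": col,
                    "group": label,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "srm": s,
                    "p_ttest": p,
                }
            )
    return pd.DataFrame(rows)


def correlation_table(
    per_knee: pd.DataFrame,
    covariates: pd.DataFrame,
    against: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Spearman correlations of CDI measures with external covariates.

    ``against`` maps report labels to covariate column names; default is
    alignment (HKA) and joint space width at baseline and change.
    """
    if against is None:
        against = {
            "hka": "hka_deg",
            "jsw_baseline": "jsw_mm",
            "jsw_change": "jsw_change_mm",
        }
    df = per_knee.merge(covariates, on="knee_id", validate="one_to_one")
    rows = []
    for region in REGIONS:
        for kind in ("baseline", "change"):
            col = f"{region}_{kind}"
            if col not in df:
                continue
            for label, cov in against.items():
                if cov not in df:
                    continue
                sub = df[[col, cov]].dropna()
                try:
                    rho = spearman(sub[col], sub[cov])
                except (UndefinedStatisticError, ValidationError):
                    rho = np.nan
                rows.append(
                    {"measure": col, "covariate": label, "rho": rho,
                     "n": len(sub)}
                )
    return pd.DataFrame(rows)


def overall_srm(per_knee: pd.DataFrame) -> dict[str, float]:
    """Whole-sample SRM of the CDI change, per region."""
    out = {}
    for region in REGIONS:
        col = f"{region}_change"
        if col in per_knee:
            out[region] = srm(per_knee[col].dropna().to_numpy())
    return out
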