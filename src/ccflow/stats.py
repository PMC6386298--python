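"""Cohort statistics: Pearson correlations, inter-grader ICC, and GEE models.

Eyes cluster within patients (1-2 eyes per patient), so marginal regression
of the yearly growth rate on flow-void covariates uses generalized
estimating equations (Gaussian family, identity link, exchangeable working
correlation within patient, robust sandwich standard errors). The screen
fits one univariable GEE per candidate covariate; candidates significant at
p < 0.05 enter a single multivariable GEE. Inter-grader repeatability uses
the two-way random-effects, absolute-agreement, single-measure ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "pearson",
    "icc",
    "GeeResult",
    "gee_screen_and_model",
    "table1_frame",
    "replicate_cohort",
]

DEFAULT_CANDIDATES = ["age", "area_baseline_mm2", "fovea_dist_mm", "fv_500", "fv_1000", "fv_out", "dfv"]


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed p from the t transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def icc(grader_a, grader_b) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) between two graders' measurements, with F-based 95% CI."""
    a = np.asarray(grader_a, float)
    b = np.asarray(grader_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("grader measurement vectors must be 1-D and the same length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired measurements")
    n = len(a)
    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "rating": np.concatenate([a, b]),
        }
    )
    res = pg.intraclass_corr(long, targets="target", raters="rater", ratings="rating")
    # absolute-agreement single-measure row; label differs across pingouin versions
    sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res.loc[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


@dataclass
class GeeResult:
    """Coefficients of one GEE fit in a Table-1-shaped layout."""

    covariates: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    n_obs: int
    n_clusters: int
    family: str = "gaussian"
    link: str = "identity"
    working_corr: str = "exchangeable"
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [c for c in self.covariates if self.pvalues[c] < alpha]


def _fit_gee(
    df: pd.DataFrame, y: str, covs: list[str], groups: str, corr: str, cov_type: str = "robust"
) -> GeeResult:
    X = sm.add_constant(df[covs].astype(float))
    design = np.asarray(X, float)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"singular design matrix; collinear columns among {['const'] + covs}")
    cov_struct = sm.cov_struct.Exchangeable() if corr == "exchangeable" else sm.cov_struct.Independence()
    model = sm.GEE(
        df[y].astype(float),
        X,
        groups=df[groups],
        family=sm.families.Gaussian(),
        cov_struct=cov_struct,
    )
    # "robust" is the sandwich estimator (the GEE convention and the SPSS
    # default); "bias_reduced" (Mancl-DeRouen) is less anticonservative when
    # there are few patient clusters.
    res = model.fit(cov_type=cov_type)
    return GeeResult(
        covariates=covs,
        coef={c: float(res.params[c]) for c in covs},
        se={c: float(res.bse[c]) for c in covs},
        pvalues={c: float(res.pvalues[c]) for c in covs},
        n_obs=int(res.nobs),
        n_clusters=int(df[groups].nunique()),
        working_corr=corr,
        meta={"cov_type": cov_type},
    )


def gee_screen_and_model(
    table: pd.DataFrame,
    candidates: list[str] | None = None,
    *,
    outcome: str = "ygr",
    cluster: str = "patient_id",
    alpha: float = 0.05,
    working_corr: str = "exchangeable",
    cov_type: str = "robust",
) -> tuple[dict[str, GeeResult], GeeResult | None]:
    """Univariable GEE screen, then one multivariable GEE on the survivors.

    Returns (per-candidate univariable results, multivariable result).
    The multivariable stage is skipped (None) when no candidate clears the
    significance gate.
    """
    candidates = candidates or [c for c in DEFAULT_CANDIDATES if c in table.columns]
    cols = [outcome, cluster] + candidates
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    df = table[cols].dropna()
    if df[cluster].nunique() < 2:
        raise ValueError("need at least 2 patient clusters for GEE")

    uni = {c: _fit_gee(df, outcome, [c], cluster, working_corr, cov_type) for c in candidates}
    selected = [c for c in candidates if uni[c].pvalues[c] < alpha]
    # dFV is a linear combination of FV_500 and FV_1000, so a screen that
    # admits all three yields an exactly singular design. Keep covariates in
    # order of univariable significance, dropping any that are collinear
    # with the ones already admitted.
    selected.sort(key=lambda c: uni[c].pvalues[c])
    kept: list[str] = []
    dropped: list[str] = []
    for c in selected:
        trial = np.column_stack(
            [np.ones(len(df))] + [np.asarray(df[k], float) for k in kept + [c]]
        )
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(c)
        else:
            dropped.append(c)
    multi = _fit_gee(df, outcome, kept, cluster, working_corr, cov_type) if kept else None
    if multi is not None and dropped:
        multi.meta["dropped_collinear"] = dropped
    return uni, multi


def table1_frame(uni: dict[str, GeeResult], multi: GeeResult | None) -> pd.DataFrame:
    """Assemble the univariable/multivariable report as a tidy table."""
    rows = []
    for cov, res in uni.items():
        in_multi = multi is not None and cov in multi.covariates
        rows.append(
            {
                "covariate": cov,
                "uni_B": res.coef[cov],
                "uni_SE": res.se[cov],
                "uni_p": res.pvalues[cov],
                "multi_B": multi.coef[cov] if in_multi else np.nan,
                "multi_SE": multi.se[cov] if in_multi else np.nan,
                "multi_p": multi.pvalues[cov] if in_multi else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["multivariable_fitted"] = multi is not None
    if multi is None:
        df.attrs["note"] = "no univariable candidate reached significance; multivariable stage skipped"
    return df


def cohort_summary(table: pd.DataFrame) -> dict[str, float]:
    """Means and SDs of the headline per-eye quantities."""
    out: dict[str, float] = {"n_eyes": float(len(table))}
    if "patient_id" in table.columns:
        out["n_patients"] = float(table["patient_id"].nunique())
    for col in ["ygr", "fv_out", "fv_500", "fv_1000", "dfv", "area_baseline_mm2",
                "area_followup_mm2", "fu_years", "fovea_dist_mm"]:
        if col in table.columns:
            out[f"mean_{col}"] = float(table[col].mean())
            out[f"sd_{col}"] = float(table[col].std(ddof=1))
    return out


def replicate_cohort(per_eye_table: str | pd.DataFrame) -> dict:
    """Recompute cohort summaries, correlations, and the GEE report from a
    per-eye measurement database (CSV/XLSX with the EyeRecord columns).

    Intended for re-analysis of a published per-eye database: given columns
    ygr, fv_out, fv_500, fv_1000, dfv (computed if absent), patient_id and
    the clinical covariates, this reproduces the cohort means, the
    yGR-vs-FV Pearson correlations, and the univariable/multivariable GEE
    coefficient table from the raw rows.
    """
    if isinstance(per_eye_table, (str, bytes)) or hasattr(per_eye_table, "__fspath__"):
        path = str(per_eye_table)
        df = pd.read_excel(path) if path.endswith((".xlsx", ".xls")) else pd.read_csv(path)
    else:
        df = per_eye_table.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "dfv" not in df.columns and {"fv_500", "fv_1000"} <= set(df.columns):
        df["dfv"] = df["fv_500"] - df["fv_1000"]
    out: dict = {"summary": cohort_summary(df)}
    for col in ["fv_out", "fv_500", "fv_1000", "dfv"]:
        if col in df.columns and "ygr" in df.columns:
            r, p = pearson(df["ygr"], df[col])
            out[f"r_ygr_{col}"] = r
            out[f"p_ygr_{col}"] = p
    if "patient_id" in df.columns and "ygr" in df.columns:
        uni, multi = gee_screen_and_model(df)
        out["table1"] = table1_frame(uni, multi)
    return out
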