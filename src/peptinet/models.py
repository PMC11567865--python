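"""Network-informed regression models.

Two analyses sit downstream of the network stages: (1) association of mean
module peptide levels with global cognition, adjusted for age, sex and
education (one OLS model per module); and (2) a three-way moderation model
asking whether continuous physical activity moderates the joint effect of
two phosphorylated-tau peptides and a synaptic module level on cellular
tangle burden.  Predictors are mean-centered before products are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


def module_score(
    X: pd.DataFrame, assignment: dict[str, int], module_id: int
) -> pd.Series:
    """Per-subject mean over the module's member columns (missing values skipped)."""
    members = [c for c in X.columns if assignment.get(c) == module_id]
    if not members:
        raise ValueError(f"module {module_id} has no member columns in this table")
    return X[members].mean(axis=1, skipna=True)


def _check_full_rank(design: pd.DataFrame) -> None:
    arr = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending columns for the error message
        bad = []
        for c in design.columns:
            rest = design.drop(columns=[c]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(arr):
                bad.append(c)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def module_cognition_association(
    module_scores: pd.DataFrame,
    cognition_z: pd.Series,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """One adjusted linear model per module: cognition ~ score + age + sex + education.

    ``module_scores`` has one column per module.  Rows with any missing value
    are dropped per model (listwise deletion).  Returns a table with
    Estimate, Std error, t ratio and p value per module.
    """
    rows = []
    for col in module_scores.columns:
        df = pd.concat(
            [cognition_z.rename("cognition"), module_scores[col].rename("score"), covariates],
            axis=1,
        ).dropna()
        if len(df) < 30:
            raise ValueError(f"module {col}: fewer than 30 complete observations")
        design = sm.add_constant(df.drop(columns=["cognition"]))
        _check_full_rank(design)
        fit = sm.OLS(df["cognition"], design).fit()
        rows.append(
            {
                "module": col,
                "estimate": fit.params["score"],
                "std_error": fit.bse["score"],
                "t": fit.tvalues["score"],
                "p": fit.pvalues["score"],
                "n": int(fit.nobs),
            }
        )
    return pd.DataFrame(rows).set_index("module")


@dataclass
class ModerationFit:
    table: pd.DataFrame    # estimate, std_error, t, p per term
    n: int
    formula: str

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "std_error"])


def threeway_moderation(
    tangles: pd.Series,
    ptau_1: pd.Series,
    ptau_2: pd.Series,
    module_score: pd.Series,
    activity: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ModerationFit:
    """OLS of tangle burden on two p-tau peptides, a module level and activity,
    with all implied two-way products and both three-way products
    (each p-tau x module x activity).

    Predictors are mean-centered before products are constructed, so main
    effects are interpretable at average levels of the moderators.
    """
    base = pd.concat(
        {
            "tangles": tangles,
            "ptau_1": ptau_1,
            "ptau_2": ptau_2,
            "module": module_score,
            "activity": activity,
        },
        axis=1,
    )
    if covariates is not None and len(covariates.columns):
        base = pd.concat([base, covariates], axis=1)
    base = base.dropna()
    if len(base) < 100:
        raise ValueError("moderation model needs at least 100 complete observations")
    if base["activity"].nunique() == 1:
        raise ValueError("activity is constant; no moderation is identifiable")

    c = base[["ptau_1", "ptau_2", "module", "activity"]]
    c = c - c.mean()
    X = pd.DataFrame(index=base.index)
    for name in ("ptau_1", "ptau_2", "module", "activity"):
        X[name] = c[name]
    for a, b in (
        ("ptau_1", "module"), ("ptau_1", "activity"),
        ("ptau_2", "module"), ("ptau_2", "activity"),
        ("module", "activity"),
    ):
        X[f"{a}:{b}"] = c[a] * c[b]
    X["ptau_1:module:activity"] = c["ptau_1"] * c["module"] * c["activity"]
    X["ptau_2:module:activity"] = c["ptau_2"] * c["module"] * c["activity"]
    if covariates is not None:
        for col in covariates.columns:
            X[col] = base[col]
    design = sm.add_constant(X)
    _check_full_rank(design)
    fit = sm.OLS(base["tangles"], design).fit()
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModerationFit(
        table=table,
        n=int(fit.nobs),
        formula="tangles ~ (ptau_1 + ptau_2) * module * activity (centered products)",
    )
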