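"""Per-patient clinical characteristics: loading, imputation, derived scores,
and univariate / multivariable association with survival.

The table carries three reserved columns — ``site``, ``survived`` (1 = alive
at last follow-up) and ``followup_years`` — plus an arbitrary set of
characteristics, each declared ``binary``, ``categorical`` or ``numeric``.
Characteristics missing in fewer than one third of patients are imputed
(mode for binary/categorical, mean for numeric); characteristics missing in
one third or more are dropped. Association testing uses a continuity-corrected
chi-squared test for categorical characteristics and a two-sample t-test for
numeric ones, with a joint multivariable model (logistic by default, OLS on
the binary outcome as an alternative) after removing columns that make the
design matrix singular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "ClinicalTable",
    "AssociationResult",
    "impute_table",
    "meld_xi",
    "univariate_association",
    "multivariable_association",
    "binarize_characteristics",
]

RESERVED = ("site", "survived", "followup_years")
VALID_KINDS = ("binary", "categorical", "numeric")


@dataclass
class ClinicalTable:
    """A per-patient characteristics table with declared column kinds.

    df is indexed by unique patient_id and contains the reserved columns plus
    the characteristics named in ``kinds``.
    """

    df: pd.DataFrame
    kinds: dict
    imputation_log: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.df.index.has_duplicates:
            raise ValueError("patient_id index must be unique")
        for col in ("survived", "followup_years"):
            if col not in self.df.columns:
                raise ValueError(f"missing reserved column {col!r}")
        if self.df["survived"].isna().any():
            missing = self.df.index[self.df["survived"].isna()].tolist()
            raise ValueError(f"missing outcome for patients: {missing}")
        if not self.df["survived"].isin([0, 1]).all():
            raise ValueError("survived must be 0/1")
        if (pd.to_numeric(self.df["followup_years"]) < 0).any():
            raise ValueError("followup_years must be >= 0")
        for col, kind in self.kinds.items():
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown kind {kind!r} for column {col!r}")
            if col not in self.df.columns:
                raise ValueError(f"declared column {col!r} absent from table")

    @property
    def characteristics(self):
        return [c for c in self.df.columns if c in self.kinds]

    @property
    def survived(self) -> np.ndarray:
        return self.df["survived"].to_numpy(dtype=int)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        # persist kinds in a header comment-free way: separate columns row
        out.to_csv(path, sep="\t")
        with open(str(path) + ".kinds", "w") as fh:
            for col, kind in self.kinds.items():
                fh.write(f"{col}\t{kind}\n")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        kinds = {}
        with open(str(path) + ".kinds") as fh:
            for line in fh:
                col, kind = line.rstrip("\n").split("\t")
                kinds[col] = kind
        return cls(df=df, kinds=kinds)


@dataclass
class AssociationResult:
    characteristic: str
    test: str
    statistic: float
    p_value: float
    multivariable_p: float | None = None
    per_level: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def impute_table(table: ClinicalTable, max_missing_fraction=1 / 3) -> ClinicalTable:
    """Fill or drop missing characteristic values.

    Columns missing in strictly less than ``max_missing_fraction`` of patients
    are imputed: the most frequent value for binary/categorical columns, the
    mean for numeric columns. Columns at or above the threshold are dropped
    and recorded in the returned table's imputation_log. The reserved outcome
    and site columns are never imputed or dropped. Idempotent.
    """
    n = len(table.df)
    if n < 2:
        raise ValueError("need at least 2 patients to impute")
    df = table.df.copy()
    kinds = dict(table.kinds)
    log = {"imputed": {}, "dropped": {}}
    for col in list(kinds):
        miss = df[col].isna()
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        frac = n_miss / n
        if frac < max_missing_fraction:
            if kinds[col] == "numeric":
                fill = pd.to_numeric(df[col]).mean()
            else:
                fill = df[col].mode(dropna=True).iloc[0]
            df.loc[miss, col] = fill
            log["imputed"][col] = {"n_missing": n_miss, "fill": fill}
        else:
            df = df.drop(columns=[col])
            del kinds[col]
            log["dropped"][col] = {"n_missing": n_miss, "fraction": frac}
    for col, kind in kinds.items():
        if kind == "numeric":
            df[col] = pd.to_numeric(df[col])
    return ClinicalTable(df=df, kinds=kinds, imputation_log=log)


def meld_xi(bilirubin_mg_dl, creatinine_mg_dl):
    """MELD-XI score: 3.78 ln(bilirubin) + 9.57 ln(creatinine) + 6.43.

    Inputs in mg/dL must be strictly positive; no clamping is applied.
    Accepts scalars or arrays.
    """
    bili = np.asarray(bilirubin_mg_dl, dtype=float)
    creat = np.asarray(creatinine_mg_dl, dtype=float)
    if np.any(bili <= 0) or np.any(creat <= 0):
        raise ValueError("MELD-XI inputs must be > 0 mg/dL")
    score = 3.78 * np.log(bili) + 9.57 * np.log(creat) + 6.43
    return float(score) if score.ndim == 0 else score


def chi2_yates(contingency: np.ndarray):
    """Continuity-corrected chi-squared test on a contingency table."""
    res = stats.chi2_contingency(np.asarray(contingency), correction=True)
    return float(res.statistic), float(res.pvalue)


def univariate_association(table: ClinicalTable, characteristic: str,
                           equal_var: bool = True) -> AssociationResult:
    """Test one characteristic against survival.

    Categorical/binary: Yates continuity-corrected chi-squared on the
    characteristic x survived table, plus per-level one-vs-rest 2x2 tests for
    characteristics with more than two levels. Numeric: two-sample t-test
    between died and survived groups.
    """
    if characteristic not in table.kinds:
        raise KeyError(f"unknown characteristic {characteristic!r}")
    kind = table.kinds[characteristic]
    col = table.df[characteristic]
    if col.isna().any():
        raise ValueError("impute the table before association testing")
    y = table.survived
    if len(np.unique(y)) < 2:
        raise ValueError("undefined test: one outcome group is empty")
    if kind == "numeric":
        vals = pd.to_numeric(col).to_numpy(dtype=float)
        died, surv = vals[y == 0], vals[y == 1]
        if np.ptp(vals) == 0:
            return AssociationResult(characteristic, "t-test", 0.0, 1.0)
        t, p = stats.ttest_ind(died, surv, equal_var=equal_var)
        return AssociationResult(characteristic, "t-test", float(t), float(p))
    ct = pd.crosstab(col, table.df["survived"])
    if ct.shape[0] < 2:
        return AssociationResult(characteristic, "chi2-yates", 0.0, 1.0)
    stat, p = chi2_yates(ct.to_numpy())
    per_level = None
    if ct.shape[0] > 2:
        per_level = {}
        for level in ct.index:
            a = ct.loc[level].to_numpy()
            b = ct.drop(index=level).sum(axis=0).to_numpy()
            _, pl = chi2_yates(np.vstack([a, b]))
            per_level[level] = pl
    return AssociationResult(characteristic, "chi2-yates", stat, p,
                             per_level=per_level)


def _design_matrix(table: ClinicalTable):
    """Numeric design matrix: binary/numeric pass through, categoricals dummy-coded."""
    cols = {}
    for col in table.characteristics:
        kind = table.kinds[col]
        if kind == "categorical":
            dummies = pd.get_dummies(table.df[col], prefix=col, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy(dtype=float)
        else:
            cols[col] = pd.to_numeric(table.df[col]).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=table.df.index)


def _drop_singular(X: pd.DataFrame):
    """Greedily drop columns that do not increase the rank of [1 | X]."""
    omitted = []
    kept = []
    base = np.ones((len(X), 1))
    current = base
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)[:, None]
        trial = np.hstack([current, v])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(current):
            kept.append(col)
            current = trial
        else:
            omitted.append(col)
    return X[kept], omitted


def multivariable_association(table: ClinicalTable, method: str = "logistic"):
    """Joint model of survival on all characteristics.

    Columns producing a singular design are omitted before fitting (greedy
    left-to-right rank check) and listed in the result. method='logistic'
    fits a logit model; method='ols' regresses the 0/1 outcome by ordinary
    least squares. Returns (dict column -> p-value, omitted columns, method).
    """
    X = _design_matrix(table)
    X, omitted = _drop_singular(X)
    y = table.survived
    if len(table.df) <= X.shape[1] + 1:
        raise ValueError("more regressors than patients after omissions")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix still singular after omission pass")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "logistic":
            model = sm.Logit(y, design)
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:
                res = model.fit(disp=0, maxiter=500, method="bfgs")
        elif method == "ols":
            res = sm.OLS(y.astype(float), design).fit()
        else:
            raise ValueError("method must be 'logistic' or 'ols'")
    pvals = dict(zip(X.columns, np.asarray(res.pvalues)[1:]))
    return pvals, omitted, method


def binarize_characteristics(table: ClinicalTable) -> pd.DataFrame:
    """Expand the characteristics into a deterministic 0/1 feature matrix.

    Binary columns pass through; categorical columns expand to one-vs-rest
    indicators (one per level, level-sorted); numeric columns split at the
    cohort median (strictly greater -> 1). Constant columns are dropped with
    a warning.
    """
    out = {}
    for col in table.characteristics:
        kind = table.kinds[col]
        series = table.df[col]
        if series.isna().any():
            raise ValueError("impute the table before binarization")
        if kind == "binary":
            vals = pd.to_numeric(series).to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                warnings.warn(f"dropping constant column {col!r}")
                continue
            out[col] = vals.astype(int)
        elif kind == "categorical":
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                warnings.warn(f"dropping constant column {col!r}")
                continue
            for level in levels:
                out[f"{col}={level}"] = (series.astype(str) == level).astype(int)
        else:
            vals = pd.to_numeric(series).to_numpy(dtype=float)
            med = np.median(vals)
            if np.ptp(vals) == 0:
                warnings.warn(f"dropping constant column {col!r}")
                continue
            out[f"{col}>median"] = (vals > med).astype(int)
    return pd.DataFrame(out, index=table.df.index)


def table_one(table: ClinicalTable, multivariable_method="logistic") -> pd.DataFrame:
    """Summary of each characteristic by outcome with univariate and
    multivariable p-values (cohort-characteristics report)."""
    pvals, omitted, method = multivariable_association(table, multivariable_method)
    y = table.survived
    rows = []
    for col in table.characteristics:
        res = univariate_association(table, col)
        kind = table.kinds[col]
        if kind == "numeric":
            vals = pd.to_numeric(table.df[col])
            summ_d = f"{vals[y == 0].mean():.2f} ({vals[y == 0].std():.2f})"
            summ_s = f"{vals[y == 1].mean():.2f} ({vals[y == 1].std():.2f})"
        else:
            ct = pd.crosstab(table.df[col], table.df["survived"])
            summ_d = "/".join(f"{k}:{v}" for k, v in ct.get(0, pd.Series()).items())
            summ_s = "/".join(f"{k}:{v}" for k, v in ct.get(1, pd.Series()).items())
        mv = [p for name, p in pvals.items() if name == col or name.startswith(col + "_")]
        rows.append({
            "characteristic": col, "kind": kind, "died": summ_d,
            "survived": summ_s, "test": res.test, "p_value": res.p_value,
            "multivariable_p": min(mv) if mv else np.nan,
            "omitted_from_multivariable": not mv,
        })
    out = pd.DataFrame(rows)
    out.attrs["multivariable_method"] = method
    out.attrs["omitted_columns"] = omitted
    return out
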