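"""Supporting statistics for the split-plot fertility trial.

Three procedures:

* ``fit_split_plot_deviance`` — linear mixed model with year, treatment,
  genotype and all interactions as fixed effects and the split-plot error
  strata (block, and treatment-within-block main plots) as random
  intercepts; reports a Wald chi-square analysis-of-deviance table. Sum-to-
  zero contrasts are used so that with a balanced design the term-wise Wald
  tests coincide with Type II tests.
* ``per_genotype_treatment_test`` — two-sided Welch t-test of low vs high
  fertility within each genotype.
* ``dunnett_vs_check`` — Dunnett many-to-one comparisons of every entry
  against the check under one treatment level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DesignError
from .trial_io import TrialDataset

__all__ = [
    "DevianceTable",
    "GenotypeTestTable",
    "DunnettResult",
    "fit_split_plot_deviance",
    "per_genotype_treatment_test",
    "dunnett_vs_check",
    "significance_code",
]

#: Fixed-effect terms in conventional reporting order.
TERM_ORDER = ("Y", "T", "G", "Y x T", "Y x G", "T x G", "Y x T x G")


def significance_code(p: float) -> str:
    """Figure-style significance bands: ***, **, *, + (p < 0.1), else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


@dataclass
class DevianceTable:
    """Wald chi-square analysis-of-deviance table for the split-plot model.

    ``data`` columns: term, chisq, df, p, code. ``simplified`` is True when
    the main-plot variance component was dropped after a singular fit.
    """

    trait: str
    data: pd.DataFrame
    simplified: bool
    converged: bool

    def row(self, term: str) -> pd.Series:
        sub = self.data[self.data["term"] == term]
        if sub.empty:
            raise KeyError(term)
        return sub.iloc[0]


def _term_label(name: str) -> str | None:
    parts = []
    for factor in name.split(":"):
        if "year" in factor:
            parts.append("Y")
        elif "treatment" in factor:
            parts.append("T")
        elif "genotype" in factor:
            parts.append("G")
        else:
            return None
    return " x ".join(parts)


def fit_split_plot_deviance(ds: TrialDataset, trait: str) -> DevianceTable:
    """Fit the split-plot mixed model and return term-wise Wald chi-squares.

    Fixed: Y + T + G + all interactions (sum-to-zero coding). Random:
    intercepts for block (year x replicate) and for the main plots
    (treatment within block). A singular fit triggers a refit with the
    block-only random structure, flagged via ``simplified``.
    """
    import statsmodels.formula.api as smf

    for col in ("year", "treatment", "genotype", "rep"):
        if col not in ds.data.columns:
            raise DesignError(f"design column {col!r} missing")
    df = ds.data.dropna(subset=[trait]).copy()
    df["block"] = df["year"].astype(str) + "/" + df["rep"].astype(str)
    # fit on a unit-variance response for conditioning; Wald statistics are
    # invariant to this rescaling
    scale = float(df[trait].std()) or 1.0
    df["_y"] = df[trait] / scale
    formula = "_y ~ C(year, Sum) * C(treatment, Sum) * C(genotype, Sum)"

    def _fit(vc):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data=df, groups=df["block"], re_formula="1", vc_formula=vc)
            res = model.fit(reml=True, method="powell")
        return model, res

    simplified = False
    try:
        model, res = _fit({"mainplot": "0 + C(treatment)"})
        if not res.converged:
            raise np.linalg.LinAlgError("mixed model did not converge")
    except (np.linalg.LinAlgError, ValueError):
        # singular/failed fit: drop the main-plot variance component
        model, res = _fit(None)
        simplified = True

    k_fe = model.k_fe
    b = np.asarray(res.fe_params, dtype=float)
    V = np.asarray(res.cov_params())[:k_fe, :k_fe]
    design_info = model.data.design_info
    rows = []
    for name, sl in design_info.term_name_slices.items():
        label = _term_label(name)
        if label is None:  # Intercept
            continue
        idx = np.arange(sl.start, sl.stop)
        bs = b[idx]
        Vs = V[np.ix_(idx, idx)]
        chisq = float(bs @ np.linalg.solve(Vs, bs))
        dof = len(idx)
        p = float(stats.chi2.sf(chisq, dof))
        rows.append({"term": label, "chisq": chisq, "df": dof, "p": p, "code": significance_code(p)})
    table = pd.DataFrame(rows).set_index("term").loc[list(TERM_ORDER)].reset_index()
    return DevianceTable(trait=trait, data=table, simplified=simplified, converged=bool(res.converged))


@dataclass
class GenotypeTestTable:
    """Per-genotype low-vs-high Welch t-test results.

    ``data`` columns: genotype, mean_lf, mean_hf, n_lf, n_hf, t,
    p_two_sided, significant, testable.
    """

    trait: str
    alpha: float
    data: pd.DataFrame

    def significant_genotypes(self) -> list[str]:
        return sorted(self.data.loc[self.data["significant"], "genotype"])


def per_genotype_treatment_test(ds: TrialDataset, trait: str, alpha: float = 0.05) -> GenotypeTestTable:
    """Two-sided Welch t-test of LF vs HF plot-level values per genotype.

    The significance flag uses a strict inequality (p < alpha). Genotypes
    with fewer than 2 observations in either treatment are flagged
    untestable instead of raising.
    """
    low, high = ds.treatment_labels
    rows = []
    for geno, sub in ds.data.groupby("genotype"):
        lf = sub.loc[sub["treatment"] == low, trait].dropna().to_numpy()
        hf = sub.loc[sub["treatment"] == high, trait].dropna().to_numpy()
        row = {
            "genotype": geno,
            "mean_lf": float(np.mean(lf)) if len(lf) else np.nan,
            "mean_hf": float(np.mean(hf)) if len(hf) else np.nan,
            "n_lf": len(lf),
            "n_hf": len(hf),
        }
        if len(lf) < 2 or len(hf) < 2:
            row.update(t=np.nan, p_two_sided=np.nan, significant=False, testable=False)
        else:
            t, p = stats.ttest_ind(lf, hf, equal_var=False)
            row.update(
                t=float(t),
                p_two_sided=float(p),
                significant=bool(p < alpha),
                testable=True,
            )
        rows.append(row)
    return GenotypeTestTable(trait=trait, alpha=alpha, data=pd.DataFrame(rows))


@dataclass
class DunnettResult:
    """Dunnett many-to-one comparisons against the check under one treatment.

    ``data`` columns: genotype, mean, estimate (mean − check mean), p_adj,
    code, significant.
    """

    trait: str
    treatment_level: str
    check_id: str
    check_mean: float
    alpha: float
    data: pd.DataFrame


def dunnett_vs_check(
    ds: TrialDataset,
    trait: str,
    treatment_level: str | None = None,
    check_id: str | None = None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> DunnettResult:
    """Compare every entry's mean with the check's under one treatment level.

    Uses the multivariate-t Dunnett adjustment (family-wise error control for
    the many-to-one family). Defaults: the low treatment level and the
    dataset's declared check.
    """
    check_id = check_id if check_id is not None else ds.check_id
    if check_id is None:
        raise ConfigurationError("no check entry declared")
    level = treatment_level if treatment_level is not None else ds.low_label
    sub = ds.data[ds.data["treatment"] == level]
    groups = {
        g: v[trait].dropna().to_numpy() for g, v in sub.groupby("genotype")
    }
    if check_id not in groups or len(groups[check_id]) < 2:
        raise ConfigurationError(f"check {check_id!r} absent (or < 2 obs) at level {level!r}")
    others = sorted(g for g in groups if g != check_id and len(groups[g]) >= 2)
    if not others:
        raise ConfigurationError("no comparator entries with >= 2 observations")
    res = stats.dunnett(*(groups[g] for g in others), control=groups[check_id], alternative=alternative)
    check_mean = float(np.mean(groups[check_id]))
    rows = []
    for g, p in zip(others, np.atleast_1d(res.pvalue)):
        m = float(np.mean(groups[g]))
        rows.append(
            {
                "genotype": g,
                "mean": m,
                "estimate": m - check_mean,
                "p_adj": float(p),
                "code": significance_code(float(p)),
                "significant": bool(p < alpha),
            }
        )
    return DunnettResult(
        trait=trait,
        treatment_level=level,
        check_id=check_id,
        check_mean=check_mean,
        alpha=alpha,
        data=pd.DataFrame(rows),
    )
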