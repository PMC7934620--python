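"""Stress tolerance indices: percent reduction, stress intensity, SFSI.

The soil fertility susceptibility index (SFSI) is a Fischer-Maurer-type
stress susceptibility index applied to soil fertility contrast. For a
genotype with mean trait value x̄_lf under low fertility and x̄_hf under high
fertility,

    PR   = (1 - x̄_lf / x̄_hf) * 100          (percent reduction)
    SI   = 1 - Ȳ_lf / Ȳ_hf                   (soil fertility intensity)
    SFSI = (1 - x̄_lf / x̄_hf) / SI

where Ȳ_lf, Ȳ_hf are the unweighted grand means of the per-genotype means.
SFSI < 1 means the genotype loses proportionally less than the trial average
under the stress; SFSI > 1 means it is more susceptible than average. The
indices are dimensionless and invariant to rescaling of the trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, StressOrientationError, UndefinedRateError
from .trial_io import GenotypeMeansTable

__all__ = [
    "reduction_rate",
    "stress_intensity",
    "compute_sfsi_table",
    "classify_tolerance",
    "pearson_correlation",
    "round_half_away",
    "StressIndexTable",
    "ToleranceReport",
    "CorrelationResult",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (report convention)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def reduction_rate(x_lf: float, x_hf: float) -> float:
    """Percent reduction (x̄_hf − x̄_lf)/x̄_hf × 100.

    Negative values (genotype performs better under the stress) are allowed
    and returned as-is.
    """
    if x_hf <= 0:
        raise UndefinedRateError(f"reduction rate undefined for x_hf={x_hf!r} (requires > 0)")
    return (1.0 - x_lf / x_hf) * 100.0


def stress_intensity(means: GenotypeMeansTable) -> float:
    """Soil fertility intensity SI = 1 − Ȳ_lf/Ȳ_hf from genotype means.

    The grand means are unweighted means over the per-genotype means, the
    convention that reproduces the "Mean" row of a genotype-means table.
    """
    df = means.data
    if len(df) < 2:
        raise StressOrientationError("stress intensity needs >= 2 genotypes")
    y_hf = float(df["x_hf"].mean())
    if y_hf <= 0:
        raise StressOrientationError("grand high-fertility mean must be positive")
    si = 1.0 - float(df["x_lf"].mean()) / y_hf
    if si <= 0:
        raise StressOrientationError(
            f"SI={si:.4f} <= 0: the population is not stressed, SFSI undefined"
        )
    return si


@dataclass
class StressIndexTable:
    """Per-genotype PR and SFSI plus the trial-level summary quantities.

    ``data`` columns: ``genotype, x_lf, x_hf, pr_percent, sfsi``, sorted by
    (sfsi, genotype). ``flagged`` lists genotypes excluded for x_hf <= 0.
    """

    trait: str
    data: pd.DataFrame
    si: float
    y_lf_bar: float
    y_hf_bar: float
    mean_pr: float
    mean_sfsi: float
    flagged: tuple[str, ...] = ()

    def row(self, genotype: str) -> pd.Series:
        sub = self.data[self.data["genotype"] == genotype]
        if sub.empty:
            raise KeyError(genotype)
        return sub.iloc[0]

    def sfsi_of(self, genotype: str) -> float:
        return float(self.row(genotype)["sfsi"])

    def to_report_frame(self) -> pd.DataFrame:
        """Presentation table with a Mean row; means/PR at 1 dp, SFSI at 2 dp."""
        out = self.data.copy()
        for col, nd in (("x_lf", 1), ("x_hf", 1), ("pr_percent", 1), ("sfsi", 2)):
            out[col] = out[col].map(lambda v: round_half_away(v, nd))
        mean_row = pd.DataFrame(
            [
                {
                    "genotype": "Mean",
                    "x_lf": round_half_away(self.y_lf_bar, 1),
                    "x_hf": round_half_away(self.y_hf_bar, 1),
                    "pr_percent": round_half_away(self.mean_pr, 1),
                    "sfsi": round_half_away(self.mean_sfsi, 2),
                }
            ]
        )
        return pd.concat([out, mean_row], ignore_index=True)


def compute_sfsi_table(means: GenotypeMeansTable) -> StressIndexTable:
    """Compute PR and SFSI for every genotype of a means table.

    Rows with x_hf <= 0 are flagged and excluded from the grand means (and
    the output rows); SI is computed from the retained rows. Raises
    StressOrientationError when SI <= 0.
    """
    df = means.data
    ok = df["x_hf"] > 0
    flagged = tuple(df.loc[~ok, "genotype"])
    kept = GenotypeMeansTable(trait=means.trait, data=df[ok].reset_index(drop=True))
    si = stress_intensity(kept)
    y_lf_bar = float(kept.data["x_lf"].mean())
    y_hf_bar = float(kept.data["x_hf"].mean())
    pr = (1.0 - kept.data["x_lf"] / kept.data["x_hf"]) * 100.0
    sfsi = pr / 100.0 / si
    out = pd.DataFrame(
        {
            "genotype": kept.data["genotype"],
            "x_lf": kept.data["x_lf"].astype(float),
            "x_hf": kept.data["x_hf"].astype(float),
            "pr_percent": pr.astype(float),
            "sfsi": sfsi.astype(float),
        }
    ).sort_values(["sfsi", "genotype"], kind="stable").reset_index(drop=True)
    return StressIndexTable(
        trait=means.trait,
        data=out,
        si=si,
        y_lf_bar=y_lf_bar,
        y_hf_bar=y_hf_bar,
        mean_pr=float(pr.mean()),
        mean_sfsi=float(sfsi.mean()),
        flagged=flagged,
    )


@dataclass
class ToleranceReport:
    """Tolerance labels per genotype relative to the check entry.

    Labels: ``tolerant`` (SFSI below the check's, and optionally PR below the
    table mean PR), ``susceptible`` (SFSI at or above the threshold),
    ``intermediate`` otherwise; the check itself is labeled ``check``.
    """

    data: pd.DataFrame  # genotype, sfsi, pr_percent, label
    check_id: str
    check_sfsi: float
    susceptible_sfsi_min: float
    tolerant_requires_low_pr: bool
    mean_pr: float

    def genotypes_labeled(self, label: str) -> list[str]:
        return sorted(self.data.loc[self.data["label"] == label, "genotype"])


def classify_tolerance(
    idx: StressIndexTable,
    check_id: str,
    susceptible_sfsi_min: float = 1.25,
    tolerant_requires_low_pr: bool = True,
) -> ToleranceReport:
    """Label each genotype tolerant / intermediate / susceptible vs the check.

    Default rule: tolerant iff SFSI < check's SFSI and (when
    ``tolerant_requires_low_pr``) PR below the table's mean PR; susceptible
    iff SFSI >= ``susceptible_sfsi_min``; the check is labeled ``check``;
    everything else is intermediate.
    """
    try:
        check_sfsi = idx.sfsi_of(check_id)
    except KeyError:
        raise ConfigurationError(f"check entry {check_id!r} absent from index table")
    rows = []
    for _, r in idx.data.iterrows():
        if r["genotype"] == check_id:
            label = "check"
        elif r["sfsi"] >= susceptible_sfsi_min:
            label = "susceptible"
        elif r["sfsi"] < check_sfsi and (
            not tolerant_requires_low_pr or r["pr_percent"] < idx.mean_pr
        ):
            label = "tolerant"
        else:
            label = "intermediate"
        rows.append(
            {
                "genotype": r["genotype"],
                "sfsi": float(r["sfsi"]),
                "pr_percent": float(r["pr_percent"]),
                "label": label,
            }
        )
    return ToleranceReport(
        data=pd.DataFrame(rows),
        check_id=check_id,
        check_sfsi=check_sfsi,
        susceptible_sfsi_min=susceptible_sfsi_min,
        tolerant_requires_low_pr=tolerant_requires_low_pr,
        mean_pr=idx.mean_pr,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with two-sided p from the t distribution (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("correlation inputs must be paired 1-d vectors")
    if len(x) < 3:
        raise ConfigurationError("correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigurationError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=len(x))
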