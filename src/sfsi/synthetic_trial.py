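"""Synthetic split-plot trial generator with analytically known truth.

Emulates the reference trial design: two fertility treatments on main plots,
genotype subplots within them, several plants per subplot, replicated blocks
over multiple years. Each observation is

    value = x(g, t) + year[y] + yxt[y] * s(t) + block(y, r) + mainplot(y, r, t) + e

with s(HF) = +1, s(LF) = -1, all random effects Gaussian on the trait scale.
``year`` and ``yxt`` effect vectors are centred to mean zero so the pooled
per-genotype means are unbiased for the configured x(g, t); the implied true
PR/SI/SFSI are computed analytically from the configuration via the indices
formulas, never from the sample. Negative simulated values are clipped at
zero (traits are masses) with a logged count.

Sub-streams of the root seed are derived per stratum and per genotype, so
adding genotypes to a configuration does not reshuffle the draws of existing
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, StressOrientationError
from .indices import StressIndexTable, compute_sfsi_table
from .trial_io import GenotypeMeansTable, TrialDataset, ValidationReport, genotype_treatment_means, load_reference_table

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_trial",
    "recovery_experiment",
    "reference_tuber_config",
    "RecoverySummary",
]


class SimConfig(BaseModel):
    """Generating parameters of a synthetic two-treatment split-plot trial.

    ``genotype_hf_means`` (g plant^-1) and ``reduction_fractions`` (fraction
    of the HF mean lost under LF; < 1, may be negative) are keyed by genotype
    and define the true cell means: x_lf = (1 - fraction) * x_hf. Effect and
    noise parameters are additive g plant^-1 on the trait scale.
    """

    genotype_hf_means: dict[str, float]
    reduction_fractions: dict[str, float]
    year_effects: tuple[float, ...] = (150.0, -150.0)
    year_by_treatment_effects: tuple[float, ...] = (50.0, -50.0)
    replicate_sd: float = Field(50.0, ge=0)
    mainplot_sd: float = Field(100.0, ge=0)
    residual_sd: float = Field(500.0, ge=0)
    n_years: int = Field(2, ge=1)
    n_reps: int = Field(2, ge=1)
    plants_per_subplot: int = Field(3, ge=1)
    treatment_labels: tuple[str, str] = ("LF", "HF")
    check_id: str | None = None
    trait: str = "trait"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if set(self.genotype_hf_means) != set(self.reduction_fractions):
            raise ConfigurationError("genotype_hf_means and reduction_fractions must share keys")
        bad = [g for g, m in self.genotype_hf_means.items() if m <= 0]
        if bad:
            raise ConfigurationError(f"HF means must be > 0; offending genotypes: {bad}")
        if any(f >= 1 for f in self.reduction_fractions.values()):
            raise ConfigurationError("reduction fractions must be < 1 (x_lf must stay positive-mean)")
        if len(self.year_effects) != self.n_years or len(self.year_by_treatment_effects) != self.n_years:
            raise ConfigurationError("effect vectors must have length n_years")
        if self.check_id is not None and self.check_id not in self.genotype_hf_means:
            raise ConfigurationError(f"check {self.check_id!r} not among configured genotypes")
        return self

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_hf_means)

    def true_means(self) -> GenotypeMeansTable:
        """Configured cell means as a GenotypeMeansTable (n = design size)."""
        n = self.n_years * self.n_reps * self.plants_per_subplot
        rows = [
            {
                "genotype": g,
                "x_lf": (1.0 - self.reduction_fractions[g]) * m,
                "x_hf": m,
                "n_lf": n,
                "n_hf": n,
            }
            for g, m in self.genotype_hf_means.items()
        ]
        return GenotypeMeansTable(trait=self.trait, data=pd.DataFrame(rows))


@dataclass
class SimTruth:
    """Analytic truth implied by a SimConfig: per-genotype means, PR, SFSI, SI.

    ``index_table`` is None when the configured population is not stressed
    (SI <= 0), in which case PR/SFSI truth is undefined by construction.
    """

    means: GenotypeMeansTable
    index_table: StressIndexTable | None

    @property
    def si(self) -> float:
        self._require_defined()
        return self.index_table.si

    @property
    def data(self) -> pd.DataFrame:
        self._require_defined()
        return self.index_table.data

    def sfsi_of(self, genotype: str) -> float:
        self._require_defined()
        return self.index_table.sfsi_of(genotype)

    def _require_defined(self) -> None:
        if self.index_table is None:
            raise StressOrientationError("configured SI <= 0: SFSI truth undefined")


def _truth_of(cfg: SimConfig) -> SimTruth:
    means = cfg.true_means()
    try:
        idx = compute_sfsi_table(means)
    except StressOrientationError:
        idx = None
    return SimTruth(means=means, index_table=idx)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_trial(cfg: SimConfig) -> tuple[TrialDataset, SimTruth]:
    """Generate one synthetic trial dataset plus its analytic truth.

    Identical configuration (including seed) gives an identical dataset.
    """
    low, high = cfg.treatment_labels
    year_eff = np.asarray(cfg.year_effects) - np.mean(cfg.year_effects)
    yxt_eff = np.asarray(cfg.year_by_treatment_effects) - np.mean(cfg.year_by_treatment_effects)
    block_rng = _stream(cfg.seed, 0)
    block = block_rng.normal(0.0, cfg.replicate_sd, size=(cfg.n_years, cfg.n_reps))
    main_rng = _stream(cfg.seed, 1)
    mainplot = main_rng.normal(0.0, cfg.mainplot_sd, size=(cfg.n_years, cfg.n_reps, 2))

    rows = []
    clipped = 0
    for gi, geno in enumerate(cfg.genotypes):
        x_hf = cfg.genotype_hf_means[geno]
        x_lf = (1.0 - cfg.reduction_fractions[geno]) * x_hf
        rng = _stream(cfg.seed, 2, gi)
        for y in range(cfg.n_years):
            for r in range(cfg.n_reps):
                for ti, (t_label, mu, sgn) in enumerate(((low, x_lf, -1.0), (high, x_hf, +1.0))):
                    resid = rng.normal(0.0, cfg.residual_sd, size=cfg.plants_per_subplot)
                    vals = mu + year_eff[y] + sgn * yxt_eff[y] + block[y, r] + mainplot[y, r, ti] + resid
                    neg = vals < 0
                    clipped += int(neg.sum())
                    vals = np.where(neg, 0.0, vals)
                    for v in vals:
                        rows.append(
                            {
                                "genotype": geno,
                                "year": y + 1,
                                "treatment": t_label,
                                "rep": r + 1,
                                cfg.trait: float(v),
                            }
                        )
    report = ValidationReport()
    if clipped:
        report.add("clipped_negative", f"{clipped} simulated values clipped at 0", count=clipped)
    ds = TrialDataset(
        data=pd.DataFrame(rows),
        traits=(cfg.trait,),
        treatment_labels=cfg.treatment_labels,
        check_id=cfg.check_id,
        validation=report,
    )
    return ds, _truth_of(cfg)


@dataclass
class RecoverySummary:
    """Bias/RMSE of pipeline-estimated SFSI against the analytic truth."""

    n_sims: int
    per_genotype: pd.DataFrame  # genotype, true_sfsi, bias, rmse
    rmse_overall: float


def recovery_experiment(cfg: SimConfig, n_sims: int, seed: int = 0) -> RecoverySummary:
    """Repeatedly simulate, run the means -> SFSI pipeline, compare to truth.

    Each repetition reseeds the generator from ``seed`` deterministically.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be >= 1")
    truth = _truth_of(cfg)
    true_sfsi = truth.data.set_index("genotype")["sfsi"]
    errors = []
    for k in range(n_sims):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))
        ds, _ = simulate_trial(cfg.model_copy(update={"seed": sub_seed}))
        means = genotype_treatment_means(ds, cfg.trait)
        est = compute_sfsi_table(means).data.set_index("genotype")["sfsi"]
        errors.append(est.reindex(true_sfsi.index) - true_sfsi)
    err = pd.concat(errors, axis=1)
    per_geno = pd.DataFrame(
        {
            "genotype": true_sfsi.index,
            "true_sfsi": true_sfsi.values,
            "bias": err.mean(axis=1).values,
            "rmse": np.sqrt((err**2).mean(axis=1)).values,
        }
    ).reset_index(drop=True)
    return RecoverySummary(
        n_sims=n_sims,
        per_genotype=per_geno,
        rmse_overall=float(np.sqrt((err.values**2).mean())),
    )


def reference_tuber_config(**overrides) -> SimConfig:
    """SimConfig calibrated to the packaged tuber-yield reference table.

    HF means and reduction fractions are read from the reference table, so
    the configured truth reproduces its PR and SFSI columns; the noise
    defaults put per-genotype t-tests at the design's n = 12 in the p-value
    range the reference trial reports.
    """
    ref = load_reference_table("tuber_yield")
    hf = dict(zip(ref["genotype"], ref["x_hf"].astype(float)))
    frac = {
        g: 1.0 - lf / h
        for g, lf, h in zip(ref["genotype"], ref["x_lf"].astype(float), ref["x_hf"].astype(float))
    }
    base = dict(
        genotype_hf_means=hf,
        reduction_fractions=frac,
        check_id="Local variety",
        trait="tuber_yield",
    )
    base.update(overrides)
    return SimConfig(**base)
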