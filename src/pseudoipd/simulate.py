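"""Simulation of true IPD under the ANCOVA generative model.

Used both to study the estimators and as the oracle for the central
sufficiency property: summarising simulated true IPD to aggregate form,
regenerating pseudo IPD from those aggregates, and refitting must reproduce
every likelihood-based estimate of the true-IPD fit.

The generative model follows the one-stage ANCOVA: per study i, baselines
are Normal(mu_i, sigma_Bi^2); the follow-up is

    y_F = beta0_i + (beta1 + u1_i) x + beta2_i (y_B - mu_i)
          + (beta3 + u3_i)(y_B - mu_i) x + beta4 mu_i x + eps,

with u1 ~ N(0, tau1_sq), u3 ~ N(0, tau3_sq) and eps drawn under any of the
four residual-variance structures.  The generative centring uses the true
study mean mu_i; the fitting modules centre on the observed study mean, as
an analyst must.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import ArmSummary, MetaAggregate

__all__ = ["SimScenario", "simulate_ipd", "summarize_to_ad"]


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated meta-analysis.

    ``residuals`` maps the residual structure to its standard deviations:
    "pooled" → one float; "by_arm" → (sd_control, sd_treated);
    "by_study" → sequence of length n_studies; "by_study_arm" → sequence of
    (sd_control, sd_treated) pairs per study.
    """

    n_studies: int
    n_per_arm: int | Sequence[int]
    mu_baseline: Sequence[float]
    sigma_baseline: Sequence[float]
    beta0: Sequence[float]
    beta1: float
    beta2: Sequence[float]
    beta3: float = 0.0
    beta4: float = 0.0
    tau1_sq: float = 0.0
    tau3_sq: float = 0.0
    interaction: bool = False
    residual_structure: str = "by_study"
    residuals: float | Sequence = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 2:
            raise ValueError("need at least 2 studies")
        for name in ("mu_baseline", "sigma_baseline", "beta0", "beta2"):
            if len(getattr(self, name)) != self.n_studies:
                raise ValueError(f"{name} must have length n_studies")
        if self.tau1_sq < 0 or self.tau3_sq < 0:
            raise ValueError("heterogeneity variances must be >= 0")
        n = self.arm_sizes
        if min(n) < 3:
            raise ValueError("n_per_arm must be >= 3")
        if any(s <= 0 for s in self.sigma_baseline):
            raise ValueError("baseline SDs must be > 0")

    @property
    def arm_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_per_arm, int):
            return (self.n_per_arm,) * self.n_studies
        return tuple(self.n_per_arm)

    def residual_sd(self, study: int, arm: int) -> float:
        rs, r = self.residual_structure, self.residuals
        if rs == "pooled":
            return float(r)
        if rs == "by_arm":
            return float(r[arm])
        if rs == "by_study":
            return float(r[study])
        if rs == "by_study_arm":
            return float(r[study][arm])
        raise ValueError(f"unknown residual structure {rs!r}")


def simulate_ipd(scenario: SimScenario) -> pd.DataFrame:
    """Draw one true-IPD realisation of the scenario.

    Returns records in the same shape the fitting modules accept:
    columns ``study, arm, treat, y_base, y_final``.
    """
    rng = np.random.default_rng(scenario.seed)
    sizes = scenario.arm_sizes
    frames = []
    for i in range(scenario.n_studies):
        u1 = rng.normal(0.0, np.sqrt(scenario.tau1_sq)) if scenario.tau1_sq > 0 else 0.0
        u3 = rng.normal(0.0, np.sqrt(scenario.tau3_sq)) if scenario.tau3_sq > 0 else 0.0
        mu, sB = scenario.mu_baseline[i], scenario.sigma_baseline[i]
        for arm in (0, 1):
            n = sizes[i]
            yb = rng.normal(mu, sB, n)
            eps = rng.normal(0.0, scenario.residual_sd(i, arm), n)
            yf = scenario.beta0[i] + scenario.beta2[i] * (yb - mu) + eps
            if arm == 1:
                yf = yf + scenario.beta1 + u1
                if scenario.interaction:
                    yf = yf + (scenario.beta3 + u3) * (yb - mu) + scenario.beta4 * mu
            frames.append(
                pd.DataFrame(
                    {
                        "study": f"S{i + 1}",
                        "arm": "treated" if arm else "control",
                        "treat": arm,
                        "y_base": yb,
                        "y_final": yf,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def summarize_to_ad(ipd: pd.DataFrame, outcome_label: str = "outcome",
                    outcome_units: str = "") -> MetaAggregate:
    """Reduce subject-level records to per-arm aggregate statistics.

    Means, SDs (n-1 denominator) and the within-arm Pearson correlation —
    the sufficient statistics from which pseudo IPD can be regenerated.
    """
    df = ipd.data if hasattr(ipd, "data") else ipd
    if "treat" not in df.columns:
        df = df.assign(treat=(df["arm"] == "treated").astype(int))
    studies = []
    for sid in df["study"].unique():
        arms = {}
        for x, label in ((1, "treated"), (0, "control")):
            g = df[(df["study"] == sid) & (df["treat"] == x)]
            if len(g) < 3:
                raise ValueError(f"study {sid!r}, arm {label}: n must be >= 3")
            yb, yf = g["y_base"].to_numpy(), g["y_final"].to_numpy()
            arms[label] = ArmSummary(
                study_id=str(sid),
                arm=label,
                n=len(g),
                mean_baseline=float(yb.mean()),
                sd_baseline=float(yb.std(ddof=1)),
                mean_final=float(yf.mean()),
                sd_final=float(yf.std(ddof=1)),
                corr=float(np.corrcoef(yb, yf)[0, 1]),
            )
        studies.append((str(sid), arms["treated"], arms["control"]))
    return MetaAggregate(tuple(studies), outcome_label, outcome_units).completed()
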