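"""Construction of pseudo individual participant data from aggregates.

Given one arm's aggregate statistics (n, baseline mean/SD, follow-up
mean/SD, correlation r), the generator produces n pseudo (baseline,
follow-up) pairs whose *sample* mean, SD (n-1 denominator) and Pearson
correlation equal the inputs exactly (to floating-point rounding):

1. draw two n-vectors from a base distribution (standard normal by default);
2. standardise each to sample mean 0 and sample SD 1; let r* be their
   sample correlation;
3. regress the second on the first and keep the residuals e (orthogonal to
   the first vector, sample variance 1 - r*^2);
4. set y3 = r * y1 + e * sqrt((1 - r^2) / (1 - r*^2)), which has sample
   SD 1 and sample correlation r with y1;
5. baseline = y1 * sd_baseline + mean_baseline;
6. follow-up = y3 * sd_final + mean_final.

Because these six per-arm moments are the sufficient statistics of the
ANCOVA linear mixed model, any likelihood-based fit of the pseudo data is
identical to the fit of the unobserved true data.  The base distribution is
therefore irrelevant to inference and only changes the (arbitrary) record
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Callable

import numpy as np
import pandas as pd

from .aggregate import ArmSummary, MetaAggregate, TREATED

__all__ = ["PseudoIPD", "generate_arm", "generate_dataset", "read_ipd", "write_ipd"]

GENERATOR_VERSION = "1"

#: give up after this many redraws of a numerically degenerate base sample
MAX_REDRAWS = 10

IPD_COLUMNS = ("study", "arm", "treat", "y_base", "y_final")


class DegenerateDrawError(RuntimeError):
    """The base draws were (numerically) collinear after repeated retries."""


@dataclass(frozen=True)
class Provenance:
    seed: int | None
    base_distribution: str
    generator_version: str = GENERATOR_VERSION


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed subject-level records plus generation provenance.

    ``data`` has one row per subject with columns ``study`` (id), ``arm``
    ("treated"/"control"), ``treat`` (0/1), ``y_base`` and ``y_final``.
    """

    data: pd.DataFrame
    provenance: Provenance

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(self.data["study"].unique())

    def study(self, study_id: str) -> pd.DataFrame:
        return self.data[self.data["study"] == study_id]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDrawError("zero-variance base draw")
    return (x - x.mean()) / sd


def generate_arm(
    summary: ArmSummary,
    rng: np.random.Generator,
    base_distribution: str | Callable[[np.random.Generator, int], np.ndarray] = "normal",
) -> pd.DataFrame:
    """Generate one arm's pseudo records; see the module docstring for steps.

    Returns a DataFrame with columns ``study, arm, treat, y_base, y_final``
    whose sample moments reproduce ``summary`` exactly.
    """
    if summary.corr is None:
        raise ValueError(
            f"study {summary.study_id!r}, arm {summary.arm!r}: correlation missing; "
            "complete the aggregate data first"
        )
    n, r = summary.n, float(summary.corr)
    if n < 3:
        raise ValueError("n must be >= 3 for exact moment matching")

    if callable(base_distribution):
        draw = base_distribution
    elif base_distribution == "normal":
        draw = lambda g, size: g.standard_normal(size)
    elif base_distribution == "uniform":
        draw = lambda g, size: g.uniform(-1.0, 1.0, size)
    elif base_distribution == "exponential":
        draw = lambda g, size: g.standard_exponential(size)
    else:
        raise ValueError(f"unknown base distribution {base_distribution!r}")

    for _ in range(MAX_REDRAWS):
        try:
            y1 = _standardize(draw(rng, n))
            y2 = _standardize(draw(rng, n))
        except DegenerateDrawError:
            continue
        r_star = float(y1 @ y2) / (n - 1)
        if abs(r_star) < 1.0 - 1e-12:
            break
    else:
        raise DegenerateDrawError(
            f"study {summary.study_id!r}, arm {summary.arm!r}: base draws collinear "
            f"after {MAX_REDRAWS} attempts"
        )

    resid = y2 - r_star * y1  # orthogonal to y1, sample variance 1 - r*^2
    y3 = r * y1 + resid * np.sqrt((1.0 - r**2) / (1.0 - r_star**2))
    return pd.DataFrame(
        {
            "study": summary.study_id,
            "arm": summary.arm,
            "treat": int(summary.arm == TREATED),
            "y_base": y1 * summary.sd_baseline + summary.mean_baseline,
            "y_final": y3 * summary.sd_final + summary.mean_final,
        }
    )


def generate_dataset(
    data: MetaAggregate,
    seed: int | None = 0,
    base_distribution: str | Callable[[np.random.Generator, int], np.ndarray] = "normal",
) -> PseudoIPD:
    """Generate pseudo IPD for every arm of a MetaAggregate.

    Each arm draws from its own random substream keyed on
    ``(seed, study_id, arm)``, so adding or removing a study leaves the other
    arms' records unchanged.
    """
    frames = []
    for arm in data.arms():
        ss = np.random.SeedSequence(
            seed, spawn_key=tuple(f"{arm.study_id}/{arm.arm}".encode())
        )
        rng = np.random.default_rng(ss)
        try:
            frames.append(generate_arm(arm, rng, base_distribution))
        except (ValueError, DegenerateDrawError) as exc:
            raise type(exc)(
                f"while generating study {arm.study_id!r} arm {arm.arm!r}: {exc}"
            ) from exc
    name = base_distribution if isinstance(base_distribution, str) else "custom"
    return PseudoIPD(
        data=pd.concat(frames, ignore_index=True),
        provenance=Provenance(seed=seed, base_distribution=name),
    )


def write_ipd(ipd: PseudoIPD | pd.DataFrame, target: str | IO[str]) -> None:
    """Write subject-level records as delimited text (full float precision)."""
    df = ipd.data if isinstance(ipd, PseudoIPD) else ipd
    df.to_csv(target, index=False, float_format="%.17g")


def read_ipd(source: str | IO[str]) -> pd.DataFrame:
    """Read subject-level records written by :func:`write_ipd`."""
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in ("study", "y_base", "y_final") if c not in df.columns]
    if missing:
        raise ValueError(f"IPD file missing columns: {missing}")
    if "treat" not in df.columns:
        if "arm" not in df.columns:
            raise ValueError("IPD file needs a 'treat' or 'arm' column")
        df["treat"] = (df["arm"] == TREATED).astype(int)
    if "arm" not in df.columns:
        df["arm"] = np.where(df["treat"] == 1, "treated", "control")
    df["study"] = df["study"].astype(str)
    return df
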