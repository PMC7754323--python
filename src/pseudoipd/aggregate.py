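"""Trial-level aggregate data for baseline/follow-up continuous outcomes.

A two-arm study is summarised per arm by the sample size, the mean and SD of
the outcome at baseline and at follow-up, and the within-arm correlation
between the two measurements.  These six numbers per arm are the sufficient
statistics of the ANCOVA linear mixed model, so they are all this package
ever needs from a study.

The correlation is rarely reported directly; it can be recovered from the
SD of the change scores,

    r = (sd_B^2 + sd_F^2 - sd_change^2) / (2 sd_B sd_F),

or, assuming the correlation is shared by both arms, from the standard error
of the between-group difference in mean change (:func:`corr_from_se_diff`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmSummary",
    "MetaAggregate",
    "AggregateSchemaError",
    "AggregateValidationError",
    "CorrelationInconsistencyError",
    "corr_from_change_sd",
    "sd_change_from_corr",
    "corr_from_se_diff",
    "read_aggregate",
    "write_aggregate",
    "apply_baseline_shift",
]

#: correlations this close to +/-1 are rejected: the pseudo-data generator
#: requires |r| < 1 and clipping would silently change the analysis.
CORR_BOUNDARY_EPS = 1e-9

TREATED = "treated"
CONTROL = "control"

CANONICAL_COLUMNS = (
    "study",
    "arm",
    "n",
    "mean_base",
    "sd_base",
    "mean_final",
    "sd_final",
    "corr",
    "sd_change",
    "se_diff_change",
)


class AggregateSchemaError(ValueError):
    """The input table is missing a required column or is malformed."""


class AggregateValidationError(ValueError):
    """A study arm's summary statistics are invalid (n, SDs, correlation)."""


class CorrelationInconsistencyError(AggregateValidationError):
    """Reported SDs are incompatible with any joint distribution (|r| >= 1)."""


def corr_from_change_sd(sd_baseline: float, sd_final: float, sd_change: float) -> float:
    """Recover the baseline/follow-up correlation from the change-score SD.

    Parameters
    ----------
    sd_baseline, sd_final, sd_change : float
        Within-arm standard deviations, all > 0.

    Returns
    -------
    float
        The correlation ``(sd_B^2 + sd_F^2 - sd_change^2) / (2 sd_B sd_F)``,
        strictly inside (-1, 1).

    Raises
    ------
    CorrelationInconsistencyError
        If the implied correlation is outside the open interval, i.e. the
        three SDs cannot arise from any joint distribution.
    """
    if sd_baseline <= 0 or sd_final <= 0 or sd_change <= 0:
        raise ValueError("standard deviations must be positive")
    r = (sd_baseline**2 + sd_final**2 - sd_change**2) / (2.0 * sd_baseline * sd_final)
    _check_corr(r, context="corr_from_change_sd")
    return r


def sd_change_from_corr(sd_baseline: float, sd_final: float, corr: float) -> float:
    """SD of the within-subject change implied by the two SDs and correlation."""
    if sd_baseline <= 0 or sd_final <= 0:
        raise ValueError("standard deviations must be positive")
    if not -1.0 < corr < 1.0:
        raise ValueError("correlation must lie strictly inside (-1, 1)")
    var = sd_baseline**2 + sd_final**2 - 2.0 * corr * sd_baseline * sd_final
    return float(np.sqrt(var))


def corr_from_se_diff(
    treated: tuple[int, float, float],
    control: tuple[int, float, float],
    se_diff_change: float,
) -> float:
    """Recover a shared correlation from the SE of the difference in mean change.

    Assumes the baseline/follow-up correlation is equal in the two arms.

    Parameters
    ----------
    treated, control : (n, sd_baseline, sd_final)
        Per-arm sample size and SDs.
    se_diff_change : float
        Standard error of the between-group difference in mean change scores.

    Returns
    -------
    float
        The common correlation, strictly inside (-1, 1).
    """
    nT, sdBT, sdFT = treated
    nC, sdBC, sdFC = control
    if min(nT, nC) < 3:
        raise ValueError("each arm needs n >= 3")
    if min(sdBT, sdFT, sdBC, sdFC) <= 0 or se_diff_change <= 0:
        raise ValueError("SDs and the standard error must be positive")
    num = sdBT**2 / nT + sdFT**2 / nT + sdBC**2 / nC + sdFC**2 / nC - se_diff_change**2
    den = 2.0 * sdBT * sdFT / nT + 2.0 * sdBC * sdFC / nC
    r = num / den
    _check_corr(r, context="corr_from_se_diff")
    return r


def _check_corr(r: float, context: str = "") -> None:
    if not np.isfinite(r) or abs(r) >= 1.0 - CORR_BOUNDARY_EPS:
        raise CorrelationInconsistencyError(
            f"implied correlation {r!r} is outside (-1, 1)"
            + (f" in {context}" if context else "")
            + "; the reported summary statistics are mutually inconsistent"
        )


@dataclass(frozen=True)
class ArmSummary:
    """Aggregate statistics of one study arm.

    ``corr`` may be None on construction when only ``sd_change`` (or the
    study-level SE of the change difference) is available; it is filled in by
    :func:`read_aggregate` or :meth:`completed`.
    """

    study_id: str
    arm: str
    n: int
    mean_baseline: float
    sd_baseline: float
    mean_final: float
    sd_final: float
    corr: float | None = None
    sd_change: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in (TREATED, CONTROL):
            raise AggregateValidationError(
                f"study {self.study_id!r}: arm must be 'treated' or 'control', got {self.arm!r}"
            )
        if self.n < 3:
            raise AggregateValidationError(
                f"study {self.study_id!r}, arm {self.arm!r}: n must be >= 3, got {self.n}"
            )
        for name in ("sd_baseline", "sd_final"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise AggregateValidationError(
                    f"study {self.study_id!r}, arm {self.arm!r}: {name} must be > 0, got {v!r}"
                )
        if self.sd_change is not None and self.sd_change <= 0:
            raise AggregateValidationError(
                f"study {self.study_id!r}, arm {self.arm!r}: sd_change must be > 0"
            )
        if self.corr is not None and abs(self.corr) >= 1.0 - CORR_BOUNDARY_EPS:
            raise AggregateValidationError(
                f"study {self.study_id!r}, arm {self.arm!r}: correlation {self.corr} "
                "must lie strictly inside (-1, 1)"
            )

    def completed(self) -> "ArmSummary":
        """Return a copy with ``corr`` and ``sd_change`` mutually filled in."""
        corr, sd_change = self.corr, self.sd_change
        if corr is None and sd_change is None:
            raise AggregateValidationError(
                f"study {self.study_id!r}, arm {self.arm!r}: neither the correlation "
                "nor the change-score SD is available"
            )
        if corr is None:
            corr = corr_from_change_sd(self.sd_baseline, self.sd_final, sd_change)
        if sd_change is None:
            sd_change = sd_change_from_corr(self.sd_baseline, self.sd_final, corr)
        return replace(self, corr=corr, sd_change=sd_change)

    @property
    def mean_change(self) -> float:
        return self.mean_final - self.mean_baseline


@dataclass(frozen=True)
class MetaAggregate:
    """A validated collection of two-arm study summaries."""

    studies: tuple[tuple[str, ArmSummary, ArmSummary], ...]
    outcome_label: str = "outcome"
    outcome_units: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for study_id, treated, control in self.studies:
            if study_id in seen:
                raise AggregateValidationError(f"duplicate study id {study_id!r}")
            seen.add(study_id)
            if treated.arm != TREATED or control.arm != CONTROL:
                raise AggregateValidationError(
                    f"study {study_id!r}: expected one treated and one control arm"
                )
            if treated.study_id != study_id or control.study_id != study_id:
                raise AggregateValidationError(
                    f"study {study_id!r}: arm study_id mismatch"
                )

    @property
    def study_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.studies)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_subjects(self) -> int:
        return sum(t.n + c.n for _, t, c in self.studies)

    def arms(self) -> Iterable[ArmSummary]:
        for _, t, c in self.studies:
            yield t
            yield c

    def study(self, study_id: str) -> tuple[ArmSummary, ArmSummary]:
        for sid, t, c in self.studies:
            if sid == study_id:
                return t, c
        raise KeyError(study_id)

    def subset(self, study_ids: Sequence[str]) -> "MetaAggregate":
        keep = set(study_ids)
        return MetaAggregate(
            tuple(s for s in self.studies if s[0] in keep),
            self.outcome_label,
            self.outcome_units,
        )

    def completed(self) -> "MetaAggregate":
        """Complete every arm's correlation / change-score SD."""
        return MetaAggregate(
            tuple((sid, t.completed(), c.completed()) for sid, t, c in self.studies),
            self.outcome_label,
            self.outcome_units,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in self.arms():
            rows.append(
                {
                    "study": arm.study_id,
                    "arm": arm.arm,
                    "n": arm.n,
                    "mean_base": arm.mean_baseline,
                    "sd_base": arm.sd_baseline,
                    "mean_final": arm.mean_final,
                    "sd_final": arm.sd_final,
                    "corr": np.nan if arm.corr is None else arm.corr,
                    "sd_change": np.nan if arm.sd_change is None else arm.sd_change,
                }
            )
        return pd.DataFrame(rows)


_LONG_REQUIRED = ("study", "arm", "n", "mean_base", "sd_base", "mean_final", "sd_final")
_WIDE_ARM_FIELDS = ("n", "mean_base", "sd_base", "mean_final", "sd_final", "corr", "sd_change")


def read_aggregate(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    outcome_label: str = "outcome",
    outcome_units: str = "",
) -> MetaAggregate:
    """Read a delimited table of per-arm (long) or per-study (wide) aggregates.

    Long layout: one row per arm with columns
    ``study, arm, n, mean_base, sd_base, mean_final, sd_final`` plus at least
    one of ``corr, sd_change, se_diff_change``.  Wide layout: one row per
    study with the same per-arm fields suffixed ``_treated`` / ``_control``
    (and optionally a study-level ``se_diff_change``).

    ``column_map`` maps canonical names to the names actually present.
    Correlations absent in a row are recovered from ``sd_change`` (per arm) or
    ``se_diff_change`` (shared across arms); a row where neither is possible
    raises :class:`AggregateValidationError`.
    """
    if isinstance(source, str) and "\n" not in source:
        df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c")
    else:
        buf = io.StringIO(source) if isinstance(source, str) else source
        df = pd.read_csv(buf, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    if df.empty:
        raise AggregateSchemaError("input table is empty")

    if "arm" in df.columns:
        return _from_long(df, outcome_label, outcome_units)
    return _from_wide(df, outcome_label, outcome_units)


def _num(row, col, study, arm, *, required=True):
    if col not in row or pd.isna(row[col]):
        if required:
            raise AggregateSchemaError(
                f"study {study!r}, arm {arm!r}: missing required value {col!r}"
            )
        return None
    try:
        return float(row[col])
    except (TypeError, ValueError) as exc:
        raise AggregateValidationError(
            f"study {study!r}, arm {arm!r}: non-numeric {col!r}: {row[col]!r}"
        ) from exc


def _build_arm(study, arm_label, row_like) -> ArmSummary:
    n = _num(row_like, "n", study, arm_label)
    if n is None or n != int(n):
        raise AggregateValidationError(f"study {study!r}, arm {arm_label!r}: n must be an integer")
    return ArmSummary(
        study_id=str(study),
        arm=arm_label,
        n=int(n),
        mean_baseline=_num(row_like, "mean_base", study, arm_label),
        sd_baseline=_num(row_like, "sd_base", study, arm_label),
        mean_final=_num(row_like, "mean_final", study, arm_label),
        sd_final=_num(row_like, "sd_final", study, arm_label),
        corr=_num(row_like, "corr", study, arm_label, required=False),
        sd_change=_num(row_like, "sd_change", study, arm_label, required=False),
    )


def _complete_pair(study, treated: ArmSummary, control: ArmSummary, se_diff) -> tuple[ArmSummary, ArmSummary]:
    # per-arm recovery first (change-score SD), then the shared-SE fallback
    def _try_complete(a: ArmSummary) -> ArmSummary | None:
        try:
            return a.completed()
        except AggregateValidationError:
            if isinstance(a.sd_change, float) or a.corr is not None:
                raise
            return None

    t, c = _try_complete(treated), _try_complete(control)
    if t is not None and c is not None:
        return t, c
    if se_diff is None:
        raise AggregateValidationError(
            f"study {study!r}: correlation not recoverable (no corr, sd_change "
            "or se_diff_change provided)"
        )
    r = corr_from_se_diff(
        (treated.n, treated.sd_baseline, treated.sd_final),
        (control.n, control.sd_baseline, control.sd_final),
        float(se_diff),
    )
    t = replace(treated, corr=r).completed() if t is None else t
    c = replace(control, corr=r).completed() if c is None else c
    return t, c


def _from_long(df: pd.DataFrame, outcome_label, outcome_units) -> MetaAggregate:
    for col in _LONG_REQUIRED:
        if col not in df.columns:
            raise AggregateSchemaError(f"missing required column {col!r}")
    studies = []
    for study, grp in df.groupby("study", sort=False):
        arms = {}
        for _, row in grp.iterrows():
            label = str(row["arm"]).strip().lower()
            if label in ("1", "treated", "treatment", "active"):
                label = TREATED
            elif label in ("0", "control", "placebo", "sham"):
                label = CONTROL
            else:
                raise AggregateValidationError(
                    f"study {study!r}: unrecognised arm label {row['arm']!r}"
                )
            if label in arms:
                raise AggregateValidationError(f"study {study!r}: duplicate {label} arm")
            arms[label] = _build_arm(study, label, row)
        if set(arms) != {TREATED, CONTROL}:
            raise AggregateValidationError(
                f"study {study!r}: needs exactly one treated and one control arm"
            )
        se_diff = None
        if "se_diff_change" in grp.columns:
            vals = grp["se_diff_change"].dropna().unique()
            if len(vals) > 1:
                raise AggregateValidationError(
                    f"study {study!r}: conflicting se_diff_change values"
                )
            se_diff = vals[0] if len(vals) else None
        t, c = _complete_pair(study, arms[TREATED], arms[CONTROL], se_diff)
        studies.append((str(study), t, c))
    return MetaAggregate(tuple(studies), outcome_label, outcome_units)


def _from_wide(df: pd.DataFrame, outcome_label, outcome_units) -> MetaAggregate:
    if "study" not in df.columns:
        raise AggregateSchemaError("missing required column 'study'")
    for field_ in ("n", "mean_base", "sd_base", "mean_final", "sd_final"):
        for suffix in ("treated", "control"):
            if f"{field_}_{suffix}" not in df.columns:
                raise AggregateSchemaError(f"missing required column '{field_}_{suffix}'")
    studies = []
    for _, row in df.iterrows():
        study = row["study"]
        arms = {}
        for suffix, label in (("treated", TREATED), ("control", CONTROL)):
            row_like = {
                f: row.get(f"{f}_{suffix}") for f in _WIDE_ARM_FIELDS if f"{f}_{suffix}" in df.columns
            }
            arms[label] = _build_arm(study, label, row_like)
        se_diff = row.get("se_diff_change")
        if se_diff is not None and pd.isna(se_diff):
            se_diff = None
        t, c = _complete_pair(study, arms[TREATED], arms[CONTROL], se_diff)
        studies.append((str(study), t, c))
    return MetaAggregate(tuple(studies), outcome_label, outcome_units)


def write_aggregate(data: MetaAggregate, target: str | IO[str], *, sep: str = ",") -> None:
    """Write a MetaAggregate in the canonical long layout (one row per arm)."""
    df = data.to_frame()
    df.to_csv(target, sep=sep, index=False, float_format="%.17g")


def apply_baseline_shift(data: MetaAggregate, shifts: Mapping[str, float]) -> MetaAggregate:
    """Shift the treated arm's baseline and follow-up means of selected studies.

    ``shifts`` maps study_id to a signed amount, in outcome units, added to the
    treated arm's ``mean_baseline`` and ``mean_final``.  SDs, sample sizes,
    correlations and control arms are unchanged, so per-arm mean changes and
    all change-score summaries are preserved exactly.
    """
    unknown = set(shifts) - set(data.study_ids)
    if unknown:
        raise KeyError(f"shift specified for unknown study ids: {sorted(unknown)}")
    studies = []
    for sid, t, c in data.studies:
        delta = float(shifts.get(sid, 0.0))
        if delta != 0.0:
            t = replace(t, mean_baseline=t.mean_baseline + delta, mean_final=t.mean_final + delta)
        studies.append((sid, t, c))
    return MetaAggregate(tuple(studies), data.outcome_label, data.outcome_units)
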