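"""Packaged example datasets.

The hypertension meta-analysis: per-arm aggregate systolic blood pressure
(SBP, mmHg) at baseline and follow-up for 10 randomised trials of
antihypertensive treatment versus placebo/no treatment (28,851 patients in
total), together with the within-arm baseline/follow-up correlations.

An "imbalanced" variant lowers the treated-arm baseline and follow-up means
of five trials by fixed amounts, mimicking substantial chance baseline
imbalance while leaving every SD, sample size, correlation and per-arm mean
change untouched.
"""

from __future__ import annotations

from importlib import resources

from .aggregate import MetaAggregate, apply_baseline_shift, read_aggregate

__all__ = ["load_hypertension", "HYPERTENSION_SHIFTS"]

#: treated-arm mean shift (mmHg) applied to construct the imbalanced variant
HYPERTENSION_SHIFTS = {
    "ATMH": -5.0,
    "HEP": -5.0,
    "HDFP": -20.0,
    "MRC-1": -20.0,
    "MRC-2": -10.0,
}


def load_hypertension(imbalanced: bool = False) -> MetaAggregate:
    """Load the 10-trial hypertension SBP aggregate dataset.

    Parameters
    ----------
    imbalanced : bool
        If True, apply the treated-arm baseline shifts that construct the
        artificially imbalanced variant.
    """
    ref = resources.files("pseudoipd.data").joinpath("hypertension_sbp.csv")
    with ref.open("r") as fh:
        data = read_aggregate(fh, outcome_label="SBP", outcome_units="mmHg")
    data = data.completed()
    if imbalanced:
        data = apply_baseline_shift(data, HYPERTENSION_SHIFTS)
    return data
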