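"""Cohort z-scores against a copy-number-neutral reference.

For each gene (or isoform) X and tumor Y,

    z(X, Y) = (value(X, Y) - mean_neutral(X)) / sd_neutral(X)

where the mean and standard deviation (sample sd, n-1 denominator) are taken
only over the samples whose copy-number segment mean for that gene lies
within +/-0.2 — the copy-number-neutral reference set.  Standardising
against copy-number-neutral tumors rather than normal tissue avoids bias
from infiltrating cell types in the normal samples.

Samples are then stratified per gene into UP (z > threshold), DOWN
(z < -threshold) and unchanged groups; the default threshold 1.65
corresponds to a one-sided upper-tail probability of ~0.0495 under the
standard normal.  The comparison at the threshold is strict, so z exactly at
the cutoff is 'unchanged'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NEUTRAL_CUTOFF = 0.2
Z_THRESHOLD = 1.65

__all__ = [
    "ExpressionCohort",
    "neutral_mask_from_segment_means",
    "cohort_zscore",
    "stratify_by_z",
    "z_tail_probability",
    "NEUTRAL_CUTOFF",
    "Z_THRESHOLD",
]


@dataclass
class ExpressionCohort:
    """An expression matrix (features x samples) with its neutral mask.

    ``neutral_mask`` flags, per (feature, sample), membership in that
    feature's copy-number-neutral reference (|segment mean| < 0.2).
    """

    matrix: pd.DataFrame
    neutral_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.neutral_mask.index) or not (
            self.matrix.columns.equals(self.neutral_mask.columns)
        ):
            raise ValueError("matrix and neutral_mask must share index and columns")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def neutral_mask_from_segment_means(
    segment_means: pd.DataFrame, cutoff: float = NEUTRAL_CUTOFF
) -> pd.DataFrame:
    """Neutral iff |copy-number segment mean| < cutoff (default 0.2)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return segment_means.abs() < cutoff


def cohort_zscore(cohort: ExpressionCohort) -> pd.DataFrame:
    """Standardise each feature against its copy-number-neutral samples.

    A feature with fewer than 2 neutral samples, or zero variance among
    them, gets an all-NA row (with a warning); sd uses the n-1 denominator.
    """
    values = cohort.matrix.to_numpy(dtype=float)
    mask = cohort.neutral_mask.to_numpy(dtype=bool)
    z = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        neutral = values[i, mask[i]]
        if neutral.size < 2:
            warnings.warn(
                f"feature {cohort.matrix.index[i]}: "
                f"{neutral.size} neutral sample(s); z set to NA"
            )
            continue
        mean = neutral.mean()
        sd = neutral.std(ddof=1)
        # constant-to-machine-precision references count as zero variance
        if sd <= 1e-12 * max(1.0, abs(mean)):
            warnings.warn(
                f"feature {cohort.matrix.index[i]}: zero variance among "
                "neutral samples; z set to NA"
            )
            continue
        z[i] = (values[i] - mean) / sd
    return pd.DataFrame(z, index=cohort.matrix.index, columns=cohort.matrix.columns)


def stratify_by_z(z: pd.DataFrame, threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Label each (feature, sample) UP / DOWN / unchanged.

    UP iff z > threshold, DOWN iff z < -threshold (strict inequalities: z
    exactly at the threshold is unchanged); NA z values are 'unchanged'.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    arr = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    labels = np.where(arr > threshold, "UP", np.where(arr < -threshold, "DOWN", "unchanged"))
    if isinstance(z, pd.DataFrame):
        return pd.DataFrame(labels, index=z.index, columns=z.columns)
    return labels


def z_tail_probability(threshold: float) -> float:
    """One-sided upper-tail probability 1 - Phi(threshold) of the standard
    normal; ~0.0495 at the default stratification threshold 1.65."""
    return float(stats.norm.sf(threshold))
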