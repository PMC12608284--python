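"""Differential-entropy features and demographic group comparisons.

Differential entropy (DE) is computed under the Gaussian assumption standard
in the EEG literature: for a signal with sample variance s^2,

    DE = 1/2 * ln(2 * pi * e * s^2)   (nats).

The continuous definition carries a minus sign (h = -∫ f ln f); volt-scale
EEG therefore yields negative DE values (around -10 nats for sigma ~ 1e-5 V).
The scale identity DE(aX) = DE(X) + ln|a| holds exactly for the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet

__all__ = [
    "differential_entropy",
    "de_table",
    "subject_means",
    "GroupComparison",
    "compare_groups",
    "CATEGORY_SPLITS",
    "split_mask",
]

#: Category rules used for demographic group analyses: (column, threshold)
#: with group 1 = value < threshold, group 2 = value >= threshold; sex splits
#: on the binary code directly.
CATEGORY_SPLITS = {
    "age": ("age", 30),
    "sex": ("sex", 1),
    "education": ("education_years", 16),
}


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian-assumption differential entropy of one signal, in nats."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    var = x.var(ddof=1)
    if var == 0:
        raise ValueError("constant signal has undefined differential entropy")
    return 0.5 * float(np.log(2.0 * np.pi * np.e * var))


def de_table(epochs: EpochSet, band: str = "broadband") -> pd.DataFrame:
    """Per-epoch, per-channel DE table (tidy long format)."""
    var = epochs.data.var(axis=-1, ddof=1)
    if (var == 0).any():
        raise ValueError("constant channel encountered; reject or drop first")
    de = 0.5 * np.log(2.0 * np.pi * np.e * var)  # (n_epochs, n_channels)
    n_epochs, n_channels = de.shape
    return pd.DataFrame(
        {
            "subject_id": np.repeat(epochs.subject_ids, n_channels),
            "epoch": np.repeat(np.arange(n_epochs), n_channels),
            "channel": np.tile(np.asarray(epochs.channel_names), n_epochs),
            "band": band,
            "de_nats": de.ravel(),
            "label": np.repeat(
                np.where(epochs.labels == 1, "MDD", "HC"), n_channels
            ),
            "age": np.repeat(epochs.demographics["age"].to_numpy(), n_channels),
            "sex": np.repeat(epochs.demographics["sex"].to_numpy(), n_channels),
            "education_years": np.repeat(
                epochs.demographics["education_years"].to_numpy(), n_channels
            ),
        }
    )


def subject_means(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a DE table to one mean DE value per subject."""
    keep = ["label", "age", "sex", "education_years"]
    return (
        table.groupby("subject_id")
        .agg({"de_nats": "mean", **{k: "first" for k in keep}})
        .reset_index()
    )


def split_mask(table: pd.DataFrame, category: str) -> np.ndarray:
    """Boolean mask for group 1 of a demographic category split."""
    if category not in CATEGORY_SPLITS:
        raise ValueError(f"unknown category {category!r}; choose from {sorted(CATEGORY_SPLITS)}")
    column, threshold = CATEGORY_SPLITS[category]
    return table[column].to_numpy() < threshold


@dataclass
class GroupComparison:
    category: str
    group1_n: int
    group2_n: int
    group1_mean: float
    group2_mean: float
    group1_var: float
    group2_var: float
    t_statistic: float
    p_value: float
    paired: bool


def compare_groups(values: np.ndarray, group1_mask: np.ndarray,
                   category: str = "custom",
                   paired: bool = False) -> GroupComparison:
    """Two-sample (or paired) t-test between the two groups of a split.

    ``values`` is a per-observation DE vector (e.g. per-subject means);
    ``group1_mask`` selects the first group, its complement the second.
    Paired mode requires equal group sizes ordered by pairing key.
    """
    values = np.asarray(values, dtype=np.float64)
    group1_mask = np.asarray(group1_mask, dtype=bool)
    g1 = values[group1_mask]
    g2 = values[~group1_mask]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"both groups need >= 2 members (got {len(g1)} and {len(g2)})"
        )
    if paired:
        if len(g1) != len(g2):
            raise ValueError("paired comparison requires equal group sizes")
        t, p = stats.ttest_rel(g1, g2)
    else:
        t, p = stats.ttest_ind(g1, g2)
    return GroupComparison(
        category=category,
        group1_n=len(g1), group2_n=len(g2),
        group1_mean=float(g1.mean()), group2_mean=float(g2.mean()),
        group1_var=float(g1.var(ddof=1)), group2_var=float(g2.var(ddof=1)),
        t_statistic=float(t), p_value=float(p), paired=paired,
    )
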