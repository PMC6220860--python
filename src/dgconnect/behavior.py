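"""Behavioural statistics for the novel-object-recognition arm.

Covers the novelty preference index, the t-tests used on it, single-outlier
screening (Grubbs) and the a-posteriori power analysis for the two-sample
comparison of group NPI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError

__all__ = [
    "npi",
    "npi_from_records",
    "grubbs_outlier",
    "PowerSpec",
    "ttest_power",
    "paired_t",
    "unpaired_t",
    "one_sample_t",
]


def npi(time_A: float, time_B: float) -> float:
    """Novelty preference index (B - A) / (B + A).

    ``time_B`` is seconds exploring the novel object, ``time_A`` the familiar
    one.  Ranges over [-1, 1]: -1 = familiar only, 0 = no discrimination,
    1 = novel only.  A zero total (full immobility — the a-priori exclusion
    criterion) leaves the index undefined.
    """
    total = time_A + time_B
    if total <= 0:
        raise DegenerateDataError(
            "zero total exploration time: NPI undefined (full-immobility exclusion)"
        )
    return (time_B - time_A) / total


def npi_from_records(records: pd.DataFrame, phase: str = "test") -> pd.Series:
    """Per-animal NPI for one phase of an exploration-record table."""
    sub = records[records["phase"] == phase]
    return pd.Series(
        [npi(a, b) for a, b in zip(sub["time_A"], sub["time_B"])],
        index=sub["animal_id"].to_numpy(),
        name="npi",
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value for a sample of size n."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_outlier(values, alpha: float = 0.05):
    """Single-outlier Grubbs test (two-sided).

    Computes G = max_i |x_i - mean| / sd and compares with the critical value
    at ``alpha``.  Returns the index of the flagged observation or ``None``.
    Applied at most once by convention: remove the flagged point and re-test
    explicitly if a second pass is wanted.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ConfigurationError("Grubbs test needs at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return None  # constant sample: G undefined, nothing to flag
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / sd
    return i if g > grubbs_critical(x.size, alpha) else None


@dataclass
class PowerSpec:
    """Inputs for the two-sample t-test power computation (NPI units)."""

    mean_1: float
    mean_2: float
    pooled_sd: float
    n_1: int
    n_2: int
    alpha: float = 0.05

    def __post_init__(self):
        if self.pooled_sd <= 0:
            raise ConfigurationError("pooled_sd must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_1 < 2 or self.n_2 < 2:
            raise ConfigurationError("need n >= 2 per group")


def ttest_power(spec: PowerSpec | None = None, **kwargs) -> float:
    """Power of the two-sided two-sample pooled-variance t-test.

    Exact noncentral-t formulation: with noncentrality
    ncp = |mean_1 - mean_2| / pooled_sd * sqrt(n_1 n_2 / (n_1 + n_2)) and
    df = n_1 + n_2 - 2, power = P(|T'_ncp| > t_crit) where t_crit is the
    two-sided critical value at ``alpha``.  Returns a probability in (0, 1).
    """
    if spec is None:
        spec = PowerSpec(**kwargs)
    df = spec.n_1 + spec.n_2 - 2
    ncp = (
        abs(spec.mean_1 - spec.mean_2)
        / spec.pooled_sd
        * np.sqrt(spec.n_1 * spec.n_2 / (spec.n_1 + spec.n_2))
    )
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def _check_variance(*samples):
    if all(np.std(s, ddof=1) == 0 for s in samples):
        raise DegenerateDataError("degenerate (zero-variance) sample(s); t-test undefined")


def paired_t(values_1, values_2):
    """Two-tailed paired Student's t-test; returns (t, p)."""
    a = np.asarray(values_1, dtype=float)
    b = np.asarray(values_2, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("paired samples must have equal length")
    _check_variance(a - b)
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(group_1, group_2, equal_var: bool = True):
    """Two-tailed unpaired Student's t-test (pooled variance); returns (t, p)."""
    a = np.asarray(group_1, dtype=float)
    b = np.asarray(group_2, dtype=float)
    _check_variance(a, b)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def one_sample_t(values, mu: float = 0.0):
    """Two-tailed one-sample t-test of the mean against ``mu``; returns (t, p).

    Supports the NPI-against-zero (no-discrimination) comparison.
    """
    x = np.asarray(values, dtype=float)
    _check_variance(x)
    res = stats.ttest_1samp(x, mu)
    return float(res.statistic), float(res.pvalue)
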