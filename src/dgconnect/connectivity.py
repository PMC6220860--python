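"""Seed-based functional connectivity with jackknife uncertainty.

For each seed region and each group separately, the seed's uptake ratio is
regressed on all other regions by PLS1 and each target's contribution is
summarised by its VIP value.  Uncertainty comes from the delete-one-animal
jackknife:

    SD_jack = sqrt( (n-1)/n * sum_i (theta_(i) - mean(theta_(.)))^2 )

with theta_(i) the VIP vector refitted without animal i, and the 95% CI is
theta_full +/- t_{0.975, n-1} * SD_jack (t multiplier rather than 1.96 —
conservative at n = 10).

A target is called functionally connected to the seed when the CI clears the
conventional VIP threshold 0.8; the default criterion requires the CI *lower
bound* to exceed the threshold (the conservative reading of "the 95% CI
exceeds 0.8"), with a point-estimate mode available for sensitivity analysis.

Between groups, each edge's VIP difference is tested with a Welch-type
statistic built from the jackknife SEs, Bonferroni-corrected over the seed's
target family, and classified:

    increased / decreased — significant and connected in both groups;
    gained / lost         — significant and connected in the treated /
                            control group only;
    unchanged             — otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._base import BaseEstimator, check_fitted
from .exceptions import ConfigurationError, DegenerateDataError, MissingDataError
from .pls import _pls1_core, _standardize, vip_from_fit

__all__ = [
    "SeedConnectivity",
    "jackknife",
    "jackknife_vip",
    "call_connection",
    "compare_groups",
    "build_connectivity_report",
    "LABELS",
]

logger = logging.getLogger(__name__)

LABELS = ("unchanged", "increased", "decreased", "gained", "lost")

#: default seed regions (those with overt metabolic change in the emulated design)
DEFAULT_SEEDS = ("DSub", "MD", "Hab", "GP")

#: swap map under exchange of the two group labels
_LABEL_SWAP = {
    "gained": "lost",
    "lost": "gained",
    "increased": "decreased",
    "decreased": "increased",
    "unchanged": "unchanged",
}


def _vip_stat(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """Standardise and fit PLS1, returning the VIP vector.

    Lean internal path used inside jackknife loops.  Columns that are
    constant in the (sub)sample contribute weight zero.
    """
    Xs, _, _, _ = _standardize(X)
    y_sd = y.std(ddof=1)
    if y_sd <= 0:
        raise DegenerateDataError("seed region has zero variance in this (sub)sample")
    ys = (y - y.mean()) / y_sd
    a_max = min(n_components, X.shape[0] - 1, X.shape[1])
    W, _, _, _, ss = _pls1_core(Xs, ys, a_max)
    return vip_from_fit(W, ss)


def jackknife(rows: np.ndarray, stat: Callable[[np.ndarray], np.ndarray]):
    """Delete-one jackknife of an arbitrary row-wise statistic.

    Returns ``(theta_full, sd_jack, loo)`` where ``loo`` stacks the n
    leave-one-out replicates.  The statistic may be scalar- or vector-valued.
    """
    rows = np.asarray(rows)
    n = rows.shape[0]
    if n < 3:
        raise ConfigurationError("jackknife needs at least 3 observations")
    theta = np.atleast_1d(np.asarray(stat(rows), dtype=float))
    idx = np.arange(n)
    loo = np.empty((n,) + theta.shape)
    for i in range(n):
        loo[i] = stat(rows[idx != i])
    sd = np.sqrt((n - 1) / n * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))
    return theta, sd, loo


def jackknife_vip(
    table: pd.DataFrame,
    seed: str,
    group: str,
    n_components: int = 2,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Full-sample VIP plus jackknife SD and CI for one seed in one group.

    Returns a frame indexed by target region with columns
    ``vip``, ``sd_jack``, ``ci_low``, ``ci_high``.
    """
    regions = [c for c in table.columns if c not in ("animal_id", "group")]
    if seed not in regions:
        raise ConfigurationError(f"unknown seed region {seed!r}")
    sub = table.loc[table["group"] == group, regions]
    if sub.shape[0] < 3:
        raise ConfigurationError(f"group {group!r} has fewer than 3 animals")
    if sub.isna().any().any():
        bad = [c for c in regions if sub[c].isna().any()]
        raise MissingDataError(f"missing uptake values in group {group!r}, regions {bad}")
    targets = [r for r in regions if r != seed]
    data = sub[targets + [seed]].to_numpy(dtype=float)
    n = data.shape[0]

    theta, sd, _ = jackknife(data, lambda d: _vip_stat(d[:, :-1], d[:, -1], n_components))
    tmult = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    return pd.DataFrame(
        {
            "vip": theta,
            "sd_jack": sd,
            "ci_low": theta - tmult * sd,
            "ci_high": theta + tmult * sd,
        },
        index=pd.Index(targets, name="target"),
    )


def call_connection(
    ci_low: float,
    vip: float = np.nan,
    threshold: float = 0.8,
    criterion: str = "ci_lower",
) -> bool:
    """Connectivity call for one edge.

    ``ci_lower`` (default): connected iff the CI lower bound exceeds the
    threshold.  ``point``: connected iff the VIP point estimate exceeds it.
    """
    if criterion == "ci_lower":
        return bool(ci_low > threshold)
    if criterion == "point":
        return bool(vip > threshold)
    raise ConfigurationError(f"unknown connection criterion {criterion!r}")


@dataclass
class EdgeComparison:
    seed: str
    target: str
    t_statistic: float
    df: float
    p_raw: float
    p_bonferroni: float
    label: str


def _welch_from_jackknife(vip_c, sd_c, n_c, vip_t, sd_t, n_t):
    """Welch statistic and Satterthwaite df from jackknife SEs (vectorised)."""
    v_c, v_t = np.square(sd_c), np.square(sd_t)
    pooled = v_c + v_t
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (vip_t - vip_c) / np.sqrt(pooled)
        df = pooled**2 / (v_c**2 / (n_c - 1) + v_t**2 / (n_t - 1))
    t = np.where(pooled > 0, t, 0.0)
    df = np.where(pooled > 0, df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def _classify(significant, conn_c, conn_t, vip_c, vip_t):
    """Vectorised label assignment from the gained/lost/increased/decreased rules."""
    labels = np.full(np.shape(significant), "unchanged", dtype=object)
    both = significant & conn_c & conn_t
    labels[both & (vip_t > vip_c)] = "increased"
    labels[both & (vip_t < vip_c)] = "decreased"
    labels[significant & conn_t & ~conn_c] = "gained"
    labels[significant & conn_c & ~conn_t] = "lost"
    return labels


def compare_groups(
    est_control: pd.Series | dict,
    est_treated: pd.Series | dict,
    family_size: int,
    n_control: int,
    n_treated: int,
    alpha: float = 0.05,
    threshold: float = 0.8,
    criterion: str = "ci_lower",
) -> EdgeComparison:
    """Between-group comparison of one edge's VIP estimates.

    Each estimate must provide ``vip``, ``sd_jack``, ``ci_low`` (and ``seed``/
    ``target`` if available).  Raises :class:`DegenerateDataError` when both
    jackknife SDs are zero.
    """
    c, t = dict(est_control), dict(est_treated)
    if c.get("seed", t.get("seed")) != t.get("seed", c.get("seed")) or c.get(
        "target", t.get("target")
    ) != t.get("target", c.get("target")):
        raise ConfigurationError("estimates do not refer to the same (seed, target) edge")
    if c["sd_jack"] == 0 and t["sd_jack"] == 0:
        raise DegenerateDataError("both jackknife SDs are zero; comparison undefined")

    tstat, df, p_raw = _welch_from_jackknife(
        c["vip"], c["sd_jack"], n_control, t["vip"], t["sd_jack"], n_treated
    )
    p_bonf = min(1.0, float(p_raw) * family_size)
    conn_c = call_connection(c["ci_low"], c["vip"], threshold, criterion)
    conn_t = call_connection(t["ci_low"], t["vip"], threshold, criterion)
    label = _classify(
        np.array(p_bonf < alpha), np.array(conn_c), np.array(conn_t),
        np.array(c["vip"]), np.array(t["vip"]),
    ).item()
    return EdgeComparison(
        seed=str(c.get("seed", "")),
        target=str(c.get("target", "")),
        t_statistic=float(tstat),
        df=float(df),
        p_raw=float(p_raw),
        p_bonferroni=p_bonf,
        label=label,
    )


class SeedConnectivity(BaseEstimator):
    """Seed-based group connectivity analysis of an uptake-ratio table.

    Parameters
    ----------
    seeds : sequence of str
        Seed region names (each regressed on all remaining regions).
    n_components : int, default 2
        PLS components per fit; the protocol this emulates does not fix the
        value, so it is configurable and echoed in all outputs.
    vip_threshold : float, default 0.8
    ci_level : float, default 0.95
    alpha : float, default 0.05
        Significance level for the Bonferroni-corrected group comparison.
    family : {"per_seed", "global"}, default "per_seed"
        Bonferroni family: the seed's own targets (p-1 tests) or all
        seeds x targets jointly.
    criterion : {"ci_lower", "point"}, default "ci_lower"
        Connectivity-call rule, see :func:`call_connection`.
    control_label : str or None
        Group treated as control/reference.  ``None`` uses the first label in
        table row order.

    Attributes (after fit)
    ----------------------
    edges_ : DataFrame — per (seed, target, group): vip, sd_jack, ci_low,
        ci_high, connected.
    comparisons_ : DataFrame — per (seed, target): t, df, p_raw, p_bonferroni,
        label.
    labels_ : DataFrame — seeds x regions label matrix in input region order
        (a seed's own cell is the empty string).
    groups_ : (control_label, treated_label).
    """

    def __init__(
        self,
        seeds: Sequence[str] = DEFAULT_SEEDS,
        n_components: int = 2,
        vip_threshold: float = 0.8,
        ci_level: float = 0.95,
        alpha: float = 0.05,
        family: str = "per_seed",
        criterion: str = "ci_lower",
        control_label: str | None = None,
    ):
        self.seeds = seeds
        self.n_components = n_components
        self.vip_threshold = vip_threshold
        self.ci_level = ci_level
        self.alpha = alpha
        self.family = family
        self.criterion = criterion
        self.control_label = control_label

    def _validate(self, table: pd.DataFrame):
        if not (0 < self.ci_level < 1):
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.vip_threshold <= 0:
            raise ConfigurationError("vip_threshold must be > 0")
        if self.family not in ("per_seed", "global"):
            raise ConfigurationError("family must be 'per_seed' or 'global'")
        for col in ("animal_id", "group"):
            if col not in table.columns:
                raise ConfigurationError(f"uptake table must have an {col!r} column")
        regions = [c for c in table.columns if c not in ("animal_id", "group")]
        unknown = [s for s in self.seeds if s not in regions]
        if unknown:
            raise ConfigurationError(f"unknown seed region(s): {unknown}")
        levels = list(dict.fromkeys(table["group"]))
        if len(levels) != 2:
            raise ConfigurationError(f"expected exactly two group levels, found {levels}")
        control = self.control_label if self.control_label is not None else levels[0]
        if control not in levels:
            raise ConfigurationError(f"control_label {control!r} not among groups {levels}")
        treated = next(g for g in levels if g != control)
        return regions, control, treated

    def fit(self, table: pd.DataFrame, y=None):
        regions, control, treated = self._validate(table)
        n_by_group = table["group"].value_counts().to_dict()
        n_targets = len(regions) - 1
        family_size = (
            n_targets if self.family == "per_seed" else n_targets * len(self.seeds)
        )

        edge_frames, comp_frames = [], []
        label_matrix = pd.DataFrame("", index=list(self.seeds), columns=regions, dtype=object)
        for seed in self.seeds:
            logger.info(
                "seed %s: n_components=%d, criterion=%s, threshold=%.3g, "
                "Bonferroni family=%d (%s)",
                seed, self.n_components, self.criterion, self.vip_threshold,
                family_size, self.family,
            )
            per_group = {}
            for grp in (control, treated):
                est = jackknife_vip(table, seed, grp, self.n_components, self.ci_level)
                est["connected"] = [
                    call_connection(lo, v, self.vip_threshold, self.criterion)
                    for lo, v in zip(est["ci_low"], est["vip"])
                ]
                per_group[grp] = est
                out = est.reset_index()
                out.insert(0, "group", grp)
                out.insert(0, "seed", seed)
                edge_frames.append(out)

            ec, et = per_group[control], per_group[treated]
            tstat, df, p_raw = _welch_from_jackknife(
                ec["vip"].to_numpy(), ec["sd_jack"].to_numpy(), n_by_group[control],
                et["vip"].to_numpy(), et["sd_jack"].to_numpy(), n_by_group[treated],
            )
            p_bonf = np.minimum(1.0, p_raw * family_size)
            labels = _classify(
                p_bonf < self.alpha,
                ec["connected"].to_numpy(bool),
                et["connected"].to_numpy(bool),
                ec["vip"].to_numpy(),
                et["vip"].to_numpy(),
            )
            comp = pd.DataFrame(
                {
                    "seed": seed,
                    "target": ec.index,
                    "t": tstat,
                    "df": df,
                    "p_raw": p_raw,
                    "p_bonferroni": p_bonf,
                    "label": labels,
                }
            )
            comp_frames.append(comp)
            label_matrix.loc[seed, comp["target"]] = labels

        self.edges_ = pd.concat(edge_frames, ignore_index=True)
        self.comparisons_ = pd.concat(comp_frames, ignore_index=True)
        self.labels_ = label_matrix
        self.groups_ = (control, treated)
        self.family_size_ = family_size
        self.region_order_ = regions
        return self

    def fit_report(self, table: pd.DataFrame) -> dict:
        """Fit and return the report pieces as a dict of DataFrames."""
        self.fit(table)
        return {"edges": self.edges_, "comparisons": self.comparisons_, "labels": self.labels_}


def build_connectivity_report(table: pd.DataFrame, seeds: Sequence[str], **params) -> dict:
    """One-call report: per-seed edge tables, comparisons and label matrix."""
    return SeedConnectivity(seeds=seeds, **params).fit_report(table)


def swap_label(label: str) -> str:
    """Label under exchange of the two groups (gained<->lost, increased<->decreased)."""
    return _LABEL_SWAP[label]
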