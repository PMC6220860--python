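"""Uptake-ratio quantification from section-level autoradiography measurements.

Regional glucose-uptake activity is measured on film sections, either
directly as tissue-equivalent activity (nCi/g) or as optical densities to be
converted through co-exposed calibrated standards.  A region's local cerebral
glucose utilisation is expressed as the dimensionless uptake ratio

    UR = region concentration / whole-brain concentration

for the same animal, removing global dose and film-exposure effects.  The
whole-brain denominator is the mean over all measurements in the sections in
which the region of interest appears (per-RoI denominator, the default); a
per-animal global mean is available behind a switch since the conventional
phrasing is ambiguous between the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .exceptions import (
    CalibrationError,
    CalibrationRangeError,
    ConfigurationError,
    DegenerateDataError,
    MissingDataError,
    QuantificationError,
)

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "whole_brain_average",
    "uptake_ratio",
    "uptake_table_from_sections",
    "region_group_ttest",
    "all_region_ttests",
    "RegionComparison",
]

SECTION_COLUMNS = ("animal_id", "group", "region", "section_index", "value", "value_kind")


class CalibrationCurve:
    """Monotone optical-density -> activity mapping fitted to co-exposed standards.

    ``method='pchip'`` (default) interpolates the standards with a monotone
    piecewise cubic, guaranteeing an invertible curve that passes exactly
    through every calibration point.  ``method='poly'`` fits a low-order
    polynomial instead (not exactly interpolating; checked for monotonicity
    over the standards' range).  Queries outside the calibrated OD range
    raise unless ``extrapolate=True``.
    """

    def __init__(self, activities, optical_densities, method: str = "pchip", degree: int = 3):
        act = np.asarray(activities, dtype=float)
        od = np.asarray(optical_densities, dtype=float)
        if act.size < 4:
            raise CalibrationError(f"need at least 4 standards, got {act.size}")
        if (act <= 0).any():
            raise CalibrationError("standard activities must be strictly positive")
        order = np.argsort(act)
        act, od = act[order], od[order]
        d = np.diff(od)
        if (d > 0).all():
            sign = 1.0
        elif (d < 0).all():
            sign = -1.0
        else:
            raise CalibrationError("optical densities are not strictly monotone in activity")
        self.activities = act
        self.optical_densities = od
        self.od_range = (float(od.min()), float(od.max()))
        self.method = method
        x = sign * od  # increasing axis for the interpolator
        self._sign = sign
        if method == "pchip":
            self._f = PchipInterpolator(x, act, extrapolate=True)
        elif method == "poly":
            degree = min(degree, act.size - 1)
            coefs = np.polyfit(x, act, degree)
            f = np.poly1d(coefs)
            grid = np.linspace(x.min(), x.max(), 512)
            if np.any(np.diff(f(grid)) <= 0):
                raise CalibrationError(
                    f"degree-{degree} polynomial fit is not monotone over the standards' range"
                )
            self._f = f
        else:
            raise ConfigurationError(f"unknown calibration method {method!r}")

    def __call__(self, optical_density, extrapolate: bool = False):
        od = np.asarray(optical_density, dtype=float)
        lo, hi = self.od_range
        if not extrapolate and (np.any(od < lo) or np.any(od > hi)):
            raise CalibrationRangeError(
                f"optical density outside calibrated range [{lo:.4g}, {hi:.4g}]; "
                "pass extrapolate=True to override"
            )
        out = self._f(self._sign * od)
        return float(out) if np.isscalar(optical_density) else out


def fit_calibration(standards, method: str = "pchip", degree: int = 3) -> CalibrationCurve:
    """Fit a :class:`CalibrationCurve` from standards.

    ``standards`` is a DataFrame with columns ``activity`` and
    ``optical_density``, or an iterable of (activity, optical_density) pairs.
    """
    if isinstance(standards, pd.DataFrame):
        act, od = standards["activity"], standards["optical_density"]
    else:
        pairs = list(standards)
        act = [p[0] for p in pairs]
        od = [p[1] for p in pairs]
    return CalibrationCurve(act, od, method=method, degree=degree)


def _check_sections(sections: pd.DataFrame):
    missing = [c for c in ("animal_id", "region", "section_index", "value") if c not in sections.columns]
    if missing:
        raise ConfigurationError(f"section table lacks required column(s): {missing}")
    if (sections["value"] < 0).any():
        raise ConfigurationError("section concentrations must be non-negative")


def whole_brain_average(
    sections: pd.DataFrame, animal_id: str, region: str, per_animal: bool = False
) -> float:
    """Whole-brain denominator for one animal and one query region.

    Default (``per_animal=False``): the arithmetic mean of *all* measurements
    (every region) restricted to the sections in which the query region was
    measured.  ``per_animal=True``: the mean over the animal's entire section
    set, one denominator per animal.
    """
    _check_sections(sections)
    mine = sections[sections["animal_id"] == animal_id]
    if mine.empty:
        raise MissingDataError(f"no section data for animal {animal_id!r}")
    if per_animal:
        return float(mine["value"].mean())
    in_region = mine[mine["region"] == region]
    if in_region.empty:
        raise MissingDataError(f"region {region!r} absent for animal {animal_id!r}")
    section_set = set(in_region["section_index"])
    pool = mine[mine["section_index"].isin(section_set)]
    return float(pool["value"].mean())


def uptake_ratio(region_concentration: float, whole_brain: float) -> float:
    """Dimensionless uptake ratio UR = region / whole-brain concentration."""
    if whole_brain <= 0:
        raise QuantificationError("whole-brain concentration must be > 0")
    return float(region_concentration) / float(whole_brain)


def uptake_table_from_sections(
    sections: pd.DataFrame,
    calibration: CalibrationCurve | None = None,
    denominator: str = "per_roi",
) -> pd.DataFrame:
    """Collapse a section-level table into an animal x region uptake-ratio table.

    Optical-density rows (``value_kind == 'optical_density'``) are converted
    through ``calibration`` first.  Region concentration is the mean over the
    region's sections; the denominator follows :func:`whole_brain_average`
    (``denominator`` in {"per_roi", "per_animal"}).
    """
    _check_sections(sections)
    if denominator not in ("per_roi", "per_animal"):
        raise ConfigurationError("denominator must be 'per_roi' or 'per_animal'")
    sections = sections.copy()
    if "value_kind" in sections.columns:
        is_od = sections["value_kind"] == "optical_density"
        if is_od.any():
            if calibration is None:
                raise ConfigurationError(
                    "optical-density rows present but no calibration curve supplied"
                )
            sections.loc[is_od, "value"] = calibration(
                sections.loc[is_od, "value"].to_numpy()
            )
    has_group = "group" in sections.columns
    regions = list(dict.fromkeys(sections["region"]))
    rows = []
    for animal_id, mine in sections.groupby("animal_id", sort=False):
        row = {"animal_id": animal_id}
        if has_group:
            groups = set(mine["group"])
            if len(groups) != 1:
                raise ConfigurationError(f"animal {animal_id!r} has multiple group labels")
            row["group"] = groups.pop()
        for region in regions:
            in_region = mine[mine["region"] == region]
            if in_region.empty:
                row[region] = np.nan
                continue
            conc = float(in_region["value"].mean())
            wb = whole_brain_average(
                sections, animal_id, region, per_animal=(denominator == "per_animal")
            )
            row[region] = uptake_ratio(conc, wb)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegionComparison:
    region: str
    mean_per_group: dict
    t_statistic: float
    df: float
    p_value: float
    significant: bool


def region_group_ttest(
    table: pd.DataFrame, region: str, alpha: float = 0.05, equal_var: bool = True
) -> RegionComparison:
    """Two-sided two-sample t-test of one region's uptake ratio between groups.

    Pooled-variance Student's t by default (``equal_var=False`` for Welch).
    Each region is tested on its own, with no multiplicity correction — the
    convention for overt regional screening.  Missing cells are dropped
    pairwise per region.
    """
    if region not in table.columns:
        raise ConfigurationError(f"unknown region {region!r}")
    levels = list(dict.fromkeys(table["group"]))
    if len(levels) != 2:
        raise ConfigurationError(f"expected exactly two group levels, found {levels}")
    samples = [
        table.loc[table["group"] == g, region].dropna().to_numpy(dtype=float) for g in levels
    ]
    if any(s.size < 2 for s in samples):
        raise ConfigurationError(f"both groups need >= 2 animals with region {region!r}")
    if all(s.std(ddof=1) == 0 for s in samples):
        raise DegenerateDataError(f"zero within-group variance in both groups for {region!r}")
    res = stats.ttest_ind(samples[0], samples[1], equal_var=equal_var)
    df = (
        samples[0].size + samples[1].size - 2
        if equal_var
        else float(res.df)
    )
    p = float(res.pvalue)
    return RegionComparison(
        region=region,
        mean_per_group={g: float(s.mean()) for g, s in zip(levels, samples)},
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=p,
        significant=bool(p < alpha),
    )


def all_region_ttests(table: pd.DataFrame, alpha: float = 0.05, equal_var: bool = True) -> pd.DataFrame:
    """Region-wise group comparison for every region column of the table."""
    regions = [c for c in table.columns if c not in ("animal_id", "group")]
    recs = []
    for region in regions:
        r = region_group_ttest(table, region, alpha=alpha, equal_var=equal_var)
        rec = {"region": r.region, "t": r.t_statistic, "df": r.df, "p": r.p_value,
               "significant": r.significant}
        for g, m in r.mean_per_group.items():
            rec[f"mean_{g}"] = m
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
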