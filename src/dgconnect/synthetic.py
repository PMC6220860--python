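"""Synthetic two-group uptake-ratio studies and behavioural records.

No animal-level data accompany the study design this package implements, so
testing the pipeline end to end requires a generator that emulates it: two
treatment groups, ~10 animals each, 49 brain regions whose uptake ratios
co-vary through shared latent factors, and known, injected between-group
connectivity differences for recovery testing.

The generator is a latent factor model.  For an animal in group ``g`` the
region vector is

    x = 1 + L_g z + eps,      z ~ N(0, I_k),  eps ~ N(0, noise_sd^2 I),

with ``L_g`` the group's regions x factors loading matrix.  Functional
connectivity in the seed-regression sense is exactly shared latent variance,
so this model gives closed-form expected correlations for oracle tests:
corr(x_i, x_j) = (L_i . L_j) / sqrt((|L_i|^2 + s^2)(|L_j|^2 + s^2)).
Columns are recentred to mean exactly 1 afterwards (uptake ratios are
near-unity by construction); adding a per-column constant leaves every
covariance untouched.

Draw ordering is fixed — per animal in row order (group 1 block then group 2
block): first the ``k`` latent draws, then the ``p`` noise draws — so a single
integer seed reproduces a study bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "REGION_NAMES_49",
    "DEFAULT_SEED_REGIONS",
    "SyntheticConfig",
    "GeneratedStudy",
    "BehaviorConfig",
    "default_loadings",
    "generate_uptake",
    "generate_behavior",
]

#: The 49 regions of interest quantified in the study design we emulate,
#: in a fixed anatomical-atlas order.  Used as default column names.
REGION_NAMES_49 = (
    "FRA", "DLO", "LO", "MO", "aPrL", "mPrL", "IL", "Cg1", "Ins", "Piri",
    "S1", "ENT", "PRh", "RSc", "AcbC", "AcbSh", "DLST", "VMST", "GP", "LS",
    "MS", "VDB", "HDB", "BLA", "CeA", "MeA", "AV", "AM", "MD", "VL",
    "VM", "aRT", "MG", "Hab", "MB", "DH_CA1", "DH_CA2", "DH_DG", "DH_Mol", "DSub",
    "VH_CA1", "VH_CA3", "VH_DG", "VH_LMol", "VTA", "SNC", "SNR", "DR", "MR",
)

#: Seed regions showing overt metabolic change in the emulated design.
DEFAULT_SEED_REGIONS = ("DSub", "MD", "Hab", "GP")


def default_loadings(
    n_regions: int, n_latent: int, primary: float = 0.08, secondary: float = 0.03
) -> np.ndarray:
    """Deterministic loading matrix: region r loads ``primary`` on factor
    r mod k and ``secondary`` on factor (r+1) mod k.

    With the default ``primary`` = 0.08 and ``noise_sd`` = 0.05, two regions
    sharing a dominant factor correlate at ~0.7 — the strong-covariance regime
    a seed analysis is meant to detect — while uptake values stay within a few
    percent of 1, matching the scale of real uptake-ratio tables.
    """
    if n_latent < 1 or n_regions < 1:
        raise ConfigurationError("n_regions and n_latent must be positive")
    L = np.zeros((n_regions, n_latent))
    for r in range(n_regions):
        L[r, r % n_latent] += primary
        if n_latent > 1:
            L[r, (r + 1) % n_latent] += secondary
    return L


@dataclass
class SyntheticConfig:
    """Study-design parameters for :func:`generate_uptake`.

    ``edge_effects`` entries are ``(seed, target, group, delta)``: in the named
    group, ``delta`` is added to the target region's loading on the seed's
    dominant factor, creating (or destroying) shared variance for exactly that
    seed-target pair.  Seeds/targets/groups may be given as names or indices.
    """

    n_per_group: int = 10
    n_regions: int = 49
    seed_regions: Sequence = DEFAULT_SEED_REGIONS
    n_latent: int = 3
    loading_matrix_per_group: tuple | None = None
    noise_sd: float = 0.05
    edge_effects: Sequence[tuple] = ()
    rng_seed: int = 0
    group_labels: tuple[str, str] = ("control", "treated")
    region_names: Sequence[str] | None = None

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be >= 3 (jackknife needs >= 3 replicates)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if len(set(self.group_labels)) != 2:
            raise ConfigurationError("exactly two distinct group labels required")
        if self.region_names is None:
            if self.n_regions == len(REGION_NAMES_49):
                self.region_names = REGION_NAMES_49
            else:
                width = len(str(self.n_regions))
                self.region_names = tuple(f"R{i + 1:0{width}d}" for i in range(self.n_regions))
        if len(self.region_names) != self.n_regions:
            raise ConfigurationError("region_names length must equal n_regions")
        self.region_names = tuple(self.region_names)
        self.seed_regions = tuple(self._region_index(s) for s in self.seed_regions)
        if len(set(self.seed_regions)) != len(self.seed_regions):
            raise ConfigurationError("duplicate seed regions")

        if self.loading_matrix_per_group is None:
            L = default_loadings(self.n_regions, self.n_latent)
            self.loading_matrix_per_group = (L, L.copy())
        if len(self.loading_matrix_per_group) != 2:
            raise ConfigurationError("loading_matrix_per_group must hold one matrix per group")
        mats = []
        for L in self.loading_matrix_per_group:
            L = np.asarray(L, dtype=float)
            if L.shape != (self.n_regions, self.n_latent):
                raise ConfigurationError(
                    f"loading matrix shape {L.shape} not conformable with "
                    f"(n_regions={self.n_regions}, n_latent={self.n_latent})"
                )
            mats.append(L)
        self.loading_matrix_per_group = tuple(mats)

        norm_effects = []
        for eff in self.edge_effects:
            seed, target, group, delta = eff
            norm_effects.append(
                (
                    self._region_index(seed),
                    self._region_index(target),
                    self._group_index(group),
                    float(delta),
                )
            )
        self.edge_effects = tuple(norm_effects)
        for seed, target, _, _ in self.edge_effects:
            if seed == target:
                raise ConfigurationError("edge effect cannot link a seed to itself")
            if seed not in self.seed_regions:
                raise ConfigurationError(
                    f"edge effect names seed index {seed}, not in seed_regions"
                )

    def _region_index(self, region) -> int:
        if isinstance(region, str):
            try:
                return self.region_names.index(region)
            except ValueError:
                raise ConfigurationError(f"unknown region name {region!r}") from None
        idx = int(region)
        if not 0 <= idx < self.n_regions:
            raise ConfigurationError(f"region index {idx} out of range [0, {self.n_regions})")
        return idx

    def _group_index(self, group) -> int:
        if isinstance(group, str):
            try:
                return self.group_labels.index(group)
            except ValueError:
                raise ConfigurationError(f"unknown group label {group!r}") from None
        idx = int(group)
        if idx not in (0, 1):
            raise ConfigurationError("group index must be 0 or 1")
        return idx


@dataclass
class GeneratedStudy:
    """A synthetic uptake table plus the edge-level ground truth behind it."""

    uptake: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticConfig = field(repr=False)


def _effective_loadings(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    mats = [L.copy() for L in cfg.loading_matrix_per_group]
    for seed, target, group, delta in cfg.edge_effects:
        factor = int(np.argmax(np.abs(mats[group][seed])))
        mats[group][target, factor] += delta
    return tuple(mats)


def generate_uptake(cfg: SyntheticConfig) -> GeneratedStudy:
    """Draw a two-group uptake-ratio table under the latent factor model.

    Returns a :class:`GeneratedStudy` whose ``uptake`` frame has columns
    ``animal_id``, ``group`` and one column per region (mean exactly 1), and
    whose ``truth`` frame lists every configured (seed, target) pair with a
    ``differs`` flag marking the perturbed ones.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    mats = _effective_loadings(cfg)
    n, p, k = cfg.n_per_group, cfg.n_regions, cfg.n_latent

    rows, animal_ids, groups = [], [], []
    for g, label in enumerate(cfg.group_labels):
        L = mats[g]
        prefix = label[:1].upper()
        for a in range(n):
            z = rng.standard_normal(k)
            eps = rng.standard_normal(p) * cfg.noise_sd
            rows.append(1.0 + L @ z + eps)
            animal_ids.append(f"{prefix}{a + 1:02d}")
            groups.append(label)

    data = np.vstack(rows)
    data += 1.0 - data.mean(axis=0)  # recentre each column to mean 1; covariance unchanged

    uptake = pd.DataFrame(data, columns=list(cfg.region_names))
    uptake.insert(0, "group", groups)
    uptake.insert(0, "animal_id", animal_ids)

    perturbed = {(s, t): (g, d) for s, t, g, d in cfg.edge_effects}
    records = []
    for seed in cfg.seed_regions:
        for target in range(p):
            if target == seed:
                continue
            g, d = perturbed.get((seed, target), (None, 0.0))
            records.append(
                {
                    "seed": cfg.region_names[seed],
                    "target": cfg.region_names[target],
                    "differs": (seed, target) in perturbed,
                    "group_perturbed": cfg.group_labels[g] if g is not None else "",
                    "effect_size": d,
                }
            )
    truth = pd.DataFrame.from_records(records)
    return GeneratedStudy(uptake=uptake, truth=truth, config=cfg)


@dataclass
class BehaviorConfig:
    """Parameters for :func:`generate_behavior`.

    Defaults reproduce the emulated behavioural arm: 19 control and 20
    treated animals, novelty-preference-index (NPI) means 0.201 and 0.050
    with pooled SD 0.15.  Total test-phase exploration time is Normal
    (truncated positive); 40 +/- 10 s is a realistic figure for a 5-minute
    object-recognition test phase in mice.
    """

    n_per_group: tuple[int, int] = (19, 20)
    mean_npi_per_group: tuple[float, float] = (0.201, 0.050)
    npi_sd: float = 0.15
    total_exploration_mean: float = 40.0
    total_exploration_sd: float = 10.0
    rng_seed: int = 0
    group_labels: tuple[str, str] = ("control", "treated")

    def __post_init__(self):
        if any(abs(m) > 1 for m in self.mean_npi_per_group):
            raise ConfigurationError("|mean_npi| must be <= 1")
        if self.npi_sd <= 0:
            raise ConfigurationError("npi_sd must be > 0")
        if self.total_exploration_mean <= 0 or self.total_exploration_sd <= 0:
            raise ConfigurationError("total exploration time parameters must be positive")
        if any(n < 2 for n in self.n_per_group):
            raise ConfigurationError("need at least 2 animals per group")


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_behavior(cfg: BehaviorConfig) -> pd.DataFrame:
    """Exploration-time records realising a target NPI distribution.

    Works the index definition NPI = (B - A)/(B + A) backwards: draw
    NPI ~ Normal(mean, sd) truncated to (-1, 1) and a positive total time T,
    then A = T (1 - NPI)/2, B = T (1 + NPI)/2, so recomputing the index from
    (A, B) returns the drawn value.  Training-phase records (two identical
    objects, expected index 0) are generated the same way with mean 0.

    Returns a frame with columns animal_id, group, phase, time_A, time_B.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    records = []
    for g, label in enumerate(cfg.group_labels):
        n = cfg.n_per_group[g]
        for phase, mean in (("training", 0.0), ("test", cfg.mean_npi_per_group[g])):
            npi_draw = _truncnorm(rng, mean, cfg.npi_sd, -1.0, 1.0, n)
            total = _truncnorm(
                rng, cfg.total_exploration_mean, cfg.total_exploration_sd, 0.0, np.inf, n
            )
            for a in range(n):
                records.append(
                    {
                        "animal_id": f"{label[:1].upper()}{a + 1:02d}",
                        "group": label,
                        "phase": phase,
                        "time_A": total[a] * (1.0 - npi_draw[a]) / 2.0,
                        "time_B": total[a] * (1.0 + npi_draw[a]) / 2.0,
                        # ground truth for recovery checks; downstream loaders ignore it
                        "npi_drawn": npi_draw[a],
                    }
                )
    return pd.DataFrame.from_records(records)
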