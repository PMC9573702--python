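"""Synthetic spot-volume tables with known ground truth.

The generator emulates the structure of a three-cultivar 2-DE comparison:
~345 validated spots quantified on 3 groups x 4 replicate gels, a minority
of spots carrying a true between-group abundance shift, a few spots truly
absent from one group (group-unique spots), per-gel multiplicative
total-intensity variation, log-normal replicate noise, and random dropout
(a truly present spot failing detection on an individual gel).

Volumes follow a mean-preserving log-normal model: the expected volume of
spot *s* on gel *g* is ``baseline[s] * multiplier[s, group(g)] * scale[g]``,
and the replicate noise has unit mean with coefficient of variation
``cv_replicate``.  Gel-level scaling is included specifically so that
total-density normalization has a real nuisance effect to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExperimentDesign, SpotVolumeTable
from .errors import ConfigError, ConsistencyError

LABEL_NULL = "null"
LABEL_DIFFERENTIAL = "differential"
LABEL_UNIQUE = "unique-to-group"


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: 345 spots, 3 cultivars x 4 replicates.

    ``frac_differential`` spots receive a single-group mean shift of
    ``2**e`` with ``e`` drawn uniformly from ``effect_log2_range`` and a
    random sign; ``frac_unique`` spots are truly absent from one group.
    ``cv_replicate`` is the within-group coefficient of variation of
    volumes, ``gel_scale_sd`` the standard deviation of the per-gel
    log-normal intensity factor (on the log scale), ``dropout_prob`` the
    per-cell probability that a truly present spot goes undetected.
    """

    n_spots: int = 345
    groups: tuple[str, ...] = ("Agata", "Kennebec", "Agria")
    replicates: int = 4
    frac_differential: float = 0.22
    effect_log2_range: tuple[float, float] = (0.5, 2.0)
    cv_replicate: float = 0.25
    dropout_prob: float = 0.05
    frac_unique: float = 0.03
    gel_scale_sd: float = 0.2
    baseline_median: float = 1000.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ConfigError("n_spots must be >= 1")
        if len(self.groups) < 2:
            raise ConfigError("need at least two groups")
        if self.replicates < 2:
            raise ConfigError("need at least two replicates per group")
        for name in ("frac_differential", "frac_unique", "dropout_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_differential + self.frac_unique > 1:
            raise ConfigError("frac_differential + frac_unique exceeds 1")
        if self.cv_replicate <= 0:
            raise ConfigError("cv_replicate must be > 0")
        if self.gel_scale_sd < 0 or self.baseline_median <= 0:
            raise ConfigError("invalid scale parameters")
        lo, hi = self.effect_log2_range
        if lo < 0 or hi < lo:
            raise ConfigError("effect_log2_range must satisfy 0 <= lo <= hi")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset.

    ``multipliers`` holds the true group mean factor per (spot, group)
    (0 for the excluded group of a unique spot), ``present`` the true
    presence flags, ``labels`` one of ``null`` / ``differential`` /
    ``unique-to-group`` per spot.
    """

    baseline: pd.Series
    multipliers: pd.DataFrame
    present: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        null = (self.multipliers.eq(1.0).all(axis=1)) & self.present.all(axis=1)
        labelled_null = self.labels.eq(LABEL_NULL)
        if not null.equals(labelled_null):
            raise ConsistencyError("labels inconsistent with multipliers/presence")

    def affected(self, group_x: str, group_y: str) -> pd.Series:
        """True where a spot genuinely differs between the two groups."""
        diff_mult = self.multipliers[group_x] != self.multipliers[group_y]
        diff_pres = self.present[group_x] != self.present[group_y]
        return diff_mult | diff_pres

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth: one row per spot with its affected group."""
        rows = []
        for spot in self.labels.index:
            label = self.labels.at[spot]
            group, mult = "", ""
            if label != LABEL_NULL:
                mults = self.multipliers.loc[spot]
                off = mults[mults != 1.0]
                if not off.empty:
                    group = off.index[0]
                    mult = off.iloc[0]
            rows.append({"spot_id": spot, "label": label,
                         "group": group, "multiplier": mult})
        return pd.DataFrame(rows).set_index("spot_id")


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[SpotVolumeTable, ExperimentDesign, SyntheticTruth]:
    """Draw one synthetic dataset; identical config (incl. seed) -> identical output."""
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_label, rng_gel, rng_noise, rng_drop = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )
    n = config.n_spots
    groups = list(config.groups)
    n_groups = len(groups)
    gel_ids = [f"{g}_{r}" for g in groups for r in range(1, config.replicates + 1)]
    gel_group_idx = np.repeat(np.arange(n_groups), config.replicates)
    spot_ids = [f"S{i + 1:04d}" for i in range(n)]

    baseline = config.baseline_median * rng_base.lognormal(
        mean=0.0, sigma=config.baseline_log_sd, size=n
    )

    n_unique = int(round(config.frac_unique * n))
    n_diff = int(round(config.frac_differential * n))
    perm = rng_label.permutation(n)
    unique_idx = perm[:n_unique]
    diff_idx = perm[n_unique:n_unique + n_diff]

    multipliers = np.ones((n, n_groups))
    present = np.ones((n, n_groups), dtype=bool)
    labels = np.array([LABEL_NULL] * n, dtype=object)

    excluded = rng_label.integers(0, n_groups, size=n_unique)
    for i, g in zip(unique_idx, excluded):
        present[i, g] = False
        multipliers[i, g] = 0.0
        labels[i] = LABEL_UNIQUE

    affected_group = rng_label.integers(0, n_groups, size=n_diff)
    signs = np.where(rng_label.random(n_diff) < 0.5, -1.0, 1.0)
    lo, hi = config.effect_log2_range
    effects = rng_label.uniform(lo, hi, size=n_diff)
    for i, g, s, e in zip(diff_idx, affected_group, signs, effects):
        multipliers[i, g] = 2.0 ** (s * e)
        labels[i] = LABEL_DIFFERENTIAL

    n_gels = len(gel_ids)
    if config.gel_scale_sd > 0:
        gel_scale = rng_gel.lognormal(0.0, config.gel_scale_sd, size=n_gels)
    else:
        gel_scale = np.ones(n_gels)

    # unit-mean log-normal replicate noise with the configured CV
    sigma = math.sqrt(math.log1p(config.cv_replicate ** 2))
    noise = rng_noise.lognormal(-0.5 * sigma ** 2, sigma, size=(n, n_gels))

    vols = (
        baseline[:, None]
        * multipliers[:, gel_group_idx]
        * gel_scale[None, :]
        * noise
    )
    truly_present = present[:, gel_group_idx]
    dropped = rng_drop.random((n, n_gels)) < config.dropout_prob
    missing = ~truly_present | dropped
    vols = np.where(missing, np.nan, vols)

    table = SpotVolumeTable(pd.DataFrame(vols, index=spot_ids, columns=gel_ids))
    design = ExperimentDesign.from_mapping(
        {gid: groups[gi] for gid, gi in zip(gel_ids, gel_group_idx)}
    )
    truth = SyntheticTruth(
        baseline=pd.Series(baseline, index=spot_ids, name="baseline"),
        multipliers=pd.DataFrame(multipliers, index=spot_ids, columns=groups),
        present=pd.DataFrame(present, index=spot_ids, columns=groups),
        labels=pd.Series(labels, index=spot_ids, name="label"),
    )
    return table, design, truth


def truth_confusion(truth: SyntheticTruth, results) -> pd.DataFrame:
    """Confusion counts of significance calls against ground truth.

    Returns one row per group pair with TP/FP/TN/FN; every result is
    counted exactly once.  A result whose spot is unknown to the truth
    raises :class:`ConsistencyError`.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    known = set(truth.labels.index)
    for r in results:
        if r.spot_id not in known:
            raise ConsistencyError(f"result spot {r.spot_id!r} absent from truth")
        key = (r.group_x, r.group_y)
        c = counts.setdefault(key, {"TP": 0, "FP": 0, "TN": 0, "FN": 0})
        affected = bool(truth.affected(r.group_x, r.group_y).at[r.spot_id])
        if r.significant and affected:
            c["TP"] += 1
        elif r.significant:
            c["FP"] += 1
        elif affected:
            c["FN"] += 1
        else:
            c["TN"] += 1
    rows = [
        {"group_x": gx, "group_y": gy, **c} for (gx, gy), c in counts.items()
    ]
    return pd.DataFrame(rows)
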