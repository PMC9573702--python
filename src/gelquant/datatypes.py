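"""Core containers for 2-DE spot-volume analysis.

A 2-DE (two-dimensional gel electrophoresis) experiment quantifies each
protein spot on each gel as a non-negative densitometric *volume*
(integrated, background-subtracted stain intensity).  A spot that was not
detected or not matched on a particular gel has no volume at all — that is
semantically different from a detected spot with zero volume, and the
containers here preserve the distinction: missing entries are NaN, explicit
zeros are kept as zeros.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

#: metadata columns recognised in spot-table files (gel coordinates of a spot)
SPOT_META_COLUMNS = ("pI_obs", "Mr_obs_kDa")


@dataclass
class SpotVolumeTable:
    """Spots x gels matrix of densitometric volumes.

    Parameters
    ----------
    volumes
        DataFrame indexed by spot id with one column per gel id.  NaN means
        the spot was not detected on that gel; 0.0 means detected with zero
        volume.  Units are arbitrary densitometric units.
    spot_meta
        Optional per-spot metadata (observed isoelectric point ``pI_obs`` in
        pH units and molecular mass ``Mr_obs_kDa`` in kDa), indexed like
        ``volumes``.
    """

    volumes: pd.DataFrame
    spot_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vols = self.volumes
        if not isinstance(vols, pd.DataFrame):
            raise ValidationError("volumes must be a pandas DataFrame")
        if vols.index.has_duplicates:
            dups = vols.index[vols.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate spot ids: {dups}")
        if vols.columns.has_duplicates:
            dups = vols.columns[vols.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gel ids: {dups}")
        vols = vols.astype(float)
        neg = vols.lt(0)
        if neg.any().any():
            spot = vols.index[neg.any(axis=1)][0]
            gel = vols.columns[neg.loc[spot]][0]
            raise ValidationError(
                f"negative volume at spot {spot!r}, gel {gel!r}: "
                f"{vols.at[spot, gel]}"
            )
        vols.index.name = "spot_id"
        vols.columns.name = "gel_id"
        self.volumes = vols
        if self.spot_meta is not None:
            meta = self.spot_meta
            if not meta.index.equals(vols.index):
                meta = meta.reindex(vols.index)
            self.spot_meta = meta

    # -- basic views ---------------------------------------------------

    @property
    def spot_ids(self) -> list:
        return self.volumes.index.tolist()

    @property
    def gel_ids(self) -> list:
        return self.volumes.columns.tolist()

    @property
    def n_spots(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_gels(self) -> int:
        return self.volumes.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.volumes.isna().sum().sum())

    def subset_spots(self, spot_ids) -> "SpotVolumeTable":
        """Return the table restricted to ``spot_ids`` (order preserved)."""
        spot_ids = list(spot_ids)
        missing = set(spot_ids) - set(self.volumes.index)
        if missing:
            raise ValidationError(f"unknown spot ids: {sorted(missing)}")
        meta = None if self.spot_meta is None else self.spot_meta.loc[spot_ids]
        return SpotVolumeTable(self.volumes.loc[spot_ids].copy(), meta)

    def equals(self, other: "SpotVolumeTable", tol: float = 1e-9) -> bool:
        """Equality of ids, missingness pattern, and volumes within ``tol``."""
        if self.spot_ids != other.spot_ids or self.gel_ids != other.gel_ids:
            return False
        a, b = self.volumes.to_numpy(), other.volumes.to_numpy()
        if not np.array_equal(np.isnan(a), np.isnan(b)):
            return False
        mask = ~np.isnan(a)
        return bool(np.allclose(a[mask], b[mask], rtol=0, atol=tol))


@dataclass
class ExperimentDesign:
    """Mapping of gels to experimental groups (cultivars) and replicates.

    ``assignment`` is indexed by gel id and carries ``group`` and integer
    ``replicate`` columns.  Groups are ordered by first appearance; pairwise
    comparisons enumerate ordered combinations of that ordering.
    """

    assignment: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.assignment
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"gel assigned more than once: {dups}")
        if "group" not in df.columns:
            raise ValidationError("design needs a 'group' column")
        if "replicate" not in df.columns:
            df = df.copy()
            df["replicate"] = df.groupby("group", sort=False).cumcount() + 1
        df = df[["group", "replicate"]].copy()
        df.index.name = "gel_id"
        df["group"] = df["group"].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        counts = df["group"].value_counts()
        if len(counts) < 2:
            raise ValidationError("a design needs at least two groups")
        small = counts[counts < 2]
        if not small.empty:
            raise ValidationError(
                f"groups with fewer than 2 gels: {small.index.tolist()}"
            )
        self.assignment = df

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ExperimentDesign":
        """Build a design from ``{gel_id: group}`` (replicates in dict order)."""
        df = pd.DataFrame({"group": pd.Series(mapping)})
        return cls(df)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment["group"]:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def gel_ids(self) -> list:
        return self.assignment.index.tolist()

    def gels(self, group: str) -> list:
        mask = self.assignment["group"] == group
        return self.assignment.index[mask].tolist()

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.groups, 2))

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.gels(g)) for g in self.groups}

    @property
    def replicates_per_group(self) -> int:
        sizes = set(self.group_sizes.values())
        if len(sizes) != 1:
            raise ValidationError("design is unbalanced; no single n exists")
        return sizes.pop()

    def check_table(self, table: SpotVolumeTable) -> None:
        """Every gel of ``table`` must be assigned exactly once."""
        unknown = set(table.gel_ids) - set(self.assignment.index)
        if unknown:
            raise ValidationError(
                f"gels missing from the design: {sorted(unknown)}"
            )


@dataclass
class BootstrapSettings:
    """Settings of the bootstrap significance procedure.

    B
        Number of Monte-Carlo resamples per spot and comparison.
    confidence
        Nominal (unadjusted) confidence level of the intervals.
    family
        What the Bonferroni family counts: ``"pairs"`` adjusts per spot over
        the group pairs (m = number of pairs); ``"spots_pairs"`` adjusts over
        every (validated spot, pair) combination jointly.
    bonferroni_m
        Explicit family size; overrides ``family`` when set.
    mode
        ``"group_ci_overlap"`` (default) builds one BC interval per group
        for that group's own mean and flags the spot when the two intervals
        are disjoint; ``"difference_ci"`` flags it when the BC interval of
        the difference of group means excludes 0.  The overlap rule is the
        default because with n = 4 replicates it keeps the familywise false
        positive rate below the nominal level, whereas the percentile-type
        interval of the difference is markedly anti-conservative at such
        small n.
    seed
        Master seed; each (pair, spot) comparison derives its own substream.
    """

    B: int = 2000
    confidence: float = 0.95
    family: str = "pairs"
    bonferroni_m: int | None = None
    mode: str = "group_ci_overlap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")
        if not 0 < self.confidence < 1:
            raise ConfigError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.family not in ("pairs", "spots_pairs"):
            raise ConfigError(f"unknown family {self.family!r}")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ConfigError("bonferroni_m must be >= 1")
        if self.mode not in ("difference_ci", "group_ci_overlap"):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def resolved_family(self, n_spots: int, n_pairs: int) -> int:
        if self.bonferroni_m is not None:
            return self.bonferroni_m
        if self.family == "pairs":
            return n_pairs
        return max(1, n_spots * n_pairs)


@dataclass
class AnalysisConfig:
    """End-to-end analysis settings.

    ``min_present_replicates`` is the reproducibility threshold: a spot
    counts as present in a group only if detected in at least that many of
    the group's biological replicates (default 3 of 4).  ``presence_scope``
    selects whether a spot is retained when it passes that rule in at least
    one group (``"any"``, the default — required so group-unique spots
    survive) or in every group (``"all"``).
    """

    min_present_replicates: int = 3
    presence_scope: str = "any"
    normalization_constant: float | str = "mean-total"
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    round_fc: int = 2
    round_rc: int = 3

    def __post_init__(self) -> None:
        if self.min_present_replicates < 1:
            raise ConfigError("min_present_replicates must be >= 1")
        if self.presence_scope not in ("any", "all"):
            raise ConfigError(f"unknown presence_scope {self.presence_scope!r}")
        if isinstance(self.normalization_constant, str):
            if self.normalization_constant != "mean-total":
                raise ConfigError(
                    "normalization_constant must be a positive number or 'mean-total'"
                )
        elif self.normalization_constant <= 0:
            raise ConfigError("normalization_constant must be positive")
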