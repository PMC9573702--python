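"""Presence calling, reproducibility filtering, total-density normalization.

A spot counts as *present* in a group when it is detected on at least
``min_present_replicates`` of the group's replicate gels (default 3 of 4).
Spots present in at least one group are retained as validated spots
(``presence_scope="any"``); group-unique spots — present in one group,
absent in another — survive this filter by construction and feed the
unshared-spot logic downstream.  An ``"all"`` scope requiring presence in
every group is available.

Total-density normalization rescales each gel so that the summed volume of
the validated spots is the same on every gel, removing gel-to-gel loading
and staining differences.  The common total is either a configured constant
(e.g. 1e6 for ppm-style volumes) or the mean of the raw per-gel totals,
which keeps volumes on their original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, ExperimentDesign, SpotVolumeTable
from .errors import NormalizationError, ValidationError


@dataclass
class PresenceMatrix:
    """Detected-replicate counts and presence flags per (spot, group)."""

    counts: pd.DataFrame
    present: pd.DataFrame
    min_present_replicates: int

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.present.index) or not list(
            self.counts.columns
        ) == list(self.present.columns):
            raise ValidationError("counts and present must be aligned")

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, spot_ids) -> "PresenceMatrix":
        spot_ids = list(spot_ids)
        return PresenceMatrix(
            self.counts.loc[spot_ids],
            self.present.loc[spot_ids],
            self.min_present_replicates,
        )

    def is_present(self, spot_id, group: str) -> bool:
        return bool(self.present.at[spot_id, group])


def call_presence(
    table: SpotVolumeTable,
    design: ExperimentDesign,
    min_present_replicates: int = 3,
) -> PresenceMatrix:
    """Count detections per (spot, group) and flag reproducible presence."""
    design.check_table(table)
    if min_present_replicates < 1:
        raise ValidationError("min_present_replicates must be >= 1")
    counts = pd.DataFrame(index=table.volumes.index)
    for group in design.groups:
        gels = [g for g in design.gels(group) if g in table.volumes.columns]
        counts[group] = table.volumes[gels].notna().sum(axis=1).astype(int)
        if min_present_replicates > len(gels):
            raise ValidationError(
                f"min_present_replicates={min_present_replicates} exceeds the "
                f"{len(gels)} gels of group {group!r}"
            )
    present = counts.ge(min_present_replicates)
    return PresenceMatrix(counts, present, min_present_replicates)


def filter_reproducible(
    table: SpotVolumeTable,
    presence: PresenceMatrix,
    scope: str = "any",
) -> SpotVolumeTable:
    """Retain validated spots (present in >=1 group, or all groups for scope="all")."""
    if scope == "any":
        keep = presence.present.any(axis=1)
    elif scope == "all":
        keep = presence.present.all(axis=1)
    else:
        raise ValidationError(f"unknown presence scope {scope!r}")
    keep = keep.reindex(table.volumes.index, fill_value=False)
    return table.subset_spots(table.volumes.index[keep])


def normalize_total_density(
    table: SpotVolumeTable,
    constant: float | str = "mean-total",
) -> SpotVolumeTable:
    """Rescale every gel to a common total volume over the table's spots.

    Each volume becomes ``raw / gel_total * C`` with ``C`` the configured
    constant or, for ``"mean-total"``, the mean of the raw per-gel totals.
    Missing entries stay missing.  A gel whose total is zero cannot be
    normalized and raises :class:`NormalizationError`.
    """
    totals = table.volumes.sum(axis=0, skipna=True)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise NormalizationError(f"zero validated-spot total on gel(s): {zero}")
    if isinstance(constant, str):
        if constant != "mean-total":
            raise ValidationError(f"unknown normalization constant {constant!r}")
        c = float(totals.mean())
    else:
        c = float(constant)
        if c <= 0:
            raise ValidationError("normalization constant must be positive")
    normalized = table.volumes.div(totals, axis=1) * c
    meta = None if table.spot_meta is None else table.spot_meta.copy()
    return SpotVolumeTable(normalized, meta)


def preprocess(
    table: SpotVolumeTable,
    design: ExperimentDesign,
    config: AnalysisConfig | None = None,
) -> tuple[SpotVolumeTable, PresenceMatrix]:
    """Presence -> filter -> normalize; returns the analysis-ready table.

    The returned :class:`PresenceMatrix` is restricted to the validated
    spots; its flags are computed before normalization and are unaffected
    by it (normalization preserves the missingness pattern).
    """
    config = config or AnalysisConfig()
    presence = call_presence(table, design, config.min_present_replicates)
    filtered = filter_reproducible(table, presence, config.presence_scope)
    presence = presence.subset(filtered.spot_ids)
    normalized = normalize_total_density(filtered, config.normalization_constant)
    return normalized, presence
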