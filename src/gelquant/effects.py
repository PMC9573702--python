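"""Fold-change (FC) and relative-change (RC) effect statistics.

FC is the ratio of group mean volumes ``y/x`` with ratios below one
replaced by their negative reciprocal (so FC = -2 means a two-fold drop);
it diverges to ±inf for unshared spots, where one group is absent.  RC is
the difference of means ``DV = y - x`` scaled by the largest |DV| observed
over *all* significant spot-pair results jointly, so it is bounded in
[-1, +1] for shared and unshared spots alike, and the extreme spot attains
exactly ±1.  The scaling denominator is taken as the maximum magnitude of
DV (its sign is reported separately); a signed-maximum reading could not
produce negative extreme values, which do occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import PairwiseSpotResult
from .errors import UndefinedEffectError, ValidationError

STATUS_SIGNIFICANT = "significant"
STATUS_NS = "ns"
STATUS_NA = "N/A"


@dataclass
class EffectSizes:
    """FC/RC per spot-pair result plus the global RC denominator.

    ``table`` has one row per result with columns ``spot_id, group_x,
    group_y, status, DV, FC, RC``; FC/RC are NaN for non-significant
    (``ns``) and not-applicable (``N/A``) rows.  ``dvr_max`` is the signed
    DV of largest magnitude among significant results (NaN when the
    significant set is empty).
    """

    table: pd.DataFrame
    dvr_max: float

    @property
    def dvr_max_abs(self) -> float:
        return abs(self.dvr_max)

    @property
    def n_significant(self) -> int:
        return int((self.table["status"] == STATUS_SIGNIFICANT).sum())


def fold_change(mean_x: float, mean_y: float) -> float:
    """FC = y/x with the negative-reciprocal convention for ratios < 1.

    ``x = 0`` gives +inf, ``y = 0`` gives -inf (unshared spots); equal
    positive means give +1.  Both means zero is undefined.
    """
    if mean_x < 0 or mean_y < 0:
        raise ValidationError("group means must be non-negative")
    if mean_x == 0 and mean_y == 0:
        raise UndefinedEffectError("fold change undefined when both means are 0")
    if mean_x == 0:
        return math.inf
    if mean_y == 0:
        return -math.inf
    fc = mean_y / mean_x
    return fc if fc >= 1 else -mean_x / mean_y


def relative_change(dv: float, dvr_max_abs: float) -> float:
    """RC = DV / |DVR_max|; bounded in [-1, 1] when the denominator is the max."""
    if not dvr_max_abs > 0:
        raise ValidationError(f"|DVR_max| must be positive, got {dvr_max_abs}")
    return dv / dvr_max_abs


def compute_effects(results: list[PairwiseSpotResult]) -> EffectSizes:
    """FC and RC for every significant result; ns / N/A elsewhere.

    The RC denominator |DVR_max| is the largest |DV| across the significant
    results of all group pairs jointly, so exactly the extreme spot-pair
    reaches |RC| = 1 (up to ties).
    """
    sig = [r for r in results if r.significant]
    dvr_max = math.nan
    if sig:
        extreme = max(sig, key=lambda r: abs(r.dv))
        dvr_max = float(extreme.dv)
        if abs(dvr_max) == 0:
            raise ValidationError("significant results all have DV = 0")
    rows = []
    for r in results:
        if not r.applicable:
            status, fc, rc = STATUS_NA, np.nan, np.nan
        elif not r.significant:
            status, fc, rc = STATUS_NS, np.nan, np.nan
        else:
            status = STATUS_SIGNIFICANT
            fc = fold_change(r.mean_x, r.mean_y)
            rc = relative_change(r.dv, abs(dvr_max))
        rows.append(
            {
                "spot_id": r.spot_id,
                "group_x": r.group_x,
                "group_y": r.group_y,
                "status": status,
                "DV": r.dv if r.applicable else np.nan,
                "FC": fc,
                "RC": rc,
            }
        )
    return EffectSizes(table=pd.DataFrame(rows), dvr_max=dvr_max)


def _format_fc(fc: float, decimals: int) -> str:
    if math.isinf(fc):
        return "+inf" if fc > 0 else "-inf"
    return f"{fc:+.{decimals}f}"


def format_effects(
    effects: EffectSizes, round_fc: int = 2, round_rc: int = 3
) -> pd.DataFrame:
    """Render the effect table as strings with ns / N/A / ±inf sentinels.

    One row per spot, one FC and one RC column per group pair — the layout
    used in published differential-abundance tables.
    """
    out_rows: dict[str, dict[str, str]] = {}
    pair_names: list[str] = []
    for _, row in effects.table.iterrows():
        pair = f"{row['group_x']}-{row['group_y']}"
        if pair not in pair_names:
            pair_names.append(pair)
        cell = out_rows.setdefault(row["spot_id"], {})
        if row["status"] == STATUS_SIGNIFICANT:
            cell[f"FC {pair}"] = _format_fc(row["FC"], round_fc)
            cell[f"RC {pair}"] = f"{row['RC']:+.{round_rc}f}"
        elif row["status"] == STATUS_NA:
            cell[f"FC {pair}"] = STATUS_NA
            cell[f"RC {pair}"] = STATUS_NA
        else:
            cell[f"FC {pair}"] = STATUS_NS
            cell[f"RC {pair}"] = STATUS_NS
    columns = [c for p in pair_names for c in (f"FC {p}", f"RC {p}")]
    frame = pd.DataFrame.from_dict(out_rows, orient="index")
    frame = frame.reindex(columns=columns)
    frame.index.name = "spot_id"
    return frame
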