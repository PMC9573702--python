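"""Summary statistics and report rendering.

Aggregates the stage outputs into the headline numbers of a differential
2-DE analysis — how many spots were validated, how many changed
significantly in at least one pairwise comparison, per-pair counts — plus
the effect table and the PCA variance summary.  JSON is the canonical,
machine-readable output; the Markdown rendering is derived from it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import math

import numpy as np
import pandas as pd

from .bootstrap import PairwiseSpotResult
from .effects import STATUS_SIGNIFICANT, EffectSizes
from .errors import ConsistencyError, ValidationError
from .ordination import PCAResult
from .preprocess import PresenceMatrix


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding, e.g. percent(78, 345) -> 22.6."""
    if denominator == 0:
        raise ValidationError("percentage of an empty set is undefined")
    if decimals < 0:
        raise ValidationError("decimals must be >= 0")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass
class AnalysisReport:
    """Pure summary of the stage outputs (no hidden state, JSON-serializable)."""

    n_validated_spots: int
    n_significant_spots: int
    pct_significant: float
    per_pair_significant: dict[str, int]
    dvr_max: float | None
    effect_table: list[dict] = field(default_factory=list)
    pca_variance_fraction: list[float] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sanitize(value):
    """Replace NaN/inf by JSON-safe strings, recursively."""
    if isinstance(value, dict):
        return {k: _sanitize(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_sanitize(v) for v in value]
    if isinstance(value, (float, np.floating)):
        f = float(value)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "+inf" if f > 0 else "-inf"
        return f
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def summarize(
    presence: PresenceMatrix,
    results: list[PairwiseSpotResult],
    effects: EffectSizes | None = None,
    pca: PCAResult | None = None,
    config: dict | None = None,
) -> AnalysisReport:
    """Build the report; all stage outputs must refer to the same spots."""
    validated = set(presence.counts.index)
    result_spots = {r.spot_id for r in results}
    if not result_spots.issubset(validated):
        raise ConsistencyError(
            f"results refer to spots outside the validated table: "
            f"{sorted(result_spots - validated)[:5]}"
        )
    n_validated = len(validated)
    sig_spots = {r.spot_id for r in results if r.significant}
    per_pair: dict[str, int] = {}
    for r in results:
        key = f"{r.group_x}-{r.group_y}"
        per_pair.setdefault(key, 0)
        if r.significant:
            per_pair[key] += 1
    pct = percent(len(sig_spots), n_validated) if n_validated else 0.0

    effect_rows: list[dict] = []
    dvr_max = None
    if effects is not None:
        dvr_max = None if math.isnan(effects.dvr_max) else float(effects.dvr_max)
        effect_rows = _sanitize(effects.table.to_dict(orient="records"))
    pca_var = [] if pca is None else [float(v) for v in pca.variance_fraction]

    return AnalysisReport(
        n_validated_spots=n_validated,
        n_significant_spots=len(sig_spots),
        pct_significant=pct,
        per_pair_significant=per_pair,
        dvr_max=dvr_max,
        effect_table=effect_rows,
        pca_variance_fraction=pca_var,
        config=_sanitize(config or {}),
    )


def render_report(report: AnalysisReport, outdir) -> tuple[Path, Path]:
    """Write ``report.json`` (canonical) and ``report.md`` (derived)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    md_path = outdir / "report.md"
    payload = _sanitize(report.to_dict())
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )
    md_path.write_text(_to_markdown(report), encoding="utf-8")
    return json_path, md_path


def read_report(path) -> AnalysisReport:
    """Re-read a ``report.json`` into an :class:`AnalysisReport`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnalysisReport(**payload)


def _to_markdown(report: AnalysisReport) -> str:
    lines = ["# Differential spot-abundance report", ""]
    lines.append(f"- Validated spots: {report.n_validated_spots}")
    lines.append(
        f"- Spots significant in >=1 pair: {report.n_significant_spots} "
        f"({report.pct_significant}%)"
    )
    for pair, n in report.per_pair_significant.items():
        lines.append(f"- Significant in {pair}: {n}")
    if report.dvr_max is not None:
        lines.append(f"- DVR_max (signed DV of largest magnitude): {report.dvr_max:.6g}")
    if report.pca_variance_fraction:
        first_two = sum(report.pca_variance_fraction[:2])
        lines.append(f"- PCA variance in PC1+PC2: {100 * first_two:.1f}%")
    lines.append("")
    frame = pd.DataFrame(report.effect_table)
    sig = frame[frame["status"] == STATUS_SIGNIFICANT] if not frame.empty else frame
    if sig.empty:
        lines.append("No significant spots: effect table is empty.")
        lines.append("")
        return "\n".join(lines)
    lines.append("## Effect table (significant entries)")
    lines.append("")
    lines.append("| spot | pair | FC | RC |")
    lines.append("|---|---|---|---|")
    for _, row in sig.iterrows():
        fc = row["FC"]
        fc_s = fc if isinstance(fc, str) else f"{fc:+.2f}"
        rc_s = f"{row['RC']:+.3f}"
        lines.append(
            f"| {row['spot_id']} | {row['group_x']}-{row['group_y']} "
            f"| {fc_s} | {rc_s} |"
        )
    lines.append("")
    return "\n".join(lines)


__all__ = [
    "AnalysisReport",
    "percent",
    "summarize",
    "render_report",
    "read_report",
]
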