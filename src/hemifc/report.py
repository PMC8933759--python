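"""Headline summaries: significant-ROI counts/percentages and direction tallies."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .errors import DegenerateInputError


@dataclass(frozen=True)
class SummaryCounts:
    label: str
    n_significant_rois: int
    n_total_rois: int
    percent: float
    n_rightward: int = 0
    n_leftward: int = 0


def percent_of(n: int, total: int) -> float:
    """100*n/total rounded half-up to 2 decimals (exact decimal arithmetic,
    not binary-float round-half-even)."""
    if total <= 0:
        raise DegenerateInputError("n_total must be positive")
    q = (Decimal(100 * n) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(q)


def summary_from_counts(n_significant: int, n_total: int,
                        label: str = "") -> SummaryCounts:
    return SummaryCounts(label=label, n_significant_rois=n_significant,
                         n_total_rois=n_total,
                         percent=percent_of(n_significant, n_total))


def summarize_significant_rois(edge_results: pd.DataFrame, n_total: int,
                               label: str = "") -> SummaryCounts:
    """An ROI counts as significant if it participates in >= 1 significant edge."""
    sig = edge_results[edge_results["significant"]]
    rois = set(sig["seed_roi"]) | set(sig["target_roi"])
    return summary_from_counts(len(rois), n_total, label=label)


def tally_directions(lateralization: pd.DataFrame, group: str,
                     alpha: float = 0.05) -> tuple[int, int]:
    """(n_rightward, n_leftward) among ROIs with q_fdr < alpha in ``group``."""
    if len(lateralization) == 0:
        return 0, 0
    sub = lateralization[lateralization["group"] == group]
    sig = sub[sub["q_fdr"] < alpha]
    n_right = int((sig["mean_rFC"] > sig["mean_lFC"]).sum())
    n_left = int((sig["mean_rFC"] < sig["mean_lFC"]).sum())
    return n_right, n_left


def render_markdown(summaries: list[SummaryCounts],
                    lateralization: pd.DataFrame | None = None,
                    alpha: float = 0.05) -> str:
    lines = ["# Connectivity asymmetry report", ""]
    if summaries:
        lines += ["## Significant ROIs per contrast", "",
                  "| contrast | significant | total | percent |",
                  "|---|---|---|---|"]
        for s in summaries:
            lines.append(f"| {s.label} | {s.n_significant_rois} | "
                         f"{s.n_total_rois} | {s.percent:.2f}% |")
        lines.append("")
    if lateralization is not None and len(lateralization):
        lines += [f"## Lateralization direction tallies (alpha = {alpha})", "",
                  "| group | rightward | leftward | total asymmetric |",
                  "|---|---|---|---|"]
        for group in lateralization["group"].unique():
            nr, nl = tally_directions(lateralization, group, alpha)
            lines.append(f"| {group} | {nr} | {nl} | {nr + nl} |")
        lines.append("")
    return "\n".join(lines)


def write_report(text: str, path: str | Path) -> None:
    Path(path).write_text(text)
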