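"""Hemispheric aggregate connectivity (rFC, lFC) and the asymmetry index.

For a lateral ROI, ``rFC`` (resp. ``lFC``) is the sum of absolute edge
weights over its supra-threshold connections to right- (resp. left-)
hemisphere targets; the asymmetry index is

    AI = 100 * (rFC - lFC) / ((rFC + lFC) / 2)

bounded in [-200, 200], positive for rightward asymmetry, and undefined
when both sums are zero. The supra-threshold rule defaults to the signed
reading ``r > threshold`` (positive connections only); ``mode="absolute"``
uses ``|r| > threshold``. Weights default to the Fisher z values;
``weight="r"`` sums raw correlations instead. Midline ROIs never appear
as rows nor contribute as targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .connectivity import ConnectivityMatrix, fisher_z
from .errors import DegenerateInputError, HemifcError, RoiOrderMismatchError

AI_UNDEFINED = float("nan")


@dataclass(frozen=True)
class AsymmetrySettings:
    threshold_r: float = 0.25
    mode: str = "signed"        # "signed": r > thr; "absolute": |r| > thr
    weight: str = "z"           # "z" or "r"; absolute value is summed either way

    def __post_init__(self) -> None:
        if self.mode not in {"signed", "absolute"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.weight not in {"z", "r"}:
            raise ValueError(f"unknown weight {self.weight!r}")


@dataclass(frozen=True)
class AsymmetryProfileResult:
    """Per-ROI rFC/lFC/AI table for one subject.

    ``table`` has columns roi_id, rFC, lFC, AI, n_edges_right,
    n_edges_left; AI is NaN where undefined (rFC + lFC = 0).
    """

    subject_id: str
    table: pd.DataFrame = field(compare=False)


def asymmetry_index(rfc: float, lfc: float) -> float:
    """AI = 100 (rFC - lFC) / ((rFC + lFC) / 2); NaN when the sum is zero."""
    if rfc < 0 or lfc < 0:
        raise ValueError("rFC and lFC must be non-negative")
    total = rfc + lfc
    if total == 0:
        return AI_UNDEFINED
    # clamp away float drift at the +-200 boundaries
    return float(np.clip(100.0 * (rfc - lfc) / (total / 2.0), -200.0, 200.0))


def _supra_mask(r_row: np.ndarray, settings: AsymmetrySettings) -> np.ndarray:
    if settings.mode == "signed":
        return r_row > settings.threshold_r
    return np.abs(r_row) > settings.threshold_r


def hemispheric_fc(
    conn: ConnectivityMatrix,
    atlas: RoiAtlas,
    roi: str,
    threshold_r: float = 0.25,
    mode: str = "signed",
    weight: str = "z",
) -> tuple[float, float, int, int]:
    """Supra-threshold aggregate connectivity of ``roi`` per target hemisphere.

    Returns ``(rFC, lFC, n_edges_right, n_edges_left)``. Targets are the
    lateral ROIs of the atlas other than ``roi`` itself; the homotopic
    partner is an ordinary target. An atlas side with no targets yields 0.
    """
    settings = AsymmetrySettings(threshold_r=threshold_r, mode=mode, weight=weight)
    lateral = atlas.lateral_subset()
    if roi not in lateral:
        raise HemifcError(f"ROI {roi!r} is not a lateral ROI of the atlas")
    order = list(conn.roi_order)
    for rid in lateral.roi_ids:
        if rid not in order:
            raise RoiOrderMismatchError(f"atlas ROI {rid!r} missing from matrix")
    i = order.index(roi)
    out = {}
    w_full = np.abs(conn.z[i] if settings.weight == "z" else conn.r[i])
    supra = _supra_mask(conn.r[i], settings)
    for hemi in ("R", "L"):
        targets = [order.index(t) for t in lateral.ids_in_hemisphere(hemi) if t != roi]
        if targets:
            sel = np.asarray(targets)
            keep = supra[sel]
            out[hemi] = (float(w_full[sel][keep].sum()), int(keep.sum()))
        else:
            out[hemi] = (0.0, 0)
    return out["R"][0], out["L"][0], out["R"][1], out["L"][1]


# ---------------------------------------------------------------------------
# vectorized profile over a whole matrix / cohort
# ---------------------------------------------------------------------------


def profile_matrix(
    r: np.ndarray,
    roi_order: Sequence[str],
    atlas: RoiAtlas,
    settings: AsymmetrySettings = AsymmetrySettings(),
    z: np.ndarray | None = None,
) -> pd.DataFrame:
    """rFC/lFC/AI for every lateral ROI of ``atlas``, from a correlation
    matrix over ``roi_order`` (which may contain extra, e.g. midline, ROIs).

    Used both on subject matrices and on population matrices (where ``z``
    is derived from ``r`` on the fly).
    """
    lateral = atlas.lateral_subset()
    if len(lateral) == 0:
        raise DegenerateInputError("atlas has no lateral ROIs")
    order = list(roi_order)
    try:
        idx = np.asarray([order.index(rid) for rid in lateral.roi_ids])
    except ValueError as exc:
        raise RoiOrderMismatchError(f"atlas ROI missing from matrix: {exc}") from exc

    rl = r[np.ix_(idx, idx)]
    if z is None:
        zl = np.zeros_like(rl)
        off = ~np.eye(rl.shape[0], dtype=bool)
        zl[off] = fisher_z(rl[off])
    else:
        zl = z[np.ix_(idx, idx)]

    w = np.abs(zl if settings.weight == "z" else rl)
    supra = _supra_mask(rl, settings)
    np.fill_diagonal(supra, False)
    hemis = np.asarray([lateral.hemisphere_of(rid) for rid in lateral.roi_ids])
    is_r = hemis == "R"
    is_l = hemis == "L"
    contrib = w * supra
    rfc = contrib[:, is_r].sum(axis=1)
    lfc = contrib[:, is_l].sum(axis=1)
    n_r = supra[:, is_r].sum(axis=1)
    n_l = supra[:, is_l].sum(axis=1)
    total = rfc + lfc
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(total > 0,
                      np.clip(100.0 * (rfc - lfc) / np.where(total > 0, total, 1.0)
                              * 2.0, -200.0, 200.0),
                      np.nan)
    return pd.DataFrame(
        {
            "roi_id": lateral.roi_ids,
            "rFC": rfc,
            "lFC": lfc,
            "AI": ai,
            "n_edges_right": n_r,
            "n_edges_left": n_l,
        }
    )


def profile_subject(conn: ConnectivityMatrix, atlas: RoiAtlas,
                    settings: AsymmetrySettings = AsymmetrySettings()
                    ) -> AsymmetryProfileResult:
    table = profile_matrix(conn.r, conn.roi_order, atlas, settings, z=conn.z)
    return AsymmetryProfileResult(subject_id=conn.subject_id, table=table)


def profile_cohort(conns: Sequence[ConnectivityMatrix], atlas: RoiAtlas,
                   settings: AsymmetrySettings = AsymmetrySettings()
                   ) -> list[AsymmetryProfileResult]:
    """One profile per subject; deterministic and independent of cohort order."""
    if conns:
        order0 = conns[0].roi_order
        for c in conns:
            if c.roi_order != order0:
                raise RoiOrderMismatchError(
                    f"subject {c.subject_id!r} roi_order differs within cohort"
                )
    return [profile_subject(c, atlas, settings) for c in conns]


def cohort_long_table(profiles: Sequence[AsymmetryProfileResult],
                      groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Stack per-subject profiles into the long asymmetry table."""
    frames = []
    for p in profiles:
        t = p.table.copy()
        t.insert(0, "subject_id", p.subject_id)
        if groups is not None:
            t.insert(1, "group", groups.get(p.subject_id, ""))
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def save_long_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
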