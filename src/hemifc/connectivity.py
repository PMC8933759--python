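"""Subject-level ROI-to-ROI correlation networks and edge-wise group tests.

Per subject, the full symmetric Pearson correlation matrix between ROI
time courses is computed and mapped through the variance-stabilizing
Fisher transform ``z = atanh(r)``; the z values are what the group-level
tests operate on.

The between-group edge comparison applies, per unordered ROI pair, a
two-sample t-test on the subjects' z values, then a two-level
significance rule: an edge is a *candidate* if its uncorrected p is below
the height threshold, and *significant* if it additionally survives a
Benjamini-Hochberg FDR correction at level ``fdr_q`` run within a seed
ROI's family of candidate edges (each unordered pair belongs to the
families of both of its endpoints; significance in either counts).
A matrix-wide BH correction over all candidate edges is available as an
alternative through ``correction="matrix"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import RoiAtlas
from .errors import DegenerateInputError, RoiOrderMismatchError, ZeroVarianceRoiError
from .stats import bh_fdr

_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson ``r`` and Fisher ``z`` matrices for one subject.

    The diagonal of ``r`` is 1; the diagonal of ``z`` is stored as 0 and
    never used. Off-diagonal r values are clamped to ``±(1 - 1e-12)``
    before the atanh so that z is always finite.
    """

    subject_id: str
    r: np.ndarray
    z: np.ndarray
    roi_order: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.roi_order)
        if self.r.shape != (n, n) or self.z.shape != (n, n):
            raise RoiOrderMismatchError(
                f"matrix shape {self.r.shape} does not match "
                f"{n} ROI labels for subject {self.subject_id!r}"
            )

    def index_of(self, roi_id: str) -> int:
        return self.roi_order.index(roi_id)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with the standard clamp so perfect correlations stay finite."""
    return np.arctanh(np.clip(r, -_CLAMP, _CLAMP))


def correlation_matrix(data: np.ndarray, roi_ids: Sequence[str]) -> np.ndarray:
    """Pearson correlation between columns, with explicit degeneracy checks."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise DegenerateInputError("time-series data must be 2-D (timepoints x ROIs)")
    n_t = data.shape[0]
    if n_t < 3:
        raise DegenerateInputError(
            f"need at least 3 timepoints to estimate correlations, got {n_t}"
        )
    sd = data.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [roi_ids[i] for i in zero]
        raise ZeroVarianceRoiError(
            f"zero-variance time course for ROI(s) {names}; correlation undefined"
        )
    r = np.corrcoef(data, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def compute_connectivity(ts, atlas: RoiAtlas | None = None) -> ConnectivityMatrix:
    """Build the full ROI-to-ROI connectivity matrix for one subject.

    ``ts`` is any object with ``subject_id``, ``data`` (timepoints x ROIs)
    and ``roi_ids`` attributes, e.g. a
    :class:`~hemifc.synthetic.SubjectTimeSeries`. When ``atlas`` is given,
    the column order must match the atlas order exactly.
    """
    roi_ids = tuple(ts.roi_ids)
    if atlas is not None and roi_ids != tuple(atlas.roi_ids):
        raise RoiOrderMismatchError(
            f"subject {ts.subject_id!r} column order does not match atlas order"
        )
    r = correlation_matrix(ts.data, roi_ids)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    z[off] = fisher_z(r[off])
    return ConnectivityMatrix(subject_id=ts.subject_id, r=r, z=z, roi_order=roi_ids)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def _stack_z(matrices: Sequence[ConnectivityMatrix], roi_order: tuple[str, ...],
             iu: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    rows = []
    for m in matrices:
        if m.roi_order != roi_order:
            raise RoiOrderMismatchError(
                f"subject {m.subject_id!r} roi_order differs within the contrast"
            )
        rows.append(m.z[iu])
    return np.asarray(rows)


def two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Vectorized two-sample t along axis 0; returns (t, df, p two-sided).

    ``equal_var=True`` is the classical pooled-variance Student t used by
    second-level GLM contrasts; ``False`` gives Welch.
    """
    n1, n2 = a.shape[0], b.shape[0]
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("need at least 2 subjects per group")
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(se, float(n1 + n2 - 2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se**4 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def compare_edges(
    matrices_by_group: Mapping[str, Sequence[ConnectivityMatrix]],
    contrast: tuple[str, str],
    height_p: float = 0.01,
    fdr_q: float = 0.05,
    correction: str = "seed",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Edge-wise two-sample comparison of Fisher z values between two groups.

    Returns one row per unordered ROI pair with columns ``seed_roi``,
    ``target_roi``, ``contrast``, ``mean_diff_z``, ``t_stat``, ``p_unc``,
    ``q_fdr`` and ``significant``. ``mean_diff_z`` is group A minus group B
    for ``contrast = (A, B)``. ``q_fdr`` is NaN for non-candidate edges
    (``p_unc >= height_p``); under seed-level correction it is the minimum
    q over the edge's two seed families.
    """
    ga, gb = contrast
    for label in (ga, gb):
        if label not in matrices_by_group:
            raise KeyError(f"contrast label {label!r} not present in the cohort")
    for label in (ga, gb):
        if len(matrices_by_group[label]) == 0:
            raise DegenerateInputError(f"group {label!r} is empty")
    if correction not in {"seed", "matrix"}:
        raise ValueError(f"unknown correction {correction!r}; use 'seed' or 'matrix'")

    roi_order = matrices_by_group[ga][0].roi_order
    n = len(roi_order)
    iu = np.triu_indices(n, k=1)
    za = _stack_z(matrices_by_group[ga], roi_order, iu)
    zb = _stack_z(matrices_by_group[gb], roi_order, iu)

    t, _, p = two_sample_t(za, zb, equal_var=equal_var)
    diff = za.mean(axis=0) - zb.mean(axis=0)

    candidate = p < height_p
    q = np.full(p.shape, np.nan)
    if correction == "matrix":
        idx = np.flatnonzero(candidate)
        if idx.size:
            q[idx] = bh_fdr(p[idx])
    else:
        # one FDR family per seed ROI over that seed's candidate edges; each
        # unordered pair is in two families, keep the smaller q
        incident: list[list[int]] = [[] for _ in range(n)]
        for e, (i, j) in enumerate(zip(*iu)):
            if candidate[e]:
                incident[i].append(e)
                incident[j].append(e)
        for edges in incident:
            if not edges:
                continue
            q_fam = bh_fdr(p[list(edges)])
            for e, qe in zip(edges, q_fam):
                if np.isnan(q[e]) or qe < q[e]:
                    q[e] = qe
    significant = candidate & (q < fdr_q)

    return pd.DataFrame(
        {
            "seed_roi": [roi_order[i] for i in iu[0]],
            "target_roi": [roi_order[j] for j in iu[1]],
            "contrast": f"{ga}>{gb}",
            "mean_diff_z": diff,
            "t_stat": t,
            "p_unc": p,
            "q_fdr": q,
            "significant": significant,
        }
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def save_matrix(conn: ConnectivityMatrix, path: str | Path, which: str = "r") -> None:
    """Write one square matrix (header and index = roi_ids) as TSV."""
    m = conn.r if which == "r" else conn.z
    pd.DataFrame(m, index=list(conn.roi_order), columns=list(conn.roi_order)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def load_matrix_pair(subject_id: str, r_path: str | Path,
                     z_path: str | Path | None = None) -> ConnectivityMatrix:
    """Read a square r-matrix TSV (and optionally a matching z TSV)."""
    rdf = pd.read_csv(r_path, sep="\t", index_col=0)
    roi_order = tuple(str(c) for c in rdf.columns)
    if tuple(str(i) for i in rdf.index) != roi_order:
        raise RoiOrderMismatchError(f"{r_path}: header and index ROI order differ")
    r = rdf.to_numpy(dtype=float)
    if z_path is not None:
        z = pd.read_csv(z_path, sep="\t", index_col=0).to_numpy(dtype=float)
    else:
        off = ~np.eye(r.shape[0], dtype=bool)
        z = np.zeros_like(r)
        z[off] = fisher_z(r[off])
    return ConnectivityMatrix(subject_id=subject_id, r=r, z=z, roi_order=roi_order)


def save_edges(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.10g")


def edges_long_format(conns: Sequence[ConnectivityMatrix]) -> pd.DataFrame:
    """All subjects' edges in tidy long format (subject_id, seed, target, r, z)."""
    frames = []
    for c in conns:
        iu = np.triu_indices(len(c.roi_order), k=1)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": c.subject_id,
                    "seed_roi": [c.roi_order[i] for i in iu[0]],
                    "target_roi": [c.roi_order[j] for j in iu[1]],
                    "r": c.r[iu],
                    "z": c.z[iu],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
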