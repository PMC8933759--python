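"""Synthetic multi-subject ROI time-series cohorts with known structure.

The generator builds, per group, a population correlation matrix with

* a within-hemisphere baseline correlation,
* a homotopic (mirror-pair) correlation,
* a cross-hemisphere baseline for all other lateral pairs (midline ROIs
  correlate at the cross-hemisphere baseline with everything),
* optional additive group-specific edge effects, and
* optional per-ROI asymmetry targets, realized by a monotone bisection
  search on a cross-hemisphere multiplier per profiled ROI so that the
  asymmetry module's AI, evaluated on the population matrix itself,
  attains the target.

After the edits, the matrix is projected to the nearest valid correlation
matrix (eigenvalue clipping with diagonal rescaling). Subjects are then
drawn as zero-mean stationary series with that cross-sectional covariance
and a shared AR(1) temporal coefficient; clinical covariates come from
truncated normal draws. Everything is reproducible from a single seed,
with per-subject sub-seeds derived deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal as spsig
from scipy import stats as sps
from statsmodels.stats.correlation_tools import corr_clipped

from .asymmetry import AsymmetrySettings, profile_matrix
from .atlas import RoiAtlas
from .errors import (
    CovarianceRepairError,
    DegenerateInputError,
    HemifcError,
    InfeasibleTargetError,
)

GROUP_LABELS = ("HC", "LMTLE", "RMTLE")


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int

    def __post_init__(self) -> None:
        if self.label not in GROUP_LABELS:
            raise HemifcError(
                f"unknown group label {self.label!r}; expected one of {GROUP_LABELS}"
            )
        if self.n_subjects < 1:
            raise HemifcError("n_subjects must be positive")


@dataclass(frozen=True)
class ClinicalNormal:
    """Normal distribution truncated at zero (years cannot be negative)."""

    mean: float
    sd: float

    def draw(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        a = (0.0 - self.mean) / self.sd
        return sps.truncnorm.rvs(a, np.inf, loc=self.mean, scale=self.sd,
                                 size=size, random_state=rng)


@dataclass(frozen=True)
class GroupClinicalModel:
    age: ClinicalNormal
    male_fraction: float
    onset_age: Optional[ClinicalNormal] = None
    duration: Optional[ClinicalNormal] = None


#: Default demographics for a 12/11/23 three-group cohort.
DEFAULT_CLINICAL_MODEL: dict[str, GroupClinicalModel] = {
    "LMTLE": GroupClinicalModel(
        age=ClinicalNormal(25.17, 3.69), male_fraction=9 / 12,
        onset_age=ClinicalNormal(16.42, 8.61), duration=ClinicalNormal(12.83, 8.68),
    ),
    "RMTLE": GroupClinicalModel(
        age=ClinicalNormal(29.25, 9.92), male_fraction=6 / 11,
        onset_age=ClinicalNormal(19.09, 8.81), duration=ClinicalNormal(12.73, 6.53),
    ),
    "HC": GroupClinicalModel(
        age=ClinicalNormal(31.82, 10.25), male_fraction=13 / 23,
    ),
}


@dataclass(frozen=True)
class EdgeEffect:
    """Additive change to the population correlation of one ROI pair in one
    group, applied before repair."""

    group: str
    roi_a: str
    roi_b: str
    delta: float


@dataclass
class CohortDesign:
    groups: list[GroupSpec]
    n_timepoints: int = 230          # 240 acquired volumes minus 10 discarded
    base_correlation: float = 0.35
    homotopic_correlation: float = 0.55
    cross_correlation: float = 0.30
    asymmetry_profile: dict[str, float] = field(default_factory=dict)
    # optional sparse strong cross-hemisphere structure: each homotopic pair
    # additionally correlates at strong_cross_correlation with its ring
    # neighbours' partners (strong_cross_neighbors on each side); lets designs
    # concentrate cross-hemisphere mass on a few edges far from the
    # supra-threshold boundary
    strong_cross_correlation: Optional[float] = None
    strong_cross_neighbors: int = 0
    group_edge_effects: list[EdgeEffect] = field(default_factory=list)
    ar1_coefficient: float = 0.0
    clinical_model: Mapping[str, GroupClinicalModel] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_MODEL))
    random_seed: int = 0
    correlation_jitter: float = 0.0  # sd of mirror-symmetric baseline jitter
    structure_seed: int = 202        # seeds the jitter, independent of random_seed
    asymmetry_settings: AsymmetrySettings = field(default_factory=AsymmetrySettings)
    ai_tolerance: float = 2.0        # AI units, checked after repair
    repair_tolerance: float = 0.1    # max per-entry change allowed by repair
    repair_action: str = "warn"      # "warn" or "error"

    def __post_init__(self) -> None:
        if not self.groups:
            raise HemifcError("design needs at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise HemifcError("duplicate group labels in design")
        if self.n_timepoints < 3:
            raise HemifcError("n_timepoints must be >= 3 for correlations")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise HemifcError("ar1_coefficient must lie in [0, 1)")
        for roi, ai in self.asymmetry_profile.items():
            if not -200.0 <= ai <= 200.0:
                raise HemifcError(f"AI target for {roi!r} outside [-200, 200]")
        if self.repair_action not in {"warn", "error"}:
            raise HemifcError("repair_action must be 'warn' or 'error'")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


@dataclass(frozen=True)
class SubjectTimeSeries:
    subject_id: str
    group: str
    data: np.ndarray                  # n_timepoints x n_rois
    roi_ids: tuple[str, ...]
    age: Optional[float] = None
    sex: Optional[str] = None         # "M" / "F"
    onset_age: Optional[float] = None
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_ids):
            raise HemifcError("data must be n_timepoints x n_rois")
        if self.data.shape[0] < 3:
            raise DegenerateInputError("need >= 3 timepoints")
        if np.isnan(self.data).any():
            raise HemifcError("time series contains missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# population covariance
# ---------------------------------------------------------------------------


def _base_matrix(design: CohortDesign, atlas: RoiAtlas) -> np.ndarray:
    ids = atlas.roi_ids
    n = len(ids)
    hemi = np.array([atlas.hemisphere_of(i) for i in ids])
    m = np.full((n, n), design.cross_correlation)
    same = (hemi[:, None] == hemi[None, :]) & (hemi[:, None] != "M")
    m[same] = design.base_correlation
    if design.strong_cross_neighbors > 0 and design.strong_cross_correlation is not None:
        pairs = [r.roi_id for r in atlas
                 if r.hemisphere == "L" and r.homotopic_partner is not None]
        partners = {r.roi_id: r.homotopic_partner for r in atlas}
        kp = len(pairs)
        for i in range(kp):
            for d in range(1, design.strong_cross_neighbors + 1):
                for j in ((i + d) % kp, (i - d) % kp):
                    if j == i:
                        continue
                    a = ids.index(pairs[i])
                    b = ids.index(partners[pairs[j]])
                    m[a, b] = m[b, a] = design.strong_cross_correlation
    for roi in atlas:
        if roi.homotopic_partner is not None:
            i, j = ids.index(roi.roi_id), ids.index(roi.homotopic_partner)
            m[i, j] = m[j, i] = design.homotopic_correlation
    np.fill_diagonal(m, 1.0)
    if design.correlation_jitter > 0:
        _add_mirror_jitter(m, design, atlas)
    return m


def _add_mirror_jitter(m: np.ndarray, design: CohortDesign,
                       atlas: RoiAtlas) -> None:
    """Perturb off-diagonal baseline entries with Gaussian jitter that is
    invariant under swapping every homotopic pair: entries related by the
    hemisphere swap share one draw. Keeps the equal-entry ties of the
    block construction from making AI targeting needlessly coarse."""
    from itertools import combinations

    ids = atlas.roi_ids
    key_side: dict[str, tuple[str, str | None]] = {}
    for roi in atlas:
        if roi.hemisphere != "M" and roi.homotopic_partner is not None:
            key_side[roi.roi_id] = (min(roi.roi_id, roi.homotopic_partner),
                                    roi.hemisphere)
        else:
            key_side[roi.roi_id] = (roi.roi_id, None)
    classes: dict[tuple[int, int], tuple] = {}
    for i, j in combinations(range(len(ids)), 2):
        (ka, sa), (kb, sb) = key_side[ids[i]], key_side[ids[j]]
        if ka == kb:
            cls = (ka, kb, "homotopic")
        elif sa is None or sb is None:
            cls = (*sorted((ka, kb)), "unpaired")
        else:
            cls = (*sorted((ka, kb)), "same" if sa == sb else "cross")
        classes[(i, j)] = cls
    rng = np.random.default_rng(np.random.SeedSequence(design.structure_seed))
    draws = {cls: rng.normal(0.0, design.correlation_jitter)
             for cls in sorted(set(classes.values()))}
    for (i, j), cls in classes.items():
        v = float(np.clip(m[i, j] + draws[cls], -0.99, 0.99))
        m[i, j] = m[j, i] = v


def _lateral_context(atlas: RoiAtlas):
    """Index arrays used for fast per-ROI AI evaluation on the full matrix."""
    ids = atlas.roi_ids
    lateral = atlas.lateral_subset()
    idx = np.asarray([ids.index(r) for r in lateral.roi_ids])
    hemi = np.asarray([lateral.hemisphere_of(r) for r in lateral.roi_ids])
    return lateral, idx, hemi


def _roi_ai(m: np.ndarray, row: int, idx: np.ndarray, hemi: np.ndarray,
            self_pos: int, settings: AsymmetrySettings) -> float:
    """AI of one lateral ROI evaluated directly on the full matrix ``m``."""
    r = m[row, idx]
    if settings.mode == "signed":
        supra = r > settings.threshold_r
    else:
        supra = np.abs(r) > settings.threshold_r
    supra[self_pos] = False
    w = np.abs(np.arctanh(np.clip(r, -0.999999999999, 0.999999999999))
               if settings.weight == "z" else r)
    rfc = float(w[supra & (hemi == "R")].sum())
    lfc = float(w[supra & (hemi == "L")].sum())
    total = rfc + lfc
    if total == 0:
        return float("nan")
    return 100.0 * (rfc - lfc) / (total / 2.0)


def _apply_asymmetry_targets(m: np.ndarray, targets: Mapping[str, float],
                             design: CohortDesign, atlas: RoiAtlas) -> np.ndarray:
    """Realize the per-ROI AI targets by per-ROI cross-hemisphere multipliers.

    Multipliers compose multiplicatively on shared entries (the edge
    between two profiled ROIs carries both). The per-ROI search is a plain
    bisection — AI is monotone in the multiplier because scaling positive
    entries up can only add supra-threshold mass on the scaled side — and
    sweeps repeat until the interacting targets co-converge.
    """
    if not targets:
        return m
    ids = atlas.roi_ids
    lateral, idx, hemi = _lateral_context(atlas)
    for roi in targets:
        if roi not in lateral:
            raise HemifcError(
                f"asymmetry_profile entry {roi!r} is not a lateral ROI"
            )
    base = m.copy()
    profiled = list(targets)
    rows = {roi: ids.index(roi) for roi in profiled}
    pos_in_lateral = {roi: list(lateral.roi_ids).index(roi) for roi in profiled}
    cross_cols = {}
    for roi in profiled:
        h = lateral.hemisphere_of(roi)
        other = "R" if h == "L" else "L"
        cross_cols[roi] = idx[hemi == other]
    mult = {roi: 1.0 for roi in profiled}

    def _set_row(roi: str) -> None:
        row = rows[roi]
        cols = cross_cols[roi]
        vals = base[row, cols].copy()
        for k, c in enumerate(cols):
            other_roi = ids[c]
            if other_roi in mult and other_roi != roi:
                vals[k] *= mult[other_roi]
        vals = np.clip(vals * mult[roi], -0.999, 0.999)
        m[row, cols] = vals
        m[cols, row] = vals

    def _repaired_view(a: np.ndarray) -> np.ndarray:
        # cheap eigenvalue-clip projection so the search optimizes the AI of
        # the matrix subjects will actually be drawn from
        w, u = np.linalg.eigh((a + a.T) / 2.0)
        if w.min() >= -1e-12:
            return a
        w = np.clip(w, 0.0, None)
        out = (u * w) @ u.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
        return out

    settings = design.asymmetry_settings
    for _sweep in range(25):
        worst = 0.0
        for roi in profiled:
            target = targets[roi]
            row, pos = rows[roi], pos_in_lateral[roi]

            def f(mm: float) -> float:
                mult[roi] = mm
                _set_row(roi)
                return _roi_ai(_repaired_view(m), row, idx, hemi, pos, settings)

            cols = cross_cols[roi]
            scale = np.abs(base[row, cols]).max()
            hi = 0.999 / scale if scale > 0 else 1.0
            f_lo, f_hi = f(0.0), f(hi)
            lo_v, hi_v = (f_lo, f_hi) if f_lo <= f_hi else (f_hi, f_lo)
            if np.isnan(f_lo):
                # no cross edges at m=0: the ROI is fully left- (or right-)
                # lateralized, AI = -200 or +200 depending on hemisphere
                f_lo = -200.0 if lateral.hemisphere_of(roi) == "L" else 200.0
                lo_v, hi_v = min(f_lo, f_hi), max(f_lo, f_hi)
            if not lo_v - 1e-9 <= target <= hi_v + 1e-9:
                raise InfeasibleTargetError(
                    f"AI target {target} for ROI {roi!r} infeasible; achievable "
                    f"range is [{lo_v:.2f}, {hi_v:.2f}]",
                    achievable=(lo_v, hi_v),
                )
            increasing = f_hi >= f_lo
            a, b = 0.0, hi
            for _ in range(80):
                mid = 0.5 * (a + b)
                val = f(mid)
                if np.isnan(val):
                    val = f_lo
                if (val < target) == increasing:
                    a = mid
                else:
                    b = mid
            achieved = f(0.5 * (a + b))
            worst = max(worst, abs(achieved - target))
        if worst <= 0.05:
            break
    return m


def repair_correlation(m: np.ndarray, tolerance: float = 0.1,
                       action: str = "warn") -> np.ndarray:
    """Project to the nearest valid correlation matrix by eigenvalue
    clipping with diagonal rescaling; complain if any entry moved more
    than ``tolerance``."""
    repaired = corr_clipped(m, threshold=1e-12)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    delta = float(np.abs(repaired - m).max())
    if delta > tolerance:
        msg = (f"nearest-correlation repair moved an entry by {delta:.4f} "
               f"(> tolerance {tolerance})")
        if action == "error":
            raise CovarianceRepairError(msg)
        warnings.warn(msg, stacklevel=2)
    return repaired


def build_population_covariance(design: CohortDesign, group: str,
                                atlas: RoiAtlas, repair: bool = True) -> np.ndarray:
    """The group's population ROI x ROI correlation matrix.

    Order of construction: baseline blocks, homotopic entries, asymmetry
    targeting, additive group edge effects, then (unless ``repair=False``,
    for inspection of the raw edits) projection to the nearest valid
    correlation matrix. Profiled ROIs are verified post-repair to sit
    within ``design.ai_tolerance`` AI units of their targets.
    """
    if group not in {g.label for g in design.groups}:
        raise HemifcError(f"group {group!r} not in design")
    ids = atlas.roi_ids

    def _construct(targets: Mapping[str, float]) -> np.ndarray:
        m = _base_matrix(design, atlas)
        m = _apply_asymmetry_targets(m, targets, design, atlas)
        for eff in design.group_edge_effects:
            if eff.group != group:
                continue
            i, j = ids.index(eff.roi_a), ids.index(eff.roi_b)
            m[i, j] = m[j, i] = np.clip(m[i, j] + eff.delta, -0.999, 0.999)
        return m

    profile = design.asymmetry_profile
    m = _construct(profile)  # original targets: infeasibility surfaces here
    if not repair:
        return m
    repaired = repair_correlation(m, design.repair_tolerance, design.repair_action)
    if not profile:
        return repaired

    def _achieved(mat: np.ndarray) -> dict[str, float]:
        prof = profile_matrix(mat, ids, atlas,
                              design.asymmetry_settings).set_index("roi_id")
        return {roi: float(prof.loc[roi, "AI"]) for roi in profile}

    # the PSD projection can drag profiled AIs off target; compensate by
    # re-targeting with shifted internal targets until post-repair AIs land
    eff_targets = dict(profile)
    achieved = _achieved(repaired)
    for _ in range(12):
        worst = max(abs(achieved[r] - profile[r]) for r in profile)
        if worst <= min(design.ai_tolerance, 0.5):
            break
        for roi in profile:
            adj = eff_targets[roi] + 0.9 * (profile[roi] - achieved[roi])
            eff_targets[roi] = float(np.clip(adj, -200.0, 200.0))
        try:
            m = _construct(eff_targets)
        except InfeasibleTargetError as exc:
            if exc.achievable is not None:
                lo, hi = exc.achievable
                for roi in profile:
                    eff_targets[roi] = float(np.clip(eff_targets[roi],
                                                     lo + 1e-6, hi - 1e-6))
                m = _construct(eff_targets)
            else:
                break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            repaired = repair_correlation(m, design.repair_tolerance, "warn")
        achieved = _achieved(repaired)
    for roi, target in profile.items():
        got = achieved[roi]
        if not np.isfinite(got) or abs(got - target) > design.ai_tolerance:
            warnings.warn(
                f"post-repair AI for {roi!r} is {got:.2f}, target "
                f"{target:.2f} (tolerance {design.ai_tolerance})",
                stacklevel=2,
            )
    return repaired


_COV_CACHE: dict[tuple, np.ndarray] = {}


def _group_covariance_cached(design: CohortDesign, group: str,
                             atlas: RoiAtlas) -> np.ndarray:
    # the covariance does not depend on the seed, so replicate runs that
    # differ only in random_seed can reuse it
    key = (repr(replace(design, random_seed=0, clinical_model={})), group,
           tuple(atlas.rois))
    if key not in _COV_CACHE:
        if len(_COV_CACHE) > 64:
            _COV_CACHE.clear()
        _COV_CACHE[key] = build_population_covariance(design, group, atlas)
    return _COV_CACHE[key]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _psd_factor(m: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() < -1e-8:
        raise HemifcError("covariance not PSD after repair (internal error)")
    return u * np.sqrt(np.clip(w, 0.0, None))


def _draw_series(factor: np.ndarray, n_t: int, phi: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series whose cross-sectional covariance is
    ``factor @ factor.T`` regardless of ``phi``."""
    n = factor.shape[0]
    eps = rng.standard_normal((n_t, n))
    innov = eps @ factor.T
    if phi == 0.0:
        return innov
    innov[1:] *= np.sqrt(1.0 - phi * phi)
    # x_t = phi x_{t-1} + sqrt(1-phi^2) L e_t, x_0 = L e_0
    return spsig.lfilter([1.0], [1.0, -phi], innov, axis=0)


def simulate_cohort(design: CohortDesign, atlas: RoiAtlas
                    ) -> list[SubjectTimeSeries]:
    """Draw the full cohort; reproducible from ``design.random_seed``."""
    roi_ids = tuple(atlas.roi_ids)
    root = np.random.SeedSequence(design.random_seed)
    children = root.spawn(design.n_subjects)
    subjects: list[SubjectTimeSeries] = []
    k = 0
    for spec in design.groups:
        cov = _group_covariance_cached(design, spec.label, atlas)
        factor = _psd_factor(cov)
        clin = design.clinical_model.get(spec.label)
        for i in range(spec.n_subjects):
            rng = np.random.default_rng(children[k])
            k += 1
            data = _draw_series(factor, design.n_timepoints,
                                design.ar1_coefficient, rng)
            age = sex = onset = duration = None
            if clin is not None:
                age = float(clin.age.draw(rng)[0])
                sex = "M" if rng.random() < clin.male_fraction else "F"
                if clin.onset_age is not None:
                    onset = float(clin.onset_age.draw(rng)[0])
                if clin.duration is not None:
                    duration = float(clin.duration.draw(rng)[0])
            subjects.append(SubjectTimeSeries(
                subject_id=f"{spec.label}{i + 1:02d}", group=spec.label,
                data=data, roi_ids=roi_ids, age=age, sex=sex,
                onset_age=onset, duration=duration,
            ))
    return subjects


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def write_cohort(subjects: Sequence[SubjectTimeSeries], out_dir: str | Path) -> Path:
    """One TSV per subject plus ``manifest.tsv``; byte-stable across runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        fname = f"{s.subject_id}.tsv"
        pd.DataFrame(s.data, columns=list(s.roi_ids)).to_csv(
            out / fname, sep="\t", index=False, float_format="%.6f")
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "age": "" if s.age is None else f"{s.age:.2f}",
            "sex": s.sex or "",
            "onset_age": "" if s.onset_age is None else f"{s.onset_age:.2f}",
            "duration": "" if s.duration is None else f"{s.duration:.2f}",
            "file": fname,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def load_cohort(cohort_dir: str | Path) -> list[SubjectTimeSeries]:
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.tsv", sep="\t",
                           dtype={"subject_id": str, "group": str, "sex": str})
    subjects = []
    for rec in manifest.itertuples(index=False):
        df = pd.read_csv(cohort_dir / rec.file, sep="\t")
        subjects.append(SubjectTimeSeries(
            subject_id=rec.subject_id, group=rec.group,
            data=df.to_numpy(dtype=float),
            roi_ids=tuple(str(c) for c in df.columns),
            age=None if pd.isna(rec.age) else float(rec.age),
            sex=None if pd.isna(rec.sex) else str(rec.sex),
            onset_age=None if pd.isna(rec.onset_age) else float(rec.onset_age),
            duration=None if pd.isna(rec.duration) else float(rec.duration),
        ))
    return subjects


def cohort_manifest(subjects: Sequence[SubjectTimeSeries]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [s.subject_id for s in subjects],
        "group": [s.group for s in subjects],
        "age": [s.age for s in subjects],
        "sex": [s.sex for s in subjects],
        "onset_age": [s.onset_age for s in subjects],
        "duration": [s.duration for s in subjects],
    })


# ---------------------------------------------------------------------------
# YAML design config
# ---------------------------------------------------------------------------


def _clinical_from_dict(d: Mapping) -> GroupClinicalModel:
    def cn(key):
        v = d.get(key)
        return None if v is None else ClinicalNormal(float(v["mean"]), float(v["sd"]))

    age = cn("age") or ClinicalNormal(30.0, 10.0)
    return GroupClinicalModel(age=age,
                              male_fraction=float(d.get("male_fraction", 0.5)),
                              onset_age=cn("onset_age"), duration=cn("duration"))


def design_from_yaml(path: str | Path) -> CohortDesign:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    kwargs: dict = {}
    kwargs["groups"] = [GroupSpec(g["label"], int(g["n_subjects"]))
                        for g in cfg["groups"]]
    for key in ("n_timepoints", "base_correlation", "homotopic_correlation",
                "cross_correlation", "ar1_coefficient", "random_seed",
                "ai_tolerance", "repair_tolerance", "repair_action"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "asymmetry_profile" in cfg:
        kwargs["asymmetry_profile"] = {str(k): float(v)
                                       for k, v in cfg["asymmetry_profile"].items()}
    if "group_edge_effects" in cfg:
        kwargs["group_edge_effects"] = [
            EdgeEffect(e["group"], e["roi_a"], e["roi_b"], float(e["delta"]))
            for e in cfg["group_edge_effects"]]
    if "clinical_model" in cfg:
        kwargs["clinical_model"] = {g: _clinical_from_dict(d)
                                    for g, d in cfg["clinical_model"].items()}
    if "asymmetry_settings" in cfg:
        kwargs["asymmetry_settings"] = AsymmetrySettings(**cfg["asymmetry_settings"])
    return CohortDesign(**kwargs)


def mtle_design(random_seed: int = 0, **overrides) -> CohortDesign:
    """Three-group 12/11/23 design with ipsilateral-temporal edge effects,
    at 230 retained volumes per subject."""
    effects = []
    for group, side in (("LMTLE", "L"), ("RMTLE", "R")):
        contra = "R" if side == "L" else "L"
        effects += [
            EdgeEffect(group, f"{side}_hippo", f"{contra}_hippo", -0.20),
            EdgeEffect(group, f"{side}_aMTG", f"{contra}_aMTG", -0.15),
            EdgeEffect(group, f"{side}_TP", f"{contra}_TP", -0.15),
            EdgeEffect(group, f"{side}_hippo", f"{contra}_SFG", -0.15),
            EdgeEffect(group, f"{side}_hippo", f"{side}_amyg", +0.15),
            EdgeEffect(group, f"{side}_pTFusC", f"{side}_aMTG", +0.12),
        ]
    defaults = dict(
        groups=[GroupSpec("LMTLE", 12), GroupSpec("RMTLE", 11),
                GroupSpec("HC", 23)],
        n_timepoints=230,
        group_edge_effects=effects,
        ar1_coefficient=0.3,
        random_seed=random_seed,
    )
    defaults.update(overrides)
    return CohortDesign(**defaults)
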