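import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hemifc import synthetic as sy
from hemifc.asymmetry import AsymmetrySettings, profile_matrix
from hemifc.atlas import default_atlas
from hemifc.connectivity import compute_connectivity
from hemifc.errors import HemifcError, InfeasibleTargetError

from conftest import make_paired_atlas


def hc_design(**kw):
    kw.setdefault("groups", [sy.GroupSpec("HC", 2)])
    return sy.CohortDesign(**kw)


def swap_pairs(m, atlas):
    """Permute the matrix by exchanging every homotopic pair."""
    ids = atlas.roi_ids
    perm = []
    for roi in atlas:
        perm.append(ids.index(roi.homotopic_partner)
                    if roi.homotopic_partner else ids.index(roi.roi_id))
    perm = np.asarray(perm)
    return m[np.ix_(perm, perm)]


class TestDesignValidation:
    def test_unknown_group_label(self):
        with pytest.raises(HemifcError):
            sy.GroupSpec("XX", 3)

    def test_nonpositive_subjects(self):
        with pytest.raises(HemifcError):
            sy.GroupSpec("HC", 0)

    def test_ar1_range(self):
        with pytest.raises(HemifcError):
            hc_design(ar1_coefficient=1.0)

    def test_ai_target_range(self):
        with pytest.raises(HemifcError):
            hc_design(asymmetry_profile={"L_r0": 250.0})

    def test_duplicate_groups(self):
        with pytest.raises(HemifcError):
            sy.CohortDesign(groups=[sy.GroupSpec("HC", 2), sy.GroupSpec("HC", 3)])


class TestPopulationCovariance:
    def test_valid_correlation_matrix(self, atlas4):
        m = sy.build_population_covariance(hc_design(), "HC", atlas4)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.linalg.eigvalsh(m).min() > -1e-10
        assert np.abs(m).max() <= 1.0 + 1e-12

    def test_homotopic_entries(self, atlas4):
        d = hc_design(homotopic_correlation=0.6)
        m = sy.build_population_covariance(d, "HC", atlas4, repair=False)
        ids = atlas4.roi_ids
        for i in range(4):
            a, b = ids.index(f"L_r{i}"), ids.index(f"R_r{i}")
            assert m[a, b] == pytest.approx(0.6)

    def test_swap_invariance_without_profile(self, atlas4):
        m = sy.build_population_covariance(hc_design(), "HC", atlas4)
        assert np.allclose(swap_pairs(m, atlas4), m)

    def test_swap_invariance_with_jitter(self, atlas4):
        d = hc_design(correlation_jitter=0.05)
        m = sy.build_population_covariance(d, "HC", atlas4)
        assert np.allclose(swap_pairs(m, atlas4), m)
        # and the jitter did break the equal-entry ties
        m0 = sy.build_population_covariance(hc_design(), "HC", atlas4)
        assert not np.allclose(m, m0)

    def test_edge_effect_additive_before_repair(self):
        atlas = default_atlas().subset(
            [f"{s}_{a}" for a in ("hippo", "SFG", "amyg", "TP") for s in "LR"])
        effect = sy.EdgeEffect("RMTLE", "R_hippo", "L_SFG", -0.2)
        d = sy.CohortDesign(groups=[sy.GroupSpec("RMTLE", 2), sy.GroupSpec("HC", 2)],
                            group_edge_effects=[effect])
        m_pat = sy.build_population_covariance(d, "RMTLE", atlas, repair=False)
        m_hc = sy.build_population_covariance(d, "HC", atlas, repair=False)
        ids = atlas.roi_ids
        i, j = ids.index("R_hippo"), ids.index("L_SFG")
        assert m_hc[i, j] - m_pat[i, j] == pytest.approx(0.2)
        off = np.ones_like(m_pat, dtype=bool)
        off[i, j] = off[j, i] = False
        assert np.allclose(m_pat[off], m_hc[off])

    def test_ai_target_plus_50_realized(self):
        # continuous-regime design: dense within blocks, sparse strong cross
        atlas = make_paired_atlas(10)
        d = hc_design(base_correlation=0.5, homotopic_correlation=0.6,
                      cross_correlation=0.05, strong_cross_correlation=0.6,
                      strong_cross_neighbors=2, repair_tolerance=0.5,
                      asymmetry_profile={"R_r3": 50.0})
        m = sy.build_population_covariance(d, "HC", atlas)
        prof = profile_matrix(m, atlas.roi_ids, atlas,
                              AsymmetrySettings()).set_index("roi_id")
        assert 48.0 <= float(prof.loc["R_r3", "AI"]) <= 52.0

    def test_ai_targets_both_signs(self):
        atlas = make_paired_atlas(10)
        targets = {"L_r1": -60.0, "L_r5": 0.0, "R_r7": 60.0}
        d = hc_design(base_correlation=0.5, homotopic_correlation=0.6,
                      cross_correlation=0.05, strong_cross_correlation=0.6,
                      strong_cross_neighbors=2, repair_tolerance=0.5,
                      asymmetry_profile=targets)
        m = sy.build_population_covariance(d, "HC", atlas)
        prof = profile_matrix(m, atlas.roi_ids, atlas,
                              AsymmetrySettings()).set_index("roi_id")
        for roi, t in targets.items():
            assert float(prof.loc[roi, "AI"]) == pytest.approx(t, abs=2.0)

    def test_infeasible_target_reports_range(self, atlas4):
        # all cross entries below threshold and capped: positive AI on an
        # L ROI beyond the reachable ceiling must raise with the range
        d = hc_design(base_correlation=0.3, homotopic_correlation=0.1,
                      cross_correlation=0.05,
                      asymmetry_profile={"L_r0": 190.0})
        with pytest.raises(InfeasibleTargetError) as exc:
            sy.build_population_covariance(d, "HC", atlas4)
        assert exc.value.achievable is not None

    def test_profile_on_midline_rejected(self, atlas5m):
        d = hc_design(asymmetry_profile={"M_m0": 10.0})
        with pytest.raises(HemifcError):
            sy.build_population_covariance(d, "HC", atlas5m)

    def test_repair_tolerance_escalation(self):
        atlas = make_paired_atlas(6)
        d = hc_design(base_correlation=0.7, homotopic_correlation=0.05,
                      cross_correlation=-0.5, repair_tolerance=1e-6,
                      repair_action="error")
        with pytest.raises(Exception):
            sy.build_population_covariance(d, "HC", atlas)


class TestSimulateCohort:
    def test_sample_correlation_converges(self):
        atlas = make_paired_atlas(3)
        d = hc_design(groups=[sy.GroupSpec("HC", 1)], n_timepoints=50_000,
                      random_seed=11)
        (subject,) = sy.simulate_cohort(d, atlas)
        conn = compute_connectivity(subject, atlas)
        pop = sy.build_population_covariance(d, "HC", atlas)
        assert np.abs(conn.r - pop).max() < 0.02

    def test_determinism_byte_identical(self, tmp_path):
        atlas = make_paired_atlas(2)
        d = hc_design(groups=[sy.GroupSpec("HC", 3)], n_timepoints=40,
                      random_seed=5)
        for sub in ("a", "b"):
            sy.write_cohort(sy.simulate_cohort(d, atlas), tmp_path / sub)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_seed_changes_output(self):
        atlas = make_paired_atlas(2)
        a = sy.simulate_cohort(hc_design(n_timepoints=30, random_seed=1), atlas)
        b = sy.simulate_cohort(hc_design(n_timepoints=30, random_seed=2), atlas)
        assert not np.allclose(a[0].data, b[0].data)

    def test_table1_cohort_composition(self):
        atlas = make_paired_atlas(2)
        design = sy.mtle_design(random_seed=3)
        # full default design targets the bundled atlas; build a light clone
        design = replace(design, group_edge_effects=[], n_timepoints=20)
        subjects = sy.simulate_cohort(design, atlas)
        assert len(subjects) == 46
        by_group = pd.Series([s.group for s in subjects]).value_counts()
        assert by_group["LMTLE"] == 12
        assert by_group["RMTLE"] == 11
        assert by_group["HC"] == 23
        for s in subjects:
            if s.group == "HC":
                assert s.onset_age is None and s.duration is None
            else:
                assert s.onset_age is not None and s.onset_age >= 0
                assert s.duration is not None and s.duration >= 0
            assert s.data.shape == (20, 4)

    def test_ar1_does_not_bias_mean_correlation(self):
        atlas = make_paired_atlas(2)
        pop = sy.build_population_covariance(hc_design(), "HC", atlas)
        means = {}
        for phi in (0.0, 0.6):
            d = hc_design(groups=[sy.GroupSpec("HC", 120)], n_timepoints=300,
                          ar1_coefficient=phi, random_seed=9)
            rs = [compute_connectivity(s, atlas).r
                  for s in sy.simulate_cohort(d, atlas)]
            means[phi] = np.mean(rs, axis=0)
        assert np.abs(means[0.0] - pop).max() < 0.03
        assert np.abs(means[0.6] - pop).max() < 0.03

    def test_ar1_increases_sampling_variance(self):
        atlas = make_paired_atlas(1)
        sds = {}
        for phi in (0.0, 0.7):
            d = hc_design(groups=[sy.GroupSpec("HC", 150)], n_timepoints=150,
                          ar1_coefficient=phi, random_seed=13)
            vals = [compute_connectivity(s, atlas).r[0, 1]
                    for s in sy.simulate_cohort(d, atlas)]
            sds[phi] = np.std(vals)
        assert sds[0.7] > 1.5 * sds[0.0]

    def test_temporal_autocorrelation_present(self):
        atlas = make_paired_atlas(1)
        d = hc_design(groups=[sy.GroupSpec("HC", 1)], n_timepoints=20_000,
                      ar1_coefficient=0.5, random_seed=21)
        (s,) = sy.simulate_cohort(d, atlas)
        x = s.data[:, 0]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.5, abs=0.03)


class TestCohortIo:
    def test_roundtrip(self, tmp_path):
        atlas = make_paired_atlas(2)
        d = sy.CohortDesign(groups=[sy.GroupSpec("LMTLE", 2), sy.GroupSpec("HC", 2)],
                            n_timepoints=25, random_seed=4)
        subjects = sy.simulate_cohort(d, atlas)
        sy.write_cohort(subjects, tmp_path)
        again = sy.load_cohort(tmp_path)
        assert [s.subject_id for s in again] == [s.subject_id for s in subjects]
        for a, b in zip(again, subjects):
            assert np.abs(a.data - b.data).max() < 1e-6    # %.6f on disk
            assert a.group == b.group
            assert (a.onset_age is None) == (b.onset_age is None)

    def test_manifest_columns(self, tmp_path):
        atlas = make_paired_atlas(1)
        subjects = sy.simulate_cohort(
            hc_design(n_timepoints=10, random_seed=1), atlas)
        out = sy.write_cohort(subjects, tmp_path)
        manifest = pd.read_csv(out / "manifest.tsv", sep="\t")
        assert list(manifest.columns) == [
            "subject_id", "group", "age", "sex", "onset_age", "duration", "file"]


class TestYamlDesign:
    def test_roundtrip_fields(self, tmp_path):
        text = """
groups:
  - {label: LMTLE, n_subjects: 3}
  - {label: HC, n_subjects: 4}
n_timepoints: 60
base_correlation: 0.4
homotopic_correlation: 0.5
cross_correlation: 0.2
ar1_coefficient: 0.25
random_seed: 42
asymmetry_profile: {L_r0: -30}
group_edge_effects:
  - {group: LMTLE, roi_a: L_r0, roi_b: R_r1, delta: -0.15}
clinical_model:
  LMTLE:
    age: {mean: 25.0, sd: 4.0}
    male_fraction: 0.7
    onset_age: {mean: 16.0, sd: 8.0}
    duration: {mean: 12.0, sd: 8.0}
  HC:
    age: {mean: 30.0, sd: 9.0}
    male_fraction: 0.5
"""
        p = tmp_path / "design.yaml"
        p.write_text(text)
        d = sy.design_from_yaml(p)
        assert d.n_timepoints == 60
        assert d.random_seed == 42
        assert d.asymmetry_profile == {"L_r0": -30.0}
        assert d.group_edge_effects[0].delta == -0.15
        assert d.clinical_model["LMTLE"].onset_age.mean == 16.0
        assert d.clinical_model["HC"].onset_age is None


class TestTypeICalibrationReduced:
    def test_paired_t_rejects_near_alpha(self):
        # reduced version of the full calibration criterion (see acceptance):
        # symmetric null design, 200 cohorts
        from hemifc.asymmetry import cohort_long_table, profile_cohort
        from hemifc.errors import DegenerateInputError
        from hemifc.stats import paired_t
        atlas = make_paired_atlas(5)
        base = hc_design(groups=[sy.GroupSpec("HC", 12)], n_timepoints=200,
                         base_correlation=0.45, homotopic_correlation=0.0,
                         cross_correlation=0.45)
        rej = tot = 0
        for rep in range(200):
            d = replace(base, random_seed=rep)
            conns = [compute_connectivity(s, atlas)
                     for s in sy.simulate_cohort(d, atlas)]
            tab = cohort_long_table(profile_cohort(conns, atlas))
            for _, sub in tab.groupby("roi_id"):
                try:
                    _, _, p = paired_t(sub["rFC"].to_numpy(),
                                       sub["lFC"].to_numpy())
                except DegenerateInputError:
                    continue
                rej += p < 0.05
                tot += 1
        assert 0.02 <= rej / tot <= 0.08
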