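"""Generator contracts: determinism, planted structure, invariants, I/O."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hemiconn.connectome import cortical_subgraph, hemisphere_blocks
from hemiconn.io import read_cohort
from hemiconn.metrics import commissural_ratio
from hemiconn.synthetic import (CohortConfig, SyntheticCohort, generate_cohort,
                                write_cohort)

RECORD_COLUMNS = ["center", "age", "sex", "diagnosis", "edss", "sdmt",
                  "disease_duration", "gmf", "wmf", "lvf", "cc_area",
                  "brain_volume"]


def measured_commissural(cohort):
    out = []
    for c in cohort.connectomes:
        _, _, inter, total = hemisphere_blocks(cortical_subgraph(c))
        out.append(commissural_ratio(inter, total))
    return np.array(out)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = CohortConfig(n_subjects=25, seed=11)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.records.equals(b.records)
        assert a.ground_truth == b.ground_truth
        for ca, cb in zip(a.connectomes, b.connectomes):
            assert np.array_equal(ca.weights, cb.weights)
            assert np.array_equal(ca.lengths, cb.lengths)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_subjects=10, seed=1))
        b = generate_cohort(CohortConfig(n_subjects=10, seed=2))
        assert not np.array_equal(a.connectomes[0].weights,
                                  b.connectomes[0].weights)


class TestConnectomeInvariants:
    def test_matrices_valid(self):
        cohort = generate_cohort(CohortConfig(n_subjects=12, seed=3))
        for c in cohort.connectomes:
            c.validate()  # symmetry, non-negativity, zero diagonal, lengths
            assert np.all(c.lengths[c.weights > 0] > 0)

    def test_streamline_budget_conserved(self):
        # exact conservation requires site effects off (center scales
        # multiply the weight blocks otherwise)
        cfg = CohortConfig(n_subjects=8, seed=4, site_shift_sd=0,
                           site_scale_sd=0, total_streamlines=10_000)
        cohort = generate_cohort(cfg)
        for c in cohort.connectomes:
            total = c.weights.sum() / 2
            assert abs(total - 10_000) <= 0.001 * 10_000

    def test_hemisphere_graphs_connected(self):
        from hemiconn.connectome import normalize_by_length, to_distance_graph
        from hemiconn.metrics import path_stats
        cohort = generate_cohort(CohortConfig(n_subjects=6, seed=5))
        for c in cohort.connectomes:
            cc = cortical_subgraph(normalize_by_length(c))
            left, right, _, _ = hemisphere_blocks(cc)
            assert path_stats(to_distance_graph(left)).n_unreachable == 0
            assert path_stats(to_distance_graph(right)).n_unreachable == 0


class TestPlantedStructure:
    def test_conservation_coupling_monte_carlo(self):
        """Planted rho=-0.4: corr(p_inter, intra strength) in [-0.5, -0.3]."""
        cfg = CohortConfig(n_subjects=500, seed=21, conservation_coupling=-0.4)
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth["subjects"]
        p = np.array([gt[i]["p_inter"] for i in cohort.records.index])
        f = np.array([gt[i]["intra_strength"] for i in cohort.records.index])
        r = np.corrcoef(p, f)[0, 1]
        assert -0.5 < r < -0.3

    def test_no_disease_effect_null(self):
        """disease_effect_inter=0: group difference < 2 SE, 20-seed average."""
        ts = []
        for seed in range(20):
            cfg = CohortConfig(n_subjects=400, seed=seed, disease_effect_inter=0,
                               site_shift_sd=0, site_scale_sd=0)
            cohort = generate_cohort(cfg)
            comm = measured_commissural(cohort)
            ms = (cohort.records["diagnosis"] == "MS").to_numpy()
            t, _ = sps.ttest_ind(comm[~ms], comm[ms])
            ts.append(t)
        assert abs(np.mean(ts)) < 2 / np.sqrt(len(ts))

    def test_disease_lowers_interhemispheric_share(self):
        cfg = CohortConfig(n_subjects=400, seed=0, site_shift_sd=0,
                           site_scale_sd=0)
        cohort = generate_cohort(cfg)
        comm = measured_commissural(cohort)
        ms = (cohort.records["diagnosis"] == "MS").to_numpy()
        t, p = sps.ttest_ind(comm[~ms], comm[ms])
        assert t > 0 and p < 0.01

    def test_site_effects_drive_center_anova(self):
        """Raw commissural ratio differs by center iff site effects are on.

        Fisher-combined over 5 seeds: p < 0.01 with defaults, > 0.05 with
        site effects disabled.
        """
        for shift, scale, check in ((None, None, "on"), (0.0, 0.0, "off")):
            ps = []
            for seed in range(5):
                kwargs = dict(n_subjects=400, seed=seed)
                if shift is not None:
                    kwargs.update(site_shift_sd=shift, site_scale_sd=scale)
                cohort = generate_cohort(CohortConfig(**kwargs))
                comm = measured_commissural(cohort)
                centers = cohort.records["center"].to_numpy()
                groups = [comm[centers == c] for c in np.unique(centers)]
                ps.append(sps.f_oneway(*groups).pvalue)
            stat = -2 * np.sum(np.log(ps))
            p_comb = sps.chi2.sf(stat, 2 * len(ps))
            if check == "on":
                assert p_comb < 0.01
            else:
                assert p_comb > 0.05


class TestClinicalScales:
    def test_edss_half_point_grid(self):
        cohort = generate_cohort(CohortConfig(n_subjects=120, seed=6))
        ms = cohort.records["diagnosis"] == "MS"
        edss = cohort.records.loc[ms, "edss"]
        assert edss.notna().all()
        assert np.allclose(edss * 2, np.round(edss * 2))
        assert edss.between(0, 10).all()
        assert cohort.records.loc[~ms, "edss"].isna().all()

    def test_sdmt_integer_nonnegative(self):
        cohort = generate_cohort(CohortConfig(n_subjects=120, seed=7))
        sdmt = cohort.records.loc[cohort.records["diagnosis"] == "MS", "sdmt"]
        assert np.allclose(sdmt, np.round(sdmt))
        assert (sdmt >= 0).all()

    def test_proportions_in_unit_interval(self):
        cohort = generate_cohort(CohortConfig(n_subjects=80, seed=8))
        for col in ("gmf", "wmf", "lvf"):
            assert cohort.records[col].between(0, 1).all()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"ms_fraction": 0.0},
        {"ms_fraction": float("nan")},
        {"conservation_coupling": -1.5},
        {"site_scale_sd": -0.1},
        {"n_subjects": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs).validate()

    def test_no_patients_rejected(self):
        with pytest.raises(ValueError, match="no patients"):
            CohortConfig(n_subjects=2, ms_fraction=0.01).validate()


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=5, seed=9))
        write_cohort(cohort, tmp_path)
        conns, records, gt, errors = read_cohort(tmp_path)
        assert not errors
        pd.testing.assert_frame_equal(records, cohort.records)
        assert gt == cohort.ground_truth
        for a, b in zip(conns, cohort.connectomes):
            assert np.array_equal(a.weights, b.weights)
            assert np.array_equal(a.lengths, b.lengths)
            assert a.labels == b.labels

    def test_subject_table_schema(self, tmp_path):
        cohort = generate_cohort(CohortConfig(n_subjects=3, seed=10))
        write_cohort(cohort, tmp_path)
        header = (tmp_path / "subjects.csv").read_text().splitlines()[0]
        assert header.split(",") == ["id"] + RECORD_COLUMNS

    def test_empty_cohort(self, tmp_path):
        empty = SyntheticCohort(
            connectomes=[],
            records=pd.DataFrame(columns=RECORD_COLUMNS,
                                 index=pd.Index([], name="id")),
            ground_truth={})
        manifest = write_cohort(empty, tmp_path)
        assert manifest["n_subjects"] == 0
        conns, records, _, errors = read_cohort(tmp_path)
        assert conns == [] and len(records) == 0 and not errors
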