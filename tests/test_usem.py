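"""Unified SEM estimation and the group-iterative path search."""

import numpy as np
import pytest

from dmnstab import synth, usem
from dmnstab.roiglm import ROITimeSeries
from dmnstab.usem import (
    Structure,
    SubjectData,
    extract_ar,
    fit_structure,
    fit_usem,
    group_search,
    individual_search,
    score_candidates,
    structure_from_names,
)

P = 10


def _sim(a, phi_diag, t, seed, missing=None):
    return synth.simulate_network_timeseries(
        a, np.diag(phi_diag), 1.0, t, burn_in=50, missing_pattern=missing, seed=seed
    )


def _datasets(a, phi_diag, n_subjects, t, seed0):
    rng = np.random.default_rng(seed0)
    return [
        SubjectData.from_timeseries(_sim(a, phi_diag, t, rng), f"S{j:03d}")
        for j in range(n_subjects)
    ]


class TestFit:
    def test_null_structure_equals_per_roi_lag1_ols(self):
        ts = _sim(np.zeros((P, P)), [0.5] * P, 500, seed=1)
        fit = fit_usem(ts)
        vals = ts.values - ts.values.mean(axis=1, keepdims=True)
        for r in range(P):
            x, y = vals[r, :-1], vals[r, 1:]
            slope = (x @ y) / (x @ x)
            assert fit.phi[r, r] == pytest.approx(slope, abs=1e-6)
            resid = y - slope * x
            assert fit.zeta_var[r] == pytest.approx(resid @ resid / len(y), abs=1e-6)

    def test_recovery_of_contemporaneous_and_ar_paths(self):
        a = np.zeros((P, P))
        a[2, 1] = 0.5
        ts = _sim(a, [0.4] * P, 2000, seed=2)
        fit = fit_usem(ts, structure_from_names([("PCC", "L_dSFG")]))
        assert fit.a[2, 1] == pytest.approx(0.5, abs=0.05)
        assert np.allclose(np.diag(fit.phi), 0.4, atol=0.05)
        assert fit.se_a[2, 1] > 0

    def test_cyclic_structure_fits_reciprocal_truth(self):
        a = np.zeros((P, P))
        a[1, 0], a[0, 1] = 0.4, -0.3
        ts = _sim(a, [0.3] * P, 2000, seed=3)
        st = Structure(p=P, contemporaneous=frozenset({(0, 1), (1, 0)}))
        fit = fit_usem(ts, st)
        assert fit.method == "ml"
        assert fit.a[1, 0] == pytest.approx(0.4, abs=0.05)
        assert fit.a[0, 1] == pytest.approx(-0.3, abs=0.05)
        assert np.allclose(np.diag(fit.phi), 0.3, atol=0.05)

    def test_missing_volume_excludes_only_touching_pairs(self):
        ts_full = _sim(np.zeros((P, P)), [0.4] * P, 300, seed=4)
        ts_hole = ts_full.with_missing([50])
        fit_hole = fit_usem(ts_hole)
        # oracle: delete the two pairs touching volume 50 by hand
        vals = ts_full.values - ts_full.values[:, ~ts_hole.missing_mask].mean(
            axis=1, keepdims=True
        )
        keep = np.ones(299, bool)
        keep[[49, 50]] = False  # pairs (49,50) and (50,51)
        for r in range(P):
            x = vals[r, :-1][keep]
            y = vals[r, 1:][keep]
            slope = (x @ y) / (x @ x)
            assert fit_hole.phi[r, r] == pytest.approx(slope, abs=1e-10)
        assert fit_hole.n_effective_pairs == 297

    def test_structure_dimension_mismatch_rejected(self):
        ts = synth.simulate_network_timeseries(
            np.zeros((3, 3)), np.diag([0.3] * 3), 1.0, 100, seed=5,
            roi_names=("a", "b", "c"),
        )
        with pytest.raises(ValueError):
            fit_usem(ts, Structure(p=10))

    def test_low_pair_count_warns(self):
        ts = _sim(np.zeros((P, P)), [0.3] * P, 60, seed=6)
        with pytest.warns(UserWarning, match="usable pairs"):
            fit_usem(ts)


class TestScoring:
    def test_existing_paths_are_not_candidates(self):
        st = structure_from_names([("mPFC", "PCC")], [("PCC", "mPFC")])
        cands = st.candidates(True)
        assert ("contemporaneous", 0, 1) not in cands
        assert ("lagged", 1, 0) not in cands
        assert ("contemporaneous", 1, 0) in cands

    def test_null_calibration_of_path_tests(self):
        """On white noise the per-subject rejection rate of any fixed
        path approximates the test level."""
        rng = np.random.default_rng(7)
        hits = {}
        n_rep = 400
        for _ in range(n_rep):
            ts = _sim(np.zeros((P, P)), [0.0] * P, 200, rng)
            data = SubjectData.from_timeseries(ts, "s")
            scores = usem._score_subject(data, Structure(p=P), True)
            for key, entry in scores.items():
                hits[key] = hits.get(key, 0) + (entry[1] < 0.05)
        fracs = np.array(list(hits.values())) / n_rep
        assert abs(fracs.mean() - 0.05) < 0.02
        assert np.all(np.abs(fracs - 0.05) < 0.05)

    def test_strong_true_path_detected_per_subject(self):
        a = np.zeros((P, P))
        a[3, 2] = 0.6
        rng = np.random.default_rng(8)
        detected = 0
        n_rep = 60
        for _ in range(n_rep):
            ts = _sim(a, [0.3] * P, 200, rng)
            data = SubjectData.from_timeseries(ts, "s")
            scores = usem._score_subject(data, Structure(p=P), True)
            detected += scores[("contemporaneous", 2, 3)][1] < 0.05
        assert detected >= 0.95 * n_rep

    def test_reverse_edge_test_is_calibrated(self):
        """The joint (Jacobian-coupled) route: testing the reverse of a
        true path must reject at roughly the nominal level."""
        a = np.zeros((P, P))
        a[1, 0] = 0.4
        st = structure_from_names([("mPFC", "PCC")])
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            ts = _sim(a, [0.4] * P, 200, rng)
            data = SubjectData.from_timeseries(ts, "s")
            scores = usem._score_subject(data, st, False)
            hits += scores[("contemporaneous", 1, 0)][1] < 0.05
        assert abs(hits / n_rep - 0.05) < 0.05

    def test_score_candidates_table_shape(self):
        datasets = _datasets(np.zeros((P, P)), [0.4] * P, 3, 150, seed0=10)
        table = score_candidates(datasets, Structure(p=P))
        assert set(table["subject_id"]) == {"S000", "S001", "S002"}
        assert len(table) == 3 * 2 * P * (P - 1)
        assert table["pvalue"].between(0, 1).all()


class TestGroupSearch:
    def test_shared_path_recovered(self):
        a = np.zeros((P, P))
        a[3, 2] = 0.4
        found = 0
        for rep in range(3):
            datasets = _datasets(a, [0.4] * P, 20, 200, seed0=20 + rep)
            res = group_search(datasets)
            found += ("contemporaneous", 2, 3) in res.structure.paths()
        assert found == 3

    def test_white_noise_gives_empty_group_model(self):
        datasets = _datasets(np.zeros((P, P)), [0.0] * P, 12, 200, seed0=30)
        res = group_search(datasets)
        assert res.structure.paths() == []

    def test_subthreshold_prevalence_path_not_added(self):
        """A path present in 60% of subjects stays out of the group model;
        present in 100% it always enters."""
        a = np.zeros((P, P))
        a[3, 2] = 0.5
        rng = np.random.default_rng(31)
        n_sub = 30
        datasets_60, datasets_100 = [], []
        for j in range(n_sub):
            a_j = a if j < int(0.6 * n_sub) else np.zeros((P, P))
            datasets_60.append(
                SubjectData.from_timeseries(_sim(a_j, [0.4] * P, 200, rng), f"A{j}")
            )
            datasets_100.append(
                SubjectData.from_timeseries(_sim(a, [0.4] * P, 200, rng), f"B{j}")
            )
        res60 = group_search(datasets_60)
        res100 = group_search(datasets_100)
        assert ("contemporaneous", 2, 3) not in res60.structure.paths()
        assert ("contemporaneous", 2, 3) in res100.structure.paths()

    def test_search_steps_increase_every_subjects_loglik(self):
        a = np.zeros((P, P))
        a[3, 2] = 0.4
        datasets = _datasets(a, [0.4] * P, 10, 200, seed0=32)
        res = group_search(datasets)
        null = Structure(p=P)
        for data in datasets:
            ll0 = fit_structure(data, null).loglik
            ll1 = fit_structure(data, res.structure).loglik
            assert ll1 > ll0

    def test_edge_list_labels(self):
        a = np.zeros((P, P))
        a[1, 0] = 0.5
        datasets = _datasets(a, [0.4] * P, 8, 300, seed0=33)
        res = group_search(datasets)
        edges = res.edge_list()
        assert {"kind", "source", "target"} <= set(edges.columns)
        if len(edges):
            assert edges.iloc[0]["source"] in res.roi_names


class TestIndividualSearch:
    def test_null_subject_gets_no_individual_paths(self):
        a = np.zeros((P, P))
        a[1, 0] = 0.4
        group = structure_from_names([("mPFC", "PCC")])
        rng = np.random.default_rng(40)
        clean = 0
        n_rep = 60
        for _ in range(n_rep):
            ts = _sim(a, [0.4] * P, 250, rng)
            res = individual_search(
                SubjectData.from_timeseries(ts, "s"), group
            )
            clean += len(res.individual_paths) == 0
        assert clean >= 0.9 * n_rep

    def test_private_path_recovered_and_kept_out_of_group(self):
        a_group = np.zeros((P, P))
        a_group[1, 0] = 0.4
        a_special = a_group.copy()
        a_special[7, 6] = 0.5
        rng = np.random.default_rng(41)
        datasets = []
        for j in range(20):
            a_j = a_special if j == 0 else a_group
            datasets.append(
                SubjectData.from_timeseries(_sim(a_j, [0.4] * P, 250, rng), f"S{j:03d}")
            )
        group = group_search(datasets)
        assert ("contemporaneous", 6, 7) not in group.structure.paths()
        res = individual_search(datasets[0], group.structure)
        assert ("contemporaneous", 6, 7) in res.individual_paths

    def test_group_paths_survive_individual_pruning(self):
        group = structure_from_names([("mPFC", "PCC"), ("PCC", "L_AG")])
        # white-noise subject: both group paths are individually useless
        ts = _sim(np.zeros((P, P)), [0.0] * P, 250, seed=42)
        res = individual_search(SubjectData.from_timeseries(ts, "s"), group)
        for path in group.paths():
            assert path in res.structure.paths()


class TestExtraction:
    def test_ar_vector_contract_and_accuracy(self):
        ts = _sim(np.zeros((P, P)), [0.7] * P, 2000, seed=50)
        fit = fit_usem(ts)
        ar = extract_ar({"S001": fit})
        assert list(ar.columns) == list(ts.roi_names)
        assert ar.shape == (1, 10)
        assert np.allclose(ar.loc["S001"], 0.7, atol=0.05)

    def test_white_noise_ar_near_zero(self):
        ts = _sim(np.zeros((P, P)), [0.0] * P, 2000, seed=51)
        ar = extract_ar({"s": fit_usem(ts)})
        assert np.all(np.abs(ar.to_numpy()) < 0.06)

    def test_empty_fits_rejected(self):
        with pytest.raises(ValueError):
            extract_ar({})


def test_permutation_equivariance():
    """Relabeling ROIs permutes every output consistently."""
    a = np.zeros((P, P))
    a[2, 1] = 0.5
    a[7, 3] = -0.4
    ts = _sim(a, np.linspace(0.2, 0.6, P), 600, seed=60)
    st = Structure(p=P, contemporaneous=frozenset({(1, 2), (3, 7)}))
    fit = fit_usem(ts, st, compute_se=False)

    perm = np.random.default_rng(0).permutation(P)
    inv = np.argsort(perm)
    names_p = tuple(np.array(ts.roi_names)[perm])
    ts_p = ROITimeSeries(ts.values[perm], ts.missing_mask, 2.0, names_p)
    st_p = Structure(
        p=P, contemporaneous=frozenset((inv[s], inv[d]) for s, d in {(1, 2), (3, 7)})
    )
    fit_p = fit_usem(ts_p, st_p, compute_se=False)
    assert np.allclose(fit_p.a, fit.a[np.ix_(perm, perm)], atol=1e-10)
    assert np.allclose(fit_p.phi, fit.phi[np.ix_(perm, perm)], atol=1e-10)
    assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-8)


def test_group_recovery_error_under_study_conditions():
    """At T = 300, N = 25, 3 shared contemporaneous paths + AR diagonals,
    the median absolute estimation error over true paths stays small."""
    from dmnstab.config import TruthConfig
    from dmnstab.synth import contemporaneous_template

    truth = TruthConfig()
    a = contemporaneous_template(truth.group_contemporaneous)
    errs = []
    rng = np.random.default_rng(61)
    for rep in range(4):
        phi = rng.uniform(0.4, 0.7, P)
        datasets = [
            SubjectData.from_timeseries(_sim(a, phi, 300, rng), f"S{j}")
            for j in range(25)
        ]
        res = group_search(datasets)
        true_paths = [(0, 1), (1, 8), (1, 9)]  # template edges, (src, dst)
        for data in datasets:
            fit = fit_structure(data, res.structure)
            errs.extend(
                abs(fit.a[dst, src] - a[dst, src]) for src, dst in true_paths
            )
            errs.extend(np.abs(np.diag(fit.phi) - phi))
    assert np.median(errs) < 0.08
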