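"""Grid search, cross-validation and the component sweep."""

import numpy as np
import pytest

from kann import (
    KannParams,
    Scenario,
    cross_validate,
    component_sweep,
    estimate_profiles,
    evaluate,
    grid_search,
    make_folds,
    simulate,
    SimConfig,
    threshold_to_discrete,
)
from kann.io import ProfileMatrix

from conftest import make_components, make_profiles, random_simplex


def naive_cross_validate(components, profiles, folds, params):
    """Independent per-fold loop: estimate each fold against the rest."""
    ids = list(profiles.sample_ids)
    est_rows, est_ids = [], []
    for f in range(folds.n_folds):
        q = [s for s in ids if folds.fold_of[s] == f]
        r = [s for s in ids if folds.fold_of[s] != f]
        est = estimate_profiles(
            components.subset(q), components.subset(r),
            profiles.reindex(r), params,
        )
        est_ids.extend(est.sample_ids)
        est_rows.append(est.proportions)
    combined = ProfileMatrix(
        tuple(est_ids), profiles.population_labels, np.vstack(est_rows)
    )
    return evaluate(combined, profiles)


def _clustered_data(rng, n=60, m=3, s=3, spread=0.3):
    """Well-separated clusters with one-hot truth."""
    centers = np.eye(s, m) * 10
    labels = np.repeat(np.arange(s), n // s)
    scores = centers[labels] + rng.normal(0, spread, size=(len(labels), m))
    one_hot = np.zeros((len(labels), s))
    one_hot[np.arange(len(labels)), labels] = 1.0
    cm = make_components(scores, np.ones(m))
    pm = make_profiles(one_hot)
    return cm, pm


class TestMakeFolds:
    def test_n_equals_f_gives_singletons(self):
        fa = make_folds([f"s{i}" for i in range(10)], 10, seed=1)
        sizes = [len(fa.members(f)) for f in range(10)]
        assert sizes == [1] * 10

    def test_fold_sizes_differ_by_at_most_one(self):
        fa = make_folds([f"s{i}" for i in range(10)], 3, seed=1)
        sizes = sorted(len(fa.members(f)) for f in range(3))
        assert sizes == [3, 3, 4]

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(25)]
        assert make_folds(ids, 5, 42).fold_of == make_folds(ids, 5, 42).fold_of

    def test_partitions_the_id_set(self):
        ids = [f"s{i}" for i in range(17)]
        fa = make_folds(ids, 4, 0)
        assert sorted(fa.fold_of) == sorted(ids)
        assert set(fa.fold_of.values()) == set(range(4))

    @pytest.mark.parametrize("f", [1, 11])
    def test_out_of_range_fold_count_rejected(self, f):
        with pytest.raises(ValueError):
            make_folds([f"s{i}" for i in range(10)], f, 0)


class TestCrossValidate:
    def test_two_folds_k1_uses_other_fold_nearest(self, rng):
        cm = make_components([[0.0], [0.1], [5.0], [5.1]], [1.0])
        pm = make_profiles([[1, 0], [0.9, 0.1], [0, 1], [0.1, 0.9]])
        folds = make_folds(cm.sample_ids, 2, seed=0)
        params = KannParams(k=1, p=0.0, n_components=1)
        out = cross_validate(cm, pm, folds, params)
        # every estimate equals the nearest other-fold reference's profile
        by_id = dict(zip(pm.sample_ids, pm.proportions))
        scores = dict(zip(cm.sample_ids, cm.scores[:, 0]))
        for sid, est_row in zip(out.sample_ids, range(len(out.sample_ids))):
            others = [s for s in pm.sample_ids
                      if folds.fold_of[s] != folds.fold_of[sid]]
            nearest = min(others, key=lambda s: (abs(scores[s] - scores[sid]),
                                                 s))
            # per-sample TVD to truth equals TVD(nearest profile, truth)
            expected = 0.5 * np.abs(by_id[nearest] - by_id[sid]).sum()
            assert out.per_sample_tvd[est_row] == pytest.approx(
                expected, abs=1e-12
            )

    def test_matches_naive_per_fold_loop(self, rng):
        data = simulate(SimConfig(n_reference=120, n_query=1, seed=7))
        folds = make_folds(data.reference.sample_ids, 5, seed=3)
        params = KannParams(k=10, p=3.0, n_components=6)
        a = cross_validate(data.reference, data.reference_profiles, folds,
                           params)
        b = naive_cross_validate(data.reference, data.reference_profiles,
                                 folds, params)
        assert a.mean_tvd == pytest.approx(b.mean_tvd, abs=1e-12)
        np.testing.assert_allclose(
            np.sort(a.per_sample_tvd), np.sort(b.per_sample_tvd), atol=1e-12
        )

    def test_infeasible_k_names_fold(self, rng):
        cm = make_components(rng.normal(size=(6, 2)), np.ones(2))
        pm = make_profiles(random_simplex(rng, 6, 2))
        folds = make_folds(cm.sample_ids, 2, seed=0)
        with pytest.raises(ValueError, match="fold"):
            cross_validate(cm, pm, folds, KannParams(k=5, n_components=2))


class TestGridSearch:
    def test_single_cell_grid_is_best(self, rng):
        cm, pm = _clustered_data(rng)
        ref_ids = cm.sample_ids[::2]
        qry_ids = tuple(s for s in cm.sample_ids if s not in set(ref_ids))
        scn = Scenario("CONTINUOUS", ref_ids, qry_ids, pm)
        res = grid_search(scn, cm, pm, [3], [2.0],
                          KannParams(k=1, n_components=3))
        assert res.best == (3, 2.0)
        assert len(res.cells) == 1

    def test_k1_beats_global_mean_on_separated_clusters(self, rng):
        cm, pm = _clustered_data(rng)
        ref_ids = cm.sample_ids[::2]
        qry_ids = tuple(s for s in cm.sample_ids if s not in set(ref_ids))
        scn = Scenario("DISCRETE", ref_ids, qry_ids, pm)
        n_r = len(ref_ids)
        res = grid_search(scn, cm, pm, [1, n_r], [0.0],
                          KannParams(k=1, n_components=3))
        assert res.best == (1, 0.0)
        cell_max = next(c for c in res.cells if c.k == n_r)
        assert res.best_cell.mean_tvd < cell_max.mean_tvd

    def test_duplicate_cells_deduplicated_with_warning(self, rng):
        cm, pm = _clustered_data(rng)
        ref_ids = cm.sample_ids[::2]
        qry_ids = tuple(s for s in cm.sample_ids if s not in set(ref_ids))
        scn = Scenario("CONTINUOUS", ref_ids, qry_ids, pm)
        with pytest.warns(UserWarning, match="duplicate"):
            res = grid_search(scn, cm, pm, [3, 3], [1.0],
                              KannParams(k=1, n_components=3))
        assert len(res.cells) == 1

    def test_infeasible_k_marked_skipped_not_dropped(self, rng):
        cm, pm = _clustered_data(rng)
        ref_ids = cm.sample_ids[::2]
        qry_ids = tuple(s for s in cm.sample_ids if s not in set(ref_ids))
        scn = Scenario("CONTINUOUS", ref_ids, qry_ids, pm)
        res = grid_search(scn, cm, pm, [1, 10_000], [0.0],
                          KannParams(k=1, n_components=3))
        skipped = [c for c in res.cells if c.skipped]
        assert len(skipped) == 1 and skipped[0].k == 10_000
        assert skipped[0].reason

    def test_empty_grid_rejected(self, rng):
        cm, pm = _clustered_data(rng)
        scn = Scenario("CONTINUOUSALL", cm.sample_ids, (), pm)
        with pytest.raises(ValueError, match="empty"):
            grid_search(scn, cm, pm, [], [],
                        KannParams(k=1, n_components=3))

    def test_best_is_argmin_over_computed_cells(self, rng):
        data = simulate(SimConfig(n_reference=100, n_query=40, seed=11))
        scn = Scenario(
            "CONTINUOUS", data.reference.sample_ids, data.query.sample_ids,
            data.reference_profiles,
        )
        all_scores = np.vstack([data.reference.scores, data.query.scores])
        cm = data.reference.__class__(
            data.reference.sample_ids + data.query.sample_ids,
            all_scores, data.reference.eigenvalues,
        )
        truth = ProfileMatrix(
            data.reference_profiles.sample_ids
            + data.query_profiles.sample_ids,
            data.query_profiles.population_labels,
            np.vstack([data.reference_profiles.proportions,
                       data.query_profiles.proportions]),
        )
        res = grid_search(scn, cm, truth, [1, 10, 100], [0.0, 3.0],
                          KannParams(k=1, n_components=6))
        usable = [c for c in res.cells if not c.skipped]
        best = min(usable, key=lambda c: (c.mean_tvd, c.k, c.p))
        assert res.best == (best.k, best.p)

    def test_continuousall_requires_folds(self, rng):
        cm, pm = _clustered_data(rng)
        scn = Scenario("CONTINUOUSALL", cm.sample_ids, (), pm)
        with pytest.raises(ValueError, match="folds"):
            grid_search(scn, cm, pm, [1], [0.0],
                        KannParams(k=1, n_components=3))

    def test_discrete_scenario_rejects_continuous_profiles(self, rng):
        cm, _ = _clustered_data(rng)
        soft = make_profiles(random_simplex(rng, cm.n_samples, 3))
        with pytest.raises(ValueError, match="one-hot"):
            Scenario("DISCRETE", cm.sample_ids[:10], cm.sample_ids[10:20],
                     soft)


class TestComponentSweep:
    def test_single_m_reduces_to_one_grid_search(self, rng):
        cm, pm = _clustered_data(rng)
        ref_ids = cm.sample_ids[::2]
        qry_ids = tuple(s for s in cm.sample_ids if s not in set(ref_ids))
        scn = Scenario("CONTINUOUS", ref_ids, qry_ids, pm)
        sweep = component_sweep(scn, cm, pm, [3], [1, 5], [0.0, 3.0],
                                KannParams(k=1, n_components=3))
        direct = grid_search(scn, cm, pm, [1, 5], [0.0, 3.0],
                             KannParams(k=1, n_components=3))
        assert sweep == [(3, direct.best_cell.mean_tvd)]

    def test_m_zero_rejected(self, rng):
        cm, pm = _clustered_data(rng)
        scn = Scenario("CONTINUOUSALL", cm.sample_ids, (), pm)
        with pytest.raises(ValueError, match="out of range"):
            component_sweep(scn, cm, pm, [0], [1], [0.0],
                            KannParams(k=1, n_components=3),
                            make_folds(cm.sample_ids, 2, 0))


class TestReferenceStyleTrends:
    def test_continuous_references_beat_discretized_ones(self):
        """Continuous reference profiles should give lower mean TVD than
        their argmax-thresholded (majority-population) one-hot versions on
        the same samples, at matched (k, p), in a large majority of
        simulation seeds."""
        wins = 0
        seeds = range(10)
        for seed in seeds:
            data = simulate(SimConfig(
                n_reference=300, n_query=100, seed=seed,
            ))
            params = KannParams(k=25, p=3.0, n_components=6)
            cont = evaluate(
                estimate_profiles(data.query, data.reference,
                                  data.reference_profiles, params),
                data.query_profiles,
            ).mean_tvd
            disc = evaluate(
                estimate_profiles(
                    data.query, data.reference,
                    threshold_to_discrete(data.reference_profiles), params,
                ),
                data.query_profiles,
            ).mean_tvd
            wins += cont <= disc
        assert wins >= 8

    def test_weighting_matters_at_maximal_k(self):
        """At k = n_R, distance weighting (p=3) should beat the unweighted
        global mean (p=0) in a large majority of seeds."""
        wins = 0
        for seed in range(10):
            data = simulate(SimConfig(
                n_reference=300, n_query=100, seed=seed,
            ))
            tvds = {}
            for p in (0.0, 3.0):
                params = KannParams(k=300, p=p, n_components=6)
                tvds[p] = evaluate(
                    estimate_profiles(data.query, data.reference,
                                      data.reference_profiles, params),
                    data.query_profiles,
                ).mean_tvd
            wins += tvds[3.0] <= tvds[0.0]
        assert wins >= 8
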