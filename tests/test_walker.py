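"""The triple-layer propagation against hand computations and a naive oracle."""

import numpy as np
import pytest

from triwalk import (
    AssociationTable,
    EntityUniverse,
    SimilarityMatrix,
    WalkConfig,
    init_priors,
    predict,
    walk_iterate,
    run_walk,
)
from triwalk.negatives import credible_negative_scores, select_negatives


def brute_force_walk(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg):
    """Per-entry triple-loop re-implementation of the update equations."""
    a = cfg.alpha
    sm, md = SM0.astype(float).copy(), MD0.astype(float).copy()
    M, N = sm.shape
    Z = md.shape[1]
    for t in range(1, cfg.n_iterations + 1):
        sm_prev, md_prev = sm.copy(), md.copy()
        new_sm = np.zeros_like(sm)
        for i in range(M):
            for j in range(N):
                if t <= cfg.l1:
                    s1 = a * sum(Ss[i, l] * sm_prev[l, j] for l in range(M)) + (1 - a) * Bp[i, j]
                    s2 = sum(SD[i, z] * md_prev[j, z] for z in range(Z))
                    new_sm[i, j] = (s1 + s2) / 2.0
                else:
                    new_sm[i, j] = (
                        a * sum(sm_prev[i, k] * Sm[k, j] for k in range(N))
                        + (1 - a) * Bp[i, j]
                    )
        new_md = np.zeros_like(md)
        for j in range(N):
            for z in range(Z):
                if t <= cfg.l2:
                    m1 = a * sum(Sm[j, k] * md_prev[k, z] for k in range(N)) + (1 - a) * Cp[j, z]
                    m2 = sum(sm_prev[i, j] * SD[i, z] for i in range(M))
                    new_md[j, z] = (m1 + m2) / 2.0
                else:
                    new_md[j, z] = (
                        a * sum(md_prev[j, w] * Sd[w, z] for w in range(Z))
                        + (1 - a) * Cp[j, z]
                    )
        sm, md = new_sm, new_md
    return sm, md


def _random_similarity(n, rng):
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2.0
    np.fill_diagonal(sym, 1.0)
    return sym


class TestHandWorked:
    def _toy(self):
        Bp = np.array([[1.0, 0.0], [0.0, 0.0]])
        Cp = np.array([[1.0], [0.0]])
        SD = np.zeros((2, 1))
        I2, I1 = np.eye(2), np.eye(1)
        return Bp, Cp, SD, I2, I1

    def test_two_by_two_single_iteration(self):
        Bp, Cp, SD, I2, I1 = self._toy()
        cfg = WalkConfig(alpha=0.4, l1=1, r1=1, l2=1, r2=1)
        scores = walk_iterate(Bp, Cp, I2, I2, I1, SD, Bp, Cp, cfg)
        assert np.allclose(scores.SM, [[0.5, 0.0], [0.0, 0.0]])
        assert np.allclose(scores.MD, [[0.5], [0.0]])

    def test_alpha_zero_halves_the_prior(self):
        Bp, Cp, SD, I2, I1 = self._toy()
        cfg = WalkConfig(alpha=0.0, l1=1, r1=1, l2=1, r2=1)
        scores = walk_iterate(Bp, Cp, I2, I2, I1, SD, Bp, Cp, cfg)
        assert np.allclose(scores.SM, Bp / 2.0)

    def test_alpha_one_ignores_the_prior(self, rng):
        m, n, z = 4, 3, 2
        SM0 = rng.random((m, n))
        MD0 = rng.random((n, z))
        Ss, Sm, Sd = (_random_similarity(k, rng) for k in (m, n, z))
        SD = (rng.random((m, z)) < 0.5).astype(float)
        cfg = WalkConfig(alpha=1.0, l1=2, r1=1, l2=1, r2=1)
        out1 = walk_iterate(SM0, MD0, Ss, Sm, Sd, SD, rng.random((m, n)), rng.random((n, z)), cfg)
        out2 = walk_iterate(SM0, MD0, Ss, Sm, Sd, SD, rng.random((m, n)), rng.random((n, z)), cfg)
        assert np.allclose(out1.SM, out2.SM)
        assert np.allclose(out1.MD, out2.MD)


class TestOracleEquivalence:
    def test_matches_naive_triple_loop(self, rng):
        for trial in range(50):
            m, n, z = (int(rng.integers(2, k)) for k in (9, 9, 7))
            SM0 = rng.random((m, n))
            MD0 = rng.random((n, z))
            Ss, Sm, Sd = (_random_similarity(k, rng) for k in (m, n, z))
            SD = (rng.random((m, z)) < 0.4).astype(float)
            Bp = rng.random((m, n))
            Cp = rng.random((n, z))
            cfg = WalkConfig(
                alpha=float(rng.uniform(0, 1)),
                l1=int(rng.integers(1, 5)),
                r1=int(rng.integers(1, 5)),
                l2=int(rng.integers(1, 5)),
                r2=int(rng.integers(1, 5)),
            )
            got = walk_iterate(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg)
            exp_sm, exp_md = brute_force_walk(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg)
            assert np.abs(got.SM - exp_sm).max() < 1e-10
            assert np.abs(got.MD - exp_md).max() < 1e-10

    def test_deep_small_molecule_walk_case(self, rng):
        m, n, z = 6, 5, 4
        SM0, MD0 = rng.random((m, n)), rng.random((n, z))
        Ss, Sm, Sd = (_random_similarity(k, rng) for k in (m, n, z))
        SD = (rng.random((m, z)) < 0.4).astype(float)
        Bp, Cp = rng.random((m, n)), rng.random((n, z))
        cfg = WalkConfig(alpha=0.4, l1=4, r1=1, l2=1, r2=1)
        got = walk_iterate(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg)
        exp_sm, exp_md = brute_force_walk(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg)
        assert np.abs(got.SM - exp_sm).max() < 1e-10
        assert np.abs(got.MD - exp_md).max() < 1e-10


class TestInvariants:
    def test_iteration_count_is_exactly_the_max_depth(self, rng):
        cfg = WalkConfig(l1=2, r1=3, l2=1, r2=1)
        assert cfg.n_iterations == 3
        m, n, z = 3, 3, 2
        out = walk_iterate(
            rng.random((m, n)), rng.random((n, z)),
            _random_similarity(m, rng), _random_similarity(n, rng),
            _random_similarity(z, rng), np.zeros((m, z)),
            rng.random((m, n)), rng.random((n, z)), cfg,
        )
        assert len(out.trace) == 3

    def test_invariant_under_entity_permutation(self, rng):
        m, n, z = 5, 4, 3
        SM0, MD0 = rng.random((m, n)), rng.random((n, z))
        Ss, Sm, Sd = (_random_similarity(k, rng) for k in (m, n, z))
        SD = (rng.random((m, z)) < 0.4).astype(float)
        Bp, Cp = rng.random((m, n)), rng.random((n, z))
        cfg = WalkConfig(alpha=0.4, l1=2, r1=1, l2=2, r2=1)
        base = walk_iterate(SM0, MD0, Ss, Sm, Sd, SD, Bp, Cp, cfg)
        p, q, r = (rng.permutation(k) for k in (m, n, z))
        perm = walk_iterate(
            SM0[np.ix_(p, q)], MD0[np.ix_(q, r)],
            Ss[np.ix_(p, p)], Sm[np.ix_(q, q)], Sd[np.ix_(r, r)],
            SD[np.ix_(p, r)], Bp[np.ix_(p, q)], Cp[np.ix_(q, r)], cfg,
        )
        assert np.allclose(perm.SM, base.SM[np.ix_(p, q)])
        assert np.allclose(perm.MD, base.MD[np.ix_(q, r)])

    def test_non_finite_state_reports_iteration(self):
        bad = np.array([[np.inf, 0.0], [0.0, 0.0]])
        cfg = WalkConfig(l1=1, r1=1, l2=1, r2=1)
        with np.errstate(invalid="ignore"):
            with pytest.raises(FloatingPointError, match="iteration 1"):
                walk_iterate(bad, np.zeros((2, 1)), np.eye(2), np.eye(2), np.eye(1),
                             np.zeros((2, 1)), bad, np.zeros((2, 1)), cfg)


def _container_instance(rng, m=4, n=3, z=2):
    rows = EntityUniverse.from_ids("small_molecule", [f"s{i}" for i in range(m)])
    cols = EntityUniverse.from_ids("mirna", [f"m{i}" for i in range(n)])
    dis = EntityUniverse.from_ids("disease", [f"d{i}" for i in range(z)])
    b = (rng.random((m, n)) < 0.4).astype(int)
    b[0, 0] = 1
    c = (rng.random((n, z)) < 0.5).astype(int)
    c[0, 0] = 1
    sd = (rng.random((m, z)) < 0.4).astype(int)
    B = AssociationTable(rows, cols, b)
    C = AssociationTable(cols, dis, c)
    SD = AssociationTable(rows, dis, sd)
    Ss = SimilarityMatrix(rows, _random_similarity(m, rng))
    Sm = SimilarityMatrix(cols, _random_similarity(n, rng))
    Sd = SimilarityMatrix(dis, _random_similarity(z, rng))
    return B, C, SD, Ss, Sm, Sd


class TestPriorsAndPredict:
    def test_prior_entries_uniform_over_edges(self):
        rows = EntityUniverse.from_ids("small_molecule", ["a", "b"])
        cols = EntityUniverse.from_ids("mirna", ["x", "y"])
        B = AssociationTable(rows, cols, np.ones((2, 2)))
        C = AssociationTable(cols, EntityUniverse.from_ids("disease", ["d"]),
                             np.ones((2, 1)))
        sm0, md0 = init_priors(B, C)
        assert np.allclose(sm0[sm0 > 0], 0.25)
        assert np.allclose(md0[md0 > 0], 0.5)

    def test_negative_weight_stamped_into_initial_state(self, rng):
        B, C, SD, Ss, Sm, Sd = _container_instance(rng)
        nset = select_negatives(credible_negative_scores(Ss, Sm, B), 1.0, B.n_edges)
        cfg = WalkConfig(negative_prior_weight=-0.01)
        sm0, _ = init_priors(B, C, nset, cfg)
        sm_id, mir_id = next(iter(sorted(nset.selected_pairs())))
        assert sm0[B.rows.index(sm_id), B.cols.index(mir_id)] == -0.01

    def test_zero_weight_leaves_prior_untouched(self, rng):
        B, C, SD, Ss, Sm, Sd = _container_instance(rng)
        nset = select_negatives(credible_negative_scores(Ss, Sm, B), 1.0, B.n_edges)
        sm0_plain, _ = init_priors(B, C)
        sm0_neg, _ = init_priors(B, C, nset, WalkConfig(negative_prior_weight=0.0))
        assert np.array_equal(sm0_plain, sm0_neg)

    def test_predict_is_deterministic_and_sorted(self, rng):
        B, C, SD, Ss, Sm, Sd = _container_instance(rng)
        t1 = predict(B, C, SD, Ss, Sm, Sd)
        t2 = predict(B, C, SD, Ss, Sm, Sd)
        assert t1.equals(t2)
        assert (t1["score"].diff().dropna() <= 1e-15).all()
        assert len(t1) == len(B.rows) * len(B.cols)

    def test_predict_top_truncates(self, rng):
        B, C, SD, Ss, Sm, Sd = _container_instance(rng)
        assert len(predict(B, C, SD, Ss, Sm, Sd, top=3)) == 3

    def test_run_walk_rejects_misaligned_inputs(self, rng):
        B, C, SD, Ss, Sm, Sd = _container_instance(rng)
        wrong = SimilarityMatrix(
            EntityUniverse.from_ids("small_molecule", ["p", "q", "r", "t"]),
            np.eye(4),
        )
        with pytest.raises(ValueError, match="aligned"):
            run_walk(B, C, SD, wrong, Sm, Sd)
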