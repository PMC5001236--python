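"""Nearest-mean, Bayesian posterior and the reference-integrated caller."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import flowcall as fc
from flowcall.callers import (
    DEFAULT_WEIGHT_GRID,
    IntegratedConfig,
    PenaltyScheme,
    _argmax_matrix_with_ties,
    bayes_call,
    call_batch,
    call_integrated,
    integrated_score,
    log_posterior_matrix,
    nearest_mean_call,
    optimize_weight,
    penalty_matrix,
    posterior,
    reference_penalty,
)
from flowcall.errors import InputError, ModelCoverageError
from flowcall.priors import (
    FlowCandidate,
    GaussianParam,
    SignalPriorSet,
    TORRENT_ZONES,
)


def cand(voltage, nucleotide="A", position=10, ref_length=None, true_length=None):
    return FlowCandidate(
        read_id="r", flow_index=0, nucleotide=nucleotide, read_position=position,
        voltage=voltage, ref_length=ref_length, true_length=true_length,
    )


def two_length_priors(mean2=2.0, mean3=3.0, sd2=0.2, sd3=0.2, prior2=0.5):
    params = {}
    for nuc in "ACGT":
        for zone in range(1, 5):
            params[(nuc, zone, 2)] = GaussianParam(mean2, sd2)
            params[(nuc, zone, 3)] = GaussianParam(mean3, sd3)
    return SignalPriorSet(
        params=params,
        length_prior={2: prior2, 3: 1 - prior2},
        length_range=(2, 3),
        zone_scheme=TORRENT_ZONES,
    )


class TestNearestMean:
    def test_exact_hit_on_class_mean(self, priors):
        assert nearest_mean_call(cand(3.68), priors).called_length == 4

    def test_midpoint_tie_goes_to_smaller_length(self, priors):
        # midpoint of the first two class means (1.85, 2.78)
        assert nearest_mean_call(cand(2.315), priors).called_length == 2

    @pytest.mark.parametrize("voltage", [0.1, 1.9, 2.5, 3.0, 4.1, 5.2, 6.5, 9.0])
    def test_matches_brute_force_distance_scan(self, priors, voltage):
        means, _ = priors.cell_arrays("A", 1)
        oracle = min(
            zip(priors.lengths, means), key=lambda t: (abs(voltage - t[1]), t[0])
        )[0]
        assert nearest_mean_call(cand(voltage), priors).called_length == oracle

    def test_uncovered_cell_group_raises(self):
        small = two_length_priors()
        bad = SignalPriorSet(
            params={k: v for k, v in small.params.items() if k[0] == "A"},
            length_prior=small.length_prior,
            length_range=(2, 3),
        )
        with pytest.raises(ModelCoverageError):
            nearest_mean_call(cand(2.0, nucleotide="C"), bad)


class TestPosterior:
    def test_symmetry_at_midpoint(self):
        p = two_length_priors()
        post = posterior(cand(2.5), p)
        assert post[2] == pytest.approx(0.5, abs=1e-12)
        assert post[3] == pytest.approx(0.5, abs=1e-12)

    def test_uninformative_likelihood_returns_prior(self):
        p = two_length_priors(mean2=2.0, mean3=2.0, prior2=0.8)
        post = posterior(cand(1.7), p)
        assert post[2] == pytest.approx(0.8)
        assert post[3] == pytest.approx(0.2)

    def test_low_voltage_concentrates_on_shortest(self, priors):
        uniform = SignalPriorSet(
            params=priors.params,
            length_prior={L: 0.2 for L in range(2, 7)},
            length_range=(2, 6),
            zone_scheme=priors.zone_scheme,
        )
        post = posterior(cand(1.85), uniform)
        # oracle: explicit Gaussian densities at all 5 lengths
        means, sds = priors.cell_arrays("A", 1)
        dens = norm.pdf(1.85, means, sds)
        assert post[2] == pytest.approx(dens[0] / dens.sum(), rel=1e-9)
        assert post[2] > 0.999

    @given(
        voltage=st.floats(min_value=0.0, max_value=10.0),
        nucleotide=st.sampled_from("ACGT"),
        position=st.integers(min_value=1, max_value=400),
    )
    @settings(max_examples=300, deadline=None)
    def test_normalization_everywhere(self, priors, voltage, nucleotide, position):
        """Posterior sums to 1 +/- 1e-9 even for extreme voltages."""
        post = posterior(cand(voltage, nucleotide, position), priors)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(np.isfinite(v) for v in post.values())


class TestReferencePenalty:
    @pytest.mark.parametrize(
        "length,ref,same_nt,expected",
        [
            (4, 4, True, 0.0),    # perfect match
            (5, 4, True, -2.0),   # insertion/deletion
            (3, 4, True, -2.0),
            (4, 4, False, -1.0),  # substitution
        ],
    )
    def test_printed_values(self, length, ref, same_nt, expected):
        assert reference_penalty(length, ref, same_nt) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(InputError):
            reference_penalty(-1, 4)

    @given(
        length=st.integers(min_value=0, max_value=10),
        ref=st.integers(min_value=0, max_value=10),
        same=st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_only_three_values(self, length, ref, same):
        assert reference_penalty(length, ref, same) in {0.0, -1.0, -2.0}


class TestIntegratedScore:
    def test_w1_reduces_to_log_posterior(self, priors):
        post = posterior(cand(3.6), priors)
        scores = integrated_score(post, ref_length=4, config=IntegratedConfig(weight=1.0))
        for L, p in post.items():
            assert scores[L] == pytest.approx(math.log(p), abs=1e-12)

    def test_w0_match_scores_zero(self, priors):
        post = posterior(cand(3.6), priors)
        scores = integrated_score(post, ref_length=4, config=IntegratedConfig(weight=0.0))
        assert scores[4] == 0.0
        assert all(scores[L] == -2.0 for L in scores if L != 4)

    def test_direct_evaluation_at_optimized_weight(self):
        # W = 0.28, posterior 0.9 on a matching length
        scores = integrated_score(
            {4: 0.9, 5: 0.1}, ref_length=4, config=IntegratedConfig(weight=0.28)
        )
        assert scores[4] == pytest.approx(0.28 * math.log(0.9), abs=1e-12)
        assert scores[4] == pytest.approx(-0.02950, abs=1e-4)


class TestCallIntegrated:
    def test_w1_equals_bayes(self, priors, rng):
        cfg = IntegratedConfig(weight=1.0)
        for _ in range(200):
            c = cand(
                float(rng.uniform(0, 8)),
                nucleotide=str(rng.choice(list("ACGT"))),
                position=int(rng.integers(1, 301)),
                ref_length=int(rng.integers(2, 7)),
            )
            assert (
                call_integrated(c, priors, config=cfg).called_length
                == bayes_call(c, priors).called_length
            )

    def test_w0_returns_reference(self, priors, rng):
        cfg = IntegratedConfig(weight=0.0)
        for _ in range(200):
            ref = int(rng.integers(2, 7))
            c = cand(float(rng.uniform(0, 8)), ref_length=ref)
            assert call_integrated(c, priors, config=cfg).called_length == ref

    def test_missing_ref_falls_back_to_bayes(self, priors, caplog):
        c = cand(3.6)
        res = call_integrated(c, priors)
        assert res.method == "bayes"
        assert res.called_length == bayes_call(c, priors).called_length

    def test_matches_exhaustive_scorer(self, priors):
        """Integrated calls equal a brute-force scorer over every length."""
        cands = fc.sample_candidates(10_000, priors, variant_rate=0.01, seed=99,
                                     nucleotide="A", zone=1)
        cfg = IntegratedConfig(weight=0.28)
        calls = call_batch(cands, priors, "integrated", cfg)
        means, sds = priors.cell_arrays("A", 1)
        prior_arr = priors.prior_array()
        for row in calls.sample(n=600, random_state=0).itertuples(index=False):
            dens = norm.pdf(row.voltage, means, sds) * prior_arr
            post = dens / dens.sum()
            best, best_score, best_post = None, -np.inf, -np.inf
            for L, p in zip(priors.lengths, post):
                pen = 0.0 if L == row.ref_length else -2.0
                s = 0.28 * math.log(max(p, 1e-300)) + 0.72 * pen
                better = s > best_score + 1e-12 or (
                    abs(s - best_score) <= 1e-12
                    and (p > best_post + 1e-12
                         or (abs(p - best_post) <= 1e-12 and L < best))
                )
                if best is None or better:
                    best, best_score, best_post = int(L), s, p
            assert row.called_length == best


class TestBatchConsistency:
    @pytest.mark.parametrize("method", ["nearest_mean", "bayes", "integrated"])
    def test_batch_equals_per_candidate(self, priors, method):
        cands = fc.sample_candidates(500, priors, variant_rate=0.05, seed=17)
        cfg = IntegratedConfig(weight=0.28)
        batch = call_batch(cands, priors, method, cfg)
        for row in batch.itertuples(index=False):
            c = FlowCandidate(
                read_id=row.read_id, flow_index=row.flow_index,
                nucleotide=row.nucleotide, read_position=int(row.read_position),
                voltage=float(row.voltage), ref_length=int(row.ref_length),
            )
            if method == "nearest_mean":
                single = nearest_mean_call(c, priors)
            elif method == "bayes":
                single = bayes_call(c, priors)
            else:
                single = call_integrated(c, priors, config=cfg)
            assert single.called_length == row.called_length


class TestOptimizeWeight:
    def test_no_variants_prefers_reference(self, priors):
        cands = fc.sample_candidates(3000, priors, variant_rate=0.0, seed=1)
        best, _ = optimize_weight(cands, priors, seed=2)
        assert best == 0.0

    def test_noise_reference_prefers_bayes(self, priors, rng):
        # reference lengths are pure noise (never the truth), so any reliance
        # on the reference can only hurt and the CV picks the Bayes-only limit
        cands = fc.sample_candidates(3000, priors, variant_rate=0.0, seed=3)
        shift = rng.integers(1, 5, size=len(cands))
        cands["ref_length"] = (cands["true_length"] - 2 + shift) % 5 + 2
        assert (cands["ref_length"] != cands["true_length"]).all()
        best, _ = optimize_weight(cands, priors, seed=4)
        assert best == 1.0

    def test_matches_brute_force_grid_evaluation(self, priors):
        """CV-selected weight equals an exhaustive per-grid-point recount."""
        cands = fc.sample_candidates(20_000, priors, variant_rate=0.01, seed=11,
                                     nucleotide="A", zone=1)
        grid = DEFAULT_WEIGHT_GRID
        best, curve = optimize_weight(cands, priors, grid=grid, folds=5, seed=12)

        # independent oracle: rebuild folds and count errors per grid point
        rng = np.random.default_rng(12)
        order = rng.permutation(len(cands))
        folds = np.array_split(order, 5)
        logpost = log_posterior_matrix(cands, priors)
        post = np.exp(logpost)
        pen = penalty_matrix(cands["ref_length"].to_numpy(int), priors.lengths)
        truth = cands["true_length"].to_numpy(int)
        cv = []
        for w in grid:
            scores = w * np.maximum(logpost, np.log(1e-300)) + (1 - w) * pen
            called = _argmax_matrix_with_ties(scores, post, priors.lengths)
            wrong = called != truth
            cv.append(np.mean([wrong[f].mean() for f in folds]))
        oracle_best = float(grid[int(np.argmin(cv))])
        assert best == oracle_best
        np.testing.assert_allclose(curve["cv_error"].to_numpy(), cv, atol=1e-12)

    def test_too_few_candidates(self, priors):
        cands = fc.sample_candidates(3, priors, seed=0)
        with pytest.raises(InputError):
            optimize_weight(cands, priors, folds=5)


class TestErrorOrdering:
    def test_integrated_beats_bayes_beats_nearest_mean(self, priors):
        """Caller ranking on 1%-variant synthetic data (fixed seed)."""
        cands = fc.sample_candidates(60_000, priors, variant_rate=0.01, seed=314)
        truth = cands["true_length"].to_numpy(int)

        def err(method, cfg=IntegratedConfig(weight=0.28)):
            calls = call_batch(cands, priors, method, cfg)
            return (calls["called_length"].to_numpy(int) != truth).mean()

        e_int = err("integrated")
        e_bayes = err("bayes")
        e_nm = err("nearest_mean")
        e_ref = err("reference_only")
        assert e_int < e_bayes < e_nm
        assert e_int <= e_ref
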