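"""Analytic tetrad distributions and the segregation classifier."""

import itertools

import numpy as np
import pytest
from scipy import stats

from yeastdmi.simcross import IncompatibilityModel, simulate_tetrad
from yeastdmi.tetradmodel import (
    SegregationCall,
    classify_segregation,
    expected_spore_inviability,
    expected_tetrad_distribution,
    haldane_tetrad_types,
    sample_viable_counts,
)


def unlinked_model(k: int, penetrance: float = 1.0) -> IncompatibilityModel:
    chroms = [f"chr{i + 1}" for i in range(k)]
    kind = "two_locus_unlinked" if k == 2 else "k_locus"
    return IncompatibilityModel(
        kind=kind,
        lethal_loci=tuple((c, 1000, "P2") for c in chroms),
        penetrance=penetrance,
    )


def closed_form_dead_distribution(k: int) -> dict:
    """Independent oracle for k unlinked loci: the dead set is the
    intersection of k uniform 2-subsets of 4 spores, so
    P(2 dead) = 6^(1-k) and E[dead] = 4 * 2^-k gives P(1 dead)."""
    p2 = 6.0 ** (1 - k)
    p1 = 4.0 * 2.0 ** (-k) - 2.0 * p2
    return {0: 1.0 - p1 - p2, 1: p1, 2: p2}


class TestExpectedDistribution:
    def test_none_model_all_tetrads_complete(self):
        dist = expected_tetrad_distribution(IncompatibilityModel(kind="none"))
        assert dist[4] == 1.0 and dist.mean_inviability() == 0.0

    def test_two_locus_unlinked_is_1_4_1(self):
        dist = expected_tetrad_distribution(unlinked_model(2))
        assert dist[4] == pytest.approx(1 / 6)
        assert dist[3] == pytest.approx(2 / 3)
        assert dist[2] == pytest.approx(1 / 6)
        assert dist[3] / dist[4] == pytest.approx(4.0)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_enumeration_matches_closed_form_oracle(self, k):
        dist = expected_tetrad_distribution(unlinked_model(k))
        oracle = closed_form_dead_distribution(k)
        for dead, p in oracle.items():
            assert dist[4 - dead] == pytest.approx(p, abs=1e-12)

    def test_three_locus_distribution(self):
        dist = expected_tetrad_distribution(unlinked_model(3))
        assert dist[4] == pytest.approx(19 / 36)
        assert dist[3] == pytest.approx(16 / 36)
        assert dist[2] == pytest.approx(1 / 36)

    def test_linked_limit_recovers_unlinked(self):
        model = IncompatibilityModel(
            kind="two_locus_linked",
            lethal_loci=(("chrI", 1000, "P2"), ("chrI", 9000, "P1")),
            r=0.5,
        )
        dist = expected_tetrad_distribution(model)
        unlinked = expected_tetrad_distribution(unlinked_model(2))
        for c in (4, 3, 2):
            assert dist[c] == pytest.approx(unlinked[c], abs=1e-9)

    def test_tight_linkage_suppresses_lethality_in_repulsion(self):
        model = IncompatibilityModel(
            kind="two_locus_linked",
            lethal_loci=(("chrI", 1000, "P2"), ("chrI", 1100, "P1")),
            r=0.01,
        )
        dist = expected_tetrad_distribution(model)
        assert dist[4] > 0.95  # lethal combination needs a recombinant

    @pytest.mark.parametrize("r", np.linspace(0, 0.5, 11))
    def test_distribution_sums_to_one_across_r_grid(self, r):
        model = IncompatibilityModel(
            kind="two_locus_linked",
            lethal_loci=(("chrI", 1000, "P2"), ("chrI", 9000, "P1")),
            r=float(r),
        )
        dist = expected_tetrad_distribution(model)
        assert sum(dist.probs.values()) == pytest.approx(1.0)
        pd_, npd, tt = haldane_tetrad_types(float(r))
        assert npd + tt / 2 == pytest.approx(float(r), abs=1e-9)

    def test_penetrance_thinning_interpolates(self):
        full = expected_tetrad_distribution(unlinked_model(2))
        half = expected_tetrad_distribution(unlinked_model(2, penetrance=0.5))
        assert half.mean_inviability() == pytest.approx(0.125)
        assert half[4] > full[4]


class TestSporeInviability:
    @pytest.mark.parametrize("k,expected", [(1, 0.5), (2, 0.25), (3, 0.125)])
    def test_halves_with_each_unlinked_locus(self, k, expected):
        assert expected_spore_inviability(unlinked_model(k)) == pytest.approx(expected)

    def test_none_model_is_zero(self):
        assert expected_spore_inviability(IncompatibilityModel(kind="none")) == 0.0

    @pytest.mark.parametrize("kind_args", [
        ("none", (), None), ("two", 2, None), ("k3", 3, None),
        ("linked", None, 0.2),
    ])
    def test_mean_inviability_identity(self, kind_args):
        name, k, r = kind_args
        if name == "none":
            model = IncompatibilityModel(kind="none")
        elif r is not None:
            model = IncompatibilityModel(
                kind="two_locus_linked",
                lethal_loci=(("chrI", 1000, "P2"), ("chrI", 9000, "P1")), r=r,
            )
        else:
            model = unlinked_model(k)
        dist = expected_tetrad_distribution(model)
        identity = sum((4 - c) * p for c, p in dist.probs.items()) / 4
        assert expected_spore_inviability(model) == pytest.approx(identity,
                                                                  abs=1e-15)


class TestSimulationAgreement:
    @pytest.mark.parametrize("model", [
        unlinked_model(2), unlinked_model(3), unlinked_model(2, penetrance=0.6),
        IncompatibilityModel(
            kind="two_locus_linked",
            lethal_loci=(("chrI", 1000, "P2"), ("chrI", 200_000, "P1")), r=0.3,
        ),
    ], ids=["two_locus", "k3", "penetrance0.6", "linked"])
    def test_sampler_matches_analytic_distribution(self, model):
        dist = expected_tetrad_distribution(model)
        counts = np.bincount(
            sample_viable_counts(model, 100_000, np.random.default_rng(0)),
            minlength=5,
        )[::-1]  # index by viable class 4..0
        probs = dist.as_array()
        keep = probs > 0
        assert counts[~keep].sum() == 0
        p = stats.chisquare(counts[keep], probs[keep] * counts.sum()).pvalue
        assert p > 0.001

    def test_full_meiosis_matches_analytic_distribution(self, small_design, rng):
        dist = expected_tetrad_distribution(small_design.model)
        n = 10_000
        counts = np.zeros(5)
        for _ in range(n):
            counts[4 - simulate_tetrad(small_design, rng).n_viable("glycerol")] += 1
        probs = dist.as_array()
        keep = probs > 0
        p = stats.chisquare(counts[keep], probs[keep] * n).pvalue
        assert p > 0.001

    def test_linked_meiosis_matches_haldane_expectation(self, rng):
        from yeastdmi.simcross import GenomeMap, make_cross

        # 100 kb apart at 0.35 cM/kb: d = 0.35 M, r = (1 - e^{-0.7})/2
        genome = GenomeMap(chromosomes=(("chrI", 300_000),), markers=())
        model = IncompatibilityModel(
            kind="two_locus_linked",
            lethal_loci=(("chrI", 100_000, "P2"), ("chrI", 200_000, "P1")),
            r=(1 - np.exp(-0.7)) / 2,
            conditions=frozenset({"c"}),
        )
        design = make_cross(genome, model, seed=1)
        dist = expected_tetrad_distribution(model)
        n = 4000
        counts = np.zeros(5)
        for _ in range(n):
            counts[4 - simulate_tetrad(design, rng).n_viable("c")] += 1
        probs = dist.as_array()
        keep = probs > 0
        p = stats.chisquare(counts[keep], probs[keep] * n).pvalue
        assert p > 0.001


class TestClassifier:
    CANDIDATES = ["none", "two_locus_unlinked", "two_locus_linked", "complex"]

    def test_all_complete_tetrads_called_none(self):
        call = classify_segregation({4: 20}, self.CANDIDATES)
        assert call.best_model == "none"
        assert call.fit_pvalue == pytest.approx(1.0)

    def test_1_4_1_counts_called_two_locus_unlinked(self):
        call = classify_segregation({4: 3, 3: 14, 2: 3}, self.CANDIDATES)
        assert call.best_model == "two_locus_unlinked"
        assert call.fit_pvalue > 0.05

    def test_call_invariant_under_candidate_permutation(self):
        observed = {4: 3, 3: 14, 2: 3}
        calls = {
            classify_segregation(observed, list(perm),
                                 compute_pvalue=False).best_model
            for perm in itertools.permutations(self.CANDIDATES)
        }
        assert calls == {"two_locus_unlinked"}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            classify_segregation({4: 10}, [])

    def test_k_locus_candidate_and_distribution(self):
        call = classify_segregation(
            {4: 53, 3: 44, 2: 3}, [("k_locus", 3), "two_locus_unlinked", "none"]
        )
        assert call.best_model == "k_locus(3)"

    def test_linked_candidate_estimates_r(self):
        # strongly linked truth: mostly 4-viable with a few tetratypes
        observed = {4: 30, 3: 6, 2: 0}
        call = classify_segregation(observed, self.CANDIDATES)
        assert call.best_model == "two_locus_linked"
        assert call.r_hat is not None and call.r_hat < 0.2

    def test_recovery_rate_exceeds_null_model_rate(self):
        truth = unlinked_model(2)
        rng = np.random.default_rng(0)
        hits_truth = hits_null = 0
        n_screens = 500
        for _ in range(n_screens):
            counts = np.bincount(sample_viable_counts(truth, 40, rng),
                                 minlength=5)
            observed = {c: int(counts[c]) for c in range(5)}
            call = classify_segregation(observed, self.CANDIDATES,
                                        compute_pvalue=False)
            hits_truth += call.best_model == "two_locus_unlinked"
            hits_null += call.best_model == "none"
        assert hits_truth / n_screens > 0.8
        assert hits_truth > hits_null

    def test_pvalue_regimes_agree_on_good_fit(self):
        # n=24 exact; n=120 Monte Carlo; n=600 chi-square
        for scale in (1, 5, 25):
            observed = {4: 4 * scale, 3: 16 * scale, 2: 4 * scale}
            call = classify_segregation(observed, self.CANDIDATES)
            assert call.best_model == "two_locus_unlinked"
            assert call.fit_pvalue > 0.05
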