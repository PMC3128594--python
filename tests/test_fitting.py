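"""Objective, proposal kernel, acceptance rule and the Metropolis fitter."""

import math

import numpy as np
import pytest

from gapswitch.core import GAP_GENES, GradientSet
from gapswitch.fitting import (DEFAULT_FIT_RANGES, DEFAULT_GRIDS, FitTargets,
                               ModelVariant, accept, filter_solutions,
                               metropolis_fit, objective,
                               per_gene_correlations, propose)
from gapswitch.reference import REFERENCE_GRID_INDICES


def _targets_from(gradients):
    return FitTargets(gradients)


class TestObjective:
    def test_exact_match_scores_one(self, wt_targets):
        assert objective(wt_targets, _targets_from(wt_targets)) == pytest.approx(1.0)

    def test_anticorrelated_gene_drags_minimum(self, wt_targets):
        flipped = wt_targets.copy()
        flipped.set("Kr", wt_targets["Kr"].max() - wt_targets["Kr"])
        r = per_gene_correlations(flipped, _targets_from(wt_targets))
        assert r["Kr"] < 0
        assert objective(flipped, _targets_from(wt_targets)) == min(r.values())

    def test_pearson_matches_textbook_formula(self):
        """Hand-computed 5-point check of the correlation core.

        a = [1,2,3,4,5], b = [2,1,4,3,6]: covariance sum 10, variance sums
        10 and 14.8, so r = 10/sqrt(148).
        """
        from gapswitch.fitting import _pearson
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 1, 4, 3, 6])
        expected = 10 / math.sqrt(148)
        assert _pearson(a, b) == pytest.approx(expected, rel=1e-12)
        from scipy.stats import pearsonr
        assert _pearson(a, b) == pytest.approx(pearsonr(a, b)[0], rel=1e-12)

    def test_zero_variance_scores_worst(self, wt_targets):
        flat = wt_targets.copy()
        flat.set("Gt", np.full(100, 5.0))
        r = per_gene_correlations(flat, _targets_from(wt_targets))
        assert r["Gt"] == -1.0

    def test_restricted_to_fitting_ranges(self, wt_targets):
        """Corrupting a profile outside its fitting range leaves r at 1."""
        corrupted = wt_targets.copy()
        hb = wt_targets["Hb"].copy()
        hb[:25] = 0.0       # Hb range starts at 30 % e.l.
        hb[75:] = 3.0
        corrupted.set("Hb", hb)
        r = per_gene_correlations(corrupted, _targets_from(wt_targets))
        assert r["Hb"] == pytest.approx(1.0)

    def test_range_validation(self, wt_targets):
        with pytest.raises(ValueError):
            FitTargets(wt_targets, ranges={**DEFAULT_FIT_RANGES, "Hb": (70, 30)})


class TestModelVariant:
    def test_b7_has_seven_open_params(self):
        v = ModelVariant.b7()
        assert v.param_names == ("K", "K1", "K2", "C", "N", "D", "rate")
        assert v.grid_sizes == (100, 100, 100, 100, 20, 100, 100)

    def test_b4_fixes_diffusion_and_sites(self):
        v = ModelVariant.b4()
        assert v.param_names == ("K", "K1", "C", "rate")
        p = v.to_model_params((10, 50, 30, 20))
        assert p.D == 0.0
        assert p.N == 5
        # the single node-specific affinity serves both toggle repressor edges
        assert p.K2 == p.K1

    def test_reference_point_materializes(self):
        v = ModelVariant.b7()
        idx = [REFERENCE_GRID_INDICES[k] for k in v.param_names]
        p = v.to_model_params(idx)
        assert p.alpha == pytest.approx(p.beta * p.C_max)

    def test_rejects_inconsistent_specs(self):
        with pytest.raises(ValueError):
            ModelVariant("bad", {"C": DEFAULT_GRIDS["C"]})
        with pytest.raises(ValueError):
            ModelVariant("bad", {"K": DEFAULT_GRIDS["K"]},
                         fixed={"K": 1.0, "rate": 0.1})


class TestPropose:
    def test_changes_exactly_one_coordinate(self, rng):
        v = ModelVariant.b7()
        current = (50, 50, 50, 50, 10, 50, 50)
        for _ in range(200):
            new = propose(current, v, rng)
            diffs = [abs(a - b) for a, b in zip(new, current)]
            assert sum(d != 0 for d in diffs) == 1
            assert max(diffs) == 1

    def test_edges_move_inward(self, rng):
        v = ModelVariant("one", {"K": DEFAULT_GRIDS["K"], "rate": DEFAULT_GRIDS["rate"]})
        for _ in range(50):
            assert propose((0, 0), v, rng) in ((1, 0), (0, 1))
            assert propose((99, 99), v, rng) in ((98, 99), (99, 98))

    def test_interior_proposal_symmetry(self, rng):
        """Empirically P(a->b) = P(b->a) for interior neighbours."""
        v = ModelVariant("one", {"K": DEFAULT_GRIDS["K"], "rate": DEFAULT_GRIDS["rate"]})
        a, b = (50, 50), (51, 50)
        n = 20_000
        ab = sum(propose(a, v, rng) == b for _ in range(n)) / n
        ba = sum(propose(b, v, rng) == a for _ in range(n)) / n
        assert ab == pytest.approx(0.25, abs=0.02)
        assert ba == pytest.approx(0.25, abs=0.02)


class TestAccept:
    def test_improvements_always_accepted(self):
        for u in (0.0, 0.5, 0.999):
            assert accept(0.2, 0.3, 0.05, u)
            assert accept(0.2, 0.2, 0.05, u)

    def test_downhill_acceptance_frequency(self, rng):
        """Acceptance frequency of a fixed downhill step approximates
        exp(delta_r / T)."""
        delta, T = -0.05, 0.05
        u = rng.random(100_000)
        freq = np.mean([accept(0.5, 0.5 + delta, T, ui) for ui in u])
        assert freq == pytest.approx(math.exp(delta / T), abs=0.01)

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            accept(0.1, 0.2, 0.0, 0.5)


class TestMetropolisFit:
    def test_self_fit_identity(self, wt_inputs, wt_targets):
        """Starting a chain at the generating grid point scores r = 1."""
        v = ModelVariant.b7()
        idx = [REFERENCE_GRID_INDICES[k] for k in v.param_names]
        sols = metropolis_fit(FitTargets(wt_targets), v, wt_inputs,
                              n_seeds=1, n_steps=0, master_seed=0,
                              initial_indices=[idx])
        assert sols[0].r == pytest.approx(1.0, abs=1e-12)

    def test_zero_steps_evaluates_seeds_only(self, wt_inputs, wt_targets):
        sols = metropolis_fit(FitTargets(wt_targets), ModelVariant.b4(),
                              wt_inputs, n_seeds=3, n_steps=0, master_seed=5)
        assert len(sols) == 3
        assert all(-1 <= s.r <= 1 for s in sols)

    def test_chain_reproducibility(self, wt_inputs, wt_targets):
        """Identical master seed reproduces the identical solution list."""
        kwargs = dict(n_seeds=2, n_steps=8, master_seed=42)
        a = metropolis_fit(FitTargets(wt_targets), ModelVariant.b4(),
                           wt_inputs, **kwargs)
        b = metropolis_fit(FitTargets(wt_targets), ModelVariant.b4(),
                           wt_inputs, **kwargs)
        for sa, sb in zip(a, b):
            assert sa.indices == sb.indices
            assert sa.r == sb.r
            assert sa.r_per_gene == sb.r_per_gene

    def test_best_of_chain_is_recorded(self, wt_inputs, wt_targets):
        sols = metropolis_fit(FitTargets(wt_targets), ModelVariant.b4(),
                              wt_inputs, n_seeds=2, n_steps=15, master_seed=3)
        for s in sols:
            assert s.r >= -1
            assert set(s.r_per_gene) == set(GAP_GENES)


class TestFilterSolutions:
    def _fake(self, r, amps):
        from gapswitch.fitting import Solution
        return Solution("B-7", (0,), {}, r,
                        {g: r for g in GAP_GENES},
                        dict(zip(GAP_GENES, amps)), 0)

    def test_threshold_strictness_and_amplitude(self):
        sols = [
            self._fake(0.69, [30, 30, 30, 30]),    # r at threshold: rejected
            self._fake(0.71, [30, 30, 30, 10]),    # weak gene: rejected
            self._fake(0.71, [30, 30, 30, 25]),    # kept
            self._fake(0.95, [50, 50, 50, 50]),    # kept
        ]
        kept = filter_solutions(sols, 0.7, 25.0)
        assert len(kept) == 2
        assert all(s.r > 0.7 for s in kept)

    def test_count_matches_independent_recount(self, rng):
        sols = [self._fake(rng.uniform(-1, 1),
                           rng.uniform(0, 50, size=4)) for _ in range(200)]
        kept = filter_solutions(sols, 0.7, 25.0)
        # second, independent filtering pass
        recount = sum(
            1 for s in sols
            if s.r > 0.7 and min(s.max_conc.values()) >= 25.0)
        assert len(kept) == recount
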