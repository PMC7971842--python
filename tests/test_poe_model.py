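"""Cell-table enumeration, cell probabilities, and the observed-data
likelihood with missing-parent marginalization — each checked against an
independent brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

from poescan import (
    MISSING,
    OBSERVABLE_CATEGORIES,
    PoeParams,
    TrioGenotype,
    build_cell_table,
    cell_probs,
    loglik_complete,
    loglik_observed,
)
from poescan.poe_model import observable_probs, stratum_index
from tests.conftest import random_params

# ---------------------------------------------------------------------------
# Oracle: pure-Python enumeration of the trio model, kept deliberately
# independent of the package's vectorized cell table.


def oracle_cells(params: PoeParams):
    """Enumerate allele transmissions; return {(m,f,c,origin): weight}."""
    genos = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    pair_to_stratum = {
        (2, 2): 0, (2, 1): 1, (2, 0): 2, (1, 1): 3, (1, 0): 4, (0, 0): 5,
    }
    r = {0: 1.0, 1: params.R1, 2: params.R2}
    s = {0: 1.0, 1: params.S1, 2: params.S2}
    weights = {}
    for m in (0, 1, 2):
        for f in (0, 1, 2):
            j = pair_to_stratum[tuple(sorted((m, f), reverse=True))]
            for am in genos[m]:
                for af in genos[f]:
                    c = am + af
                    if c == 1:
                        origin = "maternal" if am == 1 else "paternal"
                    else:
                        origin = "none"
                    w = (
                        params.mu[j]
                        * 0.25
                        * r[c]
                        * s[m]
                        * (params.W if origin == "paternal" else 1.0)
                    )
                    key = (m, f, c, origin)
                    weights[key] = weights.get(key, 0.0) + w
    return weights


def oracle_probs(params):
    w = oracle_cells(params)
    total = sum(w.values())
    return {k: v / total for k, v in w.items()}


def oracle_family_prob(params, m, f, c):
    """Sum of normalized cell probabilities compatible with the observed
    members (MISSING matches anything)."""
    probs = oracle_probs(params)
    total = 0.0
    for (cm, cf, cc, _), p in probs.items():
        if m not in (MISSING, cm):
            continue
        if f not in (MISSING, cf):
            continue
        if c not in (MISSING, cc):
            continue
        total += p
    return total


# ---------------------------------------------------------------------------


class TestCellTable:
    def test_sixteen_cells_and_fifteen_categories(self):
        table = build_cell_table()
        assert len(table) == 16
        cats = {(cell.m, cell.f, cell.c) for cell in table.cells}
        assert len(cats) == 15
        assert cats == set(OBSERVABLE_CATEGORIES)

    def test_only_het_het_het_carries_both_origins(self):
        table = build_cell_table()
        split = [
            (cell.m, cell.f, cell.c)
            for cell in table.cells
            if (cell.m, cell.f, cell.c) == (1, 1, 1)
        ]
        assert len(split) == 2
        origins = {
            cell.origin for cell in table.cells
            if (cell.m, cell.f, cell.c) == (1, 1, 1)
        }
        assert origins == {"maternal", "paternal"}
        for cell in table.cells:
            assert (cell.origin != "none") == (cell.c == 1)

    def test_transmission_factors_sum_to_one_per_ordered_pair(self):
        table = build_cell_table()
        for m, f in itertools.product((0, 1, 2), repeat=2):
            total = sum(
                cell.t for cell in table.cells if (cell.m, cell.f) == (m, f)
            )
            assert total == pytest.approx(1.0), (m, f)

    def test_forced_maternal_transmission_pair(self):
        # ordered parents (m=2, f=1): c=2 and c=1 (maternal), never c=0
        table = build_cell_table()
        cells = [c for c in table.cells if (c.m, c.f) == (2, 1)]
        assert sorted((c.c, c.t, c.origin) for c in cells) == [
            (1, 0.5, "maternal"),
            (2, 0.5, "none"),
        ]

    def test_het_het_quartering(self):
        table = build_cell_table()
        cells = sorted(
            (c.c, c.origin, c.t)
            for c in table.cells
            if (c.m, c.f) == (1, 1)
        )
        assert cells == [
            (0, "none", 0.25),
            (1, "maternal", 0.25),
            (1, "paternal", 0.25),
            (2, "none", 0.25),
        ]

    def test_stratum_assignment_is_unordered(self):
        for m, f in itertools.product((0, 1, 2), repeat=2):
            assert stratum_index(m, f) == stratum_index(f, m)


class TestCellProbs:
    def test_normalization_for_random_params(self, rng):
        for _ in range(20):
            p = cell_probs(random_params(rng))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p > 0)

    def test_null_params_reduce_to_mating_by_transmission(self):
        params = PoeParams(mu=(1.0, 2.0, 1.0, 4.0, 2.0, 1.0))
        table = build_cell_table()
        p = cell_probs(params)
        expected = np.array(
            [params.mu[c.stratum] * c.t for c in table.cells]
        )
        np.testing.assert_allclose(p, expected / expected.sum(), rtol=1e-12)

    def test_mirror_symmetry_at_null_W(self, rng):
        """With W=1 and no maternal effect, swapping the parents' roles in
        a heterozygous-child cell leaves its probability unchanged."""
        params = PoeParams(
            mu=(1.0, 2.0, 1.0, 4.0, 2.0, 1.0), R1=1.5, R2=2.0, W=1.0
        )
        probs = oracle_probs(params)
        assert probs[(2, 1, 1, "maternal")] == pytest.approx(
            probs[(1, 2, 1, "paternal")]
        )
        assert probs[(0, 1, 1, "paternal")] == pytest.approx(
            probs[(1, 0, 1, "maternal")]
        )

    def test_matches_hand_oracle_at_spec_point(self):
        params = PoeParams(
            mu=(1.0, 2.0, 1.0, 4.0, 2.0, 1.0),
            R1=1.5, R2=2.0, S1=1.2, S2=1.4, W=0.5,
        )
        table = build_cell_table()
        p = cell_probs(params)
        expected = oracle_probs(params)
        for cell, prob in zip(table.cells, p):
            key = (cell.m, cell.f, cell.c, cell.origin)
            assert prob == pytest.approx(expected[key], rel=1e-12), key

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            PoeParams(W=0.0)
        with pytest.raises(ValueError):
            PoeParams(R1=-1.0)


class TestLoglikComplete:
    def test_zero_counts_give_zero(self):
        assert loglik_complete(np.zeros(15), PoeParams()) == 0.0
        assert loglik_complete(np.zeros(16), PoeParams()) == 0.0

    def test_cell_counts_and_category_counts_agree(self, rng):
        params = random_params(rng)
        cell_counts = rng.integers(0, 30, size=16).astype(float)
        table = build_cell_table()
        cat_counts = np.zeros(15)
        cat_index = {cat: i for i, cat in enumerate(OBSERVABLE_CATEGORIES)}
        for cell, n in zip(table.cells, cell_counts):
            cat_counts[cat_index[(cell.m, cell.f, cell.c)]] += n
        assert loglik_complete(cell_counts, params) == pytest.approx(
            loglik_complete(cat_counts, params)
        )

    def test_paternal_origin_singleton_increases_in_W(self):
        counts = np.zeros(15)
        counts[OBSERVABLE_CATEGORIES.index((0, 2, 1))] = 1.0
        lls = [
            loglik_complete(counts, PoeParams(W=w)) for w in (0.5, 1.0, 2.0, 4.0)
        ]
        assert lls == sorted(lls)
        # and equals log pi(0,2,1) directly
        p = observable_probs(PoeParams(W=2.0))
        assert loglik_complete(counts, PoeParams(W=2.0)) == pytest.approx(
            math.log(p[OBSERVABLE_CATEGORIES.index((0, 2, 1))])
        )

    def test_stationary_at_generating_parameters(self, rng):
        """Counts exactly proportional to the model probabilities make the
        generating point a stationary point of the likelihood."""
        params = PoeParams(
            mu=(1.0, 2.0, 1.0, 4.0, 2.0, 1.0),
            R1=1.5, R2=2.0, S1=1.2, S2=1.4, W=0.5,
        )
        counts = 1000.0 * observable_probs(params)

        free = [
            ("mu", 0), ("mu", 1), ("mu", 2), ("mu", 3), ("mu", 4),
            ("R1", None), ("R2", None), ("S1", None), ("S2", None),
            ("W", None),
        ]

        def perturbed(name, idx, eps):
            kw = dict(
                mu=list(params.mu), R1=params.R1, R2=params.R2,
                S1=params.S1, S2=params.S2, W=params.W,
            )
            if name == "mu":
                kw["mu"][idx] *= math.exp(eps)
            else:
                kw[name] *= math.exp(eps)
            kw["mu"] = tuple(kw["mu"])
            return PoeParams(**kw)

        eps = 1e-6
        for name, idx in free:
            up = loglik_complete(counts, perturbed(name, idx, eps))
            dn = loglik_complete(counts, perturbed(name, idx, -eps))
            deriv = (up - dn) / (2 * eps)
            assert abs(deriv) < 1e-4, (name, idx, deriv)

    def test_mendelian_inconsistent_counts_raise(self):
        trios = [TrioGenotype("famX", m=0, f=0, c=2)]
        with pytest.raises(ValueError, match="inconsistent"):
            loglik_observed(trios, PoeParams())


class TestLoglikObserved:
    def test_father_missing_two_compatible_cells(self):
        params = PoeParams(
            mu=(1.0, 2.0, 1.0, 4.0, 2.0, 1.0), R1=1.3, S1=1.1, W=0.7
        )
        p = oracle_probs(params)
        trio = TrioGenotype("fam1", m=0, f=MISSING, c=0)
        expected = p[(0, 0, 0, "none")] + p[(0, 1, 0, "none")]
        assert loglik_observed([trio], params) == pytest.approx(
            math.log(expected)
        )

    def test_father_missing_homozygous_pair(self):
        params = PoeParams(mu=(2.0, 1.5, 1.0, 3.0, 1.0, 1.0), R2=1.8)
        p = oracle_probs(params)
        trio = TrioGenotype("fam1", m=2, f=MISSING, c=2)
        expected = p[(2, 2, 2, "none")] + p[(2, 1, 2, "none")]
        assert loglik_observed([trio], params) == pytest.approx(
            math.log(expected)
        )

    def test_equals_complete_likelihood_without_missingness(self, rng):
        params = random_params(rng)
        cats = list(OBSERVABLE_CATEGORIES)
        counts = rng.integers(0, 10, size=15)
        trios = []
        for (m, f, c), n in zip(cats, counts):
            trios += [
                TrioGenotype(f"fam{m}{f}{c}_{i}", m=m, f=f, c=c)
                for i in range(n)
            ]
        assert loglik_observed(trios, params) == pytest.approx(
            loglik_complete(counts.astype(float), params)
        )

    def test_matches_exhaustive_compatibility_oracle(self, rng):
        """Random parameter points and random missingness patterns agree
        with the brute-force compatibility sum to near machine precision."""
        dosages = (0, 1, 2)
        for trial in range(200):
            params = random_params(rng)
            m, f = rng.choice(dosages), rng.choice(dosages)
            # choose a reachable child dosage
            c = int(
                rng.choice([am + af for am in ((0,), (0, 1), (1,))[m]
                            for af in ((0,), (0, 1), (1,))[f]])
            )
            drop = rng.integers(0, 3)
            if drop == 1:
                m = MISSING
            elif drop == 2:
                f = MISSING
            if rng.random() < 0.15:
                m = f = MISSING
            trio = TrioGenotype("fam1", m=m, f=f, c=c)
            expected = math.log(oracle_family_prob(params, m, f, c))
            assert loglik_observed([trio], params) == pytest.approx(
                expected, abs=1e-10
            )

    def test_marginalization_consistency(self, rng):
        """Summing a hidden parent's pattern probabilities over its
        possible dosages reproduces the complete-trio distribution."""
        params = random_params(rng)
        for m in (0, 1, 2):
            for c in (0, 1, 2):
                marginal = oracle_family_prob(params, m, MISSING, c)
                total = sum(
                    oracle_family_prob(params, m, f, c) for f in (0, 1, 2)
                )
                assert marginal == pytest.approx(total, abs=1e-14)

    def test_missing_child_rejected(self):
        with pytest.raises(ValueError, match="child"):
            loglik_observed(
                [TrioGenotype("fam1", m=0, f=0, c=MISSING)], PoeParams()
            )
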