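"""Score computations: log ratios, median centering, comparison logos.

Frozen expected values were computed with an arbitrary-precision log2 /
entropy oracle (mpmath at 40 significant digits) on the worked inputs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edlogo import (
    Alphabet,
    Background,
    DomainError,
    ProbabilityMatrix,
    ScoreMatrix,
    centering_constant,
    edlogo_scores,
    log_odds,
    log_ratios,
    median_center,
    stack_height,
    standard_logo_scores,
    wkl_scores,
)
from conftest import prob_matrix, random_simplex

# mpmath oracle values for p=(0.33,0.33,0.33,0.01) vs uniform q
FIG1_RTILDE = [0.40053792958372875, 0.40053792958372875, 0.40053792958372875,
               -4.643856189774724]
FIG1_CONV = [0.0, 0.0, 0.0, -5.044394119358453]
FIG1_IC = 0.3500939883901442
FIG1_WKL = [0.13217751676263048, 0.13217751676263048, 0.13217751676263048,
            -0.04643856189774725]
FIG1_LOGODDS_AT = 5.044394119358453


@pytest.fixture
def fig1(fixtures):
    return fixtures["fig1_probs"]


class TestLogRatios:
    def test_worked_example(self, fig1, uniform_bg):
        raw = log_ratios(fig1, uniform_bg)
        assert raw.mode == "raw" and raw.centering == "none"
        np.testing.assert_allclose(raw.values[0], FIG1_RTILDE, rtol=0, atol=1e-12)

    def test_identical_distributions_give_zero(self, uniform_bg):
        pm = prob_matrix([0.25, 0.25, 0.25, 0.25])
        assert np.all(log_ratios(pm, uniform_bg).values[0] == 0)

    def test_zero_probability_is_a_domain_error(self, uniform_bg):
        pm = prob_matrix([1.0, 0.0, 0.0, 0.0])
        with pytest.raises(DomainError, match="stabiliz"):
            log_ratios(pm, uniform_bg)

    def test_zero_background_names_position_and_symbol(self):
        pm = prob_matrix([0.5, 0.5])
        bg = Background(matrix=ProbabilityMatrix(
            [1], [pm.alphabets[0]], [np.array([1.0, 0.0])]))
        with pytest.raises(DomainError, match="S1"):
            log_ratios(pm, bg)


class TestMedianCenter:
    TIE = [0.0, 0.0, 1.0, 1.0]

    @pytest.mark.parametrize("rule,expected", [
        ("conventional", [-0.5, -0.5, 0.5, 0.5]),
        ("smallest", [0.0, 0.0, 1.0, 1.0]),
        ("largest", [-1.0, -1.0, 0.0, 0.0]),
    ])
    def test_even_n_tie_example(self, fixtures, rule, expected):
        centered = median_center(fixtures["tie_tilde_r"], rule)
        assert centered.values[0].tolist() == expected
        assert stack_height(centered, 1) == 2.0

    def test_single_symbol_centers_to_zero(self):
        sm = ScoreMatrix([1], [Alphabet(("X",))], [np.array([5.0])])
        for rule in ("smallest", "conventional", "largest"):
            assert median_center(sm, rule).values[0][0] == 0.0

    def test_odd_n_rules_coincide(self):
        v = np.array([-2.0, 0.3, 1.7])
        consts = {r: centering_constant(v, r) for r in ("smallest", "conventional", "largest")}
        assert set(consts.values()) == {0.3}

    def test_applies_to_external_pssm(self):
        pssm = ScoreMatrix([1, 2], [Alphabet("ACGT")] * 2,
                           [np.array([2.0, -1.0, 0.5, 3.0]),
                            np.array([-4.0, -2.0, 0.0, 1.0])])
        adj = median_center(pssm, "conventional")
        assert adj.mode == "edlogo"
        for v in adj.values:
            assert abs(np.median(v)) < 1e-12


class TestEdlogoScores:
    def test_fig1_conventional_single_depletion(self, fig1, uniform_bg):
        r = edlogo_scores(fig1, uniform_bg, "conventional")
        np.testing.assert_allclose(r.values[0], FIG1_CONV, rtol=0, atol=1e-12)
        below = [s for s, v in zip("ACGT", r.values[0]) if v < 0]
        assert below == ["T"]

    def test_default_rule_is_smallest(self, fig1, uniform_bg):
        r = edlogo_scores(fig1, uniform_bg)
        assert r.centering == "smallest"

    def test_null_input_gives_zero_scores(self, uniform_bg):
        pm = prob_matrix([0.25] * 4)
        assert np.all(edlogo_scores(pm, uniform_bg).values[0] == 0)


class TestStackHeight:
    def test_worked_examples(self, fixtures):
        conv = median_center(fixtures["tie_tilde_r"], "conventional")
        assert stack_height(conv, 1) == 2.0
        small = median_center(fixtures["tie_tilde_r"], "smallest")
        assert stack_height(small, 1) == 2.0

    def test_zero_position(self):
        sm = ScoreMatrix([1], [Alphabet("AC")], [np.zeros(2)])
        assert stack_height(sm, 1) == 0.0


class TestStandardLogo:
    def test_zero_entropy_closed_form(self):
        h = standard_logo_scores(prob_matrix([1.0, 0.0, 0.0, 0.0]))
        assert np.allclose(h.values[0], [2.0, 0.0, 0.0, 0.0])

    def test_uniform_has_zero_information(self):
        h = standard_logo_scores(prob_matrix([0.25] * 4))
        assert np.all(h.values[0] == 0)

    def test_fig1_information_content(self, fig1):
        h = standard_logo_scores(fig1)
        assert abs(h.values[0].sum() - FIG1_IC) < 1e-12
        np.testing.assert_allclose(h.values[0], np.array([0.33, 0.33, 0.33, 0.01]) * FIG1_IC,
                                   rtol=0, atol=1e-12)

    def test_stack_height_equals_information_content(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_simplex(rng, int(rng.integers(2, 9)))
            h = standard_logo_scores(prob_matrix(p))
            ic = np.log2(p.size) + np.sum(p * np.log2(p))
            assert abs(stack_height(h, 1) - ic) < 1e-12

    def test_small_reference_rejected(self, fig1):
        from edlogo import ValidationError
        with pytest.raises(ValidationError):
            standard_logo_scores(fig1, n_ref=1)


class TestWklScores:
    def test_identity_background_gives_zero(self, uniform_bg):
        assert np.all(wkl_scores(prob_matrix([0.25] * 4), uniform_bg).values[0] == 0)

    def test_fig1_all_four_symbols_nonzero(self, fig1, uniform_bg):
        h = wkl_scores(fig1, uniform_bg)
        np.testing.assert_allclose(h.values[0], FIG1_WKL, rtol=0, atol=1e-12)
        assert np.sum(h.values[0] > 0) == 3 and np.sum(h.values[0] < 0) == 1

    def test_point_mass(self, uniform_bg):
        h = wkl_scores(prob_matrix([1.0, 0.0, 0.0, 0.0]), uniform_bg)
        assert np.allclose(h.values[0], [2.0, 0.0, 0.0, 0.0])


class TestLogOdds:
    def test_fig1_closed_form(self, fig1, uniform_bg):
        r = edlogo_scores(fig1, uniform_bg, "conventional")
        assert abs(log_odds(r, 1, "A", "T") - FIG1_LOGODDS_AT) < 1e-12

    def test_same_symbol_is_zero(self, fig1, uniform_bg):
        r = edlogo_scores(fig1, uniform_bg)
        assert log_odds(r, 1, "C", "C") == 0.0

    def test_invariant_to_centering_rule(self, fig1, uniform_bg):
        vals = [log_odds(edlogo_scores(fig1, uniform_bg, rule), 1, "A", "T")
                for rule in ("smallest", "conventional", "largest")]
        assert max(vals) - min(vals) == 0.0


# ---------------------------------------------------------------------------
# Invariants & properties
# ---------------------------------------------------------------------------

class TestParsimony:
    """The centering constant minimizes the total stack height."""

    def test_grid_oracle(self):
        rng = np.random.default_rng(2024)
        for n in range(2, 10):
            for _ in range(60):
                v = rng.normal(0, 2, size=n)
                sm = ScoreMatrix([1], [Alphabet(tuple(f"S{i}" for i in range(n)))], [v])
                grid = np.linspace(v.min() - 1, v.max() + 1, 2001)
                costs = np.abs(v[None, :] - grid[:, None]).sum(axis=1)
                best = costs.min()
                for rule in ("smallest", "conventional", "largest"):
                    c = centering_constant(v, rule)
                    achieved = np.abs(v - c).sum()
                    assert achieved <= best + 1e-9
                if n % 2 == 0:
                    # every offset in the closed central interval does equally well
                    lo = centering_constant(v, "smallest")
                    hi = centering_constant(v, "largest")
                    inner = np.linspace(lo, hi, 7)
                    inner_costs = np.abs(v[None, :] - inner[:, None]).sum(axis=1)
                    assert np.ptp(inner_costs) < 1e-9


class TestMirrorProperty:
    def test_conventional_centering_mirrors(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            p = random_simplex(rng, n)
            q = random_simplex(rng, n)
            alph = Alphabet(tuple(f"S{i}" for i in range(n)))
            pm = ProbabilityMatrix([1], [alph], [p])
            qm = Background(vector=q, alphabet=alph)
            pm2 = ProbabilityMatrix([1], [alph], [q])
            qm2 = Background(vector=p, alphabet=alph)
            fwd = edlogo_scores(pm, qm, "conventional").values[0]
            rev = edlogo_scores(pm2, qm2, "conventional").values[0]
            assert np.max(np.abs(fwd + rev)) < 1e-12

    def test_smallest_rule_breaks_the_mirror(self):
        """Documented counterexample: an even-n input where the enrichment-
        favoring rule is not mirror-symmetric under p/q exchange."""
        alph = Alphabet("ACGT")
        p = np.array([0.4, 0.4, 0.1, 0.1])
        q = np.array([0.25] * 4)
        fwd = edlogo_scores(ProbabilityMatrix([1], [alph], [p]),
                            Background(vector=q, alphabet=alph), "smallest").values[0]
        rev = edlogo_scores(ProbabilityMatrix([1], [alph], [q]),
                            Background(vector=p, alphabet=alph), "smallest").values[0]
        assert np.max(np.abs(fwd + rev)) > 0.1


class TestLogOddsIdentity:
    """Height differences equal log2((p_a/p_b)/(q_a/q_b)) for every rule."""

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_identity(self, n, seed):
        rng = np.random.default_rng(seed)
        p = random_simplex(rng, n)
        q = random_simplex(rng, n)
        alph = Alphabet(tuple(f"S{i}" for i in range(n)))
        pm = ProbabilityMatrix([1], [alph], [p])
        bg = Background(vector=q, alphabet=alph)
        for rule in ("smallest", "conventional", "largest"):
            r = edlogo_scores(pm, bg, rule)
            for a in range(n):
                for b in range(n):
                    expected = np.log2((p[a] / p[b]) / (q[a] / q[b]))
                    got = log_odds(r, 1, f"S{a}", f"S{b}")
                    assert abs(got - expected) < 1e-12


class TestTranslationInvariance:
    """Adding a constant to the raw ratios leaves the centered scores unchanged."""

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=1, max_value=9),
           st.floats(min_value=-50, max_value=50, allow_nan=False),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_shift_cancels(self, n, k, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 3, size=n)
        alph = Alphabet(tuple(f"S{i}" for i in range(n)))
        for rule in ("smallest", "conventional", "largest"):
            a = median_center(ScoreMatrix([1], [alph], [v]), rule).values[0]
            b = median_center(ScoreMatrix([1], [alph], [v + k]), rule).values[0]
            assert np.max(np.abs(a - b)) < 1e-9
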