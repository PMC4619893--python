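"""Restraint algebra: mixture densities, odds ratios, and their combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from templix.restraints import (
    AtomPairClass,
    PairId,
    RestraintItem,
    RestraintParams,
    WeightedRestraintSet,
    combined_log_odds,
    gaussian_ratio_form,
    log_odds_ratio,
    mixture_logpdf,
    modeller_additive_baseline,
    odds_ratio,
    restraint_sets_from_json,
    restraint_sets_from_tsv,
    restraint_sets_to_json,
    restraint_sets_to_tsv,
    write_modeller_style,
)

PAIR = PairId(1, 4, "CA", "CA", AtomPairClass.CA_CA)


def make_set(*items):
    return WeightedRestraintSet(pair=PAIR, items=list(items))


valid_params = st.builds(
    RestraintParams,
    w=st.floats(0.05, 0.95),
    mu=st.floats(-1.0, 4.0),
    sigma=st.floats(0.05, 0.6),
    mu_bg=st.floats(0.5, 3.5),
    sigma_bg=st.floats(0.2, 1.2),
)


class TestMixtureLogpdf:
    @pytest.mark.parametrize(
        "params, log_d, expected",
        [
            # w=1 collapses to the signal normal at its mode
            (RestraintParams(1.0, 0.0, 1.0, 0.0, 1.0), 0.0, math.log(1 / math.sqrt(2 * math.pi))),
            # w=0 collapses to the background at its mode
            (RestraintParams(0.0, 0.0, 1.0, 2.0, 0.5), 2.0, math.log(1 / (0.5 * math.sqrt(2 * math.pi)))),
        ],
    )
    def test_degenerate_weights(self, params, log_d, expected):
        assert mixture_logpdf(log_d, params) == pytest.approx(expected, rel=1e-12)

    def test_termwise_sum(self):
        # independent evaluation: sum the two weighted normal densities directly
        p = RestraintParams(0.7, 1.0, 0.2, 1.5, 0.8)
        expected = 0.7 * norm.pdf(1.1, 1.0, 0.2) + 0.3 * norm.pdf(1.1, 1.5, 0.8)
        assert mixture_logpdf(1.1, p) == pytest.approx(math.log(expected), rel=1e-12)

    def test_nonfinite_input_rejected(self):
        p = RestraintParams(0.5, 1.0, 0.2, 1.5, 0.8)
        with pytest.raises(ValueError):
            mixture_logpdf(np.nan, p)
        with pytest.raises(ValueError):
            mixture_logpdf(np.inf, p)

    @given(valid_params, st.floats(-30.0, 30.0))
    @settings(max_examples=100, deadline=None)
    def test_finite_everywhere(self, params, log_d):
        assert np.isfinite(mixture_logpdf(log_d, params))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RestraintParams(1.2, 0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            RestraintParams(0.5, 0.0, -1.0, 0.0, 1.0)


class TestOddsRatio:
    def test_no_signal_gives_unit_odds(self):
        p = RestraintParams(0.0, 0.0, 0.3, 1.0, 0.8)
        for y in (-5.0, 0.0, 7.0):
            assert odds_ratio(y, p) == pytest.approx(1.0)

    def test_tail_constant_is_one_minus_w(self):
        # flat tails: odds -> 1 - w when the signal is narrower than the background
        p = RestraintParams(0.6, 1.0, 0.2, 1.2, 0.9)
        assert odds_ratio(-40.0, p) == pytest.approx(0.4, abs=1e-9)
        assert odds_ratio(40.0, p) == pytest.approx(0.4, abs=1e-9)

    def test_common_mean_hand_value(self):
        # at the shared mean the pdf ratio is sigma_bg/sigma = 2
        p = RestraintParams(0.5, 0.0, 0.5, 0.0, 1.0)
        assert odds_ratio(0.0, p) == pytest.approx(1.5, rel=1e-12)

    @given(valid_params, st.floats(-20.0, 20.0))
    @settings(max_examples=100, deadline=None)
    def test_lower_bound(self, params, log_d):
        # odds >= 1 - w everywhere when sigma < sigma_bg
        if params.sigma < params.sigma_bg:
            assert odds_ratio(log_d, params) >= (1 - params.w) - 1e-12


class TestGaussianRatioForm:
    def test_equal_sigmas_linear_branch(self):
        p = RestraintParams(0.5, 1.0, 0.5, 2.0, 0.5)
        form = gaussian_ratio_form(p)
        assert form.is_linear and math.isinf(form.var)

    def test_centered_ratio_variance(self):
        # mu = mu_bg, sigma < sigma_bg: ratio is a centered Gaussian shape with
        # variance (sigma^-2 - sigma_bg^-2)^-1
        p = RestraintParams(0.5, 1.0, 0.3, 1.0, 0.9)
        form = gaussian_ratio_form(p)
        assert form.center == pytest.approx(1.0)
        assert form.var == pytest.approx(1.0 / (0.3**-2 - 0.9**-2), rel=1e-12)

    @given(valid_params)
    @settings(max_examples=50, deadline=None)
    def test_matches_pointwise_division(self, params):
        # brute-force oracle: direct pdf division on a grid, compared on the
        # log scale so extreme tails do not lose precision to underflow
        form = gaussian_ratio_form(params)
        grid = np.linspace(params.mu - 3, params.mu + 3, 100)
        log_direct = norm.logpdf(grid, params.mu, params.sigma) - norm.logpdf(
            grid, params.mu_bg, params.sigma_bg
        )
        if form.is_linear:
            log_form = form.log_scale + form.slope * grid
        else:
            log_form = form.log_scale - (grid - form.center) ** 2 / (2.0 * form.var)
        np.testing.assert_allclose(log_form, log_direct, rtol=1e-10, atol=1e-9)


class TestCombinedLogOdds:
    P1 = RestraintParams(0.8, 1.9, 0.15, 2.2, 0.5)
    P2 = RestraintParams(0.6, 2.1, 0.25, 2.2, 0.6)
    P3 = RestraintParams(0.9, 2.4, 0.10, 2.1, 0.7)

    def test_single_full_weight_item(self):
        rs = make_set(RestraintItem(self.P1, 1.0, "a"))
        assert combined_log_odds(2.0, rs) == pytest.approx(log_odds_ratio(2.0, self.P1))

    def test_split_weight_additivity(self):
        whole = make_set(RestraintItem(self.P1, 1.0, "a"))
        halves = make_set(
            RestraintItem(self.P1, 0.5, "a1"), RestraintItem(self.P1, 0.5, "a2")
        )
        grid = np.linspace(0.0, 4.0, 50)
        np.testing.assert_allclose(
            combined_log_odds(grid, whole), combined_log_odds(grid, halves), rtol=1e-12
        )

    def test_permutation_invariance(self):
        items = [
            RestraintItem(self.P1, 0.9, "a"),
            RestraintItem(self.P2, 0.6, "b"),
            RestraintItem(self.P3, 1.0, "c"),
        ]
        grid = np.linspace(1.0, 3.0, 25)
        fwd = combined_log_odds(grid, make_set(*items))
        rev = combined_log_odds(grid, make_set(*items[::-1]))
        np.testing.assert_allclose(fwd, rev, rtol=1e-12)

    def test_termwise_oracle(self):
        items = [
            RestraintItem(self.P1, 0.9, "a"),
            RestraintItem(self.P2, 0.6, "b"),
            RestraintItem(self.P3, 1.0, "c"),
        ]
        expected = sum(
            it.weight * log_odds_ratio(2.05, it.params) for it in items
        )
        assert combined_log_odds(2.05, make_set(*items)) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            WeightedRestraintSet(pair=PAIR, items=[])

    def test_negative_log_odds_bounded_when_tails_flat(self):
        # every item has sigma < sigma_bg -> -combined log odds bounded above,
        # in contrast with the unbounded quadratic of a single Gaussian
        rs = make_set(
            RestraintItem(self.P1, 1.0, "a"), RestraintItem(self.P2, 0.7, "b")
        )
        bound = -(
            1.0 * math.log(1 - self.P1.w) + 0.7 * math.log(1 - self.P2.w)
        )
        grid = np.linspace(-50, 50, 2001)
        assert np.max(-combined_log_odds(grid, rs)) <= bound + 1e-9

    def test_grid_bayes_equivalence(self):
        """Odds product with unit weights reproduces brute-force Bayes.

        Conditionally independent template distances are generated from an
        exact joint model (Gaussian background prior on log d, per-template
        mixture emission); the restraint p(d | d_k) is then itself a
        two-component mixture whose parameters follow from conjugacy.  The
        product of per-template odds must match the gridded posterior odds.
        """
        mu_bg, sigma_bg = 2.2, 0.6
        sigma, w_gen = 0.2, 0.75
        d_k = [2.0, 2.3, 1.8]
        grid = np.linspace(-1.0, 5.5, 4001)
        prior = norm.pdf(grid, mu_bg, sigma_bg)

        items = []
        log_lik = np.zeros_like(grid)
        for k, dk in enumerate(d_k):
            # posterior p(d | d_k) via conjugacy: signal component shrinks d_k
            # toward the background mean
            evid_sig = norm.pdf(dk, mu_bg, math.hypot(sigma, sigma_bg))
            evid_bg = norm.pdf(dk, mu_bg, sigma_bg)
            w_post = w_gen * evid_sig / (w_gen * evid_sig + (1 - w_gen) * evid_bg)
            prec = 1 / sigma**2 + 1 / sigma_bg**2
            mu_post = (dk / sigma**2 + mu_bg / sigma_bg**2) / prec
            items.append(
                RestraintItem(
                    RestraintParams(
                        w=w_post, mu=mu_post, sigma=math.sqrt(1 / prec),
                        mu_bg=mu_bg, sigma_bg=sigma_bg,
                    ),
                    1.0,
                    f"t{k}",
                )
            )
            # exact emission likelihood p(d_k | d) for the gridded joint
            log_lik += np.log(
                w_gen * norm.pdf(dk, grid, sigma) + (1 - w_gen) * evid_bg
            )

        post = prior * np.exp(log_lik - log_lik.max())
        post /= np.trapezoid(post, grid)
        brute_odds = post / prior

        ours = np.exp(combined_log_odds(grid, make_set(*items)))
        # odds agree up to the d-independent evidence constant
        ratio = ours / brute_odds
        mid = (grid > 0.5) & (grid < 4.0)
        np.testing.assert_allclose(ratio[mid], ratio[mid][0], rtol=1e-6)


class TestAdditiveBaseline:
    def test_single_component(self):
        assert modeller_additive_baseline(1.2, [(1.0, 0.5)], [1.0]) == pytest.approx(
            norm.pdf(1.2, 1.0, 0.5)
        )

    def test_two_equal_components_collapse(self):
        one = modeller_additive_baseline(0.7, [(1.0, 0.5)], [1.0])
        two = modeller_additive_baseline(0.7, [(1.0, 0.5), (1.0, 0.5)], [0.5, 0.5])
        assert two == pytest.approx(one)

    def test_separated_components_widen(self):
        # additive mixing widens the restraint instead of sharpening it
        grid = np.linspace(-6, 10, 4001)
        dens = modeller_additive_baseline(grid, [(1.0, 0.5), (3.0, 0.5)], [0.5, 0.5])
        dens = dens / np.trapezoid(dens, grid)
        mean = np.trapezoid(grid * dens, grid)
        var = np.trapezoid((grid - mean) ** 2 * dens, grid)
        assert var > 0.5**2

    def test_all_zero_alphas_rejected(self):
        with pytest.raises(ValueError):
            modeller_additive_baseline(0.0, [(0.0, 1.0)], [0.0])


class TestSerialization:
    RSETS = [
        make_set(
            RestraintItem(RestraintParams(0.8, 1.9, 0.15, 2.2, 0.5), 0.75, "tA"),
            RestraintItem(RestraintParams(0.6, 2.1, 0.25, 2.2, 0.6), 1.0, "tB"),
        ),
        WeightedRestraintSet(
            pair=PairId(2, 7, "N", "O", AtomPairClass.N_O),
            items=[RestraintItem(RestraintParams(0.9, 2.0, 0.1, 2.1, 0.7), 1.0, "tA")],
        ),
    ]

    def test_json_round_trip(self):
        back = restraint_sets_from_json(restraint_sets_to_json(self.RSETS))
        assert back == self.RSETS

    def test_tsv_round_trip(self):
        back = restraint_sets_from_tsv(restraint_sets_to_tsv(self.RSETS))
        assert back == self.RSETS

    def test_modeller_style_writer_line_count(self):
        text = write_modeller_style(self.RSETS)
        assert len(text.strip().splitlines()) == 3
        assert text.startswith("R ")
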