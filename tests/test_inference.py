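"""Variational updates: Dirichlet expectations, posterior inference,
parameter learning, and the free energy itself."""

import numpy as np
import pytest

from cannet.inference import (DirichletBank, History, dirichlet_expectations,
                              free_energy, infer_decision, infer_state,
                              update_parameters)
from cannet.pomdp import (FactorizedMapping, PriorVector, bayes_invert,
                          floor_log, sample_generative_process)


def block(p1):
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    return np.stack([p1, 1 - p1])


class TestDirichletExpectations:
    def test_symmetric_unit_concentration(self):
        conc = np.ones((1, 1, 2, 2))
        mean, _ = dirichlet_expectations(conc)
        np.testing.assert_allclose(mean, 0.5)

    def test_three_one_closed_form(self):
        conc = np.array([[[[3.0, 3.0], [1.0, 1.0]]]])
        mean, _ = dirichlet_expectations(conc)
        np.testing.assert_allclose(mean[0, 0, 0], 0.75)
        np.testing.assert_allclose(mean[0, 0, 1], 0.25)

    def test_digamma_approaches_logratio_at_large_concentration(self):
        conc = np.array([[[[100.0, 100.0], [300.0, 300.0]]]])
        _, lg_dig = dirichlet_expectations(conc, mode="digamma")
        _, lg_ratio = dirichlet_expectations(conc, mode="logratio")
        # digamma(z) - ln z ~ -1/(2z): the gap is dominated by the smaller
        # concentration, and vanishes as concentrations grow
        assert np.max(np.abs(lg_dig - lg_ratio)) < 1.0 / conc.min()
        np.testing.assert_allclose(lg_ratio[0, 0, 0, 0], np.log(0.25))
        np.testing.assert_allclose(lg_dig[0, 0, 0, 0], np.log(0.25), atol=0.005)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_expectations(np.zeros((1, 1, 2, 2)))


def _known_maps(A, B, D):
    lnA = floor_log(A.sub)
    lnBinv = floor_log(bayes_invert(B, D))
    lnD = floor_log(D.block)
    return lnA, lnBinv, lnD


class TestInferState:
    def test_symmetric_logits_give_half(self):
        lnA = np.zeros((1, 1, 2, 2))
        lnBinv = np.zeros((1, 1, 2, 2))
        lnD = np.zeros((2, 1))
        s = infer_state(block([1.0]), block([0.5]), lnA, lnBinv, lnD)
        np.testing.assert_allclose(s.p1, 0.5)

    def test_identity_likelihood_concentrates_on_observation(self):
        A = FactorizedMapping("A", np.eye(2)[None, None])
        B = FactorizedMapping.flat("B", 1, 1)
        D = PriorVector.uniform(1)
        s = infer_state(block([1.0]), block([0.5]), *_known_maps(A, B, D))
        assert s.p1[0] > 1 - 1e-8

    def test_first_step_matches_exact_bayes(self, rng):
        """With a flat transition (which washes the previous belief out to
        a uniform state prior), the update is exact Bayes' rule on the
        first observation (enumerable for one factor)."""
        for _ in range(20):
            A = FactorizedMapping.random("A", 1, 1, rng)
            B = FactorizedMapping.flat("B", 1, 1)
            D = PriorVector.from_p1(rng.uniform(0.1, 0.9, 1))
            o = int(rng.integers(0, 2))
            s = infer_state(block([float(o)]), block([0.5]),
                            *_known_maps(A, B, D))
            num = A.sub[0, 0, 1 - o, 0] * 0.5
            den = num + A.sub[0, 0, 1 - o, 1] * 0.5
            assert s.p1[0] == pytest.approx(num / den, abs=1e-9)

    def test_onehot_previous_state_matches_exact_filter(self, rng):
        for _ in range(20):
            A = FactorizedMapping.random("A", 1, 1, rng)
            B = FactorizedMapping.random("B", 1, 1, rng)
            D = PriorVector.from_p1(rng.uniform(0.1, 0.9, 1))
            o = int(rng.integers(0, 2))
            sp = int(rng.integers(0, 2))  # previous state value
            s = infer_state(block([float(o)]), block([float(sp)]),
                            *_known_maps(A, B, D))
            num = A.sub[0, 0, 1 - o, 0] * B.sub[0, 0, 0, 1 - sp]
            den = num + A.sub[0, 0, 1 - o, 1] * B.sub[0, 0, 1, 1 - sp]
            assert s.p1[0] == pytest.approx(num / den, abs=1e-9)


class TestInferDecision:
    def test_uniform_256_way_prior(self):
        """Flat policy and uniform prior over a 256-option one-hot block:
        every element is 1/256, approximately 0.0039."""
        n_d = 256
        lnCinv = np.zeros((1, n_d, 2, 2))
        E1 = np.full(n_d, 1 / 256)
        lnE = floor_log(np.stack([E1, 1 - E1]))
        d = infer_decision(block([0.5]), lnCinv, lnE)
        np.testing.assert_allclose(d.p1, 1 / 256, atol=1e-12)
        assert round(float(d.p1[0]), 4) == 0.0039

    def test_zero_logits_two_options(self):
        d = infer_decision(block([0.5]), np.zeros((1, 2, 2, 2)),
                           np.zeros((2, 2)))
        np.testing.assert_allclose(d.p1, 0.5)

    def test_random_two_option_matches_enumeration(self, rng):
        for _ in range(20):
            C = FactorizedMapping.random("C", 2, 1, rng)
            E = PriorVector.from_p1(rng.uniform(0.1, 0.9, 2))
            sp = int(rng.integers(0, 2))
            lnCinv = floor_log(bayes_invert(C, E))
            d = infer_decision(block([float(sp)]), lnCinv, floor_log(E.block))
            for k in range(2):
                num = C.sub[k, 0, 0, 1 - sp]  # P(d_k = 1 | s_prev)
                assert d.p1[k] == pytest.approx(num / (num + C.sub[k, 0, 1, 1 - sp]),
                                                abs=1e-9)


class TestUpdateParameters:
    def test_empty_history_returns_priors(self):
        bank = DirichletBank.flat(1, 1, 2)
        hist = History(np.empty((0, 2, 1)), np.zeros((1, 2, 1)) + 0.5)
        new = update_parameters(bank, hist, 0.0)
        np.testing.assert_array_equal(new.a, bank.a0)

    def test_gamma_half_keeps_only_current_decision_term(self):
        bank = DirichletBank.flat(1, 1, 1)
        obs = np.stack([block([1.0]), block([0.0])])
        states = np.stack([block([1.0]), block([1.0]), block([0.0])])
        decs = np.stack([block([1.0]), block([0.0])])
        new = update_parameters(bank, History(obs, states, decs), Gamma_t=0.5)
        # only d_2 (x) s_1 contributes: d=(0,1) outer s_prev=(1,0)
        expected = bank.c0.copy()
        expected[0, 0, 1, 0] += 1.0
        np.testing.assert_allclose(new.c, expected)

    def test_two_step_onehot_counts_by_hand(self):
        """Hand-counted co-occurrences on a printed two-step example."""
        bank = DirichletBank.flat(1, 1, 1)
        # o: 1 then 0; s: s0=1, s1=1, s2=0; d: 1 then 0; Gamma_t = 0
        obs = np.stack([block([1.0]), block([0.0])])
        states = np.stack([block([1.0]), block([1.0]), block([0.0])])
        decs = np.stack([block([1.0]), block([0.0])])
        new = update_parameters(bank, History(obs, states, decs), 0.0)
        ea = bank.a0.copy()
        ea[0, 0, 0, 0] += 1.0   # o=1 with s=1
        ea[0, 0, 1, 1] += 1.0   # o=0 with s=0
        np.testing.assert_allclose(new.a, ea)
        eb = bank.b0.copy()
        eb[0, 0, 0, 0] += 1.0   # s1=1 given s0=1
        eb[0, 0, 1, 0] += 1.0   # s2=0 given s1=1
        np.testing.assert_allclose(new.b, eb)
        ec = bank.c0.copy()
        ec[0, 0, 0, 0] += 1.0   # past d1=1 with s0=1, weight (1-2*0) = 1
        ec[0, 0, 1, 0] += 1.0   # current d2=0 with s1=1
        np.testing.assert_allclose(new.c, ec)

    def test_anti_hebbian_clamp(self, caplog):
        bank = DirichletBank(a=np.ones((1, 1, 2, 2)), b=np.ones((1, 1, 2, 2)),
                             c=np.full((1, 1, 2, 2), 0.5))
        obs = np.stack([block([1.0])] * 3)
        states = np.stack([block([1.0])] * 4)
        decs = np.stack([block([1.0])] * 3)
        with caplog.at_level("WARNING", logger="cannet"):
            new = update_parameters(bank, History(obs, states, decs), Gamma_t=1.0)
        assert np.all(new.c > 0)
        assert "nonpositive" in caplog.text

    def test_parameter_recovery_from_samples(self, rng):
        """Counts from 10^4 one-hot samples recover the true likelihood and
        transition means within 0.05."""
        A = FactorizedMapping.random("A", 1, 1, rng, low=0.2, high=0.8)
        B = FactorizedMapping.random("B", 1, 1, rng, low=0.2, high=0.8)
        D = PriorVector.uniform(1)
        traj = sample_generative_process(A, B, D, None, T=10_000, seed=3)
        ob = traj.observations.astype(float)
        obs = np.stack([ob, 1 - ob], axis=1)
        sts = np.concatenate([[[0.5]], traj.states.astype(float)])
        states = np.stack([sts, 1 - sts], axis=1)
        bank = DirichletBank.flat(1, 1, 1, value=1.0)
        new = update_parameters(bank, History(obs, states), 0.0)
        np.testing.assert_allclose(new.mean("a"), A.sub, atol=0.05)
        np.testing.assert_allclose(new.mean("b"), B.sub, atol=0.05)


def _iid_model(rng):
    """One-factor model with flat transitions: observations are iid and the
    exact evidence is enumerable."""
    A = FactorizedMapping.random("A", 1, 1, rng)
    B = FactorizedMapping.flat("B", 1, 1)
    lnA, lnB = floor_log(A.sub), floor_log(B.sub)
    return A, lnA, lnB


class TestFreeEnergy:
    def test_report_parts_sum_to_total(self, rng):
        A, lnA, lnB = _iid_model(rng)
        C = FactorizedMapping.random("C", 1, 1, rng)
        obs = np.stack([block([1.0]), block([0.0])])
        states = np.stack([block([0.5]), block([0.6]), block([0.4])])
        decs = np.stack([block([0.3]), block([0.7])])
        bank = DirichletBank.flat(1, 1, 1, value=2.0)
        bank.a0 = np.ones_like(bank.a0)
        rep = free_energy(History(obs, states, decs), lnA, lnB,
                          floor_log(C.sub), Gamma_t=0.2, bank=bank,
                          include_parameter_complexity=True)
        assert rep.total == pytest.approx(
            rep.accuracy_state_term + rep.decision_term
            + rep.parameter_complexity, abs=1e-9)
        assert rep.parameter_complexity > 0
        # the risk entropy is reported but excluded from the optimized total
        assert rep.risk_entropy == pytest.approx(
            -(0.2 * np.log(0.2) + 0.8 * np.log(0.8)))

    def test_report_tsv_export(self, rng, tmp_path):
        import pandas as pd
        from cannet.inference import free_energy_to_tsv

        A, lnA, lnB = _iid_model(rng)
        obs = np.stack([block([1.0]), block([0.0])])
        states = np.stack([block([0.5]), block([0.6]), block([0.4])])
        rep = free_energy(History(obs, states), lnA, lnB)
        free_energy_to_tsv(rep, tmp_path / "f.tsv")
        df = pd.read_csv(tmp_path / "f.tsv", sep="\t")
        assert {"time", "term", "value"} <= set(df.columns)
        total = df.loc[df.term == "total", "value"].iloc[0]
        assert total == pytest.approx(rep.total)

    def test_exact_posterior_attains_negative_log_evidence(self, rng):
        """F at the exact filtered posterior equals -ln P(o_{1:T}) on an
        iid one-factor model, and is strictly larger at any perturbation."""
        for _ in range(10):
            A, lnA, lnB = _iid_model(rng)
            T = 5
            o_vals = rng.integers(0, 2, T)
            obs = np.stack([block([float(v)]) for v in o_vals])
            states = [block([0.5])]
            log_ev = 0.0
            for v in o_vals:
                num = A.sub[0, 0, 1 - v, 0] * 0.5
                den = num + A.sub[0, 0, 1 - v, 1] * 0.5
                log_ev += np.log(den)
                states.append(block([num / den]))
            states = np.stack(states)
            rep = free_energy(History(obs, states), lnA, lnB)
            assert rep.total == pytest.approx(-log_ev, abs=1e-9)
            # perturbation strictly increases F
            pert = states.copy()
            pert[-1] = block([np.clip(states[-1][0, 0] + 0.1, 0.01, 0.99)])
            rep_p = free_energy(History(obs, pert), lnA, lnB)
            assert rep_p.total > rep.total + 1e-6

    def test_stationary_at_coordinate_minimizer(self, rng):
        from cannet.pomdp import bayes_invert, PriorVector

        A = FactorizedMapping.random("A", 1, 1, rng)
        B = FactorizedMapping.random("B", 1, 1, rng)
        lnA, lnB = floor_log(A.sub), floor_log(B.sub)
        s_prev = block(rng.uniform(0.2, 0.8, 1))
        o = block([1.0])
        # coordinate minimizer via the forward-form logits
        logits = (np.einsum("ijmk,mi->kj", lnA, o)
                  + np.einsum("jpkl,lp->kj", lnB, s_prev))
        s_star = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)

        def F(p1):
            states = np.stack([s_prev, block([p1])])
            return free_energy(History(o[None], states), lnA, lnB).total

        p = float(s_star[0, 0])
        eps = 1e-5
        grad = (F(p + eps) - F(p - eps)) / (2 * eps)
        assert abs(grad) < 1e-6

    def test_gamma_half_erases_past_decision_evidence(self, rng):
        C = FactorizedMapping.random("C", 1, 1, rng)
        A, lnA, lnB = _iid_model(rng)
        lnC = floor_log(C.sub)
        obs = np.stack([block([1.0]), block([1.0])])
        states = np.stack([block([0.5]), block([0.6]), block([0.6])])
        decs = np.stack([block([0.3]), block([0.4])])
        rep = free_energy(History(obs, states, decs), lnA, lnB, lnC,
                          Gamma_t=0.5)
        # past decision contributes only its entropy term
        d_ent = float(np.sum(decs[0] * np.log(decs[0])))
        ev_C = np.einsum("kjml,lj->mk", lnC, states[1])
        cur = float(np.sum(decs[1] * (np.log(decs[1]) - ev_C)))
        assert rep.decision_term == pytest.approx(d_ent + cur, abs=1e-9)

    def test_forward_and_inverse_forms_agree_one_factor(self, rng):
        """With the Bayes-inverse mappings, the generative-direction and
        inverse-direction evaluations coincide for one-factor models, up
        to an exactly characterized prior term on risk-modulated past
        steps (the decision log-prior enters the inverse form unmodulated
        while the forward form carries it inside the modulated evidence)."""
        for gamma in (0.0, 0.3):
            A = FactorizedMapping.random("A", 1, 1, rng)
            B = FactorizedMapping.random("B", 1, 1, rng)
            C = FactorizedMapping.random("C", 2, 1, rng)
            D = PriorVector.from_p1(rng.uniform(0.2, 0.8, 1))
            E = PriorVector.from_p1(rng.uniform(0.2, 0.8, 2))
            lnA = floor_log(A.sub)
            obs = np.stack([block([1.0]), block([0.0]), block([1.0])])
            states = np.stack([block([0.5]), block([0.3]), block([0.7]),
                               block([0.4])])
            decs = np.stack([block([0.2, 0.6]), block([0.5, 0.5]),
                             block([0.9, 0.1])])
            hist = History(obs, states, decs)
            f_fwd = free_energy(hist, lnA, floor_log(B.sub),
                                floor_log(C.sub), Gamma_t=gamma)
            f_inv = free_energy(hist, lnA, floor_log(bayes_invert(B, D)),
                                floor_log(bayes_invert(C, E)),
                                floor_log(D.block), floor_log(E.block),
                                Gamma_t=gamma, form="inverse")
            # residual: 2 * Gamma * sum over past steps of d . ln E
            resid = 2 * gamma * float(
                np.sum(decs[:-1] * floor_log(E.block)[None]))
            assert f_inv.total + resid == pytest.approx(f_fwd.total, abs=1e-9)

    def test_coordinate_updates_never_increase_free_energy(self, rng):
        """Applying the state update from any belief cannot increase F
        (checked on 100 random one-factor instances)."""
        from cannet.pomdp import bayes_invert

        worse = 0
        for _ in range(100):
            A = FactorizedMapping.random("A", 1, 1, rng)
            B = FactorizedMapping.random("B", 1, 1, rng)
            lnA, lnB = floor_log(A.sub), floor_log(B.sub)
            s_prev = block(rng.uniform(0.1, 0.9, 1))
            o = block([float(rng.integers(0, 2))])
            s_bad = block(rng.uniform(0.05, 0.95, 1))
            F_bad = free_energy(History(o[None], np.stack([s_prev, s_bad])),
                                lnA, lnB).total
            logits = (np.einsum("ijmk,mi->kj", lnA, o)
                      + np.einsum("jpkl,lp->kj", lnB, s_prev))
            s_new = np.exp(logits - logits.max(axis=0))
            s_new /= s_new.sum(axis=0, keepdims=True)
            F_new = free_energy(History(o[None], np.stack([s_prev, s_new])),
                                lnA, lnB).total
            if F_new > F_bad + 1e-10:
                worse += 1
        assert worse == 0
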