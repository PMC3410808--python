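import numpy as np
import pytest

from survperf import (
    ModelSpec,
    build_model,
    cox_model_one,
    cox_model_two,
    evaluate_all,
    fit_cox,
    integrated_brier_two_group,
    km_estimate,
    logrank_test,
    logrank_threshold_scan,
    predict_risk,
    roc_auc_at,
    somers_dxy,
)
from conftest import random_censored_instance


def dxy_bruteforce(scores, times, events):
    """O(n^2) pair enumeration oracle for Somers' D_xy."""
    n = len(times)
    usable = 0
    conc = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the subject with the shorter time and an event; at a
            # tied time, an event-vs-censored pair treats the censored subject
            # as the longer survivor
            earlier_event = times[i] < times[j] and events[i] == 1
            tied_pair = times[i] == times[j] and events[i] == 1 and events[j] == 0
            if not (earlier_event or tied_pair):
                continue
            usable += 1
            if scores[i] < scores[j]:
                conc += 1.0
            elif scores[i] == scores[j]:
                conc += 0.5
    if usable == 0:
        raise ValueError("no comparable pairs")
    return 2.0 * conc / usable - 1.0


def mann_whitney_auc(case_scores, control_scores):
    """Tie-corrected Mann–Whitney oracle for the time-dependent AUC."""
    wins = 0.0
    for c in case_scores:
        for k in control_scores:
            if c > k:
                wins += 1.0
            elif c == k:
                wins += 0.5
    return wins / (len(case_scores) * len(control_scores))


class TestSomersDxy:
    def test_perfect_concordance_signs(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.ones(4, dtype=int)
        assert somers_dxy(np.array([1.0, 2, 3, 4]), t, e) == 1.0
        assert somers_dxy(np.array([4.0, 3, 2, 1]), t, e) == -1.0

    def test_all_ties_give_zero(self):
        t = np.array([1.0, 2, 3])
        assert somers_dxy(np.zeros(3), t, np.ones(3, dtype=int)) == 0.0

    def test_hand_enumerated_example(self):
        d = somers_dxy(np.array([10.0, 8, 3, 9]), [2, 4, 5, 7], [1, 0, 1, 1])
        assert d == pytest.approx(-0.5)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            times, events, scores = random_censored_instance(
                rng, n, censor_frac=float(rng.uniform(0, 0.6)), tie_times=bool(rng.integers(2)))
            if events.sum() == 0:
                continue
            try:
                expected = dxy_bruteforce(scores, times, events)
            except ValueError:
                continue
            assert somers_dxy(scores, times, events) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_and_monotone_invariance(self, rng):
        times, events, scores = random_censored_instance(rng, 25)
        d = somers_dxy(scores, times, events)
        assert somers_dxy(-scores, times, events) == pytest.approx(-d)
        assert somers_dxy(np.exp(scores), times, events) == pytest.approx(d)

    def test_no_usable_pairs_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            somers_dxy(np.array([1.0, 2.0]), [1.0, 2.0], [0, 0])


class TestCoxModels:
    def test_cox1_from_closed_form_fit(self):
        out = cox_model_one(np.array([1.0, 0.0, 1.0]), [1, 2, 3], [1, 1, 1])
        assert out["hr"] == pytest.approx(np.exp(-np.log(2) / 2), abs=1e-6)
        assert out["ci_low"] <= out["hr"] <= out["ci_high"]
        assert 0 <= out["r2"] < 1

    def test_cox1_constant_scores_error(self):
        with pytest.raises(ValueError, match="constant"):
            cox_model_one(np.ones(4), [1, 2, 3, 4], [1, 1, 1, 1])

    def test_r2_zero_iff_null_coefficient(self, rng):
        # two duplicated outcome blocks with a perfectly balanced binary score
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.array([1, 1, 1, 1, 1, 1])
        out = cox_model_one(np.array([0.0, 1, 0, 1, 0, 1]), t, e)
        assert out["r2"] == pytest.approx(0.0, abs=1e-6)

    def test_cox2_median_split_and_symmetry(self):
        train_scores = np.array([0.0, 1, 2, 3, 4])  # median 2
        test_scores = np.array([1.0, 2.0, 3.0, 5.0])
        t = np.array([1.0, 2, 1, 2])
        e = np.array([1, 1, 1, 1])
        out = cox_model_two(train_scores, test_scores, t, e)
        # scores equal to the median go low-risk
        assert out["n_low"] == 2 and out["n_high"] == 2
        assert out["hr"] == pytest.approx(1.0, abs=1e-6)

    def test_cox2_degenerate_dichotomy(self):
        with pytest.raises(ValueError, match="degenerate dichotomy"):
            cox_model_two(np.array([0.0, 1, 2]), np.array([5.0, 6, 7]),
                          [1, 2, 3], [1, 1, 1])

    def test_cox2_score_p_equals_logrank(self, rng):
        # on untied data the Cox score test for the dichotomy is the log-rank test
        for _ in range(20):
            n = 20
            times, events, _ = random_censored_instance(rng, n)
            if events.sum() < 2:
                continue
            train_scores = rng.normal(size=30)
            test_scores = rng.normal(size=n)
            group = (test_scores > np.median(train_scores)).astype(int)
            if group.sum() in (0, n):
                continue
            chi2, p = logrank_test(times, events, group)
            fit = fit_cox(group[:, None].astype(float), times, events)
            assert fit.score_p == pytest.approx(p, abs=1e-8)


def ibs_oracle(group, times, events, tau):
    """Independent step-function integration of the two-group Brier score."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    n = len(times)

    def km_func(ts, es):
        # plain product-limit, deaths before censorings at ties
        pairs = sorted(zip(ts, es), key=lambda q: (q[0], -q[1]))
        jumps = []
        s = 1.0
        uniq = sorted(set(t for t, _ in pairs))
        for u in uniq:
            at_risk = sum(1 for t, _ in pairs if t >= u)
            d = sum(1 for t, e in pairs if t == u and e == 1)
            if d:
                s *= 1 - d / at_risk
                jumps.append((u, s))
        def f(x):
            val = 1.0
            for u, sv in jumps:
                if u <= x:
                    val = sv
            return val
        def f_left(x):
            val = 1.0
            for u, sv in jumps:
                if u < x:
                    val = sv
            return val
        return f, f_left

    km_g = {lvl: km_func(times[group == lvl], events[group == lvl])[0] for lvl in np.unique(group)}
    ghat, ghat_left = km_func(times, 1 - events)

    zero_times = sorted(t for t in times if ghat(t) <= 0)
    tau_eff = min(tau, zero_times[0]) if zero_times else tau

    def bs(t0):
        total = 0.0
        for i in range(n):
            sp = km_g[group[i]](t0)
            if times[i] <= t0 and events[i] == 1:
                w = ghat_left(times[i])
                if w > 0:
                    total += sp**2 / w
            elif times[i] > t0:
                w = ghat(t0)
                if w > 0:
                    total += (1 - sp) ** 2 / w
        return total / n

    breaks = sorted(set([0.0] + [t for t in times if t < tau_eff] + [tau_eff]))
    integral = sum(bs((a + b) / 2) * (b - a) for a, b in zip(breaks[:-1], breaks[1:]))
    return integral / tau_eff


class TestIntegratedBrier:
    def test_event_free_groups_give_zero(self):
        assert integrated_brier_two_group([0, 0, 1, 1], [1, 2, 3, 4], [0, 0, 0, 0]) == 0.0

    def test_small_hand_instance_against_oracle(self):
        group = np.array([1, 1, 0, 0])
        times = np.array([1.0, 3.0, 4.0, 5.0])
        events = np.array([1, 1, 1, 0])
        ours = integrated_brier_two_group(group, times, events)
        ref = ibs_oracle(group, times, events, tau=float(times.max()))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 20))
            times, events, _ = random_censored_instance(rng, n, censor_frac=0.3,
                                                        tie_times=bool(rng.integers(2)))
            group = rng.integers(0, 2, size=n)
            if len(np.unique(group)) < 2:
                continue
            tau = float(times.max())
            ours = integrated_brier_two_group(group, times, events, tau)
            ref = ibs_oracle(group, times, events, tau)
            assert ours == pytest.approx(ref, abs=1e-10)
            assert 0.0 <= ours <= 1.0

    def test_uncensored_equals_mean_squared_km_error(self, rng):
        # without censoring, weights vanish and the IBS is the plain
        # integrated squared error of the group KM step functions
        n = 14
        times = rng.exponential(3, size=n) + 0.1
        events = np.ones(n, dtype=int)
        group = rng.integers(0, 2, size=n)
        if len(np.unique(group)) < 2:
            group[0], group[1] = 0, 1
        tau = float(times.max())
        km_by = {lvl: km_estimate(times[group == lvl], events[group == lvl])
                 for lvl in (0, 1)}
        breaks = np.unique(np.concatenate([[0.0], times[times < tau], [tau]]))
        ref = 0.0
        for a, b in zip(breaks[:-1], breaks[1:]):
            mid_status = (times > a).astype(float)
            preds = np.array([km_by[g].evaluate(a) for g in group])
            ref += np.mean((mid_status - preds) ** 2) * (b - a)
        ref /= tau
        assert integrated_brier_two_group(group, times, events, tau) == pytest.approx(ref, abs=1e-10)

    def test_invalid_tau_errors(self):
        with pytest.raises(ValueError, match="tau"):
            integrated_brier_two_group([0, 1], [1, 2], [1, 1], tau=-1.0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([5.0, 6.0, 1.0, 2.0])
        _, auc = roc_auc_at(scores, [1, 2, 9, 9], [1, 1, 0, 0], t=5)
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc_at(np.zeros(4), [1, 2, 9, 9], [1, 1, 0, 0], t=5)
        assert auc == 0.5

    def test_hand_counted_example(self):
        curve, auc = roc_auc_at(np.array([9.0, 4, 6, 2]), [2, 3, 6, 8], [1, 1, 1, 0], t=5)
        assert auc == pytest.approx(0.75)
        assert curve.n_cases == 2 and curve.n_controls == 2 and curve.n_excluded == 0

    def test_censored_before_t_excluded(self):
        curve, _ = roc_auc_at(np.array([1.0, 2, 3, 4]), [1, 2, 6, 7], [1, 0, 1, 0], t=5)
        assert curve.n_excluded == 1

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 30))
            times, events, scores = random_censored_instance(rng, n, tie_times=True)
            scores = np.round(scores, 1)  # force score ties
            t = float(np.median(times))
            case = (times <= t) & (events == 1)
            control = times > t
            if case.sum() == 0 or control.sum() == 0:
                continue
            _, auc = roc_auc_at(scores, times, events, t)
            ref = mann_whitney_auc(scores[case], scores[control])
            assert auc == pytest.approx(ref, abs=1e-12)

    def test_no_cases_errors(self):
        with pytest.raises(ValueError, match="case"):
            roc_auc_at(np.array([1.0, 2.0]), [9, 9], [1, 1], t=5)


class TestThresholdScan:
    def test_two_subjects_single_entry(self):
        scan = logrank_threshold_scan(np.array([1.0, 2.0]), [3, 1], [1, 1])
        assert scan.k.size == 1

    def test_cluster_boundary_has_minimum_p(self):
        # two well-separated survival clusters; scores separate the clusters
        # but are uninformative within each, so the best split is the boundary
        times = np.array([1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 9.0, 9.4, 9.8, 10.2, 10.6, 11.0])
        events = np.ones(12, dtype=int)
        jitter = np.array([0.3, -0.1, 0.2, -0.3, 0.1, -0.2])
        scores = np.concatenate([10.0 + jitter, 0.0 + jitter[::-1]])
        scan = logrank_threshold_scan(scores, times, events)
        assert scan.k[np.argmin(scan.pvalues)] == 6
        # oracle: recompute each split's log-rank directly
        order = np.argsort(scores, kind="stable")
        for i, k in enumerate(scan.k):
            group = np.ones(12, dtype=int)
            group[order[:k]] = 0
            _, p = logrank_test(times, events, group)
            assert scan.pvalues[i] == pytest.approx(p)

    def test_rank_relabeling_invariance(self, rng):
        times, events, scores = random_censored_instance(rng, 15)
        if events.sum() == 0:
            events[0] = 1
        s1 = logrank_threshold_scan(scores, times, events)
        s2 = logrank_threshold_scan(np.tanh(scores) * 100, times, events)
        np.testing.assert_allclose(s1.pvalues, s2.pvalues, atol=1e-12)


class TestEvaluateAll:
    def test_deterministic_and_complete(self, small_cohort):
        train, test, _ = small_cohort
        model = build_model(ModelSpec("D"), train)
        r1 = evaluate_all(model, train, test, [3.0, 5.0])
        r2 = evaluate_all(model, train, test, [3.0, 5.0])
        assert r1.to_row() == r2.to_row()
        assert r1.dxy is not None and r1.ibs is not None
        assert set(r1.auc_by_time) == {3.0, 5.0}

    def test_strong_signal_detected(self):
        from survperf import SimConfig, generate
        dxys, ps = [], []
        for seed in range(10):
            cfg = SimConfig(n_train=80, n_test=100, n_genes=20, n_signal_genes=5,
                            beta_gene=0.6, gene_block_rho=0.4, beta_clinical=0.6,
                            censoring_rate_target=0.2, seed=seed)
            train, test, _ = generate(cfg)
            model = build_model(ModelSpec("E"), train)
            rep = evaluate_all(model, train, test, [])
            dxys.append(rep.dxy)
            ps.append(rep.cox1["p"])
        assert np.median(dxys) < -0.3
        assert np.median(ps) < 0.01
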