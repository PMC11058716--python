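"""Link deltas, Jensen-Shannon divergence, hubs and target integration."""

import numpy as np
import pytest
from scipy import stats

from protgrn.datasets import CONTROL, TREATMENT, GRNetwork
from protgrn.divergence import (
    DivergenceRecord,
    find_hubs,
    integrate_targets,
    js_divergence,
    link_deltas,
    prda,
)
from protgrn.errors import ValidationError
from protgrn.precision import PortiaGRN
from protgrn.preprocess import log2_transform
from protgrn.robustness import MGN, NoiseSpec, build_ensembles
from protgrn.roles import RoleChangeResult
from protgrn.simulate import generate_truth, perturb_hub, sample_ggm_expression


def _net(weights, condition=""):
    n = weights.shape[0]
    return GRNetwork(tuple(f"P{i}" for i in range(n)), weights,
                     condition=condition)


class TestLinkDeltas:
    def test_identical_networks_nothing_flagged(self, rng):
        w = rng.random((6, 6))
        np.fill_diagonal(w, 0)
        records = link_deltas(_net(w), _net(w.copy()))
        assert all(r.delta == 0 for r in records)
        assert not any(r.in_top_decile for r in records)

    def test_single_changed_link_flagged(self, rng):
        w = rng.random((6, 6))
        np.fill_diagonal(w, 0)
        w2 = w.copy()
        w2[2, 4] += 1.0
        records = link_deltas(_net(w), _net(w2), top_frac=0.05)
        flagged = [r for r in records if r.in_top_decile]
        assert len(flagged) >= 1
        assert flagged[0].regulator == "P2" and flagged[0].target == "P4"

    def test_flag_count_is_ceil_of_fraction(self, rng):
        n = 7  # 42 links
        a = rng.random((n, n)); np.fill_diagonal(a, 0)
        b = rng.random((n, n)); np.fill_diagonal(b, 0)
        records = link_deltas(_net(a), _net(b), top_frac=0.10)
        assert sum(r.in_top_decile for r in records) == int(np.ceil(0.10 * 42))

    def test_universe_mismatch_rejected(self, rng):
        w = rng.random((4, 4)); np.fill_diagonal(w, 0)
        other = GRNetwork(("A", "B", "C", "D"), w.copy())
        with pytest.raises(ValidationError):
            link_deltas(_net(w), other)


class TestJSDivergence:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(0, 1, 100)
        assert js_divergence(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_approach_one(self, rng):
        a = rng.normal(0, 0.1, 200)
        b = rng.normal(10, 0.1, 200)
        assert js_divergence(a, b) > 0.99

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.5, 1.2, 80)
        assert js_divergence(a, b) == pytest.approx(js_divergence(b, a))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 2), 50)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 2), 50)
            assert 0.0 <= js_divergence(a, b) <= 1.0

    def test_matches_quadrature_oracle_for_gaussians(self):
        """Empirical JS of two shifted Gaussians ~ quadrature JS within 0.02."""
        mu_shift = 1.5
        p = lambda x: stats.norm.pdf(x, 0, 1)  # noqa: E731
        q = lambda x: stats.norm.pdf(x, mu_shift, 1)  # noqa: E731
        grid = np.linspace(-8, 8 + mu_shift, 20001)
        dp, dq = p(grid), q(grid)
        m = 0.5 * (dp + dq)

        def kl(a, b):
            ratio = np.where(a > 0, a / np.maximum(b, 1e-300), 1.0)
            return np.trapezoid(a * np.log2(np.maximum(ratio, 1e-300)), grid)

        js_true = 0.5 * kl(dp, m) + 0.5 * kl(dq, m)
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(mu_shift, 1, 10_000)
        assert js_divergence(a, b) == pytest.approx(js_true, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            js_divergence([1.0], [1.0, 2.0])


class TestFindHubs:
    def _record(self, a, b, significant=True):
        return DivergenceRecord(a, b, 1.0, in_top_decile=True,
                                significant=significant)

    def test_star_center_is_hub(self):
        records = [self._record("HUB", f"L{i}") for i in range(4)]
        assert find_hubs(records) == ["HUB"]

    def test_threshold_above_degree_gives_empty(self):
        records = [self._record("HUB", f"L{i}") for i in range(3)]
        assert find_hubs(records, min_links=4) == []

    def test_matches_degree_count_oracle(self, rng):
        proteins = [f"P{i}" for i in range(8)]
        records = []
        for _ in range(30):
            a, b = rng.choice(proteins, 2, replace=False)
            records.append(self._record(a, b, significant=bool(rng.random() < 0.5)))
        degree = {}
        for r in records:
            if r.significant:
                for p in (r.regulator, r.target):
                    degree[p] = degree.get(p, 0) + 1
        expected = sorted(p for p, d in degree.items() if d >= 2)
        assert find_hubs(records, min_links=2) == expected


class TestIntegrateTargets:
    def _pra(self, protein, significant=False, critical=False):
        return RoleChangeResult(protein, 0.01, 0.01, significant, "neutral",
                                "critical" if critical else "neutral", critical)

    def _prda(self, a, b, significant=True):
        return DivergenceRecord(a, b, 1.0, in_top_decile=True,
                                significant=significant)

    def test_pra_only_is_candidate_not_principal(self):
        pra = [self._pra("X", significant=True), self._pra("Y")]
        prda_records = [self._prda("A", "B")]
        report = integrate_targets(pra, prda_records, hubs=[])
        assert "X" in report.candidates
        assert "X" not in report.principal_targets

    def test_hub_without_pra_is_principal(self):
        pra = [self._pra("A"), self._pra("B")]
        records = [self._prda("A", f"L{i}") for i in range(4)]
        report = integrate_targets(pra, records)
        assert "A" in report.principal_targets

    def test_pra_significant_prda_member_is_principal(self):
        pra = [self._pra("A", significant=True)]
        records = [self._prda("A", "B")]
        report = integrate_targets(pra, records, hubs=[])
        assert "A" in report.principal_targets

    def test_critical_transition_is_principal(self):
        pra = [self._pra("Z", significant=True, critical=True)]
        report = integrate_targets(pra, [], hubs=[])
        assert report.principal_targets == ["Z"]


class TestPRDA:
    def _run(self, truth, seed, n_reps=15, obs_noise_sd=0.0, **kw):
        infer = lambda d: PortiaGRN().fit(d).network()  # noqa: E731
        data = log2_transform(
            sample_ggm_expression(truth, seed=seed, obs_noise_sd=obs_noise_sd)
        )
        nets = {c: infer(data.condition(c)) for c in (CONTROL, TREATMENT)}
        spec = NoiseSpec(kind=MGN, sigma=0.05, n_reps=n_reps, seed=seed)
        ens = build_ensembles(
            {c: data.condition(c) for c in (CONTROL, TREATMENT)}, infer, spec
        )
        return prda(ens, nets[CONTROL], nets[TREATMENT], **kw)

    def test_restriction_contract(self):
        truth = generate_truth(8, 0.25, 0.1, seed=1)
        records = self._run(truth, seed=2, restrict_to={"P0003"})
        assert records
        assert all("P0003" in (r.regulator, r.target) for r in records)

    def test_null_safety(self):
        """Zero effect: paired null flags nothing; noisy null stays insignificant.

        With identical condition data every delta is exactly zero, so no link
        is flagged. With observation noise the realized data differences make
        |delta| and JS positively correlated by common cause, so rank-level
        flags exist — but the SD gate keeps the *significant* set (essentially)
        empty across seeds.
        """
        truth = generate_truth(8, 0.25, 0.0, seed=0)
        records = self._run(truth, seed=11, n_reps=10)
        assert not any(r.in_top_decile for r in records)

        sig_fracs, hub_free = [], 0
        for seed in range(10):
            truth = generate_truth(8, 0.25, 0.0, seed=seed)
            records = self._run(truth, seed=seed + 20, n_reps=10,
                                obs_noise_sd=0.05)
            sig_fracs.append(np.mean([r.significant for r in records]))
            hub_free += len(find_hubs(records)) == 0
        # a stray link or two may pass the gate, but never enough to
        # manufacture a hub, and the overall rate stays tiny
        assert np.mean(sig_fracs) <= 0.05
        assert hub_free >= 9

    def test_perturbed_edge_has_top_decile_js(self):
        """A strongly perturbed edge lands in the JS top decile (>=80%)."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = generate_truth(10, 0.2, 0.0, seed=seed)
            t2 = perturb_hub(truth, n_edges=1, strength=4.0, seed=seed,
                             stabilize=False)
            j, i = np.argwhere(t2.treatment_delta != 0)[0]
            records = self._run(t2, seed=seed + 300)
            pair = {t2.proteins[j], t2.proteins[i]}
            by_js = sorted(records, key=lambda r: -r.js)
            k = int(np.ceil(0.1 * len(records)))
            hits += any({r.regulator, r.target} == pair for r in by_js[:k])
        assert hits / n_seeds >= 0.8
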