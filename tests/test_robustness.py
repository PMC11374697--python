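"""Extinction cascades: hand cases, brute-force oracle, invariants."""

import numpy as np
import pytest

from landnetsim.errors import ValidationError
from landnetsim.robustness import (
    CascadeEngine,
    ExtinctionCurve,
    Scenario,
    removal_order,
    robustness,
    robustness_variability,
    run_replicates,
    simulate_cascade,
)

from conftest import make_site, random_web, rec

_EPS = 1e-9


# ---------------------------------------------------------------------------
# independent oracle: no-rewiring cascade by direct set-based fixpoint


def f0_oracle(landscape, order, theta):
    """Surviving-insect fraction after each removal, computed by recomputing
    each stage's remaining events over currently-extant resources and iterating
    organism extinctions to a fixed point (no event bookkeeping)."""
    events = {}  # (itype, consumer) -> {resource: n}
    for r in landscape.records():
        events.setdefault((r.itype.value, r.consumer), {}).setdefault(r.resource, 0)
        events[(r.itype.value, r.consumer)][r.resource] += r.count
    orig = {k: sum(d.values()) for k, d in events.items()}
    plants = set(landscape.plants())
    species = {c for _, c in events} | {
        r for d in events.values() for r in d if r not in plants
    }
    org_of = {s: landscape.organism(s) for s in species}
    orgs = set(org_of.values())

    y = [1.0]
    for k in range(1, len(order) + 1):
        removed = set(order[:k])
        alive = set(orgs)
        while True:
            dead_sp = {s for s in species if org_of[s] not in alive}
            newly_dead = set()
            for (it, c), d in events.items():
                if org_of[c] not in alive:
                    continue
                remaining = sum(
                    n for res, n in d.items() if res not in removed and res not in dead_sp
                )
                if orig[(it, c)] - remaining > theta * orig[(it, c)] + _EPS:
                    newly_dead.add(org_of[c])
            if not newly_dead:
                break
            alive -= newly_dead
        y.append(len(alive) / len(orgs))
    return y


# ---------------------------------------------------------------------------


def specialist_web(n_plants, events_each=4):
    records = [
        rec("grassland", "flower_visitor", f"p{i:02d}", f"v{i:02d}", events_each)
        for i in range(n_plants)
    ]
    ab = [("grassland", f"p{i:02d}", float(i + 1)) for i in range(n_plants)]
    return make_site(records, ab, ["grassland"])


class TestRemovalOrder:
    def make(self):
        ab = [("grassland", "p1", 1.0), ("grassland", "p2", 5.0), ("grassland", "p3", 4.0)]
        return make_site([], ab, ["grassland"])

    def test_sorts_by_commonness(self):
        order = removal_order(self.make(), "rare_to_common", np.random.default_rng(0))
        assert order == ["p1", "p3", "p2"]

    def test_tied_plants_break_uniformly(self):
        ab = [("grassland", "a", 2.0), ("grassland", "b", 2.0)]
        ls = make_site([], ab, ["grassland"])
        rng = np.random.default_rng(1)
        first = sum(removal_order(ls, "rare_to_common", rng)[0] == "a" for _ in range(1000))
        assert 440 <= first <= 560  # ~Binomial(1000, 0.5)

    def test_random_mode_is_uniform(self):
        rng = np.random.default_rng(2)
        ls = self.make()
        counts = {}
        for _ in range(6000):
            key = tuple(removal_order(ls, "random", rng))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        assert all(850 <= c <= 1150 for c in counts.values())


class TestCascadeHandCases:
    def test_two_plant_specialists(self):
        ls = specialist_web(2)
        sc = Scenario(flexibility=0.0, threshold=0.5, n_replicates=1)
        curve = simulate_cascade(ls, ["p00", "p01"], sc, np.random.default_rng(0))
        assert np.allclose(curve.y, [1.0, 0.5, 0.0])
        assert robustness(curve) == pytest.approx(0.5)

    def test_strict_threshold_survives_exact_tie(self):
        # one insect, 1 event on each of 4 plants, theta = 0.75: losing 3 of 4
        # events is exactly the threshold and does not kill
        records = [rec("grassland", "flower_visitor", f"p{i}", "A", 1) for i in range(4)]
        ls = make_site(records, [("grassland", f"p{i}", float(i + 1)) for i in range(4)],
                       ["grassland"])
        sc = Scenario(flexibility=0.0, threshold=0.75, n_replicates=1)
        curve = simulate_cascade(ls, [f"p{i}" for i in range(4)], sc, np.random.default_rng(0))
        assert np.allclose(curve.y, [1, 1, 1, 1, 0])
        assert robustness(curve) == pytest.approx(0.875)

    def test_full_flexibility_shared_pool(self):
        records = [
            rec("grassland", "flower_visitor", f"p{i}", v, 2)
            for i in range(3)
            for v in ("A", "B")
        ]
        ls = make_site(records, [("grassland", f"p{i}", float(i + 1)) for i in range(3)],
                       ["grassland"])
        sc = Scenario(flexibility=1.0, threshold=0.5, n_replicates=1)
        curve = simulate_cascade(ls, ["p0", "p1", "p2"], sc, np.random.default_rng(0))
        assert np.allclose(curve.y, [1.0, 1.0, 1.0, 0.0])

    def test_missing_plant_in_order_raises(self):
        ls = specialist_web(3)
        sc = Scenario(flexibility=0.0, threshold=0.5, n_replicates=1)
        with pytest.raises(ValidationError):
            simulate_cascade(ls, ["p00", "p01"], sc, np.random.default_rng(0))


class TestRobustnessArea:
    def test_linear_decline(self):
        x = np.linspace(0, 1, 11)
        assert robustness(ExtinctionCurve(x=x, y=1 - x)) == pytest.approx(0.5)

    def test_step_curve(self):
        c = ExtinctionCurve(x=[0, 0.5, 1], y=[1, 0.5, 0])
        assert robustness(c) == pytest.approx(0.5)

    def test_terminal_drop(self):
        c = ExtinctionCurve(x=[0, 0.25, 0.5, 0.75, 1], y=[1, 1, 1, 1, 0])
        assert robustness(c) == pytest.approx(0.875)


class TestOracleEquivalence:
    @pytest.mark.parametrize("theta", [0.25, 0.5, 0.75])
    def test_f0_matches_bruteforce_on_random_webs(self, theta):
        rng = np.random.default_rng(17)
        for _ in range(40):
            ls = random_web(rng, n_plants=int(rng.integers(2, 6)),
                            n_per_guild=int(rng.integers(2, 5)),
                            stage_links=int(rng.integers(0, 3)))
            order = [p for p in rng.permutation(sorted(ls.plants()))]
            sc = Scenario(flexibility=0.0, threshold=theta, n_replicates=1)
            curve = simulate_cascade(ls, order, sc, np.random.default_rng(0))
            assert curve.y.tolist() == f0_oracle(ls, order, theta)


class TestInvariantsAndCoupling:
    def test_specialist_closed_form_many_sizes(self):
        sc = Scenario(flexibility=0.0, threshold=0.5, n_replicates=1)
        for n in (2, 5, 17, 50):
            ls = specialist_web(n)
            order = sorted(ls.plants())
            curve = simulate_cascade(ls, order, sc, np.random.default_rng(0))
            assert robustness(curve) == pytest.approx(0.5, abs=1e-12)

    def test_event_conservation_per_stage(self):
        rng = np.random.default_rng(23)
        for f in (0.0, 0.5, 1.0):
            ls = random_web(rng, n_plants=5, n_per_guild=4, stage_links=2)
            audit = []
            sc = Scenario(flexibility=f, threshold=0.5, n_replicates=1)
            order = sorted(ls.plants())
            simulate_cascade(ls, order, sc, np.random.default_rng(1), audit_log=audit)
            for step in audit:
                for (it, c), (surviving, lost, orig) in step.items():
                    assert surviving + lost == orig

    def test_stage_coupling_never_helps(self):
        # with the same removal order and no stochastic rescue, linking two
        # consumer ids as life stages can only reduce survivors
        rng = np.random.default_rng(29)
        for _ in range(20):
            ls_linked = random_web(rng, n_plants=5, n_per_guild=3, stage_links=2)
            ls_free = make_site(
                ls_linked.records(),
                [("grassland", p, ls_linked.layers[0].abundance[p])
                 for p in ls_linked.layers[0].abundance],
                ["grassland"], stage_map={}, site=ls_linked.site,
            )
            order = sorted(ls_linked.plants())
            sc = Scenario(flexibility=0.0, threshold=0.5, n_replicates=1)
            y_linked = simulate_cascade(ls_linked, order, sc, np.random.default_rng(0)).y
            y_free = simulate_cascade(ls_free, order, sc, np.random.default_rng(0)).y
            # compare surviving counts, not fractions (denominators differ)
            n_linked = CascadeEngine(ls_linked).n_insects
            n_free = CascadeEngine(ls_free).n_insects
            assert np.all(y_linked * n_linked <= y_free * n_free + 1e-9)

    def test_replicates_deterministic_and_bounded(self, small_study):
        ls = list(small_study.landscapes.values())[0]
        sc = Scenario(flexibility=1.0, threshold=0.5, n_replicates=30, seed=42)
        a = run_replicates(ls, sc)
        b = run_replicates(ls, sc)
        assert a.values == b.values
        assert all(0.0 <= v <= 1.0 for v in a.values)


class TestVariability:
    def test_identical_groups(self):
        from landnetsim.robustness import RobustnessSample

        sc = Scenario(n_replicates=5)
        vals = [0.1, 0.4, 0.5, 0.6, 0.9]
        samples = [
            RobustnessSample(site="m1", ltype="monad", scenario=sc, values=list(vals)),
            RobustnessSample(site="t1", ltype="triad", scenario=sc, values=list(vals)),
        ]
        res, iqr = robustness_variability(samples)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_iqr_definition(self):
        from landnetsim.robustness import RobustnessSample

        sc = Scenario(n_replicates=5)
        s = RobustnessSample(site="m1", ltype="monad", scenario=sc,
                             values=[0, 0.25, 0.5, 0.75, 1])
        s2 = RobustnessSample(site="t1", ltype="triad", scenario=sc,
                              values=[0, 0.25, 0.5, 0.75, 1])
        _, iqr = robustness_variability([s, s2])
        assert iqr["monad"] == pytest.approx(0.5)

    def test_planted_spread_detected(self):
        from landnetsim.robustness import RobustnessSample

        rng = np.random.default_rng(31)
        sc = Scenario(n_replicates=500)
        samples = []
        for i in range(3):
            samples.append(RobustnessSample(
                site=f"m{i}", ltype="monad", scenario=sc,
                values=np.clip(rng.normal(0.7, 0.15, 500), 0, 1).tolist()))
            samples.append(RobustnessSample(
                site=f"t{i}", ltype="triad", scenario=sc,
                values=np.clip(rng.normal(0.7, 0.05, 500), 0, 1).tolist()))
        res, iqr = robustness_variability(samples)
        assert res.p < 0.001
        assert iqr["monad"] > iqr["triad"]
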