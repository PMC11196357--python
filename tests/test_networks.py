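"""Lag-1 VAR estimation, partial-correlation extraction, gates, and the
edge-sign plausibility statistic."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from emafeedback.errors import InsufficientDataError
from emafeedback.networks import (
    ContemporaneousNetwork,
    LagDesign,
    build_panel,
    edge_sign_plausibility,
    estimate_var_contemporaneous,
    lagged_pairs,
    network_gate,
    precision_to_pcor,
    select_network_variables,
)

from conftest import make_table

DAILY = ["morning", "noon", "afternoon", "evening"]


def _panel_from(values: dict[tuple[str, str], list[float]], variables):
    idx = pd.MultiIndex.from_tuples(
        [(dt.date.fromisoformat(d), s) for d, s in values],
        names=["date", "slot"],
    )
    return pd.DataFrame(list(values.values()), index=idx, columns=variables)


def simulate_var_design(rng, B, kappa, n_pairs, mode="daily"):
    """Direct LagDesign from a simulated stationary VAR(1)."""
    p = B.shape[0]
    chol = np.linalg.cholesky(np.linalg.inv(kappa))
    x = np.zeros(p)
    series = []
    for _ in range(n_pairs + 51):
        x = B @ x + chol @ rng.standard_normal(p)
        series.append(x.copy())
    series = np.array(series[50:])
    day0 = dt.date(2022, 1, 3)
    times = [
        ((day0 + dt.timedelta(days=t), "noon"), (day0 + dt.timedelta(days=t), "afternoon"))
        for t in range(n_pairs)
    ]
    return LagDesign(
        variables=[f"v{i}" for i in range(p)],
        predictors=series[:-1][:n_pairs],
        outcomes=series[1:][:n_pairs],
        pair_times=times,
        mode=mode,
    )


class TestNetworkGate:
    @pytest.mark.parametrize(
        "frac, expected", [(0.5, False), (0.51, True), (1.0, True), (0.0, False)]
    )
    def test_strictly_greater_than_half(self, frac, expected):
        assert network_gate(frac) is expected

    def test_monotone_in_fraction(self):
        fracs = np.linspace(0, 1, 101)
        gates = [network_gate(f) for f in fracs]
        assert gates == sorted(gates)


class TestVariableSelection:
    def _table_with_shapes(self):
        rows = []
        rng = np.random.default_rng(0)
        # symmetric triangular-ish vs heavily right-skewed responses
        sym = rng.choice([3, 4, 4, 4, 5, 3, 5, 2, 6, 4], size=60)
        skewed = rng.choice([1, 1, 1, 1, 1, 2, 2, 3, 6, 7], size=60)
        for i in range(60):
            d = (dt.date(2022, 1, 3) + dt.timedelta(days=i // 4)).isoformat()
            s = DAILY[i % 4]
            rows.append(("P1", d, s, "09:00", "happy", int(sym[i])))
            rows.append(("P1", d, s, "09:00", "sad", int(skewed[i])))
        return make_table(rows)

    def test_most_normal_wins(self):
        from scipy import stats

        table = self._table_with_shapes()
        chosen, ok = select_network_variables(table, ["happy", "sad"], k=1)
        assert chosen == ["happy"] and ok
        # oracle: direct moment computation ranks the same way
        for var, other in [("happy", "sad")]:
            a = table.values_for(var).astype(float).to_numpy()
            b = table.values_for(other).astype(float).to_numpy()
            da = abs(stats.skew(a)) + abs(stats.kurtosis(a))
            db = abs(stats.skew(b)) + abs(stats.kurtosis(b))
            assert da < db

    def test_tie_breaks_alphabetically(self):
        rows = []
        vals = [1, 2, 3, 4, 5, 6, 7] * 4
        for i, v in enumerate(vals):
            d = (dt.date(2022, 1, 3) + dt.timedelta(days=i // 4)).isoformat()
            rows.append(("P1", d, DAILY[i % 4], "09:00", "happy", v))
            rows.append(("P1", d, DAILY[i % 4], "09:00", "sad", v))
        chosen, _ = select_network_variables(make_table(rows), ["sad", "happy"], k=1)
        assert chosen == ["happy"]

    def test_fewer_eligible_than_k_flags(self):
        table = self._table_with_shapes()
        chosen, ok = select_network_variables(table, ["happy", "sad"], k=5)
        assert set(chosen) == {"happy", "sad"} and not ok
        # order is by normality distance, not input order
        assert chosen[0] == "happy"


class TestLaggedPairs:
    def test_one_full_day_gives_three_daily_pairs(self):
        panel = _panel_from(
            {("2022-01-10", s): [float(i)] for i, s in enumerate(DAILY)}, ["v"]
        )
        design = lagged_pairs(panel, ["v"], "daily")
        assert design.n_pairs == 3

    def test_two_full_days_no_overnight_pair(self):
        vals = {}
        for day in ("2022-01-10", "2022-01-11"):
            for i, s in enumerate(DAILY):
                vals[(day, s)] = [float(i)]
        design = lagged_pairs(_panel_from(vals, ["v"]), ["v"], "daily")
        assert design.n_pairs == 6  # 7 would include the overnight transition

    def test_evening_mode_requires_consecutive_days(self):
        vals = {
            ("2022-01-10", "evening"): [1.0],
            ("2022-01-11", "evening"): [2.0],
            ("2022-01-13", "evening"): [3.0],
        }
        design = lagged_pairs(_panel_from(vals, ["v"]), ["v"], "evening")
        assert design.n_pairs == 1
        assert design.pair_times[0][0][0] == dt.date(2022, 1, 10)

    def test_zero_pairs_errors(self):
        vals = {("2022-01-10", "morning"): [1.0], ("2022-01-12", "evening"): [2.0]}
        with pytest.raises(InsufficientDataError):
            lagged_pairs(_panel_from(vals, ["v"]), ["v"], "daily")

    def test_rows_with_missing_values_dropped(self):
        vals = {("2022-01-10", s): [float(i)] for i, s in enumerate(DAILY)}
        vals[("2022-01-10", "noon")] = [np.nan]
        design = lagged_pairs(_panel_from(vals, ["v"]), ["v"], "daily")
        assert design.n_pairs == 1  # only afternoon -> evening survives


class TestEstimation:
    def test_construction_invariants(self):
        rng = np.random.default_rng(0)
        B = np.eye(4) * 0.4
        K = np.eye(4)
        K[0, 1] = K[1, 0] = -0.3
        design = simulate_var_design(rng, B, K, 300)
        net = estimate_var_contemporaneous(design)
        assert np.allclose(net.pcor, net.pcor.T)
        assert np.all(np.diag(net.pcor) == 0)
        assert np.all(np.abs(net.pcor) < 1)
        assert np.linalg.eigvalsh(net.kappa).min() > 0

    def test_too_few_pairs_errors(self):
        rng = np.random.default_rng(1)
        design = simulate_var_design(rng, np.eye(2) * 0.3, np.eye(2), 20)
        with pytest.raises(InsufficientDataError):
            estimate_var_contemporaneous(design)

    def test_strong_innovation_correlation_detected_with_sign(self):
        """rho = 0.6 innovation correlation at n = 500: edge present and
        positive in nearly every replicate."""
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            K = np.linalg.inv(np.array([[1.0, 0.6], [0.6, 1.0]]))
            design = simulate_var_design(rng, np.eye(2) * 0.5, K, 500)
            net = estimate_var_contemporaneous(design)
            if net.pcor[0, 1] > 0:
                hits += 1
        assert hits >= int(0.95 * n_reps)

    def test_independent_latents_mostly_empty(self):
        """True empty contemporaneous network: most replicates return no
        edges (a scaled-down version of the full null calibration)."""
        empty = 0
        n_reps = 15
        for rep in range(n_reps):
            rng = np.random.default_rng(200 + rep)
            design = simulate_var_design(rng, np.eye(3) * 0.5, np.eye(3), 500)
            net = estimate_var_contemporaneous(design)
            if not net.edges():
                empty += 1
        assert empty >= int(0.9 * n_reps)

    def test_temporal_coefficients_recovered(self):
        rng = np.random.default_rng(5)
        B = np.diag([0.6, 0.4, 0.5])
        design = simulate_var_design(rng, B, np.eye(3), 800)
        net = estimate_var_contemporaneous(design)
        assert np.all(np.abs(np.diag(net.beta) - np.diag(B)) < 0.15)


def _toy_network(variables, pcor_entries, mode="daily"):
    p = len(variables)
    pcor = np.zeros((p, p))
    for (i, j), w in pcor_entries.items():
        pcor[i, j] = pcor[j, i] = w
    return ContemporaneousNetwork(
        variables=variables, beta=np.zeros((p, p)), kappa=np.eye(p),
        pcor=pcor, mode=mode, n_effective=100,
    )


class TestPlausibility:
    PA = {"happy", "relaxed"}
    NA = {"sad", "stressed"}

    def test_all_conforming_edges_yield_zero_proportions(self):
        nets = [
            _toy_network(
                ["happy", "relaxed", "sad", "stressed"],
                {(0, 1): 0.3, (2, 3): 0.25, (0, 2): -0.2},
            )
            for _ in range(2)
        ]
        rep = edge_sign_plausibility(nets, self.PA, self.NA)
        assert all(p == 0.0 for _, _, p in rep.classes.values())
        assert not rep.empty_pool

    def test_counting_one_deviation_in_ten(self):
        nets = []
        for k in range(10):
            w = -0.2 if k == 0 else 0.2  # one negative NA-NA edge
            nets.append(_toy_network(["sad", "stressed"], {(0, 1): w}))
        rep = edge_sign_plausibility(nets, self.PA, self.NA)
        n, d, p = rep.classes["NA-NA"]
        assert (n, d) == (10, 1) and p == pytest.approx(0.10)

    def test_zero_edges_flagged_empty(self):
        nets = [_toy_network(["happy", "sad"], {})]
        rep = edge_sign_plausibility(nets, self.PA, self.NA)
        assert rep.empty_pool
        assert rep.classes["PA-NA"] == (0, 0, 0.0)

    def test_edges_outside_affect_items_ignored(self):
        nets = [_toy_network(["happy", "tired"], {(0, 1): -0.4})]
        rep = edge_sign_plausibility(nets, self.PA, self.NA)
        assert rep.empty_pool


class TestPrecisionToPcor:
    def test_known_2x2(self):
        K = np.array([[2.0, -0.6], [-0.6, 1.5]])
        omega = precision_to_pcor(K)
        assert omega[0, 1] == pytest.approx(0.6 / np.sqrt(2.0 * 1.5))

    def test_random_pd_matrices_bounded_and_symmetric(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            A = rng.normal(size=(5, 5))
            K = A @ A.T + 5 * np.eye(5)
            omega = precision_to_pcor(K)
            assert np.allclose(omega, omega.T)
            assert np.all(np.abs(omega) < 1)
            assert np.all(np.diag(omega) == 0)


class TestBuildPanel:
    def test_panel_shape_and_values(self):
        rows = [
            ("P1", "2022-01-10", "morning", "09:00", "happy", 5),
            ("P1", "2022-01-10", "morning", "09:00", "sad", 2),
            ("P1", "2022-01-10", "noon", "12:00", "happy", 6),
        ]
        panel = build_panel(make_table(rows), ["happy", "sad"])
        assert panel.shape == (2, 2)
        assert panel.loc[(dt.date(2022, 1, 10), "morning"), "happy"] == 5
        assert np.isnan(panel.loc[(dt.date(2022, 1, 10), "noon"), "sad"])
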