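"""Aggregation rules, loss re-weighting, and the federated loop."""

import numpy as np
import pytest

import fedmsrw as fm
from fedmsrw.federation import average_aggregate, loss_weight, weighted_aggregate
from fedmsrw.metrics import ClientState
from fedmsrw.nn import SGD

from conftest import toy_fed_config


def _rand_maps(rng, n_clients, n_entries=10):
    names = [f"p{i}" for i in range(n_entries)]
    return names, [
        {n: rng.normal(size=(3, 2)).astype(np.float32) for n in names}
        for _ in range(n_clients)
    ]


class TestLossWeight:
    def test_equal_ratios_give_unit_weights(self):
        vr = [0.02, 0.02, 0.02]
        assert all(loss_weight(vr, i) == pytest.approx(1.0) for i in range(3))

    def test_hand_values_two_clients(self):
        vr = [0.01, 0.03]
        assert loss_weight(vr, 0) == pytest.approx(2.0)
        assert loss_weight(vr, 1) == pytest.approx(2 / 3, abs=1e-6)

    def test_weighted_ratio_sum_is_conserved(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vr = rng.uniform(0.005, 0.05, size=rng.integers(2, 6))
            w = np.array([loss_weight(vr, i) for i in range(len(vr))])
            if np.all((w > 0.1) & (w < 10)):  # clipping inactive
                assert (w * vr).sum() == pytest.approx(vr.sum(), abs=1e-9)

    def test_clipping_bounds_extreme_ratios(self):
        assert loss_weight([1e-9, 0.05], 0) == 10.0
        assert loss_weight([1e-9, 0.05], 1) == pytest.approx(0.5, abs=1e-3)
        with pytest.raises(ValueError):
            loss_weight([], 0)


class TestAggregation:
    def test_single_client_identity(self):
        rng = np.random.default_rng(1)
        names, maps = _rand_maps(rng, 1)
        out = average_aggregate(maps, names)
        for n in names:
            assert np.allclose(out[n], maps[0][n])

    def test_two_client_scalar_mean_and_weighted(self):
        maps = [{"x": np.array([0.0])}, {"x": np.array([1.0])}]
        assert average_aggregate(maps, ["x"])["x"][0] == pytest.approx(0.5)
        out = weighted_aggregate(maps, [1.0, 3.0], ["x"])
        assert out["x"][0] == pytest.approx(0.75)

    def test_uniform_weighted_equals_average_bitwise(self):
        rng = np.random.default_rng(2)
        for n_clients in (2, 4):
            names, maps = _rand_maps(rng, n_clients)
            avg = average_aggregate(maps, names)
            wgt = weighted_aggregate(maps, [1.0] * n_clients, names)
            for n in names:
                assert np.array_equal(avg[n], wgt[n])

    def test_weighted_matches_brute_force(self):
        rng = np.random.default_rng(3)
        names, maps = _rand_maps(rng, 5)
        a = rng.uniform(0.1, 1.0, size=5)
        out = weighted_aggregate(maps, a, names)
        for n in names:
            expect = sum(ai * m[n].astype(np.float64) for ai, m in zip(a, maps))
            expect /= a.sum()
            assert np.allclose(out[n], expect, atol=1e-6)

    def test_zero_ability_client_has_no_influence(self):
        maps = [{"x": np.array([5.0])}, {"x": np.array([-1.0])}]
        out = weighted_aggregate(maps, [0.0, 2.0], ["x"])
        assert out["x"][0] == pytest.approx(-1.0)

    def test_all_zero_abilities_instructs_fallback(self):
        maps = [{"x": np.array([1.0])}, {"x": np.array([2.0])}]
        with pytest.raises(ValueError, match="uniform"):
            weighted_aggregate(maps, [0.0, 0.0], ["x"])

    def test_names_outside_selection_not_returned(self):
        maps = [{"x": np.array([1.0]), "bn": np.array([7.0])},
                {"x": np.array([3.0]), "bn": np.array([9.0])}]
        out = average_aggregate(maps, ["x"])
        assert set(out) == {"x"}

    def test_monotone_influence_toward_abler_client(self):
        """Raising one client's ability pulls the aggregate toward it."""
        maps = [{"x": np.array([0.0])}, {"x": np.array([1.0])}]
        prev = weighted_aggregate(maps, [1.0, 1.0], ["x"])["x"][0]
        for a in (1.5, 2.0, 4.0, 10.0):
            cur = weighted_aggregate(maps, [1.0, a], ["x"])["x"][0]
            assert cur > prev
            prev = cur


class TestLocalTrainRound:
    def test_zero_lr_keeps_parameters_but_reports(self, toy_federation, toy_net_cfg):
        cfg = toy_fed_config("fedbn", lr=0.0, iters_per_round=2)
        model = fm.build_network(toy_net_cfg, 0)
        start = model.state_dict()
        out = fm.local_train_round(
            toy_federation["A"], start, ClientState(), cfg, 1.0, model,
            SGD(0.0, cfg.momentum, cfg.weight_decay), np.random.default_rng(0),
        )
        part = model.parameter_partition()
        for k in part.rest_names:  # bn running stats do change in training mode
            assert np.array_equal(out.params[k], start[k]), k
        assert 0.0 <= out.mean_ratio <= 1.0
        assert out.ability is None or 0.0 <= out.ability <= 1.0

    def test_loss_weight_scales_first_sgd_step(self, toy_federation, toy_net_cfg):
        """Doubling the loss weight with lr halved gives the same first step
        when momentum and weight decay are off (SGD scaling identity)."""
        results = []
        for weight, lr in ((1.0, 2e-3), (2.0, 1e-3)):
            cfg = toy_fed_config("fedbn", lr=lr, iters_per_round=1,
                                 momentum=0.0, weight_decay=0.0)
            model = fm.build_network(toy_net_cfg, 0)
            out = fm.local_train_round(
                toy_federation["A"], model.state_dict(), ClientState(), cfg,
                weight, model, SGD(lr, 0.0, 0.0), np.random.default_rng(3),
            )
            results.append(out.params)
        part = fm.build_network(toy_net_cfg, 0).parameter_partition()
        for k in part.rest_names:
            assert np.allclose(results[0][k], results[1][k], atol=1e-7), k

    def test_empty_client_errors(self, toy_net_cfg):
        cfg = toy_fed_config("fedbn")
        model = fm.build_network(toy_net_cfg, 0)
        with pytest.raises(ValueError, match="no training cases"):
            fm.local_train_round([], model.state_dict(), ClientState(), cfg,
                                 1.0, model)


class TestRunFederation:
    def test_rest_params_identical_across_clients_after_sync(
        self, toy_federation, toy_net_cfg
    ):
        res = fm.run_federation(
            toy_federation, toy_fed_config("fedmsrw"), toy_net_cfg
        )
        a, b = (res.client_params[c] for c in res.client_ids)
        for k in res.partition.rest_names:
            assert np.array_equal(a[k], b[k])

    def test_aggregation_weights_sum_to_one_every_round(
        self, toy_federation, toy_net_cfg
    ):
        for mode in ("fedavg", "fedbn", "fedmsrw", "ours_ent"):
            res = fm.run_federation(
                toy_federation, toy_fed_config(mode), toy_net_cfg
            )
            for entry in res.history:
                total = sum(entry["aggregation_weights"].values())
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_bn_state_never_touched_by_server_in_bn_local_modes(
        self, toy_federation, toy_net_cfg
    ):
        for mode in ("fedbn", "fedmsrw"):
            res = fm.run_federation(
                toy_federation, toy_fed_config(mode, n_rounds=5), toy_net_cfg
            )
            for entry in res.history:
                assert entry["bn_hash_post_train"] == entry["bn_hash_post_sync"]

    def test_fedavg_overwrites_bn_state(self, toy_federation, toy_net_cfg):
        res = fm.run_federation(
            toy_federation, toy_fed_config("fedavg"), toy_net_cfg
        )
        changed = [
            e["bn_hash_post_train"] != e["bn_hash_post_sync"]
            for e in res.history
        ]
        assert any(changed)

    def test_forced_fedmsrw_reduces_to_fedbn_bitwise(
        self, toy_federation, toy_net_cfg
    ):
        bn = fm.run_federation(
            toy_federation, toy_fed_config("fedbn"), toy_net_cfg
        )
        forced = fm.run_federation(
            toy_federation,
            toy_fed_config("fedmsrw", force_uniform_ability=True,
                           force_unit_loss_weight=True),
            toy_net_cfg,
        )
        for cid in bn.client_ids:
            for k, v in bn.client_params[cid].items():
                assert np.array_equal(v, forced.client_params[cid][k]), k

    def test_fedprox_mu_zero_matches_fedavg_bitwise(
        self, toy_federation, toy_net_cfg
    ):
        avg = fm.run_federation(
            toy_federation, toy_fed_config("fedavg"), toy_net_cfg
        )
        prox = fm.run_federation(
            toy_federation, toy_fed_config("fedprox", prox_mu=0.0), toy_net_cfg
        )
        for cid in avg.client_ids:
            for k, v in avg.client_params[cid].items():
                assert np.array_equal(v, prox.client_params[cid][k]), k

    def test_fedprox_penalty_changes_trajectory(self, toy_federation, toy_net_cfg):
        avg = fm.run_federation(
            toy_federation, toy_fed_config("fedavg"), toy_net_cfg
        )
        prox = fm.run_federation(
            toy_federation, toy_fed_config("fedprox", prox_mu=0.5), toy_net_cfg
        )
        same = all(
            np.array_equal(avg.global_params[k], prox.global_params[k])
            for k in avg.global_params
        )
        assert not same

    def test_loss_weights_follow_ratio_imbalance(self, toy_federation, toy_net_cfg):
        """From round 2 on, the low-burden client gets the larger loss weight."""
        res = fm.run_federation(
            toy_federation, toy_fed_config("fedmsrw"), toy_net_cfg
        )
        first = res.history[0]["loss_weight"]
        assert all(w == 1.0 for w in first.values())  # round 1 is uniform
        later = res.history[-1]
        vr = later["vr"]
        lw = later["loss_weight"]
        lo = min(vr, key=vr.get)
        hi = max(vr, key=vr.get)
        assert lw[lo] >= lw[hi]

    def test_running_vr_equals_mean_of_round_means(
        self, toy_federation, toy_net_cfg
    ):
        res = fm.run_federation(
            toy_federation, toy_fed_config("fedbn", n_rounds=4), toy_net_cfg
        )
        for cid in res.client_ids:
            means = [e["round_mean_ratio"][cid] for e in res.history]
            assert res.history[-1]["vr"][cid] == pytest.approx(
                float(np.mean(means)), abs=1e-12
            )

    def test_single_client_federation_rejected(self, toy_federation, toy_net_cfg):
        only_a = {"A": toy_federation["A"]}
        with pytest.raises(ValueError, match="at least 2"):
            fm.run_federation(only_a, toy_fed_config("fedavg"), toy_net_cfg)

    def test_ours_vol_uses_voxel_counts(self, toy_federation, toy_net_cfg):
        res = fm.run_federation(
            toy_federation, toy_fed_config("ours_vol"), toy_net_cfg
        )
        lw = res.history[-1]["loss_weight"]
        assert set(lw) == {"A", "B"}
        assert not all(w == 1.0 for w in lw.values())
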