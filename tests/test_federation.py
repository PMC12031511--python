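"""Parameter partition, aggregation, protocols, and training degeneracies."""

import numpy as np
import pytest

from fedprog.federation import (AdamW, ClientUpdate, ProtocolError,
                                SiteTrainer, TrainConfig,
                                accumulate_gradients, fedavg_aggregate,
                                partition_parameters, read_history,
                                save_checkpoint, load_checkpoint,
                                train_federated, write_history)
from fedprog.model import SiteModel, init_parameters, make_batch
from fedprog.records_io import (DYNAMIC, STATIC, FeatureManifest,
                                shared_standardize)
from fedprog.synthetic_cohort import CohortConfig, generate_cohorts


@pytest.fixture(scope="module")
def std_cohort():
    cfg = CohortConfig(n_patients=(40, 60, 30), T_range=(3, 5), seed=9)
    datasets, manifest, _ = generate_cohorts(cfg)
    return shared_standardize(datasets, manifest), manifest


def quick_cfg(**kw):
    base = dict(epochs=2, patience=0, hidden=6, batch_size=32, seed=4)
    base.update(kw)
    return TrainConfig(**base)


class TestPartition:
    def test_identical_manifests_share_all_channels(self):
        m = FeatureManifest.from_site_manifests({
            "a": {"x": DYNAMIC, "y": DYNAMIC, "age": STATIC},
            "b": {"x": DYNAMIC, "y": DYNAMIC, "age": STATIC}})
        shared, private = partition_parameters(m)
        assert {k for k in shared if k.startswith("channels.")} == \
            {f"channels.shared.{f}.{p}" for f in ("x", "y")
             for p in ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r",
                       "W_n", "U_n", "b_n")}
        for site in ("a", "b"):
            assert any(k.startswith("heads.") for k in private[site])
            assert not any(k.startswith("channels.shared")
                           for k in private[site])

    def test_disjoint_manifests_warn_and_share_nothing_dynamic(self):
        m = FeatureManifest.from_site_manifests({
            "a": {"x": DYNAMIC, "age": STATIC},
            "b": {"y": DYNAMIC, "age": STATIC}})
        with pytest.warns(UserWarning, match="no cross-site transfer"):
            shared, private = partition_parameters(m)
        assert not any(k.startswith("channels.") for k in shared)
        assert "channels.private.a.x.W_z" in private["a"]

    def test_paperlike_venn_counts(self, small_cohort):
        """8 all-shared + 3x4 pairwise = 20 shared channels; 12 private."""
        _, _, manifest, _ = small_cohort
        shared, private = partition_parameters(manifest)
        shared_feats = {k.split(".")[2] for k in shared
                        if k.startswith("channels.shared.")}
        assert len(shared_feats) == 20
        private_feats = {k.split(".")[3] for site in private.values()
                         for k in site if k.startswith("channels.private.")}
        assert len(private_feats) == 12
        assert "demographic.W_base" in shared

    def test_recalibration_and_heads_always_private(self, small_cohort):
        _, _, manifest, _ = small_cohort
        shared, private = partition_parameters(manifest)
        assert not any(k.startswith(("recalibration.", "heads."))
                       for k in shared)


class TestAggregate:
    def upd(self, inst, count, **params):
        return ClientUpdate(inst, 1, count,
                            params={k: np.asarray(v) for k, v in params.items()})

    def test_single_client_is_identity(self):
        out = fedavg_aggregate([self.upd("a", 10, w=[1.5, -2.0])], {"w"})
        assert np.array_equal(out["w"], [1.5, -2.0])

    def test_equal_counts_average(self):
        out = fedavg_aggregate([self.upd("a", 5, w=1.0),
                                self.upd("b", 5, w=3.0)], {"w"})
        assert out["w"] == 2.0

    def test_count_weighted_mean_is_exact(self):
        """values 1.0 and 3.0 with counts 1 and 3 -> (1 + 9)/4 = 2.5."""
        out = fedavg_aggregate([self.upd("a", 1, w=1.0),
                                self.upd("b", 3, w=3.0)], {"w"})
        assert out["w"] == 2.5

    def test_partial_owner_average_over_contributors_only(self):
        updates = [self.upd("a", 1, w=1.0, u=5.0),
                   self.upd("b", 3, w=3.0),
                   self.upd("c", 6, u=7.0)]
        out = fedavg_aggregate(updates, {"w", "u"})
        assert out["w"] == 2.5                       # a and b only
        assert out["u"] == (1 * 5.0 + 6 * 7.0) / 7   # a and c only

    def test_empty_update_list_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            fedavg_aggregate([], {"w"})

    def test_gradient_accumulation_sums_per_key(self):
        ups = [ClientUpdate("a", 1, 5, grads={"w": np.array(2.0)}),
               ClientUpdate("b", 1, 5, grads={"w": np.array(3.0),
                                              "v": np.array(1.0)})]
        G = accumulate_gradients(ups)
        assert G["w"] == 5.0 and G["v"] == 1.0


class TestLocalComputation:
    def test_zero_learning_rate_is_null_update(self, std_cohort):
        """local_update at lr=0 returns its input parameters bit-for-bit."""
        datasets, manifest = std_cohort
        cfg = quick_cfg(lr=0.0, epochs=1)
        params0, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        shared, _ = partition_parameters(manifest)
        tr = SiteTrainer(datasets[0], manifest, cfg, params0, shared,
                         np.random.SeedSequence(0))
        tr.local_update(1, {k: tr.params[k] for k in tr.shared_keys})
        for k, v in tr.params.items():
            assert np.array_equal(v, params0[k]), f"{k} moved at lr=0"
        res = train_federated(cfg, datasets, manifest, )
        # isolated-style check on the full loop: same seed, zero lr
        iso = train_federated(
            TrainConfig(mode="isolated", lr=0.0, epochs=1, patience=0,
                        hidden=cfg.hidden, batch_size=cfg.batch_size,
                        seed=cfg.seed), datasets, manifest)
        for inst, ps in iso.site_params.items():
            for k, v in ps.items():
                assert np.array_equal(v, params0[k]), f"{inst}/{k} moved at lr=0"
        del res

    def test_freeze_and_mask_gradient_keys(self, std_cohort):
        """A site's gradient message has no keys for features it lacks."""
        datasets, manifest = std_cohort
        cfg = quick_cfg(fed_mode="accum")
        params, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        shared, _ = partition_parameters(manifest)
        tr = SiteTrainer(datasets[0], manifest, cfg, params, shared,
                         np.random.SeedSequence(0))
        upd = tr.gradient_update(1, {k: tr.params[k] for k in tr.shared_keys})
        recorded = set(datasets[0].feature_names)
        for key in upd.grads:
            if key.startswith("channels."):
                feat = key.split(".")[-2]
                assert feat in recorded, f"gradient for unrecorded {feat}"
        missing = set(manifest.dynamic_features()) - recorded
        assert missing, "fixture should have unrecorded features"

    def test_batch_gradient_is_mean_of_single_record_gradients(self, std_cohort):
        datasets, manifest = std_cohort
        ds = datasets[2]        # mortality-only site: loss is a patient mean
        cfg = quick_cfg()
        params, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        sm = SiteModel(ds.institution_id, manifest, ds.feature_names,
                       ds.task, hidden=cfg.hidden)
        pair = make_batch(ds, [0, 1])
        loss, leaves = sm.loss(params, pair)
        loss.backward()
        singles = []
        for i in (0, 1):
            l1, lv = sm.loss(params, make_batch(ds, [i]))
            l1.backward()
            singles.append(lv)
        for k, t in leaves.items():
            if t.grad is None:
                continue
            mean_grad = (singles[0][k].grad + singles[1][k].grad) / 2
            assert np.allclose(t.grad, mean_grad, atol=1e-6), k

    def test_stale_shared_snapshot_is_protocol_error(self, std_cohort):
        datasets, manifest = std_cohort
        cfg = quick_cfg()
        params, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        shared, _ = partition_parameters(manifest)
        tr = SiteTrainer(datasets[0], manifest, cfg, params, shared,
                         np.random.SeedSequence(0))
        bad = {k: tr.params[k] + 1.0 for k in tr.shared_keys}
        with pytest.raises(ProtocolError, match="stale"):
            tr.local_update(1, bad)


class TestPooledGradientOracle:
    def test_accumulated_gradient_equals_pooled_loss_gradient(self):
        """Identical manifests and tasks: sum of per-site full-batch
        gradients == gradient of the pooled two-site loss, evaluated with a
        single model on the concatenated data (site sizes equal, so the
        pooled mean loss is half the summed site losses)."""
        cfg = CohortConfig(n_patients=(10, 10), n_institutions=2,
                           n_shared_features=4, n_pairwise_features=0,
                           n_private_features=0, tasks=("mortality",) * 2,
                           T_range=(3, 4), missing_rate=0.0, seed=13)
        datasets, manifest, _ = generate_cohorts(cfg)
        std = shared_standardize(datasets, manifest)
        tcfg = quick_cfg(fed_mode="accum", batch_size=64, dropout=0.0)
        params, _ = init_parameters(manifest, tcfg.hidden, tcfg.seed)
        shared, _ = partition_parameters(manifest)
        # make every per-site private namespace numerically identical so
        # that one pooled model can reproduce both sites' forward passes
        for n in ("Wq", "Wk", "Wv"):
            params[f"recalibration.site1.{n}"] = params[f"recalibration.site0.{n}"]
        for n in ("W_cla", "b_cla", "W_reg", "b_reg"):
            params[f"heads.site1.{n}"] = params[f"heads.site0.{n}"]
        trainers = [SiteTrainer(ds, manifest, tcfg, params, shared,
                                np.random.SeedSequence(i))
                    for i, ds in enumerate(std)]
        updates = [tr.gradient_update(1, {k: tr.params[k]
                                          for k in tr.shared_keys})
                   for tr in trainers]
        G = accumulate_gradients(updates)

        # pooled oracle: one site model over the two train splits combined
        import dataclasses
        pooled = dataclasses.replace(
            std[0], records=[std[0].records[i]
                             for i in trainers[0].splits["train"]]
            + [std[1].records[i] for i in trainers[1].splits["train"]])
        n_pool = len(pooled.records)
        assert n_pool == 2 * len(trainers[0].splits["train"])
        sm = SiteModel("site0", manifest, pooled.feature_names, "mortality",
                       hidden=tcfg.hidden, dropout=0.0)
        loss, leaves = sm.loss(params, make_batch(pooled, range(n_pool)))
        loss.backward()
        checked = 0
        for k in G:
            if k in shared:
                want = 2.0 * leaves[k].grad    # sum of means = 2 x pooled mean
                assert np.allclose(G[k], want, atol=1e-6), k
                checked += 1
        assert checked > 10


class TestTrainingLoop:
    def test_single_site_federated_equals_isolated_bitwise(self):
        cfg = CohortConfig(n_patients=(25,), n_institutions=1,
                           n_shared_features=0, n_pairwise_features=0,
                           n_private_features=4, tasks=("mortality",),
                           T_range=(3, 4), seed=2)
        datasets, manifest, _ = generate_cohorts(cfg)
        std = shared_standardize(datasets, manifest)
        fed = train_federated(quick_cfg(mode="federated", epochs=3), std, manifest)
        iso = train_federated(quick_cfg(mode="isolated", epochs=3), std, manifest)
        for k, v in fed.site_params["site0"].items():
            assert np.array_equal(v, iso.site_params["site0"][k]), k
        assert fed.history == iso.history

    def test_same_seed_reproduces_history(self, std_cohort):
        datasets, manifest = std_cohort
        h1 = train_federated(quick_cfg(), datasets, manifest).history
        h2 = train_federated(quick_cfg(), datasets, manifest).history
        assert h1 == h2

    def test_shared_keys_identical_across_sites_after_round(self, std_cohort):
        datasets, manifest = std_cohort
        res = train_federated(quick_cfg(patience=0, epochs=1), datasets,
                              manifest)
        shared, _ = partition_parameters(manifest)
        # every shared key present at several sites is bit-identical
        for k in shared:
            copies = [ps[k] for ps in res.site_params.values() if k in ps]
            for c in copies[1:]:
                assert np.array_equal(c, copies[0]), k

    def test_early_stopping_patience_ten_stops_at_round_eleven(self, std_cohort):
        datasets, manifest = std_cohort
        cfg = quick_cfg(patience=10)
        params, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        shared, _ = partition_parameters(manifest)
        tr = SiteTrainer(datasets[0], manifest, cfg, params, shared,
                         np.random.SeedSequence(0))
        series = iter([0.9 - 0.05 * i for i in range(30)])
        tr.validation_metric = lambda: (next(series), {})
        stopped_at = None
        for rnd in range(1, 30):
            tr.after_round(rnd)
            if tr.stopped:
                stopped_at = rnd
                break
        assert stopped_at == 11

    def test_accum_and_fedavg_modes_both_train(self, std_cohort):
        datasets, manifest = std_cohort
        for fm in ("fedavg", "accum"):
            res = train_federated(quick_cfg(fed_mode=fm), datasets, manifest)
            assert len(res.history) == 2 * len(datasets)

    def test_client_messages_carry_only_model_tensors(self, std_cohort):
        """Privacy locality: uploads contain parameter/gradient arrays and a
        count — every array matches a model parameter key and shape."""
        datasets, manifest = std_cohort
        cfg = quick_cfg()
        params, _ = init_parameters(manifest, cfg.hidden, cfg.seed)
        shared, _ = partition_parameters(manifest)
        for mode, method in (("fedavg", "local_update"),
                             ("accum", "gradient_update")):
            tr = SiteTrainer(datasets[0], manifest,
                             quick_cfg(fed_mode=mode), params, shared,
                             np.random.SeedSequence(0))
            upd = getattr(tr, method)(1, {k: tr.params[k]
                                          for k in tr.shared_keys})
            assert set(vars(upd)) == {"institution", "round", "count",
                                      "params", "grads"}
            payload = upd.params if upd.params is not None else upd.grads
            for key, arr in payload.items():
                assert key in params, f"unknown tensor {key} in message"
                assert np.shape(arr) == params[key].shape
            assert upd.count == len(tr.splits["train"])

    def test_checkpoint_round_trip(self, std_cohort, tmp_path):
        datasets, manifest = std_cohort
        res = train_federated(quick_cfg(), datasets, manifest)
        save_checkpoint(res, tmp_path / "ck")
        cfg2, params2, splits2 = load_checkpoint(tmp_path / "ck")
        assert cfg2 == res.config
        for inst, ps in res.site_params.items():
            for k, v in ps.items():
                assert np.array_equal(v, params2[inst][k])
            for split, idx in res.splits[inst].items():
                assert np.array_equal(idx, splits2[inst][split])

    def test_history_jsonl_round_trip(self, std_cohort, tmp_path):
        datasets, manifest = std_cohort
        res = train_federated(quick_cfg(), datasets, manifest)
        write_history(res.history, tmp_path / "h.jsonl")
        assert read_history(tmp_path / "h.jsonl") == res.history


class TestAdamW:
    def test_matches_reference_formulas_one_step(self):
        opt = AdamW(lr=0.1, weight_decay=0.0)
        p = {"w": np.array([1.0])}
        opt.step(p, {"w": np.array([0.5])})
        # first step of Adam moves by ~lr in the gradient direction
        assert p["w"][0] == pytest.approx(1.0 - 0.1, abs=1e-6)

    def test_decoupled_weight_decay_shrinks_without_gradient_memory(self):
        opt = AdamW(lr=0.1, weight_decay=0.5, decoupled=True)
        p = {"w": np.array([2.0])}
        opt.step(p, {"w": np.array([0.0])})
        assert p["w"][0] == pytest.approx(2.0 - 0.1 * 0.5 * 2.0)
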