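"""Federated training: parameter partition, FedAvg, gradient accumulation.

Two collaboration protocols are provided behind ``fed_mode``:

* ``fedavg`` — each round, every active site runs ``local_epochs`` of
  AdamW on its own loss and uploads its parameters; the server replaces
  each shared key by the sample-count-weighted mean over the sites that own
  it and broadcasts the result.
* ``accum`` — each round, every site uploads the gradient of its loss on
  one (full or mini) batch with unused-feature keys absent; the server sums
  the gradients and applies a single optimizer step to the shared keys,
  while each site steps its private keys with the same rule.

Three training modes: ``federated`` (the round loop with aggregation),
``isolated`` (the same loop, never aggregating — each site trains alone),
and ``centralized`` (the pooled-data oracle: every site's patients,
projected onto the shared feature set, train one model with a single
global recalibration and head namespace under one optimizer).

Sites exchange only ``ClientUpdate`` messages: parameter or gradient
tensors plus a sample count.  No patient-level array ever leaves a site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .evaluation import auprc
from .heads import mse_loss
from .model import SiteModel, init_parameters, make_batch
from .records_io import STATIC, FeatureManifest, InstitutionDataset


class ProtocolError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter partition
# ---------------------------------------------------------------------------

def partition_parameters(manifest: FeatureManifest,
                         ) -> tuple[set[str], dict[str, set[str]]]:
    """Shared-key set and per-institution private-key map.

    A dynamic-feature channel is shared iff the feature is recorded by at
    least two institutions; the demographic embedding is shared iff every
    institution records the same static schema; recalibration projections
    and task heads are always private.
    """
    from .encoder import CHANNEL_PARAM_NAMES
    shared_feats = manifest.shared_features()
    insts = sorted(manifest.recorded_by)
    shared_dynamic = {f for f in shared_feats
                      if manifest.feature_kinds[f] == "dynamic_numeric"}
    if len(insts) >= 2 and not shared_dynamic:
        warnings.warn("no feature is recorded by two or more institutions: "
                      "no cross-site transfer is possible", stacklevel=2)
    shared: set[str] = set()
    private: dict[str, set[str]] = {i: set() for i in insts}
    for f in shared_feats:
        if manifest.feature_kinds[f] == "dynamic_numeric":
            shared.update(f"channels.shared.{f}.{p}" for p in CHANNEL_PARAM_NAMES)
    demo_schemas = {tuple(manifest.static_features(i)) for i in insts}
    if len(demo_schemas) == 1:
        shared.add("demographic.W_base")
    else:
        for i in insts:
            private[i].add("demographic.W_base")
    for i in insts:
        for f in manifest.dynamic_features(i):
            if f not in shared_feats:
                private[i].update(f"channels.private.{i}.{f}.{p}"
                                  for p in CHANNEL_PARAM_NAMES)
        private[i].update(f"recalibration.{i}.{n}" for n in ("Wq", "Wk", "Wv"))
        private[i].update(f"heads.{i}.{n}"
                          for n in ("W_cla", "b_cla", "W_reg", "b_reg"))
    return shared, private


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Keyed AdamW (decoupled weight decay); set ``decoupled=False`` for Adam."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01,
                 decoupled: bool = True):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay, self.decoupled = weight_decay, decoupled
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        for key, g in grads.items():
            if g is None:
                continue
            p = params[key]
            if not self.decoupled and self.weight_decay:
                g = g + self.weight_decay * p
            if key not in self.m:
                self.m[key] = np.zeros_like(p)
                self.v[key] = np.zeros_like(p)
                self.t[key] = 0
            self.t[key] += 1
            t = self.t[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1 ** t)
            v_hat = self.v[key] / (1 - b2 ** t)
            upd = m_hat / (np.sqrt(v_hat) + self.eps)
            if self.decoupled and self.weight_decay:
                upd = upd + self.weight_decay * p
            params[key] = p - self.lr * upd


# ---------------------------------------------------------------------------
# messages
# ---------------------------------------------------------------------------

@dataclass
class ClientUpdate:
    """The only object a site ever sends to the server.

    Carries model-space tensors (parameters in fedavg mode, gradients in
    accum mode) and the site's training sample count — never patient-level
    data; a schema test enforces that every array matches a parameter shape.
    """

    institution: str
    round: int
    count: int
    params: dict[str, np.ndarray] | None = None
    grads: dict[str, np.ndarray] | None = None


def fedavg_aggregate(updates: list[ClientUpdate],
                     shared_keys: set[str]) -> dict[str, np.ndarray]:
    """Count-weighted mean of each shared key over the sites that carry it.

    A key owned by a strict subset of sites (a feature shared by 2 of 3) is
    averaged over the contributing sites only, reweighted by their counts.
    Private keys are untouched — they never reach the server.
    """
    if not updates:
        raise ProtocolError("fedavg_aggregate: no client updates")
    out: dict[str, np.ndarray] = {}
    for key in shared_keys:
        contributors = [(u.params[key], u.count) for u in updates
                        if u.params is not None and key in u.params]
        if not contributors:
            continue
        total = sum(c for _, c in contributors)
        if total <= 0:
            raise ProtocolError(f"fedavg_aggregate: non-positive counts for {key}")
        out[key] = sum(p * (c / total) for p, c in contributors)
    return out


def accumulate_gradients(updates: list[ClientUpdate],
                         ) -> dict[str, np.ndarray]:
    """G_t = sum over sites of their (masked) loss gradients."""
    G: dict[str, np.ndarray] = {}
    for u in updates:
        if u.grads is None:
            continue
        for key, g in u.grads.items():
            G[key] = g if key not in G else G[key] + g
    return G


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    mode: str = "federated"          # federated | isolated | centralized
    fed_mode: str = "fedavg"         # fedavg | accum
    optimizer: str = "adamw"         # adamw | adam
    lr: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 1024
    epochs: int = 50
    patience: int = 10
    local_epochs: int = 1
    finetune_epochs: int = 0
    hidden: int = 32
    dropout: float = 0.1
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("federated", "isolated", "centralized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fed_mode not in ("fedavg", "accum"):
            raise ValueError(f"unknown fed_mode {self.fed_mode!r}")
        if abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) < 0 \
                or self.split[0] <= 0:
            raise ValueError("split fractions must be >= 0 and sum to 1")


def split_indices(n: int, split: tuple[float, float, float],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Seeded shuffled train/val/test partition of range(n)."""
    perm = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    if n_train == 0 or n - n_train - n_val == 0:
        raise ValueError("split leaves an empty train or test set")
    return {"train": perm[:n_train],
            "val": perm[n_train:n_train + n_val],
            "test": perm[n_train + n_val:]}


# ---------------------------------------------------------------------------
# per-site trainer
# ---------------------------------------------------------------------------

class SiteTrainer:
    """One institution's local training state in the federation loop."""

    def __init__(self, dataset: InstitutionDataset, manifest: FeatureManifest,
                 cfg: TrainConfig, init_params: dict[str, np.ndarray],
                 shared_keys: set[str], seed_seq: np.random.SeedSequence,
                 owner: str | None = None):
        self.dataset = dataset
        self.cfg = cfg
        self.model = SiteModel(dataset.institution_id, manifest,
                               dataset.feature_names, dataset.task,
                               hidden=cfg.hidden, dropout=cfg.dropout,
                               owner=owner)
        split_ss, batch_ss, dropout_ss = seed_seq.spawn(3)
        # per-round generator roots (round index appended per use)
        self._batch_root = int(batch_ss.generate_state(1)[0])
        self._dropout_root = int(dropout_ss.generate_state(1)[0])
        self.splits = split_indices(dataset.sample_count, cfg.split,
                                    np.random.default_rng(split_ss))
        if cfg.patience > 0 and len(self.splits["val"]) == 0:
            raise ValueError(f"{dataset.institution_id}: empty validation set")
        used = set(self.model.used_keys())
        self.params = {k: init_params[k].copy() for k in used}
        self.shared_keys = shared_keys & used
        self.optimizer = AdamW(lr=cfg.lr, weight_decay=cfg.weight_decay,
                               decoupled=cfg.optimizer == "adamw")
        self.stopped = False
        self._uploaded: dict[str, np.ndarray] | None = None
        self.best_metric: float | None = None
        self.best_round = 0
        self.best_params = {k: v.copy() for k, v in self.params.items()}
        self._val_batch = (make_batch(dataset, self.splits["val"])
                           if len(self.splits["val"]) else None)
        self._cached_batches: dict = {}

    @property
    def count(self) -> int:
        return len(self.splits["train"])

    # -- local computation ----------------------------------------------
    def _check_snapshot(self, shared_snapshot: dict[str, np.ndarray]) -> None:
        for k in self.shared_keys:
            if not np.array_equal(self.params[k], shared_snapshot[k]):
                raise ProtocolError(
                    f"{self.dataset.institution_id}: stale shared snapshot "
                    f"for {k}")

    def _minibatches(self, round_idx: int):
        rng = np.random.default_rng([self._batch_root, round_idx])
        idx = self.splits["train"].copy()
        rng.shuffle(idx)
        bs = self.cfg.batch_size
        for start in range(0, len(idx), bs):
            chunk = idx[start:start + bs]
            key = tuple(chunk.tolist())
            if key not in self._cached_batches:
                if len(self._cached_batches) > 64:
                    self._cached_batches.clear()
                self._cached_batches[key] = make_batch(self.dataset, chunk)
            yield self._cached_batches[key]

    def _dropout_rng(self, round_idx: int) -> np.random.Generator:
        return np.random.default_rng([self._dropout_root, round_idx])

    def local_update(self, round_idx: int,
                     shared_snapshot: dict[str, np.ndarray]) -> ClientUpdate:
        """fedavg mode: E local epochs of the site optimizer, upload params.

        When aggregation actually moved the shared parameters away from the
        values this site uploaded last round, the client Adam moments are
        cleared first: momentum accumulated on the pre-jump trajectory is
        misdirected at the averaged point (client drift).  With a single
        site — or in isolated mode — aggregation is the identity, nothing
        moved, and the optimizer state is kept, so federated training of
        one site stays bit-identical to isolated training.
        """
        self._check_snapshot(shared_snapshot)
        if self._uploaded is not None and any(
                not np.array_equal(self._uploaded[k], self.params[k])
                for k in self.shared_keys):
            self.optimizer = AdamW(lr=self.cfg.lr,
                                   weight_decay=self.cfg.weight_decay,
                                   decoupled=self.cfg.optimizer == "adamw")
        drop_rng = self._dropout_rng(round_idx)
        last_loss = np.nan
        for _ in range(self.cfg.local_epochs):
            for batch in self._minibatches(round_idx):
                loss, leaves = self.model.loss(self.params, batch, train=True,
                                               dropout_rng=drop_rng)
                loss.backward()
                grads = {k: t.grad for k, t in leaves.items()
                         if t.grad is not None}
                self.optimizer.step(self.params, grads)
                last_loss = loss.item()
        self.last_train_loss = last_loss
        self._uploaded = {k: self.params[k].copy() for k in self.shared_keys}
        return ClientUpdate(self.dataset.institution_id, round_idx,
                            self.count,
                            params={k: self.params[k] for k in self.shared_keys})

    def gradient_update(self, round_idx: int,
                        shared_snapshot: dict[str, np.ndarray]) -> ClientUpdate:
        """accum mode: masked loss gradient on one batch, no local step."""
        self._check_snapshot(shared_snapshot)
        drop_rng = self._dropout_rng(round_idx)
        batch = next(iter(self._minibatches(round_idx)))
        loss, leaves = self.model.loss(self.params, batch, train=True,
                                       dropout_rng=drop_rng)
        loss.backward()
        self.last_train_loss = loss.item()
        grads = {k: t.grad for k, t in leaves.items() if t.grad is not None}
        return ClientUpdate(self.dataset.institution_id, round_idx,
                            self.count, grads=grads)

    def apply_shared(self, shared_params: dict[str, np.ndarray]) -> None:
        for k in self.shared_keys:
            if k in shared_params:
                self.params[k] = shared_params[k].copy()

    def step_private(self, grads: dict[str, np.ndarray]) -> None:
        private = {k: g for k, g in grads.items()
                   if k in self.params and k not in self.shared_keys}
        self.optimizer.step(self.params, private)

    # -- validation / early stopping -------------------------------------
    def higher_is_better(self) -> bool:
        return self.dataset.task in ("mortality", "both")

    def validation_metric(self) -> tuple[float, dict[str, float]]:
        """AUPRC for classification sites, MSE for regression-only sites."""
        out = self.model.predict(self.params, self._val_batch)
        metrics: dict[str, float] = {}
        if "mortality_prob" in out:
            y = self._val_batch.mortality
            try:
                metrics["val_auprc"] = auprc(out["mortality_prob"], y)
            except ValueError:       # single-class validation split
                metrics["val_auprc"] = float(np.mean(y))
        if "los_pred" in out:
            m = self._val_batch.valid
            metrics["val_mse"] = mse_loss(out["los_pred"][m],
                                          np.nan_to_num(self._val_batch.los)[m])
        primary = metrics.get("val_auprc", None)
        if primary is None:
            primary = -metrics["val_mse"]   # lower MSE is better
        return primary, metrics

    def after_round(self, round_idx: int) -> dict[str, float]:
        if self._val_batch is None:   # no validation split: keep last params
            self.best_params = {k: v.copy() for k, v in self.params.items()}
            return {}
        primary, metrics = self.validation_metric()
        if self.best_metric is None or primary > self.best_metric:
            self.best_metric = primary
            self.best_round = round_idx
            self.best_params = {k: v.copy() for k, v in self.params.items()}
        if self.cfg.patience > 0 and \
                round_idx - self.best_round >= self.cfg.patience:
            self.stopped = True
        return metrics


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    config: TrainConfig
    site_params: dict[str, dict[str, np.ndarray]]
    splits: dict[str, dict[str, np.ndarray]]
    history: list[dict] = field(default_factory=list)
    tags: dict[str, str] = field(default_factory=dict)


def train_federated(cfg: TrainConfig, datasets: list[InstitutionDataset],
                    manifest: FeatureManifest,
                    history_path: str | Path | None = None) -> TrainResult:
    """Run the configured protocol until max epochs or all-site early stop.

    ``datasets`` must already be standardized and imputed (see
    ``records_io.shared_standardize``).  Returns each site's best-validation
    parameter snapshot, the split indices, and the per-round history log.
    """
    cfg.validate()
    if cfg.mode == "centralized":
        return _train_centralized(cfg, datasets, manifest, history_path)
    shared_keys, private_map = partition_parameters(manifest)
    params, tags = init_parameters(manifest, cfg.hidden, cfg.seed)

    ss = np.random.SeedSequence(cfg.seed)
    site_seqs = ss.spawn(len(datasets))
    trainers = [SiteTrainer(ds, manifest, cfg, params, shared_keys, sq)
                for ds, sq in zip(datasets, site_seqs)]
    aggregate = cfg.mode == "federated"
    server_opt = AdamW(lr=cfg.lr, weight_decay=cfg.weight_decay,
                       decoupled=cfg.optimizer == "adamw")
    history: list[dict] = []

    global_shared = {k: params[k].copy() for k in shared_keys}
    for round_idx in range(1, cfg.epochs + 1):
        active = [tr for tr in trainers if not tr.stopped]
        if not active:
            break
        updates: list[ClientUpdate] = []
        for tr in active:
            # in isolated mode each site's reference snapshot is its own copy
            snapshot = ({k: global_shared[k] for k in tr.shared_keys}
                        if aggregate else
                        {k: tr.params[k] for k in tr.shared_keys})
            if cfg.fed_mode == "fedavg":
                updates.append(tr.local_update(round_idx, snapshot))
            else:
                updates.append(tr.gradient_update(round_idx, snapshot))
        if cfg.fed_mode == "fedavg":
            if aggregate:
                agg = fedavg_aggregate(updates, shared_keys)
                global_shared.update(agg)
                for tr in active:
                    tr.apply_shared(global_shared)
        else:  # accum
            if aggregate:
                G = accumulate_gradients(updates)
                shared_G = {k: g for k, g in G.items() if k in shared_keys}
                server_opt.step(global_shared, shared_G)
                for tr, upd in zip(active, updates):
                    tr.step_private(upd.grads)
                    tr.apply_shared(global_shared)
            else:
                for tr, upd in zip(active, updates):
                    tr.optimizer.step(tr.params, upd.grads)
        for tr in active:
            metrics = tr.after_round(round_idx)
            history.append({"round": round_idx,
                            "site": tr.dataset.institution_id,
                            "train_loss": float(tr.last_train_loss),
                            "stopped": bool(tr.stopped),
                            **{k: float(v) for k, v in metrics.items()}})
    # optional local fine-tuning from each site's best snapshot
    for tr in trainers:
        if cfg.finetune_epochs > 0:
            tr.params = {k: v.copy() for k, v in tr.best_params.items()}
            tr.stopped = False
            for e in range(cfg.finetune_epochs):
                tr.local_update(cfg.epochs + 1 + e,
                                {k: tr.params[k] for k in tr.shared_keys})
            tr.best_params = {k: v.copy() for k, v in tr.params.items()}

    result = TrainResult(
        config=cfg,
        site_params={tr.dataset.institution_id: tr.best_params
                     for tr in trainers},
        splits={tr.dataset.institution_id: tr.splits for tr in trainers},
        history=history, tags=tags)
    if history_path is not None:
        write_history(history, history_path)
    return result


def restrict_to_shared(datasets: list[InstitutionDataset],
                       manifest: FeatureManifest,
                       ) -> tuple[list[InstitutionDataset], FeatureManifest]:
    """Project every site onto the shared feature set (pooling view).

    The centralized oracle pools all sites' patients over the features
    recorded by at least two institutions; each site's private features are
    dropped, and a pooled patient keeps a row mask for shared features its
    origin site does not record.
    """
    from dataclasses import replace
    shared = manifest.shared_features()
    out_sets = []
    for ds in datasets:
        keep = [i for i, f in enumerate(ds.feature_names) if f in shared]
        names = tuple(ds.feature_names[i] for i in keep)
        recs = [replace(r, dynamics=r.dynamics[keep],
                        observed_mask=r.observed_mask[keep])
                for r in ds.records]
        out_sets.append(replace(ds, feature_names=names, records=recs))
    # the projected manifest spans every institution the federation knows,
    # so the canonical row indexing is stable whichever subset is passed
    per_site = {inst: {f: manifest.feature_kinds[f]
                       for f in manifest.recorded_by[inst]
                       if f in shared
                       or manifest.feature_kinds[f] == STATIC}
                for inst in manifest.recorded_by}
    return out_sets, FeatureManifest.from_site_manifests(per_site)


def _train_centralized(cfg: TrainConfig, datasets: list[InstitutionDataset],
                       manifest: FeatureManifest,
                       history_path: str | Path | None) -> TrainResult:
    """Pooled-data oracle: one model, one optimizer, every site's records.

    All patients are pooled over the *shared* feature set (private features
    dropped — see ``restrict_to_shared``) and a single parameter set with
    one global recalibration and head namespace is trained by interleaving
    minibatches from every site within each epoch.  Sites keep their own
    train/val/test splits so results are comparable with the other modes.
    """
    datasets, manifest = restrict_to_shared(datasets, manifest)
    params, _ = init_parameters(manifest, cfg.hidden, cfg.seed,
                                owners=["global"])
    tags = {k: "shared" for k in params}
    ss = np.random.SeedSequence(cfg.seed)
    trainers = [SiteTrainer(ds, manifest, cfg, params, set(params), sq,
                            owner="global")
                for ds, sq in zip(datasets, ss.spawn(len(datasets)))]
    for tr in trainers:
        tr.params = params          # all sites view the one global store
    opt = AdamW(lr=cfg.lr, weight_decay=cfg.weight_decay,
                decoupled=cfg.optimizer == "adamw")
    history: list[dict] = []
    for round_idx in range(1, cfg.epochs + 1):
        active = [tr for tr in trainers if not tr.stopped]
        if not active:
            break
        streams = [(tr, tr._minibatches(round_idx), tr._dropout_rng(round_idx))
                   for tr in active]
        losses = {tr.dataset.institution_id: np.nan for tr in active}
        while streams:
            for item in list(streams):
                tr, gen, drop_rng = item
                batch = next(gen, None)
                if batch is None:
                    streams.remove(item)
                    continue
                loss, leaves = tr.model.loss(params, batch, train=True,
                                             dropout_rng=drop_rng)
                loss.backward()
                opt.step(params, {k: t.grad for k, t in leaves.items()
                                  if t.grad is not None})
                losses[tr.dataset.institution_id] = loss.item()
        for tr in active:
            tr.last_train_loss = losses[tr.dataset.institution_id]
            metrics = tr.after_round(round_idx)
            history.append({"round": round_idx,
                            "site": tr.dataset.institution_id,
                            "train_loss": float(tr.last_train_loss),
                            "stopped": bool(tr.stopped),
                            **{k: float(v) for k, v in metrics.items()}})
    result = TrainResult(
        config=cfg,
        site_params={tr.dataset.institution_id: tr.best_params
                     for tr in trainers},
        splits={tr.dataset.institution_id: tr.splits for tr in trainers},
        history=history, tags=tags)
    if history_path is not None:
        write_history(history, history_path)
    return result


def write_history(history: list[dict], path: str | Path) -> None:
    """Append-only JSONL: one record per (round, site)."""
    with open(path, "a") as fh:
        for rec in history:
            fh.write(json.dumps(rec) + "\n")


def read_history(path: str | Path) -> list[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines()
            if line.strip()]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Keyed flat-parameter archive (.npz) with a JSON metadata sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for inst, ps in result.site_params.items():
        np.savez(path / f"{inst}.npz", **ps)
        np.savez(path / f"{inst}.splits.npz", **result.splits[inst])
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(result.config),
            "tags": result.tags,
            "institutions": sorted(result.site_params)}
    (path / "checkpoint.json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path,
                    ) -> tuple[TrainConfig, dict[str, dict[str, np.ndarray]],
                               dict[str, dict[str, np.ndarray]]]:
    path = Path(path)
    meta = json.loads((path / "checkpoint.json").read_text())
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    raw = meta["config"]
    raw["split"] = tuple(raw["split"])
    cfg = TrainConfig(**raw)
    site_params, splits = {}, {}
    for inst in meta["institutions"]:
        with np.load(path / f"{inst}.npz") as z:
            site_params[inst] = {k: z[k] for k in z.files}
        with np.load(path / f"{inst}.splits.npz") as z:
            splits[inst] = {k: z[k] for k in z.files}
    return cfg, site_params, splits
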