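"""Batched per-institution forward pass over the flat parameter store.

Parameters live in a flat ``{key: np.ndarray}`` dictionary whose keys encode
the namespace and sharing rule::

    channels.shared.<feature>.<p>              shared GRU channel
    channels.private.<institution>.<feature>.<p>  private GRU channel
    demographic.W_base                         shared demographic embedding
    recalibration.<institution>.Wq|Wk|Wv       private attention projections
    heads.<institution>.W_cla|b_cla|W_reg|b_reg   private task heads

The forward pass touches only the keys for features the institution records
(freeze-and-mask): unrecorded canonical rows enter the feature matrix as
zero constants, never through a channel, so their parameters receive no
gradient and do not even appear in a site's gradient dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .encoder import demographic_row, gru_forward, CHANNEL_PARAM_NAMES
from .heads import bce, classification_probability, mse, regression_prediction
from .recalibration import attend
from .records_io import FeatureManifest, InstitutionDataset

# fixed adult-population scaling for the demographic inputs
_AGE_CENTER, _AGE_SCALE = 56.5, 22.2


def channel_key_prefix(manifest: FeatureManifest, institution: str,
                       feature: str) -> str:
    if feature in manifest.shared_features():
        return f"channels.shared.{feature}"
    return f"channels.private.{institution}.{feature}"


@dataclass
class SiteBatch:
    """Padded numpy arrays for a subset of one institution's records."""

    dynamics: np.ndarray       # [B, n_site_features, T_max]
    valid: np.ndarray          # [B, T_max] bool
    demographics: np.ndarray   # [B, m], scaled
    mortality: np.ndarray | None      # [B] float
    los: np.ndarray | None            # [B, T_max] float
    patient_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.dynamics.shape[0]


def make_batch(dataset: InstitutionDataset, indices) -> SiteBatch:
    recs = [dataset.records[i] for i in indices]
    B, nf = len(recs), len(dataset.feature_names)
    T_max = max(r.T for r in recs)
    dyn = np.zeros((B, nf, T_max))
    valid = np.zeros((B, T_max), dtype=bool)
    demo = np.zeros((B, len(dataset.static_names)))
    mort = np.full(B, np.nan)
    los = np.full((B, T_max), np.nan)
    for b, r in enumerate(recs):
        dyn[b, :, :r.T] = r.dynamics
        valid[b, :r.T] = True
        demo[b] = r.demographics
        if r.mortality is not None:
            mort[b] = r.mortality
        if r.los_remaining is not None:
            los[b, :r.T] = r.los_remaining
    for j, name in enumerate(dataset.static_names):
        if name == "age":
            demo[:, j] = (demo[:, j] - _AGE_CENTER) / _AGE_SCALE
        elif name == "gender":
            demo[:, j] = demo[:, j] - 0.5
    return SiteBatch(dyn, valid, demo,
                     None if np.isnan(mort).all() else mort,
                     None if np.isnan(los).all() else los,
                     [r.patient_id for r in recs])


class SiteModel:
    """One institution's view of the model: params + manifest wiring."""

    def __init__(self, institution: str, manifest: FeatureManifest,
                 dataset_features: tuple[str, ...], task: str,
                 hidden: int = 32, dropout: float = 0.1,
                 owner: str | None = None):
        self.institution = institution
        #: namespace owner of the recalibration/head keys; differs from the
        #: institution only in centralized mode, where one "global" set is
        #: trained on every site's data
        self.owner = owner or institution
        self.manifest = manifest
        self.task = task
        self.hidden = hidden
        self.dropout = dropout
        self.canonical = manifest.dynamic_features()
        self.site_features = dataset_features
        self.row_mask = np.array(
            [f in set(dataset_features) for f in self.canonical] + [True])
        self._feat_col = {f: i for i, f in enumerate(dataset_features)}

    # -- keys -----------------------------------------------------------
    def channel_keys(self, feature: str) -> list[str]:
        prefix = channel_key_prefix(self.manifest, self.institution, feature)
        return [f"{prefix}.{p}" for p in CHANNEL_PARAM_NAMES]

    def used_keys(self) -> list[str]:
        keys = []
        for f in self.site_features:
            keys.extend(self.channel_keys(f))
        keys.append("demographic.W_base")
        keys.extend(f"recalibration.{self.owner}.{n}" for n in ("Wq", "Wk", "Wv"))
        keys.extend(f"heads.{self.owner}.{n}"
                    for n in ("W_cla", "b_cla", "W_reg", "b_reg"))
        return keys

    # -- forward ---------------------------------------------------------
    def loss(self, params: dict[str, np.ndarray], batch: SiteBatch,
             train: bool = False,
             dropout_rng: np.random.Generator | None = None,
             ) -> tuple[Tensor, dict[str, Tensor]]:
        """Site loss on a batch; returns (loss, leaf tensors by key).

        Classification sites contribute mean BCE over patients; LOS sites
        mean squared error over all valid (patient, record) pairs; "both"
        sums the two.  Call ``loss.backward()`` and read ``leaf.grad``.
        """
        leaves = {k: Tensor(params[k], requires_grad=True)
                  for k in self.used_keys()}
        need_los = self.task in ("los", "both") and batch.los is not None
        B, _, T = batch.dynamics.shape
        h = self.hidden

        # only recorded rows are materialized: unrecorded canonical rows are
        # zero constants with exactly-zero attention weight, so dropping
        # them leaves the loss and every gradient bitwise unchanged while
        # the per-row projections are gathered by canonical index (their
        # gradients scatter back, masked rows staying exactly zero)
        final_rows: list[Tensor] = []      # per recorded row, [B, h]
        step_rows: list[Tensor] = []       # per recorded row, [B, T, h]
        for f in self.canonical:
            if f not in self._feat_col:
                continue
            ch = {p: leaves[k] for p, k in
                  zip(CHANNEL_PARAM_NAMES, self.channel_keys(f))}
            x = Tensor(batch.dynamics[:, self._feat_col[f], :])
            states = gru_forward(ch, x, batch.valid)       # [B, T, h]
            final_rows.append(states[:, -1, :])
            if need_los:
                step_rows.append(states)
        demo = demographic_row(leaves["demographic.W_base"],
                               Tensor(batch.demographics))
        final_rows.append(demo)

        row_idx = np.flatnonzero(self.row_mask)
        rec = {n: leaves[f"recalibration.{self.owner}.{n}"][row_idx]
               for n in ("Wq", "Wk", "Wv")}
        compact_mask = np.ones(len(row_idx), dtype=bool)
        F_final = stack(final_rows, axis=1)                # [B, R_rec, h]
        _, _, s = attend(rec, F_final, compact_mask)
        s = self._dropout(s, train, dropout_rng)

        total: Tensor | None = None
        inst = self.owner
        if self.task in ("mortality", "both") and batch.mortality is not None:
            prob = classification_probability(
                leaves[f"heads.{inst}.W_cla"], leaves[f"heads.{inst}.b_cla"], s)
            total = bce(prob, batch.mortality)
        if need_los:
            # prefix representations: attention applied at every record
            step_rows.append(_tile_time(demo, T))
            F_steps = stack(step_rows, axis=2)             # [B, T, R_rec, h]
            _, _, s_t = attend(rec, F_steps, compact_mask)
            s_t = self._dropout(s_t, train, dropout_rng)
            pred = regression_prediction(
                leaves[f"heads.{inst}.W_reg"], leaves[f"heads.{inst}.b_reg"], s_t)
            reg = mse(pred, np.nan_to_num(batch.los), batch.valid)
            total = reg if total is None else total + reg
        if total is None:
            raise ValueError(f"site {self.institution}: no labels available for task "
                             f"{self.task!r}")
        return total, leaves

    def _dropout(self, s: Tensor, train: bool,
                 rng: np.random.Generator | None) -> Tensor:
        if not train or self.dropout <= 0.0 or rng is None:
            return s
        keep = (rng.random(s.shape) >= self.dropout) / (1.0 - self.dropout)
        return s * keep

    # -- inference -------------------------------------------------------
    def predict(self, params: dict[str, np.ndarray], batch: SiteBatch,
                ) -> dict[str, np.ndarray]:
        """Deterministic predictions: mortality probs and/or LOS estimates."""
        out: dict[str, np.ndarray] = {}
        leaves = {k: Tensor(params[k]) for k in self.used_keys()}
        B, _, T = batch.dynamics.shape
        h = self.hidden
        need_los = self.task in ("los", "both")
        final_rows, step_rows = [], []
        for f in self.canonical:
            if f not in self._feat_col:
                continue
            ch = {p: leaves[k] for p, k in
                  zip(CHANNEL_PARAM_NAMES, self.channel_keys(f))}
            states = gru_forward(ch, Tensor(batch.dynamics[:, self._feat_col[f], :]),
                                 batch.valid)
            final_rows.append(states[:, -1, :])
            if need_los:
                step_rows.append(states)
        demo = demographic_row(leaves["demographic.W_base"],
                               Tensor(batch.demographics))
        final_rows.append(demo)
        row_idx = np.flatnonzero(self.row_mask)
        rec = {n: leaves[f"recalibration.{self.owner}.{n}"][row_idx]
               for n in ("Wq", "Wk", "Wv")}
        compact_mask = np.ones(len(row_idx), dtype=bool)
        F_final = stack(final_rows, axis=1)
        _, alpha, s = attend(rec, F_final, compact_mask)
        # scatter attention weights back to canonical rows (masked rows 0)
        alpha_full = np.zeros((B, len(self.row_mask)))
        alpha_full[:, row_idx] = alpha.data
        out["alpha"] = alpha_full
        inst = self.owner
        if self.task in ("mortality", "both"):
            out["mortality_prob"] = classification_probability(
                leaves[f"heads.{inst}.W_cla"],
                leaves[f"heads.{inst}.b_cla"], s).data
        if need_los:
            step_rows.append(_tile_time(demo, T))
            F_steps = stack(step_rows, axis=2)
            _, _, s_t = attend(rec, F_steps, compact_mask)
            out["los_pred"] = regression_prediction(
                leaves[f"heads.{inst}.W_reg"],
                leaves[f"heads.{inst}.b_reg"], s_t).data
        return out


def _tile_time(row: Tensor, T: int) -> Tensor:
    """[B, h] -> [B, T, h] by repetition (gradient sums over time)."""
    return stack([row] * T, axis=1)


def init_parameters(manifest: FeatureManifest, hidden: int, seed: int,
                    owners: list[str] | None = None,
                    ) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Initialize the full flat parameter store and its shared/private tags.

    Shared leaves are initialized from a dedicated stream so every site
    starts from the identical shared state regardless of site order.
    ``owners`` overrides who owns the recalibration/head namespaces
    (default: one set per institution; centralized mode passes ["global"]).
    """
    from .encoder import init_channel_params, init_demographic_params
    from .heads import HeadParams
    from .recalibration import RecalibrationParams

    ss = np.random.SeedSequence(seed)
    shared_rng, private_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    params: dict[str, np.ndarray] = {}
    tags: dict[str, str] = {}
    shared = manifest.shared_features()
    canon = manifest.dynamic_features()
    n_rows = len(canon) + 1

    for f in canon:
        if f in shared:
            ch = init_channel_params(hidden, shared_rng)
            for p, v in ch.items():
                key = f"channels.shared.{f}.{p}"
                params[key], tags[key] = v, "shared"
    params["demographic.W_base"] = init_demographic_params(
        hidden, len(manifest.static_features()), shared_rng)
    tags["demographic.W_base"] = "shared"

    for inst in sorted(manifest.recorded_by):
        for f in manifest.dynamic_features(inst):
            if f not in shared:
                ch = init_channel_params(hidden, private_rng)
                for p, v in ch.items():
                    key = f"channels.private.{inst}.{f}.{p}"
                    params[key], tags[key] = v, "private"
    for owner in (owners if owners is not None
                  else sorted(manifest.recorded_by)):
        rec = RecalibrationParams.init(n_rows, hidden, private_rng)
        for n in ("Wq", "Wk", "Wv"):
            key = f"recalibration.{owner}.{n}"
            params[key], tags[key] = getattr(rec, n), "private"
        hp = HeadParams.init(hidden, private_rng)
        for n in ("W_cla", "b_cla", "W_reg", "b_reg"):
            key = f"heads.{owner}.{n}"
            params[key] = np.asarray(getattr(hp, n), dtype=float)
            tags[key] = "private"
    return params, tags
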