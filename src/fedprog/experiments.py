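"""Reusable experiment drivers built on the training engine.

The collaboration-benefit study asks the central scientific question of the
framework: does a small institution gain predictive performance by joining
the federation, compared with training alone on its own data?  It trains
the same architecture under three regimes — isolated, federated, and the
centralized pooled-data oracle — on freshly simulated cohorts and compares
test AUPRC for the smallest site across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import auprc
from .federation import TrainConfig, TrainResult, train_federated
from .model import SiteModel, make_batch
from .records_io import FeatureManifest, InstitutionDataset, shared_standardize
from .synthetic_cohort import CohortConfig, default_paperlike_config, generate_cohorts

#: training budget of the desk-scale benefit study: small minibatches give
#: the optimizer enough steps on cohorts of a few hundred patients
BENEFIT_EPOCHS = 10
BENEFIT_BATCH = 32


def predict_split(result: TrainResult, dataset: InstitutionDataset,
                  manifest: FeatureManifest, split: str = "test",
                  ) -> tuple[dict[str, np.ndarray], "np.ndarray"]:
    """Run a trained site model on one of its held-out splits."""
    inst = dataset.institution_id
    owner = None
    if result.config.mode == "centralized":
        # the pooled oracle was trained on the shared-feature projection
        from .federation import restrict_to_shared
        [dataset], manifest = restrict_to_shared([dataset], manifest)
        owner = "global"
    sm = SiteModel(inst, manifest, dataset.feature_names, dataset.task,
                   hidden=result.config.hidden, dropout=result.config.dropout,
                   owner=owner)
    idx = result.splits[inst][split]
    batch = make_batch(dataset, idx)
    return sm.predict(result.site_params[inst], batch), batch


@dataclass
class BenefitOutcome:
    """Per-seed test AUPRC of the smallest site under each regime."""

    seeds: list[int]
    federated: list[float] = field(default_factory=list)
    isolated: list[float] = field(default_factory=list)
    centralized: list[float] = field(default_factory=list)

    @property
    def wins(self) -> int:
        return sum(f > i for f, i in zip(self.federated, self.isolated))

    def medians(self) -> dict[str, float]:
        return {k: float(np.median(getattr(self, k)))
                for k in ("federated", "isolated", "centralized")}


def smallest_site(datasets: list[InstitutionDataset]) -> InstitutionDataset:
    return min(datasets, key=lambda d: d.sample_count)


def run_benefit_seed(seed: int, cohort: CohortConfig | None = None,
                     epochs: int = BENEFIT_EPOCHS,
                     batch_size: int = BENEFIT_BATCH,
                     modes: tuple[str, ...] = ("federated", "isolated",
                                               "centralized"),
                     ) -> dict[str, float]:
    """One seed of the benefit study; returns test AUPRC per training mode.

    The cohort and every training run derive from ``seed``; the isolated
    regime trains only the smallest site (the others are irrelevant to its
    isolated performance).
    """
    cohort = cohort if cohort is not None else default_paperlike_config(seed=seed)
    datasets, manifest, _ = generate_cohorts(cohort)
    std = shared_standardize(datasets, manifest)
    small = smallest_site(std)
    out: dict[str, float] = {}
    for mode in modes:
        train_sets = [small] if mode == "isolated" else std
        cfg = TrainConfig(mode=mode, epochs=epochs, batch_size=batch_size,
                          patience=max(epochs, 10), seed=seed)
        result = train_federated(cfg, train_sets, manifest)
        preds, batch = predict_split(result, small, manifest, "test")
        out[mode] = auprc(preds["mortality_prob"], batch.mortality)
    return out


def collaboration_benefit(seeds: list[int], **kwargs) -> BenefitOutcome:
    """Run the benefit study across seeds (fresh cohort per seed)."""
    outcome = BenefitOutcome(seeds=list(seeds))
    for seed in seeds:
        res = run_benefit_seed(seed, **kwargs)
        outcome.federated.append(res["federated"])
        outcome.isolated.append(res["isolated"])
        outcome.centralized.append(res["centralized"])
    return outcome
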