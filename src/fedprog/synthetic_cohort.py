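"""Synthetic multi-institution EHR cohorts with heterogeneous feature sets.

The generator emulates the structure of a multi-hospital collaboration:
several institutions, partially overlapping dynamic numeric feature sets
arranged in a Venn structure (globally shared / pairwise shared / private),
two common demographics (age, gender), variable-length visit sequences,
an imbalanced binary mortality outcome, and a remaining-days length-of-stay
target for a subset of sites.

Generative model (fixed, documented in docs/methods.md):

* Per patient a latent risk trajectory ``z_t`` (dimension ``latent_dim``)
  follows a Gaussian random walk: ``z_0 ~ N(0, I)``,
  ``z_t = z_{t-1} + N(0, step_sd^2 I)``.
* Every dynamic feature f has a fixed random linear readout ``a_f`` (shared
  across institutions — a lab test is the same quantity everywhere):
  ``x_{f,t} = a_f . z_t + noise_sd * eps``.
* Sequence length T decreases monotonically with early latent risk, so the
  remaining-days target ``los_t = T - 1 - t`` is predictable from the
  features; it is non-negative and decrements by exactly the unit
  inter-record gap.
* Mortality ~ Bernoulli(sigmoid(intercept + effect_weights . z_T + weak
  demographic effects)); the intercept is calibrated by bisection so the
  expected event rate matches ``mortality_base_rate``.
* Observations are dropped i.i.d. at ``missing_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .records_io import (DYNAMIC, STATIC, FeatureManifest, InstitutionDataset,
                         PatientRecord, write_institution_dataset)

_STEP_SD = 0.5          # random-walk increment sd
_AGE_LOGIT = 0.3        # weak demographic effects on the mortality logit
_GENDER_LOGIT = 0.2
_CALIBRATION_SEED = 12345  # internal seed for intercept Monte Carlo
_CALIBRATION_N = 10000


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated collaboration."""

    n_institutions: int = 3
    n_patients: tuple[int, ...] = (400, 1500, 600)
    n_shared_features: int = 8      # recorded by every institution
    n_pairwise_features: int = 4    # per pairwise-exclusive intersection
    n_private_features: int = 4     # per institution
    T_range: tuple[int, int] = (4, 10)
    latent_dim: int = 3
    effect_weights: tuple[float, ...] = (1.2, -0.8, 0.5)
    mortality_base_rate: float = 0.15
    noise_sd: float = 0.5
    missing_rate: float = 0.2
    tasks: tuple[str, ...] = ("both", "both", "mortality")
    seed: int = 0

    def validate(self) -> None:
        if self.n_institutions < 1:
            raise ConfigError("need at least one institution")
        if len(self.n_patients) != self.n_institutions:
            raise ConfigError("n_patients must have one entry per institution")
        if len(self.tasks) != self.n_institutions:
            raise ConfigError("tasks must have one entry per institution")
        if min(self.n_shared_features, self.n_pairwise_features,
               self.n_private_features) < 0:
            raise ConfigError("feature counts must be non-negative")
        if self.n_pairwise_features > 0 and self.n_institutions < 2:
            raise ConfigError("pairwise features require >= 2 institutions")
        if self.n_institutions >= 2 and self.n_shared_features == 0 \
                and self.n_pairwise_features == 0:
            raise ConfigError("at least one shared feature is required for "
                              "a federation to be meaningful")
        if not (0.0 < self.mortality_base_rate < 1.0):
            raise ConfigError("mortality_base_rate must be in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if len(self.effect_weights) != self.latent_dim:
            raise ConfigError("effect_weights length must equal latent_dim")
        if self.T_range[0] < 1 or self.T_range[1] < self.T_range[0]:
            raise ConfigError("invalid T_range")


def default_paperlike_config(seed: int = 0) -> CohortConfig:
    """Three institutions mirroring an asymmetric real collaboration.

    Feature Venn: 8 globally shared + 4 per pairwise intersection + 4
    private per site (union 8 + 3*4 + 3*4 = 32 dynamic features).  Sites 1
    and 2 predict both mortality and remaining length of stay; site 3 is
    mortality-only.  Cohort sizes 400/1500/600 keep the small-site /
    large-site asymmetry of real multi-hospital studies at desk scale.
    """
    return CohortConfig(seed=seed)


@dataclass
class GroundTruth:
    """Simulation internals for parameter-recovery tests (never trained on)."""

    readout: dict[str, list[float]]               # feature -> a_f
    intercept: float
    z: dict[str, list[list[float]]] = field(default_factory=dict)
    event_prob: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"readout": self.readout, "intercept": self.intercept,
                           "z": self.z, "event_prob": self.event_prob})


def _feature_venn(cfg: CohortConfig) -> dict[str, dict[str, str]]:
    """Assign feature names per institution realizing the Venn structure."""
    insts = [f"site{i}" for i in range(cfg.n_institutions)]
    per_site: dict[str, dict[str, str]] = {s: {} for s in insts}
    for k in range(cfg.n_shared_features):
        for s in insts:
            per_site[s][f"lab_all_{k:02d}"] = DYNAMIC
    if cfg.n_institutions >= 2:
        for i, j in combinations(range(cfg.n_institutions), 2):
            for k in range(cfg.n_pairwise_features):
                name = f"lab_pair{i}{j}_{k:02d}"
                per_site[insts[i]][name] = DYNAMIC
                per_site[insts[j]][name] = DYNAMIC
    for i, s in enumerate(insts):
        for k in range(cfg.n_private_features):
            per_site[s][f"lab_priv{i}_{k:02d}"] = DYNAMIC
        per_site[s]["age"] = STATIC
        per_site[s]["gender"] = STATIC
    return per_site


def _logit_samples(cfg: CohortConfig, effect: np.ndarray,
                   rng: np.random.Generator, n: int) -> np.ndarray:
    """Monte Carlo draws of the mortality logit without the intercept."""
    T = rng.integers(cfg.T_range[0], cfg.T_range[1] + 1, size=n)
    zT_sd = np.sqrt(1.0 + (T - 1) * _STEP_SD ** 2)          # per-dimension
    risk = (rng.standard_normal((n, cfg.latent_dim)) * zT_sd[:, None]) @ effect
    age = rng.uniform(18, 95, size=n)
    gender = rng.integers(0, 2, size=n)
    return (risk + _AGE_LOGIT * (age - 56.5) / 22.0
            + _GENDER_LOGIT * (gender - 0.5))


def calibrate_intercept(cfg: CohortConfig) -> float:
    """Bisection on the intercept so E[sigmoid(b + logit)] hits the base rate.

    Uses a fixed-seed Monte Carlo sample of the logit distribution so the
    intercept is a deterministic function of the configuration.
    """
    effect = np.asarray(cfg.effect_weights, dtype=float)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    logits = _logit_samples(cfg, effect, rng, _CALIBRATION_N)
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(mid + logits)))).mean() < cfg.mortality_base_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohorts(cfg: CohortConfig,
                     ) -> tuple[list[InstitutionDataset], FeatureManifest,
                                GroundTruth]:
    """Simulate one multi-institution cohort; deterministic in ``cfg.seed``."""
    cfg.validate()
    per_site = _feature_venn(cfg)
    manifest = FeatureManifest.from_site_manifests(per_site)
    all_dynamic = manifest.dynamic_features()

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    effect = np.asarray(cfg.effect_weights, dtype=float)
    # fixed random linear readout per feature, shared across institutions
    readout = {f: rng.standard_normal(cfg.latent_dim) for f in all_dynamic}
    intercept = calibrate_intercept(cfg)
    truth = GroundTruth({f: a.tolist() for f, a in readout.items()}, intercept)

    T_min, T_max = cfg.T_range
    effect_norm = float(np.linalg.norm(effect))
    datasets: list[InstitutionDataset] = []
    for i in range(cfg.n_institutions):
        inst = f"site{i}"
        dyn_feats = manifest.dynamic_features(inst)
        A = np.stack([readout[f] for f in dyn_feats])   # [n_feat, latent]
        records: list[PatientRecord] = []
        for p in range(cfg.n_patients[i]):
            pid = f"{inst}_p{p:05d}"
            # latent random walk over the maximum horizon
            steps = rng.standard_normal((T_max, cfg.latent_dim)) * _STEP_SD
            steps[0] = rng.standard_normal(cfg.latent_dim)
            z_full = np.cumsum(steps, axis=0)            # [T_max, latent]
            # stay length: monotone decreasing in early latent risk
            if effect_norm > 0:
                early = z_full[:T_min].mean(axis=0) @ effect / effect_norm
            else:
                early = 0.0
            mid_T = 0.5 * (T_min + T_max)
            T = int(np.clip(round(mid_T - 0.25 * (T_max - T_min) * early),
                            T_min, T_max))
            z = z_full[:T]
            dyn = A @ z.T + cfg.noise_sd * rng.standard_normal((len(dyn_feats), T))
            mask = rng.random((len(dyn_feats), T)) >= cfg.missing_rate
            dyn = np.where(mask, dyn, 0.0)
            age = rng.uniform(18, 95)
            gender = int(rng.integers(0, 2))
            logit = (intercept + effect @ z[-1]
                     + _AGE_LOGIT * (age - 56.5) / 22.0
                     + _GENDER_LOGIT * (gender - 0.5))
            prob = 1.0 / (1.0 + np.exp(-logit))
            mort = int(rng.random() < prob)
            task = cfg.tasks[i]
            los = (np.arange(T)[::-1].astype(float)
                   if task in ("los", "both") else None)
            records.append(PatientRecord(
                patient_id=pid, dynamics=dyn, observed_mask=mask,
                demographics=np.array([age, float(gender)]),
                mortality=mort if task in ("mortality", "both") else None,
                los_remaining=los))
            truth.z[pid] = z.tolist()
            truth.event_prob[pid] = float(prob)
        ds = InstitutionDataset(inst, cfg.tasks[i], dyn_feats,
                                ("age", "gender"), records)
        ds.validate()
        datasets.append(ds)
    return datasets, manifest, truth


def write_cohorts(cfg: CohortConfig, out_dir: str | Path,
                  ) -> list[Path]:
    """Generate and write institution directories plus groundtruth.json."""
    datasets, _manifest, truth = generate_cohorts(cfg)
    out_dir = Path(out_dir)
    paths = []
    for ds in datasets:
        p = out_dir / ds.institution_id
        write_institution_dataset(ds, p)
        site_truth = GroundTruth(
            truth.readout, truth.intercept,
            {pid: truth.z[pid] for pid in (r.patient_id for r in ds.records)},
            {pid: truth.event_prob[pid]
             for pid in (r.patient_id for r in ds.records)})
        (p / "groundtruth.json").write_text(site_truth.to_json())
        paths.append(p)
    return paths
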