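"""Institution dataset model, on-disk format, and federated standardization.

An institution dataset lives in a directory of plain-text files:

* ``manifest.json`` — ``{institution_id, task, features: [{name, kind}]}``
* ``timeseries.csv`` — long format ``patient_id,time_index,feature,value``
* ``demographics.csv`` — ``patient_id`` plus one column per static feature
* ``labels.csv`` — ``patient_id,time_index,mortality,los_remaining``

Standardization follows the privacy pattern of the federation: sites exchange
per-feature moment triples ``(count, sum, sumsq)`` — never raw values — and
every site applies the merged (pooled) mean/std to the features it shares.
Population (divide-by-N) variance is used so that moment merging is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

DYNAMIC = "dynamic_numeric"
STATIC = "static_demographic"

#: below this pooled std a feature is degenerate and passes through unscaled
STD_FLOOR = 1e-8


class FormatError(ValueError):
    """A required file is missing or structurally unreadable."""


class SchemaError(ValueError):
    """File contents contradict the manifest or the expected columns."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureManifest:
    """The universe of harmonized feature names and who records what.

    ``recorded_by`` maps institution id to the subset of ``feature_names``
    that institution records.  A dynamic feature is *shared* when at least
    two institutions record it, *private to i* when only institution ``i``
    does.  The canonical order is the sorted union across institutions.
    """

    feature_names: tuple[str, ...]
    feature_kinds: dict[str, str]
    recorded_by: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for inst, feats in self.recorded_by.items():
            if not feats:
                raise SchemaError(f"institution {inst!r} records no features")
            unknown = set(feats) - set(self.feature_names)
            if unknown:
                raise SchemaError(f"{inst!r} records unknown features {sorted(unknown)}")

    @staticmethod
    def from_site_manifests(per_site: dict[str, dict[str, str]]) -> "FeatureManifest":
        """Build the global manifest from {site: {feature: kind}} maps."""
        kinds: dict[str, str] = {}
        for feats in per_site.values():
            for name, kind in feats.items():
                if kinds.setdefault(name, kind) != kind:
                    raise SchemaError(f"feature {name!r} has conflicting kinds")
        names = tuple(sorted(kinds))
        recorded = {s: tuple(sorted(f)) for s, f in per_site.items()}
        return FeatureManifest(names, kinds, recorded)

    def dynamic_features(self, institution: str | None = None) -> tuple[str, ...]:
        pool = set(self.feature_names if institution is None
                   else self.recorded_by[institution])
        return tuple(f for f in self.feature_names
                     if self.feature_kinds[f] == DYNAMIC and f in pool)

    def static_features(self, institution: str | None = None) -> tuple[str, ...]:
        pool = set(self.feature_names if institution is None
                   else self.recorded_by[institution])
        return tuple(f for f in self.feature_names
                     if self.feature_kinds[f] == STATIC and f in pool)

    def shared(self, i: str, j: str) -> set[str]:
        return set(self.recorded_by[i]) & set(self.recorded_by[j])

    def shared_features(self) -> set[str]:
        """Features recorded by at least two institutions."""
        counts: dict[str, int] = {}
        for feats in self.recorded_by.values():
            for f in feats:
                counts[f] = counts.get(f, 0) + 1
        return {f for f, c in counts.items() if c >= 2}

    def private_features(self, institution: str) -> set[str]:
        return set(self.recorded_by[institution]) - self.shared_features()


@dataclass
class PatientRecord:
    """One patient's longitudinal record at a single institution.

    ``dynamics`` is ``[n_recorded_features, T]`` in the institution's sorted
    dynamic-feature order; ``observed_mask`` marks cells actually measured.
    ``los_remaining`` (when the site does length-of-stay prediction) holds
    the remaining days to outcome at each record.
    """

    patient_id: str
    dynamics: np.ndarray
    observed_mask: np.ndarray
    demographics: np.ndarray
    mortality: int | None = None
    los_remaining: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.dynamics.shape[1]

    def validate(self, n_features: int) -> None:
        if self.dynamics.ndim != 2 or self.dynamics.shape[0] != n_features:
            raise SchemaError(
                f"patient {self.patient_id}: dynamics shape {self.dynamics.shape} "
                f"does not match {n_features} recorded features")
        if self.dynamics.shape != self.observed_mask.shape:
            raise SchemaError(f"patient {self.patient_id}: mask shape mismatch")
        if self.T < 1:
            raise SchemaError(f"patient {self.patient_id}: empty sequence")
        if self.los_remaining is not None:
            los = np.asarray(self.los_remaining, dtype=float)
            if len(los) != self.T:
                raise SchemaError(f"patient {self.patient_id}: los length != T")
            if (los < 0).any() or (np.diff(los) > 0).any():
                raise SchemaError(
                    f"patient {self.patient_id}: los_remaining must be "
                    "non-negative and non-increasing")


@dataclass
class InstitutionDataset:
    institution_id: str
    task: str  # mortality | los | both
    feature_names: tuple[str, ...]   # recorded dynamic features, sorted
    static_names: tuple[str, ...]    # recorded demographics, sorted
    records: list[PatientRecord] = field(default_factory=list)

    @property
    def sample_count(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        if self.task not in ("mortality", "los", "both"):
            raise SchemaError(f"unknown task {self.task!r}")
        for rec in self.records:
            rec.validate(len(self.feature_names))
            if self.task in ("mortality", "both") and rec.mortality is None:
                raise SchemaError(f"patient {rec.patient_id}: missing mortality label")
            if self.task in ("los", "both") and rec.los_remaining is None:
                raise SchemaError(f"patient {rec.patient_id}: missing los labels")


@dataclass
class StandardizationMetadata:
    """Per-feature pooled first/second moments, population convention."""

    count: dict[str, int]
    mean: dict[str, float]
    std: dict[str, float]

    def is_degenerate(self, feature: str) -> bool:
        return self.count[feature] == 0 or self.std[feature] < STD_FLOOR


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_institution_dataset(dataset: InstitutionDataset, path: str | Path) -> None:
    """Write the dataset directory (UTF-8 CSV, comma separated, '.' decimal)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "institution_id": dataset.institution_id,
        "task": dataset.task,
        "features": ([{"name": f, "kind": DYNAMIC} for f in dataset.feature_names]
                     + [{"name": f, "kind": STATIC} for f in dataset.static_names]),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))

    ts_rows, demo_rows, label_rows = [], [], []
    for rec in dataset.records:
        for fi, feat in enumerate(dataset.feature_names):
            for t in range(rec.T):
                if rec.observed_mask[fi, t]:
                    ts_rows.append((rec.patient_id, t, feat,
                                    repr(float(rec.dynamics[fi, t]))))
        demo_rows.append((rec.patient_id, *[repr(float(v))
                                            for v in rec.demographics]))
        for t in range(rec.T):
            label_rows.append((
                rec.patient_id, t,
                "" if rec.mortality is None else rec.mortality,
                "" if rec.los_remaining is None else repr(float(rec.los_remaining[t])),
            ))
    pd.DataFrame(ts_rows, columns=["patient_id", "time_index", "feature", "value"]) \
        .to_csv(path / "timeseries.csv", index=False)
    pd.DataFrame(demo_rows, columns=["patient_id", *dataset.static_names]) \
        .to_csv(path / "demographics.csv", index=False)
    pd.DataFrame(label_rows, columns=["patient_id", "time_index",
                                      "mortality", "los_remaining"]) \
        .to_csv(path / "labels.csv", index=False)


def load_institution_dataset(path: str | Path) -> InstitutionDataset:
    """Load and validate one institution directory.

    Missing cells (feature/time pairs absent from ``timeseries.csv``) get
    ``observed_mask=False``; row order follows the sorted manifest order.
    ``groundtruth.json`` (written only by the simulator) is never read here,
    so simulated truth cannot leak into a training path.
    """
    path = Path(path)
    for fname in ("manifest.json", "timeseries.csv", "demographics.csv", "labels.csv"):
        if not (path / fname).exists():
            raise FormatError(f"{path}: missing required file {fname}")
    manifest = json.loads((path / "manifest.json").read_text())
    feats = {e["name"]: e["kind"] for e in manifest["features"]}
    dynamic = tuple(sorted(f for f, k in feats.items() if k == DYNAMIC))
    static = tuple(sorted(f for f, k in feats.items() if k == STATIC))
    task = manifest["task"]

    # round_trip parsing so write -> load is bit-exact on float values
    ts = pd.read_csv(path / "timeseries.csv", float_precision="round_trip",
                     dtype={"patient_id": str, "feature": str, "value": str})
    demo = pd.read_csv(path / "demographics.csv", dtype={"patient_id": str},
                       float_precision="round_trip")
    labels = pd.read_csv(path / "labels.csv", dtype={"patient_id": str},
                         float_precision="round_trip")

    unknown = set(ts["feature"].unique()) - set(dynamic)
    if unknown:
        raise SchemaError(f"{path}: timeseries features not in manifest: "
                          f"{sorted(unknown)}")
    bad = ts[pd.to_numeric(ts["value"], errors="coerce").isna()
             & ts["value"].notna()]
    if len(bad):
        raise SchemaError(f"{path}: non-numeric value in timeseries.csv "
                          f"row {bad.index[0] + 2}")  # +2: header + 0-base
    ts["value"] = ts["value"].astype(float)   # exact per-element conversion

    feat_idx = {f: i for i, f in enumerate(dynamic)}
    demo = demo.set_index("patient_id")
    records: list[PatientRecord] = []
    label_groups = dict(iter(labels.groupby("patient_id", sort=False)))
    ts_groups = dict(iter(ts.groupby("patient_id", sort=False)))
    for pid in labels["patient_id"].unique():
        lab = label_groups[pid].sort_values("time_index")
        T = int(lab["time_index"].max()) + 1
        dyn = np.zeros((len(dynamic), T))
        mask = np.zeros((len(dynamic), T), dtype=bool)
        g = ts_groups.get(pid)
        if g is not None:
            obs = g.dropna(subset=["value"])
            rows = obs["feature"].map(feat_idx).to_numpy()
            cols = obs["time_index"].to_numpy(dtype=int)
            dyn[rows, cols] = obs["value"].to_numpy()
            mask[rows, cols] = True
        mort = lab["mortality"].iloc[0]
        mort = None if pd.isna(mort) else int(mort)
        los = lab["los_remaining"].to_numpy(dtype=float)
        los = None if np.isnan(los).all() else los
        records.append(PatientRecord(
            patient_id=str(pid), dynamics=dyn, observed_mask=mask,
            demographics=demo.loc[str(pid), list(static)].to_numpy(dtype=float)
            if static else np.zeros(0),
            mortality=mort, los_remaining=los))
    ds = InstitutionDataset(manifest["institution_id"], task, dynamic,
                            static, records)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# moment sharing and standardization
# ---------------------------------------------------------------------------

def compute_local_moments(dataset: InstitutionDataset,
                          features: list[str] | tuple[str, ...],
                          ) -> dict[str, tuple[int, float, float]]:
    """Per-feature ``(count, sum, sum_of_squares)`` over observed cells only.

    These triples are the only statistics a site ever exports: they allow
    pooled standardization without exchanging any raw value.
    """
    out: dict[str, tuple[int, float, float]] = {}
    idx = {f: i for i, f in enumerate(dataset.feature_names)}
    for feat in features:
        if feat not in idx:
            raise SchemaError(
                f"feature {feat!r} not recorded by {dataset.institution_id}")
        i = idx[feat]
        vals = np.concatenate([rec.dynamics[i][rec.observed_mask[i]]
                               for rec in dataset.records]) \
            if dataset.records else np.zeros(0)
        out[feat] = (int(vals.size), float(vals.sum()),
                     float((vals ** 2).sum()))
    return out


def merge_moments(moment_sets: list[dict[str, tuple[int, float, float]]],
                  ) -> StandardizationMetadata:
    """Count-weighted merge of moment triples into pooled mean/std.

    The merge is exact (population variance), so the result is identical to
    computing moments on the concatenation of all sites' values, in any
    merge order.  A feature with total count 0 or pooled std below
    ``STD_FLOOR`` is degenerate: ``standardize`` passes it through.
    """
    if not moment_sets:
        raise ValueError("merge_moments: empty input")
    keys = set(moment_sets[0])
    for ms in moment_sets[1:]:
        if set(ms) != keys:
            raise SchemaError("merge_moments: feature lists differ across sets")
    count, mean, std = {}, {}, {}
    for feat in keys:
        n = sum(ms[feat][0] for ms in moment_sets)
        s = sum(ms[feat][1] for ms in moment_sets)
        ss = sum(ms[feat][2] for ms in moment_sets)
        count[feat] = n
        if n == 0:
            mean[feat], std[feat] = 0.0, 0.0
            continue
        mu = s / n
        var = max(ss / n - mu * mu, 0.0)
        mean[feat], std[feat] = mu, float(np.sqrt(var))
    return StandardizationMetadata(count, mean, std)


def write_moments(moments: dict[str, tuple[int, float, float]],
                  path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {f: {"count": c, "sum": s, "sumsq": ss}
         for f, (c, s, ss) in moments.items()}, indent=1))


def read_moments(path: str | Path) -> dict[str, tuple[int, float, float]]:
    raw = json.loads(Path(path).read_text())
    return {f: (int(v["count"]), float(v["sum"]), float(v["sumsq"]))
            for f, v in raw.items()}


def standardize(dataset: InstitutionDataset,
                metadata: StandardizationMetadata) -> InstitutionDataset:
    """Return a copy with observed values z-scored feature-wise.

    ``metadata`` must cover every recorded feature (pooled moments for
    shared features, local moments for private ones).  Masked cells are
    left untouched; degenerate features pass through unchanged.
    """
    missing = set(dataset.feature_names) - set(metadata.count)
    if missing:
        raise SchemaError(f"standardize: no metadata for {sorted(missing)}")
    new_records = []
    for rec in dataset.records:
        dyn = rec.dynamics.copy()
        for i, feat in enumerate(dataset.feature_names):
            if metadata.is_degenerate(feat):
                continue
            obs = rec.observed_mask[i]
            dyn[i, obs] = (dyn[i, obs] - metadata.mean[feat]) / metadata.std[feat]
        new_records.append(replace(rec, dynamics=dyn))
    return replace(dataset, records=new_records)


def impute(dataset: InstitutionDataset,
           metadata: StandardizationMetadata | None = None,
           demographic_fill: dict[int, float] | None = None,
           ) -> InstitutionDataset:
    """Mean-impute unobserved dynamic cells; the mask is preserved.

    In standardized space the feature mean is 0, so continuous imputation
    fills zeros.  ``observed_mask`` still records the original missingness
    because the recalibration attention consumes it downstream.
    ``demographic_fill`` maps demographic column index to a fill value
    (mode for categorical, mean for continuous) applied to NaN entries.
    """
    new_records = []
    for rec in dataset.records:
        dyn = rec.dynamics.copy()
        dyn[~rec.observed_mask] = 0.0
        demo = rec.demographics.copy()
        if demographic_fill:
            for j, v in demographic_fill.items():
                if np.isnan(demo[j]):
                    demo[j] = v
        new_records.append(replace(rec, dynamics=dyn, demographics=demo))
    return replace(dataset, records=new_records)


def shared_standardize(datasets: list[InstitutionDataset],
                       manifest: FeatureManifest,
                       ) -> list[InstitutionDataset]:
    """Full preprocessing pipeline used before any training mode.

    Shared features are standardized with moments merged across every site
    recording them; private features with local moments; then unobserved
    cells are mean-imputed (zero in standardized space).
    """
    shared = manifest.shared_features()
    local = {ds.institution_id:
             compute_local_moments(ds, ds.feature_names) for ds in datasets}
    out = []
    for ds in datasets:
        merged: dict[str, tuple[int, float, float]] = {}
        for feat in ds.feature_names:
            if feat in shared:
                contributions = [
                    {feat: local[o.institution_id][feat]} for o in datasets
                    if feat in o.feature_names]
                merged[feat] = (
                    sum(c[feat][0] for c in contributions),
                    sum(c[feat][1] for c in contributions),
                    sum(c[feat][2] for c in contributions))
            else:
                merged[feat] = local[ds.institution_id][feat]
        meta = merge_moments([merged])
        out.append(impute(standardize(ds, meta), meta))
    return out
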