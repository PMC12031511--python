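"""Attention-based feature recalibration with hard masking.

Each canonical row i of the feature matrix F owns a triple of square
projection matrices (W_i^q, W_i^k, W_i^v).  A shared context vector f_bar
(the mean of the *recorded* rows) is projected into per-row queries; rows
into keys and values.  Scores of unrecorded rows are replaced by a large
negative constant so that after the softmax their weight underflows to
exactly zero — the suppressed rows contribute nothing to the health-status
representation s and receive exactly-zero gradients (the freeze-and-mask
contract).  Recalibration parameters are always private to an institution:
they encode which features matter for *its* task and case mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, as_tensor, masked_softmax, rowdot,
                       rowwise_linear, rowwise_context_linear,
                       weighted_row_sum)
from .encoder import FeatureMatrix

#: score assigned to unrecorded rows ("a negative number with large
#: absolute value"); exp(MASK_VALUE - max) underflows to exactly 0.
MASK_VALUE = -1e9


class DegenerateInputError(ValueError):
    pass


@dataclass
class RecalibrationParams:
    """Per-canonical-row projection triples, each [R, h, h]."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray

    @staticmethod
    def init(n_rows: int, h: int, rng: np.random.Generator) -> "RecalibrationParams":
        bound = 1.0 / np.sqrt(h)
        return RecalibrationParams(
            *(rng.uniform(-bound, bound, (n_rows, h, h)) for _ in range(3)))


@dataclass
class AttentionState:
    """Intermediate attention quantities for one patient (interpretability)."""

    f_bar: np.ndarray
    zeta: np.ndarray      # raw scores, MASK_VALUE at unrecorded rows
    alpha: np.ndarray     # attention weights, sum to 1, 0 at masked rows
    s: np.ndarray         # health-status representation


# -- batched tensor path (training) -----------------------------------------

def context_vector(F: Tensor, row_mask: np.ndarray) -> Tensor:
    """Mean over recorded rows: F is [..., R, h], row_mask is bool [R]."""
    row_mask = np.asarray(row_mask, dtype=bool)
    if not row_mask.any():
        raise DegenerateInputError("no recorded rows to pool")
    sel = row_mask.astype(float)[:, None]
    return (F * sel).sum(axis=-2) * (1.0 / row_mask.sum())


def attention_weights(params: dict[str, Tensor], F: Tensor,
                      f_bar: Tensor, row_mask: np.ndarray,
                      ) -> tuple[Tensor, Tensor]:
    """Raw scores zeta and masked softmax weights alpha, shapes [..., R]."""
    q = rowwise_context_linear(params["Wq"], f_bar)    # [..., R, h]
    k = rowwise_linear(params["Wk"], F)
    zeta = rowdot(q, k)
    zeta = zeta.where(row_mask, MASK_VALUE)
    alpha = masked_softmax(zeta, row_mask, axis=-1)
    return zeta, alpha


def recalibrated_representation(params: dict[str, Tensor], alpha: Tensor,
                                F: Tensor) -> Tensor:
    """s = sum_i alpha_i * (W_i^v f_i); masked rows contribute exactly 0."""
    v = rowwise_linear(params["Wv"], F)                # [..., R, h]
    return weighted_row_sum(alpha, v)


def attend(params: dict[str, Tensor], F: Tensor,
           row_mask: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
    """Full recalibration: returns (zeta, alpha, s)."""
    f_bar = context_vector(F, row_mask)
    zeta, alpha = attention_weights(params, F, f_bar, row_mask)
    s = recalibrated_representation(params, alpha, F)
    return zeta, alpha, s


# -- single-patient numpy surface -------------------------------------------

def compute_context(F: FeatureMatrix) -> np.ndarray:
    """f_bar: mean of the recorded rows of F."""
    return context_vector(as_tensor(F.F), F.recorded_row_mask).data


def attention_scores(params: RecalibrationParams, F: FeatureMatrix,
                     f_bar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(zeta, alpha) for one patient."""
    tensors = {"Wq": as_tensor(params.Wq), "Wk": as_tensor(params.Wk),
               "Wv": as_tensor(params.Wv)}
    zeta, alpha = attention_weights(tensors, as_tensor(F.F),
                                    as_tensor(f_bar), F.recorded_row_mask)
    return zeta.data, alpha.data


def recalibrate(alpha: np.ndarray, params: RecalibrationParams,
                F: FeatureMatrix) -> np.ndarray:
    """Weighted value sum s for one patient."""
    tensors = {"Wv": as_tensor(params.Wv)}
    return recalibrated_representation(tensors, as_tensor(alpha),
                                       as_tensor(F.F)).data


def attention_state(params: RecalibrationParams,
                    F: FeatureMatrix) -> AttentionState:
    f_bar = compute_context(F)
    zeta, alpha = attention_scores(params, F, f_bar)
    s = recalibrate(alpha, params, F)
    return AttentionState(f_bar, zeta, alpha, s)


def export_attention_csv(states: dict[str, AttentionState],
                         row_names: tuple[str, ...], path) -> None:
    """Per-patient attention weights as CSV: patient_id, feature, weight."""
    import pandas as pd
    rows = [(pid, name, float(w))
            for pid, st in states.items()
            for name, w in zip(row_names, st.alpha)]
    pd.DataFrame(rows, columns=["patient_id", "feature", "weight"]) \
        .to_csv(path, index=False)
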