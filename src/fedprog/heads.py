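"""Task-specific prediction heads and losses.

Each institution owns a private classification head (mortality at sequence
end) and, when it does length-of-stay prediction, a private regression head
applied to the representation of every prefix of the stay, so the predicted
remaining days at record t depend only on data up to t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

#: predicted probabilities are clamped into [EPS, 1-EPS] for loss stability
PROB_EPS = 1e-7


@dataclass
class HeadParams:
    W_cla: np.ndarray   # [h]
    b_cla: float
    W_reg: np.ndarray   # [h]
    b_reg: float

    @staticmethod
    def init(h: int, rng: np.random.Generator) -> "HeadParams":
        bound = 1.0 / np.sqrt(h)
        return HeadParams(rng.uniform(-bound, bound, h), 0.0,
                          rng.uniform(-bound, bound, h), 0.0)


# -- tensor path -------------------------------------------------------------

def classification_probability(W: Tensor, b: Tensor, s: Tensor) -> Tensor:
    """sigmoid(W . s + b), clamped; s is [..., h], output [...]."""
    return (s @ W + b).sigmoid().clip(PROB_EPS, 1.0 - PROB_EPS)


def regression_prediction(W: Tensor, b: Tensor, s: Tensor) -> Tensor:
    """Affine map W . s + b with no output nonlinearity."""
    return s @ W + b


def bce(y_hat: Tensor, y: np.ndarray,
        sample_mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)] (non-negative)."""
    y = np.asarray(y, dtype=float)
    terms = -(y * y_hat.log() + (1.0 - y) * (1.0 - y_hat).log())
    if sample_mask is None:
        return terms.mean()
    m = np.asarray(sample_mask, dtype=float)
    return (terms * m).sum() * (1.0 / m.sum())


def mse(y_hat: Tensor, y: np.ndarray,
        sample_mask: np.ndarray | None = None) -> Tensor:
    """Mean squared error; with a mask, the mean runs over valid records."""
    y = np.asarray(y, dtype=float)
    sq = (y_hat - y) ** 2
    if sample_mask is None:
        return sq.mean()
    m = np.asarray(sample_mask, dtype=float)
    return (sq * m).sum() * (1.0 / m.sum())


# -- plain numpy surface ------------------------------------------------------

def predict_classification(head: HeadParams, s: np.ndarray) -> float | np.ndarray:
    """Mortality probability in (0, 1) for one representation (or a batch)."""
    out = classification_probability(as_tensor(head.W_cla),
                                     as_tensor(head.b_cla), as_tensor(s)).data
    return float(out) if out.ndim == 0 else out


def predict_regression(head: HeadParams, s: np.ndarray) -> float | np.ndarray:
    """Remaining-days prediction for one representation (or a batch)."""
    out = regression_prediction(as_tensor(head.W_reg),
                                as_tensor(head.b_reg), as_tensor(s)).data
    return float(out) if out.ndim == 0 else out


def bce_loss(y_hat, y) -> float:
    y_hat = np.clip(np.asarray(y_hat, dtype=float), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y_hat.size < 1:
        raise ValueError("bce_loss: shape mismatch or empty input")
    return float(-(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat)).mean())


def mse_loss(y_hat, y) -> float:
    y_hat, y = np.asarray(y_hat, dtype=float), np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y_hat.size < 1:
        raise ValueError("mse_loss: shape mismatch or empty input")
    return float(((y_hat - y) ** 2).mean())


def rmse_loss(y_hat, y) -> float:
    return float(np.sqrt(mse_loss(y_hat, y)))


def mae_loss(y_hat, y) -> float:
    y_hat, y = np.asarray(y_hat, dtype=float), np.asarray(y, dtype=float)
    return float(np.abs(y_hat - y).mean())
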