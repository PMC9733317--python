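"""Constraint-driven refinement of the embedding space.

Expert pair relations (must-link / cannot-link) are used to learn a
linear transform ``W`` of the frozen backend embedding space that pulls
same-domain items together and pushes different-domain items apart — a
desk-scale metric-learning counterpart to fine-tuning a sentence
encoder on the same constraints.  The interface is deliberately small
(a fitted transform applied to any :class:`EmbeddingMatrix`), so a true
encoder fine-tuner can replace it without touching the callers.

The objective is contrastive:

    L(W) = mean_ML ||W d||^2 + mean_CL max(0, margin - ||W d||)^2

with ``d`` the difference vector of a constrained pair.  ``W`` starts
at the identity and is fitted by full-batch gradient descent with
step-halving, which makes the epoch-loss sequence non-increasing by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .embedding import EmbeddingMatrix
from .metrics import PairAnnotation

__all__ = ["ConstraintRefiner", "RefinementResults"]


class ConstraintRefiner:
    """Metric-learning model over a frozen embedding space.

    Parameters
    ----------
    base : EmbeddingMatrix
        Embeddings the constraints refer to (ids must cover the pairs).
    pairs : iterable of PairAnnotation
        At least one must-link and one cannot-link relation.
    margin : float
        Target separation for cannot-link pairs, on the scale of the
        (typically unit-norm) base vectors.
    learning_rate, epochs, seed
        Full-batch gradient-descent settings; the step is halved whenever
        it would increase the loss, so training is monotone.
    """

    def __init__(
        self,
        base: EmbeddingMatrix,
        pairs: Iterable[PairAnnotation],
        *,
        margin: float = 1.0,
        learning_rate: float = 0.5,
        epochs: int = 60,
        seed: int = 0,
    ):
        self.base = base
        self.pairs = list(pairs)
        n_ml = sum(p.same_domain for p in self.pairs)
        if n_ml == 0 or n_ml == len(self.pairs):
            raise ValueError(
                "refinement needs both must-link and cannot-link pairs "
                f"(got {n_ml} must-link of {len(self.pairs)})"
            )
        self.margin = margin
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed

    def _differences(self) -> tuple[np.ndarray, np.ndarray]:
        index = {i: r for r, i in enumerate(self.base.ids)}
        rows_a = [index[p.item_a] for p in self.pairs]
        rows_b = [index[p.item_b] for p in self.pairs]
        diffs = self.base.X[rows_a] - self.base.X[rows_b]
        ml = np.array([p.same_domain for p in self.pairs])
        return diffs[ml], diffs[~ml]

    def _loss_grad(
        self, W: np.ndarray, d_ml: np.ndarray, d_cl: np.ndarray, want_grad: bool = True
    ) -> tuple[float, np.ndarray | None]:
        z_ml = d_ml @ W.T
        z_cl = d_cl @ W.T
        dist_cl = np.linalg.norm(z_cl, axis=1)
        viol = np.maximum(0.0, self.margin - dist_cl)
        loss = float((z_ml**2).sum(axis=1).mean() + (viol**2).mean())
        if not want_grad:
            return loss, None
        grad = (2.0 / len(d_ml)) * z_ml.T @ d_ml
        active = viol > 0
        if active.any():
            safe = np.where(dist_cl > 1e-12, dist_cl, 1.0)
            coeff = np.where(active, -2.0 * viol / safe, 0.0) / len(d_cl)
            grad += (coeff[:, None] * z_cl).T @ d_cl
        return loss, grad

    def fit(self) -> "RefinementResults":
        d_ml, d_cl = self._differences()
        dim = self.base.dim
        W = np.eye(dim)
        lr = self.learning_rate
        loss, grad = self._loss_grad(W, d_ml, d_cl)
        history = [loss]
        for _ in range(self.epochs):
            stepped = False
            while lr > 1e-10:
                W_new = W - lr * grad
                loss_new, grad_new = self._loss_grad(W_new, d_ml, d_cl)
                if loss_new <= loss:
                    W, loss, grad = W_new, loss_new, grad_new
                    stepped = True
                    break
                lr /= 2.0
            history.append(loss)
            if not stepped:
                break
        return RefinementResults(model=self, transform=W, loss_history=history)


@dataclass
class RefinementResults:
    """A fitted linear refinement: apply it to any matrix in the base space."""

    model: ConstraintRefiner
    transform: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    def apply(self, matrix: EmbeddingMatrix) -> EmbeddingMatrix:
        if matrix.dim != self.transform.shape[1]:
            raise ValueError(
                f"matrix dim {matrix.dim} does not match transform {self.transform.shape}"
            )
        return EmbeddingMatrix(list(matrix.ids), matrix.X @ self.transform.T, matrix.backend_name)

    def compose(self, other: "RefinementResults | np.ndarray") -> np.ndarray:
        """Total transform applying ``other`` first, then this refinement."""
        prev = other.transform if isinstance(other, RefinementResults) else other
        return self.transform @ prev

    def summary(self) -> str:
        h = self.loss_history
        return (
            "Constraint refinement\n"
            "=====================\n"
            f"pairs         {len(self.model.pairs)} "
            f"({sum(p.same_domain for p in self.model.pairs)} must-link)\n"
            f"epochs run    {len(h) - 1}\n"
            f"loss          {h[0]:.5f} -> {h[-1]:.5f}"
        )
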