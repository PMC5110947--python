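"""Gaussian naive Bayes classifier, written out from the Bayes rule.

For a residue with feature vector X = (x_1, ..., x_d) and class y ∈ {0, 1}
(1 = hot spot), naive Bayes factorizes the posterior numerator as
P(y) ∏_i P(x_i | y) with per-feature Gaussian likelihoods.  The decision
rule is the argmax of that numerator; a residue is called a hot spot only
when the class-1 score strictly exceeds the class-0 score, so exact ties go
to the majority-negative class.

Scoring happens in log space (sums of log densities) because products of
hundreds of densities underflow; the contract is exact equivalence with the
linear-domain product wherever the latter is representable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Union

import numpy as np
from scipy.special import logsumexp

__all__ = ["GNBModel", "fit", "predict", "predict_proba", "save_model", "load_model"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GNBModel:
    """Fitted class priors and per-class, per-feature Gaussian parameters.

    ``theta[c, j]`` and ``var[c, j]`` are the mean and (smoothed, population)
    variance of feature j in class c; ``priors[c]`` the training frequency of
    class c.  ``epsilon`` is the variance floor added to every variance.
    """

    priors: np.ndarray  # shape (2,), priors[1] = P(y=1)
    theta: np.ndarray  # shape (2, d)
    var: np.ndarray  # shape (2, d)
    epsilon: float

    @property
    def n_features(self) -> int:
        return self.theta.shape[1]

    def _check_x(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: model has {self.n_features}, input has {x.shape[1]}"
            )
        return x

    def joint_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        """log P(y) + Σ_i log N(x_i; μ_yi, σ_yi²) for y = 0, 1; shape (n, 2)."""
        x = self._check_x(x)
        scores = np.empty((x.shape[0], 2))
        for c in (0, 1):
            diff = x - self.theta[c]
            log_density = -0.5 * (_LOG_2PI + np.log(self.var[c]) + diff**2 / self.var[c])
            scores[:, c] = np.log(self.priors[c]) + log_density.sum(axis=1)
        return scores


def fit(x: np.ndarray, y: np.ndarray, var_smoothing: float = 1e-9) -> GNBModel:
    """Fit priors, means and variances from pooled training residues.

    Priors are the class frequencies; variances are population variances
    (divide by the class count) floored by
    ``epsilon = var_smoothing × max_j Var(x_j)`` over the pooled data, which
    keeps constant features (e.g. all-zero padded columns within one class)
    from producing degenerate densities.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"{x.shape[0]} feature rows vs {y.shape[0]} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training labels: both classes must be present")
    if np.isnan(x).any():
        raise ValueError("missing feature values in training data")

    epsilon = var_smoothing * float(x.var(axis=0).max())
    priors = np.empty(2)
    theta = np.empty((2, x.shape[1]))
    var = np.empty((2, x.shape[1]))
    for c in (0, 1):
        rows = x[y == c]
        priors[c] = rows.shape[0] / x.shape[0]
        theta[c] = rows.mean(axis=0)
        var[c] = rows.var(axis=0) + epsilon
    return GNBModel(priors=priors, theta=theta, var=var, epsilon=epsilon)


def predict(model: GNBModel, x: np.ndarray) -> np.ndarray:
    """Class labels by the argmax rule; ties resolve to class 0."""
    scores = model.joint_log_likelihood(x)
    return (scores[:, 1] > scores[:, 0]).astype(int)


def predict_proba(model: GNBModel, x: np.ndarray) -> np.ndarray:
    """Posterior P(y=1 | X) per row, normalized via log-sum-exp."""
    scores = model.joint_log_likelihood(x)
    return np.exp(scores[:, 1] - logsumexp(scores, axis=1))


def save_model(model: GNBModel, sink: Union[str, IO[str]]) -> None:
    """Serialize a fitted model as a flat JSON document."""
    payload = {
        "priors": model.priors.tolist(),
        "theta": model.theta.tolist(),
        "var": model.var.tolist(),
        "epsilon": model.epsilon,
        "n_features": model.n_features,
    }
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        json.dump(payload, sink, indent=1)


def load_model(source: Union[str, IO[str]]) -> GNBModel:
    if isinstance(source, str):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = json.load(source)
    model = GNBModel(
        priors=np.asarray(payload["priors"], dtype=float),
        theta=np.asarray(payload["theta"], dtype=float),
        var=np.asarray(payload["var"], dtype=float),
        epsilon=float(payload["epsilon"]),
    )
    if model.n_features != payload["n_features"]:
        raise ValueError("corrupt model file: feature dimension mismatch")
    return model
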