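"""First-order Sugeno ANFIS with subtractive-clustering rule initialization.

The rule base is seeded by Chiu's subtractive clustering: every training
point receives a potential equal to a Gaussian-weighted count of its
neighbours within ``radius`` (in normalized coordinates); the highest
potential point becomes a cluster center, its neighbourhood potential is
subtracted, and the process repeats until the accept/reject thresholds stop
it (or a requested number of rules is reached).

Each rule r has Gaussian membership functions per input feature and a
first-order consequent ``y_r = a_r . x + b_r``.  Rule firing strengths are
the product of the memberships, normalized to sum to one; the model output
is the firing-weighted average of the consequents (the Sugeno
center-of-gravity defuzzification).  Training is the hybrid scheme: a
least-squares solve for the consequents alternated with gradient-descent
updates of the membership centers and widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

_EPS = 1e-12


def subtractive_clustering(
    X: np.ndarray,
    radius: float = 0.5,
    squash: float = 1.5,
    accept_ratio: float = 0.5,
    reject_ratio: float = 0.15,
    max_centers: Optional[int] = None,
) -> np.ndarray:
    """Select cluster centers by Chiu's subtractive method.

    ``radius`` is the neighbourhood radius in min-max normalized
    coordinates.  With ``max_centers`` set, the accept/reject test is
    bypassed and exactly the ``max_centers`` strongest centers are returned
    (or fewer if the data has fewer points).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n == 0:
        raise ValueError("no data to cluster")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / rng_

    alpha = 4.0 / radius**2
    beta = 4.0 / (squash * radius) ** 2
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    potential = np.exp(-alpha * d2).sum(axis=1)

    centers_idx: list[int] = []
    taken = np.zeros(n, dtype=bool)
    p_first = 0.0
    limit = min(max_centers, n) if max_centers is not None else n
    while len(centers_idx) < limit:
        masked = np.where(taken, -np.inf, potential)
        k = int(np.argmax(masked))
        pk = float(masked[k])
        if not np.isfinite(pk):
            break
        if not centers_idx:
            p_first = pk
        elif max_centers is None:
            if pk < reject_ratio * p_first:
                break
            if pk < accept_ratio * p_first:
                # accept only if sufficiently far from existing centers
                dmin = np.sqrt(min(d2[k, c] for c in centers_idx))
                if dmin / radius + pk / p_first < 1.0:
                    taken[k] = True
                    continue
        centers_idx.append(k)
        taken[k] = True
        potential = potential - pk * np.exp(-beta * d2[k])
    if not centers_idx:
        raise ValueError("cluster radius yielded no centers; increase the radius")
    return X[np.asarray(centers_idx)]


@dataclass
class ANFISModel:
    """A trained (or initialized) Sugeno fuzzy rule base."""

    centers: np.ndarray  # (n_rules, n_features)
    sigmas: np.ndarray  # (n_rules, n_features), > 0
    coeffs: np.ndarray  # (n_rules, n_features + 1); last column = intercept
    epochs_trained: int = 0
    error_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_rules(self) -> int:
        return int(self.centers.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.centers.shape[1])


def firing_strengths(model: ANFISModel, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Raw and normalized rule firing strengths, shape (n, n_rules)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.n_features}"
        )
    diff = X[:, None, :] - model.centers[None, :, :]
    log_mf = -(diff**2) / (2.0 * model.sigmas[None, :, :] ** 2)
    log_w = log_mf.sum(axis=2)
    # subtract the row max before exponentiating so normalization is stable
    w = np.exp(log_w - log_w.max(axis=1, keepdims=True))
    wn = w / w.sum(axis=1, keepdims=True)
    return w, wn


def anfis_predict(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Continuous Sugeno output: firing-weighted consequent average."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, wn = firing_strengths(model, X)
    rule_out = X @ model.coeffs[:, :-1].T + model.coeffs[:, -1][None, :]
    return np.sum(wn * rule_out, axis=1)


def _lse_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, wn = firing_strengths(model, X)
    n, d = X.shape
    Xa = np.concatenate([X, np.ones((n, 1))], axis=1)  # (n, d+1)
    A = (wn[:, :, None] * Xa[:, None, :]).reshape(n, model.n_rules * (d + 1))
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return theta.reshape(model.n_rules, d + 1)


def _premise_gradients(
    model: ANFISModel, X: np.ndarray, y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, float]:
    w, wn = firing_strengths(model, X)
    rule_out = X @ model.coeffs[:, :-1].T + model.coeffs[:, -1][None, :]
    y_hat = np.sum(wn * rule_out, axis=1)
    err = y_hat - y
    n = X.shape[0]
    W = w.sum(axis=1, keepdims=True)
    # dE/dw_r = (2/n) err * (y_r - y_hat) / W
    dE_dw = (2.0 / n) * err[:, None] * (rule_out - y_hat[:, None]) / np.maximum(W, _EPS)
    diff = X[:, None, :] - model.centers[None, :, :]
    sig2 = model.sigmas[None, :, :] ** 2
    dw_dc = w[:, :, None] * diff / sig2
    dw_ds = w[:, :, None] * diff**2 / (sig2 * model.sigmas[None, :, :])
    grad_c = np.sum(dE_dw[:, :, None] * dw_dc, axis=0)
    grad_s = np.sum(dE_dw[:, :, None] * dw_ds, axis=0)
    rmse = float(np.sqrt(np.mean(err**2)))
    return grad_c, grad_s, rmse


def anfis_train(
    X: np.ndarray,
    y: np.ndarray,
    n_epochs: int = 300,
    cluster_radius: float = 0.5,
    n_rules: Optional[int] = None,
    learning_rate: float = 0.01,
) -> ANFISModel:
    """Hybrid least-squares / gradient training of a Sugeno ANFIS.

    With ``n_rules`` set, exactly that many rules are seeded from the
    strongest subtractive-clustering centers.  Epoch 0 is a single
    least-squares pass for the consequents; each subsequent epoch performs a
    gradient step on the Gaussian premise parameters followed by a fresh
    least-squares solve.  The per-epoch RMSE trace is stored on the model.
    ``n_epochs=0`` therefore returns the initialized model with consequents
    from one least-squares pass only.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 2 and X.shape[0] == 1 and y.size > 1:
        X = X.T
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite training values")

    centers = subtractive_clustering(X, radius=cluster_radius, max_centers=n_rules)
    if n_rules is not None and centers.shape[0] < n_rules:
        raise ValueError(
            f"only {centers.shape[0]} distinct centers available for {n_rules} rules"
        )
    span = np.where(X.max(axis=0) > X.min(axis=0), X.max(axis=0) - X.min(axis=0), 1.0)
    sigmas = np.full_like(centers, 1.0) * (cluster_radius * span / np.sqrt(8.0))[None, :]
    model = ANFISModel(centers=centers, sigmas=sigmas,
                       coeffs=np.zeros((centers.shape[0], X.shape[1] + 1)))

    model.coeffs = _lse_consequents(model, X, y)
    _, _, rmse = _premise_gradients(model, X, y)
    trace = [rmse]
    lr = learning_rate
    for _ in range(n_epochs):
        grad_c, grad_s, _ = _premise_gradients(model, X, y)
        scale_c = np.maximum(np.abs(grad_c).max(), _EPS)
        scale_s = np.maximum(np.abs(grad_s).max(), _EPS)
        step_c = lr * span[None, :] * grad_c / scale_c
        step_s = lr * span[None, :] * grad_s / scale_s
        new_centers = model.centers - step_c
        new_sigmas = np.maximum(model.sigmas - step_s, 1e-3 * span[None, :])
        candidate = ANFISModel(centers=new_centers, sigmas=new_sigmas,
                               coeffs=model.coeffs)
        candidate.coeffs = _lse_consequents(candidate, X, y)
        _, _, new_rmse = _premise_gradients(candidate, X, y)
        if new_rmse <= trace[-1]:
            model.centers, model.sigmas, model.coeffs = (
                candidate.centers, candidate.sigmas, candidate.coeffs)
            lr *= 1.05
            trace.append(new_rmse)
        else:
            lr *= 0.7  # reject the step, shrink the rate
            trace.append(trace[-1])
        model.epochs_trained += 1
    model.error_trace = np.asarray(trace)
    return model


def anfis_classify(model: ANFISModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Crisp {0, 1} labels by thresholding the continuous Sugeno output."""
    return (anfis_predict(model, X) >= threshold).astype(int)
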