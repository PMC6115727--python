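"""Gaussian naive Bayes with empirical class priors.

The wrapper classifier of the feature-selection stage.  Priors are the
relative class frequencies observed in training (which tempers, rather than
ignores, class imbalance); each (class, feature) pair gets an independent
Gaussian with a floored variance.  Deliberately hand-rolled: the contract
needs an absolute variance floor and a fixed "earlier class wins" tie rule,
and the model doubles as the closed-form oracle target in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VAR_FLOOR_DEFAULT = 1e-9


@dataclass
class NBModel:
    class_ids: list
    class_priors: np.ndarray     # c, sums to 1
    means: np.ndarray            # c x f
    variances: np.ndarray        # c x f, floored
    variance_floor: float


def nb_fit(X: np.ndarray, y, variance_floor: float = VAR_FLOOR_DEFAULT,
           class_ids=None) -> NBModel:
    """Fit per-class Gaussians (ML estimates, ddof=0) and empirical priors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if class_ids is None:
        class_ids = sorted(set(y))
    class_ids = list(class_ids)
    c, f = len(class_ids), X.shape[1]
    priors = np.empty(c)
    means = np.empty((c, f))
    variances = np.empty((c, f))
    for i, cls in enumerate(class_ids):
        rows = X[y == cls]
        if rows.shape[0] == 0:
            raise ValueError(f"class {cls!r} absent from training data")
        priors[i] = rows.shape[0] / X.shape[0]
        means[i] = rows.mean(axis=0)
        variances[i] = np.maximum(rows.var(axis=0), variance_floor)
    return NBModel(class_ids=class_ids, class_priors=priors, means=means,
                   variances=variances, variance_floor=variance_floor)


def nb_log_posterior(m: NBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalised log posterior per (sample, class):
    log prior + sum_f log N(x_f; mean, var)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.means.shape[1]:
        raise ValueError(
            f"feature count mismatch: model has {m.means.shape[1]}, data has {X.shape[1]}"
        )
    # (n, 1, f) against (c, f)
    diff = X[:, None, :] - m.means[None, :, :]
    log_lik = -0.5 * (np.log(2.0 * np.pi * m.variances)[None, :, :]
                      + diff * diff / m.variances[None, :, :]).sum(axis=2)
    return np.log(m.class_priors)[None, :] + log_lik


def nb_predict(m: NBModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the log posterior; exact ties go to the class listed
    earlier in ``class_ids``."""
    lp = nb_log_posterior(m, X)
    idx = lp.argmax(axis=1)  # argmax returns the first maximum
    return np.asarray([m.class_ids[i] for i in idx], dtype=object)
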