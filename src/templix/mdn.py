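"""Mixture density networks predicting restraint parameters.

One small feed-forward network per atom-pair class maps the alignment
features ``(log d_t, pp, sim)`` — log template distance, posterior
probability that both aligned residue pairs are correct, and global sequence
similarity in bits per aligned pair — to the five parameters
``(w, mu, sigma, mu_bg, sigma_bg)`` of the two-component mixture restraint.

The architecture encodes the model structurally: the hidden layer has five
tanh nodes, of which the two lowest receive no connection from ``log d_t``,
and the background outputs ``mu_bg`` and ``sigma_bg`` are wired only to those
two nodes.  The background component therefore cannot depend on the template
distance, exactly as the mixture model demands.

Training maximizes the likelihood of observed ``log d`` values under the
predicted mixtures (quasi-Newton optimization of the mean negative
log-likelihood with analytic gradients), restarted from several random
initializations and keeping the best run.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from templix.restraints import SIGMA_FLOOR, AtomPairClass, RestraintParams

logger = logging.getLogger(__name__)

N_HIDDEN = 5
_N_FULL = 3  # hidden nodes seeing all three inputs
PARAM_NAMES = ("w", "mu", "sigma", "mu_bg", "sigma_bg")

# input order: (log_dt, pp, sim); output order: PARAM_NAMES
_MASK1 = np.ones((N_HIDDEN, 3))
_MASK1[_N_FULL:, 0] = 0.0  # restricted hidden nodes never see log_dt
_MASK2 = np.ones((5, N_HIDDEN))
_MASK2[3:, :_N_FULL] = 0.0  # mu_bg, sigma_bg wired only to restricted nodes


def _softplus(z):
    return np.logaddexp(0.0, z)


def _unpack(theta):
    w1 = theta[:15].reshape(N_HIDDEN, 3) * _MASK1
    b1 = theta[15:20]
    w2 = theta[20:45].reshape(5, N_HIDDEN) * _MASK2
    b2 = theta[45:50]
    return w1, b1, w2, b2


def _forward_raw(theta, X):
    w1, b1, w2, b2 = _unpack(theta)
    h = np.tanh(X @ w1.T + b1)
    z = h @ w2.T + b2
    return h, z


def _params_from_z(z, sigma_floor):
    w = expit(z[:, 0])
    mu = z[:, 1]
    sigma = _softplus(z[:, 2]) + sigma_floor
    mu_bg = z[:, 3]
    sigma_bg = _softplus(z[:, 4]) + sigma_floor
    return np.column_stack([w, mu, sigma, mu_bg, sigma_bg])


def _nll_and_grad(theta, X, y, sigma_floor):
    """Mean negative log-likelihood of y under the predicted mixtures + gradient."""
    w1, b1, w2, b2 = _unpack(theta)
    a1 = X @ w1.T + b1
    h = np.tanh(a1)
    z = h @ w2.T + b2
    P = _params_from_z(z, sigma_floor)
    w, mu, sigma, mu_bg, sigma_bg = P.T

    r1 = (y - mu) / sigma
    r2 = (y - mu_bg) / sigma_bg
    # log of the weighted component densities; log_expit gives log(w), log(1-w)
    la = log_expit(z[:, 0]) - 0.5 * r1**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    lb = log_expit(-z[:, 0]) - 0.5 * r2**2 - np.log(sigma_bg) - 0.5 * np.log(2 * np.pi)
    m = np.maximum(la, lb)
    logp = m + np.log(np.exp(la - m) + np.exp(lb - m))
    nll = -np.mean(logp)

    # responsibilities
    g1 = np.exp(la - logp)
    g2 = np.exp(lb - logp)
    n = X.shape[0]
    dz = np.empty_like(z)
    dz[:, 0] = -(g1 - w) / n
    dz[:, 1] = -(g1 * r1 / sigma) / n
    dz[:, 2] = -(g1 * (r1**2 - 1.0) / sigma) * expit(z[:, 2]) / n
    dz[:, 3] = -(g2 * r2 / sigma_bg) / n
    dz[:, 4] = -(g2 * (r2**2 - 1.0) / sigma_bg) * expit(z[:, 4]) / n

    dw2 = (dz.T @ h) * _MASK2
    db2 = dz.sum(axis=0)
    dh = dz @ (w2 * _MASK2)
    da1 = dh * (1.0 - h**2)
    dw1 = (da1.T @ X) * _MASK1
    db1 = da1.sum(axis=0)
    grad = np.concatenate([dw1.ravel(), db1, dw2.ravel(), db2])
    return nll, grad


class MixtureDensityNetwork(BaseEstimator):
    """Predicts two-component mixture restraint parameters from alignment features.

    Parameters
    ----------
    n_restarts : int, default=50
        Number of random initializations; the run with the lowest final
        negative log-likelihood is kept.
    max_iter : int, default=500
        Iteration cap per restart for the L-BFGS optimizer.
    tol : float, default=1e-7
        Convergence tolerance on the mean negative log-likelihood.
    sigma_floor : float, default=1e-6
        Lower bound added to both predicted standard deviations (log-Angstrom).
    atom_class : AtomPairClass or None
        Optional tag recording which atom-pair class the model was fitted for.
    random_state : int or None
        Master seed; restart seeds are drawn from it via a counter.

    Attributes
    ----------
    theta_ : ndarray of shape (50,)
        Flattened network weights of the best restart.
    loss_ : float
        Final mean negative log-likelihood.
    history_ : list of float
        Loss trace (per accepted optimizer iterate) of the best restart.
    n_iter_ : int
        Iterations used by the best restart.
    """

    def __init__(
        self,
        n_restarts: int = 50,
        max_iter: int = 500,
        tol: float = 1e-7,
        sigma_floor: float = SIGMA_FLOOR,
        atom_class: AtomPairClass | None = None,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.sigma_floor = sigma_floor
        self.atom_class = atom_class
        self.random_state = random_state

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Fit on features X = (log_dt, pp, sim) and targets y = log d."""
        X, y = check_X_y(X, y, ensure_min_samples=1)
        if X.shape[1] != 3:
            raise ValueError("X must have three columns: log_dt, pp, sim")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts):
            theta0 = self._init_theta(rng, y)
            trace: list[float] = []

            def _record(intermediate_result):
                trace.append(float(intermediate_result.fun))

            res = minimize(
                _nll_and_grad,
                theta0,
                args=(X, y, self.sigma_floor),
                jac=True,
                method="L-BFGS-B",
                callback=_record,
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
            )
            if not res.success and res.status != 1:  # status 1 = maxiter
                logger.warning("MDN restart %d did not converge: %s", restart, res.message)
            if best is None or res.fun < best.fun:
                best = res
                best_trace = trace
        if best.status == 1:
            warnings.warn("MDN training hit the iteration cap; returning best-so-far")
        self.theta_ = best.x
        self.loss_ = float(best.fun)
        self.history_ = best_trace
        self.n_iter_ = int(best.nit)
        return self

    def _init_theta(self, rng, y):
        theta = rng.normal(0.0, 0.5, size=50)
        # start the widths near the target spread and the mixture balanced
        spread = max(float(np.std(y)), 0.05)
        b_sigma = np.log(np.expm1(max(spread, self.sigma_floor * 10)))
        theta[45] = 0.0  # w ~ 0.5
        theta[46] = float(np.mean(y))
        theta[47] = b_sigma
        theta[48] = float(np.mean(y))
        theta[49] = b_sigma
        return theta

    def predict(self, X):
        """Predicted (w, mu, sigma, mu_bg, sigma_bg), one row per input."""
        check_is_fitted(self, "theta_")
        X = check_array(X)
        _, z = _forward_raw(self.theta_, X)
        return _params_from_z(z, self.sigma_floor)

    def predict_params(self, X) -> list[RestraintParams]:
        return [RestraintParams(*row) for row in self.predict(X)]

    def score(self, X, y):
        """Mean log-likelihood (higher is better), for sklearn model selection."""
        check_is_fitted(self, "theta_")
        X, y = check_X_y(X, y)
        return -_nll_and_grad(self.theta_, X, y, self.sigma_floor)[0]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        import json

        check_is_fitted(self, "theta_")
        w1, b1, w2, b2 = _unpack(self.theta_)
        return json.dumps(
            {
                "atom_class": self.atom_class.value if self.atom_class else None,
                "sigma_floor": self.sigma_floor,
                "w1": {"shape": list(w1.shape), "data": w1.ravel().tolist()},
                "b1": {"shape": [b1.size], "data": b1.tolist()},
                "w2": {"shape": list(w2.shape), "data": w2.ravel().tolist()},
                "b2": {"shape": [b2.size], "data": b2.tolist()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureDensityNetwork":
        import json

        d = json.loads(text)
        model = cls(
            sigma_floor=d["sigma_floor"],
            atom_class=AtomPairClass(d["atom_class"]) if d["atom_class"] else None,
        )
        theta = np.concatenate(
            [
                np.asarray(d["w1"]["data"]),
                np.asarray(d["b1"]["data"]),
                np.asarray(d["w2"]["data"]),
                np.asarray(d["b2"]["data"]),
            ]
        )
        model.theta_ = theta
        model.loss_ = np.nan
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def mdn_forward(model: MixtureDensityNetwork, features) -> RestraintParams:
    """Evaluate the network on one feature vector (log_dt, pp, sim)."""
    row = np.atleast_2d(np.asarray(features, dtype=float))
    return model.predict_params(row)[0]


def mdn_nll(model: MixtureDensityNetwork, X, y) -> float:
    """Mean negative log-likelihood of a dataset under the fitted model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0:
        raise ValueError("empty dataset")
    return _nll_and_grad(model.theta_, X, y, model.sigma_floor)[0]


def train_mdn(X, y, n_restarts: int = 50, seed: int | None = None, **kwargs):
    """Fit a :class:`MixtureDensityNetwork`; best of ``n_restarts`` random starts."""
    model = MixtureDensityNetwork(n_restarts=n_restarts, random_state=seed, **kwargs)
    return model.fit(X, y)


def fit_atom_class_suite(
    datasets: dict[AtomPairClass, tuple[np.ndarray, np.ndarray]],
    n_restarts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> dict[AtomPairClass, MixtureDensityNetwork]:
    """Fit one network per atom-pair class; all four classes are required."""
    missing = [c for c in AtomPairClass if c not in datasets]
    if missing:
        raise ValueError(f"missing datasets for classes: {[c.value for c in missing]}")
    suite = {}
    for k, cls in enumerate(AtomPairClass):
        X, y = datasets[cls]
        if np.asarray(X).size == 0:
            raise ValueError(f"empty dataset for class {cls.value}")
        sub_seed = None if seed is None else seed + k
        suite[cls] = train_mdn(
            X, y, n_restarts=n_restarts, seed=sub_seed, atom_class=cls, **kwargs
        )
    return suite
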