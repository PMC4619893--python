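"""Template ranking and selection.

Three strategies are provided, in increasing sophistication:

* **Single-template**: a small feed-forward network predicts the TMscore of
  the model that would be built from each query-template alignment (inputs:
  raw alignment score, secondary-structure score per query residue, expected
  number of correctly aligned residues per query residue, template
  resolution); the hit with the highest prediction wins.
* **Simple multi-template baseline**: starting from the predictor's top hit,
  add candidates whose predicted TMscore is at least 90% of the first
  template's, that are structurally similar to the first template
  (pairwise structural score > 0.7) and to every already-selected template
  (> 0.8), up to ten templates.
* **Greedy coverage/quality selection**: the first template comes from the
  predictor; afterwards each remaining candidate t is scored

      S(t) = sum over aligned columns (i, i') of  exp(alpha * delta_s(i, t)) - beta,

  where ``s(i, t) = P_hom(t) * p(i <> i' | q, t)`` is the local alignment
  quality and ``delta_s`` its improvement over the best accepted template at
  residue i.  The candidate with the highest positive score is accepted and
  all scores are recomputed; the loop stops when no score is positive or the
  set reaches ``max_templates``.  Defaults alpha = 0.95, beta = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


@dataclass
class TemplateHit:
    """One query-template alignment with global features and column posteriors."""

    template_id: str
    p_hom: float
    raw_score: float
    ss_score_norm: float
    exp_correct_norm: float
    resolution: float | None = None
    aligned_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # (query residue i, template residue i', posterior pp_i)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hom <= 1.0:
            raise ValueError("p_hom must be in [0, 1]")
        last = None
        for i, _ip, pp in self.aligned_pairs:
            if last is not None and i <= last:
                raise ValueError("aligned query indices must be strictly increasing")
            if not 0.0 <= pp <= 1.0:
                raise ValueError("column posteriors must be in [0, 1]")
            last = i

    def pp_at(self, i: int) -> float | None:
        for qi, _ti, pp in self.aligned_pairs:
            if qi == i:
                return pp
        return None


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the greedy selection.

    ``alpha`` sets the nonlinearity rewarding local improvements, ``beta``
    the per-residue acceptance threshold, ``max_templates`` the cap on the
    accepted set and ``candidate_pool`` how many top hits enter the pool.
    """

    alpha: float = 0.95
    beta: float = 1.0
    max_templates: int = 8
    candidate_pool: int = 100
    simple_max_templates: int = 10
    resolution_impute: float = 3.5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.max_templates < 1:
            raise ValueError("max_templates must be >= 1")


def hit_features(hit: TemplateHit, resolution_impute: float = 3.5) -> np.ndarray:
    res = hit.resolution if hit.resolution is not None else resolution_impute
    return np.array([hit.raw_score, hit.ss_score_norm, hit.exp_correct_norm, res])


class TMScorePredictor(RegressorMixin, BaseEstimator):
    """Feed-forward TMscore predictor: 4 inputs, 3 tanh hidden nodes, logistic output.

    Features are standardized on the training set (the scaler is stored with
    the model).  Training minimizes squared error with several random
    restarts; the output is bounded in [0, 1] by the logistic link.
    """

    N_HIDDEN = 3

    def __init__(
        self,
        n_restarts: int = 10,
        max_iter: int = 500,
        tol: float = 1e-10,
        random_state: int | None = None,
    ):
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _net(theta, Z):
        w1 = theta[:12].reshape(3, 4)
        b1 = theta[12:15]
        w2 = theta[15:18]
        b2 = theta[18]
        h = np.tanh(Z @ w1.T + b1)
        return expit(h @ w2 + b2)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 4:
            raise ValueError(
                "X needs four columns: raw_score, ss_score_norm, exp_correct_norm, resolution"
            )
        if X.shape[0] < 10:
            raise ValueError("need at least 10 training examples")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = (X - self.mean_) / self.scale_
        if np.ptp(y) == 0.0:
            warnings.warn("constant targets; returning a constant predictor")
            theta = np.zeros(19)
            theta[18] = logit(np.clip(y[0], 1e-9, 1 - 1e-9))
            self.theta_ = theta
            self.loss_ = 0.0
            return self

        def loss(theta):
            pred = self._net(theta, Z)
            return float(np.mean((pred - y) ** 2))

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            theta0 = rng.normal(0.0, 0.5, size=19)
            res = minimize(
                loss, theta0, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol},
            )
            if best is None or res.fun < best.fun:
                best = res
        self.theta_ = best.x
        self.loss_ = float(best.fun)
        return self

    def predict(self, X):
        check_is_fitted(self, "theta_")
        X = check_array(X)
        Z = (X - self.mean_) / self.scale_
        return self._net(self.theta_, Z)

    def to_json(self) -> str:
        import json

        check_is_fitted(self, "theta_")
        return json.dumps(
            {
                "theta": {"shape": [19], "data": self.theta_.tolist()},
                "mean": self.mean_.tolist(),
                "scale": self.scale_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TMScorePredictor":
        import json

        d = json.loads(text)
        model = cls()
        model.theta_ = np.asarray(d["theta"]["data"])
        model.mean_ = np.asarray(d["mean"])
        model.scale_ = np.asarray(d["scale"])
        model.loss_ = np.nan
        return model


def train_tmpredictor(X, y, seed: int | None = None, n_restarts: int = 10) -> TMScorePredictor:
    """Fit a :class:`TMScorePredictor`; deterministic given the seed."""
    return TMScorePredictor(n_restarts=n_restarts, random_state=seed).fit(X, y)


def predict_tmscore(
    predictor: TMScorePredictor, hit: TemplateHit, resolution_impute: float = 3.5
) -> float:
    """Predicted model TMscore for one hit (missing resolution imputed)."""
    return float(predictor.predict(hit_features(hit, resolution_impute)[None, :])[0])


def _rank_key(pred: float, hit: TemplateHit):
    # descending prediction, ties by higher p_hom then lexicographic id
    return (-pred, -hit.p_hom, hit.template_id)


def select_single(hits: list[TemplateHit], predictor: TMScorePredictor, config=None) -> str:
    """Template id with the highest predicted TMscore."""
    if not hits:
        raise ValueError("no hits to select from")
    cfg = config or SelectionConfig()
    preds = {h.template_id: predict_tmscore(predictor, h, cfg.resolution_impute) for h in hits}
    best = min(hits, key=lambda h: _rank_key(preds[h.template_id], h))
    return best.template_id


def select_simple_multi(
    hits: list[TemplateHit],
    predictor: TMScorePredictor,
    tm_struct: dict[tuple[str, str], float],
    config: SelectionConfig | None = None,
) -> list[str]:
    """Threshold-based baseline multi-template selection.

    The first template is the predictor's top hit and is always included.
    A further candidate is added while the set is below the cap if its
    prediction is >= 90% of the first template's, its structural score to
    the first template exceeds 0.7, and its structural score to every
    selected template exceeds 0.8.
    """
    cfg = config or SelectionConfig()
    if not hits:
        raise ValueError("no hits to select from")

    def pair_score(a: str, b: str) -> float | None:
        return tm_struct.get((a, b), tm_struct.get((b, a)))

    preds = {h.template_id: predict_tmscore(predictor, h, cfg.resolution_impute) for h in hits}
    ranked = sorted(hits, key=lambda h: _rank_key(preds[h.template_id], h))
    first = ranked[0].template_id
    selected = [first]
    for hit in ranked[1:]:
        if len(selected) >= cfg.simple_max_templates:
            break
        tid = hit.template_id
        if preds[tid] < 0.9 * preds[first]:
            continue
        scores = [pair_score(tid, s) for s in selected]
        if any(s is None for s in scores):
            warnings.warn(f"missing pairwise structural score for {tid}; skipped")
            continue
        if scores[0] <= 0.7:  # similarity to the first template
            continue
        if any(s <= 0.8 for s in scores[1:]):  # mutual similarity among additions
            continue
        selected.append(tid)
    return selected


def local_quality(hit: TemplateHit, i: int) -> float:
    """``s(i, t) = P_hom(t) * p(i <> i' | q, t)``; zero where t leaves i uncovered."""
    pp = hit.pp_at(i)
    return 0.0 if pp is None else hit.p_hom * pp


def delta_s(hit: TemplateHit, i: int, accepted: list[TemplateHit]) -> float:
    """Local improvement of ``hit`` at residue i over the accepted set.

    The max over an empty or non-covering accepted set is 0, so covering a
    new residue is rewarded with the full local quality.
    """
    best = max((local_quality(t, i) for t in accepted), default=0.0)
    return local_quality(hit, i) - best


def template_score(
    hit: TemplateHit, accepted: list[TemplateHit], config: SelectionConfig | None = None
) -> float:
    """``S(t) = sum over aligned columns of exp(alpha * delta_s) - beta``."""
    cfg = config or SelectionConfig()
    return float(
        sum(
            np.exp(cfg.alpha * delta_s(hit, i, accepted)) - cfg.beta
            for i, _ip, _pp in hit.aligned_pairs
        )
    )


def greedy_select(
    hits: list[TemplateHit],
    predictor: TMScorePredictor,
    config: SelectionConfig | None = None,
) -> list[tuple[str, float]]:
    """Greedy coverage/quality selection.

    Returns the accepted templates in acceptance order as
    ``(template_id, score_at_acceptance)``; the first entry carries its
    predicted TMscore instead of an S score.  Candidates are restricted to
    the configured pool of top hits by predicted TMscore.
    """
    cfg = config or SelectionConfig()
    if not hits:
        raise ValueError("no hits to select from")
    preds = {h.template_id: predict_tmscore(predictor, h, cfg.resolution_impute) for h in hits}
    pool = sorted(hits, key=lambda h: _rank_key(preds[h.template_id], h))[: cfg.candidate_pool]
    by_id = {h.template_id: h for h in pool}
    first_id = select_single(pool, predictor, cfg)
    accepted = [by_id[first_id]]
    result = [(first_id, preds[first_id])]
    candidates = [h for h in pool if h.template_id != first_id]
    while candidates and len(accepted) < cfg.max_templates:
        scored = [(template_score(h, accepted, cfg), h) for h in candidates]
        best_score, best_hit = min(
            scored, key=lambda t: (-t[0], -t[1].p_hom, t[1].template_id)
        )
        if best_score <= 0.0:
            break
        accepted.append(best_hit)
        result.append((best_hit.template_id, best_score))
        candidates = [h for h in candidates if h.template_id != best_hit.template_id]
    return result


def selection_to_tsv(selection: list[tuple[str, float]]) -> str:
    lines = ["rank\ttemplate_id\tscore_at_acceptance"]
    for rank, (tid, score) in enumerate(selection, start=1):
        lines.append(f"{rank}\t{tid}\t{score!r}")
    return "\n".join(lines) + "\n"
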