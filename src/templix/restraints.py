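"""Two-component Gaussian-mixture distance restraints in log-distance space.

A template-derived restraint on the distance ``d`` between two query atoms is
the density

    p(log d) = w * N(log d | mu, sigma^2) + (1 - w) * N(log d | mu_bg, sigma_bg^2)

where the signal component is peaked near the log template distance and the
background component absorbs alignment errors: with probability ``1 - w`` at
least one of the two aligned residue pairs is wrong and the template distance
carries no information about ``d``.  Restraints from several templates are
combined multiplicatively on the odds-ratio scale

    p(d | d_1..d_K) / p(d)  ~  prod_k [ p(d | d_k) / p(d) ]^{w_k}

with template weights ``w_k`` in (0, 1] correcting for redundancy among
related templates (see :mod:`templix.weighting`).  The odds ratio of one
restraint,

    p(d | d_k) / p(d) = 1 - w + w * N(log d | mu, sigma^2) / N(log d | mu_bg, sigma_bg^2),

has flat tails approaching the constant ``1 - w``, so an unsatisfiable
restraint costs a bounded penalty instead of the unbounded quadratic of a
single-Gaussian restraint.

All distances are in Angstrom and all restraint math is carried out on the
natural logarithm of the distance.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

#: Lower bound on standard deviations (log-Angstrom) to avoid density overflow.
SIGMA_FLOOR = 1e-6

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class AtomPairClass(enum.Enum):
    """The four atom-pair classes that carry template distance restraints."""

    CA_CA = "CA_CA"
    N_O = "N_O"
    SC_MC = "SC_MC"
    SC_SC = "SC_SC"


@dataclass(frozen=True)
class RestraintParams:
    """Parameters of one two-component mixture restraint.

    Attributes
    ----------
    w : float
        Mixture weight in [0, 1]; probability that both residue pairs are
        correctly aligned.
    mu, sigma : float
        Mean and standard deviation of the signal component (log-Angstrom).
    mu_bg, sigma_bg : float
        Mean and standard deviation of the background component
        (log-Angstrom).
    """

    w: float
    mu: float
    sigma: float
    mu_bg: float
    sigma_bg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"mixture weight w={self.w} outside [0, 1]")
        if not (self.sigma > 0.0 and self.sigma_bg > 0.0):
            raise ValueError("sigma and sigma_bg must be positive")
        for name in ("w", "mu", "sigma", "mu_bg", "sigma_bg"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite restraint parameter {name}")
        # floor the widths in place (frozen dataclass -> object.__setattr__)
        object.__setattr__(self, "sigma", max(self.sigma, SIGMA_FLOOR))
        object.__setattr__(self, "sigma_bg", max(self.sigma_bg, SIGMA_FLOOR))


@dataclass(frozen=True)
class PairId:
    """Identifier of a restrained query atom pair."""

    i: int
    j: int
    atom_i: str
    atom_j: str
    atom_class: AtomPairClass


@dataclass(frozen=True)
class RestraintItem:
    """One template's contribution to a restrained pair."""

    params: RestraintParams
    weight: float
    template_id: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"template weight {self.weight} outside [0, 1]")


@dataclass
class WeightedRestraintSet:
    """All template restraints on one query atom pair, with template weights."""

    pair: PairId
    items: list[RestraintItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("restraint set needs at least one item")


def _check_log_d(log_d) -> np.ndarray:
    log_d = np.asarray(log_d, dtype=float)
    if not np.all(np.isfinite(log_d)):
        raise ValueError("log_d must be finite")
    return log_d


def mixture_logpdf(log_d, params: RestraintParams):
    """Log density of the two-component mixture at ``log_d``.

    Evaluated through a log-sum-exp of the two weighted component log
    densities so the result is finite for every finite ``log_d``.
    """
    log_d = _check_log_d(log_d)
    log_sig = norm.logpdf(log_d, params.mu, params.sigma)
    log_bg = norm.logpdf(log_d, params.mu_bg, params.sigma_bg)
    with np.errstate(divide="ignore"):
        terms = np.stack(
            [np.log(params.w) + log_sig, np.log1p(-params.w) + log_bg]
        )
    out = logsumexp(terms, axis=0)
    return out if out.shape else float(out)


def log_odds_ratio(log_d, params: RestraintParams):
    """Log of ``p(d | d_k) / p(d)`` (see :func:`odds_ratio`); stable in the tails."""
    log_d = _check_log_d(log_d)
    log_sig = norm.logpdf(log_d, params.mu, params.sigma)
    log_bg = norm.logpdf(log_d, params.mu_bg, params.sigma_bg)
    with np.errstate(divide="ignore"):
        out = np.logaddexp(np.log1p(-params.w), np.log(params.w) + log_sig - log_bg)
    return out if out.shape else float(out)


def odds_ratio(log_d, params: RestraintParams):
    """Odds ratio ``1 - w + w * N(log d | mu, sigma^2) / N(log d | mu_bg, sigma_bg^2)``.

    Strictly positive; approaches the constant ``1 - w`` in both tails
    whenever ``sigma < sigma_bg``.
    """
    return np.exp(log_odds_ratio(log_d, params))


@dataclass(frozen=True)
class GaussianRatioForm:
    """Closed form of the Gaussian ratio N(.|mu,sigma^2)/N(.|mu_bg,sigma_bg^2).

    For ``sigma != sigma_bg`` the ratio is ``exp(log_scale) *
    exp(-(y - center)^2 / (2 * var))`` — an (unnormalized) Gaussian shape when
    ``var > 0`` (i.e. ``sigma < sigma_bg``), an inverted one when ``var < 0``.
    For ``sigma == sigma_bg`` the quadratic terms cancel and the ratio is the
    exponential-linear ``exp(log_scale + slope * y)``; ``var`` is then
    infinite and ``center`` is NaN.
    """

    log_scale: float
    center: float
    var: float
    slope: float = 0.0

    @property
    def is_linear(self) -> bool:
        return math.isinf(self.var)

    def __call__(self, y):
        y = np.asarray(y, dtype=float)
        if self.is_linear:
            return np.exp(self.log_scale + self.slope * y)
        return np.exp(self.log_scale - (y - self.center) ** 2 / (2.0 * self.var))


def gaussian_ratio_form(params: RestraintParams) -> GaussianRatioForm:
    """Complete the square in the ratio of the signal and background Gaussians."""
    s2, b2 = params.sigma**2, params.sigma_bg**2
    log_pref = math.log(params.sigma_bg / params.sigma)
    a = 0.5 / s2 - 0.5 / b2  # quadratic coefficient of -log ratio
    if a == 0.0:
        slope = (params.mu - params.mu_bg) / s2
        const = log_pref - (params.mu**2 - params.mu_bg**2) / (2.0 * s2)
        return GaussianRatioForm(log_scale=const, center=math.nan, var=math.inf, slope=slope)
    center = (params.mu / s2 - params.mu_bg / b2) / (2.0 * a)
    log_scale = (
        log_pref
        - params.mu**2 / (2.0 * s2)
        + params.mu_bg**2 / (2.0 * b2)
        + a * center**2
    )
    return GaussianRatioForm(log_scale=log_scale, center=center, var=0.5 / a)


def combined_log_odds(log_d, rset: WeightedRestraintSet):
    """Weighted sum of per-template log odds ratios for one atom pair.

    This is the log of the multi-template restraint
    ``prod_k [p(d | d_k)/p(d)]^{w_k}``; finite for all finite ``log_d`` and
    invariant under permutation of items and under splitting an item into
    copies whose weights sum to the original.
    """
    if not rset.items:
        raise ValueError("empty restraint set")
    log_d = np.asarray(log_d, dtype=float)
    total = np.zeros_like(log_d, dtype=float)
    for item in rset.items:
        total = total + item.weight * log_odds_ratio(log_d, item.params)
    return total if total.shape else float(total)


def modeller_additive_baseline(
    log_d,
    restraints: Sequence[tuple[float, float]],
    alphas: Sequence[float],
):
    """Additive-mixture baseline: ``sum_k alpha_k N(log d | mu_k, sigma_k^2)``.

    The classical heuristic for multi-template restraints: single-Gaussian
    component densities mixed additively with user-supplied constants.
    Implemented only as a comparison baseline; its width grows with template
    disagreement instead of shrinking.
    """
    alphas = np.asarray(alphas, dtype=float)
    if len(restraints) != alphas.size:
        raise ValueError("need one alpha per restraint")
    if np.any(alphas < 0.0):
        raise ValueError("alphas must be nonnegative")
    if not np.any(alphas > 0.0):
        raise ValueError("all alphas zero")
    log_d = _check_log_d(log_d)
    dens = np.zeros_like(log_d, dtype=float)
    for (mu, sigma), alpha in zip(restraints, alphas):
        dens = dens + alpha * norm.pdf(log_d, mu, sigma)
    return dens if dens.shape else float(dens)


# ---------------------------------------------------------------------------
# serialization


def restraint_sets_to_json(rsets: Iterable[WeightedRestraintSet]) -> str:
    """Canonical JSON interchange for restraint sets."""
    payload = []
    for rs in rsets:
        payload.append(
            {
                "pair": {
                    "i": rs.pair.i,
                    "j": rs.pair.j,
                    "atom_i": rs.pair.atom_i,
                    "atom_j": rs.pair.atom_j,
                    "class": rs.pair.atom_class.value,
                },
                "items": [
                    {
                        "w": it.params.w,
                        "mu": it.params.mu,
                        "sigma": it.params.sigma,
                        "mu_bg": it.params.mu_bg,
                        "sigma_bg": it.params.sigma_bg,
                        "weight": it.weight,
                        "template": it.template_id,
                    }
                    for it in rs.items
                ],
            }
        )
    return json.dumps(payload, indent=1)


def restraint_sets_from_json(text: str) -> list[WeightedRestraintSet]:
    out = []
    for entry in json.loads(text):
        pair = PairId(
            i=entry["pair"]["i"],
            j=entry["pair"]["j"],
            atom_i=entry["pair"]["atom_i"],
            atom_j=entry["pair"]["atom_j"],
            atom_class=AtomPairClass(entry["pair"]["class"]),
        )
        items = [
            RestraintItem(
                params=RestraintParams(
                    w=it["w"],
                    mu=it["mu"],
                    sigma=it["sigma"],
                    mu_bg=it["mu_bg"],
                    sigma_bg=it["sigma_bg"],
                ),
                weight=it["weight"],
                template_id=it["template"],
            )
            for it in entry["items"]
        ]
        out.append(WeightedRestraintSet(pair=pair, items=items))
    return out


_TSV_HEADER = "i\tj\tatom_i\tatom_j\tclass\tw\tmu\tsigma\tmu_bg\tsigma_bg\tweight\ttemplate"


def restraint_sets_to_tsv(rsets: Iterable[WeightedRestraintSet]) -> str:
    """Flat one-item-per-row TSV dialect (streaming-friendly)."""
    lines = [_TSV_HEADER]
    for rs in rsets:
        for it in rs.items:
            lines.append(
                "\t".join(
                    [
                        str(rs.pair.i),
                        str(rs.pair.j),
                        rs.pair.atom_i,
                        rs.pair.atom_j,
                        rs.pair.atom_class.value,
                        repr(it.params.w),
                        repr(it.params.mu),
                        repr(it.params.sigma),
                        repr(it.params.mu_bg),
                        repr(it.params.sigma_bg),
                        repr(it.weight),
                        it.template_id,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def restraint_sets_from_tsv(text: str) -> list[WeightedRestraintSet]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _TSV_HEADER:
        raise ValueError("unrecognized restraint TSV header")
    by_pair: dict[PairId, list[RestraintItem]] = {}
    order: list[PairId] = []
    for ln in lines[1:]:
        f = ln.split("\t")
        pair = PairId(int(f[0]), int(f[1]), f[2], f[3], AtomPairClass(f[4]))
        item = RestraintItem(
            params=RestraintParams(
                w=float(f[5]), mu=float(f[6]), sigma=float(f[7]),
                mu_bg=float(f[8]), sigma_bg=float(f[9]),
            ),
            weight=float(f[10]),
            template_id=f[11],
        )
        if pair not in by_pair:
            by_pair[pair] = []
            order.append(pair)
        by_pair[pair].append(item)
    return [WeightedRestraintSet(pair=p, items=by_pair[p]) for p in order]


def write_modeller_style(rsets: Iterable[WeightedRestraintSet]) -> str:
    """Best-effort MODELLER-flavoured restraint lines.

    One numeric record per restraint item, field order::

        R <i> <j> <class index 1..4> <weight> <w> <mu> <sigma> <mu_bg> <sigma_bg>

    Lossy (atom names and template ids are dropped); the JSON writer is the
    canonical interchange.
    """
    class_index = {c: k + 1 for k, c in enumerate(AtomPairClass)}
    lines = []
    for rs in rsets:
        for it in rs.items:
            lines.append(
                "R %4d %4d %d %10.6f %10.6f %12.6f %12.6f %12.6f %12.6f"
                % (
                    rs.pair.i,
                    rs.pair.j,
                    class_index[rs.pair.atom_class],
                    it.weight,
                    it.params.w,
                    it.params.mu,
                    it.params.sigma,
                    it.params.mu_bg,
                    it.params.sigma_bg,
                )
            )
    return "\n".join(lines) + "\n"
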