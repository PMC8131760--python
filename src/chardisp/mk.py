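"""Two-state Mk model: transition probabilities, pruning likelihood, ML fits.

The model is a continuous-time Markov chain on states {0, 1} with generator

    Q = [[-q01, q01],
         [q10, -q10]]

where q01 is the gain rate (absent -> present) and q10 the loss rate, both
in transitions per unit branch length.  ER constrains q01 = q10 = q (one
free parameter); ARD leaves both free.  The likelihood of tip states on a
phylogeny is computed with Felsenstein's pruning algorithm with per-node
rescaling; the root is summed against a weight vector — flat (1/2, 1/2) by
default, or "unweighted" (1, 1) to match the root convention of ape's
``ace`` (a constant +ln 2 shift), or the stationary law, or user-given.

A tree-free baseline ("total garbage test") fits tip states as i.i.d.
Bernoulli draws; a much worse likelihood than the Mk fits indicates the
phylogeny carries real signal for the trait.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import NumericalError, ValidationError
from .treedata import Phylogeny, TipStates

__all__ = [
    "RateModel",
    "MkFit",
    "GarbageFit",
    "ModelComparison",
    "transition_matrix",
    "stationary",
    "log_likelihood",
    "fit",
    "garbage_fit",
    "compare_models",
]

RATE_LOWER = 1e-8
RATE_UPPER = 1e3

RootPrior = Union[str, Sequence[float]]


@dataclass(frozen=True)
class RateModel:
    """ER or ARD parameterization of the 2-state generator matrix."""

    family: str  # "ER" | "ARD"
    q01: float  # absent -> present (gain)
    q10: float  # present -> absent (loss)

    def __post_init__(self) -> None:
        if self.family not in ("ER", "ARD"):
            raise ValidationError(f"family must be 'ER' or 'ARD', got {self.family!r}")
        if self.q01 < 0 or self.q10 < 0:
            raise ValidationError("rates must be non-negative")
        if self.family == "ER" and self.q01 != self.q10:
            raise ValidationError("ER requires q01 == q10")

    @classmethod
    def er(cls, q: float) -> "RateModel":
        return cls("ER", q, q)

    @classmethod
    def ard(cls, q01: float, q10: float) -> "RateModel":
        return cls("ARD", q01, q10)

    @property
    def n_free_parameters(self) -> int:
        return 1 if self.family == "ER" else 2

    @property
    def rates(self) -> tuple[float, ...]:
        return (self.q01,) if self.family == "ER" else (self.q01, self.q10)

    @property
    def generator(self) -> np.ndarray:
        return np.array([[-self.q01, self.q01], [self.q10, -self.q10]])


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Q t) for the 2-state chain, in closed form.

    With s = q01 + q10 and stationary row pi = (q10, q01)/s,
    P(t) = Pi + exp(-s t) (I - Pi); for s = 0 the chain is frozen and
    P(t) = I.
    """
    if t < 0:
        raise ValidationError(f"elapsed time must be non-negative, got {t}")
    s = model.q01 + model.q10
    if s == 0.0:
        return np.eye(2)
    e = math.exp(-s * t)
    p0, p1 = model.q10 / s, model.q01 / s
    return np.array(
        [
            [p0 + p1 * e, p1 - p1 * e],
            [p0 - p0 * e, p1 + p0 * e],
        ]
    )


def stationary(model: RateModel) -> np.ndarray:
    """Long-run state frequencies (q10, q01)/(q01 + q10)."""
    s = model.q01 + model.q10
    if s == 0.0:
        raise ValidationError("both rates are zero: no unique stationary distribution")
    return np.array([model.q10 / s, model.q01 / s])


def _resolve_root_prior(root_prior: RootPrior, model: RateModel) -> tuple[float, float]:
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return 0.5, 0.5
        if root_prior == "unweighted":
            # ape::ace convention: sum root partials with weight 1 each,
            # shifting lnL by +ln 2 relative to the flat prior
            return 1.0, 1.0
        if root_prior == "stationary":
            p = stationary(model)
            return float(p[0]), float(p[1])
        raise ValidationError(
            f"root_prior must be 'flat', 'unweighted', 'stationary' or a 2-vector, got {root_prior!r}"
        )
    p = np.asarray(root_prior, dtype=float)
    if p.shape != (2,) or p.min() < 0 or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError("root prior must be a probability 2-vector")
    return float(p[0]), float(p[1])


def log_likelihood(
    tree: Phylogeny,
    states: TipStates,
    model: RateModel,
    root_prior: RootPrior = "flat",
    marginalize_missing: bool = False,
) -> float:
    """Pruning-algorithm log-likelihood (nats) of tip states under the model.

    Partial likelihoods are swept post-order with per-node renormalization
    (accumulated in log space) so deep trees cannot underflow.  With
    ``marginalize_missing`` an unknown tip contributes the partial vector
    (1, 1) instead of being an error.
    """
    pr0, pr1 = _resolve_root_prior(root_prior, model)
    s = model.q01 + model.q10
    n = tree.n_nodes
    L0 = [0.0] * n
    L1 = [0.0] * n
    log_scale = 0.0

    pi0 = model.q10 / s if s else 0.0
    pi1 = model.q01 / s if s else 0.0

    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            lab = tree.labels[node]
            st = states.states.get(lab, None)
            if st is None:
                if not marginalize_missing:
                    raise ValidationError(
                        f"leaf {lab!r} has no determined state; drop unknown-state "
                        "tips first or pass marginalize_missing=True"
                    )
                L0[node] = L1[node] = 1.0
            else:
                L0[node] = 1.0 if st == 0 else 0.0
                L1[node] = 1.0 if st == 1 else 0.0
            continue
        a0, a1 = 1.0, 1.0
        for c in kids:
            c0, c1 = L0[c], L1[c]
            if s == 0.0:
                m0, m1 = c0, c1
            else:
                e = math.exp(-s * tree.branch_lengths[c])
                # rows of P(t): [pi0 + pi1*e, pi1 - pi1*e], [pi0 - pi0*e, pi1 + pi0*e]
                m0 = (pi0 + pi1 * e) * c0 + (pi1 - pi1 * e) * c1
                m1 = (pi0 - pi0 * e) * c0 + (pi1 + pi0 * e) * c1
            a0 *= m0
            a1 *= m1
        tot = a0 + a1
        if tot <= 0.0:
            return -math.inf
        L0[node] = a0 / tot
        L1[node] = a1 / tot
        log_scale += math.log(tot)

    root = tree.root
    lik = pr0 * L0[root] + pr1 * L1[root]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + log_scale


@dataclass
class MkFit:
    """Maximum-likelihood Mk fit with Wald standard errors and diagnostics."""

    model: RateModel
    log_lik: float
    standard_errors: Optional[tuple[float, ...]]
    root_prior: str
    converged: bool
    at_boundary: bool
    n_tips: int
    n_iterations: int = 0
    message: str = ""

    @property
    def n_free_parameters(self) -> int:
        return self.model.n_free_parameters


def _make_model(family: str, theta: Sequence[float]) -> RateModel:
    if family == "ER":
        return RateModel.er(theta[0])
    return RateModel.ard(theta[0], theta[1])


def fit(
    tree: Phylogeny,
    states: TipStates,
    family: str = "ER",
    root_prior: RootPrior = "flat",
    marginalize_missing: bool = False,
) -> MkFit:
    """Fit an ER or ARD model by maximum likelihood.

    Rates are optimized on the log scale (positivity for free) within
    [1e-8, 1e3], from two starting points scaled by tree height; the better
    optimum is kept.  Standard errors come from the inverse observed
    information (central-difference Hessian of -lnL on the natural scale);
    they are reported as unavailable when the Hessian is not positive
    definite, e.g. at a boundary.
    """
    if family not in ("ER", "ARD"):
        raise ValidationError(f"family must be 'ER' or 'ARD', got {family!r}")
    if not marginalize_missing:
        missing = [t for t in tree.leaf_labels if states.states.get(t) is None]
        if missing:
            raise ValidationError(
                f"{len(missing)} leaves have unknown states (e.g. {missing[:3]}); "
                "drop them first or pass marginalize_missing=True"
            )
    n_obs = sum(1 for t in tree.leaf_labels if states.states.get(t) is not None)
    if n_obs < 2:
        raise ValidationError("need at least two tips with determined states")

    height = max(tree.depths())
    if height <= 0:
        raise ValidationError("tree has zero height; rates are not identifiable")
    k = 1 if family == "ER" else 2

    def nll(log_theta: np.ndarray) -> float:
        theta = np.exp(log_theta)
        model = _make_model(family, theta)
        ll = log_likelihood(tree, states, model, root_prior, marginalize_missing)
        return -ll if math.isfinite(ll) else 1e12

    lb, ub = math.log(RATE_LOWER), math.log(RATE_UPPER)
    bounds = [(lb, ub)] * k
    starts = [np.full(k, math.log(0.1 / height)), np.full(k, math.log(1.0 / height))]
    # coarse log-grid pre-scan guards against the saturation ridge at large q,
    # where local search can strand far from the interior optimum
    grid = [math.log(g / height) for g in (0.01, 0.05, 0.3, 3.0, 10.0, 100.0)]
    best_grid = min(grid, key=lambda x: nll(np.full(k, x)))
    starts.append(np.full(k, best_grid))

    best = None
    n_iter = 0
    messages = []
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        n_iter += int(res.nit)
        messages.append(str(res.message))
        if best is None or res.fun < best.fun:
            best = res

    assert best is not None
    log_theta_hat = np.asarray(best.x, dtype=float)
    theta_hat = np.exp(log_theta_hat)
    model_hat = _make_model(family, theta_hat)
    lnl_hat = -float(best.fun)
    at_boundary = bool(np.any(log_theta_hat <= lb + 1e-6) or np.any(log_theta_hat >= ub - 1e-6))

    ses = _wald_standard_errors(tree, states, family, theta_hat, root_prior, marginalize_missing)
    if at_boundary:
        ses = None

    prior_name = root_prior if isinstance(root_prior, str) else "given"
    return MkFit(
        model=model_hat,
        log_lik=lnl_hat,
        standard_errors=ses,
        root_prior=prior_name,
        converged=bool(best.success),
        at_boundary=at_boundary,
        n_tips=n_obs,
        n_iterations=n_iter,
        message="; ".join(dict.fromkeys(messages)),
    )


def _wald_standard_errors(
    tree: Phylogeny,
    states: TipStates,
    family: str,
    theta_hat: np.ndarray,
    root_prior: RootPrior,
    marginalize_missing: bool,
) -> Optional[tuple[float, ...]]:
    """SEs from the central-difference Hessian of -lnL at the MLE (natural scale)."""

    def nll_nat(theta: np.ndarray) -> float:
        if np.any(theta <= 0):
            return math.inf
        model = _make_model(family, theta)
        ll = log_likelihood(tree, states, model, root_prior, marginalize_missing)
        return -ll if math.isfinite(ll) else math.inf

    k = len(theta_hat)
    h = np.maximum(1e-4, 1e-4 * np.abs(theta_hat))
    H = np.empty((k, k))
    f0 = nll_nat(theta_hat)
    try:
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (nll_nat(theta_hat + ei) - 2 * f0 + nll_nat(theta_hat - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                fpp = nll_nat(theta_hat + ei + ej)
                fpm = nll_nat(theta_hat + ei - ej)
                fmp = nll_nat(theta_hat - ei + ej)
                fmm = nll_nat(theta_hat - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            return None
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0):
            return None
        return tuple(float(v) for v in np.sqrt(var))
    except (np.linalg.LinAlgError, OverflowError):
        return None


@dataclass
class GarbageFit:
    """Tree-free i.i.d. Bernoulli baseline fit ("total garbage test")."""

    p_hat: float
    log_lik: float
    n_tips: int


def garbage_fit(states: TipStates) -> GarbageFit:
    """ML Bernoulli fit ignoring the phylogeny.

    p_hat = n1/(n0+n1), lnL = n1 ln p_hat + n0 ln(1 - p_hat) with the
    convention 0 ln 0 = 0.
    """
    n1, n0 = states.n_present, states.n_absent
    n = n0 + n1
    if n == 0:
        raise ValidationError("no determined states: cannot fit the garbage model")
    p = n1 / n
    lnl = 0.0
    if n1:
        lnl += n1 * math.log(p)
    if n0:
        lnl += n0 * math.log(1 - p)
    return GarbageFit(p_hat=p, log_lik=lnl, n_tips=n)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested Mk fits."""

    lnl_reduced: float
    lnl_full: float
    statistic: float
    df: int
    p_value: float


def compare_models(reduced: MkFit, full: MkFit) -> ModelComparison:
    """Chi-square LRT of a reduced model (ER) against a full one (ARD).

    The statistic 2(lnL_full - lnL_reduced) is referred to a chi-square
    with df = difference in free-parameter counts.  Tiny negative statistics
    (optimizer noise) are clamped to zero with a warning; larger ones mean
    the models were not actually nested and raise.
    """
    df = full.n_free_parameters - reduced.n_free_parameters
    if df <= 0:
        raise ValidationError(
            f"models are not nested: reduced has {reduced.n_free_parameters} "
            f"free parameter(s), full has {full.n_free_parameters}"
        )
    stat = 2.0 * (full.log_lik - reduced.log_lik)
    if stat < 0:
        if stat > -1e-6:
            warnings.warn(
                f"clamping tiny negative LRT statistic {stat:.2e} to 0 (optimizer noise)",
                RuntimeWarning,
                stacklevel=2,
            )
            stat = 0.0
        else:
            raise NumericalError(
                f"reduced model fits better than full by {-stat / 2:.6g} log units; "
                "nesting violated or full-model optimization failed"
            )
    p = float(stats.chi2.sf(stat, df))
    return ModelComparison(
        lnl_reduced=reduced.log_lik,
        lnl_full=full.log_lik,
        statistic=stat,
        df=df,
        p_value=p,
    )
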