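"""Maximum-likelihood estimation on a fixed tree topology.

Parameters are split into four blocks — branch lengths, the gamma shape
``alpha``, mixture weights, and the 189 free linked exchangeabilities (the
Y/V entry is pinned to 1) — each optimized by the method suited to it:

* branch lengths: quasi-Newton (L-BFGS-B) on log-lengths with analytic
  gradients from the pruning engine;
* alpha: bounded one-dimensional search on [0.02, 100];
* weights: EM-style responsibility updates, which are monotone in the
  log-likelihood and need no extra likelihood evaluations once the
  per-class site likelihoods are in hand;
* exchangeabilities: quasi-Newton on log-exchangeabilities (positivity is
  enforced by the log transform) with analytic gradients, initialized at
  all-ones (POISSON) by default.

``fit_joint`` cycles the enabled blocks (branch lengths, alpha, weights,
exchangeabilities) until the outer improvement falls below tolerance; the
recorded log-likelihood trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .core_model import (
    CONSTRAINED_PAIR,
    ExchangeabilityMatrix,
    ProfileMixture,
    lg_matrix,
    poisson_matrix,
)
from .likelihood import (
    DiscreteRates,
    LikelihoodEngine,
    LikelihoodResult,
    MixtureModelSpec,
    count_free_parameters,
    discretize_gamma,
    information_criteria,
)
from .phylo_io import Alignment, Tree, compress_patterns

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_exchangeabilities",
    "fit_weights",
    "fit_alpha",
    "fit_branch_lengths",
    "fit_joint",
]

ALPHA_BOUNDS = (0.02, 100.0)
MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 1e3


@dataclass
class FitOptions:
    """Which parameter blocks to estimate, starting points, and tolerances."""

    estimate_exchangeabilities: bool = True
    estimate_weights: bool = True
    estimate_alpha: bool = True
    estimate_branch_lengths: bool = True
    init_S: object = "poisson"  # "poisson", "lg", or an ExchangeabilityMatrix
    outer_tol: float = 0.01
    max_outer_rounds: int = 100
    gradient_tol: float = 1e-2
    max_inner_iter: int = 500
    lbfgs_memory: int = 40
    weights_tol: float = 1e-8
    weight_floor: float = 1e-8
    alpha_tol: float = 1e-4
    seed: int | None = None

    def __post_init__(self):
        if not any([self.estimate_exchangeabilities, self.estimate_weights,
                    self.estimate_alpha, self.estimate_branch_lengths]):
            raise ValueError("at least one parameter block must be estimated")
        for name in ("outer_tol", "gradient_tol", "weights_tol", "alpha_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def initial_matrix(self, spec_S: ExchangeabilityMatrix) -> ExchangeabilityMatrix:
        if isinstance(self.init_S, ExchangeabilityMatrix):
            return self.init_S.constrained()
        if self.init_S == "poisson":
            return poisson_matrix().constrained()
        if self.init_S == "lg":
            return lg_matrix().constrained()
        if self.init_S == "spec":
            return spec_S.constrained()
        raise ValueError(f"unknown init_S {self.init_S!r}")


@dataclass
class FitResult:
    """Estimates, trace, and bookkeeping from a fit."""

    S_hat: ExchangeabilityMatrix
    weights_hat: np.ndarray
    alpha_hat: float | None
    branch_lengths_hat: np.ndarray
    tree: Tree
    spec: MixtureModelSpec
    loglik_trace: list
    final: LikelihoodResult
    converged: bool
    k: int | None = None
    flags: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.final.total_loglik

    def report(self, n: int | None = None) -> dict:
        n = n if n is not None else self.final.n_sites
        out = {
            "loglik": self.loglik,
            "alpha": self.alpha_hat,
            "weights": list(map(float, self.weights_hat)),
            "branch_lengths": list(map(float, self.branch_lengths_hat)),
            "converged": self.converged,
            "flags": list(self.flags),
            "n_sites": n,
            "loglik_trace": list(map(float, self.loglik_trace)),
        }
        if self.k is not None:
            aic, bic = information_criteria(self.loglik, self.k, n)
            out.update(k=self.k, AIC=aic, BIC=bic)
        return out


class _Fitter:
    """Mutable optimization state shared by the block updates."""

    def __init__(self, aln: Alignment, spec: MixtureModelSpec, options: FitOptions):
        self.options = options
        self.table = compress_patterns(aln)
        self.table.taxa = aln.taxa
        self.tree = spec.tree.copy()
        self.engine = LikelihoodEngine(self.table, self.tree)
        self.profiles = spec.mixture.profiles
        self.weights = spec.mixture.weights.copy()
        self.rates = spec.rates
        self.alpha = spec.rates.alpha
        self.blens = np.maximum(self.tree.branch_lengths(), MIN_BRANCH_LENGTH)
        if options.estimate_exchangeabilities:
            self.S = options.initial_matrix(spec.S)
        else:
            self.S = spec.S
        self.trace: list[float] = []
        self.flags: list[str] = []

    # -- helpers -----------------------------------------------------------

    @property
    def mixture(self) -> ProfileMixture:
        return ProfileMixture(self.profiles, self.weights, "estimated")

    def current_rates(self) -> DiscreteRates:
        if self.alpha is not None and self.rates.K > 1:
            return discretize_gamma(self.alpha, self.rates.K)
        return self.rates

    def loglik(self) -> float:
        total, _, _ = self.engine.loglik(self.S, self.mixture,
                                         self.current_rates(), self.blens)
        return total

    def record(self, value: float) -> None:
        if self.trace and value < self.trace[-1] - 1e-6:
            self.flags.append(f"non-monotone step: {self.trace[-1]} -> {value}")
        self.trace.append(float(value))

    # -- blocks ------------------------------------------------------------

    def update_branch_lengths(self) -> float:
        opts = self.options
        rates = self.current_rates()
        x0 = np.log(self.blens)
        bounds = [(np.log(MIN_BRANCH_LENGTH), np.log(MAX_BRANCH_LENGTH))] * x0.size
        mix = self.mixture

        def objective(x):
            out = self.engine.loglik_and_gradients(
                self.S, mix, rates, np.exp(x), wrt=("branch_lengths",))
            return -out["loglik"], -out["log_blen"]

        res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": opts.max_inner_iter,
                                "gtol": opts.gradient_tol,
                                "maxcor": opts.lbfgs_memory,
                                "ftol": 1e-12})
        if -res.fun >= (self.trace[-1] if self.trace else -np.inf):
            self.blens = np.exp(res.x)
        ll = self.loglik()
        self.record(ll)
        return ll

    def update_alpha(self) -> float:
        if self.rates.K < 2:
            raise ValueError("alpha not identifiable with a single rate category")
        mix = self.mixture

        def negll(a):
            total, _, _ = self.engine.loglik(
                self.S, mix, discretize_gamma(a, self.rates.K), self.blens)
            return -total

        res = minimize_scalar(negll, bounds=ALPHA_BOUNDS, method="bounded",
                              options={"xatol": self.options.alpha_tol})
        if self.alpha is None or -res.fun >= -negll(self.alpha) - 1e-9:
            self.alpha = float(res.x)
        if self.alpha >= ALPHA_BOUNDS[1] * 0.999:
            self.flags.append("alpha at upper bound (rate-homogeneous data)")
        if self.alpha <= ALPHA_BOUNDS[0] * 1.001:
            self.flags.append("alpha at lower bound")
        ll = self.loglik()
        self.record(ll)
        return ll

    def update_weights(self) -> float:
        rates = self.current_rates()
        _, _, logL = self.engine.loglik(self.S, self.mixture, rates, self.blens)
        # per-class site log-likelihoods, independent of the weights
        log_lc = logsumexp(logL + np.log(rates.weights)[None, :, None], axis=1)
        counts = self.table.counts
        n = counts.sum()
        dupes = len({tuple(np.round(p.freqs, 12)) for p in self.profiles})
        if dupes < len(self.profiles):
            self.flags.append("duplicate profiles: weights not identifiable")
        w = self.weights.copy()
        for _ in range(500):
            logpost = np.log(w)[:, None] + log_lc
            logpost -= logsumexp(logpost, axis=0, keepdims=True)
            new = np.exp(logpost) @ counts / n
            if np.any(new < self.options.weight_floor):
                self.flags.append("weight floored at minimum")
                new = np.maximum(new, self.options.weight_floor)
                new /= new.sum()
            if np.max(np.abs(new - w)) < self.options.weights_tol:
                w = new
                break
            w = new
        self.weights = w / w.sum()
        ll = self.loglik()
        self.record(ll)
        return ll

    def update_exchangeabilities(self) -> float:
        opts = self.options
        rates = self.current_rates()
        mix = self.mixture
        iu = np.triu_indices(20, k=1)
        fixed = next(t for t in range(190)
                     if (iu[0][t], iu[1][t]) == CONSTRAINED_PAIR)
        free = np.array([t for t in range(190) if t != fixed])
        s0 = self.S.constrained().upper_triangle()
        x0 = np.log(np.maximum(s0[free], 1e-8))

        def make_S(x):
            vals = np.empty(190)
            vals[free] = np.exp(x)
            vals[fixed] = 1.0
            return ExchangeabilityMatrix.from_upper_triangle(vals, name="GTR")

        def objective(x):
            S = make_S(x)
            out = self.engine.loglik_and_gradients(
                S, mix, rates, self.blens, wrt=("exchangeabilities",))
            f, grad = -out["loglik"], -out["log_s"][free]
            if not np.isfinite(f) or not np.all(np.isfinite(grad)):
                return np.inf, np.zeros_like(grad)
            return f, grad

        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=[(np.log(1e-6), np.log(1e6))] * free.size,
                       options={"maxiter": opts.max_inner_iter,
                                "gtol": opts.gradient_tol,
                                "maxcor": opts.lbfgs_memory,
                                "ftol": 1e-12})
        candidate = make_S(res.x)
        if -res.fun >= (self.trace[-1] if self.trace else -np.inf):
            self.S = candidate
        if not res.success and res.status != 1:  # status 1 = maxiter reached
            self.flags.append(f"exchangeability optimizer: {res.message}")
        ll = self.loglik()
        self.record(ll)
        return ll

    # -- assembly ----------------------------------------------------------

    def result(self, converged: bool) -> FitResult:
        rates = self.current_rates()
        total, site, _ = self.engine.loglik(self.S, self.mixture, rates, self.blens)
        sitewise = self.table.expand(site)
        final = LikelihoodResult(total, sitewise, self.table.n_sites,
                                 self.table.n_patterns)
        tree = self.tree.copy()
        tree.set_branch_lengths(self.blens)
        opts = self.options
        n_taxa = len(self.table.taxa)
        k = count_free_parameters(
            n_taxa,
            exchangeabilities_estimated=opts.estimate_exchangeabilities,
            n_classes=len(self.profiles),
            weights_estimated=opts.estimate_weights and len(self.profiles) > 1,
            gamma_estimated=opts.estimate_alpha and self.rates.K > 1,
            branch_lengths_estimated=opts.estimate_branch_lengths,
            n_branches=self.blens.size if opts.estimate_branch_lengths else None,
        )
        spec = MixtureModelSpec(self.S, self.mixture, rates, tree)
        return FitResult(
            S_hat=self.S if not opts.estimate_exchangeabilities
            else self.S.constrained(),
            weights_hat=self.weights.copy(),
            alpha_hat=self.alpha,
            branch_lengths_hat=self.blens.copy(),
            tree=tree,
            spec=spec,
            loglik_trace=self.trace,
            final=final,
            converged=converged,
            k=k,
            flags=self.flags,
        )


def _single_block(aln, spec, options, block) -> FitResult:
    fitter = _Fitter(aln, spec, options)
    ll0 = fitter.loglik()
    if not np.isfinite(ll0):
        raise ValueError("non-finite log-likelihood at the starting point")
    fitter.record(ll0)
    converged = False
    for _ in range(options.max_outer_rounds):
        before = fitter.trace[-1]
        after = getattr(fitter, f"update_{block}")()
        if after - before < options.outer_tol:
            converged = True
            break
    return fitter.result(converged)


def fit_exchangeabilities(aln: Alignment, spec: MixtureModelSpec,
                          options: FitOptions | None = None) -> FitResult:
    """Estimate the 189 free linked exchangeabilities, other blocks fixed.

    The returned matrix is in constrained form (Y/V entry exactly 1).  By
    default the search starts from POISSON (all exchangeabilities one).
    """
    options = options or FitOptions()
    options = replace(options, estimate_exchangeabilities=True,
                      estimate_weights=False, estimate_alpha=False,
                      estimate_branch_lengths=False)
    return _single_block(aln, spec, options, "exchangeabilities")


def fit_weights(aln: Alignment, spec: MixtureModelSpec,
                options: FitOptions | None = None) -> np.ndarray:
    """Estimate mixture weights by monotone EM; returns the weight vector."""
    options = options or FitOptions()
    options = replace(options, estimate_exchangeabilities=False,
                      estimate_weights=True, estimate_alpha=False,
                      estimate_branch_lengths=False, init_S="spec")
    if spec.mixture.n_classes == 1:
        return np.array([1.0])
    res = _single_block(aln, spec, options, "weights")
    return res.weights_hat


def fit_alpha(aln: Alignment, spec: MixtureModelSpec,
              options: FitOptions | None = None) -> float:
    """Estimate the gamma shape by bounded search; returns alpha."""
    if spec.rates.K < 2:
        raise ValueError("alpha not identifiable with a single rate category")
    options = options or FitOptions()
    options = replace(options, estimate_exchangeabilities=False,
                      estimate_weights=False, estimate_alpha=True,
                      estimate_branch_lengths=False, init_S="spec")
    res = _single_block(aln, spec, options, "alpha")
    return float(res.alpha_hat)


def fit_branch_lengths(aln: Alignment, spec: MixtureModelSpec,
                       options: FitOptions | None = None) -> Tree:
    """Estimate branch lengths on the fixed topology; returns the new tree."""
    options = options or FitOptions()
    options = replace(options, estimate_exchangeabilities=False,
                      estimate_weights=False, estimate_alpha=False,
                      estimate_branch_lengths=True, init_S="spec")
    res = _single_block(aln, spec, options, "branch_lengths")
    return res.tree


def fit_joint(aln: Alignment, spec: MixtureModelSpec,
              options: FitOptions | None = None) -> FitResult:
    """Coordinate-ascent over the enabled blocks until convergence.

    Block order within a round: branch lengths, alpha, weights,
    exchangeabilities.  Disabled blocks stay at their values in ``spec``
    (e.g. freeze branch lengths and alpha for the fast two-stage protocol
    in which only exchangeabilities and weights are re-estimated).
    """
    options = options or FitOptions()
    fitter = _Fitter(aln, spec, options)
    ll0 = fitter.loglik()
    if not np.isfinite(ll0):
        raise ValueError("non-finite log-likelihood at the starting point")
    fitter.record(ll0)
    blocks = []
    if options.estimate_branch_lengths:
        blocks.append("branch_lengths")
    if options.estimate_alpha:
        if spec.rates.K < 2:
            raise ValueError("alpha not identifiable with a single rate category")
        blocks.append("alpha")
    if options.estimate_weights and spec.mixture.n_classes > 1:
        blocks.append("weights")
    if options.estimate_exchangeabilities:
        blocks.append("exchangeabilities")
    if not blocks:
        raise ValueError("no estimable blocks for this model")
    converged = False
    for _ in range(options.max_outer_rounds):
        before = fitter.trace[-1]
        for block in blocks:
            getattr(fitter, f"update_{block}")()
        if fitter.trace[-1] - before < options.outer_tol:
            converged = True
            break
    return fitter.result(converged)
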