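"""Profile-mixture likelihood under linked exchangeabilities.

The likelihood of a site pattern ``x_p`` on a fixed tree ``T`` marginalizes
the latent profile class and rate category:

    L(x_p) = sum_c w_c sum_k d_k P(x_p | T, S, pi_c, r_k),

and the alignment log-likelihood is the sum of ``log L(x_p)`` over sites.
Each inner term is computed by Felsenstein pruning with branch transition
matrices ``exp(Q_{pi_c} r_k t_b)``, where every class rate matrix is built
from the one shared exchangeability matrix ``S`` and normalized to unit mean
rate.  Rate heterogeneity uses the discretized mean-one gamma with ``K``
equal-probability categories.

The engine also returns analytic gradients of the log-likelihood with
respect to (log) exchangeabilities, (log) branch lengths, and mixture
weights, obtained from a single additional root-to-tip pass; these drive the
estimation routines in :mod:`gtrlink.optimize`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .core_model import (
    ExchangeabilityMatrix,
    Profile,
    ProfileMixture,
    RateMatrix,
    build_rate_matrix,
)
from .phylo_io import Alignment, SitePatternTable, Tree, compress_patterns

__all__ = [
    "DiscreteRates",
    "discretize_gamma",
    "MixtureModelSpec",
    "LikelihoodResult",
    "LikelihoodEngine",
    "site_pattern_likelihood",
    "log_likelihood",
    "information_criteria",
    "count_free_parameters",
    "loglik_difference",
]


@dataclass(frozen=True)
class DiscreteRates:
    """K rate categories (r_k, d_k) with mean rate one."""

    rates: np.ndarray
    weights: np.ndarray
    alpha: float | None = None

    def __post_init__(self):
        r = np.asarray(self.rates, float)
        d = np.asarray(self.weights, float)
        if r.shape != d.shape or r.ndim != 1 or r.size < 1:
            raise ValueError("rates and weights must be matching 1-d arrays")
        if np.any(r < 0) or np.any(d <= 0):
            raise ValueError("rates must be >= 0 and weights > 0")
        if abs(d.sum() - 1.0) > 1e-10:
            raise ValueError("rate weights must sum to 1")
        if abs(float(d @ r) - 1.0) > 1e-8:
            raise ValueError("mean rate must equal 1")
        r.setflags(write=False)
        d.setflags(write=False)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", d)

    @property
    def K(self) -> int:
        return self.rates.size

    @classmethod
    def homogeneous(cls) -> "DiscreteRates":
        return cls(np.array([1.0]), np.array([1.0]))


def discretize_gamma(alpha: float, K: int, method: str = "mean") -> DiscreteRates:
    """Equal-probability discretization of the mean-one gamma distribution.

    Category rates are the conditional means of the gamma(shape=alpha,
    mean=1) distribution between consecutive ``1/K`` quantiles (Yang-style
    discretization), renormalized so the discrete mean is exactly one.
    ``method="median"`` uses within-category medians instead.
    """
    alpha = float(alpha)
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError("gamma shape alpha must be positive")
    K = int(K)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return DiscreteRates(np.array([1.0]), np.array([1.0]), alpha=alpha)
    d = np.full(K, 1.0 / K)
    if method == "mean":
        edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
        upper = np.concatenate([gammainc(alpha + 1.0, alpha * edges), [1.0]])
        lower = np.concatenate([[0.0], upper[:-1]])
        r = K * (upper - lower)
    elif method == "median":
        r = gamma_dist.ppf((np.arange(K) + 0.5) / K, a=alpha, scale=1.0 / alpha)
    else:
        raise ValueError("method must be 'mean' or 'median'")
    r = r / float(d @ r)
    return DiscreteRates(r, d, alpha=alpha)


@dataclass
class MixtureModelSpec:
    """The full parameter bundle the likelihood engine consumes."""

    S: ExchangeabilityMatrix
    mixture: ProfileMixture
    rates: DiscreteRates
    tree: Tree

    def replace(self, **kwargs) -> "MixtureModelSpec":
        data = {"S": self.S, "mixture": self.mixture,
                "rates": self.rates, "tree": self.tree}
        data.update(kwargs)
        return MixtureModelSpec(**data)


@dataclass
class LikelihoodResult:
    total_loglik: float
    sitewise_logliks: np.ndarray
    n_sites: int
    n_patterns: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("site_index\tloglik\n")
            for i, value in enumerate(self.sitewise_logliks, start=1):
                fh.write(f"{i}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder-array view of a tree bound to alignment rows."""

    def __init__(self, tree: Tree, taxa: list[str]):
        nodes = tree.postorder()
        labels = [n.label for n in nodes if n.is_leaf]
        if set(labels) != set(taxa):
            missing = sorted(set(labels) ^ set(taxa))
            raise ValueError(f"tree and alignment taxon sets differ: {missing}")
        self.n_nodes = len(nodes)
        self.node_of = {id(n): i for i, n in enumerate(nodes)}
        self.children = [[self.node_of[id(c)] for c in n.children] for n in nodes]
        self.blen = np.array([0.0 if n is tree.root else n.length for n in nodes])
        self.is_leaf = np.array([n.is_leaf for n in nodes])
        taxon_row = {t: i for i, t in enumerate(taxa)}
        self.leaf_row = {i: taxon_row[n.label]
                         for i, n in enumerate(nodes) if n.is_leaf}
        self.root = self.n_nodes - 1
        # branch b <-> non-root node b (postorder order, matching Tree.branch_lengths)
        self.branch_nodes = [i for i in range(self.n_nodes) if i != self.root]


def _divided_difference(lam: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """F_ab = (e^{lam_a tau} - e^{lam_b tau}) / (lam_a - lam_b), F_aa = tau e^{lam_a tau}.

    Vectorized over a vector of time scalings: returns (len(taus), 20, 20).
    """
    taus = np.atleast_1d(np.asarray(taus, float))[:, None, None]
    la = lam[None, :, None]
    lb = lam[None, None, :]
    delta = la - lb
    small = np.abs(delta) < 1e-10
    safe = np.where(small, 1.0, delta)
    with np.errstate(over="ignore", invalid="ignore"):
        f = np.exp(lb * taus) * np.expm1(delta * taus) / safe
        mid = taus * np.exp(0.5 * (la + lb) * taus)
    return np.where(small, mid, f)


class LikelihoodEngine:
    """Evaluates the mixture log-likelihood and its gradients on fixed data.

    The engine is bound to one pattern table and one tree topology; branch
    lengths and all model parameters vary per call, which is what iterative
    estimation needs.
    """

    def __init__(self, patterns: SitePatternTable, tree: Tree):
        self.patterns = patterns
        self.tree = tree
        taxa = getattr(patterns, "taxa", None)
        self.index = _TreeIndex(tree, taxa if taxa is not None else tree.leaf_labels())
        # leaf conditional likelihoods, shared by all classes/rates
        npat = patterns.n_patterns
        self.leafL = {}
        for node_id, row in self.index.leaf_row.items():
            codes = patterns.patterns[row]
            m = np.zeros((20, npat))
            obs = codes >= 0
            m[codes[obs], np.nonzero(obs)[0]] = 1.0
            m[:, ~obs] = 1.0
            self.leafL[node_id] = m

    # -- forward pass ------------------------------------------------------

    def _branch_transition(self, u, lam, s, taus: np.ndarray) -> np.ndarray:
        """P for all rate categories and branches at once: (K, n_branch, 20, 20)."""
        e = np.exp(taus[..., None] * lam)  # (K, nb, 20)
        p = (u[None, None, :, :] * e[:, :, None, :]) @ u.T
        p *= (s[None, :] / s[:, None])[None, None, :, :]
        p[taus == 0.0] = np.eye(20)  # exact identity, not eigen round-off
        return p

    def _down_pass(self, P: np.ndarray, K: int, keep: bool = False):
        """Postorder conditional likelihoods for one class, batched over the
        K rate categories.

        Arrays per node are (K, 20, n_patterns) with per-pattern log-scalers
        (K, n_patterns); ``P`` is indexed [rate, branch].
        """
        idx = self.index
        npat = self.patterns.n_patterns
        branch_of = {node: b for b, node in enumerate(idx.branch_nodes)}
        Lhat: dict[int, np.ndarray] = {}
        Mhat: dict[int, np.ndarray] = {}
        slog: dict[int, np.ndarray] = {}
        zeros = np.zeros((K, npat))
        for node in range(idx.n_nodes):
            if idx.is_leaf[node]:
                Lhat[node] = np.broadcast_to(self.leafL[node], (K, 20, npat))
                slog[node] = zeros
            else:
                raw = None
                acc = zeros
                for child in idx.children[node]:
                    m = P[:, branch_of[child]] @ Lhat[child]
                    if keep:
                        Mhat[child] = m
                    raw = m if raw is None else raw * m
                    acc = acc + slog[child]
                scale = raw.max(axis=1)
                zero = scale <= 0.0
                div = np.where(zero, 1.0, scale)
                Lhat[node] = raw / div[:, None, :]
                with np.errstate(divide="ignore"):
                    acc = acc + np.where(zero, -np.inf, np.log(div))
                slog[node] = acc
                if not keep:
                    for child in idx.children[node]:
                        if not idx.is_leaf[child]:
                            del Lhat[child], slog[child]
        return Lhat, Mhat, slog

    def _class_loglik(self, profile, Q, rates, blens, keep=False):
        """log P(x_p | class, k) for one class: ((K, n_pat), P, stores)."""
        idx = self.index
        u, lam, s = Q.eig()
        taus = rates.rates[:, None] * blens[None, :]
        P = self._branch_transition(u, lam, s, taus)
        Lhat, Mhat, slog = self._down_pass(P, rates.K, keep=keep)
        # tiny negatives can appear through eigen round-off at extreme
        # parameter values explored by the optimizer
        rootvec = np.maximum(np.einsum("i,kip->kp", profile.freqs,
                                       Lhat[idx.root]), 0.0)
        with np.errstate(divide="ignore"):
            logL = np.log(rootvec) + slog[idx.root]
        return logL, P, (Lhat, Mhat, slog)

    def _all_class_logliks(self, S, mixture, rates, blens):
        C = mixture.n_classes
        logL = np.empty((C, rates.K, self.patterns.n_patterns))
        qs = []
        for c, profile in enumerate(mixture.profiles):
            Q = build_rate_matrix(S, profile)
            qs.append(Q)
            logL[c], _, _ = self._class_loglik(profile, Q, rates, blens)
        return logL, qs

    def loglik(self, S, mixture, rates, blens=None):
        """Total log-likelihood, per-pattern log-likelihoods, per-(c,k) table."""
        if blens is None:
            blens = self.index.blen[self.index.branch_nodes]
        logL, _ = self._all_class_logliks(S, mixture, rates,
                                          np.asarray(blens, float))
        logw = np.log(mixture.weights)[:, None, None] + \
            np.log(rates.weights)[None, :, None]
        site = logsumexp((logL + logw).reshape(-1, logL.shape[2]), axis=0)
        total = float(self.patterns.counts @ site)
        return total, site, logL

    # -- gradients ---------------------------------------------------------

    def loglik_and_gradients(self, S, mixture, rates, blens=None,
                             wrt=("exchangeabilities", "branch_lengths")):
        """Log-likelihood plus analytic gradients.

        The mixture site likelihoods are computed first; a second pass per
        class then runs root-to-tip accumulation and converts per-branch
        sensitivities into gradients with respect to the rate matrix (via
        the eigen-space divided-difference form of the matrix-exponential
        derivative) and on to the exchangeabilities.

        Gradient keys: ``log_s``/``grad_s`` (190-vector, order of
        ``ExchangeabilityMatrix.upper_triangle``), ``log_blen``/``blen``
        (per branch, postorder), ``weights`` (per class).
        """
        idx = self.index
        if blens is None:
            blens = idx.blen[idx.branch_nodes]
        blens = np.asarray(blens, float)
        counts = self.patterns.counts
        npat = self.patterns.n_patterns
        C, K = mixture.n_classes, rates.K

        logL, qs = self._all_class_logliks(S, mixture, rates, blens)
        logw = np.log(mixture.weights)[:, None, None] + \
            np.log(rates.weights)[None, :, None]
        site = logsumexp((logL + logw).reshape(-1, npat), axis=0)
        total = float(counts @ site)

        out: dict = {"loglik": total, "site": site}
        want_s = "exchangeabilities" in wrt
        want_b = "branch_lengths" in wrt
        if "weights" in wrt:
            # dl/dw_c = sum_p counts_p * (sum_k d_k L_ckp) / L_p
            log_lc = logsumexp(logL + np.log(rates.weights)[None, :, None], axis=1)
            out["weights"] = np.exp(log_lc - site[None, :]) @ counts
        if not (want_s or want_b):
            return out
        if not np.isfinite(total):
            # gradients undefined at an impossible point; report zeros
            if want_b:
                out["log_blen"] = np.zeros(len(idx.branch_nodes))
                out["blen"] = np.zeros(len(idx.branch_nodes))
            if want_s:
                out["grad_s"] = np.zeros(190)
                out["log_s"] = np.zeros(190)
            return out

        branch_of = {node: b for b, node in enumerate(idx.branch_nodes)}
        grad_t = np.zeros(len(idx.branch_nodes))
        grad_s_mat = np.zeros((20, 20))
        d_k = rates.weights

        for c, profile in enumerate(mixture.profiles):
            Q = qs[c]
            u, lam, s = Q.eig()
            _, P, (Lhat, Mhat, slog) = self._class_loglik(
                profile, Q, rates, blens, keep=True)
            w_c = mixture.weights[c]
            Gq = np.zeros((20, 20))
            left = u * s[:, None]          # Dg U
            right = u.T * (1.0 / s)[None, :]  # U^T Dg^{-1}
            Ahat: dict[int, np.ndarray] = {
                idx.root: np.broadcast_to(profile.freqs[None, :, None],
                                          (K, 20, npat))}
            alog: dict[int, np.ndarray] = {idx.root: np.zeros((K, npat))}
            for node in range(idx.n_nodes - 1, -1, -1):  # preorder
                if idx.is_leaf[node]:
                    continue
                for child in idx.children[node]:
                    base = Ahat[node]
                    blog = alog[node]
                    for sib in idx.children[node]:
                        if sib is child:
                            continue
                        base = base * Mhat[sib]
                        blog = blog + slog[sib]
                    b = branch_of[child]
                    with np.errstate(over="ignore"):
                        gam = (counts[None, :] * w_c * d_k[:, None] *
                               np.exp(blog + slog[child] - site[None, :]))
                    # per-rate sensitivity to the branch transition matrix
                    G = (base * gam[:, None, :]) @ Lhat[child].transpose(0, 2, 1)
                    if want_b:
                        qp = Q.entries[None, :, :] @ P[:, b]
                        grad_t[b] += float(np.einsum(
                            "kij,kij,k->", G, qp, rates.rates))
                    if want_s:
                        taus = rates.rates * blens[b]
                        F = _divided_difference(lam, taus)
                        inner = right @ G @ left
                        Gq += left @ (inner * F).sum(axis=0) @ right
                    down = P[:, b].transpose(0, 2, 1) @ base
                    scale = down.max(axis=1)
                    zero = scale <= 0.0
                    div = np.where(zero, 1.0, scale)
                    Ahat[child] = down / div[:, None, :]
                    with np.errstate(divide="ignore"):
                        alog[child] = blog + np.where(zero, -np.inf, np.log(div))
            if want_s:
                # chain rule through q_ij = s_ij pi_j / z,  z = sum pi_i s_ij pi_j
                pi = profile.freqs
                z = float(pi @ (S.entries * pi[None, :]).sum(axis=1))
                T = Gq * pi[None, :]
                dg = np.diag(Gq)
                term = T + T.T - np.outer(dg, pi) - np.outer(pi, dg)
                c0 = float(np.sum(Gq * Q.entries))
                grad_s_mat += (term - 2.0 * c0 * np.outer(pi, pi)) / z

        if want_b:
            out["log_blen"] = grad_t * blens
            out["blen"] = grad_t
        if want_s:
            iu = np.triu_indices(20, k=1)
            out["grad_s"] = grad_s_mat[iu]
            out["log_s"] = grad_s_mat[iu] * S.upper_triangle()
        return out


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _engine_for(aln: Alignment, spec: MixtureModelSpec) -> tuple[LikelihoodEngine, SitePatternTable]:
    table = compress_patterns(aln)
    table.taxa = aln.taxa
    return LikelihoodEngine(table, spec.tree), table


def site_pattern_likelihood(pattern, spec: MixtureModelSpec) -> float:
    """Mixture likelihood of a single site pattern.

    ``pattern`` maps taxon name to a one-letter residue (or a missing-data
    symbol), or is a string ordered like the tree's leaf labels.
    """
    labels = spec.tree.leaf_labels()
    if isinstance(pattern, str):
        if len(pattern) != len(labels):
            raise ValueError("pattern length does not match tree leaf count")
        pattern = dict(zip(labels, pattern))
    missing = set(labels) - set(pattern)
    if missing:
        raise ValueError(f"pattern lacks states for taxa {sorted(missing)}")
    aln = Alignment(labels, [str(pattern[t]) for t in labels])
    engine, _ = _engine_for(aln, spec)
    _, site, _ = engine.loglik(spec.S, spec.mixture, spec.rates)
    return float(np.exp(site[0]))


def log_likelihood(aln: Alignment, spec: MixtureModelSpec) -> LikelihoodResult:
    """Total and per-site log-likelihood of an alignment under the model."""
    engine, table = _engine_for(aln, spec)
    total, site, _ = engine.loglik(spec.S, spec.mixture, spec.rates)
    sitewise = table.expand(site)
    if not np.isfinite(total):
        bad = [i + 1 for i in range(aln.n_sites) if not np.isfinite(sitewise[i])]
        raise ZeroLikelihoodError(total, bad)
    return LikelihoodResult(total, sitewise, aln.n_sites, table.n_patterns)


class ZeroLikelihoodError(ValueError):
    """Raised when one or more sites have likelihood zero under every class."""

    def __init__(self, total, sites):
        self.total = total
        self.sites = sites
        preview = ", ".join(map(str, sites[:10])) + ("..." if len(sites) > 10 else "")
        super().__init__(f"zero site likelihood (total {total}) at sites: {preview}")


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL with n = alignment sites."""
    if k < 0 or int(k) != k:
        raise ValueError("parameter count k must be a non-negative integer")
    if n < 1:
        raise ValueError("site count n must be >= 1")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n) - 2.0 * loglik
    return aic, bic


def count_free_parameters(n_taxa: int,
                          exchangeabilities_estimated: bool = False,
                          n_classes: int = 1,
                          weights_estimated: bool = False,
                          f_class: bool = False,
                          gamma_estimated: bool = False,
                          branch_lengths_estimated: bool = True,
                          n_branches: int | None = None) -> int:
    """Free-parameter count of a profile-mixture fit.

    Estimated exchangeabilities contribute 189 (one entry pinned to 1);
    estimated weights ``C - 1`` where ``C`` counts all classes including an
    F class; an estimated empirical-frequency ("+F") class 19; the gamma
    shape 1; branch lengths ``2 n_taxa - 3`` on an unrooted binary tree
    (override via ``n_branches`` for other shapes).  ``n_classes`` counts
    the fixed-profile classes, excluding the F class.
    """
    total_classes = n_classes + (1 if f_class else 0)
    if total_classes < 1:
        raise ValueError("model needs at least one profile class")
    k = 0
    if exchangeabilities_estimated:
        k += 189
    if weights_estimated:
        k += total_classes - 1
    if f_class:
        k += 19
    if gamma_estimated:
        k += 1
    if branch_lengths_estimated:
        if n_branches is None:
            if n_taxa < 3:
                raise ValueError("n_taxa must be >= 3 for default branch counting")
            n_branches = 2 * n_taxa - 3
        k += n_branches
    return k


def loglik_difference(res_true: LikelihoodResult,
                      res_alt: LikelihoodResult) -> tuple[float, np.ndarray]:
    """D = lnL(true) - lnL(alt) and the per-site differences."""
    if res_true.n_sites != res_alt.n_sites:
        raise ValueError("results computed on different numbers of sites")
    deltas = res_true.sitewise_logliks - res_alt.sitewise_logliks
    return res_true.total_loglik - res_alt.total_loglik, deltas
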