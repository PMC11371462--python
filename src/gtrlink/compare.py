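"""Model comparison and simulation-study harnesses.

Covers three reporting tasks: information-criterion tables for competing
fits on the same alignment, fixed-topology preference experiments (which of
two candidate topologies attains the higher maximized log-likelihood,
replicated over simulated alignments, with McNemar tests between fitting
models), and parameter-recovery experiments summarizing how well
exchangeabilities, weights, the gamma shape, and branch lengths are
re-estimated from data simulated under known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom, chi2

from .core_model import ExchangeabilityMatrix, sad
from .likelihood import LikelihoodResult, MixtureModelSpec, information_criteria
from .optimize import FitOptions, FitResult, fit_joint
from .phylo_io import Tree
from .simulate import SimulationSpec, simulate_alignment

__all__ = [
    "ModelComparisonRow",
    "model_table",
    "PreferenceSummary",
    "mcnemar_test",
    "topology_preference_experiment",
    "RecoverySummary",
    "recovery_experiment",
]


@dataclass
class ModelComparisonRow:
    label: str
    loglik: float
    k: int
    AIC: float
    BIC: float
    best_loglik: bool = False
    best_AIC: bool = False
    best_BIC: bool = False

    def as_dict(self) -> dict:
        return {"model": self.label, "loglik": self.loglik, "k": self.k,
                "AIC": self.AIC, "BIC": self.BIC,
                "best": {"loglik": self.best_loglik, "AIC": self.best_AIC,
                         "BIC": self.best_BIC}}


def model_table(fits, n: int) -> list[ModelComparisonRow]:
    """Build an AIC/BIC comparison table from (label, loglik-or-result, k).

    All fits must have been computed on the same alignment of ``n`` sites.
    The best value per column is flagged.
    """
    rows = []
    for label, res, k in fits:
        if isinstance(res, LikelihoodResult):
            if res.n_sites != n:
                raise ValueError(f"fit {label!r} computed on {res.n_sites} "
                                 f"sites, expected {n}")
            loglik = res.total_loglik
        else:
            loglik = float(res)
        aic, bic = information_criteria(loglik, k, n)
        rows.append(ModelComparisonRow(label, loglik, int(k), aic, bic))
    if rows:
        best_ll = max(r.loglik for r in rows)
        best_aic = min(r.AIC for r in rows)
        best_bic = min(r.BIC for r in rows)
        for r in rows:
            r.best_loglik = r.loglik == best_ll
            r.best_AIC = r.AIC == best_aic
            r.best_BIC = r.BIC == best_bic
    return rows


def table_to_tsv(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("model\tloglik\tk\tAIC\tBIC\n")
        for r in rows:
            fh.write(f"{r.label}\t{r.loglik:.6f}\t{r.k}\t{r.AIC:.6f}\t{r.BIC:.6f}\n")


# ---------------------------------------------------------------------------
# Topology preference
# ---------------------------------------------------------------------------

def mcnemar_test(b: int, c: int, exact_threshold: int = 25) -> tuple[float, float]:
    """McNemar's test from the two discordant counts of a paired 2x2 table.

    ``b`` and ``c`` count replicates where exactly one of the two models
    preferred the true tree.  Uses the exact binomial form when
    ``b + c < exact_threshold``, otherwise the continuity-corrected
    chi-square.  Returns (statistic, p-value); the statistic is ``b`` itself
    in the exact case.
    """
    b, c = int(b), int(c)
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if n < exact_threshold:
        p = min(1.0, 2.0 * binom.cdf(min(b, c), n, 0.5))
        return float(min(b, c)), float(p)
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(stat), float(chi2.sf(stat, df=1))


@dataclass
class PreferenceSummary:
    """Per-model record of how often the true tree beat the alternative."""

    label: str
    correct: np.ndarray  # per-replicate: 1.0 true preferred, 0.5 tie, 0.0 not
    deltas: np.ndarray  # per-replicate log-likelihood differences
    ties: int = 0

    @property
    def proportion_correct(self) -> float:
        return float(np.mean(self.correct))


def topology_preference_experiment(generating: SimulationSpec, true_tree: Tree,
                                   artifact_tree: Tree, fitting_models: dict,
                                   n_replicates: int, seed: int,
                                   tie_tol: float = 1e-6) -> dict:
    """Simulate on the true tree; ask which topology each model prefers.

    ``fitting_models`` maps a label to ``(spec_builder, FitOptions)`` where
    ``spec_builder(aln, tree)`` returns the :class:`MixtureModelSpec` to fit
    on a given topology.  For each replicate and model, free parameters are
    re-fit on both topologies and the topology with the higher maximized
    log-likelihood wins; ties (|delta| < tie_tol) count one half.

    Returns ``{"summaries": {label: PreferenceSummary},
    "mcnemar": {(label_a, label_b): (statistic, p)}}``.
    """
    if set(true_tree.leaf_labels()) != set(artifact_tree.leaf_labels()):
        raise ValueError("the two topologies must share a leaf set")
    if true_tree.bipartitions() == artifact_tree.bipartitions():
        raise ValueError("the two topologies are identical")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    labels = list(fitting_models)
    correct = {m: np.zeros(n_replicates) for m in labels}
    deltas = {m: np.zeros(n_replicates) for m in labels}
    ties = {m: 0 for m in labels}
    for rep in range(n_replicates):
        sim_spec = replace(generating, seed=int(seed) + 10_000 * rep)
        sim = simulate_alignment(sim_spec)
        for label in labels:
            builder, options = fitting_models[label]
            lls = []
            for tree in (true_tree, artifact_tree):
                spec = builder(sim.alignment, tree.copy())
                fit = fit_joint(sim.alignment, spec, options)
                lls.append(fit.loglik)
            delta = lls[0] - lls[1]
            deltas[label][rep] = delta
            if abs(delta) < tie_tol:
                correct[label][rep] = 0.5
                ties[label] += 1
            else:
                correct[label][rep] = 1.0 if delta > 0 else 0.0

    summaries = {m: PreferenceSummary(m, correct[m], deltas[m], ties[m])
                 for m in labels}
    tests = {}
    for i, a in enumerate(labels):
        for b_label in labels[i + 1:]:
            a_wins = correct[a] > 0.5
            b_wins = correct[b_label] > 0.5
            disc_b = int(np.sum(a_wins & ~b_wins))
            disc_c = int(np.sum(~a_wins & b_wins))
            tests[(a, b_label)] = mcnemar_test(disc_b, disc_c)
    return {"summaries": summaries, "mcnemar": tests}


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoverySummary:
    """Replicate-level recovery diagnostics against the generating truth."""

    sad_values: np.ndarray  # sad(S_hat, S_true) per replicate
    sad_start: float  # sad(initial matrix, S_true)
    weight_errors: np.ndarray  # (replicates, C) estimated - true
    alpha_errors: np.ndarray  # per replicate (nan if alpha not estimated)
    branch_errors: np.ndarray  # (replicates, B) estimated - true
    mean_matrix: ExchangeabilityMatrix
    sad_mean_matrix: float
    traces_monotone: bool
    fits: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "sad_per_replicate": self.sad_values.tolist(),
            "sad_start": self.sad_start,
            "median_sad": float(np.median(self.sad_values)),
            "sad_mean_matrix": self.sad_mean_matrix,
            "max_abs_weight_error": float(np.nanmax(np.abs(self.weight_errors))),
            "median_abs_alpha_error": float(np.nanmedian(np.abs(self.alpha_errors))),
            "median_abs_branch_error": float(np.nanmedian(np.abs(self.branch_errors))),
            "traces_monotone": self.traces_monotone,
        }


def recovery_experiment(generating: SimulationSpec, n_replicates: int,
                        options: FitOptions | None = None) -> RecoverySummary:
    """Simulate/refit replicates and summarize parameter recovery.

    Each replicate simulates an alignment under ``generating`` (seed offset
    by replicate index), runs :func:`fit_joint` with ``options``, and
    records the SAD to the true matrix, weight and alpha errors, and
    branch-length errors.  Also reports the SAD between the replicate-mean
    estimated matrix and the truth, which shrinks with averaging when the
    estimator is consistent.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    options = options or FitOptions()
    true_S = generating.S
    true_w = generating.mixture.weights
    true_alpha = generating.rates.alpha
    true_blens = generating.tree.branch_lengths()

    sads, w_err, a_err, b_err, fits = [], [], [], [], []
    monotone = True
    mats = []
    for rep in range(n_replicates):
        sim_spec = replace(generating, seed=int(generating.seed) + 10_000 * rep)
        sim = simulate_alignment(sim_spec)
        model = MixtureModelSpec(generating.S, generating.mixture,
                                 generating.rates, generating.tree.copy())
        fit = fit_joint(sim.alignment, model, options)
        fits.append(fit)
        sads.append(sad(fit.S_hat, true_S))
        mats.append(fit.S_hat.entries / fit.S_hat.upper_triangle().sum())
        w_err.append(fit.weights_hat - true_w)
        a_err.append(np.nan if (fit.alpha_hat is None or true_alpha is None)
                     else fit.alpha_hat - true_alpha)
        b_err.append(fit.branch_lengths_hat - true_blens)
        trace = np.asarray(fit.loglik_trace)
        if np.any(np.diff(trace) < -1e-6):
            monotone = False
    mean_matrix = ExchangeabilityMatrix(np.mean(mats, axis=0), name="mean")
    start = options.initial_matrix(generating.S)
    return RecoverySummary(
        sad_values=np.array(sads),
        sad_start=sad(start, true_S),
        weight_errors=np.array(w_err),
        alpha_errors=np.array(a_err),
        branch_errors=np.array(b_err),
        mean_matrix=mean_matrix,
        sad_mean_matrix=sad(mean_matrix, true_S),
        traces_monotone=monotone,
        fits=fits,
    )
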