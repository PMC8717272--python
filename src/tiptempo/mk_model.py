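"""Mk (k-state continuous-time Markov) models of discrete trait evolution.

Provides rate-matrix construction for the ER / SYM / ARD parameterizations,
transition probabilities, the pruning (post-order) likelihood on a dated
tree, maximum-likelihood fitting with multi-start optimization on the
log-rate scale, and AIC-based model comparison between SYM and ARD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .tree_io import PhyloTree

__all__ = [
    "RateMatrix",
    "MkFit",
    "ModelSelection",
    "n_free_rates",
    "build_rate_matrix",
    "transition_probabilities",
    "branch_transition_matrices",
    "log_likelihood",
    "fit_mk",
    "compare_models",
]

MODELS = ("ER", "SYM", "ARD")


def n_free_rates(model: str, k: int) -> int:
    """Number of free rate parameters for a model class with k states."""
    if model == "ER":
        return 1
    if model == "SYM":
        return k * (k - 1) // 2
    if model == "ARD":
        return k * (k - 1)
    raise ValueError(f"unknown model class: {model!r}")


@dataclass
class RateMatrix:
    """A k-state instantaneous rate matrix (rates per Ma).

    Off-diagonal entries are non-negative, rows sum to zero.  ER has a
    single shared rate, SYM a symmetric off-diagonal (k(k-1)/2 free
    rates), ARD all k(k-1) rates free.
    """

    Q: np.ndarray
    model: str
    params: np.ndarray
    state_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.params = np.asarray(self.params, dtype=float)
        k = self.k
        if not self.state_labels:
            self.state_labels = tuple(str(i) for i in range(k))
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("negative off-diagonal rate")
        scale = max(1.0, float(np.abs(self.Q).max()))
        if np.max(np.abs(self.Q.sum(axis=1))) > 1e-10 * scale:
            raise ValueError("rate-matrix rows must sum to zero")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.Q, self.Q.T))

    def stationary_distribution(self) -> np.ndarray:
        """Left null vector of Q, normalized (uniform for ER/SYM)."""
        if self.is_symmetric:
            return np.full(self.k, 1.0 / self.k)
        ns = scipy.linalg.null_space(self.Q.T)
        if ns.shape[1] == 0:
            raise np.linalg.LinAlgError("no stationary distribution found")
        pi = np.abs(ns[:, 0])
        return pi / pi.sum()


def build_rate_matrix(params, model: str, k: int,
                      state_labels: tuple[str, ...] = ()) -> RateMatrix:
    """Assemble a RateMatrix from its free-rate vector.

    SYM parameters fill the upper triangle row-wise and are mirrored;
    ARD parameters fill the off-diagonal row-wise.
    """
    params = np.asarray(params, dtype=float)
    expected = n_free_rates(model, k)
    if params.shape != (expected,):
        raise ValueError(
            f"{model} with k={k} needs {expected} rates, got {params.shape}")
    if np.any(params < 0):
        raise ValueError("rates must be non-negative")
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = params[0]
    elif model == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = params
        Q.T[iu] = params
    else:  # ARD
        mask = ~np.eye(k, dtype=bool)
        Q[mask] = params
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q=Q, model=model, params=params,
                      state_labels=state_labels)


def transition_probabilities(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt): the k x k transition kernel over a duration t >= 0."""
    if t < 0:
        raise ValueError(f"duration must be non-negative, got {t}")
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, float)
    P = scipy.linalg.expm(Qm * t)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def branch_transition_matrices(Q: RateMatrix, durations: np.ndarray) -> np.ndarray:
    """exp(Q t) for a whole vector of durations at once.

    Symmetric matrices (ER/SYM) go through a single eigendecomposition;
    ARD falls back to a general eigendecomposition with an expm fallback
    when the eigenvector basis is ill-conditioned.  Returns an array of
    shape (len(durations), k, k).
    """
    t = np.asarray(durations, dtype=float)
    if np.any(t < 0):
        raise ValueError("durations must be non-negative")
    k = Q.k
    if Q.is_symmetric:
        lam, U = scipy.linalg.eigh(Q.Q)
        E = np.exp(np.outer(t, lam))                       # (m, k)
        P = np.einsum("ij,mj,lj->mil", U, E, U)
    else:
        lam, U = scipy.linalg.eig(Q.Q)
        try:
            Ui = np.linalg.inv(U)
            cond = np.linalg.cond(U)
        except np.linalg.LinAlgError:
            cond = np.inf
        if cond < 1e8:
            E = np.exp(np.outer(t, lam))
            P = np.einsum("ij,mj,jl->mil", U, E, Ui).real
        else:
            P = np.stack([scipy.linalg.expm(Q.Q * ti) for ti in t])
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


@dataclass
class MkFit:
    """Result of a maximum-likelihood Mk fit."""

    rate_matrix: RateMatrix
    log_likelihood: float
    aic: float
    root_prior: np.ndarray
    converged: bool
    n_tips: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if np.any(self.root_prior < 0) or abs(self.root_prior.sum() - 1) > 1e-12:
            raise ValueError("root prior must be a probability vector")

    def report(self) -> str:
        """Plain-text key/value dump of the fit."""
        rm = self.rate_matrix
        lines = [
            f"model = {rm.model}",
            f"k = {rm.k}",
            f"states = {','.join(rm.state_labels)}",
            f"logL = {self.log_likelihood:.10g}",
            f"AIC = {self.aic:.10g}",
            f"converged = {self.converged}",
            f"root_prior = {','.join(f'{p:.10g}' for p in self.root_prior)}",
        ]
        for i in range(rm.k):
            lines.append("Q[%d] = %s" % (i, ",".join(f"{q:.10g}" for q in rm.Q[i])))
        return "\n".join(lines) + "\n"


def _encode_tip_states(tree: PhyloTree, tip_states: dict[str, int], k: int
                       ) -> np.ndarray:
    """Per-node one-hot (tips) / all-ones (internal) conditional array."""
    L = np.ones((tree.n_nodes, k))
    for nid, lab in tree.tip_label.items():
        if lab not in tip_states:
            raise ValueError(f"missing tip state for {lab!r}")
        s = int(tip_states[lab])
        if not 0 <= s < k:
            raise ValueError(f"tip state {s} for {lab!r} outside [0,{k})")
        L[nid] = 0.0
        L[nid, s] = 1.0
    return L


def _pruning_partials(tree: PhyloTree, tip_states: dict[str, int],
                      Q: RateMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Post-order conditional likelihoods with per-node rescaling.

    Returns (partials, P, log_scale): partials[v] is the scaled
    conditional likelihood of the data below node v given its state,
    P[v] the transition matrix on the branch above v, and log_scale the
    accumulated log of the scaling factors.
    """
    k = Q.k
    partials = _encode_tip_states(tree, tip_states, k)
    P = branch_transition_matrices(Q, tree.branch_length)
    log_scale = 0.0
    for v in range(tree.n_nodes - 1, -1, -1):
        kids = tree.children[v]
        if not kids:
            continue
        acc = partials[v].copy()  # ones for internal nodes
        for c in kids:
            acc *= P[c] @ partials[c]
        m = acc.max()
        if m <= 0:
            raise ValueError(
                f"zero conditional likelihood at node {v}: tip configuration "
                "impossible under this rate matrix")
        partials[v] = acc / m
        log_scale += np.log(m)
    return partials, P, log_scale


def log_likelihood(tree: PhyloTree, tip_states: dict[str, int],
                   Q: RateMatrix, root_prior: np.ndarray) -> float:
    """Pruning log-likelihood of tip states under Q with the given root prior."""
    root_prior = np.asarray(root_prior, dtype=float)
    partials, _, log_scale = _pruning_partials(tree, tip_states, Q)
    lik = float(root_prior @ partials[tree.root])
    if lik <= 0:
        raise ValueError("zero likelihood at root")
    return np.log(lik) + log_scale


@dataclass
class ModelSelection:
    chosen: str
    delta_aic: float
    aic: dict[str, float] = field(default_factory=dict)


def fit_mk(tree: PhyloTree, tip_states: dict[str, int], model: str,
           root_prior_mode: str = "stationary", k: int | None = None,
           n_starts: int = 5, tol: float = 1e-8, seed: int = 0,
           state_labels: tuple[str, ...] = ()) -> MkFit:
    """Maximum-likelihood Mk fit with multi-start optimization.

    Rates are optimized on the log scale (they span orders of magnitude
    and the ARD surface can be multimodal); ``n_starts`` dispersed
    starting points are used and the best optimum kept.  The root prior
    is the stationary distribution of the fitted Q by default, or flat.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model class: {model!r}")
    if root_prior_mode not in ("stationary", "flat"):
        raise ValueError(f"unknown root prior mode: {root_prior_mode!r}")
    observed = {int(tip_states[lab]) for lab in tree.tip_label.values()
                if lab in tip_states}
    missing = [lab for lab in tree.tip_label.values() if lab not in tip_states]
    if missing:
        raise ValueError(f"missing tip states for: {sorted(missing)[:5]}")
    if len(observed) < 2:
        raise ValueError(
            "need at least 2 distinct observed states to identify rates")
    if k is None:
        k = max(observed) + 1
    npar = n_free_rates(model, k)
    rng = np.random.default_rng(seed)

    # crude rate scale: at least one change implied per distinct state,
    # spread over the whole tree length
    base = max(len(observed) - 1, 1) / max(tree.total_length, 1e-9)

    def neg_ll(log_rates: np.ndarray) -> float:
        Q = build_rate_matrix(np.exp(log_rates), model, k, state_labels)
        prior = (Q.stationary_distribution() if root_prior_mode == "stationary"
                 else np.full(k, 1.0 / k))
        try:
            return -log_likelihood(tree, tip_states, Q, prior)
        except (ValueError, np.linalg.LinAlgError):
            return 1e10

    # Rates are bounded above at ~100 expected changes on an average
    # branch: past that the likelihood sits on its saturation plateau
    # (transition rows ~ stationary), so the cap loses no information
    # while keeping downstream path simulation tractable.
    mean_edge = max(tree.total_length / max(tree.n_nodes - 1, 1), 1e-9)
    log_ub = np.log(100.0 / mean_edge)
    factors = [1.0, 0.1, 10.0, 0.01, 3.0]
    best = None
    f0_best = np.inf
    for i in range(n_starts):
        x0 = np.full(npar, np.log(base * factors[i % len(factors)]))
        if i >= len(factors) or npar > 1:
            x0 = x0 + rng.normal(0.0, 0.5 if i < len(factors) else 1.5, npar)
        x0 = np.minimum(x0, log_ub)
        f0 = neg_ll(x0)
        f0_best = min(f0_best, f0)
        res = scipy.optimize.minimize(
            neg_ll, x0, method="L-BFGS-B",
            bounds=[(np.log(1e-9), log_ub)] * npar,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(
            f"Mk optimization failed on all {n_starts} starts: {best.message}")
    rates = np.exp(best.x)
    Q = build_rate_matrix(rates, model, k, state_labels)
    prior = (Q.stationary_distribution() if root_prior_mode == "stationary"
             else np.full(k, 1.0 / k))
    logL = -float(best.fun)
    converged = bool(best.success) and logL >= -f0_best - 1e-6
    return MkFit(rate_matrix=Q, log_likelihood=logL,
                 aic=2.0 * npar - 2.0 * logL, root_prior=prior,
                 converged=converged, n_tips=tree.n_tips,
                 message=str(best.message))


def compare_models(fit_sym: MkFit, fit_ard: MkFit) -> ModelSelection:
    """Pick the lower-AIC model; ties go to the fewer-parameter (SYM) fit."""
    if fit_sym.rate_matrix.k != fit_ard.rate_matrix.k or \
            fit_sym.n_tips != fit_ard.n_tips:
        raise ValueError("fits compare different data shapes")
    aic = {"SYM": fit_sym.aic, "ARD": fit_ard.aic}
    delta = abs(aic["SYM"] - aic["ARD"])
    chosen = "ARD" if aic["ARD"] < aic["SYM"] else "SYM"
    return ModelSelection(chosen=chosen, delta_aic=delta, aic=aic)
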