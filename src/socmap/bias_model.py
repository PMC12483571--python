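"""Semantic-bias clustering model of drag-and-drop placements.

The model treats a participant's 2D arrangement of network members as the
outcome of a biased clustering process over semantic attributes.  Each
student i carries an attribute vector D_i in R^3: trait valence (anchored at
"Smiley"), club athleticism (anchored at "Running") and a binary centrality
indicator (bridged topology only).  A binary condition tensor C marks, for
each pair (i, j), whether both students have positive-valence traits
(k = 1), whether both attend physical/athletic clubs (k = 2) and whether at
least one is a central node (k = 3).

The pairwise similarity kernel is a factorized squared exponential

    f(D_i, D_j, C_ij) = prod_k exp(-[C_ijk * beta_k + (1 - C_ijk) * beta_hat_k]
                                   * (D_ik - D_jk)^2)          for i != j

and f = alpha on the diagonal, where alpha is a dispersion parameter (the
tendency to treat a student as a singleton with no close associates).
Row-normalizing f yields the probability of assigning student i to the same
group as student j; the self term (alpha) stays in the denominator.

A participant's layout is converted into an empirical inverse-distance
probability distribution (closer placements = higher judged friendship
likelihood) and parameters are fitted by minimizing the Kullback-Leibler
divergence between the empirical distribution and the model's off-diagonal
assignment probabilities, in log-parameter space with a trust-region
quasi-Newton method.  A leave-one-student-out protocol compares the biased
model against an unbiased variant that shares a single beta across all
attributes and both condition states.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import spatial, stats

from socmap.design import SocialNetwork
from socmap.exceptions import ConfigurationError, StructuralError

Variant = Literal["biased", "unbiased"]

#: probability floor used inside logarithms
PROB_FLOOR = 1e-12
#: distance floor (box units) for the empirical inverse-distance distribution
DIST_EPS = 1e-6
#: bounds for log-parameters during optimization
LOG_BOUNDS = (-12.0, 8.0)


# ---------------------------------------------------------------------------
# attribute matrix and condition tensor
# ---------------------------------------------------------------------------

def attribute_matrix(net: SocialNetwork) -> np.ndarray:
    """N x 3 attribute matrix D.

    Column 0: node trait-valence score (mean of the node's two edge traits,
    since traits are attached to friendships but D is per student).
    Column 1: node club-athleticism score.  Column 2: centrality indicator
    (all zero for the ring topology).
    """
    t = [net.node_trait_score(v) for v in net.nodes]
    c = [net.node_context_score(v) for v in net.nodes]
    z = [1.0 if v in net.central_nodes else 0.0 for v in net.nodes]
    return np.column_stack([t, c, z])


def condition_tensor(net: SocialNetwork) -> np.ndarray:
    """N x N x 3 binary condition tensor C (symmetric in i, j).

    C[i, j, 0] = both students have positive-valence traits;
    C[i, j, 1] = both attend physical (athletic) clubs;
    C[i, j, 2] = at least one of the two is a central node (zero slice for
    the ring).
    """
    D = attribute_matrix(net)
    pos = D[:, 0] > 0
    ath = D[:, 1] > 0
    cen = D[:, 2] > 0
    n = len(net.nodes)
    C = np.zeros((n, n, 3))
    C[:, :, 0] = np.outer(pos, pos)
    C[:, :, 1] = np.outer(ath, ath)
    C[:, :, 2] = cen[:, None] | cen[None, :]
    return C


def active_mask_for(net: SocialNetwork) -> np.ndarray:
    """Default active bias dimensions: (trait, context) for the ring,
    (trait, context, centrality) for the bridged topology."""
    if net.central_nodes:
        return np.array([True, True, True])
    return np.array([True, True, False])


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class BiasParams:
    """Positive per-dimension biases and the dispersion parameter.

    ``beta[k]`` scales the squared attribute difference along dimension k
    when the shared-condition indicator C_ijk is 1; ``beta_hat[k]`` applies
    when it is 0.  On the log scale, log(beta) = 0 is neutral, > 0 expands
    (over-weights) the dimension and < 0 compresses it.  ``alpha`` is the
    self-similarity (singleton) weight.  Dimensions with ``active_mask``
    False are ignored by the kernel.
    """

    beta: np.ndarray
    beta_hat: np.ndarray
    alpha: float
    active_mask: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([True, True, False])
    )

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        act = self.active_mask
        if np.any(self.beta[act] < 0) or np.any(self.beta_hat[act] < 0):
            raise ConfigurationError("active biases must be non-negative")


@dataclass
class ProbMatrix:
    """Row-stochastic assignment probabilities.

    ``kind == 'model'`` rows include the diagonal self term (alpha mass);
    ``kind == 'empirical'`` rows have zero diagonal and are normalized over
    the off-diagonal entries.
    """

    P: np.ndarray
    kind: Literal["model", "empirical"]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-10):
            raise StructuralError("rows must sum to 1")
        if self.kind == "empirical" and np.any(np.diag(self.P) != 0):
            raise StructuralError("empirical matrix must have zero diagonal")


# ---------------------------------------------------------------------------
# kernel and probabilities
# ---------------------------------------------------------------------------

def _f_matrix(D: np.ndarray, C: np.ndarray, params: BiasParams) -> np.ndarray:
    """Pairwise similarity matrix (diagonal = alpha)."""
    act = np.flatnonzero(params.active_mask)
    diff2 = (D[:, None, :] - D[None, :, :]) ** 2
    expo = np.zeros(C.shape[:2])
    for k in act:
        rate = C[:, :, k] * params.beta[k] + (1 - C[:, :, k]) * params.beta_hat[k]
        expo -= rate * diff2[:, :, k]
    f = np.exp(expo)
    np.fill_diagonal(f, params.alpha)
    return f


def similarity_f(
    D_i: np.ndarray,
    D_j: np.ndarray,
    C_ij: np.ndarray,
    params: BiasParams,
    same: bool = False,
) -> float:
    """Factorized squared-exponential similarity for one pair.

    Returns alpha when ``same`` is True (the i = j branch).
    """
    if same:
        return float(params.alpha)
    D_i = np.asarray(D_i, dtype=float)
    D_j = np.asarray(D_j, dtype=float)
    C_ij = np.asarray(C_ij, dtype=float)
    act = np.flatnonzero(params.active_mask)
    out = 1.0
    for k in act:
        rate = C_ij[k] * params.beta[k] + (1 - C_ij[k]) * params.beta_hat[k]
        out *= float(np.exp(-rate * (D_i[k] - D_j[k]) ** 2))
    return out


def assignment_probs(D: np.ndarray, C: np.ndarray, params: BiasParams) -> ProbMatrix:
    """Row-normalized assignment probabilities P(c_i = j | D, C, theta).

    The normalizer includes the self term f(i, i) = alpha, so each row sums
    to 1 over all N columns including the diagonal.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] < 2:
        raise ConfigurationError("need at least two students")
    f = _f_matrix(D, C, params)
    S = f.sum(axis=1, keepdims=True)
    if np.any(S <= 0) or not np.all(np.isfinite(S)):
        raise StructuralError("degenerate similarity row")
    return ProbMatrix(P=f / S, kind="model")


def empirical_probs(pm, epsilon: float = DIST_EPS) -> ProbMatrix:
    """Inverse-distance empirical distribution over a participant's layout.

    P_ij is proportional to 1 / max(d(S_i, S_j), epsilon) for j != i, row
    normalized over the off-diagonal; the diagonal is zero.
    """
    coords = pm.coords if hasattr(pm, "coords") else np.asarray(pm, dtype=float)
    d = spatial.distance_matrix(coords, coords)
    off = ~np.eye(len(coords), dtype=bool)
    if epsilon <= 0 and np.any(d[off] == 0):
        raise StructuralError("coincident placements require epsilon > 0")
    inv = np.zeros_like(d)
    inv[off] = 1.0 / np.maximum(d[off], epsilon)
    return ProbMatrix(P=inv / inv.sum(axis=1, keepdims=True), kind="empirical")


def kl_rows(emp: ProbMatrix, model: ProbMatrix) -> float:
    """Row-summed KL divergence of empirical from model probabilities.

    Computed over off-diagonal entries only (the empirical distribution has
    no self term) while the model keeps its alpha mass in the denominator;
    0 * log 0 = 0 and model entries are floored at 1e-12 inside the log.
    """
    E, M = emp.P, model.P
    if E.shape != M.shape:
        raise StructuralError("shape mismatch")
    off = ~np.eye(len(E), dtype=bool)
    e = E[off]
    m = np.maximum(M[off], PROB_FLOOR)
    mask = e > 0
    return float(np.sum(e[mask] * (np.log(e[mask]) - np.log(m[mask]))))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: BiasParams
    variant: Variant
    final_kl: float
    init_kl: float
    n_iter: int
    converged: bool
    participant_id: str = ""


def _n_free(variant: Variant, active_mask: np.ndarray) -> int:
    if variant == "unbiased":
        return 2
    return 2 * int(np.sum(active_mask)) + 1


def _unpack(x: np.ndarray, variant: Variant, active_mask: np.ndarray) -> BiasParams:
    act = np.flatnonzero(active_mask)
    beta = np.zeros(3)
    beta_hat = np.zeros(3)
    if variant == "unbiased":
        beta[act] = beta_hat[act] = np.exp(x[0])
        alpha = float(np.exp(x[1]))
    else:
        m = len(act)
        beta[act] = np.exp(x[:m])
        beta_hat[act] = np.exp(x[m : 2 * m])
        alpha = float(np.exp(x[2 * m]))
    return BiasParams(beta=beta, beta_hat=beta_hat, alpha=alpha, active_mask=active_mask)


class _KLProblem:
    """Precomputed structure for KL fitting of one (E, D, C) instance.

    In log-parameter space x = (log beta..., log beta_hat..., log alpha) the
    objective decomposes as

        KL(x) = sum e log e  -  sum_{i, j != i} e_ij log f_ij  +  sum_i log S_i

    because empirical rows sum to one.  With M_a the fixed nonnegative
    matrix multiplying parameter a in -log f (condition-gated squared
    attribute differences) the per-entry derivative of log f with respect to
    x_a is G^a = -exp(x_a) M_a, giving analytic gradient and Hessian in a
    handful of N x N products.
    """

    def __init__(self, E, D, C, variant: Variant, active_mask: np.ndarray):
        self.E = E
        n = len(D)
        self.n = n
        act = np.flatnonzero(active_mask)
        diff2 = (D[:, None, :] - D[None, :, :]) ** 2
        Ms = []
        if variant == "unbiased":
            M = np.zeros((n, n))
            for k in act:
                M += diff2[:, :, k]  # shared beta: both condition states
            Ms.append(M)
        else:
            for k in act:
                Ms.append(C[:, :, k] * diff2[:, :, k])
            for k in act:
                Ms.append((1 - C[:, :, k]) * diff2[:, :, k])
        for M in Ms:
            np.fill_diagonal(M, 0.0)
        self.Ms = Ms
        self.n_free = len(Ms) + 1
        mask = E > 0
        self._e_log_e = float(np.sum(E[mask] * np.log(E[mask])))
        self._diag = np.eye(n, dtype=bool)

    def value_grad_hess(self, x: np.ndarray, want_hess: bool = True):
        rates = np.exp(x[:-1])
        alpha = float(np.exp(x[-1]))
        expo = np.zeros((self.n, self.n))
        for r, M in zip(rates, self.Ms):
            expo -= r * M
        f = np.exp(expo)
        f[self._diag] = alpha
        S = f.sum(axis=1, keepdims=True)
        P = f / S
        E = self.E
        kl = self._e_log_e - float(np.sum(E * expo)) + float(np.log(S).sum())

        W = P - E                      # E has zero diagonal; P keeps alpha mass
        Gs = [-r * M for r, M in zip(rates, self.Ms)]
        diagP = np.diag(P)
        g = np.array([float(np.sum(W * G)) for G in Gs] + [float(diagP.sum())])
        if not want_hess:
            return kl, g, None

        nf = self.n_free
        H = np.zeros((nf, nf))
        rs = [np.sum(P * G, axis=1) for G in Gs] + [diagP]
        for a in range(nf - 1):
            for b in range(a, nf - 1):
                H[a, b] = float(np.sum(P * Gs[a] * Gs[b]) - rs[a] @ rs[b])
                H[b, a] = H[a, b]
            H[a, a] += g[a]            # d2(log f)/dx_a^2 = G^a for beta terms
            H[a, -1] = H[-1, a] = float(-rs[a] @ diagP)  # G^alpha diag-only
        H[-1, -1] = float(diagP.sum() - diagP @ diagP)   # log alpha exactly linear
        return kl, g, H


def _kl_and_grad(
    x: np.ndarray,
    E: np.ndarray,
    D: np.ndarray,
    C: np.ndarray,
    variant: Variant,
    active_mask: np.ndarray,
):
    """KL objective and analytic gradient (scipy-compatible signature)."""
    prob = _KLProblem(E, D, C, variant, active_mask)
    kl, g, _ = prob.value_grad_hess(np.asarray(x, dtype=float), want_hess=False)
    return kl, g


def _newton_tr(prob: _KLProblem, x0: np.ndarray, max_iter: int, gtol: float):
    """Damped-Newton minimization with an adaptive trust parameter.

    Solves (H + lam I) p = -g each step; lam shrinks on accepted steps and
    grows on rejected ones, interpolating between Newton and gradient
    descent (a Levenberg-style trust region).  Iterates are kept inside the
    log-parameter box.
    """
    lo, hi = LOG_BOUNDS
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    f, g, H = prob.value_grad_hess(x)
    lam = 1e-3
    nf = len(x)
    n_iter = 0

    def kkt_norm(x, g):
        # projected gradient: components pinned at an active bound don't count
        gp = g.copy()
        gp[(x <= lo + 1e-9) & (g > 0)] = 0.0
        gp[(x >= hi - 1e-9) & (g < 0)] = 0.0
        return np.linalg.norm(gp, ord=np.inf)

    for n_iter in range(1, max_iter + 1):
        if kkt_norm(x, g) < gtol:
            return x, f, n_iter, True
        accepted = False
        for _ in range(25):
            try:
                p = np.linalg.solve(H + lam * np.eye(nf), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            x_new = np.clip(x + p, lo, hi)
            f_new, g_new, H_new = prob.value_grad_hess(x_new)
            if np.isfinite(f_new) and f_new <= f:
                x, f, g, H = x_new, f_new, g_new, H_new
                lam = max(lam * 0.3, 1e-10)
                accepted = True
                break
            lam *= 4.0
        if not accepted:
            return x, f, n_iter, kkt_norm(x, g) < 1e2 * gtol
    return x, f, n_iter, kkt_norm(x, g) < gtol


def fit(
    pm,
    D: np.ndarray,
    C: np.ndarray,
    variant: Variant = "biased",
    active_mask: Optional[np.ndarray] = None,
    init: Optional[np.ndarray] = None,
    seed: int = 0,
    n_starts: int = 1,
    max_iter: int = 200,
    gtol: float = 1e-8,
) -> FitResult:
    """Fit bias parameters to one participant's placements by KL minimization.

    Optimization runs in log-parameter space (positivity by construction)
    with a Newton method under an adaptive trust damping, using analytic
    gradients and Hessians.  ``n_starts`` seeded restarts guard against
    local minima; the best final KL is returned and never exceeds the KL at
    the (first) initialization.  The unbiased variant has exactly two free
    parameters (shared log-beta and log-alpha); the biased variant has
    2 * (number of active dimensions) + 1.
    """
    if active_mask is None:
        active_mask = np.array([True, True, False])
    active_mask = np.asarray(active_mask, dtype=bool)
    emp = pm if isinstance(pm, ProbMatrix) else empirical_probs(pm)
    E = emp.P
    nf = _n_free(variant, active_mask)
    rng = np.random.default_rng(seed)

    x0s = []
    if init is not None:
        x0s.append(np.asarray(init, dtype=float))
    else:
        x0s.append(np.zeros(nf))
    while len(x0s) < n_starts:
        x0s.append(rng.normal(scale=1.0, size=nf))

    prob = _KLProblem(E, D, C, variant, active_mask)
    init_kl, _, _ = prob.value_grad_hess(
        np.clip(x0s[0], *LOG_BOUNDS), want_hess=False
    )
    best = None
    total_iter = 0
    for x0 in x0s:
        x, f, n_iter, ok = _newton_tr(prob, x0, max_iter=max_iter, gtol=gtol)
        total_iter += n_iter
        if best is None or f < best[1]:
            best = (x, f, ok)
    x_best, final_kl, converged = best
    if final_kl > init_kl:  # failed to improve on the start point: keep it
        x_best, final_kl, converged = np.clip(x0s[0], *LOG_BOUNDS), float(init_kl), False
    return FitResult(
        params=_unpack(x_best, variant, active_mask),
        variant=variant,
        final_kl=float(final_kl),
        init_kl=float(init_kl),
        n_iter=total_iter,
        converged=bool(converged),
    )


# ---------------------------------------------------------------------------
# leave-one-student-out model comparison
# ---------------------------------------------------------------------------

@dataclass
class LooResult:
    delta_kl: np.ndarray          # per participant, mean over held-out students
    t_stat: float
    p_value: float                # one-sided: biased better (delta > 0)
    n_participants: int


def _held_out_kl(
    E_full: np.ndarray, P_model: np.ndarray, s: int
) -> float:
    """KL of the held-out student's empirical row under a full-N model."""
    n = len(E_full)
    e = E_full[s]
    m = np.maximum(P_model[s], PROB_FLOOR)
    mask = (np.arange(n) != s) & (e > 0)
    return float(np.sum(e[mask] * (np.log(e[mask]) - np.log(m[mask]))))


def loo_compare(
    pms: Sequence,
    D: np.ndarray,
    C: np.ndarray,
    active_mask: Optional[np.ndarray] = None,
    max_iter: int = 60,
    seed: int = 0,
) -> LooResult:
    """Leave-one-student-out comparison of biased vs unbiased variants.

    For each participant and each held-out student s, both variants are
    fitted on the sub-problem that excludes s's row and column, then
    evaluated on s's empirical row under assignment probabilities recomputed
    over the full network.  The per-participant score is the mean KL
    difference (unbiased - biased) over held-out students; a positive mean
    means the biased model generalizes better.  Returns the across-
    participant paired t statistic (one-sided p).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ConfigurationError("need at least 3 students to hold one out")
    if len(pms) < 2:
        raise ConfigurationError("need at least 2 participants")
    if active_mask is None:
        active_mask = np.array([True, True, False])

    deltas = np.zeros(len(pms))
    for p_idx, pm in enumerate(pms):
        coords = pm.coords if hasattr(pm, "coords") else np.asarray(pm, dtype=float)
        E_full = empirical_probs(coords).P
        d_s = []
        for s in range(n):
            keep = np.arange(n) != s
            sub_emp = empirical_probs(coords[keep])
            D_sub = D[keep]
            C_sub = C[np.ix_(keep, keep)]
            kls = {}
            for variant in ("biased", "unbiased"):
                fr = fit(
                    sub_emp, D_sub, C_sub, variant=variant,
                    active_mask=active_mask, seed=seed, max_iter=max_iter,
                    gtol=1e-6,
                )
                P_full = assignment_probs(D, C, fr.params).P
                kls[variant] = _held_out_kl(E_full, P_full, s)
            d_s.append(kls["unbiased"] - kls["biased"])
        deltas[p_idx] = np.mean(d_s)
    t, p = stats.ttest_1samp(deltas, 0.0, alternative="greater")
    return LooResult(
        delta_kl=deltas, t_stat=float(t), p_value=float(p),
        n_participants=len(pms),
    )


# ---------------------------------------------------------------------------
# relating fitted biases to recall
# ---------------------------------------------------------------------------

@dataclass
class BiasRecallReport:
    f_stats: dict
    p_values: dict
    pearson_r: float
    pearson_p: float
    subgroup_r: Optional[dict] = None
    flagged: bool = False


def bias_recall_regression(
    bias: np.ndarray,
    accuracy: np.ndarray,
    moderator: Optional[np.ndarray] = None,
) -> BiasRecallReport:
    """Linear model of friendship recall accuracy on a fitted log-bias.

    ``bias`` is the per-participant log bias of interest (typically the
    negative-trait bias log beta_hat_1); ``moderator`` an optional second
    log-bias (e.g. centrality) whose interaction with ``bias`` is added.
    When a moderator is given, subgroup Pearson correlations are reported
    after a median split (low/high moderator) for visualization parity.
    """
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm
    import pandas as pd

    bias = np.asarray(bias, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if np.ptp(bias) == 0 or np.ptp(accuracy) == 0:
        return BiasRecallReport({}, {}, float("nan"), float("nan"), flagged=True)

    df = pd.DataFrame({"acc": accuracy, "bias": bias})
    formula = "acc ~ bias"
    if moderator is not None:
        df["mod"] = np.asarray(moderator, dtype=float)
        formula = "acc ~ bias * mod"
    import statsmodels.formula.api as smf

    model = smf.ols(formula, data=df).fit()
    an = anova_lm(model, typ=2)
    f_stats = {t: float(an.loc[t, "F"]) for t in an.index if t != "Residual"}
    p_values = {t: float(an.loc[t, "PR(>F)"]) for t in an.index if t != "Residual"}
    r, rp = stats.pearsonr(bias, accuracy)

    subgroup = None
    if moderator is not None:
        med = np.median(df["mod"])
        lo = df["mod"] <= med
        subgroup = {}
        for label, sel in (("low", lo), ("high", ~lo)):
            if sel.sum() >= 3 and np.ptp(df.loc[sel, "bias"]) > 0:
                rr, _ = stats.pearsonr(df.loc[sel, "bias"], df.loc[sel, "acc"])
                subgroup[label] = float(rr)
            else:
                subgroup[label] = float("nan")
    return BiasRecallReport(
        f_stats=f_stats, p_values=p_values,
        pearson_r=float(r), pearson_p=float(rp), subgroup_r=subgroup,
    )
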