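"""State-dependent diversification of generalists vs specialists (BiSSE).

The binary-state speciation-extinction model couples a binary character
(0 = generalist, 1 = specialist) to the tree-generating process with six
rates: state-specific speciation (lambda_g, lambda_s), extinction
(mu_g, mu_s) and transitions (t_gs, t_sg).  The likelihood is computed by
postorder pruning, integrating for every branch the coupled ODEs

    dE_k/dt = mu_k - (lambda_k + mu_k + q_k) E_k + lambda_k E_k^2 + q_k E_j
    dD_k/dt = -(lambda_k + mu_k + q_k) D_k + 2 lambda_k E_k D_k + q_k D_j

from tip (t = 0, E = 0, D = tip-state indicator) to the branch's parent
node, multiplying D values of sister branches with the speciation rate at
every internal node (the root included) and weighting root states by
their conditional likelihoods.  Branches are integrated with fixed-step
RK4 (step bounded by 0.02 / total-rate) and per-branch renormalisation of
D against underflow.

The equal-rate limit factorises into a constant-rate birth-death tree
likelihood times a two-state Markov (Mk2) character likelihood; both have
closed forms and serve as the module's reference point
(:func:`bd_mk2_loglik`).

The two-step fit mirrors the standard protocol: step 1 constrains
lambda_g = lambda_s, mu_g = mu_s and symmetric transitions (3 free
parameters, started from a constant-rate birth-death fit); step 2 frees
all six rates, started from step 1's optimum, and the nested models are
compared with a chi-squared likelihood-ratio test on 3 degrees of
freedom.  Diversification potential DP = lambda + t - mu summarises each
state's capacity to generate diversity; by default t is the transition
rate INTO the focal state (the transition adds to that state's standing
diversity).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist, mannwhitneyu

from .containers import BisseFit

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# tree flattening
# ---------------------------------------------------------------------------

def tree_to_arrays(tree, states: dict):
    """Flatten a rooted bifurcating dendropy tree into postorder arrays.

    Returns (left, right, blen, tip_state) where internal nodes carry
    child indices and tips carry -1; ``tip_state`` is 0/1 for tips and
    -1 for internal nodes.  Node order is postorder, root last.
    """
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    left = np.full(n, -1, dtype=np.int64)
    right = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    tip_state = np.full(n, -1, dtype=np.int64)
    for i, nd in enumerate(nodes):
        kids = nd.child_nodes()
        if kids:
            if len(kids) != 2:
                raise ValueError("tree must be bifurcating")
            left[i] = index[id(kids[0])]
            right[i] = index[id(kids[1])]
        else:
            label = nd.taxon.label if nd.taxon else None
            if label not in states:
                raise ValueError(f"tip without state: {label}")
            tip_state[i] = int(states[label])
        blen[i] = nd.edge.length or 0.0
    if int((tip_state >= 0).sum()) < 2:
        raise ValueError("need >= 2 tips")
    return left, right, blen, tip_state


@njit(cache=True)
def _bisse_prune(left, right, blen, tip_state, params, max_dt):
    lam0, lam1, mu0, mu1, q01, q10 = params
    n = left.shape[0]
    E = np.zeros((n, 2))
    D = np.zeros((n, 2))
    logscale = 0.0
    for i in range(n):
        if tip_state[i] >= 0:
            E[i, 0] = 0.0
            E[i, 1] = 0.0
            D[i, tip_state[i]] = 1.0
        else:
            l, r = left[i], right[i]
            D[i, 0] = lam0 * D[l, 0] * D[r, 0]
            D[i, 1] = lam1 * D[l, 1] * D[r, 1]
            E[i, 0] = E[l, 0]
            E[i, 1] = E[l, 1]
        if i == n - 1:
            break  # root: no branch above
        T = blen[i]
        if T > 0.0:
            nsteps = int(T / max_dt) + 1
            if nsteps > 100000:
                nsteps = 100000
            h = T / nsteps
            e0, e1 = E[i, 0], E[i, 1]
            d0, d1 = D[i, 0], D[i, 1]
            for _ in range(nsteps):
                # RK4 on (e0, e1, d0, d1)
                a0, a1, b0, b1 = _deriv(e0, e1, d0, d1, lam0, lam1,
                                        mu0, mu1, q01, q10)
                k1 = (a0, a1, b0, b1)
                a0, a1, b0, b1 = _deriv(e0 + 0.5 * h * k1[0],
                                        e1 + 0.5 * h * k1[1],
                                        d0 + 0.5 * h * k1[2],
                                        d1 + 0.5 * h * k1[3],
                                        lam0, lam1, mu0, mu1, q01, q10)
                k2 = (a0, a1, b0, b1)
                a0, a1, b0, b1 = _deriv(e0 + 0.5 * h * k2[0],
                                        e1 + 0.5 * h * k2[1],
                                        d0 + 0.5 * h * k2[2],
                                        d1 + 0.5 * h * k2[3],
                                        lam0, lam1, mu0, mu1, q01, q10)
                k3 = (a0, a1, b0, b1)
                a0, a1, b0, b1 = _deriv(e0 + h * k3[0], e1 + h * k3[1],
                                        d0 + h * k3[2], d1 + h * k3[3],
                                        lam0, lam1, mu0, mu1, q01, q10)
                e0 += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + a0)
                e1 += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + a1)
                d0 += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + b0)
                d1 += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + b1)
            E[i, 0], E[i, 1] = e0, e1
            s = d0 + d1
            if s <= 0.0 or not np.isfinite(s):
                return -np.inf
            D[i, 0], D[i, 1] = d0 / s, d1 / s
            logscale += np.log(s)
    root = n - 1
    total = D[root, 0] + D[root, 1]
    if total <= 0.0 or not np.isfinite(total):
        return -np.inf
    # root weighting: state weights proportional to conditional likelihoods
    val = (D[root, 0] ** 2 + D[root, 1] ** 2) / total
    return np.log(val) + logscale


@njit(cache=True, inline="always")
def _deriv(e0, e1, d0, d1, lam0, lam1, mu0, mu1, q01, q10):
    de0 = mu0 - (lam0 + mu0 + q01) * e0 + lam0 * e0 * e0 + q01 * e1
    de1 = mu1 - (lam1 + mu1 + q10) * e1 + lam1 * e1 * e1 + q10 * e0
    dd0 = -(lam0 + mu0 + q01) * d0 + 2.0 * lam0 * e0 * d0 + q01 * d1
    dd1 = -(lam1 + mu1 + q10) * d1 + 2.0 * lam1 * e1 * d1 + q10 * d0
    return de0, de1, dd0, dd1


def bisse_loglik(tree, states: dict, params, dt_scale: float = 0.02) -> float:
    """Log-likelihood of (tree, tip states) under six BiSSE rates.

    ``params`` = (lambda_g, lambda_s, mu_g, mu_s, t_gs, t_sg); ``tree``
    may be a dendropy tree or a pre-flattened array tuple.
    """
    p = np.asarray(params, float)
    if p.shape != (6,) or (p < 0).any():
        raise ValueError("params must be six non-negative rates")
    if isinstance(tree, tuple):
        left, right, blen, tip_state = tree
    else:
        left, right, blen, tip_state = tree_to_arrays(tree, states)
    rate_scale = max(p[0] + p[2] + p[4], p[1] + p[3] + p[5], 1e-8)
    max_dt = dt_scale / rate_scale
    ll = _bisse_prune(left, right, blen, tip_state, p, max_dt)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite BiSSE likelihood "
                                 f"at params {p.tolist()}")
    return float(ll)


# ---------------------------------------------------------------------------
# closed-form equal-rate reference: birth-death x Mk2
# ---------------------------------------------------------------------------

def _bd_branch_logd(t, lam, mu):
    """log D(t) for a single surviving lineage under constant-rate BD."""
    r = lam - mu
    if abs(r) < 1e-12:
        return -2.0 * np.log1p(lam * t)
    ert = np.exp(r * t)
    return r * t + 2.0 * np.log(r) - 2.0 * np.log(lam * ert - mu)


def bd_loglik(tree_arrays, lam: float, mu: float) -> float:
    """Closed-form constant-rate birth-death tree log-likelihood using the
    same pruning conventions as the BiSSE code (speciation-rate factor at
    every internal node including the root, no survival conditioning).

    Requires an ultrametric tree: the per-lineage density D solves the
    same ODE everywhere, so the factor contributed by a branch spanning
    node ages [a, a + T] is D(a + T) / D(a) with D anchored at the
    present (D(0) = 1).
    """
    left, right, blen, tip_state = tree_arrays
    n = left.shape[0]
    age = np.zeros(n)
    ll = 0.0
    for i in range(n):
        if tip_state[i] < 0:
            age[i] = age[left[i]] + blen[left[i]]
        if i < n - 1:
            ll += (_bd_branch_logd(age[i] + blen[i], lam, mu)
                   - _bd_branch_logd(age[i], lam, mu))
    n_internal = int((tip_state < 0).sum())
    ll += n_internal * np.log(lam)
    return float(ll)


def mk2_loglik(tree_arrays, q01: float, q10: float) -> float:
    """Closed-form two-state Markov character log-likelihood by pruning,
    with root weights proportional to the conditional likelihoods."""
    left, right, blen, tip_state = tree_arrays
    n = left.shape[0]
    C = np.zeros((n, 2))
    logscale = 0.0
    s = q01 + q10
    for i in range(n):
        if tip_state[i] >= 0:
            C[i, tip_state[i]] = 1.0
        else:
            C[i] = C[left[i]] * C[right[i]]
        if i == n - 1:
            break
        t = blen[i]
        if s == 0:
            p00 = p11 = 1.0
        else:
            est = np.exp(-s * t)
            p00 = (q10 + q01 * est) / s
            p11 = (q01 + q10 * est) / s
        c0 = p00 * C[i, 0] + (1.0 - p11) * C[i, 1]
        c1 = (1.0 - p00) * C[i, 0] + p11 * C[i, 1]
        C[i, 0], C[i, 1] = c0, c1
        tot = c0 + c1
        if tot <= 0:
            return -np.inf
        C[i] /= tot
        logscale += np.log(tot)
    root = n - 1
    tot = C[root].sum()
    return float(np.log((C[root] ** 2).sum() / tot) + logscale)


def bd_mk2_loglik(tree, states: dict, lam: float, mu: float, q: float,
                  ) -> float:
    """Equal-rate BiSSE factorisation: BD tree term + symmetric Mk2 term."""
    arrays = tree_to_arrays(tree, states) if not isinstance(tree, tuple) \
        else tree
    return bd_loglik(arrays, lam, mu) + mk2_loglik(arrays, q, q)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _bd_starting_point(arrays) -> tuple[float, float]:
    """Constant-rate birth-death ML fit of the tree alone."""
    def nll(logp):
        lam, mu = np.exp(logp)
        return -bd_loglik(arrays, lam, mu)
    left, right, blen, tip_state = arrays
    n_tips = int((tip_state >= 0).sum())
    total_len = float(blen.sum())
    lam0 = max(n_tips / max(total_len, 1e-8), 1e-3)
    best = None
    for mu_frac in (0.1, 0.5):
        res = minimize(nll, np.log([lam0, mu_frac * lam0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    lam, mu = np.exp(best.x)
    return float(lam), float(mu)


def bisse_fit(tree, states: dict, n_starts: int = 3, seed: int = 0,
              dt_scale: float = 0.02) -> BisseFit:
    """Two-step constrained/full BiSSE maximum-likelihood fit.

    Step 1 fits (lambda, mu, t) with rates shared between states from a
    character-independent birth-death starting point; step 2 frees all
    six rates starting from step 1's optimum (plus jittered restarts)
    and the nested fits are compared with a chi-squared LRT (df = 3).
    """
    arrays = tree_to_arrays(tree, states)
    svals = set(states.values())
    if not {0, 1} <= {int(v) for v in svals}:
        raise ValueError("both states (0 and 1) must be present at the tips")
    rng = np.random.default_rng(seed)
    lam0, mu0 = _bd_starting_point(arrays)
    mu0 = max(mu0, 1e-4)
    q0 = max(lam0 / 10.0, 1e-4)

    def nll_con(logp):
        lam, mu, q = np.exp(logp)
        try:
            return -bisse_loglik(arrays, states, (lam, lam, mu, mu, q, q),
                                 dt_scale=dt_scale)
        except FloatingPointError:
            return 1e10

    res_con = minimize(nll_con, np.log([lam0, mu0, q0]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7,
                                "maxiter": 2000})
    lam_c, mu_c, q_c = np.exp(res_con.x)
    ll_con = -res_con.fun

    def nll_full(logp):
        p = np.exp(logp)
        try:
            return -bisse_loglik(arrays, states, p, dt_scale=dt_scale)
        except FloatingPointError:
            return 1e10

    x0 = np.log([lam_c, lam_c, mu_c, mu_c, q_c, q_c])
    best = None
    for k in range(n_starts):
        start = x0 if k == 0 else x0 + rng.normal(0, 0.3, size=6)
        res = minimize(nll_full, start, method="Nelder-Mead",
                       options={"xatol": 1e-5, "fatol": 1e-7,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    ll_full = -best.fun
    if ll_full < ll_con:       # nested models: full can only be better
        ll_full = ll_con
        best_x = x0
    else:
        best_x = best.x
    lam_g, lam_s, mu_g, mu_s, t_gs, t_sg = np.exp(best_x)

    stat = max(2.0 * (ll_full - ll_con), 0.0)
    df = 3
    pval = float(chi2_dist.sf(stat, df))
    dp_g = diversification_potential(lam_g, t_sg, mu_g)
    dp_s = diversification_potential(lam_s, t_gs, mu_s)
    return BisseFit(
        lambda_g=float(lam_g), lambda_s=float(lam_s),
        mu_g=float(mu_g), mu_s=float(mu_s),
        t_gs=float(t_gs), t_sg=float(t_sg),
        loglik_full=float(ll_full), loglik_constrained=float(ll_con),
        chi2_stat=float(stat), chi2_df=df, chi2_p=pval,
        dp_g=dp_g, dp_s=dp_s,
        dp_ratio=dp_s / dp_g if dp_g != 0 else float("nan"),
        dp_g_tout=diversification_potential(lam_g, t_gs, mu_g),
        dp_s_tout=diversification_potential(lam_s, t_sg, mu_s),
    )


def diversification_potential(lam: float, t_in: float, mu: float) -> float:
    """DP = lambda + t - mu (t = transition rate into the focal state)."""
    if lam < 0 or t_in < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    return float(lam + t_in - mu)


def dp_ratio(dp_s: float, dp_g: float) -> float:
    """Specialist-to-generalist diversification-potential ratio."""
    if dp_g == 0:
        raise ZeroDivisionError("dp_g is zero; ratio undefined")
    return float(dp_s / dp_g)


# ---------------------------------------------------------------------------
# branch lengths
# ---------------------------------------------------------------------------

def root_to_tip_lengths(tree, tips: list[str] | None = None) -> dict:
    """Sum of branch lengths from the root to each (selected) tip."""
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if tips is not None and label not in tips:
            continue
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        out[label] = d
    return out


def compare_branch_lengths(tree, states: dict) -> dict:
    """Median root-to-tip distance per state plus a rank-sum test."""
    dists = root_to_tip_lengths(tree)
    g = [d for t, d in dists.items() if states.get(t) == 0]
    s = [d for t, d in dists.items() if states.get(t) == 1]
    if not g or not s:
        raise ValueError("both states needed for a comparison")
    stat, p = mannwhitneyu(g, s, alternative="two-sided")
    return {"median_generalist": float(np.median(g)),
            "median_specialist": float(np.median(s)),
            "rank_sum_p": float(p), "n_generalist": len(g),
            "n_specialist": len(s)}
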