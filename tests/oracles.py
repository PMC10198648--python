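"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's numba kernel: branch integration
uses scipy's LSODA at tight tolerances, trait likelihoods use matrix
exponentials, and the constant-rate birth-death likelihood uses its
closed form.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm


def sse_rhs(t, y, lam, mu, qmat):
    n = len(lam)
    E, D = y[:n], y[n:]
    qrow = qmat.sum(axis=1)
    dE = mu - (lam + mu + qrow) * E + lam * E**2 + qmat @ E
    dD = -(lam + mu + qrow) * D + 2 * lam * E * D + qmat @ D
    return np.concatenate([dE, dD])


def integrate_branch_ref(E0, D0, lam, mu, qmat, length, rtol=1e-10, atol=1e-13):
    if length == 0:
        return np.array(E0), np.array(D0)
    sol = solve_ivp(
        sse_rhs,
        (0.0, length),
        np.concatenate([E0, D0]),
        args=(np.asarray(lam), np.asarray(mu), np.asarray(qmat)),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    assert sol.success
    y = sol.y[:, -1]
    n = len(lam)
    return y[:n], y[n:]


def loglik_ref(clade, params, rho, condition=True, root_weighting="fitzjohn",
               rtol=1e-10, atol=1e-13):
    """Dense-solver recursive reference log-likelihood."""
    sp = params.space
    n = sp.n_states
    lam, mu, qmat = params.lam, params.mu, params.q_matrix()
    rho = np.asarray(rho, dtype=float)
    exam = np.array([sp.examined_of(i) for i in range(n)])
    logscale = [0.0]

    def visit(node):
        children = node.child_nodes()
        if not children:
            obs = clade.tip_states[node.taxon.label][0]
            E = 1.0 - rho[exam]
            D = np.where(exam == obs, rho[obs], 0.0)
        else:
            (El, Dl), (Er, Dr) = (visit(c) for c in children)
            assert np.allclose(El, Er, atol=1e-6)
            E = (El + Er) / 2
            D = lam * Dl * Dr
            s = D.max()
            D = D / s
            logscale[0] += np.log(s)
        if node.parent_node is not None and node.edge.length:
            E, D = integrate_branch_ref(E, D, lam, mu, qmat, node.edge.length, rtol, atol)
        return E, D

    E, D = visit(clade.tree.seed_node)
    if root_weighting == "fitzjohn":
        w = D / D.sum()
    elif root_weighting == "equal":
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(root_weighting, dtype=float)
    if condition:
        lik = np.sum(w * D / (lam * (1.0 - E) ** 2))
    else:
        lik = np.sum(w * D)
    return np.log(lik) + logscale[0]


def bd_loglik_ref(clade, lam, mu, f, condition=True):
    """Closed-form constant-rate birth-death log-likelihood with sampling f.

    Single-state analogue of the SSE computation: per-branch propagation
    via p1(t), one lambda factor per internal node, crown conditioning by
    lambda (1 - E(T))^2.
    """
    r = lam - mu

    def p1(t):
        denom = f * lam + (lam * (1 - f) - mu) * np.exp(-r * t)
        return f * r**2 * np.exp(-r * t) / denom**2

    def E_of(t):
        denom = f * lam + (lam * (1 - f) - mu) * np.exp(-r * t)
        return 1.0 - f * r / denom

    clade.tree.calc_node_root_distances(return_leaf_distances_only=False)
    T = max(leaf.root_distance for leaf in clade.tree.leaf_node_iter())

    def visit(node):
        # depths are time-before-present; D propagates bottom -> top as p1 ratio
        children = node.child_nodes()
        if not children:
            logd = np.log(f)
        else:
            logd = np.log(lam) + sum(visit(c) for c in children)
        if node.parent_node is not None:
            depth_node = T - node.root_distance
            depth_parent = T - node.parent_node.root_distance
            logd += np.log(p1(depth_parent)) - np.log(p1(depth_node))
        return logd

    ll = visit(clade.tree.seed_node)
    if condition:
        ll -= np.log(lam * (1.0 - E_of(T)) ** 2)
    return ll


def mk_loglik_ref(clade, n_states, pair_rate, root_freqs=None):
    """Symmetric Mk likelihood of the examined tip states via expm pruning."""
    Q = np.full((n_states, n_states), pair_rate)
    np.fill_diagonal(Q, -(n_states - 1) * pair_rate)
    if root_freqs is None:
        root_freqs = np.full(n_states, 1.0 / n_states)

    def visit(node):
        children = node.child_nodes()
        if not children:
            obs = clade.tip_states[node.taxon.label][0]
            L = np.zeros(n_states)
            L[obs] = 1.0
        else:
            L = np.ones(n_states)
            for c in children:
                L = L * visit(c)
        if node.parent_node is not None and node.edge.length:
            L = expm(Q * node.edge.length) @ L
        return L

    L = visit(clade.tree.seed_node)
    return np.log(np.sum(root_freqs * L))
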