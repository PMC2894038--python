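"""Five estimators of the second-order variance decomposition (V_j, V_jj').

All estimators consume a response function R(w) of J independent zero-mean
Gaussian factors with standard deviations lambda_j and return a
:class:`~vbsa.variance.VarianceDecomposition`.  Counted system evaluations
match the closed-form budgets in :func:`vbsa.variance.evaluation_budget`
exactly -- no point is ever evaluated twice.

MC   Saltelli-style Latin-hypercube double-matrix design, 2L(J+1) evals.
DA   degree-4-exact central finite differences of a second-order Taylor
     surrogate at w=0, 2J(J+1)+1 evals.
PA   per-factor quadratic + per-pair bilinear-quartic polynomial regression
     on axis points and pair grids (cut-HDMR style), J(J-1)S^2/2 + JS + 1.
GHI  exact first/second-order cut-HDMR components on Gauss-Hermite nodes,
     expectations by Q-point quadrature, 2J(J-1)floor(Q/2)^2+2Jfloor(Q/2)+1.
OHA  global least-squares fit of an orthonormal-Hermite (polynomial chaos)
     surrogate on L Latin-hypercube samples, L evals.

Because cut-HDMR components (DA, PA, GHI surrogates) are anchored at w=0
rather than orthogonal under the Gaussian measure, pair components
contribute to one-factor conditional means; V_j and V_jj' are always
computed as Var[E[R~|W_j]] and Var[E[R~|W_j,W_j']] - V_j - V_j' of the
surrogate R~, which reduces to the familiar Gaussian-moment formulas for
the Taylor surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri, roots_hermitenorm

from .factors import as_response_function
from .variance import assemble_decomposition, evaluation_budget

_SQRT2 = np.sqrt(2.0)


def _sigmas(space):
    return np.asarray(getattr(space, "sigmas", space), dtype=float)


# ---------------------------------------------------------------------------
# sampling

def lhs_gaussian(L, sigmas, rng=None):
    """Latin hypercube sample of L points from N(0, diag(sigmas^2)).

    Per column, one uniform draw per probability stratum ((i-1+u)/L) in
    randomly permuted order, mapped through the Gaussian inverse CDF.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(rng)
    sigmas = _sigmas(sigmas)
    J = sigmas.size
    W = np.empty((L, J))
    for j in range(J):
        strata = rng.permutation(L)
        u = rng.random(L)
        W[:, j] = ndtri((strata + u) / L) * sigmas[j]
    return W


def mc_estimate(f, space, L, seed=None):
    """Monte Carlo estimate of (V_j, V_jj') from a double-matrix design.

    Two independent LHS matrices A, B plus the column-swapped hybrids
    A_B^(j) (A with column j from B) and B_A^(j), exactly 2L(J+1)
    evaluations.  With centered responses c = R - f0 (f0 the mean over
    A u B), the correlation identities of the design give direct
    estimators

        V_j   = (1/L) sum_l c(B)_l [c(A_B^(j)) - c(A)]_l
        V_jj' = (1/L) sum_l [c(B_A^(j)) - c(B)]_l [c(A_B^(j')) - c(A)]_l

    (each also evaluated with the A/B roles swapped and averaged).  The
    difference form subtracts the shared-coordinate lower-order effects in
    expectation, so the noise scales with the effect sizes rather than
    with the response mean -- essential when R has a large mean and small
    variance, as log-responses do.
    """
    sigmas = _sigmas(space)
    J = sigmas.size
    f = as_response_function(f, J)
    ss = np.random.SeedSequence(seed)
    child_a, child_b = ss.spawn(2)
    A = lhs_gaussian(L, sigmas, np.random.default_rng(child_a))
    B = lhs_gaussian(L, sigmas, np.random.default_rng(child_b))
    RA = f.batch(A)
    RB = f.batch(B)
    f0 = 0.5 * (RA.mean() + RB.mean())
    vtot = np.concatenate([RA, RB]).var()
    cA, cB = RA - f0, RB - f0

    c_AB = np.empty((J, L))   # centered R on A with column j from B
    c_BA = np.empty((J, L))   # centered R on B with column j from A
    for j in range(J):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        c_AB[j] = f.batch(ABj) - f0
        BAj = B.copy()
        BAj[:, j] = A[:, j]
        c_BA[j] = f.batch(BAj) - f0

    Vj = np.array([
        0.5 * (np.mean(cB * (c_AB[j] - cA)) + np.mean(cA * (c_BA[j] - cB)))
        for j in range(J)
    ])
    Vjj = np.zeros((J, J))
    for j in range(J):
        for jp in range(j + 1, J):
            v = 0.5 * (
                np.mean((c_BA[j] - cB) * (c_AB[jp] - cA))
                + np.mean((c_BA[jp] - cB) * (c_AB[j] - cA))
            )
            Vjj[j, jp] = Vjj[jp, j] = v
    return assemble_decomposition(
        Vj, Vjj, "mc", evaluation_budget("mc", J, L=L),
        meta={"L": L, "seed": seed, "f0": float(f0),
              "Vtot_estimate": float(vtot)},
    )


# ---------------------------------------------------------------------------
# derivative approximation

@dataclass
class DerivativeSurrogate:
    """Gradient and Hessian of R at w=0 plus the finite-difference step."""

    r0: float
    grad: np.ndarray
    hess: np.ndarray
    step: float


def finite_difference_derivatives(f, space, delta=0.1):
    """Degree-4-exact symmetric finite differences at w=0.

    Per factor: five-point stencils on +/-delta, +/-2*delta; per pair: the
    four-point cross stencil on (+/-delta, +/-delta).  2J(J+1)+1
    evaluations total.  A plain three-point design would cost 2J^2+1 but
    carries O(delta^2) error even on quartics; the five-point stencils are
    exact through degree 4.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    sigmas = _sigmas(space)
    J = sigmas.size
    f = as_response_function(f, J)
    r0 = f(np.zeros(J))
    grad = np.zeros(J)
    hess = np.zeros((J, J))
    d = float(delta)
    for j in range(J):
        def ax(x, j=j):
            w = np.zeros(J)
            w[j] = x
            return f(w)
        rp, rm = ax(d), ax(-d)
        rp2, rm2 = ax(2 * d), ax(-2 * d)
        grad[j] = (8.0 * (rp - rm) - (rp2 - rm2)) / (12.0 * d)
        hess[j, j] = (-rp2 + 16.0 * rp - 30.0 * r0 + 16.0 * rm - rm2) / (12.0 * d * d)
    for j in range(J):
        for jp in range(j + 1, J):
            def pt(x, y, j=j, jp=jp):
                w = np.zeros(J)
                w[j], w[jp] = x, y
                return f(w)
            cross = (pt(d, d) - pt(d, -d) - pt(-d, d) + pt(-d, -d)) / (4.0 * d * d)
            hess[j, jp] = hess[jp, j] = cross
    return DerivativeSurrogate(r0=r0, grad=grad, hess=hess, step=d)


def da_estimate(f, space, delta=0.1):
    """Derivative approximation: Gaussian-moment ANOVA of the second-order
    Taylor surrogate,

        V_j   = g_j^2 lambda_j^2 + (1/2) h_jj^2 lambda_j^4
        V_jj' = h_jj'^2 lambda_j^2 lambda_j'^2.
    """
    sigmas = _sigmas(space)
    J = sigmas.size
    sur = finite_difference_derivatives(f, space, delta=delta)
    lam2 = sigmas**2
    Vj = sur.grad**2 * lam2 + 0.5 * np.diag(sur.hess) ** 2 * lam2**2
    Vjj = sur.hess**2 * np.outer(lam2, lam2)
    np.fill_diagonal(Vjj, 0.0)
    return assemble_decomposition(
        Vj, Vjj, "da", evaluation_budget("da", J),
        meta={"delta": delta, "surrogate": sur},
    )


# ---------------------------------------------------------------------------
# polynomial approximation

@dataclass
class CutPolynomialSurrogate:
    """Per-factor quadratics and per-pair cross polynomials fitted by
    least squares on axis points and pair grids."""

    alpha0: float
    axis: np.ndarray          # (J, 2): coefficients of w, w^2
    pairs: dict               # (j, jp) -> 2x2 array, [k1-1, k2-1]
    S: int


def _hermite_anova(sigmas, a1, a2, pair_alpha):
    """ANOVA variances of a polynomial surrogate via its orthonormal
    Hermite expansion in the standardized factors x_j = w_j/lambda_j.

    ``a1``/``a2`` are the *effective* per-factor coefficients of w_j, w_j^2
    in the one-factor conditional mean (pair terms already marginalized
    in); ``pair_alpha[(j,jp)][k1-1,k2-1]`` multiplies w_j^k1 w_jp^k2.

    Uses w = lambda*psi1 and w^2 = lambda^2(sqrt(2) psi2 + psi0); squared
    coefficients of the orthonormal basis are the variance contributions.
    """
    lam = np.asarray(sigmas, dtype=float)
    Vj = (a1 * lam) ** 2 + 2.0 * (a2 * lam**2) ** 2
    J = lam.size
    Vjj = np.zeros((J, J))
    scale = {1: lambda l: l, 2: lambda l: _SQRT2 * l * l}
    for (j, jp), alpha in pair_alpha.items():
        v = 0.0
        for k1 in (1, 2):
            for k2 in (1, 2):
                c = alpha[k1 - 1, k2 - 1] * scale[k1](lam[j]) * scale[k2](lam[jp])
                v += c * c
        Vjj[j, jp] = Vjj[jp, j] = v
    return Vj, Vjj


def pa_estimate(f, space, S=4):
    """Polynomial approximation on regression points at +/-1, +/-2, ...
    standard deviations per factor (S points) and their S x S pair grids.

    The center value anchors alpha0 = R(0); per-factor quadratics are
    fitted to the axis residual, per-pair cross terms
    alpha^(k1,k2) w^k1 w'^k2 (1 <= k1,k2 <= 2) to the pair-grid residual.
    Indices come from the Gaussian-moment ANOVA of the full surrogate.
    """
    if S < 2 or S % 2:
        raise ValueError("S must be even and >= 2")
    sigmas = _sigmas(space)
    J = sigmas.size
    f = as_response_function(f, J)
    alpha0 = f(np.zeros(J))
    mults = np.array([m for m in range(-S // 2, S // 2 + 1) if m != 0], dtype=float)

    axis_vals = np.empty((J, S))
    axis_coef = np.empty((J, 2))
    for j in range(J):
        pts = mults * sigmas[j]
        for i, x in enumerate(pts):
            w = np.zeros(J)
            w[j] = x
            axis_vals[j, i] = f(w)
        X = np.column_stack([pts, pts**2])
        axis_coef[j], *_ = np.linalg.lstsq(X, axis_vals[j] - alpha0, rcond=None)

    pairs = {}
    for j in range(J):
        pj = mults * sigmas[j]
        fj = axis_coef[j, 0] * pj + axis_coef[j, 1] * pj**2
        for jp in range(j + 1, J):
            pjp = mults * sigmas[jp]
            fjp = axis_coef[jp, 0] * pjp + axis_coef[jp, 1] * pjp**2
            R = np.empty((S, S))
            for a, x in enumerate(pj):
                for b, y in enumerate(pjp):
                    w = np.zeros(J)
                    w[j], w[jp] = x, y
                    R[a, b] = f(w)
            resid = (R - alpha0 - fj[:, None] - fjp[None, :]).ravel()
            WX, WY = np.meshgrid(pj, pjp, indexing="ij")
            X = np.column_stack(
                [
                    (WX**k1 * WY**k2).ravel()
                    for k1 in (1, 2)
                    for k2 in (1, 2)
                ]
            )
            coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
            pairs[(j, jp)] = coef.reshape(2, 2)

    # effective one-factor coefficients: pair terms with the partner
    # marginalized (E[w'] = 0, E[w'^2] = lambda'^2)
    a1 = axis_coef[:, 0].copy()
    a2 = axis_coef[:, 1].copy()
    for (j, jp), alpha in pairs.items():
        a1[j] += alpha[0, 1] * sigmas[jp] ** 2
        a2[j] += alpha[1, 1] * sigmas[jp] ** 2
        a1[jp] += alpha[1, 0] * sigmas[j] ** 2
        a2[jp] += alpha[1, 1] * sigmas[j] ** 2
    Vj, Vjj = _hermite_anova(sigmas, a1, a2, pairs)
    sur = CutPolynomialSurrogate(alpha0=alpha0, axis=axis_coef, pairs=pairs, S=S)
    return assemble_decomposition(
        Vj, Vjj, "pa", evaluation_budget("pa", J, S=S),
        meta={"S": S, "surrogate": sur},
    )


# ---------------------------------------------------------------------------
# Gauss-Hermite integration

@dataclass
class QuadratureRule:
    """Probabilists' Gauss-Hermite rule: exact for polynomials of degree
    <= 2Q-1 under the standard normal density."""

    Q: int
    nodes: np.ndarray
    weights: np.ndarray


def gauss_hermite_rule(Q):
    if not (1 <= Q <= 50):
        raise ValueError("Q must be in [1, 50]")
    nodes, weights = roots_hermitenorm(int(Q))
    weights = weights / weights.sum()   # normalize to the N(0,1) measure
    # symmetrize: zero out the (analytically zero) middle node of odd rules
    nodes = nodes.copy()
    nodes[np.abs(nodes) < 1e-12] = 0.0
    return QuadratureRule(Q=int(Q), nodes=nodes, weights=weights)


def ghi_estimate(f, space, Q=5):
    """Gauss-Hermite integration of the exact cut-HDMR surrogate.

    Components anchored at w=0:
        f0 = R(0);  f_j(w) = R(w e_j) - f0;
        f_jj'(w,w') = R(w e_j + w' e_j') - f_j(w) - f_j'(w') - f0,
    tabulated on per-factor scaled nodes lambda_j x_q.  All expectations
    (component means and the conditional means through which pair
    components enter one-factor effects) are Q-point quadratures.  Zero
    nodes of odd-Q rules reuse the center evaluation and axis values, so
    the counted budget is exactly 2J(J-1)floor(Q/2)^2 + 2Jfloor(Q/2) + 1.
    """
    if Q < 2:
        raise ValueError("Q must be >= 2")
    sigmas = _sigmas(space)
    J = sigmas.size
    f = as_response_function(f, J)
    rule = gauss_hermite_rule(Q)
    x, omega = rule.nodes, rule.weights
    nz = x != 0.0

    r0 = f(np.zeros(J))
    axis = np.empty((J, Q))          # R on the j-axis at lambda_j x_q
    for j in range(J):
        for q in range(Q):
            if nz[q]:
                w = np.zeros(J)
                w[j] = sigmas[j] * x[q]
                axis[j, q] = f(w)
            else:
                axis[j, q] = r0
    fj = axis - r0                   # (J, Q) first-order components

    pair_comp = {}
    for j in range(J):
        for jp in range(j + 1, J):
            R = np.empty((Q, Q))
            for a in range(Q):
                for b in range(Q):
                    if nz[a] and nz[b]:
                        w = np.zeros(J)
                        w[j] = sigmas[j] * x[a]
                        w[jp] = sigmas[jp] * x[b]
                        R[a, b] = f(w)
                    elif nz[a]:
                        R[a, b] = axis[j, a]
                    elif nz[b]:
                        R[a, b] = axis[jp, b]
                    else:
                        R[a, b] = r0
            pair_comp[(j, jp)] = R - r0 - fj[j][:, None] - fj[jp][None, :]

    # conditional means of pair components: g_{j|jp}(q) = E[f_jjp(x_q, W')]
    G = np.zeros((J, Q))             # G[j] = sum over partners of g_{j|k}
    g = {}
    for (j, jp), comp in pair_comp.items():
        gj = comp @ omega
        gjp = omega @ comp
        g[(j, jp)] = (gj, gjp)
        G[j] += gj
        G[jp] += gjp

    # first-order effects of the truncated surrogate
    Vj = np.empty(J)
    m1 = np.empty((J, Q))
    for j in range(J):
        m = fj[j] + G[j]
        m1[j] = m
        mean = omega @ m
        Vj[j] = omega @ (m - mean) ** 2

    Vjj = np.zeros((J, J))
    W2 = np.outer(omega, omega)
    for (j, jp), comp in pair_comp.items():
        gj, gjp = g[(j, jp)]
        m = (
            (m1[j] - gj)[:, None]
            + (m1[jp] - gjp)[None, :]
            + comp
        )
        mean = float((W2 * m).sum())
        closed = float((W2 * (m - mean) ** 2).sum())
        Vjj[j, jp] = Vjj[jp, j] = closed - Vj[j] - Vj[jp]

    return assemble_decomposition(
        Vj, Vjj, "ghi", evaluation_budget("ghi", J, Q=Q),
        meta={"Q": Q},
    )


# ---------------------------------------------------------------------------
# orthonormal Hermite approximation

def hermite_basis(k, x):
    """Orthonormal Hermite polynomials under N(0,1):
    psi0 = 1, psi1(x) = x, psi2(x) = (x^2 - 1)/sqrt(2)."""
    x = np.asarray(x, dtype=float)
    if k == 0:
        return np.ones_like(x)
    if k == 1:
        return x
    if k == 2:
        return (x * x - 1.0) / _SQRT2
    raise ValueError("k must be 0, 1, or 2")


@dataclass
class HermiteSurrogate:
    """Coefficients of the degree-2 orthonormal-Hermite (polynomial chaos)
    expansion in standardized factors x_j = w_j / lambda_j."""

    alpha0: float
    axis: np.ndarray          # (J, 2): psi1, psi2 coefficients
    pairs: dict               # (j, jp) -> (d, d) array of psi_k psi_k' coefs
    L: int
    seed: object = None


def oha_estimate(f, space, L=6000, seed=None, pair_degree=2):
    """Orthonormal Hermite approximation: global least-squares fit on L
    Latin-hypercube Gaussian samples.

    Regresses R on {1} u {psi_k(x_j)} u {psi_k(x_j) psi_k'(x_jp)},
    k, k' in {1..pair_degree}; by orthonormality of this ANOVA basis the
    variance terms are plain sums of squared coefficients:
    V_j = sum_k alpha_jk^2, V_jj' = sum_kk' alpha_jj'kk'^2.  Budget L.
    """
    sigmas = _sigmas(space)
    J = sigmas.size
    if pair_degree not in (1, 2):
        raise ValueError("pair_degree must be 1 or 2")
    n_coef = 1 + 2 * J + pair_degree**2 * (J * (J - 1) // 2)
    if L <= n_coef:
        raise ValueError(f"L must exceed the coefficient count {n_coef}")
    f = as_response_function(f, J)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    W = lhs_gaussian(L, sigmas, rng)
    R = f.batch(W)
    X = W / sigmas

    psi = {k: hermite_basis(k, X) for k in (1, 2)}   # (L, J) each
    cols = [np.ones(L)]
    for j in range(J):
        cols.append(psi[1][:, j])
        cols.append(psi[2][:, j])
    pair_index = []
    for j in range(J):
        for jp in range(j + 1, J):
            pair_index.append((j, jp))
            for k1 in range(1, pair_degree + 1):
                for k2 in range(1, pair_degree + 1):
                    cols.append(psi[k1][:, j] * psi[k2][:, jp])
    design = np.column_stack(cols)
    coef, _, rank, sv = np.linalg.lstsq(design, R, rcond=None)
    if rank < design.shape[1] or sv[0] / sv[-1] > 1e8:
        raise np.linalg.LinAlgError(
            "ill-conditioned Hermite regression design; increase L"
        )

    axis = coef[1 : 1 + 2 * J].reshape(J, 2)
    Vj = (axis**2).sum(axis=1)
    Vjj = np.zeros((J, J))
    off = 1 + 2 * J
    nper = pair_degree**2
    pairs = {}
    for i, (j, jp) in enumerate(pair_index):
        block = coef[off + i * nper : off + (i + 1) * nper]
        pairs[(j, jp)] = block.reshape(pair_degree, pair_degree)
        v = float((block**2).sum())
        Vjj[j, jp] = Vjj[jp, j] = v
    sur = HermiteSurrogate(alpha0=float(coef[0]), axis=axis, pairs=pairs,
                           L=L, seed=seed)
    return assemble_decomposition(
        Vj, Vjj, "oha", evaluation_budget("oha", J, L=L),
        meta={"L": L, "seed": seed, "pair_degree": pair_degree,
              "surrogate": sur},
    )


ESTIMATORS = {
    "mc": mc_estimate,
    "da": da_estimate,
    "pa": pa_estimate,
    "ghi": ghi_estimate,
    "oha": oha_estimate,
}
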