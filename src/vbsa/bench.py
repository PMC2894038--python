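"""Verification harness: analytic test functions with closed-form variance
decompositions, a brute-force tensor-quadrature ANOVA oracle, and a
synthetic phosphorylation-cascade fixture.

Every closed form used as a test target is cross-checkable against
:func:`tensor_quadrature_oracle`, which computes *all* ANOVA terms of a
smooth function of a few Gaussian factors on a full tensor Gauss-Hermite
grid by inclusion-exclusion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateResponseError
from .estimators import gauss_hermite_rule
from .network import ReactionNetwork, ReversibleReaction, simulate


@dataclass
class AnalyticTestFunction:
    """A test response with known Gaussian ANOVA decomposition."""

    family: str
    sigmas: np.ndarray
    Vj: np.ndarray
    Vjj: np.ndarray
    Vtot: float
    _batch: callable = field(repr=False, default=None)
    V_subsets: dict = field(default_factory=dict)   # tuple(sorted u) -> V_u

    @property
    def J(self):
        return self.sigmas.size

    def __call__(self, w):
        return float(self._batch(np.atleast_2d(np.asarray(w, dtype=float)))[0])

    def batch(self, W):
        return np.asarray(self._batch(np.asarray(W, dtype=float)), dtype=float)

    @property
    def V2(self):
        """Second-order portion: sum of first-order and pair terms."""
        J = self.Vj.size
        return float(self.Vj.sum() + self.Vjj[np.triu_indices(J, 1)].sum())


def quadratic_function(a, c, B, sigmas):
    """f(w) = sum a_j w_j + sum c_j w_j^2 + sum_{j<j'} B_jj' w_j w_j'.

    Exact ANOVA: V_j = a_j^2 l_j^2 + 2 c_j^2 l_j^4,
    V_jj' = B_jj'^2 l_j^2 l_j'^2, no terms of order >= 3.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    J = a.size
    B = np.zeros((J, J)) if B is None else np.asarray(B, dtype=float)
    if np.any(np.diag(B) != 0):
        raise ValueError("B must have zero diagonal")
    if np.abs(B - B.T).max(initial=0.0) > 0:
        B = np.triu(B, 1) + np.triu(B, 1).T   # symmetrize from upper triangle

    def batch(W):
        return W @ a + (W * W) @ c + 0.5 * ((W @ B) * W).sum(axis=1)

    lam2 = sigmas**2
    Vj = a**2 * lam2 + 2.0 * c**2 * lam2**2
    Vjj = B**2 * np.outer(lam2, lam2)
    np.fill_diagonal(Vjj, 0.0)
    Vtot = float(Vj.sum() + Vjj[np.triu_indices(J, 1)].sum())
    return AnalyticTestFunction(
        family="quadratic", sigmas=sigmas, Vj=Vj, Vjj=Vjj, Vtot=Vtot, _batch=batch
    )


def additive_function(sigmas):
    """f(w) = sum_j w_j / lambda_j: unit first-order variances, no
    interactions of any order."""
    sigmas = np.asarray(sigmas, dtype=float)
    return quadratic_function(1.0 / sigmas, np.zeros_like(sigmas), None, sigmas)


def pure_interaction_function(sigmas):
    """f(w) = w_1 w_2: the whole variance sits in one pair term."""
    sigmas = np.asarray(sigmas, dtype=float)
    J = sigmas.size
    B = np.zeros((J, J))
    B[0, 1] = B[1, 0] = 1.0
    return quadratic_function(np.zeros(J), np.zeros(J), B, sigmas)


def product_exponential_function(a, sigmas):
    """f(w) = exp(sum a_j w_j): a genuinely nonadditive stress test.

    The multiplicative structure gives every ANOVA subset u a closed form

        V_u = prod_{j in u} (e^{2 a_j^2 l_j^2} - e^{a_j^2 l_j^2})
              * prod_{j not in u} e^{a_j^2 l_j^2},

    so for J >= 3 the second-order truncation misses exactly the
    higher-order subset terms.
    """
    a = np.asarray(a, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.sum(np.abs(a) * sigmas) > 3.0:
        raise ValueError("sum |a_j| lambda_j > 3: overflow-prone regime")
    J = a.size
    m = a**2 * sigmas**2                 # per-factor log-moments
    e1, e2 = np.exp(m), np.exp(2 * m)
    diff = e2 - e1

    def batch(W):
        return np.exp(W @ a)

    Vj = np.array([diff[j] * np.prod(np.delete(e1, j)) for j in range(J)])
    Vjj = np.zeros((J, J))
    for j in range(J):
        for jp in range(j + 1, J):
            rest = np.prod(np.delete(e1, [j, jp]))
            Vjj[j, jp] = Vjj[jp, j] = diff[j] * diff[jp] * rest
    Vtot = float(np.prod(e2) - np.prod(e1))
    subsets = {}
    if J <= 12:
        for r in range(1, J + 1):
            for u in itertools.combinations(range(J), r):
                rest = np.prod(np.delete(e1, u))
                subsets[u] = float(np.prod(diff[list(u)]) * rest)
    return AnalyticTestFunction(
        family="product_exponential", sigmas=sigmas, Vj=Vj, Vjj=Vjj,
        Vtot=Vtot, _batch=batch, V_subsets=subsets,
    )


# ---------------------------------------------------------------------------
# brute-force oracle

@dataclass
class OracleANOVA:
    """Full ANOVA decomposition from the tensor-quadrature oracle."""

    V: dict                      # tuple(sorted subset) -> V_u
    total: float

    @property
    def J(self):
        return max(max(u) for u in self.V) + 1 if self.V else 0

    @property
    def Vj(self):
        out = np.zeros(self.J)
        for j in range(self.J):
            out[j] = self.V.get((j,), 0.0)
        return out

    @property
    def Vjj(self):
        J = self.J
        out = np.zeros((J, J))
        for j in range(J):
            for jp in range(j + 1, J):
                out[j, jp] = out[jp, j] = self.V.get((j, jp), 0.0)
        return out


def tensor_quadrature_oracle(f, sigmas, Q=30, max_J=4):
    """All ANOVA variance terms of f under independent N(0, lambda_j^2)
    factors, by full tensor-grid Gauss-Hermite quadrature.

    Conditional means for every subset are weight contractions of the full
    Q^J value tensor; subset variances follow by inclusion-exclusion.
    Refuses J > max_J (cost Q^J).
    """
    sigmas = np.asarray(getattr(f, "sigmas", sigmas) if sigmas is None
                        else sigmas, dtype=float)
    J = sigmas.size
    if J > max_J:
        raise ValueError(f"oracle refuses J={J} > max_J={max_J} (cost Q^J)")
    rule = gauss_hermite_rule(Q)
    x, omega = rule.nodes, rule.weights

    grids = np.meshgrid(*[sigmas[j] * x for j in range(J)], indexing="ij")
    points = np.column_stack([grid.ravel() for grid in grids])
    batch = getattr(f, "batch", None)
    if batch is not None:
        values = np.asarray(batch(points), dtype=float)
    else:
        values = np.array([float(f(w)) for w in points])
    T = values.reshape((rule.Q,) * J)

    def contract(subset):
        """E[f | W_u] on the subset's grid: sum out the other axes."""
        out = T
        for ax in sorted(set(range(J)) - set(subset), reverse=True):
            out = np.tensordot(out, omega, axes=([ax], [0]))
        return out

    mean = float(contract(()))
    V = {}
    for r in range(1, J + 1):
        for u in itertools.combinations(range(J), r):
            Mu = contract(u)
            wgrid = omega
            for _ in range(r - 1):
                wgrid = np.multiply.outer(wgrid, omega)
            var_c = float((wgrid * (Mu - mean) ** 2).sum())
            V[u] = var_c - sum(
                V[v]
                for rr in range(1, r)
                for v in itertools.combinations(u, rr)
            )
    total = sum(V.values())
    return OracleANOVA(V=V, total=float(total))


# ---------------------------------------------------------------------------
# synthetic cascade fixture

_TIER_NAMES = ["MKKK", "MKK", "ERK"]

# base rate constants: bimolecular association, dissociation, catalysis,
# and the (small) reverse of the catalytic step
_KA, _KD, _KC, _KCR = 1e-3, 1e-1, 1e-1, 1e-6
_KSIG, _KSIGR = 2e-3, 1e-8    # signal inactivation


def synthetic_cascade_fixture(tiers=3, seed=0, jitter=0.3, solver_opts=None):
    """A MAPK-style phosphorylation cascade with randomized bounded rates.

    Tier 1 is a kinase activated by a decaying input signal; each further
    tier is a double-phosphorylation cycle (distributive kinase/phosphatase
    mechanism, two reversible binding steps and two reversible catalytic
    steps per direction).  For ``tiers=3`` the network has exactly M = 21
    reversible reactions and N = 23 species, with the terminal
    doubly-phosphorylated species ("ERK-PP") as the designated output (set
    as ``network.output_species``).

    Nominal rates are base values jittered by exp(U(-jitter, jitter)) under
    ``seed``; the nominal output trajectory is asserted to be a transient
    pulse (rises from ~0, peaks, decays below 5% of peak within the 6-hour
    window).  If the jittered network fails the pulse assertion, the next
    seed substream is tried (at most 10 attempts).
    """
    if tiers < 1:
        raise ValueError("tiers must be >= 1")
    children = np.random.SeedSequence(seed).spawn(10)
    last_err = None
    for child in children:
        rng = np.random.default_rng(child)
        net = _build_cascade(tiers, rng, jitter)
        try:
            _assert_pulse(net, solver_opts)
        except DegenerateResponseError as exc:
            last_err = exc
            continue
        return net
    raise DegenerateResponseError(
        f"no pulse-shaped cascade found in 10 attempts: {last_err}"
    )


def _tier_name(t):
    return _TIER_NAMES[t - 1] if t <= len(_TIER_NAMES) else f"K{t}"


def _build_cascade(tiers, rng, jitter):
    def j():
        return float(np.exp(rng.uniform(-jitter, jitter)))

    species = []
    initials = []

    def add(name, q0):
        species.append(name)
        initials.append(q0)

    reactions = []
    rid = [0]

    def rx(reac, prod, kf, kr):
        rid[0] += 1
        reactions.append(
            ReversibleReaction(f"R{rid[0]}", reac, prod, kf * j(), kr * j())
        )

    k1 = _tier_name(1)
    add("E1", 30.0)
    add(k1, 100.0)
    add(f"C:{k1}", 0.0)
    add(f"{k1}*", 0.0)
    add("P1", 30.0)
    add(f"C:{k1}*", 0.0)
    rx({"E1": 1, k1: 1}, {f"C:{k1}": 1}, _KA, _KD)
    rx({f"C:{k1}": 1}, {f"{k1}*": 1, "E1": 1}, _KC, _KCR)
    rx({f"{k1}*": 1, "P1": 1}, {f"C:{k1}*": 1}, _KA, _KD)
    rx({f"C:{k1}*": 1}, {k1: 1, "P1": 1}, _KC, _KCR)

    upstream = f"{k1}*"
    for t in range(2, tiers + 1):
        s = _tier_name(t)
        ph = f"P{t}"
        add(s, 300.0)
        add(f"C:{s}:a", 0.0)
        add(f"{s}-P", 0.0)
        add(f"C:{s}:b", 0.0)
        add(f"{s}-PP", 0.0)
        add(ph, 60.0)
        add(f"C:{s}:c", 0.0)
        add(f"C:{s}:d", 0.0)
        rx({s: 1, upstream: 1}, {f"C:{s}:a": 1}, _KA, _KD)
        rx({f"C:{s}:a": 1}, {f"{s}-P": 1, upstream: 1}, _KC, _KCR)
        rx({f"{s}-P": 1, upstream: 1}, {f"C:{s}:b": 1}, _KA, _KD)
        rx({f"C:{s}:b": 1}, {f"{s}-PP": 1, upstream: 1}, _KC, _KCR)
        rx({f"{s}-PP": 1, ph: 1}, {f"C:{s}:c": 1}, _KA, _KD)
        rx({f"C:{s}:c": 1}, {f"{s}-P": 1, ph: 1}, _KC, _KCR)
        rx({f"{s}-P": 1, ph: 1}, {f"C:{s}:d": 1}, _KA, _KD)
        rx({f"C:{s}:d": 1}, {s: 1, ph: 1}, _KC, _KCR)
        upstream = f"{s}-PP"

    add("E1i", 0.0)
    rx({"E1": 1}, {"E1i": 1}, _KSIG, _KSIGR)

    net = ReactionNetwork(species, np.array(initials), reactions)
    net.output_species = upstream
    return net


def _assert_pulse(net, solver_opts=None):
    opts = {"rtol": 1e-6, "atol": 1e-8}
    if solver_opts:
        opts.update(solver_opts)
    traj = simulate(net, t_max=21600.0, n_points=1201, solver_opts=opts)
    q = traj.species(net.output_species)
    peak = q.max()
    imax = int(q.argmax())
    if not (
        peak > 1.0
        and 0 < imax < q.size - 1
        and q[0] < 0.01 * peak
        and q[-1] < 0.05 * peak
    ):
        raise DegenerateResponseError(
            f"output {net.output_species!r} is not a transient pulse "
            f"(peak {peak:.3g}, start {q[0]:.3g}, end {q[-1]:.3g})"
        )
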