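"""Second-order variance decomposition, sensitivity indices, classification.

For a response R(W) of J independent factors, the ANOVA decomposition of
Var[R] is truncated at pairwise terms:

    V = sum_j V_j + sum_{j<j'} V_jj'

with first-order terms V_j = Var[E[R|W_j]] and second-order interaction
terms V_jj' = Var[E[R|W_j,W_j']] - V_j - V_j'.  The single-effect
sensitivity index (SESI) and joint-effect sensitivity index (JESI) of
factor j are

    sigma_j = V_j / V,      eta_j = sum_{j' != j} V_jj' / V.

Since each pair contributes to two JESIs, sum_j sigma_j + 1/2 sum_j eta_j = 1.
Factors are classified against a threshold theta (default 10%):
singular (sigma >= theta > eta), joint (eta >= theta > sigma),
singular_joint (both), noninfluential (neither).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedIndicesError

CLASSES = ("singular", "joint", "singular_joint", "noninfluential")


@dataclass
class VarianceDecomposition:
    """First- and second-order variance terms produced by an estimator."""

    Vj: np.ndarray                  # (J,), clamped nonnegative
    Vjj: np.ndarray                 # (J, J) symmetric, zero diagonal
    V: float                        # second-order portion, sum of the above
    method: str
    budget: int                     # counted system evaluations
    meta: dict = field(default_factory=dict)

    @property
    def J(self):
        return self.Vj.size


def assemble_decomposition(Vj_raw, Vjj_raw, method, budget, meta=None):
    """Validate, clamp, and total raw variance estimates.

    Negative entries (possible for sampling-based estimators) are clamped to
    zero for index computation; the raw values and a clamp mask are kept in
    ``meta``.  ``Vjj_raw`` must be symmetric to 1e-12 (relative to its
    largest entry); NaNs are rejected with the offending position named.
    """
    Vj_raw = np.asarray(Vj_raw, dtype=float).copy()
    Vjj_raw = np.asarray(Vjj_raw, dtype=float).copy()
    J = Vj_raw.size
    if Vjj_raw.shape != (J, J):
        raise ValueError(f"Vjj must be ({J}, {J})")
    if np.any(np.isnan(Vj_raw)):
        j = int(np.nonzero(np.isnan(Vj_raw))[0][0])
        raise ValueError(f"NaN in first-order variance for factor {j}")
    if np.any(np.isnan(Vjj_raw)):
        j, jp = map(int, np.argwhere(np.isnan(Vjj_raw))[0])
        raise ValueError(f"NaN in pair variance for factors ({j}, {jp})")
    scale = max(np.abs(Vjj_raw).max(initial=0.0), 1.0)
    if np.abs(Vjj_raw - Vjj_raw.T).max(initial=0.0) > 1e-12 * scale:
        raise ValueError("Vjj is not symmetric")
    np.fill_diagonal(Vjj_raw, 0.0)

    Vj = np.maximum(Vj_raw, 0.0)
    Vjj = np.maximum(Vjj_raw, 0.0)
    clamped_j = Vj_raw < 0
    clamped_jj = Vjj_raw < 0
    np.fill_diagonal(clamped_jj, False)
    V = float(Vj.sum() + Vjj[np.triu_indices(J, 1)].sum())
    meta = dict(meta or {})
    meta.update(
        raw_Vj=Vj_raw,
        raw_Vjj=Vjj_raw,
        clamped_Vj=clamped_j,
        clamped_Vjj=clamped_jj,
        n_clamped=int(clamped_j.sum() + clamped_jj.sum() // 2),
    )
    return VarianceDecomposition(
        Vj=Vj, Vjj=Vjj, V=V, method=method, budget=int(budget), meta=meta
    )


@dataclass
class SensitivityReport:
    """Per-factor indices and classifications for one analysis."""

    sesi: np.ndarray                # fractions in [0, 1]
    jesi: np.ndarray
    labels: list
    method: str
    budget: int
    theta: float = 0.10
    classification: list = field(default_factory=list)
    decomposition: VarianceDecomposition = None

    @property
    def sesi_pct(self):
        return 100.0 * self.sesi

    @property
    def jesi_pct(self):
        return 100.0 * self.jesi


def sesi_jesi(dec, labels=None):
    """Compute SESI/JESI from a decomposition (indices only; run
    :func:`classify` to fill in classifications)."""
    if not (dec.V > 0):
        raise UndefinedIndicesError(
            "second-order variance portion is zero; indices undefined"
        )
    sesi = dec.Vj / dec.V
    jesi = dec.Vjj.sum(axis=1) / dec.V
    if labels is None:
        labels = [f"w{j + 1}" for j in range(dec.J)]
    return SensitivityReport(
        sesi=sesi,
        jesi=jesi,
        labels=list(labels),
        method=dec.method,
        budget=dec.budget,
        decomposition=dec,
    )


def classify(report, theta=0.10):
    """Classify each factor against the threshold (strict >= at the
    boundary) and return the report with ``classification`` filled in."""
    out = []
    for s, e in zip(report.sesi, report.jesi):
        if s >= theta and e < theta:
            out.append("singular")
        elif s < theta and e >= theta:
            out.append("joint")
        elif s >= theta and e >= theta:
            out.append("singular_joint")
        else:
            out.append("noninfluential")
    report.classification = out
    report.theta = float(theta)
    return report


def evaluation_budget(method, J, L=None, S=None, Q=None):
    """Number of system integrations each estimator performs.

    MC: 2L(J+1); DA: 2J(J+1)+1; PA: J(J-1)S^2/2 + JS + 1;
    GHI: 2J(J-1)floor(Q/2)^2 + 2J*floor(Q/2) + 1; OHA: L.
    """
    method = str(method).lower()
    J = int(J)
    if method == "mc":
        if L is None:
            raise ValueError("MC budget requires L")
        return 2 * int(L) * (J + 1)
    if method == "da":
        return 2 * J * (J + 1) + 1
    if method == "pa":
        if S is None:
            raise ValueError("PA budget requires S")
        return J * (J - 1) * int(S) ** 2 // 2 + J * int(S) + 1
    if method == "ghi":
        if Q is None:
            raise ValueError("GHI budget requires Q")
        h = int(Q) // 2
        return 2 * J * (J - 1) * h * h + 2 * J * h + 1
    if method == "oha":
        if L is None:
            raise ValueError("OHA budget requires L")
        return int(L)
    raise ValueError(f"unknown method {method!r}")
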