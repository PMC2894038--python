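"""Gaussian perturbation factors on standard chemical potentials.

In Eyring-Polanyi transition-state theory a reaction's forward and reverse
rate constants are set by the standard chemical potential of its activated
complex and of the reactant/product species.  Perturbing these potentials
(measured in k_B T units) by zero-mean Gaussians W_j with standard
deviations lambda_j moves the rate constants log-linearly:

ROSA (reaction-oriented, one factor per reaction, J = M):
    raising the activated-complex potential of reaction m by w_m raises its
    barrier in both directions,

        K_f = kf0 * exp(-w_m),   K_r = kr0 * exp(-w_m),

    so the equilibrium constant K_f/K_r is invariant -- detailed balance is
    preserved for every realization.

SOSA (species-oriented, one factor per species, J = N):
    raising the potential of species n by w_n destabilizes it, accelerating
    the reactions that consume it,

        K_f = kf0 * exp(sum_n nu_nm  w_n),
        K_r = kr0 * exp(sum_n nu'_nm w_n),

    so ln(K_f/K_r) shifts by sum_n (nu_nm - nu'_nm) w_n, exactly the shift
    in reaction free energy -- again thermodynamically consistent, and
    Wegscheider cycle conditions are preserved.

A +/- lambda excursion of an activated-complex potential moves the rate
constants within the percentage interval 100[exp(-lambda)-1, exp(lambda)-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError, ModelValidationError
from .network import simulate
from .responses import log_response

MODES = ("rosa", "sosa")
_W_GUARD = 50.0  # |w| beyond this would overflow exp in the rate map


@dataclass
class FactorSpace:
    """The J independent Gaussian perturbation factors W.

    ``mode`` is 'rosa' (J = M reaction factors) or 'sosa' (J = N species
    factors); ``sigmas`` holds the per-factor standard deviations
    (dimensionless, potentials in k_B T units); ``labels`` names each factor
    (reaction ids / species names).
    """

    mode: str
    sigmas: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if self.sigmas.size < 1 or np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be strictly positive")
        if not self.labels:
            self.labels = [f"w{j + 1}" for j in range(self.sigmas.size)]
        if len(self.labels) != self.sigmas.size:
            raise ValueError("labels/sigmas length mismatch")

    @property
    def J(self):
        return self.sigmas.size

    @classmethod
    def for_network(cls, network, mode, lam):
        """Build the factor space attached to a network: one factor per
        reaction (ROSA) or per species (SOSA), each with standard deviation
        ``lam`` (scalar, replicated, or a full per-factor vector)."""
        mode = str(mode).lower()
        if mode == "rosa":
            J, labels = network.M, [rx.rid for rx in network.reactions]
        elif mode == "sosa":
            J, labels = network.N, list(network.species_names)
        else:
            raise ValueError(f"mode must be one of {MODES}")
        sig = np.asarray(lam, dtype=float)
        if sig.ndim == 0:
            sig = np.full(J, float(sig))
        if sig.shape != (J,):
            raise ValueError(f"lambda must be scalar or length {J}")
        return cls(mode=mode, sigmas=sig, labels=labels)


def perturbation_interval(lam):
    """Percentage interval 100[exp(-lam)-1, exp(lam)-1] of rate-constant
    variation induced by a +/- lam potential excursion."""
    if not (lam > 0):
        raise ValueError("lam must be positive")
    return 100.0 * (np.exp(-lam) - 1.0), 100.0 * (np.exp(lam) - 1.0)


def rates_from_factors(network, space, w):
    """Map a factor realization w to the perturbed rate-constant vector
    (length 2M, interleaved forward/reverse)."""
    w = np.asarray(w, dtype=float)
    if w.shape != (space.J,):
        raise ModelValidationError(f"expected {space.J} factors, got {w.shape}")
    if np.any(np.abs(w) >= _W_GUARD):
        raise ModelValidationError("factor value too large (exp overflow guard)")
    nominal = network.nominal_rates
    kf0, kr0 = nominal[0::2], nominal[1::2]
    if space.mode == "rosa":
        if space.J != network.M:
            raise ModelValidationError("ROSA factor count must equal M")
        scale = np.exp(-w)
        kf, kr = kf0 * scale, kr0 * scale
    else:
        if space.J != network.N:
            raise ModelValidationError("SOSA factor count must equal N")
        kf = kf0 * np.exp(network.Vr.T @ w)
        kr = kr0 * np.exp(network.Vp.T @ w)
    out = np.empty(2 * network.M)
    out[0::2], out[1::2] = kf, kr
    return out


class ResponseFunction:
    """A counted, optionally cached evaluator w -> R(w).

    ``eval_count`` increments exactly once per uncached evaluation of the
    underlying system (one ODE integration for model-based responses); cache
    keys are the exact bytes of w.  ``batch`` evaluates a sample matrix
    row-wise, using a vectorized kernel when one is supplied.
    """

    def __init__(self, evaluator, J, cache=True, batch_evaluator=None, label=None):
        self._evaluator = evaluator
        self._batch = batch_evaluator
        self.J = int(J)
        self.label = label
        self.eval_count = 0
        self.cache_enabled = bool(cache)
        self._cache = {}

    def __call__(self, w):
        w = np.asarray(w, dtype=float)
        if w.shape != (self.J,):
            raise EvaluationError(f"expected length-{self.J} factor vector", w=w)
        key = w.tobytes() if self.cache_enabled else None
        if key is not None and key in self._cache:
            return self._cache[key]
        try:
            value = float(self._evaluator(w))
        except Exception as exc:
            raise EvaluationError(f"response evaluation failed: {exc}", w=w) from exc
        if not np.isfinite(value):
            raise EvaluationError(f"non-finite response {value}", w=w)
        self.eval_count += 1
        if key is not None:
            self._cache[key] = value
        return value

    def batch(self, W):
        W = np.asarray(W, dtype=float)
        if W.ndim != 2 or W.shape[1] != self.J:
            raise EvaluationError(f"expected (n, {self.J}) sample matrix")
        if self._batch is not None and not self.cache_enabled:
            vals = np.asarray(self._batch(W), dtype=float)
            if not np.all(np.isfinite(vals)):
                bad = int(np.nonzero(~np.isfinite(vals))[0][0])
                raise EvaluationError("non-finite response in batch", w=W[bad])
            self.eval_count += W.shape[0]
            return vals
        return np.array([self(w) for w in W])

    def clear_cache(self):
        self._cache.clear()


def make_response_function(network, space, response_spec, solver_opts=None,
                           cache=True):
    """Compose rate mapping -> ODE integration -> log-response into a
    :class:`ResponseFunction` (one counted system integration per call)."""

    def evaluator(w):
        rates = rates_from_factors(network, space, w)
        traj = simulate(
            network,
            rates,
            t_max=response_spec.t_max,
            n_points=response_spec.n_points,
            solver_opts=solver_opts,
        )
        return log_response(traj, response_spec)

    return ResponseFunction(
        evaluator,
        J=space.J,
        cache=cache,
        label=f"{response_spec.kind}({response_spec.species})",
    )


def as_response_function(f, J, cache=False):
    """Coerce a plain callable (or pass through a ResponseFunction) for use
    by the estimators."""
    if isinstance(f, ResponseFunction):
        return f
    batch = getattr(f, "batch", None)
    return ResponseFunction(f, J=J, cache=cache, batch_evaluator=batch)
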