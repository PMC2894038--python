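"""Mass-action reaction networks and their deterministic kinetics.

A network consists of N molecular species with initial concentrations
q(0) (molecules/cell) and M reversible reactions

    sum_n nu_nm X_n  <->  sum_n nu'_nm X_n

with nonnegative forward/reverse rate constants (s^-1, normalized).  The
concentration dynamics follow the kinetic equations

    dq_n/dt = sum_m (nu'_nm - nu_nm) rho_m(t)
    rho_m   = kappa_f,m prod_n q_n^nu_nm - kappa_r,m prod_n q_n^nu'_nm

Model files are a small YAML subset; see :func:`parse_network`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.integrate import odeint

from ._kinetics import mass_action_jac, mass_action_rhs
from .errors import (
    FixtureUnavailableError,
    IntegrationError,
    ModelParseError,
    ModelValidationError,
)

MAX_STOICH = 4  # sanity bound on mass-action exponents

DEFAULT_SOLVER_OPTS = {"rtol": 1e-8, "atol": 1e-10, "mxstep": 100000}


@dataclass(frozen=True)
class ReversibleReaction:
    """One reversible mass-action reaction.

    ``reactants``/``products`` map species names to stoichiometric
    coefficients (positive integers <= 4); ``kf``/``kr`` are the nominal
    forward and reverse rate constants.
    """

    rid: str
    reactants: dict
    products: dict
    kf: float
    kr: float

    def __post_init__(self):
        if self.kf < 0 or self.kr < 0:
            raise ModelValidationError(
                f"reaction {self.rid!r}: negative rate constant"
            )
        if not self.reactants and not self.products:
            raise ModelValidationError(
                f"reaction {self.rid!r}: both reaction sides are empty"
            )
        for side in (self.reactants, self.products):
            for name, nu in side.items():
                if int(nu) != nu or nu < 0 or nu > MAX_STOICH:
                    raise ModelValidationError(
                        f"reaction {self.rid!r}: stoichiometry {nu!r} for "
                        f"{name!r} must be an integer in [0, {MAX_STOICH}]"
                    )


@dataclass
class ReactionNetwork:
    """Species, initial concentrations and reversible reactions."""

    species_names: list
    initial_concentrations: np.ndarray
    reactions: list

    # dense stoichiometry matrices, built on construction
    Vr: np.ndarray = field(init=False, repr=False)   # (N, M) reactant nu
    Vp: np.ndarray = field(init=False, repr=False)   # (N, M) product nu'
    S: np.ndarray = field(init=False, repr=False)    # net, Vp - Vr

    def __post_init__(self):
        names = list(self.species_names)
        if len(names) < 1 or len(self.reactions) < 1:
            raise ModelValidationError("need at least one species and one reaction")
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate species names")
        q0 = np.asarray(self.initial_concentrations, dtype=float)
        if q0.shape != (len(names),):
            raise ModelValidationError("initial_concentrations length mismatch")
        if np.any(q0 < 0):
            raise ModelValidationError("negative initial concentration")
        self.initial_concentrations = q0
        index = {n: i for i, n in enumerate(names)}
        N, M = len(names), len(self.reactions)
        self.Vr = np.zeros((N, M))
        self.Vp = np.zeros((N, M))
        for m, rx in enumerate(self.reactions):
            for side, V in ((rx.reactants, self.Vr), (rx.products, self.Vp)):
                for name, nu in side.items():
                    if name not in index:
                        raise ModelValidationError(
                            f"reaction {rx.rid!r} references unknown species {name!r}"
                        )
                    V[index[name], m] = nu
        self.S = self.Vp - self.Vr

    @property
    def N(self):
        return len(self.species_names)

    @property
    def M(self):
        return len(self.reactions)

    def species_index(self, name):
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ModelValidationError(f"unknown species {name!r}") from None

    @property
    def nominal_rates(self):
        """Rate constants as a length-2M vector, interleaved
        (forward_1, reverse_1, forward_2, reverse_2, ...)."""
        out = np.empty(2 * self.M)
        for m, rx in enumerate(self.reactions):
            out[2 * m] = rx.kf
            out[2 * m + 1] = rx.kr
        return out


@dataclass
class Trajectory:
    """Solution of the kinetic equations on a uniform time grid."""

    times: np.ndarray            # (T,), seconds, times[0] == 0
    concentrations: np.ndarray   # (N, T), molecules/cell
    species_names: list

    def species(self, name):
        return self.concentrations[self.species_names.index(name)]

    def to_csv(self):
        header = ",".join(["time"] + list(self.species_names))
        body = np.column_stack([self.times, self.concentrations.T])
        lines = [header]
        lines += [",".join(f"{x:.10g}" for x in row) for row in body]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model file parsing

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][\w\-\*']*)\s*$")


def _parse_side(text, rid):
    """Parse a reaction side like ``"2 A + B"`` into {name: coeff}.

    Empty string / None / "0" denote the empty side (synthesis/degradation).
    """
    if text is None:
        return {}
    text = str(text).strip()
    if text in ("", "0"):
        return {}
    side = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ModelParseError(
                f"reaction {rid!r}: cannot parse term {term.strip()!r}"
            )
        coeff = int(m.group(1)) if m.group(1) else 1
        name = m.group(2)
        side[name] = side.get(name, 0) + coeff
    return side


def _format_side(side):
    parts = []
    for name in sorted(side):
        nu = side[name]
        parts.append(name if nu == 1 else f"{nu} {name}")
    return " + ".join(parts) if parts else "0"


def parse_network(text):
    """Parse a model file (YAML subset) into a :class:`ReactionNetwork`.

    Schema::

        species:
          - {name: A, initial: 10.0}
        reactions:
          - {id: R1, reactants: "2 A", products: "B", kf: 1.0, kr: 0.5}

    ``id`` is optional (defaults to R<position>); sides are written as
    ``"coeff name + ..."`` with coefficient 1 omitted.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise ModelParseError(f"malformed model file{line}: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise ModelParseError("model file must have 'species:' and 'reactions:' keys")

    names, q0 = [], []
    for i, entry in enumerate(doc["species"]):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ModelParseError(f"species entry {i + 1} missing 'name'")
        names.append(str(entry["name"]))
        q0.append(float(entry.get("initial", 0.0)))

    reactions = []
    for i, entry in enumerate(doc["reactions"]):
        if not isinstance(entry, dict):
            raise ModelParseError(f"reaction entry {i + 1} is not a mapping")
        rid = str(entry.get("id", f"R{i + 1}"))
        try:
            kf = float(entry["kf"])
            kr = float(entry["kr"])
        except KeyError as exc:
            raise ModelParseError(f"reaction {rid!r}: missing {exc}") from None
        reactions.append(
            ReversibleReaction(
                rid=rid,
                reactants=_parse_side(entry.get("reactants"), rid),
                products=_parse_side(entry.get("products"), rid),
                kf=kf,
                kr=kr,
            )
        )
    return ReactionNetwork(names, np.array(q0), reactions)


def write_network(network):
    """Serialize a network to the canonical model-file form.

    ``parse_network(write_network(net))`` reproduces the network exactly;
    species order is preserved, side terms are sorted by name.
    """
    lines = ["species:"]
    for name, q in zip(network.species_names, network.initial_concentrations):
        lines.append(f"  - {{name: {name}, initial: {q:.10g}}}")
    lines.append("reactions:")
    for rx in network.reactions:
        lines.append(
            f"  - {{id: {rx.rid}, "
            f'reactants: "{_format_side(rx.reactants)}", '
            f'products: "{_format_side(rx.products)}", '
            f"kf: {rx.kf:.10g}, kr: {rx.kr:.10g}}}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# kinetics

def _split_rates(network, rates):
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (2 * network.M,):
        raise ModelValidationError(
            f"expected {2 * network.M} rate constants, got {rates.shape}"
        )
    return rates[0::2].copy(), rates[1::2].copy()


def reaction_fluxes(network, rates, q):
    """Reaction fluxes rho_m = kf_m prod q^nu - kr_m prod q^nu'."""
    kf, kr = _split_rates(network, rates)
    q = np.asarray(q, dtype=float)
    if q.shape != (network.N,):
        raise ModelValidationError(f"expected {network.N} concentrations")
    qcol = q[:, None]
    fwd = np.prod(np.where(network.Vr > 0, qcol ** network.Vr, 1.0), axis=0)
    rev = np.prod(np.where(network.Vp > 0, qcol ** network.Vp, 1.0), axis=0)
    return kf * fwd - kr * rev


def concentration_derivatives(network, rates, q):
    """dq/dt = S @ rho with net stoichiometry S = nu' - nu."""
    return network.S @ reaction_fluxes(network, rates, q)


def simulate(network, rates=None, t_max=21600.0, n_points=1201, solver_opts=None):
    """Integrate the kinetic equations with a stiff (LSODA) solver.

    Parameters
    ----------
    rates : length-2M vector or None
        Interleaved forward/reverse rate constants; nominal values if None.
    t_max, n_points
        Uniform output grid [0, t_max] with n_points points.  Defaults give
        the 6-hour observation window used for signaling transients.
    solver_opts : dict
        Overrides for rtol (1e-8), atol (1e-10), mxstep.

    Returns a :class:`Trajectory`; raises :class:`IntegrationError` when the
    solver does not converge. Tolerance-level negative undershoots in the
    output are clipped to zero.
    """
    if rates is None:
        rates = network.nominal_rates
    kf, kr = _split_rates(network, rates)
    if np.any(kf < 0) or np.any(kr < 0):
        raise ModelValidationError("negative rate constant")
    if t_max <= 0:
        raise ModelValidationError("t_max must be positive")
    opts = dict(DEFAULT_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)
    times = np.linspace(0.0, float(t_max), int(n_points))
    args = (kf, kr, network.Vr, network.Vp, network.S)
    out, info = odeint(
        mass_action_rhs,
        network.initial_concentrations,
        times,
        args=args,
        Dfun=mass_action_jac,
        rtol=opts["rtol"],
        atol=opts["atol"],
        mxstep=opts["mxstep"],
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"ODE solver failed: {info['message']}")
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite concentrations in solution")
    qmax = out.max(initial=0.0)
    floor = -(100.0 * opts["atol"] + 1e-6 * max(qmax, 1.0))
    if out.min() < floor:
        raise IntegrationError(
            f"solution went significantly negative (min {out.min():.3g}); "
            "tighten solver tolerances"
        )
    out = np.clip(out, 0.0, None)
    return Trajectory(times, out.T, list(network.species_names))


def mapk_fixture():
    """The 21-reaction / 23-species MAPK signaling cascade model.

    The nominal rate constants and initial concentrations of this model are
    published only in a supplementary parameter file that is not distributed
    with this package.  Until a transcription is added under
    ``vbsa/data/mapk_cascade.yaml``, this raises
    :class:`FixtureUnavailableError`; analyses and tests fall back to
    :func:`vbsa.bench.synthetic_cascade_fixture`, a synthetic cascade of the
    same size and qualitative behavior.
    """
    try:
        from importlib.resources import files

        path = files("vbsa").joinpath("data/mapk_cascade.yaml")
        text = path.read_text()
    except (FileNotFoundError, ModuleNotFoundError):
        raise FixtureUnavailableError(
            "MAPK cascade parameter file not available; use "
            "vbsa.bench.synthetic_cascade_fixture() instead"
        ) from None
    net = parse_network(text)
    if net.M != 21 or net.N != 23:
        raise ModelValidationError(
            f"MAPK fixture must have M=21, N=23 (got M={net.M}, N={net.N})"
        )
    return net
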