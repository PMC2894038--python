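"""Analysis configuration and end-to-end orchestration."""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, fields

import yaml

from . import __version__
from .errors import ConfigError
from .estimators import ESTIMATORS
from .factors import FactorSpace, make_response_function
from .network import parse_network
from .reporting import report_to_dict
from .responses import RESPONSE_DEFS, RESPONSE_KINDS, ResponseSpec
from .variance import classify, sesi_jesi


@dataclass
class AnalysisConfig:
    """Everything one sensitivity run needs; mirrors the CLI flags."""

    model: str = None             # model file path (None: pass network directly)
    mode: str = "rosa"
    response: str = "log_duration"
    species: str = None           # output species; defaults to the network's
    lam: float = 0.1              # perturbation level lambda (scalar or list)
    method: str = "oha"
    L: int = 6000                 # MC / OHA sample count
    S: int = 4                    # PA regression points per factor
    Q: int = 5                    # GHI quadrature order
    delta: float = 0.1            # DA finite-difference step
    seed: int = 0
    theta: float = 0.10           # classification threshold
    t_max: float = 21600.0
    eps: float = 1e-3
    n_points: int = 1201
    response_defs: str = "heinrich"
    rtol: float = 1e-8
    atol: float = 1e-10
    out: str = None               # report JSON path

    def __post_init__(self):
        if self.method not in ESTIMATORS:
            raise ConfigError(f"method must be one of {sorted(ESTIMATORS)}")
        if self.mode not in ("rosa", "sosa"):
            raise ConfigError("mode must be 'rosa' or 'sosa'")
        if self.response not in RESPONSE_KINDS:
            raise ConfigError(f"response must be one of {RESPONSE_KINDS}")
        if self.response_defs not in RESPONSE_DEFS:
            raise ConfigError(f"response_defs must be one of {RESPONSE_DEFS}")
        if not (0 < self.theta < 1):
            raise ConfigError("theta must lie in (0, 1)")


def load_config(text):
    """Parse a YAML config; unknown keys are rejected."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    if "lambda" in doc:   # YAML key mirrors the CLI flag
        doc["lam"] = doc.pop("lambda")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**doc)


def run_analysis(config, network=None):
    """Run one sensitivity analysis: parse model, build the factor space
    and counted response function, estimate (V_j, V_jj'), derive and
    classify SESI/JESI.

    Returns ``(report, report_dict)``; deterministic given the seed.
    """
    t_start = time.perf_counter()
    if network is None:
        if config.model is None:
            raise ConfigError("config.model or an explicit network is required")
        with open(config.model) as fh:
            network = parse_network(fh.read())
    species = config.species or getattr(network, "output_species", None)
    if species is None:
        raise ConfigError("no output species configured")

    space = FactorSpace.for_network(network, config.mode, config.lam)
    spec = ResponseSpec(
        species=species,
        kind=config.response,
        t_max=config.t_max,
        eps=config.eps,
        definitions=config.response_defs,
        n_points=config.n_points,
    )
    f = make_response_function(
        network, space, spec,
        solver_opts={"rtol": config.rtol, "atol": config.atol},
        cache=False,
    )
    method = config.method
    kwargs = {
        "mc": {"L": config.L, "seed": config.seed},
        "da": {"delta": config.delta},
        "pa": {"S": config.S},
        "ghi": {"Q": config.Q},
        "oha": {"L": config.L, "seed": config.seed},
    }[method]
    dec = ESTIMATORS[method](f, space, **kwargs)
    report = classify(sesi_jesi(dec, labels=space.labels), config.theta)

    cfg_echo = asdict(config)
    doc = report_to_dict(
        report,
        extra={
            "software": f"vbsa {__version__}",
            "mode": config.mode,
            "response": config.response,
            "species": species,
            "lambda": config.lam,
            "params": kwargs,
            "seed": config.seed,
            "evals_counted": f.eval_count,
            "wall_time_s": round(time.perf_counter() - t_start, 3),
            "config": cfg_echo,
        },
    )
    if config.out:
        import json

        with open(config.out, "w") as fh:
            json.dump(doc, fh, indent=1)
    return report, doc


def sweep_lambdas(config, lambdas, network=None):
    """Run one report per perturbation level (e.g. 0.1, 0.2, 0.3, 0.4)."""
    out = []
    for lam in lambdas:
        cfg = AnalysisConfig(**{**asdict(config), "lam": float(lam), "out": None})
        out.append(run_analysis(cfg, network=network))
    return out
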