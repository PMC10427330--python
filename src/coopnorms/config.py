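"""TOML run configuration: schema, defaults and validation.

A run config has a ``command`` key (simulate | equilibria | scan | regime
| cycles), a ``model`` block (threshold distribution, naive belief,
population size), a ``rates`` block and an optional command-specific
block.  Every applied default is logged; unknown keys and out-of-domain
values raise a validation error naming the key.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .bifurcation import SCAN_PARAMETERS
from .community import CommunityParams
from .threshold import NormSensitivity, naive_belief

__all__ = ["RunConfig", "load_config", "build_params", "DEFAULTS"]

logger = logging.getLogger(__name__)

COMMANDS = ("simulate", "equilibria", "scan", "regime", "cycles")

DEFAULTS: dict = {
    "model": {
        "mu": 0.5,
        "sigma2": 0.04,
        "p_tilde": "auto",
        "K": 1.0,
        # Reference distribution used to resolve p_tilde = "auto" (the
        # high-cooperation root of the bistable default threshold map).
        "reference_mu": 0.5,
        "reference_sigma2": 0.04,
    },
    "rates": {
        "inflow": 1.0,
        "learning": 1.0,
        "outflow": 0.2,
        "phi": 1.0,
    },
    "simulate": {
        # "founding" = a small seed community of naive believers;
        # alternatives: "random" (seeded) or a {S, I, y, p} table.
        "initial": "founding",
        "t_end": 100.0,
        "n_samples": 1001,
    },
    "scan": {
        "parameter": "ratio",
        "start": 0.05,
        "stop": 1.0,
        "num": 40,
    },
    "regime": {
        "sigma2_values": [0.01, 0.02, 0.03, 0.04, 0.06],
    },
    "cycles": {
        "inflow_values": [0.02, 0.05, 0.1, 0.2],
        "t_end": 3000.0,
        "n_samples": 6001,
        "transient_fraction": 0.5,
    },
    "equilibria": {},
}


class ConfigError(ValueError):
    """A configuration key is unknown or out of domain."""


@dataclass(frozen=True)
class RunConfig:
    command: str
    model: dict
    rates: dict
    options: dict = field(default_factory=dict)


#: Keys allowed in a section beyond the defaulted ones.
_OPTIONAL = {"scan": {"values"}}


def _merged(section: str, given: dict) -> dict:
    out = dict(DEFAULTS.get(section, {}))
    allowed = set(out) | _OPTIONAL.get(section, set())
    for key in given:
        if key not in allowed:
            raise ConfigError(f"unknown key {section}.{key!r}")
    out.update(given)
    for key, val in DEFAULTS.get(section, {}).items():
        if key not in given:
            logger.info("config: using default %s.%s = %r", section, key, val)
    return out


def _require(cond: bool, key: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for {key!r}: {message}")


def load_config(path, command: str | None = None) -> RunConfig:
    """Parse and validate a TOML run configuration.

    ``command`` (e.g. from a CLI subcommand) overrides the file's own
    ``command`` key; the override is logged.
    """
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)

    known = set(COMMANDS) | {"command", "model", "rates"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown top-level key {key!r}")

    file_command = raw.get("command")
    if command is not None and command != file_command:
        if file_command is not None:
            logger.info(
                "CLI subcommand %r takes precedence over config command %r",
                command, file_command,
            )
        file_command = command
    command = file_command
    if command not in COMMANDS:
        raise ConfigError(f"invalid value for 'command': {command!r}; expected one of {COMMANDS}")

    model = _merged("model", raw.get("model", {}))
    rates = _merged("rates", raw.get("rates", {}))
    options = _merged(command, raw.get(command, {}))

    _require(0.0 < model["mu"] < 1.0, "model.mu", "mean must lie in (0, 1)")
    _require(
        isinstance(model["sigma2"], (int, float)) and model["sigma2"] > 0,
        "model.sigma2",
        f"variance must be positive, got {model['sigma2']}",
    )
    pt = model["p_tilde"]
    _require(
        pt == "auto" or (isinstance(pt, (int, float)) and 0.0 < pt <= 1.0),
        "model.p_tilde",
        "naive belief must be 'auto' or in (0, 1]",
    )
    _require(model["K"] > 0, "model.K", "population size must be positive")
    _require(0.0 < model["reference_mu"] < 1.0, "model.reference_mu", "must lie in (0, 1)")
    _require(model["reference_sigma2"] > 0, "model.reference_sigma2",
             "variance must be positive")
    for key in ("inflow", "learning", "outflow", "phi"):
        _require(rates[key] >= 0, f"rates.{key}", "rates must be non-negative")

    if command == "scan":
        _require(
            options["parameter"] in SCAN_PARAMETERS,
            "scan.parameter",
            f"expected one of {SCAN_PARAMETERS}",
        )
        if "values" not in options:
            _require(options["start"] < options["stop"], "scan.start", "start must be < stop")
            _require(int(options["num"]) >= 2, "scan.num", "need at least 2 grid points")
    if command == "cycles":
        _require(len(options["inflow_values"]) > 0, "cycles.inflow_values", "must be non-empty")
        _require(options["t_end"] > 0, "cycles.t_end", "must be positive")
    if command == "simulate":
        _require(options["t_end"] > 0, "simulate.t_end", "must be positive")
        _require(int(options["n_samples"]) >= 2, "simulate.n_samples", "need >= 2 samples")

    return RunConfig(command=command, model=model, rates=rates, options=options)


def build_params(config: RunConfig) -> CommunityParams:
    """Construct model parameters from a validated config.

    ``p_tilde = "auto"`` resolves to the high-cooperation fixed point of
    the reference threshold distribution; a monostable reference is an
    error.
    """
    norms = NormSensitivity(config.model["mu"], config.model["sigma2"])
    pt = config.model["p_tilde"]
    if pt == "auto":
        reference = NormSensitivity(
            config.model["reference_mu"], config.model["reference_sigma2"]
        )
        pt = naive_belief(reference)
        logger.info("config: resolved p_tilde = 'auto' to %.12g", pt)
    return CommunityParams(
        inflow_rate=config.rates["inflow"],
        learning_rate=config.rates["learning"],
        outflow_rate=config.rates["outflow"],
        resusceptibility=config.rates["phi"],
        K=config.model["K"],
        p_tilde=float(pt),
        norms=norms,
    )
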