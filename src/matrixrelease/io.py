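"""Configuration parsing, result serialization and named parameter fixtures."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .analysis import ConstantRateRegion, DeviationSummary
from .core import DimensionlessParams, PhysicalParams, nondimensionalize
from .pde import Mesh, ReleaseCurve, SolverOptions

__all__ = ["RunConfig", "load_config", "write_results", "make_fixture", "FIXTURES"]

_MODES = {"simulate", "analytic", "higuchi", "constant-rate", "deviation", "sweep"}

_PHYSICAL_KEYS = {"D", "k", "A0", "r0", "Cs", "Ca0", "n"}
_DIMENSIONLESS_KEYS = {"K", "G", "n"}
_SOLVER_KEYS = {"mesh", "rel_tol", "abs_tol", "quad_rel_tol", "front_epsilon",
                "tau_end"}


def _pkg_version() -> str:
    try:
        return version("matrixrelease")
    except PackageNotFoundError:  # pragma: no cover - editable edge case
        return "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Fully validated run description: mode, parameters, solver settings."""

    mode: str
    params: DimensionlessParams
    mesh: Mesh = field(default_factory=Mesh)
    solver: SolverOptions = field(default_factory=SolverOptions)
    tau_end: float | None = None
    physical: PhysicalParams | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    The file must contain exactly one of a ``physical:`` block
    (D, k, A0, r0, Cs, Ca0, n) or a ``dimensionless:`` block (K, G, n),
    an optional ``mode`` (default ``simulate``) and an optional
    ``solver:`` block (mesh, rel_tol, abs_tol, quad_rel_tol,
    front_epsilon, tau_end).  Unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")

    known_top = {"mode", "physical", "dimensionless", "solver"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    mode = raw.get("mode", "simulate")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")

    has_phys = "physical" in raw
    has_dim = "dimensionless" in raw
    if has_phys == has_dim:
        raise ValueError(
            "config must contain exactly one of 'physical' or 'dimensionless'"
        )

    physical = None
    if has_phys:
        block = dict(raw["physical"])
        unknown = set(block) - _PHYSICAL_KEYS
        if unknown:
            raise ValueError(f"unknown physical keys: {sorted(unknown)}")
        physical = PhysicalParams(**block)
        params = nondimensionalize(physical)
    else:
        block = dict(raw["dimensionless"])
        unknown = set(block) - _DIMENSIONLESS_KEYS
        if unknown:
            raise ValueError(f"unknown dimensionless keys: {sorted(unknown)}")
        params = DimensionlessParams(**block)

    solver_block = dict(raw.get("solver", {}))
    unknown = set(solver_block) - _SOLVER_KEYS
    if unknown:
        raise ValueError(f"unknown solver keys: {sorted(unknown)}")
    mesh = Mesh(int(solver_block.pop("mesh", 2000)))
    tau_end = solver_block.pop("tau_end", None)
    solver = SolverOptions(**solver_block)
    return RunConfig(
        mode=mode,
        params=params,
        mesh=mesh,
        solver=solver,
        tau_end=None if tau_end is None else float(tau_end),
        physical=physical,
    )


def _sidecar(params: DimensionlessParams, solver: SolverOptions | None,
             extra: dict | None = None) -> dict:
    meta = {
        "params": {"K": params.K, "G": params.G, "n": params.n},
        "package_version": _pkg_version(),
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    if solver is not None:
        meta["solver"] = {
            "rel_tol": solver.rel_tol,
            "abs_tol": solver.abs_tol,
            "quad_rel_tol": solver.quad_rel_tol,
            "front_epsilon": solver.front_epsilon,
        }
    if extra:
        meta.update(extra)
    return meta


def write_results(result, path: str | Path,
                  solver: SolverOptions | None = None) -> Path:
    """Write a result object as CSV plus a JSON metadata sidecar.

    Floats are written with 17 significant digits (lossless for doubles,
    so written curves roundtrip exactly); the sidecar (same stem,
    ``.json`` suffix) records the parameters, solver options, package
    version and timestamp so any run can be reproduced from it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if isinstance(result, ReleaseCurve):
        df = pd.DataFrame(
            {
                "tau": result.tau,
                "fraction_released": result.fraction_released,
                "rate": result.rate,
                "eta_star": result.eta_star,
            }
        )
        meta = _sidecar(result.params, solver, {"kind": "release_curve"})
    elif isinstance(result, ConstantRateRegion):
        df = pd.DataFrame(
            [
                {
                    "tau_s": result.tau_s,
                    "tau_c": result.tau_c,
                    "rate_start": result.rate_start,
                    "rate_end": result.rate_end,
                    "rate_middle": result.rate_middle,
                    "coverage_percent": result.coverage_percent,
                    "no_region": result.no_region,
                }
            ]
        )
        meta = {"kind": "constant_rate_region", "written_at":
                datetime.now(timezone.utc).isoformat(),
                "package_version": _pkg_version()}
    elif isinstance(result, DeviationSummary):
        df = pd.DataFrame({"tau": result.tau_grid, "deviation": result.deviation})
        meta = {
            "kind": "deviation_summary",
            "max_deviation": result.max_deviation,
            "max_deviation_percent": result.max_deviation_percent,
            "tau_at_max": result.tau_at_max,
            "extremum_at_endpoint": result.extremum_at_endpoint,
            "package_version": _pkg_version(),
            "written_at": datetime.now(timezone.utc).isoformat(),
        }
    elif isinstance(result, pd.DataFrame):
        df = result
        meta = {"kind": "sweep", "rows": len(result),
                "package_version": _pkg_version(),
                "written_at": datetime.now(timezone.utc).isoformat()}
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")

    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
    return path


def write_profiles(states, path: str | Path) -> Path:
    """Write a sequence of radial profiles as long-format CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"tau": s.tau, "eta": s.eta, "phi": s.phi, "phi_a": s.phi_a}
        )
        for s in states
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def _fixture_table() -> dict[str, DimensionlessParams]:
    """Named parameterizations of the reference release experiments."""
    fixtures: dict[str, DimensionlessParams] = {}
    # oracle-validation cases: fixed G = 1e3 over K, and K = 1/101 over G
    for K, label in [(1 / 101, "K101"), (1 / 11, "K11"), (1 / 2, "K2")]:
        fixtures[f"validation_fixedG_{label}"] = DimensionlessParams(
            K=K, G=1e3, n=0.0
        )
    for G, label in [(10.0, "G10"), (1e2, "G100"), (1e3, "G1000")]:
        fixtures[f"validation_fixedK_{label}"] = DimensionlessParams(
            K=1 / 101, G=G, n=0.0
        )
    # zero-order window study: 2 K x 3 G x 3 shapes
    for K, klabel in [(1 / 2, "K2"), (1 / 101, "K101")]:
        for G, glabel in [(0.1, "G0.1"), (1.0, "G1"), (10.0, "G10")]:
            for n, nlabel in [(0.0, "n0"), (0.5, "n12"), (2 / 3, "n23")]:
                fixtures[f"window_{klabel}_{glabel}_{nlabel}"] = (
                    DimensionlessParams(K=K, G=G, n=n)
                )
    # Higuchi-deviation study: 3 K x 4 G, spherical particles
    for K, klabel in [(1 / 2, "K2"), (1 / 11, "K11"), (1 / 101, "K101")]:
        for G, glabel in [(1.0, "G1"), (10.0, "G10"), (1e3, "G1000"),
                          (1e5, "G100000")]:
            fixtures[f"deviation_{klabel}_{glabel}"] = DimensionlessParams(
                K=K, G=G, n=2 / 3
            )
    return fixtures


FIXTURES = _fixture_table()


def make_fixture(case_id: str) -> DimensionlessParams:
    """Parameters of a named reference experiment (see :data:`FIXTURES`)."""
    try:
        return FIXTURES[case_id]
    except KeyError:
        raise KeyError(
            f"unknown fixture {case_id!r}; valid cases: {sorted(FIXTURES)}"
        ) from None
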