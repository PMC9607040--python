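"""Parametric sweeps over the observables, with shipped figure recipes.

A :class:`SweepSpec` fixes a base parameter set, one swept parameter with a
value list, an observable, an abscissa grid (``y`` for profiles, ``alpha``
for flow-rate/wall-slip curves) and the model variants to run.  The result
is a long-format table with one row per (swept value, abscissa value,
variant).

The shipped recipes encode the parametric studies of the source figures
(traveling-wave streaming in the weakly and strongly elastic regimes).
Where a study's legend values are not fixed by its caption, the recipe
documents a default list; for the high-Reynolds flow-rate study the default
relaxation times are small (``alpha * lambda1 * R = O(10)``) because the
elasticity scale at ``R = 1e4`` makes order-unity ``lambda1`` deeply
resonant, where no smooth single-valued flow-rate curve exists.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .errors import PeristreamError
from .observables import compute_observables
from .params import FlowParameters, Variant

log = logging.getLogger(__name__)

OBSERVABLES = ("G", "mean_u", "Q", "d_wall")
PROFILE_OBSERVABLES = ("G", "mean_u")


@dataclass(frozen=True)
class SweepSpec:
    base: FlowParameters
    sweep_parameter: str
    sweep_values: tuple[float, ...]
    observable: str
    grid: tuple[float, ...]
    variants: tuple[Variant, ...] = (Variant.LINEAR, Variant.UCM)

    def __post_init__(self):
        if self.observable not in OBSERVABLES:
            raise ValueError(f"observable must be one of {OBSERVABLES}")
        if len(self.sweep_values) == 0:
            raise ValueError("sweep_values must be non-empty")
        vals = np.asarray(self.sweep_values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("sweep_values must be finite")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or not np.all(np.diff(g) > 0):
            raise ValueError("grid must be non-empty and strictly monotone")
        object.__setattr__(self, "variants",
                           tuple(Variant.coerce(v) for v in self.variants))

    @property
    def abscissa(self) -> str:
        return "y" if self.observable in PROFILE_OBSERVABLES else "alpha"


@dataclass(frozen=True)
class SweepResult:
    table: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """Comma-separated, '.' decimal, header row; metadata as '#' lines."""
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, index=False)

    @staticmethod
    def read_csv(path) -> pd.DataFrame:
        return pd.read_csv(path, comment="#")


def _observable_values(spec: SweepSpec, params: FlowParameters, grid: np.ndarray) -> np.ndarray:
    if spec.observable in PROFILE_OBSERVABLES:
        obs = compute_observables(params)
        so = obs.second_order
        if spec.observable == "G":
            from .observables import perturbation_G

            return np.asarray(perturbation_G(so.E, params, grid), dtype=float)
        return params.epsilon**2 * np.asarray(so.U20(grid), dtype=float)
    # alpha-abscissa scalars: one solve per grid point
    out = np.empty(grid.size, dtype=float)
    for i, a in enumerate(grid):
        obs = compute_observables(params.with_(alpha=float(a)), n_y=3)
        out[i] = obs.Q if spec.observable == "Q" else obs.d_wall
    return out


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run the sweep; per-point failures are logged and skipped (NaN rows),
    and an aggregate error is raised if more than half the points fail."""
    grid = np.asarray(spec.grid, dtype=float)
    rows = []
    failures = 0
    total = 0
    for value in spec.sweep_values:
        for variant in spec.variants:
            params = spec.base.with_(**{spec.sweep_parameter: value}, variant=variant)
            total += 1
            try:
                vals = _observable_values(spec, params, grid)
            except PeristreamError as exc:
                failures += 1
                log.warning("sweep point failed (%s=%s, %s): %s",
                            spec.sweep_parameter, value, variant.value, exc)
                vals = np.full(grid.size, np.nan)
            for x, v in zip(grid, vals):
                rows.append({
                    spec.sweep_parameter: value,
                    spec.abscissa: x,
                    "variant": variant.value,
                    spec.observable: v,
                })
    if failures > total // 2:
        raise PeristreamError(f"{failures}/{total} sweep points failed")
    table = pd.DataFrame(rows)
    meta = {
        "package_version": _pkg_version,
        "observable": spec.observable,
        "sweep_parameter": spec.sweep_parameter,
        "base_params": spec.base.to_mapping(),
        "n_failures": failures,
    }
    return SweepResult(table=table, metadata=meta)


# ---------------------------------------------------------------------------
# config mapping <-> spec

def spec_from_config(config: Mapping[str, Any]) -> SweepSpec:
    """Build a sweep spec from a flat mapping (YAML-friendly).

    Keys: the flat parameter keys (alpha, reynolds, chi, lambda1, epsilon),
    plus observable, sweep_parameter, sweep_values, variants, and either
    ``grid`` (explicit list) or ``grid_start``/``grid_stop``/``grid_num``.
    """
    cfg = dict(config)
    observable = cfg.pop("observable")
    sweep_parameter = cfg.pop("sweep_parameter")
    sweep_values = tuple(float(v) for v in cfg.pop("sweep_values"))
    variants = tuple(cfg.pop("variants", ("LINEAR", "UCM")))
    if "grid" in cfg:
        grid = tuple(float(v) for v in cfg.pop("grid"))
    else:
        grid = tuple(np.linspace(float(cfg.pop("grid_start")),
                                 float(cfg.pop("grid_stop")),
                                 int(cfg.pop("grid_num"))))
    cfg.setdefault("variant", variants[0])
    base = FlowParameters.from_mapping(cfg)
    return SweepSpec(base=base, sweep_parameter=sweep_parameter,
                     sweep_values=sweep_values, observable=observable,
                     grid=grid, variants=variants)


def _alpha_grid(num: int = 200, start: float = 0.01, stop: float = 2.0):
    return {"grid_start": start, "grid_stop": stop, "grid_num": num}


def _y_grid(num: int = 201, start: float = 0.0, stop: float = 1.0):
    return {"grid_start": start, "grid_stop": stop, "grid_num": num}


#: figure recipes: caption parameters transcribed; legend lists are
#: documented defaults where the captions leave them open
FIGURE_RECIPES: dict[str, dict[str, Any]] = {
    # G(y) for several relaxation times; R=10, chi=0.3, alpha=0.5
    "fig2": {"observable": "G", "sweep_parameter": "lambda1",
             "sweep_values": [0.0, 0.2, 0.5, 1.0],
             "alpha": 0.5, "reynolds": 10.0, "chi": 0.3, "epsilon": 0.1,
             **_y_grid()},
    # G(y) for several compressibilities; R=100, alpha=0.5, lambda1=0.5
    "fig3": {"observable": "G", "sweep_parameter": "chi",
             "sweep_values": [0.001, 0.2, 0.4, 0.6],
             "alpha": 0.5, "reynolds": 100.0, "lambda1": 0.5, "epsilon": 0.1,
             **_y_grid()},
    # D_wall vs alpha for several relaxation times; R=50, chi=0.001
    "fig4": {"observable": "d_wall", "sweep_parameter": "lambda1",
             "sweep_values": [0.0, 0.5, 1.0, 5.0],
             "alpha": 0.5, "reynolds": 50.0, "chi": 0.001, "epsilon": 0.1,
             **_alpha_grid()},
    # D_wall vs alpha for several compressibilities; R=10, lambda1=1
    "fig5": {"observable": "d_wall", "sweep_parameter": "chi",
             "sweep_values": [0.1, 0.3, 0.6],
             "alpha": 0.5, "reynolds": 10.0, "lambda1": 1.0, "epsilon": 0.1,
             **_alpha_grid()},
    # <u>(y) for several relaxation times; R=10, alpha=0.5, chi=0.05
    "fig6": {"observable": "mean_u", "sweep_parameter": "lambda1",
             "sweep_values": [0.5, 1.0, 2.0, 5.0],
             "alpha": 0.5, "reynolds": 10.0, "chi": 0.05, "epsilon": 0.1,
             **_y_grid(start=-1.0)},
    # <u>(y) for several compressibilities; alpha=0.4, lambda1=0.5; R=10 / R=1
    "fig7a": {"observable": "mean_u", "sweep_parameter": "chi",
              "sweep_values": [0.1, 0.3, 0.6],
              "alpha": 0.4, "reynolds": 10.0, "lambda1": 0.5, "epsilon": 0.1,
              **_y_grid(start=-1.0)},
    "fig7b": {"observable": "mean_u", "sweep_parameter": "chi",
              "sweep_values": [0.1, 0.3, 0.6],
              "alpha": 0.4, "reynolds": 1.0, "lambda1": 0.5, "epsilon": 0.1,
              **_y_grid(start=-1.0)},
    # <Q> vs alpha for several relaxation times; R=1e4, chi=0.3.  Default
    # legend keeps alpha*lambda1*R = O(10): see module docstring.
    "fig8": {"observable": "Q", "sweep_parameter": "lambda1",
             "sweep_values": [0.0, 0.001, 0.002, 0.005],
             "alpha": 0.5, "reynolds": 1.0e4, "chi": 0.3, "epsilon": 0.1,
             **_alpha_grid()},
    # <Q> vs alpha at lambda1=10000; R=1e4, chi=0.6 (strongly elastic)
    "fig9": {"observable": "Q", "sweep_parameter": "lambda1",
             "sweep_values": [10000.0],
             "alpha": 0.5, "reynolds": 1.0e4, "chi": 0.6, "epsilon": 0.1,
             **_alpha_grid(num=160)},
}


def figure_spec(name: str, **overrides: Any) -> SweepSpec:
    """Spec for a shipped figure recipe, with optional config overrides."""
    if name not in FIGURE_RECIPES:
        raise KeyError(f"unknown recipe {name!r}; have {sorted(FIGURE_RECIPES)}")
    cfg = {**FIGURE_RECIPES[name], **overrides}
    return spec_from_config(cfg)
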