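"""Run configuration: presets, flat YAML configs, validation.

A run config resolves, before any compute starts, to a model parameter set,
a lattice, an initial condition, optional clones, and integration settings.
Unknown keys are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .lattice import CellLattice, build_chain, build_hex_disc, build_hex_rect
from .model_core import HillSpec, ModelParams, Variant
from .perturbations import CloneCondition, CloneSpec, disc_clone_cells, rect_clone_cells
from .simulate import ICKind, InitialCondition

__all__ = [
    "PRESETS",
    "load_preset",
    "params_from_dict",
    "params_to_dict",
    "RunConfig",
    "load_config",
    "dump_config",
]

PRESETS = ("fig2a", "fig2b", "fig2e", "fig3", "fig4a", "fig4b")

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def params_from_dict(d: dict) -> ModelParams:
    unknown = set(d) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    d = dict(d)
    if "variant" in d:
        d["variant"] = Variant(d["variant"])
    if "hill_specs" in d:
        d["hill_specs"] = {k: HillSpec(**v) for k, v in d["hill_specs"].items()}
    return ModelParams(**d)


def params_to_dict(params: ModelParams) -> dict:
    d = dataclasses.asdict(params)
    d["variant"] = params.variant.value
    d["hill_specs"] = {k: {"exponent": s.exponent, "threshold": s.threshold}
                       for k, s in params.hill_specs.items()}
    return d


def load_preset(name: str) -> ModelParams:
    """Load a named parameter preset shipped with the package."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("pnwave.presets").joinpath(f"{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    hills = raw.pop("hills", {})
    params = {k: v for k, v in raw.items()}
    if hills:
        params["hill_specs"] = hills
    return params_from_dict(params)


_LATTICE_KEYS = {"kind", "n", "n_cols", "n_rows", "radius"}
_IC_KEYS = {"kind", "amplitude", "n_columns", "theta", "cells"}
_CLONE_KEYS = {"condition", "magnitude", "shape", "cells",
               "col_range", "row_range", "center", "radius"}
_INTEGRATION_KEYS = {"t_end", "dt", "record_every", "seed"}
_TOP_KEYS = {"preset", "params", "lattice", "initial_condition", "clones",
             "integration", "output", "log_level"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """A fully validated simulation request."""

    params: ModelParams
    lattice_spec: dict = field(default_factory=lambda: {"kind": "chain", "n": 100})
    ic_spec: dict = field(default_factory=lambda: {"kind": "LEFT_COLUMNS"})
    clone_specs: list[dict] = field(default_factory=list)
    t_end: float = 25.0
    dt: float | None = None
    record_every: float = 0.5
    seed: int | None = None
    output: str | None = None
    log_level: str = "INFO"

    def build_lattice(self) -> CellLattice:
        spec = self.lattice_spec
        kind = spec["kind"].lower()
        if kind == "chain":
            return build_chain(int(spec.get("n", 100)))
        if kind in ("hex_rect", "hex"):
            return build_hex_rect(int(spec.get("n_cols", 20)), int(spec.get("n_rows", 20)))
        if kind in ("hex_disc", "disc"):
            return build_hex_disc(float(spec.get("radius", 15)))
        raise ValueError(f"unknown lattice kind {spec['kind']!r}")

    def build_ic(self) -> InitialCondition:
        spec = dict(self.ic_spec)
        kind = ICKind(spec.pop("kind", "LEFT_COLUMNS"))
        kw = {}
        if "amplitude" in spec:
            kw["amplitude"] = spec["amplitude"]
        if "n_columns" in spec:
            kw["n_columns"] = int(spec["n_columns"])
        if "theta" in spec:
            kw["theta"] = tuple(float(t) for t in spec["theta"])
        if "cells" in spec:
            kw["cells"] = tuple(int(c) for c in spec["cells"])
        return InitialCondition(kind=kind, **kw)

    def build_clones(self, lattice: CellLattice) -> list[CloneSpec]:
        out = []
        for spec in self.clone_specs:
            cond = CloneCondition(spec["condition"])
            shape = spec.get("shape", "cells")
            if shape == "cells":
                cells = tuple(int(c) for c in spec["cells"])
            elif shape == "rect":
                cells = rect_clone_cells(lattice, tuple(spec["col_range"]),
                                         tuple(spec["row_range"]))
            elif shape == "disc":
                cells = disc_clone_cells(lattice, int(spec["center"]),
                                         float(spec["radius"]))
            else:
                raise ValueError(f"unknown clone shape {shape!r}")
            out.append(CloneSpec(cells=cells, condition=cond,
                                 magnitude=spec.get("magnitude")))
        return out

    def validate(self) -> "RunConfig":
        _check_keys(self.lattice_spec, _LATTICE_KEYS, "lattice")
        _check_keys(self.ic_spec, _IC_KEYS, "initial_condition")
        for i, c in enumerate(self.clone_specs):
            _check_keys(c, _CLONE_KEYS, f"clones[{i}]")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.params.gamma > 0 and self.seed is None:
            raise ValueError("stochastic config (gamma > 0) requires a seed")
        # dry-build everything so invalid configs fail before any compute
        lat = self.build_lattice()
        self.build_ic()
        self.build_clones(lat)
        return self


def load_config(path) -> RunConfig:
    """Read and validate a YAML run config; defaults filled, unknown keys
    rejected with the offending key named."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check_keys(raw, _TOP_KEYS, "config")
    if "preset" in raw and "params" in raw:
        raise ValueError("give either 'preset' or 'params', not both")
    if "preset" in raw:
        params = load_preset(raw["preset"])
    elif "params" in raw:
        p = dict(raw["params"])
        hills = p.pop("hills", None)
        if hills:
            p["hill_specs"] = hills
        params = params_from_dict(p)
    else:
        raise ValueError("config needs a 'preset' or a 'params' section")
    integ = dict(raw.get("integration", {}))
    _check_keys(integ, _INTEGRATION_KEYS, "integration")
    cfg = RunConfig(
        params=params,
        lattice_spec=dict(raw.get("lattice", {"kind": "chain", "n": 100})),
        ic_spec=dict(raw.get("initial_condition", {"kind": "LEFT_COLUMNS"})),
        clone_specs=list(raw.get("clones", [])),
        t_end=float(integ.get("t_end", 25.0)),
        dt=integ.get("dt"),
        record_every=float(integ.get("record_every", 0.5)),
        seed=integ.get("seed"),
        output=raw.get("output"),
        log_level=raw.get("log_level", "INFO"),
    )
    return cfg.validate()


def dump_config(cfg: RunConfig, path) -> None:
    doc = {
        "params": {**{k: v for k, v in params_to_dict(cfg.params).items()
                      if k != "hill_specs"},
                   "hills": params_to_dict(cfg.params)["hill_specs"]},
        "lattice": cfg.lattice_spec,
        "initial_condition": cfg.ic_spec,
        "clones": cfg.clone_specs,
        "integration": {k: v for k, v in
                        [("t_end", cfg.t_end), ("dt", cfg.dt),
                         ("record_every", cfg.record_every), ("seed", cfg.seed)]
                        if v is not None},
        "output": cfg.output,
        "log_level": cfg.log_level,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
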