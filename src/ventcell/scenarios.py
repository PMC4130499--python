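"""Named scenario presets and sweep drivers.

Each preset resolves to a complete configuration (every value defaulted and
recorded) and optionally carries sweep axes.  The registry covers the
published figure-level experiments: permeability and gradient sweeps with
the ATPase or Ech alone, pumping with and without a gradient, the
antiporter (SPAP) series, pump+SPAP synergy, turnover-efficiency and
stoichiometry sensitivity, and external-pH fluctuations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import build_runspec, default_config, merge_config, set_by_path
from .simulator import SimConfig, SimResult

__all__ = [
    "SweepAxis",
    "Scenario",
    "FluctuationSpec",
    "SCENARIOS",
    "list_scenarios",
    "resolve_scenario",
    "run_scenario",
    "run_sweep",
    "fluctuating_run",
    "acid_adaptation_sweep",
]

PERMEABILITY_GRID = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)  # cm/s
THREE_UNIT_GRADIENTS = ((5.0, 8.0), (6.0, 9.0), (7.0, 10.0))


@dataclass(frozen=True)
class SweepAxis:
    """One swept parameter: a dotted config path with its values, or a
    labelled list of override bundles (dict values), for covarying pairs
    such as (ph_acid, ph_alk) gradients."""

    name: str
    values: tuple

    def apply(self, config: dict, value) -> None:
        if isinstance(value, dict):
            for path, entry in value.items():
                set_by_path(config, path, entry)
        else:
            set_by_path(config, self.name, value)

    def label(self, value) -> str:
        if isinstance(value, dict):
            return "/".join(str(v) for v in value.values())
        return str(value)


def _gradient_axis(pairs) -> SweepAxis:
    return SweepAxis(
        name="gradient",
        values=tuple(
            {"environment.ph_acid": acid, "environment.ph_alk": alk}
            for acid, alk in pairs
        ),
    )


@dataclass(frozen=True)
class Scenario:
    """A named preset: sparse overrides on the default config plus axes."""

    name: str
    description: str
    overrides: dict = field(default_factory=dict)
    axes: tuple[SweepAxis, ...] = ()
    reference_only: bool = False

    def resolve(self, user_overrides: dict | None = None) -> dict:
        """Fully resolved nested config; user overrides win and are recorded."""
        config = merge_config(default_config(), self.overrides)
        if user_overrides:
            config = merge_config(config, user_overrides)
        return config


def _s(name, description, overrides, axes=(), **kw) -> Scenario:
    return Scenario(name, description, overrides, tuple(axes), **kw)


_BASE_ATPASE = {"proteins": {"atpase": {"surface_fraction": 0.01}}}

SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        _s(
            "fig3a",
            "1% ATPase, 7:10 gradient, H+ permeability swept 1e-2..1e-6 cm/s",
            _BASE_ATPASE,
            [SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID)],
        ),
        _s(
            "fig3b",
            "1% ATPase at tight membrane (1e-6 cm/s), 3-unit gradients swept",
            {
                "proteins": {"atpase": {"surface_fraction": 0.01}},
                "membrane": {"permeability_h_cm_s": 1e-6},
            },
            [_gradient_axis(THREE_UNIT_GRADIENTS)],
        ),
        _s(
            "fig3c",
            "ATPase crowding at 1e-3 cm/s, surface fraction swept",
            {"membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.atpase.surface_fraction", (0.01, 0.05, 0.10, 0.50))],
        ),
        _s(
            "fig3d",
            "Ech instead of ATPase at 1e-3 cm/s, surface fraction swept",
            {"membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.ech.surface_fraction", (0.01, 0.05, 0.10, 0.50))],
        ),
        _s(
            "fig4a",
            "H+ pump without SPAP: 1% ATPase, pump fraction x permeability",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "pump": {"pumped_ion": "H"}}},
            [
                SweepAxis("proteins.pump.surface_fraction", (0.01, 0.05)),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig4b",
            "Na+ pump without SPAP: 1% ATPase, pump fraction x permeability",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "pump": {"pumped_ion": "Na"}}},
            [
                SweepAxis("proteins.pump.surface_fraction", (0.01, 0.05)),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig4cd",
            "Pumping without a gradient: both fluids at pH 7, 5% pump",
            {
                "environment": {"ph_acid": 7.0, "ph_alk": 7.0},
                "proteins": {"atpase": {"surface_fraction": 0.01},
                             "pump": {"surface_fraction": 0.05}},
            },
            [
                SweepAxis("proteins.pump.pumped_ion", ("H", "Na")),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig5a",
            "SPAP time course: 1% ATPase, 1e-3 cm/s, 7:10, SPAP 0 vs 5%",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.spap.surface_fraction", (0.0, 0.05))],
        ),
        _s(
            "fig5b",
            "SPAP saturation across 3-unit gradients, 1% ATPase, 1e-3 cm/s",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [
                _gradient_axis(THREE_UNIT_GRADIENTS),
                SweepAxis("proteins.spap.surface_fraction", (0.0, 0.01, 0.05, 0.10)),
            ],
        ),
        _s(
            "fig5c",
            "SPAP in shallow gradients (alkaline side fixed at pH 10)",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [
                SweepAxis("environment.ph_acid", (7.0, 7.5, 8.0, 8.5)),
                SweepAxis("proteins.spap.surface_fraction", (0.01, 0.10)),
            ],
        ),
        _s(
            "fig6a",
            "H+ pump with 1% SPAP: pump fraction x permeability, 7:10",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "spap": {"surface_fraction": 0.01},
                          "pump": {"pumped_ion": "H"}}},
            [
                SweepAxis("proteins.pump.surface_fraction", (0.01, 0.05)),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig6b",
            "Na+ pump with 1% SPAP: pump fraction x permeability, 7:10",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "spap": {"surface_fraction": 0.01},
                          "pump": {"pumped_ion": "Na"}}},
            [
                SweepAxis("proteins.pump.surface_fraction", (0.01, 0.05)),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig6c",
            "SPAP + 5% H+ pump in shallower gradients (alkaline pH 10)",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "spap": {"surface_fraction": 0.01},
                          "pump": {"surface_fraction": 0.05, "pumped_ion": "H"}}},
            [
                SweepAxis("environment.ph_acid", (7.0, 7.5, 8.5)),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "fig6d",
            "SPAP + 5% pump with no gradient (both fluids pH 7)",
            {
                "environment": {"ph_acid": 7.0, "ph_alk": 7.0},
                "proteins": {"atpase": {"surface_fraction": 0.01},
                             "spap": {"surface_fraction": 0.01},
                             "pump": {"surface_fraction": 0.05}},
            },
            [
                SweepAxis("proteins.pump.pumped_ion", ("H", "Na")),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "figS1",
            "Turnover efficiency 10/50/100%: 5% pump, 1% ATPase, 1% SPAP, 7:10",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "spap": {"surface_fraction": 0.01},
                          "pump": {"surface_fraction": 0.05, "pumped_ion": "H"}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [
                SweepAxis(
                    "efficiency",
                    tuple(
                        {
                            "proteins.atpase.efficiency_scale": e,
                            "proteins.spap.efficiency_scale": e,
                            "proteins.pump.efficiency_scale": e,
                        }
                        for e in (0.1, 0.5, 1.0)
                    ),
                ),
            ],
        ),
        _s(
            "figS2",
            "ATPase stoichiometry 3.3 vs 6 ions/ATP, 1% ATPase, 1e-3 cm/s",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.atpase.ions_per_cycle", (3.3, 6.0))],
        ),
        _s(
            "figS3",
            "Fluctuating acid-side pH (alkaline fixed at 10), +/- 5% SPAP",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.spap.surface_fraction", (0.0, 0.05))],
        ),
        _s(
            "figS4",
            "Fluctuating alkaline-side pH (acid fixed at 7), +/- 5% SPAP",
            {"proteins": {"atpase": {"surface_fraction": 0.01}},
             "membrane": {"permeability_h_cm_s": 1e-3}},
            [SweepAxis("proteins.spap.surface_fraction", (0.0, 0.05))],
        ),
        _s(
            "figS5",
            "Acid adaptation: 3-unit gradients x permeability, 5% H+ pump + SPAP",
            {"proteins": {"atpase": {"surface_fraction": 0.01},
                          "spap": {"surface_fraction": 0.01},
                          "pump": {"surface_fraction": 0.05, "pumped_ion": "H"}}},
            [
                _gradient_axis(THREE_UNIT_GRADIENTS),
                SweepAxis("membrane.permeability_h_cm_s", PERMEABILITY_GRID),
            ],
        ),
        _s(
            "open_system",
            "Open-system reference: interior clamped to the alkaline fluid",
            _BASE_ATPASE,
            (),
            reference_only=True,
        ),
    ]
}


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def resolve_scenario(name: str, user_overrides: dict | None = None) -> tuple[Scenario, dict]:
    """Look up a preset and resolve its config; unknown names list options."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(list_scenarios())}"
        )
    scenario = SCENARIOS[name]
    return scenario, scenario.resolve(user_overrides)


def run_scenario(name: str, user_overrides: dict | None = None) -> SimResult:
    """Run a preset as a single simulation (first value of each sweep axis)."""
    scenario, config = resolve_scenario(name, user_overrides)
    for axis in scenario.axes:
        axis.apply(config, axis.values[0])
    spec = build_runspec(config)
    return spec.cell().run(spec.sim)


def run_sweep(
    name_or_scenario: str | Scenario,
    user_overrides: dict | None = None,
) -> pd.DataFrame:
    """Execute the full Cartesian product of a scenario's sweep axes.

    One row per grid cell, in deterministic (itertools.product) order, with
    the steady-state summary of each run; a failed run is recorded in-row
    under ``error`` and the sweep continues.
    """
    if isinstance(name_or_scenario, Scenario):
        scenario = name_or_scenario
        base = scenario.resolve(user_overrides)
    else:
        scenario, base = resolve_scenario(name_or_scenario, user_overrides)
    axes = scenario.axes or (SweepAxis("singleton", (None,)),)
    rows = []
    for combo in itertools.product(*(axis.values for axis in axes)):
        config = merge_config(base, None)
        row: dict = {}
        for axis, value in zip(axes, combo):
            if value is not None or axis.name != "singleton":
                axis.apply(config, value)
            row[axis.name] = axis.label(value)
        try:
            spec = build_runspec(config)
            result = spec.cell().run(spec.sim)
            row.update(result.summary)
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - recorded in-row by contract
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# External-pH fluctuations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationSpec:
    """Mixing-driven fluctuation of one external fluid's pH.

    ``process``: 'random_walk' (bounded Gaussian walk, sigma = amplitude per
    step) or 'sinusoid' (period = 20 * step_interval).  The fluctuating side
    is clamped to [ph_min, ph_max]; identical seeds give identical traces.
    """

    side: str = "acid"  # 'acid' | 'alk'
    process: str = "random_walk"
    step_interval: float = 1.0  # s
    amplitude: float = 0.25  # pH units
    ph_min: float | None = None  # default: baseline -1.5
    ph_max: float | None = None  # default: baseline +1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("acid", "alk"):
            raise ValueError("side must be 'acid' or 'alk'")
        if self.process not in ("random_walk", "sinusoid"):
            raise ValueError("process must be 'random_walk' or 'sinusoid'")
        if self.step_interval <= 0.0:
            raise ValueError("step_interval must be > 0")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be >= 0")

    def trace(self, baseline: float, n_steps: int) -> np.ndarray:
        """The external-pH value for each interval, length ``n_steps``."""
        lo = baseline - 1.5 if self.ph_min is None else self.ph_min
        hi = baseline + 1.5 if self.ph_max is None else self.ph_max
        lo, hi = max(lo, 0.0), min(hi, 14.0)
        if self.process == "sinusoid":
            t = np.arange(n_steps) * self.step_interval
            period = 20.0 * self.step_interval
            values = baseline + self.amplitude * np.sin(2.0 * np.pi * t / period)
        else:
            rng = np.random.default_rng(self.seed)
            steps = rng.normal(0.0, self.amplitude, size=n_steps)
            steps[0] = 0.0
            values = baseline + np.cumsum(steps)
            # reflect the walk off the bounds step by step
            for i in range(1, n_steps):
                v = values[i - 1] + steps[i]
                if v > hi:
                    v = hi - (v - hi)
                if v < lo:
                    v = lo + (lo - v)
                values[i] = v
        return np.clip(values, lo, hi)


def fluctuating_run(
    name_or_config: str | dict,
    fluctuation: FluctuationSpec,
    user_overrides: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run with one external fluid's pH re-clamped every interval.

    Returns the concatenated trajectory (with an ``ph_external`` column for
    the fluctuating side) and a histogram summary of the reported -dG.
    """
    if isinstance(name_or_config, str):
        scenario, config = resolve_scenario(name_or_config, user_overrides)
        for axis in scenario.axes:
            axis.apply(config, axis.values[0])
    else:
        config = merge_config(name_or_config, user_overrides)
    spec = build_runspec(config)
    sim = spec.sim
    key = "ph_acid" if fluctuation.side == "acid" else "ph_alk"
    baseline = getattr(spec.environment, key)
    n_segments = max(1, int(round(sim.t_end / fluctuation.step_interval)))
    trace = fluctuation.trace(baseline, n_segments)
    state = None
    frames = []
    for i, ph in enumerate(trace):
        env = replace(spec.environment, **{key: float(ph)})
        cell = replace(spec, environment=env).cell()
        seg_end = min((i + 1) * fluctuation.step_interval, sim.t_end)
        seg_sim = SimConfig(
            dt=sim.dt,
            t_end=seg_end,
            steady_tol=0.0,  # never stop early inside a segment
            steady_window=sim.steady_window,
            record_interval=sim.record_interval,
            rel_change_tol=sim.rel_change_tol,
            ph_step_tol=sim.ph_step_tol,
            max_halvings=sim.max_halvings,
        )
        result = cell.run(seg_sim, initial_state=state)
        state = result.final_state
        frame = result.timeseries
        if i > 0:
            frame = frame.iloc[1:]
        frame = frame.assign(ph_external=float(ph))
        frames.append(frame)
    trajectory = pd.concat(frames, ignore_index=True)
    values = trajectory["minus_dg_reported"].to_numpy()
    counts, edges = np.histogram(values, bins=30)
    summary = {
        "mean_minus_dg": float(values.mean()),
        "min_minus_dg": float(values.min()),
        "max_minus_dg": float(values.max()),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }
    return trajectory, summary


def acid_adaptation_sweep(user_overrides: dict | None = None) -> pd.DataFrame:
    """The 3-unit-gradient x permeability grid with 5% H+ pump and SPAP."""
    return run_sweep("figS5", user_overrides)
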