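"""Batch harness estimating the test's power and false-positive rate.

Sensitivity is tp / (tp + fn): the fraction of replicate simulations of a
non-random scenario whose p-value falls at or below the significance level
alpha.  Run on a truly random (monomer) scenario the same quantity is the
false-positive rate, which for this exact test equals alpha by construction.

Replicate sub-seeds are derived from the master seed by spawn keys, so a
given (seed, scenario, replicate index) always yields the same p-value
regardless of execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_stats import StatisticConfig
from .errors import ConfigurationError
from .localizations import RegionOfInterest
from .significance import run_clasta_test
from .simulate import Scenario, simulate_experiment

#: Default inset (nm) of the analysis ROI relative to the simulated field.
#: Localization error blurs records out across the field border, depleting
#: both channels in the same border band; that shared structure is present
#: in the observed pair but not in the toroidally shifted controls and
#: would register as spurious cross-correlation.  Insetting by a bit over
#: three error sigmas removes the band, just as real analyses place the
#: ROI centrally within the cell, away from its edges.
DEFAULT_ANALYSIS_MARGIN = 100.0


@dataclass
class PowerResult:
    """Sensitivity estimate for one scenario."""

    scenario: Scenario
    alpha: float
    n_sims: int
    p_values: np.ndarray

    @property
    def n_rejections(self) -> int:
        return int(np.sum(self.p_values <= self.alpha))

    @property
    def sensitivity(self) -> float:
        return self.n_rejections / self.n_sims

    @property
    def standard_error(self) -> float:
        """Binomial standard error of the sensitivity estimate."""
        s = self.sensitivity
        return float(np.sqrt(s * (1 - s) / self.n_sims))


def _analysis_roi(scenario: Scenario, margin: float) -> RegionOfInterest:
    roi = scenario.roi
    if margin < 0 or 2 * margin >= min(roi.width, roi.height):
        raise ConfigurationError("analysis margin must be >= 0 and smaller "
                                 "than half the ROI extent")
    if margin == 0:
        return roi
    return RegionOfInterest(roi.x_min + margin, roi.y_min + margin,
                            roi.x_max - margin, roi.y_max - margin)


def _replicate_p_value(
    scenario: Scenario,
    child_seed: np.random.SeedSequence,
    n_controls: int,
    config: StatisticConfig,
    analysis_roi: RegionOfInterest,
) -> float:
    ss_sim, ss_test = child_seed.spawn(2)
    red, blue, _ = simulate_experiment(scenario, seed=np.random.default_rng(ss_sim))
    red, blue = red.crop(analysis_roi), blue.crop(analysis_roi)
    result = run_clasta_test(
        red, blue, config=config, n_controls=n_controls,
        direction="clustering", seed=np.random.default_rng(ss_test),
    )
    return result.p_value


def estimate_sensitivity(
    scenario: Scenario,
    alpha: float = 0.05,
    n_sims: int = 100,
    n_controls: int = 99,
    seed: int = 0,
    config: StatisticConfig | None = None,
    analysis_margin: float = DEFAULT_ANALYSIS_MARGIN,
) -> PowerResult:
    """Estimate sensitivity = P(p <= alpha) over ``n_sims`` replicates.

    Each replicate simulates a fresh experiment from ``scenario``, crops
    both channels to the analysis ROI (the simulated field inset by
    ``analysis_margin`` nm on every side) and runs the randomization test
    with ``n_controls`` toroidal shifts.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be >= 1")
    if not 0 < alpha <= 1:
        raise ConfigurationError("alpha must be in (0, 1]")
    config = config if config is not None else StatisticConfig()
    roi = _analysis_roi(scenario, analysis_margin)
    children = np.random.SeedSequence(seed).spawn(n_sims)
    p_values = np.array([
        _replicate_p_value(scenario, child, n_controls, config, roi)
        for child in children
    ])
    return PowerResult(scenario=scenario, alpha=alpha, n_sims=n_sims,
                       p_values=p_values)


def _set_field(scenario: Scenario, path: str, value) -> Scenario:
    """Return a scenario with the dotted dataclass field ``path`` replaced."""
    parts = path.split(".")
    if len(parts) == 1:
        parts = _locate_field(scenario, parts[0])
    obj = scenario
    chain = [obj]
    for name in parts[:-1]:
        if not hasattr(obj, name):
            raise ConfigurationError(f"unknown scenario field {path!r}")
        obj = getattr(obj, name)
        chain.append(obj)
    if not dataclasses.is_dataclass(chain[-1]) or not hasattr(chain[-1], parts[-1]):
        raise ConfigurationError(f"unknown scenario field {path!r}")
    new = dataclasses.replace(chain[-1], **{parts[-1]: value})
    for container, name in zip(reversed(chain[:-1]), reversed(parts[:-1])):
        new = dataclasses.replace(container, **{name: new})
    return new


def _locate_field(scenario: Scenario, name: str) -> list[str]:
    """Resolve a bare field name to its dotted path within the scenario."""
    if hasattr(scenario, name):
        return [name]
    for sub in ("pattern", "labeling", "artifacts"):
        if hasattr(getattr(scenario, sub), name):
            return [sub, name]
    raise ConfigurationError(f"unknown scenario field {name!r}")


def run_grid(
    base_scenario: Scenario,
    axis: str,
    values,
    alpha: float = 0.05,
    n_sims: int = 100,
    n_controls: int = 99,
    seed: int = 0,
    analysis_margin: float = DEFAULT_ANALYSIS_MARGIN,
) -> list[PowerResult]:
    """One sensitivity estimate per value of a scenario parameter.

    ``axis`` is a scenario field, either dotted ("pattern.molecule_density")
    or bare ("molecule_density", resolved against the nested specs).  Cell i
    uses master sub-seed (seed, cell i), so grids are reproducible and
    embarrassingly parallel.
    """
    results = []
    for i, value in enumerate(values):
        scenario = _set_field(base_scenario, axis, value)
        roi = _analysis_roi(scenario, analysis_margin)
        cell_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        children = cell_seed.spawn(n_sims)
        config = StatisticConfig()
        p_values = np.array([
            _replicate_p_value(scenario, child, n_controls, config, roi)
            for child in children
        ])
        results.append(PowerResult(scenario=scenario, alpha=alpha,
                                   n_sims=n_sims, p_values=p_values))
    return results


def results_to_frame(axis: str, values, results: list[PowerResult]) -> pd.DataFrame:
    """Tidy table of a grid run: one row per (axis value, sensitivity)."""
    return pd.DataFrame({
        "axis": axis,
        "value": list(values),
        "pattern": [r.scenario.pattern.kind for r in results],
        "n_mer": [r.scenario.pattern.n_mer for r in results],
        "n_sims": [r.n_sims for r in results],
        "n_rejections": [r.n_rejections for r in results],
        "sensitivity": [r.sensitivity for r in results],
    })
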