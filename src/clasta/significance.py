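"""The 2-CLASTA randomization test.

The null hypothesis is a spatially random distribution of *biomolecules*
(not of localizations: blinking makes every localization map look clustered).
Correlations between the two color channels are broken by toroidally
shifting one channel inside the ROI; each random shift yields one control
realization of the null.  Ranking the observed summary statistic g within
the N control values gives an exact one-sided Monte-Carlo p-value on the
grid {1/(N+1), ..., 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cross_stats import StatisticConfig, cdf_integral, empirical_cdf, statistic_values
from .errors import ConfigurationError, InsufficientDataError
from .localizations import LocalizationSet, RegionOfInterest

DIRECTIONS = ("clustering", "repulsion")


@dataclass
class ClastaResult:
    """Outcome of one randomization test.

    ``p_value`` is exact on the grid {1/(N+1), ..., 1}.  ``g_data`` and
    ``g_controls`` are the integral statistics of the observed pair and the
    N toroidally shifted controls; ``r_max_used`` is the realized upper
    integration limit.  When the test was run with ``keep_values=True``,
    ``data_values`` / ``control_values`` hold the underlying per-point
    statistic samples for plotting cdf curves.
    """

    p_value: float
    g_data: float
    g_controls: np.ndarray
    r_max_used: float
    n_controls: int
    direction: str
    statistic: StatisticConfig
    shift_vectors: np.ndarray
    seed: int | None = None
    data_values: np.ndarray | None = field(default=None, repr=False)
    control_values: list | None = field(default=None, repr=False)

    @property
    def rank(self) -> int:
        return round(self.p_value * (self.n_controls + 1))

    def cdf_curves(self, n_grid: int = 512):
        """(r, cdf_data, cdf_control_mean) on a grid over [0, r_max_used].

        Requires the test to have been run with ``keep_values=True``.
        """
        if self.data_values is None or self.control_values is None:
            raise ValueError("per-point values were not kept; rerun with keep_values=True")
        r = np.linspace(0.0, self.r_max_used, n_grid)
        cdf_data = empirical_cdf(self.data_values)(r)
        ctrl = np.mean([empirical_cdf(v)(r) for v in self.control_values], axis=0)
        return r, cdf_data, ctrl

    def to_dict(self) -> dict:
        """JSON-serializable summary (omits the bulky per-point samples)."""
        return {
            "p_value": self.p_value,
            "g_data": self.g_data,
            "g_controls": [float(g) for g in self.g_controls],
            "r_max_used": self.r_max_used,
            "n_controls": self.n_controls,
            "direction": self.direction,
            "statistic": {
                "kind": self.statistic.kind,
                "k": self.statistic.k,
                "r_star": self.statistic.r_star,
                "r_max": self.statistic.r_max,
            },
            "shift_vectors": [[float(a), float(b)] for a, b in self.shift_vectors],
            "seed": self.seed,
        }


def toroidal_shift(
    points: LocalizationSet, v, roi: RegionOfInterest | None = None
) -> LocalizationSet:
    """Translate a channel by ``v`` with periodic wrap-around at the ROI.

    Each coordinate is shifted and re-entered modulo the ROI width/height
    into [min, max); frames are unchanged.  All points must lie inside the
    ROI beforehand.
    """
    roi = roi if roi is not None else points.roi
    if not _inside_closed(points, roi):
        raise ValueError("all points must lie inside the ROI before a toroidal shift")
    vx, vy = float(v[0]), float(v[1])
    x = (points.x - roi.x_min + vx) % roi.width + roi.x_min
    y = (points.y - roi.y_min + vy) % roi.height + roi.y_min
    return points.with_coords(x, y)


def _inside_closed(points: LocalizationSet, roi: RegionOfInterest) -> bool:
    # closed bounds: data read without an explicit ROI carries its bounding
    # box, whose max edges the wrap maps onto the min edges
    return bool(
        np.all((points.x >= roi.x_min) & (points.x <= roi.x_max)
               & (points.y >= roi.y_min) & (points.y <= roi.y_max))
    )


def _wrap(xy: np.ndarray, v: np.ndarray, roi: RegionOfInterest) -> np.ndarray:
    lo = np.array([roi.x_min, roi.y_min])
    size = np.array([roi.width, roi.height])
    return (xy - lo + v) % size + lo


def _rank(g_data: float, g_controls: np.ndarray, ascending: bool) -> int:
    # ties take the worst (largest) rank: conservative, favors the null
    if ascending:
        return 1 + int(np.sum(g_controls <= g_data))
    return 1 + int(np.sum(g_controls >= g_data))


def run_clasta_test(
    query: LocalizationSet,
    reference: LocalizationSet,
    config: StatisticConfig | None = None,
    n_controls: int = 99,
    direction: str = "clustering",
    seed=None,
    keep_values: bool = False,
) -> ClastaResult:
    """Run the randomization test of ``query`` against ``reference``.

    The ``query`` channel (conventionally red) is the one that gets
    toroidally shifted; only cross-channel correlations matter, so the
    choice of which channel plays query does not change the null law.

    Parameters
    ----------
    config : StatisticConfig
        Statistic variant; default parameter-free nearest-neighbor form.
    n_controls : int
        Number N of random toroidal shifts (default 99, giving a p-value
        resolution of 0.01).
    direction : {"clustering", "repulsion"}
        Side of the test.  Clustering shortens cross-channel NN distances
        (large g for nn/knn, large L for lcross); repulsion is the reverse.
    seed : int, SeedSequence, Generator, optional
        Controls the shift vectors; same seed, same p-value, bit-exactly.
    keep_values : bool
        Retain per-point statistic samples for cdf plotting.
    """
    config = config if config is not None else StatisticConfig()
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    if n_controls < 1:
        raise ConfigurationError("n_controls must be >= 1")
    if len(query) == 0 or len(reference) == 0:
        raise InsufficientDataError("both channels must be non-empty")
    if query.roi != reference.roi:
        raise ConfigurationError("query and reference must share the same ROI")
    roi = query.roi
    if not _inside_closed(query, roi) or not _inside_closed(reference, roi):
        raise ConfigurationError(
            "channels contain localizations outside the ROI; crop() them first"
        )

    rng = np.random.default_rng(seed)
    tree = cKDTree(reference.xy)
    n_ref = len(reference)
    area = roi.area

    data_values = statistic_values(query.xy, tree, n_ref, config, area)
    shifts = rng.uniform(0.0, 1.0, size=(n_controls, 2)) * [roi.width, roi.height]
    control_values = [
        statistic_values(_wrap(query.xy, v, roi), tree, n_ref, config, area)
        for v in shifts
    ]

    if config.r_max == "auto":
        r_max = float(max(data_values.max(), max(v.max() for v in control_values)))
        if r_max <= 0:  # degenerate: all statistic values are exactly zero
            r_max = 1.0
    else:
        r_max = float(config.r_max)

    g_data = cdf_integral(empirical_cdf(data_values), r_max)
    g_controls = np.array(
        [cdf_integral(empirical_cdf(v), r_max) for v in control_values]
    )

    # clustering -> large g for nn/knn (short distances), ranked descending;
    # for lcross, clustering -> large L values -> *small* g, ranked ascending
    ascending = (config.kind == "lcross") == (direction == "clustering")
    rank = _rank(g_data, g_controls, ascending)
    p_value = rank / (n_controls + 1)

    return ClastaResult(
        p_value=p_value,
        g_data=g_data,
        g_controls=g_controls,
        r_max_used=r_max,
        n_controls=n_controls,
        direction=direction,
        statistic=config,
        shift_vectors=shifts,
        seed=seed if isinstance(seed, int) else None,
        data_values=data_values if keep_values else None,
        control_values=control_values if keep_values else None,
    )


def decide(p_value: float, alpha: float = 0.05) -> bool:
    """Reject the null iff p <= alpha.

    With p on the grid {1/(N+1), ..., 1} and alpha a multiple of 1/(N+1),
    the rule p <= alpha gives a false-positive rate exactly equal to alpha.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return p_value <= alpha
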