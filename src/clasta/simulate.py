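"""Generative model of two-color SMLM experiments.

The pipeline mirrors how a real localization map arises, stage by stage:

1. place biomolecules in the ROI (random / n-mers / circular or
   rectangular enrichment domains),
2. assign each molecule at most one label, red or blue, by binomial
   statistics (labeling efficiency x labeling ratio),
3. turn each label into >= 1 detections ("blinking") with a frame index,
4. blur each detection with an isotropic Gaussian localization error,
5. add unspecifically bound labels and false-positive background signals,
6. apply linear stage drift (both channels) and residual chromatic
   aberration (red channel only).

All lengths are nm; densities are per um^2.  Every stage takes an explicit
`numpy` Generator, so a scenario is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .localizations import LocalizationSet, RegionOfInterest

NM2_PER_UM2 = 1e6

PATTERN_KINDS = ("random", "oligomer", "circular_domains", "rectangular_domains")


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PatternSpec:
    """Ground-truth molecule pattern.

    ``molecule_density`` is the target total density (molecules/um^2,
    default 75).  For ``oligomer``, every n-mer carries ``n_mer`` molecules
    at the same position (a monomer pattern, n_mer=1, is complete spatial
    randomness).  For domain patterns, ``fraction_in_domains`` of the
    molecules are Poisson-allocated to domains of the given geometry and
    the rest are placed uniformly outside all domains.
    """

    kind: str = "random"
    n_mer: int = 1
    domain_radius: float = 100.0
    rect_size: tuple[float, float] = (80.0, 400.0)
    domain_density: float = 10.0
    fraction_in_domains: float = 1.0
    molecule_density: float = 75.0

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ConfigurationError(f"unknown pattern kind {self.kind!r}")
        if not 1 <= self.n_mer <= 4:
            raise ConfigurationError("n_mer must be in 1..4")
        if self.domain_radius <= 0 or min(self.rect_size) <= 0:
            raise ConfigurationError("domain dimensions must be positive")
        if self.domain_density < 0 or self.molecule_density < 0:
            raise ConfigurationError("densities must be non-negative")
        if not 0 <= self.fraction_in_domains <= 1:
            raise ConfigurationError("fraction_in_domains must be in [0, 1]")


@dataclass(frozen=True)
class LabelingSpec:
    """Stochastic labeling: efficiency = P(molecule carries any label),
    ratio = P(label is red | labeled).  Each molecule joins at most one
    channel."""

    efficiency: float = 1.0
    ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.efficiency <= 1 and 0 <= self.ratio <= 1):
            raise ConfigurationError("efficiency and ratio must be in [0, 1]")


@dataclass(frozen=True)
class BlinkModel:
    """Detections per label and their frame assignment.

    ``distribution`` selects the law of the detection count m >= 1:

    - ``lognormal``: params (mu, sigma) of the underlying normal; the draw
      is rounded up, so m >= 1 always.
    - ``geometric``: params (mean,); support {1, 2, ...}.
    - ``fixed``: params (m,).
    - ``table``: params (values, probabilities) as an empirical histogram.

    ``frame_assignment`` is ``uniform`` (i.i.d. frames) or ``burst``
    (geometric on-times separated by geometric off-times, truncated at
    ``n_frames``).
    """

    distribution: str = "lognormal"
    params: tuple = (1.1, 0.9)
    frame_assignment: str = "uniform"
    mean_t_on: float = 2.0
    mean_t_off: float = 50.0
    n_frames: int = 10_000

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "geometric", "fixed", "table"):
            raise ConfigurationError(f"unknown detection distribution {self.distribution!r}")
        if self.frame_assignment not in ("uniform", "burst"):
            raise ConfigurationError(f"unknown frame assignment {self.frame_assignment!r}")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")

    # -- constructors ------------------------------------------------------
    @classmethod
    def lognormal(cls, mu: float, sigma: float, **kw) -> "BlinkModel":
        return cls(distribution="lognormal", params=(float(mu), float(sigma)), **kw)

    @classmethod
    def geometric(cls, mean: float, **kw) -> "BlinkModel":
        if mean < 1:
            raise ConfigurationError("geometric mean must be >= 1")
        return cls(distribution="geometric", params=(float(mean),), **kw)

    @classmethod
    def fixed(cls, m: int, **kw) -> "BlinkModel":
        if m < 1:
            raise ConfigurationError("fixed detection count must be >= 1")
        return cls(distribution="fixed", params=(int(m),), **kw)

    @classmethod
    def from_table(cls, values, probabilities, **kw) -> "BlinkModel":
        v = np.asarray(values, dtype=np.int64)
        p = np.asarray(probabilities, dtype=float)
        if v.size != p.size or v.size == 0:
            raise ConfigurationError("table needs matching non-empty values/probabilities")
        if v.min() < 1:
            raise ConfigurationError("every label yields at least one detection")
        if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
            raise ConfigurationError("table probabilities must sum to 1")
        return cls(distribution="table", params=(tuple(v.tolist()), tuple(p.tolist())), **kw)

    # -- sampling ----------------------------------------------------------
    def sample_detections(self, n_labels: int, rng: np.random.Generator) -> np.ndarray:
        """Detection counts m_j >= 1 for each of n_labels labels."""
        if n_labels == 0:
            return np.zeros(0, dtype=np.int64)
        if self.distribution == "lognormal":
            mu, sigma = self.params
            return np.ceil(rng.lognormal(mu, sigma, n_labels)).astype(np.int64)
        if self.distribution == "geometric":
            (mean,) = self.params
            return rng.geometric(1.0 / mean, n_labels).astype(np.int64)
        if self.distribution == "fixed":
            return np.full(n_labels, int(self.params[0]), dtype=np.int64)
        values, probs = self.params
        return rng.choice(np.asarray(values, np.int64), size=n_labels,
                          p=np.asarray(probs, float))

    def sample_frames(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Frame index (1-based) for each detection, label by label."""
        total = int(counts.sum())
        if self.frame_assignment == "uniform":
            return rng.integers(1, self.n_frames + 1, size=total)
        frames = np.empty(total, dtype=np.int64)
        pos = 0
        p_off = min(1.0, 1.0 / self.mean_t_on)   # leave the on-state
        p_on = min(1.0, 1.0 / self.mean_t_off)   # re-enter the on-state
        for m in counts:
            t = int(rng.integers(1, self.n_frames + 1))
            got = 0
            while got < m:
                burst = int(rng.geometric(p_off))
                for _ in range(burst):
                    if got >= m:
                        break
                    # detections past the movie end pile up on the last frame
                    frames[pos] = min(t, self.n_frames)
                    pos += 1
                    got += 1
                    t += 1
                if got < m:
                    t += int(rng.geometric(p_on))
        return frames


#: Parametric stand-ins for typical SNAP-tag dye blinking: the far-red dye
#: re-activates more often than the green one, giving ~5 vs ~3.5 detections
#: per label on average, with the heavy right tail seen in experiments.
SNAP_LIKE_RED = BlinkModel.lognormal(1.1, 0.9)
SNAP_LIKE_BLUE = BlinkModel.lognormal(0.9, 0.8)
#: False-positive background signals blink only briefly.
BACKGROUND_BLINK = BlinkModel.geometric(2.0)


@dataclass(frozen=True)
class ArtifactSpec:
    """Measurement imperfections applied on top of the ideal label map."""

    localization_error_sigma: float = 30.0
    unspecific_label_density: float = 0.0   # labels/um^2 per channel
    background_density_red: float = 0.0     # signals/um^2
    background_density_blue: float = 0.0
    background_blink: BlinkModel = BACKGROUND_BLINK
    drift_total: tuple[float, float] = (0.0, 0.0)  # nm over n_frames
    aberration_beta: float = 0.0
    aberration_center: tuple[float, float] = (2500.0, 2500.0)

    def __post_init__(self) -> None:
        if self.localization_error_sigma < 0:
            raise ConfigurationError("localization error sigma must be >= 0")
        if min(self.unspecific_label_density, self.background_density_red,
               self.background_density_blue) < 0:
            raise ConfigurationError("densities must be >= 0")
        if self.aberration_beta < 0:
            raise ConfigurationError("aberration beta must be >= 0")

    @classmethod
    def ideal(cls, **kw) -> "ArtifactSpec":
        """No unspecific labels, no background, no drift, no aberration."""
        return cls(**kw)

    @classmethod
    def realistic(cls, **kw) -> "ArtifactSpec":
        """5 unspecific labels/um^2 per channel; 1 (red) and 2 (blue)
        background signals/um^2."""
        kw.setdefault("unspecific_label_density", 5.0)
        kw.setdefault("background_density_red", 1.0)
        kw.setdefault("background_density_blue", 2.0)
        return cls(**kw)


@dataclass(frozen=True)
class Scenario:
    """Complete parameterization of one simulated two-color experiment."""

    roi: RegionOfInterest = field(default_factory=lambda: RegionOfInterest.square(10_000.0))
    pattern: PatternSpec = field(default_factory=PatternSpec)
    labeling: LabelingSpec = field(default_factory=LabelingSpec)
    blink_red: BlinkModel = SNAP_LIKE_RED
    blink_blue: BlinkModel = SNAP_LIKE_BLUE
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec.ideal)
    seed: int | None = None

    @classmethod
    def ideal(cls, pattern: PatternSpec | None = None, **kw) -> "Scenario":
        """100% labeling efficiency, no unspecific signals."""
        kw.setdefault("labeling", LabelingSpec(efficiency=1.0))
        kw.setdefault("artifacts", ArtifactSpec.ideal())
        if pattern is not None:
            kw["pattern"] = pattern
        return cls(**kw)

    @classmethod
    def realistic(cls, pattern: PatternSpec | None = None, **kw) -> "Scenario":
        """40% labeling efficiency plus unspecific labels and background."""
        kw.setdefault("labeling", LabelingSpec(efficiency=0.4))
        kw.setdefault("artifacts", ArtifactSpec.realistic())
        if pattern is not None:
            kw["pattern"] = pattern
        return cls(**kw)


# --------------------------------------------------------------------------
# stage 1: molecule placement


def _uniform_in_roi(n: int, roi: RegionOfInterest, rng) -> np.ndarray:
    return rng.uniform([roi.x_min, roi.y_min], [roi.x_max, roi.y_max], size=(n, 2))


def _points_in_circles(centers, radius, counts, rng) -> np.ndarray:
    """Uniform points inside discs, ``counts[i]`` in disc i."""
    total = int(counts.sum())
    reps = np.repeat(np.arange(len(centers)), counts)
    r = radius * np.sqrt(rng.random(total))
    theta = rng.uniform(0, 2 * np.pi, total)
    return centers[reps] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _points_in_rects(centers, size, counts, rng) -> np.ndarray:
    total = int(counts.sum())
    reps = np.repeat(np.arange(len(centers)), counts)
    off = rng.uniform(-0.5, 0.5, size=(total, 2)) * np.asarray(size)
    return centers[reps] + off


def _inside_any_domain(points, centers, pattern: PatternSpec) -> np.ndarray:
    """Mask of points lying inside at least one domain."""
    if pattern.kind == "circular_domains":
        tree = cKDTree(centers)
        counts = tree.query_ball_point(points, pattern.domain_radius,
                                       return_length=True)
        return np.asarray(counts) > 0
    w, h = pattern.rect_size
    tree = cKDTree(centers)
    halfdiag = 0.5 * math.hypot(w, h)
    cand = tree.query_ball_point(points, halfdiag)
    mask = np.zeros(len(points), dtype=bool)
    for i, idx in enumerate(cand):
        if not idx:
            continue
        d = np.abs(points[i] - centers[idx])
        mask[i] = bool(np.any((d[:, 0] <= w / 2) & (d[:, 1] <= h / 2)))
    return mask


def place_molecules(
    pattern: PatternSpec, roi: RegionOfInterest, rng: np.random.Generator
) -> np.ndarray:
    """Ground-truth molecule positions (n, 2) in nm for one realization.

    Oligomers put ``n_mer`` molecules at each of ``floor(total/n_mer)``
    uniformly random centers (zero intra-oligomer spacing).  Domain
    patterns draw per-domain occupancies i.i.d. Poisson with mean
    ``total * fraction / n_domains`` and place the remaining molecules
    uniformly outside all domains by rejection sampling.
    """
    area_um2 = roi.area / NM2_PER_UM2
    total = int(round(pattern.molecule_density * area_um2))
    if pattern.kind in ("random", "oligomer"):
        n = 1 if pattern.kind == "random" else pattern.n_mer
        centers = _uniform_in_roi(total // n, roi, rng)
        return np.repeat(centers, n, axis=0)

    n_domains = int(round(pattern.domain_density * area_um2))
    if n_domains == 0:
        if pattern.fraction_in_domains > 0:
            raise ConfigurationError(
                "fraction_in_domains > 0 requires at least one domain"
            )
        return _uniform_in_roi(total, roi, rng)
    centers = _uniform_in_roi(n_domains, roi, rng)
    n_in_target = total * pattern.fraction_in_domains
    counts = rng.poisson(n_in_target / n_domains, n_domains)
    if pattern.kind == "circular_domains":
        inside = _points_in_circles(centers, pattern.domain_radius, counts, rng)
    else:
        inside = _points_in_rects(centers, pattern.rect_size, counts, rng)

    n_out = total - int(round(n_in_target))
    outside = np.empty((0, 2))
    while len(outside) < n_out:
        batch = _uniform_in_roi(max(n_out, 256), roi, rng)
        keep = batch[~_inside_any_domain(batch, centers, pattern)]
        outside = np.vstack([outside, keep])
    outside = outside[:n_out]
    return np.vstack([inside, outside])


# --------------------------------------------------------------------------
# stages 2-6


def assign_labels(
    molecules: np.ndarray, labeling: LabelingSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split molecules into (red, blue) label positions.

    Each molecule is independently unlabeled with probability
    1 - efficiency, else red with probability ``ratio`` and blue otherwise,
    so no molecule ever contributes to both channels.
    """
    n = len(molecules)
    u = rng.random(n)
    labeled = u < labeling.efficiency
    is_red = rng.random(n) < labeling.ratio
    return molecules[labeled & is_red], molecules[labeled & ~is_red]


def simulate_blinking(
    label_positions: np.ndarray,
    blink: BlinkModel,
    roi: RegionOfInterest,
    rng: np.random.Generator,
    channel_id: str = "channel",
) -> LocalizationSet:
    """Expand each label into its detections (pre-localization-error).

    Label j yields m_j >= 1 records at the label position with frame
    indices drawn from the blink model's frame assignment.
    """
    counts = blink.sample_detections(len(label_positions), rng)
    xy = np.repeat(label_positions, counts, axis=0) if len(label_positions) else np.empty((0, 2))
    frames = blink.sample_frames(counts, rng)
    return LocalizationSet(channel_id=channel_id, x=xy[:, 0], y=xy[:, 1],
                           frame=frames, roi=roi)


def apply_localization_error(
    ls: LocalizationSet, sigma: float, rng: np.random.Generator
) -> LocalizationSet:
    """Displace each record by i.i.d. Gaussian(0, sigma) in x and y."""
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    if sigma == 0 or len(ls) == 0:
        return ls
    noise = rng.normal(0.0, sigma, size=(len(ls), 2))
    return ls.with_coords(ls.x + noise[:, 0], ls.y + noise[:, 1])


def _extra_signals(
    density_per_um2: float,
    blink: BlinkModel,
    sigma: float,
    roi: RegionOfInterest,
    rng: np.random.Generator,
    channel_id: str,
) -> LocalizationSet:
    n = rng.poisson(density_per_um2 * roi.area / NM2_PER_UM2)
    pos = _uniform_in_roi(n, roi, rng)
    ls = simulate_blinking(pos, blink, roi, rng, channel_id)
    return apply_localization_error(ls, sigma, rng)


def _concat(a: LocalizationSet, b: LocalizationSet) -> LocalizationSet:
    return LocalizationSet(
        channel_id=a.channel_id,
        x=np.concatenate([a.x, b.x]),
        y=np.concatenate([a.y, b.y]),
        frame=np.concatenate([a.frame, b.frame]),
        roi=a.roi,
    )


def add_unspecific_and_background(
    red: LocalizationSet,
    blue: LocalizationSet,
    artifacts: ArtifactSpec,
    roi: RegionOfInterest,
    rng: np.random.Generator,
    blink_red: BlinkModel = SNAP_LIKE_RED,
    blink_blue: BlinkModel = SNAP_LIKE_BLUE,
) -> tuple[LocalizationSet, LocalizationSet]:
    """Append unspecifically bound labels and false-positive background.

    Unspecific labels blink like the channel's specific labels; background
    signals use ``artifacts.background_blink``.  Counts are Poisson with
    mean density x area; positions are uniform in the ROI.
    """
    sigma = artifacts.localization_error_sigma
    if artifacts.unspecific_label_density > 0:
        red = _concat(red, _extra_signals(artifacts.unspecific_label_density,
                                          blink_red, sigma, roi, rng, red.channel_id))
        blue = _concat(blue, _extra_signals(artifacts.unspecific_label_density,
                                            blink_blue, sigma, roi, rng, blue.channel_id))
    if artifacts.background_density_red > 0:
        red = _concat(red, _extra_signals(artifacts.background_density_red,
                                          artifacts.background_blink, sigma, roi,
                                          rng, red.channel_id))
    if artifacts.background_density_blue > 0:
        blue = _concat(blue, _extra_signals(artifacts.background_density_blue,
                                            artifacts.background_blink, sigma, roi,
                                            rng, blue.channel_id))
    return red, blue


def apply_drift(
    ls: LocalizationSet, drift_total, n_frames: int
) -> LocalizationSet:
    """Linear stage drift: record at frame t moves by drift_total * t/n_frames.

    Alternating-laser acquisition means both channels share one clock, so
    the same displacement law is applied to each channel in turn.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    dx, dy = float(drift_total[0]), float(drift_total[1])
    if (dx, dy) == (0.0, 0.0) or len(ls) == 0:
        return ls
    t = ls.frame / n_frames
    return ls.with_coords(ls.x + dx * t, ls.y + dy * t)


def apply_chromatic_aberration(
    red: LocalizationSet, beta: float, center
) -> LocalizationSet:
    """Radial linear distortion of the red channel:
    (x, y) -> (x, y) + beta * (x - x0, y - y0)."""
    if beta < 0:
        raise ConfigurationError("beta must be >= 0")
    if beta == 0 or len(red) == 0:
        return red
    x0, y0 = float(center[0]), float(center[1])
    return red.with_coords(red.x + beta * (red.x - x0), red.y + beta * (red.y - y0))


def simulate_experiment(
    scenario: Scenario, seed=None
) -> tuple[LocalizationSet, LocalizationSet, np.ndarray]:
    """Run the full pipeline; returns (red, blue, ground-truth molecules).

    Deterministic given a seed (argument overrides ``scenario.seed``).
    Records pushed outside the ROI by error, drift or aberration are kept;
    crop to the scenario ROI before statistical analysis.
    """
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    roi, art = scenario.roi, scenario.artifacts

    truth = place_molecules(scenario.pattern, roi, rng)
    red_pos, blue_pos = assign_labels(truth, scenario.labeling, rng)
    red = simulate_blinking(red_pos, scenario.blink_red, roi, rng, "red")
    blue = simulate_blinking(blue_pos, scenario.blink_blue, roi, rng, "blue")
    red = apply_localization_error(red, art.localization_error_sigma, rng)
    blue = apply_localization_error(blue, art.localization_error_sigma, rng)
    red, blue = add_unspecific_and_background(
        red, blue, art, roi, rng, scenario.blink_red, scenario.blink_blue
    )
    n_frames = max(scenario.blink_red.n_frames, scenario.blink_blue.n_frames)
    red = apply_drift(red, art.drift_total, n_frames)
    blue = apply_drift(blue, art.drift_total, n_frames)
    red = apply_chromatic_aberration(red, art.aberration_beta, art.aberration_center)
    return red, blue, truth


# --------------------------------------------------------------------------
# YAML (de)serialization of scenarios, used by the CLI


def scenario_to_dict(s: Scenario) -> dict:
    def blink(b: BlinkModel) -> dict:
        return {
            "distribution": b.distribution,
            "params": list(b.params) if b.distribution != "table"
            else [list(b.params[0]), list(b.params[1])],
            "frame_assignment": b.frame_assignment,
            "mean_t_on": b.mean_t_on,
            "mean_t_off": b.mean_t_off,
            "n_frames": b.n_frames,
        }

    return {
        "roi": [s.roi.x_min, s.roi.y_min, s.roi.x_max, s.roi.y_max],
        "pattern": {
            "kind": s.pattern.kind,
            "n_mer": s.pattern.n_mer,
            "domain_radius": s.pattern.domain_radius,
            "rect_size": list(s.pattern.rect_size),
            "domain_density": s.pattern.domain_density,
            "fraction_in_domains": s.pattern.fraction_in_domains,
            "molecule_density": s.pattern.molecule_density,
        },
        "labeling": {"efficiency": s.labeling.efficiency, "ratio": s.labeling.ratio},
        "blink_red": blink(s.blink_red),
        "blink_blue": blink(s.blink_blue),
        "artifacts": {
            "localization_error_sigma": s.artifacts.localization_error_sigma,
            "unspecific_label_density": s.artifacts.unspecific_label_density,
            "background_density_red": s.artifacts.background_density_red,
            "background_density_blue": s.artifacts.background_density_blue,
            "background_blink": blink(s.artifacts.background_blink),
            "drift_total": list(s.artifacts.drift_total),
            "aberration_beta": s.artifacts.aberration_beta,
            "aberration_center": list(s.artifacts.aberration_center),
        },
        "seed": s.seed,
    }


def scenario_from_dict(d: dict) -> Scenario:
    def blink(bd: dict | None, default: BlinkModel) -> BlinkModel:
        if bd is None:
            return default
        params = bd.get("params", list(default.params))
        if bd.get("distribution", default.distribution) == "table":
            params = (tuple(params[0]), tuple(params[1]))
        else:
            params = tuple(params)
        return BlinkModel(
            distribution=bd.get("distribution", default.distribution),
            params=params,
            frame_assignment=bd.get("frame_assignment", "uniform"),
            mean_t_on=bd.get("mean_t_on", 2.0),
            mean_t_off=bd.get("mean_t_off", 50.0),
            n_frames=bd.get("n_frames", 10_000),
        )

    roi = RegionOfInterest(*d["roi"]) if "roi" in d else RegionOfInterest.square(10_000.0)
    pd_ = d.get("pattern", {})
    pattern = PatternSpec(
        kind=pd_.get("kind", "random"),
        n_mer=pd_.get("n_mer", 1),
        domain_radius=pd_.get("domain_radius", 100.0),
        rect_size=tuple(pd_.get("rect_size", (80.0, 400.0))),
        domain_density=pd_.get("domain_density", 10.0),
        fraction_in_domains=pd_.get("fraction_in_domains", 1.0),
        molecule_density=pd_.get("molecule_density", 75.0),
    )
    ld = d.get("labeling", {})
    labeling = LabelingSpec(efficiency=ld.get("efficiency", 1.0),
                            ratio=ld.get("ratio", 0.5))
    ad = d.get("artifacts", {})
    artifacts = ArtifactSpec(
        localization_error_sigma=ad.get("localization_error_sigma", 30.0),
        unspecific_label_density=ad.get("unspecific_label_density", 0.0),
        background_density_red=ad.get("background_density_red", 0.0),
        background_density_blue=ad.get("background_density_blue", 0.0),
        background_blink=blink(ad.get("background_blink"), BACKGROUND_BLINK),
        drift_total=tuple(ad.get("drift_total", (0.0, 0.0))),
        aberration_beta=ad.get("aberration_beta", 0.0),
        aberration_center=tuple(ad.get("aberration_center", (2500.0, 2500.0))),
    )
    return Scenario(
        roi=roi, pattern=pattern, labeling=labeling,
        blink_red=blink(d.get("blink_red"), SNAP_LIKE_RED),
        blink_blue=blink(d.get("blink_blue"), SNAP_LIKE_BLUE),
        artifacts=artifacts, seed=d.get("seed"),
    )


def preset_scenario(name: str, pattern: PatternSpec | None = None) -> Scenario:
    """Bundled scenario presets: "ideal" and "realistic"."""
    if name == "ideal":
        return Scenario.ideal(pattern)
    if name == "realistic":
        return Scenario.realistic(pattern)
    raise ConfigurationError(f"unknown preset {name!r}; choose 'ideal' or 'realistic'")
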