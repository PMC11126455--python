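"""Synthetic drying-droplet movies with three-stage texture dynamics.

Emulates what a crossed-polarizer movie of a drying liquid-crystal/protein
droplet looks like statistically, for five buffer-concentration classes
(0x .. 1x):

* **initial stage** — a dim, spatially smooth birefringence field with a
  small temporal drift; nearly indistinguishable between classes.
* **middle stage** — mean intensity rises logistically toward a
  class-specific ceiling while spatially correlated bright domains grow
  (a correlated random field thresholded at a falling level); the rise is
  steeper for low-salt classes (0x–0.5x) than for 0.75x–1x.
* **final stage** — statistically stationary texture whose intensity
  ceiling and characteristic domain size are class specific (higher buffer
  concentration quenches birefringence, so the ceiling decreases from 0x
  to 1x), plus small per-frame noise.

Everything outside the fixed circular mask (the pinned contact line) is
level 0, matching the dark field seen outside a droplet between crossed
polarizers.  All randomness flows from a single integer seed; per-class
seeds are derived by fixed offsets so adding a class never perturbs the
others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import CLASS_LABELS, DropletSeries, circular_mask, save_series, stage_of

_CLASS_SEED_OFFSETS = {lbl: 1000 * (k + 1) for k, lbl in enumerate(CLASS_LABELS)}

# amplitude of the slow initial-stage intensity drift, as a fraction of the
# initial texture sd
_DRIFT_COEF = 0.4


@dataclass(frozen=True)
class ClassProfile:
    """Texture dynamics of one droplet class.

    Parameters
    ----------
    label : str
        Class name (initial buffer concentration), one of ``0x .. 1x``.
    intensity_ceiling : float
        8-bit level the bright domains approach in the final stage; ordered
        non-increasing from 0x to 1x (salt quenches birefringence).
    surge_rate : float
        Dimensionless steepness of the middle-stage intensity rise; larger
        for 0x–0.5x than for 0.75x–1x.
    domain_scale : float
        Correlation length (px) of the birefringent domains in the final
        stage; sets the zone/dependence texture signature.
    noise_sd : float
        Per-frame additive noise, in 8-bit levels.
    bright_fraction : float
        Fraction of the ROI covered by bright birefringent domains in the
        final stage; decreases with buffer concentration (salt suppresses
        the optically active area as well as its intensity).
    """

    label: str
    intensity_ceiling: float
    surge_rate: float
    domain_scale: float
    noise_sd: float
    bright_fraction: float = 0.5

    def validate(self) -> None:
        if not 1 <= self.intensity_ceiling <= 255:
            raise ValueError("intensity_ceiling must lie in [1, 255]")
        if self.surge_rate < 0 or self.domain_scale <= 0 or self.noise_sd < 0:
            raise ValueError("surge_rate/noise_sd must be >= 0 and domain_scale > 0")
        if not 0.0 < self.bright_fraction < 1.0:
            raise ValueError("bright_fraction must lie in (0, 1)")


#: default per-class dynamics: ceiling and domain size fall with buffer
#: concentration; the surge is steep for 0x–0.5x and gradual for 0.75x–1x
DEFAULT_PROFILES = (
    ClassProfile("0x", intensity_ceiling=235.0, surge_rate=10.0, domain_scale=8.0,
                 noise_sd=4.0, bright_fraction=0.70),
    ClassProfile("0.25x", intensity_ceiling=205.0, surge_rate=9.0, domain_scale=6.0,
                 noise_sd=4.0, bright_fraction=0.60),
    ClassProfile("0.5x", intensity_ceiling=175.0, surge_rate=8.0, domain_scale=4.5,
                 noise_sd=4.0, bright_fraction=0.50),
    ClassProfile("0.75x", intensity_ceiling=145.0, surge_rate=3.5, domain_scale=3.0,
                 noise_sd=4.0, bright_fraction=0.40),
    ClassProfile("1x", intensity_ceiling=115.0, surge_rate=3.0, domain_scale=2.0,
                 noise_sd=4.0, bright_fraction=0.30),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic dataset.

    Defaults follow the imaging protocol being emulated: ~300 frames per
    droplet, 150x150 px frames, stage breakpoints at 0.40 and 0.75 of
    normalised drying time, a pinned circular ROI at 90% of the half-width.
    """

    n_frames: int = 300
    frame_size: int = 150
    stage_fractions: tuple[float, float] = (0.40, 0.75)
    droplet_radius_fraction: float = 0.9
    seed: int = 0
    profiles: tuple[ClassProfile, ...] = DEFAULT_PROFILES
    base_level: float = 20.0
    initial_texture_sd: float = 5.0

    def validate(self) -> None:
        b1, b2 = self.stage_fractions
        if not (0.0 < b1 < b2 < 1.0):
            raise ValueError("stage_fractions must satisfy 0 < b1 < b2 < 1")
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.frame_size < 32:
            raise ValueError("frame_size must be >= 32")
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("profile labels must be distinct")
        for p in self.profiles:
            p.validate()
        ceilings = [p.intensity_ceiling for p in self.profiles]
        if any(a < b for a, b in zip(ceilings, ceilings[1:])):
            raise ValueError("intensity ceilings must be non-increasing from 0x to 1x")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.profiles)

    def profile(self, label: str) -> ClassProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise ValueError(f"unknown label {label!r}; valid labels: {self.labels}")


def make_default_config(
    seed: int, *, n_frames: int = 300, frame_size: int = 150,
    stage_fractions: tuple[float, float] = (0.40, 0.75),
) -> SimulationConfig:
    """Default five-class configuration, reproducible from ``seed``."""
    cfg = SimulationConfig(
        n_frames=n_frames, frame_size=frame_size,
        stage_fractions=stage_fractions, seed=seed,
    )
    cfg.validate()
    return cfg


def _correlated_field(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation
    length ``scale`` (white noise smoothed by a Gaussian kernel)."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=scale, mode="reflect")
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _rise(u: np.ndarray | float, rate: float) -> np.ndarray | float:
    """Normalised middle-stage ramp in [0, 1]; rate 0 disables the rise."""
    if rate == 0:
        return np.zeros_like(np.asarray(u, dtype=float))
    return np.tanh(rate * np.asarray(u, dtype=float)) / np.tanh(rate)


def generate_droplet_series(
    config: SimulationConfig, label: str, *, droplet_id: str | None = None
) -> DropletSeries:
    """Simulate one droplet movie for class ``label``.

    Deterministic given (config, label): the per-class seed is
    ``config.seed + fixed class offset``.
    """
    config.validate()
    prof = config.profile(label)
    offset = _CLASS_SEED_OFFSETS.get(label, 1000 * (list(config.labels).index(label) + 1))
    rng = np.random.default_rng(config.seed + offset)

    size = config.frame_size
    mask = circular_mask((size, size), config.droplet_radius_fraction)
    b1, b2 = config.stage_fractions
    times = np.arange(config.n_frames, dtype=float) / (config.n_frames - 1)
    stages = np.array([stage_of(t, (b1, b2)) for t in times], dtype=object)

    # frozen spatial structure of the series
    domain_field = _correlated_field(rng, size, prof.domain_scale)
    initial_field = _correlated_field(rng, size, 6.0) * config.initial_texture_sd
    # bright-domain threshold falls through the middle stage: domains grow
    # from nothing to the class-specific final coverage
    q_hi, q_lo = np.quantile(domain_field[mask], [0.999, 1.0 - prof.bright_fraction])

    frames = np.zeros((config.n_frames, size, size), dtype=np.uint8)
    amplitude = prof.intensity_ceiling - config.base_level
    for k, t in enumerate(times):
        if t < b1:
            u = 0.0
        elif t < b2:
            u = (t - b1) / (b2 - b1)
        else:
            u = 1.0
        s = float(_rise(u, prof.surge_rate))
        thresh = q_hi - (q_hi - q_lo) * s
        bright = domain_field >= thresh
        img = config.base_level + initial_field * (1.0 - 0.8 * s)
        img = img + amplitude * s * bright
        # small deterministic drift in the initial stage (slow settling flow);
        # scaled by the texture amplitude so a flat initial field is truly static
        img = img + _DRIFT_COEF * config.initial_texture_sd * np.sin(2 * np.pi * t) * (1.0 - s)
        if prof.noise_sd > 0:
            img = img + rng.normal(0.0, prof.noise_sd, size=(size, size))
        frame = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        frame[~mask] = 0
        frames[k] = frame

    return DropletSeries(
        frames=frames, mask=mask, times_norm=times, stages=stages,
        label=label, droplet_id=droplet_id or f"sim_{label}_seed{config.seed}",
    )


def generate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> list[DropletSeries]:
    """One series per class; optionally dumped to ``out_dir`` as PNG + JSON."""
    config.validate()
    dataset = [generate_droplet_series(config, lbl) for lbl in config.labels]
    if out_dir is not None:
        out_dir = Path(out_dir)
        for series in dataset:
            save_series(series, out_dir / series.label.replace(".", "p"))
        (out_dir / "config.json").write_text(json.dumps(config_to_dict(config), indent=2))
    return dataset


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_frames": config.n_frames,
        "frame_size": config.frame_size,
        "stage_fractions": list(config.stage_fractions),
        "droplet_radius_fraction": config.droplet_radius_fraction,
        "seed": config.seed,
        "base_level": config.base_level,
        "initial_texture_sd": config.initial_texture_sd,
        "profiles": [
            {
                "label": p.label,
                "intensity_ceiling": p.intensity_ceiling,
                "surge_rate": p.surge_rate,
                "domain_scale": p.domain_scale,
                "noise_sd": p.noise_sd,
                "bright_fraction": p.bright_fraction,
            }
            for p in config.profiles
        ],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    profiles = tuple(
        ClassProfile(
            label=p["label"],
            intensity_ceiling=p["intensity_ceiling"],
            surge_rate=p["surge_rate"],
            domain_scale=p["domain_scale"],
            noise_sd=p["noise_sd"],
            bright_fraction=p.get("bright_fraction", 0.5),
        )
        for p in d.get("profiles", [])
    ) or DEFAULT_PROFILES
    return SimulationConfig(
        n_frames=d.get("n_frames", 300),
        frame_size=d.get("frame_size", 150),
        stage_fractions=tuple(d.get("stage_fractions", (0.40, 0.75))),
        droplet_radius_fraction=d.get("droplet_radius_fraction", 0.9),
        seed=d.get("seed", 0),
        base_level=d.get("base_level", 20.0),
        initial_texture_sd=d.get("initial_texture_sd", 5.0),
        profiles=profiles,
    )
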