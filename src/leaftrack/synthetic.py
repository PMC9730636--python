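"""Synthetic maize development simulator with ground-truth ranks.

Emulates the acquisition regime of a greenhouse phenotyping platform:
~43 daily time points per plant, leaves emerging bottom-to-top at a fixed
phyllochron from the whorl at the stem tip, growing along a logistic
length curve, ligulating (geometry freezing, collar fixed just below the
stem tip) after a fixed lag, and basal leaves disappearing by senescence.
Corruption reproduces the named failure modes of real segmentations:
randomly missed leaves, occasional ear-like artefact leaves inserted among
the upper collars, and zero-mean feature noise.

The defaults ARE the study conditions; they are not tuned per run.
Thermal time is emitted at 1 day_20degC per calendar day (constant-
temperature greenhouse assumption), configurable via ``thermal_scale``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    GROWING,
    LIGULATED,
    LeafObservation,
    PlantSnapshot,
    Polyline3D,
    wrap_angle,
)

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate_plant", "corrupt"]

# per-feature noise scales (the "feature scale" that feature_noise_sd
# multiplies): typical insertion height, leaf length, azimuth range
_H_SCALE = 500.0  # mm
_L_SCALE = 800.0  # mm
_A_SCALE = math.pi  # rad


@dataclass
class SimulationConfig:
    """Conditions of one simulated plant time-series."""

    seed: int = 0
    n_leaves: int = 16
    n_timepoints: int = 43
    dt: float = 1.0  # days between acquisitions
    phyllochron: float = 2.0  # days between successive emergences
    ligulation_lag: float = 8.0  # days from emergence to ligulation
    senescence_start: float = 30.0  # day the first basal leaf drops
    senescence_rate: float = 0.3  # leaves dropped per day afterwards
    stem_height_max: float = 2000.0  # mm
    stem_growth_rate: float = 0.15  # logistic steepness (1/day)
    stem_t_mid: float = 25.0  # logistic midpoint (day)
    length_max_profile: Optional[list[float]] = None  # per-rank asymptotes (mm)
    azimuth_jitter: float = 0.1  # rad, around the alternating +-pi/2 pattern
    feature_noise_sd: float = 0.0  # fraction of feature scale
    p_missing_leaf: float = 0.0
    p_artefact_leaf: float = 0.0
    thermal_scale: float = 1.0  # day_20degC per calendar day
    plant_id: str = "synthetic"

    def __post_init__(self) -> None:
        for p in (self.p_missing_leaf, self.p_artefact_leaf):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.phyllochron <= 0:
            raise ValueError("phyllochron must be positive")

    def length_asymptote(self, rank: int) -> float:
        """Asymptotic blade length per rank: bell-shaped over the profile."""
        if self.length_max_profile is not None:
            return self.length_max_profile[rank - 1]
        # bell peaking near 2/3 of the leaf count, maize-like (~1000 mm max)
        peak = 2.0 * self.n_leaves / 3.0
        width = self.n_leaves / 1.5
        return 300.0 + 700.0 * math.exp(-(((rank - peak) / width) ** 2))


@dataclass
class SimulatedTruth:
    """A corrupted-view series bundled with its ground truth."""

    series: list[PlantSnapshot]
    truth_ranks: dict[str, object] = field(default_factory=dict)
    truth_stages: list[tuple[float, int, int]] = field(default_factory=list)
    truth_lengths: dict[int, float] = field(default_factory=dict)
    config: Optional[SimulationConfig] = None


def _stem_height(cfg: SimulationConfig, t: float) -> float:
    base = 20.0
    return base + cfg.stem_height_max / (
        1.0 + math.exp(-cfg.stem_growth_rate * (t - cfg.stem_t_mid))
    ) - cfg.stem_height_max / (1.0 + math.exp(cfg.stem_growth_rate * cfg.stem_t_mid))


def _emergence_time(cfg: SimulationConfig, rank: int) -> float:
    return 1.0 + (rank - 1) * cfg.phyllochron


def _midrib(
    base_height: float, azimuth: float, length: float, droop: float
) -> Polyline3D:
    """Smooth arching midrib from the insertion point.

    Rises out of the whorl then bends towards the azimuth direction; the
    shape is a fixed smooth family so day-to-day change tracks length and
    insertion height only (small at daily sampling).
    """
    s = np.linspace(0.0, 1.0, 12)
    ux, uy = math.cos(azimuth), math.sin(azimuth)
    radial = length * (0.75 * s + 0.15 * s**2)
    height = base_height + length * (0.8 * s - droop * s**2)
    pts = np.column_stack([ux * radial, uy * radial, height])
    return Polyline3D(pts)


def _leaf_length(cfg: SimulationConfig, rank: int, t: float) -> float:
    """Logistic growth from emergence, frozen at the asymptote at ligulation."""
    t_em = _emergence_time(cfg, rank)
    t_lig = t_em + cfg.ligulation_lag
    l_max = cfg.length_asymptote(rank)
    if t >= t_lig:
        return l_max
    # logistic reaching ~99% of the asymptote at ligulation
    k = 10.0 / cfg.ligulation_lag
    t_mid = t_em + cfg.ligulation_lag / 2.0
    return l_max / (1.0 + math.exp(-k * (t - t_mid)))


def simulate_plant(config: SimulationConfig) -> SimulatedTruth:
    """Generate one noise-free ground-truth plant time-series.

    Deterministic for a given config (the seed drives azimuth jitter and,
    later, corruption).  Leaves emerge bottom-to-top at phyllochron
    intervals; a leaf's collar fixes just below the current stem tip at
    ligulation; basal leaves disappear by senescence.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_leaves
    # alternating azimuth pattern with jitter, fixed per leaf for life
    azimuths = [
        wrap_angle(
            (math.pi / 2.0 if r % 2 else -math.pi / 2.0)
            + rng.normal(0.0, config.azimuth_jitter)
        )
        for r in range(1, n + 1)
    ]
    # a collar appears below the whorl: the rolled growing leaves extend
    # well above the highest collar, so the collar fixes ~100 mm under the
    # stem tip reached at ligulation
    lig_heights = {
        r: max(
            5.0,
            _stem_height(config, _emergence_time(config, r) + config.ligulation_lag)
            - 100.0,
        )
        for r in range(1, n + 1)
    }

    snapshots: list[PlantSnapshot] = []
    truth_ranks: dict[str, object] = {}
    truth_stages = []
    for it in range(config.n_timepoints):
        t = it * config.dt
        h_stem = _stem_height(config, t)
        n_dropped = (
            0
            if t < config.senescence_start
            else int((t - config.senescence_start) * config.senescence_rate) + 1
        )
        ligulated: list[LeafObservation] = []
        growing: list[LeafObservation] = []
        n_vis = 0
        n_lig = 0
        for r in range(1, n + 1):
            t_em = _emergence_time(config, r)
            t_lig = t_em + config.ligulation_lag
            if t < t_em:
                continue
            n_vis = max(n_vis, r)
            is_lig = t >= t_lig
            if is_lig:
                n_lig = max(n_lig, r)
            if r <= n_dropped:
                continue  # senesced and fallen
            length = _leaf_length(config, r, t)
            # droop increases smoothly with age and freezes at ligulation
            age = min(1.0, (t - t_em) / config.ligulation_lag)
            droop = 0.25 + 0.20 * age
            if is_lig:
                h_ins = lig_heights[r]
            else:
                h_ins = h_stem + 5.0  # whorl: emerges at the stem tip
            uid = f"t{it}_r{r}"
            leaf = LeafObservation(
                uid=uid,
                time=t,
                thermal_time=t * config.thermal_scale,
                azimuth=azimuths[r - 1],
                insertion_height=h_ins,
                length=length,
                midrib=_midrib(h_ins, azimuths[r - 1], length, droop),
                status=LIGULATED if is_lig else GROWING,
            )
            truth_ranks[uid] = r
            (ligulated if is_lig else growing).append(leaf)
        ligulated.sort(key=lambda lf: lf.insertion_height)
        stem = Polyline3D(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, max(h_stem, 1.0)]])
        )
        collars = _collar_views(ligulated)
        snapshots.append(
            PlantSnapshot(
                time=t,
                thermal_time=t * config.thermal_scale,
                stem=stem,
                ligulated=ligulated,
                growing=growing,
                collars_per_view=collars,
                stem_height=h_stem,
            )
        )
        truth_stages.append((t, n_vis, n_lig))

    truth_lengths = {r: config.length_asymptote(r) for r in range(1, n + 1)}
    return SimulatedTruth(
        series=snapshots,
        truth_ranks=truth_ranks,
        truth_stages=truth_stages,
        truth_lengths=truth_lengths,
        config=config,
    )


def _collar_views(ligulated: list[LeafObservation], n_views: int = 12):
    """Distribute collar detections over side views; max equals stem height."""
    views: list[list[float]] = [[] for _ in range(n_views)]
    for i, lf in enumerate(ligulated):
        views[i % n_views].append(lf.insertion_height)
    return views


def corrupt(sim: SimulatedTruth, config: SimulationConfig) -> SimulatedTruth:
    """Corrupt a ground-truth series into a realistic pipeline input.

    Per snapshot, independently: with probability ``p_missing_leaf`` one
    uniformly-chosen leaf is missed by the segmentation; with probability
    ``p_artefact_leaf`` one ear-like artefact leaf (short, inserted among
    the upper collars, never below the 5th) is added; insertion height,
    length and azimuth are perturbed with zero-mean Gaussian noise of
    sd = ``feature_noise_sd`` x feature scale.  Truth labels are carried
    over; artefacts are flagged.
    """
    rng = np.random.default_rng([config.seed, 1])
    out_snaps: list[PlantSnapshot] = []
    truth_ranks = dict(sim.truth_ranks)
    sd_h = config.feature_noise_sd * _H_SCALE
    sd_l = config.feature_noise_sd * _L_SCALE
    sd_a = config.feature_noise_sd * _A_SCALE
    for it, snap in enumerate(sim.series):
        all_leaves = snap.leaves
        missed = -1
        if (
            config.p_missing_leaf > 0
            and all_leaves
            and rng.random() < config.p_missing_leaf
        ):
            missed = int(rng.integers(len(all_leaves)))
        leaves: list[LeafObservation] = []
        for j, lf in enumerate(all_leaves):
            if j == missed:
                truth_ranks.pop(lf.uid, None)
                continue
            noisy = replace(lf)
            if config.feature_noise_sd > 0:
                # observation noise on the extracted features h, l, alpha;
                # the midrib polyline itself is carried unchanged
                noisy.insertion_height = max(
                    0.0, lf.insertion_height + rng.normal(0.0, sd_h)
                )
                noisy.length = max(1.0, lf.length + rng.normal(0.0, sd_l))
                noisy.azimuth = wrap_angle(lf.azimuth + rng.normal(0.0, sd_a))
            leaves.append(noisy)
        lig_heights = sorted(
            lf.insertion_height for lf in leaves if lf.status == LIGULATED
        )
        # ear-like artefacts only ever appear among the upper collars; a
        # plant with fewer than five collars cannot host one
        if (
            config.p_artefact_leaf > 0
            and len(lig_heights) >= 5
            and rng.random() < config.p_artefact_leaf
        ):
            stem_h = snap.stem_height or snap.stem.points[:, 2].max()
            floor = lig_heights[4]
            h_art = floor + rng.random() * max(lig_heights[-1] - floor, 1.0)
            az = wrap_angle(rng.uniform(-math.pi, math.pi))
            length = 80.0 + rng.random() * 120.0  # ear-like: short
            uid = f"t{it}_art{rng.integers(10**6)}"
            art = LeafObservation(
                uid=uid,
                time=snap.time,
                thermal_time=snap.thermal_time,
                azimuth=az,
                insertion_height=h_art,
                length=length,
                midrib=_midrib(h_art, az, length, 0.45),
                status=LIGULATED if h_art <= stem_h else GROWING,
                is_artefact=True,
            )
            truth_ranks[uid] = "artefact"
            leaves.append(art)
        lig = sorted(
            (lf for lf in leaves if lf.status == LIGULATED),
            key=lambda lf: lf.insertion_height,
        )
        grow = [lf for lf in leaves if lf.status == GROWING]
        out_snaps.append(
            PlantSnapshot(
                time=snap.time,
                thermal_time=snap.thermal_time,
                stem=snap.stem,
                ligulated=lig,
                growing=grow,
                collars_per_view=_collar_views(lig),
                stem_height=snap.stem_height,
            )
        )
    return SimulatedTruth(
        series=out_snaps,
        truth_ranks=truth_ranks,
        truth_stages=list(sim.truth_stages),
        truth_lengths=dict(sim.truth_lengths),
        config=config,
    )
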