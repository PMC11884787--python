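"""Movie-like participant recordings on synthetic cortical sheets.

The generative model mirrors the assumptions of the downstream analyses:

* a shared, temporally smooth latent time course drives every participant
  watching the same movie (the converse of the shared-response model);
* each participant mixes the latents through a unit-by-latent loading matrix
  whose columns combine (i) area-anchored patterns whose weight decays with
  hierarchy distance and drops across streams - this plants the homotopic
  same > adjacent > distal correlation structure, (ii) the two ground-truth
  retinotopic maps, scaled by ``map_coupling``, and (iii) seeded
  participant-specific smooth patterns;
* spatially smoothed Gaussian noise is added at a signal-to-noise ratio
  ``snr``, plus a motion confound: a per-participant motion time course
  times a single smooth global spatial pattern;
* the hemodynamic delay is emulated by an integer-TR shift with cropping;
* each unit's time course is z-scored within movie.

The spatial-frequency loading column is demeaned within area before use
(its area means are constant across areas and would only add a uniform
shared signal), so the planted within-area map structure leaves the
planted between-area time-course structure untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .sheet import (
    CorticalSheet,
    GradientLine,
    GroundTruthMaps,
    HEMIS,
    build_cortical_sheet,
    generate_ground_truth_maps,
    jitter_maps,
    trace_gradient_lines,
)
__all__ = [
    "SimulationConfig",
    "ParticipantRecording",
    "StudyBundle",
    "child_rng",
    "child_seed",
    "simulate_movie_responses",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """A simulation configuration value is out of range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic movie-watching cohort.

    Defaults are the package's standard cohort: 15 participants (the study
    sample size), a 24 x 32 grid per hemisphere, two 90-TR movies at TR 2 s,
    10 shared latents (matching the shared-space dimensionality used for
    alignment), map coupling 0.5, SNR 1, a mild motion confound, and a 2-TR
    (4 s) hemodynamic shift.
    """

    n_participants: int = 15
    grid_height: int = 24
    grid_width: int = 32
    n_timepoints: int = 90  # per movie, before hemodynamic cropping
    n_movies: int = 2
    tr: float = 2.0
    k_latent: int = 10
    map_coupling: float = 0.5  # fraction of loading variance carried by the maps
    snr: float = 1.0  # shared-signal sd over noise sd
    motion_amplitude: float = 0.5
    hemodynamic_shift_trs: int = 2
    map_jitter_scale: float = 0.0  # between-participant map misalignment, grid units
    noise_smoothing: float = 1.5  # spatial sigma of the noise, grid units
    idiosyncrasy: float = 0.2  # participant-specific loading perturbation scale
    structured: bool = True  # False: loadings are anatomy-free smooth patterns
    scheme: str = "retinotopic"
    seed: int = 42

    def __post_init__(self):
        if min(self.n_participants, self.n_timepoints, self.n_movies, self.k_latent) < 1:
            raise ConfigurationError("counts must be >= 1")
        if not (0.0 <= self.map_coupling <= 1.0):
            raise ConfigurationError("map_coupling must be in [0, 1]")
        if self.snr <= 0:
            raise ConfigurationError("snr must be > 0")
        if self.hemodynamic_shift_trs < 0:
            raise ConfigurationError("hemodynamic_shift_trs must be >= 0")
        if self.hemodynamic_shift_trs >= self.n_timepoints:
            raise ConfigurationError("hemodynamic shift must be shorter than a movie")
        if self.k_latent < 3:
            raise ConfigurationError("k_latent must be >= 3 (two map latents plus areas)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def child_seed(master_seed: int, *path) -> np.random.SeedSequence:
    """Deterministic seed fan-out: one master seed, a tuple-addressed child.

    The path elements (small ints or short strings) address independent
    streams, so every stage of a pipeline is reproducible in isolation.
    """
    key = tuple(
        int.from_bytes(p.encode()[:4].ljust(4, b"\0"), "little")
        if isinstance(p, str)
        else int(p)
        for p in path
    )
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)


def child_rng(master_seed: int, *path) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *path))


@dataclass(frozen=True)
class ParticipantRecording:
    """Unit x time movie responses for one participant.

    ``data`` concatenates all movies; ``movie_intervals`` are half-open
    timepoint intervals delimiting each movie after hemodynamic cropping.
    Each unit's time course is z-scored within movie. The generating loading
    matrix and the participant's own (possibly jittered) ground-truth maps
    are retained for oracle tests and for the alignment analyses.
    """

    data: np.ndarray  # (n_units, T_total)
    tr: float
    movie_intervals: tuple[tuple[int, int], ...]
    motion: np.ndarray  # (T_total,)
    seed: int
    participant: int
    loadings: np.ndarray  # (n_units, k_latent)
    maps: GroundTruthMaps

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def movie_data(self, movie: int) -> np.ndarray:
        s, e = self.movie_intervals[movie]
        return self.data[:, s:e]

    def movie_motion(self, movie: int) -> np.ndarray:
        s, e = self.movie_intervals[movie]
        return self.motion[s:e]


def _shared_latents(k: int, t: int, rng: np.random.Generator) -> np.ndarray:
    """Order-2 autoregressive latents low-passed at 0.3 x Nyquist, unit variance.

    The cutoff approximates the hemodynamic passband at a 2 s TR; it keeps
    enough temporal degrees of freedom that a time-reversed recording shares
    no systematic structure with the forward latents.
    """
    n_burn = 50
    e = rng.standard_normal((k, t + n_burn))
    s = np.zeros_like(e)
    a1, a2 = 0.5, 0.2
    for i in range(2, t + n_burn):
        s[:, i] = a1 * s[:, i - 1] + a2 * s[:, i - 2] + e[:, i]
    s = s[:, n_burn:]
    b, a = signal.butter(2, 0.3)
    s = signal.filtfilt(b, a, s, axis=1)
    s -= s.mean(axis=1, keepdims=True)
    sd = s.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return s / sd


def _unit_variance(v: np.ndarray) -> np.ndarray:
    sd = float(v.std())
    return v / sd if sd > 0 else v


def _smooth_pattern(sheet: CorticalSheet, rng: np.random.Generator, sigma=2.0) -> np.ndarray:
    parts = [
        ndimage.gaussian_filter(
            rng.standard_normal((sheet.height, sheet.width)), sigma, mode="wrap"
        ).ravel()
        for _ in HEMIS
    ]
    return _unit_variance(np.concatenate(parts))


def _area_anchor_patterns(
    sheet: CorticalSheet, n_cols: int, decay: float = 0.5, cross_stream: float = 0.3
) -> np.ndarray:
    """Columns anchored at (level, stream) pairs, decaying with hierarchy distance."""
    anchors = [(a.level, a.stream) for a in sheet.areas]
    cols = []
    for j in range(n_cols):
        lvl, stream = anchors[j % len(anchors)]
        w = decay ** np.abs(sheet.level - lvl)
        w = np.where(sheet.stream == stream, w, cross_stream * w)
        cols.append(_unit_variance(w.astype(float)))
    return np.column_stack(cols)


def _unstructured_loadings(
    sheet: CorticalSheet, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Anatomy-free loading columns for "pure noise" cohorts.

    Half the columns are phase-random periodic oscillations along the area
    axis (period two area heights, like banding artifacts) plus smooth
    residue; the rest are large-scale smooth random patterns. Nothing is
    locked to the area layout: the oscillation phase is uniform, so any
    resemblance to a retinotopic map is coincidental, and the statistics are
    invariant under circular grid shifts.
    """
    h, w = sheet.height, sheet.width
    rows = np.arange(h)[:, None]
    cycles = len(sheet.areas) / 2.0
    cols = []
    for j in range(k):
        if j < k // 2:
            phase = rng.uniform(0, h)
            osc = np.sin(2 * np.pi * cycles * (rows + phase) / h)
            grid = np.broadcast_to(osc, (h, w)).copy()
            grid += 0.3 * ndimage.gaussian_filter(
                rng.standard_normal((h, w)), 2.0, mode="wrap"
            )
            cols.append(_unit_variance(np.concatenate([grid.ravel()] * 2)))
        else:
            cols.append(_smooth_pattern(sheet, rng, sigma=(3.0, 6.0)))
    return np.column_stack(cols)


def _demean_within_area(values: np.ndarray, sheet: CorticalSheet) -> np.ndarray:
    out = values.astype(float).copy()
    for hemi in HEMIS:
        for a in sheet.areas:
            idx = sheet.area_indices(a.name, hemi)
            out[idx] -= out[idx].mean()
    return out


def participant_loadings(
    sheet: CorticalSheet,
    maps: GroundTruthMaps,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Loading matrix for one participant: area anchors + map columns + idiosyncrasy.

    With ``config.structured = False`` every column is instead an
    anatomy-free smooth random pattern: a "pure noise" cohort whose spatial
    organization bears no relation to the area layout, used as the null for
    selection-specificity experiments.
    """
    k = config.k_latent
    if not config.structured:
        return _unstructured_loadings(sheet, k, rng)
    n_map = 2
    n_area = k - n_map
    base = np.zeros((sheet.n_units, k))
    base[:, :n_area] = _area_anchor_patterns(sheet, n_area) * np.sqrt(
        max(1.0 - config.map_coupling, 0.0)
    )
    # The SF column is demeaned within area (its area means are a constant
    # offset that would add a uniform shared signal across areas); the
    # meridian column keeps its alternating area means, which are part of
    # its boundary-crossing sign structure.
    sf_col = _unit_variance(_demean_within_area(maps.spatial_frequency, sheet))
    mer_col = _unit_variance(np.asarray(maps.meridian, dtype=float))
    for j, col in enumerate((sf_col, mer_col)):
        base[:, n_area + j] = col * np.sqrt(config.map_coupling)
    if config.idiosyncrasy > 0:
        idio = np.column_stack([_smooth_pattern(sheet, rng) for _ in range(k)])
        base = base + config.idiosyncrasy * idio
    return base


def simulate_movie_responses(
    sheet: CorticalSheet,
    maps: GroundTruthMaps,
    config: SimulationConfig,
) -> list[ParticipantRecording]:
    """Generate the full cohort of participant recordings.

    The latent time courses are drawn once per movie (identical across
    participants); loadings, noise, motion, and optional map jitter are
    per participant, all seeded from ``config.seed`` through the
    tuple-addressed fan-out, so identical configs give bit-identical cohorts.
    """
    if config.snr <= 0:
        raise ConfigurationError("snr must be > 0")
    shift = config.hemodynamic_shift_trs
    t_rec = config.n_timepoints - shift
    latents = [
        _shared_latents(config.k_latent, config.n_timepoints, child_rng(config.seed, 0, m))
        for m in range(config.n_movies)
    ]
    # motion transients drive consistent activity across areas: a global
    # offset plus smooth spatial variation
    motion_pattern = 1.0 + _smooth_pattern(sheet, child_rng(config.seed, 1))
    recordings = []
    for i in range(config.n_participants):
        p_seed = int(child_seed(config.seed, 2, i).generate_state(1)[0] % (2**31))
        if config.map_jitter_scale > 0:
            p_maps = jitter_maps(
                maps,
                sheet,
                config.map_jitter_scale,
                seed=child_seed(config.seed, 3, i),
            )
        else:
            p_maps = maps
        loadings = participant_loadings(sheet, p_maps, config, child_rng(config.seed, 4, i))
        noise_rng = child_rng(config.seed, 5, i)
        motion_rng = child_rng(config.seed, 6, i)
        blocks, motions, intervals = [], [], []
        start = 0
        for m in range(config.n_movies):
            # hemodynamic shift with cropping: the recorded window lags the
            # stimulus by `shift` TRs, so `shift` TRs are lost per movie
            s_m = latents[m][:, : config.n_timepoints - shift] if shift else latents[m]
            x = loadings @ s_m
            sig_sd = float(x.std())
            noise = noise_rng.standard_normal((sheet.n_units, t_rec))
            if config.noise_smoothing > 0:
                for hemi in HEMIS:
                    sl = sheet.hemi_slice(hemi)
                    g = noise[sl].reshape(sheet.height, sheet.width, t_rec)
                    noise[sl] = ndimage.gaussian_filter(
                        g, (config.noise_smoothing, config.noise_smoothing, 0), mode="wrap"
                    ).reshape(-1, t_rec)
            noise_sd = float(noise.std())
            if noise_sd > 0:
                noise *= (sig_sd / config.snr) / noise_sd
            mo = np.abs(
                signal.lfilter([1.0], [1.0, -0.7], motion_rng.standard_normal(t_rec))
            )
            x = x + noise + config.motion_amplitude * np.outer(motion_pattern, mo)
            # z-score per movie, per unit
            x = x - x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            x = x / sd
            blocks.append(x)
            motions.append(mo)
            intervals.append((start, start + t_rec))
            start += t_rec
        recordings.append(
            ParticipantRecording(
                data=np.concatenate(blocks, axis=1),
                tr=config.tr,
                movie_intervals=tuple(intervals),
                motion=np.concatenate(motions),
                seed=p_seed,
                participant=i,
                loadings=loadings,
                maps=p_maps,
            )
        )
    return recordings


@dataclass(frozen=True)
class StudyBundle:
    """A complete synthetic study: sheet, maps, lines, recordings, provenance."""

    sheet: CorticalSheet
    maps: GroundTruthMaps  # cohort-level base maps (pre-jitter)
    lines_parallel: list[GradientLine]
    lines_perpendicular: list[GradientLine]
    recordings: list[ParticipantRecording]
    config: SimulationConfig
    provenance: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.recordings)


def simulate_cohort(config: SimulationConfig | None = None) -> StudyBundle:
    """Build sheet, ground-truth maps, gradient lines, and recordings in one call."""
    config = config or SimulationConfig()
    sheet = build_cortical_sheet(config.grid_height, config.grid_width, config.scheme)
    maps = generate_ground_truth_maps(sheet)
    recordings = simulate_movie_responses(sheet, maps, config)
    return StudyBundle(
        sheet=sheet,
        maps=maps,
        lines_parallel=trace_gradient_lines(sheet, "parallel"),
        lines_perpendicular=trace_gradient_lines(sheet, "perpendicular"),
        recordings=recordings,
        config=config,
        provenance={"config": config.to_dict()},
    )
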