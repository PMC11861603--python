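"""Synthetic tri-axial accelerometer segments with subject structure.

The generator emulates the statistical families of chest-worn accelerometer
recordings of daily activities and falls: periodic gait-like signals (a
fundamental near the cadence plus two harmonics riding on the gravity
projection), transient falls (quiescence, an impact spike, then a reoriented
gravity vector), quasi-static postures, and posture transitions (a smooth
1-2 s swing between gravity vectors).  Per-subject random effects (lognormal
amplitude and frequency multipliers held fixed within subject) induce the
intra-subject correlation that makes subject-independent splitting matter.

Values are dimensionless raw counts with 512 counts per g, so gravity sits
near 512 and fall impacts reach 2-3.5 g.  Walking cadence defaults to 1.5 Hz
(about 90 steps per minute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import AccelSegment

__all__ = [
    "COUNTS_PER_G",
    "ActivityArchetype",
    "SyntheticConfig",
    "simulate_segment",
    "simulate_dataset",
    "default_taxonomy_15",
    "subset_config",
    "four_class_config",
]

#: Raw-count scale: counts per 1 g of acceleration.
COUNTS_PER_G = 512.0

ARCHETYPE_KINDS = ("periodic", "transient_fall", "static", "transition")

# canonical chest-sensor gravity projections (unit vectors)
_G_STAND = (0.0, 0.98, 0.2)
_G_SIT = (0.0, 0.9, 0.44)
_G_SUPINE = (0.0, 0.17, 0.99)
_G_PRONE = (0.0, 0.17, -0.99)
_G_LEFT = (-0.97, 0.24, 0.0)
_G_RIGHT = (0.97, 0.24, 0.0)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("gravity vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class ActivityArchetype:
    """Generative parameters of one activity class.

    amplitude is the per-axis dynamic amplitude in counts; impact_magnitude
    (counts) applies to falls; gravity vectors are unit 3-vectors before and
    after the movement; noise_sigma is the sensor noise level in counts.
    """

    name: str
    kind: str
    base_freq_hz: float | None = None
    freq_jitter: float = 0.1
    amplitude: tuple[float, float, float] = (60.0, 120.0, 80.0)
    gravity_before: tuple[float, float, float] = _G_STAND
    gravity_after: tuple[float, float, float] | None = None
    impact_magnitude: float = 0.0
    noise_sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "periodic" and (self.base_freq_hz is None or self.base_freq_hz <= 0):
            raise ValueError("periodic archetypes need base_freq_hz > 0")
        object.__setattr__(self, "gravity_before", tuple(_unit(self.gravity_before)))
        ga = self.gravity_after if self.gravity_after is not None else self.gravity_before
        object.__setattr__(self, "gravity_after", tuple(_unit(ga)))
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset-level generative parameters.

    reps_per_class=5 mirrors each subject repeating every activity five
    times; subject_effect_sd is the lognormal sd of per-subject amplitude and
    frequency multipliers.
    """

    archetypes: tuple[ActivityArchetype, ...]
    n_subjects: int = 10
    reps_per_class: int = 5
    fs: float = 250.0
    segment_seconds: float = 10.0
    subject_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.reps_per_class < 1:
            raise ValueError("reps_per_class must be >= 1")
        object.__setattr__(self, "archetypes", tuple(self.archetypes))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def simulate_segment(archetype: ActivityArchetype,
                     subject_effects: dict | None = None,
                     fs: float = 250.0, seconds: float = 10.0,
                     seed: int | np.random.Generator = 0,
                     subject_id: str = "S000", segment_index: int = 0) -> AccelSegment:
    """Draw one segment from an archetype.

    subject_effects holds multiplicative random effects: ``amp_mult`` scales
    dynamic amplitudes and impact magnitudes, ``freq_mult`` scales the
    fundamental frequency.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eff = subject_effects or {}
    amp_mult = float(eff.get("amp_mult", 1.0))
    freq_mult = float(eff.get("freq_mult", 1.0))

    n = int(round(fs * seconds))
    t = np.arange(n) / fs
    g_before = np.asarray(archetype.gravity_before) * COUNTS_PER_G
    g_after = np.asarray(archetype.gravity_after) * COUNTS_PER_G
    amp = np.asarray(archetype.amplitude, dtype=np.float64) * amp_mult
    sig = np.tile(g_before, (n, 1))

    if archetype.kind == "periodic":
        f = archetype.base_freq_hz * freq_mult
        f *= 1.0 + archetype.freq_jitter * rng.uniform(-1.0, 1.0)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        wave = (np.sin(2 * np.pi * f * t + phases[0])
                + 0.5 * np.sin(4 * np.pi * f * t + phases[1])
                + 0.25 * np.sin(6 * np.pi * f * t + phases[2]))
        sig = sig + wave[:, None] * amp[None, :]
        # impulsive ground-contact transients once per cycle: short (~20 ms)
        # spikes whose harmonics extend well beyond the smooth gait components,
        # as heel strikes / rope landings do in real recordings
        phase0 = rng.uniform(0.0, 1.0 / f)
        strikes = np.arange(phase0, seconds, 1.0 / f)
        strikes = strikes + rng.normal(0.0, 0.01, size=strikes.shape)
        impact = np.zeros(n)
        for ts in strikes:
            impact += np.exp(-0.5 * ((t - ts) / 0.01) ** 2)
        sig = sig + impact[:, None] * amp[None, :] * 1.5
    elif archetype.kind == "transition":
        t0 = rng.uniform(0.35, 0.55) * seconds
        dur = rng.uniform(1.0, 2.0)
        w = _smoothstep((t - t0) / dur)
        sig = (1.0 - w)[:, None] * g_before + w[:, None] * g_after
        # movement burst around the transition
        bump = np.exp(-0.5 * ((t - t0 - dur / 2) / (dur / 3)) ** 2)
        sig = sig + bump[:, None] * amp[None, :] * 0.5
    elif archetype.kind == "transient_fall":
        t_impact = rng.uniform(seconds / 3.0, 2.0 * seconds / 3.0)
        w = _smoothstep((t - t_impact) / 0.4)
        sig = (1.0 - w)[:, None] * g_before + w[:, None] * g_after
        direction = g_after - g_before
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else np.array([0.0, -1.0, 0.0])
        spike = np.exp(-0.5 * ((t - t_impact) / 0.05) ** 2)
        sig = sig + spike[:, None] * direction[None, :] * archetype.impact_magnitude * amp_mult
        # post-impact jostle, decaying over ~1 s
        jostle = (np.exp(-np.clip(t - t_impact, 0, None) / 0.5)
                  * (t >= t_impact)
                  * np.sin(2 * np.pi * 6.0 * (t - t_impact)))
        sig = sig + jostle[:, None] * amp[None, :] * 0.6
    # static: gravity projection only

    if archetype.noise_sigma > 0:
        sig = sig + rng.normal(0.0, archetype.noise_sigma, size=sig.shape)
    return AccelSegment(samples=sig, fs=fs, subject_id=subject_id,
                        label=archetype.name, segment_index=segment_index)


def simulate_dataset(cfg: SyntheticConfig) -> list[AccelSegment]:
    """n_subjects x n_classes x reps segments, deterministic for a fixed seed.

    Per-subject random effects are drawn once per subject and reused for all
    of that subject's segments.
    """
    master = np.random.default_rng(cfg.seed)
    segments: list[AccelSegment] = []
    for si in range(cfg.n_subjects):
        subject_id = f"S{si:03d}"
        effects = {
            "amp_mult": float(np.exp(master.normal(0.0, cfg.subject_effect_sd))),
            "freq_mult": float(np.exp(master.normal(0.0, cfg.subject_effect_sd))),
        }
        for arch in cfg.archetypes:
            for rep in range(cfg.reps_per_class):
                segments.append(simulate_segment(
                    arch, effects, cfg.fs, cfg.segment_seconds, master,
                    subject_id=subject_id, segment_index=rep))
    return segments


def _default_archetypes() -> tuple[ActivityArchetype, ...]:
    return (
        ActivityArchetype("UPS", "periodic", base_freq_hz=1.3,
                          amplitude=(70.0, 130.0, 90.0)),
        ActivityArchetype("DWS", "periodic", base_freq_hz=1.7,
                          amplitude=(80.0, 150.0, 100.0)),
        ActivityArchetype("SC", "transition", amplitude=(30.0, 90.0, 60.0),
                          gravity_before=_G_STAND, gravity_after=_G_SIT),
        ActivityArchetype("GC", "transition", amplitude=(30.0, 90.0, 60.0),
                          gravity_before=_G_SIT, gravity_after=_G_STAND),
        ActivityArchetype("LUB", "transition", amplitude=(50.0, 70.0, 80.0),
                          gravity_before=_G_SIT, gravity_after=_G_SUPINE),
        ActivityArchetype("LDB", "transition", amplitude=(50.0, 70.0, 80.0),
                          gravity_before=_G_SUPINE, gravity_after=_G_SIT),
        ActivityArchetype("WK", "periodic", base_freq_hz=1.5,
                          amplitude=(60.0, 120.0, 80.0)),
        ActivityArchetype("SQ", "periodic", base_freq_hz=0.5,
                          amplitude=(40.0, 180.0, 120.0)),
        ActivityArchetype("JR", "periodic", base_freq_hz=2.5,
                          amplitude=(120.0, 300.0, 150.0)),
        # falls: FF vs FFK differ only in impact magnitude and post-fall pitch
        ActivityArchetype("FF", "transient_fall", amplitude=(40.0, 80.0, 60.0),
                          gravity_before=_G_STAND, gravity_after=(0.0, 0.1, -0.99),
                          impact_magnitude=3.2 * COUNTS_PER_G, noise_sigma=20.0),
        ActivityArchetype("FFK", "transient_fall", amplitude=(40.0, 80.0, 60.0),
                          gravity_before=_G_STAND, gravity_after=(0.0, 0.3, -0.95),
                          impact_magnitude=2.2 * COUNTS_PER_G, noise_sigma=20.0),
        ActivityArchetype("FB", "transient_fall", amplitude=(40.0, 80.0, 60.0),
                          gravity_before=_G_STAND, gravity_after=(0.0, 0.2, 0.98),
                          impact_magnitude=3.0 * COUNTS_PER_G, noise_sigma=20.0),
        # LF and RF are mirror images across the x-axis sign
        ActivityArchetype("LF", "transient_fall", amplitude=(80.0, 60.0, 40.0),
                          gravity_before=_G_STAND, gravity_after=_G_LEFT,
                          impact_magnitude=2.8 * COUNTS_PER_G, noise_sigma=20.0),
        ActivityArchetype("RF", "transient_fall", amplitude=(80.0, 60.0, 40.0),
                          gravity_before=_G_STAND, gravity_after=_G_RIGHT,
                          impact_magnitude=2.8 * COUNTS_PER_G, noise_sigma=20.0),
        ActivityArchetype("FOB", "transient_fall", amplitude=(60.0, 50.0, 60.0),
                          gravity_before=_G_SUPINE, gravity_after=(-0.7, 0.14, -0.7),
                          impact_magnitude=3.5 * COUNTS_PER_G, noise_sigma=20.0),
    )


def default_taxonomy_15(n_subjects: int = 10, reps_per_class: int = 5,
                        seed: int = 0, subject_effect_sd: float = 0.1) -> SyntheticConfig:
    """The full 15-class configuration: 5 periodic, 4 transition, 6 fall
    archetypes, with deliberately similar pairs (FF/FFK, LF/RF) to reproduce
    the confusability structure of real recordings."""
    return SyntheticConfig(archetypes=_default_archetypes(), n_subjects=n_subjects,
                           reps_per_class=reps_per_class, seed=seed,
                           subject_effect_sd=subject_effect_sd)


def subset_config(abbreviations: list[str], n_subjects: int = 10,
                  reps_per_class: int = 5, seed: int = 0,
                  subject_effect_sd: float = 0.1) -> SyntheticConfig:
    """Configuration restricted to the named archetypes (by abbreviation)."""
    by_name = {a.name: a for a in _default_archetypes()}
    missing = [a for a in abbreviations if a not in by_name]
    if missing:
        raise ValueError(f"unknown archetypes: {missing}")
    return SyntheticConfig(archetypes=tuple(by_name[a] for a in abbreviations),
                           n_subjects=n_subjects, reps_per_class=reps_per_class,
                           seed=seed, subject_effect_sd=subject_effect_sd)


def four_class_config(n_subjects: int = 40, reps_per_class: int = 2,
                      seed: int = 0) -> SyntheticConfig:
    """A compact 4-class study condition spanning all signal families:
    walking, jump rope, sitting down, and a forward fall."""
    return subset_config(["WK", "JR", "SC", "FF"], n_subjects=n_subjects,
                         reps_per_class=reps_per_class, seed=seed)
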