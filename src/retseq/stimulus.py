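"""Light stimuli and the canonical response-feature windows.

Three stimulus classes are used throughout: a full-field "chirp" (luminance
steps plus frequency and contrast sweeps, used for functional typing), a
bright moving bar presented in eight directions, and binary dense noise
(checkerboard) for receptive-field mapping.

Intensities are unitless in [0, 1]; 0.5 is the mean-gray background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ChirpConfig",
    "FullFieldStimulus",
    "MovingBarStimulus",
    "DenseNoiseStimulus",
    "FeatureWindows",
    "make_chirp",
    "make_dense_noise",
    "default_feature_windows",
]


class InvalidStimulusConfig(ValueError):
    """Raised when a stimulus configuration cannot produce a valid stimulus."""


@dataclass(frozen=True)
class ChirpConfig:
    """Parameterization of the full-field chirp.

    Default segment durations total 32 s: gray lead, On step, Off step, gray,
    an 8 s frequency sweep (0.5 -> 8 Hz at full contrast), gray, an 8 s
    contrast sweep (0 -> 100% at 2 Hz), and a trailing gray.
    """

    rate: float = 50.0          # frames/s
    lead_gray_s: float = 2.0
    on_step_s: float = 3.0
    off_step_s: float = 3.0
    gray1_s: float = 2.0
    freq_sweep_s: float = 8.0
    gray2_s: float = 3.0
    contrast_sweep_s: float = 8.0
    gray3_s: float = 3.0
    f_start_hz: float = 0.5
    f_end_hz: float = 8.0
    contrast_freq_hz: float = 2.0
    sweep_law: str = "linear"   # instantaneous-frequency law: "linear" only

    @property
    def duration_s(self) -> float:
        return (self.lead_gray_s + self.on_step_s + self.off_step_s
                + self.gray1_s + self.freq_sweep_s + self.gray2_s
                + self.contrast_sweep_s + self.gray3_s)


@dataclass(frozen=True)
class FullFieldStimulus:
    """A full-field luminance sequence with named, annotated segments."""

    intensity: np.ndarray                       # unitless, in [0, 1]
    rate: float                                 # frames/s
    segments: tuple[tuple[str, float, float], ...]  # (name, start_s, end_s)
    duration_s: float

    def __post_init__(self):
        n_expected = int(round(self.rate * self.duration_s))
        if len(self.intensity) != n_expected:
            raise InvalidStimulusConfig(
                f"intensity length {len(self.intensity)} != "
                f"round(rate*duration) = {n_expected}")
        if np.any(self.intensity < 0) or np.any(self.intensity > 1):
            raise InvalidStimulusConfig("intensities must lie in [0, 1]")
        # segments must tile [0, duration] without overlap
        t = 0.0
        for name, start, end in self.segments:
            if not np.isclose(start, t) or end < start:
                raise InvalidStimulusConfig(
                    f"segments do not tile stimulus time (at '{name}')")
            t = end
        if not np.isclose(t, self.duration_s):
            raise InvalidStimulusConfig("segments do not cover full duration")

    def segment(self, name: str) -> tuple[float, float]:
        for seg_name, start, end in self.segments:
            if seg_name == name:
                return (start, end)
        raise KeyError(f"no segment named '{name}'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.intensity)) / self.rate


@dataclass(frozen=True)
class MovingBarStimulus:
    """Bright bar (0.3 x 1 mm^2) moving at 1 mm/s in eight directions.

    The bar is represented by its per-direction response snippet window only;
    no pixel rendering is needed by any downstream computation.
    """

    bar_size_mm: tuple[float, float] = (0.3, 1.0)
    speed_mm_s: float = 1.0
    directions_deg: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 45))
    snippet_s: float = 4.0

    def __post_init__(self):
        if len(self.directions_deg) != 8:
            raise InvalidStimulusConfig("moving bar uses exactly 8 directions")
        diffs = np.diff(np.sort(np.mod(self.directions_deg, 360.0)))
        if not np.allclose(diffs, 45.0):
            raise InvalidStimulusConfig("directions must be equally spaced (45 deg)")


@dataclass(frozen=True)
class DenseNoiseStimulus:
    """Binary dense-noise movie S(x, y, t) on a checkerboard grid."""

    frames: np.ndarray      # (rows, cols, t), values in {0, 1}
    rows: int
    cols: int
    check_um: float
    rate: float             # Hz
    seed: int
    balanced: bool = True

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate


@dataclass(frozen=True)
class FeatureWindows:
    """The eight canonical response-feature windows.

    Six windows subdivide the chirp (On, Off, low/high frequency, low/high
    contrast) and two the moving-bar snippet (On = leading edge, Off =
    trailing edge). Window order is fixed and used for all feature-wise
    difference analyses.
    """

    chirp: tuple[tuple[str, float, float], ...]
    bar: tuple[tuple[str, float, float], ...]

    CHIRP_NAMES = ("on", "off", "low_freq", "high_freq",
                   "low_contrast", "high_contrast")
    BAR_NAMES = ("bar_on", "bar_off")

    def __post_init__(self):
        if len(self.chirp) != 6 or len(self.bar) != 2:
            raise InvalidStimulusConfig("expected 6 chirp + 2 bar windows")
        for wins in (self.chirp, self.bar):
            spans = sorted((s, e) for _, s, e in wins)
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if s1 < e0 - 1e-12:
                    raise InvalidStimulusConfig("feature windows overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _, _ in self.chirp) + tuple(n for n, _, _ in self.bar)

    def window(self, name: str) -> tuple[float, float]:
        for n, s, e in self.chirp + self.bar:
            if n == name:
                return (s, e)
        raise KeyError(f"no feature window named '{name}'")


def make_chirp(cfg: ChirpConfig | None = None) -> FullFieldStimulus:
    """Build the full-field chirp stimulus from a configuration.

    The frequency sweep uses a linear instantaneous-frequency ramp with
    continuous phase, phi(t) = 2*pi*(f0*t + (f1-f0)*t^2/(2*T)); the contrast
    sweep is a fixed-frequency sinusoid with linearly growing amplitude.
    Zero-length segments are omitted from the annotation; the remaining
    segments still tile the full duration.
    """
    cfg = cfg or ChirpConfig()
    if cfg.rate <= 0:
        raise InvalidStimulusConfig("rate must be positive")
    if cfg.duration_s <= 0:
        raise InvalidStimulusConfig("duration must be positive")
    for name in ("lead_gray_s", "on_step_s", "off_step_s", "gray1_s",
                 "freq_sweep_s", "gray2_s", "contrast_sweep_s", "gray3_s"):
        if getattr(cfg, name) < 0:
            raise InvalidStimulusConfig(f"{name} must be non-negative")

    n = int(round(cfg.rate * cfg.duration_s))
    t = np.arange(n) / cfg.rate
    intensity = np.full(n, 0.5)

    seg_durations = [
        ("lead_gray", cfg.lead_gray_s),
        ("on_step", cfg.on_step_s),
        ("off_step", cfg.off_step_s),
        ("gray1", cfg.gray1_s),
        ("freq_sweep", cfg.freq_sweep_s),
        ("gray2", cfg.gray2_s),
        ("contrast_sweep", cfg.contrast_sweep_s),
        ("gray3", cfg.gray3_s),
    ]
    segments = []
    start = 0.0
    for name, dur in seg_durations:
        if dur > 0:
            segments.append((name, start, start + dur))
        start += dur

    for name, seg_start, seg_end in segments:
        mask = (t >= seg_start - 1e-12) & (t < seg_end - 1e-12)
        tau = t[mask] - seg_start
        if name == "on_step":
            intensity[mask] = 1.0
        elif name == "off_step":
            intensity[mask] = 0.0
        elif name == "freq_sweep":
            T = seg_end - seg_start
            f0, f1 = cfg.f_start_hz, cfg.f_end_hz
            phase = 2 * np.pi * (f0 * tau + (f1 - f0) * tau ** 2 / (2 * T))
            intensity[mask] = 0.5 + 0.5 * np.sin(phase)
        elif name == "contrast_sweep":
            T = seg_end - seg_start
            amp = 0.5 * tau / T
            intensity[mask] = 0.5 + amp * np.sin(2 * np.pi * cfg.contrast_freq_hz * tau)

    return FullFieldStimulus(
        intensity=intensity, rate=cfg.rate,
        segments=tuple(segments), duration_s=cfg.duration_s)


def chirp_instantaneous_frequency(cfg: ChirpConfig, t_in_sweep: float) -> float:
    """Instantaneous frequency (Hz) at time ``t_in_sweep`` into the sweep."""
    T = cfg.freq_sweep_s
    return cfg.f_start_hz + (cfg.f_end_hz - cfg.f_start_hz) * t_in_sweep / T


def make_dense_noise(rows: int = 20, cols: int = 15, rate: float = 5.0,
                     duration_s: float = 300.0, seed: int = 0,
                     balanced: bool = True,
                     check_um: float = 40.0) -> DenseNoiseStimulus:
    """Generate a binary dense-noise (checkerboard) movie.

    With ``balanced=True`` every check shows an equal number of black and
    white frames (difference at most one), in shuffled order — a balanced
    random sequence. Otherwise frames are i.i.d. Bernoulli(0.5).
    """
    if rows <= 0 or cols <= 0 or rate <= 0 or duration_s <= 0:
        raise InvalidStimulusConfig("rows, cols, rate, duration must be positive")
    n_frames = int(round(rate * duration_s))
    if n_frames < 1:
        raise InvalidStimulusConfig("duration shorter than one frame")
    rng = np.random.default_rng(seed)
    if balanced:
        base = np.zeros(n_frames, dtype=np.uint8)
        base[: n_frames // 2 + (n_frames % 2)] = 1
        frames = np.empty((rows, cols, n_frames), dtype=np.uint8)
        for i in range(rows):
            for j in range(cols):
                frames[i, j] = rng.permutation(base)
    else:
        frames = (rng.random((rows, cols, n_frames)) < 0.5).astype(np.uint8)
    return DenseNoiseStimulus(frames=frames, rows=rows, cols=cols,
                              check_um=check_um, rate=rate, seed=seed,
                              balanced=balanced)


def default_feature_windows(chirp: FullFieldStimulus,
                            bar: MovingBarStimulus) -> FeatureWindows:
    """Derive the eight canonical feature windows from stimulus annotations.

    Chirp: On/Off from the step segments; low/high frequency and low/high
    contrast are the first/second halves of the respective sweeps. Bar: the
    leading-edge (On) half and trailing-edge (Off) half of the snippet.
    """
    required = ("on_step", "off_step", "freq_sweep", "contrast_sweep")
    names = {name for name, _, _ in chirp.segments}
    for req in required:
        if req not in names:
            raise InvalidStimulusConfig(
                f"chirp lacks required segment '{req}'")

    on = chirp.segment("on_step")
    off = chirp.segment("off_step")
    fs, fe = chirp.segment("freq_sweep")
    cs, ce = chirp.segment("contrast_sweep")
    f_mid = (fs + fe) / 2
    c_mid = (cs + ce) / 2
    chirp_windows = (
        ("on", on[0], on[1]),
        ("off", off[0], off[1]),
        ("low_freq", fs, f_mid),
        ("high_freq", f_mid, fe),
        ("low_contrast", cs, c_mid),
        ("high_contrast", c_mid, ce),
    )
    half = bar.snippet_s / 2
    bar_windows = (("bar_on", 0.0, half), ("bar_off", half, bar.snippet_s))
    return FeatureWindows(chirp=chirp_windows, bar=bar_windows)


def save_stimulus_h5(group, stim) -> None:
    """Serialize a stimulus into an open h5py group."""
    if isinstance(stim, FullFieldStimulus):
        group.create_dataset("intensity", data=stim.intensity)
        group.attrs["kind"] = "full_field"
        group.attrs["rate"] = stim.rate
        group.attrs["duration_s"] = stim.duration_s
        group.attrs["segments"] = json.dumps(list(stim.segments))
    elif isinstance(stim, DenseNoiseStimulus):
        group.create_dataset("frames", data=stim.frames)
        group.attrs["kind"] = "dense_noise"
        for key in ("rows", "cols", "check_um", "rate", "seed", "balanced"):
            group.attrs[key] = getattr(stim, key)
    elif isinstance(stim, MovingBarStimulus):
        group.attrs["kind"] = "moving_bar"
        group.attrs["config"] = json.dumps(asdict(stim))
    else:
        raise TypeError(f"cannot serialize {type(stim).__name__}")


def load_stimulus_h5(group):
    """Inverse of :func:`save_stimulus_h5`."""
    kind = group.attrs["kind"]
    if kind == "full_field":
        segments = tuple(tuple(s) for s in json.loads(group.attrs["segments"]))
        return FullFieldStimulus(
            intensity=group["intensity"][:], rate=float(group.attrs["rate"]),
            segments=segments, duration_s=float(group.attrs["duration_s"]))
    if kind == "dense_noise":
        return DenseNoiseStimulus(
            frames=group["frames"][:], rows=int(group.attrs["rows"]),
            cols=int(group.attrs["cols"]), check_um=float(group.attrs["check_um"]),
            rate=float(group.attrs["rate"]), seed=int(group.attrs["seed"]),
            balanced=bool(group.attrs["balanced"]))
    if kind == "moving_bar":
        cfg = json.loads(group.attrs["config"])
        cfg["bar_size_mm"] = tuple(cfg["bar_size_mm"])
        cfg["directions_deg"] = tuple(cfg["directions_deg"])
        return MovingBarStimulus(**cfg)
    raise ValueError(f"unknown stimulus kind '{kind}'")
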