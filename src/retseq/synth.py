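"""Synthetic paired recordings from ground-truth cell archetypes.

The generator emulates the sequential-recording paradigm: every simulated
cell is recorded twice (rec1, rec2) for each stimulus. Between the two
recordings, type-specific *adaptational* gain changes apply in both
protocols, and in the control/drug protocol an additional drug effect
applies — a fractional reduction ``rho`` of the contrast-suppression weight
and a kinetic speed-up ``kappa`` of the temporal kernel. Ground truth is
stored for every cell, so every pipeline stage (quality control, suppression
metrics, effect disentangling, receptive fields, clustering, the
spike-to-pseudo-calcium bridge) can be validated without external data.

Response model (linear-nonlinear cascade with subtractive suppression):

    v(t) = (k_tau * s)(t)                   band-passed stimulus drive
    a(t) = max(0, b + g * f(v) - w_sup * |v(t)|)
    c(t) = (a * h_Ca)(t) + noise            h_Ca(t) = exp(-t/tau_Ca)

where ``f`` is a polarity-rectifying nonlinearity f(v) = max(0, p*v) and the
biphasic kernel k_tau acts as the band-pass whose rectified output |v| is a
running estimate of temporal contrast energy. A cell with w_sup > 0 and
tonic baseline b > 0 is therefore suppressed-by-contrast (SbC): its
activity drops below baseline whenever the stimulus modulates.

All randomness flows from one master seed through named child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ResponseMatrix
from .stimulus import (
    ChirpConfig,
    DenseNoiseStimulus,
    FeatureWindows,
    FullFieldStimulus,
    MovingBarStimulus,
    default_feature_windows,
    make_chirp,
    make_dense_noise,
)

__all__ = [
    "CellArchetype",
    "EffectSpec",
    "SimulatedCell",
    "SimulatedExperiment",
    "make_archetype_bank",
    "make_effect_spec",
    "simulate_response",
    "simulate_spikes",
    "simulate_paired_experiment",
    "PRESETS",
    "PROTOCOLS",
]

PRESETS = ("g32-default", "mixed-population", "ln-basic")
PROTOCOLS = ("ctrl-ctrl", "ctrl-drug")

_FS_SIM = 50.0  # internal simulation rate, Hz


@dataclass(frozen=True)
class CellArchetype:
    """Ground-truth parameters of one simulated cell type.

    Spatial filter: difference of Gaussians on the dense-noise grid (checks);
    the surround shares the center's shape with covariance scaled by
    ``surround_sigma_factor`` and amplitude scaled by ``surround_scale``.
    Temporal kernel: biphasic with time constant ``tau_k`` (s). Suppression
    weight ``w_sup`` >= 0 subtracts rectified band-passed drive (temporal
    contrast energy) from the activity. ``tau_ca`` is the calcium-indicator
    decay constant; ``noise_sd`` the per-repetition additive noise.
    """

    type_label: str
    polarity: int = 1                       # p in {-1, +1}
    # spatial DoG (dense-noise check units)
    center_xy: tuple[float, float] = (9.5, 7.0)
    sigma_x: float = 1.6
    sigma_y: float = 1.6
    angle_deg: float = 0.0
    surround_scale: float = 0.2
    surround_sigma_factor: float = 2.0
    # temporal kernel
    tau_k: float = 0.2                      # s
    biphasic_weight: float = 0.5
    # nonlinearity
    baseline: float = 0.0                   # b >= 0, tonic activity
    gain: float = 1.0                       # g
    rectify: bool = True
    # suppression
    w_sup: float = 0.0
    # direction tuning (von Mises concentration; 0 = not direction selective)
    ds_kappa: float = 0.0
    preferred_direction_deg: float = 0.0
    # calcium & noise
    tau_ca: float = 0.8                     # s
    noise_sd: float = 0.2
    spike_scale: float = 10.0               # Hz per activity unit

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("spatial sigmas must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.tau_k <= 0 or self.tau_ca <= 0:
            raise ValueError("time constants must be positive")
        if self.w_sup < 0:
            raise ValueError("suppression weight must be non-negative")

    def with_drug(self, rho: float, kappa: float) -> "CellArchetype":
        """Apply a drug effect: reduce w_sup by fraction rho, speed 1/tau_k by kappa."""
        if not 0 <= rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if kappa < 1:
            raise ValueError("kappa must be >= 1")
        return replace(self, w_sup=self.w_sup * (1.0 - rho),
                       tau_k=self.tau_k / kappa)

    def spatial_filter(self, rows: int, cols: int) -> np.ndarray:
        """Evaluate the DoG spatial filter on a (rows, cols) check grid."""
        yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        x0, y0 = self.center_xy
        th = np.deg2rad(self.angle_deg)
        dx, dy = xx - x0, yy - y0
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        center = np.exp(-0.5 * ((u / self.sigma_x) ** 2 + (v / self.sigma_y) ** 2))
        k = self.surround_sigma_factor
        surround = np.exp(-0.5 * ((u / (k * self.sigma_x)) ** 2
                                  + (v / (k * self.sigma_y)) ** 2))
        return self.polarity * (center - self.surround_scale * surround)

    def temporal_kernel(self, fs: float = _FS_SIM) -> np.ndarray:
        """Biphasic temporal kernel sampled at ``fs``; unit absolute area."""
        t = np.arange(0, 6 * self.tau_k, 1.0 / fs)
        k1 = (t / self.tau_k) * np.exp(1 - t / self.tau_k)
        t2 = 2 * self.tau_k
        k2 = (t / t2) * np.exp(1 - t / t2)
        k = k1 - self.biphasic_weight * k2
        return k / (np.sum(np.abs(k)) / fs)


@dataclass(frozen=True)
class EffectSpec:
    """Per-type adaptational and drug effects between rec1 and rec2.

    ``adaptation`` maps type_label -> {feature window name -> multiplicative
    gain applied to the activity inside that window in recording 2} (missing
    windows/types mean gain 1, i.e. identity). ``drug`` maps type_label ->
    (rho, kappa): rho in [0, 1] is the fractional reduction of w_sup, kappa
    >= 1 the kinetic speed-up factor applied to 1/tau_k; the identity effect
    is rho = 0, kappa = 1.
    """

    adaptation: dict = field(default_factory=dict)
    drug: dict = field(default_factory=dict)

    def __post_init__(self):
        for label, (rho, kappa) in self.drug.items():
            if not 0 <= rho <= 1:
                raise ValueError(f"rho for '{label}' must lie in [0, 1]")
            if kappa < 1:
                raise ValueError(f"kappa for '{label}' must be >= 1")

    def adaptation_gains(self, type_label: str) -> dict:
        return self.adaptation.get(type_label, {})

    def drug_params(self, type_label: str) -> tuple[float, float]:
        return self.drug.get(type_label, (0.0, 1.0))

    def category(self, type_label: str) -> str:
        """Ground-truth category: drug-affected / adaptational / stable."""
        rho, kappa = self.drug_params(type_label)
        if rho > 0 or kappa > 1:
            return "drug-affected"
        gains = self.adaptation_gains(type_label)
        if any(not np.isclose(g, 1.0) for g in gains.values()):
            return "adaptational"
        return "stable"


@dataclass
class SimulatedCell:
    """One simulated cell's paired recordings plus ground truth."""

    cell_id: str
    type_label: str
    chirp: tuple[ResponseMatrix, ResponseMatrix] | None = None
    bar: tuple[dict, dict] | None = None        # direction -> ResponseMatrix
    noise: tuple[ResponseMatrix, ResponseMatrix] | None = None
    spikes: tuple[np.ndarray, np.ndarray] | None = None
    archetype: CellArchetype | None = None      # rec1 (jittered) archetype
    confidence: float = 1.0                     # classifier-confidence stand-in
    field_id: int = 0                           # simulated recording field


@dataclass
class SimulatedExperiment:
    """Paired control/control or control/drug recordings for a population."""

    preset: str
    protocol: str
    seed: int
    cells: list
    effect_spec: EffectSpec
    chirp_stim: FullFieldStimulus
    bar_stim: MovingBarStimulus
    windows: FeatureWindows
    noise_stim: DenseNoiseStimulus | None = None

    @property
    def cell_ids(self) -> list:
        return [c.cell_id for c in self.cells]

    def ground_truth_category(self, type_label: str) -> str:
        return self.effect_spec.category(type_label)


# ---------------------------------------------------------------------------
# archetype banks

def _sbc(label, *, baseline, gain, w_sup, tau_k, noise_sd=0.18, **kw):
    """An Off-polarity suppressed-by-contrast archetype."""
    return CellArchetype(type_label=label, polarity=-1, baseline=baseline,
                         gain=gain, w_sup=w_sup, tau_k=tau_k,
                         noise_sd=noise_sd, **kw)


def make_archetype_bank(preset: str) -> list:
    """Deterministic bank of cell archetypes for a named preset.

    Presets: ``"g32-default"`` — three suppressed-by-contrast archetypes with
    tonic baselines, differing in suppression weight and temporal kinetics
    (emulating functionally distinct SbC sub-types); ``"mixed-population"`` —
    stable, adaptational, and drug-affected type groups (see
    :func:`make_effect_spec`); ``"ln-basic"`` — plain On/Off
    linear-nonlinear cells without suppression.
    """
    if preset == "g32-default":
        return [
            _sbc("sbc1", baseline=1.0, gain=2.2, w_sup=2.4, tau_k=0.08,
                 sigma_x=1.4, sigma_y=1.4, surround_scale=0.30,
                 noise_sd=0.15),
            _sbc("sbc2", baseline=1.1, gain=1.5, w_sup=0.6, tau_k=0.25,
                 biphasic_weight=0.3, sigma_x=1.8, sigma_y=1.5,
                 surround_scale=0.20, noise_sd=0.12),
            _sbc("sbc3", baseline=1.3, gain=0.05, w_sup=3.2, tau_k=0.50,
                 sigma_x=2.2, sigma_y=2.2, surround_scale=0.15),
        ]
    if preset == "mixed-population":
        return [
            CellArchetype(type_label="stable_on", polarity=+1,
                          baseline=0.2, gain=1.5, tau_k=0.15),
            CellArchetype(type_label="stable_off", polarity=-1,
                          baseline=0.2, gain=1.5, tau_k=0.20),
            CellArchetype(type_label="adapt_slow_on", polarity=+1,
                          baseline=0.3, gain=1.8, tau_k=0.35,
                          biphasic_weight=0.2, noise_sd=0.15),
            CellArchetype(type_label="adapt_on_step", polarity=+1,
                          baseline=0.2, gain=1.4, tau_k=0.12),
            _sbc("drug_sbc_strong", baseline=1.0, gain=0.5, w_sup=2.2,
                 tau_k=0.12),
            _sbc("drug_sbc_weak", baseline=0.9, gain=0.8, w_sup=1.5,
                 tau_k=0.25),
        ]
    if preset == "ln-basic":
        # high-SNR LN cells used mainly for receptive-field validation
        return [
            CellArchetype(type_label="on", polarity=+1, baseline=0.2,
                          gain=8.0, w_sup=0.0, tau_k=0.15,
                          center_xy=(7.0, 10.0), sigma_x=1.5, sigma_y=1.5,
                          noise_sd=0.05),
            CellArchetype(type_label="off", polarity=-1, baseline=0.2,
                          gain=8.0, w_sup=0.0, tau_k=0.20,
                          center_xy=(10.0, 6.0), sigma_x=1.8, sigma_y=1.4,
                          noise_sd=0.05),
        ]
    raise ValueError(f"unknown preset '{preset}'; available: {PRESETS}")


def make_effect_spec(preset: str) -> EffectSpec:
    """The adaptational/drug effects paired with each archetype bank."""
    if preset == "g32-default":
        # SbC sub-types show little adaptation; the drug removes most of
        # their contrast suppression and speeds their kinetics, more in
        # sub-type 1 than 3.
        return EffectSpec(
            adaptation={},
            drug={"sbc1": (0.8, 1.5), "sbc2": (0.9, 1.3), "sbc3": (0.5, 1.2)},
        )
    if preset == "mixed-population":
        return EffectSpec(
            adaptation={
                "adapt_slow_on": {"low_freq": 0.5, "low_contrast": 0.5,
                                  "high_contrast": 0.6},
                "adapt_on_step": {"on": 1.5, "bar_on": 1.4},
            },
            drug={"drug_sbc_strong": (0.7, 1.5), "drug_sbc_weak": (0.4, 1.2)},
        )
    if preset == "ln-basic":
        return EffectSpec()
    raise ValueError(f"unknown preset '{preset}'; available: {PRESETS}")


# ---------------------------------------------------------------------------
# response simulation

def _full_field_drive(arch: CellArchetype, stim: FullFieldStimulus,
                      fs: float) -> np.ndarray:
    """Stimulus contrast series resampled to ``fs`` (zero-order hold)."""
    s = 2.0 * (stim.intensity - 0.5)
    n = int(round(stim.duration_s * fs))
    idx = np.minimum((np.arange(n) / fs * stim.rate).astype(int), len(s) - 1)
    return s[idx]


def _noise_drive(arch: CellArchetype, stim: DenseNoiseStimulus,
                 fs: float) -> np.ndarray:
    w = arch.spatial_filter(stim.rows, stim.cols) * arch.polarity
    # polarity is reapplied by the nonlinearity; keep drive polarity-neutral
    w = w / np.sum(np.abs(w))
    contrast = 2.0 * stim.frames.astype(float) - 1.0
    drive_frames = np.tensordot(w, contrast, axes=([0, 1], [0, 1]))
    n = int(round(stim.duration_s * fs))
    idx = np.minimum((np.arange(n) / fs * stim.rate).astype(int),
                     len(drive_frames) - 1)
    return drive_frames[idx]


def _bar_drive(arch: CellArchetype, stim: MovingBarStimulus,
               direction_deg: float, fs: float) -> np.ndarray:
    """Leading-edge / trailing-edge contrast profile for one bar direction.

    A bright bar crossing the receptive field produces a positive-contrast
    leading edge in the first snippet half and a negative-contrast trailing
    edge in the second; direction selectivity scales the profile with a
    von-Mises tuning factor.
    """
    n = int(round(stim.snippet_s * fs))
    t = np.arange(n) / fs
    drive = np.zeros(n)
    half = stim.snippet_s / 2
    lead = (t >= 0.25 * half) & (t < 0.65 * half)
    trail = (t >= half + 0.25 * half) & (t < half + 0.65 * half)
    drive[lead] = 1.0
    drive[trail] = -1.0
    dtheta = np.deg2rad(direction_deg - arch.preferred_direction_deg)
    tuning = np.exp(arch.ds_kappa * (np.cos(dtheta) - 1.0))
    return drive * tuning


def activity_trace(arch: CellArchetype, drive: np.ndarray,
                   fs: float = _FS_SIM,
                   gain_windows: dict | None = None,
                   windows: FeatureWindows | None = None) -> np.ndarray:
    """Noiseless activity a(t) of an archetype given a stimulus drive."""
    k = arch.temporal_kernel(fs)
    v = np.convolve(drive, k)[: len(drive)] / fs
    if arch.rectify:
        f = np.maximum(0.0, arch.polarity * v)
    else:
        f = arch.polarity * v
    a = np.maximum(0.0, arch.baseline + arch.gain * f
                   - arch.w_sup * np.abs(v))
    if gain_windows:
        if windows is None:
            raise ValueError("gain_windows given without FeatureWindows")
        t = np.arange(len(a)) / fs
        for name, gain in gain_windows.items():
            start, end = windows.window(name)
            mask = (t >= start) & (t < end)
            a[mask] = arch.baseline + gain * (a[mask] - arch.baseline)
            a[mask] = np.maximum(0.0, a[mask])
    return a


def _calcium(a: np.ndarray, tau_ca: float, fs: float) -> np.ndarray:
    t = np.arange(0, 5 * tau_ca, 1.0 / fs)
    h = np.exp(-t / tau_ca)
    h /= np.sum(h) / fs
    # steady-state initial condition: pad with the pre-stimulus activity so
    # the kernel's onset transient does not contaminate the baseline window
    pad = np.full(len(h), a[0])
    c = np.convolve(np.concatenate([pad, a]), h)[: len(pad) + len(a)] / fs
    return c[len(pad):]


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    n_out = int(round(len(x) / fs_in * fs_out))
    t_out = np.arange(n_out) / fs_out
    t_in = np.arange(len(x)) / fs_in
    return np.interp(t_out, t_in, x)


def simulate_response(arch: CellArchetype, stimulus, n_reps: int = 5,
                      fs_out: float = 7.8125, seed: int = 0,
                      gain_windows: dict | None = None,
                      windows: FeatureWindows | None = None,
                      direction_deg: float | None = None) -> ResponseMatrix:
    """Simulate a repetition-stacked calcium response to one stimulus.

    The noiseless trace is the archetype's activity convolved with the
    calcium kernel, resampled to ``fs_out``; each repetition adds i.i.d.
    Gaussian noise of sd ``noise_sd``. Same seed, same output.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    fs = _FS_SIM
    if isinstance(stimulus, FullFieldStimulus):
        drive = _full_field_drive(arch, stimulus, fs)
    elif isinstance(stimulus, DenseNoiseStimulus):
        drive = _noise_drive(arch, stimulus, fs)
    elif isinstance(stimulus, MovingBarStimulus):
        if direction_deg is None:
            raise ValueError("moving bar needs direction_deg")
        drive = _bar_drive(arch, stimulus, direction_deg, fs)
    else:
        raise TypeError(f"unsupported stimulus {type(stimulus).__name__}")
    a = activity_trace(arch, drive, fs, gain_windows=gain_windows,
                       windows=windows)
    c = _calcium(a, arch.tau_ca, fs)
    c_out = _resample(c, fs, fs_out)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, arch.noise_sd, size=(len(c_out), n_reps))
    values = c_out[:, None] + noise
    return ResponseMatrix(values=values, fs=fs_out)


def simulate_spikes(arch: CellArchetype, stimulus, duration_s: float,
                    seed: int = 0, dead_time_s: float = 0.002) -> np.ndarray:
    """Inhomogeneous Poisson spike times with an absolute dead time.

    The rate is ``spike_scale * a(t)`` (Hz), with the stimulus tiled to cover
    ``duration_s``. Spikes are drawn by thinning a homogeneous Poisson
    process at the peak rate; a 2 ms dead time is enforced sequentially.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = _FS_SIM
    if isinstance(stimulus, FullFieldStimulus):
        drive = _full_field_drive(arch, stimulus, fs)
    elif isinstance(stimulus, DenseNoiseStimulus):
        drive = _noise_drive(arch, stimulus, fs)
    else:
        raise TypeError(f"unsupported stimulus {type(stimulus).__name__}")
    a = activity_trace(arch, drive, fs)
    rate = arch.spike_scale * a
    n = int(np.ceil(duration_s * fs))
    reps = int(np.ceil(n / len(rate)))
    rate = np.tile(rate, reps)[:n]
    rate_max = float(np.max(rate))
    if rate_max <= 0:
        return np.array([])
    rng = np.random.default_rng(seed)
    n_cand = rng.poisson(rate_max * duration_s)
    cand = np.sort(rng.uniform(0, duration_s, size=n_cand))
    keep = rng.random(n_cand) < rate[np.minimum((cand * fs).astype(int), n - 1)] / rate_max
    cand = cand[keep]
    spikes = []
    last = -np.inf
    for t in cand:
        if t - last >= dead_time_s:
            spikes.append(t)
            last = t
    return np.asarray(spikes)


# ---------------------------------------------------------------------------
# paired experiments

def _jitter(arch: CellArchetype, rng: np.random.Generator,
            rel_sd: float = 0.05) -> CellArchetype:
    """Per-cell multiplicative parameter jitter (within-type variability)."""
    def j():
        return float(np.exp(rng.normal(0.0, rel_sd)))
    return replace(arch, baseline=arch.baseline * j(), gain=arch.gain * j(),
                   w_sup=arch.w_sup * j(), tau_k=arch.tau_k * j())


def simulate_paired_experiment(preset: str, protocol: str, seed: int = 0,
                               n_cells_per_type: int = 30, n_reps: int = 5,
                               include_noise: bool = False,
                               include_spikes: bool = False,
                               noise_duration_s: float = 300.0,
                               jitter_sd: float = 0.05,
                               n_fields: int = 3) -> SimulatedExperiment:
    """Simulate a full paired (sequential) recording of a cell population.

    rec1 uses the base (per-cell jittered) archetypes; rec2 applies the
    preset's adaptational window gains (both protocols) and, for
    ``"ctrl-drug"`` only, additionally the drug effect (rho, kappa).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol '{protocol}'; use one of {PROTOCOLS}")
    bank = make_archetype_bank(preset)
    effects = make_effect_spec(preset)

    chirp = make_chirp(ChirpConfig())
    bar = MovingBarStimulus()
    windows = default_feature_windows(chirp, bar)
    ss = np.random.SeedSequence(seed)
    stim_seed, cells_seed = [int(s.generate_state(1)[0] % (2 ** 31))
                             for s in ss.spawn(2)]
    noise_stim = None
    if include_noise:
        noise_stim = make_dense_noise(duration_s=noise_duration_s,
                                      seed=stim_seed)

    cells = []
    cell_rng = np.random.default_rng(cells_seed)
    for arch in bank:
        gains = effects.adaptation_gains(arch.type_label)
        rho, kappa = effects.drug_params(arch.type_label)
        for i in range(n_cells_per_type):
            cid = f"{arch.type_label}_{i:03d}"
            a1 = _jitter(arch, cell_rng, jitter_sd) if jitter_sd > 0 else arch
            a2 = a1.with_drug(rho, kappa) if protocol == "ctrl-drug" else a1
            seeds = cell_rng.integers(0, 2 ** 31, size=6)
            chirp1 = simulate_response(a1, chirp, n_reps, seed=int(seeds[0]))
            chirp2 = simulate_response(a2, chirp, n_reps, seed=int(seeds[1]),
                                       gain_windows=gains, windows=windows)
            bar1, bar2 = {}, {}
            for k_dir, d in enumerate(bar.directions_deg):
                bar1[d] = simulate_response(
                    a1, bar, n_reps, seed=int(seeds[2]) + k_dir,
                    direction_deg=d)
                bar2[d] = simulate_response(
                    a2, bar, n_reps, seed=int(seeds[3]) + k_dir,
                    gain_windows=gains, windows=windows, direction_deg=d)
            cell = SimulatedCell(cell_id=cid, type_label=arch.type_label,
                                 chirp=(chirp1, chirp2), bar=(bar1, bar2),
                                 archetype=a1, field_id=i % n_fields)
            if include_noise:
                cell.noise = (
                    simulate_response(a1, noise_stim, 1, seed=int(seeds[4])),
                    simulate_response(a2, noise_stim, 1, seed=int(seeds[5])),
                )
            if include_spikes:
                dur = chirp.duration_s * n_reps
                cell.spikes = (
                    simulate_spikes(a1, chirp, dur, seed=int(seeds[4]) + 1),
                    simulate_spikes(a2, chirp, dur, seed=int(seeds[5]) + 1),
                )
            cells.append(cell)

    return SimulatedExperiment(preset=preset, protocol=protocol, seed=seed,
                               cells=cells, effect_spec=effects,
                               chirp_stim=chirp, bar_stim=bar,
                               windows=windows, noise_stim=noise_stim)
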