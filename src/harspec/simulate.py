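"""Seeded synthetic 6-axis IMU streams for three activities.

Generates labelled accelerometer + gyroscope time series whose spectral
signatures separate standing (ST), sitting (SI) and walking (WA):

* walking — periodic gait components (a fundamental near 1.5 Hz plus its
  second harmonic, with phase jitter) on both sensors, plus noise;
* standing — quasi-static accelerometer, with the dominant energy on the
  gyroscope channels as sparse Poisson-timed "turn" bursts (arm turns);
* sitting — near-static, noise only.

A constant gravity offset rides on the accelerometer z axis so that the
"least spectral density" end of downstream feature vectors sees a realistic
DC component.  All randomness flows through ``numpy.random.default_rng``
seeded per call: identical arguments reproduce streams bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ActivitySpec",
    "ImuStream",
    "DEFAULT_SPECS",
    "default_specs",
    "simulate_activity",
    "make_dataset",
]

#: Canonical activity codes, in the row/column order used throughout.
CLASSES = ("ST", "SI", "WA")

GRAVITY_MPS2 = 9.81


@dataclass(frozen=True)
class ActivitySpec:
    """Generative parameters for one activity class.

    Parameters
    ----------
    label
        Activity code, one of ``ST``, ``SI``, ``WA``.
    fundamental_hz
        Dominant periodic frequency in Hz; 0 for quasi-static classes.
    accel_amplitude
        Peak amplitude of the periodic accelerometer component, m/s².
    gyro_amplitude
        Peak amplitude of the periodic gyroscope component (walking) or of
        the turn bursts (standing), deg/s.
    noise_sd
        Standard deviation of the additive Gaussian sensor noise (applied
        to the accelerometer; the gyroscope receives ``gyro_noise_scale``
        times this value).
    turn_rate
        Expected gyroscope burst events per minute; only meaningful for
        standing.
    gravity_mps2
        Constant offset added to the accelerometer z channel.
    """

    label: str
    fundamental_hz: float = 0.0
    accel_amplitude: float = 0.0
    gyro_amplitude: float = 0.0
    noise_sd: float = 0.0
    turn_rate: float = 0.0
    gyro_noise_scale: float = 1.0
    gravity_mps2: float = GRAVITY_MPS2

    def __post_init__(self) -> None:
        if self.fundamental_hz < 0:
            raise ValueError("fundamental_hz must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.accel_amplitude < 0 or self.gyro_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class ImuStream:
    """A labelled 6-axis IMU recording.

    ``data`` has shape ``(n, 6)`` with columns ``ax, ay, az`` (m/s²) and
    ``gx, gy, gz`` (deg/s); ``fs`` is the sampling frequency in Hz.
    """

    data: np.ndarray
    fs: float
    label: str
    seed: int | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 6 or data.shape[0] < 1:
            raise ValueError("ImuStream data must have shape (n >= 1, 6)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def accel(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.data[:, 3:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def default_specs() -> dict[str, ActivitySpec]:
    """Default generative parameters for the three activities."""
    return {
        "ST": ActivitySpec(
            label="ST",
            fundamental_hz=0.0,
            accel_amplitude=0.05,
            gyro_amplitude=45.0,
            noise_sd=0.15,
            turn_rate=8.0,
            gyro_noise_scale=4.0,
        ),
        "SI": ActivitySpec(
            label="SI",
            fundamental_hz=0.0,
            accel_amplitude=0.0,
            gyro_amplitude=0.0,
            noise_sd=0.05,
            gyro_noise_scale=2.0,
        ),
        "WA": ActivitySpec(
            label="WA",
            fundamental_hz=1.5,
            accel_amplitude=3.0,
            gyro_amplitude=60.0,
            noise_sd=0.3,
            gyro_noise_scale=4.0,
        ),
    }


#: Module-level copy of the defaults (treat as read-only).
DEFAULT_SPECS = default_specs()


def _turn_bursts(rng: np.random.Generator, n: int, fs: float, rate_per_min: float,
                 amplitude: float) -> np.ndarray:
    """Sparse smooth gyroscope bursts with Poisson-timed onsets."""
    out = np.zeros(n)
    if rate_per_min <= 0 or amplitude <= 0:
        return out
    expected = rate_per_min * n / fs / 60.0
    n_events = rng.poisson(expected)
    if n_events == 0:
        return out
    width = max(int(0.4 * fs), 3)  # ~0.4 s half-width turn
    t = np.arange(-2 * width, 2 * width + 1)
    pulse = np.exp(-0.5 * (t / width) ** 2)
    centers = rng.integers(0, n, size=n_events)
    signs = rng.choice([-1.0, 1.0], size=n_events)
    for c, s in zip(centers, signs):
        lo = max(0, c - 2 * width)
        hi = min(n, c + 2 * width + 1)
        out[lo:hi] += s * amplitude * pulse[lo - (c - 2 * width): hi - (c - 2 * width)]
    return out


def simulate_activity(spec: ActivitySpec, duration_s: float, fs: float,
                      seed: int) -> ImuStream:
    """Generate one labelled 6-axis stream for ``spec``.

    Walking streams carry sinusoids at the fundamental and its second
    harmonic (with seeded phase jitter) on every axis of both sensors;
    standing streams put their dominant energy on the gyroscope via sparse
    turn bursts; sitting streams are noise-dominated.  Deterministic given
    ``(spec, duration_s, fs, seed)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    n = int(np.floor(duration_s * fs))
    if n < 1:
        raise ValueError("duration_s * fs must be >= 1")

    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    data = np.zeros((n, 6))

    if spec.fundamental_hz > 0:
        # Gait model: fundamental + half-amplitude second harmonic, with a
        # slowly drifting phase so windows are not phase-locked.
        for col in range(6):
            amp = spec.accel_amplitude if col < 3 else spec.gyro_amplitude
            if amp == 0:
                continue
            phase0 = rng.uniform(0, 2 * np.pi)
            jitter = np.cumsum(rng.normal(0, 0.02, size=n))
            axis_scale = rng.uniform(0.7, 1.0)
            data[:, col] += amp * axis_scale * np.sin(
                2 * np.pi * spec.fundamental_hz * t + phase0 + jitter)
            data[:, col] += 0.5 * amp * axis_scale * np.sin(
                2 * np.pi * 2 * spec.fundamental_hz * t + 2 * phase0 + jitter)
    elif spec.turn_rate > 0:
        for col in range(3, 6):
            data[:, col] += _turn_bursts(rng, n, fs, spec.turn_rate,
                                         spec.gyro_amplitude)
    # Quasi-static accelerometer wobble for ST (sub-Hz sway).
    if spec.fundamental_hz == 0 and spec.accel_amplitude > 0:
        for col in range(3):
            phase0 = rng.uniform(0, 2 * np.pi)
            data[:, col] += spec.accel_amplitude * np.sin(2 * np.pi * 0.3 * t + phase0)

    if spec.noise_sd > 0:
        data[:, :3] += rng.normal(0, spec.noise_sd, size=(n, 3))
        data[:, 3:] += rng.normal(0, spec.noise_sd * spec.gyro_noise_scale,
                                  size=(n, 3))
    data[:, 2] += spec.gravity_mps2
    return ImuStream(data=data, fs=fs, label=spec.label, seed=seed)


def make_dataset(specs: list[ActivitySpec], streams_per_class: int, fs: float,
                 seed: int, duration_s: float = 10.0) -> list[ImuStream]:
    """Balanced labelled collection: ``streams_per_class`` streams per spec.

    Per-stream seeds are spawned deterministically from ``seed`` via
    ``numpy.random.SeedSequence`` so the whole dataset is reproducible and
    streams are mutually independent.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if streams_per_class < 1:
        raise ValueError("streams_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs) * streams_per_class)
    streams: list[ImuStream] = []
    k = 0
    for spec in specs:
        for _ in range(streams_per_class):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            streams.append(simulate_activity(spec, duration_s, fs, child_seed))
            k += 1
    return streams
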