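"""Synthetic three-class EEG generator.

Emulates the statistical contrast the reconstruction method exploits, not
the physiology: a reference class a small autoencoder can learn well
(interictal: low-amplitude background with sparse sharp biphasic spikes)
and two classes that reconstruct poorly through an interictal-trained model
(healthy: moderate 8-12 Hz alpha-band rhythm over a pink background;
ictal: large rhythmic ~4 Hz oscillation with slow amplitude jitter).

Per-record random substreams are derived from the master seed by a
(class, index) counter, so any single record is reproducible independently
of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import BONN_FS, CLASSES, DEFAULT_LENGTH, EegDataset, EegRecord, minmax_normalize


@dataclass(frozen=True)
class ClassParams:
    """Spectral/morphological parameters for one synthetic class.

    Amplitudes are in arbitrary pre-normalization units; frequencies in Hz.
    """

    background_amp: float = 0.3
    band: tuple[float, float] = (0.5, 40.0)  # pink-background shaping band
    rhythm_band: tuple[float, float] | None = None  # dominant rhythm drawn per record
    rhythm_amp: float = 0.0
    rhythm_jitter: float = 0.0  # relative sd of slow amplitude modulation
    spike_rate: float = 0.0  # Poisson events per second
    spike_amp: float = 0.0
    spike_width_s: float = 0.06  # biphasic template duration
    noise_sd: float = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults mirror the Bonn A/D/E contrast."""

    n_per_class: int = 100
    length: int = DEFAULT_LENGTH
    fs: float = BONN_FS
    seed: int = 0
    class_params: dict[str, ClassParams] = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.length < 64:
            raise ValueError("length must be >= 64")
        for label, p in self.class_params.items():
            if label not in CLASSES:
                raise ValueError(f"unknown class {label!r}")
            lo, hi = p.band
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"{label}: band {p.band} outside (0, fs/2)")
            if p.rhythm_band is not None:
                lo, hi = p.rhythm_band
                if not (0 < lo <= hi < self.fs / 2):
                    raise ValueError(f"{label}: rhythm band {p.rhythm_band} outside (0, fs/2)")
            for name in ("background_amp", "rhythm_amp", "spike_amp", "noise_sd"):
                if getattr(p, name) < 0:
                    raise ValueError(f"{label}: {name} must be >= 0")


DEFAULT_PARAMS: dict[str, ClassParams] = {
    "healthy": ClassParams(
        background_amp=0.25,
        rhythm_band=(8.0, 12.0),
        rhythm_amp=0.5,
        rhythm_jitter=0.15,
        noise_sd=0.1,
    ),
    "interictal": ClassParams(
        background_amp=0.3,
        spike_rate=0.8,
        spike_amp=2.0,
        noise_sd=0.1,
    ),
    "ictal": ClassParams(
        background_amp=0.3,
        rhythm_band=(3.0, 5.0),
        rhythm_amp=3.0,
        rhythm_jitter=0.2,
        noise_sd=0.1,
    ),
}

#: Harder variant with the class contrast compressed: weaker seizure
#: rhythm, smaller spikes, more noise.  Used to compare feature extractors
#: away from the ceiling where every classifier saturates.
REDUCED_CONTRAST_PARAMS: dict[str, ClassParams] = {
    "healthy": replace(DEFAULT_PARAMS["healthy"], rhythm_amp=0.3, noise_sd=0.2),
    "interictal": replace(DEFAULT_PARAMS["interictal"], spike_amp=0.9, noise_sd=0.2),
    "ictal": replace(DEFAULT_PARAMS["ictal"], rhythm_amp=0.9, noise_sd=0.2),
}


def reduced_contrast_config(**kwargs) -> SyntheticConfig:
    """A :class:`SyntheticConfig` with the compressed class contrast."""
    kwargs.setdefault("class_params", dict(REDUCED_CONTRAST_PARAMS))
    return SyntheticConfig(**kwargs)


def _pink_background(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance 1/f-weighted noise restricted to ``band``."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    weight = np.zeros_like(freqs)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    weight[inside] = 1.0 / np.sqrt(freqs[inside])
    x = np.fft.irfft(spectrum * weight, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _biphasic_spike(width_samples: int) -> np.ndarray:
    """Sharp positive deflection followed by a slower negative rebound."""
    t = np.linspace(-1.0, 1.0, width_samples)
    return np.exp(-((t + 0.3) ** 2) / 0.02) - 0.6 * np.exp(-((t - 0.3) ** 2) / 0.08)


def _record_rng(seed: int, label: str, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(CLASSES.index(label), index))
    return np.random.default_rng(ss)


def generate_record(
    label: str, cfg: SyntheticConfig, index: int = 0, rng: np.random.Generator | None = None
) -> EegRecord:
    """Generate one synthetic record of class ``label``.

    The raw signal is the sum of a pink background, an optional per-record
    rhythm (frequency drawn uniformly from the class rhythm band, amplitude
    slowly modulated), optional Poisson-timed biphasic spikes, and white
    Gaussian noise; it is then min-max normalized to [0, 1].
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    p = cfg.class_params.get(label)
    if p is None:
        raise ValueError(f"no parameters configured for class {label!r}")
    if rng is None:
        rng = _record_rng(cfg.seed, label, index)
    n, fs = cfg.length, cfg.fs
    t = np.arange(n) / fs

    x = p.background_amp * _pink_background(rng, n, fs, p.band)

    if p.rhythm_band is not None and p.rhythm_amp > 0:
        f0 = rng.uniform(*p.rhythm_band)
        phase = rng.uniform(0, 2 * np.pi)
        envelope = np.ones(n)
        if p.rhythm_jitter > 0:
            # slow (~0.5 Hz) multiplicative amplitude modulation
            slow = _pink_background(rng, n, fs, (0.1, 1.0))
            envelope = np.clip(1.0 + p.rhythm_jitter * slow, 0.2, None)
        x = x + p.rhythm_amp * envelope * np.sin(2 * np.pi * f0 * t + phase)

    if p.spike_rate > 0 and p.spike_amp > 0:
        width = max(3, int(round(p.spike_width_s * fs)))
        template = _biphasic_spike(width)
        n_events = rng.poisson(p.spike_rate * n / fs)
        starts = rng.integers(0, n - width, size=n_events) if n_events else []
        for s in starts:
            x[s : s + width] += p.spike_amp * rng.uniform(0.7, 1.3) * template

    x = x + rng.normal(scale=p.noise_sd, size=n) if p.noise_sd > 0 else x
    return EegRecord(
        samples=minmax_normalize(x),
        fs=fs,
        label=label,
        record_id=f"syn-{label}-{index:04d}",
    )


def generate_dataset(cfg: SyntheticConfig) -> EegDataset:
    """Generate ``n_per_class`` records for each class, deterministically.

    Records are ordered by class (healthy, interictal, ictal) then index.
    """
    records = [
        generate_record(label, cfg, index=i)
        for label in CLASSES
        for i in range(cfg.n_per_class)
    ]
    return EegDataset(records)
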