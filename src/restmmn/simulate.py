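"""Synthetic EEG cohort generator with known ground truth.

Emulates the two-block study design: a 7-minute eyes-closed resting
recording whose inter-channel coherence is controlled per frequency band,
and a duration-deviant auditory oddball session (540 standard / 60 deviant,
ISI 500 ms) whose deviant trials carry a mismatch-negativity deflection of
known depth and latency at Fz.

The resting model sums, over the five analysis bands, a band-limited source
shared across channels and a private band-limited source per channel:

    x_c(t) = sum_b a_b [ sqrt(k_b) g_c s_b(t) + sqrt(1-k_b) p_cb(t) ] + n_c(t)

with coupling 0 <= k_b < 1, fixed per-channel gains g_c spreading the
pairwise coherence around the binarization threshold, and white sensor
noise n_c. Expected pairwise coherence in band b increases monotonically
with k_b (k_b = 0 gives independent channels; k_b -> 1 with no sensor noise
gives coherence -> 1 in-band).

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, Optional, Tuple, Union

import numpy as np
import scipy.fft as sfft
from scipy import signal as sps

from .datatypes import BANDS, EventList, Recording, ValidationError, get_band

__all__ = [
    "SCALP_19",
    "ODDBALL_CHANNELS",
    "MMN_PROFILE",
    "RestingGenParams",
    "OddballGenParams",
    "GroupParams",
    "CohortSpec",
    "default_cohort_spec",
    "generate_stimulus_sequence",
    "generate_resting_recording",
    "generate_oddball_recording",
    "generate_cohort",
    "draw_cohort_truths",
    "iter_cohort",
    "GROUPS",
]

GROUPS = ("AVH", "NonAVH", "HC")

#: 19-channel scalp subset of the 10-20 montage used for network nodes.
SCALP_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Oddball montage: scalp nodes plus the two mastoids needed for
#: offline re-referencing.
ODDBALL_CHANNELS = SCALP_19 + ("TP9", "TP10")

#: MMN spatial profile: maximal at Fz, 0.7 at F3/F4, 0.3 over the remaining
#: fronto-central sites, absent posteriorly (fronto-central scalp maximum).
MMN_PROFILE: Dict[str, float] = {
    "Fz": 1.0, "F3": 0.7, "F4": 0.7,
    "Fp1": 0.3, "Fp2": 0.3, "F7": 0.3, "F8": 0.3, "Cz": 0.3,
}

#: Per-band source amplitudes (uV), a coarse 1/f-like resting spectrum.
_BAND_AMP_UV = {"delta": 20.0, "theta": 12.0, "alpha": 15.0, "beta": 6.0, "gamma": 3.0}

#: Blink-artifact spatial profile (frontal maximum).
_BLINK_PROFILE: Dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.5, "F8": 0.5,
    "Fz": 0.5, "F3": 0.5, "F4": 0.5,
}


@dataclass
class RestingGenParams:
    """Parameters of the resting-state generator (7-min block defaults)."""

    n_channels: int = 19
    duration_s: float = 420.0
    fs: float = 500.0
    band_coupling: Dict[str, float] = field(
        default_factory=lambda: {b: 0.5 for b in BANDS}
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if not 1 <= self.n_channels <= len(SCALP_19):
            raise ValidationError(
                f"n_channels must be in [1, {len(SCALP_19)}]"
            )
        for name, kappa in self.band_coupling.items():
            get_band(name)
            if not 0.0 <= kappa < 1.0:
                raise ValidationError(
                    f"coupling for {name} must lie in [0, 1), got {kappa}"
                )


@dataclass
class OddballGenParams:
    """Parameters of the duration-deviant oddball generator.

    ``mmn_amplitude_uv`` is the depth of the deviant-only negative bump at
    Fz (magnitude convention, >= 0); ``mmn_latency_ms`` its peak time after
    stimulus onset; ``mmn_width_ms`` the Gaussian standard deviation of the
    bump. ``noise_sd`` is white trial noise per sample (uV).
    """

    n_standard: int = 540
    n_deviant: int = 60
    isi_ms: float = 500.0
    std_duration_ms: float = 100.0
    dev_duration_ms: float = 50.0
    mmn_amplitude_uv: float = 3.0
    mmn_latency_ms: float = 180.0
    mmn_width_ms: float = 35.0
    noise_sd: float = 1.5
    pink_sd: float = 0.0
    artifact_rate: float = 0.05
    fs: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_standard < 0 or self.n_deviant < 0:
            raise ValidationError("stimulus counts must be non-negative")
        if not 0.0 <= self.mmn_latency_ms <= 450.0:
            raise ValidationError("mmn_latency_ms must lie within the 0-450 ms epoch")
        if self.mmn_amplitude_uv < 0:
            raise ValidationError("mmn_amplitude_uv is a magnitude (>= 0)")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValidationError("artifact_rate must lie in [0, 1]")


def generate_stimulus_sequence(
    params: OddballGenParams, rng: Optional[np.random.Generator] = None
) -> EventList:
    """Random oddball sequence: a uniform permutation of standards/deviants.

    Onsets are spaced by stimulus duration + ISI starting at 1 s, so each
    event's window (including the 200 ms pre-stimulus baseline) fits the
    recording.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = params.n_standard + params.n_deviant
    conditions = np.array(
        ["standard"] * params.n_standard + ["deviant"] * params.n_deviant, dtype=object
    )
    rng.shuffle(conditions)
    durations = np.where(
        conditions == "deviant", params.dev_duration_ms, params.std_duration_ms
    ).astype(float)
    onsets = np.empty(n)
    t = 1.0
    for k in range(n):
        onsets[k] = t
        t += durations[k] / 1000.0 + params.isi_ms / 1000.0
    return EventList(onsets=onsets, conditions=conditions, durations_ms=durations)


def _band_sos(name: str, fs: float):
    band = get_band(name)
    return sps.butter(4, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


_GAIN_CACHE: dict = {}


def _band_gain(name: str, n_samp: int, fs: float) -> tuple[np.ndarray, slice]:
    """Two-pass (zero-phase) squared-magnitude response of the band's
    4th-order Butterworth filter on the rfft grid, with its support."""
    key = (name, n_samp, fs)
    if key not in _GAIN_CACHE:
        sos = _band_sos(name, fs)
        freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
        _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
        gain = np.abs(h) ** 2
        gain[gain < 1e-8] = 0.0
        nz = np.flatnonzero(gain)
        support = slice(int(nz[0]), int(nz[-1]) + 1)
        _GAIN_CACHE[key] = (gain[support], support)
    return _GAIN_CACHE[key]


def _complex_gauss(
    rng: np.random.Generator, shape: tuple, n_samp: int
) -> np.ndarray:
    """rfft-bin coefficients of unit white noise (re/im ~ N(0, n/2))."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return (re + 1j * im).astype(np.complex64) * np.float32(np.sqrt(n_samp / 2.0))


def generate_resting_recording(
    params: RestingGenParams,
    subject_id: str = "",
    group_label: str = "",
) -> Recording:
    """Simulate a resting recording under the shared/private coupling model."""
    rng = np.random.default_rng(params.seed)
    n_samp = int(round(params.duration_s * params.fs))
    n_ch = params.n_channels
    # fixed per-channel gains spread pairwise coherence across pairs
    gains = np.linspace(0.7, 1.3, n_ch)
    n_bins = n_samp // 2 + 1
    # accumulate every band's shared/private sources in the frequency
    # domain (coefficients drawn only over each band's support), then
    # invert once per channel
    spec = np.zeros((n_ch, n_bins), dtype=np.complex64)
    for name in BANDS:
        kappa = params.band_coupling.get(name, 0.0)
        gain, support = _band_gain(name, n_samp, params.fs)
        sources = _complex_gauss(rng, (n_ch + 1, len(gain)), n_samp) * gain.astype(
            np.float32
        )
        shared, private = sources[0], sources[1:]
        amp = _BAND_AMP_UV[name]
        spec[:, support] += np.float32(amp) * (
            np.float32(np.sqrt(kappa)) * gains[:, None].astype(np.float32) * shared[None, :]
            + np.float32(np.sqrt(1.0 - kappa)) * private
        )
    if params.noise_sd > 0:
        spec += np.float32(params.noise_sd) * _complex_gauss(rng, (n_ch, n_bins), n_samp)
    spec[:, 0] = spec[:, 0].real * np.sqrt(2.0)  # DC/Nyquist bins are real
    if n_samp % 2 == 0:
        spec[:, -1] = spec[:, -1].real * np.sqrt(2.0)
    sig = sfft.irfft(spec, n=n_samp, axis=-1)
    return Recording(
        signal=sig,
        fs=params.fs,
        channel_labels=list(SCALP_19[:n_ch]),
        reference="FCz",
        subject_id=subject_id,
        group_label=group_label,
    )


def _evoked_template(t_ms: np.ndarray) -> np.ndarray:
    """Biphasic base response (identical for both conditions): an N1-like
    trough at 100 ms followed by a P2-like peak at 200 ms."""
    return -2.0 * np.exp(-0.5 * ((t_ms - 100.0) / 15.0) ** 2) + 2.5 * np.exp(
        -0.5 * ((t_ms - 200.0) / 25.0) ** 2
    )


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int], fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit variance per channel."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_oddball_recording(
    params: OddballGenParams,
    subject_id: str = "",
    group_label: str = "",
) -> Recording:
    """Simulate an oddball session with events attached.

    Both conditions receive the same biphasic evoked template; deviants add
    a negative Gaussian bump of depth ``mmn_amplitude_uv`` peaking at
    ``mmn_latency_ms``, spatially weighted by :data:`MMN_PROFILE`. Blink-like
    transients exceeding +/-100 uV are injected per trial with probability
    ``artifact_rate``.
    """
    rng = np.random.default_rng(params.seed)
    events = generate_stimulus_sequence(params, rng)
    fs = params.fs
    last = events.onsets[-1] if len(events) else 1.0
    n_samp = int(round((last + 1.5) * fs))
    labels = list(ODDBALL_CHANNELS)
    n_ch = len(labels)

    sig = np.zeros((n_ch, n_samp))
    if params.noise_sd > 0:
        sig += params.noise_sd * rng.standard_normal((n_ch, n_samp))
    if params.pink_sd > 0:
        sig += params.pink_sd * _pink_noise(rng, (n_ch, n_samp), fs)

    # response templates on the 0..450 ms post-onset grid
    t_ms = np.arange(int(round(0.45 * fs)) + 1) * (1000.0 / fs)
    base = _evoked_template(t_ms)
    mmn = -params.mmn_amplitude_uv * np.exp(
        -0.5 * ((t_ms - params.mmn_latency_ms) / params.mmn_width_ms) ** 2
    )
    evoked_w = np.array([MMN_PROFILE.get(lab, 0.0) for lab in labels])
    blink_w = np.array([_BLINK_PROFILE.get(lab, 0.1) for lab in labels])
    blink_t = np.arange(int(round(0.3 * fs)) + 1) * (1000.0 / fs)

    for onset, cond in zip(events.onsets, events.conditions):
        i0 = int(round(onset * fs))
        span = slice(i0, i0 + len(t_ms))
        wave = base + (mmn if cond == "deviant" else 0.0)
        sig[:, span] += evoked_w[:, None] * wave[None, :]
        if params.artifact_rate > 0 and rng.random() < params.artifact_rate:
            amp = rng.uniform(250.0, 400.0) * rng.choice([-1.0, 1.0])
            center = rng.uniform(50.0, 250.0)
            bump = amp * np.exp(-0.5 * ((blink_t - center) / 60.0) ** 2)
            j0 = i0 + int(round(-0.05 * fs))
            seg = slice(max(j0, 0), min(j0 + len(blink_t), n_samp))
            sig[:, seg] += blink_w[:, None] * bump[None, : seg.stop - seg.start]

    return Recording(
        signal=sig,
        fs=fs,
        channel_labels=labels,
        reference="FCz",
        events=events,
        subject_id=subject_id,
        group_label=group_label,
    )


@dataclass
class GroupParams:
    """Per-group cohort parameters: size, MMN distribution, band coupling."""

    n_subjects: int = 15
    mmn_amplitude_mean_uv: float = 4.5
    mmn_amplitude_sd_uv: float = 1.3
    mmn_latency_mean_ms: float = 178.0
    mmn_latency_sd_ms: float = 14.0
    band_coupling: Dict[str, float] = field(
        default_factory=lambda: {b: 0.50 for b in BANDS}
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


@dataclass
class CohortSpec:
    """Three-group cohort specification (AVH / NonAVH / HC).

    A per-subject latent trait z ~ N(0,1) jointly shifts the subject's band
    coupling (k_b + kappa_subject_sd * z) and, with correlation
    ``trait_correlation``, the subject's MMN amplitude. Within a group this
    induces the positive coupling between network density (hence C, and
    inversely L) and MMN amplitude that the analysis stage should detect;
    between groups the means are set independently.
    """

    groups: Dict[str, GroupParams] = field(default_factory=dict)
    kappa_subject_sd: float = 0.06
    trait_correlation: float = 0.85
    resting_duration_s: float = 420.0
    resting_noise_sd: float = 1.0
    oddball_noise_sd: float = 1.5
    artifact_rate: float = 0.05
    fs: float = 500.0

    def __post_init__(self) -> None:
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        if not -1.0 < self.trait_correlation < 1.0:
            raise ValidationError("trait_correlation must lie in (-1, 1)")


def default_cohort_spec(**overrides) -> CohortSpec:
    """The emulated study conditions: 15 subjects per group; AVH with
    elevated band coupling (strongest on delta and beta) and reduced MMN
    amplitude (2.93 uV vs 4.48 / 4.56 uV)."""
    avh_coupling = {"delta": 0.62, "theta": 0.59, "alpha": 0.52, "beta": 0.62, "gamma": 0.59}
    ctrl_coupling = {b: 0.50 for b in BANDS}
    groups = {
        "AVH": GroupParams(
            n_subjects=15,
            mmn_amplitude_mean_uv=2.93,
            mmn_amplitude_sd_uv=1.684,
            mmn_latency_mean_ms=179.20,
            mmn_latency_sd_ms=12.667,
            band_coupling=dict(avh_coupling),
        ),
        "NonAVH": GroupParams(
            n_subjects=15,
            mmn_amplitude_mean_uv=4.48,
            mmn_amplitude_sd_uv=1.290,
            mmn_latency_mean_ms=177.36,
            mmn_latency_sd_ms=14.762,
            band_coupling=dict(ctrl_coupling),
        ),
        "HC": GroupParams(
            n_subjects=15,
            mmn_amplitude_mean_uv=4.56,
            mmn_amplitude_sd_uv=1.305,
            mmn_latency_mean_ms=177.23,
            mmn_latency_sd_ms=16.361,
            band_coupling=dict(ctrl_coupling),
        ),
    }
    return CohortSpec(groups=groups, **overrides)


def _draw_subject(
    group: str, gp: GroupParams, spec: CohortSpec, idx: int, rng: np.random.Generator
) -> dict:
    z = rng.standard_normal()
    eps = rng.standard_normal()
    rho = spec.trait_correlation
    amp = gp.mmn_amplitude_mean_uv + gp.mmn_amplitude_sd_uv * (
        rho * z + np.sqrt(1.0 - rho**2) * eps
    )
    amp = max(amp, 0.0)  # amplitudes are magnitudes; truncate at zero
    lat = float(
        np.clip(rng.normal(gp.mmn_latency_mean_ms, gp.mmn_latency_sd_ms), 115.0, 235.0)
    )
    coupling = {
        b: float(np.clip(k + spec.kappa_subject_sd * z, 0.02, 0.95))
        for b, k in gp.band_coupling.items()
    }
    return {
        "subject_id": f"{group}{idx + 1:02d}",
        "group": group,
        "trait_z": float(z),
        "mmn_amplitude_uv": float(amp),
        "mmn_latency_ms": lat,
        "band_coupling": coupling,
    }


def draw_cohort_truths(spec: CohortSpec, seed: int) -> list[dict]:
    """Draw every subject's ground-truth parameters without synthesizing
    any signal (cheap; used for Monte-Carlo checks of the sampling model).

    Per-subject generator seeds are derived from ``seed`` via
    ``numpy.random.SeedSequence(seed).spawn``, so any subject can be
    regenerated independently of the others.
    """
    if not spec.groups:
        raise ValidationError("cohort spec defines no groups")
    root = np.random.SeedSequence(seed)
    n_total = sum(gp.n_subjects for gp in spec.groups.values())
    children = root.spawn(n_total + 1)
    draw_rng = np.random.default_rng(children[0])
    truths = []
    k = 1
    for group in GROUPS:
        if group not in spec.groups:
            continue
        gp = spec.groups[group]
        for idx in range(gp.n_subjects):
            truth = _draw_subject(group, gp, spec, idx, draw_rng)
            rest_seed, odd_seed = [int(s) for s in children[k].generate_state(2) >> 1]
            k += 1
            truth["resting_seed"] = rest_seed
            truth["oddball_seed"] = odd_seed
            truths.append(truth)
    return truths


def iter_cohort(
    spec: CohortSpec, seed: int
) -> Iterator[Tuple[dict, Recording, Recording]]:
    """Yield (ground-truth record, resting recording, oddball recording) per
    subject, lazily, without touching disk."""
    for truth in draw_cohort_truths(spec, seed):
        group = truth["group"]
        rest = generate_resting_recording(
            RestingGenParams(
                duration_s=spec.resting_duration_s,
                fs=spec.fs,
                band_coupling=truth["band_coupling"],
                noise_sd=spec.resting_noise_sd,
                seed=truth["resting_seed"],
            ),
            subject_id=truth["subject_id"],
            group_label=group,
        )
        odd = generate_oddball_recording(
            OddballGenParams(
                mmn_amplitude_uv=truth["mmn_amplitude_uv"],
                mmn_latency_ms=truth["mmn_latency_ms"],
                noise_sd=spec.oddball_noise_sd,
                artifact_rate=spec.artifact_rate,
                fs=spec.fs,
                seed=truth["oddball_seed"],
            ),
            subject_id=truth["subject_id"],
            group_label=group,
        )
        yield truth, rest, odd


def generate_cohort(
    spec: CohortSpec, out_dir: Union[str, Path], seed: int
) -> dict:
    """Write one resting and one oddball recording per subject plus a JSON
    manifest recording every drawn ground-truth parameter."""
    from .io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "spec": _spec_to_jsonable(spec), "subjects": []}
    for truth, rest, odd in iter_cohort(spec, seed):
        sid = truth["subject_id"]
        write_recording(rest, out / f"{sid}_resting")
        write_recording(odd, out / f"{sid}_oddball")
        truth["resting_file"] = f"{sid}_resting"
        truth["oddball_file"] = f"{sid}_oddball"
        manifest["subjects"].append(truth)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = asdict(spec)
    return d
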