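"""Synthetic cohorts: phase-coupled EEG plus behavioral data with known truth.

Each simulated channel is 1/f^a background noise (unit RMS, independent per
channel).  A coupling between two channels adds a shared narrow-band
oscillation — Gaussian noise concentrated around the band's geometric-center
frequency, equivalently a carrier with a slow random amplitude/phase
envelope — where the second channel's copy has every spectral component
rotated by the requested phase lag.  A nonzero, non-pi lag makes the
imaginary cross-spectrum of the pair single-signed, which is exactly the
structure the wPLI estimator detects; independent couplings are independent
processes, so uncoupled pairs stay at the estimator's noise floor.

Behavioral data: pitch-adjustment trials with Normal cents error around the
octave-equivalent target, Bernoulli AQ item responses driven by a logistic
trait parameter, Bernoulli PIS naming accuracy, and Normal starting ages.

Group structure: the default cohort mirrors the study design — 31 AP and 33
RP musicians, 28 channels, 512 Hz, two resting conditions.  Both groups
share identical alpha and theta couplings; the beta-band coupling topology
differs (AP: a triangle-free 3-regular bipartite coupling graph; RP: three
K4 cliques with the same degrees), giving the AP group a lower beta
clustering coefficient as the recoverable ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as _fft

from apnet.behavior import PITCH_CLASSES, PitchTrial, default_aq_item_key
from apnet.spectral_connectivity import BANDS, BandSpec, EEGRecording

__all__ = [
    "DEFAULT_MONTAGE",
    "CouplingSpec",
    "BehaviorParams",
    "CohortConfig",
    "Subject",
    "Cohort",
    "default_couplings",
    "simulate_recording",
    "simulate_pitch_trials",
    "simulate_aq_responses",
    "simulate_pis_answers",
    "generate_cohort",
    "one_over_f_noise",
]

#: The study montage: 28 scalp electrodes of the extended 10-20 system.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "FC3", "FC4", "C3", "C4", "CP3", "CP4",
    "P3", "P4", "F7", "F8", "FT7", "FT8", "T7", "T8", "TP7", "TP8",
    "P7", "P8", "O1", "O2", "Oz", "Fz", "Cz", "Pz",
)

#: Pitch classes in canonical (sharp) spelling, used for target cycling.
_PC_LABELS = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")


@dataclass(frozen=True)
class CouplingSpec:
    """A phase-lagged narrow-band coupling between two channels.

    ``strength`` is the RMS amplitude of the shared oscillation relative to
    the unit-RMS background noise.  Zero and pi lags are rejected for
    nonzero strength: they produce a purely real cross-spectrum and are
    invisible to wPLI by construction.  ``center_freq`` defaults to the
    band's geometric-center frequency.
    """

    channel_pair: tuple[str, str]
    band: str
    phase_lag: float
    strength: float
    center_freq: float | None = None

    def __post_init__(self) -> None:
        a, b = self.channel_pair
        if a == b:
            raise ValueError("coupling requires two distinct channels")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        if not -math.pi < self.phase_lag <= math.pi:
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if self.strength > 0 and (
            self.phase_lag == 0.0 or abs(self.phase_lag) == math.pi
        ):
            raise ValueError(
                "zero/pi phase lags are invisible to wPLI; use a lag in "
                "(0, pi) or (-pi, 0)"
            )


@dataclass(frozen=True)
class BehaviorParams:
    """Per-group behavioral generating parameters."""

    mad_sigma_cents: float  # SD of single-trial cents error
    aq_theta: float  # logistic trait location; E[AQ] = 50*logistic(theta)
    starting_age_mean: float
    starting_age_sd: float
    pis_p_correct: float  # per-tone naming accuracy

    def __post_init__(self) -> None:
        if self.mad_sigma_cents < 0:
            raise ValueError("mad_sigma_cents must be non-negative")
        if not 0 <= self.pis_p_correct <= 1:
            raise ValueError("pis_p_correct must be a probability")


def default_couplings() -> dict[str, list[CouplingSpec]]:
    """Default group coupling structure.

    Shared across groups: one alpha coupling (O1-O2) and one theta coupling
    (Fz-Pz), so those bands carry identical structure and serve as the null
    comparison.  Beta couplings occupy twelve channels with an identical
    3-regular degree sequence in both groups but opposite topology: RP gets
    three K4 cliques (18 edges, 12 closed triangles), AP a 3-regular
    bipartite graph on the same channels (18 edges, triangle-free), so the
    AP group has lower beta clustering across the whole density sweep while
    degrees — and hence path-length structure — stay comparable.
    """
    lag = math.pi / 2
    strength = 1.2
    shared = [
        CouplingSpec(("O1", "O2"), "alpha", lag, strength),
        CouplingSpec(("Fz", "Pz"), "theta", lag, strength),
    ]
    quads = (
        ("F3", "C3", "P3", "F7"),
        ("F4", "C4", "P4", "F8"),
        ("T7", "P7", "T8", "P8"),
    )
    rp_beta = [
        CouplingSpec((a, b), "beta", lag, strength)
        for quad in quads
        for idx, a in enumerate(quad)
        for b in quad[idx + 1 :]
    ]
    left = ("F3", "C3", "P3", "F4", "C4", "P4")
    right = ("F7", "T7", "P7", "F8", "T8", "P8")
    ap_beta = [
        CouplingSpec((left[i], right[(i + shift) % 6]), "beta", lag, strength)
        for i in range(6)
        for shift in (0, 1, 2)
    ]
    return {"AP": shared + ap_beta, "RP": shared + rp_beta}


#: Behavioral defaults per group, anchored to the study's group summaries
#: (AP MAD ~41 cents, RP ~297 cents; AQ means 20.5 vs 16.9; starting ages
#: 5.97 +- 2.97 vs 7.12 +- 2.22; AP name >12/36 tones, RP far fewer).
DEFAULT_BEHAVIOR: dict[str, BehaviorParams] = {
    "AP": BehaviorParams(52.0, -0.365, 5.97, 2.97, 0.85),
    "RP": BehaviorParams(450.0, -0.674, 7.12, 2.22, 0.15),
}


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"AP": 31, "RP": 33}
    )
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 512.0
    duration_s: float = 300.0
    conditions: tuple[str, ...] = ("EO", "EC")
    couplings_per_group: dict[str, list[CouplingSpec]] = field(
        default_factory=default_couplings
    )
    behavior_params: dict[str, BehaviorParams] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR)
    )
    noise_exponent: float = 1.0
    n_pitch_trials: int = 108
    seed: int = 0

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        if self.duration_s < 4.0:
            raise ValueError("duration must cover at least one 4-s epoch")
        for g in self.n_per_group:
            if g not in self.behavior_params:
                raise ValueError(f"missing behavior params for group {g!r}")


@dataclass
class Subject:
    subject_id: str
    group: str
    recordings: dict[str, EEGRecording]
    pitch_trials: list[PitchTrial]
    aq_responses: dict[int, int]
    pis_answers: list[str]
    starting_age: float


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig
    pis_key: list[str]

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


def one_over_f_noise(
    n_samples: int,
    fs: float,
    exponent: float,
    rng: np.random.Generator,
    n_channels: int | None = None,
) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise.

    With ``n_channels`` a (channels, samples) array of independent traces is
    returned; otherwise a single 1-D trace.
    """
    shape = (1 if n_channels is None else n_channels, n_samples)
    white = rng.standard_normal(shape).astype(np.float32)
    spec = _fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros(freqs.shape, dtype=np.float32)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    x = _fft.irfft(spec * gain[None, :], n_samples, axis=1).astype(np.float64)
    x /= np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x[0] if n_channels is None else x


def _band_center(band: BandSpec) -> float:
    return math.sqrt(band.f_lo * band.f_hi)


def simulate_recording(
    montage: Sequence[str],
    fs: float,
    duration_s: float,
    couplings: Sequence[CouplingSpec],
    noise_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    condition: str = "EO",
    bands: dict[str, BandSpec] | None = None,
) -> EEGRecording:
    """Simulate one multichannel recording with the given coupling structure."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bands = bands or BANDS
    montage = tuple(montage)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    index = {ch: i for i, ch in enumerate(montage)}
    for c in couplings:
        for ch in c.channel_pair:
            if ch not in index:
                raise ValueError(f"unknown channel label {ch!r}")
        if c.band not in bands:
            raise ValueError(f"unknown band {c.band!r}")
        if bands[c.band].f_hi >= fs / 2:
            raise ValueError(f"band {c.band!r} exceeds Nyquist at fs={fs}")
    n = int(round(fs * duration_s))
    data = one_over_f_noise(n, fs, noise_exponent, rng, n_channels=len(montage))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    active = [c for c in couplings if c.strength > 0]
    if active:
        # Shared oscillations: narrow-band Gaussian noise, i.e. a carrier at
        # f0 with a slow random amplitude/phase envelope.  The second
        # channel's copy is obtained by rotating every positive-frequency
        # component by -phase_lag, a constant spectral phase shift.
        # Independent couplings are independent processes, so only the
        # specified pairs acquire a nonzero imaginary cross-spectrum.
        specs = _fft.rfft(rng.standard_normal((len(active), n)).astype(np.float32), axis=1)
        bumps = np.empty(specs.shape, dtype=np.float32)
        lags = np.empty(len(active))
        for k, c in enumerate(active):
            band = bands[c.band]
            f0 = c.center_freq if c.center_freq is not None else _band_center(band)
            if not band.f_lo <= f0 <= band.f_hi:
                raise ValueError(
                    f"center_freq {f0} outside band {band.name} "
                    f"[{band.f_lo}, {band.f_hi}]"
                )
            bw = min((band.f_hi - band.f_lo) / 8.0, 1.0)
            bumps[k] = np.exp(-0.5 * ((freqs - f0) / bw) ** 2)
            bumps[k, 0] = 0.0
            lags[k] = c.phase_lag
        shaped = specs * bumps
        leads = _fft.irfft(shaped, n, axis=1).astype(np.float64)
        lagds = _fft.irfft(
            shaped * np.exp(-1j * lags)[:, None].astype(np.complex64), n, axis=1
        ).astype(np.float64)
        scales = np.array([c.strength for c in active]) / np.sqrt(
            np.mean(leads**2, axis=1)
        )
        for k, c in enumerate(active):
            i, j = index[c.channel_pair[0]], index[c.channel_pair[1]]
            data[i] += scales[k] * leads[k]
            data[j] += scales[k] * lagds[k]
    return EEGRecording(
        subject_id=subject_id,
        condition=condition,
        fs=fs,
        channel_labels=montage,
        data=data,
    )


def simulate_pitch_trials(
    n_trials: int = 108,
    sigma_cents: float = 50.0,
    bias_cents: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[PitchTrial]:
    """Simulate pitch-adjustment trials.

    Targets cycle through the 12 pitch classes, three of each per block of
    36, shuffled within block (semi-random order).  The final frequency is
    the target pitch class at a random octave whose equal-tempered frequency
    lies inside the adjustable 220-880 Hz range, shifted by a Normal cents
    error eps ~ N(bias, sigma^2).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if sigma_cents < 0:
        raise ValueError("sigma_cents must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[PitchTrial] = []
    block_template = [pc for pc in _PC_LABELS for _ in range(3)]
    made = 0
    block = 0
    while made < n_trials:
        order = list(block_template)
        rng.shuffle(order)
        for pc in order:
            if made >= n_trials:
                break
            semitone = PITCH_CLASSES[pc]
            # Equal-tempered frequencies of this pitch class, all octaves.
            candidates = [
                440.0 * 2.0 ** ((semitone - 9) / 12.0 + octave)
                for octave in range(-4, 5)
            ]
            in_range = [f for f in candidates if 220.0 <= f <= 880.0]
            target_f = in_range[rng.integers(len(in_range))]
            eps = rng.normal(bias_cents, sigma_cents) if sigma_cents > 0 or bias_cents else 0.0
            final = target_f * 2.0 ** (eps / 1200.0)
            trials.append(PitchTrial(target_pitch_class=pc, final_freq=final, block=block))
            made += 1
        block += 1
    return trials


def simulate_aq_responses(
    trait_theta: float,
    item_key: dict[int, tuple[str, bool]] | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[int, int]:
    """Simulate 50 AQ item responses.

    Each item is endorsed in the autistic direction with probability
    logistic(trait_theta); the 4-level response respects the item's keying
    direction (reverse-keyed items express endorsement as disagreement).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    key = default_aq_item_key() if item_key is None else dict(item_key)
    if len(key) != 50:
        raise ValueError(f"item key must cover 50 items, got {len(key)}")
    p = 1.0 / (1.0 + math.exp(-trait_theta))
    responses: dict[int, int] = {}
    for item, (_sub, reverse) in sorted(key.items()):
        endorsed = rng.random() < p
        agree = endorsed != reverse  # endorsement means disagree on reverse items
        # mild vs strong chosen at random; scoring only uses the direction
        strong = rng.random() < 0.5
        if agree:
            responses[item] = 1 if strong else 2
        else:
            responses[item] = 4 if strong else 3
    return responses


def simulate_pis_answers(
    key: Sequence[str],
    p_correct: float,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Simulate PIS naming: correct with probability p, else a wrong class."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    answers = []
    for true in key:
        if rng.random() < p_correct:
            answers.append(true)
        else:
            wrong = [pc for pc in _PC_LABELS if PITCH_CLASSES[pc] != PITCH_CLASSES[true]]
            answers.append(wrong[rng.integers(len(wrong))])
    return answers


def default_pis_key(seed: int = 12345) -> list[str]:
    """A fixed 36-tone naming key: all 12 classes three times, shuffled."""
    rng = np.random.default_rng(seed)
    key = [pc for pc in _PC_LABELS for _ in range(3)]
    rng.shuffle(key)
    return key


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort; bit-identical under (config, seed)."""
    config = config or CohortConfig()
    root = np.random.SeedSequence(config.seed)
    pis_key = default_pis_key()
    subjects: list[Subject] = []
    groups = sorted(config.n_per_group)
    n_total = sum(config.n_per_group.values())
    subject_seeds = root.spawn(n_total)
    idx = 0
    for group in groups:
        params = config.behavior_params[group]
        couplings = config.couplings_per_group.get(group, [])
        for k in range(config.n_per_group[group]):
            sid = f"{group}{k + 1:02d}"
            streams = subject_seeds[idx].spawn(4 + len(config.conditions))
            idx += 1
            rec_rngs = [np.random.default_rng(s) for s in streams[: len(config.conditions)]]
            beh_rngs = [np.random.default_rng(s) for s in streams[len(config.conditions):]]
            recordings = {
                cond: simulate_recording(
                    config.montage,
                    config.fs,
                    config.duration_s,
                    couplings,
                    noise_exponent=config.noise_exponent,
                    seed=rng,
                    subject_id=sid,
                    condition=cond,
                )
                for cond, rng in zip(config.conditions, rec_rngs)
            }
            trial_rng, aq_rng, pis_rng, misc_rng = beh_rngs
            # Mild subject-level heterogeneity around the group parameters.
            sigma_i = params.mad_sigma_cents * math.exp(0.25 * misc_rng.standard_normal())
            theta_i = params.aq_theta + 0.5 * misc_rng.standard_normal()
            age_i = max(2.0, misc_rng.normal(params.starting_age_mean, params.starting_age_sd))
            subjects.append(
                Subject(
                    subject_id=sid,
                    group=group,
                    recordings=recordings,
                    pitch_trials=simulate_pitch_trials(
                        config.n_pitch_trials, sigma_i, 0.0, trial_rng
                    ),
                    aq_responses=simulate_aq_responses(theta_i, seed=aq_rng),
                    pis_answers=simulate_pis_answers(pis_key, params.pis_p_correct, pis_rng),
                    starting_age=float(age_i),
                )
            )
    return Cohort(subjects=subjects, config=config, pis_key=pis_key)
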