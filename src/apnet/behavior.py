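"""Behavioral scoring: pitch adjustment, AQ questionnaire, PIS tone naming.

Pitch-adjustment trials are scored in cents relative to the nearest
octave-equivalent target in 440-Hz equal temperament.  Per subject the two
summary scores are

    MAD   = (1/N) * sum_i |C_i|          (adjustment accuracy, cents)
    SDfoM = SD of the |C_i| values       (adjustment consistency, cents;
                                          sample SD, divisor N-1)

and for regressions both are z-standardized against the non-AP reference
group.  The AQ is a 50-item instrument (5 subscales x 10 items, half
reverse-keyed); one point per item endorsed in the autistic direction.  The
PIS is a 36-tone naming screen; more than 12 correct assigns the AP group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PitchTrial",
    "SubjectScores",
    "PITCH_CLASSES",
    "AQ_SUBSCALES",
    "default_aq_item_key",
    "pitch_class_semitone",
    "cents_to_nearest_target",
    "mad",
    "sdfom",
    "z_scores",
    "score_aq",
    "score_pis",
    "assign_group",
]

# Semitone index of each pitch-class spelling, C = 0.  Enharmonic spellings
# map to the same index (F# == Gb).
PITCH_CLASSES: dict[str, int] = {
    "C": 0, "B#": 0,
    "C#": 1, "Db": 1,
    "D": 2,
    "D#": 3, "Eb": 3,
    "E": 4, "Fb": 4,
    "F": 5, "E#": 5,
    "F#": 6, "Gb": 6,
    "G": 7,
    "G#": 8, "Ab": 8,
    "A": 9,
    "A#": 10, "Bb": 10,
    "B": 11, "Cb": 11,
}

AQ_SUBSCALES = (
    "social_skills",
    "attention_switching",
    "attention_to_detail",
    "communication",
    "imagination",
)

#: Agreement levels for AQ items (4-level forced choice).
AQ_LEVELS = (1, 2, 3, 4)  # 1 definitely agree ... 4 definitely disagree


@dataclass(frozen=True)
class PitchTrial:
    """One pitch-adjustment trial: a target note label and the final frequency."""

    target_pitch_class: str
    final_freq: float
    block: int = 0

    def __post_init__(self) -> None:
        if self.final_freq <= 0:
            raise ValueError(f"final_freq must be positive, got {self.final_freq}")
        if pitch_class_semitone(self.target_pitch_class) is None:
            raise ValueError(f"unknown pitch class {self.target_pitch_class!r}")


@dataclass
class SubjectScores:
    """Per-subject behavioral summary."""

    subject_id: str
    mad: float
    sdfom: float
    aq_total: int
    aq_subscales: dict[str, int]
    pis_correct: int
    group: str
    starting_age: float
    z_mad: float | None = None
    z_sdfom: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mad < 0 or self.sdfom < 0:
            raise ValueError("MAD and SDfoM must be non-negative")
        if sum(self.aq_subscales.values()) != self.aq_total:
            raise ValueError("AQ subscales must sum to the total")
        if not 0 <= self.pis_correct <= 36:
            raise ValueError("PIS correct count must be in 0..36")


def pitch_class_semitone(label: str) -> int | None:
    """Semitone index (C = 0) of a note label; accepts 'F#/Gb' style spellings."""
    for part in str(label).split("/"):
        part = part.strip()
        if part in PITCH_CLASSES:
            return PITCH_CLASSES[part]
    return None


def cents_to_nearest_target(final_freq: float, target_pitch_class: str) -> float:
    """Signed cents deviation to the nearest octave-equivalent target tone.

    Targets are defined by A4 = 440 Hz equal temperament; the deviation is
    folded into [-600, +600) so every frequency is compared to the target
    octave nearest to it (subjects choose their octave freely).  The
    half-open upper edge resolves the exact-tritone tie deterministically.
    """
    if final_freq <= 0:
        raise ValueError(f"frequency must be positive, got {final_freq}")
    pc = pitch_class_semitone(target_pitch_class)
    if pc is None:
        raise ValueError(f"unknown pitch class {target_pitch_class!r}")
    cents_from_a4 = 1200.0 * math.log2(final_freq / 440.0)
    target_cents = 100.0 * (pc - PITCH_CLASSES["A"])
    dev = cents_from_a4 - target_cents
    return float((dev + 600.0) % 1200.0 - 600.0)


def mad(deviations: Sequence[float]) -> float:
    """Mean absolute deviation (cents) over trials."""
    c = np.asarray(deviations, dtype=float)
    if c.size == 0:
        raise ValueError("need at least one deviation")
    return float(np.mean(np.abs(c)))


def sdfom(deviations: Sequence[float]) -> float:
    """Sample SD (divisor N-1) of the absolute deviations around the MAD."""
    c = np.abs(np.asarray(deviations, dtype=float))
    if c.size < 2:
        raise ValueError("need at least two deviations")
    return float(np.std(c, ddof=1))


def z_scores(
    mad_value: float,
    sdfom_value: float,
    reference: Sequence[SubjectScores],
) -> tuple[float, float]:
    """Z-standardize MAD/SDfoM against a reference (non-AP) group."""
    if len(reference) < 2:
        raise ValueError("reference group needs at least two subjects")
    ref_mad = np.array([s.mad for s in reference], dtype=float)
    ref_sd = np.array([s.sdfom for s in reference], dtype=float)
    sd_mad = ref_mad.std(ddof=1)
    sd_sd = ref_sd.std(ddof=1)
    if sd_mad == 0 or sd_sd == 0:
        raise ValueError("reference group has zero variance")
    return (
        float((mad_value - ref_mad.mean()) / sd_mad),
        float((sdfom_value - ref_sd.mean()) / sd_sd),
    )


def default_aq_item_key() -> dict[int, tuple[str, bool]]:
    """Synthetic 50-item AQ key: item -> (subscale, reverse_keyed).

    Five subscales of ten items each; within each subscale the odd items are
    forward-keyed (agreement is autistic-like) and the even items reverse-
    keyed, giving the instrument's half/half polarity split.  Item text is
    not reproduced; only the scoring structure matters here.
    """
    key: dict[int, tuple[str, bool]] = {}
    item = 1
    for sub in AQ_SUBSCALES:
        for j in range(10):
            key[item] = (sub, j % 2 == 1)
            item += 1
    return key


def score_aq(
    responses: Mapping[int, int],
    item_key: Mapping[int, tuple[str, bool]] | None = None,
) -> tuple[int, dict[str, int]]:
    """Score AQ responses (levels 1-4, 1 = definitely agree).

    One point per item endorsed (mildly or strongly agreeing) in the keyed
    autistic direction; reverse-keyed items count disagreement instead.
    Returns ``(total, subscale_counts)``.
    """
    key = default_aq_item_key() if item_key is None else dict(item_key)
    missing = sorted(set(key) - set(responses))
    if missing:
        raise ValueError(f"missing responses for items {missing}")
    subscales = {sub: 0 for sub in AQ_SUBSCALES}
    for item, (sub, reverse) in key.items():
        resp = int(responses[item])
        if resp not in AQ_LEVELS:
            raise ValueError(f"item {item}: response {resp} not in {AQ_LEVELS}")
        agree = resp in (1, 2)
        endorsed = (not agree) if reverse else agree
        if endorsed:
            subscales.setdefault(sub, 0)
            subscales[sub] += 1
    return sum(subscales.values()), subscales


def score_pis(answers: Sequence[str], key: Sequence[str]) -> int:
    """Count octave-free pitch-class matches over the 36-tone naming screen."""
    if len(answers) != 36 or len(key) != 36:
        raise ValueError("PIS requires exactly 36 answers and 36 key entries")
    correct = 0
    for ans, true in zip(answers, key):
        a = pitch_class_semitone(ans)
        t = pitch_class_semitone(true)
        if t is None:
            raise ValueError(f"invalid key entry {true!r}")
        if a is not None and a == t:
            correct += 1
    return correct


def assign_group(
    pis_correct: int,
    override: str | None = None,
    log: list[str] | None = None,
) -> str:
    """AP iff more than 12 of 36 tones named correctly, unless overridden.

    Overrides mirror the study practice of re-assigning borderline subjects;
    each override is appended to ``log`` when provided.
    """
    if not 0 <= pis_correct <= 36:
        raise ValueError("PIS correct count must be in 0..36")
    rule = "AP" if pis_correct > 12 else "RP"
    if override is not None:
        if override not in ("AP", "RP"):
            raise ValueError("override must be 'AP' or 'RP'")
        if log is not None:
            log.append(
                f"group override: rule={rule} (PIS={pis_correct}) -> {override}"
            )
        return override
    return rule
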