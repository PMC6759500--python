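"""Synthetic stimulus corpus and simulated respondents.

The generator stands in for a 32-excerpt music corpus: 16 *happy* excerpts
(major-triad arpeggios, tempo list with median 138 bpm) and 16 *sad*
excerpts (minor-triad arpeggios, median 53 bpm), each 3 s at 44.1 kHz.
Notes are four-harmonic complexes whose harmonic amplitudes double from one
partial to the next.  Tempo lists are fixed, not sampled, so the corpus
medians land on 138/53 exactly; only the per-excerpt fundamentals are drawn
from the seeded generator.

Simulated respondents answer the two-alternative forced-choice task from
the fine-structure cue: the probability of following the TFS label decays
exponentially with band decomposition,

    P(correct | tfs, condition j) = γ + (p₀ − γ)·exp(−β_g · j),

with guess rate γ = 0.5, group baseline p₀ at the original (j = 0) and a
group decay rate β_g (musicians decay slower than non-musicians).  One
physical response is drawn per trial and scored against both cue labels;
since a chimera's ENV label is the complement of its TFS label, the
envelope-cue accuracy is 1 − P(correct | tfs) for decomposed conditions —
an increasing curve bounded below γ — so the ENV benefit comes out
negative, the qualitative structure the analysis is built to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .chimera_synth import CONDITION_ORDER
from .hilbert_core import Waveform
from .psychometrics import GROUPS, SEXES

logger = logging.getLogger("emochimera")


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# fixed tempo lists (bpm); medians are exactly 138 and 53
HAPPY_TEMPI = (120, 124, 128, 130, 132, 134, 136, 138,
               138, 140, 142, 144, 146, 150, 154, 160)
SAD_TEMPI = (40, 42, 44, 46, 48, 50, 52, 53,
             53, 54, 56, 58, 60, 62, 64, 66)

# equal-temperament triad intervals in semitones (root, third, fifth, octave)
MAJOR_TRIAD = (0, 4, 7, 12)
MINOR_TRIAD = (0, 3, 7, 12)


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic stimulus corpus."""

    n_per_emotion: int = 16
    happy_tempi: tuple = HAPPY_TEMPI
    sad_tempi: tuple = SAD_TEMPI
    duration_s: float = 3.0
    rate: float = 44100.0
    harmonic_count: int = 4
    fundamental_range_hz: tuple = (196.0, 392.0)  # G3–G4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.happy_tempi) < self.n_per_emotion or len(self.sad_tempi) < self.n_per_emotion:
            raise ConfigError("tempo lists must cover n_per_emotion excerpts")
        lo, hi = self.fundamental_range_hz
        if lo < 80.0 or hi * (2 ** (12 / 12)) * self.harmonic_count > self.rate / 2:
            raise ConfigError("fundamentals must sit in [80, 8820] with harmonics below Nyquist")
        if min(self.happy_tempi + self.sad_tempi) <= 0:
            raise ConfigError("tempi must be positive")


def _harmonic_note(f0: float, n_samples: int, rate: float, harmonic_count: int) -> np.ndarray:
    """A note of ``harmonic_count`` partials, amplitudes doubling (1:2:4:...)
    and a (π/2)/t phase step from each partial to its predecessor."""
    t = np.arange(n_samples) / rate
    note = np.zeros(n_samples)
    phase = 0.0
    for h in range(1, harmonic_count + 1):
        if h > 1:
            phase += (np.pi / 2) / h
        note += (2.0 ** (h - 1)) * np.cos(2 * np.pi * f0 * h * t + phase)
    return note / (2.0 ** harmonic_count - 1)  # unit amplitude sum


def _arpeggio(f0: float, tempo_bpm: float, triad, cfg: CorpusConfig) -> np.ndarray:
    """Arpeggiated triad at the note rate set by the tempo."""
    n_total = int(round(cfg.duration_s * cfg.rate))
    n_note = max(1, int(round(60.0 / tempo_bpm * cfg.rate)))
    ramp_n = min(int(0.010 * cfg.rate), n_note // 4)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n)) if ramp_n else np.ones(0)
    out = np.zeros(n_total)
    pos = step = 0
    while pos < n_total:
        semi = triad[step % len(triad)]
        note = _harmonic_note(f0 * 2.0 ** (semi / 12.0), min(n_note, n_total - pos),
                              cfg.rate, cfg.harmonic_count)
        if note.size > 2 * ramp_n > 0:
            note[:ramp_n] *= ramp
            note[-ramp_n:] *= ramp[::-1]
        out[pos:pos + note.size] = note
        pos += n_note
        step += 1
    return 0.5 * out / np.max(np.abs(out))


def generate_corpus(cfg: CorpusConfig = CorpusConfig()):
    """Generate the labelled excerpt list and its manifest.

    Returns ``(waveforms, manifest)`` where the manifest records id, label,
    mode, tempo_bpm and fundamental_hz per excerpt.  Deterministic under
    ``cfg.seed``: the only random draw is each excerpt's fundamental.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.fundamental_range_hz
    waveforms, rows = [], []
    for label, tempi, triad in (("happy", cfg.happy_tempi, MAJOR_TRIAD),
                                ("sad", cfg.sad_tempi, MINOR_TRIAD)):
        for i in range(cfg.n_per_emotion):
            f0 = float(rng.uniform(lo, hi))
            tempo = float(tempi[i])
            wid = f"{label}_{i:02d}"
            samples = _arpeggio(f0, tempo, triad, cfg)
            waveforms.append(Waveform(samples=samples, rate=cfg.rate, label=label, id=wid))
            rows.append({"id": wid, "label": label,
                         "mode": "major" if label == "happy" else "minor",
                         "tempo_bpm": tempo, "fundamental_hz": f0})
    manifest = pd.DataFrame(rows)
    logger.info("generated %d excerpts (%d per emotion), seed=%d",
                len(waveforms), cfg.n_per_emotion, cfg.seed)
    return waveforms, manifest


def generate_example_pair(duration_s: float = 3.0, rate: float = 44100.0):
    """The worked-example pair: a 440 Hz pure tone and its 4-harmonic complex.

    The complex holds 440, 880, 1320 and 1760 Hz partials with amplitudes
    doubling from each partial to the next (1:2:4:8) and successive phase
    offsets of (π/2)/t.
    """
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    pure = Waveform(0.9 * np.cos(2 * np.pi * 440.0 * t), rate, label="none", id="tone440")
    complex_ = Waveform(0.9 * _harmonic_note(440.0, n, rate, 4), rate,
                        label="none", id="harm440x4")
    return pure, complex_


# ---------------------------------------------------------------------------
# Simulated respondents
# ---------------------------------------------------------------------------

#: Group baselines p₀ (proportion correct at the original stimuli).
DEFAULT_BASELINES = {"poor": 0.805, "good": 0.965, "first_year": 0.930, "last_year": 0.902}

#: Group decay rates β per condition step; musicians < non-musicians.
DEFAULT_DECAY = {"poor": 0.75, "good": 0.55, "first_year": 0.40, "last_year": 0.35}


@dataclass(frozen=True)
class RespondentConfig:
    """Parameters of the simulated respondent population."""

    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    decay: dict = field(default_factory=lambda: dict(DEFAULT_DECAY))
    guess_rate: float = 0.5
    n_per_group: int = 16  # 8 male + 8 female
    sex_offset: float = 0.0  # additive p0 shift for females
    seed: int = 0

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.baselines or g not in self.decay:
                raise ConfigError(f"missing parameters for group {g!r}")
            if not self.guess_rate <= self.baselines[g] <= 1.0:
                raise ConfigError("baselines must lie in [guess_rate, 1]")
        if max(self.decay["first_year"], self.decay["last_year"]) >= \
                min(self.decay["poor"], self.decay["good"]):
            logger.warning("musician decay rates are not below non-musician rates")


def expected_accuracy(cfg: RespondentConfig, group: str, condition_index, sex: str = "male"):
    """Generating P(correct | tfs) at condition index j (org = 0 … nb64 = 6)."""
    p0 = cfg.baselines[group] + (cfg.sex_offset if sex == "female" else 0.0)
    j = np.asarray(condition_index, dtype=float)
    return cfg.guess_rate + (p0 - cfg.guess_rate) * np.exp(-cfg.decay[group] * j)


def simulate_responses(manifest: pd.DataFrame, cfg: RespondentConfig = RespondentConfig()
                       ) -> pd.DataFrame:
    """Simulate the forced-choice response table for a stimulus manifest.

    One response is drawn per (participant, stimulus, condition) trial from
    the TFS psychometric function; the table carries that same response
    twice, scored against the TFS-source label (``cue='tfs'``) and the
    ENV-source label (``cue='env'``).  Deterministic under ``cfg.seed``.
    """
    missing = set(CONDITION_ORDER) - set(manifest["condition"].unique())
    if missing:
        raise ConfigError(f"manifest is missing conditions {sorted(missing)}")
    cond_index = {c: j for j, c in enumerate(CONDITION_ORDER)}

    tfs_label = manifest["true_label"].to_numpy()
    same_source = (manifest["tfs_source"] == manifest["env_source"]).to_numpy()
    opposite = np.where(tfs_label == "happy", "sad", "happy")
    env_label = np.where(same_source, tfs_label, opposite)
    j = manifest["condition"].map(cond_index).to_numpy(dtype=float)
    stim = manifest["stimulus_id"].to_numpy()
    cond = manifest["condition"].to_numpy()

    rng = np.random.default_rng(cfg.seed)
    frames = []
    for group in GROUPS:
        for i in range(cfg.n_per_group):
            sex = SEXES[0] if i < cfg.n_per_group // 2 else SEXES[1]
            pid = f"{group}_{i:02d}"
            p = expected_accuracy(cfg, group, j, sex=sex)
            follows_tfs = rng.random(len(manifest)) < p
            response = np.where(follows_tfs, tfs_label, opposite)
            for cue, truth in (("tfs", tfs_label), ("env", env_label)):
                frames.append(pd.DataFrame({
                    "participant_id": pid, "group": group, "sex": sex,
                    "stimulus_id": stim, "condition": cond, "cue": cue,
                    "true_label": truth, "response": response,
                }))
    table = pd.concat(frames, ignore_index=True)
    logger.info("simulated %d trials for %d participants, seed=%d",
                len(table), len(GROUPS) * cfg.n_per_group, cfg.seed)
    return table


def fit_decay(condition_index, proportion_correct, guess_rate: float = 0.5):
    """Recover (p₀, β) of the exponential psychometric decay by least squares.

    Fits p(j) = γ + (p₀ − γ)·exp(−β·j) to observed proportions; used for
    parameter-recovery checks of the simulator.
    """
    j = np.asarray(condition_index, dtype=float)
    y = np.asarray(proportion_correct, dtype=float)

    def model(jj, p0, beta):
        return guess_rate + (p0 - guess_rate) * np.exp(-beta * jj)

    (p0, beta), _ = scipy.optimize.curve_fit(
        model, j, y, p0=[0.9, 0.5], bounds=([guess_rate, 0.0], [1.0, 10.0]))
    return float(p0), float(beta)
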