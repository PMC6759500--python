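"""Auditory-chimera synthesis: crossing envelope and fine structure per band.

A chimera pairs two sources (one happy, one sad excerpt), filters both into
the same analysis bands, decomposes every band into envelope (ENV) and
temporal fine structure (TFS), and recombines the TFS of one source with
the ENV of the other in each band before summing across bands:

    chimera_a = Σ_k  ENV_b,k · TFS_a,k        (TFS from a, ENV from b)
    chimera_b = Σ_k  ENV_a,k · TFS_b,k        (TFS from b, ENV from a)

The chimera's *true* emotion label follows its TFS source.  With more
bands the per-band envelopes become flatter and the original ENV cue
migrates into the fine structure, so the band count (nb condition) tunes
which cue carries the emotion.

``build_stimulus_set`` produces the full presentation set: for a balanced
corpus of N excerpts it emits one original (``org``) entry per excerpt plus
one chimera per band condition, N × 7 rows for the default six conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .filterbank import BandSpec, band_edges, split_bands
from .hilbert_core import InvalidInputError, Waveform, extract_env_tfs, write_wav

logger = logging.getLogger("emochimera")

#: Presentation conditions in canonical order.
CONDITION_ORDER = ("org", "nb2", "nb4", "nb8", "nb16", "nb32", "nb64")

#: Band counts behind the chimera conditions, in order.
DEFAULT_BAND_CONDITIONS = (2, 4, 8, 16, 32, 64)

DEFAULT_DURATION_S = 3.0
DEFAULT_TARGET_RMS_DB = -20.0
DEFAULT_RAMP_S = 0.005


class InvalidCorpusError(ValueError):
    """Raised when the corpus is not balanced between emotions."""


def condition_name(n_bands: int) -> str:
    return f"nb{n_bands}"


def rms_db(x: np.ndarray) -> float:
    """RMS level in dB re full scale (dBFS)."""
    return 20.0 * np.log10(np.sqrt(np.mean(np.square(x))))


def _normalize_rms(x: np.ndarray, target_rms_db: float) -> np.ndarray:
    if not np.any(x):
        return x  # silent signal has no defined level
    return x * 10.0 ** ((target_rms_db - rms_db(x)) / 20.0)


def prepare_stimulus(
    w: Waveform,
    duration_s: float = DEFAULT_DURATION_S,
    target_rms_db: float = DEFAULT_TARGET_RMS_DB,
    ramp_s: float = DEFAULT_RAMP_S,
) -> Waveform:
    """Curtail, ramp and level-normalize a source excerpt.

    Takes ``duration_s`` seconds from the signal onset, applies raised-cosine
    onset/offset ramps of ``ramp_s``, and rescales so the RMS level equals
    ``target_rms_db`` dBFS exactly.
    """
    n = int(round(duration_s * w.rate))
    if w.samples.size < n:
        raise InvalidInputError(
            f"input {w.id!r} is {w.duration_s:.3f} s, shorter than {duration_s} s"
        )
    x = w.samples[:n].copy()
    n_ramp = int(round(ramp_s * w.rate))
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    x = _normalize_rms(x, target_rms_db)
    return Waveform(samples=x, rate=w.rate, label=w.label, id=w.id)


@dataclass(frozen=True)
class ChimeraPair:
    """Both hybrids built from one source pair at one band condition."""

    tfs_source_id: str
    env_source_id: str
    n_bands: int
    chimera_a: Waveform  # TFS of source A, ENV of source B
    chimera_b: Waveform  # TFS of source B, ENV of source A
    true_label_a: str
    true_label_b: str


def make_chimera(
    a: Waveform,
    b: Waveform,
    spec: BandSpec,
    target_rms_db: float = DEFAULT_TARGET_RMS_DB,
) -> ChimeraPair:
    """Cross envelope and fine structure of two equal-length sources per band."""
    if a.rate != b.rate or a.samples.size != b.samples.size:
        raise InvalidInputError("chimera sources must share rate and length")
    mix_a = np.zeros_like(a.samples)
    mix_b = np.zeros_like(b.samples)
    for band_a, band_b in zip(split_bands(a, spec), split_bands(b, spec)):
        da = extract_env_tfs(Waveform(band_a.samples, a.rate))
        db = extract_env_tfs(Waveform(band_b.samples, b.rate))
        mix_a += db.envelope * da.fine_structure
        mix_b += da.envelope * db.fine_structure
    mix_a = _normalize_rms(mix_a, target_rms_db)
    mix_b = _normalize_rms(mix_b, target_rms_db)
    for name, mix in (("chimera_a", mix_a), ("chimera_b", mix_b)):
        peak = np.max(np.abs(mix))
        if peak > 1.0:
            logger.warning("%s (%s/%s) peaks at %.3f > 1; reduce target level to avoid clipping",
                           name, a.id, b.id, peak)
    nb = condition_name(spec.n_bands)
    return ChimeraPair(
        tfs_source_id=a.id,
        env_source_id=b.id,
        n_bands=spec.n_bands,
        chimera_a=Waveform(mix_a, a.rate, label=a.label, id=f"{a.id}_{nb}"),
        chimera_b=Waveform(mix_b, b.rate, label=b.label, id=f"{b.id}_{nb}"),
        true_label_a=a.label,
        true_label_b=b.label,
    )


def default_pairing(corpus: list) -> list:
    """Deterministic happy_i ↔ sad_i pairing, each emotion sorted by id."""
    happy = sorted((w for w in corpus if w.label == "happy"), key=lambda w: w.id)
    sad = sorted((w for w in corpus if w.label == "sad"), key=lambda w: w.id)
    if len(happy) != len(sad) or not happy:
        raise InvalidCorpusError(
            f"corpus must balance emotions; got {len(happy)} happy, {len(sad)} sad"
        )
    return list(zip(happy, sad))


def build_stimulus_set(
    corpus: list,
    out_dir=None,
    conditions: tuple = DEFAULT_BAND_CONDITIONS,
    pairing: list | None = None,
    edge_mode: str = "cochlear_map",
    duration_s: float = DEFAULT_DURATION_S,
    target_rms_db: float = DEFAULT_TARGET_RMS_DB,
    write_audio: bool = True,
) -> pd.DataFrame:
    """Generate the full presentation set and its manifest.

    Every excerpt contributes one ``org`` row plus one chimera row per band
    condition in which it is the TFS source and its opposite-emotion partner
    the ENV source.  True labels follow the TFS source.  Returns the manifest
    (stimulus_id, condition, path, true_label, tfs_source, env_source,
    n_bands); WAV files are written under ``out_dir`` when ``write_audio``.

    ``pairing`` may be a list of (happy_id, sad_id) tuples; by default
    excerpts are paired by sorted-id rank within each emotion.
    """
    prepared = {w.id: prepare_stimulus(w, duration_s, target_rms_db) for w in corpus}
    if pairing is None:
        pairs = default_pairing(list(prepared.values()))
    else:
        pairs = [(prepared[h], prepared[s]) for h, s in pairing]
        if len(pairs) * 2 != len(prepared):
            raise InvalidCorpusError("pairing must cover the whole corpus exactly once")

    out_path = Path(out_dir) if out_dir is not None else None
    if write_audio and out_path is None:
        raise InvalidInputError("out_dir is required when write_audio=True")
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def emit(w: Waveform, condition: str, tfs_src: str, env_src: str) -> dict:
        path = ""
        if write_audio:
            path = str(out_path / f"{w.id}.wav")
            write_wav(path, w)
        return {
            "stimulus_id": w.id,
            "condition": condition,
            "path": path,
            "true_label": w.label,
            "tfs_source": tfs_src,
            "env_source": env_src,
        }

    rows_by_stim: dict = {}
    for w in prepared.values():
        rows_by_stim[w.id] = [emit(
            Waveform(w.samples, w.rate, w.label, f"{w.id}_org"), "org", w.id, w.id)]
    for h, s in pairs:
        for nb in conditions:
            spec = band_edges(nb, mode=edge_mode)
            pair = make_chimera(h, s, spec, target_rms_db=target_rms_db)
            cond = condition_name(nb)
            rows_by_stim[h.id].append(emit(pair.chimera_a, cond, h.id, s.id))
            rows_by_stim[s.id].append(emit(pair.chimera_b, cond, s.id, h.id))

    rows = [r for sid in sorted(rows_by_stim) for r in rows_by_stim[sid]]
    manifest = pd.DataFrame(rows)
    logger.info("stimulus set: %d excerpts x %d conditions = %d rows",
                len(prepared), len(conditions) + 1, len(manifest))
    return manifest
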