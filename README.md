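# emochimera

Auditory-chimera synthesis and forced-choice psychophysics analysis for
emotion discrimination in music.

Music conveys emotion through two separable acoustic carriers: the
**temporal fine structure** (TFS) — the rapid oscillation of the waveform,
which carries pitch and mode — and the **envelope** (ENV) — its slow
amplitude modulation.  Auditory *chimeras* let an experimenter put these
cues in conflict: both sources are filtered into the same analysis bands,
each band is split via the Hilbert analytic signal
A(t) = x(t) + i·H[x](t) into ENV(t) = |A(t)| and TFS(t) = cos φ(t), and
the chimera recombines the TFS of one source with the ENV of the other in
every band.  Presenting such hybrids of a happy (major-mode, fast) and a
sad (minor-mode, slow) excerpt in a happy/sad two-alternative forced
choice, across band counts from 2 to 64, measures *which* cue listeners
use to resolve emotion and how that differs between listener groups
(non-musician poor/good performers; first-/last-year conservatory
students).

The package is aimed at auditory psychophysicists: it covers stimulus
synthesis (Hilbert decomposition, Greenwood cochlear-map filterbank,
chimera recombination, 224-stimulus presentation sets), response analysis
(discrimination curves; Grier's A′; d′ with log-linear correction; the
normalized cue benefit (TFS − ENV)/(1 − ENV)), group inference
(repeated-measures ANOVA with Greenhouse–Geisser correction, canonical
discriminant analysis of the 7-condition identification profile), and a
synthetic corpus/respondent generator so the full pipeline runs and is
testable without any human data.  `docs/methods.md` documents the models
and the design choices.

## Worked example

```python
import numpy as np
import emochimera as ec

# the fixed six-band edge table (Hz)
ec.band_edges(6, mode="fixed_table").edges
# (80.0, 260.0, 600.0, 1240.0, 2420.0, 4650.0, 8820.0)

# chimera of a 440 Hz pure tone (TFS) and its 4-harmonic complex (ENV):
# the percept-defining spectral peak follows the fine-structure source
pure, complex_ = ec.generate_example_pair()
pair = ec.make_chimera(pure, complex_, ec.band_edges(2))
spec = np.abs(np.fft.rfft(pair.chimera_a.samples))
np.fft.rfftfreq(pair.chimera_a.samples.size, 1/44100.0)[np.argmax(spec)]
# 440.0  (Hz)

# signal-detection indices
ec.a_prime(0.75, 0.25)                        # 0.8333  (Grier A')
ec.a_prime_relative_difference(0.7725, 0.5794)  # 25.0   (% A' happy-vs-sad)

# synthetic corpus -> full stimulus set -> simulated responses -> curves
waves, manifest = ec.generate_corpus(ec.CorpusConfig(seed=0))
manifest.groupby("label")["tempo_bpm"].median()   # happy 138.0, sad 53.0 bpm
stim = ec.build_stimulus_set(waves, write_audio=False)
len(stim)                                         # 224 = 32 excerpts x 7 conditions
rt = ec.score_responses(ec.simulate_responses(stim, ec.RespondentConfig(seed=1)))
curves = ec.discrimination_curve(rt[rt.cue == "tfs"], by=("group",))
curves.pivot(index="group", columns="condition", values="percent_correct").round(1)
```

```
condition    org   nb2   nb4   nb8  nb16  nb32  nb64
group
first_year  91.8  78.3  67.4  64.5  56.8  55.9  54.7
good        95.7  76.6  64.1  62.1  54.3  48.4  51.8
last_year   90.4  82.2  71.9  62.3  62.9  59.4  58.4
poor        78.5  64.5  57.0  57.0  52.5  49.8  52.7
```

Percent correct starts at each group's baseline on the originals and
decays toward the 50% guess rate as band decomposition destroys the
fine-structure cue — fastest for non-musician poor performers, slowest
for musicians.  A repeated-measures ANOVA over conditions for the good
performers prints

```
F(4.059, 60.89) = 70.69, p = 2.574e-22, GG eps = 0.6766
```

— the fractional degrees of freedom are the Greenhouse–Geisser sphericity
correction (ε = 0.68) applied to the uncorrected (6, 90) layout.

## Command line

```bash
emochimera simulate corpus --out corpus/ --seed 1      # 32 synthetic WAVs
emochimera batch --corpus corpus/ --out stimuli/       # 224-stimulus set + manifest
emochimera simulate responses --manifest stimuli/manifest.csv --out resp.csv --seed 1
emochimera analyze --responses resp.csv --by group --out analysis/
emochimera report --seed 1 --out report.json           # seeded end-to-end JSON
```

Every subcommand logs to stderr and writes a `run_config.json` echo next
to its outputs; a JSON config file (`--config`) supplies defaults that
CLI flags override.

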