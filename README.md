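# speechbci

A self-contained, synthetic re-creation of an intracortical speech
brain–computer-interface decoding pipeline, for researchers who want to
study, test or extend the computational machinery of attempted-speech
decoding without access to human neural recordings.

Microelectrode arrays in ventral premotor cortex record multiunit
threshold-crossing counts (TX) and spike-band power (SBP) while a
participant attempts to speak. A recurrent network converts these features
into per-time-step phoneme probabilities; a language model then infers the
most probable word sequence. This package implements that pipeline end to
end, together with the neural-tuning and representational analyses that
accompany it, driven entirely by a bundled Poisson spiking simulator with
articulatory phoneme tuning — so every result here is computable on a
laptop, and every analysis can be validated against planted ground truth.

## The model

**Encoding (simulator).** Each electrode *e* has a linear tuning
*w<sub>e</sub>* to a latent articulatory trajectory *a(t)* (place, manner,
voicing for consonants; tongue height, backness, rounding for vowels):

    rate_e(t) = softplus( b_e + w_e · a(t) + day offset + drift )
    TX_e(t)   ~ Poisson( rate_e(t) · Δt ),    Δt = 20 ms

with across-day offsets/channel relabelings, slow within-day drift, and a
delay/go trial structure.

**Decoding.** Features are causally smoothed, z-scored (optionally with
exponentially weighted *rolling adaptation*), stacked into 80 ms steps and
fed through a day-specific affine input layer into a gated-recurrent stack
with a softmax over 41 tokens (39 ARPABET phonemes + interword silence
`<sil>` + CTC blank). Training minimizes the connectionist temporal
classification (CTC) negative log-likelihood

    L = − log Σ_π P(π | x),   over all frame paths π that collapse to the
                              target phoneme sequence,

computed by the forward–backward recursion (implemented here in NumPy,
gradients included). Decoding is CTC prefix beam search over a lexicon
trie with shallow fusion of a trigram language model (interpolated
absolute-discount backoff, also implemented here), scored as

    total = α · log P_CTC(phonemes | x) + β · log P_LM(words) + γ · |words|.

An exhaustive oracle (full CTC marginalization per candidate word sequence)
verifies the beam search exactly on small instances.

**Analyses.** Instructed-delay tuning (PSTHs, leave-one-out Gaussian naive
Bayes classification, one-way ANOVA tuning maps, FVAF), saliency-vector
extraction by constrained input optimization, representational similarity
against articulatory features with a label-permutation null and
cross-validated Procrustes, and design sweeps (electrode count, vocabulary
size, training size, across-day pattern stability).

## Worked example

```python
from speechbci.pipeline import run_pipeline, PipelineConfig

cfg = PipelineConfig(n_train=150, n_test=10, epochs=12)
res = run_pipeline(seed=42, cfg=cfg)
print(f"greedy phoneme error rate : {res.per:.1%}")
print(f"beam+trigram word error   : {res.wer_lm:.1%}")
print(f"no-LM baseline word error : {res.wer_nolm:.1%}")
for ref, hyp in zip(res.test_sentences[:3], res.hyp_lm[:3]):
    print(f"  REF: {ref:<28}  HYP: {hyp}")
```

prints

```
greedy phoneme error rate : 17.3%
beam+trigram word error   : 4.7%
no-LM baseline word error : 27.9%
  REF: WHERE IS MY MUSIC             HYP: WHERE IS MY MUSIC
  REF: YES YOU ARE VERY GOOD         HYP: YES YOU ARE VERY GOOD
  REF: OKAY I NEED MUSIC             HYP: OKAY I NEED MUSIC
```

The greedy phoneme error rate (17.3%) measures the recurrent decoder
alone; the trigram language model then repairs most phoneme-level mistakes
(word error 4.7% versus 27.9% for the no-LM nearest-pronunciation
baseline) — the division of labor the pipeline is built around.

A command-line interface wraps the same stages:

```bash
speechbci simulate --seed 1 --out data/
speechbci train    --seed 1 --data data/ --out decoder.npz
speechbci decode   --seed 1 --data data/ --checkpoint decoder.npz --out report.tsv
speechbci evaluate --report report.tsv
speechbci sweep    --kind electrodes --seed 1 --out sweeps/
```

## Layout

| module | contents |
| --- | --- |
| `speechbci.phonemes` | ARPABET inventory, CMUdict lexicon, sentence→label conversion |
| `speechbci.articulation` | articulatory feature table, vowel coordinate systems |
| `speechbci.corpus` | 50-word assistive vocabulary, sentence grammar, distractor words |
| `speechbci.simulator` | Poisson spiking generator with non-stationarities |
| `speechbci.features` | smoothing, z-scoring, rolling adaptation, 80 ms stacking |
| `speechbci.rnn` | GRU decoder with day input layers, CTC training (NumPy) |
| `speechbci.ctc` | CTC loss/gradient, forward algorithm, greedy decode |
| `speechbci.lm` | trigram LM with absolute-discount backoff, ARPA export |
| `speechbci.decode` | lexicon-trie prefix beam search, exhaustive oracle |
| `speechbci.metrics` | phoneme/word error rates |
| `speechbci.tuning` | PSTH, naive Bayes, ANOVA and FVAF maps |
| `speechbci.rsa` | saliency vectors, similarity, permutation null, Procrustes |
| `speechbci.experiments` | electrode/vocabulary/training-size/day sweeps |
| `speechbci.io`, `speechbci.cli` | HDF5 container, config, command line |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
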