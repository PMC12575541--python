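# phasecast

Joint **surgical-phase recognition and long-horizon anticipation** as a
generative sequence task, at desk scale.

Intraoperative guidance needs more than knowing the current phase of a
procedure: it needs a plausible picture of the *next half hour*. This
package implements that as sequence generation over per-second phase
timelines: given everything observed up to time *t*, predict the phase
active at each of the next *N* minutes

```
f_theta : X_{<=t} -> (y_{t+0·60}, y_{t+1·60}, ..., y_{t+N·60})
```

over a vocabulary of 7 surgical phases plus an end-of-surgery (EOS)
class, and — as a twin regression task — the remaining minutes until
each class's next occurrence, clamped to [0, N].

It is written for researchers in surgical workflow analysis (and anyone
working on dense long-horizon action anticipation) who want a complete,
CPU-sized, fully reproducible reference pipeline: every model trains in
minutes on synthetic workflows, and the same code consumes real
Cholec80/AutoLaparo-style annotation files plus any external per-frame
feature matrix.

## What is inside

- **Timelines** (`phasecast.timelines`) — per-second phase timelines,
  Cholec80 / AutoLaparo / generic-TSV annotation parsers, and target
  construction for classification and remaining-time regression (EOS
  fills times past the end of the procedure).
- **Workflow simulator** (`phasecast.simulate`) — a semi-Markov generator
  with near-linear phase order, log-normal durations (procedures average
  about 38 min), optional skip/repeat deviations, and a noisy
  prototype-based observation model standing in for vision features.
- **Transition priors and baselines** (`phasecast.priors`) — the tensor
  P(class *j* at +*h* min | class *i* now) counted over every second of a
  training corpus; the Naive1 continuation and Naive2 conditional-sampling
  baselines.
- **Context encoder** (`phasecast.encoder`) — windowed self-attention
  (disjoint W-second windows) over the last L seconds, linear compression
  to a small latent width, and two max-pooling compressions: cumulative
  *key-pooling* into M context tokens and 60-second *interval-pooling*;
  plus the recognition head (skip-fused, one class distribution per recent
  second).
- **Decoders** (`phasecast.decoders`) — single-pass cross-attention
  decoding (SP), prior-initialised query tokens (SP\*), autoregressive
  generation with causal masking over interval tokens (AR),
  remaining-time regression, and the sort-and-bin regression-to-
  classification mapping (R2C). Training uses teacher forcing (ground-
  truth current phase selects the prior row) with weighted cross-entropy
  and MSE losses. All attention modules run on a small numpy autodiff
  core (`phasecast.nn`).
- **Metrics** (`phasecast.metrics`) — per-horizon and mean weighted F1
  with per-sequence EOS capping, IoU-matched segment F1, inMAE / outMAE /
  wMAE for remaining-time predictions, remaining-surgery-duration
  MAE-5/-30/-ALL, and validation-based model selection.
- **CLI** (`phasecast` command) — `simulate`, `extract-priors`, `train`,
  `predict`, `baseline`, `evaluate`, `render`; YAML configs, JSONL
  prediction interchange, config-hash + seed provenance on every file.

## Worked example

```bash
cd examples && python 03_train_sp_decoder.py
```

trains a prior-initialised single-pass decoder on 40 simulated procedures
(~1 min on one CPU) and prints:

```
final training loss 0.770 (recognition 0.030 + anticipation 0.740)
mean F1 over 15 min: SP* 0.508  naive1 0.334
```

The first line is the joint training objective at the last step
(recognition is essentially solved; the anticipation term carries the
irreducible uncertainty of the stochastic workflow). The second line
scores 15-minute-horizon phase sequences on ten held-out procedures with
EOS-capped mean weighted F1: the learned decoder (0.51) clearly beats
extending the current phase forward (0.33), which is the
expected picture on workflows whose phases last a few minutes. The other
examples cover simulation, priors/baselines, remaining-time targets with
R2C, and rendering the anticipation-timeline figure.

The same pipeline runs from the shell:

```bash
phasecast -c cfg.yaml simulate --out data/
phasecast -c cfg.yaml extract-priors --data data/ --out prior.json
phasecast -c cfg.yaml train --data data/ --kind sp_star --prior prior.json --out model.npz
phasecast -c cfg.yaml predict --ckpt model.npz --data data/ --out pred.jsonl
phasecast -c cfg.yaml evaluate --pred pred.jsonl --data data/ --out report.json
```

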