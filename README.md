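# abrwave

Automatic recognition of the characteristic waves of the human auditory
brainstem response (ABR) — waves **I**, **III** and **V** — from averaged
click-ABR sweeps, using per-sample BiLSTM sequence labeling.

## The problem

ABR testing records scalp potentials evoked by acoustic clicks; the
latencies of waves I, III and V (and their interwave intervals) are the
quantities audiologists read off to assess brainstem auditory function and
estimate hearing thresholds. Marking those waves by hand is slow and
subjective, especially for abnormal-hearing patients whose early waves are
faint, fused or absent. `abrwave` frames wave marking as binary per-sample
sequence classification:

1. each 1,024-sample sweep (t = −12.78 … 12.80 ms, Δt = 0.025 ms, µV) is
   cut to the 321 samples of the 0–8 ms analysis window;
2. each clinician mark becomes a 1 at its nearest sample, dilated by
   ±4 samples (0.1 ms) into a nine-sample feature area — 3 : 318 positives
   would otherwise starve the loss;
3. a stack of (Bi)LSTM layers with a shared affine–softmax head emits a
   feature probability for every sample, trained with per-step
   cross-entropy (the LSTM cell is the standard gated recursion
   f·i·a·o with memory cell `C_t = C_{t−1}⊙f_t + i_t⊙a_t`,
   `h_t = o_t⊙tanh C_t`);
4. postprocessing thresholds the probabilities, merges positive runs whose
   gaps are under 20 samples (0.5 ms) into wave regions, takes the mean of
   each region's first and last sample times as its latency, and names
   regions I/III/V by clinical latency gates;
5. accuracy is `ACC = r_p / p_n` — the fraction of manually marked points
   recovered within a maximum allowable error (ME) of 0.1 / 0.15 / 0.2 ms.

Optional preprocessing decomposes the window with a six-level discrete
wavelet transform and rebuilds it from the level-6 approximation plus
level 4–6 details only, suppressing high-frequency interference.

No public clinical ABR corpus exists, so the package ships a synthetic
sweep generator (`abrwave.simulator`) that emulates five-peak ABR
morphology, latency jitter, amplitude variation, absent waves in abnormal
hearing, broadband noise, baseline drift and late-window myogenic
artifacts, with exact ground-truth annotations. All experiments and tests
run against it.

## Worked example

```python
import numpy as np
from abrwave import (simulate_dataset, extract_window, annotation_to_labels,
                     augment_labels, SequenceModelConfig, build_model, train,
                     predict_probs, regions_from_probs, accuracy)
from abrwave.experiments import make_preset

pairs = simulate_dataset(n=80, class_mix=0.0,
                         config=make_preset("easy"), seed=7)
items = [(extract_window(r), augment_labels(annotation_to_labels(a)))
         for r, a in pairs]
cfg = SequenceModelConfig(directionality="bi", num_layers=1,
                          hidden_nodes=64, epochs=25, batch_size=16, seed=0)
model, log = train(build_model(cfg), items[:60], cfg)

scored = []
for rec, ann in pairs[60:]:
    peaks = regions_from_probs(predict_probs(model, extract_window(rec)))
    scored.append((peaks, ann))
res = accuracy(scored, tol=0.2)
print(f"train loss {log.final_train_loss:.4f}")
print(f"ACC@0.2ms = {res.acc:.3f} ({res.r_p}/{res.p_n})")
print("wave V latency of first test sweep:", scored[0][0].latency("V"), "ms")
```

prints (exact values vary with seed/config):

```
train loss 0.0751
ACC@0.2ms = 0.967 (58/60)
wave V latency of first test sweep: 5.575 ms
```

i.e. after 25 epochs the one-layer BiLSTM recovers 58 of the 60 annotated
wave latencies in the 20 held-out sweeps to within 0.2 ms; the first test
sweep's wave-V region center lands at 5.575 ms against a ground-truth mark
of 5.45 ms (an error of 0.125 ms, inside the 0.2 ms clinical tolerance).

The same workflow is scriptable from the shell:

```bash
abrwave simulate --n 614 --abnormal-frac 0.705 --seed 7 --out data/
abrwave train --data data/ --out model --layers 3 --hidden 512 --seed 0
abrwave predict --model model --data data/ --out pred/
abrwave evaluate --pred pred/ --truth data/ --me 0.1,0.15,0.2
abrwave grid --config config.yaml --experiment architecture --out results/
```

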