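# cgad — confidence-guided adaptive diffusion for image classification

`cgad` is a reference implementation of classification by **label-space
diffusion with confidence-guided adaptive noise injection**, aimed at
medical-image-style problems where per-sample reliability is heterogeneous
(blurred lesion boundaries, low contrast, ambiguous morphology). It is a
pure-Python/numpy package — the networks, their gradients and the
diffusion mathematics are all self-contained — with a library API, short
example scripts and a thin `cgad` command-line interface.

## The method

A K-dimensional class-score vector diffuses instead of the image. During
training the clean state `y0` is the one-hot label; the forward chain at
step `t` is

    y_t = √ᾱ_t · y0 + √(1−ᾱ_t) · (1−c) · ε + (1−ᾱ_t) · (y_g + y_l)

where `ε ~ N(0, I)`, `ᾱ_t` is the cumulative noise-decay factor, and
`y_g`, `y_l` are global/local prior score vectors from a structure-aware
image network (dilated-convolution context blocks, region-of-interest
pathway with channel attention). The scalar `c` is the classifier's
maximum softmax probability — a cheap per-sample reliability proxy,
detached from the graph — so uncertain samples are perturbed strongly and
confident ones barely at all. A conditional network `ε_θ(y_t, t, ρ(x), G)`
learns the injected noise; the clean estimate

    ŷ0 = (y_t − (1−ᾱ_t)·G − (1−c)·√(1−ᾱ_t)·ε_θ) / √ᾱ_t

inverts the forward map, and the reverse chain applies the DDPM posterior
to the guidance-shifted state. The objective combines denoising
regression, a multi-view maximum-mean-discrepancy regularizer over
prior-specific noise predictions, a periodically activated auxiliary
cross-entropy, and a prior-reconstruction constraint:

    L = L_denoise + λ·(L_MMD + L_aux) + L_recon,   λ = 0.5.

At inference the predicted class distribution stands in for `y0`, the
chain runs in reverse, and the argmax of the recovered clean vector is
the prediction. See `docs/methods.md` for assumptions, parameter defaults
and design rationale.

The package also ships a procedural **lesion-image benchmark** whose
`ambiguity` parameter interpolates class-generating distributions from
fully separable (Bayes error ≈ 0) to identical (chance level), yielding
the heterogeneous-confidence regime the method targets.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

trains on two separable synthetic lesion classes (48 images per class,
64×64, small networks, 50 epochs, ~3 min on one CPU) and prints:

```
denoise loss: first 5 steps 2.16 -> last 5 steps 0.55
mean classifier confidence, last epoch: 0.596
held-out accuracy=1.000  macro-F1=1.000  kappa=1.000
confusion matrix:
 [[10  0]
 [ 0 10]]
```

The denoise loss falling well below 2.0 (the variance of the injected
noise, i.e. the score of a predictor that outputs zero) shows the network
genuinely predicts the noise; accuracy is computed entirely from
reverse-sampled predictions, not from the auxiliary classifier. The other
examples cover dataset generation (`01`), the diffusion algebra (`02`),
and the fixed-vs-adaptive stability diagnostics (`04`).

Command-line equivalents:

```bash
cgad generate-data --out data/ --n-per-class 48 --k 2 --ambiguity 0.0
cgad train --data data/ --out run/
cgad eval  --data data/ --out eval/ --model run/ --trajectories
cgad ablate --data data/ --out ablation/ --seeds 0,1,2
cgad diagnose --ours run/loss_per_step.csv --baseline run0/loss_per_step.csv --out diag/
```

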