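# radiogen

Conditional-GAN radiogenomics on synthetic phantom cohorts: generate 3D
breast-MRI-like volumes from per-patient multi-omic latent features,
score their realism with a volumetric Fréchet distance, and test whether
the generated images carry extractable molecular signal (driver-gene
mutation status, 5-class molecular subtype).

## The problem

Radiogenomic studies need imaging, genomics, and labels for the *same*
patients, but public cohorts are largely unpaired: hundreds of patients
have multi-omic profiles while only a few dozen have usable DCE-MRI.
One proposed remedy is to train a conditional GAN on the small paired
subset — generator G(z) maps a patient's 17-dim multi-omic latent vector
z (from a tensor factorization of expression, methylation and
copy-number data) to a 32x128x128 volume, while a discriminator D(x, z)
scores volume/condition pairs — and then synthesize images for the
patients who lack them.  The synthesis is judged two ways:

* **distributional realism** — the squared Fréchet distance between
  Gaussians fitted to volumetric features of real and generated sets,
    d² = |μ_r − μ_g|² + Tr(Σ_r + Σ_g − 2(Σ_r Σ_g)^{1/2}),
  compared against autoencoder baselines under 10-fold cross-validation;
* **clinical usability** — a 3D CNN (conv 32/16/8 + max-pool blocks,
  128-unit dense, dropout 0.5, sigmoid or 5-score head) trained on the
  generated volumes to predict *TP53* / *PIK3CA* / *CDH1* mutation
  status (ROC-AUC, PR-AUC) and molecular subtype (macro
  precision/recall/F1), against an L1-logistic multi-omic baseline.

Since the clinical cohorts and pretrained feature networks are not
redistributable, this package re-implements the full pipeline and
exercises it on *synthetic phantom cohorts* with known generative ground
truth (see `docs/methods.md`): latent vectors drive both the labels
(logistic/softmax links, reference prevalences such as TP53 235/690) and
the phantom lesion's appearance, so conditioning fidelity, signal
recovery, null behaviour, and baseline orderings all become testable
properties.

The training stack (3D conv/transposed-conv layers, LSGAN loop, Adam,
plateau scheduling) is a compact, fully seeded numpy engine under
`radiogen.nn`; standard steps (NIfTI I/O, resizing, AUCs, logistic
regression, K-fold) use nibabel / scikit-image / scikit-learn.

## Worked example

```bash
cd analysis
python 01_simulate_cohort.py --seed 1
python 02_train_cgan.py      --seed 1
python 03_evaluate_fid.py    --seed 1
python 04_mutation_prediction.py --seed 1 --genes TP53
python 05_subtype_prediction.py  --seed 1
```

`01` simulates 200 patients (8x32x32 phantoms at desk scale) and prints
the realized label rates:

```
  gene  target_prevalence  observed_prevalence
  TP53             0.3406                0.320
PIK3CA             0.3580                0.365
  CDH1             0.1623                0.125
```

`02` trains the conditional GAN (500 epochs, ~3.5 minutes on one CPU)
and reports how faithfully generation tracks the conditioning signal:

```
trained 500 epochs; final G loss 0.3513, D loss 0.2530
lesion-score conditioning (Spearman over 200 patients): 0.995
```

— the discriminator loss sits near the least-squares-GAN equilibrium of
0.25, and the mean intensity inside the lesion region of a *generated*
volume rank-correlates 0.995 with the lesion score u·z carried by the
latent: the generator renders the molecular conditioning rather than
ignoring it.  `03` compares Fréchet distances (lower = closer to the
real distribution):

```
                 model  fid_mean  fid_spread
                  cgan  0.015959    0.000477
           autoencoder  0.016414    0.000344
pretrained_autoencoder  0.042062    0.000603
   untrained_generator  5.854794    0.040824
```

`04` trains the mutation CNN per arm; on phantoms the generated-volume
arm reaches held-out ROC-AUC 0.872 for TP53 (0.892 from real volumes,
~0.5 when labels are permuted), and `05` runs the 5-class subtype
experiment (macro recall 0.38 against a 0.20 chance level — the phantom
exposes a single image scalar, so only the extreme subtype classes
separate well).  Numbers vary a little with `--seed`; the tables land in
`results/`.

The same pipeline is available end-to-end as a config-driven run:

```bash
radiogen-cgan run-all --config experiment.yaml
```

which writes volumes, checkpoints, fold tables, per-arm reports, a
consolidated `report.json` / `report.md`, and a hash manifest under the
configured run directory (byte-identical on rerun with the same config).

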