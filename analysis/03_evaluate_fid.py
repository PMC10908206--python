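"""Score generative realism: Fréchet distance of cGAN vs baselines.

Compares, against the real phantom volumes, the volumes produced from
latents alone by (a) the trained cGAN, (b) a plain autoencoder with a
post-hoc latent bridge, (c) the same with a frozen random encoder, and
(d) the untrained generator.  The expected ordering is
cGAN < autoencoders << untrained.  Requires results/cgan/cgan.ckpt
(from 02_train_cgan.py).  Outputs results/fid.csv.
"""

import argparse

import numpy as np
import pandas as pd

from radiogen.baselines import baseline_generate, train_baseline
from radiogen.cgan import CganCheckpoint, build_generator, generate_volumes
from radiogen.cohort import simulate_cohort
from radiogen.fid import default_extractor, fid_with_uncertainty

from common import RESULTS, SHAPE, baseline_config, cgan_config, cohort_spec


def main(seed: int) -> None:
    records = simulate_cohort(cohort_spec(seed))
    lat = np.stack([r.latent for r in records])
    real = [r.volumes[0] for r in records]
    extractor = default_extractor(SHAPE)

    ckpt_path = RESULTS / "cgan" / "cgan.ckpt"
    if not ckpt_path.exists():
        raise SystemExit("run 02_train_cgan.py first (missing cgan.ckpt)")
    ckpt = CganCheckpoint.load(ckpt_path)

    arms = {"cgan": generate_volumes(ckpt, lat)}
    for mode, label in [("trainable", "autoencoder"),
                        ("pretrained_frozen", "pretrained_autoencoder")]:
        bc = train_baseline(records, baseline_config(seed, mode))
        arms[label] = baseline_generate(bc, lat)
    g0 = build_generator(cgan_config(seed))
    arms["untrained_generator"] = generate_volumes(
        CganCheckpoint(config=cgan_config(seed),
                       generator_state=g0.state_dict(),
                       discriminator_state={}, epoch=0), lat)

    rows = []
    for name, vols in arms.items():
        mean, spread = fid_with_uncertainty(real, vols, extractor,
                                            n_boot=20, seed=seed)
        rows.append({"model": name, "fid_mean": mean, "fid_spread": spread})
    df = pd.DataFrame(rows).sort_values("fid_mean").reset_index(drop=True)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "fid.csv", index=False)
    print(df.to_string(index=False))
    best = df.iloc[0]["model"]
    print(f"\nlowest Fréchet distance: {best}"
          + (" (adversarial training beats reconstruction baselines)"
             if best == "cgan" else ""))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
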