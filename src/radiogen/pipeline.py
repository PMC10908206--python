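"""Config-driven end-to-end experiment: simulate a phantom cohort, train
and cross-validate the conditional GAN, train autoencoder baselines,
generate cohort-wide volumes, and run the mutation-status and subtype
experiments, writing a consolidated report.

Every stage receives a seed derived from the single global seed by a
fixed counter scheme, logs its parameters, and writes its outputs to
files under the run directory so partial pipelines can be inspected.
Reruns with an identical config reproduce the consolidated report
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .baselines import BaselineConfig, BaselineSampler, train_baseline
from .cgan import (CganCheckpoint, CganConfig, CganSampler, build_generator,
                   train_cgan)
from .classify import CnnConfig
from .cohort import (CohortSpec, GeneSpec, intercept_for_prevalence,
                     simulate_cohort)
from .fid import crossval_fid, default_extractor, fid_with_uncertainty
from .metrics import ArmData, run_mutation_experiment, run_subtype_experiment
from .volio import split_train_test, write_latents, write_manifest

log = logging.getLogger("radiogen")


@dataclass
class GeneConfig:
    name: str
    prevalence: float = 0.5
    effect_size: float = 3.0
    effect_axis: int = 0


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/experiment"
    # cohort
    n_patients: int = 120
    latent_dim: int = 17
    volume_shape: tuple[int, int, int] = (8, 32, 32)
    genes: list[GeneConfig] = field(default_factory=lambda: [
        GeneConfig("TP53", 235 / 690, 3.0, 0),
        GeneConfig("PIK3CA", 247 / 690, 3.0, 1),
        GeneConfig("CDH1", 112 / 690, 3.0, 2),
    ])
    subtype_effect_size: float = 2.0
    lesion_effect_size: float = 2.0
    lesion_effect_axis: int = 0
    noise_sd: float = 0.05
    # cGAN
    cgan: dict = field(default_factory=dict)
    # baselines
    baseline: dict = field(default_factory=dict)
    # FID
    fid_folds: int = 2
    fid_boot: int = 20
    extractor_channels: tuple[int, ...] = (8, 16, 32)
    # classifiers
    classifier: dict = field(default_factory=dict)
    test_fraction: float = 0.2

    def cohort_spec(self) -> CohortSpec:
        ld = self.latent_dim
        gene_specs = []
        for g in self.genes:
            eff = np.zeros(ld)
            eff[g.effect_axis % ld] = g.effect_size
            gene_specs.append(GeneSpec(
                g.name, eff,
                intercept_for_prevalence(g.prevalence, abs(g.effect_size))))
        # subtype loadings graded along the lesion axis (the one direction
        # the phantom renders) plus a small private axis per class
        sub = np.zeros((5, ld))
        for k in range(5):
            sub[k, self.lesion_effect_axis % ld] = \
                (k - 2) * 0.75 * self.subtype_effect_size
            sub[k, (3 + k) % ld] += 0.4 * self.subtype_effect_size
        les = np.zeros(ld)
        les[self.lesion_effect_axis % ld] = self.lesion_effect_size
        return CohortSpec(n_patients=self.n_patients, latent_dim=ld,
                          volume_shape=tuple(self.volume_shape),
                          gene_specs=gene_specs, subtype_coeffs=sub,
                          lesion_effect=les, noise_sd=self.noise_sd,
                          seed=stage_seed(self.seed, 0))

    def cgan_config(self, seed: int) -> CganConfig:
        kw = dict(volume_shape=tuple(self.volume_shape),
                  cond_dim=self.latent_dim, batch_size=16,
                  lr_generator=1e-3, lr_discriminator=5e-4, epochs=60,
                  base_channels=8, recon_weight=10.0)
        kw.update(self.cgan)
        kw["seed"] = seed
        return CganConfig(**kw)

    def baseline_config(self, seed: int, mode: str) -> BaselineConfig:
        kw = dict(volume_shape=tuple(self.volume_shape),
                  cond_dim=self.latent_dim, epochs=60, learning_rate=1e-3,
                  batch_size=16, base_channels=8)
        kw.update(self.baseline)
        kw["seed"] = seed
        kw["encoder_mode"] = mode
        return BaselineConfig(**kw)

    def cnn_config(self, seed: int, n_outputs: int) -> CnnConfig:
        kw = dict(volume_shape=tuple(self.volume_shape), batch_size=16,
                  epochs=12, learning_rate=1e-3, plateau_patience=5)
        kw.update(self.classifier)
        kw["seed"] = seed
        kw["n_outputs"] = n_outputs
        return CnnConfig(**kw)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed fan-out (counter scheme)."""
    return int((int(global_seed) * 10007 + 31 * stage_index + 17) % (2 ** 31))


def validate_config(path: str | Path) -> tuple[ExperimentConfig | None, list[str]]:
    """Parse a YAML experiment config, returning all violations at once."""
    path = Path(path)
    if not path.exists():
        return None, [f"config file not found: {path}"]
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        return None, [f"YAML parse error in {path}: {exc}"]
    if not isinstance(raw, dict):
        return None, [f"{path}: top level must be a mapping"]

    errors: list[str] = []
    known = set(ExperimentConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"{key}: unknown configuration key")
    if "seed" not in raw:
        log.warning("config %s: missing seed; defaulting to 0", path)
    genes = raw.get("genes")
    if genes is not None:
        parsed_genes = []
        if not isinstance(genes, list):
            errors.append("genes: must be a list of mappings")
        else:
            for i, g in enumerate(genes):
                try:
                    parsed_genes.append(GeneConfig(**g))
                    if not 0 < parsed_genes[-1].prevalence < 1:
                        errors.append(f"genes[{i}].prevalence: must be in (0,1)")
                except TypeError as exc:
                    errors.append(f"genes[{i}]: {exc}")
        raw = {**raw, "genes": parsed_genes}
    for key, minval in [("n_patients", 0), ("latent_dim", 1), ("fid_folds", 2),
                        ("fid_boot", 1)]:
        if key in raw and raw[key] < minval:
            errors.append(f"{key}: must be >= {minval}, got {raw[key]}")
    if "noise_sd" in raw and raw["noise_sd"] < 0:
        errors.append("noise_sd: must be >= 0")
    if "test_fraction" in raw and not 0 < raw["test_fraction"] < 1:
        errors.append("test_fraction: must be in (0,1)")
    for sub, cls in [("cgan", CganConfig), ("baseline", BaselineConfig),
                     ("classifier", CnnConfig)]:
        if sub in raw:
            if not isinstance(raw[sub], dict):
                errors.append(f"{sub}: must be a mapping")
                continue
            for k, v in raw[sub].items():
                if k not in cls.__dataclass_fields__:
                    errors.append(f"{sub}.{k}: unknown key")
                elif k == "epochs" and v < 1:
                    errors.append(f"{sub}.epochs: must be >= 1, got {v}")
                elif k.startswith("lr") or k.endswith("rate"):
                    if v <= 0:
                        errors.append(f"{sub}.{k}: must be > 0, got {v}")
    if errors:
        return None, errors
    if "volume_shape" in raw:
        raw = {**raw, "volume_shape": tuple(raw["volume_shape"])}
    try:
        cfg = ExperimentConfig(**raw)
        cfg.cohort_spec()          # triggers cohort invariant checks
        cfg.cgan_config(0)
        cfg.cnn_config(0, 1)
    except (TypeError, ValueError) as exc:
        return None, [str(exc)]
    return cfg, []


def _json_bytes(obj) -> bytes:
    return json.dumps(obj, indent=2, sort_keys=True,
                      default=lambda o: float(o) if isinstance(o, np.floating)
                      else int(o) if isinstance(o, np.integer)
                      else o.tolist() if isinstance(o, np.ndarray)
                      else str(o)).encode()


def run_all(config: ExperimentConfig) -> Path:
    """Execute the full study design; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.StreamHandler(sys.stderr)
    fhandler = logging.FileHandler(out / "run.log", mode="w")
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    log.addHandler(fhandler)
    try:
        return _run_all(config, out)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        log.removeHandler(fhandler)
        fhandler.close()


def _stage(name):
    log.info("stage: %s", name)


def _run_all(config: ExperimentConfig, out: Path) -> Path:
    report: dict = {"config": {**asdict(config),
                               "volume_shape": list(config.volume_shape)}}

    _stage("simulate")
    spec = config.cohort_spec()
    records = simulate_cohort(spec)
    if not records:
        raise ValueError("empty cohort; n_patients must be > 0 for run_all")
    write_manifest(records, out / "volumes", out / "cohort.csv")
    write_latents(records, out / "latents.csv")

    _stage("split")
    gene0 = config.genes[0].name
    train_recs, test_recs = split_train_test(
        records, test_fraction=config.test_fraction,
        stratify_key=lambda r: r.mutation_labels[gene0],
        seed=stage_seed(config.seed, 1))

    _stage("train-cgan (k-fold FID)")
    extractor = default_extractor(tuple(config.volume_shape),
                                  channels=tuple(config.extractor_channels))

    def trainer(recs, fold_seed):
        ckpt = train_cgan(recs, config.cgan_config(fold_seed))
        return CganSampler(ckpt)

    cv = crossval_fid(train_recs, trainer, k=config.fid_folds,
                      extractor=extractor, n_boot=config.fid_boot,
                      seed=stage_seed(config.seed, 2))
    cv.table.to_csv(out / "cgan_fid_folds.csv", index=False)
    best_ckpt: CganCheckpoint = cv.best_artifact.checkpoint
    best_ckpt.save(out / "cgan_best.ckpt")
    np.savetxt(out / "cgan_best_losses.csv",
               np.column_stack([best_ckpt.g_losses, best_ckpt.d_losses]),
               delimiter=",", header="g_loss,d_loss", comments="")

    _stage("train-baselines")
    test_lat = np.stack([r.latent for r in test_recs])
    test_vols = [r.volumes[0] for r in test_recs]
    baselines_fid = {}
    for mode, label in [("trainable", "autoencoder"),
                        ("pretrained_frozen", "pretrained_autoencoder")]:
        bc = train_baseline(train_recs,
                            config.baseline_config(stage_seed(config.seed, 3), mode))
        bc.save(out / f"{label}.ckpt")
        fake = BaselineSampler(bc).generate(test_lat)
        baselines_fid[label] = fid_with_uncertainty(
            test_vols, fake, extractor, n_boot=config.fid_boot,
            seed=stage_seed(config.seed, 4))

    gan_cfg = config.cgan_config(stage_seed(config.seed, 2))
    untrained = build_generator(gan_cfg)
    unt_ckpt = CganCheckpoint(config=gan_cfg,
                              generator_state=untrained.state_dict(),
                              discriminator_state={}, epoch=0)
    fake = CganSampler(unt_ckpt).generate(test_lat)
    baselines_fid["untrained_generator"] = fid_with_uncertainty(
        test_vols, fake, extractor, n_boot=config.fid_boot,
        seed=stage_seed(config.seed, 4))
    fake = CganSampler(best_ckpt).generate(test_lat)
    baselines_fid["cgan"] = fid_with_uncertainty(
        test_vols, fake, extractor, n_boot=config.fid_boot,
        seed=stage_seed(config.seed, 4))
    report["fid"] = {
        "fold_table": cv.table.to_dict(orient="records"),
        "best_fold": cv.best_fold,
        "test_set": {k: {"mean": v[0], "spread": v[1]}
                     for k, v in sorted(baselines_fid.items())},
    }

    _stage("generate cohort-wide volumes")
    all_lat = np.stack([r.latent for r in records])
    gen_vols = CganSampler(best_ckpt).generate(all_lat)

    _stage("mutation experiments")
    real_vols = [r.volumes[0] for r in records]
    report["mutation"] = {}
    for gi, gene in enumerate(config.genes):
        labels = np.array([r.mutation_labels[gene.name] for r in records])
        arms = {
            "real": ArmData(volumes=real_vols, labels=labels),
            "generated": ArmData(volumes=gen_vols, labels=labels),
            "combined": ArmData(volumes=real_vols + gen_vols,
                                labels=np.concatenate([labels, labels])),
            "omic-baseline": ArmData(labels=labels, latents=all_lat),
        }
        reports = run_mutation_experiment(
            arms, gene.name,
            config.cnn_config(stage_seed(config.seed, 5 + gi), 1),
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, 5 + gi))
        report["mutation"][gene.name] = {
            arm: rep.to_dict() for arm, rep in sorted(reports.items())}

    _stage("subtype experiment")
    subtypes = np.array([r.subtype for r in records])
    arms = {
        "generated": ArmData(volumes=gen_vols, labels=subtypes),
        "combined": ArmData(volumes=real_vols + gen_vols,
                            labels=np.concatenate([subtypes, subtypes])),
    }
    reports = run_subtype_experiment(
        arms, config.cnn_config(stage_seed(config.seed, 9), 5),
        test_fraction=config.test_fraction, seed=stage_seed(config.seed, 9))
    report["subtype"] = {arm: rep.to_dict() for arm, rep in sorted(reports.items())}

    _stage("consolidated report")
    (out / "report.json").write_bytes(_json_bytes(report))
    _write_markdown(report, out / "report.md")
    _write_run_manifest(out)
    return out


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Experiment report", "", "## FID (test set)", ""]
    lines.append("| model | FID mean | spread |")
    lines.append("|---|---|---|")
    for name, v in report["fid"]["test_set"].items():
        lines.append(f"| {name} | {v['mean']:.4f} | {v['spread']:.4f} |")
    lines += ["", "## Mutation status (ROC-AUC / PR-AUC)", "",
              "| gene | arm | ROC-AUC | PR-AUC |", "|---|---|---|---|"]
    for gene, arms in report["mutation"].items():
        for arm, rep in arms.items():
            lines.append(f"| {gene} | {arm} | {rep['roc_auc']:.4f} | "
                         f"{rep['pr_auc']:.4f} |")
    lines += ["", "## Subtype (macro P / R / F1)", "",
              "| arm | precision | recall | F1 |", "|---|---|---|---|"]
    for arm, rep in report["subtype"].items():
        lines.append(f"| {arm} | {rep['precision']:.4f} | {rep['recall']:.4f} | "
                     f"{rep['f1']:.4f} |")
    path.write_text("\n".join(lines) + "\n")


def _write_run_manifest(out: Path) -> None:
    entries = []
    for p in sorted(out.rglob("*")):
        if p.is_dir() or p.name == "run_manifest.json":
            continue
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        entries.append({"path": str(p.relative_to(out)),
                        "bytes": p.stat().st_size, "sha256": digest})
    (out / "run_manifest.json").write_bytes(_json_bytes({"artifacts": entries}))
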