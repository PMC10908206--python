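"""Volume and table I/O: read/write/resize/normalize 3D volumes, cohort
manifests, and reproducible train/test splits and CV folds.

Volumes follow the (slice, row, col) axis convention with the slice axis
first; the pipeline's working resolution is 32 x 128 x 128.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import KFold


@dataclass
class Volume3D:
    """One 3D intensity grid plus its declared intensity range."""

    data: np.ndarray
    intensity_range: tuple[float, float] = (0.0, 1.0)
    view: str = "side"          # metadata only: side | top-down

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"volume shape entries must be >= 1, got {self.data.shape}")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError(f"invalid intensity range {self.intensity_range}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def rescaled(self, target: tuple[float, float]) -> "Volume3D":
        """Linearly map the declared range onto ``target``."""
        lo, hi = self.intensity_range
        a, b = target
        data = (self.data.astype(np.float32) - lo) / (hi - lo) * (b - a) + a
        return Volume3D(data, intensity_range=target, view=self.view)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or a compressed archive (.npz)."""
    import nibabel as nib

    path = Path(path)
    name = path.name
    if name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                              affine=np.eye(4))
        img.header["descrip"] = f"range {volume.intensity_range}"
        nib.save(img, str(path))
    elif name.endswith(".npz"):
        np.savez_compressed(path, data=volume.data.astype(np.float32),
                            intensity_range=np.asarray(volume.intensity_range),
                            view=np.asarray(volume.view))
    else:
        raise IOError(f"unsupported volume format for {path}")


def read_volume(path: str | Path,
                intensity_range: tuple[float, float] | None = None) -> Volume3D:
    """Read a NIfTI or .npz volume; errors name the offending path."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    name = path.name
    try:
        if name.endswith((".nii", ".nii.gz")):
            data = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float32)
            rng = intensity_range or (0.0, 1.0)
            return Volume3D(data, intensity_range=rng)
        if name.endswith(".npz"):
            with np.load(path, allow_pickle=False) as z:
                rng = tuple(float(v) for v in z["intensity_range"]) \
                    if "intensity_range" in z else (intensity_range or (0.0, 1.0))
                view = str(z["view"]) if "view" in z else "side"
                return Volume3D(z["data"].astype(np.float32),
                                intensity_range=rng, view=view)
    except (OSError, KeyError, ValueError) as exc:
        raise IOError(f"failed to read volume {path}: {exc}") from exc
    raise IOError(f"unsupported volume format for {path}")


def resize_volume(volume: Volume3D,
                  target_shape: tuple[int, int, int] = (32, 128, 128)) -> Volume3D:
    """Trilinear resize to ``target_shape``; a constant maps to itself."""
    if any(s < 1 for s in target_shape):
        raise ValueError(f"target shape entries must be >= 1, got {target_shape}")
    if tuple(target_shape) == volume.shape:
        return Volume3D(volume.data.astype(np.float32, copy=True),
                        volume.intensity_range, volume.view)
    out = _sk_resize(volume.data.astype(np.float64), target_shape, order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return Volume3D(out.astype(np.float32), volume.intensity_range, volume.view)


def normalize_intensity(volume: Volume3D, mode: str = "minmax") -> Volume3D:
    """Normalize to [0,1] ("minmax") or [-1,1] ("tanh").

    A constant volume maps to the midpoint of the target range.
    """
    if mode == "minmax":
        lo_t, hi_t = 0.0, 1.0
    elif mode == "tanh":
        lo_t, hi_t = -1.0, 1.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    data = volume.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi - lo < 1e-12:
        out = np.full_like(data, 0.5 * (lo_t + hi_t))
    else:
        out = (data - lo) / (hi - lo) * (hi_t - lo_t) + lo_t
    return Volume3D(out, intensity_range=(lo_t, hi_t), view=volume.view)


def split_train_test(records: list, test_fraction: float = 0.2,
                     stratify_key=None, seed: int = 0) -> tuple[list, list]:
    """Stratified train/test split.

    Per-stratum test counts are round(stratum_size * fraction), then
    adjusted (largest strata first) so the total equals
    round(n * fraction).  Strata with < 2 members go to train with a
    warning.  ``stratify_key`` maps a record to its stratum label; None
    puts everything in one stratum.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    n = len(records)
    rng = np.random.default_rng(seed)
    key = stratify_key if stratify_key is not None else (lambda r: 0)
    strata: dict = {}
    for i, r in enumerate(records):
        strata.setdefault(key(r), []).append(i)

    eligible = {}
    forced_train = []
    for label, idx in sorted(strata.items(), key=lambda kv: str(kv[0])):
        if len(idx) < 2:
            warnings.warn(
                f"stratum {label!r} has fewer than 2 members; placed in train")
            forced_train.extend(idx)
        else:
            eligible[label] = idx

    n_eligible = sum(len(v) for v in eligible.values())
    total_test = int(round(n * test_fraction))
    total_test = min(total_test, n_eligible)
    counts = {lab: int(round(len(idx) * test_fraction))
              for lab, idx in eligible.items()}
    # adjust to the exact total, largest strata first for minimal distortion
    order = sorted(eligible, key=lambda lab: -len(eligible[lab]))
    k = 0
    while sum(counts.values()) != total_test and order:
        lab = order[k % len(order)]
        delta = 1 if sum(counts.values()) < total_test else -1
        new = counts[lab] + delta
        if 0 <= new <= len(eligible[lab]):
            counts[lab] = new
        k += 1

    test_idx: list[int] = []
    for lab, idx in sorted(eligible.items(), key=lambda kv: str(kv[0])):
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[j] for j in perm[:counts[lab]])
    test_set = set(test_idx)
    train = [records[i] for i in range(n) if i not in test_set]
    test = [records[i] for i in sorted(test_set)]
    return train, test


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """k shuffled disjoint folds of range(n); sizes differ by at most 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n))]


# ---------------------------------------------------------------------------
# cohort tables

def write_manifest(records: list, volume_dir: str | Path,
                   manifest_path: str | Path, fmt: str = "npz") -> pd.DataFrame:
    """Write each record's volumes plus a manifest CSV referencing them."""
    volume_dir = Path(volume_dir)
    volume_dir.mkdir(parents=True, exist_ok=True)
    genes = sorted({g for r in records for g in r.mutation_labels})
    rows = []
    for r in records:
        paths = []
        for j, vol in enumerate(r.volumes):
            p = volume_dir / f"{r.patient_id}_{j}.{fmt}"
            write_volume(vol, p)
            paths.append(str(p))
        row = {"patient_id": r.patient_id, "subtype": r.subtype,
               "provenance": r.provenance, "volume_paths": ";".join(paths)}
        for g in genes:
            row[g] = r.mutation_labels[g]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(manifest_path, index=False)
    return df


def write_latents(records: list, path: str | Path) -> pd.DataFrame:
    d = len(records[0].latent) if records else 0
    df = pd.DataFrame(
        [{"patient_id": r.patient_id,
          **{f"latent_{j}": r.latent[j] for j in range(d)}} for r in records])
    df.to_csv(path, index=False)
    return df


def read_latents(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("latent_")]
    return list(df["patient_id"].astype(str)), df[cols].to_numpy(dtype=float)
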