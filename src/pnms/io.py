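"""NIfTI and configuration I/O.

Volumes travel as NIfTI-1 files with the voxel size carried in the
header; run configuration round-trips through YAML so every analysis
directory contains the resolved configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .volume import Volume

__all__ = ["read_volume", "write_volume", "save_subject", "RunConfig"]


def read_volume(path: str | Path, symmetric_space: bool = True) -> Volume:
    """Read a 3D NIfTI-1 volume; voxel sizes come from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume(np.asarray(data, dtype=float), tuple(float(z) for z in zooms),
                  symmetric_space=symmetric_space)


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (float32 data, voxel sizes in the header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*vol.voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_zooms(vol.voxel_mm)
    nib.save(img, str(path))
    return path


def save_subject(subject, out_dir: str | Path) -> Path:
    """Write one phantom subject: one NIfTI per map plus a truth sidecar."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    maps = {
        "pet": subject.pet,
        "gm_density": subject.gm_density,
        "flair": subject.flair,
        "tissue_gm": subject.tissue_gm,
        "tissue_wm": subject.tissue_wm,
        "tissue_csf": subject.tissue_csf,
        "roi_labels": subject.roi_labels,
        "brain_mask": subject.brain_mask,
        "ablation_mask": subject.ablation_mask,
    }
    for name, vol in maps.items():
        write_volume(vol, out / f"{name}.nii")
    sidecar = {
        "subject_id": subject.subject_id,
        "ez_side": subject.ez_side,
        "outcome": subject.outcome,
        "truth": subject.truth,
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run."""

    seed: int = 0
    n_subjects: int = 30
    out_dir: str = "pnms_run"
    # preprocessing
    fwhm_mm: float = 6.0
    pvc: bool = True
    eps: float = 1e-6
    gm_floor: float = 0.3
    ai_shift: str = "minmax"          # AI computed on positively shifted images
    order: tuple[str, ...] = ("smooth", "pvc", "zscore", "ai")
    normalization: str = "zscore"      # or "proportional"
    # pNMS / statistics
    pnms_threshold: float = -0.06
    knot_probs: tuple[float, ...] = (0.10, 0.50, 0.90)
    or_scale_ai: float = 0.01          # OR reported per 0.01 AI units
    # interpretation
    cv_k: int = 5
    cv_iterations: int = 1000
    # outputs
    write_volumes: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["order"] = list(self.order)
        d["knot_probs"] = list(self.knot_probs)
        return d

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "order" in kwargs:
            kwargs["order"] = tuple(kwargs["order"])
        if "knot_probs" in kwargs:
            kwargs["knot_probs"] = tuple(kwargs["knot_probs"])
        return cls(**kwargs)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        side-output flags excluded, so reruns into different directories
        compare equal)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_volumes", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
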