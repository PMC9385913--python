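"""NIfTI and tabular I/O, run configuration, and run logging.

Conventions (asserted in the I/O tests): voxel arrays are (x, y, z) in
NIfTI ijk order with 0-based indices; masks are written as uint8 0/1;
voxel spacing is carried in the NIfTI header zooms.  Machine-readable
reports are JSON, per-sample tables are CSV, run configuration is YAML —
one format per role.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from contourqa.core import Volume
from contourqa.datapipe import AugmentConfig
from contourqa.metrics import FailureRuleConfig
from contourqa.phantom import ClinicalRecord, PhantomCase, PhantomConfig
from contourqa.qa_net import NetConfig
from contourqa.train_eval import TrainConfig

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# volumes and masks
# ---------------------------------------------------------------------------


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(vol: Volume, path) -> None:
    # float64 on disk so a write-read round trip is bit-identical
    nib.save(nib.Nifti1Image(vol.data.astype(np.float64), _affine(vol.spacing)), str(path))


def read_volume(path) -> Volume:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data, spacing)


def write_mask(mask: np.ndarray, spacing: Sequence[float], path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing)), str(path))


def read_mask(path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI mask {path}: {exc}") from exc
    uniq = np.unique(data)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{path}: mask is not binary (values {uniq[:10]})")
    return data.astype(bool)


# ---------------------------------------------------------------------------
# cohort persistence
# ---------------------------------------------------------------------------


def save_cohort(cohort: Sequence[PhantomCase], out_dir) -> Path:
    """Write a cohort as NIfTI files plus a manifest CSV (one row/contour)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cohort:
        img_path = out_dir / f"{case.case_id}_image.nii.gz"
        gt_path = out_dir / f"{case.case_id}_gt.nii.gz"
        write_volume(case.image, img_path)
        write_mask(case.gt, case.image.spacing, gt_path)
        for j, (mask, true_dice) in enumerate(case.auto_contours):
            con_path = out_dir / f"{case.case_id}_contour{j}.nii.gz"
            write_mask(mask, case.image.spacing, con_path)
            c = case.clinical
            rows.append({
                "case_id": case.case_id,
                "contour_index": j,
                "image": img_path.name,
                "gt": gt_path.name,
                "contour": con_path.name,
                "true_dice": true_dice,
                "age": c.age,
                "prostate_volume": c.prostate_volume,
                "isup_grade": c.isup_grade,
                "pirads": c.pirads,
                "ipsa": c.ipsa,
                "risk_class": c.risk_class,
                "target_dice": c.target_dice,
            })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(cohort_dir) -> list[PhantomCase]:
    """Read a cohort written by :func:`save_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = cohort_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {cohort_dir}")
    df = pd.read_csv(manifest)
    cases: list[PhantomCase] = []
    for cid, grp in df.groupby("case_id", sort=True):
        first = grp.iloc[0]
        image = read_volume(cohort_dir / first["image"])
        gt = read_mask(cohort_dir / first["gt"])
        clinical = ClinicalRecord(
            age=float(first["age"]),
            prostate_volume=float(first["prostate_volume"]),
            isup_grade=int(first["isup_grade"]),
            pirads=int(first["pirads"]),
            ipsa=float(first["ipsa"]),
            risk_class=str(first["risk_class"]),
            target_dice=float(first["target_dice"]),
        )
        case = PhantomCase(case_id=str(cid), image=image, gt=gt, clinical=clinical)
        for _, row in grp.sort_values("contour_index").iterrows():
            mask = read_mask(cohort_dir / row["contour"])
            case.auto_contours.append((mask, float(row["true_dice"])))
        cases.append(case)
    return cases


def dump_samples(samples, out_dir, spacing=(1.0, 1.0, 1.0)) -> Path:
    """Inspection cache: write samples as NIfTI pairs plus a JSONL audit.

    Each sample's image and contour channels become
    ``sample<k>_image.nii.gz`` / ``sample<k>_contour.nii.gz``, and one
    JSONL line records its target, flags and provenance metadata (e.g. the
    sampled augmentation parameters).  Returns the JSONL path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit = out_dir / "samples.jsonl"
    with audit.open("w") as fh:
        for k, s in enumerate(samples):
            write_volume(Volume(s.tensor[..., 0], spacing),
                         out_dir / f"sample{k}_image.nii.gz")
            write_mask(s.tensor[..., 1].astype(bool), spacing,
                       out_dir / f"sample{k}_contour.nii.gz")
            fh.write(json.dumps({
                "index": k,
                "case_id": s.case_id,
                "target": s.target,
                "is_fake": s.is_fake,
                "meta": s.meta,
            }) + "\n")
    return audit


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def derive_seed(master: int, label: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Top-level configuration tying the pipeline together.

    Every sub-seed is derived from ``seed`` by :func:`derive_seed`; no
    hidden global RNG state is consulted anywhere.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    failure_rule: FailureRuleConfig = field(default_factory=FailureRuleConfig)
    output_dir: str = "runs"
    seed: int = 0

    def with_derived_seeds(self) -> "RunConfig":
        return RunConfig(
            phantom=dataclasses.replace(self.phantom, seed=derive_seed(self.seed, "phantom")),
            augment=dataclasses.replace(self.augment, seed=derive_seed(self.seed, "augment")),
            net=dataclasses.replace(self.net, seed=derive_seed(self.seed, "net")),
            train=dataclasses.replace(self.train, seed=derive_seed(self.seed, "train")),
            failure_rule=self.failure_rule,
            output_dir=self.output_dir,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "augment": dataclasses.asdict(self.augment),
            "net": self.net.to_dict(),
            "train": dataclasses.asdict(self.train),
            "failure_rule": dataclasses.asdict(self.failure_rule),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(dd, *keys):
            for k in keys:
                if k in dd and isinstance(dd[k], list):
                    dd[k] = tuple(dd[k])
            return dd

        return cls(
            phantom=PhantomConfig(**tup(dict(d.get("phantom", {})),
                                        "shape", "organ_radius_range",
                                        "organ_z_radius_range", "spacing")),
            augment=AugmentConfig(**tup(dict(d.get("augment", {})), "scale_range")),
            net=NetConfig.from_dict(d.get("net", NetConfig().to_dict())),
            train=TrainConfig(**d.get("train", {})),
            failure_rule=FailureRuleConfig(**d.get("failure_rule", {})),
            output_dir=d.get("output_dir", "runs"),
            seed=d.get("seed", 0),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# reports and run logs
# ---------------------------------------------------------------------------


def write_json_report(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": REPORT_SCHEMA_VERSION, **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_pairs_csv(rows: list[dict], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


class RunLogger:
    """Logs resolved config, seeds, library versions and wall time."""

    def __init__(self, command: str, out_dir, config: Optional[dict] = None):
        self.command = command
        self.out_dir = Path(out_dir)
        self.config = config or {}
        self.t0 = time.time()

    def finish(self, **extra) -> Path:
        import contourqa

        entry = {
            "command": self.command,
            "config": self.config,
            "versions": {
                "contourqa": contourqa.__version__,
                "numpy": np.__version__,
                "python": platform.python_version(),
            },
            "wall_time_s": round(time.time() - self.t0, 3),
            **extra,
        }
        self.out_dir.mkdir(parents=True, exist_ok=True)
        path = self.out_dir / f"{self.command}_log.json"
        path.write_text(json.dumps(entry, indent=2, sort_keys=True, default=str))
        return path
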