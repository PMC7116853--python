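"""Data containers, dataset manifests and NIfTI I/O.

A *subject* couples a multi-modal image with whatever labels its dataset
provides: tissue-only (control datasets), lesion-only (lesion datasets) or
the full joint map (fully-annotated test sets).  Manifests describe a cohort
of subjects, each with an available-modality mask and a domain tag, and can
live purely in memory (synthetic cohorts) or be written to / read from disk
as a CSV plus NIfTI volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .taxonomy import ClassTaxonomy

__all__ = ["MultiModalImage", "JointLabelMap", "Subject", "DatasetManifest",
           "LABEL_KINDS", "save_nifti", "load_nifti"]

LABEL_KINDS = ("tissue", "lesion", "joint")


@dataclass
class MultiModalImage:
    """A voxel grid with a declared, possibly partial, set of modality channels.

    ``channels`` has shape ``(M, *spatial)``; ``available`` marks which of the
    M modalities are genuinely present.  Channels of absent modalities carry
    no information (they are zeroed at construction time by the generator).
    """

    channels: np.ndarray
    available: np.ndarray
    spacing: tuple[float, ...] = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.available = np.asarray(self.available, dtype=bool)
        if self.available.shape != (self.channels.shape[0],):
            raise ValueError("available mask must have one entry per modality")
        if self.spacing is None:
            self.spacing = (1.0,) * (self.channels.ndim - 1)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def num_modalities(self) -> int:
        return self.channels.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.channels.shape[1:]


@dataclass
class JointLabelMap:
    """Integer per-voxel labels over ``{0} ∪ C_T ∪ C_L``."""

    labels: np.ndarray
    taxonomy: ClassTaxonomy

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind not in "iu":
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label map must be integer-valued")
            self.labels = self.labels.astype(np.int32)
        present = set(np.unique(self.labels).tolist())
        allowed = set(self.taxonomy.all_classes)
        if not present <= allowed:
            raise ValueError(
                f"labels {sorted(present - allowed)} outside taxonomy {sorted(allowed)}")


@dataclass
class Subject:
    """One cohort member: image, exposed labels and bookkeeping tags."""

    subject_id: str
    image: MultiModalImage
    labels: np.ndarray
    label_kind: str
    domain: str

    def __post_init__(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"label kind must be one of {LABEL_KINDS}")


@dataclass
class DatasetManifest:
    """A cohort of subjects sharing a dataset role.

    ``sidecar_joint`` optionally holds exact joint ground-truth label maps
    (keyed by subject id) that are *not* exposed to training — evaluation
    reads them to score joint predictions on cohorts whose training labels
    are task-specific.
    """

    role: str
    subjects: list[Subject] = field(default_factory=list)
    taxonomy: ClassTaxonomy | None = None
    sidecar_joint: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def validate(self) -> None:
        """Check each record's label kind against its declared role."""
        expected = {"control": "tissue", "pseudo": "tissue",
                    "lesion": "lesion", "test": "joint"}
        want = expected.get(self.role)
        for s in self.subjects:
            if want is not None and s.label_kind != want:
                raise ValueError(
                    f"subject {s.subject_id}: label kind {s.label_kind!r} "
                    f"inconsistent with role {self.role!r}")

    def subset(self, indices) -> "DatasetManifest":
        subs = [self.subjects[i] for i in indices]
        side = {s.subject_id: self.sidecar_joint[s.subject_id]
                for s in subs if s.subject_id in self.sidecar_joint}
        return DatasetManifest(self.role, subs, self.taxonomy, side)

    # -- disk round trip ---------------------------------------------------

    def write(self, out_dir: str | Path) -> Path:
        """Write NIfTI volumes and a manifest CSV (+ JSON sidecar) to a
        directory; returns the CSV path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.subjects:
            spacing = s.image.spacing
            mod_paths = []
            for m in range(s.image.num_modalities):
                p = out_dir / f"{s.subject_id}_mod{m}.nii.gz"
                save_nifti(s.image.channels[m], p, spacing)
                mod_paths.append(p.name)
            lab_path = out_dir / f"{s.subject_id}_labels.nii.gz"
            save_nifti(s.labels.astype(np.int16), lab_path, spacing)
            row = {
                "subject_id": s.subject_id,
                "modality_paths": ";".join(mod_paths),
                "available_mask": "".join(
                    "1" if a else "0" for a in s.image.available),
                "label_path": lab_path.name,
                "label_kind": s.label_kind,
                "domain": s.domain,
                "spacing": ";".join(str(x) for x in spacing),
            }
            if s.subject_id in self.sidecar_joint:
                jp = out_dir / f"{s.subject_id}_joint_gt.nii.gz"
                save_nifti(self.sidecar_joint[s.subject_id].astype(np.int16),
                           jp, spacing)
                row["joint_gt_path"] = jp.name
            rows.append(row)
        csv_path = out_dir / f"manifest_{self.role}.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        meta = {"role": self.role}
        if self.taxonomy is not None:
            meta["tissue_classes"] = list(self.taxonomy.tissue_classes)
            meta["lesion_classes"] = list(self.taxonomy.lesion_classes)
        with open(csv_path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)
        return csv_path

    @classmethod
    def read(cls, csv_path: str | Path) -> "DatasetManifest":
        csv_path = Path(csv_path)
        base = csv_path.parent
        with open(csv_path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        taxonomy = None
        if "tissue_classes" in meta:
            taxonomy = ClassTaxonomy(tuple(meta["tissue_classes"]),
                                     tuple(meta["lesion_classes"]))
        df = pd.read_csv(csv_path)
        subjects, sidecar = [], {}
        for _, row in df.iterrows():
            spacing = tuple(float(x) for x in str(row["spacing"]).split(";"))
            chans = np.stack([load_nifti(base / p)
                              for p in row["modality_paths"].split(";")])
            avail = np.array([c == "1" for c in str(row["available_mask"])])
            img = MultiModalImage(chans, avail, spacing)
            labels = load_nifti(base / row["label_path"]).astype(np.int32)
            subjects.append(Subject(str(row["subject_id"]), img, labels,
                                    row["label_kind"], row["domain"]))
            jp = row.get("joint_gt_path")
            if isinstance(jp, str) and jp:
                sidecar[str(row["subject_id"])] = load_nifti(
                    base / jp).astype(np.int32)
        return cls(meta["role"], subjects, taxonomy, sidecar)


def save_nifti(array: np.ndarray, path: str | Path,
               spacing: tuple[float, ...] | None = None) -> None:
    arr = np.asarray(array)
    affine = np.eye(4)
    if spacing is not None:
        for i, s in enumerate(spacing[:3]):
            affine[i, i] = s
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)
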