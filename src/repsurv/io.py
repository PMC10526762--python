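"""Study manifests and NIfTI input/output.

A cohort is described by a manifest CSV with one row per subject:
``subject_id, image, labels`` (paths to the intensity and label-mask
NIfTI files) plus the clinical fields ``time_days, event, rep_label`` and
optionally ``mgmt`` / ``idh`` status. Label codes follow the BraTS
convention {0, 1, 2, 4}; categorical vocabularies are validated at load.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .texture import LabeledStudy

log = logging.getLogger(__name__)

__all__ = ["load_manifest", "load_study", "ALLOWED_LABELS"]

ALLOWED_LABELS = {0, 1, 2, 4}
MGMT_VOCAB = {"hypermethylated", "unmethylated", "indeterminate"}
IDH_VOCAB = {"wild type", "mutant", "indeterminate"}
_AFFINE_TOL = 1e-4


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    df = pd.read_csv(path)
    required = {"subject_id", "image", "labels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = Path(path).parent
    for col in ("image", "labels"):
        df[col] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df[col]]
        absent = [p for p in df[col] if not Path(p).exists()]
        if absent:
            raise FileNotFoundError(f"manifest {col} path(s) not found: {absent[:3]}")
    for col, vocab in (("mgmt", MGMT_VOCAB), ("idh", IDH_VOCAB)):
        if col in df.columns:
            bad = set(df[col].dropna()) - vocab
            if bad:
                raise ValueError(f"{col} values outside vocabulary {sorted(vocab)}: {sorted(bad)}")
    return df


def load_study(row) -> LabeledStudy:
    """Load one subject's intensity + label NIfTI pair as a LabeledStudy."""
    img = nib.load(row["image"])
    lab = nib.load(row["labels"])
    sid = str(row.get("subject_id", ""))
    if img.shape != lab.shape:
        raise ValueError(f"subject {sid}: image shape {img.shape} != labels shape {lab.shape}")
    if not np.allclose(img.affine, lab.affine, atol=_AFFINE_TOL):
        raise ValueError(f"subject {sid}: image/label affines disagree beyond tolerance")
    intensity = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(lab.dataobj).astype(np.int32)
    codes = set(np.unique(labels).tolist())
    if not codes <= ALLOWED_LABELS:
        raise ValueError(f"subject {sid}: label codes {sorted(codes - ALLOWED_LABELS)} "
                         f"not in allowed set {sorted(ALLOWED_LABELS)}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabeledStudy(intensity=intensity, labels=labels, spacing=spacing, subject_id=sid)
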