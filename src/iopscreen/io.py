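"""File formats: PNG cohorts, clinical CSV tables, optional DICOM ingestion.

Canonical on-disk cohort layout: a directory of 8-bit grayscale PNGs plus a
comma-separated clinical table (header required, UTF-8, '.' decimal) with
one row per sample: the eight clinical attributes, the binary label, the
patient id and the image path (relative to the table's directory).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import ATTRIBUTES, ClinicalRecord, PhantomSample

__all__ = [
    "write_cohort",
    "read_image_table",
    "load_image",
    "save_image",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = (*ATTRIBUTES, "label", "patient_id", "path")


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)

def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF; DICOM if pydicom is available)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _load_dicom(path)
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def _load_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as e:  # pragma: no cover
        raise ImportError("DICOM support requires the 'dicom' extra (pydicom)") from e
    ds = pydicom.dcmread(path)
    for tag in ("PatientName", "PatientID", "PatientBirthDate"):
        v = getattr(ds, tag, "")
        if v not in ("", None, "Anonymous", "ANON"):
            raise ValueError(f"DICOM file {path.name} is not anonymized ({tag} set)")
    arr = ds.pixel_array.astype(float)
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)


def write_cohort(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write PNG images and the clinical CSV; returns the table path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        rel = f"images/sample_{i:05d}.png"
        save_image(s.image, out_dir / rel)
        row = {a: getattr(s.record, a) for a in ATTRIBUTES}
        row.update(label=s.label, patient_id=s.patient_id, path=rel)
        rows.append(row)
    table = out_dir / "clinical.csv"
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(table, index=False)
    return table


@dataclasses.dataclass
class LoadedDataset:
    images: np.ndarray          # (n, H, W) in [0, 1]
    records: list[ClinicalRecord]
    labels: np.ndarray
    patient_ids: np.ndarray
    table: pd.DataFrame
    failures: list[str]         # paths that could not be read


def read_image_table(image_dir: str | Path, clinical_csv: str | Path) -> LoadedDataset:
    """Load an image+table dataset, validating the schema.

    Rows whose image file is missing or unreadable are dropped and reported
    in ``failures``; a missing column raises a schema error naming it.
    """
    image_dir = Path(image_dir)
    df = pd.read_csv(clinical_csv)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing column(s): {missing}")
    images, records, labels, pids, keep, failures = [], [], [], [], [], []
    for i, row in df.iterrows():
        p = image_dir / str(row["path"])
        try:
            img = load_image(p)
        except (OSError, ValueError) as e:
            failures.append(f"{row['path']}: {e.__class__.__name__}")
            continue
        images.append(img)
        records.append(ClinicalRecord(**{a: float(row[a]) for a in ATTRIBUTES}))
        labels.append(str(row["label"]))
        pids.append(row["patient_id"])
        keep.append(i)
    if not images:
        raise ValueError("no readable images in dataset")
    return LoadedDataset(
        np.stack(images), records, np.array(labels), np.array(pids),
        df.iloc[keep].reset_index(drop=True), failures,
    )
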