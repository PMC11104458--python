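"""Dataset and artifact I/O.

A dataset bundle is an HDF5 tracing store (``/tracings``: N x T x 12 float32
mV, ``/exam_id``: int64 — the public CODE-subset layout, sample axis on disk,
leads last) plus a CSV metadata table and a JSON manifest recording counts,
sampling rate, lead order and a content hash.  In memory, tracings are
transposed to (leads, samples).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .leads import ABNORMALITIES, LEAD_NAMES
from .synthgen import ECGRecord, SubjectRecord

__all__ = ["DatasetBundle", "write_dataset", "read_dataset",
           "export_heatmaps", "import_heatmaps", "METADATA_COLUMNS"]

METADATA_COLUMNS = ("exam_id", "age", "is_male", "hypertension", *ABNORMALITIES,
                    "follow_up_years", "death")


@dataclass
class DatasetBundle:
    h5_path: Path
    meta_path: Path
    manifest: dict


def _meta_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"exam_id": s.exam_id, "age": s.age, "is_male": int(s.is_male),
               "hypertension": int(s.hypertension)}
        row.update({a: int(s.flags[a]) for a in ABNORMALITIES})
        row["follow_up_years"] = s.follow_up
        row["death"] = int(s.death)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def write_dataset(records: list[ECGRecord], subjects: list[SubjectRecord],
                  h5_path: str | Path, meta_path: str | Path) -> DatasetBundle:
    """Write tracings + metadata + manifest; exam_id sets must match."""
    if not records:
        raise ValueError("no records to write")
    rec_ids = [r.exam_id for r in records]
    sub_ids = [s.exam_id for s in subjects]
    if len(set(rec_ids)) != len(rec_ids):
        raise ValueError("duplicate exam_id among records")
    if set(rec_ids) != set(sub_ids):
        raise ValueError("exam_id sets of tracings and metadata differ")
    h5_path, meta_path = Path(h5_path), Path(meta_path)
    t = records[0].signal.shape[1]
    fs = records[0].fs
    tracings = np.stack([r.signal.T for r in records]).astype(np.float32)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("tracings", data=tracings)
        f.create_dataset("exam_id", data=np.asarray(rec_ids, dtype=np.int64))
    meta = _meta_frame(subjects).set_index("exam_id").loc[rec_ids].reset_index()
    meta.to_csv(meta_path, index=False)
    digest = hashlib.sha256(tracings.tobytes()
                            + meta.to_csv(index=False).encode()).hexdigest()
    manifest = {"n": len(records), "t": int(t), "fs": float(fs),
                "lead_order": list(LEAD_NAMES), "sha256": digest}
    manifest_path = h5_path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return DatasetBundle(h5_path=h5_path, meta_path=meta_path, manifest=manifest)


def read_dataset(h5_path: str | Path, meta_path: str | Path,
                 target_fs: float | None = None, target_len: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read a bundle back: (tracings (N, 12, T), exam_ids, metadata frame).

    With ``target_fs``, tracings stored at another rate are polyphase-resampled;
    shorter tracings are zero-padded to ``target_len``.
    """
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "r") as f:
        for key in ("tracings", "exam_id"):
            if key not in f:
                raise ValueError(f"tracing store is missing key '{key}'")
        tracings = f["tracings"][...].astype(float)
        ids = f["exam_id"][...]
    x = np.transpose(tracings, (0, 2, 1))  # -> (N, leads, T)
    manifest_path = h5_path.with_suffix(".manifest.json")
    fs = None
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("lead_order") != list(LEAD_NAMES):
            raise ValueError("lead order in manifest does not match the "
                             "standard montage")
        fs = manifest.get("fs")
    if target_fs is not None and fs is not None and fs != target_fs:
        from fractions import Fraction
        frac = Fraction(int(round(target_fs)), int(round(fs)))
        x = resample_poly(x, frac.numerator, frac.denominator, axis=2)
    if target_len is not None:
        if x.shape[2] < target_len:
            pad = target_len - x.shape[2]
            x = np.pad(x, ((0, 0), (0, 0), (0, pad)))
        elif x.shape[2] > target_len:
            x = x[:, :, :target_len]
    meta = pd.read_csv(meta_path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if set(meta["exam_id"]) != set(int(i) for i in ids):
        raise ValueError("exam_id sets of tracings and metadata differ")
    return x, ids, meta


def export_heatmaps(heatmaps: np.ndarray, probabilities: np.ndarray,
                    exam_ids: np.ndarray, path: str | Path, label: str = "",
                    fmt: str = "hdf5") -> Path:
    """Write heatmaps (N, 12, T) to HDF5 (default) or per-record CSV."""
    heatmaps = np.asarray(heatmaps, dtype=np.float32)
    if len(heatmaps) != len(exam_ids) or len(probabilities) != len(exam_ids):
        raise ValueError("heatmaps, probabilities and exam_ids must align")
    path = Path(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("heatmaps", data=np.transpose(heatmaps, (0, 2, 1)))
            f.create_dataset("probability", data=np.asarray(probabilities,
                                                            dtype=np.float32))
            f.create_dataset("exam_id", data=np.asarray(exam_ids, dtype=np.int64))
            f.attrs["label"] = label
        return path
    if fmt == "csv":
        frames = []
        for hm, pid in zip(heatmaps, exam_ids):
            n_lead, t = hm.shape
            frames.append(pd.DataFrame({
                "exam_id": np.repeat(pid, n_lead * t),
                "lead": np.repeat(LEAD_NAMES, t),
                "sample": np.tile(np.arange(t), n_lead),
                "value": hm.ravel()}))
        pd.concat(frames).to_csv(path, index=False)
        return path
    raise ValueError(f"unknown heatmap format {fmt!r}")


def import_heatmaps(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read heatmaps back from the HDF5 layout."""
    with h5py.File(path, "r") as f:
        hm = np.transpose(f["heatmaps"][...], (0, 2, 1)).astype(float)
        prob = f["probability"][...].astype(float)
        ids = f["exam_id"][...]
    return hm, prob, ids
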