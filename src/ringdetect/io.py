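"""Image and annotation IO plus model-container persistence.

Images: grayscale 8/16-bit TIFF or PNG (multi-channel rejected).  Boxes in
CSV files use 0-based inclusive pixel corners, stated in each header.  A
trained detector persists as a directory holding one ``.npz`` of arrays
(dictionary words, discriminative weights, query patch pixels, SVM
parameters) and a ``meta.json`` with the configuration and format version.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dsift import InvalidInputError

MODEL_FORMAT_VERSION = 1

DET_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "score", "label"]
GT_COLUMNS = ["image_id", "x_min", "y_min", "x_max", "y_max", "label"]

_CORNER_NOTE = "# boxes use 0-based inclusive pixel corners (x = row, y = col)\n"


def load_image(path) -> np.ndarray:
    """Load a grayscale TIFF/PNG as float64; reject multi-channel input."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise InvalidInputError(f"unsupported image format {suffix!r} (need TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise InvalidInputError(
            f"{path.name}: expected a single-channel grayscale image, got shape {arr.shape}"
        )
    return arr.astype(np.float64)


def save_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        raise InvalidInputError("images are written as float32 TIFF only")


def write_detections_csv(path, rows) -> None:
    """rows: iterable of (image_id, Detection)."""
    records = [
        {
            "image_id": image_id,
            "x_min": int(d.box[0]),
            "y_min": int(d.box[1]),
            "x_max": int(d.box[2]),
            "y_max": int(d.box[3]),
            "score": float(d.score),
            "label": int(bool(d.label)),
        }
        for image_id, d in rows
    ]
    df = pd.DataFrame.from_records(records, columns=DET_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_CORNER_NOTE)
        df.to_csv(fh, index=False, float_format="%.9g")


def read_detections_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_ground_truth_csv(path, rows) -> None:
    """rows: iterable of (image_id, box, label)."""
    records = [
        {
            "image_id": image_id,
            "x_min": int(b[0]),
            "y_min": int(b[1]),
            "x_max": int(b[2]),
            "y_max": int(b[3]),
            "label": label,
        }
        for image_id, b, label in rows
    ]
    df = pd.DataFrame.from_records(records, columns=GT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_CORNER_NOTE)
        df.to_csv(fh, index=False)


def read_ground_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_model(path, detector) -> None:
    """Persist a trained detector (see :mod:`ringdetect.pipeline`) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(
        path / "arrays.npz",
        words=detector.dictionary.words,
        alpha=detector.weights.alpha,
        delta=detector.weights.delta,
        d=detector.weights.d,
        query_pixels=np.stack([q.pixels for q in detector.queries]),
        svm_weights=detector.svm.weights,
        svm_bias=np.array([detector.svm.bias]),
    )
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "K": int(detector.dictionary.K),
        "kmeans_seed": int(detector.dictionary.kmeans_seed),
        "chosen_C": float(detector.svm.chosen_C),
        "cv_folds": int(detector.svm.cv_folds),
        "config": detector.config.to_dict(),
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_model(path):
    from .bow import Dictionary, DiscriminativeWeights
    from .config import DetectorConfig
    from .identification import SvmModel
    from .localization import make_query_patch
    from .pipeline import TrainedDetector

    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise InvalidInputError(f"{path} is not a model container (meta.json missing)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise InvalidInputError(
            f"unsupported model format version {meta.get('format_version')!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    arrays = np.load(path / "arrays.npz")
    config = DetectorConfig.from_dict(meta["config"])
    dictionary = Dictionary(words=arrays["words"], kmeans_seed=meta["kmeans_seed"])
    weights = DiscriminativeWeights(
        alpha=arrays["alpha"], delta=arrays["delta"], d=arrays["d"]
    )
    queries = [
        make_query_patch(p, dictionary, config.grid_spec)
        for p in arrays["query_pixels"]
    ]
    svm = SvmModel(
        weights=arrays["svm_weights"],
        bias=float(arrays["svm_bias"][0]),
        chosen_C=meta["chosen_C"],
        cv_folds=meta["cv_folds"],
    )
    return TrainedDetector(
        dictionary=dictionary, weights=weights, queries=queries, svm=svm, config=config
    )
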