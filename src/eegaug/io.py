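"""File formats: map-set containers, and the optional SEED-style reader.

Map sets are stored as a single NPZ array container (``maps`` of shape
(n, bands, H, W), plus the per-band normalizer when known) with a CSV
sidecar of labels and segment indices, so the arrays stay opaque to tools
that only need the metadata. The SEED-style reader is isolated here; no
other module touches file formats.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .features import EEGSegment


def save_maps(path, maps: np.ndarray, labels: np.ndarray,
              normalizer: np.ndarray | None = None,
              segment_indices: np.ndarray | None = None) -> None:
    path = Path(path)
    maps = np.asarray(maps, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if maps.shape[0] != labels.shape[0]:
        raise ValueError("one label per map required")
    payload = {"maps": maps}
    if normalizer is not None:
        payload["normalizer"] = np.asarray(normalizer, dtype=np.float64)
    np.savez_compressed(path, **payload)
    if segment_indices is None:
        segment_indices = np.arange(len(labels))
    sidecar = path.with_suffix(".csv")
    pd.DataFrame({"segment_index": np.asarray(segment_indices),
                  "label": labels}).to_csv(sidecar, index=False)


def load_maps(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    path = Path(path)
    with np.load(path) as data:
        maps = data["maps"]
        normalizer = data["normalizer"] if "normalizer" in data.files else None
    sidecar = path.with_suffix(".csv")
    if sidecar.exists():
        labels = pd.read_csv(sidecar)["label"].to_numpy(dtype=np.int64)
    else:
        labels = np.zeros(maps.shape[0], dtype=np.int64)
    return maps, labels, normalizer


def read_seed_mat(path, fs: float = 200.0, segment_s: float = 1.0,
                  channel_names: tuple[str, ...] | None = None,
                  ) -> list[EEGSegment]:
    """Read a SEED-style MATLAB container of per-trial EEG arrays.

    Expected layout: 2-D double arrays (channels x samples), one per trial,
    in natural variable-name order, plus a ``label``/``labels`` vector with
    one emotion index per trial. Each trial is cut into non-overlapping
    ``segment_s``-second segments; a trial shorter than one segment yields
    no segments and a warning.
    """
    from scipy.io import loadmat

    raw = loadmat(path)
    label_key = next((k for k in ("label", "labels") if k in raw), None)
    if label_key is None:
        raise ValueError("malformed container: missing 'label' vector")
    labels = np.asarray(raw[label_key]).ravel().astype(np.int64)
    trial_keys = sorted(
        (k for k, v in raw.items()
         if not k.startswith("__") and k != label_key
         and isinstance(v, np.ndarray) and v.ndim == 2 and v.size > 1),
        key=lambda k: (len(k), k))
    if len(trial_keys) != len(labels):
        raise ValueError(
            f"label vector has {len(labels)} entries but file holds "
            f"{len(trial_keys)} trial arrays")
    seg_len = int(round(segment_s * fs))
    segments: list[EEGSegment] = []
    for key, lab in zip(trial_keys, labels):
        trial = np.asarray(raw[key], dtype=np.float64)
        names = channel_names or tuple(f"ch{i:02d}" for i in range(trial.shape[0]))
        n_seg = trial.shape[1] // seg_len
        if n_seg == 0:
            warnings.warn(f"trial {key!r} shorter than one segment; skipped",
                          stacklevel=2)
            continue
        for s in range(n_seg):
            segments.append(EEGSegment(
                data=trial[:, s * seg_len:(s + 1) * seg_len], fs=fs,
                channel_names=names, label=int(lab)))
    return segments
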