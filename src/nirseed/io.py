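"""Spectral table IO, white-reference correction and the train/prediction split.

The exchange format is plain CSV: the spectra file has a header row of
wavelengths (nm) followed by one row of corrected intensities per kernel;
the companion labels file has columns ``id,label,set`` aligned with the
spectra rows by position.  Labels are −1 (aged, harvest 2018) or +1 (new,
harvest 2021).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpectralDataset", "white_correct", "read_dataset", "write_dataset", "partition"]


@dataclass
class SpectralDataset:
    """Corrected spectra with wavelengths, class labels and sample ids."""

    wavelengths: np.ndarray  # (p,) strictly increasing, nm
    X: np.ndarray            # (n, p) corrected intensities
    y: np.ndarray            # (n,) labels in {-1, +1}
    ids: list[str]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.ids = [str(i) for i in self.ids]
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.X.ndim != 2 or self.X.shape[1] != self.wavelengths.size:
            raise ValueError("X column count must equal wavelength count")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        bad = set(np.unique(self.y)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be -1 or +1, found {sorted(bad)}")
        if len(self.ids) != self.X.shape[0] or self.y.size != self.X.shape[0]:
            raise ValueError("ids, y and X row counts must agree")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        rows = np.asarray(rows)
        return SpectralDataset(
            wavelengths=self.wavelengths,
            X=self.X[rows],
            y=self.y[rows],
            ids=[self.ids[i] for i in rows],
        )

    def select_channels(self, cols: np.ndarray) -> "SpectralDataset":
        cols = np.asarray(cols)
        return SpectralDataset(
            wavelengths=self.wavelengths[cols],
            X=self.X[:, cols],
            y=self.y,
            ids=list(self.ids),
        )


def white_correct(raw: np.ndarray, white: np.ndarray) -> np.ndarray:
    """Channel-wise white-reference correction ``S_c = S_raw / S_white``.

    ``white`` is the spectrum of the empty light path; every channel must be
    strictly positive.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float).ravel()
    if raw.ndim != 2:
        raise ValueError("raw must be a 2-D (kernels x channels) matrix")
    if raw.shape[1] != white.size:
        raise ValueError(
            f"channel mismatch: raw has {raw.shape[1]} columns, white has {white.size}"
        )
    nonpos = np.flatnonzero(white <= 0)
    if nonpos.size:
        raise ValueError(f"white reference not strictly positive at channel {nonpos[0]}")
    return raw / white[None, :]


def write_dataset(dataset: SpectralDataset, spectra_path, labels_path,
                  sets: list[str] | None = None) -> None:
    """Write the two-file CSV dialect (10 significant digits)."""
    header = ",".join(format(w, ".10g") for w in dataset.wavelengths)
    with open(spectra_path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, dataset.X, fmt="%.10g", delimiter=",")
    if sets is None:
        sets = [""] * dataset.n_samples
    pd.DataFrame({"id": dataset.ids, "label": dataset.y, "set": sets}).to_csv(
        labels_path, index=False
    )


def read_dataset(spectra_path, labels_path) -> SpectralDataset:
    """Read the two-file CSV dialect back into a validated dataset."""
    with open(spectra_path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        wavelengths = np.asarray([float(tok) for tok in header.split(",")])
        X = np.loadtxt(fh, delimiter=",", ndmin=2)
    labels = pd.read_csv(labels_path, dtype={"id": str})
    missing = {"id", "label"} - set(labels.columns)
    if missing:
        raise ValueError(f"labels file lacks columns {sorted(missing)}")
    y = labels["label"].to_numpy()
    if not np.isin(y, (-1, 1)).all():
        bad = sorted(set(y) - {-1, 1})
        raise ValueError(f"labels must be -1 or +1, found {bad}")
    return SpectralDataset(
        wavelengths=wavelengths,
        X=X,
        y=y.astype(int),
        ids=list(labels["id"]),
    )


def partition(dataset: SpectralDataset, train_fraction: float = 0.8,
              seed: int = 0) -> tuple[SpectralDataset, SpectralDataset]:
    """Stratified random split into training and prediction sets.

    Per class, ``round(train_fraction * class size)`` kernels (round half up)
    go to the training set via a seeded shuffle without replacement.  The
    default 0.8 on a 200/200 dataset yields the 160/40-per-class partition
    used for harvest-year modelling.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    classes = np.unique(dataset.y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_rows: list[np.ndarray] = []
    pred_rows: list[np.ndarray] = []
    for cls in classes:
        rows = np.flatnonzero(dataset.y == cls)
        if rows.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_train = int(np.floor(train_fraction * rows.size + 0.5))
        n_train = min(max(n_train, 1), rows.size - 1)
        perm = rng.permutation(rows)
        train_rows.append(np.sort(perm[:n_train]))
        pred_rows.append(np.sort(perm[n_train:]))
    train_idx = np.sort(np.concatenate(train_rows))
    pred_idx = np.sort(np.concatenate(pred_rows))
    return dataset.subset(train_idx), dataset.subset(pred_idx)
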