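"""Data containers, I/O, normalization and synthetic benchmark generation.

The central container is :class:`DataMatrix`: a dense n x d matrix of samples
by features, with optional integer class labels (used for evaluation only,
never by the solver) and an optional image geometry for vectorized-image data,
which enables the rectangular block-noise corruption used in robustness
experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import loadmat

logger = logging.getLogger(__name__)

# de-facto key conventions of the common benchmark .mat repositories
_MAT_X_KEYS = ("X", "fea")
_MAT_LABEL_KEYS = ("Y", "gnd")


@dataclass
class DataMatrix:
    """A dense sample-by-feature matrix with optional labels and image geometry.

    Parameters
    ----------
    X : ndarray of shape (n, d)
        Rows are samples, columns are features.  Must be finite.
    labels : ndarray of shape (n,), optional
        Integer class labels; used only for clustering evaluation.
    feature_ids : sequence of str, optional
        Names for the d features.
    image_shape : tuple (height, width), optional
        If each row is a vectorized image, its geometry; height * width must
        equal d.  Required by :func:`add_block_noise`.
    """

    X: np.ndarray
    labels: np.ndarray | None = None
    feature_ids: list[str] | None = None
    image_shape: tuple[int, int] | None = None
    informative_idx: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {self.X.shape}")
        n, d = self.X.shape
        if n < 2 or d < 2:
            raise ValueError(f"need at least 2 samples and 2 features, got {n}x{d}")
        if not np.all(np.isfinite(self.X)):
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise ValueError(f"non-finite entry at row {bad[0]}, column {bad[1]}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.shape[0] != n:
                raise ValueError(
                    f"labels length {self.labels.shape[0]} does not match n={n} rows"
                )
            self.labels = self.labels.astype(int)
        if self.feature_ids is not None:
            self.feature_ids = [str(f) for f in self.feature_ids]
            if len(self.feature_ids) != d:
                raise ValueError(
                    f"feature_ids length {len(self.feature_ids)} does not match d={d}"
                )
        if self.image_shape is not None:
            h, w = self.image_shape
            if h * w != d:
                raise ValueError(f"image_shape {h}x{w} incompatible with d={d}")
            self.image_shape = (int(h), int(w))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int | None:
        if self.labels is None:
            return None
        return int(np.unique(self.labels).size)

    def to_csv(self, path, labels_path=None) -> None:
        """Write X as a headerless CSV; labels, if any, one integer per line."""
        pd.DataFrame(self.X).to_csv(path, header=False, index=False)
        if labels_path is not None and self.labels is not None:
            pd.Series(self.labels).to_csv(labels_path, header=False, index=False)


def load_matrix(path, format: str = "csv", labels_key_or_column=None, transpose: bool = False) -> DataMatrix:
    """Load a dense numeric matrix from delimited text or a MAT container.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"csv", "tsv", "mat"}
        File format.  MAT files are searched for the conventional keys
        ``X``/``fea`` (data) and ``Y``/``gnd`` (labels).
    labels_key_or_column : optional
        For csv/tsv: a column index or name holding per-sample labels (string
        labels are factor-encoded to 0..c-1).  For mat: the key of the label
        array (defaults to ``Y``/``gnd`` if present).
    transpose : bool
        Transpose after loading, for features-in-rows files.
    """
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, header=None)
        except pd.errors.ParserError as exc:  # ragged rows: keep pandas' line number
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        labels = None
        if labels_key_or_column is not None:
            col = labels_key_or_column
            if isinstance(col, str) and col not in df.columns:
                try:
                    col = int(col)
                except ValueError:
                    pass
            if col not in df.columns:
                raise ValueError(f"label column {col!r} not found in {path}")
            raw = df[col]
            labels = pd.factorize(raw)[0]
            df = df.drop(columns=[col])
        for c in df.columns:
            if not pd.api.types.is_numeric_dtype(df[c]):
                bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
                raise ValueError(
                    f"non-numeric cell in column {c}, row {bad[0] if len(bad) else '?'} of {path}"
                )
        X = df.to_numpy(dtype=float)
    elif format == "mat":
        contents = loadmat(path)
        X = None
        for key in _MAT_X_KEYS:
            if key in contents:
                X = np.asarray(contents[key], dtype=float)
                break
        if X is None:
            raise ValueError(f"no data key {_MAT_X_KEYS} found in {path}")
        labels = None
        label_keys = (labels_key_or_column,) if labels_key_or_column else _MAT_LABEL_KEYS
        for key in label_keys:
            if key is not None and key in contents:
                labels = pd.factorize(np.asarray(contents[key]).ravel())[0]
                break
        if labels_key_or_column and labels is None:
            raise ValueError(f"label key {labels_key_or_column!r} not found in {path}")
    else:
        raise ValueError(f"unknown format {format!r}")

    if transpose:
        X = X.T
    logger.info("loaded %s: %d samples x %d features", path, X.shape[0], X.shape[1])
    return DataMatrix(X=X, labels=labels)


def minmax_normalize(data: DataMatrix) -> DataMatrix:
    """Map each column independently to [0, 1] via (x - min) / (max - min).

    Constant columns map to all zeros.  Nonnegativity of X is what lets the
    multiplicative solver updates preserve the signs of W and H, so this is
    the default preprocessing of the pipeline.
    """
    X = data.X
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0
    span_safe = np.where(constant, 1.0, span)
    Xn = (X - lo) / span_safe
    Xn[:, constant] = 0.0
    logger.info(
        "min-max normalized %d columns (%d constant)", X.shape[1], int(constant.sum())
    )
    return replace(data, X=Xn)


def make_synthetic(
    n: int = 100,
    d_informative: int = 10,
    d_noise: int = 190,
    c: int = 3,
    separation: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> DataMatrix:
    """Generate a Gaussian-cluster benchmark with informative and noise features.

    Rows are drawn from ``c`` spherical Gaussian clusters (sd ``noise_sd``)
    whose means differ by ``separation`` only on the first ``d_informative``
    columns; the remaining ``d_noise`` columns are i.i.d. Gaussian(0,
    noise_sd) noise carrying no class signal.  The defaults mirror the study
    conditions used throughout the test-bench: 100 samples, 3 clusters, 10
    informative features padded with 190 pure-noise ones, and a
    separation-to-noise ratio of 5.

    The informative features occupy the leading columns and their indices are
    recorded in ``informative_idx`` so that feature-recovery metrics are
    index-based and unambiguous.
    """
    if c < 2 or n < c:
        raise ValueError(f"need n >= c >= 2, got n={n}, c={c}")
    if d_informative < 1 or d_noise < 0:
        raise ValueError("d_informative must be >= 1 and d_noise >= 0")
    rng = np.random.default_rng(seed)
    d = d_informative + d_noise
    labels = np.arange(n) % c
    # cluster mean pattern: cluster j is offset by `separation` on the
    # informative columns congruent to j (mod c), so any two means differ by
    # `separation` in >= 1 coordinate and only on informative columns
    centers = np.zeros((c, d))
    for j in range(c):
        cols = np.arange(d_informative)[np.arange(d_informative) % c == j]
        centers[j, cols] = separation
    X = centers[labels] + rng.normal(0.0, noise_sd, size=(n, d))
    return DataMatrix(
        X=X,
        labels=labels,
        feature_ids=[f"f{i}" for i in range(d)],
        informative_idx=np.arange(d_informative),
    )


def add_block_noise(
    data: DataMatrix,
    block: tuple[int, int],
    n_blocks_per_sample: int = 1,
    fill: str = "constant",
    fill_value: float = 0.0,
    seed: int = 0,
) -> DataMatrix:
    """Overwrite random rectangular blocks of each vectorized-image sample.

    For every sample, ``n_blocks_per_sample`` rectangles of shape ``block``
    at uniformly random positions are overwritten either with a constant
    (``fill="constant"``, value ``fill_value``) or with uniform(0, 1) noise
    (``fill="uniform"``).  Exactly the pixels inside the rectangles change;
    labels are untouched.
    """
    if data.image_shape is None:
        raise ValueError("add_block_noise requires image_shape on the DataMatrix")
    h, w = data.image_shape
    bh, bw = block
    if bh > h or bw > w or bh < 1 or bw < 1:
        raise ValueError(f"block {bh}x{bw} does not fit inside image {h}x{w}")
    if fill not in ("constant", "uniform"):
        raise ValueError(f"unknown fill {fill!r}")
    rng = np.random.default_rng(seed)
    imgs = data.X.reshape(data.n, h, w).copy()
    for i in range(data.n):
        for _ in range(n_blocks_per_sample):
            r = rng.integers(0, h - bh + 1)
            col = rng.integers(0, w - bw + 1)
            if fill == "constant":
                imgs[i, r : r + bh, col : col + bw] = fill_value
            else:
                imgs[i, r : r + bh, col : col + bw] = rng.uniform(0.0, 1.0, size=(bh, bw))
    return replace(data, X=imgs.reshape(data.n, data.d))
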