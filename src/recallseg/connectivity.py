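"""Scene-windowed Pearson functional connectivity and edge-feature tensors.

For each (scene, subject) pair the ROI-by-ROI Pearson correlation matrix is
computed over the scene's TR window, then vectorized to its strictly-lower
triangle — the r = (R^2 - R)/2 unique edges — and stacked into a
(W scenes, M subjects, r edges) feature tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .timing import TRWindow

__all__ = [
    "ROITimeSeriesSet",
    "SceneFC",
    "FeatureTensor",
    "compute_scene_fc",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "assemble_feature_tensor",
    "n_edges",
]


def n_edges(n_rois: int) -> int:
    """Unique off-diagonal edges of an R x R symmetric matrix: (R^2 - R)/2."""
    return (n_rois * n_rois - n_rois) // 2


@dataclass
class ROITimeSeriesSet:
    """One subject's ROI time series (run_trs x R) with ROI/network labels."""

    subject_id: str
    data: np.ndarray
    roi_ids: list[str]
    networks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (TR x ROI)")
        if self.data.shape[1] != len(self.roi_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_ids)} roi_ids"
            )
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 ROIs")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id!r}: non-finite values")

    def select_network(self, network: str) -> "ROITimeSeriesSet":
        """Restrict to the ROIs tagged with ``network`` (e.g. DMN, Auditory)."""
        keep = [i for i, r in enumerate(self.roi_ids) if self.networks.get(r) == network]
        if len(keep) < 2:
            raise ValueError(f"network {network!r} has fewer than 2 ROIs")
        return ROITimeSeriesSet(
            self.subject_id,
            self.data[:, keep],
            [self.roi_ids[i] for i in keep],
            {self.roi_ids[i]: network for i in keep},
        )


@dataclass
class SceneFC:
    """Pearson correlation matrix of one subject over one scene window."""

    scene_index: int
    subject_id: str
    matrix: np.ndarray


def compute_scene_fc(ts: ROITimeSeriesSet, window: TRWindow, scene_index: int = 0) -> SceneFC:
    """Pearson FC of all ROI pairs over the window's TRs.

    Raises if the window is shorter than 3 TRs or any ROI is constant within
    it (its correlation is undefined).
    """
    if len(window) < 3:
        raise ValueError(f"window {window} too short for correlation (< 3 TRs)")
    if window.end_tr > ts.data.shape[0]:
        raise ValueError(
            f"window end {window.end_tr} exceeds run length {ts.data.shape[0]}"
        )
    seg = ts.data[window.start_tr : window.end_tr]
    flat = np.nonzero(np.ptp(seg, axis=0) == 0)[0]
    if flat.size:
        names = [ts.roi_ids[i] for i in flat]
        raise ValueError(
            f"subject {ts.subject_id!r}: constant series in window for ROI(s) {names}"
        )
    fc = np.corrcoef(seg, rowvar=False)
    fc = np.clip(fc, -1.0, 1.0)
    np.fill_diagonal(fc, 1.0)
    return SceneFC(scene_index, ts.subject_id, fc)


def vectorize_lower_triangle(fc: SceneFC | np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Strictly-lower-triangular entries in row-major order, length (R^2-R)/2."""
    m = fc.matrix if isinstance(fc, SceneFC) else np.asarray(fc, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected square matrix, got shape {m.shape}")
    if np.abs(m - m.T).max() > atol:
        raise ValueError("matrix is not symmetric within tolerance")
    rows, cols = np.tril_indices(m.shape[0], k=-1)
    return m[rows, cols]


def devectorize_lower_triangle(vec: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (symmetric, unit diagonal)."""
    vec = np.asarray(vec, dtype=float)
    r = vec.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * r)) / 2))
    if n_edges(n) != r:
        raise ValueError(f"length {r} is not (R^2-R)/2 for any integer R")
    m = np.full((n, n), diag, dtype=float)
    rows, cols = np.tril_indices(n, k=-1)
    m[rows, cols] = vec
    m[cols, rows] = vec
    return m


@dataclass
class FeatureTensor:
    """(W scenes, M subjects, r edges) stack of vectorized FC matrices."""

    data: np.ndarray  # (W, M, r)
    subject_ids: list[str]
    n_rois: int
    scene_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("tensor must be (W, M, r)")
        if self.data.shape[2] != n_edges(self.n_rois):
            raise ValueError(
                f"edge dim {self.data.shape[2]} != (R^2-R)/2 for R={self.n_rois}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("tensor contains non-finite values")
        if self.data.shape[1] != len(self.subject_ids):
            raise ValueError("subject_ids length mismatch")
        if not self.scene_indices:
            self.scene_indices = list(range(self.data.shape[0]))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def flatten(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W*M, r) sample matrix plus aligned scene and subject index arrays.

        Samples are ordered scene-major, so sample w*M + m is (scene w,
        subject m); the index maps support leakage-aware (subject-grouped)
        cross-validation downstream.
        """
        w, m, r = self.data.shape
        scenes = np.repeat(np.asarray(self.scene_indices), m)
        subjects = np.tile(np.arange(m), w)
        return self.data.reshape(w * m, r), scenes, subjects


def assemble_feature_tensor(
    fcs: list[SceneFC],
    subject_ids: list[str] | None = None,
    fisher_z: bool = False,
) -> FeatureTensor:
    """Stack a complete W x M grid of SceneFC into a (W, M, r) tensor.

    ``fisher_z`` applies arctanh to the edges (correlations clipped to
    +-(1 - 1e-7) first); off by default.
    """
    if not fcs:
        raise ValueError("no FC matrices supplied")
    sizes = {fc.matrix.shape[0] for fc in fcs}
    if len(sizes) != 1:
        raise ValueError(f"mismatched ROI counts across FC matrices: {sorted(sizes)}")
    n_rois = sizes.pop()
    scenes = sorted({fc.scene_index for fc in fcs})
    if subject_ids is None:
        subject_ids = sorted({fc.subject_id for fc in fcs})
    by_cell = {(fc.scene_index, fc.subject_id): fc for fc in fcs}
    missing = [
        (t, s) for t in scenes for s in subject_ids if (t, s) not in by_cell
    ]
    if missing:
        raise ValueError(f"missing (scene, subject) cells: {missing[:10]}")
    data = np.stack(
        [
            np.stack(
                [vectorize_lower_triangle(by_cell[(t, s)]) for s in subject_ids]
            )
            for t in scenes
        ]
    )
    if fisher_z:
        data = np.arctanh(np.clip(data, -1 + 1e-7, 1 - 1e-7))
    return FeatureTensor(data, list(subject_ids), n_rois, scene_indices=scenes)
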