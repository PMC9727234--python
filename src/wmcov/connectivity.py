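"""Regional wavelet features and interregional connectivity matrices.

Given a per-subject feature volume and a label atlas, each region is reduced
to the mean feature vector over its voxels; the connectivity matrix is the
Pearson correlation of those vectors between every pair of regions. A
kernel-density KL-divergence similarity on raw voxel intensities is provided
as a baseline metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .wavelets import FeatureVolume

__all__ = [
    "Atlas",
    "RegionalFeatureMatrix",
    "ConnectivityMatrix",
    "EdgeVector",
    "regional_features",
    "wavelet_pearson_connectivity",
    "kl_similarity_connectivity",
    "vectorize_edges",
    "devectorize_edges",
    "GridMismatchError",
    "EmptyRegionError",
    "DegenerateRegionError",
]


class GridMismatchError(ValueError):
    """Voxel grids of two inputs do not match."""


class EmptyRegionError(ValueError):
    """A region lost all its voxels (e.g. after masking)."""


class DegenerateRegionError(ValueError):
    """A region's data admit no well-defined similarity (constant/zero-var)."""


@dataclass
class Atlas:
    """Integer label volume: 0 = background, 1..R = regions."""

    labels: np.ndarray
    region_names: list[str] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        present = np.unique(lab)
        present = present[present > 0]
        r = int(present.max()) if present.size else 0
        if r == 0:
            raise ValueError("atlas has no labelled regions")
        if not np.array_equal(present, np.arange(1, r + 1)):
            raise ValueError(
                f"atlas labels must be consecutive 1..R; found {present.tolist()}"
            )
        self.labels = lab
        if self.region_names is not None and len(self.region_names) != r:
            raise ValueError("region_names length must equal number of regions")

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_voxels(self, region: int) -> np.ndarray:
        return self.labels == region

    def save(self, path: str) -> None:
        import nibabel as nib

        affine = self.affine if self.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), path)

    @classmethod
    def load(cls, path: str) -> "Atlas":
        import nibabel as nib

        img = nib.load(path)
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int64),
            affine=np.asarray(img.affine),
        )


@dataclass
class RegionalFeatureMatrix:
    """R regions x C channels of mean wavelet features — a subject fingerprint."""

    values: np.ndarray
    region_ids: list[int]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be 2D (regions x channels)")
        if v.shape != (len(self.region_ids), len(self.channel_labels)):
            raise ValueError("values shape inconsistent with ids/labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("regional feature matrix contains non-finite values")
        self.values = v


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R interregional similarity with unit diagonal."""

    values: np.ndarray
    metric: str
    n_samples_per_entry: int | None = None
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v
        if not self.region_ids:
            self.region_ids = list(range(1, v.shape[0] + 1))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str, region_names: list[str] | None = None) -> None:
        names = region_names or [f"R{i}" for i in self.region_ids]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(path)
        meta = {"metric": self.metric, "n_samples_per_entry": self.n_samples_per_entry}
        with open(_sidecar(path), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def from_csv(cls, path: str) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        try:
            with open(_sidecar(path)) as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {"metric": "unknown", "n_samples_per_entry": None}
        n = meta.get("n_samples_per_entry")
        return cls(
            values=df.to_numpy(dtype=np.float64),
            metric=meta["metric"],
            n_samples_per_entry=int(n) if n is not None else None,
        )


def _sidecar(path: str) -> str:
    return path[: -len(".csv")] + ".json" if path.endswith(".csv") else path + ".json"


@dataclass
class EdgeVector:
    """Strict upper triangle of a connectivity matrix, row-major order."""

    values: np.ndarray
    edge_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or len(v) != len(self.edge_index):
            raise ValueError("edge values and index length mismatch")
        prev = None
        for i, j in self.edge_index:
            if not i < j:
                raise ValueError(f"edge index ({i},{j}) violates i < j")
            if prev is not None and (i, j) <= prev:
                raise ValueError("edge_index not strictly ordered")
            prev = (i, j)
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Operations


def regional_features(
    fv: FeatureVolume, atlas: Atlas, mask: np.ndarray | None = None
) -> RegionalFeatureMatrix:
    """Per-region mean of every feature channel.

    ``values[r, c]`` is the mean of channel ``c`` over the voxels labelled
    ``r + 1`` (intersected with ``mask`` if supplied). A region with no voxel
    left raises :class:`EmptyRegionError` rather than yielding NaN.
    """
    if fv.grid_shape != atlas.grid_shape:
        raise GridMismatchError(
            f"feature grid {fv.grid_shape} != atlas grid {atlas.grid_shape}"
        )
    labels = atlas.labels
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != atlas.grid_shape:
            raise GridMismatchError(
                f"mask grid {mask.shape} != atlas grid {atlas.grid_shape}"
            )
        labels = np.where(mask.astype(bool), labels, 0)
    R = atlas.n_regions
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels, minlength=R + 1)[1 : R + 1]
    for r in range(1, R + 1):
        if counts[r - 1] == 0:
            raise EmptyRegionError(f"region {r} has no voxels after masking")
    C = fv.n_channels
    out = np.empty((R, C), dtype=np.float64)
    flat = fv.data.reshape(-1, C)
    for c in range(C):
        sums = np.bincount(flat_labels, weights=flat[:, c], minlength=R + 1)
        out[:, c] = sums[1 : R + 1] / counts
    return RegionalFeatureMatrix(
        values=out,
        region_ids=list(range(1, R + 1)),
        channel_labels=list(fv.channel_labels),
    )


def wavelet_pearson_connectivity(rfm: RegionalFeatureMatrix) -> ConnectivityMatrix:
    """Pearson correlation of regional feature vectors across channels."""
    X = rfm.values
    R, C = X.shape
    if C < 3:
        raise ValueError(f"need at least 3 channels for correlation, got {C}")
    sd = X.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [rfm.region_ids[i] for i in degenerate]
        raise DegenerateRegionError(
            f"constant feature vector for region(s) {names}; "
            "Pearson correlation undefined"
        )
    corr = np.corrcoef(X)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(
        values=corr,
        metric="wavelet_pearson",
        n_samples_per_entry=C,
        region_ids=list(rfm.region_ids),
    )


def kl_similarity_connectivity(
    volume: np.ndarray,
    atlas: Atlas,
    mask: np.ndarray | None = None,
    n_grid: int = 128,
    bandwidth_rule: str = "silverman",
) -> ConnectivityMatrix:
    """KL-divergence similarity between regional intensity distributions.

    Each region's voxel intensities are smoothed with a Gaussian KDE
    (Silverman or Scott bandwidth), evaluated on a shared grid spanning the
    pooled intensity range, floored at 1e-12 and renormalised; the edge value
    is ``exp(-(KL(P_i||P_j) + KL(P_j||P_i)))`` with exact 1.0 on the diagonal.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.shape != atlas.grid_shape:
        raise GridMismatchError(
            f"volume grid {vol.shape} != atlas grid {atlas.grid_shape}"
        )
    labels = atlas.labels
    if mask is not None:
        labels = np.where(np.asarray(mask).astype(bool), labels, 0)
    R = atlas.n_regions
    samples = []
    for r in range(1, R + 1):
        x = vol[labels == r]
        x = x[np.isfinite(x)]
        if x.size < 10:
            raise EmptyRegionError(
                f"region {r} has only {x.size} finite voxels (< 10) for KDE"
            )
        if x.std() == 0:
            raise DegenerateRegionError(
                f"region {r} has zero intensity variance; KDE bandwidth undefined"
            )
        samples.append(x)
    pooled_lo = min(x.min() for x in samples)
    pooled_hi = max(x.max() for x in samples)
    span = pooled_hi - pooled_lo
    grid = np.linspace(pooled_lo - 0.05 * span, pooled_hi + 0.05 * span, n_grid)

    densities = np.empty((R, n_grid), dtype=np.float64)
    for r, x in enumerate(samples):
        kde = gaussian_kde(x, bw_method=bandwidth_rule)
        p = np.maximum(kde(grid), 1e-12)
        densities[r] = p / p.sum()

    logp = np.log(densities)
    out = np.ones((R, R), dtype=np.float64)
    for i in range(R):
        for j in range(i + 1, R):
            d_ij = float(np.sum(densities[i] * (logp[i] - logp[j])))
            d_ji = float(np.sum(densities[j] * (logp[j] - logp[i])))
            sim = float(np.exp(-(d_ij + d_ji)))
            out[i, j] = out[j, i] = sim
    return ConnectivityMatrix(
        values=out,
        metric="kl_similarity",
        n_samples_per_entry=None,
        region_ids=list(range(1, R + 1)),
    )


def vectorize_edges(conn: ConnectivityMatrix | np.ndarray) -> EdgeVector:
    """Row-major strict upper triangle; length R(R-1)/2."""
    values = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(values - values.T).max() > 1e-9:
        raise ValueError("matrix asymmetry exceeds 1e-9; refusing to vectorize")
    R = values.shape[0]
    iu = np.triu_indices(R, k=1)
    edge_index = list(zip((iu[0] + 1).tolist(), (iu[1] + 1).tolist()))
    return EdgeVector(values=values[iu].astype(np.float64), edge_index=edge_index)


def devectorize_edges(edges: EdgeVector, n_regions: int | None = None) -> np.ndarray:
    """Rebuild the symmetric hollow matrix from an edge vector."""
    if n_regions is None:
        n_regions = max(j for _, j in edges.edge_index)
    out = np.zeros((n_regions, n_regions), dtype=np.float64)
    for (i, j), v in zip(edges.edge_index, edges.values):
        out[i - 1, j - 1] = out[j - 1, i - 1] = v
    return out
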