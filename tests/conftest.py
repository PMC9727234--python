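import numpy as np
import pytest

from wmcov.connectivity import (
    regional_features,
    vectorize_edges,
    wavelet_pearson_connectivity,
)
from wmcov.phantom import PhantomSpec, generate_atlas, generate_cohort
from wmcov.wavelets import build_feature_volume, dwt3


def subject_edges(volume, atlas, basis="sym4", levels=3):
    """Volume -> wavelet-Pearson edge vector (the standard per-subject path)."""
    fv = build_feature_volume(dwt3(volume, basis=basis, levels=levels))
    conn = wavelet_pearson_connectivity(regional_features(fv, atlas))
    return vectorize_edges(conn)


def cohort_edge_table(spec: PhantomSpec, atlas_seed: int = 5):
    """Generate a phantom cohort and push it through the wavelet pipeline.

    Returns (edge_table N x E, score table, edge_index, atlas).
    """
    atlas = generate_atlas(spec.grid_shape, spec.n_regions, atlas_seed)
    volumes, table = generate_cohort(atlas, spec)
    rows, edge_index = [], None
    for vol in volumes:
        ev = subject_edges(vol, atlas)
        edge_index = ev.edge_index
        rows.append(ev.values)
    return np.stack(rows), table, edge_index, atlas


@pytest.fixture(scope="session")
def small_atlas():
    return generate_atlas((32, 32, 32), 12, seed=5)


@pytest.fixture(scope="session")
def coupled_cohort():
    """One implanted edge (3,7) with rho=0.9, N=80, low score noise."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        n_regions=12,
        n_subjects=80,
        coupled_edges=[(3, 7, 0.9)],
        score_noise_sd=0.1,
        seed=11,
    )
    X, table, edge_index, atlas = cohort_edge_table(spec)
    return {
        "X": X,
        "scores": table["score"].to_numpy(),
        "ages": table["age"].to_numpy(),
        "edge_index": edge_index,
        "implanted": (3, 7),
        "atlas": atlas,
    }
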