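import numpy as np
import pandas as pd
import pytest

from histofuse import Correspondences3D, RigidTransform3D
from histofuse.datasets import laryngeal_study_errors


def random_rigid_3d(rng: np.random.Generator) -> RigidTransform3D:
    """A uniformly random proper rigid motion (QR-based rotation)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return RigidTransform3D(Q, rng.uniform(-20, 20, size=3))


def landmark_pairs(
    rng: np.random.Generator, n: int = 13, noise_sd: float = 0.0
) -> tuple[RigidTransform3D, Correspondences3D]:
    """Seeded source points, a ground-truth motion, and (optionally noisy) targets."""
    T = random_rigid_3d(rng)
    src = rng.uniform(0, 60, size=(n, 3))
    tgt = T.apply(src)
    if noise_sd > 0:
        tgt = tgt + rng.normal(0, noise_sd, size=tgt.shape)
    return T, Correspondences3D([f"L{i+1}" for i in range(n)], src, tgt)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def study_rows():
    """(sample_id, ctin_ctex | None, ctex_hist) triples of the bundled study table."""
    df = laryngeal_study_errors()
    return [
        (
            r.sample_id,
            None if pd.isna(r.ctin_ctex_mm) else float(r.ctin_ctex_mm),
            float(r.ctex_hist_mm),
        )
        for r in df.itertuples()
    ]
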