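import numpy as np
import pytest

from actimetry import build_cb1_like_bundle, default_selections


@pytest.fixture(scope="session")
def bundle():
    return build_cb1_like_bundle(seed=7)


@pytest.fixture(scope="session")
def selections():
    return default_selections()


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent superposition oracle (Horn's quaternion method).

    Builds the 4x4 key matrix from the correlation of centred coordinate
    sets; the largest eigenvalue lambda_max gives the minimal residual
        rmsd = sqrt(max(0, (Ga + Gb - 2 lambda_max)) / M).
    Shares no code with the SVD-based fit it cross-checks.
    """
    P = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    Q = np.asarray(reference, float) - np.mean(reference, axis=0)
    M = P.shape[0]
    Sxx, Sxy, Sxz = (P[:, 0] @ Q[:, 0], P[:, 0] @ Q[:, 1], P[:, 0] @ Q[:, 2])
    Syx, Syy, Syz = (P[:, 1] @ Q[:, 0], P[:, 1] @ Q[:, 1], P[:, 1] @ Q[:, 2])
    Szx, Szy, Szz = (P[:, 2] @ Q[:, 0], P[:, 2] @ Q[:, 1], P[:, 2] @ Q[:, 2])
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    resid = max(0.0, float(np.sum(P**2) + np.sum(Q**2) - 2.0 * lam))
    return np.sqrt(resid / M)
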