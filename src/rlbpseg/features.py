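"""3D local binary pattern (LBP) features and their random-projection
variant (RLBP).

Both descriptors start from the difference vector of a cubic image patch:
``y_i = x_i - x_c`` where ``x_c`` is the centre intensity.  The LBP code
binarises each entry directly, ``bit_i = 1 iff y_i >= 0``; small intensity
differences flip sign under noise, which makes LBP noise-sensitive.  The
RLBP code instead binarises ``L`` random weighted sums, ``bit_j = 1 iff
w_j . y >= 0`` with the weights drawn i.i.d. uniform on [-1, 1], so large,
stable differences dominate each bit and the code is statistically more
robust to noise.

The step function maps 0 to 1 (``s(0) = 1``) in both descriptors, so a flat
patch produces an all-ones code.  One projection matrix is drawn per
segmentation run and shared across all voxels and atlases, which keeps
target and training features directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DifferenceVector",
    "RlbpProjection",
    "difference_vector",
    "difference_vectors",
    "lbp_code",
    "make_projection",
    "save_projection",
    "load_projection",
    "rlbp_code",
    "rlbp_codes",
    "hamming",
    "NoiseTrialResult",
    "noise_robustness_trial",
]

DifferenceVector = np.ndarray  # length-n float vector with a zero centre entry


def _center_index(n: int) -> int:
    root = round(n ** (1.0 / 3.0))
    if root ** 3 != n or root % 2 == 0:
        raise ValueError(f"patch length {n} is not an odd cube")
    return (n - 1) // 2


def difference_vector(patch: np.ndarray) -> DifferenceVector:
    """``y = [x_1 - x_c, ..., x_n - x_c]`` for a flat odd-cube patch.

    The centre element (which is identically zero) is retained, so
    ``len(y) == len(patch)``.  Invariant to adding a constant to the patch.
    """
    patch = np.asarray(patch, dtype=np.float64).ravel()
    c = _center_index(patch.size)
    return patch - patch[c]


def difference_vectors(patches: np.ndarray) -> np.ndarray:
    """Row-wise :func:`difference_vector` for a ``(K, n)`` patch matrix."""
    patches = np.asarray(patches, dtype=np.float64)
    c = _center_index(patches.shape[1])
    return patches - patches[:, c:c + 1]


def lbp_code(y: DifferenceVector) -> np.ndarray:
    """Binarise a difference vector entrywise: ``bit_i = 1 iff y_i >= 0``.

    The centre bit is always 1 (``s(0) = 1``).
    """
    return (np.asarray(y) >= 0).astype(np.uint8)


@dataclass(frozen=True)
class RlbpProjection:
    """The ``L x n`` random weight matrix of an RLBP extractor.

    Entries are i.i.d. uniform on [-1, 1], drawn deterministically from
    ``seed``.  Row ``j`` is the weight vector of output bit ``j``.
    """

    W: np.ndarray
    seed: int

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]


def make_projection(L: int, n: int, seed: int = 0) -> RlbpProjection:
    """Draw an ``L x n`` projection with entries uniform on [-1, 1]."""
    if L < 1 or n < 1:
        raise ValueError(f"projection dimensions must be positive, got L={L}, n={n}")
    rng = np.random.default_rng(seed)
    return RlbpProjection(rng.uniform(-1.0, 1.0, size=(L, n)), seed=int(seed))


def save_projection(proj: RlbpProjection, path) -> None:
    """Write a projection as whitespace-separated text with an L/n/seed header."""
    header = f"rlbp-projection L={proj.L} n={proj.n} seed={proj.seed}"
    np.savetxt(path, proj.W, header=header)


def load_projection(path) -> RlbpProjection:
    with open(path) as fh:
        header = fh.readline()
    fields = dict(tok.split("=") for tok in header.split() if "=" in tok)
    W = np.loadtxt(path, ndmin=2)
    proj = RlbpProjection(W, seed=int(fields.get("seed", -1)))
    if proj.L != int(fields["L"]) or proj.n != int(fields["n"]):
        raise ValueError(f"projection file {path} header disagrees with matrix shape {W.shape}")
    return proj


def rlbp_code(y: DifferenceVector, proj: RlbpProjection) -> np.ndarray:
    """``bit_j = 1 iff w_j . y >= 0`` — sign pattern of the random sums.

    Invariant to multiplying ``y`` by any positive scalar; the zero vector
    maps to the all-ones code.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size != proj.n:
        raise ValueError(f"difference vector length {y.size} != projection n {proj.n}")
    return (proj.W @ y >= 0).astype(np.uint8)


def rlbp_codes(Y: np.ndarray, proj: RlbpProjection) -> np.ndarray:
    """Row-wise :func:`rlbp_code` for a ``(K, n)`` matrix of difference vectors."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[1] != proj.n:
        raise ValueError(f"difference vector length {Y.shape[1]} != projection n {proj.n}")
    return (Y @ proj.W.T >= 0).astype(np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bits between two equal-length binary codes."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"code shapes differ: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


@dataclass
class NoiseTrialResult:
    """Hamming distances between the codes of a clean and a noisy patch."""

    rlbp_distances: np.ndarray  # one per projection draw
    lbp_distance: int
    L: int
    n: int

    def histogram(self) -> np.ndarray:
        """Counts of trials at each Hamming distance 0..L."""
        return np.bincount(self.rlbp_distances, minlength=self.L + 1)


def noise_robustness_trial(
    patch: np.ndarray,
    noise_sd: float,
    L: int = 20,
    n_trials: int = 100,
    seed: int = 0,
) -> NoiseTrialResult:
    """Compare LBP and RLBP code stability under additive Gaussian noise.

    A single noisy copy of ``patch`` is drawn (sd ``noise_sd``); the LBP
    Hamming distance between the clean and noisy codes is deterministic,
    while the RLBP distance is recomputed ``n_trials`` times with a fresh
    random projection each time.  The histogram of RLBP distances
    concentrates near zero when the random sums are dominated by large,
    noise-stable intensity differences.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    patch = np.asarray(patch, dtype=np.float64).ravel()
    n = patch.size
    rng = np.random.default_rng(seed)
    noisy = patch + rng.normal(0.0, noise_sd, size=n)

    y_clean = difference_vector(patch)
    y_noisy = difference_vector(noisy)
    lbp_d = hamming(lbp_code(y_clean), lbp_code(y_noisy))

    dists = np.empty(n_trials, dtype=np.int64)
    for t in range(n_trials):
        proj = RlbpProjection(rng.uniform(-1.0, 1.0, size=(L, n)), seed=-1)
        dists[t] = hamming(rlbp_code(y_clean, proj), rlbp_code(y_noisy, proj))
    return NoiseTrialResult(dists, lbp_d, L=L, n=n)
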