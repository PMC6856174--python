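"""Atlas ranking by normalized mutual information (NMI) with the target.

NMI here is the Studholme normalization ``(H(A) + H(B)) / H(A, B)`` computed
from a joint intensity histogram with equal-width bins spanning each image's
own min-max range.  It equals 2 when the intensities are related one-to-one
and tends to 1 for independent images; zero-count bins contribute nothing to
the entropies.
"""

from __future__ import annotations

import numpy as np

from .fusion import AtlasSet
from .volume_io import BoundingBox, Volume, crop, crop_labels

__all__ = ["nmi", "rank_atlases", "select_atlases"]


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def nmi(a: Volume | np.ndarray, b: Volume | np.ndarray, bins: int = 64) -> float:
    """Normalized mutual information of two same-shape volumes.

    Degenerate case: if either image is constant the joint entropy can be
    zero; such pairs are deterministically related, so 2.0 is returned.
    """
    da = (a.data if isinstance(a, Volume) else np.asarray(a)).ravel()
    db = (b.data if isinstance(b, Volume) else np.asarray(b)).ravel()
    if da.shape != db.shape:
        raise ValueError(f"volume sizes differ: {da.size} vs {db.size}")
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    joint, _, _ = np.histogram2d(da, db, bins=bins)
    p = joint / joint.sum()
    h_joint = _entropy(p.ravel())
    if h_joint == 0.0:
        return 2.0
    return (_entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0))) / h_joint


def rank_atlases(
    target: Volume,
    pool: AtlasSet,
    box: BoundingBox | None = None,
    bins: int = 64,
) -> list[tuple[int, float]]:
    """(atlas index, NMI) pairs sorted by descending NMI, ties by index."""
    tgt = crop(target, box) if box is not None else target
    scores = []
    for i, img in enumerate(pool.images):
        atl = crop(img, box) if box is not None else img
        scores.append(nmi(tgt, atl, bins=bins))
    order = np.argsort(-np.asarray(scores), kind="stable")
    return [(int(i), float(scores[i])) for i in order]


def select_atlases(
    target: Volume,
    pool: AtlasSet,
    N: int,
    box: BoundingBox | None = None,
    bins: int = 64,
) -> AtlasSet:
    """Keep the N pool atlases most similar to the target inside ``box``.

    When a box is given, the returned atlases are cropped to it (the fusion
    stage operates on the cropped region).
    """
    if N > len(pool):
        raise ValueError(f"requested N={N} atlases from a pool of {len(pool)}")
    ranking = rank_atlases(target, pool, box=box, bins=bins)
    keep = [i for i, _ in ranking[:N]]
    if box is None:
        return AtlasSet([pool.images[i] for i in keep], [pool.labels[i] for i in keep])
    return AtlasSet(
        [crop(pool.images[i], box) for i in keep],
        [crop_labels(pool.labels[i], box) for i in keep],
    )
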