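"""Baseline label-fusion engines: nonlocal patch-based weighted voting (NLP)
and LBP-feature ridge fusion.

NLP labels an ambiguous voxel by a weighted vote over all (atlas,
neighborhood voxel) pairs.  The weight of a candidate is a Gaussian kernel
on its patch distance to the target patch,

    w = exp(-||P(x) - P(x_sj)||^2 / sigma_x^2),

with the locally adaptive bandwidth sigma_x = min over candidates of
(||P(x) - P(x_sj)||_2 + eps), eps = 1e-20 for numerical stability.  The
most similar candidate therefore always receives weight close to 1.  Signed
labels are summed with these weights and thresholded at zero (weight
normalization would not change the sign).

The LBP baseline is the ridge-fusion pipeline of :mod:`rlbpseg.fusion` with
raw sign-of-difference codes (length ``n``) in place of the random
projections — the controlled comparison isolating what the random
combinations contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import AtlasSet, FusionConfig, majority_vote, segment
from .volume_io import LabelMap, Volume, extract_patches, patch_offsets

__all__ = ["NlpConfig", "nlp_weights", "nlp_fuse", "lbp_fuse"]


@dataclass
class NlpConfig:
    """NLP parameters; the published optimum uses patch radius 1."""

    r_p: int = 1
    r_s: int = 1
    epsilon: float = 1e-20

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.r_p < 1 or self.r_s < 0:
            raise ValueError("require r_p >= 1 and r_s >= 0")


def nlp_weights(
    target_patch: np.ndarray,
    atlas_patches: np.ndarray,
    epsilon: float = 1e-20,
) -> np.ndarray:
    """Gaussian patch-similarity weights with the adaptive sigma rule.

    All weights lie in (0, 1]; the candidate nearest the target patch
    attains the maximum.
    """
    target_patch = np.asarray(target_patch, dtype=np.float64).ravel()
    atlas_patches = np.atleast_2d(np.asarray(atlas_patches, dtype=np.float64))
    if atlas_patches.shape[0] == 0:
        raise ValueError("need at least one atlas patch")
    if atlas_patches.shape[1] != target_patch.size:
        raise ValueError(
            f"patch lengths differ: target {target_patch.size}, "
            f"atlas {atlas_patches.shape[1]}"
        )
    d = np.linalg.norm(atlas_patches - target_patch[None, :], axis=1)
    sigma = d.min() + epsilon
    return np.exp(-(d ** 2) / sigma ** 2)


def nlp_fuse(
    target: Volume,
    atlases: AtlasSet,
    cfg: NlpConfig | None = None,
    return_ambiguous: bool = False,
):
    """Nonlocal patch-based weighted-vote fusion.

    Unanimous voxels keep their label (same shortcut as the ridge engine);
    each ambiguous voxel is the sign of the weighted sum of signed labels
    over the search neighborhood of every atlas, sign(0) = +1.
    """
    cfg = cfg or NlpConfig()
    if target.shape != atlases.shape:
        raise ValueError(f"target shape {target.shape} != atlas shape {atlases.shape}")
    label_stack = atlases.label_stack()
    maj, ambiguous = majority_vote(label_stack)
    out = maj.copy()
    amb_idx = np.argwhere(ambiguous)
    if amb_idx.shape[0] > 0:
        shape = np.asarray(target.shape)
        nbr_offs = patch_offsets(cfg.r_s)
        images = atlases.image_stack()
        signed = label_stack.astype(np.int8) * 2 - 1
        N = images.shape[0]

        for s in range(0, amb_idx.shape[0], 1024):
            idx = amb_idx[s:s + 1024]
            a = idx.shape[0]
            tgt_patches = extract_patches(target.data, idx, cfg.r_p)  # (a, n)
            nbrs = idx[:, None, :] + nbr_offs[None, :, :]  # (a, m, 3)
            valid = np.all((nbrs >= 0) & (nbrs < shape[None, None, :]), axis=2)
            nc = np.clip(nbrs, 0, shape - 1)
            m = nbr_offs.shape[0]

            d2 = np.empty((a, N, m), dtype=np.float64)
            lab = np.empty((a, N, m), dtype=np.float64)
            for i in range(N):
                ap = extract_patches(images[i], nc.reshape(-1, 3), cfg.r_p)
                ap = ap.reshape(a, m, -1)
                d2[:, i, :] = np.sum((ap - tgt_patches[:, None, :]) ** 2, axis=2)
                lab[:, i, :] = signed[i, nc[..., 0], nc[..., 1], nc[..., 2]]
            d = np.sqrt(d2)
            d[~np.broadcast_to(valid[:, None, :], d.shape)] = np.inf
            sigma = d.reshape(a, -1).min(axis=1) + cfg.epsilon
            w = np.exp(-d2 / sigma[:, None, None] ** 2)
            w[np.isinf(d)] = 0.0
            vote = np.sum(w * lab, axis=(1, 2))
            out[idx[:, 0], idx[:, 1], idx[:, 2]] = (vote >= 0).astype(np.uint8)
    lab_out = LabelMap(out, target.spacing, target.origin)
    if return_ambiguous:
        return lab_out, ambiguous
    return lab_out


def lbp_fuse(
    target: Volume,
    atlases: AtlasSet,
    cfg: FusionConfig | None = None,
    return_ambiguous: bool = False,
):
    """Ridge label fusion on plain LBP codes — identical scaffolding to the
    RLBP engine, features of length ``n = (2 r_p + 1)**3``."""
    return segment(target, atlases, cfg, feature="lbp", return_ambiguous=return_ambiguous)
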