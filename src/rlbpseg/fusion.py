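"""Voxel-wise label fusion by local ridge regression on binary texture codes.

The pipeline, per target image:

1. **Majority voting** over the N warped atlas label maps gives an initial
   segmentation.  Voxels where the atlases vote unanimously keep that label.
2. Every *ambiguous* voxel ``x`` (any disagreement at all) gets its own
   training set ``D_x``: one sample per (atlas, neighborhood voxel) pair,
   taken from the cubic search neighborhood of radius ``r_s`` around ``x``
   in every atlas.  Each sample is the binary feature code of that atlas
   voxel's patch together with its signed label in {-1, +1}.
3. A ridge-regression model ``argmin_b  ||b||^2 / 2 + C/2 * sum (l - b.f)^2``
   is fitted in closed form via the regularized normal equations
   ``(I/C + F'F) b = F'l`` and the voxel is labeled ``sign(b . f_x)`` with
   ``sign(0) := +1``.

Training-set rows whose neighborhood voxel falls outside the volume are
dropped.  Single-class training sets skip the solve and assign that class
(the ridge prediction would have the same sign for any C > 0).  When the
feature dimension exceeds the number of samples the equivalent dual system
``b = F'(FF' + I/C)^{-1} l`` is solved instead; both routes agree to solver
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import RlbpProjection, difference_vectors, make_projection
from .volume_io import LabelMap, PatchGeometry, Volume, extract_patches, patch_offsets

__all__ = [
    "AtlasSet",
    "FusionConfig",
    "TrainingSet",
    "RidgeModel",
    "majority_vote",
    "build_training_set",
    "ridge_fit",
    "predict_label",
    "segment",
]


@dataclass
class AtlasSet:
    """N atlas (image, label) pairs already warped into the target space."""

    images: list[Volume]
    labels: list[LabelMap]

    def __post_init__(self) -> None:
        if len(self.images) == 0:
            raise ValueError("atlas set must contain at least one atlas")
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} label maps"
            )
        shape = self.images[0].shape
        for v in self.images + self.labels:  # type: ignore[operator]
            if v.shape != shape:
                raise ValueError("all atlas images and labels must share one shape")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.images[0].shape

    def image_stack(self) -> np.ndarray:
        return np.stack([v.data for v in self.images])

    def label_stack(self) -> np.ndarray:
        return np.stack([l.data for l in self.labels])


@dataclass
class FusionConfig:
    """Fusion parameters; defaults are the published optimum for bilateral
    hippocampus segmentation (N=20 atlases, L=1000 random projections,
    C=4**-4, search radius 1, patch radius 4)."""

    n_atlases: int = 20
    L: int = 1000
    C: float = 4.0 ** -4
    r_s: int = 1
    r_p: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 1 or self.L < 1:
            raise ValueError("n_atlases and L must be positive")
        if self.C <= 0:
            raise ValueError(f"balance parameter C must be > 0, got {self.C}")
        if self.r_s < 0 or self.r_p < 1:
            raise ValueError("require r_s >= 0 and r_p >= 1")

    @property
    def geometry(self) -> PatchGeometry:
        return PatchGeometry(r_p=self.r_p, r_s=self.r_s)


@dataclass
class TrainingSet:
    """Per-voxel training data: binary feature rows with signed labels."""

    features: np.ndarray  # (M, L) uint8
    labels: np.ndarray  # (M,) int8 in {-1, +1}
    provenance: list[tuple[int, tuple[int, int, int]]] = field(default_factory=list)

    @property
    def M(self) -> int:
        return self.features.shape[0]


@dataclass
class RidgeModel:
    beta: np.ndarray
    C: float


# ---------------------------------------------------------------------------
# Majority voting


def majority_vote(atlas_labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel majority label and the non-unanimous (ambiguous) mask.

    Accepts a sequence of :class:`LabelMap` or {0,1} arrays of one shape.
    Ties with an even atlas count go to foreground; such voxels are
    ambiguous anyway and are overwritten by the regression stage.
    """
    arrays = [l.data if isinstance(l, LabelMap) else np.asarray(l) for l in atlas_labels]
    if len(arrays) == 0:
        raise ValueError("majority_vote needs at least one atlas label map")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("atlas label maps must all share one shape")
    votes = np.zeros(shape, dtype=np.int64)
    for a in arrays:
        votes += a.astype(np.int64)
    n = len(arrays)
    maj = (2 * votes >= n).astype(np.uint8)
    ambiguous = (votes != 0) & (votes != n)
    return maj, ambiguous


# ---------------------------------------------------------------------------
# Training sets (reference per-voxel path; `segment` uses a vectorised
# equivalent and is cross-checked against this one in the tests)


def _encode(patches: np.ndarray, proj: RlbpProjection | None) -> np.ndarray:
    """Binary codes of a (K, n) patch matrix: RLBP if a projection is given,
    plain LBP otherwise."""
    Y = difference_vectors(patches)
    if proj is None:
        return (Y >= 0).astype(np.uint8)
    return (Y @ proj.W.T >= 0).astype(np.uint8)


def build_training_set(
    atlases: AtlasSet,
    x,
    geo: PatchGeometry,
    proj: RlbpProjection | None,
) -> TrainingSet:
    """Assemble ``D_x`` for one target voxel.

    Rows are ordered atlas-major, then neighborhood offset in lexicographic
    order.  Neighborhood voxels outside the volume are dropped, so ``M`` can
    be smaller than ``N * (2 r_s + 1)**3`` near the border.
    """
    x = np.asarray(x, dtype=np.intp)
    shape = np.asarray(atlases.shape)
    if np.any(x < 0) or np.any(x >= shape):
        raise IndexError(f"voxel {tuple(x)} outside volume of shape {atlases.shape}")
    nbrs = x[None, :] + patch_offsets(geo.r_s)
    inside = np.all((nbrs >= 0) & (nbrs < shape[None, :]), axis=1)
    nbrs = nbrs[inside]

    feats, labels, prov = [], [], []
    for i, (img, lab) in enumerate(zip(atlases.images, atlases.labels)):
        patches = extract_patches(img.data, nbrs, geo.r_p)
        feats.append(_encode(patches, proj))
        signed = lab.signed()
        labels.append(signed[nbrs[:, 0], nbrs[:, 1], nbrs[:, 2]])
        prov.extend((i, tuple(v)) for v in nbrs)
    return TrainingSet(np.concatenate(feats), np.concatenate(labels), prov)


# ---------------------------------------------------------------------------
# Ridge regression, closed form


def ridge_fit(ts: TrainingSet, C: float, mode: str = "auto") -> RidgeModel:
    """Solve ``(I/C + F'F) beta = F'l`` exactly.

    The system is symmetric positive definite for any C > 0, so a Cholesky
    (or equivalently ``scipy``'s SPD solver) never fails.  ``mode`` selects
    the primal (L x L) or dual (M x M) formulation; ``auto`` picks the
    smaller system.  Both give identical beta up to solver precision.
    """
    if C <= 0:
        raise ValueError(f"balance parameter C must be > 0, got {C}")
    F = np.asarray(ts.features, dtype=np.float64)
    l = np.asarray(ts.labels, dtype=np.float64)
    M, L = F.shape
    if M < 1:
        raise ValueError("training set is empty")
    if mode == "auto":
        mode = "primal" if L <= M else "dual"
    if mode == "primal":
        G = F.T @ F
        G[np.diag_indices_from(G)] += 1.0 / C
        beta = np.linalg.solve(G, F.T @ l)
    elif mode == "dual":
        K = F @ F.T
        K[np.diag_indices_from(K)] += 1.0 / C
        beta = F.T @ np.linalg.solve(K, l)
    else:
        raise ValueError(f"unknown ridge mode {mode!r}")
    return RidgeModel(beta, C)


def predict_label(model: RidgeModel, f_x: np.ndarray) -> int:
    """``sign(beta . f_x)`` with the boundary convention ``sign(0) = +1``."""
    f_x = np.asarray(f_x, dtype=np.float64)
    if f_x.shape != model.beta.shape:
        raise ValueError(
            f"feature dimension {f_x.shape} != model dimension {model.beta.shape}"
        )
    return 1 if float(model.beta @ f_x) >= 0 else -1


# ---------------------------------------------------------------------------
# Full segmentation


def segment(
    target: Volume,
    atlases: AtlasSet,
    cfg: FusionConfig | None = None,
    feature: str = "rlbp",
    return_ambiguous: bool = False,
):
    """Segment a target volume against its warped atlas set.

    Unanimous voxels keep the unanimous majority-vote label; each ambiguous
    voxel is classified by its own closed-form ridge fit on ``feature``
    codes ("rlbp" or "lbp").  Returns a :class:`LabelMap` (optionally with
    the ambiguous mask).
    """
    cfg = cfg or FusionConfig()
    if feature not in ("rlbp", "lbp"):
        raise ValueError(f"unknown feature kind {feature!r}")
    if target.shape != atlases.shape:
        raise ValueError(
            f"target shape {target.shape} != atlas shape {atlases.shape}"
        )
    geo = cfg.geometry
    proj = make_projection(cfg.L, geo.n, cfg.seed) if feature == "rlbp" else None

    label_stack = atlases.label_stack()
    maj, ambiguous = majority_vote(label_stack)
    out = maj.copy()
    amb_idx = np.argwhere(ambiguous)
    if amb_idx.shape[0] > 0:
        preds = _classify_ambiguous(
            target.data, atlases.image_stack(), label_stack, amb_idx, geo, proj, cfg.C
        )
        out[amb_idx[:, 0], amb_idx[:, 1], amb_idx[:, 2]] = (preds > 0).astype(np.uint8)
    lab = LabelMap(out, target.spacing, target.origin)
    if return_ambiguous:
        return lab, ambiguous
    return lab


def _classify_ambiguous(
    target: np.ndarray,
    images: np.ndarray,  # (N, X, Y, Z)
    labels: np.ndarray,  # (N, X, Y, Z) uint8
    amb_idx: np.ndarray,  # (A, 3)
    geo: PatchGeometry,
    proj: RlbpProjection | None,
    C: float,
    chunk: int = 256,
) -> np.ndarray:
    """Vectorised ridge classification of all ambiguous voxels.

    Features are precomputed once per atlas on the union of needed voxels
    (the ambiguous set dilated by r_s); per-voxel systems are then solved in
    batches.  Out-of-bounds neighborhood rows are encoded as all-zero
    features with label 0, which contribute nothing to ``F'F`` or ``F'l``
    and are therefore algebraically identical to dropping them.
    """
    N = images.shape[0]
    shape = np.asarray(target.shape)
    amb_mask = np.zeros(target.shape, dtype=bool)
    amb_mask[amb_idx[:, 0], amb_idx[:, 1], amb_idx[:, 2]] = True
    struct = np.ones((2 * geo.r_s + 1,) * 3, dtype=bool)
    need_mask = ndimage.binary_dilation(amb_mask, structure=struct) if geo.r_s > 0 else amb_mask
    need_idx = np.argwhere(need_mask)
    K = need_idx.shape[0]
    row_of = np.full(target.shape, -1, dtype=np.int64)
    row_of[need_idx[:, 0], need_idx[:, 1], need_idx[:, 2]] = np.arange(K)

    Lf = proj.L if proj is not None else geo.n

    def encode_volume(data: np.ndarray) -> np.ndarray:
        codes = np.empty((K, Lf), dtype=np.uint8)
        for s in range(0, K, 4096):
            block = need_idx[s:s + 4096]
            patches = extract_patches(data, block, geo.r_p)
            codes[s:s + 4096] = _encode(patches, proj)
        return codes

    atlas_codes = np.stack([encode_volume(images[i]) for i in range(N)])  # (N, K, Lf)
    target_codes = encode_volume(target)[
        row_of[amb_idx[:, 0], amb_idx[:, 1], amb_idx[:, 2]]
    ]  # (A, Lf)

    signed = labels.astype(np.int8) * 2 - 1  # (N, X, Y, Z)
    nbr_offs = patch_offsets(geo.r_s)  # (m, 3)
    m = nbr_offs.shape[0]
    A = amb_idx.shape[0]
    preds = np.empty(A, dtype=np.int8)

    M = N * m
    dual = Lf > M

    for s in range(0, A, chunk):
        idx = amb_idx[s:s + chunk]  # (a, 3)
        a = idx.shape[0]
        nbrs = idx[:, None, :] + nbr_offs[None, :, :]  # (a, m, 3)
        valid = np.all((nbrs >= 0) & (nbrs < shape[None, None, :]), axis=2)  # (a, m)
        nc = np.clip(nbrs, 0, shape - 1)
        rows = row_of[nc[..., 0], nc[..., 1], nc[..., 2]]  # (a, m)

        # (a, N, m, Lf) -> (a, M, Lf); invalid rows zeroed
        F = atlas_codes[:, rows, :].transpose(1, 0, 2, 3).astype(np.float64)
        F *= valid[:, None, :, None]
        F = F.reshape(a, M, Lf)
        lab_rows = signed[:, nc[..., 0], nc[..., 1], nc[..., 2]].transpose(1, 0, 2)
        lab_rows = (lab_rows * valid[:, None, :]).reshape(a, M).astype(np.float64)

        pos = (lab_rows > 0).sum(axis=1)
        neg = (lab_rows < 0).sum(axis=1)
        single = (pos == 0) | (neg == 0)

        score = np.empty(a, dtype=np.float64)
        if not np.all(single):
            solve_ix = np.flatnonzero(~single)
            Fb = F[solve_ix]
            lb = lab_rows[solve_ix]
            fx = target_codes[s + solve_ix].astype(np.float64)
            if dual:
                Kmat = Fb @ Fb.transpose(0, 2, 1)
                Kmat[:, np.arange(M), np.arange(M)] += 1.0 / C
                alpha = np.linalg.solve(Kmat, lb[..., None])[..., 0]
                score_b = np.einsum("am,am->a", np.einsum("aml,al->am", Fb, fx), alpha)
            else:
                G = Fb.transpose(0, 2, 1) @ Fb
                G[:, np.arange(Lf), np.arange(Lf)] += 1.0 / C
                rhs = np.einsum("aml,am->al", Fb, lb)
                beta = np.linalg.solve(G, rhs[..., None])[..., 0]
                score_b = np.einsum("al,al->a", beta, fx)
            score[solve_ix] = score_b
        score[single] = np.where(pos[single] > 0, 1.0, -1.0)
        preds[s:s + a] = np.where(score >= 0, 1, -1)
    return preds
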