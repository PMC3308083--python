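"""ROI-masked grey-level co-occurrence texture analysis of cartilage T2 maps.

Per compartment and slice, the T2 map is quantized to integer grey levels,
co-occurrence matrices are accumulated for a one-pixel offset in four
orientations (0 deg = anterior-posterior / column axis, 90 deg =
superior-inferior / row axis), and three Haralick features are computed:

    entropy  = sum_ij p(i,j) (-ln p(i,j))          [nats]
    contrast = sum_ij p(i,j) (i - j)^2
    variance = sum_ij p(i,j) (i - mu)^2,  mu = sum_i i p_i(i)

Features are averaged across the four orientations per slice, then aggregated
over slices (pair-count weighted by default). Only pixel pairs with *both*
members inside the mask are counted, so background never contaminates the
cartilage texture; the symmetric (direction-insensitive) counting convention
is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import COMPARTMENTS, COMPARTMENT_LABELS, TextureConfig
from .exceptions import EmptyROIError, InputError
from .relaxometry import T2Map

__all__ = [
    "GLCMatrix",
    "ORIENTATION_OFFSETS",
    "quantize_map",
    "compute_glcm",
    "glcm_entropy",
    "glcm_contrast",
    "glcm_variance",
    "compartment_texture",
]

#: (row, col) displacement per orientation at unit offset.
ORIENTATION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),     # anterior-posterior (along image columns)
    45: (-1, 1),
    90: (-1, 0),   # superior-inferior (along image rows)
    135: (-1, -1),
}

FEATURES = ("contrast", "entropy", "variance")


@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities over grey-level pairs."""

    p: np.ndarray
    n_levels: int
    pair_count: int
    orientation: int
    offset: int


def quantize_map(t2map: T2Map | np.ndarray, mask: np.ndarray,
                 config: TextureConfig | None = None,
                 valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Quantize a T2 map (2D or 3D) to integer grey levels inside the mask.

    ``integer_ms`` mode rounds T2 to the nearest millisecond and clamps to
    ``level_clamp``; ``fixed_bins`` mode uses uniform bins over
    ``fixed_bins_range``. Invalid (non-fitted) pixels are removed from the
    returned mask. Raises :class:`EmptyROIError` if nothing survives.
    """
    config = (config or TextureConfig()).validate()
    if isinstance(t2map, T2Map):
        values, validity = t2map.t2, t2map.valid
    else:
        values = np.asarray(t2map, dtype=float)
        validity = valid if valid is not None else np.isfinite(values)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != values.shape:
        raise InputError("mask and T2 map shapes differ")
    good = mask & validity & np.isfinite(values)
    if not good.any():
        raise EmptyROIError("no valid pixels in ROI after filtering")
    q = np.zeros(values.shape, dtype=np.int64)
    if config.quantization == "integer_ms":
        lo, hi = config.level_clamp
        q[good] = np.clip(np.round(values[good]).astype(np.int64), lo, hi)
    else:
        lo, hi = config.fixed_bins_range
        lev = np.floor((values[good] - lo) / (hi - lo) * config.n_levels)
        q[good] = np.clip(lev, 0, config.n_levels - 1).astype(np.int64)
    return q, good


def compute_glcm(qimage: np.ndarray, mask: np.ndarray, offset: int = 1,
                 orientation: int = 0, symmetric: bool = True,
                 n_levels: int | None = None) -> GLCMatrix:
    """Count co-occurring grey-level pairs at the given offset/orientation.

    All ordered pairs (p, p + d) with both pixels in the mask are counted;
    symmetric mode folds in the transposed counts. The matrix is normalized
    to sum to 1 (``pair_count`` keeps the raw total).
    """
    if orientation not in ORIENTATION_OFFSETS:
        raise InputError(f"orientation must be one of {sorted(ORIENTATION_OFFSETS)}")
    qimage = np.asarray(qimage)
    mask = np.asarray(mask).astype(bool)
    if qimage.ndim != 2 or mask.shape != qimage.shape:
        raise InputError("qimage must be 2D and match the mask shape")
    levels = int(n_levels if n_levels is not None else max(int(qimage[mask].max(initial=0)) + 1, 1))
    dr, dc = (d * offset for d in ORIENTATION_OFFSETS[orientation])
    nr, nc = qimage.shape

    src_r = slice(max(0, -dr), min(nr, nr - dr))
    src_c = slice(max(0, -dc), min(nc, nc - dc))
    dst_r = slice(max(0, dr), min(nr, nr + dr))
    dst_c = slice(max(0, dc), min(nc, nc + dc))

    both = mask[src_r, src_c] & mask[dst_r, dst_c]
    i = qimage[src_r, src_c][both]
    j = qimage[dst_r, dst_c][both]
    counts = np.zeros((levels, levels))
    np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return GLCMatrix(p=p, n_levels=levels, pair_count=int(total),
                     orientation=orientation, offset=offset)


def _require_pairs(g: GLCMatrix) -> None:
    if g.pair_count == 0:
        raise EmptyROIError("GLCM has no pixel pairs")


def glcm_entropy(g: GLCMatrix) -> float:
    """Shannon entropy (nats) of the co-occurrence distribution."""
    _require_pairs(g)
    p = g.p[g.p > 0]
    return float(np.sum(p * (-np.log(p))))


def glcm_contrast(g: GLCMatrix) -> float:
    """Mean squared grey-level difference of co-occurring pairs."""
    _require_pairs(g)
    idx = np.arange(g.n_levels)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float(np.sum(g.p * diff2))


def glcm_variance(g: GLCMatrix) -> float:
    """Dispersion of co-occurring grey levels about the marginal mean."""
    _require_pairs(g)
    idx = np.arange(g.n_levels)
    mu = float(np.sum(idx[:, None] * g.p))  # marginal mean of the symmetric matrix
    return float(np.sum(g.p * (idx[:, None] - mu) ** 2))


def _slice_features(q2d: np.ndarray, m2d: np.ndarray,
                    config: TextureConfig) -> tuple[dict[str, float], int] | None:
    """Orientation-averaged features for one slice, or None if no pairs anywhere."""
    feats = {f: [] for f in FEATURES}
    total_pairs = 0
    for ori in config.orientations:
        g = compute_glcm(q2d, m2d, offset=config.offset, orientation=ori,
                         symmetric=config.symmetric)
        if g.pair_count == 0:
            continue
        total_pairs += g.pair_count
        feats["contrast"].append(glcm_contrast(g))
        feats["entropy"].append(glcm_entropy(g))
        feats["variance"].append(glcm_variance(g))
    if total_pairs == 0:
        return None
    return {f: float(np.mean(v)) for f, v in feats.items()}, total_pairs


def compartment_texture(t2map: T2Map, masks: np.ndarray,
                        config: TextureConfig | None = None) -> pd.DataFrame:
    """Per-compartment mean T2 and GLCM features for a 3D map, slice by slice.

    ``masks`` is the integer label volume (labels 1-5 = patella, MF, MT, LF,
    LT). Returns a DataFrame indexed by compartment plus an ``"all"`` row
    holding the unweighted mean of the available compartment values. A
    compartment with no valid pairs is reported as NaN and excluded from the
    ``"all"`` average.
    """
    config = (config or TextureConfig()).validate()
    masks = np.asarray(masks)
    if masks.shape != t2map.shape:
        raise InputError("label volume and T2 map shapes differ")
    rows = {}
    for comp in COMPARTMENTS:
        cmask = masks == COMPARTMENT_LABELS[comp]
        row: dict[str, float] = {f: np.nan for f in FEATURES}
        row.update(mean_t2=np.nan, n_pixels=0, n_pairs=0)
        good_all = cmask & t2map.valid & np.isfinite(t2map.t2)
        if good_all.any():
            row["mean_t2"] = float(t2map.t2[good_all].mean())
            row["n_pixels"] = int(good_all.sum())
            per_slice, weights = [], []
            for s in range(t2map.shape[0]):
                if not good_all[s].any():
                    continue
                q2d, m2d = quantize_map(t2map.t2[s], cmask[s], config,
                                        valid=t2map.valid[s])
                sf = _slice_features(q2d, m2d, config)
                if sf is None:
                    continue
                per_slice.append(sf[0])
                weights.append(sf[1])
            if per_slice:
                w = np.asarray(weights, dtype=float)
                if config.slice_aggregation == "unweighted":
                    w = np.ones_like(w)
                w = w / w.sum()
                for f in FEATURES:
                    row[f] = float(np.sum(w * np.array([sf[f] for sf in per_slice])))
                row["n_pairs"] = int(np.sum(weights))
        rows[comp] = row
    out = pd.DataFrame(rows).T
    present = out.dropna(subset=["mean_t2"])
    all_row = {c: (float(present[c].mean()) if len(present) else np.nan)
               for c in ("mean_t2", *FEATURES)}
    all_row["n_pixels"] = int(out["n_pixels"].sum())
    all_row["n_pairs"] = int(out["n_pairs"].sum())
    out.loc["all"] = all_row
    out.index.name = "compartment"
    return out
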