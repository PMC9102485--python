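"""Semi-global stereo matching: census cost, path aggregation, winner selection.

The matcher approximates a full 2-D smoothness prior on the disparity field by
summing, for every pixel ``p`` and candidate disparity ``d``, the costs of 1-D
minimum-cost paths arriving at ``(p, d)`` from several directions.  Along one
path the recursion is

    L_r(p, d) = C(p, d) + min( L_r(p-r, d),
                               L_r(p-r, d-1) + P1,
                               L_r(p-r, d+1) + P1,
                               min_k L_r(p-r, k) + P2 )
                - min_k L_r(p-r, k)

where ``C`` is the pixelwise matching cost, ``P1`` penalizes one-level
disparity changes (slanted/curved surfaces) and ``P2 >= P1`` penalizes jumps
(depth discontinuities).  The trailing subtraction is the standard
normalization that keeps path costs bounded; it shifts every disparity's cost
at a pixel by the same constant and so never changes the winner.

The pixelwise cost is the Hamming distance between census transforms — a
radiometrically robust cost that only compares intensity *orderings* inside a
window, so it tolerates exposure differences between the two eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SGMParams",
    "CostVolume",
    "DisparityMap",
    "census_transform",
    "matching_cost",
    "aggregate_paths",
    "aggregate_single_path",
    "select_disparity",
    "cross_check",
    "compute_disparity",
]

INVALID = np.nan


@dataclass(frozen=True)
class SGMParams:
    """Search range, cost window, smoothness penalties, and refinement flags."""

    d_min: int = 0
    d_max: int = 64
    census_window: int = 5
    P1: int = 10
    P2: int = 120
    n_paths: int = 8
    subpixel: bool = True
    cross_check_tol: float = 1.0

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.d_max <= self.d_min:
            raise ValueError(f"need 0 <= d_min < d_max, got [{self.d_min}, {self.d_max}]")
        if self.census_window < 3 or self.census_window % 2 == 0:
            raise ValueError("census_window must be odd and >= 3")
        if self.P1 > self.P2:
            raise ValueError(f"P1 ({self.P1}) must not exceed P2 ({self.P2})")
        if self.n_paths not in (4, 8):
            raise ValueError("n_paths must be 4 or 8")

    @property
    def n_disp(self) -> int:
        return self.d_max - self.d_min + 1


@dataclass
class CostVolume:
    """Matching costs C(p, d) and, once aggregated, path sums S(p, d)."""

    C: np.ndarray                  # (rows, cols, n_disp) int32
    S: np.ndarray | None = None    # same shape, filled by aggregate_paths
    d_min: int = 0


@dataclass
class DisparityMap:
    """Left-referenced disparity in px with a validity mask.

    Invalid pixels hold NaN in ``disparity`` and False in ``valid``.
    """

    disparity: np.ndarray
    valid: np.ndarray
    params: SGMParams | None = None


def census_transform(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Per-pixel census bit string packed into uint64.

    Bit ``i`` (row-major neighbor order, center skipped) is 1 iff the
    neighbor's intensity is strictly below the center's.  Borders use edge
    replication.  Adding a constant to the image leaves the transform
    unchanged.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("census_transform expects a 2-D grayscale image")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(img.shape):
        raise ValueError(f"window {window} larger than image {img.shape}")
    r = window // 2
    if window * window - 1 > 64:
        raise ValueError("census window too large to pack into 64 bits")
    padded = np.pad(img, r, mode="edge")
    out = np.zeros(img.shape, dtype=np.uint64)
    bit = 0
    h, w = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy == 0 and dx == 0:
                continue
            neigh = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            out |= (neigh < img).astype(np.uint64) << np.uint64(bit)
            bit += 1
    return out


def matching_cost(
    left_census: np.ndarray, right_census: np.ndarray, params: SGMParams
) -> CostVolume:
    """Hamming-distance cost volume C(p, d) over the disparity search range.

    ``C[r, c, i]`` compares the left code at column ``c`` with the right code
    at ``c - (d_min + i)``; columns whose match falls outside the right image
    get the maximum cost (window^2 - 1) so they never win spuriously cheaply.
    """
    if left_census.shape != right_census.shape:
        raise ValueError("census rasters must have identical shapes")
    h, w = left_census.shape
    n = params.n_disp
    max_cost = params.census_window**2 - 1
    C = np.full((h, w, n), max_cost, dtype=np.int32)
    for i, d in enumerate(range(params.d_min, params.d_max + 1)):
        if d >= w:
            continue
        x = left_census[:, d:] ^ right_census[:, : w - d]
        C[:, d:, i] = np.bitwise_count(x).astype(np.int32)
    return CostVolume(C=C, d_min=params.d_min)


_DIRECTIONS_4 = [(0, 1), (0, -1), (1, 0), (-1, 0)]
_DIRECTIONS_8 = _DIRECTIONS_4 + [(1, 1), (1, -1), (-1, 1), (-1, -1)]


def _path_step(L_prev: np.ndarray, C_cur: np.ndarray, P1: int, P2: int,
               normalize: bool) -> np.ndarray:
    """One recursion step for a batch of pixels: L_prev, C_cur are (N, D)."""
    m = L_prev.min(axis=-1, keepdims=True)
    big = np.iinfo(np.int32).max // 4
    up = np.empty_like(L_prev)
    up[..., :-1] = L_prev[..., 1:]
    up[..., -1] = big
    down = np.empty_like(L_prev)
    down[..., 1:] = L_prev[..., :-1]
    down[..., 0] = big
    best = np.minimum(np.minimum(L_prev, m + P2), np.minimum(up, down) + P1)
    L = C_cur + best
    if normalize:
        L -= m
    return L


def _aggregate_one(C: np.ndarray, dr: int, dc: int, P1: int, P2: int,
                   normalize: bool) -> np.ndarray:
    """Aggregate along direction (dr, dc); pixels with no predecessor get L = C."""
    h, w, n = C.shape
    L = np.empty_like(C)
    if dr == 0:
        # pure horizontal: sweep columns
        cols = range(w) if dc == 1 else range(w - 1, -1, -1)
        first = True
        prev = None
        for c in cols:
            if first:
                L[:, c] = C[:, c]
                first = False
            else:
                L[:, c] = _path_step(L[:, c - dc], C[:, c], P1, P2, normalize)
        return L
    rows = range(h) if dr == 1 else range(h - 1, -1, -1)
    first = True
    for r in rows:
        if first:
            L[r] = C[r]
            first = False
            continue
        prev = L[r - dr]
        if dc == 0:
            L[r] = _path_step(prev, C[r], P1, P2, normalize)
        else:
            # predecessor of (r, c) is (r-dr, c-dc): shift previous row
            shifted = np.empty_like(prev)
            if dc == 1:
                shifted[1:] = prev[:-1]
                shifted[0] = 0
            else:
                shifted[:-1] = prev[1:]
                shifted[-1] = 0
            L[r] = _path_step(shifted, C[r], P1, P2, normalize)
            # border column has no predecessor
            edge = 0 if dc == 1 else w - 1
            L[r, edge] = C[r, edge]
    return L


def aggregate_single_path(
    cost: CostVolume, params: SGMParams, direction: tuple[int, int] = (0, 1),
    normalize: bool = True,
) -> np.ndarray:
    """L_r for one path direction only (useful against brute-force oracles)."""
    dr, dc = direction
    if (dr, dc) not in _DIRECTIONS_8:
        raise ValueError(f"direction must be one of {_DIRECTIONS_8}")
    return _aggregate_one(cost.C, dr, dc, params.P1, params.P2, normalize)


def aggregate_paths(cost: CostVolume, params: SGMParams, normalize: bool = True) -> CostVolume:
    """Fill S(p, d) by summing the 1-D path aggregations over all directions.

    ``n_paths`` = 4 uses the axis directions, 8 adds the diagonals.  With
    ``normalize=False`` the per-pixel min subtraction is skipped and each
    L_r(p, d) equals the raw minimum, over all disparity assignments of the
    path pixels ending at d, of the summed matching + transition costs
    (useful for exact comparison against brute-force enumeration).
    """
    dirs = _DIRECTIONS_8 if params.n_paths == 8 else _DIRECTIONS_4
    S = np.zeros_like(cost.C)
    for dr, dc in dirs:
        S += _aggregate_one(cost.C, dr, dc, params.P1, params.P2, normalize)
    return CostVolume(C=cost.C, S=S, d_min=cost.d_min)


def select_disparity(cost: CostVolume, params: SGMParams) -> DisparityMap:
    """Winner-take-all over aggregated costs with optional subpixel refinement.

    Ties break toward the smallest disparity.  Subpixel refinement fits a
    parabola through the aggregated costs at (d-1, d, d+1) and shifts the
    winner to the vertex, ``d + (S- - S+) / (2 (S- - 2 S0 + S+))``; winners at
    the range ends are left at integer precision.
    """
    S = cost.S if cost.S is not None else cost.C
    if S.shape[-1] < 1:
        raise ValueError("empty disparity range")
    idx = np.argmin(S, axis=-1)
    disp = idx.astype(np.float64) + cost.d_min
    if params.subpixel and S.shape[-1] >= 3:
        h, w, n = S.shape
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        interior = (idx > 0) & (idx < n - 1)
        i = np.clip(idx, 1, n - 2)
        s0 = S[rr, cc, i]
        sm = S[rr, cc, i - 1]
        sp = S[rr, cc, i + 1]
        denom = sm - 2 * s0 + sp
        ok = interior & (denom > 0)
        offset = np.zeros_like(disp)
        offset[ok] = (sm[ok] - sp[ok]) / (2.0 * denom[ok])
        disp += np.clip(offset, -0.5, 0.5)
    valid = np.ones_like(disp, dtype=bool)
    return DisparityMap(disparity=disp, valid=valid, params=params)


def cross_check(
    left_disp: DisparityMap, right_disp: DisparityMap, tol: float = 1.0
) -> np.ndarray:
    """Left-right consistency mask.

    A left pixel ``(r, c)`` with disparity ``d`` is kept iff its match
    ``(r, c - d)`` lands inside the right map and the right disparity there
    (sampled at the nearest column) agrees within ``tol`` px.  Occluded
    regions fail this check because the two views disagree about them.
    """
    dL = left_disp.disparity
    h, w = dL.shape
    cols = np.arange(w)[None, :].repeat(h, axis=0)
    target = np.rint(cols - dL).astype(np.int64)
    inb = (target >= 0) & (target < w) & np.isfinite(dL)
    tgt = np.clip(target, 0, w - 1)
    rows = np.arange(h)[:, None].repeat(w, axis=1)
    dR = right_disp.disparity[rows, tgt]
    ok = inb & np.isfinite(dR) & (np.abs(dL - dR) <= tol)
    return ok & left_disp.valid


def _right_cost_from_left(C_left: np.ndarray, params: SGMParams) -> np.ndarray:
    """Right-referenced cost volume by re-indexing the left one.

    C_R(r, c, d) = C_L(r, c + d, d); columns whose match exits the left image
    get the maximum cost.
    """
    h, w, n = C_left.shape
    max_cost = params.census_window**2 - 1
    CR = np.full_like(C_left, max_cost)
    for i, d in enumerate(range(params.d_min, params.d_max + 1)):
        if d >= w:
            continue
        CR[:, : w - d, i] = C_left[:, d:, i]
    return CR


def compute_disparity(
    left: np.ndarray, right: np.ndarray, params: SGMParams, cross: bool = True
) -> DisparityMap:
    """Full matcher: census -> cost -> aggregation -> winner -> consistency.

    When ``cross`` is set a right-referenced disparity map is computed from
    the re-indexed cost volume and inconsistent pixels are invalidated
    (NaN), which removes occlusions and most gross mismatches.
    """
    cl = census_transform(left, params.census_window)
    cr = census_transform(right, params.census_window)
    cost = matching_cost(cl, cr, params)
    agg = aggregate_paths(cost, params)
    disp = select_disparity(agg, params)
    if cross:
        cost_r = CostVolume(C=_right_cost_from_left(cost.C, params), d_min=params.d_min)
        agg_r = aggregate_paths(cost_r, params)
        disp_r = select_disparity(agg_r, params)
        ok = cross_check(disp, disp_r, params.cross_check_tol)
        disp.valid = ok
        disp.disparity = np.where(ok, disp.disparity, INVALID)
    return disp
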