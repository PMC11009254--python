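"""Bundle recognition and tract-profile extraction.

A bundle is recognized from candidate streamlines by four geometric
conditions: a streamline must (1) not cross the sagittal midline, (2) pass
within tolerance of both inclusion ROIs, (3) stay clear of the exclusion
ROI, and (4) terminate within tolerance of the two endpoint ROIs.
Recognized bundles are then cleaned of outliers in length and trajectory,
and summarized as a tract profile: a scalar tissue property sampled at a
fixed number of equidistant nodes along the bundle core, averaged across
streamlines with weights that down-weight streamlines far from the core.
"""

from __future__ import annotations

import numpy as np

from .scenes import Scene

Bundle = list  # list of (n_i, 3) float arrays


def resample_streamline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equidistant (arc-length) nodes."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("a streamline needs >= 2 three-dimensional points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:  # degenerate: all points coincide
        return np.repeat(pts[:1], n_points, axis=0)
    t = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])


def streamline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _crosses_midline(pts: np.ndarray, midline_x: float) -> bool:
    side = pts[:, 0] - midline_x
    return bool((side > 0).any() and (side < 0).any())


def filter_streamlines(scene: Scene, tol: float = 3.0) -> Bundle:
    """Recognize the bundle: keep streamlines meeting all four conditions.

    1. no point on both sides of the sagittal midline plane;
    2. at least one point within ``tol`` mm of each inclusion ROI;
    3. no point within ``tol`` mm of the exclusion ROI;
    4. the two termini lie within ``tol`` mm of the two endpoint ROIs
       (better of the two terminus-to-ROI assignments).

    Distances are signed point-to-surface distances (negative inside), so
    "within tol" includes points inside an ROI.  Idempotent: filtering a
    filtered bundle changes nothing.
    """
    kept: Bundle = []
    for pts in scene.streamlines:
        pts = np.asarray(pts, dtype=float)
        if _crosses_midline(pts, scene.midline_x):
            continue
        if any(roi.distance(pts).min() > tol for roi in scene.include_rois):
            continue
        if scene.exclude_roi.distance(pts).min() <= tol:
            continue
        ra, rb = scene.endpoint_rois
        first, last = pts[0], pts[-1]
        direct = max(ra.distance(first[None])[0], rb.distance(last[None])[0])
        swapped = max(rb.distance(first[None])[0], ra.distance(last[None])[0])
        if min(direct, swapped) > tol:
            continue
        kept.append(pts)
    return kept


def clean_bundle(bundle: Bundle, distance_z_thresh: float = 3.0,
                 length_z_thresh: float = 4.0, n_iter: int = 5,
                 n_resample: int = 100) -> Bundle:
    """Remove outliers in length and trajectory, iteratively.

    Each pass resamples all streamlines, computes the bundle core (the
    node-wise mean), and removes streamlines whose length z-score exceeds
    ``length_z_thresh`` or whose mean node-wise distance from the core has
    a z-score above ``distance_z_thresh``.  Removal is decided against the
    statistics of the pass, so it is order-independent within a pass.
    Bundles of fewer than 3 streamlines are returned unchanged.
    """
    current = [np.asarray(s, dtype=float) for s in bundle]
    for _ in range(n_iter):
        if len(current) < 3:
            break
        resampled = np.stack([resample_streamline(s, n_resample) for s in current])
        lengths = np.array([streamline_length(s) for s in current])
        core = resampled.mean(axis=0)
        core_dist = np.linalg.norm(resampled - core[None], axis=2).mean(axis=1)

        def zscores(x: np.ndarray) -> np.ndarray:
            sd = x.std(ddof=1)
            if sd == 0.0:
                return np.zeros_like(x)
            return (x - x.mean()) / sd

        bad = (np.abs(zscores(lengths)) > length_z_thresh) | \
              (np.abs(zscores(core_dist)) > distance_z_thresh)
        if not bad.any():
            break
        current = [s for s, b in zip(current, bad) if not b]
    return current


def _orient_bundle(resampled: np.ndarray) -> np.ndarray:
    """Flip streamlines so they all run the same way as the first one."""
    ref = resampled[0]
    out = resampled.copy()
    for i in range(1, len(out)):
        fwd = np.linalg.norm(out[i] - ref, axis=1).sum()
        rev = np.linalg.norm(out[i][::-1] - ref, axis=1).sum()
        if rev < fwd:
            out[i] = out[i][::-1]
    return out


def compute_tract_profile(bundle: Bundle, scalar_field,
                          n_points: int = 100) -> np.ndarray | None:
    """Profile a scalar field along the bundle core at ``n_points`` nodes.

    Streamlines are resampled to ``n_points`` equidistant nodes and
    oriented consistently (each is flipped if that brings it closer to the
    first streamline).  At each node the field is sampled at every
    streamline's node position and averaged with Gaussian weights
    ``exp(-d²/2)`` on the Mahalanobis distance ``d`` of the position from
    the node's point cloud, so stray streamlines contribute little.

    ``scalar_field`` maps an (m, 3) array of positions to m values.
    Returns ``None`` for an empty bundle (a missing profile).
    """
    if len(bundle) == 0:
        return None
    resampled = np.stack([resample_streamline(s, n_points) for s in bundle])
    resampled = _orient_bundle(resampled)
    n_sl = resampled.shape[0]
    profile = np.empty(n_points)
    for j in range(n_points):
        cloud = resampled[:, j, :]
        values = np.asarray(scalar_field(cloud), dtype=float)
        if n_sl == 1:
            profile[j] = values[0]
            continue
        mu = cloud.mean(axis=0)
        cov = np.cov(cloud.T, ddof=1)
        cov[np.diag_indices_from(cov)] += 1e-6 * max(np.trace(cov) / 3.0, 1e-6)
        delta = cloud - mu
        d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
        w = np.exp(-0.5 * np.clip(d2, 0.0, 700.0))
        profile[j] = float(np.average(values, weights=w))
    return profile


def trim_profile(profile: np.ndarray, n_trim: int = 10) -> np.ndarray:
    """Drop ``n_trim`` nodes from each end of a profile.

    The first and last nodes of a tract profile are the most contaminated
    by partial-volume effects with gray matter, so the standard analysis
    keeps only the middle of the profile (100 → 80 nodes by default).
    """
    profile = np.asarray(profile)
    if n_trim < 0:
        raise ValueError("n_trim must be non-negative")
    if 2 * n_trim >= profile.shape[-1]:
        raise ValueError("trimming would remove every node")
    if n_trim == 0:
        return profile
    return profile[..., n_trim:-n_trim]
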