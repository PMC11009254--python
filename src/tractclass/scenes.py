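"""Synthetic 3D streamline scenes for exercising bundle recognition.

A scene bundles candidate streamlines (polylines in mm coordinates) with
the anatomical landmarks the recognizer needs: two inclusion ROIs, one
exclusion ROI, two endpoint ROIs, and the sagittal midline plane (x = 0).
ROIs are spheres here — the point is the geometry of the acceptance
conditions, not anatomical realism.

Scenes are built so that a known subset of streamlines satisfies all four
acceptance conditions *by construction*; the scene records those labels so
recognition can be tested against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_N_POINTS = 31


@dataclass(frozen=True)
class SphereROI:
    """Spherical region of interest; distances are to the surface."""
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from each point to the sphere surface (< 0 inside)."""
        d = np.linalg.norm(np.asarray(points) - np.asarray(self.center), axis=-1)
        return d - self.radius


@dataclass
class Scene:
    """Candidate streamlines plus the ROIs used to recognize a bundle."""
    streamlines: list[np.ndarray]
    include_rois: tuple[SphereROI, SphereROI]
    exclude_roi: SphereROI
    endpoint_rois: tuple[SphereROI, SphereROI]
    midline_x: float = 0.0
    #: by-construction survival labels, parallel to ``streamlines``
    expected_survivors: np.ndarray = field(default_factory=lambda: np.array([], bool))


@dataclass(frozen=True)
class SceneConfig:
    """How many streamlines of each kind to construct.

    The valid streamlines run along y at x ≈ -25 mm (left hemisphere),
    from one endpoint ROI to the other, passing through both inclusion
    ROIs and staying clear of the exclusion ROI.  Each invalid kind
    violates exactly one acceptance condition.
    """
    n_valid: int = 10
    n_midline_crossers: int = 3      # wander across x = 0
    n_exclusion_hits: int = 3        # approach the exclusion ROI within 2 mm
    n_far_endpoint: int = 3          # terminate 5 mm short of an endpoint ROI
    n_off_track: int = 3             # never come near the inclusion ROIs
    jitter_mm: float = 0.8


def generate_bundle_scene(seed: int, cfg: SceneConfig | None = None) -> Scene:
    """Construct a deterministic scene with known survivors.

    The geometry: endpoint ROIs (radius 4) at y = ∓40, inclusion ROIs
    (radius 5) at y = ∓15, all centred at x = -25, z = 0; exclusion ROI
    (radius 5) above the bundle at z = 15.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(seed)
    x0 = -25.0
    ep_a = SphereROI((x0, -40.0, 0.0), 4.0)
    ep_b = SphereROI((x0, 40.0, 0.0), 4.0)
    inc_a = SphereROI((x0, -15.0, 0.0), 5.0)
    inc_b = SphereROI((x0, 15.0, 0.0), 5.0)
    exc = SphereROI((x0, 0.0, 15.0), 5.0)

    y = np.linspace(-40.0, 40.0, _N_POINTS)

    def base_line(jitter: bool = True) -> np.ndarray:
        pts = np.column_stack([np.full_like(y, x0), y, np.zeros_like(y)])
        if jitter:
            pts[:, [0, 2]] += rng.normal(0.0, cfg.jitter_mm, size=(len(y), 2))
            pts[0] = (x0, -40.0, 0.0) + rng.normal(0, 0.5, 3)
            pts[-1] = (x0, 40.0, 0.0) + rng.normal(0, 0.5, 3)
        return pts

    streamlines: list[np.ndarray] = []
    labels: list[bool] = []

    for _ in range(cfg.n_valid):
        streamlines.append(base_line())
        labels.append(True)

    for _ in range(cfg.n_midline_crossers):
        pts = base_line()
        # swing across the sagittal midline near the middle of the path
        bump = 30.0 * np.exp(-0.5 * ((y - 0.0) / 8.0) ** 2)
        pts[:, 0] = x0 + bump  # reaches x = +5 at the apex
        streamlines.append(pts)
        labels.append(False)

    for _ in range(cfg.n_exclusion_hits):
        pts = base_line()
        # closest approach 2 mm from the exclusion ROI surface:
        # apex at (x0, 0, 8) is 7 mm from the centre, radius 5
        pts[:, 2] += 8.0 * np.exp(-0.5 * (y / 6.0) ** 2)
        idx = np.argmin(np.abs(y))
        pts[idx] = (x0, 0.0, 8.0)
        streamlines.append(pts)
        labels.append(False)

    for _ in range(cfg.n_far_endpoint):
        pts = base_line()
        # terminal point 9 mm from the endpoint centre = 5 mm from surface
        pts = pts[y <= 31.0]
        pts[-1] = (x0, 31.0, 0.0)
        streamlines.append(pts)
        labels.append(False)

    for _ in range(cfg.n_off_track):
        pts = base_line(jitter=False)
        pts[:, 2] += 15.0  # parallel but 15 mm above: misses inclusion ROIs
        # and also the exclusion ROI? no: z=15 passes through it; shift x too
        pts[:, 0] -= 20.0
        streamlines.append(pts)
        labels.append(False)

    return Scene(streamlines=streamlines,
                 include_rois=(inc_a, inc_b),
                 exclude_roi=exc,
                 endpoint_rois=(ep_a, ep_b),
                 midline_x=0.0,
                 expected_survivors=np.array(labels, dtype=bool))


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _roi_to_dict(roi: SphereROI) -> dict:
    return {"center": list(map(float, roi.center)), "radius": float(roi.radius)}


def _roi_from_dict(d: dict) -> SphereROI:
    return SphereROI(tuple(d["center"]), d["radius"])


def scene_to_json(scene: Scene, path) -> None:
    obj = {
        "streamlines": [s.tolist() for s in scene.streamlines],
        "include_rois": [_roi_to_dict(r) for r in scene.include_rois],
        "exclude_roi": _roi_to_dict(scene.exclude_roi),
        "endpoint_rois": [_roi_to_dict(r) for r in scene.endpoint_rois],
        "midline_x": scene.midline_x,
        "expected_survivors": scene.expected_survivors.astype(int).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def scene_from_json(path) -> Scene:
    with open(path) as fh:
        obj = json.load(fh)
    return Scene(
        streamlines=[np.asarray(s, dtype=float) for s in obj["streamlines"]],
        include_rois=tuple(_roi_from_dict(r) for r in obj["include_rois"]),
        exclude_roi=_roi_from_dict(obj["exclude_roi"]),
        endpoint_rois=tuple(_roi_from_dict(r) for r in obj["endpoint_rois"]),
        midline_x=obj["midline_x"],
        expected_survivors=np.asarray(obj["expected_survivors"], dtype=bool),
    )
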