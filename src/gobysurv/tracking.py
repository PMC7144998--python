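"""Multi-fish centroid tracking in a circular arena.

Fish recorded from above in a 23 cm circular arena are nearly transparent,
so tracking works on local contrast: the arena disc is located by global
thresholding, candidate fish are segmented by an adaptive (Gaussian-weighted
neighbourhood) threshold, blobs are filtered by area to reject shadows and
specks, and blob-to-fish identity is maintained frame-to-frame by
minimum-cost assignment (Hungarian/Munkres) on the Euclidean distance
matrix.  When occlusion or poor segmentation yields fewer blobs than fish,
unmatched fish keep their previous position and are flagged imputed; they
rejoin the assignment on later frames.

Trajectories are converted to swimming speeds (mm/s) and averaged in
non-overlapping 60-frame bins, yielding 40 bins before and 40 after the
stimulus at the standard 20 frames/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure

from gobysurv.vitality import SpeedSeries

__all__ = [
    "ArenaGeometry",
    "Blob",
    "Trajectory",
    "TrackingConfig",
    "detect_arena",
    "segment_blobs",
    "assign_blobs",
    "track",
    "extract_binned_speeds",
    "ARENA_DIAMETER_MM",
]

#: Physical diameter of the recording arena (mm).
ARENA_DIAMETER_MM = 230.0


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena disc in pixel coordinates; sets the mm-per-pixel scale."""

    center: tuple[float, float]  # (x, y)
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be > 0")

    @property
    def mm_per_px(self) -> float:
        return ARENA_DIAMETER_MM / (2.0 * self.radius)

    def mask(self, shape: tuple[int, int], margin_px: float = 2.0) -> np.ndarray:
        """Boolean mask of pixels inside the arena (shrunk by margin_px)."""
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        cx, cy = self.center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= (self.radius - margin_px) ** 2


@dataclass(frozen=True)
class Blob:
    """A segmented candidate-fish region: centroid (x, y) and pixel area."""

    centroid: tuple[float, float]
    area: int


@dataclass
class Trajectory:
    """Per-frame positions (x, y) of one fish; imputed frames carried forward."""

    fish_id: int
    positions: np.ndarray  # (n_frames, 2)
    imputed: np.ndarray  # (n_frames,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if len(self.positions) != len(self.imputed):
            raise ValueError("positions and imputed flags must align per frame")


@dataclass
class TrackingConfig:
    """Segmentation and arena-detection knobs.

    ``fish_polarity`` says whether fish are darker or brighter than their
    local background; ``arena_polarity`` likewise for the arena disc against
    the surround.  The adaptive threshold subtracts ``adaptive_offset`` from
    a Gaussian-weighted neighbourhood mean over ``adaptive_block`` pixels
    (odd).  Blobs outside [min_area, max_area] are discarded.
    """

    arena_threshold: float | None = None  # None -> Otsu
    arena_polarity: str = "bright"
    fish_polarity: str = "dark"
    adaptive_block: int = 25
    adaptive_offset: float = 10.0
    min_area: int = 4
    max_area: int = 400
    redetect_arena: bool = False  # reuse first-frame geometry by default

    def __post_init__(self) -> None:
        if self.adaptive_block % 2 == 0 or self.adaptive_block < 3:
            raise ValueError("adaptive_block must be odd and >= 3")
        for p in (self.arena_polarity, self.fish_polarity):
            if p not in ("bright", "dark"):
                raise ValueError("polarity must be 'bright' or 'dark'")


def detect_arena(
    frame: np.ndarray,
    threshold: float | None = None,
    polarity: str = "bright",
) -> ArenaGeometry:
    """Locate the circular arena by global thresholding.

    The largest connected region above (below, for dark polarity) the
    threshold is taken as the arena; its centroid and equivalent-circle
    radius define the geometry.  Default threshold is Otsu's.
    """
    img = np.asarray(frame, dtype=float)
    if threshold is None:
        threshold = float(filters.threshold_otsu(img))
    binary = img > threshold if polarity == "bright" else img < threshold
    if not binary.any():
        raise ValueError("no region found above the arena threshold")
    labels = measure.label(binary)
    regions = measure.regionprops(labels)
    arena = max(regions, key=lambda r: r.area)
    cy, cx = arena.centroid
    radius = math.sqrt(arena.area / math.pi)
    return ArenaGeometry(center=(cx, cy), radius=radius)


def segment_blobs(
    frame: np.ndarray,
    arena: ArenaGeometry,
    adaptive_block: int = 25,
    adaptive_offset: float = 10.0,
    min_area: int = 4,
    max_area: int = 400,
    fish_polarity: str = "dark",
) -> list[Blob]:
    """Adaptive-threshold segmentation of candidate fish inside the arena.

    Illumination is not uniform across the arena, so each pixel is compared
    to a Gaussian-weighted mean of its neighbourhood rather than a single
    global threshold.  Connected components are filtered to
    [min_area, max_area]; centroids are centres of mass.
    """
    img = np.asarray(frame, dtype=float)
    local = filters.threshold_local(
        img, block_size=adaptive_block, method="gaussian", offset=adaptive_offset
    )
    binary = (img < local) if fish_polarity == "dark" else (img > local)
    binary &= arena.mask(img.shape)
    blobs = []
    for r in measure.regionprops(measure.label(binary)):
        if min_area <= r.area <= max_area:
            cy, cx = r.centroid
            blobs.append(Blob(centroid=(cx, cy), area=int(r.area)))
    return blobs


def assign_blobs(
    prev_positions: Sequence[tuple[float, float]],
    blobs: Sequence[Blob],
) -> tuple[dict[int, int], set[int]]:
    """Match fish to blobs by minimum total Euclidean distance.

    Returns ``(assignment, imputed)`` where ``assignment[fish] = blob`` and
    ``imputed`` holds fish indices left without a blob (fewer blobs than
    fish: those fish keep their previous position).  Surplus blobs are
    ignored.  The Hungarian solution is deterministic; cost ties resolve to
    the lowest fish index.
    """
    if len(prev_positions) == 0:
        raise ValueError("need at least one tracked fish")
    if not blobs:
        return {}, set(range(len(prev_positions)))
    pf = np.asarray(prev_positions, dtype=float)
    pb = np.asarray([b.centroid for b in blobs], dtype=float)
    cost = np.linalg.norm(pf[:, None, :] - pb[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignment = {int(r): int(c) for r, c in zip(rows, cols)}
    imputed = set(range(len(prev_positions))) - set(assignment)
    return assignment, imputed


def track(
    frames: Sequence[np.ndarray] | np.ndarray,
    initial_positions: Sequence[tuple[float, float]],
    config: TrackingConfig | None = None,
) -> list[Trajectory]:
    """Track every fish through a frame stack.

    The first frame fixes the arena geometry (re-detected per frame if
    ``config.redetect_arena``); initial fish positions are supplied by the
    caller (selected manually in practice).  Per frame: segment blobs,
    assign, carry forward unmatched fish.
    """
    config = config or TrackingConfig()
    n_frames = len(frames)
    n_fish = len(initial_positions)
    if n_fish == 0:
        raise ValueError("need at least one initial position")
    if n_frames == 0:
        return [
            Trajectory(i, np.empty((0, 2)), np.empty(0, dtype=bool))
            for i in range(n_fish)
        ]
    shape = np.asarray(frames[0]).shape
    positions = np.empty((n_frames, n_fish, 2))
    imputed = np.zeros((n_frames, n_fish), dtype=bool)
    current = np.asarray(initial_positions, dtype=float)

    arena = detect_arena(
        frames[0], threshold=config.arena_threshold, polarity=config.arena_polarity
    )
    for f in range(n_frames):
        frame = np.asarray(frames[f])
        if frame.shape != shape:
            raise ValueError(f"frame {f} has shape {frame.shape}, expected {shape}")
        if config.redetect_arena and f > 0:
            arena = detect_arena(
                frame, threshold=config.arena_threshold, polarity=config.arena_polarity
            )
        blobs = segment_blobs(
            frame,
            arena,
            adaptive_block=config.adaptive_block,
            adaptive_offset=config.adaptive_offset,
            min_area=config.min_area,
            max_area=config.max_area,
            fish_polarity=config.fish_polarity,
        )
        assignment, missing = assign_blobs(current, blobs)
        for i in range(n_fish):
            if i in assignment:
                current[i] = blobs[assignment[i]].centroid
            imputed[f, i] = i in missing
        positions[f] = current
    return [
        Trajectory(i, positions[:, i, :], imputed[:, i]) for i in range(n_fish)
    ]


def extract_binned_speeds(
    traj: Trajectory,
    mm_per_px: float,
    stimulus_frame: int | None = None,
    fps: float = 20.0,
    bin_frames: int = 60,
    n_bins: int = 40,
    haul_id: str = "",
) -> SpeedSeries:
    """Binned swimming speeds around the stimulus.

    Per-frame speed is the Euclidean displacement between consecutive
    positions times fps times mm_per_px; averaging over ``bin_frames``
    consecutive frames reduces temporal autocorrelation, giving ``n_bins``
    values on each side of the stimulus (40 + 40 for 2 min at 20 fps with
    60-frame bins).  Carried-forward (imputed) frames contribute zero
    displacement; the accumulated movement registers when the fish is
    reacquired.  ``stimulus_frame`` defaults to the stack midpoint.
    """
    pos = traj.positions
    if stimulus_frame is None:
        stimulus_frame = len(pos) // 2
    window = bin_frames * n_bins
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)  # disp[j]: frame j -> j+1
    if stimulus_frame - window < 0 or stimulus_frame + window > len(disp):
        raise ValueError(
            f"trajectory must span {window} frames on each side of the stimulus; "
            f"have {len(pos)} frames with stimulus at {stimulus_frame}"
        )
    speed = disp * fps * mm_per_px
    before = speed[stimulus_frame - window: stimulus_frame]
    after = speed[stimulus_frame: stimulus_frame + window]
    return SpeedSeries(
        haul_id=haul_id,
        fish_id=str(traj.fish_id),
        before=before.reshape(n_bins, bin_frames).mean(axis=1),
        after=after.reshape(n_bins, bin_frames).mean(axis=1),
    )
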