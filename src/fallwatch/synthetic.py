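"""Synthetic silhouettes, activity sequences and shadowed scenes with ground truth.

Real posture/fall footage cannot ship with the package, so every test input
is generated here from seeds:

* :func:`render_posture` draws a single binary silhouette of an articulated
  stick-and-capsule body (shank, thigh, torso, head) posed as one of the four
  posture classes, with size/aspect/rotation jitter and boundary noise.
* :func:`generate_sequence` animates the same body through scripted
  activities (fall, slow lie-down, walk, sit, bend) and returns per-frame
  masks, a floor mask and frame-level ground truth.  Falls reach the lying
  pose within <= 25 frames; deliberate lying takes >= 80 frames — the same
  timing contrast the rule engine keys on.
* :func:`generate_shadow_scene` builds a textured background, a cast-shadow
  region (value channel scaled by rho with hue/saturation preserved) and a
  differently-hued person region, with truth masks for both.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.draw import disk, polygon

from .classifier import POSTURE_CODES

__all__ = [
    "PostureShapeParams",
    "ScenarioScript",
    "SequenceData",
    "ShadowScene",
    "render_posture",
    "posture_dataset",
    "generate_sequence",
    "generate_shadow_scene",
    "render_color_sequence",
]

EIGHT = np.ones((3, 3), dtype=bool)

# Body segment proportions (fractions of the body scale S).
SHANK_LEN = 0.25
THIGH_LEN = 0.22
TORSO_LEN = 0.56
LIMB_WIDTH = 0.16
TORSO_WIDTH = 0.32
HEAD_RADIUS = 0.10


@dataclass(frozen=True)
class PostureShapeParams:
    """Knobs of the single-silhouette generator (defaults: moderate jitter)."""

    label: int = POSTURE_CODES["stand"]
    frame_shape: tuple[int, int] = (128, 128)  # (rows, cols)
    scale: float = 48.0  # body height scale in pixels
    position: tuple[float, float] | None = None  # base point (x, y); None = random
    scale_jitter: float = 0.2  # relative +- on scale
    aspect_jitter: float = 0.15  # relative +- on segment widths
    rotation_jitter: float = 0.10  # std-dev (radians) on joint angles
    noise_amp: int = 2  # boundary-noise ring thickness in pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale < 20:
            raise ValueError("scale must be >= 20 px")
        if self.noise_amp >= self.scale / 4:
            raise ValueError("noise amplitude must stay below scale/4")


def _capsule(mask: np.ndarray, p: np.ndarray, q: np.ndarray, width: float) -> None:
    """Draw a thick segment (rectangle plus end caps) from p to q, in place."""
    h, w = mask.shape
    d = q - p
    length = math.hypot(*d)
    if length > 1e-9:
        nvec = np.array([-d[1], d[0]]) / length * (width / 2)
        corners = np.array([p + nvec, q + nvec, q - nvec, p - nvec])
        rr, cc = polygon(corners[:, 1], corners[:, 0], shape=(h, w))
        mask[rr, cc] = True
    for center in (p, q):
        rr, cc = disk((center[1], center[0]), width / 2, shape=(h, w))
        mask[rr, cc] = True


def _direction(phi: float) -> np.ndarray:
    """Unit vector at angle ``phi`` from vertical-up, rotating toward +x."""
    return np.array([math.sin(phi), -math.cos(phi)])


def _body_offsets(
    scale: float, phi_torso: float, phi_thigh: float, phi_shank: float
) -> np.ndarray:
    """Key body points (feet, knee, hip, chest, head) relative to the base."""
    knee = _direction(phi_shank) * (SHANK_LEN * scale)
    hip = knee + _direction(phi_thigh) * (THIGH_LEN * scale)
    chest = hip + _direction(phi_torso) * (TORSO_LEN * scale)
    head = hip + _direction(phi_torso) * (TORSO_LEN * scale + 0.8 * HEAD_RADIUS * scale)
    return np.array([np.zeros(2), knee, hip, chest, head])


def draw_person(
    frame_shape: tuple[int, int],
    base: tuple[float, float],
    scale: float,
    phi_torso: float,
    phi_thigh: float,
    phi_shank: float,
    width_factor: float = 1.0,
    check_bounds: bool = True,
) -> np.ndarray:
    """Rasterize the articulated body; angles in radians from vertical.

    The kinematic chain runs feet -> shank -> knee -> thigh -> hip -> torso
    -> head.  ``base`` is the foot point (x, y).  Raises when the shape would
    leave the frame.
    """
    h, w = frame_shape
    s = scale
    base = np.asarray(base, dtype=float)
    knee = base + _direction(phi_shank) * (SHANK_LEN * s)
    hip = knee + _direction(phi_thigh) * (THIGH_LEN * s)
    chest = hip + _direction(phi_torso) * (TORSO_LEN * s)
    head = hip + _direction(phi_torso) * (TORSO_LEN * s + 0.8 * HEAD_RADIUS * s)
    limb_w = LIMB_WIDTH * s * width_factor
    torso_w = TORSO_WIDTH * s * width_factor
    if check_bounds:
        margin = torso_w / 2 + HEAD_RADIUS * s + 1
        pts = np.array([base, knee, hip, chest, head])
        if (
            (pts[:, 0] < margin).any()
            or (pts[:, 0] >= w - margin).any()
            or (pts[:, 1] < margin).any()
            or (pts[:, 1] >= h - margin).any()
        ):
            raise ValueError("shape out of frame")
    mask = np.zeros(frame_shape, dtype=bool)
    _capsule(mask, base, knee, limb_w)
    _capsule(mask, knee, hip, limb_w)
    _capsule(mask, hip, chest, torso_w)
    rr, cc = disk((head[1], head[0]), HEAD_RADIUS * s, shape=frame_shape)
    mask[rr, cc] = True
    return mask


#: Canonical joint angles (torso, thigh, shank) per posture, radians.
_POSES = {
    POSTURE_CODES["stand"]: (0.0, 0.0, 0.0),
    POSTURE_CODES["lie"]: (math.pi / 2, math.pi / 2, math.pi / 2),
    POSTURE_CODES["sit"]: (-0.12, -math.pi / 2, 0.0),
    POSTURE_CODES["bend"]: (math.radians(65), 0.0, 0.0),
}


def _sample_pose(label: int, rng: np.random.Generator, jitter: float) -> np.ndarray:
    """Class-conditional joint angles: canonical pose plus within-class
    variability (different people bend/sit to different depths) plus a small
    global jitter on every joint."""
    torso, thigh, shank = _POSES[label]
    phis = np.array([torso, thigh, shank], dtype=float)
    if jitter > 0:
        if label == POSTURE_CODES["bend"]:
            phis[0] = rng.uniform(math.radians(48), math.radians(80))
        elif label == POSTURE_CODES["sit"]:
            phis[0] = torso + rng.uniform(-0.2, 0.15)
            phis[1] = thigh + rng.normal(0, 2 * jitter)
        phis += rng.normal(0, jitter, 3)
    return phis


def _apply_boundary_noise(mask: np.ndarray, amp: int, rng: np.random.Generator, p: float = 0.3) -> np.ndarray:
    """Randomly flip pixels in a ring of thickness ``amp`` around the boundary,
    then keep the largest 8-connected component and fill holes."""
    if amp > 0 and mask.any():
        outer = ndimage.binary_dilation(mask, EIGHT, iterations=amp) & ~mask
        inner = mask & ~ndimage.binary_erosion(mask, EIGHT, iterations=amp)
        noisy = mask.copy()
        noisy[outer & (rng.random(mask.shape) < p)] = True
        noisy[inner & (rng.random(mask.shape) < p)] = False
        mask = noisy
    labels, n = ndimage.label(mask, structure=EIGHT)
    if n > 1:
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        mask = labels == areas.argmax()
    return ndimage.binary_fill_holes(mask)


def render_posture(params: PostureShapeParams) -> tuple[np.ndarray, int]:
    """One jittered silhouette of the requested posture class.

    Returns ``(mask, label)``; the mask is a single 8-connected component
    and the call is deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.frame_shape
    s = params.scale * (1 + rng.uniform(-params.scale_jitter, params.scale_jitter))
    width_factor = 1 + rng.uniform(-params.aspect_jitter, params.aspect_jitter)
    phis = _sample_pose(params.label, rng, params.rotation_jitter)
    if params.position is not None:
        base = params.position
    else:
        # Random base chosen so the whole posed body fits in the frame:
        # compute the body-point offsets for this pose, then sample the base
        # uniformly over the admissible rectangle.
        offsets = _body_offsets(s, *phis)
        margin = TORSO_WIDTH * s * width_factor / 2 + HEAD_RADIUS * s + 2
        x_lo = margin - offsets[:, 0].min()
        x_hi = w - margin - offsets[:, 0].max()
        y_lo = margin - offsets[:, 1].min()
        y_hi = h - margin - offsets[:, 1].max()
        if x_hi <= x_lo or y_hi <= y_lo:
            raise ValueError("shape out of frame: scale too large for frame")
        base = (rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi))
    mask = draw_person((h, w), base, s, *phis, width_factor=width_factor)
    mask = _apply_boundary_noise(mask, params.noise_amp, rng)
    return mask, params.label


def posture_dataset(
    n_per_class: int,
    seed: int = 0,
    frame_shape: tuple[int, int] = (128, 128),
    scale: float = 48.0,
    scale_jitter: float = 0.2,
    aspect_jitter: float = 0.15,
    rotation_jitter: float = 0.10,
    noise_amp: int = 2,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Balanced labeled set of jittered silhouettes: (masks, labels)."""
    masks, labels = [], []
    root = np.random.default_rng(seed)
    for label in sorted(_POSES):
        for _ in range(n_per_class):
            sub = int(root.integers(0, 2**31 - 1))
            m, _ = render_posture(
                PostureShapeParams(
                    label=label,
                    frame_shape=frame_shape,
                    scale=scale,
                    scale_jitter=scale_jitter,
                    aspect_jitter=aspect_jitter,
                    rotation_jitter=rotation_jitter,
                    noise_amp=noise_amp,
                    seed=sub,
                )
            )
            masks.append(m)
            labels.append(label)
    return masks, np.array(labels, dtype=int)


@dataclass(frozen=True)
class ScenarioScript:
    """Script for one activity sequence."""

    scenario: str  # fall | lie_down | sit | walk | bend
    n_frames: int | None = None  # None -> walk + transition + tail
    transition_frames: int = 0  # fall <= 25, lie_down >= 80
    walk_frames: int = 20
    tail_frames: int = 40
    frame_shape: tuple[int, int] = (120, 160)
    scale: float = 44.0
    floor_top_frac: float = 0.4  # floor = lower (1 - frac) of the frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in {"fall", "lie_down", "sit", "walk", "bend"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        t = self.resolved_transition
        if self.scenario == "fall" and not (1 <= t <= 25):
            raise ValueError("fall scripts need transition_frames in [1, 25]")
        if self.scenario == "lie_down" and t < 80:
            raise ValueError("lie_down scripts need transition_frames >= 80")
        if self.n_frames is not None and self.n_frames < t + self.tail_frames:
            raise ValueError("n_frames too small for transition + inactivity tail")

    @property
    def resolved_transition(self) -> int:
        if self.transition_frames:
            return self.transition_frames
        return {"fall": 18, "lie_down": 90, "sit": 8, "bend": 15, "walk": 0}[
            self.scenario
        ]


@dataclass
class SequenceData:
    scenario: str
    masks: list[np.ndarray] = field(repr=False)
    floor: np.ndarray = field(repr=False)
    truth_labels: np.ndarray  # per-frame posture codes
    truth_verdict: bool  # does this sequence contain a fall?
    truth_fall_frame: int | None


def _fall_pose(progress: float) -> tuple[float, float, float]:
    """Joint angles along the stand -> bend -> lie trajectory.

    The torso tips first; the legs follow once the torso has passed ~45
    degrees, so mid-transition frames look like a bend (torso down, legs
    still under the body), never like a sit.
    """
    torso = math.pi / 2 * progress
    leg = min(math.pi / 2, max(0.0, 2.0 * (torso - math.pi / 4)))
    return torso, leg, leg


def _truth_label(torso: float, thigh: float) -> int:
    if thigh <= -math.pi / 4:  # thigh folded forward: sitting
        return POSTURE_CODES["sit"]
    if torso < math.radians(30):
        return POSTURE_CODES["stand"]
    if thigh >= math.radians(60):
        return POSTURE_CODES["lie"]
    return POSTURE_CODES["bend"]


def generate_sequence(script: ScenarioScript) -> SequenceData:
    """Animate the scripted activity; see the module docstring for scenarios."""
    rng = np.random.default_rng(script.seed)
    h, w = script.frame_shape
    s = script.scale
    floor = np.zeros((h, w), dtype=bool)
    floor[int(script.floor_top_frac * h) :, :] = True
    t_trans = script.resolved_transition
    n_frames = script.n_frames or (script.walk_frames + t_trans + script.tail_frames)

    ground_y = 0.85 * h
    # The bend scenario plays on raised furniture so the body straddles the
    # floor boundary and the 85% coverage rule fails.
    if script.scenario == "bend":
        ground_y = script.floor_top_frac * h + 0.35 * s
    x_start, x_stop = 0.25 * w, 0.45 * w

    poses: list[tuple[float, float, float, tuple[float, float]]] = []
    for t in range(n_frames):
        if t < script.walk_frames or script.scenario == "walk":
            frac = min(1.0, t / max(1, script.walk_frames))
            base = (x_start + frac * (x_stop - x_start), ground_y)
            poses.append((0.0, 0.0, 0.0, base))
            continue
        base = (x_stop, ground_y)
        progress = min(1.0, (t - script.walk_frames + 1) / t_trans)
        if script.scenario in ("fall", "lie_down"):
            poses.append((*_fall_pose(progress), base))
        elif script.scenario == "sit":
            poses.append((-0.12 * progress, -math.pi / 2 * progress, 0.0, base))
        elif script.scenario == "bend":
            poses.append((math.radians(65) * progress, 0.0, 0.0, base))

    masks, labels = [], []
    for torso, thigh, shank, base in poses:
        mask = draw_person((h, w), base, s, torso, thigh, shank, check_bounds=False)
        mask = _apply_boundary_noise(mask, 1, rng, p=0.025)
        masks.append(mask)
        labels.append(_truth_label(torso, thigh))

    verdict = script.scenario == "fall"
    fall_frame = None
    if verdict:
        # The alarm is due one inactivity window after the transition settles.
        fall_frame = script.walk_frames + t_trans + 25 - 1
    return SequenceData(
        scenario=script.scenario,
        masks=masks,
        floor=floor,
        truth_labels=np.array(labels, dtype=int),
        truth_verdict=verdict,
        truth_fall_frame=fall_frame,
    )


@dataclass
class ShadowScene:
    reference_rgb: np.ndarray = field(repr=False)
    frame_rgb: np.ndarray = field(repr=False)
    shadow_truth: np.ndarray = field(repr=False)
    person_truth: np.ndarray = field(repr=False)
    rho: float


def _texture_value(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Striped-plus-wavy value channel in [95, 225]: textured everywhere."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    p1, p2 = rng.uniform(0, 2 * math.pi, 2)
    return 160 + 40 * np.sin(2 * math.pi * xx / 7 + p1) + 25 * np.sin(
        2 * math.pi * yy / 11 + p2
    )


def generate_shadow_scene(
    seed: int = 0,
    shape: tuple[int, int] = (96, 128),
    rho: float = 0.7,
) -> ShadowScene:
    """Reference + current frame where a shadow dims the background (value
    channel scaled by ``rho``, chromaticity preserved) and a person of a
    different hue stands elsewhere.  Includes black/white anchor patches so
    per-frame value normalization is identical in both frames.
    """
    if not (0.5 <= rho <= 0.9):
        raise ValueError("rho must lie in [0.5, 0.9]")
    rng = np.random.default_rng(seed)
    h, w = shape
    v_ref = _texture_value(shape, rng)
    hue_bg, sat_bg = 80.0, 110.0

    hsv_ref = np.stack(
        [np.full(shape, hue_bg / 256.0), np.full(shape, sat_bg / 255.0), v_ref / 255.0],
        axis=-1,
    )

    # Shadow ellipse in the lower-left quadrant.
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = 0.65 * h + rng.uniform(-4, 4), 0.28 * w + rng.uniform(-4, 4)
    ry, rx = 0.20 * h, 0.17 * w
    shadow = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    # Person silhouette on the right, hue opposite the background.
    base = (0.72 * w + rng.uniform(-3, 3), 0.82 * h)
    person = draw_person(shape, base, 0.5 * h, *rng.normal(0, 0.04, 3))
    person &= ~shadow

    hsv_cur = hsv_ref.copy()
    hsv_cur[shadow, 2] *= rho
    hue_person = ((hue_bg + 128.0) % 256.0) / 256.0
    hsv_cur[person, 0] = hue_person
    hsv_cur[person, 1] = 160.0 / 255.0
    hsv_cur[person, 2] = rng.uniform(100, 220, size=int(person.sum())) / 255.0

    ref_rgb = (hsv2rgb(hsv_ref) * 255).round().astype(np.uint8)
    cur_rgb = (hsv2rgb(hsv_cur) * 255).round().astype(np.uint8)
    # Black and white anchor patches (identical in both frames) pin the
    # value-channel min/max so Eq-style normalization divides by 255 in both.
    for img in (ref_rgb, cur_rgb):
        img[0:2, 0:2] = 0
        img[0:2, 2:4] = 255
    return ShadowScene(
        reference_rgb=ref_rgb,
        frame_rgb=cur_rgb,
        shadow_truth=shadow,
        person_truth=person,
        rho=rho,
    )


def render_color_sequence(
    seq: SequenceData,
    n_background_frames: int = 12,
    seed: int = 0,
) -> list[np.ndarray]:
    """Paint a mask sequence onto a textured background as RGB frames,
    prepending background-only frames for model training."""
    rng = np.random.default_rng(seed)
    shape = seq.floor.shape
    v_ref = _texture_value(shape, rng)
    hsv_bg = np.stack(
        [np.full(shape, 80.0 / 256.0), np.full(shape, 110.0 / 255.0), v_ref / 255.0],
        axis=-1,
    )
    bg_rgb = (hsv2rgb(hsv_bg) * 255).round().astype(np.uint8)
    frames = [bg_rgb.copy() for _ in range(n_background_frames)]
    for mask in seq.masks:
        hsv = hsv_bg.copy()
        hsv[mask, 0] = 208.0 / 256.0
        hsv[mask, 1] = 160.0 / 255.0
        hsv[mask, 2] = rng.uniform(100, 220, size=int(mask.sum())) / 255.0
        frames.append((hsv2rgb(hsv) * 255).round().astype(np.uint8))
    return frames
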