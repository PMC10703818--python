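"""Synthetic cat-face generator for end-to-end pipeline testing.

No public image/annotation dataset exists for the Feline Grimace Scale, so the
package ships a generative stand-in with the statistical structure the
pipeline assumes: a canonical 37-landmark frontal face template, per-action-
unit deformation fields that move landmarks the way pain does (ears lower and
rotate outward, eyes squint, muzzle compresses, whiskers straighten and drop,
head lowers), isotropic annotation noise, similarity-transform nuisance
variation (pose/scale/position), a deterministic raster renderer, and
imperfect raters drawn from a confusion matrix over the 0/1/2 AU scores.

Every stochastic choice flows through one seeded ``numpy.random.Generator``;
identical seeds reproduce datasets bit for bit.

All template coordinates and deformation magnitudes are synthetic — authored
for this package, not measured from real cats — and are calibrated so that
default painful and non-painful groups are separable but overlapping under
default noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .schema import AUS, FaceAnnotation, N_LANDMARKS
from .scoring import RaterScoreSet

__all__ = [
    "PainState",
    "GeneratorParams",
    "TEMPLATE",
    "sample_face",
    "sample_pain_state",
    "render_face",
    "simulate_raters",
    "generate_dataset",
    "SyntheticDataset",
]

#: Canonical frontal-face template, authored in a nominal 224x224 frame
#: (pixels, origin top-left, y down).  Row i is landmark i+1.
TEMPLATE = np.array([
    (80, 60), (60, 20), (45, 65), (70, 48),          # 1-4   left ear
    (144, 60), (164, 20), (179, 65), (154, 48),      # 5-8   right ear
    (38, 110), (186, 110),                           # 9-10  cheeks
    (56, 144), (168, 144),                           # 11-12 whisker field tips
    (90, 100), (62, 100), (76, 92), (76, 108),       # 13-16 left eye
    (134, 100), (162, 100), (148, 92), (148, 108),   # 17-20 right eye
    (112, 120), (112, 132), (92, 150), (132, 150),   # 21-24 nose bridge/tip, mouth
    (112, 142), (112, 166),                          # 25-26 lips
    (70, 138), (66, 150), (62, 162),                 # 27-29 left whisker pad
    (154, 138), (158, 150), (162, 162),              # 30-32 right whisker pad
    (102, 130), (122, 130),                          # 33-34 nose wings
    (112, 190), (60, 170), (164, 170),               # 35-37 chin, jaw angles
], dtype=float)

TEMPLATE_SIZE = 224
TEMPLATE_CENTER = np.array([112.0, 105.0])


def _field(entries: dict) -> np.ndarray:
    d = np.zeros((N_LANDMARKS, 2))
    for idx, (dx, dy) in entries.items():
        d[idx - 1] = (dx, dy)
    return d


#: Unit-intensity landmark displacement per action unit (px in the template
#: frame); displacement scales linearly with the AU's pain intensity.
DEFORMATION_FIELDS = {
    # ears rotate outward and lower: tips move most
    "ear_position": _field({
        1: (-4, 4), 2: (-16, 12), 3: (-6, 6), 4: (-10, 8),
        5: (4, 4), 6: (16, 12), 7: (6, 6), 8: (10, 8)}),
    # orbital tightening: lids close toward the eye axis
    "orbital_tightening": _field({
        15: (0, 6), 16: (0, -6), 19: (0, 6), 20: (0, -6)}),
    # muzzle tension: muzzle landmarks compress 25% toward their centroid
    "muzzle_tension": _field({
        21: (0, 5), 22: (0, 2), 23: (5, -2.5), 24: (-5, -2.5),
        25: (0, -0.5), 26: (0, -6.5), 33: (2.5, 2.5), 34: (-2.5, 2.5)}),
    # whiskers straighten (pads align vertically) and advance downward
    "whiskers_change": _field({
        27: (6, 4), 28: (2, 8), 29: (-2, 12),
        30: (-6, 4), 31: (-2, 8), 32: (2, 12),
        11: (8, 12), 12: (-8, 12)}),
    # head lowers relative to the eye line
    "head_position": _field({
        9: (0, 6), 10: (0, 6), 35: (0, 16), 36: (0, 12), 37: (0, 12)}),
}

#: The descriptor (canonical-registry id) most directly driven by each AU,
#: and the sign of its response to rising pain intensity.
PRIMARY_DESCRIPTORS = {
    "ear_position": ("ear_tip_spread", +1),
    "orbital_tightening": ("eye_aperture_lateral", -1),
    "muzzle_tension": ("nose_width", -1),
    "whiskers_change": ("whisker_pad_to_eye", +1),
    "head_position": ("chin_drop", +1),
}


@dataclass(frozen=True)
class PainState:
    """Latent pain intensity per action unit, each in [0, 1]."""

    intensities: tuple  # length 5, order = schema.AUS

    def __post_init__(self):
        if len(self.intensities) != len(AUS):
            raise ValueError(f"expected {len(AUS)} intensities")
        if any(not 0.0 <= v <= 1.0 for v in self.intensities):
            raise ValueError("intensities must lie in [0, 1]")

    def true_levels(self) -> tuple:
        """Discretise intensities to ordinal AU scores (thresholds 1/3, 2/3)."""
        return tuple(0 if v < 1 / 3 else (1 if v < 2 / 3 else 2)
                     for v in self.intensities)


#: Default rater confusion matrix: row = true level, column = assigned score.
#: End levels: 0.8 correct / 0.15 adjacent / 0.05 two-off; the middle level
#: has two adjacent neighbours and no two-off, so 0.1 to each side.
DEFAULT_RATER_ERROR = np.array([
    [0.80, 0.15, 0.05],
    [0.10, 0.80, 0.10],
    [0.05, 0.15, 0.80],
])


@dataclass
class GeneratorParams:
    """Study conditions of the synthetic data.

    noise_sigma
        Isotropic landmark annotation jitter, px in the template frame.
    rotation_range, scale_range, translation_range
        Nuisance similarity-transform ranges (degrees, unitless, px).
    deformation_scale
        Global multiplier on the per-AU displacement fields.
    painful_intensity / nonpainful_intensity
        (mean, sd) of the truncated-normal per-AU intensity draw for the two
        latent groups.
    rater_error
        3x3 confusion matrix, rows sum to 1.
    prevalence
        Probability a sampled face belongs to the painful group.
    """

    noise_sigma: float = 1.5
    rotation_range: tuple = (-15.0, 15.0)
    scale_range: tuple = (0.85, 1.2)
    translation_range: tuple = (-20.0, 20.0)
    deformation_scale: float = 1.0
    painful_intensity: tuple = (0.8, 0.15)
    nonpainful_intensity: tuple = (0.12, 0.08)
    rater_error: np.ndarray = field(
        default_factory=lambda: DEFAULT_RATER_ERROR.copy())
    prevalence: float = 0.5
    n_raters: int = 3

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        m = np.asarray(self.rater_error, float)
        if m.shape != (3, 3) or not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rater_error must be 3x3 with rows summing to 1")
        self.rater_error = m


def deformed_template(state: PainState, params: GeneratorParams) -> np.ndarray:
    """Template landmarks displaced linearly by each AU's intensity."""
    pts = TEMPLATE.copy()
    for au, u in zip(AUS, state.intensities):
        pts += params.deformation_scale * u * DEFORMATION_FIELDS[au]
    return pts


def sample_pain_state(painful: bool, params: GeneratorParams,
                      rng: np.random.Generator) -> PainState:
    """Draw per-AU intensities for a painful or non-painful face."""
    mu, sd = params.painful_intensity if painful else params.nonpainful_intensity
    vals = np.clip(rng.normal(mu, sd, size=len(AUS)), 0.0, 1.0)
    return PainState(tuple(float(v) for v in vals))


def sample_face(state: PainState, params: GeneratorParams,
                rng: np.random.Generator, image_id: str = "synthetic"):
    """Sample one face; returns (nuisance-transformed annotation, aligned truth).

    The aligned truth is the deformed template plus annotation noise; the
    observed annotation additionally carries a random similarity transform
    (rotation about the template centre, uniform scale, translation).
    """
    pts = deformed_template(state, params)
    if params.noise_sigma > 0:
        pts = pts + rng.normal(0.0, params.noise_sigma, size=pts.shape)
    aligned = FaceAnnotation(image_id, pts, (TEMPLATE_SIZE, TEMPLATE_SIZE))

    theta = np.deg2rad(rng.uniform(*params.rotation_range))
    s = rng.uniform(*params.scale_range)
    t = rng.uniform(*params.translation_range, size=2)
    c, sn = np.cos(theta), np.sin(theta)
    rot = s * np.array([[c, -sn], [sn, c]])
    moved = (pts - TEMPLATE_CENTER) @ rot.T + TEMPLATE_CENTER + t
    observed = FaceAnnotation(image_id, moved, (TEMPLATE_SIZE, TEMPLATE_SIZE))
    return observed, aligned


def render_face(ann: FaceAnnotation, size: int = TEMPLATE_SIZE) -> np.ndarray:
    """Deterministic grayscale raster of an annotated face.

    Head ellipse, ear triangles, eye ellipses, nose polygon, mouth and jaw
    lines and whisker polylines are all drawn from the landmark coordinates,
    so the drawn features move with the landmarks.  Returns a (size, size)
    uint8 array.
    """
    scale = size / TEMPLATE_SIZE
    p = {i: tuple(ann.point(i) * scale) for i in range(1, N_LANDMARKS + 1)}

    def seg(i, j):
        return [p[i], p[j]]

    xs = [p[i][0] for i in (9, 10)]
    head_box = [min(xs), (p[15][1] + p[19][1]) / 2 - 55 * scale,
                max(xs), p[35][1]]
    if head_box[0] >= head_box[2] or head_box[1] >= head_box[3]:
        raise ValueError("degenerate head geometry")
    img = Image.new("L", (size, size), 0)
    d = ImageDraw.Draw(img)
    d.ellipse(head_box, fill=110)
    for tri in ((1, 2, 3), (5, 6, 7)):
        d.polygon([p[i] for i in tri], fill=110, outline=200)
    for eye in ((13, 14, 15, 16), (17, 18, 19, 20)):
        ex = [p[i][0] for i in eye]
        ey = [p[i][1] for i in eye]
        box = [min(ex), min(ey), max(ex), max(ey)]
        if box[0] < box[2] and box[1] < box[3]:
            d.ellipse(box, fill=230)
    d.polygon([p[21], p[33], p[22], p[34]], fill=180)
    d.line(seg(23, 25) + seg(25, 24), fill=200, width=1)
    d.line(seg(25, 26), fill=200, width=1)
    d.line(seg(36, 35) + seg(35, 37), fill=160, width=1)
    for pad, tip in (((27, 28, 29), 11), ((30, 31, 32), 12)):
        for i in pad:
            d.line(seg(i, tip), fill=250, width=1)
    return np.asarray(img, dtype=np.uint8)


def simulate_raters(state: PainState, n_raters: int, params: GeneratorParams,
                    rng: np.random.Generator, image_id: str = "synthetic"):
    """Imperfect raters: each AU score drawn from the confusion-matrix row of
    the true ordinal level, independently per rater and AU."""
    if n_raters < 1:
        raise ValueError("need at least one rater")
    levels = state.true_levels()
    out = []
    for r in range(n_raters):
        scores = tuple(int(rng.choice(3, p=params.rater_error[lvl]))
                       for lvl in levels)
        out.append(RaterScoreSet(image_id, f"rater{r + 1}", scores))
    return out


def planted_feature_data(n: int, n_informative: int, n_noise: int,
                         task: str = "binary", seed: int = 0,
                         label_noise: float = 0.3):
    """Feature-selection oracle data: standard-normal features of which only
    the first ``n_informative`` carry signal (an equal-weight sum), the rest
    being pure noise.  Binary labels threshold the noisy signal at zero."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_informative + n_noise))
    signal = X[:, :n_informative].sum(axis=1) / np.sqrt(n_informative)
    noisy = signal + label_noise * rng.normal(size=n)
    if task == "binary":
        return X, (noisy > 0).astype(int)
    if task == "regression":
        return X, noisy
    raise ValueError(f"unknown task {task!r}")


@dataclass
class FaceRecord:
    image_id: str
    painful: bool
    state: PainState
    annotation: FaceAnnotation          # nuisance-transformed (as "observed")
    aligned_annotation: FaceAnnotation  # noise only, template frame
    rater_scores: list


@dataclass
class SyntheticDataset:
    records: list
    params: GeneratorParams
    seed: int

    def __len__(self):
        return len(self.records)

    @property
    def annotations(self):
        return [r.annotation for r in self.records]

    @property
    def painful_fraction(self) -> float:
        return float(np.mean([r.painful for r in self.records]))

    def rater_score_sets(self):
        return [s for r in self.records for s in r.rater_scores]


def generate_dataset(n: int, params: GeneratorParams | None = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate *n* faces with latent truth, annotations and rater scores."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        image_id = f"syn{k:05d}"
        painful = bool(rng.random() < params.prevalence)
        state = sample_pain_state(painful, params, rng)
        observed, aligned = sample_face(state, params, rng, image_id)
        raters = simulate_raters(state, params.n_raters, params, rng, image_id)
        records.append(FaceRecord(image_id, painful, state, observed,
                                  aligned, raters))
    return SyntheticDataset(records, params, seed)
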