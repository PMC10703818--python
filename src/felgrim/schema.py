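"""Landmark schema and annotation I/O for the Feline Grimace Scale (FGS).

The FGS scores five facial action units (AUs) — ear position, orbital
tightening, muzzle tension, whiskers change and head position — each on a
0/1/2 scale.  The automated pipeline localises 37 facial landmarks per image;
this module fixes the landmark registry (indices, AU membership and the
special-role landmark sets used for alignment, cropping and error
normalisation) and reads/writes per-image annotation files.

Landmark coordinates are pixels with the origin at the image top-left corner,
x increasing rightward and y increasing downward.  Landmark indices are
1-based everywhere (files, APIs, schema sets).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AUS",
    "N_LANDMARKS",
    "LandmarkSchema",
    "FaceAnnotation",
    "MalformedAnnotationError",
    "build_default_schema",
    "load_annotation",
    "save_annotation",
    "validate_annotation",
]

#: The five FGS action units, in canonical order.
AUS = (
    "ear_position",
    "orbital_tightening",
    "muzzle_tension",
    "whiskers_change",
    "head_position",
)

N_LANDMARKS = 37

#: Landmarks defining the rotation angle for face alignment (eye groups).
ROTATION_SET = frozenset({13, 14, 17, 18})
#: Peripheral landmarks defining the face crop box.
CROP_SET = frozenset({3, 10, 29, 30, 31, 32, 36, 37})
#: Landmark pair whose distance normalises landmark prediction errors.
NORMALIZATION_PAIR = (33, 34)
#: Landmarks excluded from the NRMSEw variant (largest prediction errors).
NRMSEW_EXCLUDED = frozenset({6, 7, 27, 28, 29, 30, 31, 32, 36, 37})


class MalformedAnnotationError(ValueError):
    """Annotation file does not contain exactly 37 well-formed landmarks."""


@dataclass(frozen=True)
class LandmarkSchema:
    """Registry of the 37 facial landmarks and their special roles.

    Parameters
    ----------
    au_of : dict
        Mapping landmark index (1..37) -> action-unit name.
    names : dict
        Mapping landmark index -> short anatomical name.
    rotation_set, crop_set, nrmsew_excluded : frozenset of int
        Role sets; see module constants for the canonical values.
    normalization_pair : (int, int)
        Landmark pair defining the error-normalisation distance.
    """

    au_of: dict = field(default_factory=dict)
    names: dict = field(default_factory=dict)
    rotation_set: frozenset = ROTATION_SET
    crop_set: frozenset = CROP_SET
    normalization_pair: tuple = NORMALIZATION_PAIR
    nrmsew_excluded: frozenset = NRMSEW_EXCLUDED

    def __post_init__(self):
        idx = sorted(self.au_of)
        if idx != list(range(1, N_LANDMARKS + 1)):
            raise ValueError("schema must assign AUs to exactly indices 1..37")
        bad = set(self.au_of.values()) - set(AUS)
        if bad:
            raise ValueError(f"unknown action units: {sorted(bad)}")
        for au in AUS:
            if not any(v == au for v in self.au_of.values()):
                raise ValueError(f"action unit {au!r} has no landmarks")
        if not self.rotation_set <= self.au_indices("orbital_tightening"):
            raise ValueError("rotation landmarks must belong to orbital_tightening")
        if len(self.nrmsew_excluded) != 10:
            raise ValueError("nrmsew_excluded must contain exactly 10 landmarks")
        for s in (self.rotation_set, self.crop_set, self.nrmsew_excluded):
            if not s <= set(range(1, N_LANDMARKS + 1)):
                raise ValueError("role sets must be subsets of 1..37")
        a, b = self.normalization_pair
        if not (1 <= a <= N_LANDMARKS and 1 <= b <= N_LANDMARKS and a != b):
            raise ValueError("normalization_pair must be two distinct indices in 1..37")

    def au_indices(self, au: str) -> set:
        """Landmark indices assigned to action unit *au*."""
        return {i for i, a in self.au_of.items() if a == au}

    @property
    def au_counts(self) -> dict:
        return {au: len(self.au_indices(au)) for au in AUS}


# Default AU allocation.  The anatomical table is authored in-package: the
# published role sets (rotation, crop, normalisation, error-exclusion) pin the
# eye, nose and peripheral landmarks; the remaining indices are allocated to
# plausible facial regions.  Any user schema satisfying the invariants is
# accepted by every function that takes a schema.
_DEFAULT_ALLOCATION = {
    "ear_position": (1, 2, 3, 4, 5, 6, 7, 8),
    "head_position": (9, 10, 35, 36, 37),
    "whiskers_change": (11, 12, 27, 28, 29, 30, 31, 32),
    "orbital_tightening": (13, 14, 15, 16, 17, 18, 19, 20),
    "muzzle_tension": (21, 22, 23, 24, 25, 26, 33, 34),
}

_DEFAULT_NAMES = {
    1: "left ear inner base", 2: "left ear tip", 3: "left ear outer base",
    4: "left ear mid ridge", 5: "right ear inner base", 6: "right ear tip",
    7: "right ear outer base", 8: "right ear mid ridge",
    9: "left cheek margin", 10: "right cheek margin",
    11: "left whisker field tip", 12: "right whisker field tip",
    13: "left medial canthus", 14: "left lateral canthus",
    15: "left upper eyelid", 16: "left lower eyelid",
    17: "right medial canthus", 18: "right lateral canthus",
    19: "right upper eyelid", 20: "right lower eyelid",
    21: "nose bridge", 22: "nose tip", 23: "left mouth corner",
    24: "right mouth corner", 25: "upper lip midpoint", 26: "lower lip midpoint",
    27: "left whisker pad upper", 28: "left whisker pad middle",
    29: "left whisker pad lower", 30: "right whisker pad upper",
    31: "right whisker pad middle", 32: "right whisker pad lower",
    33: "left nose wing", 34: "right nose wing",
    35: "chin bottom", 36: "left jaw angle", 37: "right jaw angle",
}


def build_default_schema() -> LandmarkSchema:
    """Return the canonical 37-landmark / 5-AU schema shipped with the package."""
    au_of = {i: au for au, idxs in _DEFAULT_ALLOCATION.items() for i in idxs}
    return LandmarkSchema(au_of=au_of, names=dict(_DEFAULT_NAMES))


@dataclass
class FaceAnnotation:
    """37 landmark pixel coordinates for one face image."""

    image_id: str
    points: np.ndarray  # (37, 2) float array, columns x, y
    image_size: tuple | None = None  # (width, height) in px

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise MalformedAnnotationError(
                f"expected {N_LANDMARKS} landmark points, found {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise MalformedAnnotationError("non-finite landmark coordinate")
        self.points = pts

    def point(self, index: int) -> np.ndarray:
        """Coordinate of 1-based landmark *index*."""
        return self.points[index - 1]

    def replace(self, points: np.ndarray, image_size=None) -> "FaceAnnotation":
        return FaceAnnotation(self.image_id, np.asarray(points, float),
                              image_size if image_size is not None else self.image_size)

    def __eq__(self, other):
        return (isinstance(other, FaceAnnotation)
                and self.image_id == other.image_id
                and np.array_equal(self.points, other.points))


# ---------------------------------------------------------------------------
# Annotation file I/O
#
# txt dialect: one line per landmark, "index x y", whitespace separated —
# mirrors the annotation software's per-image .txt exports.
# csv dialect: header image_id,l1_x,l1_y,...,l37_y, one row per image.
# ---------------------------------------------------------------------------

def _parse_txt(stream: io.TextIOBase, image_id: str) -> FaceAnnotation:
    pts = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise MalformedAnnotationError(
                f"line {lineno}: expected 'index x y', got {line!r}")
        try:
            idx = int(parts[0])
            x, y = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise MalformedAnnotationError(f"line {lineno}: non-numeric field: {exc}")
        if idx in pts:
            raise MalformedAnnotationError(f"line {lineno}: duplicate landmark {idx}")
        pts[idx] = (x, y)
    if sorted(pts) != list(range(1, N_LANDMARKS + 1)):
        raise MalformedAnnotationError(
            f"expected {N_LANDMARKS} landmark points, found {len(pts)}")
    arr = np.array([pts[i] for i in range(1, N_LANDMARKS + 1)], dtype=float)
    return FaceAnnotation(image_id, arr)


def _parse_csv_row(header: Sequence[str], row: Sequence[str]) -> FaceAnnotation:
    rec = dict(zip(header, row))
    try:
        xy = [(float(rec[f"l{i}_x"]), float(rec[f"l{i}_y"]))
              for i in range(1, N_LANDMARKS + 1)]
    except KeyError as exc:
        raise MalformedAnnotationError(f"missing CSV column {exc}")
    except ValueError as exc:
        raise MalformedAnnotationError(f"non-numeric coordinate: {exc}")
    return FaceAnnotation(rec.get("image_id", ""), np.array(xy))


def load_annotation(source, dialect: str = "txt", image_id: str = "") -> FaceAnnotation:
    """Read one :class:`FaceAnnotation` from a text stream or path.

    ``txt`` expects 37 lines of ``index x y``; ``csv`` expects a header row
    ``image_id,l1_x,l1_y,...,l37_y`` followed by one data row.
    """
    close = False
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        source = open(source, "r")
        close = True
    try:
        if dialect == "txt":
            return _parse_txt(source, image_id)
        if dialect == "csv":
            reader = csv.reader(source)
            header = next(reader)
            row = next(reader)
            ann = _parse_csv_row(header, row)
            if image_id:
                ann.image_id = image_id
            return ann
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    finally:
        if close:
            source.close()


def save_annotation(ann: FaceAnnotation, target, dialect: str = "txt") -> None:
    """Write *ann* to a text stream or path; inverse of :func:`load_annotation`."""
    close = False
    if isinstance(target, (str,)) or hasattr(target, "__fspath__"):
        target = open(target, "w")
        close = True
    try:
        if dialect == "txt":
            for i in range(1, N_LANDMARKS + 1):
                x, y = ann.point(i)
                target.write(f"{i} {float(x)!r} {float(y)!r}\n")
        elif dialect == "csv":
            w = csv.writer(target)
            header = ["image_id"]
            for i in range(1, N_LANDMARKS + 1):
                header += [f"l{i}_x", f"l{i}_y"]
            w.writerow(header)
            row = [ann.image_id]
            for i in range(1, N_LANDMARKS + 1):
                x, y = ann.point(i)
                row += [repr(float(x)), repr(float(y))]
            w.writerow(row)
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")
    finally:
        if close:
            target.close()


def validate_annotation(ann: FaceAnnotation, image_size=None,
                        schema: LandmarkSchema | None = None) -> list:
    """Report (not raise) annotation quality problems.

    Returns a list of human-readable strings: out-of-bounds points, coincident
    duplicate points, and a degenerate normalisation pair (zero distance, which
    would break NRMSE and every nose-width-normalised descriptor).
    """
    schema = schema or build_default_schema()
    report = []
    size = image_size or ann.image_size
    if size is not None:
        w, h = size
        for i in range(1, N_LANDMARKS + 1):
            x, y = ann.point(i)
            if not (0 <= x <= w and 0 <= y <= h):
                report.append(f"out-of-bounds: landmark {i} at ({x}, {y}) "
                              f"outside [0, {w}]x[0, {h}]")
    pts = ann.points
    for i in range(N_LANDMARKS):
        for j in range(i + 1, N_LANDMARKS):
            if pts[i, 0] == pts[j, 0] and pts[i, 1] == pts[j, 1]:
                report.append(f"coincident: landmarks {i + 1} and {j + 1} "
                              f"share position ({pts[i, 0]}, {pts[i, 1]})")
    a, b = schema.normalization_pair
    if float(np.hypot(*(ann.point(a) - ann.point(b)))) == 0.0:
        report.append(f"degenerate-normalization: landmarks {a} and {b} coincide")
    return report
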