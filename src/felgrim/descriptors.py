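"""Geometric descriptors of the cat face computed from 37 facial landmarks.

Thirty-five similarity-invariant features — unsigned angles, ratios of
inter-landmark distances and ratios of quadrilateral areas — summarise the
facial configuration for FGS score prediction.  Counts per action unit are
fixed: 10 (ear position), 5 (orbital tightening), 8 (muzzle tension),
5 (whiskers change) and 7 (head position).  Most descriptors average the same
geometric property over left/right homologous landmark sets, so the feature
vector is insensitive to which side of the face expresses a change more
strongly as well as to translation, rotation, uniform scaling and reflection
of the annotation.

The default registry ships with the package; alternative registries (e.g. a
different anatomical definition of the same 35 features) load from a YAML
file without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .schema import AUS, FaceAnnotation, N_LANDMARKS

__all__ = [
    "DescriptorDef",
    "DescriptorRegistry",
    "DegenerateGeometryError",
    "angle_deg",
    "quad_area",
    "evaluate_descriptor",
    "evaluate_registry",
    "subset_registry",
    "build_default_registry",
    "load_registry",
    "save_registry",
]

#: Per-AU descriptor counts of the canonical registry.
AU_DESCRIPTOR_COUNTS = {
    "ear_position": 10,
    "orbital_tightening": 5,
    "muzzle_tension": 8,
    "whiskers_change": 5,
    "head_position": 7,
}

KINDS = ("angle", "distance_ratio", "area_ratio")


class DegenerateGeometryError(ValueError):
    """Landmark configuration breaks a geometric computation."""


def angle_deg(vertex, a, b) -> float:
    """Unsigned angle at *vertex* between arms toward *a* and *b*, in [0, 180]."""
    vertex = np.asarray(vertex, float)
    va = np.asarray(a, float) - vertex
    vb = np.asarray(b, float) - vertex
    na, nb = np.hypot(*va), np.hypot(*vb)
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError("angle arm coincides with vertex")
    cosang = float(np.dot(va, vb) / (na * nb))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def quad_area(p1, p2, p3, p4) -> float:
    """Absolute shoelace area of the quadrilateral p1-p2-p3-p4 (traversal order)."""
    pts = np.asarray([p1, p2, p3, p4], float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


@dataclass(frozen=True)
class DescriptorDef:
    """One geometric descriptor.

    ``angle``: value is the mean of the unsigned angles of ``triples``, each a
    (vertex, arm_a, arm_b) landmark-index triple.
    ``distance_ratio``: mean distance over ``numerator`` index pairs divided by
    the mean distance over ``denominator`` pairs.
    ``area_ratio``: mean shoelace area over ``numerator`` index 4-tuples
    divided by the mean area over ``denominator`` 4-tuples.
    """

    id: str
    au: str
    kind: str
    triples: tuple = ()
    numerator: tuple = ()
    denominator: tuple = ()

    def __post_init__(self):
        if self.au not in AUS:
            raise ValueError(f"unknown action unit {self.au!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        groups: list = []
        if self.kind == "angle":
            if not self.triples:
                raise ValueError(f"{self.id}: angle needs >=1 triple")
            for t in self.triples:
                if len(t) != 3 or len(set(t)) != 3:
                    raise ValueError(f"{self.id}: angle triple {t} has repeated indices")
            groups = [i for t in self.triples for i in t]
        else:
            if not self.numerator or not self.denominator:
                raise ValueError(f"{self.id}: ratio needs numerator and denominator")
            k = 2 if self.kind == "distance_ratio" else 4
            for grp in (*self.numerator, *self.denominator):
                if len(grp) != k:
                    raise ValueError(f"{self.id}: expected index {k}-tuples")
            groups = [i for grp in (*self.numerator, *self.denominator) for i in grp]
        for i in groups:
            if not 1 <= i <= N_LANDMARKS:
                raise ValueError(f"{self.id}: landmark index {i} outside 1..37")


def evaluate_descriptor(d: DescriptorDef, ann: FaceAnnotation) -> float:
    """Evaluate one descriptor on an annotation (degrees for angles, else unit-free)."""
    p = ann.point
    try:
        if d.kind == "angle":
            return float(np.mean([angle_deg(p(v), p(a), p(b)) for v, a, b in d.triples]))
        if d.kind == "distance_ratio":
            num = np.mean([np.hypot(*(p(i) - p(j))) for i, j in d.numerator])
            den = np.mean([np.hypot(*(p(i) - p(j))) for i, j in d.denominator])
        else:
            num = np.mean([quad_area(p(a), p(b), p(c), p(e)) for a, b, c, e in d.numerator])
            den = np.mean([quad_area(p(a), p(b), p(c), p(e)) for a, b, c, e in d.denominator])
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"descriptor {d.id}: {exc}") from exc
    if den == 0.0:
        raise DegenerateGeometryError(f"descriptor {d.id}: zero denominator")
    return float(num / den)


@dataclass(frozen=True)
class DescriptorRegistry:
    """Ordered collection of descriptor definitions with unique ids."""

    defs: tuple = field(default_factory=tuple)
    canonical: bool = False  # enforce the 35-descriptor / per-AU-count contract

    def __post_init__(self):
        ids = [d.id for d in self.defs]
        if len(set(ids)) != len(ids):
            raise ValueError("descriptor ids must be unique")
        if self.canonical:
            if len(self.defs) != 35:
                raise ValueError(f"canonical registry needs 35 descriptors, "
                                 f"got {len(self.defs)}")
            counts = self.au_counts
            if counts != AU_DESCRIPTOR_COUNTS:
                raise ValueError(f"canonical per-AU counts must be "
                                 f"{AU_DESCRIPTOR_COUNTS}, got {counts}")

    def __len__(self):
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    @property
    def ids(self) -> list:
        return [d.id for d in self.defs]

    @property
    def au_counts(self) -> dict:
        return {au: sum(d.au == au for d in self.defs) for au in AUS}


def evaluate_registry(reg: DescriptorRegistry, ann: FaceAnnotation) -> dict:
    """Evaluate every descriptor; returns {id: finite value} in registry order."""
    out = {}
    for d in reg:
        v = evaluate_descriptor(d, ann)
        if not math.isfinite(v):
            raise DegenerateGeometryError(f"descriptor {d.id}: non-finite value")
        out[d.id] = v
    return out


def feature_matrix(reg: DescriptorRegistry, anns) -> np.ndarray:
    """(n_images, n_descriptors) matrix of descriptor values."""
    return np.array([[evaluate_descriptor(d, a) for d in reg] for a in anns])


def subset_registry(reg: DescriptorRegistry, exclude_aus=()) -> DescriptorRegistry:
    """Registry without the descriptors of the excluded action units.

    Excluding whiskers change leaves 30 of the 35 canonical descriptors;
    excluding head position leaves 28; excluding both leaves 23.
    """
    exclude = set(exclude_aus)
    bad = exclude - set(AUS)
    if bad:
        raise ValueError(f"unknown action units: {sorted(bad)}")
    return DescriptorRegistry(tuple(d for d in reg.defs if d.au not in exclude))


# ---------------------------------------------------------------------------
# Canonical registry.  Landmark semantics follow the default schema in
# .schema: ears 1-8, cheeks 9/10, whisker tips 11/12, eyes 13-20, muzzle
# 21-26 + nose wings 33/34, whisker pads 27-32, chin/jaw 35-37.  Reference
# denominators (cheek width 9-10, nose width 33-34) make each ratio a
# similarity-invariant proportion of the face.
# ---------------------------------------------------------------------------

def _dr(id_, au, num, den):
    return DescriptorDef(id=id_, au=au, kind="distance_ratio",
                         numerator=tuple(map(tuple, num)),
                         denominator=tuple(map(tuple, den)))


def _ang(id_, au, triples):
    return DescriptorDef(id=id_, au=au, kind="angle",
                         triples=tuple(map(tuple, triples)))


def _ar(id_, au, num, den):
    return DescriptorDef(id=id_, au=au, kind="area_ratio",
                         numerator=tuple(map(tuple, num)),
                         denominator=tuple(map(tuple, den)))


_CHEEK = [(9, 10)]      # face width reference
_NOSE = [(33, 34)]      # nose width reference

_CANONICAL_DEFS = (
    # --- ear position (10 distance ratios) ---
    _dr("ear_tip_spread", "ear_position", [(2, 6)], _CHEEK),
    _dr("ear_inner_length", "ear_position", [(1, 2), (5, 6)], _NOSE),
    _dr("ear_outer_length", "ear_position", [(3, 2), (7, 6)], _NOSE),
    _dr("ear_tip_to_eye", "ear_position", [(2, 15), (6, 19)], _CHEEK),
    _dr("ear_base_width", "ear_position", [(1, 3), (5, 7)], _NOSE),
    _dr("ear_tip_to_chin", "ear_position", [(2, 35), (6, 35)], _CHEEK),
    _dr("ear_inner_base_gap", "ear_position", [(1, 5)], _CHEEK),
    _dr("ear_outer_base_gap", "ear_position", [(3, 7)], _CHEEK),
    _dr("ear_tip_to_nose", "ear_position", [(2, 22), (6, 22)], _CHEEK),
    _dr("ear_mid_spread", "ear_position", [(4, 8)], _NOSE),
    # --- orbital tightening (5 mean angles, left/right averaged) ---
    _ang("eye_aperture_lateral", "orbital_tightening",
         [(14, 15, 16), (18, 19, 20)]),
    _ang("eye_aperture_medial", "orbital_tightening",
         [(13, 15, 16), (17, 19, 20)]),
    _ang("upper_lid_flatness", "orbital_tightening",
         [(15, 13, 14), (19, 17, 18)]),
    _ang("lower_lid_flatness", "orbital_tightening",
         [(16, 13, 14), (20, 17, 18)]),
    _ang("eye_to_nose_angle", "orbital_tightening",
         [(13, 14, 21), (17, 18, 21)]),
    # --- muzzle tension (8 distance ratios) ---
    _dr("nose_width", "muzzle_tension", _NOSE, _CHEEK),
    _dr("mouth_width", "muzzle_tension", [(23, 24)], _CHEEK),
    _dr("muzzle_height", "muzzle_tension", [(21, 26)], _CHEEK),
    _dr("nose_to_lip", "muzzle_tension", [(22, 25)], _CHEEK),
    _dr("mouth_to_nosewing", "muzzle_tension", [(23, 33), (24, 34)], _CHEEK),
    _dr("nose_to_chinlip", "muzzle_tension", [(22, 26)], _CHEEK),
    _dr("nose_length", "muzzle_tension", [(21, 22)], _CHEEK),
    _dr("mouth_to_eye", "muzzle_tension", [(23, 14), (24, 18)], _CHEEK),
    # --- whiskers change (5 distance ratios) ---
    _dr("whisker_pad_to_eye", "whiskers_change", [(27, 16), (30, 20)], _CHEEK),
    _dr("whisker_pad_extent", "whiskers_change", [(27, 29), (30, 32)], _NOSE),
    _dr("whisker_tip_to_cheek", "whiskers_change", [(11, 9), (12, 10)], _CHEEK),
    _dr("whisker_pad_gap", "whiskers_change", [(27, 30)], _CHEEK),
    _dr("whisker_tip_spread", "whiskers_change", [(11, 12)], _NOSE),
    # --- head position (5 distance + 2 area ratios) ---
    _dr("chin_drop", "head_position", [(35, 22)], _NOSE),
    _dr("jaw_drop", "head_position", [(36, 23), (37, 24)], _NOSE),
    _dr("face_height", "head_position", [(35, 21)], _CHEEK),
    _dr("cheek_to_eye", "head_position", [(9, 14), (10, 18)], _NOSE),
    _ar("lower_face_area", "head_position",
        [(23, 36, 35, 37)], [(9, 36, 37, 10)]),
    _ar("eye_to_jaw_area", "head_position",
        [(14, 18, 37, 36)], [(13, 17, 34, 33)]),
    _dr("head_aspect", "head_position", _CHEEK, [(21, 35)]),
)


def build_default_registry() -> DescriptorRegistry:
    """The canonical 35-descriptor registry (10/5/8/5/7 per action unit)."""
    return DescriptorRegistry(_CANONICAL_DEFS, canonical=True)


# --- YAML round-trip so alternative anatomical definitions can be dropped in ---

def save_registry(reg: DescriptorRegistry, path) -> None:
    data = []
    for d in reg:
        rec = {"id": d.id, "au": d.au, "kind": d.kind}
        if d.kind == "angle":
            rec["triples"] = [list(t) for t in d.triples]
        else:
            rec["numerator"] = [list(t) for t in d.numerator]
            rec["denominator"] = [list(t) for t in d.denominator]
        data.append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump({"descriptors": data}, fh, sort_keys=False)


def load_registry(path, canonical: bool = False) -> DescriptorRegistry:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    defs = []
    for rec in data["descriptors"]:
        defs.append(DescriptorDef(
            id=rec["id"], au=rec["au"], kind=rec["kind"],
            triples=tuple(map(tuple, rec.get("triples", ()))),
            numerator=tuple(map(tuple, rec.get("numerator", ()))),
            denominator=tuple(map(tuple, rec.get("denominator", ()))),
        ))
    return DescriptorRegistry(tuple(defs), canonical=canonical)
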