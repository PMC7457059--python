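"""Assembly of the rigid-body spring-network pelvis model.

Two free rigid bodies (sacrum and first caudal vertebra) hang in a network
of tension-only nonlinear springs anchored to the fixed hemipelves:

* dorsal and ventral sacroiliac sheet ligaments: 10 springs per side each,
  in a crisscross pattern over 4 + 4 attachment points,
* sacroiliac joint: 10 short springs per side spanning the joint gap,
* sacrotuberous ligament: 2 springs per side in a "Y" whose junction is
  the ischiatic tuberosity insertion,
* a single compression-only hyperelastic bar for the sacrocaudal joint
  between sacrum and C1.

Total census: 32 springs per side, 64 in all.  The hemipelves are treated
as fixed environment (a rigid bone held at the acetabula is held
everywhere), and the bones themselves are rigid -- ligament stiffness is
orders of magnitude below bone stiffness, so ligament strain is dominated
by rigid-body motion of the sacrum and C1.

Because the sacroiliac springs themselves carry no compressive load (in a
full continuum model bone-on-bone contact does), an optional linear
compression-only penalty across each SIJ spring pair (default on,
1e3 N/mm) prevents interpenetration of sacrum and ilium.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import JointLaw, LigamentLaw
from .synthetic_pelvis import SIDES, PelvisLandmarks

__all__ = [
    "SpringElement",
    "JointElement",
    "RigidBody",
    "Model",
    "crisscross_springs",
    "sacrotuberous_springs",
    "build_model",
    "SPRING_CENSUS",
]

#: Expected number of springs per group per side.
SPRING_CENSUS = {"dorsal_si": 10, "ventral_si": 10, "sij": 10, "sacrotuberous": 2}

GROUPS = tuple(SPRING_CENSUS)

#: Crisscross topology over 4 sacrum points S1..S4 and 4 ilium points I1..I4:
#: the 4 parallels plus the 6 nearest diagonals.
CRISSCROSS_PAIRS = (
    (0, 0), (1, 1), (2, 2), (3, 3),
    (0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2),
)


@dataclass(frozen=True)
class Attachment:
    """Reference to a point on a body ('sacrum', 'c1') or the fixed world."""

    body: str  # "world", "sacrum" or "c1"
    point: tuple[float, float, float]  # reference (undeformed) mm coordinates

    def __post_init__(self) -> None:
        if self.body not in ("world", "sacrum", "c1"):
            raise ValueError(f"unknown body {self.body!r}")


@dataclass(frozen=True)
class SpringElement:
    """A tension-only nonlinear spring between two attachments."""

    name: str
    end_a: Attachment
    end_b: Attachment
    rest_length: float
    law: LigamentLaw
    group: str
    side: str

    def __post_init__(self) -> None:
        if self.group not in SPRING_CENSUS:
            raise ValueError(f"unknown ligament group {self.group!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be L or R, got {self.side!r}")
        if not self.rest_length > 0:
            raise ValueError(
                f"spring {self.name}: zero or negative rest length "
                f"({self.rest_length}); endpoints coincide?"
            )


@dataclass(frozen=True)
class JointElement:
    """Compression-only bar for the sacrocaudal joint.

    Axial force = stress(eps_c) * area with
    eps_c = (rest_thickness - gap) / rest_thickness, where gap is the
    current distance between the two interface points.  The law may be the
    polynomial joint law or a fitted Mooney-Rivlin solid; either exposes
    ``stress`` and ``energy_density`` over compressive strain magnitude.
    """

    face_sacrum: Attachment
    face_c1: Attachment
    area: float
    rest_thickness: float
    law: object

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError(f"joint area must be positive, got {self.area}")
        if not self.rest_thickness > 0:
            raise ValueError(
                f"joint rest thickness must be positive, got {self.rest_thickness}"
            )


@dataclass(frozen=True)
class RigidBody:
    """A free rigid body, posed by translation + rotation about its origin."""

    name: str
    origin: tuple[float, float, float]  # reference position of the body frame


@dataclass
class Model:
    """Assembled mechanical model: bodies, springs, joint, penalty, load point."""

    bodies: dict[str, RigidBody]
    springs: list[SpringElement]
    joint: JointElement
    load_point: Attachment
    sij_penalty_stiffness: float = 1.0e3  # N/mm, compression-only; 0 disables
    regularization_stiffness: float = 1.0e-6  # N/mm grounding spring per body

    def __post_init__(self) -> None:
        census: dict[tuple[str, str], int] = {}
        for s in self.springs:
            census[(s.group, s.side)] = census.get((s.group, s.side), 0) + 1
        for group, n in SPRING_CENSUS.items():
            for side in SIDES:
                got = census.get((group, side), 0)
                if got != n:
                    raise ValueError(
                        f"spring census violation: {group}/{side} has {got}, expected {n}"
                    )

    def springs_by(self, group: str | None = None, side: str | None = None):
        return [
            s
            for s in self.springs
            if (group is None or s.group == group) and (side is None or s.side == side)
        ]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def att(a: Attachment) -> dict:
            return {"body": a.body, "point": list(a.point)}

        law = self.springs[0].law
        return {
            "bodies": {n: {"origin": list(b.origin)} for n, b in self.bodies.items()},
            "ligament_law": {
                "strain_breakpoints": list(law.strain_breakpoints),
                "band_stiffness": list(law.band_stiffness),
            },
            "joint": {
                "face_sacrum": att(self.joint.face_sacrum),
                "face_c1": att(self.joint.face_c1),
                "area": self.joint.area,
                "rest_thickness": self.joint.rest_thickness,
                "law": {"a": self.joint.law.a, "b": self.joint.law.b}
                if isinstance(self.joint.law, JointLaw)
                else {
                    "c10": self.joint.law.c10,
                    "c01": self.joint.law.c01,
                    "c11": self.joint.law.c11,
                },
            },
            "springs": [
                {
                    "name": s.name,
                    "end_a": att(s.end_a),
                    "end_b": att(s.end_b),
                    "rest_length": s.rest_length,
                    "group": s.group,
                    "side": s.side,
                }
                for s in self.springs
            ],
            "load_point": att(self.load_point),
            "sij_penalty_stiffness": self.sij_penalty_stiffness,
            "regularization_stiffness": self.regularization_stiffness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        from .materials import MooneyRivlin3

        law = LigamentLaw(
            strain_breakpoints=tuple(d["ligament_law"]["strain_breakpoints"]),
            band_stiffness=tuple(d["ligament_law"]["band_stiffness"]),
        )

        def att(a: dict) -> Attachment:
            return Attachment(body=a["body"], point=tuple(a["point"]))

        jl = d["joint"]["law"]
        joint_law = JointLaw(a=jl["a"], b=jl["b"]) if "a" in jl else MooneyRivlin3(**jl)
        return cls(
            bodies={
                n: RigidBody(name=n, origin=tuple(b["origin"]))
                for n, b in d["bodies"].items()
            },
            springs=[
                SpringElement(
                    name=s["name"],
                    end_a=att(s["end_a"]),
                    end_b=att(s["end_b"]),
                    rest_length=s["rest_length"],
                    law=law,
                    group=s["group"],
                    side=s["side"],
                )
                for s in d["springs"]
            ],
            joint=JointElement(
                face_sacrum=att(d["joint"]["face_sacrum"]),
                face_c1=att(d["joint"]["face_c1"]),
                area=d["joint"]["area"],
                rest_thickness=d["joint"]["rest_thickness"],
                law=joint_law,
            ),
            load_point=att(d["load_point"]),
            sij_penalty_stiffness=d["sij_penalty_stiffness"],
            regularization_stiffness=d["regularization_stiffness"],
        )

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path) -> "Model":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Topology builders
# --------------------------------------------------------------------------

def crisscross_springs(sacrum_pts: np.ndarray, ilium_pts: np.ndarray):
    """Index pairs and lengths for the 10-spring crisscross sheet pattern.

    4 parallel springs S_i--I_i plus the 6 adjacent diagonals S_i--I_{i+1}
    and S_{i+1}--I_i.  Returns a list of (i_sacrum, i_ilium, rest_length).
    """
    sp = np.asarray(sacrum_pts, dtype=float)
    ip = np.asarray(ilium_pts, dtype=float)
    if sp.shape != (4, 3) or ip.shape != (4, 3):
        raise ValueError(
            f"crisscross pattern needs 4 + 4 points, got {sp.shape} and {ip.shape}"
        )
    out = []
    for i, j in CRISSCROSS_PAIRS:
        L = float(np.linalg.norm(ip[j] - sp[i]))
        if L <= 0:
            raise ValueError(f"coincident attachment points S{i+1}/I{j+1}")
        out.append((i, j, L))
    return out


def sacrotuberous_springs(origin_s3, origin_c1, insertion_tuber):
    """The two-spring "Y": S3 and C1 origins joined at the tuberosity.

    Returns [(origin, insertion, rest_length), ...] with the shared
    insertion point second in each pair.
    """
    pts = [np.asarray(p, dtype=float).reshape(3) for p in (origin_s3, origin_c1)]
    tub = np.asarray(insertion_tuber, dtype=float).reshape(3)
    out = []
    for p in pts:
        L = float(np.linalg.norm(tub - p))
        if L <= 0:
            raise ValueError("sacrotuberous origin coincides with tuberosity insertion")
        out.append((p, tub, L))
    return out


def build_model(
    lm: PelvisLandmarks,
    ligament_law: LigamentLaw | None = None,
    joint_law: object | None = None,
    sij_penalty_stiffness: float = 1.0e3,
    regularization_stiffness: float = 1.0e-6,
) -> Model:
    """Assemble the full model from a landmark set.

    Rest lengths are taken from the reference geometry, so every spring is
    at exactly zero strain (and the model is stress-free) in the reference
    configuration.
    """
    lig = ligament_law or LigamentLaw()
    jlaw = joint_law or JointLaw()

    sacrum_origin = tuple(lm.sacrocaudal_sacrum)
    c1_origin = tuple(lm.sacrocaudal_c1)
    bodies = {
        "sacrum": RigidBody(name="sacrum", origin=sacrum_origin),
        "c1": RigidBody(name="c1", origin=c1_origin),
    }

    springs: list[SpringElement] = []

    def add(name, body_a, pa, body_b, pb, group, side):
        L = float(np.linalg.norm(np.asarray(pb, float) - np.asarray(pa, float)))
        springs.append(
            SpringElement(
                name=name,
                end_a=Attachment(body=body_a, point=tuple(np.asarray(pa, float))),
                end_b=Attachment(body=body_b, point=tuple(np.asarray(pb, float))),
                rest_length=L,
                law=lig,
                group=group,
                side=side,
            )
        )

    for side in SIDES:
        for group, sac_cls, il_cls in (
            ("dorsal_si", lm.dorsal_sacrum_pts, lm.dorsal_ilium_pts),
            ("ventral_si", lm.ventral_sacrum_pts, lm.ventral_ilium_pts),
        ):
            for k, (i, j, _L) in enumerate(
                crisscross_springs(sac_cls[side], il_cls[side])
            ):
                add(
                    f"{group}_{side}_{k}",
                    "sacrum", sac_cls[side][i],
                    "world", il_cls[side][j],
                    group, side,
                )
        # SIJ: 10 short parallel springs across the joint gap
        sac = lm.sij_sacrum_pts[side]
        il = lm.sij_ilium_pts[side]
        for k in range(10):
            add(f"sij_{side}_{k}", "sacrum", sac[k], "world", il[k], "sij", side)
        # sacrotuberous "Y": one spring from sacrum (S3), one from C1
        for k, (origin, tub, _L) in enumerate(
            sacrotuberous_springs(
                lm.st_origin_s3[side][0],
                lm.st_origin_c1[side][0],
                lm.st_insertion_tuber[side][0],
            )
        ):
            add(
                f"sacrotuberous_{side}_{k}",
                "sacrum" if k == 0 else "c1", origin,
                "world", tub,
                "sacrotuberous", side,
            )

    # rest thickness = reference interface gap, so the reference configuration
    # is exactly stress-free even for perturbed geometry
    gap0 = float(np.linalg.norm(lm.sacrocaudal_c1 - lm.sacrocaudal_sacrum))
    joint = JointElement(
        face_sacrum=Attachment(body="sacrum", point=tuple(lm.sacrocaudal_sacrum)),
        face_c1=Attachment(body="c1", point=tuple(lm.sacrocaudal_c1)),
        area=lm.sacrocaudal_area,
        rest_thickness=gap0,
        law=jlaw,
    )
    return Model(
        bodies=bodies,
        springs=springs,
        joint=joint,
        load_point=Attachment(body="sacrum", point=tuple(lm.load_point)),
        sij_penalty_stiffness=sij_penalty_stiffness,
        regularization_stiffness=regularization_stiffness,
    )
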