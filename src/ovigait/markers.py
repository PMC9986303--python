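"""Marker-set vocabulary for the 42-landmark ovine capture protocol.

Axial landmarks (head and spine) are unsided; limb landmarks carry a
``_FL_``/``_HL_`` limb tag and an ``_L``/``_R`` side suffix, e.g.
``DPHAL_FL_L`` is the distal phalange (hoof) marker of the left forelimb.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Limb identifiers: fore/hind x left/right.
LIMBS = ("FL_L", "FL_R", "HL_L", "HL_R")

AXIAL_MARKERS = ("HEAD", "T1", "T13", "L7")

#: Distal-to-proximal anatomical landmark names of each limb chain.
FORELIMB_CHAIN = ("GTUB", "LEPIRAD", "ULNA", "METAR", "PPHAL", "PHAL", "DPHAL")
HINDLIMB_CHAIN = (
    "ILIUM", "ISCHTUB", "GTROC", "LEPI", "LTIB", "TIB",
    "CALC", "LMAL", "FTAR", "PPHAL", "PHAL", "DPHAL",
)


def limb_marker(base: str, limb: str) -> str:
    """Full label of an anatomical landmark on a given limb (e.g. DPHAL, FL_L)."""
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}; expected one of {LIMBS}")
    return f"{base}_{limb}"


def limb_markers(limb: str) -> tuple[str, ...]:
    chain = FORELIMB_CHAIN if limb.startswith("FL") else HINDLIMB_CHAIN
    return tuple(limb_marker(b, limb) for b in chain)


#: The complete 42-marker set.
FULL_MARKER_SET = AXIAL_MARKERS + tuple(
    m for limb in LIMBS for m in limb_markers(limb)
)

#: Marker subsets required by each analysis.
REQUIRED_MARKERS = {
    "global": AXIAL_MARKERS,
    "forelimb": {
        "L": limb_markers("FL_L"),
        "R": limb_markers("FL_R"),
    },
    "hindlimb": {
        "L": limb_markers("HL_L"),
        "R": limb_markers("HL_R"),
    },
    "full": FULL_MARKER_SET,
}


@dataclass(frozen=True)
class JointDefinition:
    """A planar joint: the signed angle between two marker-pair vectors.

    Each vector runs from the first to the second named landmark; the angle
    is measured in the sagittal (progression-vertical) plane, zero when the
    distal vector continues the proximal one (straight limb), negative for
    flexion.
    """

    joint: str
    proximal: tuple[str, str]
    distal: tuple[str, str]
    limb_kind: str  # "FL" or "HL"

    def marker_labels(self, limb: str) -> tuple[str, str, str, str]:
        if not limb.startswith(self.limb_kind):
            raise ValueError(f"joint {self.joint} is not defined on limb {limb}")
        p1, p2 = (limb_marker(m, limb) for m in self.proximal)
        d1, d2 = (limb_marker(m, limb) for m in self.distal)
        return p1, p2, d1, d2


#: Joint vector definitions from the capture protocol's landmark chains.
JOINTS = {
    "fetlock_fore": JointDefinition("fetlock_fore", ("METAR", "PPHAL"), ("PPHAL", "PHAL"), "FL"),
    "carpus": JointDefinition("carpus", ("LEPIRAD", "ULNA"), ("METAR", "PPHAL"), "FL"),
    "elbow": JointDefinition("elbow", ("GTUB", "LEPIRAD"), ("LEPIRAD", "ULNA"), "FL"),
    "fetlock_hind": JointDefinition("fetlock_hind", ("FTAR", "PPHAL"), ("PPHAL", "PHAL"), "HL"),
    "tarsus": JointDefinition("tarsus", ("TIB", "LMAL"), ("FTAR", "PPHAL"), "HL"),
    "stifle": JointDefinition("stifle", ("GTROC", "LEPI"), ("LTIB", "LMAL"), "HL"),
}

#: Joints computed on each limb kind.
FORELIMB_JOINTS = ("fetlock_fore", "carpus", "elbow")
HINDLIMB_JOINTS = ("fetlock_hind", "tarsus", "stifle")


def joints_for_limb(limb: str) -> tuple[str, ...]:
    return FORELIMB_JOINTS if limb.startswith("FL") else HINDLIMB_JOINTS
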