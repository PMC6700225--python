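"""Structural state space of Golgi-processed N-glycans.

A glycan is tracked by the handful of features the processing enzymes read
and write: the unremoved glucose left over from ER processing, the mannose
count of the trimmed core, the state of up to four GlcNAc-initiated
antennae, and core fucosylation.  Each antenna progresses independently
through GlcNAc -> Gal -> Sia, and a sialic-acid cap is terminal.

The four antenna slots correspond to the transferase that initiates them:
``armA`` (Mgat1, the alpha-1,3 arm), ``armB`` (Mgat2, the alpha-1,6 arm),
``arm4`` (Mgat4) and ``arm6`` (Mgat5).  Distinct slot assignments are
distinct structures even when they share a monosaccharide composition, so
state codes are bijective while composition strings are not.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum


class Antenna(str, Enum):
    """Maturation state of one GlcNAc-initiated antenna."""

    ABSENT = "absent"
    GLCNAC = "GlcNAc"
    GAL = "Gal"
    SIA = "Sia"


_ANTENNA_CODE = {
    Antenna.ABSENT: "-",
    Antenna.GLCNAC: "N",
    Antenna.GAL: "G",
    Antenna.SIA: "S",
}
_CODE_ANTENNA = {v: k for k, v in _ANTENNA_CODE.items()}

ARM_FIELDS = ("armA", "armB", "arm4", "arm6")

_CODE_RE = re.compile(r"^g([01])m([3-9])a([-NGS])b([-NGS])c([-NGS])d([-NGS])f([01])$")


@dataclass(frozen=True, slots=True)
class GlycanState:
    """One N-glycan structure, as seen by the Golgi enzymes.

    Raises ``ValueError`` on construction if the feature combination is
    structurally impossible (e.g. antennae on an untrimmed core).
    """

    glc: int = 0
    man: int = 3
    armA: Antenna = Antenna.ABSENT
    armB: Antenna = Antenna.ABSENT
    arm4: Antenna = Antenna.ABSENT
    arm6: Antenna = Antenna.ABSENT
    fuc: int = 0

    def __post_init__(self) -> None:
        if self.glc not in (0, 1):
            raise ValueError(f"glc must be 0 or 1, got {self.glc}")
        if not 3 <= self.man <= 9:
            raise ValueError(f"man must be in 3..9, got {self.man}")
        if self.fuc not in (0, 1):
            raise ValueError(f"fuc must be 0 or 1, got {self.fuc}")
        for name in ARM_FIELDS:
            if not isinstance(getattr(self, name), Antenna):
                raise ValueError(f"{name} must be an Antenna value")
        if self.glc == 1 and self.man != 9:
            raise ValueError("glucose persists only on the untrimmed Man9 core")
        if self.armA is Antenna.ABSENT:
            if any(getattr(self, a) is not Antenna.ABSENT for a in ("armB", "arm4", "arm6")):
                raise ValueError("antennae beyond armA require the Mgat1 antenna")
            if self.fuc:
                raise ValueError("core fucosylation requires the Mgat1 antenna")
        if self.man > 5 and self.armA is not Antenna.ABSENT:
            raise ValueError("Mgat1 antenna requires trimming to Man5 or below")
        for name in ("armB", "arm4", "arm6"):
            if getattr(self, name) is not Antenna.ABSENT and self.man != 3:
                raise ValueError(f"{name} requires the fully trimmed Man3 core")
        if self.arm4 is not Antenna.ABSENT and self.armB is Antenna.ABSENT:
            raise ValueError("the Mgat4 antenna requires the Mgat2 antenna")

    # -- canonical bijective encoding ------------------------------------

    def code(self) -> str:
        """Compact canonical state code, e.g. ``g0m3aSbS c-...`` -> ``g0m3aSbSc-d-f1``."""
        return (
            f"g{self.glc}m{self.man}"
            f"a{_ANTENNA_CODE[self.armA]}b{_ANTENNA_CODE[self.armB]}"
            f"c{_ANTENNA_CODE[self.arm4]}d{_ANTENNA_CODE[self.arm6]}"
            f"f{self.fuc}"
        )

    @classmethod
    def from_code(cls, code: str) -> "GlycanState":
        m = _CODE_RE.match(code)
        if m is None:
            raise ValueError(f"malformed glycan state code: {code!r}")
        glc, man, a, b, c, d, fuc = m.groups()
        return cls(
            glc=int(glc),
            man=int(man),
            armA=_CODE_ANTENNA[a],
            armB=_CODE_ANTENNA[b],
            arm4=_CODE_ANTENNA[c],
            arm6=_CODE_ANTENNA[d],
            fuc=int(fuc),
        )

    # -- derived structural quantities -----------------------------------

    def arms(self) -> tuple[Antenna, Antenna, Antenna, Antenna]:
        return (self.armA, self.armB, self.arm4, self.arm6)

    @property
    def antennarity(self) -> int:
        return sum(a is not Antenna.ABSENT for a in self.arms())

    @property
    def n_gal(self) -> int:
        """Antennae carrying galactose (including those further capped by Sia)."""
        return sum(a in (Antenna.GAL, Antenna.SIA) for a in self.arms())

    @property
    def n_sia(self) -> int:
        return sum(a is Antenna.SIA for a in self.arms())

    def replace(self, **changes) -> "GlycanState":
        fields = {f: getattr(self, f) for f in ("glc", "man", *ARM_FIELDS, "fuc")}
        fields.update(changes)
        return GlycanState(**fields)

    def progress(self) -> int:
        """Number of enzymatic events separating this state from its entry form.

        Every rule advances exactly one coordinate by one step, so the event
        count along any path from a fixed entry glycan to this state is
        path-independent.
        """
        trims = (1 - self.glc) + (9 - self.man)
        arm_steps = 0
        for a in self.arms():
            arm_steps += {Antenna.ABSENT: 0, Antenna.GLCNAC: 1, Antenna.GAL: 2, Antenna.SIA: 3}[a]
        return trims + arm_steps + self.fuc


# Oligomannose species delivered from the ER into the first cisterna.
ENTRY_GLYCANS: dict[str, GlycanState] = {
    "Man9GlcNAc2": GlycanState(glc=0, man=9),
    "Man8GlcNAc2": GlycanState(glc=0, man=8),
    "GlcMan9GlcNAc2": GlycanState(glc=1, man=9),
}


def composition(state: GlycanState) -> str:
    """Monosaccharide composition string in the flat field notation.

    Distinct structures can share a composition (a Mgat4- and a Mgat5-derived
    tri-antennary glycan, for instance), so this mapping is deliberately
    non-injective; use :meth:`GlycanState.code` for a bijective identifier.
    """
    n_glcnac = 2 + state.antennarity
    parts = []
    if state.glc:
        parts.append(f"Glc{state.glc}")
    if state.fuc:
        parts.append(f"Fuc{state.fuc}")
    parts.append(f"GlcNAc{n_glcnac}")
    parts.append(f"Man{state.man}")
    if state.n_gal:
        parts.append(f"Gal{state.n_gal}")
    if state.n_sia:
        parts.append(f"NeuAc{state.n_sia}")
    return "".join(parts)


@dataclass(frozen=True, slots=True)
class GlycanClass:
    """Maturity classification of a glycan structure."""

    category: str  # "oligomannose" | "hybrid" | "complex"
    antennarity: int
    sialylation: int
    fucosylated: bool


def classify(state: GlycanState) -> GlycanClass:
    """Assign the standard maturity class.

    Oligomannose: no Mgat1 antenna, core still Man5 or larger. Hybrid: Mgat1
    antenna present but mannose trimming incomplete. Complex: Man3 core with
    at least the Mgat1 antenna.
    """
    if state.armA is Antenna.ABSENT:
        if state.man < 5:
            raise ValueError(f"unclassifiable (unreachable) state: {state.code()}")
        category = "oligomannose"
    elif state.man > 3:
        category = "hybrid"
    else:
        category = "complex"
    return GlycanClass(
        category=category,
        antennarity=state.antennarity,
        sialylation=state.n_sia,
        fucosylated=bool(state.fuc),
    )
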