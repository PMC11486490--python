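"""Retrotransposon class/family taxonomy.

Retrotransposons (RTEs) fall into three classes — LINE, SINE and LTR — each with a
small number of abundant families in the human genome. Satellite repeats are tandem
(non-RTE) repeats carried along as a negative-control class. Anything else seen in a
repeat annotation is binned as ``Other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RTE_CLASSES = ("LINE", "SINE", "LTR")
CONTROL_CLASSES = ("Satellite",)

_DEFAULT_CLASS_TO_FAMILIES: dict[str, tuple[str, ...]] = {
    "LINE": ("L1", "L2"),
    "SINE": ("Alu", "MIR"),
    "LTR": ("ERV1", "ERVL", "ERVL-MaLR", "ERVK"),
    "Satellite": ("Satellite",),
}


@dataclass(frozen=True)
class RTETaxonomy:
    """Mapping from RTE classes to their member families.

    Each family belongs to exactly one class. ``control_classes`` names the
    non-RTE repeat classes (satellite DNA) kept as controls.
    """

    class_to_families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_TO_FAMILIES)
    )
    control_classes: tuple[str, ...] = CONTROL_CLASSES

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls, fams in self.class_to_families.items():
            for fam in fams:
                if fam in seen and seen[fam] != cls:
                    raise ValueError(
                        f"family {fam!r} assigned to both {seen[fam]!r} and {cls!r}"
                    )
                seen[fam] = cls

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_to_families)

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(f for fams in self.class_to_families.values() for f in fams)

    def family_to_class(self, family: str) -> str | None:
        for cls, fams in self.class_to_families.items():
            if family in fams:
                return cls
        return None


DEFAULT_TAXONOMY = RTETaxonomy()
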