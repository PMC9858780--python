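"""Coiled-coil repeat vocabulary shared by the generator and the scanner.

Coiled coils are built from sequence repeats whose hydrophobic core
positions recur with a characteristic periodicity: seven-residue repeats
(heptads, positions labelled a-g, core at a/d, periodicity 7/2 = 3.5),
eleven-residue repeats (hendecads, a-k, core at a/d/h, periodicity
11/3 ~ 3.667) and fifteen-residue repeats (pentadecads, a-o, core at
a/d/h/l, periodicity 15/4 = 3.75).  The degree and handedness of
supercoiling follows from the difference between this sequence
periodicity and the structural periodicity of an undistorted alpha-helix,
3.63 residues per turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Structural periodicity of an undistorted alpha-helix (residues/turn).
HELIX_PERIOD = 3.63


@dataclass(frozen=True)
class RepeatClass:
    """One of the three canonical coiled-coil sequence repeat types."""

    name: str
    repeat_length: int
    core_offsets: tuple[int, ...]  # positions of hydrophobic core within the repeat
    position_labels: str

    def __post_init__(self) -> None:
        assert len(self.position_labels) == self.repeat_length
        assert all(0 <= o < self.repeat_length for o in self.core_offsets)

    @property
    def hydrophobics_per_repeat(self) -> int:
        return len(self.core_offsets)

    @property
    def periodicity(self) -> float:
        """Residues per hydrophobic-core position (7/2, 11/3 or 15/4)."""
        return self.repeat_length / self.hydrophobics_per_repeat

    @property
    def core_labels(self) -> frozenset[str]:
        return frozenset(self.position_labels[o] for o in self.core_offsets)


HEPTAD = RepeatClass("heptad", 7, (0, 3), "abcdefg")
HENDECAD = RepeatClass("hendecad", 11, (0, 3, 7), "abcdefghijk")
PENTADECAD = RepeatClass("pentadecad", 15, (0, 3, 7, 11), "abcdefghijklmno")

REPEAT_CLASSES: dict[str, RepeatClass] = {
    rc.name: rc for rc in (HEPTAD, HENDECAD, PENTADECAD)
}
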