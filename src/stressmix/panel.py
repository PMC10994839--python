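"""Chemical panels and mixture designs on the subset lattice.

A :class:`ChemicalPanel` fixes an ordered set of chemical names for the
lifetime of an analysis; a :class:`MixtureDesign` is a subset of that panel,
stored internally as a bitmask over panel indices so that subset tests and
power-set enumeration on the 2^n lattice are O(1)/O(2^n).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence


class PanelError(ValueError):
    """A chemical name or index does not belong to the panel."""


@dataclass(frozen=True)
class ChemicalPanel:
    """An ordered, immutable panel of chemical identifiers.

    Subset encodings (bitmasks) refer to positions in ``names``; the order is
    fixed for the lifetime of an analysis.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise PanelError("panel must contain at least one chemical")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelError(f"duplicate chemical names in panel: {dupes}")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise PanelError(
                f"chemical {name!r} is not in the panel {list(self.names)}"
            ) from None

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True, order=False)
class MixtureDesign:
    """A subset of a chemical panel, canonically encoded as a bitmask.

    The empty mixture encodes the no-chemical control. Two designs with the
    same member set compare equal regardless of construction order.
    """

    mask: int
    panel_size: int = field(compare=False)

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise PanelError("panel_size must be >= 1")
        if self.mask < 0 or self.mask >= (1 << self.panel_size):
            raise PanelError(
                f"mask {self.mask} out of range for a panel of {self.panel_size}"
            )

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_indices(cls, indices: Iterable[int], panel: ChemicalPanel) -> "MixtureDesign":
        mask = 0
        for i in indices:
            if not 0 <= i < panel.size:
                raise PanelError(f"index {i} out of range for panel of {panel.size}")
            mask |= 1 << i
        return cls(mask, panel.size)

    @classmethod
    def from_names(cls, names: Iterable[str], panel: ChemicalPanel) -> "MixtureDesign":
        return cls.from_indices((panel.index(n) for n in names), panel)

    @classmethod
    def control(cls, panel: ChemicalPanel) -> "MixtureDesign":
        return cls(0, panel.size)

    # -- set views --------------------------------------------------------
    @property
    def members(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.panel_size) if self.mask >> i & 1)

    @property
    def size(self) -> int:
        return self.mask.bit_count()

    @property
    def is_control(self) -> bool:
        return self.mask == 0

    def names(self, panel: ChemicalPanel) -> tuple[str, ...]:
        if panel.size != self.panel_size:
            raise PanelError("design does not belong to this panel")
        return tuple(panel.names[i] for i in self.members)

    def label(self, panel: ChemicalPanel, sep: str = ";") -> str:
        """Human/CSV label: semicolon-joined names, empty for the control."""
        return sep.join(self.names(panel))

    # -- lattice relations ------------------------------------------------
    def issubset(self, other: "MixtureDesign") -> bool:
        return self.mask & ~other.mask == 0

    def singletons(self) -> list["MixtureDesign"]:
        return [MixtureDesign(1 << i, self.panel_size) for i in self.members]

    def subsets(self, min_size: int = 1, max_size: int | None = None) -> list["MixtureDesign"]:
        """All sub-designs with sizes in [min_size, max_size], ordered by
        (size, lexicographic member indices). ``max_size`` defaults to
        ``self.size`` (the design itself included)."""
        if max_size is None:
            max_size = self.size
        out = []
        for k in range(min_size, max_size + 1):
            for combo in itertools.combinations(self.members, k):
                m = 0
                for i in combo:
                    m |= 1 << i
                out.append(MixtureDesign(m, self.panel_size))
        return out

    def sort_key(self) -> tuple[int, tuple[int, ...]]:
        return (self.size, self.members)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"MixtureDesign({set(self.members) or '{}'}, n={self.panel_size})"


def enumerate_mixtures(panel: ChemicalPanel) -> list[MixtureDesign]:
    """All 2^n − 1 non-empty subsets of the panel, ordered by
    (size, lexicographic member indices).

    An 8-chemical panel yields the full-factorial 255 mixture designs.
    """
    designs = [MixtureDesign(m, panel.size) for m in range(1, 1 << panel.size)]
    designs.sort(key=MixtureDesign.sort_key)
    return designs
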