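"""Genome coordinate model for deletion-bin mapping.

Chromosomes are linear sequences with a single centromere splitting them into
a short (S) and a long (L) arm.  All coordinates are 0-based half-open bp.
Positions along an arm are also expressed as *fraction length* (FL): the
distance from the centromere divided by the arm length, so FL 0 is the
centromere and FL 1 the telomere.  A deletion stock with breakpoint FL 0.41
retains the proximal 41% of the arm and lacks the distal 59%.

By convention wheat pseudomolecules place the short arm on the low-coordinate
side; :class:`Chromosome` carries a ``short_arm_low`` flag so mirrored
assemblies can be represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ARMS = ("S", "L")


class LayoutError(KeyError):
    """Unknown chromosome or arm."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the reference layout."""

    name: str
    length: int
    centromere: int
    short_arm_low: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive, got {self.length}")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"{self.name}: centromere must lie strictly inside (0, length), "
                f"got {self.centromere} for length {self.length}"
            )

    def arm_of(self, position: float) -> str:
        """Arm containing ``position`` (centromere itself belongs to the high arm)."""
        low = position < self.centromere
        if self.short_arm_low:
            return "S" if low else "L"
        return "L" if low else "S"

    def arm_length(self, arm: str) -> int:
        if arm not in ARMS:
            raise LayoutError(f"unknown arm {arm!r}; expected one of {ARMS}")
        low_arm = "S" if self.short_arm_low else "L"
        return self.centromere if arm == low_arm else self.length - self.centromere

    def arm_span(self, arm: str) -> tuple[int, int]:
        """Half-open bp interval occupied by ``arm``."""
        low_arm = "S" if self.short_arm_low else "L"
        if arm == low_arm:
            return 0, self.centromere
        if arm in ARMS:
            return self.centromere, self.length
        raise LayoutError(f"unknown arm {arm!r}; expected one of {ARMS}")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered collection of chromosomes defining the coordinate frame."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        chroms = tuple(self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [c.name for c in chroms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise LayoutError(f"chromosome {name!r} not in layout (have {self.names})")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "GenomeLayout":
        return cls(
            tuple(
                Chromosome(
                    name=str(r["name"]),
                    length=int(r["length"]),
                    centromere=int(r["centromere"]),
                    short_arm_low=bool(r.get("short_arm_low", True)),
                )
                for r in records
            )
        )

    def to_records(self) -> list[dict]:
        return [
            {
                "name": c.name,
                "length": c.length,
                "centromere": c.centromere,
                "short_arm_low": c.short_arm_low,
            }
            for c in self.chromosomes
        ]


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-width tiling bin, 0-based half-open, with a global index."""

    chrom: str
    start: int
    end: int
    index: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class ArmCoordinate:
    """Arm-relative position: chromosome, arm, and fraction length in [0, 1]."""

    chrom: str
    arm: str
    fl: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise LayoutError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if not 0.0 <= self.fl <= 1.0:
            raise ValueError(f"fl must lie in [0, 1], got {self.fl}")


def build_bins(layout: GenomeLayout, width: int) -> list[GenomicBin]:
    """Tile every chromosome with non-overlapping ``width``-bp bins.

    The last bin of each chromosome may be shorter.  Global indices run
    consecutively in chromosome order.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    bins: list[GenomicBin] = []
    idx = 0
    for c in layout.chromosomes:
        for start in range(0, c.length, width):
            bins.append(GenomicBin(c.name, start, min(start + width, c.length), idx))
            idx += 1
    return bins


def fl_of(layout: GenomeLayout, chrom: str, position: float) -> ArmCoordinate:
    """Arm coordinate of a bp position.

    The centromere maps to FL 0 on the long-arm side; ``position == length``
    is accepted as the distal telomere boundary (FL 1.0).
    """
    c = layout[chrom]
    if not 0 <= position <= c.length:
        raise ValueError(
            f"position {position} outside chromosome {chrom} [0, {c.length})"
        )
    if position < c.centromere:
        arm = "S" if c.short_arm_low else "L"
        fl = (c.centromere - position) / c.centromere
    else:
        arm = "L" if c.short_arm_low else "S"
        fl = (position - c.centromere) / (c.length - c.centromere)
    return ArmCoordinate(chrom, arm, fl)


def position_of(layout: GenomeLayout, coord: ArmCoordinate) -> int:
    """Inverse of :func:`fl_of`, rounding half away from the centromere."""
    c = layout[coord.chrom]
    low_arm = "S" if c.short_arm_low else "L"
    if coord.arm == low_arm:
        raw = c.centromere - coord.fl * c.centromere
        return math.ceil(raw - 0.5)
    raw = c.centromere + coord.fl * (c.length - c.centromere)
    return math.floor(raw + 0.5)


@dataclass
class BinIndex:
    """Vectorised lookup tables over an ordered bin list.

    Precomputes per-bin numpy arrays (chrom, start, end, midpoint) plus the
    per-chromosome global index ranges, for use by the simulation and calling
    code.
    """

    bins: list[GenomicBin]
    chrom: np.ndarray = field(init=False)
    start: np.ndarray = field(init=False)
    end: np.ndarray = field(init=False)
    mid: np.ndarray = field(init=False)
    chrom_slices: dict[str, slice] = field(init=False)

    def __post_init__(self) -> None:
        self.chrom = np.array([b.chrom for b in self.bins], dtype=object)
        self.start = np.array([b.start for b in self.bins], dtype=np.int64)
        self.end = np.array([b.end for b in self.bins], dtype=np.int64)
        self.mid = (self.start + self.end) / 2.0
        self.chrom_slices = {}
        i = 0
        n = len(self.bins)
        while i < n:
            name = self.bins[i].chrom
            j = i
            while j < n and self.bins[j].chrom == name:
                j += 1
            if name in self.chrom_slices:
                raise ValueError(f"bins for chromosome {name} are not contiguous")
            self.chrom_slices[name] = slice(i, j)
            i = j

    def __len__(self) -> int:
        return len(self.bins)

    def bin_at(self, chrom: str, position: float) -> int:
        """Global index of the bin containing ``position`` on ``chrom``."""
        sl = self.chrom_slices.get(chrom)
        if sl is None:
            raise LayoutError(f"chromosome {chrom!r} has no bins")
        starts = self.start[sl]
        ends = self.end[sl]
        k = int(np.searchsorted(starts, position, side="right")) - 1
        if k < 0 or position >= ends[k]:
            raise ValueError(f"position {position} not covered by bins on {chrom}")
        return sl.start + k

    def arm_mask(self, layout: GenomeLayout, chrom: str, arm: str) -> np.ndarray:
        """Boolean mask (over all bins) of bins whose midpoint lies on ``arm``."""
        c = layout[chrom]
        lo, hi = c.arm_span(arm)
        return (self.chrom == chrom) & (self.mid >= lo) & (self.mid < hi)


def bins_to_frame(bins: Sequence[GenomicBin]):
    """Bin list as a pandas DataFrame (chrom, start, end, index)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "index": [b.index for b in bins],
        }
    )
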