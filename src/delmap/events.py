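"""Karyotype events of wheat cytogenetic stocks and their copy-number expansion.

The panel vocabulary covers the classic Chinese Spring aneuploid stocks:
nullisomics (a chromosome pair missing), tetrasomics (four doses), ditelosomics
(only one arm retained as a telocentric pair), terminal-deletion stocks
(distal part of one arm missing beyond an FL breakpoint) and arm-addition
stocks (extra telocentric arm pairs on top of the normal complement).
Stocks are homozygous, so copy numbers move in steps of two by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import ARMS, BinIndex, GenomeLayout, GenomicBin, fl_of

EVENT_KINDS = (
    "nullisomy",
    "tetrasomy",
    "telosomic",
    "terminal_deletion",
    "arm_addition",
)


class ConflictError(ValueError):
    """Two events assign different copy numbers to the same bin."""


@dataclass(frozen=True)
class KaryotypeEvent:
    """One structural event of a stock's karyotype.

    ``arm`` is required for telosomic (the retained arm), terminal_deletion
    (the deleted arm) and arm_addition (the added arm).  ``fl_retained`` is
    required for terminal_deletion only: the fraction of the arm, measured
    from the centromere, still present.  ``extra_copies`` counts extra arm
    *pairs* for arm_addition (or chromosome pairs for tetrasomy).
    """

    kind: str
    chrom: str
    arm: str | None = None
    fl_retained: float | None = None
    extra_copies: int = 1

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected {EVENT_KINDS}")
        needs_arm = self.kind in ("telosomic", "terminal_deletion", "arm_addition")
        if needs_arm and self.arm not in ARMS:
            raise ValueError(f"{self.kind} requires arm in {ARMS}, got {self.arm!r}")
        if self.kind == "terminal_deletion":
            if self.fl_retained is None or not 0.0 <= self.fl_retained <= 1.0:
                raise ValueError(
                    f"terminal_deletion requires fl_retained in [0, 1], got {self.fl_retained}"
                )
        elif self.fl_retained is not None:
            raise ValueError(f"fl_retained is only meaningful for terminal_deletion")
        if self.extra_copies < 1:
            raise ValueError(f"extra_copies must be >= 1, got {self.extra_copies}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "chrom": self.chrom}
        if self.arm is not None:
            d["arm"] = self.arm
        if self.fl_retained is not None:
            d["fl_retained"] = self.fl_retained
        if self.kind in ("tetrasomy", "arm_addition"):
            d["extra_copies"] = self.extra_copies
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KaryotypeEvent":
        return cls(
            kind=d["kind"],
            chrom=d["chrom"],
            arm=d.get("arm"),
            fl_retained=d.get("fl_retained"),
            extra_copies=int(d.get("extra_copies", 1)),
        )


def copy_number_track(
    layout: GenomeLayout,
    bins: Sequence[GenomicBin] | BinIndex,
    events: Iterable[KaryotypeEvent],
) -> np.ndarray:
    """Expand karyotype events into a per-bin integer copy-number vector.

    Baseline is 2 everywhere.  A bin belongs to an arm by its midpoint, and a
    terminal deletion removes the bins whose midpoint FL exceeds
    ``fl_retained``.  Contradictory assignments to the same bin raise
    :class:`ConflictError` naming the first offending bin.
    """
    bi = bins if isinstance(bins, BinIndex) else BinIndex(list(bins))
    cn = np.full(len(bi), 2, dtype=np.int64)
    assigned = np.full(len(bi), -1, dtype=np.int64)  # -1 = untouched

    def apply(mask: np.ndarray, value: int) -> None:
        clash = mask & (assigned >= 0) & (assigned != value)
        if clash.any():
            b = bi.bins[int(np.flatnonzero(clash)[0])]
            raise ConflictError(
                f"conflicting copy numbers for bin {b.chrom}:{b.start}-{b.end} "
                f"(index {b.index}): {int(assigned[b.index])} vs {value}"
            )
        cn[mask] = value
        assigned[mask] = value

    for ev in events:
        chrom_mask = bi.chrom == ev.chrom
        if not chrom_mask.any():
            raise ValueError(f"event chromosome {ev.chrom!r} has no bins in the layout")
        if ev.kind == "nullisomy":
            apply(chrom_mask, 0)
        elif ev.kind == "tetrasomy":
            apply(chrom_mask, 2 + 2 * ev.extra_copies)
        elif ev.kind == "telosomic":
            retained = bi.arm_mask(layout, ev.chrom, ev.arm)
            other = "S" if ev.arm == "L" else "L"
            apply(bi.arm_mask(layout, ev.chrom, other), 0)
            apply(retained, 2)
        elif ev.kind == "terminal_deletion":
            arm_mask = bi.arm_mask(layout, ev.chrom, ev.arm)
            idxs = np.flatnonzero(arm_mask)
            mids = bi.mid[idxs]
            fls = np.array(
                [fl_of(layout, ev.chrom, m).fl for m in mids], dtype=float
            )
            deleted = np.zeros(len(bi), dtype=bool)
            deleted[idxs[fls > ev.fl_retained]] = True
            apply(deleted, 0)
        elif ev.kind == "arm_addition":
            apply(bi.arm_mask(layout, ev.chrom, ev.arm), 2 + 2 * ev.extra_copies)
    return cn
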