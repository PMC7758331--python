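"""Dosage calling from binned read counts: normalization, smoothing,
state calling, segmentation, and karyotype-event classification.

The normalization is the two-step scheme used for GBS coverage panels:
(1) within-line scaling by total read count, removing library-size
differences; (2) per-bin log2 ratio against a euploid reference line,
removing shared capture-efficiency heterogeneity along the genome.  The
resulting track sits near ``log2(cn/2)``: 0 at two copies, 1 at four,
strongly negative at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import KaryotypeEvent
from .genome import BinIndex, GenomeLayout, fl_of

#: log2-ratio thresholds at the midpoints between expected ratios of copy
#: numbers 0..4 relative to 2 (expected: -inf, -1, 0, 0.585, 1).
DEFAULT_THRESHOLDS = (-2.0, -0.5, 0.5, 0.8)


@dataclass
class BinCountPanel:
    """Line x bin matrix of non-negative read counts over an ordered bin list."""

    bins: BinIndex
    counts: pd.DataFrame  # index: line names, columns: 0..nbins-1

    def __post_init__(self) -> None:
        if not isinstance(self.bins, BinIndex):
            self.bins = BinIndex(list(self.bins))
        if self.counts.shape[1] != len(self.bins):
            raise ValueError(
                f"counts have {self.counts.shape[1]} columns but layout has "
                f"{len(self.bins)} bins"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lines(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class DosageProfile:
    """Called dosage track of one line."""

    line: str
    log2_ratio: np.ndarray
    smoothed: np.ndarray
    state: np.ndarray  # per-bin integer copy number 0..4
    segments: dict[str, list[tuple[int, int, int]]]  # chrom -> (start, end, state), global bin idx, end-exclusive
    precision: np.ndarray | None = None  # per-bin effective depth (weight for segment means)


def two_step_normalize(
    panel: BinCountPanel, reference: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Library-size normalization followed by per-bin log2 ratio to a reference.

    ``p[i, b] = (c[i, b] + pseudocount) / sum_b (c[i, b] + pseudocount)`` and
    the returned matrix is ``log2(p[i, b] / p[ref, b])``.  The reference row
    is exactly zero.  With ``pseudocount == 0`` an all-zero reference bin is
    an error instructing to set a positive pseudocount.
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if reference not in panel.counts.index:
        raise ValueError(f"reference line {reference!r} not in panel")
    c = panel.counts.to_numpy(dtype=float) + pseudocount
    totals = c.sum(axis=1)
    if (totals <= 0).any():
        bad = [panel.lines[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"lines with zero total count: {bad}")
    p = c / totals[:, None]
    ref = p[panel.counts.index.get_loc(reference)]
    if (ref == 0).any():
        raise ZeroDivisionError(
            "reference has zero-count bins; set pseudocount > 0 to avoid "
            "division by zero"
        )
    with np.errstate(divide="ignore"):
        r = np.log2(p / ref[None, :])
    return pd.DataFrame(r, index=panel.counts.index)


def smooth_track(
    values: np.ndarray, window: int, bins: BinIndex | None = None
) -> np.ndarray:
    """Running median with edge truncation; never crosses chromosome boundaries.

    ``window`` must be odd; ``window == 1`` is the identity.  When ``bins`` is
    given the filter is applied independently per chromosome.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    if window == 1:
        return values.copy()
    out = np.empty_like(values)
    half = window // 2

    def run(seg: np.ndarray, dst: np.ndarray) -> None:
        n = len(seg)
        if n >= window:
            windows = np.lib.stride_tricks.sliding_window_view(seg, window)
            dst[half : n - half] = np.median(windows, axis=1)
        # truncated windows at the edges
        for i in range(min(half, n)):
            dst[i] = np.median(seg[: i + half + 1])
        for i in range(max(n - half, 0), n):
            dst[i] = np.median(seg[max(0, i - half) :])

    if bins is None:
        run(values, out)
    else:
        for sl in bins.chrom_slices.values():
            run(values[sl], out[sl])
    return out


def call_states(
    smoothed: np.ndarray, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Map smoothed log2 ratios to integer copy-number states 0..len(thresholds)."""
    t = np.asarray(thresholds, dtype=float)
    if len(t) < 1 or (np.diff(t) <= 0).any():
        raise ValueError(f"thresholds must be strictly increasing, got {list(t)}")
    return np.searchsorted(t, np.asarray(smoothed, dtype=float), side="right").astype(
        np.int64
    )


def _rle(states: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        runs.append((i, j, int(states[i])))
        i = j
    return runs


def segment_states(
    states: np.ndarray,
    min_run: int = 3,
    smoothed: np.ndarray | None = None,
    bins: BinIndex | None = None,
) -> dict[str, list[tuple[int, int, int]]]:
    """Maximal constant runs per chromosome, absorbing runs shorter than
    ``min_run`` into the neighbouring segment with the closer mean smoothed
    ratio (ties go to the proximal / lower-index neighbour).

    Returned tuples are (start, end, state) in global bin indices,
    end-exclusive; segments partition every chromosome's bins.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    states = np.asarray(states)
    if smoothed is None:
        smoothed = states.astype(float)
    slices = (
        bins.chrom_slices if bins is not None else {"all": slice(0, len(states))}
    )
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, sl in slices.items():
        seg_states = states[sl]
        seg_smooth = np.asarray(smoothed)[sl]
        runs = _rle(seg_states)
        # absorb short runs, shortest first, until all runs satisfy min_run
        # (or only one run is left)
        while len(runs) > 1:
            lengths = [e - s for s, e, _ in runs]
            short = [k for k, ln in enumerate(lengths) if ln < min_run]
            if not short:
                break
            k = min(short, key=lambda k: (lengths[k], k))
            s, e, _ = runs[k]
            mean_here = float(np.mean(seg_smooth[s:e]))
            cand = []
            if k > 0:
                ps, pe, pstate = runs[k - 1]
                cand.append((abs(mean_here - float(np.mean(seg_smooth[ps:pe]))), k - 1))
            if k < len(runs) - 1:
                ns, ne, nstate = runs[k + 1]
                cand.append((abs(mean_here - float(np.mean(seg_smooth[ns:ne]))), k + 1))
            # ties: proximal (lower-index) neighbour wins
            cand.sort(key=lambda t: (t[0], t[1]))
            tgt = cand[0][1]
            if tgt < k:
                runs[tgt] = (runs[tgt][0], e, runs[tgt][2])
            else:
                runs[tgt] = (s, runs[tgt][1], runs[tgt][2])
            del runs[k]
            # merge adjacent equal-state runs created by the absorption
            merged = [runs[0]]
            for r in runs[1:]:
                if r[2] == merged[-1][2]:
                    merged[-1] = (merged[-1][0], r[1], r[2])
                else:
                    merged.append(r)
            runs = merged
        off = sl.start
        out[chrom] = [(s + off, e + off, st) for s, e, st in runs]
    return out


@dataclass
class CalledEvent:
    """A classified karyotype event, or an unclassified pattern with its raw
    segments attached (never silently dropped)."""

    chrom: str
    event: KaryotypeEvent | None = None
    breakpoint_interval: tuple[int, int] | None = None  # bp, one bin wide
    segments: list[tuple[int, int, int]] | None = None

    @property
    def kind(self) -> str:
        return self.event.kind if self.event is not None else "unclassified"

    def to_dict(self) -> dict:
        d = {"chrom": self.chrom, "kind": self.kind}
        if self.event is not None:
            d.update(self.event.to_dict())
        if self.breakpoint_interval is not None:
            d["breakpoint_interval"] = list(self.breakpoint_interval)
        if self.segments is not None:
            d["segments"] = [list(s) for s in self.segments]
        return d


def _relabel_runs(
    states: np.ndarray,
    smoothed: np.ndarray,
    order: np.ndarray,
    min_event: int,
    homozygous: bool,
    precision: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """Arm-level dosage runs from per-bin states, in the given bin order.

    Each maximal constant-state run is re-labelled by the precision-weighted
    mean of its raw log2 ratios (weights = per-bin effective depth, so
    low-coverage bins, whose ratios are noisiest, count least; raw rather
    than smoothed values, so one outlier cannot leak into its neighbours'
    contribution): <= -2 is
    dosage 0, >= 0.5 is dosage 4 (homozygous stocks carry 0/2/4 doses),
    otherwise 2; with ``homozygous=False`` the per-bin thresholds are applied
    to the run mean instead, keeping odd dosages.  Runs shorter than
    ``min_event`` bins — below any credible cytogenetic event — are absorbed
    into the neighbouring run with the closer mean ratio.  Returns
    (start, end, dosage) runs in positions of ``order``.
    """
    vals = states[order]
    sm = smoothed[order]
    wts = None if precision is None else precision[order]

    def wmean(lo: int, hi: int) -> float:
        if wts is None:
            return float(np.mean(sm[lo:hi]))
        w = wts[lo:hi]
        tot = float(w.sum())
        if tot <= 0:
            return float(np.mean(sm[lo:hi]))
        return float((sm[lo:hi] * w).sum() / tot)

    def label(lo: int, hi: int) -> int:
        m = wmean(lo, hi)
        if homozygous:
            if m <= -2.0:
                return 0
            return 4 if m >= 0.5 else 2
        return int(call_states(np.array([m]))[0])

    runs = [(s, e, label(s, e)) for s, e, _ in _rle(vals)]

    def merge(rs):
        out = [rs[0]]
        for r in rs[1:]:
            if r[2] == out[-1][2]:
                out[-1] = (out[-1][0], r[1], r[2])
            else:
                out.append(r)
        return out

    runs = merge(runs)
    while len(runs) > 1:
        lengths = [e - s for s, e, _ in runs]
        short = [k for k, ln in enumerate(lengths) if ln < min_event]
        if not short:
            break
        k = min(short, key=lambda k: (lengths[k], k))
        s, e, _ = runs[k]
        mean_here = wmean(s, e)
        cand = []
        if k > 0:
            ps, pe, _ = runs[k - 1]
            cand.append((abs(mean_here - wmean(ps, pe)), k - 1))
        if k < len(runs) - 1:
            ns, ne, _ = runs[k + 1]
            cand.append((abs(mean_here - wmean(ns, ne)), k + 1))
        cand.sort(key=lambda t: (t[0], t[1]))
        tgt = cand[0][1]
        if tgt < k:
            runs[tgt] = (runs[tgt][0], e, runs[tgt][2])
        else:
            runs[tgt] = (s, runs[tgt][1], runs[tgt][2])
        del runs[k]
        runs = merge(runs)
    return runs


def _arm_pattern(
    states: np.ndarray,
    smoothed: np.ndarray,
    idxs: np.ndarray,
    proximal_first: bool,
    min_event: int,
    homozygous: bool,
    precision: np.ndarray | None = None,
) -> tuple[str, int | None]:
    """Classify the dosage pattern of one arm.

    Returns (pattern, boundary_global_bin) where pattern is one of
    'normal', 'missing', 'doubled', 'deletion', 'complex'.  For 'deletion'
    the boundary bin is the first deleted bin in proximal->distal order.
    """
    order = idxs if proximal_first else idxs[::-1]
    runs = _relabel_runs(states, smoothed, order, min_event, homozygous, precision)
    if len(runs) == 1:
        st = runs[0][2]
        return {0: "missing", 2: "normal", 4: "doubled"}.get(st, "complex"), None
    if len(runs) == 2 and runs[0][2] == 2 and runs[1][2] == 0:
        boundary = int(order[runs[1][0]])
        return "deletion", boundary
    return "complex", None


def classify_events(
    profile: DosageProfile,
    layout: GenomeLayout,
    bins: BinIndex,
    min_event: int = 5,
    homozygous: bool = True,
) -> list[CalledEvent]:
    """Template-match per-chromosome segment patterns to karyotype events.

    Whole-chromosome 0 -> nullisomy; whole 4 -> tetrasomy; one arm 2 / other
    arm 0 -> telosomic; proximal 2 then distal 0 on one arm -> terminal
    deletion with the FL of the state-change boundary; one arm 4 with the
    rest 2 -> arm addition.  Composite karyotypes (e.g. a nullisomic
    chromosome plus a tetrasomic homoeologue) emerge as one event per
    chromosome.  Anything else is reported as unclassified with its raw
    segments.

    Arm dosage is assessed at the segment level (see :func:`_relabel_runs`):
    segment-mean log2 ratios decide between the homozygous 0/2/4 doses, and
    runs shorter than ``min_event`` bins are treated as depth artifacts.
    """
    called: list[CalledEvent] = []
    for chrom, sl in bins.chrom_slices.items():
        segs = profile.segments.get(chrom)
        if segs is None:
            continue
        states = profile.state
        arm_info = {}
        c = layout[chrom]
        for arm in ("S", "L"):
            mask = bins.arm_mask(layout, chrom, arm)
            idxs = np.flatnonzero(mask)
            if len(idxs) == 0:
                arm_info[arm] = ("empty", None)
                continue
            lo, hi = c.arm_span(arm)
            # proximal->distal: away from the centromere
            proximal_first = lo == c.centromere
            arm_info[arm] = _arm_pattern(
                states, profile.log2_ratio, idxs, proximal_first, min_event,
                homozygous, profile.precision,
            )

        pat = {arm: arm_info[arm][0] for arm in ("S", "L")}
        ev: CalledEvent | None = None
        if pat == {"S": "normal", "L": "normal"}:
            continue  # euploid chromosome, no event
        if pat == {"S": "missing", "L": "missing"}:
            ev = CalledEvent(chrom, KaryotypeEvent("nullisomy", chrom))
        elif pat == {"S": "doubled", "L": "doubled"}:
            ev = CalledEvent(chrom, KaryotypeEvent("tetrasomy", chrom))
        elif pat["S"] == "normal" and pat["L"] == "missing":
            ev = CalledEvent(chrom, KaryotypeEvent("telosomic", chrom, arm="S"))
        elif pat["S"] == "missing" and pat["L"] == "normal":
            ev = CalledEvent(chrom, KaryotypeEvent("telosomic", chrom, arm="L"))
        elif pat["S"] == "doubled" and pat["L"] == "normal":
            ev = CalledEvent(chrom, KaryotypeEvent("arm_addition", chrom, arm="S"))
        elif pat["S"] == "normal" and pat["L"] == "doubled":
            ev = CalledEvent(chrom, KaryotypeEvent("arm_addition", chrom, arm="L"))
        else:
            for arm in ("S", "L"):
                if arm_info[arm][0] == "deletion" and pat["S" if arm == "L" else "L"] in (
                    "normal",
                    "empty",
                ):
                    boundary_bin = arm_info[arm][1]
                    b = bins.bins[boundary_bin]
                    # boundary = edge of the first deleted bin nearest the
                    # centromere
                    lo, hi = c.arm_span(arm)
                    boundary_pos = b.start if lo == c.centromere else b.end
                    fl = fl_of(layout, chrom, boundary_pos).fl
                    ev = CalledEvent(
                        chrom,
                        KaryotypeEvent(
                            "terminal_deletion", chrom, arm=arm, fl_retained=fl
                        ),
                        breakpoint_interval=(b.start, b.end),
                    )
                    break
        if ev is None:
            ev = CalledEvent(chrom, segments=list(segs))
        called.append(ev)
    return called


@dataclass
class KaryotypeResult:
    profiles: dict[str, DosageProfile]
    events: dict[str, list[CalledEvent]]


def call_karyotypes(
    panel: BinCountPanel,
    layout: GenomeLayout,
    reference: str,
    pseudocount: float = 0.5,
    window: int = 3,
    min_run: int = 3,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_event: int = 5,
    homozygous: bool = True,
) -> KaryotypeResult:
    """Full calling pipeline: normalize, smooth, call, segment, classify."""
    ratios = two_step_normalize(panel, reference, pseudocount)
    c_ref = panel.counts.loc[reference].to_numpy(dtype=float) + pseudocount
    profiles: dict[str, DosageProfile] = {}
    events: dict[str, list[CalledEvent]] = {}
    for line in panel.lines:
        r = ratios.loc[line].to_numpy()
        sm = smooth_track(r, window, bins=panel.bins)
        st = call_states(sm, thresholds)
        segs = segment_states(st, min_run=min_run, smoothed=sm, bins=panel.bins)
        # re-derive per-bin states from segments so state and segments agree
        st_final = st.copy()
        for chrom_segs in segs.values():
            for s, e, state in chrom_segs:
                st_final[s:e] = state
        c_line = panel.counts.loc[line].to_numpy(dtype=float) + pseudocount
        # effective depth of the ratio: harmonic combination of the two
        # libraries' bin counts (inverse of the ratio's sampling variance up
        # to a constant)
        prec = 1.0 / (1.0 / c_line + 1.0 / c_ref)
        prof = DosageProfile(
            line=line, log2_ratio=r, smoothed=sm, state=st_final, segments=segs,
            precision=prec,
        )
        profiles[line] = prof
        events[line] = classify_events(
            prof, layout, panel.bins, min_event=min_event, homozygous=homozygous
        )
    return KaryotypeResult(profiles=profiles, events=events)
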