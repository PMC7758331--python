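"""Deletion-bin mapping: intersect per-line absence calls with a binary
viability phenotype to localize the causal interval.

The logic is the classic deletion-panel argument: a bin can harbour the
causal locus only if it is absent in every non-viable line and present in
every viable line.  Lines whose viability is explained by homoeologous dosage
compensation (a homoeologue at tetrasomic dose substituting for the missing
locus) are excluded from the "present in viable lines" constraint, since
their phenotype carries no information about the target chromosome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import ArmCoordinate, BinIndex, GenomeLayout, fl_of
from .simulate import VIABLE, NON_VIABLE, CompensationRule

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"
PHENOTYPES = (VIABLE, NON_VIABLE, UNKNOWN)


@dataclass
class LineCall:
    """Per-line mapping input: intervals called at copy number zero plus the
    cross-viability phenotype."""

    line: str
    absent_intervals: list[tuple[str, int, int]]
    phenotype: str
    compensated: bool = False

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"{self.line}: phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )
        ivs = sorted(self.absent_intervals)
        for chrom, s, e in ivs:
            if s >= e:
                raise ValueError(f"{self.line}: empty interval {chrom}:{s}-{e}")
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError(
                    f"{self.line}: overlapping absent intervals {c1}:{s1}-{e1} and {c2}:{s2}-{e2}"
                )
        self.absent_intervals = ivs


@dataclass
class CandidateInterval:
    """A maximal run of candidate bins, with FL bounds attached."""

    chrom: str
    start: int
    end: int
    fl_start: ArmCoordinate
    fl_end: ArmCoordinate
    supporting_lines: list[str] = field(default_factory=list)
    excluded_lines: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "fl_start": {"arm": self.fl_start.arm, "fl": self.fl_start.fl},
            "fl_end": {"arm": self.fl_end.arm, "fl": self.fl_end.fl},
            "supporting_lines": list(self.supporting_lines),
            "excluded_lines": dict(self.excluded_lines),
        }


@dataclass
class MapResult:
    intervals: list[CandidateInterval]
    candidate_bins: np.ndarray  # boolean over all bins
    warnings: list[str] = field(default_factory=list)
    excluded_lines: dict[str, str] = field(default_factory=dict)


def absent_mask(call: LineCall, bins: BinIndex) -> np.ndarray:
    """Boolean per-bin absence: a bin counts as absent when its midpoint lies
    in one of the line's absent intervals."""
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, s, e in call.absent_intervals:
        sl = bins.chrom_slices.get(chrom)
        if sl is None:
            raise ValueError(f"{call.line}: unknown chromosome {chrom!r} in call")
        mids = bins.mid[sl]
        mask[sl] |= (mids >= s) & (mids < e)
    return mask


def calls_from_dosage(
    states: pd.DataFrame,
    bins: BinIndex,
    phenotypes: dict[str, str],
) -> list[LineCall]:
    """Build LineCalls from a line x bin dosage-state matrix: absence =
    called copy number 0, merged into maximal intervals."""
    calls = []
    for line in states.index:
        st = states.loc[line].to_numpy()
        ivs: list[tuple[str, int, int]] = []
        for chrom, sl in bins.chrom_slices.items():
            zero = st[sl] == 0
            i = 0
            n = sl.stop - sl.start
            while i < n:
                if zero[i]:
                    j = i
                    while j < n and zero[j]:
                        j += 1
                    ivs.append(
                        (
                            chrom,
                            int(bins.start[sl.start + i]),
                            int(bins.end[sl.start + j - 1]),
                        )
                    )
                    i = j
                else:
                    i += 1
        calls.append(
            LineCall(
                line=line,
                absent_intervals=ivs,
                phenotype=phenotypes.get(line, UNKNOWN),
            )
        )
    return calls


def apply_compensation(
    calls: Sequence[LineCall],
    rule: CompensationRule,
    states: pd.DataFrame,
    bins: BinIndex,
) -> list[LineCall]:
    """Flag lines whose compensating homoeologue is at the required dose.

    A line is compensated when its called dosage is at least
    ``rule.required_copies`` over every bin of the compensating chromosome
    (the homoeolocus position is unknown a priori, so the whole chromosome
    must carry the dose).  Compensated lines are excluded from mapping
    constraints downstream.
    """
    sl = bins.chrom_slices.get(rule.chrom)
    if sl is None:
        raise ValueError(f"compensation chromosome {rule.chrom!r} has no bins")
    out = []
    for call in calls:
        comp = False
        if call.line in states.index:
            dosage = states.loc[call.line].to_numpy()[sl]
            comp = bool(len(dosage) and (dosage >= rule.required_copies).all())
        out.append(
            LineCall(
                line=call.line,
                absent_intervals=list(call.absent_intervals),
                phenotype=call.phenotype,
                compensated=comp,
            )
        )
    return out


def map_locus(
    calls: Sequence[LineCall], bins: BinIndex, layout: GenomeLayout
) -> MapResult:
    """Candidate locus interval(s) from absence calls and viability.

    Candidate bins are those absent in every constraining (non-compensated,
    known-phenotype) non-viable line and absent in no constraining viable
    line.  Maximal runs of candidate bins become :class:`CandidateInterval`s
    with FL bounds.  An empty result carries diagnostics instead of raising.
    """
    result_warnings: list[str] = []
    excluded: dict[str, str] = {}
    nonviable, viable = [], []
    for call in calls:
        if call.phenotype == UNKNOWN:
            excluded[call.line] = "phenotype unknown"
            logger.info("line %s ignored: phenotype unknown", call.line)
            continue
        if call.compensated:
            excluded[call.line] = (
                "compensated: viability explained by homoeologous dosage"
            )
            continue
        (nonviable if call.phenotype == NON_VIABLE else viable).append(call)

    if not nonviable:
        msg = "no constraining non-viable lines: candidate set is undefined"
        result_warnings.append(msg)
        warnings.warn(msg)
        return MapResult(
            intervals=[],
            candidate_bins=np.zeros(len(bins), dtype=bool),
            warnings=result_warnings,
            excluded_lines=excluded,
        )

    cand = np.ones(len(bins), dtype=bool)
    for call in nonviable:
        cand &= absent_mask(call, bins)
    for call in viable:
        cand &= ~absent_mask(call, bins)

    intervals: list[CandidateInterval] = []
    for chrom, sl in bins.chrom_slices.items():
        c = cand[sl]
        i = 0
        n = sl.stop - sl.start
        while i < n:
            if c[i]:
                j = i
                while j < n and c[j]:
                    j += 1
                start = int(bins.start[sl.start + i])
                end = int(bins.end[sl.start + j - 1])
                iv = CandidateInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    fl_start=fl_of(layout, chrom, start),
                    fl_end=fl_of(layout, chrom, end),
                    supporting_lines=[cl.line for cl in nonviable],
                    excluded_lines=dict(excluded),
                )
                intervals.append(iv)
                i = j
            else:
                i += 1
    if not intervals:
        result_warnings.append(
            "no bin satisfies all constraints: phenotype/call conflict or "
            "locus outside the binned region"
        )
    return MapResult(
        intervals=intervals,
        candidate_bins=cand,
        warnings=result_warnings,
        excluded_lines=excluded,
    )


@dataclass
class Conflict:
    line: str
    phenotype: str
    reason: str


def detect_conflicts(
    calls: Sequence[LineCall], candidate: CandidateInterval, bins: BinIndex
) -> list[Conflict]:
    """Lines inconsistent with a candidate interval under the no-compensation
    model: viable lines lacking the whole candidate, and non-viable lines
    retaining all of it."""
    sl = bins.chrom_slices[candidate.chrom]
    in_cand = np.zeros(len(bins), dtype=bool)
    mids = bins.mid[sl]
    in_cand[sl] = (mids >= candidate.start) & (mids < candidate.end)
    out = []
    for call in calls:
        if call.phenotype == UNKNOWN:
            continue
        absent = absent_mask(call, bins)
        if call.phenotype == VIABLE and (absent[in_cand]).all():
            out.append(
                Conflict(
                    call.line,
                    call.phenotype,
                    "viable although the whole candidate interval is absent",
                )
            )
        elif call.phenotype == NON_VIABLE and not absent[in_cand].any():
            out.append(
                Conflict(
                    call.line,
                    call.phenotype,
                    "non-viable although the candidate interval is fully present",
                )
            )
    return out


def genes_in_interval(
    gff3_path,
    interval: CandidateInterval,
    feature_type: str = "gene",
    confidence_attr: str | None = None,
    confidence_value: str | None = None,
) -> tuple[list[str], int, int]:
    """Genes overlapping a candidate interval (any-overlap rule).

    GFF3 is 1-based inclusive and is converted to the 0-based half-open
    convention internally.  Malformed records are warned about and skipped;
    the skipped count is returned.  Returns (gene ids, count, n_skipped).
    """
    from gffutils.feature import feature_from_line

    genes: list[str] = []
    skipped = 0
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                start0, end0 = feat.start - 1, feat.end  # to half-open
                if start0 < 0 or end0 <= start0:
                    raise ValueError("invalid coordinates")
            except Exception as exc:  # malformed record: warn + skip
                warnings.warn(f"skipping malformed GFF3 record at line {lineno}: {exc}")
                skipped += 1
                continue
            if feat.featuretype != feature_type:
                continue
            if feat.seqid != interval.chrom:
                continue
            if not (start0 < interval.end and end0 > interval.start):
                continue
            if confidence_attr is not None:
                vals = feat.attributes.get(confidence_attr, [])
                if confidence_value is not None and confidence_value not in vals:
                    continue
                if confidence_value is None and not vals:
                    continue
            ids = feat.attributes.get("ID", [])
            genes.append(ids[0] if ids else f"{feat.seqid}:{feat.start}-{feat.end}")
    if skipped:
        logger.warning("skipped %d malformed GFF3 records", skipped)
    return genes, len(genes), skipped
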