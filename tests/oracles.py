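"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def oracle_candidate_bins(calls, bins) -> np.ndarray:
    """Exhaustive per-bin consistency test, coded independently of
    map_locus: a bin qualifies iff it is absent in every constraining
    non-viable line and in no constraining viable line."""
    ok = np.zeros(len(bins), dtype=bool)
    constraining = [
        c for c in calls if c.phenotype != "unknown" and not c.compensated
    ]
    nonviable = [c for c in constraining if c.phenotype == "non_viable"]
    if not nonviable:
        return ok
    for b in bins.bins:
        mid = (b.start + b.end) / 2

        def absent_in(call):
            return any(
                ch == b.chrom and s <= mid < e for ch, s, e in call.absent_intervals
            )

        ok[b.index] = all(absent_in(c) for c in nonviable) and not any(
            absent_in(c) for c in constraining if c.phenotype == "viable"
        )
    return ok


def direct_two_step(counts: np.ndarray, ref_row: int, pseudocount: float) -> np.ndarray:
    """Independent, literal evaluation of the two normalization steps:
    (1) divide pseudocounted counts by the genotype total, (2) per-bin log2
    ratio to the reference sample."""
    out = np.empty(counts.shape)
    ps = counts + pseudocount
    props = np.array([row / row.sum() for row in ps])
    for i in range(counts.shape[0]):
        for b in range(counts.shape[1]):
            out[i, b] = np.log2(props[i, b] / props[ref_row, b])
    return out
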