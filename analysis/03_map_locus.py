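"""Localize the viability locus by deletion-bin mapping.

Two complementary runs:

1. The published panel encoded directly from its breakpoint/viability table:
   first without line 1DL-2 (the initial panel), then with it.  The proximal
   bound of the 1DL candidate moves from FL 0.29 to FL 0.41 — the locus lies
   distal to the largest non-viable breakpoint, with N1D/T1B excluded by the
   1B-tetrasomy compensation rule.

2. End-to-end on the simulated panel: karyotype events called from noisy
   counts feed the same mapper, recovering an interval containing the
   planted locus.
"""

import json
from pathlib import Path

from delmap import io as dio
from delmap.events import copy_number_track
from delmap.karyotype import BinCountPanel, call_karyotypes
from delmap.mapping import apply_compensation, calls_from_dosage, detect_conflicts, map_locus
from delmap.panels import DEFAULT_COMPENSATION, default_config, published_mapping_inputs
from delmap.simulate import simulate_counts

import pandas as pd

SEED = 20150413

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def published_panel() -> dict:
    report = {}
    for label, include in (("initial_panel", False), ("with_1DL-2", True)):
        layout, bins, calls = published_mapping_inputs(include_1dl2=include)
        res = map_locus(calls, bins, layout)
        (iv,) = res.intervals
        report[label] = iv.to_dict()
        print(
            f"{label}: candidate {iv.chrom}:{iv.start:,}-{iv.end:,} "
            f"({iv.fl_start.arm} arm, FL {iv.fl_start.fl:.2f}-{iv.fl_end.fl:.2f}); "
            f"excluded: {sorted(res.excluded_lines)}"
        )
        conflicts = detect_conflicts(
            [c for c in calls if not c.compensated], iv, bins
        )
        assert not conflicts, conflicts
    return report


def simulated_panel() -> dict:
    config = default_config(seed=SEED)
    sim = simulate_counts(config)
    panel = BinCountPanel(bins=sim.bins, counts=sim.counts)
    called = call_karyotypes(panel, config.layout, "CS")
    tracks = {
        line: copy_number_track(
            config.layout, sim.bins, [ev.event for ev in evs if ev.event is not None]
        )
        for line, evs in called.events.items()
    }
    dosage = pd.DataFrame.from_dict(tracks, orient="index")
    calls = calls_from_dosage(dosage, sim.bins, sim.truth_phenotype)
    calls = apply_compensation(calls, DEFAULT_COMPENSATION, dosage, sim.bins)
    res = map_locus(calls, sim.bins, config.layout)
    (iv,) = [i for i in res.intervals if i.chrom == "1D"]
    locus_bin = sim.locus_bin
    contained = bool(res.candidate_bins[locus_bin])
    print(
        f"simulated panel: candidate {iv.chrom}:{iv.start:,}-{iv.end:,} "
        f"(FL {iv.fl_start.fl:.2f}-{iv.fl_end.fl:.2f}); "
        f"planted locus bin contained: {contained}"
    )
    dio.write_bed(
        [(iv.chrom, iv.start, iv.end, "candidate")], RESULTS / "candidate_simulated.bed"
    )
    out = iv.to_dict()
    out["planted_locus_contained"] = contained
    return out


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    report = {"published_panel": published_panel(), "simulated_panel": simulated_panel()}
    (RESULTS / "mapping_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    print(f"report -> {RESULTS / 'mapping_report.json'}")


if __name__ == "__main__":
    main()
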