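"""Call per-line dosage and karyotype events from the simulated panel.

Runs the two-step normalization against the euploid reference, median
smoothing, dosage-state calling and segmentation, then classifies each
chromosome's pattern into karyotype events.  The deletion breakpoints come
back as fraction-length (FL) coordinates directly comparable to the
published deletion-stock nomenclature, and the addition line is recovered
from its short-arm coverage excess alone — the same signal that led to the
GBS re-classification of stock 1DL-8 as a 1DS addition line.
"""

import json
from pathlib import Path

from delmap.karyotype import BinCountPanel, call_karyotypes
from delmap.panels import DELETION_BREAKPOINTS, default_config
from delmap.simulate import simulate_counts

SEED = 20150413  # same panel as 01_simulate_panel.py

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    config = default_config(seed=SEED)
    sim = simulate_counts(config)
    panel = BinCountPanel(bins=sim.bins, counts=sim.counts)
    result = call_karyotypes(panel, config.layout, "CS")

    events = {
        line: [ev.to_dict() for ev in evs] for line, evs in result.events.items()
    }
    (RESULTS / "karyotype_events.json").write_text(
        json.dumps(events, indent=2, sort_keys=True) + "\n"
    )

    print("called events on the group-1 chromosomes:")
    n_breakpoints_exact = 0
    n_spurious = 0
    for line, evs in result.events.items():
        shown = []
        for ev in evs:
            if ev.kind == "unclassified":
                n_spurious += 1
                continue
            desc = f"{ev.kind}({ev.chrom}"
            if ev.event.arm:
                desc += ev.event.arm
            if ev.event.fl_retained is not None:
                desc += f", FL {ev.event.fl_retained:.2f}"
                true_fl = DELETION_BREAKPOINTS.get(line, (None, None))[1]
                if true_fl is not None and abs(ev.event.fl_retained - true_fl) < 1e-9:
                    n_breakpoints_exact += 1
            shown.append(desc + ")")
        print(f"  {line:11s} {', '.join(shown) if shown else '(euploid)'}")
    print(
        f"{n_breakpoints_exact}/{len(DELETION_BREAKPOINTS)} deletion breakpoints "
        f"recovered at the exact FL; {n_spurious} unclassified depth artifact(s) "
        "elsewhere in the genome (reported, not dropped)"
    )
    print(f"events -> {RESULTS / 'karyotype_events.json'}")


if __name__ == "__main__":
    main()
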