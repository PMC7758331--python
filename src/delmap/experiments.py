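"""Reusable simulation experiments quantifying pipeline accuracy.

Each experiment regenerates its own synthetic panels from a master seed and
measures the pipeline against the simulation truth: terminal-deletion
breakpoint recovery under count noise, karyotype classification in the
noise-free limit, and planted-locus recovery of the deletion-bin mapper over
random panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import KaryotypeEvent, copy_number_track
from .genome import (
    ArmCoordinate,
    BinIndex,
    Chromosome,
    GenomeLayout,
    build_bins,
    position_of,
)
from .karyotype import BinCountPanel, call_karyotypes
from .mapping import apply_compensation, calls_from_dosage, map_locus
from .panels import BIN_WIDTH
from .simulate import CompensationRule, SimulationConfig, simulate_counts, simulate_viability


def _six_chrom_layout() -> GenomeLayout:
    """Six 500 Mb chromosomes: enough euploid background that a single
    deletion shifts a line's library-size normalization by only a few
    percent, as in a full aneuploid genome."""
    cens = {"A": 200_000_000, "B": 150_000_000, "D": 100_000_000}
    return GenomeLayout(
        tuple(
            Chromosome(f"{g}{s}", 500_000_000, cens[s])
            for g in (1, 2)
            for s in ("A", "B", "D")
        )
    )


@dataclass
class BreakpointRecovery:
    n_lines: int
    n_classified: int
    n_within_one_bin: int

    @property
    def recovery_rate(self) -> float:
        return self.n_within_one_bin / self.n_lines


def breakpoint_recovery_experiment(
    n_lines: int = 200,
    seed: int = 0,
    mean_depth: float = 50.0,
    capture_weight_dispersion: float = 0.5,
    count_noise: str = "poisson",
) -> BreakpointRecovery:
    """Recovery of terminal-deletion breakpoints from noisy counts.

    Each replicate simulates an independent two-line panel (euploid reference
    plus one deletion stock with a random arm and breakpoint FL) at 1 Mb
    bins, runs the full calling pipeline, and scores whether the called
    breakpoint bin lies within one bin of the simulated truth.
    """
    master = np.random.default_rng(seed)
    layout = _six_chrom_layout()
    chrom = "1D"
    n_classified = 0
    n_ok = 0
    for i in range(n_lines):
        arm = "S" if master.random() < 0.5 else "L"
        fl_retained = float(master.uniform(0.15, 0.85))
        events = [
            KaryotypeEvent("terminal_deletion", chrom, arm=arm, fl_retained=fl_retained)
        ]
        config = SimulationConfig(
            layout=layout,
            bin_width=BIN_WIDTH,
            panel=[("REF", []), ("DEL", events)],
            reference_line="REF",
            locus=ArmCoordinate(chrom, "L", 0.9),
            mean_depth=mean_depth,
            capture_weight_dispersion=capture_weight_dispersion,
            count_noise=count_noise,
            seed=int(master.integers(2**31)),
        )
        sim = simulate_counts(config)
        panel = BinCountPanel(bins=sim.bins, counts=sim.counts)
        result = call_karyotypes(panel, layout, "REF")
        truth_cn = sim.truth_copy_number.loc["DEL"].to_numpy()
        sl = sim.bins.chrom_slices[chrom]
        truth_first_deleted = int(np.flatnonzero(truth_cn[sl] == 0)[0]) + sl.start
        for ev in result.events["DEL"]:
            if ev.kind == "terminal_deletion" and ev.chrom == chrom and ev.event.arm == arm:
                n_classified += 1
                called_bin = sim.bins.bin_at(chrom, ev.breakpoint_interval[0])
                if arm == "S":
                    # proximal->distal runs against the coordinate axis: the
                    # first deleted bin is the distal-most, highest-index one
                    zero = np.flatnonzero(truth_cn[sl] == 0)
                    truth_first_deleted = int(zero[-1]) + sl.start
                    called_bin = sim.bins.bin_at(chrom, ev.breakpoint_interval[1] - 1)
                if abs(called_bin - truth_first_deleted) <= 1:
                    n_ok += 1
                break
    return BreakpointRecovery(n_lines, n_classified, n_ok)


def zero_noise_classification_experiment(seed: int = 0) -> dict[str, bool]:
    """Noise-free classification of all five event kinds.

    Simulates one panel containing every event kind with the degenerate
    count law and checks each line's called events against the truth.
    Returns per-line correctness.
    """
    layout = _six_chrom_layout()
    panel_events = [
        ("REF", []),
        ("NULLI", [KaryotypeEvent("nullisomy", "1D")]),
        ("TETRA", [KaryotypeEvent("tetrasomy", "1B")]),
        ("TELO", [KaryotypeEvent("telosomic", "1D", arm="S")]),
        ("DEL", [KaryotypeEvent("terminal_deletion", "1D", arm="L", fl_retained=0.41)]),
        ("ADD", [KaryotypeEvent("arm_addition", "1D", arm="S")]),
        (
            "COMPOSITE",
            [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1A")],
        ),
    ]
    config = SimulationConfig(
        layout=layout,
        bin_width=BIN_WIDTH,
        panel=panel_events,
        reference_line="REF",
        locus=ArmCoordinate("1D", "L", 0.9),
        count_noise="none",
        capture_weight_dispersion=0.5,
        seed=seed,
    )
    sim = simulate_counts(config)
    panel = BinCountPanel(bins=sim.bins, counts=sim.counts)
    result = call_karyotypes(panel, layout, "REF")

    def called(line):
        return sorted(
            (ev.chrom, ev.kind, ev.event.arm if ev.event else None)
            for ev in result.events[line]
        )

    expected = {
        "REF": [],
        "NULLI": [("1D", "nullisomy", None)],
        "TETRA": [("1B", "tetrasomy", None)],
        "TELO": [("1D", "telosomic", "S")],
        "DEL": [("1D", "terminal_deletion", "L")],
        "ADD": [("1D", "arm_addition", "S")],
        "COMPOSITE": [("1A", "tetrasomy", None), ("1D", "nullisomy", None)],
    }
    out = {}
    for line, exp in expected.items():
        ok = called(line) == sorted(exp)
        if line == "DEL" and ok:
            ev = next(e for e in result.events["DEL"] if e.kind == "terminal_deletion")
            ok = abs(ev.event.fl_retained - 0.41) < 1e-9
        out[line] = ok
    return out


@dataclass
class RandomPanel:
    """One random deletion panel with truth, ready for mapping."""

    layout: GenomeLayout
    bins: BinIndex
    dosage: pd.DataFrame
    phenotypes: dict[str, str]
    locus_bin: int
    compensation: CompensationRule


def random_panel(rng: np.random.Generator, n_lines: int = 8) -> RandomPanel:
    """Random panel of deletion/telosomic/nullisomic-tetrasomic stocks on a
    small two-chromosome layout, with the phenotype generated by the
    viability rule from a random planted locus."""
    layout = GenomeLayout(
        (
            Chromosome("T", 60_000_000, 20_000_000),
            Chromosome("H", 60_000_000, 20_000_000),  # compensating homoeologue
        )
    )
    bins = BinIndex(build_bins(layout, 1_000_000))
    locus_arm = "L" if rng.random() < 0.7 else "S"
    locus = ArmCoordinate("T", locus_arm, float(rng.uniform(0.1, 0.95)))
    compensation = CompensationRule("H", required_copies=4)

    lines: list[tuple[str, list[KaryotypeEvent]]] = [("REF", [])]
    for i in range(n_lines):
        kind = rng.choice(
            ["terminal_deletion", "telosomic", "nulli_tetra", "none"],
            p=[0.6, 0.15, 0.15, 0.1],
        )
        evs: list[KaryotypeEvent] = []
        if kind == "terminal_deletion":
            evs = [
                KaryotypeEvent(
                    "terminal_deletion",
                    "T",
                    arm="S" if rng.random() < 0.4 else "L",
                    fl_retained=float(rng.uniform(0.0, 0.95)),
                )
            ]
        elif kind == "telosomic":
            evs = [KaryotypeEvent("telosomic", "T", arm="S" if rng.random() < 0.5 else "L")]
        elif kind == "nulli_tetra":
            evs = [KaryotypeEvent("nullisomy", "T")]
            if rng.random() < 0.5:
                evs.append(KaryotypeEvent("tetrasomy", "H"))
        lines.append((f"L{i}", evs))

    dosage = pd.DataFrame.from_dict(
        {name: copy_number_track(layout, bins, evs) for name, evs in lines},
        orient="index",
    )
    phenotypes = simulate_viability(dosage, layout, bins, locus, compensation)
    pos = min(position_of(layout, locus), layout["T"].length - 1)
    return RandomPanel(
        layout=layout,
        bins=bins,
        dosage=dosage,
        phenotypes=phenotypes,
        locus_bin=bins.bin_at("T", pos),
        compensation=compensation,
    )


@dataclass
class MapperSoundness:
    n_panels: int
    n_informative: int
    n_locus_contained: int

    @property
    def containment_rate(self) -> float:
        return self.n_locus_contained / max(1, self.n_informative)


def mapper_soundness_experiment(n_panels: int = 500, seed: int = 0) -> MapperSoundness:
    """Planted-locus recovery over random panels.

    A panel is informative when it retains at least one constraining
    (non-compensated) non-viable line; for those the candidate set must
    contain the planted locus bin.
    """
    rng = np.random.default_rng(seed)
    n_informative = 0
    n_contained = 0
    for _ in range(n_panels):
        panel = random_panel(rng)
        calls = calls_from_dosage(panel.dosage, panel.bins, panel.phenotypes)
        calls = apply_compensation(calls, panel.compensation, panel.dosage, panel.bins)
        informative = any(
            c.phenotype == "non_viable" and not c.compensated for c in calls
        )
        if not informative:
            continue
        n_informative += 1
        result = map_locus(calls, panel.bins, panel.layout)
        if result.candidate_bins[panel.locus_bin]:
            n_contained += 1
    return MapperSoundness(n_panels, n_informative, n_contained)
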