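"""Bundled study conditions: the Chinese Spring group-1 aneuploid panel.

The panel comprises the euploid Chinese Spring (CS) reference, the
nullisomic-tetrasomic lines N1D/T1A and N1D/T1B, the ditelosomics Dt1DS and
Dt1DL, five 1DS and five 1DL terminal-deletion stocks with their published
fraction-length (FL) breakpoints, and the 1DS arm-addition line CSDt1DSAL
(originally distributed as deletion line 1DL-8 and re-classified by
GBS/FISH as carrying two extra 1D short arms).  Hybrid-seed viability in
crosses with rye is non-viable exactly for the stocks missing the distal
1DL region (N1D/T1A, Dt1DS, 1DL-4/-1/-3/-6 and later 1DL-2), while
N1D/T1B is viable because tetrasomy of homoeologous chromosome 1B
compensates for the missing 1D dose.

The genome layout here is SYNTHETIC: the published analysis used the
Chinese Spring reference assembly, whose centromere coordinates are not part
of this package's inputs, so chromosome sizes are round numbers chosen so
that every published FL breakpoint falls exactly on a 1 Mb bin boundary
(1D: 500 Mb with the centromere at 100 Mb gives a 400 Mb long arm, on which
e.g. FL 0.29 is the bin edge at 216 Mb).  Mapping results are therefore
exact in FL units, while bp coordinates are illustrative only.
"""

from __future__ import annotations

from .events import KaryotypeEvent
from .genome import ArmCoordinate, Chromosome, GenomeLayout
from .simulate import CompensationRule, SimulationConfig, TraitSpec

BIN_WIDTH = 1_000_000

#: FL breakpoints of the deletion stocks (fraction of the arm retained).
DELETION_BREAKPOINTS = {
    "1DS-5": ("S", 0.70),
    "1DS-4": ("S", 0.66),
    "1DS-1": ("S", 0.59),
    "1DS-2": ("S", 0.57),
    "1DS-3": ("S", 0.48),
    "1DL-4": ("L", 0.18),
    "1DL-1": ("L", 0.23),
    "1DL-3": ("L", 0.25),
    "1DL-6": ("L", 0.29),
    "1DL-2": ("L", 0.41),
}

#: Published hybrid-seed viability in crosses with rye.
VIABILITY = {
    "CS": "viable",
    "N1D/T1A": "non_viable",
    "N1D/T1B": "viable",
    "Dt1DS": "non_viable",
    "Dt1DL": "viable",
    "1DS-5": "viable",
    "1DS-4": "viable",
    "1DS-1": "viable",
    "1DS-2": "viable",
    "1DS-3": "viable",
    "1DL-4": "non_viable",
    "1DL-1": "non_viable",
    "1DL-3": "non_viable",
    "1DL-6": "non_viable",
    "1DL-2": "non_viable",
    "CSDt1DSAL": "viable",
}


def group1_layout() -> GenomeLayout:
    """Synthetic group-1 layout (1A, 1B, 1D) with round-number arms."""
    return GenomeLayout(
        (
            Chromosome("1A", 500_000_000, 200_000_000),
            Chromosome("1B", 500_000_000, 150_000_000),
            Chromosome("1D", 500_000_000, 100_000_000),
        )
    )


def wheat_layout() -> GenomeLayout:
    """Synthetic 21-chromosome hexaploid layout (groups 1-7 x A/B/D).

    Ratio-to-total normalization tolerates aneuploidy only while the affected
    fraction of the genome is small, as in real hexaploid wheat; simulations
    therefore use the full complement, with the group-1 chromosomes identical
    to :func:`group1_layout`.
    """
    cens = {"A": 200_000_000, "B": 150_000_000, "D": 100_000_000}
    chroms = []
    for group in range(1, 8):
        for sub in ("A", "B", "D"):
            chroms.append(Chromosome(f"{group}{sub}", 500_000_000, cens[sub]))
    return GenomeLayout(tuple(chroms))


def panel_events(include_1dl2: bool = True) -> list[tuple[str, list[KaryotypeEvent]]]:
    """Karyotype events of every panel line, in publication order."""

    def tdel(name: str) -> list[KaryotypeEvent]:
        arm, fl = DELETION_BREAKPOINTS[name]
        return [KaryotypeEvent("terminal_deletion", "1D", arm=arm, fl_retained=fl)]

    panel: list[tuple[str, list[KaryotypeEvent]]] = [
        ("CS", []),
        (
            "N1D/T1A",
            [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1A")],
        ),
        (
            "N1D/T1B",
            [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1B")],
        ),
        ("Dt1DS", [KaryotypeEvent("telosomic", "1D", arm="S")]),
        ("1DS-5", tdel("1DS-5")),
        ("1DS-4", tdel("1DS-4")),
        ("1DS-1", tdel("1DS-1")),
        ("1DS-2", tdel("1DS-2")),
        ("1DS-3", tdel("1DS-3")),
        ("Dt1DL", [KaryotypeEvent("telosomic", "1D", arm="L")]),
        ("1DL-4", tdel("1DL-4")),
        ("1DL-1", tdel("1DL-1")),
        ("1DL-3", tdel("1DL-3")),
        ("1DL-6", tdel("1DL-6")),
        ("CSDt1DSAL", [KaryotypeEvent("arm_addition", "1D", arm="S")]),
    ]
    if include_1dl2:
        panel.insert(-1, ("1DL-2", tdel("1DL-2")))
    return panel


#: Causal locus planted distally on 1DL (FL 0.75, well below every published
#: non-viable breakpoint), compensated by tetrasomic 1B.
DEFAULT_LOCUS = ArmCoordinate("1D", "L", 0.75)
DEFAULT_COMPENSATION = CompensationRule("1B", required_copies=4)


def default_trait_model() -> dict[str, TraitSpec]:
    """Five main-spike traits with euploid baselines and locus-absence
    effects matching the published contrasts in sign and rough size:
    locus-absent lines have longer spikes, far fewer grains, lower
    thousand-grain weight and lower seed set."""
    return {
        "spike_length_cm": TraitSpec(baseline=8.2, sd=0.5, effect=2.8),
        "spikelet_number": TraitSpec(baseline=21.4, sd=1.0, effect=0.4),
        "grain_number": TraitSpec(baseline=63.8, sd=5.0, effect=-43.6),
        "tgw_g": TraitSpec(baseline=35.3, sd=2.0, effect=-13.0),
        "seed_set_pct": TraitSpec(baseline=87.3, sd=5.0, effect=-41.8),
    }


def published_mapping_inputs(include_1dl2: bool = False):
    """Encode the published panel directly as mapping inputs.

    Expands each line's karyotype events to a per-bin dosage track on the
    synthetic layout, derives absence calls and compensation flags from the
    dosage, and attaches the published viability phenotypes.  Returns
    ``(layout, bins, calls)`` ready for :func:`delmap.mapping.map_locus`.
    """
    import pandas as pd

    from .events import copy_number_track
    from .genome import BinIndex, build_bins
    from .mapping import apply_compensation, calls_from_dosage

    layout = group1_layout()
    bins = BinIndex(build_bins(layout, BIN_WIDTH))
    events = panel_events(include_1dl2=include_1dl2)
    dosage = pd.DataFrame.from_dict(
        {name: copy_number_track(layout, bins, evs) for name, evs in events},
        orient="index",
    )
    calls = calls_from_dosage(dosage, bins, VIABILITY)
    calls = apply_compensation(calls, DEFAULT_COMPENSATION, dosage, bins)
    return layout, bins, calls


def default_config(
    seed: int = 0, include_1dl2: bool = True, **overrides
) -> SimulationConfig:
    """Simulation config reproducing the bundled panel's study conditions."""
    kwargs = dict(
        layout=wheat_layout(),
        bin_width=BIN_WIDTH,
        panel=panel_events(include_1dl2=include_1dl2),
        reference_line="CS",
        locus=DEFAULT_LOCUS,
        compensation=DEFAULT_COMPENSATION,
        mean_depth=50.0,
        capture_weight_dispersion=0.5,
        count_noise="poisson",
        trait_model=default_trait_model(),
        n_trait_replicates=5,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
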