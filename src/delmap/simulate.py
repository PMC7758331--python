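"""Synthetic GBS bin-count panels with known karyotype truth.

Emulates the depth structure of genotyping-by-sequencing over a panel of
aneuploid stocks: a per-bin capture efficiency shared by all lines (GBS
restriction-site density varies along the genome but is reproducible between
libraries), per-line library-size factors, and Poisson or negative-binomial
count noise on top of the copy-number-scaled expectation

    E[count_{i,b}] = s_i * d * w_b * cn_{i,b} / 2

with s_i the library factor, d the panel mean depth per bin at two copies,
w_b the capture weight (log-normal, mean 1) and cn the per-bin copy number
from the line's karyotype events.  A planted viability locus with a
homoeologous dosage-compensation rule and Gaussian per-line trait replicates
give every downstream stage a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import KaryotypeEvent, copy_number_track
from .genome import ArmCoordinate, BinIndex, GenomeLayout, build_bins, position_of

VIABLE = "viable"
NON_VIABLE = "non_viable"


@dataclass(frozen=True)
class CompensationRule:
    """Homoeologous dosage compensation: a line missing the causal locus is
    still viable when the compensating chromosome is present at
    ``required_copies`` (tetrasomic dose by default) at the homoeologous
    position."""

    chrom: str
    required_copies: int = 4


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait generative model: line mean = baseline + effect * x, where
    x = 1 for locus-absent uncompensated lines, ``compensation_fraction`` for
    locus-absent compensated lines, and 0 otherwise."""

    baseline: float
    sd: float
    effect: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"trait sd must be >= 0, got {self.sd}")


@dataclass
class SimulationConfig:
    layout: GenomeLayout
    bin_width: int
    panel: list[tuple[str, list[KaryotypeEvent]]]
    reference_line: str
    locus: ArmCoordinate
    compensation: CompensationRule | None = None
    mean_depth: float = 50.0
    library_size_factors: Mapping[str, float] | None = None
    capture_weight_dispersion: float = 0.5
    count_noise: str = "poisson"  # "poisson" | "negative_binomial" | "none"
    nb_dispersion: float = 5.0
    trait_model: Mapping[str, TraitSpec] | None = None
    n_trait_replicates: int = 5
    compensation_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        names = [name for name, _ in self.panel]
        if len(set(names)) != len(names):
            raise ValueError("panel line names must be unique")
        if self.reference_line not in names:
            raise ValueError(
                f"reference line {self.reference_line!r} must be part of the panel"
            )
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.capture_weight_dispersion < 0:
            raise ValueError("capture_weight_dispersion must be >= 0")
        if self.count_noise not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        if self.library_size_factors is not None:
            bad = {k: v for k, v in self.library_size_factors.items() if v <= 0}
            if bad:
                raise ValueError(f"library size factors must be positive: {bad}")
        if self.locus.chrom not in self.layout:
            raise ValueError(f"locus chromosome {self.locus.chrom!r} not in layout")


@dataclass
class SimulatedPanel:
    """Counts plus full ground truth for one simulated panel."""

    bins: BinIndex
    counts: pd.DataFrame  # lines x bins
    truth_copy_number: pd.DataFrame  # lines x bins, int
    truth_phenotype: dict[str, str]
    truth_traits: pd.DataFrame | None  # long: line, replicate, trait, value
    capture_weights: np.ndarray
    locus_bin: int


def _locus_bin(layout: GenomeLayout, bins: BinIndex, locus: ArmCoordinate) -> int:
    pos = position_of(layout, locus)
    c = layout[locus.chrom]
    pos = min(pos, c.length - 1)  # FL 1.0 maps to the telomere boundary
    return bins.bin_at(locus.chrom, pos)


def _homoeolocus_bin(
    layout: GenomeLayout, bins: BinIndex, locus: ArmCoordinate, rule: CompensationRule
) -> int:
    """Bin of the compensating homoeolocus: same arm and FL on the
    compensating chromosome."""
    coord = ArmCoordinate(rule.chrom, locus.arm, locus.fl)
    pos = min(position_of(layout, coord), layout[rule.chrom].length - 1)
    return bins.bin_at(rule.chrom, pos)


def simulate_viability(
    truth_cn: pd.DataFrame,
    layout: GenomeLayout,
    bins: BinIndex,
    locus: ArmCoordinate,
    compensation: CompensationRule | None = None,
) -> dict[str, str]:
    """Deterministic viability phenotype from truth copy numbers.

    A line is viable iff it retains at least one dose at the locus bin, or the
    compensating homoeolocus carries at least ``required_copies`` doses.
    """
    lb = _locus_bin(layout, bins, locus)
    comp_bin = (
        _homoeolocus_bin(layout, bins, locus, compensation) if compensation else None
    )
    pheno: dict[str, str] = {}
    for line in truth_cn.index:
        ok = truth_cn.iloc[:, lb][line] >= 1
        if not ok and comp_bin is not None:
            ok = truth_cn.iloc[:, comp_bin][line] >= compensation.required_copies
        pheno[line] = VIABLE if ok else NON_VIABLE
    return pheno


def simulate_traits(
    truth_cn: pd.DataFrame,
    layout: GenomeLayout,
    bins: BinIndex,
    locus: ArmCoordinate,
    trait_model: Mapping[str, TraitSpec],
    n_replicates: int,
    rng: np.random.Generator,
    compensation: CompensationRule | None = None,
    compensation_fraction: float = 0.5,
) -> pd.DataFrame:
    """Gaussian trait replicates per line under the planted-locus model.

    Compensated locus-absent lines sit a configurable fraction of the effect
    away from baseline (partial compensation of quantitative traits).
    With sd = 0 replicates equal the line means exactly.
    """
    if n_replicates < 2:
        raise ValueError(f"n_replicates must be >= 2, got {n_replicates}")
    lb = _locus_bin(layout, bins, locus)
    comp_bin = (
        _homoeolocus_bin(layout, bins, locus, compensation) if compensation else None
    )
    rows = []
    for line in truth_cn.index:
        absent = truth_cn.iloc[:, lb][line] == 0
        compensated = (
            comp_bin is not None
            and truth_cn.iloc[:, comp_bin][line] >= compensation.required_copies
        )
        if absent and not compensated:
            x = 1.0
        elif absent and compensated:
            x = compensation_fraction
        else:
            x = 0.0
        for trait, spec in trait_model.items():
            mean = spec.baseline + spec.effect * x
            vals = mean + spec.sd * rng.standard_normal(n_replicates)
            for rep, v in enumerate(vals, start=1):
                rows.append((line, rep, trait, float(v)))
    return pd.DataFrame(rows, columns=["line", "replicate", "trait", "value"])


def simulate_counts(config: SimulationConfig) -> SimulatedPanel:
    """Draw one panel of bin counts plus ground truth, reproducibly.

    Capture weights are drawn once and shared by every line; all randomness
    derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    bins = BinIndex(build_bins(config.layout, config.bin_width))
    nbins = len(bins)

    sigma = config.capture_weight_dispersion
    if sigma > 0:
        # log-normal with E[w] = 1
        w = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=nbins)
    else:
        w = np.ones(nbins)

    names = [name for name, _ in config.panel]
    factors = {
        name: (config.library_size_factors or {}).get(name, 1.0) for name in names
    }

    cn_rows = {}
    for name, evs in config.panel:
        cn_rows[name] = copy_number_track(config.layout, bins, evs)
    truth_cn = pd.DataFrame.from_dict(cn_rows, orient="index")
    truth_cn = truth_cn.loc[names]

    mu = (
        np.array([factors[n] for n in names])[:, None]
        * config.mean_depth
        * w[None, :]
        * truth_cn.to_numpy()
        / 2.0
    )
    if config.count_noise == "poisson":
        counts = rng.poisson(mu).astype(np.int64)
    elif config.count_noise == "negative_binomial":
        k = config.nb_dispersion
        if k <= 0:
            raise ValueError(f"nb_dispersion must be positive, got {k}")
        p = k / (k + mu)
        counts = rng.negative_binomial(k, p).astype(np.int64)
    else:  # "none": deterministic expectation (may be fractional)
        counts = mu
    counts_df = pd.DataFrame(counts, index=names)

    pheno = simulate_viability(
        truth_cn, config.layout, bins, config.locus, config.compensation
    )
    traits = None
    if config.trait_model is not None:
        traits = simulate_traits(
            truth_cn,
            config.layout,
            bins,
            config.locus,
            config.trait_model,
            config.n_trait_replicates,
            rng,
            config.compensation,
            config.compensation_fraction,
        )
    return SimulatedPanel(
        bins=bins,
        counts=counts_df,
        truth_copy_number=truth_cn,
        truth_phenotype=pheno,
        truth_traits=traits,
        capture_weights=w,
        locus_bin=_locus_bin(config.layout, bins, config.locus),
    )
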