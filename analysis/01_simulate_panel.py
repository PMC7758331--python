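"""Simulate the full 16-line aneuploid panel with known ground truth.

Generates GBS-like bin counts (1 Mb bins, mean 50 reads/bin at two copies,
shared log-normal capture weights, Poisson noise) for the euploid reference,
the nullisomic-tetrasomics, ditelosomics, ten terminal-deletion stocks and
the 1DS addition line, plus the planted 1DL viability locus, the
1B-tetrasomy compensation rule and five spike traits.

Small summary tables go to results/; the bulky count matrix goes to
scratch/ (regenerated deterministically from the seed whenever needed).
"""

from pathlib import Path

from delmap import io as dio
from delmap.karyotype import BinCountPanel
from delmap.panels import default_config
from delmap.simulate import simulate_counts

SEED = 20150413  # date-style seed of the simulated "field season"

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "panel"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    config = default_config(seed=SEED)
    sim = simulate_counts(config)

    dio.write_layout(config.layout, SCRATCH / "layout.yaml")
    dio.write_counts(BinCountPanel(bins=sim.bins, counts=sim.counts), SCRATCH / "counts.tsv")
    dio.write_phenotypes(sim.truth_phenotype, RESULTS / "phenotypes.tsv")
    sim.truth_traits.to_csv(RESULTS / "trait_observations.tsv", sep="\t", index=False)

    n_nonviable = sum(v == "non_viable" for v in sim.truth_phenotype.values())
    print(f"simulated {len(sim.counts)} lines x {len(sim.bins)} bins (seed {SEED})")
    print(f"phenotypes: {n_nonviable} non-viable / {len(sim.truth_phenotype)} lines")
    print(f"counts -> {SCRATCH / 'counts.tsv'}")
    print(f"phenotypes, trait observations -> {RESULTS}")


if __name__ == "__main__":
    main()
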