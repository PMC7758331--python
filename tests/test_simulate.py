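"""Synthetic panel generator: event expansion, count law, viability, traits."""

import numpy as np
import pandas as pd
import pytest

from delmap.events import ConflictError, KaryotypeEvent, copy_number_track
from delmap.genome import ArmCoordinate, BinIndex, Chromosome, GenomeLayout, build_bins, fl_of
from delmap.simulate import (
    CompensationRule,
    SimulationConfig,
    TraitSpec,
    simulate_counts,
    simulate_traits,
    simulate_viability,
)


@pytest.fixture
def layout3():
    return GenomeLayout(
        (
            Chromosome("1A", 200, 100),
            Chromosome("1B", 200, 100),
            Chromosome("1D", 200, 100),
        )
    )


@pytest.fixture
def bins3(layout3):
    return BinIndex(build_bins(layout3, 10))


class TestCopyNumberTrack:
    def test_no_events_is_disomic_everywhere(self, layout3, bins3):
        assert (copy_number_track(layout3, bins3, []) == 2).all()

    def test_nullisomic_tetrasomic_line(self, layout3, bins3):
        """N1D/T1A-style karyotype: all 1D bins 0, all 1A bins 4, others 2."""
        cn = copy_number_track(
            layout3,
            bins3,
            [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1A")],
        )
        assert (cn[bins3.chrom == "1D"] == 0).all()
        assert (cn[bins3.chrom == "1A"] == 4).all()
        assert (cn[bins3.chrom == "1B"] == 2).all()

    def test_telosomic_and_addition(self, layout3, bins3):
        telo = copy_number_track(
            layout3, bins3, [KaryotypeEvent("telosomic", "1D", arm="S")]
        )
        s_mask = bins3.arm_mask(layout3, "1D", "S")
        l_mask = bins3.arm_mask(layout3, "1D", "L")
        assert (telo[s_mask] == 2).all() and (telo[l_mask] == 0).all()
        add = copy_number_track(
            layout3, bins3, [KaryotypeEvent("arm_addition", "1D", arm="S")]
        )
        assert (add[s_mask] == 4).all() and (add[l_mask] == 2).all()

    def test_terminal_deletion_matches_per_position_oracle(self, layout3, bins3):
        """Bin membership decided by midpoint: independently evaluate the
        deletion rule at every bin midpoint."""
        fl_ret = 0.41
        cn = copy_number_track(
            layout3,
            bins3,
            [KaryotypeEvent("terminal_deletion", "1D", arm="L", fl_retained=fl_ret)],
        )
        for b in bins3.bins:
            if b.chrom != "1D":
                expected = 2
            else:
                coord = fl_of(layout3, "1D", b.midpoint)
                deleted = coord.arm == "L" and coord.fl > fl_ret
                expected = 0 if deleted else 2
            assert cn[b.index] == expected, b

    def test_conflicting_events_raise_naming_bin(self, layout3, bins3):
        with pytest.raises(ConflictError, match="1D"):
            copy_number_track(
                layout3,
                bins3,
                [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1D")],
            )

    def test_event_validation(self):
        with pytest.raises(ValueError):
            KaryotypeEvent("terminal_deletion", "1D", arm="L")  # missing fl
        with pytest.raises(ValueError):
            KaryotypeEvent("telosomic", "1D")  # missing arm
        with pytest.raises(ValueError):
            KaryotypeEvent("banana", "1D")


def _config(layout3, **kw):
    defaults = dict(
        layout=layout3,
        bin_width=10,
        panel=[
            ("REF", []),
            ("DEL", [KaryotypeEvent("terminal_deletion", "1D", arm="L", fl_retained=0.5)]),
        ],
        reference_line="REF",
        locus=ArmCoordinate("1D", "L", 0.9),
        mean_depth=40.0,
        capture_weight_dispersion=0.0,
        count_noise="none",
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateCounts:
    def test_noise_free_counts_equal_expectation(self, layout3):
        """With the degenerate law, unit factors and no weight dispersion the
        counts are exactly mean_depth * cn / 2."""
        sim = simulate_counts(_config(layout3))
        cn = sim.truth_copy_number.to_numpy()
        assert np.array_equal(sim.counts.to_numpy(), 40.0 * cn / 2.0)

    def test_library_size_factor_scales_expectation(self, layout3):
        sim = simulate_counts(
            _config(layout3, library_size_factors={"DEL": 3.0})
        )
        assert np.array_equal(
            sim.counts.loc["DEL"].to_numpy(),
            3.0 * sim.counts.loc["REF"].to_numpy()
            * sim.truth_copy_number.loc["DEL"].to_numpy() / 2,
        )

    def test_poisson_mean_matches_closed_form(self, layout3):
        """Monte-Carlo: across 200 replicate draws the per-bin empirical mean
        sits within 3 standard errors of the closed-form expectation."""
        reps = []
        for seed in range(200):
            sim = simulate_counts(
                _config(
                    layout3, count_noise="poisson", capture_weight_dispersion=0.0,
                    seed=seed,
                )
            )
            reps.append(sim.counts.loc["DEL"].to_numpy())
        reps = np.array(reps, dtype=float)
        mu = 40.0 * sim.truth_copy_number.loc["DEL"].to_numpy() / 2.0
        se = np.sqrt(np.maximum(mu, 1e-12) / 200)
        assert (np.abs(reps.mean(axis=0) - mu) <= 3 * se + 1e-9).all()

    def test_bit_identical_given_seed(self, layout3):
        cfg = _config(layout3, count_noise="poisson", capture_weight_dispersion=0.5)
        a = simulate_counts(cfg)
        b = simulate_counts(cfg)
        assert a.counts.equals(b.counts)
        assert a.truth_copy_number.equals(b.truth_copy_number)
        assert a.truth_phenotype == b.truth_phenotype
        assert np.array_equal(a.capture_weights, b.capture_weights)

    def test_expected_total_reads_conserved_noise_free(self, layout3):
        """Noise-free totals equal factor * depth * sum_b w_b * cn_b / 2."""
        cfg = _config(layout3, capture_weight_dispersion=0.5, seed=9)
        sim = simulate_counts(cfg)
        for line in ("REF", "DEL"):
            cn = sim.truth_copy_number.loc[line].to_numpy()
            expected = 40.0 * (sim.capture_weights * cn / 2.0).sum()
            assert sim.counts.loc[line].sum() == pytest.approx(expected)

    def test_invalid_parameters_rejected(self, layout3):
        with pytest.raises(ValueError, match="mean_depth"):
            _config(layout3, mean_depth=0)
        with pytest.raises(ValueError, match="positive"):
            _config(layout3, library_size_factors={"REF": -1})
        with pytest.raises(ValueError, match="reference"):
            _config(layout3, reference_line="nope")


class TestViability:
    def test_rule_reproduces_panel_phenotypes(self, layout3, bins3):
        """Euploid viable; nullisomic with non-homoeologous tetrasomy
        non-viable; nullisomic with compensating tetrasomy viable."""
        locus = ArmCoordinate("1D", "L", 0.9)
        comp = CompensationRule("1B", required_copies=4)
        tracks = {
            "CS": [],
            "N1D/T1A": [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1A")],
            "N1D/T1B": [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1B")],
        }
        cn = pd.DataFrame.from_dict(
            {k: copy_number_track(layout3, bins3, v) for k, v in tracks.items()},
            orient="index",
        )
        pheno = simulate_viability(cn, layout3, bins3, locus, comp)
        assert pheno == {
            "CS": "viable",
            "N1D/T1A": "non_viable",
            "N1D/T1B": "viable",
        }

    def test_required_copies_gate(self, layout3, bins3):
        cn = pd.DataFrame.from_dict(
            {
                "X": copy_number_track(
                    layout3,
                    bins3,
                    [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1B")],
                )
            },
            orient="index",
        )
        locus = ArmCoordinate("1D", "L", 0.9)
        strict = CompensationRule("1B", required_copies=99)
        assert simulate_viability(cn, layout3, bins3, locus, strict) == {
            "X": "non_viable"
        }


class TestTraits:
    def test_zero_sd_gives_exact_line_means(self, layout3, bins3, rng):
        cn = pd.DataFrame.from_dict(
            {"CS": copy_number_track(layout3, bins3, []),
             "NULL": copy_number_track(layout3, bins3, [KaryotypeEvent("nullisomy", "1D")])},
            orient="index",
        )
        model = {"grain_number": TraitSpec(baseline=60.0, sd=0.0, effect=-40.0)}
        obs = simulate_traits(
            cn, layout3, bins3, ArmCoordinate("1D", "L", 0.9), model, 3, rng
        )
        assert (obs[obs["line"] == "CS"]["value"] == 60.0).all()
        assert (obs[obs["line"] == "NULL"]["value"] == 20.0).all()

    def test_compensated_lines_sit_between(self, layout3, bins3, rng):
        cn = pd.DataFrame.from_dict(
            {"COMP": copy_number_track(
                layout3, bins3,
                [KaryotypeEvent("nullisomy", "1D"), KaryotypeEvent("tetrasomy", "1B")],
            )},
            orient="index",
        )
        model = {"t": TraitSpec(baseline=100.0, sd=0.0, effect=-50.0)}
        obs = simulate_traits(
            cn, layout3, bins3, ArmCoordinate("1D", "L", 0.9), model, 2, rng,
            compensation=CompensationRule("1B", 4), compensation_fraction=0.5,
        )
        assert (obs["value"] == 75.0).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            TraitSpec(baseline=1.0, sd=-0.1)

    def test_replicate_floor(self, layout3, bins3, rng):
        cn = pd.DataFrame.from_dict(
            {"CS": copy_number_track(layout3, bins3, [])}, orient="index"
        )
        with pytest.raises(ValueError, match="n_replicates"):
            simulate_traits(
                cn, layout3, bins3, ArmCoordinate("1D", "L", 0.9),
                {"t": TraitSpec(1.0, 1.0)}, 1, rng,
            )

    def test_null_effects_rarely_flagged(self):
        """With all effects zero, the downstream protected-LSD table flags
        nothing in at least 94% of (run, trait) families at alpha 0.05."""
        from delmap.panels import default_config, group1_layout
        from delmap.simulate import simulate_counts
        from delmap.traits import anova_lsd

        layout = group1_layout()
        null_model = {
            "t1": TraitSpec(baseline=10.0, sd=1.0, effect=0.0),
            "t2": TraitSpec(baseline=50.0, sd=5.0, effect=0.0),
        }
        clean_families = 0
        total = 0
        for seed in range(100):
            cfg = default_config(
                seed=seed, layout=layout, trait_model=null_model,
                count_noise="none", capture_weight_dispersion=0.0,
            )
            sim = simulate_counts(cfg)
            res = anova_lsd(sim.truth_traits, control="CS", alphas=(0.05, 0.01))
            for trait in res.flags.columns:
                total += 1
                if (res.flags[trait] == "").all():
                    clean_families += 1
        assert clean_families / total >= 0.94
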