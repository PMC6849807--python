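import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sporetrace.mpn import MpnDesign, estimate_mpn
from sporetrace.simulate import (
    MicrocosmConfig,
    SimConfig,
    StationLayout,
    TaxonParams,
    compute_truth,
    default_config,
    expected_deposition,
    generate_dataset,
    simulate_deposition,
    simulate_microcosm,
    simulate_mpn_assay,
    simulate_sequencing,
    sulfate_exhaustion_time,
)
from sporetrace.tables_io import StationClass


def _mini_config(taxa, stations=None, **micro_kwargs):
    stations = stations or (
        StationLayout("A", -2.0, StationClass.NON_TIDAL, "brackish"),
        StationLayout("E", 28.0, StationClass.TIDAL, "brackish"),
        StationLayout("F", 50.0, StationClass.MARINE, "marine"),
    )
    return SimConfig(
        stations=stations, taxa=tuple(taxa), microcosm=MicrocosmConfig(**micro_kwargs)
    )


class TestDeposition:
    def test_marine_taxon_absent_above_tidal_limit(self):
        taxon = TaxonParams(
            "m", "marine", marine_input_per_g=1e5, upstream_decay_km=1000.0
        )
        cfg = _mini_config([taxon])
        means = expected_deposition(cfg)
        assert means.loc["m", "A"] == 0.0
        assert means.loc["m", "F"] > 0

    def test_terrestrial_decay_is_exponential_in_distance(self):
        L = 15.0
        taxon = TaxonParams("t", "terrestrial", terrestrial_input_per_g=1e6,
                            downstream_decay_km=L)
        stations = (
            StationLayout("A", 0.0, StationClass.NON_TIDAL, "brackish"),
            StationLayout("B", L, StationClass.TIDAL, "brackish"),
            StationLayout("F", 2 * L, StationClass.MARINE, "marine"),
        )
        means = expected_deposition(_mini_config([taxon], stations))
        assert means.loc["t", "A"] / means.loc["t", "B"] == pytest.approx(math.e)
        assert means.loc["t", "B"] / means.loc["t", "F"] == pytest.approx(math.e)

    def test_sub_floor_means_truncate_to_zero(self):
        taxon = TaxonParams("t", "terrestrial", terrestrial_input_per_g=1e4,
                            downstream_decay_km=1.0)
        means = expected_deposition(_mini_config([taxon]))
        assert means.loc["t", "A"] == 1e4
        assert means.loc["t", "E"] == 0.0  # e-30 of the input, below the floor

    def test_poisson_noise_around_the_mean(self):
        taxon = TaxonParams("t", "terrestrial", terrestrial_input_per_g=50.0,
                            downstream_decay_km=1e6)
        cfg = _mini_config([taxon])
        draws = np.array(
            [simulate_deposition(cfg, seed=s).loc["t", "A"] for s in range(500)]
        )
        se = math.sqrt(50 / len(draws))
        assert abs(draws.mean() - 50) < 3 * se

    def test_negative_decay_rejected(self):
        with pytest.raises(ValueError, match="decay"):
            TaxonParams("t", "terrestrial", terrestrial_input_per_g=1.0,
                        downstream_decay_km=-1.0)


class TestMicrocosm:
    SRB = TaxonParams(
        "srb", "terrestrial", terrestrial_input_per_g=1e4,
        is_sulfate_reducer=True, growth_rate_per_h=0.5,
        cap_cells_per_g=1e12, salinity_tolerance=frozenset({"brackish"}),
    )

    def test_no_spores_means_no_sulfate_drawdown(self):
        cfg = _mini_config([self.SRB])
        _, chem = simulate_microcosm({"srb": 0.0}, cfg)
        assert (chem["sulfate_mM"] == 20.0).all()

    def test_single_srb_converts_all_sulfate_to_sulfide(self):
        cfg = _mini_config([self.SRB])
        _, chem = simulate_microcosm({"srb": 1e4}, cfg)
        final = chem.iloc[-1]
        assert final["sulfate_mM"] == pytest.approx(0.0, abs=1e-9)
        assert final["sulfide_mM"] == pytest.approx(20.0, abs=1e-9)

    def test_mass_balance_at_every_solver_step(self):
        cfg = _mini_config([self.SRB])
        _, chem = simulate_microcosm({"srb": 1e4}, cfg)
        total = chem["sulfate_mM"] + chem["sulfide_mM"]
        assert np.allclose(total, 20.0, atol=1e-6)
        assert (np.diff(chem["sulfate_mM"]) <= 1e-12).all()

    def test_salinity_intolerant_taxon_never_germinates(self):
        cfg = _mini_config([self.SRB])
        biomass, chem = simulate_microcosm({"srb": 1e4}, cfg, medium_salinity="marine")
        assert (chem["sulfate_mM"] == 20.0).all()
        # only the dormant-spore DNA remains
        assert (biomass.loc["srb"] == 1e4).all()

    def test_default_config_exhausts_sulfate_within_120h_everywhere(self, sim_config):
        means = expected_deposition(sim_config)
        for st in sim_config.stations:
            _, chem = simulate_microcosm(
                means[st.station_id], sim_config, medium_salinity=st.medium_salinity
            )
            t = sulfate_exhaustion_time(chem, sim_config.microcosm.sampling_times_h)
            assert t is not None and t <= 120.0


class TestSequencing:
    def test_single_taxon_gets_all_reads(self):
        biomass = pd.DataFrame({"s1": [500.0]}, index=["only"])
        counts = simulate_sequencing(biomass, default_config().sequencing, seed=1)
        assert counts.counts.loc["only", "s1"] == counts.library_sizes()["s1"]

    def test_zero_biomass_sample_rejected(self):
        biomass = pd.DataFrame({"s1": [0.0]}, index=["only"])
        with pytest.raises(ValueError, match="zero total biomass"):
            simulate_sequencing(biomass, default_config().sequencing, seed=1)

    def test_multinomial_fraction_matches_biomass_ratio(self):
        biomass = pd.DataFrame({"s": [9.0, 1.0]}, index=["big", "small"])
        model = default_config().sequencing
        fracs = []
        for seed in range(200):
            t = simulate_sequencing(biomass, model, seed=seed)
            fracs.append(t.counts.loc["big", "s"] / t.library_sizes()["s"])
        fracs = np.array(fracs)
        se = math.sqrt(0.9 * 0.1 / 10_000) / math.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.9) < 4 * se

    def test_baseline_samples_keep_spores_below_baseline_cutoff(self, dataset):
        rel = dataset["counts"].counts / dataset["library_sizes"]
        spores = [i for i in rel.index if not i.startswith("BG")]
        baseline_cols = [c for c in rel.columns if c.endswith("_0h")]
        assert (rel.loc[spores, baseline_cols] < 0.001).all().all()

    def test_library_size_model_matches_study_scale(self, sim_config):
        sizes = []
        for seed in range(20):
            ds = generate_dataset(sim_config, seed=seed)
            sizes.append(ds["library_sizes"])
        mins = np.array([s.min() for s in sizes])
        means = np.array([s.mean() for s in sizes])
        assert 9000 < mins.mean() < 17000  # smallest library ~ 12 852
        assert 22000 < means.mean() < 30000  # mean library ~ 25 729


class TestMpnAssay:
    DESIGN = MpnDesign.tenfold(0.1, 3)

    def test_zero_density_gives_all_negative(self):
        obs = simulate_mpn_assay(0.0, self.DESIGN, seed=4)
        assert obs.positives == (0, 0, 0)

    def test_ln2_dose_gives_half_positive(self):
        density = math.log(2) / 0.1
        hits = sum(
            simulate_mpn_assay(density, MpnDesign(((0.1, 3),)), seed=s).positives[0]
            for s in range(400)
        )
        n = 3 * 400
        se = math.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 4 * se

    def test_median_windowed_estimate_within_factor_two(self):
        """2000 simulated assays at 23 spores/g: the windowed MLE's median
        should land within a factor of two of the truth."""
        lam = 23.0
        estimates = []
        for seed in range(2000):
            obs = simulate_mpn_assay(lam, self.DESIGN, germination_prob=1.0, seed=seed)
            if obs.all_negative or obs.all_positive:
                continue
            from sporetrace.mpn import mpn_point_estimate

            estimates.append(mpn_point_estimate(obs).mpn_per_g)
        med = float(np.median(estimates))
        assert lam / 2 <= med <= lam * 2


class TestGroundTruth:
    def test_default_truth_composition(self, sim_truth):
        labels = pd.Series(sim_truth.expected_label)
        assert (labels == "terrestrial").sum() == 40
        assert (labels == "marine").sum() == 10
        assert (labels == "cosmopolitan").sum() == 10
        # the vegetative background is never enrichable
        assert (labels == "unclassified").sum() == 15

    def test_truth_is_recomputable_with_no_hidden_state(self, sim_config, sim_truth):
        again = compute_truth(sim_config)
        pd.testing.assert_frame_equal(again.enrichable, sim_truth.enrichable)
        assert again.expected_label == sim_truth.expected_label

    def test_spore_density_scaled_down_degrades_recovery(self, sim_config):
        """Sanity that detectability is not vacuous: with deposition cut
        100-fold most taxa fall under the establishment floor."""
        weak_taxa = tuple(
            TaxonParams(
                **{
                    **t.__dict__,
                    "terrestrial_input_per_g": t.terrestrial_input_per_g / 100,
                    "marine_input_per_g": t.marine_input_per_g / 100,
                }
            )
            for t in sim_config.taxa
        )
        weak = SimConfig(
            stations=sim_config.stations,
            taxa=weak_taxa,
            microcosm=sim_config.microcosm,
            sequencing=sim_config.sequencing,
        )
        truth = compute_truth(weak)
        strong = compute_truth(sim_config)
        assert len(truth.detectable_otus()) < len(strong.detectable_otus())


class TestDatasetGeneration:
    def test_default_run_shape(self, dataset):
        assert dataset["counts"].counts.shape == (75, 36)
        assert len(dataset["metadata"]) == 36

    def test_byte_reproducibility_for_fixed_seed(self, sim_config, tmp_path):
        a = generate_dataset(sim_config, seed=42, out_dir=tmp_path / "a")
        b = generate_dataset(sim_config, seed=42, out_dir=tmp_path / "b")
        for name in ("counts", "metadata", "taxonomy", "sulfate", "truth"):
            assert (
                a["paths"][name].read_bytes() == b["paths"][name].read_bytes()
            ), name

    def test_different_seeds_differ(self, sim_config, tmp_path):
        a = generate_dataset(sim_config, seed=1, out_dir=tmp_path / "a")
        b = generate_dataset(sim_config, seed=2, out_dir=tmp_path / "b")
        assert a["paths"]["counts"].read_bytes() != b["paths"]["counts"].read_bytes()

    def test_truth_json_scores_downstream_modules(self, dataset):
        truth = json.loads(Path(dataset["paths"]["truth"]).read_text())
        assert set(truth["expected_label"]) == set(dataset["counts"].otu_ids)
        assert set(truth["enrichable"]) == set("ABCDEF")
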