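"""Generator behaviour: configuration, determinism, inheritance structure,
hybrid construction, coverage, and dataset emission."""

import numpy as np
import pandas as pd
import pytest

import myzopop as mp
from myzopop.genotype_io import ABSENT
from myzopop.simulate import ConfigError

from conftest import SMALL_DESIGN, pops_of, small_config


class TestScenarioConfig:
    def test_defaults_match_study_parameters(self):
        cfg = mp.build_scenario_config()
        assert cfg.mu == 4.6e-9
        assert cfg.gen_time_years == {"card": 2.25, "tris": 2.51, "pulc": 2.37}
        # ~1.1 My divergence and ~100 y contact, in generations
        assert cfg.T_div == pytest.approx(1.1e6 / 2.38, rel=0.01)
        assert cfg.T_contact == pytest.approx(100 / 2.38, rel=0.01)
        assert cfg.depth_mean == 16.95
        assert cfg.compartment_scalings["Z"] == 0.75
        assert cfg.compartment_scalings["W"] == 0.25

    def test_override_applies(self):
        assert mp.build_scenario_config({"mu": 1e-8}).mu == 1e-8

    def test_unknown_field_is_named(self):
        with pytest.raises(ConfigError, match="not_a_field"):
            mp.build_scenario_config({"not_a_field": 1})

    def test_time_ordering_enforced(self):
        with pytest.raises(ConfigError):
            mp.build_scenario_config({"T_contact": 2e6})

    def test_rates_bounded(self):
        with pytest.raises(ConfigError):
            mp.build_scenario_config({"m_c2t": 1.5})

    def test_sample_sheet_counts(self):
        cfg = small_config()
        sheet = mp.build_sample_sheet(cfg)
        assert len(sheet) == sum(SMALL_DESIGN.values())


class TestDeterminism:
    def test_same_seed_identical_output(self):
        cfg = small_config(seed=99)
        a, _ = mp.simulate_compartment_genotypes(cfg, "neoPAR")
        b, _ = mp.simulate_compartment_genotypes(cfg, "neoPAR")
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert np.array_equal(a.gt, b.gt)

    def test_different_seed_differs(self):
        a, _ = mp.simulate_compartment_genotypes(small_config(seed=1), "neoPAR")
        b, _ = mp.simulate_compartment_genotypes(small_config(seed=2), "neoPAR")
        assert len(a.sites) != len(b.sites) or not np.array_equal(a.gt, b.gt)


class TestInheritanceStructure:
    def test_males_have_no_w_genotypes(self, contact_ds):
        sheet = contact_ds.sample_sheet
        males = sheet[sheet["sex"] == "M"]["sample_id"]
        for comp in ("W", "neoW"):
            t = contact_ds.tables[comp]
            idx = t.sample_index(list(males))
            assert (t.gt[:, idx, :] == ABSENT).all()

    def test_females_hemizygous_on_z(self, contact_ds):
        sheet = contact_ds.sample_sheet
        females = sheet[sheet["sex"] == "F"]["sample_id"]
        t = contact_ds.tables["Z"]
        idx = t.sample_index(list(females))
        assert (t.gt[:, idx, 1] == ABSENT).all()
        assert (t.gt[:, idx, 0] != ABSENT).all()

    def test_isolated_species_diverged(self, nomig_ds):
        """With zero migration and ~1.1 My isolation, between-species dxy
        exceeds within-species pi in every compartment."""
        pops = pops_of(nomig_ds)
        sheet, cmap = nomig_ds.sample_sheet, nomig_ds.compartment_map
        for comp, t in nomig_ds.tables.items():
            card = [s for s in pops["card_allo"] if _carries(t, s)]
            tris = [s for s in pops["tris_allo"] if _carries(t, s)]
            pi = mp.windowed_pi(t, tris, cmap, sample_sheet=sheet,
                                window_size=10**9, min_sites=0)
            dxy = mp.windowed_dxy(t, card, tris, cmap, sample_sheet=sheet,
                                  window_size=10**9, min_sites=0)
            pi_v = np.nansum(pi["diff_count"]) / np.nansum(pi["comparison_count"])
            dxy_v = np.nansum(dxy["diff_count"]) / np.nansum(dxy["comparison_count"])
            assert dxy_v > pi_v, comp

    def test_compartment_ne_scaling(self):
        """Single-population neutral diversity scales with the compartment's
        effective-size multiplier (0.75 Z-like, 0.25 maternal)."""
        cfg = small_config(
            Ne_tris=20_000, m_c2t=0.0, m_t2c=0.0, seed=23,
            seq_lengths={"autosome": 400_000, "Z": 400_000, "W": 400_000},
            n_autosome_contigs=1,
            sample_design={("tris", "allopatric", "M"): 8,
                           ("tris", "allopatric", "F"): 8},
            hybrid_design={},
        )
        vals = {}
        for comp in ("autosome", "Z", "W"):
            t, _ = mp.simulate_compartment_genotypes(cfg, comp)
            sheet = mp.build_sample_sheet(cfg)
            pop = [s for s in sheet["sample_id"] if _carries(t, s)]
            cmap = mp.default_compartment_map(cfg)
            pi = mp.windowed_pi(t, pop, cmap, sample_sheet=sheet)
            vals[comp] = float(
                np.nansum(pi["diff_count"]) / np.nansum(pi["comparison_count"])
            )
        assert vals["Z"] / vals["autosome"] == pytest.approx(0.75, abs=0.12)
        assert vals["W"] / vals["autosome"] == pytest.approx(0.25, abs=0.08)


def _carries(table, sample):
    j = table.samples.index(sample)
    return (table.gt[:, j, 0] != ABSENT).any()


class TestHybrids:
    def test_f1_from_isolated_parents_is_heterozygous(self, nomig_ds):
        """F1s built from unadmixed parents are heterozygous at every
        diagnostic autosomal locus: hybrid index 0.5, heterozygosity 1."""
        tv = nomig_ds.variant_table()
        sheet = nomig_ds.sample_sheet
        # species-wide reference panel: the F1 parents are inside it, so a
        # fixed difference forces heterozygosity in their offspring
        panel = mp.fixed_difference_panel(
            tv,
            mp.samples_for(sheet, species="card"),
            mp.samples_for(sheet, species="tris"),
            compartment_map=nomig_ds.compartment_map,
        ).subset(("autosome", "neoPAR"))
        f1s = nomig_ds.truth.samples.query("hybrid_class == 'F1'")["sample_id"]
        assert len(f1s) > 0
        for s in f1s:
            rec = mp.hybrid_index_and_het(tv, panel, s)
            assert rec.h == pytest.approx(0.5, abs=1e-12)
            assert rec.h_int == pytest.approx(1.0, abs=1e-12)

    def test_backcross_truth_ancestry(self):
        """BC1-to-card cohorts have expected card ancestry 0.75 (binomial
        over gametes sampled from the F1)."""
        cfg = small_config(
            m_c2t=0.0, m_t2c=0.0, seed=31,
            hybrid_design={"BC_card": 30, "BC_tris": 30},
        )
        ds = mp.simulate_dataset(cfg)
        tr = ds.truth.samples
        bc_card = tr.query("hybrid_class == 'BC_card'")["true_card_fraction"]
        bc_tris = tr.query("hybrid_class == 'BC_tris'")["true_card_fraction"]
        # cohort mean within 3 binomial-ish SEs of the expectation
        assert bc_card.mean() == pytest.approx(0.75, abs=0.05)
        assert bc_tris.mean() == pytest.approx(0.25, abs=0.05)

    def test_maternal_transmission(self, nomig_ds):
        """F1s with a card mother carry card mt and (females) card W."""
        tr = nomig_ds.truth.samples
        f1 = tr.query("hybrid_class == 'F1'")
        assert (f1["maternal_origin"] == "card").all()
        tv = nomig_ds.variant_table()
        pops = pops_of(nomig_ds)
        panel = mp.fixed_difference_panel(
            tv, pops["card_allo"], pops["tris_allo"],
            compartment_map=nomig_ds.compartment_map,
        )
        mat = mp.maternal_assignments(tv, panel, list(f1["sample_id"]))
        assert set(mat["maternal_assignment"]) == {"card"}

    def test_no_female_parents_raises(self):
        cfg = small_config(
            sample_design={
                ("card", "allopatric", "M"): 5,
                ("tris", "allopatric", "M"): 5, ("tris", "allopatric", "F"): 5,
                ("pulc", "allopatric", "F"): 1,
            },
            hybrid_design={"F1": 1},
        )
        with pytest.raises(ConfigError, match="female"):
            mp.simulate_dataset(cfg)


class TestCoverage:
    def test_sex_specific_depth_ratios(self, contact_ds):
        prof = contact_ds.coverage
        df = prof.depths.copy()
        df["sex"] = df["sample"].map(prof.sex)
        by = df.groupby(["contig", "sex"])["mean_depth"].mean().unstack()
        assert by.loc["W", "M"] == pytest.approx(0.0, abs=0.01)
        assert by.loc["Z", "F"] / by.loc["Z", "M"] == pytest.approx(0.5, rel=0.02)
        assert by.loc["chr1", "M"] / by.loc["chr1", "F"] == pytest.approx(1.0, rel=0.02)


class TestEmission:
    def test_round_trip_and_failure_injection(self, tmp_path):
        cfg = small_config(
            seq_lengths={"autosome": 30_000, "W": 10_000, "mt": 8_000},
            n_autosome_contigs=1,
            fail_fraction=0.1, heteroplasmy_fraction=0.02, seed=41,
        )
        ds = mp.simulate_dataset(cfg, materialize=True)
        paths = mp.emit_dataset(ds, tmp_path)
        sheet = mp.read_sample_sheet(paths["samples"])
        cmap = mp.CompartmentMap.from_bed(paths["bed"])
        back = mp.read_allsites_vcf(paths["vcf"], sheet, cmap)
        assert np.array_equal(back.gt, ds.allsites.gt)
        assert back.sites["pos"].tolist() == ds.allsites.sites["pos"].tolist()
        pd.testing.assert_frame_equal(sheet, ds.sample_sheet)

        filtered = mp.apply_hard_site_filters(back)
        masked = (filtered.gt >= 0).any(axis=(1, 2)) != (back.gt >= 0).any(axis=(1, 2))
        frac = masked.mean()
        assert 0.07 < frac < 0.13  # the injected failing fraction
        # every masked site really violates a hard-filter threshold
        a = back.annotations[masked]
        violates = (
            (a["QD"] < 2) | (a["SOR"] > 3) | (a["FS"] > 60) | (a["MQ"] < 40)
            | (a["MQRankSum"] < -12.5) | (a["ReadPosRankSum"] < -8.0)
        )
        assert violates.all()

    def test_unknown_vcf_sample_rejected(self, tmp_path):
        cfg = small_config(
            seq_lengths={"mt": 5_000}, hybrid_design={}, seed=43,
        )
        ds = mp.simulate_dataset(cfg, materialize=True)
        paths = mp.emit_dataset(ds, tmp_path)
        bad_sheet = ds.sample_sheet.iloc[:-1]
        with pytest.raises(mp.GenotypeIOError, match=ds.sample_sheet.iloc[-1]["sample_id"]):
            mp.read_allsites_vcf(
                paths["vcf"], bad_sheet, mp.CompartmentMap.from_bed(paths["bed"])
            )


class TestWrightFisherEngine:
    def test_wf_engine_runs_and_is_deterministic(self):
        cfg = small_config(
            Ne_card=5_000, Ne_tris=5_000, Ne_pulc=5_000,
            T_div=20_000, T_contact=40, T_out=40_000,
            seq_lengths={"mt": 16_000}, hybrid_design={}, seed=47,
        )
        a, _ = mp.simulate_compartment_genotypes(cfg, "mt", engine="wf")
        b, _ = mp.simulate_compartment_genotypes(cfg, "mt", engine="wf")
        assert np.array_equal(a.gt, b.gt)
        assert a.n_sites > 0

    def test_wf_engine_separates_species(self):
        cfg = small_config(
            Ne_card=5_000, Ne_tris=5_000, Ne_pulc=5_000,
            T_div=20_000, T_contact=40, T_out=40_000,
            m_c2t=0.0, m_t2c=0.0,
            seq_lengths={"mt": 16_000}, hybrid_design={}, seed=49,
        )
        t, _ = mp.simulate_compartment_genotypes(cfg, "mt", engine="wf")
        sheet = mp.build_sample_sheet(cfg)
        cmap = mp.default_compartment_map(cfg)
        pops = {
            "card": mp.samples_for(sheet, species="card", locality="allopatric"),
            "tris": mp.samples_for(sheet, species="tris", locality="allopatric"),
        }
        pi = mp.windowed_pi(t, pops["tris"], cmap, sample_sheet=sheet)
        dxy = mp.windowed_dxy(t, pops["card"], pops["tris"], cmap, sample_sheet=sheet)
        assert dxy["value"].iloc[0] > pi["value"].iloc[0]
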