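"""Synthetic site-table generator: determinism, law-of-large-numbers
consistency with the solved spectra, and the table format round trip."""

import numpy as np
import pandas as pd
import pytest

import sfsdyn as sd
from sfsdyn import synth
from sfsdyn.diffusion import ParameterError
from sfsdyn.summaries import prob_polymorphic, sample_sfs


class TestConfigValidation:
    def test_bad_weights_rejected(self):
        with pytest.raises(ParameterError):
            synth.GeneratorConfig(dfe=((1e-3, 0.9),), neutral_weight=0.5)

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            synth.GeneratorConfig(
                dfe=((1e-3, 0.5),), neutral_weight=0.5,
                misassignment_rate=1.5)

    def test_exac_scale_sample_sizes(self):
        gc = synth.GeneratorConfig().exac_scale()
        assert gc.afr_chroms == 2 * 5203
        assert gc.nfe_chroms == 2 * 33_370


class TestGenerateSites:
    def test_seed_determinism(self, generator_config, present_spectra):
        a = synth.generate_sites(generator_config, present_spectra)
        b = synth.generate_sites(generator_config, present_spectra)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_class_rejected(self, generator_config, present_spectra):
        partial = {0.0: present_spectra[0.0]}
        with pytest.raises(ParameterError):
            synth.generate_sites(generator_config, partial)

    def test_counts_within_called(self, synthetic_table):
        for pop in ("afr", "nfe"):
            assert (synthetic_table[f"{pop}_der"]
                    <= synthetic_table[f"{pop}_called"]).all()
            assert (synthetic_table[f"{pop}_der"] >= 0).all()

    def test_yield_near_target(self, generator_config, synthetic_table):
        got = len(synthetic_table)
        assert got == pytest.approx(generator_config.n_sites_target, rel=0.25)

    def test_gerp_monotone_in_true_s(self, synthetic_table):
        """With a positive score slope, mean true s rises across realized
        score bins (truth columns make this directly checkable)."""
        tab = synthetic_table[synthetic_table.true_s > 0]
        bins = pd.qcut(tab.gerp, 8)
        mean_s = tab.groupby(bins, observed=True).true_s.mean()
        assert np.all(np.diff(mean_s.to_numpy()) > 0)

    def test_all_flipped_when_epsilon_one(self, present_spectra):
        gc = synth.GeneratorConfig(
            n_sites_target=2000, dfe=((1e-4, 0.5),), neutral_weight=0.5,
            misassignment_rate=1.0, seed=3)
        tab = synth.generate_sites(
            gc, {k: present_spectra[k] for k in (1e-4, 0.0)})
        assert tab.flipped.all()

    def test_sample_counts_follow_projected_sfs(self, present_spectra):
        """Conditional on polymorphism, the derived-count histogram in the
        African-like sample converges to the projected sample SFS."""
        n = 40
        gc = synth.GeneratorConfig(
            n_sites_target=60_000, dfe=(), neutral_weight=1.0,
            afr_chroms=n, nfe_chroms=n, misassignment_rate=0.0,
            missingness=synth.MissingnessModel(
                p_bad=0.0, good_alpha=1e6, good_beta=1e-3), seed=7)
        f_afr, _ = present_spectra[0.0]
        tab = synth.generate_sites(gc, {0.0: (f_afr, f_afr)})
        poly = tab[(tab.afr_der > 0) & (tab.afr_der < n)]
        observed = np.bincount(poly.afr_der, minlength=n + 1)[1:n]
        observed = observed / observed.sum()
        expected = sample_sfs(f_afr, n).expected_counts
        expected = expected / expected.sum()
        # chi-square-ish bound at Monte-Carlo scale
        resid = (observed - expected) / np.sqrt(
            expected * (1 - expected) / len(poly))
        assert np.abs(resid).max() < 5.0

    def test_neutral_het_ratio_matches_solved_spectra(self, present_spectra):
        """Mean per-site heterozygosity ratio between the two samples
        approaches the ratio of solved population heterozygosities."""
        f_afr, f_nfe = present_spectra[0.0]
        gc = synth.GeneratorConfig(
            n_sites_target=80_000, dfe=(), neutral_weight=1.0,
            misassignment_rate=0.0,
            missingness=synth.MissingnessModel(
                p_bad=0.0, good_alpha=1e6, good_beta=1e-3), seed=9)
        tab = synth.generate_sites(gc, {0.0: (f_afr, f_nfe)})
        het = {}
        for pop in ("afr", "nfe"):
            p = tab[f"{pop}_der"] / tab[f"{pop}_called"]
            het[pop] = (2 * p * (1 - p)).mean()
        got = het["afr"] / het["nfe"]
        want = sd.heterozygosity(f_afr) / sd.heterozygosity(f_nfe)
        assert got == pytest.approx(want, rel=0.05)


class TestTableIO:
    def test_round_trip(self, synthetic_table, tmp_path):
        path = tmp_path / "sites.tsv"
        synth.write_site_table(synthetic_table, path)
        again = synth.read_site_table(path)
        pd.testing.assert_frame_equal(
            again, synthetic_table[synth.SITE_TABLE_COLUMNS],
            check_dtype=False)

    def test_truth_columns_optional_on_read(self, synthetic_table, tmp_path):
        path = tmp_path / "observed.tsv"
        cols = ["site_id", "gerp", "afr_der", "afr_called", "nfe_der",
                "nfe_called"]
        synthetic_table[cols].to_csv(path, sep="\t", index=False)
        tab = synth.read_site_table(path)
        assert tab.anc_known.all()
        assert tab.true_s.isna().all()

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("site_id\tgerp\n1\t2.0\n")
        with pytest.raises(synth.TableFormatError):
            synth.read_site_table(path)

    def test_inconsistent_counts_reported_with_line(self, tmp_path):
        path = tmp_path / "bad2.tsv"
        path.write_text(
            "site_id\tgerp\tafr_der\tafr_called\tnfe_der\tnfe_called\n"
            "0\t1.0\t5\t10\t0\t10\n"
            "1\t1.0\t12\t10\t0\t10\n"
        )
        with pytest.raises(synth.TableFormatError, match="line 3"):
            synth.read_site_table(path)

    def test_empty_table_round_trip(self, synthetic_table, tmp_path):
        path = tmp_path / "empty.tsv"
        synth.write_site_table(synthetic_table.iloc[:0], path)
        again = synth.read_site_table(path)
        assert len(again) == 0
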