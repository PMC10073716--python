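"""Cumulative burden, reporter quantification, and marker summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from upmprofiler._stats import pooled_ttest
from upmprofiler.io_formats import CHANNELS, PSMRecord, ReporterDesign
from upmprofiler.quantification import (DIFFERENCE_LABEL, cumulative_signal,
                                        marker_summary, normalize_channels,
                                        protein_channel_table,
                                        quantify_channel_table,
                                        quantify_proteins)
from upmprofiler.synthetic_data import (ProteinSpec, SimulationConfig,
                                        SiteSpec, simulate)
from upmprofiler.upm_annotation import DELTA_CARBAMYL

DESIGN = ReporterDesign()


def hcit_psm(pool, sid, intensity=1.0):
    channel = DESIGN.pool_to_channel[pool]
    return PSMRecord(sid, "AKPW", "P1", 1, ((1, DELTA_CARBAMYL),), 0.001,
                     {channel: intensity}, pool)


class TestCumulative:
    def test_group_sums_and_difference(self):
        psms = ([hcit_psm("NZ1", f"a{i}") for i in range(3)]
                + [hcit_psm("nonNZ1", f"b{i}") for i in range(5)])
        df = cumulative_signal(psms, "hCit", DESIGN)
        assert df.loc["NZ", "spectral_counts"] == 3
        assert df.loc["nonNZ", "spectral_counts"] == 5
        assert df.loc[DIFFERENCE_LABEL, "spectral_counts"] == 2

    def test_no_psms_of_class(self):
        psms = [hcit_psm("NZ1", "a")]
        df = cumulative_signal(psms, "Cit", DESIGN)
        assert (df.loc[["NZ", "nonNZ"], "spectral_counts"] == 0).all()

    def test_pool_partition_resums_to_group(self):
        rng = np.random.default_rng(0)
        psms = [hcit_psm(pool, f"s{i}", float(rng.uniform(0.5, 2)))
                for i, pool in enumerate(rng.choice(DESIGN.pools, size=40))]
        by_pool = cumulative_signal(psms, "hCit", DESIGN, by="pool")
        by_group = cumulative_signal(psms, "hCit", DESIGN, by="group")
        for group in ("NZ", "nonNZ"):
            pools = [p for p in DESIGN.pools if DESIGN.pool_group(p) == group]
            assert by_pool.loc[pools, "spectral_counts"].sum() == \
                by_group.loc[group, "spectral_counts"]
            assert by_pool.loc[pools, "intensity"].sum() == pytest.approx(
                by_group.loc[group, "intensity"])

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            cumulative_signal([], "NotAClass", DESIGN)


class TestPooledTTest:
    def test_agrees_with_scipy_on_regular_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(loc=0.5, size=7)
            t, p, _ = pooled_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_guard(self):
        t, p, _ = pooled_ttest([10, 10, 10], [20, 20, 20, 20, 20])
        assert np.isfinite(t) and p < 1e-6

    def test_exact_tie_gives_unit_p(self):
        t, p, _ = pooled_ttest([5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)


class TestQuantify:
    def _table(self, values):
        return pd.DataFrame([values], index=["P1"], columns=list(CHANNELS))

    def test_flat_protein_ratio_one_p_one(self):
        out = quantify_channel_table(self._table([7.0] * 8), DESIGN,
                                     normalization="none")
        assert out.loc["P1", "ratio"] == pytest.approx(1.0)
        assert out.loc["P1", "p"] == pytest.approx(1.0)

    def test_two_fold_textbook_t(self):
        # NZ channels 113,114,119 = 10; nonNZ = 20: ratio 2, degenerate
        # variance floored, p essentially zero
        values = {c: (10.0 if DESIGN.channel_to_group[c] == "NZ" else 20.0)
                  for c in CHANNELS}
        out = quantify_channel_table(
            pd.DataFrame([values], index=["P1"]), DESIGN, normalization="none")
        assert out.loc["P1", "ratio"] == pytest.approx(2.0)
        assert out.loc["P1", "p"] < 1e-9

    def test_channel_scale_invariance(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.uniform(1, 100, size=(6, 8)),
                             index=[f"P{i}" for i in range(6)],
                             columns=list(CHANNELS))
        base = quantify_channel_table(table, DESIGN)
        scaled = table.copy()
        scaled["115"] *= 7.3  # blow up one channel before normalization
        out = quantify_channel_table(scaled, DESIGN)
        for col in ["ratio", "t", "p", "mean_NZ", "mean_nonNZ"]:
            np.testing.assert_allclose(out[col], base[col], rtol=1e-10)
        norm_cols = [c for c in base.columns if c.startswith("norm_")]
        np.testing.assert_allclose(out[norm_cols], base[norm_cols], rtol=1e-10)

    def test_total_normalization_equalizes_column_sums(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.uniform(1, 100, size=(5, 8)),
                             columns=list(CHANNELS))
        norm = normalize_channels(table, "total")
        sums = norm.sum(axis=0)
        np.testing.assert_allclose(sums, sums.iloc[0])
        np.testing.assert_allclose(sums, 1.0)

    def test_spectral_count_totals_permutation_invariant(self):
        psms = [hcit_psm(pool, f"s{i}") for i, pool in
                enumerate(["NZ1", "nonNZ2", "NZ3", "nonNZ5", "NZ1"])]
        forward = cumulative_signal(psms, "hCit", DESIGN)
        backward = cumulative_signal(list(reversed(psms)), "hCit", DESIGN)
        pd.testing.assert_frame_equal(forward, backward)
        assert forward["spectral_counts"].dtype.kind in "iu" or \
            (forward["spectral_counts"] % 1 == 0).all()

    def test_planted_two_fold_change_recovered(self):
        """A protein doubled in the nonNZ group at low reporter noise is
        called significant (p <= 0.05) in at least 95 of 100 simulations."""
        background = [
            ProteinSpec(f"BG{i}_HUMAN", 120, 1.0,
                        n_background_peptides=2) for i in range(7)]
        planted = ProteinSpec("PLANT_HUMAN", 120, 1.0,
                              group_abundance={"NZ": 1.0, "nonNZ": 2.0},
                              n_background_peptides=2)
        hits = 0
        for seed in range(100):
            config = SimulationConfig(
                seed=seed, proteins=tuple(background + [planted]),
                psm_rate=10.0, reporter_sigma=0.1,
                deamidation_rate=0.0, nterm_carbamyl_rate=0.0,
                decoy_fraction=0.0)
            data = simulate(config)
            out = quantify_proteins(data.psms, DESIGN)
            row = out.loc["PLANT_HUMAN"]
            if row["p"] <= 0.05 and row["ratio"] > 1:
                hits += 1
        assert hits >= 95


class TestMarkers:
    def _quants(self):
        table = pd.DataFrame(
            {c: [30.0, 10.0, 20.0] for c in CHANNELS},
            index=["EXO1", "MICRO1", "OTHER"])
        return quantify_channel_table(table, DESIGN, normalization="none")

    def test_absent_marker_counted_not_detected(self):
        df, cmp = marker_summary(self._quants(), ["EXO1", "GHOST"])
        assert not df.set_index("marker").loc["GHOST", "detected"]
        assert cmp["n_not_detected"] == 1

    def test_equal_intensities_give_equal_averages(self):
        table = pd.DataFrame({c: [5.0, 5.0] for c in CHANNELS},
                             index=["M1", "M2"])
        quants = quantify_channel_table(table, DESIGN, normalization="none")
        df, _ = marker_summary(quants, ["M1", "M2"])
        vals = df["relative_intensity"]
        assert vals.iloc[0] == pytest.approx(vals.iloc[1])

    def test_exosome_dominance_sign(self):
        # fixture built with exosome marker 3x the microvesicle marker
        df, cmp = marker_summary(self._quants(), ["EXO1", "MICRO1"],
                                 exosome_list=["EXO1"],
                                 microvesicle_list=["MICRO1"])
        assert cmp["exosome_mean"] > cmp["microvesicle_mean"]
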