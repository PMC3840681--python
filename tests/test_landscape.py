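"""Window binning, transcription metrics (incl. OTA), and recombination association."""

import numpy as np
import pandas as pd
import pytest

from meiolandscape import landscape as L
from meiolandscape.types import (
    Chromosome,
    Gene,
    GenomeAnnotation,
    RecombinationMap,
    ValidationError,
)


def annotation_one_chrom(length, genes):
    return GenomeAnnotation(
        chromosomes=[Chromosome("chr2L", length, "autosome")], genes=genes
    )


class TestBinGenome:
    def test_partial_terminal_window_flagged(self):
        ann = annotation_one_chrom(250_000, [])
        w = L.bin_genome(ann, 100_000)
        assert len(w) == 3
        assert w["partial"].tolist() == [False, False, True]
        assert (w["end"] - w["start"]).tolist() == [100_000, 100_000, 50_000]

    def test_window_larger_than_chromosome(self):
        ann = annotation_one_chrom(40_000, [])
        w = L.bin_genome(ann, 100_000)
        assert len(w) == 1 and bool(w["partial"].iloc[0])

    def test_windows_tile_the_chromosome_exactly(self):
        ann = annotation_one_chrom(333_333, [])
        w = L.bin_genome(ann, 100_000)
        assert (w["end"] - w["start"]).sum() == 333_333


def calls_frame(gene_ids, active, fpkm):
    return pd.DataFrame(
        {"active": active, "fpkm": fpkm}, index=pd.Index(gene_ids, name="gene_id")
    )


class TestWindowMetrics:
    def test_kb_transcribed_counts_overlap_once(self):
        genes = [
            Gene("g1", "chr2L", 100, 600, "+", 500),
            Gene("g2", "chr2L", 400, 900, "+", 500),
        ]
        ann = annotation_one_chrom(100_000, genes)
        calls = calls_frame(["g1", "g2"], [True, True], [1.0, 1.0])
        m = L.window_metrics(ann, calls, L.bin_genome(ann, 100_000))
        assert m["kb_transcribed"].iloc[0] == pytest.approx(0.8)
        assert m["n_transcribed"].iloc[0] == 2

    def test_ota_is_log10_of_fpkm_length_sum(self):
        genes = [
            Gene("g1", "chr2L", 0, 1_000, "+", 1_000),
            Gene("g2", "chr2L", 2_000, 4_000, "+", 2_000),
        ]
        ann = annotation_one_chrom(100_000, genes)
        calls = calls_frame(["g1", "g2"], [True, True], [10.0, 5.0])
        m = L.window_metrics(ann, calls, L.bin_genome(ann, 100_000))
        assert m["ota"].iloc[0] == pytest.approx(np.log10(20_000))

    def test_empty_window_has_undefined_ota(self):
        ann = annotation_one_chrom(100_000, [Gene("g1", "chr2L", 0, 500, "+", 500)])
        calls = calls_frame(["g1"], [False], [0.0])
        m = L.window_metrics(ann, calls, L.bin_genome(ann, 100_000))
        assert m["n_transcribed"].iloc[0] == 0
        assert m["kb_transcribed"].iloc[0] == 0.0
        assert np.isnan(m["ota"].iloc[0])

    def test_ota_increases_with_any_gene_fpkm_and_ignores_order(self):
        genes = [
            Gene("g1", "chr2L", 0, 1_000, "+", 1_000),
            Gene("g2", "chr2L", 2_000, 4_000, "+", 2_000),
        ]
        ann = annotation_one_chrom(100_000, genes)
        base = L.window_metrics(
            ann, calls_frame(["g1", "g2"], [True, True], [10.0, 5.0]),
            L.bin_genome(ann, 100_000),
        )["ota"].iloc[0]
        swapped = L.window_metrics(
            ann, calls_frame(["g2", "g1"], [True, True], [5.0, 10.0]),
            L.bin_genome(ann, 100_000),
        )["ota"].iloc[0]
        raised = L.window_metrics(
            ann, calls_frame(["g1", "g2"], [True, True], [11.0, 5.0]),
            L.bin_genome(ann, 100_000),
        )["ota"].iloc[0]
        assert swapped == pytest.approx(base)
        assert raised > base

    def test_kb_transcribed_matches_per_base_scan(self):
        rng = np.random.default_rng(3)
        for trial in range(30):
            length = 10_000
            n = rng.integers(1, 15)
            starts = rng.integers(0, length - 200, n)
            ends = starts + rng.integers(50, 400, n)
            ends = np.minimum(ends, length)
            genes = [
                Gene(f"g{i}", "chr2L", int(s), int(e), "+", int(e - s))
                for i, (s, e) in enumerate(zip(starts, ends))
            ]
            ann = annotation_one_chrom(length, genes)
            ids = [g.gene_id for g in ann.genes]
            calls = calls_frame(ids, [True] * len(ids), [1.0] * len(ids))
            windows = L.bin_genome(ann, 2_500)
            m = L.window_metrics(ann, calls, windows)
            covered = np.zeros(length, dtype=bool)
            for g in genes:
                covered[g.start : g.end] = True
            for _, row in m.iterrows():
                expect = covered[row["start"] : row["end"]].sum() / 1000.0
                assert row["kb_transcribed"] == pytest.approx(expect, abs=1e-12)


def uniform_map(n, rates, chrom="chr2L", width=100_000):
    return RecombinationMap(
        windows=pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * width,
                "end": (np.arange(n) + 1) * width,
                "rate": rates,
            }
        )
    )


def metrics_frame(n, n_transcribed, kb=None, ota=None, chrom="chr2L", width=100_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
            "partial": False,
            "n_transcribed": n_transcribed,
            "kb_transcribed": kb if kb is not None else np.asarray(n_transcribed) * 1.5,
            "ota": ota if ota is not None else np.log10(np.asarray(n_transcribed) + 1.0),
        }
    )


class TestCorrelation:
    def test_identical_metric_gives_rho_one(self):
        rates = np.arange(10, dtype=float)
        m = metrics_frame(10, rates)
        corr = L.correlate_with_recombination(m, uniform_map(10, rates))
        row = corr[corr["metric"] == "n_transcribed"].iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_negated_metric_gives_rho_minus_one(self):
        vals = np.arange(10, dtype=float)
        m = metrics_frame(10, vals)
        corr = L.correlate_with_recombination(m, uniform_map(10, -vals + 100))
        assert corr[corr["metric"] == "n_transcribed"]["rho"].iloc[0] == pytest.approx(
            -1.0
        )

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        vals = rng.integers(0, 20, 10).astype(float)
        rates = rng.uniform(0, 5, 10)
        m = metrics_frame(10, vals)
        corr = L.correlate_with_recombination(m, uniform_map(10, rates))
        rho = corr[corr["metric"] == "n_transcribed"]["rho"].iloc[0]
        rx = pd.Series(vals).rank().to_numpy()
        ry = pd.Series(rates).rank().to_numpy()
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_windows_rejected(self):
        m = metrics_frame(2, [1.0, 2.0])
        with pytest.raises(ValidationError):
            L.correlate_with_recombination(m, uniform_map(2, [1.0, 2.0]))


class TestRegression:
    def test_exact_linear_fixture_matches_normal_equations(self):
        n = [1.0, 2.0, 3.0, 4.0]
        kb = [0.5, 0.1, 0.9, 0.4]
        ota = [3.0, 3.5, 2.5, 4.0]
        m = metrics_frame(4, n, kb=kb, ota=ota)
        rate = 1.0 + 2.0 * np.asarray(n) - 0.5 * np.asarray(kb) + 0.25 * np.asarray(ota)
        reg = L.multiple_regression(m, uniform_map(4, rate), min_windows=4)
        X = np.column_stack([np.ones(4), n, kb, ota])
        oracle, *_ = np.linalg.lstsq(X, rate, rcond=None)
        np.testing.assert_allclose(reg["coefficient"].to_numpy(), oracle, atol=1e-8)

    def test_planted_single_predictor_recovered(self):
        rng = np.random.default_rng(2)
        nwin = 60
        n_t = rng.integers(0, 12, nwin).astype(float)
        m = metrics_frame(nwin, n_t, kb=rng.uniform(0, 5, nwin), ota=rng.normal(3, 1, nwin))
        # rate depends on the gene count only, plus faint noise so the
        # residual variance (and hence the t-tests) are well defined
        rate = 0.5 + 0.4 * n_t + rng.normal(0, 0.05, nwin)
        reg = L.multiple_regression(m, uniform_map(nwin, rate))
        by = reg.set_index("predictor")
        assert by.loc["n_transcribed", "p"] < 1e-10
        assert by.loc["n_transcribed", "coefficient"] == pytest.approx(0.4, abs=0.05)
        assert by.loc["kb_transcribed", "p"] > 0.01
        assert by.loc["ota", "p"] > 0.01

    def test_constant_rate_yields_null_slopes(self):
        rng = np.random.default_rng(4)
        m = metrics_frame(
            20,
            rng.integers(0, 9, 20).astype(float),
            kb=rng.uniform(0, 5, 20),
            ota=rng.normal(3, 1, 20),
        )
        reg = L.multiple_regression(m, uniform_map(20, np.full(20, 2.0)))
        by = reg.set_index("predictor")
        for name in ("n_transcribed", "kb_transcribed", "ota"):
            assert by.loc[name, "coefficient"] == pytest.approx(0.0, abs=1e-10)
            assert by.loc[name, "p"] == pytest.approx(1.0)

    def test_constant_predictor_named_in_error(self):
        m = metrics_frame(12, np.zeros(12))
        m["ota"] = np.nan  # undefined everywhere -> constant after imputation
        with pytest.raises(ValidationError, match="(?i)n_transcribed|ota"):
            L.multiple_regression(m, uniform_map(12, np.arange(12.0)))

    def test_undefined_ota_imputed_and_counted(self):
        rng = np.random.default_rng(7)
        m = metrics_frame(
            20,
            rng.integers(0, 9, 20).astype(float),
            kb=rng.uniform(0, 5, 20),
            ota=rng.normal(3, 1, 20),
        )
        m.loc[3, "ota"] = np.nan
        reg = L.multiple_regression(m, uniform_map(20, rng.uniform(1, 4, 20)))
        assert reg.attrs["n_ota_imputed"] == 1


class TestZeroVsNonzero:
    def test_disjoint_rate_ranges_are_significant(self):
        n_t = np.array([0] * 20 + [3] * 20, dtype=float)
        rates = np.concatenate([np.linspace(0, 1, 20), np.linspace(5, 6, 20)])
        m = metrics_frame(40, n_t)
        u, p = L.zero_vs_nonzero_transcription(m, uniform_map(40, rates))
        assert p < 1e-6

    def test_empty_group_rejected(self):
        m = metrics_frame(10, np.ones(10))
        with pytest.raises(ValidationError):
            L.zero_vs_nonzero_transcription(m, uniform_map(10, np.arange(10.0)))
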