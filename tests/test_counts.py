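import numpy as np
import pandas as pd
import pytest

from trdecomp import counts as gc
from trdecomp import synthetic as syn


@pytest.fixture
def genes_two_strands() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": ["tp", "tm"],
            "gene_id": ["gp", "gm"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "start": [10_000, 100_000],
            "end": [50_001, 140_000],
            "tss": [10_000, 139_999],
            "tes": [50_000, 100_000],
        }
    )


class TestAnnotationIO:
    def test_gtf_coordinates_converted(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\ttranscript\t1001\t2000\t.\t-\t.\tgene_id "g2"; transcript_id "t2";\n'
        )
        df = gc.load_annotation(str(gtf)).set_index("transcript_id")
        assert df.loc["t1", ["start", "end", "tss", "tes"]].tolist() == [1000, 2000, 1000, 1999]
        assert df.loc["t2", ["tss", "tes"]].tolist() == [1999, 1000]

    def test_bed_strand_flip(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t1000\t2000\tx\t0\t-\n")
        df = gc.load_annotation(str(bed), fmt="BED12")
        assert df.loc[0, "tss"] == 1999 and df.loc[0, "tes"] == 1000

    def test_unknown_strand_rejected(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t1000\t2000\tx\t0\t.\n")
        with pytest.raises(ValueError, match="strand"):
            gc.load_annotation(str(bed), fmt="BED12")

    def test_empty_file_warns(self, tmp_path, caplog):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        with caplog.at_level("WARNING"):
            df = gc.load_annotation(str(gtf))
        assert df.empty and "empty" in caplog.text


class TestWindows:
    def test_window_coordinates(self, genes_two_strands):
        win = gc.build_windows(genes_two_strands, with_gb=True)
        w = win.set_index(["gene_id", "site"])
        assert (w.loc[("gp", "TSS"), ["start", "end"]] == [9250, 10750]).all()
        assert (w.loc[("gp", "TES"), ["start", "end"]] == [50_000, 51_500]).all()
        # minus strand: TSS symmetric, TES extends downstream (lower coords)
        assert (w.loc[("gm", "TSS"), ["start", "end"]] == [139_249, 140_749]).all()
        assert (w.loc[("gm", "TES"), ["start", "end"]] == [98_501, 100_001]).all()
        # GB strictly between the windows, in transcription direction
        assert (w.loc[("gp", "GB"), ["start", "end"]] == [10_750, 50_000]).all()
        assert (w.loc[("gm", "GB"), ["start", "end"]] == [100_001, 139_249]).all()

    def test_minus_strand_tss_window_is_strand_invariant(self):
        g = pd.DataFrame(
            {
                "transcript_id": ["a", "b"], "gene_id": ["a", "b"],
                "chrom": "chr1", "strand": ["+", "-"],
                "start": [10_000, 5_000], "end": [20_000, 10_001],
                "tss": [10_000, 10_000], "tes": [19_999, 5_000],
            }
        )
        win = gc.build_windows(g).set_index(["gene_id", "site"])
        assert (
            win.loc[("a", "TSS"), ["start", "end"]].tolist()
            == win.loc[("b", "TSS"), ["start", "end"]].tolist()
            == [9250, 10750]
        )

    def test_lengths_and_clipping(self):
        g = pd.DataFrame(
            {
                "transcript_id": ["t"], "gene_id": ["t"], "chrom": ["chr1"],
                "strand": ["+"], "start": [100], "end": [5000],
                "tss": [100], "tes": [4999],
            }
        )
        win = gc.build_windows(g)
        tssw = win[win["site"] == "TSS"].iloc[0]
        assert tssw["start"] == 0 and tssw["clipped"]
        tesw = win[win["site"] == "TES"].iloc[0]
        assert tesw["end"] - tesw["start"] == 1500 and not tesw["clipped"]

    def test_gb_empty_when_windows_touch(self):
        g = pd.DataFrame(
            {
                "transcript_id": ["t"], "gene_id": ["t"], "chrom": ["chr1"],
                "strand": ["+"], "start": [10_000], "end": [10_700],
                "tss": [10_000], "tes": [10_699],
            }
        )
        win = gc.build_windows(g, with_gb=True)
        assert "GB" not in set(win["site"])


def _reads(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


class TestCountSites:
    def test_half_open_window_bounds(self, genes_two_strands):
        win = gc.build_windows(genes_two_strands)
        reads = _reads(
            [
                ("chr1", 9250, 9300, "in_lo", 0, "+"),
                ("chr1", 10750, 10800, "out_hi", 0, "+"),
                ("chr1", 10749, 10799, "in_hi", 0, "+"),
            ]
        )
        c = gc.count_sites(reads, win).set_index(["gene_id", "site"])["count"]
        assert c[("gp", "TSS")] == 2
        assert c.sum() == 2

    def test_five_prime_is_strand_aware(self, genes_two_strands):
        win = gc.build_windows(genes_two_strands)
        # minus-strand read: 5' end = end - 1
        reads = _reads([("chr1", 139_000, 139_250, "r", 0, "-")])
        c = gc.count_sites(reads, win).set_index(["gene_id", "site"])["count"]
        assert c[("gm", "TSS")] == 1  # 139249 is the window start, inclusive

    def test_overlap_mode_counts_partial_overlap(self, genes_two_strands):
        win = gc.build_windows(genes_two_strands)
        reads = _reads([("chr1", 9200, 9260, "r", 0, "+")])  # 5' outside, body inside
        five = gc.count_sites(reads, win).set_index(["gene_id", "site"])["count"]
        ov = gc.count_sites(reads, win, mode="overlap").set_index(["gene_id", "site"])["count"]
        assert five[("gp", "TSS")] == 0 and ov[("gp", "TSS")] == 1

    def test_library_size_counts_unannotated_chroms(self, genes_two_strands, caplog):
        win = gc.build_windows(genes_two_strands)
        reads = _reads(
            [("chr1", 9300, 9350, "a", 0, "+"), ("chrUn", 0, 50, "b", 0, "+")]
        )
        with caplog.at_level("WARNING"):
            c = gc.count_sites(reads, win)
        assert c["library_size_millions"].iloc[0] == 2 / 1e6
        assert c["count"].sum() == 1 and "chrUn" in caplog.text

    def test_input_order_invariance(self, genes_two_strands):
        win = gc.build_windows(genes_two_strands)
        rng = np.random.default_rng(0)
        reads = _reads(
            [("chr1", int(p), int(p) + 50, f"r{i}", 0, "+")
             for i, p in enumerate(rng.integers(9000, 52_000, 200))]
        )
        a = gc.count_sites(reads, win)["count"]
        b = gc.count_sites(reads.sample(frac=1, random_state=1), win)["count"]
        assert (a == b).all()


def test_roundtrip_simulated_reads_reproduce_counts():
    cfg = syn.SimConfig(seed=21)
    specs, traj = syn.make_scenarios(10, cfg)
    tbl, _ = syn.simulate_counts(specs, traj, cfg)
    genes = syn.make_gene_models(tbl["gene_id"].unique())
    win = gc.build_windows(genes)
    reads = syn.simulate_reads(tbl, win, seed=2)
    rec = gc.count_design(
        {key: sub for key, sub in reads.groupby(["condition", "replicate"])}, win
    )
    merged = tbl.merge(
        rec, on=["gene_id", "condition", "replicate", "site"], suffixes=("_t", "_r")
    )
    assert len(merged) == len(tbl)
    assert (merged["count_t"] == merged["count_r"]).all()


class TestBinsAndQC:
    def test_bin_assignment_and_conservation(self):
        sizes = {"chr1": 25_000}
        reads = _reads(
            [("chr1", 0, 50, "a", 0, "+"), ("chr1", 9_999, 10_049, "b", 0, "+"),
             ("chr1", 10_000, 10_050, "c", 0, "+")]
        )
        bins = gc.bin_counts(reads, sizes)
        assert bins[("chr1", 0)] == 2 and bins[("chr1", 10_000)] == 1
        assert bins.sum() == len(reads)
        assert len(bins) == 3  # ceil(25000/10000) bins tile the chromosome

    def test_missing_chrom_size_errors(self):
        with pytest.raises(KeyError, match="chr2"):
            gc.bin_counts(_reads([("chr2", 0, 50, "a", 0, "+")]), {"chr1": 1000})

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=10_000)
        bins = pd.DataFrame(
            {"s1": base, "s2": 2 * base, "noise": rng.poisson(50, size=10_000)}
        )
        r = gc.correlation_matrix(bins)
        assert np.allclose(np.diag(r), 1)
        assert np.allclose(r, r.T)
        assert 0.99 < r.loc["s1", "s2"] < 1  # scaled copy: near-perfect in log space
        assert abs(r.loc["s1", "noise"]) < 0.05

    def test_zero_variance_sample_reported_missing(self, caplog):
        bins = pd.DataFrame({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            r = gc.correlation_matrix(bins)
        assert np.isnan(r.loc["a", "b"]) and r.loc["a", "a"] == 1

    def test_detect_genes_flank_boundaries(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "start": [10_000], "end": [20_000]}
        )
        inside = _reads([("chr1", 15_000, 15_050, "r", 0, "+")])
        near = _reads([("chr1", 9_000, 9_050, "r", 0, "+")])  # at flank start
        beyond = _reads([("chr1", 8_999, 9_049, "r", 0, "+")])  # outside flank
        assert gc.detect_genes(inside, genes)["detected"].iloc[0]
        assert gc.detect_genes(near, genes)["detected"].iloc[0]
        assert not gc.detect_genes(beyond, genes)["detected"].iloc[0]

    def test_cumulative_read_share(self, caplog):
        curve = gc.cumulative_read_share([10, 80, 10])
        assert curve["cumulative_fraction"].tolist() == pytest.approx([0.8, 0.9, 1.0])
        assert curve["cumulative_fraction"].is_monotonic_increasing
        uniform = gc.cumulative_read_share([5] * 4)
        assert np.allclose(uniform["cumulative_fraction"], uniform["rank_fraction"])
        assert gc.cumulative_read_share([7])["cumulative_fraction"].tolist() == [1.0]
        with caplog.at_level("WARNING"):
            assert gc.cumulative_read_share([0, 0]).empty


def test_representative_transcript_selection():
    counts = pd.DataFrame(
        {
            "transcript_id": ["t1", "t1", "t2", "t2"],
            "gene_id": "g",
            "site": ["TSS", "TES"] * 2,
            "start": [0, 5000, 0, 4000],
            "end": [1500, 6500, 1500, 5500],
            "count": [10, 5, 10, 4],
            "library_size_millions": 1.0,
        }
    )
    kept = gc.select_representative_transcripts(counts)
    assert set(kept["transcript_id"]) == {"t1"}  # highest pooled TSS+TES count
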