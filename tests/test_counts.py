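import numpy as np
import pandas as pd
import pysam
import pytest

from dmsort import counts as cm
from dmsort import design as dm
from dmsort import simulate as sim
from dmsort.counts import UNEXPECTED, WILDTYPE, DesignIndex, VariantCountTable


@pytest.fixture(scope="module")
def lib(usage):
    lib = dm.enumerate_missense("MAKLHG", (2, 6), usage, rng_seed=1, mode="argmax")
    return dm.add_synonymous_controls(lib, [3, 4], usage, rng_seed=2)


@pytest.fixture(scope="module")
def index(lib):
    return DesignIndex.from_design(lib)


def make_read(reference, start=0, seq=None, cigar=None, name="r1"):
    header = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "ref", "LN": len(reference)}]}
    )
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_id = 0
    read.reference_start = start
    read.query_sequence = seq if seq is not None else reference[start:]
    read.cigarstring = cigar or f"{len(read.query_sequence)}M"
    read.mapping_quality = 60
    return read


class TestExtractProgrammedCodon:
    def test_reference_identical_read_is_wildtype(self, index):
        read = make_read(index.reference)
        assert cm.extract_programmed_codon(read, index) == WILDTYPE

    def test_single_programmed_codon_yields_that_variant(self, lib, index):
        v = lib.missense[0]
        s = 3 * (v.position - 1)
        seq = index.reference[:s] + v.mut_codon + index.reference[s + 3 :]
        read = make_read(index.reference, seq=seq)
        assert cm.extract_programmed_codon(read, index) == v.variant_id

    def test_two_programmed_codons_are_unexpected(self, lib, index):
        v1 = next(v for v in lib.missense if v.position == 2)
        v2 = next(v for v in lib.missense if v.position == 4)
        seq = list(index.reference)
        seq[3 : 6] = v1.mut_codon
        seq[9 : 12] = v2.mut_codon
        read = make_read(index.reference, seq="".join(seq))
        assert cm.extract_programmed_codon(read, index) == UNEXPECTED

    def test_non_programmed_codon_is_unexpected(self, lib, index):
        v = lib.missense[0]
        s = 3 * (v.position - 1)
        # a codon for the same target residue that the design did not program
        other = next(
            c
            for c in dm.AA_TO_CODONS[v.mut_aa]
            if c not in index.programmed[v.position] and c != index.wt_codon[v.position]
        )
        seq = index.reference[:s] + other + index.reference[s + 3 :]
        read = make_read(index.reference, seq=seq)
        assert cm.extract_programmed_codon(read, index) == UNEXPECTED

    def test_deletion_inside_designed_codon_is_unexpected(self, index):
        seq = index.reference[:4] + index.reference[5:]  # drop one base of codon 2
        read = make_read(index.reference, seq=seq, cigar="4M1D" + f"{len(seq) - 4}M")
        assert cm.extract_programmed_codon(read, index) == UNEXPECTED

    def test_read_covering_no_designed_codon_is_skipped(self, index):
        read = make_read(index.reference, start=0, seq=index.reference[:3])  # codon 1 only
        assert cm.extract_programmed_codon(read, index) is None

    def test_unmapped_read_is_skipped(self, index):
        read = make_read(index.reference)
        read.is_unmapped = True
        assert cm.extract_programmed_codon(read, index) is None


class TestClassifySam:
    def test_sam_file_roundtrip(self, lib, index, tmp_path):
        v = lib.missense[0]
        s = 3 * (v.position - 1)
        mutant = index.reference[:s] + v.mut_codon + index.reference[s + 3 :]
        path = tmp_path / "sample.sam"
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "ref", "LN": len(index.reference)}]}
        )
        with pysam.AlignmentFile(path, "w", header=header) as out:
            out.write(make_read(index.reference, name="wt"))
            out.write(make_read(index.reference, seq=mutant, name="mut"))
        calls, skipped = cm.classify_sam(path, index)
        assert calls == [WILDTYPE, v.variant_id]
        assert skipped == 0


class TestTabulate:
    @pytest.fixture()
    def spec(self):
        return sim.SortSpec("surface", ["negative", "low", "up", "high"], (0.25, 0.5, 0.75), 1000, 2)

    def test_empty_input_gives_zero_filled_grid(self, lib, spec):
        calls = pd.DataFrame({"replicate": [], "bin": [], "call": []})
        table = cm.tabulate(calls, lib, spec)
        assert len(table.df) == len(lib.variants) * 4 * 2
        assert (table.df["count"] == 0).all()
        assert (table.unexpected["unexpected_count"] == 0).all()

    def test_three_calls_count_three_in_one_cell(self, lib, spec):
        vid = lib.missense[0].variant_id
        calls = pd.DataFrame(
            {"replicate": [1, 1, 1], "bin": ["up"] * 3, "call": [vid] * 3}
        )
        table = cm.tabulate(calls, lib, spec)
        cell = table.df.query("replicate == 1 and bin == 'up' and variant == @vid")
        assert cell["count"].item() == 3
        assert table.df["count"].sum() == 3

    def test_unknown_bin_label_is_a_manifest_error(self, lib, spec):
        calls = pd.DataFrame({"replicate": [1], "bin": ["mystery"], "call": [WILDTYPE]})
        with pytest.raises(cm.ManifestError):
            cm.tabulate(calls, lib, spec)

    def test_tabulated_per_read_calls_reproduce_simulator_counts(self, lib):
        spec = sim.SortSpec("surface", ["lo", "hi"], (0.5,), 2000, 2)
        exp = sim.simulate_experiment(lib, sim.surface_model(), spec,
                                      depth_per_bin=500, unexpected_rate=0.01, seed=9)
        records = []
        for row in exp.counts.itertuples():
            records.extend(
                {"replicate": row.replicate, "bin": row.bin, "call": row.variant}
                for _ in range(row.count)
            )
        for row in exp.unexpected.itertuples():
            records.extend(
                {"replicate": row.replicate, "bin": row.bin, "call": UNEXPECTED}
                for _ in range(row.unexpected_count)
            )
        table = cm.tabulate(pd.DataFrame(records), lib, spec)
        key = ["replicate", "bin", "variant"]
        got = table.df.set_index(key)["count"].sort_index()
        want = exp.counts.set_index(key)["count"].sort_index()
        pd.testing.assert_series_equal(got, want)
        got_u = table.unexpected.set_index(["replicate", "bin"])["unexpected_count"].sort_index()
        want_u = exp.unexpected.set_index(["replicate", "bin"])["unexpected_count"].sort_index()
        pd.testing.assert_series_equal(got_u, want_u)


class TestRatiosAndCoverage:
    def test_ratio_arithmetic(self, lib):
        spec = sim.SortSpec("surface", ["lo", "hi"], (0.5,), 100, 1)
        vid = lib.missense[0].variant_id
        calls = pd.DataFrame(
            {"replicate": [1] * 100, "bin": ["lo"] * 100,
             "call": [vid] * 90 + [UNEXPECTED] * 10}
        )
        ratios = cm.unexpected_expected_ratio(cm.tabulate(calls, lib, spec))
        lo = ratios.query("bin == 'lo'")
        assert lo["ratio"].item() == pytest.approx(10 / 90)
        assert np.isnan(ratios.query("bin == 'hi'")["ratio"].item())  # zero expected

    def test_simulated_ratio_matches_flip_probability(self, small_library):
        rate = 0.02
        exp = sim.simulate_experiment(
            small_library, sim.surface_model(), sim.surface_sort_spec(),
            depth_per_bin=100 * len(small_library.variants),
            unexpected_rate=rate, seed=5,
        )
        ratios = cm.unexpected_expected_ratio(VariantCountTable.from_simulation(exp))
        assert abs(ratios["ratio"].mean() - rate / (1 - rate)) < 0.01

    def test_all_zero_table_detects_nothing(self, lib):
        spec = sim.SortSpec("surface", ["lo", "hi"], (0.5,), 100, 1)
        calls = pd.DataFrame({"replicate": [], "bin": [], "call": []})
        report = cm.coverage_report(cm.tabulate(calls, lib, spec), lib)
        assert report["detected_fraction"] == 0.0

    def test_uniform_counts_above_threshold(self, lib):
        spec = sim.SortSpec("surface", ["lo"], (), 100, 1)
        df = pd.DataFrame(
            {
                "axis": "surface", "replicate": 1, "bin": "lo",
                "variant": [v.variant_id for v in lib.variants],
                "position": [v.position for v in lib.variants],
                "wt_aa": [v.wt_aa for v in lib.variants],
                "mut_aa": [v.mut_aa for v in lib.variants],
                "mut_codon": [v.mut_codon for v in lib.variants],
                "kind": [v.kind for v in lib.variants],
                "count": 21,
            }
        )
        table = VariantCountTable(df, pd.DataFrame(
            {"axis": ["surface"], "replicate": [1], "bin": ["lo"], "unexpected_count": [0]}
        ))
        report = cm.coverage_report(table, lib, threshold=20)
        assert report["above_threshold_fraction"] == 1.0

    def test_simulated_deep_library_is_nearly_fully_detected(self, surface_experiment, small_library):
        report = cm.coverage_report(
            VariantCountTable.from_simulation(surface_experiment), small_library
        )
        assert report["detected_fraction"] >= 0.99
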