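"""I/O round-trips, coordinate conventions, and probe-context assignment."""

import json

import numpy as np
import pandas as pd
import pytest

from metamethyl.annotation_io import (
    Blacklist,
    GenomicTrack,
    MethylationDataset,
    SampleRecord,
    annotate_probes,
    apply_blacklist,
    map_region_to_genes,
    read_bed_track,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_outputs,
    write_probe_annotation,
    write_sample_sheet,
)
from metamethyl.epigenetic_clock import ClockModel, predict_age


class TestBetaMatrix:
    def test_round_trip_identity(self, tmp_path):
        beta = pd.DataFrame(
            {"s1": [0.1, 0.5, 0.9], "s2": [0.2, np.nan, 0.8]},
            index=["cg1", "cg2", "cg3"],
        )
        path = tmp_path / "beta.tsv"
        write_beta_matrix(beta, path)
        back = read_beta_matrix(path)
        pd.testing.assert_frame_equal(back, beta, check_names=False)

    def test_value_above_one_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ncg1\t1.2\n")
        with pytest.raises(ValueError, match="cg1"):
            read_beta_matrix(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ns2\nxcg\tabc\n")
        with pytest.raises(ValueError, match="s1"):
            read_beta_matrix(path)

    def test_duplicate_probe_named(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\ncg1\t0.5\ncg1\t0.6\n")
        with pytest.raises(ValueError, match="cg1"):
            read_beta_matrix(path)

    def test_header_only_file_is_valid_empty_matrix(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("probe_id\ts1\ts2\n")
        assert read_beta_matrix(path).shape == (0, 2)


class TestSampleSheet:
    def test_round_trip_and_shared_subject(self, tmp_path):
        records = [
            SampleRecord("a", "subj1", 25.0, sex="M", bmi=24.2),
            SampleRecord("b", "subj1", 25.1, sex="M"),
        ]
        path = tmp_path / "sheet.csv"
        write_sample_sheet(records, path)
        back = read_sample_sheet(path)
        assert [r.subject_id for r in back] == ["subj1", "subj1"]
        assert back[0].bmi == 24.2
        assert back[1].bmi is None  # missing stays missing

    def test_missing_age_column_reported(self, tmp_path):
        path = tmp_path / "sheet.csv"
        path.write_text("sample_id,subject_id\na,u1\n")
        with pytest.raises(ValueError, match="age"):
            read_sample_sheet(path)

    def test_fractional_age_parses(self, tmp_path):
        path = tmp_path / "sheet.csv"
        path.write_text("sample_id,subject_id,age\na,u1,45.4\n")
        assert read_sample_sheet(path)[0].age == 45.4

    def test_non_positive_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            SampleRecord("a", "u1", 0.0)


class TestBlacklist:
    @pytest.mark.parametrize(
        "blacklist, expected",
        [
            (frozenset({"cg2", "cg4"}), ["cg1", "cg3", "cg5"]),
            (frozenset(), ["cg1", "cg2", "cg3", "cg4", "cg5"]),
            (frozenset({f"cg{i}" for i in range(1, 9)}), []),
        ],
    )
    def test_set_difference_preserves_order(self, blacklist, expected):
        probes = [f"cg{i}" for i in range(1, 6)]
        beta = pd.DataFrame({"s1": np.linspace(0.1, 0.5, 5)}, index=probes)
        ds = MethylationDataset("d", beta, [SampleRecord("s1", "u1", 30.0)])
        out = apply_blacklist(ds, Blacklist(blacklist))
        assert list(out.beta.index) == expected


class TestBedTrack:
    def test_point_containment_and_half_open_end(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t100\t200\tEnh\n")
        track = read_bed_track(path, "states")
        # 1-based position 150 is 0-based 149: inside
        assert track.query_point("chr1", 149)[0][2] == "Enh"
        # 1-based position 200 is 0-based 199: last base of [100, 200)
        assert track.query_point("chr1", 199)
        # 1-based position 201 is 0-based 200: outside
        assert not track.query_point("chr1", 200)

    def test_inverted_interval_reports_line(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t100\t200\n" "chr1\t500\t400\n")
        with pytest.raises(ValueError, match="2"):
            read_bed_track(path, "x")

    def test_empty_file_all_queries_miss(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("")
        track = read_bed_track(path, "x")
        assert len(track) == 0
        assert track.query_point("chr1", 100) == []


class TestAnnotateProbes:
    def probes(self, positions):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": positions},
            index=[f"cg{i}" for i in range(len(positions))],
        )

    @pytest.mark.parametrize(
        "pos, context",
        [
            (1_200, "island"),  # inside [1000, 1500)
            (2_500, "shore"),  # 1001 bp past the island end
            (4_499, "shelf"),  # 3000 bp past the island end
            (11_500, "open_sea"),  # 10 001 bp away
            (3_499, "shore"),  # exactly 2000 bp: boundary belongs to shore
            (5_499, "shelf"),  # exactly 4000 bp: boundary belongs to shelf
        ],
    )
    def test_island_context_distance_bands(self, toy_tracks, pos, context):
        ann = annotate_probes(
            self.probes([pos]),
            toy_tracks["islands"],
            toy_tracks["states"],
            {"ctcf": toy_tracks["ctcf"], "ezh2": toy_tracks["ezh2"]},
            {},
        )
        assert ann["island_context"].iloc[0] == context

    def test_overlapping_states_smallest_start_wins(self, toy_tracks):
        ann = annotate_probes(
            self.probes([1_000]),
            toy_tracks["islands"],
            toy_tracks["states"],
            {},
            {},
        )
        # position is inside both Enh [0,5000) and TssA [900,2000)
        assert ann["chromatin_state"].iloc[0] == "Enh"

    def test_unknown_chromosome_defaults_quiescent_flagged(self, toy_tracks):
        probes = pd.DataFrame({"chrom": ["chrX"], "pos": [100]}, index=["cgX"])
        ann = annotate_probes(probes, toy_tracks["islands"], toy_tracks["states"], {}, {})
        assert ann["chromatin_state"].iloc[0] == "Quies"
        assert bool(ann["state_imputed"].iloc[0])

    def test_contexts_partition_probes(self, signal_sim):
        ann = signal_sim["annotation"]
        located = ann[ann["chrom"].notna()]
        assert located["island_context"].isin(
            ["island", "shore", "shelf", "open_sea"]
        ).all()
        assert located["island_context"].notna().all()


class TestRegionGeneMap:
    def test_union_empty_and_enhancer_link(self):
        ann = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [100, 200, 5_000],
                "genes": [("A",), ("A", "B"), ("DIST",)],
            },
            index=["cg1", "cg2", "cg3"],
        )
        assert map_region_to_genes("chr1", 0, 300, ann) == {"A", "B"}
        assert map_region_to_genes("chr1", 1_000, 2_000, ann) == set()
        # cg3 is intergenic but enhancer-linked to a distant gene
        assert map_region_to_genes("chr1", 4_900, 5_100, ann) == {"DIST"}


class TestProbeAnnotationRoundTrip:
    def test_one_probe_position_convention(self, tmp_path):
        ann = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "pos": [999],  # 0-based internal
                "island_context": ["island"],
                "chromatin_state": ["TssA"],
                "ctcf": [0],
                "ezh2": [1],
                "genes": [("A", "B")],
                "state_imputed": [False],
            },
            index=pd.Index(["cg1"], name="probe_id"),
        )
        path = tmp_path / "ann.tsv"
        write_probe_annotation(ann, path)
        on_disk = pd.read_csv(path, sep="\t")
        assert on_disk["pos"].iloc[0] == 1_000  # 1-based manifest convention
        back = read_probe_annotation(path)
        assert back["pos"].iloc[0] == 999
        assert back["genes"].iloc[0] == ("A", "B")


class TestWriteOutputs:
    def _dmrs(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [99],
                "end": [301],
                "n_cpgs": [3],
                "probe_ids": [("cg1", "cg2", "cg3")],
                "mean_b": [-0.001],
                "direction": ["hypo"],
                "fisher_p": [1e-5],
                "stouffer_p": [1e-4],
                "hmfdr": [1e-3],
                "genes": [{"A"}],
            }
        )

    def test_dmr_bed_uses_zero_based_start(self, tmp_path):
        written = write_outputs(tmp_path, dmrs=self._dmrs())
        lines = written["dmrs_bed"].read_text().splitlines()
        chrom, start, end, name, score, strand = lines[0].split("\t")
        assert (chrom, start, end, strand) == ("chr1", "99", "301", ".")
        assert float(score) == pytest.approx(4.0)  # -log10 stouffer

    def test_empty_dmr_set_valid_bed(self, tmp_path):
        written = write_outputs(tmp_path, dmrs=self._dmrs().iloc[:0])
        assert written["dmrs_bed"].read_text() == ""

    def test_clock_model_json_round_trip(self, tmp_path):
        model = ClockModel(
            probe_ids=["cg1", "cg2"],
            coefficients=np.array([0.3, -0.2]),
            intercept=0.15,
            adult_age=20.0,
            calibration_reference={"weights": [0.4, 0.2, 0.4]},
            probe_means=np.array([0.5, 0.6]),
        )
        written = write_outputs(tmp_path, clock_model=model)
        back = ClockModel.from_dict(json.loads(written["clock_model"].read_text()))
        beta = pd.DataFrame({"s1": [0.52, 0.61]}, index=["cg1", "cg2"])
        ds = MethylationDataset("d", beta, [SampleRecord("s1", "u1", 33.0)])
        pd.testing.assert_series_equal(predict_age(model, ds), predict_age(back, ds))
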