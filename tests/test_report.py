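import pytest

from guidefinder import (
    ExonSet,
    PatternConfig,
    PlantSpec,
    load_exons,
    make_synthetic_genome,
    run_pipeline,
)
from guidefinder.report import (
    load_genome,
    load_query,
    write_candidates_fasta,
    write_full_tsv,
    write_track_bed,
)
from guidefinder.sequence import revcomp

from conftest import PROTO


@pytest.fixture(scope="module")
def pipeline_instance():
    """Fixtures genome whose query contains the planted protospacer + PAM."""
    plants = [
        PlantSpec(PROTO, frozenset(), "CGG", "+", "chr1", 150, nearest_exon_gap=0),
        PlantSpec(PROTO, frozenset({1, 2, 9, 10}), "TGG", "-", "chr1", 900, nearest_exon_gap=300),
        PlantSpec(PROTO, frozenset({3, 15}), "AGG", "+", "chr2", 500),
    ]
    return make_synthetic_genome(seed=2, n_chroms=2, chrom_length=2000, plants=plants)


@pytest.fixture(scope="module")
def pipeline_report(pipeline_instance):
    inst = pipeline_instance
    query = inst.genome["chr1"][100:200]  # spans the perfect plant
    cfg = PatternConfig()
    return run_pipeline(query, inst.genome, ExonSet(inst.exons), cfg)


class TestLoaders:
    def test_raw_sequence(self):
        assert load_query("acg t\nTT") == "acgtTT"

    def test_fasta_first_record(self, tmp_path):
        p = tmp_path / "q.fa"
        p.write_text(">q1 description\nACGT\nACGT\n>q2\nTTTT\n")
        assert load_query(p) == "ACGTACGT"

    def test_raw_file(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text("ACGT\nACGT\n")
        assert load_query(p) == "ACGTACGT"

    def test_genome_names_cut_at_whitespace(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1 assembly x\nACGTACGT\n>chr2\nTTTTAAAA\n")
        genome = load_genome(p)
        assert set(genome) == {"chr1", "chr2"}
        assert genome["chr1"] == "ACGTACGT"


class TestPipeline:
    def test_truth_recovery(self, pipeline_instance, pipeline_report):
        report = pipeline_report
        site = next(s for s in report.sites if s.candidate.protospacer == PROTO)
        assert site.on_target is not None and site.on_target.start == 150
        starts = {(h.chrom, h.start) for h, _ in site.off_targets}
        assert ("chr1", 900) in starts
        assert ("chr2", 500) in starts
        dists = {h.start: a.distance for h, a in site.off_targets}
        assert dists[900] == 300
        assert dists[500] is None  # no exon on chr2

    def test_every_candidate_ranked_once(self, pipeline_report):
        labels = [s.candidate.site_id for s in pipeline_report.sites]
        assert labels == [f"T{i}" for i in range(1, len(labels) + 1)]
        assert [s.rank for s in pipeline_report.sites] == list(range(1, len(labels) + 1))

    def test_zero_candidate_query(self, pipeline_instance):
        report = run_pipeline("A" * 40, pipeline_instance.genome, None, PatternConfig())
        assert report.sites == []

    def test_invalid_query_stage_tagged(self, pipeline_instance):
        with pytest.raises(RuntimeError, match="discovery"):
            run_pipeline("ACGT!!" + "A" * 30, pipeline_instance.genome, None, PatternConfig())

    def test_empty_genome_stage_tagged(self):
        query = PROTO + "CGG"
        with pytest.raises(RuntimeError, match="index"):
            run_pipeline(query, {}, None, PatternConfig())


class TestWriters:
    def test_candidates_fasta_round_trip(self, pipeline_report, tmp_path):
        path = tmp_path / "cand.fasta"
        write_candidates_fasta(pipeline_report.sites, path)
        records = {}
        header = None
        for line in path.read_text().splitlines():
            if line.startswith(">"):
                header = line[1:]
                records[header] = ""
            else:
                records[header] += line
        assert len(records) == len(pipeline_report.sites)
        for site in pipeline_report.sites:
            c = site.candidate
            header = f"{c.site_id}|{c.query_start + 1}-{c.query_end}|{c.strand}"
            assert records[header] == c.sequence
            assert len(records[header]) == 23

    def test_empty_fasta(self, tmp_path):
        path = tmp_path / "empty.fasta"
        write_candidates_fasta([], path)
        assert path.read_text() == ""

    def test_tsv_schema_and_rendering(self, pipeline_report, tmp_path):
        path = tmp_path / "results.tsv"
        write_full_tsv(pipeline_report, path)
        site_rows, ot_rows = [], []
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            (site_rows if fields[0] == "site" else ot_rows).append(fields)
        assert len(site_rows) == len(pipeline_report.sites)
        assert {len(r) for r in site_rows} == {11}
        if ot_rows:
            assert {len(r) for r in ot_rows} == {12}
        # 4-decimal score rendering
        for r in site_rows:
            assert len(r[7].split(".")[1]) == 4
        # mismatch lowercase rendering: lowercase count equals mismatch count
        for r in ot_rows:
            seq, n_mm = r[5], int(r[6])
            assert sum(1 for ch in seq if ch.islower()) == n_mm

    def test_tsv_mismatch_positions_lowercased(self, pipeline_report, tmp_path):
        site = next(s for s in pipeline_report.sites if s.candidate.protospacer == PROTO)
        hit, _ = next((h, a) for h, a in site.off_targets if h.start == 500)
        path = tmp_path / "results.tsv"
        write_full_tsv(pipeline_report, path)
        row = next(
            line.split("\t")
            for line in path.read_text().splitlines()
            if line.startswith("offtarget\tchr2\t501\t")
        )
        seq = row[5]
        lowered = {i + 1 for i, ch in enumerate(seq[:20]) if ch.islower()}
        assert lowered == set(hit.mismatch_positions) == {3, 15}

    def test_zero_offtarget_site_line_score(self, pipeline_instance, tmp_path):
        # query away from plants -> candidates with zero off-targets get 0.0000
        inst = pipeline_instance
        report = run_pipeline(inst.genome["chr2"][1200:1400], inst.genome, None, PatternConfig())
        zero_sites = [s for s in report.sites if s.total_off_targets == 0]
        path = tmp_path / "r.tsv"
        write_full_tsv(report, path)
        for s in zero_sites:
            row = next(
                line.split("\t")
                for line in path.read_text().splitlines()
                if line.startswith(f"site\t{s.candidate.site_id}\t")
            )
            assert row[7] == "0.0000"

    def test_bed_min_max_rescale(self, pipeline_report, tmp_path):
        path = tmp_path / "track.bed"
        write_track_bed(pipeline_report, path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        placed = [s for s in pipeline_report.sites if s.on_target is not None]
        assert len(rows) == len(placed)
        scores = [int(r[4]) for r in rows]
        ranks = [s.rank_score for s in placed]
        if len(set(ranks)) > 1:
            assert max(scores) == 1000 and min(scores) == 0
        else:
            assert set(scores) == {1000}
        # intervals round-trip against the on-target loci
        for r, s in zip(rows, placed):
            assert (r[0], int(r[1]), int(r[2]), r[3], r[5]) == (
                s.on_target.chrom, s.on_target.start, s.on_target.end,
                s.candidate.site_id, s.on_target.strand,
            )

    def test_bed_single_site_gets_1000(self, pipeline_instance, tmp_path):
        inst = pipeline_instance
        query = inst.genome["chr1"][145:178]  # only the perfect plant window
        report = run_pipeline(query, inst.genome, ExonSet(inst.exons), PatternConfig())
        placed = [s for s in report.sites if s.on_target is not None]
        path = tmp_path / "one.bed"
        write_track_bed(report, path)
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert len(rows) == len(placed)
        if len({s.rank_score for s in placed}) == 1:
            assert {int(r[4]) for r in rows} == {1000}

    def test_determinism_byte_identical(self, pipeline_instance, tmp_path):
        inst = pipeline_instance
        query = inst.genome["chr1"][100:200]
        outputs = []
        for run in ("a", "b"):
            report = run_pipeline(query, inst.genome, ExonSet(inst.exons), PatternConfig())
            d = tmp_path / run
            d.mkdir()
            write_candidates_fasta(report.sites, d / "c.fasta")
            write_full_tsv(report, d / "r.tsv")
            write_track_bed(report, d / "t.bed")
            outputs.append(tuple((d / n).read_bytes() for n in ("c.fasta", "r.tsv", "t.bed")))
        assert outputs[0] == outputs[1]
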