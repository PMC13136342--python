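import numpy as np
import pytest

from tdrprof.annotations import AnnotationBundle, GenomicInterval, Transcript, TrnaModel
from tdrprof.classify import (
    ReadRecord,
    alignments_from_sam,
    extract_22g,
    revcomp,
    sequential_classify,
    size_select,
    tabulate,
    toy_align,
    trim_adapter,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTrimAdapter:
    def test_adapter_suffix_removed(self):
        r = ReadRecord("r1", "ACGTACGTACGTACGTACGTAC" + ADAPTER)
        assert trim_adapter(r, ADAPTER).seq == "ACGTACGTACGTACGTACGTAC"

    def test_read_without_adapter_unchanged(self):
        r = ReadRecord("r1", _seq(0, 30))
        assert trim_adapter(r, ADAPTER) is r

    def test_adapter_at_position_zero_discards_read(self):
        assert trim_adapter(ReadRecord("r1", ADAPTER + "ACGT"), ADAPTER) is None

    def test_single_mismatch_fallback(self):
        key = ADAPTER[:8]
        mutated = "C" + key[1:]  # one mismatch in the first base
        r = ReadRecord("r1", "AAAATTTTCCCCGGGGAAAT" + mutated)
        assert trim_adapter(r, ADAPTER).seq == "AAAATTTTCCCCGGGGAAAT"

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(ReadRecord("r1", "ACGT"), "")


class TestSizeSelect:
    def test_18_to_40_boundaries_inclusive(self):
        reads = [ReadRecord(f"r{n}", "A" * n) for n in (17, 18, 40, 41)]
        kept = {r.length for r in size_select(reads)}
        assert kept == {18, 40}

    def test_empty_input(self):
        assert size_select([]) == []

    def test_uniform_length_all_retained(self):
        reads = [ReadRecord(f"r{i}", "A" * 22) for i in range(5)]
        assert len(size_select(reads)) == 5


class TestToyAlign:
    def test_exact_substring_hit(self):
        ref = _seq(1, 80)
        read = ReadRecord("r1", ref[10:32])
        hits = toy_align(read, {"t1": ref}, target_class="tRNA")
        assert len(hits) == 1
        h = hits[0]
        assert (h.target_start, h.target_end, h.antisense, h.mismatches) == (10, 32, False, 0)

    def test_reverse_complement_hit_is_antisense(self):
        ref = _seq(2, 80)
        read = ReadRecord("r1", revcomp(ref[20:42]))
        (h,) = toy_align(read, {"t1": ref})
        assert h.antisense and (h.target_start, h.target_end) == (20, 42)

    def test_best_stratum_matches_exhaustive_scan(self):
        # a read present in two references: brute-force enumeration of all
        # windows (both strands) is the oracle for the best-stratum hit set
        shared = _seq(3, 22)
        refs = {"a": _seq(4, 30) + shared + _seq(5, 30), "b": shared + _seq(6, 40)}
        read = ReadRecord("r1", shared)
        hits = toy_align(read, refs)
        expected = set()
        for ref_id, ref in refs.items():
            for i in range(len(ref) - 21):
                if ref[i : i + 22] == read.seq:
                    expected.add((ref_id, i, False))
                if ref[i : i + 22] == revcomp(read.seq):
                    expected.add((ref_id, i, True))
        assert {(h.target_id, h.target_start, h.antisense) for h in hits} == expected
        assert len(hits) == 2

    def test_mismatch_stratum(self):
        ref = _seq(7, 60)
        mutated = list(ref[5:27])
        mutated[10] = {"A": "C"}.get(mutated[10], "A")
        read = ReadRecord("r1", "".join(mutated))
        assert toy_align(read, {"t": ref}, max_mismatch=0) == []
        hits = toy_align(read, {"t": ref}, max_mismatch=1)
        assert [h.mismatches for h in hits] == [1]


def _mini_bundle():
    """Bundle where one 22-mer is shared between an rRNA and a tRNA."""
    body = _seq(10, 72)
    model = TrnaModel(
        name="tRNA-Gly-GCC-1-1",
        amino_acid="Gly",
        anticodon=body[33:36],
        isoacceptor_id="Gly-GCC",
        isodecoder_id="Gly-GCC-1",
        mature_seq=body,
        anticodon_start=33,
    )
    rrna = {"rrn-x": _seq(11, 50) + body[:22] + _seq(12, 50)}
    return AnnotationBundle(
        genome={"chrI": _seq(13, 200)},
        rrna=rrna,
        mirna={"mir-1": _seq(14, 22)},
        trna=[model],
        pirna={"21ur-1": "T" + _seq(15, 20)},
        transcripts=[Transcript("gene-1", [GenomicInterval("chrI", 50, 150, "+")], "+")],
    )


class TestSequentialClassify:
    def test_class_priority_first_hit_wins(self):
        b = _mini_bundle()
        read = ReadRecord("r1", b.trna[0].mature_seq[:22])  # hits rRNA and tRNA
        (a,) = sequential_classify([read], b)
        assert a.cls == "rRNA"

    def test_permuting_order_only_moves_multi_class_reads(self):
        b = _mini_bundle()
        shared = ReadRecord("r1", b.trna[0].mature_seq[:22])
        trna_only = ReadRecord("r2", b.trna[0].mature_seq[30:60])
        default = sequential_classify([shared, trna_only], b)
        flipped = sequential_classify(
            [shared, trna_only], b, order=("tRNA", "rRNA", "miRNA", "piRNA")
        )
        by_id = lambda asg: {a.read_id: a.cls for a in asg}
        assert by_id(default) == {"r1": "rRNA", "r2": "tRNA"}
        assert by_id(flipped) == {"r1": "tRNA", "r2": "tRNA"}

    def test_multimapper_splits_weight_within_class(self):
        b = _mini_bundle()
        # second isodecoder sharing the first 25 nt
        twin = TrnaModel(
            name="tRNA-Gly-GCC-2-1",
            amino_acid="Gly",
            anticodon=b.trna[0].anticodon,
            isoacceptor_id="Gly-GCC",
            isodecoder_id="Gly-GCC-2",
            mature_seq=b.trna[0].mature_seq[:40] + _seq(16, 32),
            anticodon_start=33,
        )
        b.trna.append(twin)
        # window inside the shared first 40 nt but not a substring of the
        # rRNA decoy (which only carries the first 22 nt of the body)
        read = ReadRecord("r1", b.trna[0].mature_seq[10:32])
        hits = sequential_classify([read], b)
        assert {h.feature_id for h in hits} == {"tRNA-Gly-GCC-1-1", "tRNA-Gly-GCC-2-1"}
        assert all(h.weight == pytest.approx(0.5) for h in hits)
        assert sum(h.weight for h in hits) == pytest.approx(1.0)

    def test_unmatched_read_is_unassigned(self):
        b = _mini_bundle()
        (a,) = sequential_classify([ReadRecord("r1", "A" * 25)], b)
        assert a.cls == "unassigned" and a.weight == 1.0

    def test_unknown_class_in_order_rejected(self, bundle):
        with pytest.raises(ValueError, match="unknown class"):
            sequential_classify([], bundle, order=("rRNA", "snoRNA"))

    def test_recovery_and_conservation_on_generated_library(self, classified, small_library):
        assignments, _, truth = classified
        total_weight = sum(a.weight for a in assignments)
        assert total_weight == pytest.approx(len(small_library[0]))
        pred = {}
        for a in assignments:
            pred.setdefault(a.read_id, set()).add(a.cls)
        t = truth.set_index("read_id")["cls"]
        assert all(pred[rid] == {t[rid]} for rid in t.index)


class TestTabulate:
    def test_percentages_and_denominators(self, classified):
        assignments, _, truth = classified
        table = tabulate(assignments, "s1")
        pct = table.class_percentages()
        assert sum(pct.values()) == pytest.approx(100.0)
        assert table.totals["genome_minus_rRNA"] == pytest.approx(
            table.totals["total_genome"] - table.class_total("rRNA")
        )
        observed_trna_pct = pct["tRNA"]
        expected = 100 * (truth["cls"] == "tRNA").mean()
        assert observed_trna_pct == pytest.approx(expected, abs=1e-9)

    def test_fractional_weights_conserved_per_feature(self):
        from tdrprof.classify import ReadAssignment

        asg = [
            ReadAssignment("r1", "tRNA", "iso1", 0.5),
            ReadAssignment("r1", "tRNA", "iso2", 0.5),
        ]
        table = tabulate(asg)
        assert table.counts[("tRNA", "iso1")] == pytest.approx(0.5)
        assert table.class_total("tRNA") == pytest.approx(1.0)

    def test_empty_library_is_an_error(self):
        from tdrprof.classify import ReadAssignment

        with pytest.raises(ValueError, match="empty library"):
            tabulate([ReadAssignment("r1", "unassigned")])


class Test22G:
    def _reads_against(self, bundle, gene_id):
        gene = bundle.transcript(gene_id)
        span = gene.span
        sense = bundle.genome[span.chrom][span.start : span.end]
        if gene.strand == "-":
            sense = revcomp(sense)
        # qualifying: antisense, 22 nt, 5' G  -> sense window ending in C
        q_start = next(i for i in range(len(sense) - 21) if sense[i + 21] == "C")
        qualifying = revcomp(sense[q_start : q_start + 22])
        # decoys: sense 22 nt starting G; antisense 21 nt starting G; antisense 22 nt not G
        s_start = next(i for i in range(len(sense) - 21) if sense[i] == "G")
        sense_decoy = sense[s_start : s_start + 22]
        a21_start = next(i for i in range(len(sense) - 20) if sense[i + 20] == "C")
        anti_21 = revcomp(sense[a21_start : a21_start + 21])
        a22_start = next(i for i in range(len(sense) - 21) if sense[i + 21] not in "C")
        anti_not_g = revcomp(sense[a22_start : a22_start + 22])
        assert anti_not_g[0] != "G"
        return [
            ReadRecord("q1", qualifying),
            ReadRecord("d_sense", sense_decoy),
            ReadRecord("d_len", anti_21),
            ReadRecord("d_nt", anti_not_g),
        ]

    def test_three_way_exclusion(self, bundle):
        reads = self._reads_against(bundle, "rnst-2")
        assignments = sequential_classify(reads, bundle)
        reads_by_id = {r.read_id: r for r in reads}
        count, kept = extract_22g(assignments, reads_by_id, "rnst-2", bundle)
        assert count == pytest.approx(1.0)
        assert [a.read_id for a in kept] == ["q1"]

    def test_no_reads_gives_zero(self, bundle):
        count, kept = extract_22g([], {}, "rnst-2", bundle)
        assert count == 0.0 and kept == []

    def test_two_qualifying_reads_are_additive(self, bundle):
        reads = self._reads_against(bundle, "rnst-2")[:1]
        reads.append(ReadRecord("q2", reads[0].seq))
        assignments = sequential_classify(reads, bundle)
        count, _ = extract_22g(
            assignments, {r.read_id: r for r in reads}, "rnst-2", bundle
        )
        assert count == pytest.approx(2.0)

    def test_unknown_gene_is_an_error(self, bundle):
        with pytest.raises(KeyError):
            extract_22g([], {}, "no-such-gene", bundle)


class TestSamIngestion:
    def test_sam_round_trip(self, tmp_path):
        sam = tmp_path / "hits.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:tRNA-Gly-GCC-1-1\tLN:75\n"
            "r1\t0\ttRNA-Gly-GCC-1-1\t1\t255\t22M\t*\t0\t0\t" + "A" * 22 + "\t*\tNM:i:0\n"
            "r2\t16\ttRNA-Gly-GCC-1-1\t31\t255\t20M\t*\t0\t0\t" + "C" * 20 + "\t*\tNM:i:1\n"
        )
        hits = alignments_from_sam(sam, "tRNA")
        assert len(hits) == 2
        assert (hits[0].target_start, hits[0].target_end, hits[0].antisense) == (0, 22, False)
        assert (hits[1].target_start, hits[1].antisense, hits[1].mismatches) == (30, True, 1)
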