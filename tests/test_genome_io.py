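"""Genome ingestion, QC, composition metrics and gene partitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stopflux import genome_io as gio
from stopflux import synthetic_data as sd
from stopflux._encoding import revcomp


def _write(tmp_path, fasta_records, gff_lines):
    fa = tmp_path / "g.fa"
    with open(fa, "w") as fh:
        for name, seq in fasta_records.items():
            fh.write(f">{name}\n{seq}\n")
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n" + "\n".join(gff_lines) + "\n")
    return fa, gff


def _gff_line(contig, type_, start, end, strand, attrs):
    a = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\tx\t{type_}\t{start}\t{end}\t.\t{strand}\t.\t{a}"


@pytest.fixture
def two_exon_gene(tmp_path):
    # layout: 1..4 pad, exon1 5..13 (CDS), intron 14..19, exon2 20..28 (CDS)
    contig = "AAAA" + "ATGGCGAAA" + "TTTTTT" + "GCGAAATAA" + "CCCC"
    lines = [
        _gff_line("c1", "gene", 5, 28, "+", {"ID": "g1"}),
        _gff_line("c1", "mRNA", 5, 28, "+", {"ID": "t1", "Parent": "g1"}),
        _gff_line("c1", "exon", 5, 13, "+", {"ID": "e1", "Parent": "t1"}),
        _gff_line("c1", "exon", 20, 28, "+", {"ID": "e2", "Parent": "t1"}),
        _gff_line("c1", "CDS", 5, 13, "+", {"ID": "c1a", "Parent": "t1"}),
        _gff_line("c1", "CDS", 20, 28, "+", {"ID": "c1b", "Parent": "t1"}),
    ]
    return _write(tmp_path, {"c1": contig}, lines), contig


def test_forward_gene_splices_exons(two_exon_gene):
    (fa, gff), _ = two_exon_gene
    records = gio.load_genome(fa, gff).gene_records()
    assert len(records) == 1
    r = records[0]
    assert r.cds == "ATGGCGAAA" + "GCGAAATAA"
    assert r.introns == ["TTTTTT"]
    assert r.stop == "TAA"


def test_minus_strand_gene_is_reverse_complement(tmp_path, two_exon_gene):
    """Flipping the contig and all strands must leave every sequence unchanged."""
    (fa, gff), contig = two_exon_gene
    fwd = gio.load_genome(fa, gff).gene_records()[0]
    L = len(contig)
    flipped = revcomp(contig)

    def flip(a, b):
        return L - b + 1, L - a + 1

    lines = []
    for t, a, b in [("gene", 5, 28), ("mRNA", 5, 28), ("exon", 5, 13),
                    ("exon", 20, 28), ("CDS", 5, 13), ("CDS", 20, 28)]:
        fa2, fb2 = flip(a, b)
        attrs = {"ID": f"{t}{a}", "Parent": "t1"} if t not in ("gene", "mRNA") else {}
        if t == "gene":
            attrs = {"ID": "g1"}
        elif t == "mRNA":
            attrs = {"ID": "t1", "Parent": "g1"}
        lines.append(_gff_line("c1", t, fa2, fb2, "-", attrs))
    fa_p, gff_p = _write(tmp_path, {"c1": flipped}, lines)
    rev = gio.load_genome(fa_p, gff_p).gene_records()[0]
    assert rev.cds == fwd.cds
    assert rev.introns == fwd.introns


def test_missing_contig_is_hard_error(tmp_path):
    fa, gff = _write(tmp_path, {"c1": "ACGT"}, [_gff_line("c2", "gene", 1, 2, "+", {"ID": "g"})])
    with pytest.raises(ValueError, match="c2"):
        gio.load_genome(fa, gff)


def test_bundle_roundtrip_reproduces_sequences(small_bundle, small_bundle_dir):
    """Writing a synthetic bundle and reloading it reproduces each gene's CDS."""
    bundle = gio.load_genome(small_bundle_dir / "reference.fa",
                             small_bundle_dir / "annotation.gff3")
    records = {r.gene_id: r for r in bundle.gene_records()}
    checked = 0
    for g in small_bundle.genes:
        if g.qc_violation:
            continue
        assert records[g.gene_id].stop == g.stop
        checked += 1
    assert checked > 0


class TestQCFilter:
    def _rec(self, cds, gid="g"):
        return gio.GeneRecord(gene_id=gid, transcript_id=gid, contig="c",
                              start=1, end=len(cds), strand="+", cds=cds)

    def test_premature_stop_rejected(self):
        kept, reasons = gio.qc_filter([self._rec("ATGTAATGA")], return_counts=True)
        assert kept == [] and reasons["premature_stop"] == 1

    def test_clean_gene_retained(self):
        kept = gio.qc_filter([self._rec("ATGAAATGA")])
        assert len(kept) == 1 and kept[0].stop == "TGA"

    def test_planted_violations_filtered_exactly(self):
        cfg = sd.SyntheticConfig(seed=3, n_genes=100, n_qc_violations=10, n_mutations=1)
        contigs, gff_lines, truths, gene_cds, _ = sd.make_reference(cfg)
        recs = [self._rec(gene_cds[t.gene_id], t.gene_id) for t in truths]
        kept = gio.qc_filter(recs)
        assert len(kept) == 90


class TestComposition:
    def test_gc3_excludes_stop(self):
        assert gio.gc3("ATGGCGTAA") == 1.0

    def test_intronic_gc_at_repeats(self):
        g = gio.GeneRecord("g", "t", "c", 1, 9, "+", "ATGTAA", introns=["ATATAT", "TATA"])
        assert gio.intronic_gc(g) == 0.0

    def test_intronless_gene_has_no_intronic_gc(self):
        g = gio.GeneRecord("g", "t", "c", 1, 9, "+", "ATGTAA")
        assert gio.intronic_gc(g) is None

    def test_planted_intron_gc_recovered(self):
        rng = np.random.default_rng(5)
        intron = sd.random_sequence(50_000, 0.42, rng)
        g = gio.GeneRecord("g", "t", "c", 1, 9, "+", "ATGTAA", introns=[intron])
        se = np.sqrt(0.42 * 0.58 / 50_000)
        assert abs(gio.intronic_gc(g) - 0.42) < 3 * se


class TestTrinucProfile:
    def test_frame_free_hand_enumeration(self):
        prof = gio.trinuc_profile("TAATAA", frame_free=True)
        assert prof.as_dict()["TAA"] == 2
        assert prof.as_dict()["AAT"] == 1
        assert prof.as_dict()["ATA"] == 1
        assert prof.total == 4

    def test_in_frame_codons(self):
        prof = gio.trinuc_profile("TAATAA", frame_free=False)
        assert prof.as_dict()["TAA"] == 2 and prof.total == 2

    def test_empty_profile_flagged(self):
        prof = gio.trinuc_profile("")
        assert prof.total == 0 and prof.frequencies is None

    @settings(deadline=None, max_examples=50)
    @given(st.text(alphabet="ACGTN", min_size=3, max_size=60))
    def test_window_count_identity(self, seq):
        """Frame-free windows = L-2 minus windows containing an N."""
        prof = gio.trinuc_profile(seq, frame_free=True)
        n_windows = len(seq) - 2
        with_n = sum("N" in seq[i : i + 3] for i in range(n_windows))
        assert prof.total == n_windows - with_n
        if prof.total:
            assert abs(prof.frequencies.sum() - 1.0) < 1e-9

    def test_iid_sequence_matches_multinomial_expectation(self):
        rng = np.random.default_rng(11)
        seq = sd.random_sequence(1_000_000, 0.4, rng)
        prof = gio.trinuc_profile(seq)
        f = prof.frequencies
        p = np.array([0.3, 0.2, 0.2, 0.3])
        expected = np.einsum("a,b,c->abc", p, p, p).reshape(64)
        se = np.sqrt(expected * (1 - expected) / prof.total)
        # overlapping windows are correlated; allow the stated 5-SE band
        assert np.all(np.abs(f - expected) < 5 * np.sqrt(3) * se)


class TestStopUsage:
    def test_uniform_counts(self):
        u = gio.stop_usage({"TAA": 1, "TGA": 1, "TAG": 1})
        assert all(abs(v - 1 / 3) < 1e-12 for v in u.values())

    def test_skewed_counts(self):
        u = gio.stop_usage({"TAA": 0, "TGA": 3, "TAG": 1})
        assert (u["TAA"], u["TGA"], u["TAG"]) == (0.0, 0.75, 0.25)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            gio.stop_usage({"TAA": 0, "TGA": 0, "TAG": 0})

    def test_planted_stop_distribution_recovered(self, small_bundle):
        truth = np.asarray(small_bundle.config.stop_distribution)
        usage = gio.stop_usage({s: sum(g.stop == s for g in small_bundle.genes)
                                for s in ("TAA", "TGA", "TAG")})
        n = len(small_bundle.genes)
        for i, s in enumerate(("TAA", "TGA", "TAG")):
            se = np.sqrt(truth[i] * (1 - truth[i]) / n)
            assert abs(usage[s] - truth[i]) < 4 * se


class TestPartitions:
    def _recs(self, n):
        return [gio.GeneRecord(f"g{i:04d}", f"t{i}", "c", 1 + i, 2 + i, "+", "ATGTAA")
                for i in range(n)]

    def test_decile_bins_partition(self):
        recs = self._recs(100)
        bins = gio.decile_bins(recs, key=lambda r: r.start)
        assert [len(b) for b in bins] == [10] * 10
        flat = [r.gene_id for b in bins for r in b]
        assert sorted(flat) == sorted(r.gene_id for r in recs)

    def test_too_few_records_error(self):
        with pytest.raises(ValueError):
            gio.decile_bins(self._recs(7), key=lambda r: r.start)

    def test_half_split_balances_events(self):
        recs = self._recs(200)
        events = {r.gene_id: (1 if i % 5 == 0 else 0) for i, r in enumerate(recs)}
        low, high = gio.half_split(recs, key=lambda r: r.start, events=events)
        assert len(low) + len(high) == 200
        ev_low = sum(events[r.gene_id] for r in low)
        ev_high = sum(events[r.gene_id] for r in high)
        assert abs(ev_low - ev_high) <= 1


class TestRecombination:
    def test_single_interval(self):
        rmap = gio.RecombinationMap.from_records([("c", 0, 1000, 2.0)])
        r = gio.GeneRecord("g", "t", "c", 101, 200, "+", "ATGTAA")
        gio.assign_recombination([r], rmap)
        assert r.recomb_rate == 2.0

    def test_snp_mean(self):
        rmap = gio.RecombinationMap.from_records([("c", 0, 100, 1.0), ("c", 100, 200, 3.0)])
        r = gio.GeneRecord("g", "t", "c", 1, 200, "+", "ATGTAA")
        gio.assign_recombination([r], rmap, snp_positions={"c": [50, 150]})
        assert r.recomb_rate == 2.0

    def test_no_overlap_leaves_rate_absent(self):
        rmap = gio.RecombinationMap.from_records([("c", 0, 100, 1.0)])
        r = gio.GeneRecord("g", "t", "c", 500, 600, "+", "ATGTAA")
        gio.assign_recombination([r], rmap)
        assert r.recomb_rate is None

    def test_overlap_mean_matches_per_base_oracle(self):
        rng = np.random.default_rng(2)
        edges = np.sort(rng.choice(np.arange(1, 5000), size=20, replace=False))
        spans = list(zip(np.concatenate([[0], edges]), np.concatenate([edges, [5000]])))
        rates = rng.uniform(0, 5, len(spans))
        rmap = gio.RecombinationMap.from_records(
            [("c", int(a), int(b), float(x)) for (a, b), x in zip(spans, rates)]
        )
        g0, g1 = 1234, 4321  # 0-based half-open gene span
        r = gio.GeneRecord("g", "t", "c", g0 + 1, g1, "+", "ATGTAA")
        gio.assign_recombination([r], rmap)
        per_base = np.mean([rmap.rate_at("c", p) for p in range(g0, g1)])
        assert abs(r.recomb_rate - per_base) < 1e-9
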