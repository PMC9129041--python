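"""Genome and annotation ingestion, per-gene sequence classes and composition metrics.

This module turns a genome FASTA plus a GFF3 annotation into per-gene
records holding the spliced CDS, UTRs and introns, applies the quality
filters used throughout the stop-codon flux analyses (CDS length divisible
by three, no premature stop, canonical terminator), and computes the
composition covariates those analyses condition on: GC3, intronic GC (a
proxy for isochore GC), local recombination rate and protein abundance.

Coordinates are GFF3 1-based inclusive at the boundary and 0-based
half-open internally; all reported coordinates are 1-based.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from ._encoding import (
    BASES,
    MISSING,
    STOPS,
    TRINUCS,
    encode,
    gc_fraction,
    revcomp,
)

log = logging.getLogger(__name__)

_GFF_TYPES = {
    "gene",
    "mRNA",
    "exon",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
}


@dataclass
class Feature:
    """One GFF3 feature line (1-based inclusive coordinates)."""

    contig: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str]

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


@dataclass
class GeneRecord:
    """One gene's sequence classes and covariates (canonical transcript)."""

    gene_id: str
    transcript_id: str
    contig: str
    start: int  # 1-based inclusive gene span
    end: int
    strand: str
    cds: str  # spliced, stop codon included
    utr5: str = ""
    utr3: str = ""
    introns: list[str] = field(default_factory=list)
    recomb_rate: float | None = None
    recomb_source: str | None = None
    abundance: float | None = None

    @property
    def stop(self) -> str:
        return self.cds[-3:]

    @property
    def gc3(self) -> float:
        return gc3(self.cds)

    @property
    def intronic_gc(self) -> float | None:
        return intronic_gc(self)


@dataclass
class GenomeBundle:
    """A genome's contigs plus its annotation features."""

    contigs: dict[str, str]
    features: list[Feature]

    def gene_records(self) -> list[GeneRecord]:
        return extract_genes(self)


@dataclass
class TrinucleotideProfile:
    """Counts and frequencies over the 64 trinucleotides."""

    counts: np.ndarray  # shape (64,), int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray | None:
        """64-simplex, or None for an empty profile."""
        t = self.total
        if t == 0:
            return None
        return self.counts / t

    def as_dict(self) -> dict[str, int]:
        return {t: int(c) for t, c in zip(TRINUCS, self.counts)}


@dataclass
class RecombinationMap:
    """Sorted, non-overlapping rate intervals per contig (0-based half-open)."""

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # contig -> (starts, ends, rates)

    @classmethod
    def from_records(cls, records) -> "RecombinationMap":
        """records: iterable of (contig, start, end, rate), half-open 0-based."""
        by_contig: dict[str, list[tuple[int, int, float]]] = {}
        for contig, start, end, rate in records:
            if rate < 0:
                raise ValueError(f"negative recombination rate at {contig}:{start}")
            by_contig.setdefault(str(contig), []).append((int(start), int(end), float(rate)))
        out = {}
        for contig, rows in by_contig.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping recombination intervals on {contig}")
            out[contig] = (starts, ends, np.array([r[2] for r in rows]))
        return cls(out)

    @classmethod
    def read_tsv(cls, path) -> "RecombinationMap":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
                except ValueError:
                    continue  # header line
        return cls.from_records(rows)

    def rate_at(self, contig: str, position: int) -> float | None:
        """Rate of the interval containing a 0-based position, else None."""
        if contig not in self.intervals:
            return None
        starts, ends, rates = self.intervals[contig]
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < ends[i]:
            return float(rates[i])
        return None


# ---------------------------------------------------------------------------
# parsing


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path) -> list[Feature]:
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            if cols[2] not in _GFF_TYPES:
                continue
            features.append(
                Feature(
                    contig=cols[0],
                    type=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=_parse_attributes(cols[8]),
                )
            )
    return features


def load_genome(fasta_path, gff_path) -> GenomeBundle:
    """Load a genome FASTA and its GFF3 annotation into one bundle.

    Raises ValueError naming the offending feature if any feature refers to
    a contig absent from the FASTA or overruns its contig.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    features = read_gff3(gff_path)
    for f in features:
        if f.contig not in contigs:
            raise ValueError(f"feature {f.id or f.type} refers to missing contig {f.contig!r}")
        if f.start < 1 or f.end > len(contigs[f.contig]):
            raise ValueError(f"feature {f.id or f.type} span {f.start}-{f.end} outside contig {f.contig!r}")
    return GenomeBundle(contigs=contigs, features=features)


def _extract(contig_seq: str, spans: list[tuple[int, int]], strand: str) -> str:
    """Splice 1-based inclusive spans; reverse-complement on '-'."""
    spans = sorted(spans)
    seq = "".join(contig_seq[s - 1 : e] for s, e in spans)
    return revcomp(seq) if strand == "-" else seq


def extract_genes(bundle: GenomeBundle) -> list[GeneRecord]:
    """Build one GeneRecord per gene from the bundle.

    One transcript is chosen per gene: the one tagged canonical if any,
    else the longest CDS, ties broken lexicographically by transcript id.
    Introns are the gaps between consecutive exons, reported 5'->3'.
    """
    genes = {f.id: f for f in bundle.features if f.type == "gene" and f.id}
    mrnas = [f for f in bundle.features if f.type == "mRNA"]
    children: dict[str, list[Feature]] = {}
    for f in bundle.features:
        if f.parent:
            children.setdefault(f.parent, []).append(f)

    records = []
    for gene_id, gene in sorted(genes.items()):
        candidates = [m for m in mrnas if m.parent == gene_id]
        if not candidates:
            continue

        def cds_len(m: Feature) -> int:
            return sum(c.end - c.start + 1 for c in children.get(m.id, []) if c.type == "CDS")

        canonical = [m for m in candidates if m.attributes.get("canonical") == "1"
                     or "Ensembl_canonical" in m.attributes.get("tag", "")]
        pool = canonical or candidates
        transcript = sorted(pool, key=lambda m: (-cds_len(m), m.id))[0]

        parts = children.get(transcript.id, [])
        cds_spans = [(f.start, f.end) for f in parts if f.type == "CDS"]
        exon_spans = sorted((f.start, f.end) for f in parts if f.type == "exon")
        if not cds_spans:
            continue
        contig_seq = bundle.contigs[gene.contig]
        strand = transcript.strand
        cds = _extract(contig_seq, cds_spans, strand)
        utr5 = _extract(contig_seq, [(f.start, f.end) for f in parts if f.type == "five_prime_UTR"], strand)
        utr3 = _extract(contig_seq, [(f.start, f.end) for f in parts if f.type == "three_prime_UTR"], strand)
        intron_spans = [
            (exon_spans[i][1] + 1, exon_spans[i + 1][0] - 1)
            for i in range(len(exon_spans) - 1)
            if exon_spans[i + 1][0] - exon_spans[i][1] > 1
        ]
        introns = [_extract(contig_seq, [sp], strand) for sp in intron_spans]
        if strand == "-":
            introns = introns[::-1]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                transcript_id=transcript.id or gene_id,
                contig=gene.contig,
                start=gene.start,
                end=gene.end,
                strand=strand,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                introns=introns,
            )
        )
    return records


# ---------------------------------------------------------------------------
# QC and composition metrics


def _has_internal_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in STOPS for i in range(0, len(cds) - 3, 3))


def qc_filter(records: list[GeneRecord], return_counts: bool = False):
    """Keep genes with CDS length divisible by 3, no premature stop codon in
    frame, and a TAA/TGA/TAG terminator. Rejection reasons are counted and
    logged; filtering never raises."""
    kept = []
    reasons: Counter = Counter()
    for r in records:
        if len(r.cds) < 6 or len(r.cds) % 3 != 0:
            reasons["length_not_multiple_of_3"] += 1
        elif r.cds[-3:] not in STOPS:
            reasons["no_canonical_stop"] += 1
        elif _has_internal_stop(r.cds):
            reasons["premature_stop"] += 1
        else:
            kept.append(r)
    if reasons:
        log.info("qc_filter rejected %d genes: %s", sum(reasons.values()), dict(reasons))
    if return_counts:
        return kept, reasons
    return kept


def gc3(cds: str) -> float:
    """G+C fraction at third codon positions, stop codon excluded.

    The stop codon is the response variable of the flux analyses, so it is
    kept out of this covariate.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    body = cds[:-3] if cds[-3:] in STOPS else cds
    thirds = encode(body)[2::3]
    valid = thirds != MISSING
    if not valid.any():
        return float("nan")
    return float(((thirds == 1) | (thirds == 2)).sum() / valid.sum())


def intronic_gc(gene: GeneRecord) -> float | None:
    """G+C over all unambiguous intronic bases; None for intronless genes."""
    if not gene.introns:
        return None
    return gc_fraction("".join(gene.introns))


def trinuc_profile(sequences, frame_free: bool = True) -> TrinucleotideProfile:
    """Trinucleotide counts over one or many sequences.

    frame_free=True counts every overlapping width-3 window (step 1);
    frame_free=False counts in-frame codons only. Windows containing any
    non-ACGT character are skipped.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(64, dtype=np.int64)
    for seq in sequences:
        if len(seq) < 3:
            continue
        codes = encode(seq).astype(np.int64)
        if frame_free:
            a, b, c = codes[:-2], codes[1:-1], codes[2:]
        else:
            usable = (len(codes) // 3) * 3
            codons = codes[:usable].reshape(-1, 3)
            a, b, c = codons[:, 0], codons[:, 1], codons[:, 2]
        ok = (a != MISSING) & (b != MISSING) & (c != MISSING)
        idx = 16 * a[ok] + 4 * b[ok] + c[ok]
        counts += np.bincount(idx, minlength=64)
    return TrinucleotideProfile(counts=counts)


def stop_usage(source) -> dict[str, float]:
    """Relative frequencies of TAA/TGA/TAG.

    ``source`` may be a TrinucleotideProfile, a list of GeneRecords (focal
    stop codons are used) or a mapping of stop -> count.
    """
    if isinstance(source, TrinucleotideProfile):
        counts = {s: int(source.counts[TRINUCS.index(s)]) for s in STOPS}
    elif isinstance(source, dict):
        counts = {s: source.get(s, 0) for s in STOPS}
    else:
        c = Counter(r.stop for r in source)
        counts = {s: c.get(s, 0) for s in STOPS}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no stop trinucleotides present")
    return {s: counts[s] / total for s in STOPS}


# ---------------------------------------------------------------------------
# partitions


def decile_bins(records, key, bins: int = 10):
    """Partition records into ``bins`` equal-size bins ordered by ``key``.

    Bin sizes differ by at most one; together the bins contain every input
    record exactly once.
    """
    records = list(records)
    if len(records) < bins:
        raise ValueError(f"cannot split {len(records)} records into {bins} bins")
    order = sorted(records, key=key)
    return [list(chunk) for chunk in np.array_split(np.array(order, dtype=object), bins)]


def half_split(records, key, events):
    """Split key-ordered records into two halves balanced on flux events.

    ``events`` maps each record to its flux-event count (callable or dict by
    gene_id). The cut point on the key-sorted list is chosen so the two
    halves carry as near-equal event totals as a gene boundary allows.
    Returns (low, high) by key.
    """
    records = sorted(records, key=key)
    if callable(events):
        ev = np.array([events(r) for r in records], dtype=float)
    else:
        ev = np.array([events[r.gene_id] for r in records], dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(ev)])
    total = cum[-1]
    imbalance = np.abs(2 * cum - total)
    k = int(np.argmin(imbalance))
    return records[:k], records[k:]


def assign_recombination(records, rmap: RecombinationMap, snp_positions=None):
    """Attach a recombination rate (cM/Mb) to each gene.

    With ``snp_positions`` (contig -> sorted array of 0-based positions),
    the rate is the mean map rate at the gene's internal SNPs. Otherwise the
    documented fallback is used: the length-weighted mean rate of map
    intervals overlapping the gene span. Genes with no overlap or no mapped
    SNPs get rate None and are excluded from recombination analyses.
    """
    for r in records:
        g0, g1 = r.start - 1, r.end  # half-open
        rate = None
        source = None
        if snp_positions is not None:
            pos = np.asarray(snp_positions.get(r.contig, []), dtype=np.int64)
            inside = pos[(pos >= g0) & (pos < g1)]
            vals = [v for p in inside if (v := rmap.rate_at(r.contig, int(p))) is not None]
            if vals:
                rate = float(np.mean(vals))
                source = "snp_mean"
        else:
            if r.contig in rmap.intervals:
                starts, ends, rates = rmap.intervals[r.contig]
                ov = np.minimum(ends, g1) - np.maximum(starts, g0)
                ov = np.clip(ov, 0, None).astype(float)
                if ov.sum() > 0:
                    rate = float(np.average(rates, weights=ov))
                    source = "overlap_weighted"
        r.recomb_rate = rate
        r.recomb_source = source
    return records


def assign_abundance(records, table: dict[str, float]):
    """Attach protein abundance (ppm) from a gene-id -> abundance mapping."""
    for r in records:
        r.abundance = table.get(r.gene_id)
    return records


def read_abundance_tsv(path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            try:
                out[parts[0]] = float(parts[1])
            except ValueError:
                continue
    return out
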