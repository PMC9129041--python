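"""Synthetic genomes, trios, mutation tables and maps with known ground truth.

Every input the pipeline consumes can be generated here with its
generating parameters recorded, so each stage is testable by parameter
recovery: an isochore-structured reference with annotated genes, trio
alignments evolved from a known ancestral sequence under a known mutation
matrix with a tunable AT->GC fixation bias B, de novo mutation tables
sampled from that matrix, a GC-correlated recombination map and log-normal
protein abundances.

The fixation bias acts at the acceptance step, not the mutation step:
substitutions are proposed from the mutation matrix and AT->GC proposals
are accepted with probability min(1, B * base), GC->AT with
min(1, base / B) and GC-conserving ones with base (default base = 0.5).
This separates the two opposing forces the analyses contrast - an AT-biased
mutation process and a GC-favouring fixation process. Trio alignments are
generated ungapped (the alignment is the identity), isolating flux
inference from aligner error.

Defaults emulate a mammalian setting: an AT-biased, transition-rich
mutation matrix (equilibrium GC* ~ 0.32), genome-wide stop usage of
roughly TAA 28% / TGA 52% / TAG 20%, and isochore GC levels of 0.35/0.55.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._encoding import BASES, BASE_INDEX, STOPS, decode, encode, revcomp

#: Relative per-incidence mutation rates (rows = from A,C,G,T). AT-biased and
#: transition-rich; two-class equilibrium GC* = 0.28/(0.28+0.60) ~ 0.318.
DEFAULT_MUTATION_MATRIX = np.array(
    [
        [0.00, 0.08, 0.20, 0.07],
        [0.10, 0.00, 0.09, 0.50],
        [0.50, 0.09, 0.00, 0.10],
        [0.07, 0.20, 0.08, 0.00],
    ]
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 200
    isochore_levels: tuple = ((0.35, 30000), (0.55, 30000))  # (GC, block length)
    mean_cds_length: int = 900
    utr5_length: int = 120
    utr3_length: int = 240
    n_introns: int = 2
    intron_length: int = 400
    intergenic: int = 400
    stop_distribution: tuple = (0.28, 0.52, 0.20)  # TAA, TGA, TAG
    mutation_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_MUTATION_MATRIX.copy())
    branch_lengths: tuple = (0.04, 0.04, 0.08)  # ingroup1, ingroup2, outgroup
    gbgc_B: float = 1.0
    gbgc_scope: str = "high_gc"  # "high_gc": B acts only in blocks above the mean level
    acceptance_base: float = 0.5
    recomb_coupling: float = 0.5
    n_mutations: int = 20000
    n_qc_violations: int = 0
    minus_strand_fraction: float = 0.3

    def __post_init__(self):
        if self.gbgc_B <= 0:
            raise ValueError("B must be positive")
        for gc, length in self.isochore_levels:
            if not (0 < gc < 1) or length <= 0:
                raise ValueError("isochore levels need GC in (0,1) and positive length")


@dataclass
class SyntheticGeneTruth:
    gene_id: str
    block_gc: float
    strand: str
    stop: str
    gbgc_B: float
    qc_violation: str | None = None
    ancestral_stop: str | None = None
    tip_stops: tuple | None = None


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    contigs: dict
    gff_lines: list
    genes: list  # SyntheticGeneTruth
    trios: dict  # gene_id -> (seq1, seq2, seq3)
    mutations: pd.DataFrame | None = None
    recomb_map: pd.DataFrame | None = None
    abundance: dict | None = None

    def truth(self) -> dict:
        cfg = asdict(self.config)
        cfg["mutation_matrix"] = self.config.mutation_matrix.tolist()
        return {
            "config": cfg,
            "genes": [asdict(g) for g in self.genes],
        }


# ---------------------------------------------------------------------------
# sequence primitives


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_sequence(length: int, gc: float, rng) -> str:
    return decode(rng.choice(4, size=length, p=_base_probs(gc)).astype(np.int8))


def _random_sense_codons(n: int, gc: float, rng) -> str:
    """n codons drawn i.i.d. at the target base composition, stops rejected."""
    out = []
    need = n
    while need > 0:
        draw = rng.choice(4, size=(need + 8, 3), p=_base_probs(gc)).astype(np.int8)
        for row in draw:
            codon = decode(row)
            if codon not in STOPS:
                out.append(codon)
                if len(out) == n:
                    break
        need = n - len(out)
    return "".join(out)


def evolve_sequence(seq: str, matrix: np.ndarray, t: float, rng, B: float = 1.0,
                    base: float = 0.5, rounds: int = 1, log_events: bool = False,
                    context_multipliers: dict | None = None):
    """Evolve a sequence for t expected proposals/site under the matrix.

    Per round each site proposes a substitution with probability
    (t/rounds) * q_x / q_mean (q_x the site's total mutation rate, q_mean
    the mean row sum of the base matrix), the target drawn proportional to
    the (context-modulated) matrix row; acceptance follows the B rule
    described in the module docstring. ``context_multipliers`` maps
    (dinucleotide, alt) -> factor applied to mutations of the
    dinucleotide's first base, e.g. {("CG", "T"): 10} for CpG
    hypermutability; neighbours are re-read every round as the sequence
    changes. Returns (sequence, events); events is a list of
    (position, from, to) accepted substitutions (empty unless log_events).
    """
    codes = encode(seq).astype(np.int8)
    valid = codes != 4
    q_mean = matrix.sum(axis=1).mean()
    is_gc = np.array([False, True, True, False])
    events = []
    per_round = t / rounds
    for _ in range(rounds):
        eff = matrix[np.clip(codes, 0, 3)].astype(float)  # (L, 4)
        if context_multipliers:
            nxt = np.roll(codes, -1)
            nxt[-1] = 4
            for (dinuc, alt), factor in context_multipliers.items():
                a, b = BASE_INDEX[dinuc[0]], BASE_INDEX[dinuc[1]]
                eff[(codes == a) & (nxt == b), BASE_INDEX[alt]] *= factor
        site_rate = np.where(valid, eff.sum(axis=1), 0.0)
        p_prop = np.minimum(1.0, per_round * site_rate / q_mean)
        u = rng.random(codes.size)
        prop_sites = np.where(u < p_prop)[0]
        if prop_sites.size == 0:
            continue
        rows = eff[prop_sites]
        cum = np.cumsum(rows, axis=1)
        u2 = rng.random(prop_sites.size) * cum[:, -1]
        dst = (u2[:, None] > cum).sum(axis=1)
        src = codes[prop_sites].astype(np.int64)
        acc = np.full(prop_sites.size, base)
        at_gc = ~is_gc[src] & is_gc[dst]
        gc_at = is_gc[src] & ~is_gc[dst]
        acc[at_gc] = np.minimum(1.0, base * B)
        acc[gc_at] = np.minimum(1.0, base / B)
        u3 = rng.random(prop_sites.size)
        accepted = u3 < acc
        sites = prop_sites[accepted]
        if log_events:
            events.extend(
                (int(i), BASES[codes[i]], BASES[d]) for i, d in zip(sites, dst[accepted])
            )
        codes[sites] = dst[accepted].astype(np.int8)
    return decode(codes), events


def evolve_trio(cds: str, matrix: np.ndarray, branch_lengths, rng, B: float = 1.0,
                base: float = 0.5):
    """Evolve an ancestral CDS independently along the three branches.

    Returns ((tip1, tip2, tip3), events-per-branch). Branch order is
    (ingroup1, ingroup2, outgroup); the ancestral sequence is the state at
    the single internal node, so the true ancestral stop codon is the last
    codon of ``cds``.
    """
    tips = []
    logs = []
    for t in branch_lengths:
        tip, ev = evolve_sequence(cds, matrix, t, rng, B=B, base=base, log_events=True)
        tips.append(tip)
        logs.append(ev)
    return tuple(tips), logs


# ---------------------------------------------------------------------------
# reference + annotation


def _build_gene(gene_id: str, gc: float, strand: str, cfg: SyntheticConfig, rng,
                qc_violation: str | None = None):
    """Return (sense-transcript pieces, stop codon). Pieces are labelled
    (kind, sequence) with kinds utr5/cds/intron/utr3."""
    n_codons = max(100, int(rng.normal(cfg.mean_cds_length, cfg.mean_cds_length * 0.15)) // 3)
    stop = STOPS[rng.choice(3, p=np.asarray(cfg.stop_distribution) / np.sum(cfg.stop_distribution))]
    body = _random_sense_codons(n_codons - 2, gc, rng)
    if qc_violation == "premature_stop":
        k = 3 * (n_codons // 2)
        body = body[:k] + "TAA" + body[k + 3 :]
    cds = "ATG" + body + stop
    if qc_violation == "length":
        cds = cds[:-1]  # truncate: length no longer divisible by 3
    n_parts = cfg.n_introns + 1
    bounds = np.linspace(0, len(cds), n_parts + 1).astype(int)
    cds_parts = [cds[bounds[i] : bounds[i + 1]] for i in range(n_parts)]
    utr5 = random_sequence(cfg.utr5_length, gc, rng)
    utr3 = random_sequence(cfg.utr3_length, gc, rng)
    pieces = [("utr5", utr5)]
    for i, part in enumerate(cds_parts):
        pieces.append(("cds", part))
        if i < cfg.n_introns:
            pieces.append(("intron", random_sequence(cfg.intron_length, gc, rng)))
    pieces.append(("utr3", utr3))
    return pieces, stop, cds


def _gff(contig, type_, start, end, strand, attrs) -> str:
    a = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\tstopflux\t{type_}\t{start}\t{end}\t.\t{strand}\t.\t{a}"


def make_reference(config: SyntheticConfig, rng=None):
    """Build the isochore reference, its GFF3 annotation and gene truths.

    Returns (contigs, gff_lines, gene_truths, gene_cds) where gene_cds maps
    gene id -> ancestral spliced CDS (stop included).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    contig = "chr1"
    segments: list[str] = []
    gff: list[str] = [
        "##gff-version 3",
    ]
    truths: list[SyntheticGeneTruth] = []
    gene_cds: dict[str, str] = {}
    offset = 0  # 0-based position of next segment
    placed = 0
    level_i = 0
    mean_gc = float(np.mean([gc for gc, _ in config.isochore_levels]))
    blocks = []  # (start, end, gc) for truth / recomb coupling

    n_violate = config.n_qc_violations
    violation_kinds = (["premature_stop", "length"] * n_violate)[:n_violate]

    while placed < config.n_genes:
        gc, block_len = config.isochore_levels[level_i % len(config.isochore_levels)]
        level_i += 1
        block_start = offset
        block_end = offset + block_len
        blocks.append((block_start, block_end, gc))
        while placed < config.n_genes:
            gene_id = f"gene{placed:05d}"
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            violation = violation_kinds[placed] if placed < len(violation_kinds) else None
            pieces, stop, cds = _build_gene(gene_id, gc, strand, config, rng, violation)
            gene_len = sum(len(s) for _, s in pieces)
            if offset + config.intergenic + gene_len > block_end:
                break
            spacer = random_sequence(config.intergenic, gc, rng)
            segments.append(spacer)
            offset += len(spacer)
            gstart = offset  # 0-based
            sense = "".join(s for _, s in pieces)
            segments.append(revcomp(sense) if strand == "-" else sense)
            offset += gene_len

            # map sense-strand piece offsets to genomic 1-based coordinates
            def span(o, l):
                if strand == "+":
                    return gstart + o + 1, gstart + o + l
                return gstart + gene_len - o - l + 1, gstart + gene_len - o

            g1, g2 = gstart + 1, gstart + gene_len
            tid = f"{gene_id}.t1"
            gff.append(_gff(contig, "gene", g1, g2, strand, {"ID": gene_id}))
            gff.append(_gff(contig, "mRNA", g1, g2, strand, {"ID": tid, "Parent": gene_id, "canonical": "1"}))
            o = 0
            exon_open = None  # (start sense offset)
            exons = []
            for kind, s in pieces:
                if kind == "intron":
                    exons.append((exon_open, o))
                    exon_open = None
                else:
                    if exon_open is None:
                        exon_open = o
                    a, b = span(o, len(s))
                    if kind == "cds":
                        gff.append(_gff(contig, "CDS", a, b, strand, {"ID": f"{tid}.cds", "Parent": tid}))
                    elif kind == "utr5":
                        gff.append(_gff(contig, "five_prime_UTR", a, b, strand, {"ID": f"{tid}.u5", "Parent": tid}))
                    elif kind == "utr3":
                        gff.append(_gff(contig, "three_prime_UTR", a, b, strand, {"ID": f"{tid}.u3", "Parent": tid}))
                o += len(s)
            exons.append((exon_open, o))
            for k, (a_off, b_off) in enumerate(exons):
                a, b = span(a_off, b_off - a_off)
                gff.append(_gff(contig, "exon", a, b, strand, {"ID": f"{tid}.e{k}", "Parent": tid}))

            B = config.gbgc_B if (config.gbgc_scope == "all" or gc >= mean_gc) else 1.0
            truths.append(SyntheticGeneTruth(gene_id=gene_id, block_gc=gc, strand=strand,
                                             stop=stop, gbgc_B=B, qc_violation=violation))
            gene_cds[gene_id] = cds
            placed += 1
        pad = block_end - offset
        if pad > 0:
            segments.append(random_sequence(pad, gc, rng))
            offset = block_end

    contigs = {contig: "".join(segments)}
    return contigs, gff, truths, gene_cds, blocks


# ---------------------------------------------------------------------------
# downstream inputs


def sample_denovo(reference: dict, matrix: np.ndarray, n: int, rng,
                  context_multipliers: dict | None = None) -> pd.DataFrame:
    """Sample n de novo point mutations from the mutation matrix.

    Sites are drawn proportionally to the total mutation rate of their
    reference base (optionally modulated by dinucleotide context
    multipliers {(dinucleotide, alt): factor}, the factor applying to
    mutations of the dinucleotide's first base); the alternate allele is
    drawn proportionally to the matrix row. Output columns: Chr, Pos (1-
    based), Ref, Alt.
    """
    contigs = sorted(reference)
    names = []
    codes_all = []
    offsets = [0]
    for c in contigs:
        codes_all.append(encode(reference[c]))
        names.append(c)
        offsets.append(offsets[-1] + len(reference[c]))
    codes = np.concatenate(codes_all).astype(np.int64)
    valid = codes != 4

    eff = matrix[np.clip(codes, 0, 3)]  # (L, 4) per-site rates (copy)
    if context_multipliers:
        nxt = np.roll(codes, -1)
        for (dinuc, alt), factor in context_multipliers.items():
            a, b = BASE_INDEX[dinuc[0]], BASE_INDEX[dinuc[1]]
            mask = (codes == a) & (nxt == b)
            mask[np.asarray(offsets[1:]) - 1] = False  # context must not cross contigs
            eff[mask, BASE_INDEX[alt]] *= factor
    site_rate = np.where(valid, eff.sum(axis=1), 0.0)
    p = site_rate / site_rate.sum()
    sites = rng.choice(codes.size, size=n, replace=True, p=p)
    row = eff[sites]
    cum = np.cumsum(row, axis=1)
    u = rng.random(n) * cum[:, -1]
    alts = (u[:, None] > cum).sum(axis=1)

    contig_idx = np.searchsorted(np.asarray(offsets), sites, side="right") - 1
    pos = sites - np.asarray(offsets)[contig_idx] + 1
    return pd.DataFrame(
        {
            "Chr": [names[i] for i in contig_idx],
            "Pos": pos,
            "Ref": [BASES[codes[s]] for s in sites],
            "Alt": [BASES[a] for a in alts],
        }
    )


def make_recomb_map(reference: dict, coupling: float, rng, window: int = 10000,
                    mean_rate: float = 1.2, log_sd: float = 0.8) -> pd.DataFrame:
    """Log-normal per-window rates whose correlation with window GC is the
    coupling knob (0 = independent, 1 = deterministic in GC rank)."""
    if not (0 <= coupling <= 1):
        raise ValueError("coupling must lie in [0, 1]")
    rows = []
    for contig, seq in sorted(reference.items()):
        codes = encode(seq)
        n_win = max(1, len(seq) // window)
        for w in range(n_win):
            lo, hi = w * window, min(len(seq), (w + 1) * window)
            sub = codes[lo:hi]
            ok = sub != 4
            gc = float(((sub == 1) | (sub == 2))[ok].mean()) if ok.any() else 0.5
            rows.append([contig, lo, hi, gc])
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "gc"])
    z = (df["gc"] - df["gc"].mean()) / (df["gc"].std() or 1.0)
    eps = rng.standard_normal(len(df))
    logr = log_sd * (coupling * z + np.sqrt(1 - coupling**2) * eps) + np.log(mean_rate)
    df["rate"] = np.exp(logr)
    return df[["contig", "start", "end", "rate", "gc"]]


def make_abundance(gene_ids, rng, median_ppm: float = 10.0, log_sd: float = 1.5) -> dict:
    """Log-normal protein abundances (ppm) per gene."""
    vals = np.exp(rng.normal(np.log(median_ppm), log_sd, size=len(gene_ids)))
    return dict(zip(gene_ids, vals.tolist()))


def sample_stop_flux_genes(n: int, switch_probs: dict, rng,
                           ancestral_distribution: tuple = (0.45, 0.45, 0.10)):
    """Ancestral stops plus two ingroup tips with planted per-lineage
    switch probabilities.

    ``switch_probs`` maps (ancestral, derived) -> per-lineage probability;
    ``ancestral_distribution`` is over (TAA, TGA, TAG). Returns a list of
    (ancestral, tip1, tip2) triples - the exact shape count_stop_flux eats.
    """
    anc = rng.choice(3, size=n, p=np.asarray(ancestral_distribution))
    out = []
    for a in anc:
        anc_stop = STOPS[a]
        tips = []
        for _ in range(2):
            tip = anc_stop
            u = rng.random()
            acc = 0.0
            for (src, dst), p in switch_probs.items():
                if src != anc_stop:
                    continue
                acc += p
                if u < acc:
                    tip = dst
                    break
            tips.append(tip)
        out.append((anc_stop, tips[0], tips[1]))
    return out


# ---------------------------------------------------------------------------
# orchestration


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate every pipeline input for one synthetic study, deterministically.

    The trio alignments are evolved from each gene's ancestral CDS; per-gene
    true ancestral and tip stop codons land in the truth records.
    """
    rng = np.random.default_rng(config.seed)
    contigs, gff, truths, gene_cds, _blocks = make_reference(config, rng)
    trios = {}
    for g in truths:
        if g.qc_violation:
            continue
        cds = gene_cds[g.gene_id]
        tips, _logs = evolve_trio(cds, config.mutation_matrix, config.branch_lengths,
                                  rng, B=g.gbgc_B, base=config.acceptance_base)
        trios[g.gene_id] = tips
        g.ancestral_stop = cds[-3:]
        g.tip_stops = tuple(t[-3:] for t in tips)
    mutations = sample_denovo(contigs, config.mutation_matrix, config.n_mutations, rng)
    recomb = make_recomb_map(contigs, config.recomb_coupling, rng)
    abundance = make_abundance([g.gene_id for g in truths], rng)
    return SyntheticBundle(config=config, contigs=contigs, gff_lines=gff, genes=truths,
                           trios=trios, mutations=mutations, recomb_map=recomb,
                           abundance=abundance)


def gbgc_boost_experiment(seed: int, B: float = 2.0, n_blocks: int = 24,
                          block_length: int = 20000, ancestral_gc: float = 0.45,
                          t: float = 0.6, rounds: int = 3,
                          n_mutations_per_class: int = 15000,
                          matrix: np.ndarray | None = None):
    """One seed of the fixation-boost sign-recovery experiment.

    Isochore blocks start at a common ancestral composition above the
    mutational equilibrium (the mammalian situation: genome GC exceeds the
    AT-biased mutational equilibrium). Alternating blocks receive the
    fixation bias B while the rest evolve neutrally, so with B > 1 the
    biased blocks become the GC-rich sequence class; with B = 1 the two
    classes are statistically exchangeable. Each class's mutational-null
    trinucleotide expectation is rebuilt from de novo mutations sampled on
    that class's own evolved sequence (dinucleotide matrix -> stationary
    distribution -> first-order Markov closed form). Returns the
    per-trinucleotide BoostRecord table (D1 = biased/GC-rich class,
    D2 = neutral/GC-poor class).
    """
    from . import boost_enrichment, markov_null, mut_equilibrium
    from .genome_io import trinuc_profile

    matrix = DEFAULT_MUTATION_MATRIX if matrix is None else matrix
    rng = np.random.default_rng(seed)
    classes = {"top": [], "bottom": []}
    for i in range(n_blocks):
        block = random_sequence(block_length, ancestral_gc, rng)
        biased = i % 2 == 1
        evolved, _ = evolve_sequence(block, matrix, t, rng,
                                     B=B if biased else 1.0, rounds=rounds)
        classes["top" if biased else "bottom"].append(evolved)

    def expectation(seqs):
        ref = {"c": "".join(seqs)}
        df = sample_denovo(ref, matrix, n_mutations_per_class, rng)
        muts = [
            mut_equilibrium.MutationRecord(r.Chr, int(r.Pos), r.Ref, r.Alt)
            for r in df.itertuples(index=False)
        ]
        mat = mut_equilibrium.build_dinuc_matrix(muts, ref, list(ref.values()))
        stationary = mut_equilibrium.solve_stationary(mat.rates)
        return markov_null.closed_form_trinuc(markov_null.markov_from_dinuc(stationary))

    return boost_enrichment.boost_table(
        trinuc_profile(classes["top"]), expectation(classes["top"]),
        trinuc_profile(classes["bottom"]), expectation(classes["bottom"]),
        sequence_class="synthetic",
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as FASTA/GFF3/TSV/JSON files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "reference.fa", "w") as fh:
        for name, seq in bundle.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    (out / "annotation.gff3").write_text("\n".join(bundle.gff_lines) + "\n")
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gene_id, tips in bundle.trios.items():
        with open(aln_dir / f"{gene_id}.fa", "w") as fh:
            for role, seq in zip(("ingroup1", "ingroup2", "outgroup"), tips):
                fh.write(f">{role}\n{seq}\n")
    if bundle.mutations is not None:
        bundle.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    if bundle.recomb_map is not None:
        bundle.recomb_map[["contig", "start", "end", "rate"]].to_csv(
            out / "recombination.tsv", sep="\t", index=False, header=False
        )
    if bundle.abundance is not None:
        with open(out / "abundance.tsv", "w") as fh:
            for gid, ppm in bundle.abundance.items():
                fh.write(f"{gid}\t{ppm:.4f}\n")
    (out / "truth.json").write_text(json.dumps(bundle.truth(), indent=1))
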