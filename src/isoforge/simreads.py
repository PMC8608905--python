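"""Long-read cDNA simulator with an RNA 5'-decay gamma model, plus the
package's toy-reference generator.

Reads are drawn from template transcripts (not from a read-length
distribution as in genomic long-read simulators): a template is sampled
with probability proportional to relative expression x transcript
length, a gamma-distributed number of bases is removed from its 5' end
(RNA decay; the 3' end is kept exact, matching the much higher fidelity
of long-read TTS calls), and per-base substitution / insertion /
deletion errors are applied so that the read length responds to the
errors inserted.

The decay model is fitted from observed 5' shortenings by the method of
L-moments for the gamma distribution (the classic rational
approximation of the L-CV -> shape relation), which is robust to the
heavy right tail produced by reads mis-assigned to distant annotated
TSSs; fit input is truncated at 10 kb by default for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import revcomp
from .genome_model import ExonChain
from .io_formats import BreakpointRecord, ReadRecord, ReferenceAnnotation

__all__ = [
    "DecayModel",
    "ErrorModel",
    "LengthDistribution",
    "ToyReference",
    "fit_decay_gamma",
    "gamma_from_l_moments",
    "sampling_weights",
    "simulate_reads",
    "measure_shortening",
    "make_toy_reference",
    "transcript_sequence",
    "truncate_chain_5prime",
    "perfect_read_records",
]

MIN_READ_LENGTH = 200  # shortest surviving read, per the library prep setting


@dataclass
class DecayModel:
    """5' shortening length in nt ~ Gamma(shape, scale)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError("shape must be finite and > 0")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scale must be finite and > 0")

    @property
    def mean(self) -> float:
        return self.shape * self.scale


@dataclass
class ErrorModel:
    """Independent per-base substitution / insertion / deletion rates."""

    p_sub: float = 0.01
    p_ins: float = 0.01
    p_del: float = 0.01

    def __post_init__(self) -> None:
        for p in (self.p_sub, self.p_ins, self.p_del):
            if not 0 <= p < 1:
                raise ValueError("error rates must be in [0, 1)")
        if self.p_sub + self.p_ins + self.p_del >= 1:
            raise ValueError("total error rate must be < 1")

    @property
    def is_zero(self) -> bool:
        return self.p_sub == self.p_ins == self.p_del == 0


@dataclass
class LengthDistribution:
    """Target read-length model used when no decay fit is available:
    either log-normal(mu, sigma) or an empirical sample of lengths that
    is permuted onto the reads."""

    mu: float = 8.0
    sigma: float = 0.6
    empirical: np.ndarray | None = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.empirical is not None:
            lengths = np.asarray(self.empirical, dtype=float)
            if (lengths <= 0).any():
                raise ValueError("empirical lengths must be > 0")
            reps = int(np.ceil(n / len(lengths)))
            pool = np.tile(lengths, reps)
            return rng.permutation(pool)[:n]
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


# ---------------------------------------------------------------------------
# Gamma fit by L-moments
# ---------------------------------------------------------------------------

def _sample_l_moments(x: np.ndarray):
    """First two sample L-moments from order statistics (unbiased
    probability-weighted moment estimators)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    b0 = x.mean()
    w = np.arange(n) / (n - 1)
    b1 = float(np.mean(w * x))
    return b0, 2 * b1 - b0


def fit_decay_gamma(shortenings, truncate_at: float | None = 10000.0) -> DecayModel:
    """Fit Gamma(shape, scale) to observed 5' shortenings by L-moments.

    Uses the two-branch rational approximation of the gamma shape as a
    function of the L-CV t = l2/l1 (split at t = 0.5), then
    scale = l1 / shape.  Values above ``truncate_at`` are discarded
    before fitting (pass None to disable); zeros are allowed.
    """
    x = np.asarray(list(shortenings), dtype=float)
    if truncate_at is not None:
        x = x[x <= truncate_at]
    if len(x) < 20:
        raise ValueError(f"need >= 20 values to fit (have {len(x)})")
    if (x < 0).any():
        raise ValueError("shortenings must be >= 0")
    l1, l2 = _sample_l_moments(x)
    return gamma_from_l_moments(l1, l2)


def gamma_from_l_moments(l1: float, l2: float) -> DecayModel:
    """Invert the gamma L-moment relation: given location l1 and scale
    l2, return Gamma(shape, scale) with those population L-moments
    (rational approximation in the L-CV t = l2/l1, two branches split
    at t = 0.5); scale = l1 / shape."""
    if l1 <= 0 or l2 <= 0:
        raise ValueError("L-moments must be positive")
    t = l2 / l1
    if t >= 1:
        raise ValueError("L-CV out of gamma range")
    if t < 0.5:
        z = np.pi * t * t
        alpha = (1.0 - 0.3080 * z) / (z * (1.0 + z * (-0.05812 + 0.01765 * z)))
    else:
        z = 1.0 - t
        alpha = z * (0.7213 - 0.5947 * z) / (1.0 + z * (-2.1817 + 1.2113 * z))
    if not (np.isfinite(alpha) and alpha > 0):
        raise ValueError("L-CV out of gamma range")
    return DecayModel(shape=float(alpha), scale=float(l1 / alpha))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def sampling_weights(rel_expr, lengths) -> np.ndarray:
    """Template sampling probabilities, proportional to relative
    expression x transcript length (reconstituting the length-dependent
    yield of SMRT cDNA sequencing)."""
    e = np.asarray(rel_expr, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if (e < 0).any():
        raise ValueError("expression must be >= 0")
    w = e * ln
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    return w / total


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def _apply_errors(seq: str, err: ErrorModel, rng: np.random.Generator):
    """Insert per-base errors; returns (sequence, n_sub, n_ins, n_del)."""
    if err.is_zero:
        return seq, 0, 0, 0
    codes = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    L = len(codes)
    u = rng.random(L)
    sub = u < err.p_sub
    ins = (u >= err.p_sub) & (u < err.p_sub + err.p_ins)
    dele = (u >= err.p_sub + err.p_ins) & (u < err.p_sub + err.p_ins + err.p_del)
    out = codes.copy()
    if sub.any():
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    keep_counts = np.ones(L, dtype=np.int64)
    keep_counts[dele] = 0
    keep_counts[ins] = 2
    idx = np.repeat(np.arange(L), keep_counts)
    res = out[idx]
    if ins.any():
        # the second copy of each inserted position becomes a random base
        second = np.zeros(len(idx), dtype=bool)
        second[1:] = idx[1:] == idx[:-1]
        res[second] = rng.integers(0, 4, size=int(second.sum()))
    return _BASES[res].tobytes().decode(), int(sub.sum()), int(ins.sum()), int(dele.sum())


def simulate_reads(
    transcriptome: dict,
    rel_expr,
    n_reads: int,
    err: ErrorModel | None = None,
    decay: DecayModel | None = None,
    length_dist: LengthDistribution | None = None,
    seed: int = 0,
    read_prefix: str = "read",
    quality_char: str = "I",
    min_length: int = MIN_READ_LENGTH,
    max_redraws: int = 100,
):
    """Simulate long cDNA reads from a transcriptome.

    ``transcriptome``: transcript_id -> sequence (5'->3').
    ``rel_expr``: transcript_id -> relative expression, or an array in
    transcriptome order.  Exactly one of ``decay`` / ``length_dist``
    shapes the 5' shortening (both None = full-length reads).

    Returns (reads, truth): reads are (read_id, sequence, quality)
    triples; truth is a DataFrame with read_id, transcript_id,
    shortening and error counts.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if decay is not None and length_dist is not None:
        raise ValueError("give at most one of decay / length_dist")
    err = err or ErrorModel(0.0, 0.0, 0.0)
    rng = np.random.default_rng(seed)
    tids = list(transcriptome)
    seqs = [transcriptome[t] for t in tids]
    if any(len(s) == 0 for s in seqs):
        raise ValueError("transcript sequences must be non-empty")
    lengths = np.array([len(s) for s in seqs], dtype=float)
    if isinstance(rel_expr, dict):
        expr = np.array([rel_expr[t] for t in tids], dtype=float)
    else:
        expr = np.asarray(rel_expr, dtype=float)
    probs = sampling_weights(expr, lengths)

    reads, truth_rows = [], []
    for i in range(n_reads):
        tix = int(rng.choice(len(tids), p=probs))
        s = 0
        if decay is not None:
            for _ in range(max_redraws):
                s = int(rng.gamma(decay.shape, decay.scale))
                if len(seqs[tix]) - s >= min_length:
                    break
                tix = int(rng.choice(len(tids), p=probs))
            else:
                s = 0  # give up shortening rather than looping forever
        elif length_dist is not None:
            target = int(length_dist.draw(1, rng)[0])
            target = max(min(target, len(seqs[tix])), min(min_length, len(seqs[tix])))
            s = len(seqs[tix]) - target
        seq = seqs[tix][s:] if s > 0 else seqs[tix]
        seq, n_sub, n_ins, n_del = _apply_errors(seq, err, rng)
        rid = f"{read_prefix}{i + 1:07d}"
        reads.append((rid, seq, quality_char * len(seq)))
        truth_rows.append((rid, tids[tix], s, n_sub, n_ins, n_del))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "transcript_id", "shortening", "n_sub", "n_ins", "n_del"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Shortening measurement from aligned reads
# ---------------------------------------------------------------------------

def measure_shortening(reads, ann: ReferenceAnnotation) -> list:
    """Per read, the distance (in transcript coordinates) from its 5'
    end to the nearest annotated TSS upstream of it, among annotated
    transcripts the read is a 5'-truncated form of (or equal to).
    Reads with no upstream TSS are excluded.
    """
    by_key: dict = {}
    for tid, chain in ann.transcripts.items():
        jt = tuple((j.donor_pos, j.acceptor_pos) for j in chain.junctions)
        by_key.setdefault((chain.chrom, chain.strand), []).append((tid, chain, jt))

    out = []
    for r in reads:
        chain = r.chain
        candidates = by_key.get((chain.chrom, chain.strand), [])
        best = None
        rj = tuple((j.donor_pos, j.acceptor_pos) for j in chain.junctions)
        for tid, t, jt in candidates:
            k = len(rj)
            if k > len(jt):
                continue
            if k:
                suffix = jt[-k:] if chain.strand == "+" else jt[:k]
                if suffix != rj:
                    continue
            elif not (t.start <= chain.start and chain.end <= t.end):
                continue
            d = _transcript_offset(t, chain)
            if d is not None and d >= 0 and (best is None or d < best):
                best = d
        if best is not None:
            out.append(best)
    return out


def _transcript_offset(t: ExonChain, read: ExonChain):
    """Transcript-coordinate distance from t's TSS to the read 5' end."""
    pos = read.start if t.strand == "+" else read.end
    off = 0
    exons = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    for s, e in exons:
        if t.strand == "+":
            if pos < s:
                return None  # read 5' end in an intron of t
            if pos < e:
                return off + (pos - s)
            off += e - s
        else:
            if pos > e:
                return None
            if pos > s:
                return off + (e - pos)
            off += e - s
    return None


# ---------------------------------------------------------------------------
# Perfect-alignment records (simulation truth -> ReadRecords)
# ---------------------------------------------------------------------------

def truncate_chain_5prime(chain: ExonChain, shortening: int) -> ExonChain:
    """Remove ``shortening`` transcript bases from the chain's 5' end."""
    if shortening <= 0:
        return chain
    exons = list(chain.exons if chain.strand == "+" else reversed(chain.exons))
    left = shortening
    new = []
    for i, (s, e) in enumerate(exons):
        ln = e - s
        if left >= ln:
            left -= ln
            continue
        if chain.strand == "+":
            new.append((s + left, e))
        else:
            new.append((s, e - left))
        new.extend(exons[i + 1 :])
        break
    if not new:
        raise ValueError("shortening removes the whole transcript")
    if chain.strand == "-":
        new = list(reversed(new))
    return ExonChain(chain.chrom, chain.strand, new)


def perfect_read_records(truth: pd.DataFrame, ann: ReferenceAnnotation,
                         sample_id: str, fl_counts: dict | None = None) -> list:
    """Turn a simulation truth table into the ReadRecords an ideal
    spliced aligner would produce (exact chains, 5' truncated by the
    simulated shortening)."""
    fl_counts = fl_counts or {}
    out = []
    for row in truth.itertuples(index=False):
        chain = truncate_chain_5prime(ann.transcripts[row.transcript_id], int(row.shortening))
        out.append(
            ReadRecord(
                read_id=row.read_id,
                sample_id=sample_id,
                chain=chain,
                fl_count=int(fl_counts.get(row.read_id, 1)),
                mapq=60,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Toy reference generator
# ---------------------------------------------------------------------------

@dataclass
class ToyReference:
    genome: dict  # chrom -> sequence
    annotation: ReferenceAnnotation
    rearranged_genome: dict | None = None
    breakpoints: list = field(default_factory=list)

    def transcript_sequences(self) -> dict:
        return {
            tid: transcript_sequence(self.genome, chain)
            for tid, chain in self.annotation.transcripts.items()
        }


def transcript_sequence(genome: dict, chain: ExonChain) -> str:
    seq = "".join(str(genome[chain.chrom][s:e]) for s, e in chain.exons)
    return revcomp(seq) if chain.strand == "-" else seq


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def make_toy_reference(
    n_genes: int = 10,
    isoforms_per_gene: int = 3,
    seed: int = 0,
    rearrange: bool = False,
    exons_per_gene: tuple = (4, 8),
    exon_len: tuple = (120, 400),
    intron_len: tuple = (200, 800),
    spacing: int = 2000,
    chrom: str = "chrT",
) -> ToyReference:
    """Build a random toy genome + annotation with GT-AG introns.

    Every gene gets a full-length isoform plus exon-skipping variants;
    all isoforms retain the transcript-5'-most exon and its junction so
    that no isoform's junction chain is a 5'-truncated suffix of a
    sibling's (keeps decay-free simulations exactly recoverable).  With
    ``rearrange=True``, a second genome carrying a translocation between
    two gene loci (breakpoints in introns, so the novel junction is
    GT-AG) and its breakpoint truth are returned.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    pieces = [_random_seq(rng, spacing)]
    pos = spacing
    transcripts, transcript_gene, genes = {}, {}, {}
    gene_layouts = []  # (gene_id, strand, exon list) for rearrangement

    for g in range(1, n_genes + 1):
        gid = f"gene{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if rearrange and g in (1, n_genes):
            strand = "+"  # rearrangement partners must be co-oriented
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        for k in range(n_ex):
            e_len = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exon_seq = _random_seq(rng, e_len)
            exons.append((pos, pos + e_len))
            pieces.append(exon_seq)
            pos += e_len
            if k < n_ex - 1:
                i_len = int(rng.integers(intron_len[0], intron_len[1] + 1))
                intron = _random_seq(rng, i_len)
                if strand == "+":
                    intron = "GT" + intron[2:-2] + "AG"
                else:
                    intron = "CT" + intron[2:-2] + "AC"  # GT-AG on '-'
                pieces.append(intron)
                pos += i_len
        pieces.append(_random_seq(rng, spacing))
        pos += spacing
        gene_layouts.append((gid, strand, exons))

        # isoform 1: all exons; others: skip random internal exons but
        # always keep the transcript-first exon (and hence its junction)
        chains_seen = set()
        genes[gid] = []
        n_iso = min(isoforms_per_gene, max(1, n_ex - 1))
        made = 0
        attempts = 0
        while made < n_iso and attempts < 50:
            attempts += 1
            if made == 0:
                chosen = list(range(n_ex))
            else:
                internal = list(range(1, n_ex - 1)) if strand == "+" else list(range(1, n_ex - 1))
                n_skip = int(rng.integers(1, max(2, len(internal))))
                skip = set(rng.choice(internal, size=min(n_skip, len(internal)), replace=False).tolist())
                first = 0 if strand == "+" else n_ex - 1
                skip.discard(first)
                chosen = [k for k in range(n_ex) if k not in skip]
            if len(chosen) < 2:
                continue
            key = tuple(chosen)
            if key in chains_seen:
                continue
            chains_seen.add(key)
            tid = f"{gid}.t{made + 1}"
            transcripts[tid] = ExonChain(chrom, strand, [exons[k] for k in chosen])
            transcript_gene[tid] = gid
            genes[gid].append(tid)
            made += 1

    genome = {chrom: "".join(pieces)}
    ann = ReferenceAnnotation(transcripts, transcript_gene, genes)
    toy = ToyReference(genome=genome, annotation=ann)

    if rearrange and n_genes >= 2:
        plus_genes = [g for g in gene_layouts if g[1] == "+" and len(g[2]) >= 2]
        if len(plus_genes) < 2:
            raise ValueError("rearrangement needs two multi-exon '+' genes")
        # make the planted fusion junction the unique canonical candidate
        # within a refinement radius: flatten the donor neighbourhood so no
        # spurious GT can pair with a downstream AG at a joint offset
        seq = genome[chrom]
        donor = plus_genes[0][2][0][1]
        pad = 16
        seq = seq[: donor - pad] + "C" * pad + seq[donor : donor + 2] + "C" * pad + seq[donor + 2 + pad :]
        genome[chrom] = seq
        toy.genome = genome
        toy.rearranged_genome, toy.breakpoints = _make_rearrangement(
            seq, gene_layouts, chrom
        )
    return toy


def _make_rearrangement(seq: str, gene_layouts, chrom: str):
    """Translocate: join the first intron-interior of a '+' gene A to an
    intron-interior upstream of a later exon of another '+' gene B.
    The junction A-exon1 .. B-exon_k is then spliceable with GT-AG."""
    plus_genes = [g for g in gene_layouts if g[1] == "+" and len(g[2]) >= 2]
    if len(plus_genes) < 2:
        raise ValueError("rearrangement needs two multi-exon '+' genes")
    (gidA, _, exA), (gidB, _, exB) = plus_genes[0], plus_genes[-1]
    # breakpoint A: inside the first intron of gene A (keep donor GT)
    intronA = (exA[0][1], exA[1][0])
    posA = intronA[0] + (intronA[1] - intronA[0]) // 2
    # breakpoint B: inside the intron upstream of gene B's last exon (keep acceptor AG)
    intronB = (exB[-2][1], exB[-1][0])
    posB = intronB[0] + (intronB[1] - intronB[0]) // 2
    fused = seq[:posA] + seq[posB:]
    rearranged = {f"{chrom}_fused": fused}
    bps = [BreakpointRecord(chrom, posA, "+", chrom, posB, "+", f"sv_{gidA}_{gidB}")]
    return rearranged, bps
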