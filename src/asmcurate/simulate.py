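"""Synthetic diploid assemblies, reads and annotations with known truth.

The generator emulates the failure mode the purge stage exists for: a
diploid genome whose heterozygous regions come out of assembly twice, as a
long contig from one haplotype plus a shorter, partially redundant contig
(haplotig) from the other. It also emits GC/coverage-shifted foreign
contigs, one circular-origin mitochondrion-like contig with its reference,
planted SSR loci at recorded coordinates, and error-bearing short reads —
everything labelled in a TruthTable so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import SeqRecord, gc_fraction
from .errors import ValidationError
from .purge import ContigAnnotation, PurgeDecision
from .core import AlignmentBlock

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationParams:
    """Study conditions for one synthetic diploid assembly."""

    genome_len: int = 2_000_000
    heterozygosity: float = 0.01  # per-base SNP rate between haplotypes
    n_haplotig_pairs: int = 20
    n_unique_contigs: int = 20
    contig_len_range: tuple[int, int] = (10_000, 30_000)
    n_contaminants: int = 3
    contaminant_gc_shift: float = 0.25  # added to the host GC fraction
    contaminant_coverage: float = 5.0
    host_coverage: float = 60.0
    mito_len: int = 16_000
    read_len: int = 150
    read_error_rate: float = 0.01
    #: (motif, n_units, count) triples inserted into unique contigs
    planted_ssrs: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("A", 12, 3), ("AC", 8, 3), ("AAT", 6, 3), ("ACGT", 5, 3)]
    )
    overlap_fraction_range: tuple[float, float] = (0.85, 0.95)
    host_gc: float = 0.35
    seed: int = 0

    def __post_init__(self):
        for r in (self.heterozygosity, self.read_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate {r} outside [0,1]")
        if self.genome_len <= 0 or self.mito_len <= 0 or self.read_len <= 0:
            raise ValidationError("lengths must be positive")
        lo, hi = self.contig_len_range
        if not 0 < lo <= hi:
            raise ValidationError("bad contig_len_range")


@dataclass
class HaplotigPairTruth:
    kept_expected_id: str
    removable_id: str
    true_overlap_fraction: float
    true_identity: float


@dataclass
class TruthTable:
    haplotig_pairs: list[HaplotigPairTruth]
    contaminant_ids: list[str]
    mito_id: str
    #: (contig_id, start, end, motif, n_units) for every planted SSR
    ssr_loci: list[tuple[str, int, int, str, int]]


@dataclass
class SimulationResult:
    contigs: list[SeqRecord]
    annotations: list[ContigAnnotation]
    truth: TruthTable
    mito_reference: SeqRecord
    #: blast6-style hits of the mito contig against the reference
    mito_hits: list[AlignmentBlock]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _mutate_haplotype(
    rng: np.random.Generator, arr: np.ndarray, snp_rate: float, indel_rate: float
) -> tuple[np.ndarray, int]:
    """Derive the alternate haplotype: substitutions at snp_rate, 1-10 bp
    indels at indel_rate. Returns (mutated array, realized SNP count)."""
    out = arr.copy()
    snp_mask = rng.random(out.size) < snp_rate
    n_snp = int(snp_mask.sum())
    if n_snp:
        out[snp_mask] = (out[snp_mask] + rng.integers(1, 4, n_snp).astype(np.uint8)) % 4
    n_indel = rng.binomial(out.size, indel_rate) if indel_rate > 0 else 0
    if n_indel:
        sites = np.sort(rng.choice(out.size, size=min(n_indel, out.size), replace=False))
        pieces: list[np.ndarray] = []
        prev = 0
        for site in sites:
            pieces.append(out[prev:site])
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                prev = min(out.size, site + size)
            else:  # insertion
                pieces.append(_random_seq(rng, size, 0.5))
                prev = site
        pieces.append(out[prev:])
        out = np.concatenate(pieces) if pieces else out
    return out, n_snp


def simulate_diploid_assembly(params: Optional[SimulationParams] = None) -> SimulationResult:
    """Build a labelled synthetic assembly.

    Disjoint windows of one ancestral sequence become: haplotig pairs (a
    long haplotype-A contig plus a shorter haplotype-B contig lying
    mostly — by the drawn overlap fraction — within the long one's
    window), unique contigs from homozygous regions, foreign contigs with
    shifted GC and low coverage, and a rotated copy of a circular
    mitochondrion. Fully reproducible from the seed.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.contig_len_range
    spacer = 200
    h = params.heterozygosity
    indel_rate = h / 10.0

    # budget check before generating anything big
    worst = params.n_haplotig_pairs * (2 * hi + spacer) + params.n_unique_contigs * (hi + spacer)
    if worst > params.genome_len * 3:
        raise ValidationError(
            f"contig_len_range {params.contig_len_range} needs up to {worst} bp "
            f"of ancestral sequence but genome_len is {params.genome_len}"
        )

    # draw all layout decisions first so the ancestral length needed is known
    pair_draws = []
    need = 0
    for _ in range(params.n_haplotig_pairs):
        a, b = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
        long_len, short_len = max(a, b), min(a, b)
        f = float(rng.uniform(*params.overlap_fraction_range))
        overlap = int(round(f * short_len))
        overlap = min(overlap, short_len, long_len)
        region = long_len + (short_len - overlap)
        pair_draws.append((long_len, short_len, overlap, region))
        need += region + spacer
    uniq_lens = [int(rng.integers(lo, hi + 1)) for _ in range(params.n_unique_contigs)]
    need += sum(u + spacer for u in uniq_lens)
    if need > params.genome_len:
        raise ValidationError(
            f"layout needs {need} bp of ancestral sequence; genome_len "
            f"{params.genome_len} is too small for contig_len_range {params.contig_len_range}"
        )

    ancestral = _random_seq(rng, need, params.host_gc)
    cursor = 0
    contigs: list[SeqRecord] = []
    truth_pairs: list[HaplotigPairTruth] = []

    for i, (long_len, short_len, overlap, region) in enumerate(pair_draws):
        win = ancestral[cursor : cursor + region]
        cursor += region + spacer
        long_arr = win[:long_len]
        short_src = win[long_len - overlap : long_len - overlap + short_len]
        short_arr, n_snp = _mutate_haplotype(rng, short_src, h, indel_rate)
        long_id, short_id = f"pair{i:03d}L", f"pair{i:03d}S"
        contigs.append(SeqRecord(long_id, _decode(long_arr)))
        contigs.append(SeqRecord(short_id, _decode(short_arr)))
        snp_in_overlap = n_snp * overlap / short_len  # SNPs are uniform
        truth_pairs.append(HaplotigPairTruth(
            long_id, short_id,
            true_overlap_fraction=overlap / short_len,
            true_identity=1.0 - snp_in_overlap / overlap if overlap else 1.0,
        ))

    uniq_records: list[SeqRecord] = []
    for i, ulen in enumerate(uniq_lens):
        arr = ancestral[cursor : cursor + ulen]
        cursor += ulen + spacer
        uniq_records.append(SeqRecord(f"uniq{i:03d}", _decode(arr)))

    ssr_truth = _plant_ssrs(rng, uniq_records, params.planted_ssrs)
    contigs.extend(uniq_records)

    contaminant_ids: list[str] = []
    cont_gc = min(0.95, params.host_gc + params.contaminant_gc_shift)
    for i in range(params.n_contaminants):
        clen = int(rng.integers(lo, hi + 1))
        cid = f"contam{i:02d}"
        contigs.append(SeqRecord(cid, _decode(_random_seq(rng, clen, cont_gc))))
        contaminant_ids.append(cid)

    mito_arr = _random_seq(rng, params.mito_len, params.host_gc)
    rotation = int(rng.integers(1, params.mito_len))
    mito_contig_arr = np.concatenate([mito_arr[rotation:], mito_arr[:rotation]])
    mito_id = "mito"
    contigs.append(SeqRecord(mito_id, _decode(mito_contig_arr)))
    mito_reference = SeqRecord("mito_ref", _decode(mito_arr))
    mito_hits = _mito_hit_table(mito_id, "mito_ref", params.mito_len, rotation)

    annotations = []
    for rec in contigs:
        if rec.id in contaminant_ids:
            cov, taxon, tr, bu = params.contaminant_coverage, "Bacteria", False, False
        elif rec.id == mito_id:
            cov, taxon, tr, bu = params.host_coverage * 20, "Arthropoda", False, False
        else:
            cov, taxon, tr, bu = params.host_coverage, "Arthropoda", True, True
        annotations.append(ContigAnnotation(
            rec.id, len(rec), gc_fraction(rec.sequence), cov,
            best_hit_taxon=taxon, has_transcript_evidence=tr, has_busco_gene=bu,
        ))

    truth = TruthTable(truth_pairs, contaminant_ids, mito_id, ssr_truth)
    return SimulationResult(contigs, annotations, truth, mito_reference, mito_hits)


def _plant_ssrs(
    rng: np.random.Generator,
    records: list[SeqRecord],
    planted: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int, str, int]]:
    """Overwrite windows of the given records with perfect SSRs.

    Boundary bases are forced to break the repeat (the base before the
    locus differs from the motif's last base; the base after differs from
    its first), so detection recovers the exact planted coordinates.
    """
    truth: list[tuple[str, int, int, str, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(records))}
    if not records:
        if planted:
            raise ValidationError("no contigs available for planting SSRs")
        return truth
    for motif, n_units, count in planted:
        motif = motif.upper()
        span = len(motif) * n_units
        for _ in range(count):
            for _attempt in range(200):
                ri = int(rng.integers(0, len(records)))
                seq = records[ri].sequence
                if len(seq) < span + 4:
                    continue
                start = int(rng.integers(2, len(seq) - span - 2))
                pad = (start - len(motif) - 2, start + span + len(motif) + 2)
                if any(s < pad[1] and pad[0] < e for s, e in occupied[ri]):
                    continue
                guard_l = _other_base(rng, motif[-1])
                guard_r = _other_base(rng, motif[0])
                new = (seq[: start - 1] + guard_l + motif * n_units + guard_r
                       + seq[start + span + 1 :])
                records[ri] = SeqRecord(records[ri].id, new)
                occupied[ri].append(pad)
                truth.append((records[ri].id, start, start + span, motif, n_units))
                break
            else:
                raise ValidationError(
                    f"could not place planted SSR ({motif}){n_units} after 200 tries"
                )
    return truth


def _other_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _mito_hit_table(
    contig_id: str, ref_id: str, mito_len: int, rotation: int
) -> list[AlignmentBlock]:
    """The two exact hits a rotated circular contig has against its
    reference, in blast6 form (synthetic stand-in for a real search)."""
    head = mito_len - rotation
    hits = []
    if head > 0:
        hits.append(AlignmentBlock(contig_id, ref_id, 0, head, rotation, mito_len,
                                   "+", head, 1.0, float(head), 1e-180, "blast6"))
    if rotation > 0:
        hits.append(AlignmentBlock(contig_id, ref_id, head, mito_len, 0, rotation,
                                   "+", rotation, 1.0, float(rotation), 1e-180, "blast6"))
    return hits


def simulate_reads(
    contigs: Sequence[SeqRecord],
    coverage: float,
    read_len: int,
    error_rate: float,
    seed: int,
) -> list[SeqRecord]:
    """Uniform shotgun reads with substitution errors.

    Strand is random; correct bases get Q40, error positions Q10. The
    expected base yield is coverage x total length (within one read).
    """
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    for rec in contigs:
        n = len(rec)
        if read_len > n:
            raise ValidationError(
                f"read_len {read_len} exceeds contig {rec.id} length {n}"
            )
        n_reads = int(round(coverage * n / read_len))
        if n_reads == 0:
            continue
        arr = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)
        enc = np.full(arr.size, 4, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            enc[arr == b] = i
        starts = rng.integers(0, n - read_len + 1, n_reads)
        mat = enc[starts[:, None] + np.arange(read_len)[None, :]]
        minus = rng.random(n_reads) < 0.5
        rev = mat[minus][:, ::-1]
        mat[minus] = np.where(rev < 4, 3 - rev, 4)  # revcomp, N stays N
        n_mask = mat > 3
        err = (rng.random(mat.shape) < error_rate) & ~n_mask
        if err.any():
            mat[err] = (mat[err] + rng.integers(1, 4, int(err.sum())).astype(np.uint8)) % 4
        qual = np.full(mat.shape, 40, dtype=np.int64)
        qual[err] = 10
        chars = np.frombuffer(b"ACGTN", dtype=np.uint8)[np.minimum(mat, 4)]
        for i in range(n_reads):
            reads.append(SeqRecord(
                f"{rec.id}_read{i:06d}",
                chars[i].tobytes().decode("ascii"),
                qual[i].tolist(),
            ))
    return reads


@dataclass
class PurgeEvaluation:
    precision: float
    recall: float
    n_removed: int
    n_removable: int
    zero_removals: bool


def evaluate_purge(
    decisions: Sequence[PurgeDecision], truth: TruthTable
) -> PurgeEvaluation:
    """Score purge decisions against the simulation truth.

    A true positive is a non-restored removal whose removed_id is a
    removable haplotig in the truth table. With zero removals, precision
    is reported as 1.0 with the zero-removal flag set.
    """
    removable = {p.removable_id for p in truth.haplotig_pairs}
    removed = [d.removed_id for d in decisions if not d.restored]
    tp = sum(1 for r in removed if r in removable)
    precision = tp / len(removed) if removed else 1.0
    recall = tp / len(removable) if removable else 1.0
    return PurgeEvaluation(precision, recall, len(removed), len(removable),
                           zero_removals=not removed)
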