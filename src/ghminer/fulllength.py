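"""Full-length enzyme recovery with homopolymer frameshift correction.

Contigs of at least 1 kb are searched in all six translated frames against
an EC-annotated reference enzyme set (Smith-Waterman local alignments,
BLOSUM62, affine gaps, Karlin-Altschul E-values).  A contig-reference pair
becomes a candidate when its chained alignment segments cover >= 90% of the
reference, the best segment is significant (E <= 1e-10 by default), and the
reference has a known enzymatic function (an EC number).

Pyrosequencing indels break a coding region into alignment segments that sit
in *different* frames.  Each such frame switch delineates a small window in
which the correction stage tries every single-base deletion and every
single-base duplication, keeps the edit that strictly improves the total
translated-alignment score, and repeats until no frame switches remain.
Accepted edits never lower the score, and running the corrector on its own
output is a no-op.  Gene models are then called on the corrected contig by a
simple longest-ORF caller (maximal stop-free intervals >= 300 nt, most
upstream ATG/GTG/TTG start) — deliberately minimal, and labelled
``orf-caller`` in reports to distinguish it from trained gene finders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .gh_inventory import DepthContig, six_frame_translate

# minimum stop-free peptide segment worth aligning; shorter fragments carry
# no usable signal and inflate the HSP list
MIN_SEGMENT_AA = 8


@dataclass
class EnzymeReference:
    """One reference enzyme: peptide, optional EC number, family label."""

    ref_id: str
    peptide: str
    ec: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide or "*" in self.peptide:
            raise ValueError("reference peptide must be non-empty and stop-free")

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class RecoveryParams:
    """Search, filtering and correction parameters.

    Alignment defaults are the standard protein-search settings (BLOSUM62,
    gap open 11 / extend 1) with published ungapped Karlin-Altschul
    constants; ``pad`` is the half-width in nt of the edit-search window
    around each detected frame switch.
    """

    e_max: float = 1e-10
    min_target_coverage: float = 0.90
    min_contig_length: int = 1000
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.3176
    ka_k: float = 0.134
    pad: int = 12
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_target_coverage <= 1.0:
            raise ValueError("min_target_coverage must be in (0,1]")
        if self.e_max <= 0:
            raise ValueError("e_max must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        aln = Align.PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = substitution_matrices.load(self.matrix)
        # a gap of length g costs gap_open + g * gap_extend
        aln.open_gap_score = -(self.gap_open + self.gap_extend)
        aln.extend_gap_score = -self.gap_extend
        return aln


@dataclass
class HSP:
    """One local translated-alignment segment (contig frame vs reference)."""

    contig_id: str
    ref_id: str
    frame: int
    pep_begin: int  # frame-local aa coords, 0-based half-open
    pep_end: int
    ref_begin: int
    ref_end: int
    raw_score: float
    bit_score: float
    evalue: float

    @property
    def strand(self) -> int:
        return 1 if self.frame > 0 else -1

    def nt_span(self, contig_length: int) -> tuple[int, int]:
        """Forward-strand nucleotide span (0-based half-open)."""
        k = abs(self.frame)
        lo = (k - 1) + 3 * self.pep_begin
        hi = (k - 1) + 3 * self.pep_end
        if self.frame > 0:
            return lo, hi
        return contig_length - hi, contig_length - lo


@dataclass
class EditOperation:
    """One single-base edit accepted during frameshift correction."""

    contig_id: str
    position: int  # coordinates at the time of application
    position_input: int  # mapped back to the uncorrected input sequence
    kind: str  # "delete" | "duplicate"
    base: str
    run_length: int
    score_before: float
    score_after: float

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "duplicate"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.score_after < self.score_before:
            raise ValueError("accepted edits must not decrease the score")


@dataclass
class CandidateGene:
    """A recovered full-length enzyme candidate."""

    contig_id: str
    corrected_sequence: str
    peptide: str
    ref_id: str
    ec: str | None
    family: str | None
    coverage: float
    n_corrections: int
    trunc_n: int
    trunc_c: int
    gene_start: int
    gene_end: int
    strand: str
    edits: list[EditOperation] = field(default_factory=list)


@dataclass
class Gene:
    """One ORF call, forward-strand coordinates, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    peptide: str


# ---------------------------------------------------------------------------
# translated search
# ---------------------------------------------------------------------------


def _segments(pep: str):
    """Stop-free segments of a frame translation with their aa offsets."""
    offset = 0
    for seg in pep.split("*"):
        if len(seg) >= MIN_SEGMENT_AA:
            yield offset, seg
        offset += len(seg) + 1


def translated_search(
    contig: DepthContig,
    refs: Sequence[EnzymeReference],
    params: RecoveryParams | None = None,
    max_evalue: float = 10.0,
    skip_length_check: bool = False,
) -> list[HSP]:
    """Local alignments of all six frame translations against every reference.

    Bit scores are ``(lambda * S - ln K) / ln 2`` and
    ``E = m * n * 2**(-bits)`` with m the reference length and n the total
    translated length searched.  Contigs below ``min_contig_length`` raise
    unless ``skip_length_check`` (the corrector re-searches sub-windows).
    """
    params = params or RecoveryParams()
    if not refs:
        raise ValueError("empty reference set")
    if not skip_length_check and len(contig) < params.min_contig_length:
        raise ValueError(
            f"contig {contig.contig_id} is {len(contig)} nt, below the "
            f"{params.min_contig_length} nt search floor"
        )
    aligner = params.aligner()
    matrix = aligner.substitution_matrix
    frames = six_frame_translate(contig.sequence)
    n_total = sum(len(p) for p in frames.values())
    ln2 = np.log(2.0)
    hsps: list[HSP] = []
    for frame, pep in frames.items():
        for offset, seg in _segments(pep):
            for ref in refs:
                alignments = aligner.align(seg, ref.peptide)
                if len(alignments) == 0:
                    continue
                best = alignments[0]
                if float(best.score) <= 0:
                    continue
                for t_lo, t_hi, q_lo, q_hi, score in _xdrop_split(
                    best, seg, ref.peptide, matrix, params
                ):
                    bits = (
                        params.ka_lambda * score - np.log(params.ka_k)
                    ) / ln2
                    evalue = len(ref) * n_total * 2.0 ** (-bits)
                    if evalue > max_evalue:
                        continue
                    hsps.append(
                        HSP(
                            contig_id=contig.contig_id,
                            ref_id=ref.ref_id,
                            frame=frame,
                            pep_begin=offset + t_lo,
                            pep_end=offset + t_hi,
                            ref_begin=q_lo,
                            ref_end=q_hi,
                            raw_score=score,
                            bit_score=float(bits),
                            evalue=float(evalue),
                        )
                    )
    return hsps


#: score drop that terminates an alignment segment, as in BLAST's X-drop:
#: an optimal Smith-Waterman can bridge a long dissimilar stretch (e.g. the
#: out-of-frame region between two compensating indels) with mismatches,
#: hiding the frame structure inside one alignment; splitting at deep score
#: valleys restores the segment view a seeded search would report
XDROP = 20.0


def _xdrop_split(alignment, target: str, query: str, matrix, params):
    """Split one optimal local alignment at score valleys deeper than XDROP.

    Yields ``(t_lo, t_hi, q_lo, q_hi, score)`` sub-segments with positive
    score, in alignment order.
    """
    tgt_blocks, qry_blocks = alignment.aligned
    # per-column scores: residue pairs within blocks, whole gaps lumped
    cols: list[tuple[int, int, int, int, float]] = []
    for b, ((t0, t1), (q0, q1)) in enumerate(zip(tgt_blocks, qry_blocks)):
        if b > 0:
            pt1, pq1 = int(tgt_blocks[b - 1][1]), int(qry_blocks[b - 1][1])
            gap = max(int(t0) - pt1, int(q0) - pq1)
            if gap > 0:
                penalty = -(params.gap_open + params.gap_extend * gap)
                cols.append((pt1, int(t0), pq1, int(q0), float(penalty)))
        for i in range(int(t1) - int(t0)):
            ti, qi = int(t0) + i, int(q0) + i
            s = float(matrix[target[ti], query[qi]])
            cols.append((ti, ti + 1, qi, qi + 1, s))

    def emit(part):
        if not part:
            return
        score = sum(c[4] for c in part)
        if score <= 0:
            return
        yield (part[0][0], part[-1][1], part[0][2], part[-1][3], score)

    stack = [cols]
    while stack:
        part = stack.pop()
        running = 0.0
        peak, peak_idx = 0.0, -1
        split_at = None
        for i, c in enumerate(part):
            running += c[4]
            if running > peak:
                peak, peak_idx = running, i
            elif peak - running >= XDROP:
                split_at = i
                break
        if split_at is None:
            yield from emit(part)
            continue
        # left side ends at the peak; right side restarts at the valley
        # bottom between the peak and the end
        yield from emit(part[: peak_idx + 1])
        running = 0.0
        low, low_idx = 0.0, split_at
        for i in range(peak_idx + 1, len(part)):
            running += part[i][4]
            if running < low:
                low, low_idx = running, i
        stack.append(part[low_idx + 1 :])


def _select_chain(hsps: Sequence[HSP]) -> list[HSP]:
    """Non-redundant same-strand HSP chain, sorted by reference position.

    Picks the strand with the larger total raw score, then greedily accepts
    HSPs by descending score, rejecting any whose reference span overlaps an
    accepted one by more than half of the shorter span.
    """
    by_strand: dict[int, list[HSP]] = {1: [], -1: []}
    for h in hsps:
        by_strand[h.strand].append(h)
    totals = {s: sum(h.raw_score for h in v) for s, v in by_strand.items()}
    strand = max(totals, key=totals.get)
    accepted: list[HSP] = []
    for h in sorted(by_strand[strand], key=lambda x: -x.raw_score):
        redundant = False
        for a in accepted:
            ov = min(h.ref_end, a.ref_end) - max(h.ref_begin, a.ref_begin)
            shorter = min(h.ref_end - h.ref_begin, a.ref_end - a.ref_begin)
            if ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            accepted.append(h)
    return sorted(accepted, key=lambda x: x.ref_begin)


def reference_coverage(hsps: Sequence[HSP], ref: EnzymeReference) -> float:
    """Fraction of the reference covered by the union of chained HSP spans."""
    chain = _select_chain(hsps)
    intervals = sorted((h.ref_begin, h.ref_end) for h in chain)
    covered = 0
    cur_lo, cur_hi = -1, -1
    for lo, hi in intervals:
        if lo > cur_hi:
            covered += cur_hi - cur_lo if cur_hi > cur_lo else 0
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo if cur_hi > cur_lo else 0
    return covered / len(ref)


@dataclass
class CandidatePair:
    contig_id: str
    ref: EnzymeReference
    hsps: list[HSP]
    coverage: float
    best_evalue: float
    total_score: float


def candidate_filter(
    hsps: Sequence[HSP],
    refs: Sequence[EnzymeReference],
    params: RecoveryParams | None = None,
) -> list[CandidatePair]:
    """Keep contig-reference pairs passing coverage, E-value and EC filters."""
    params = params or RecoveryParams()
    ref_by_id = {r.ref_id: r for r in refs}
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.contig_id, h.ref_id), []).append(h)
    passing = []
    for (cid, rid), group in groups.items():
        ref = ref_by_id[rid]
        if ref.ec is None:
            continue
        cov = reference_coverage(group, ref)
        best_e = min(h.evalue for h in group)
        if cov >= params.min_target_coverage and best_e <= params.e_max:
            chain = _select_chain(group)
            passing.append(
                CandidatePair(
                    contig_id=cid,
                    ref=ref,
                    hsps=chain,
                    coverage=cov,
                    best_evalue=best_e,
                    total_score=sum(h.raw_score for h in chain),
                )
            )
    return passing


# ---------------------------------------------------------------------------
# frameshift detection and correction
# ---------------------------------------------------------------------------


def detect_frameshift_candidates(
    hsps: Sequence[HSP],
    contig_length: int,
    params: RecoveryParams | None = None,
) -> list[tuple[int, int]]:
    """Contig windows between reference-consecutive HSPs in different frames.

    Raises on HSPs from both strands (a chimeric candidate is reported, not
    corrected).  Each window is padded by ``pad`` nt and clamped to the
    contig.
    """
    params = params or RecoveryParams()
    if not hsps:
        raise ValueError("need at least one HSP")
    # weak antisense noise is expected; *significant* alignments on both
    # strands mark a chimeric candidate that must not be auto-corrected
    significant_strands = {h.strand for h in hsps if h.evalue <= 1e-5}
    if len(significant_strands) > 1:
        raise ValueError("significant HSPs on both strands: chimeric candidate")
    chain = _select_chain(hsps)
    boundaries: list[tuple[int, int]] = []
    for a, b in zip(chain, chain[1:]):
        if a.frame == b.frame:
            continue
        sa = a.nt_span(contig_length)
        sb = b.nt_span(contig_length)
        edges = sorted([min(sa[1], sb[1]), max(sa[0], sb[0])])
        lo = max(0, edges[0] - params.pad)
        hi = min(contig_length, edges[1] + params.pad)
        boundaries.append((lo, hi))
    return boundaries


def _run_length_at(seq: str, pos: int) -> int:
    base = seq[pos]
    lo = pos
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = pos
    while hi + 1 < len(seq) and seq[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def _score_only(
    seq: str,
    ref: EnzymeReference,
    aligner: Align.PairwiseAligner,
    strands: tuple[int, ...] = (1, -1),
    floor: float = 40.0,
) -> float:
    """Junk-suppressed translated-alignment score of a sequence vs a ref.

    Sums ``max(0, score - floor)`` over the best local score of every
    stop-free segment in every frame of the allowed strands (score-only, no
    traceback).  This is the greedy correction objective: repairing a
    frameshift merges two real fragments into one, removing one ``floor``
    deduction plus the junction gain, so every true fix strictly improves
    the value — while spurious garbage-frame alignments (typically scoring
    around 30) stay below the floor and cannot steer the edit choice.
    """
    from Bio.Seq import Seq as _Seq

    from .gh_inventory import _translate_frame

    best = 0.0
    for strand in strands:
        total = 0.0
        reading = seq if strand > 0 else str(_Seq(seq).reverse_complement())
        for offset in (0, 1, 2):
            pep = _translate_frame(reading, offset)
            for _, seg in _segments(pep):
                s = aligner.score(seg, ref.peptide)
                if s > floor:
                    total += s - floor
        best = max(best, total)
    return best


def correct_frameshifts(
    contig: DepthContig,
    ref: EnzymeReference,
    params: RecoveryParams | None = None,
) -> tuple[DepthContig, list[EditOperation]]:
    """Greedy single-base frameshift correction against one reference.

    Iterates: find frame-switch boundaries, try every single-base deletion
    and duplication inside each padded window, apply the edit with the best
    strictly-improved chained translated-alignment score (ties broken toward
    longer homopolymer runs, then leftmost position — the expected
    pyrosequencing error locus), and repeat until no boundary remains, no
    edit improves, or ``max_iterations`` is reached.  The final score is
    never below the input score; re-running on corrected output is a no-op.
    """
    params = params or RecoveryParams()
    aligner = params.aligner()
    seq = contig.sequence
    # maps current positions back to input coordinates
    orig_index = list(range(len(seq)))
    edits: list[EditOperation] = []
    seen: set[str] = {seq}

    def hsps_for(s: str) -> list[HSP]:
        return translated_search(
            DepthContig(contig.contig_id, s, contig.n_reads),
            [ref],
            params,
            skip_length_check=True,
        )

    for _ in range(params.max_iterations):
        hsps = hsps_for(seq)
        if not hsps:
            break
        try:
            boundaries = detect_frameshift_candidates(hsps, len(seq), params)
        except ValueError:
            warnings.warn(
                f"{contig.contig_id}: chimeric HSPs, correction aborted"
            )
            break
        if not boundaries:
            break
        totals = {1: 0.0, -1: 0.0}
        for h in hsps:
            totals[h.strand] += h.raw_score
        strand = (1,) if totals[1] >= totals[-1] else (-1,)
        # score only the aligned region (plus margin): local alignment
        # scores are unchanged and the edit enumeration gets much cheaper
        spans = [h.nt_span(len(seq)) for h in hsps] + list(boundaries)
        reg_lo = max(0, min(s[0] for s in spans) - 60)
        reg_hi = min(len(seq), max(s[1] for s in spans) + 60)
        sub = seq[reg_lo:reg_hi]
        base_score = _score_only(sub, ref, aligner, strand)
        best_edit = None  # ((score, post-edit run length, -pos), pos, kind, seq)
        for lo, hi in boundaries:
            for pos in range(lo, min(hi, len(seq))):
                p = pos - reg_lo
                for kind in ("delete", "duplicate"):
                    run = _run_length_at(seq, pos)
                    if kind == "delete":
                        cand = sub[:p] + sub[p + 1 :]
                        run_after = run - 1
                    else:
                        cand = sub[:p] + sub[p] + sub[p:]
                        run_after = run + 1
                    score = _score_only(cand, ref, aligner, strand)
                    if score <= base_score:
                        continue
                    # among equal scores prefer the edit that leaves the
                    # longest homopolymer run (the pyrosequencing error
                    # locus), then the leftmost position
                    key = (score, run_after, -pos)
                    if best_edit is None or key > best_edit[0]:
                        best_edit = (key, pos, kind)
        if best_edit is None:
            break
        key, pos, kind = best_edit
        if kind == "delete":
            cand = seq[:pos] + seq[pos + 1 :]
        else:
            cand = seq[:pos] + seq[pos] + seq[pos:]
        if cand in seen:
            warnings.warn(
                f"{contig.contig_id}: edit oscillation detected, stopping"
            )
            break
        seen.add(cand)
        edits.append(
            EditOperation(
                contig_id=contig.contig_id,
                position=pos,
                position_input=orig_index[pos],
                kind=kind,
                base=seq[pos],
                run_length=_run_length_at(seq, pos),
                score_before=base_score,
                score_after=key[0],
            )
        )
        if kind == "delete":
            del orig_index[pos]
        else:
            orig_index.insert(pos, orig_index[pos])
        seq = cand
    return DepthContig(contig.contig_id, seq, contig.n_reads), edits


# ---------------------------------------------------------------------------
# ORF calling and truncation
# ---------------------------------------------------------------------------

START_CODONS = ("ATG", "GTG", "TTG")


def call_genes(
    contig: DepthContig, min_orf_nt: int = 300
) -> list[Gene]:
    """Longest-ORF gene calls on all six frames.

    Per frame, each maximal stop-free interval of at least ``min_orf_nt`` nt
    yields at most one gene, started at its most upstream ATG/GTG/TTG; the
    reported nt span includes the trailing stop codon when present, on
    forward-strand coordinates with a strand flag.  Alternative starts are
    translated as M.
    """
    from Bio.Seq import Seq

    seq = contig.sequence
    rc = str(Seq(seq).reverse_complement())
    n = len(seq)
    genes: list[Gene] = []
    frames = six_frame_translate(seq)
    for frame, pep in frames.items():
        k = abs(frame)
        reading = seq if frame > 0 else rc
        intervals = []
        start_aa = 0
        for i, aa in enumerate(pep + "*"):
            if aa == "*":
                if i > start_aa:
                    intervals.append((start_aa, i, i < len(pep)))
                start_aa = i + 1
        for lo_aa, hi_aa, has_stop in intervals:
            if 3 * (hi_aa - lo_aa) < min_orf_nt:
                continue
            start_codon_aa = None
            for i in range(lo_aa, hi_aa):
                codon_nt = (k - 1) + 3 * i
                if reading[codon_nt : codon_nt + 3] in START_CODONS:
                    start_codon_aa = i
                    break
            if start_codon_aa is None:
                continue
            if 3 * (hi_aa - start_codon_aa) < min_orf_nt:
                continue
            end_aa = hi_aa + (1 if has_stop else 0)
            lo_nt = (k - 1) + 3 * start_codon_aa
            hi_nt = (k - 1) + 3 * end_aa
            if frame > 0:
                span = (lo_nt, hi_nt)
            else:
                span = (n - hi_nt, n - lo_nt)
            peptide = "M" + pep[start_codon_aa + 1 : hi_aa]
            genes.append(
                Gene(
                    contig_id=contig.contig_id,
                    start=span[0],
                    end=span[1],
                    strand="+" if frame > 0 else "-",
                    frame=frame,
                    peptide=peptide,
                )
            )
    return sorted(genes, key=lambda g: (g.start, g.end))


def truncation_assessment(
    hsps: Sequence[HSP],
    ref: EnzymeReference,
    contig_length: int,
    edge_margin: int = 3,
) -> tuple[int, int]:
    """Unaligned reference residues at each end attributable to contig edges.

    An end counts as truncated only when the alignment abuts the contig end
    (within ``edge_margin`` nt on the appropriate strand side); otherwise the
    shortfall reflects genuine sequence divergence, not a broken contig.
    Returns ``(n_truncation, c_truncation)`` in aa.
    """
    chain = _select_chain(hsps)
    if not chain:
        return 0, 0
    first, last = chain[0], chain[-1]
    strand = first.strand
    n_trunc = c_trunc = 0
    n_missing = first.ref_begin
    c_missing = len(ref) - last.ref_end
    span_first = first.nt_span(contig_length)
    span_last = last.nt_span(contig_length)
    if strand > 0:
        n_at_edge = span_first[0] <= edge_margin
        c_at_edge = contig_length - span_last[1] <= edge_margin
    else:
        n_at_edge = contig_length - span_first[1] <= edge_margin
        c_at_edge = span_last[0] <= edge_margin
    if n_missing > 0 and n_at_edge:
        n_trunc = n_missing
    if c_missing > 0 and c_at_edge:
        c_trunc = c_missing
    return n_trunc, c_trunc


# ---------------------------------------------------------------------------
# full recovery pipeline
# ---------------------------------------------------------------------------


def recover_genes(
    contigs: Sequence[DepthContig],
    refs: Sequence[EnzymeReference],
    params: RecoveryParams | None = None,
) -> list[CandidateGene]:
    """End-to-end recovery: search, filter, correct, call, assess.

    Each contig is corrected against its single best-scoring passing
    reference; the reported gene is the ORF call overlapping the alignment
    span on the matching strand (largest overlap wins).
    """
    params = params or RecoveryParams()
    candidates: list[CandidateGene] = []
    for contig in contigs:
        if len(contig) < params.min_contig_length:
            continue
        hsps = translated_search(contig, refs, params)
        pairs = candidate_filter(hsps, refs, params)
        if not pairs:
            continue
        best = max(pairs, key=lambda p: p.total_score)
        corrected, edits = correct_frameshifts(contig, best.ref, params)
        final_hsps = translated_search(
            corrected, [best.ref], params, skip_length_check=True
        )
        if not final_hsps:
            continue
        chain = _select_chain(final_hsps)
        coverage = reference_coverage(final_hsps, best.ref)
        trunc_n, trunc_c = truncation_assessment(
            final_hsps, best.ref, len(corrected)
        )
        strand = "+" if chain[0].strand > 0 else "-"
        spans = [h.nt_span(len(corrected)) for h in chain]
        aln_lo = min(s[0] for s in spans)
        aln_hi = max(s[1] for s in spans)
        gene_pick = None
        for gene in call_genes(corrected):
            if gene.strand != strand:
                continue
            ov = min(gene.end, aln_hi) - max(gene.start, aln_lo)
            if ov > 0 and (gene_pick is None or ov > gene_pick[0]):
                gene_pick = (ov, gene)
        if gene_pick is None:
            continue
        gene = gene_pick[1]
        candidates.append(
            CandidateGene(
                contig_id=contig.contig_id,
                corrected_sequence=corrected.sequence,
                peptide=gene.peptide,
                ref_id=best.ref.ref_id,
                ec=best.ref.ec,
                family=best.ref.family,
                coverage=coverage,
                n_corrections=len(edits),
                trunc_n=trunc_n,
                trunc_c=trunc_c,
                gene_start=gene.start,
                gene_end=gene.end,
                strand=gene.strand,
                edits=edits,
            )
        )
    return candidates


def candidates_report(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    """Supplementary-table-shaped report of recovered candidates."""
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "best_hit": c.ref_id,
                "ec": c.ec or "",
                "family": c.family or "",
                "coverage": c.coverage,
                "n_frameshift_corrections": c.n_corrections,
                "trunc_N_aa": c.trunc_n,
                "trunc_C_aa": c.trunc_c,
                "gene_start": c.gene_start,
                "gene_end": c.gene_end,
                "strand": c.strand,
                "caller": "orf-caller",
            }
            for c in candidates
        ]
    )


def read_reference_fasta(path) -> list[EnzymeReference]:
    """Read references from FASTA with ``id|EC|family`` headers.

    An empty EC field (``id||family``) means no known enzymatic function.
    """
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        rid = parts[0]
        ec = parts[1] if len(parts) > 1 and parts[1] else None
        family = parts[2] if len(parts) > 2 and parts[2] else None
        refs.append(EnzymeReference(rid, str(rec.seq), ec, family))
    return refs


def write_reference_fasta(refs: Sequence[EnzymeReference], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(r.peptide),
            id=f"{r.ref_id}|{r.ec or ''}|{r.family or ''}",
            description="",
        )
        for r in refs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
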