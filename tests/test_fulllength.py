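"""Translated search, frameshift correction, ORF calling, truncation."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ghminer import fulllength as fl
from ghminer import gh_inventory as ghi
from ghminer import synthetic_data as sd

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local(a: str, b: str, open_cost=12, extend_cost=1) -> float:
    """Quadratic-time affine-gap local alignment score (independent oracle).

    A gap of length g costs open_cost + (g-1)*extend_cost.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


AMINO = "ACDEFGHIKLMNPQRSTVWY"


def make_gene_contig(peptide: str, seed: int, flank: int = 300, strand: str = "+"):
    """Contig embedding one ATG..stop gene encoding M+peptide."""
    rng = np.random.default_rng(seed)
    nt = sd._encode_peptide("M" + peptide, rng) + "TAA"
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    left = sd._random_dna(flank, rng)
    right = sd._random_dna(flank, rng)
    start = len(left)
    return (
        ghi.DepthContig("g1", left + nt + right, 5),
        start,
        start + len(nt),
    )


@pytest.fixture(scope="module")
def reference():
    prof = sd.make_profile("GH9_dom", 260, seed=31, family="GH9")
    pep = "M" + sd.sample_family_protein(prof, seed=32)
    return fl.EnzymeReference("ref_GH9", pep, ec="3.2.1.4", family="GH9")


class TestTranslatedSearch:
    def test_exact_encoding_yields_full_coverage_hsp(self, reference):
        contig, start, end = make_gene_contig(reference.peptide[1:], seed=1)
        hsps = fl.translated_search(contig, [reference])
        best = max(hsps, key=lambda h: h.raw_score)
        assert best.ref_begin == 0 and best.ref_end == len(reference)
        assert best.frame > 0
        lo, hi = best.nt_span(len(contig))
        assert start <= lo < hi <= end

    def test_reverse_strand_hit_in_negative_frame(self, reference):
        contig, start, end = make_gene_contig(
            reference.peptide[1:], seed=2, strand="-"
        )
        hsps = fl.translated_search(contig, [reference])
        best = max(hsps, key=lambda h: h.raw_score)
        assert best.frame < 0
        lo, hi = best.nt_span(len(contig))
        assert start <= lo < hi <= end

    def test_short_contig_rejected_unless_skipped(self, reference):
        contig = ghi.DepthContig("s", "ACGT" * 100, 1)
        with pytest.raises(ValueError, match="below"):
            fl.translated_search(contig, [reference])
        assert fl.translated_search(contig, [reference], skip_length_check=True) == []

    def test_empty_reference_set_rejected(self, reference):
        contig, *_ = make_gene_contig(reference.peptide[1:], seed=3)
        with pytest.raises(ValueError, match="empty"):
            fl.translated_search(contig, [])

    def test_alignment_scores_match_gotoh_oracle(self):
        """PairwiseAligner configuration reproduces the independent DP."""
        rng = np.random.default_rng(55)
        params = fl.RecoveryParams()
        aligner = params.aligner()
        for _ in range(50):
            a = "".join(AMINO[i] for i in rng.integers(0, 20, size=rng.integers(8, 25)))
            b = "".join(AMINO[i] for i in rng.integers(0, 20, size=rng.integers(8, 25)))
            got = aligner.score(a, b)
            want = gotoh_local(a, b)
            assert got == pytest.approx(want), (a, b)


class TestEvalues:
    def test_karlin_altschul_example(self):
        """S=30, lambda=0.318, K=0.134, m=n=100 gives E ~ 0.096."""
        params = fl.RecoveryParams(ka_lambda=0.318, ka_k=0.134)
        bits = (params.ka_lambda * 30 - math.log(params.ka_k)) / math.log(2)
        evalue = 100 * 100 * 2.0 ** (-bits)
        direct = params.ka_k * 100 * 100 * math.exp(-params.ka_lambda * 30)
        assert evalue == pytest.approx(direct, rel=1e-12)
        assert evalue == pytest.approx(0.096, abs=0.001)

    def test_evalue_decreases_with_score(self, reference):
        params = fl.RecoveryParams()
        ln2 = math.log(2)
        scores = [20, 40, 80, 160]
        es = [
            100 * 1000 * 2 ** (-(params.ka_lambda * s - math.log(params.ka_k)) / ln2)
            for s in scores
        ]
        assert es == sorted(es, reverse=True)


class TestCandidateFilter:
    def hsp(self, ref_begin, ref_end, evalue=1e-50, frame=1, score=500.0):
        return fl.HSP("c", "r", frame, 0, ref_end - ref_begin, ref_begin,
                      ref_end, score, 100.0, evalue)

    def test_coverage_at_boundary(self):
        ref = fl.EnzymeReference("r", "A" * 300, ec="3.2.1.4")
        passing = fl.candidate_filter([self.hsp(0, 271)], [ref])
        assert len(passing) == 1 and passing[0].coverage == pytest.approx(271 / 300)
        assert not fl.candidate_filter([self.hsp(0, 269)], [ref])

    def test_evalue_gate(self):
        ref = fl.EnzymeReference("r", "A" * 100, ec="3.2.1.4")
        assert fl.candidate_filter([self.hsp(0, 100, evalue=1e-11)], [ref])
        assert not fl.candidate_filter([self.hsp(0, 100, evalue=1e-9)], [ref])

    def test_missing_ec_fails_regardless_of_score(self):
        ref = fl.EnzymeReference("r", "A" * 100, ec=None)
        assert not fl.candidate_filter([self.hsp(0, 100, evalue=1e-300)], [ref])

    def test_chained_coverage_unions_spans(self):
        ref = fl.EnzymeReference("r", "A" * 300, ec="3.2.1.4")
        pieces = [self.hsp(0, 150, frame=1), self.hsp(160, 300, frame=2)]
        passing = fl.candidate_filter(pieces, [ref])
        assert len(passing) == 1
        assert passing[0].coverage == pytest.approx(290 / 300)


class TestDetectFrameshifts:
    def hsp(self, frame, pep_begin, pep_end, ref_begin, ref_end, score=300.0):
        return fl.HSP("c", "r", frame, pep_begin, pep_end, ref_begin, ref_end,
                      score, 100.0, 1e-40)

    def test_single_hsp_no_boundary(self):
        assert fl.detect_frameshift_candidates([self.hsp(1, 0, 100, 0, 100)], 400) == []

    def test_frame_switch_gives_one_boundary(self):
        hsps = [self.hsp(1, 0, 50, 0, 50), self.hsp(3, 55, 100, 50, 95)]
        bounds = fl.detect_frameshift_candidates(hsps, 400)
        assert len(bounds) == 1
        lo, hi = bounds[0]
        # junction lies between nt 150 (end of first) and nt 167 (start of
        # second), padded by 12
        assert lo == 150 - 12 and hi == 167 + 12

    def test_two_switches_two_boundaries(self):
        hsps = [
            self.hsp(1, 0, 30, 0, 30),
            self.hsp(2, 35, 65, 30, 60),
            self.hsp(1, 70, 100, 60, 90),
        ]
        assert len(fl.detect_frameshift_candidates(hsps, 400)) == 2

    def test_same_frame_no_boundary(self):
        hsps = [self.hsp(1, 0, 50, 0, 50), self.hsp(1, 60, 100, 55, 95)]
        assert fl.detect_frameshift_candidates(hsps, 400) == []

    def test_significant_hits_on_both_strands_is_chimeric(self):
        hsps = [self.hsp(1, 0, 50, 0, 50), self.hsp(-1, 0, 50, 50, 100)]
        with pytest.raises(ValueError, match="chimeric"):
            fl.detect_frameshift_candidates(hsps, 400)


class TestCorrectFrameshifts:
    def test_unmutated_gene_is_untouched(self, reference):
        contig, *_ = make_gene_contig(reference.peptide[1:], seed=4)
        corrected, edits = fl.correct_frameshifts(contig, reference)
        assert corrected.sequence == contig.sequence
        assert edits == []

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_single_planted_deletion_recovered(self, reference, strand):
        contig, start, end = make_gene_contig(
            reference.peptide[1:], seed=5, strand=strand
        )
        model = sd.ErrorModel(indel_prob=lambda n: 1.0, seed=6)
        mutated, planted = sd.plant_frameshifts(
            [contig], model,
            regions={"g1": [(start + 75, end - 75)]},
            max_per_contig=1,
        )
        assert len(planted) == 1
        corrected, edits = fl.correct_frameshifts(mutated[0], reference)
        assert len(edits) == 1
        e = edits[0]
        row = planted.iloc[0]
        assert row.run_start - 1 <= e.position_input <= row.run_end
        assert e.score_after >= e.score_before
        # the truth peptide is encoded again after correction
        frames = ghi.six_frame_translate(corrected.sequence)
        assert any(reference.peptide in p for p in frames.values())

    def test_two_disjoint_indels_recovered(self, reference):
        contig, start, end = make_gene_contig(reference.peptide[1:], seed=7)
        model = sd.ErrorModel(indel_prob=lambda n: 1.0, seed=8)
        mutated, planted = sd.plant_frameshifts(
            [contig], model,
            regions={"g1": [(start + 75, end - 75)]},
            max_per_contig=2, min_spacing=200,
        )
        assert len(planted) == 2
        corrected, edits = fl.correct_frameshifts(mutated[0], reference)
        assert len(edits) == 2
        for e in edits:
            off = sum(
                1 if k == "delete" else -1
                for k, pm in zip(planted.kind, planted.position_mutated)
                if pm < e.position_input
            )
            pos = e.position_input + off
            assert (
                (planted.run_start - 1 <= pos) & (pos <= planted.run_end)
            ).any()

    def test_idempotent_on_corrected_output(self, reference):
        contig, start, end = make_gene_contig(reference.peptide[1:], seed=9)
        model = sd.ErrorModel(indel_prob=lambda n: 1.0, seed=10)
        mutated, _ = sd.plant_frameshifts(
            [contig], model,
            regions={"g1": [(start + 75, end - 75)]},
            max_per_contig=1,
        )
        once, edits1 = fl.correct_frameshifts(mutated[0], reference)
        twice, edits2 = fl.correct_frameshifts(once, reference)
        assert edits1 and not edits2
        assert twice.sequence == once.sequence


class TestCallGenes:
    @staticmethod
    def _long_gene_catalog():
        prof = sd.make_profile("GH48_dom", 150, seed=41, family="GH48")
        return ghi.FamilyCatalog(
            [ghi.FamilyEntry("GH48", ["GH48_dom"], "cellulases")], [prof]
        )

    def test_planted_gene_at_truth_coords(self):
        spec = sd.CommunitySpec(
            [sd.TaxonSpec("T", 1.0, 1.0, [("GH48", 1)])],
            contig_length_range=(1200, 1600),
            seed=0,
        )
        contigs, truth = sd.build_contig_set(spec, self._long_gene_catalog(), seed=23)
        row = truth.iloc[0]
        genes = fl.call_genes(contigs[0])
        match = [
            g for g in genes
            if g.start == row.start and g.end == row.end and g.strand == row.strand
        ]
        # the ORF caller may open at an upstream in-frame start; at minimum
        # one call must cover the gene with the right strand and end
        if not match:
            match = [
                g for g in genes
                if g.end == row.end and g.strand == row.strand and g.start <= row.start
            ]
        assert len(match) == 1
        assert match[0].peptide.endswith(row.peptide[1:])

    def test_short_orfs_not_called(self):
        rng = np.random.default_rng(77)
        # 200 nt stop-free in frame +1 is below the 300 nt floor
        pep = "".join("ACDEFGHIKLMN"[i % 12] for i in range(66))
        nt = sd._encode_peptide("M" + pep, rng) + "TAA"
        contig = ghi.DepthContig("s", nt, 1)
        genes = [g for g in fl.call_genes(contig) if g.frame == 1]
        assert genes == []

    def test_coordinates_are_forward_strand(self):
        spec = sd.CommunitySpec(
            [sd.TaxonSpec("T", 1.0, 1.0, [("GH48", 1)])],
            contig_length_range=(1200, 1600),
            seed=3,
        )
        contigs, truth = sd.build_contig_set(spec, self._long_gene_catalog(), seed=29)
        for row in truth.itertuples():
            genes = fl.call_genes(
                [c for c in contigs if c.contig_id == row.contig_id][0]
            )
            hits = [g for g in genes if g.end == row.end or g.start == row.start]
            assert hits, "planted gene not recovered by ORF caller"
            assert all(0 <= g.start < g.end <= len(contigs[0]) for g in genes)


class TestTruncation:
    def hsp(self, frame, pep_begin, pep_end, ref_begin, ref_end):
        return fl.HSP("c", "r", frame, pep_begin, pep_end, ref_begin, ref_end,
                      500.0, 100.0, 1e-40)

    def test_full_alignment_no_truncation(self):
        ref = fl.EnzymeReference("r", "A" * 100, ec="1.1.1.1")
        hsps = [self.hsp(1, 50, 150, 0, 100)]
        assert fl.truncation_assessment(hsps, ref, 600) == (0, 0)

    def test_c_terminal_truncation_at_contig_edge(self):
        ref = fl.EnzymeReference("r", "A" * 140, ec="1.1.1.1")
        # alignment ends 40 aa short of the reference C-terminus and the
        # contig ends flush with the alignment
        hsps = [self.hsp(1, 0, 100, 0, 100)]
        assert fl.truncation_assessment(hsps, ref, 302) == (0, 40)

    def test_no_truncation_when_contig_continues(self):
        ref = fl.EnzymeReference("r", "A" * 140, ec="1.1.1.1")
        hsps = [self.hsp(1, 0, 100, 0, 100)]
        assert fl.truncation_assessment(hsps, ref, 500) == (0, 0)

    def test_n_terminal_truncation_reverse_strand(self):
        ref = fl.EnzymeReference("r", "A" * 120, ec="1.1.1.1")
        # reverse-strand alignment whose N-terminal end abuts the right
        # contig edge
        hsps = [self.hsp(-1, 0, 100, 20, 120)]
        assert fl.truncation_assessment(hsps, ref, 300) == (20, 0)


def test_recover_pipeline_end_to_end(reference):
    """Search -> filter -> correct -> call on one broken gene."""
    contig, start, end = make_gene_contig(reference.peptide[1:], seed=12, flank=400)
    model = sd.ErrorModel(indel_prob=lambda n: 1.0, seed=13)
    mutated, planted = sd.plant_frameshifts(
        [contig], model,
        regions={"g1": [(start + 75, end - 75)]},
        max_per_contig=1,
    )
    decoy = fl.EnzymeReference("decoy", "W" * 80, ec=None)
    cands = fl.recover_genes(mutated, [reference, decoy])
    assert len(cands) == 1
    c = cands[0]
    assert c.ref_id == "ref_GH9"
    assert c.n_corrections == len(planted) == 1
    assert c.coverage >= 0.9
    assert c.ec == "3.2.1.4"
    assert reference.peptide[1:] in c.peptide
    report = fl.candidates_report(cands)
    assert report.loc[0, "caller"] == "orf-caller"


def test_reference_fasta_round_trip(tmp_path, reference):
    noec = fl.EnzymeReference("x1", "MKLV" * 10, ec=None, family="GH5")
    path = tmp_path / "refs.faa"
    fl.write_reference_fasta([reference, noec], path)
    back = fl.read_reference_fasta(path)
    assert back[0].ref_id == "ref_GH9" and back[0].ec == "3.2.1.4"
    assert back[1].ec is None and back[1].family == "GH5"
    assert back[0].peptide == reference.peptide
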