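# Methods

`ghminer` reconstructs, as reusable library code, the computational analyses
of a bench-scale composting experiment aimed at discovering lignocellulolytic
enzymes: a switchgrass feedstock inoculated with green-waste compost,
monitored by gas mass balances and substrate chemistry, profiled by SSU rRNA
amplicons at two timepoints, and mined for glycoside-hydrolase (GH) genes by
shotgun sequencing of the adapted community. Every stage is driven by plain
text inputs and is fully exercised offline against synthetic data with known
ground truth.

## Respiration mass balances (`respiration`)

A reactor aerated at flow `F` (mg air · day⁻¹ · gdw⁻¹) with influent/effluent
gas mass fractions (mg gas · mg air⁻¹) obeys

    CER = F · (CO₂,out − CO₂,in)
    OUR = F · (O₂,in − O₂,out)

in mg gas · day⁻¹ · gdw⁻¹, with O₂ uptake positive. This is the unique mass
balance consistent with those symbol definitions and units; inputs are taken
to be mass fractions by contract, with any molar/percent conversion done
upstream. Cumulative respiration is the composite trapezoid over the
sampling grid (20-minute default). Points flagged as mixing/water-addition
events are real measurements and are integrated as-is; sensor gaps are
spanned by a single trapezoid, never interpolated. On smooth profiles the
integration error falls roughly quadratically with the sampling interval;
the test suite checks a 20-minute versus 10-minute grid.

## Composition accounting (`composition`)

Mineral ash is assumed conserved through the incubation, so the rise of the
ash fraction of total dry solids from `a_i` to `a_f` implies a total solids
loss of `1 − a_i/a_f` (11.5% → 17.5% gives 34%). Final component
measurements per kg of final dry solids are converted to the initial-mass
basis by the surviving-solids factor `a_i/a_f`; a component's loss is then
`100·(initial − final)/initial`. Pooled losses over several components are
mass-weighted (total mass lost over total initial mass), not the mean of row
percentages — with the published sugar masses the mass-weighted pool
reproduces the printed 28% average while the unweighted mean (30.25%) does
not, which fixes the convention. Reported losses are rounded half-up to
integers; machine output keeps full precision.

## Amplicon community comparison (`amplicon`)

Reads carry a 5-bp sample barcode; demultiplexing is an exact-prefix match
(a partition: every read lands in exactly one sample bucket or in
`unassigned`), the barcode is trimmed, and reads shorter than 220 nt after
trimming are dropped (boundary inclusive; the trim-then-filter order and
inclusivity are this package's choices, stated here because the protocol
text does not fix them). Phylotype assignment is exact-label tallying of
the labels synthetic reads carry; OTU clustering of real data is out of
scope, and an externally produced count table can be substituted via
`load_phylotype_table`.

Communities are compared on relative abundances by Bray–Curtis
dissimilarity `Σ|pᵢ−qᵢ| / Σ(pᵢ+qᵢ)` (0 identical, 1 disjoint; not a metric,
so only range/identity/symmetry properties are asserted). Per-phylotype
fold enrichment between timepoints is the exact ratio `p_t1/p_t0` when the
taxon was detectable at t0 (`p_t0 ≥ τ`, default τ = 0.09% of sample reads);
below the floor only the lower bound `p_t1/τ` is defensible and the row is
flagged as a `≥` bound. Taxa absent at t1 are reported with fold 0 rather
than dropped. The report is sorted by t1 abundance, matching a
rank-abundance overlay.

## Depth-weighted GH inventory (`gh_inventory`, `hmmio`)

Families are modelled by profile HMMs (one or two domain models per family,
read from HMMER3 ASCII text). Contigs are translated in all six frames
(codon table 11; stops as `*`, any codon containing a non-ACGT base as `X`)
and scored with a Plan7-style single-hit local Viterbi: entry into any match
state at cost log₂(1/L), free exit from any match state, emission log-odds
in bits against a uniform 1/20 background (unless the profile supplies one),
transitions at their log₂ probabilities. `X` scores 0 bits anywhere;
alignments never cross `*`. Hits below 25 bits (configurable) are discarded
— a deliberately conservative floor, since the original study's significance
criterion for its "conservatively identified" gene set is not recoverable.
At most one hit per contig–family pair survives: the best score across
frames and across the family's domain models, which both implements the
stated best-hit rule for multi-model families and prevents one gene split
across frames from being counted twice.

Each hit contributes its contig's approximate fold coverage,
`n_reads · 400 / contig_length` (400 nt being the median read length the
weighting convention assumes), so dominant populations weigh more than rare
ones. Family percentages are weights normalized over all hit families (they
sum to 100 by construction) and are aggregated into five functional groups:
cellulases, endohemicellulases, cell wall elongation, debranching,
oligosaccharide-degrading. Only assembled contigs enter the inventory;
unassembled singletons are not weighted separately. When a contig carries
two same-family genes the pair still counts once — the unit is the
contig–family pair, a semantics choice stated here because the alternative
(counting domains) is equally defensible.

The DP is vectorized over match states per consumed residue; delete-state
chains within a column are resolved by a running-maximum over
`M[j] + t_MD(j) − Σt_DD` prefix terms. Probability-zero transitions are
clamped to −10⁹ bits instead of −∞ to keep the arithmetic finite; any path
using one is unreachable in practice. Equality with exhaustive path
enumeration is asserted for all profile lengths ≤ 4 × peptide lengths ≤ 6
over randomized emission/transition draws.

## Full-length recovery and frameshift correction (`fulllength`)

Contigs ≥ 1 kb are searched against an EC-annotated reference enzyme set
(the curated-database stand-in) by Smith–Waterman local alignment of each
stop-free segment (≥ 8 aa) of each frame translation, under BLOSUM62 with
affine gaps (open 11, extend 1 — a length-g gap costs 11 + g). Raw scores
convert to bits via the ungapped Karlin–Altschul constants λ = 0.3176,
K = 0.134 (standard published values; the original search's exact settings
are not recoverable), and `E = m·n·2^(−S′)` with m the reference length and
n the total translated length searched. A contig–reference pair passes when
the union of its chained same-strand alignment spans covers ≥ 90% of the
reference, the best segment has E ≤ 1e−10, and the reference has an EC
number. Coverage uses the chained union rather than a single segment
because an uncorrected frameshift splits a true full-length gene into
several segments that only jointly cover the reference.

One deliberate departure from a plain optimal-alignment view: an optimal
Smith–Waterman (which has no X-drop termination) will bridge the
out-of-frame stretch between two *compensating* indels with a run of
mismatches, producing one alignment that hides the frame structure.
Alignments are therefore split at internal score valleys deeper than 20
(the behaviour a seeded, X-drop-terminated search would exhibit), which
restores the segment view frameshift detection needs.

A frameshift candidate is any pair of reference-consecutive chained
segments lying in different frames on the same strand; the junction between
their contig spans, padded by ±12 nt, is the edit search window.
Significant alignments (E ≤ 1e−5) on both strands mark a chimeric candidate
that is reported, never auto-corrected; weak antisense noise is ignored.
Correction is greedy: every single-base deletion and duplication in every
window is scored, the best strictly-improving edit is applied, and
detection re-runs until no boundary remains, nothing improves, or 10
iterations pass. The objective is a junk-suppressed segment-score sum —
`Σ max(0, S_segment − 40)` over the gene strand — chosen so that repairing
any junction strictly improves the objective (merging two fragments removes
one floor deduction plus the junction gain) while garbage-frame alignments
(typically ~30) cannot steer the choice. Scoring is restricted to the
aligned region ± 60 nt, which leaves local-alignment scores unchanged and
keeps the enumeration cheap. Ties between equal-scoring edits prefer the
edit that leaves the longest homopolymer run in the corrected sequence
(the pyrosequencing error locus), then the leftmost position. Accepted
edits never lower the objective, re-running the corrector on its own output
is a no-op, and an oscillation guard stops identical-sequence revisits.
Within a homopolymer run the exact edit position is unidentifiable from
protein-level scores (all in-run single-base edits give the same
nucleotide sequence), and for length-2 runs a synonymous-codon tie can
occasionally place an edit one base outside the true run; both ambiguities
are inherent to reference-guided correction and are why recovery is scored
as "within the true run ± 1 nt".

Gene models on corrected contigs come from a simple ORF caller — maximal
stop-free intervals ≥ 300 nt, started at their most upstream ATG/GTG/TTG,
reported in forward-strand 0-based half-open coordinates including the stop
codon, with alternative starts translated as M. Reports label this
provenance `orf-caller`; it deliberately replaces trained gene finders and
will happily open at an upstream in-frame start in flanking sequence, which
is why recovery tests anchor on the stop-codon end. Truncation at contig
edges is assessed per terminus: unaligned reference residues at an end
count as truncation only when the alignment abuts the contig end within
3 nt; otherwise the shortfall is treated as genuine divergence.

The full pipeline (`recover_genes`) corrects each contig against its single
best-scoring passing reference. Correcting against several homologs and
reconciling is possible in principle but out of scope.

## Synthetic data (`synthetic_data`)

The generators emulate, with known truth, the features the pipeline
actually consumes:

* **Profiles and peptides.** `make_profile` builds peaked domain models
  (one dominant residue per match state, conservation 0.8 by default,
  strongly match-to-match transitions); `sample_family_protein` walks the
  match states. Real curated family models are more heterogeneous; nothing
  downstream depends on that.
* **Contigs.** Planted genes are ATG-started, single-stop coding sequences
  (codon table 11, synonymous codons uniform), placed on either strand with
  50–300 nt GC-0.5 intergenic spacers, packed into contigs drawn from the
  spec's length range. Truth tables record coordinates, strand, family and
  peptide, and are sufficient for all recovery tests. Read counts are
  Poisson with mean `abundance_t1 · coverage_scale · length/400`, floored
  at 1 — matching the downstream weighting convention; t1 abundance is used
  because the sequenced metagenome is the final sample. `coverage_scale`
  (default 20×) supplies the absolute depth the community spec does not
  carry.
* **Indels.** Homopolymer runs of length ≥ 2 mutate independently with
  probability `0.002·(run−1)` capped at 0.05 by default — an increasing-
  with-run-length shape plausible for pyrosequencing flow miscalls; the
  magnitude is a free simulator parameter, not an instrument measurement.
  A mutation deletes or duplicates one run base (equal odds). Optional
  region restrictions, per-contig caps and minimum spacing let benchmarks
  plant controlled error loads; the correction benchmark restricts indels
  to the gene body minus 75-nt margins (an indel closer to a gene end
  leaves too short an anchor fragment for any reference-guided detector)
  and spaces them ≥ 150 nt so windows stay disjoint.
* **Count tables, gas, composition.** Phylotype tables are multinomial
  draws at both timepoints; gas tables are built by inverting the mass
  balances exactly (so round-trip recovery is limited only by float
  arithmetic); composition tables apply chosen loss fractions and a
  consistent ash pair.

Everything is a pure function of (spec, seed): reruns are byte-identical.
What passing synthetic tests do *not* show: robustness to assembly
artifacts, chimeras, quality-score-correlated errors, diverged homologs
(references here match planted genes near-exactly), or real OTU clustering
noise.

## Benchmarks and sizes

`ghminer.benchmarks` fixes the validation conditions: 100 single-gene
contigs with 0–3 planted indels each (per-gene budget uniform) for
frameshift correction; a four-family community planted at 40/30/20/10
expected weight with ten genes per family at ≥ 5× coverage for inventory
recovery (enough contigs that Poisson read-count noise sits well inside the
±5-point tolerance); a 22-fold enrichment from 0.2% initial abundance at
depth 10⁶ for the amplicon path; closed-form profiles for respiration.
These sizes are the package's chosen study conditions and are what the
acceptance tests assert against (≥ 90% of indels corrected within the true
run, ≥ 85% of gene peptides restored exactly, inventory within ±5 points,
enrichment within 20%, respiration round trip to 1e−12 relative).

## Known limitations

* The Viterbi scorer is single-hit local only: no glocal/multi-hit modes
  and no E-value calibration for HMM bit scores (the threshold is in bits).
* Frameshift correction assumes one good reference per contig and indels
  sparse enough that anchor fragments survive; dense errors (< ~25 aa
  between indels) can evade valley splitting.
* The ORF caller has no coding-potential model; on real data it would
  over-extend starts and call spurious ORFs, which is acceptable for its
  role (locating corrected genes, denominator for the GH-per-ORF fraction).
* Amplicon handling assumes error-free barcodes and labels; there is no
  chimera detection or taxonomy assignment.
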