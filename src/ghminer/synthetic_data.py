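"""Ground-truth generators for every pipeline input.

Emulates the data a bench-scale composting experiment plus 454-style
sequencing would produce, with full knowledge of the truth:

* a two-timepoint community with chosen fold enrichments and a detection
  floor (phylotype count tables);
* contigs carrying planted GH genes at chosen family proportions, with
  read counts reflecting taxon abundance (Poisson around
  ``abundance * length / 400`` times a coverage scale);
* pyrosequencing-style single-base indels confined to homopolymer runs,
  with an edit truth list for frameshift-correction benchmarking;
* gas time series constructed by inverting the respiration mass balances,
  so the downstream rates are recovered exactly;
* composition tables with known per-component losses and a consistent
  ash pair.

Every generator is a pure function of its spec and seed: rerunning with the
same arguments is byte-identical.  Truth tables are designed to be
sufficient for downstream recovery tests without re-reading sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gh_inventory import DepthContig, FamilyCatalog
from .hmmio import AMINO_ACIDS, ProfileHMM

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class TaxonSpec:
    """One community member: label, initial abundance, enrichment, genes."""

    label: str
    abundance_t0: float
    fold_change: float
    gh_genes: list[tuple[str, int]] = field(default_factory=list)

    @property
    def abundance_t1(self) -> float:
        return self.abundance_t0 * self.fold_change


@dataclass
class CommunitySpec:
    """A two-timepoint community with per-taxon GH gene complements."""

    taxa: list[TaxonSpec]
    contig_length_range: tuple[int, int] = (2000, 4000)
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.taxa:
            if t.fold_change <= 0:
                raise ValueError(f"fold change for {t.label} must be > 0")
            if any(n < 0 for _, n in t.gh_genes):
                raise ValueError("gene counts must be >= 0")
        s0 = sum(t.abundance_t0 for t in self.taxa)
        s1 = sum(t.abundance_t1 for t in self.taxa)
        if abs(s0 - 1.0) > 1e-9:
            raise ValueError(f"t0 abundances sum to {s0}, expected 1")
        if abs(s1 - 1.0) > 1e-9:
            raise ValueError(f"t1 abundances sum to {s1}, expected 1")


def default_indel_prob(run_length: int) -> float:
    """454-like homopolymer indel probability: grows with run length.

    ``0.002 * (run_length - 1)`` capped at 0.05; the magnitude is a free
    parameter of the simulator, not an empirical instrument error rate.
    """
    return min(0.002 * (run_length - 1), 0.05)


@dataclass
class ErrorModel:
    """Pyrosequencing-style error model: homopolymer indels + substitutions."""

    indel_prob: Callable[[int], float] = default_indel_prob
    substitution_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_prob <= 1.0:
            raise ValueError("substitution probability must be in [0,1]")


# ---------------------------------------------------------------------------
# synthetic profile HMMs and peptide sampling
# ---------------------------------------------------------------------------


def make_profile(
    name: str,
    length: int,
    seed: int,
    family: str | None = None,
    conservation: float = 0.8,
) -> ProfileHMM:
    """Build a synthetic domain model with one dominant residue per state.

    Each match state emits one residue with probability ``conservation`` and
    the remaining 19 uniformly; transitions are strongly match-to-match.
    Serves as a stand-in for a curated family domain model.
    """
    if length < 1:
        raise ValueError("profile length must be >= 1")
    rng = np.random.default_rng(seed)
    dominant = rng.integers(0, 20, size=length)
    match = np.full((length, 20), (1.0 - conservation) / 19.0)
    match[np.arange(length), dominant] = conservation
    insert = np.full((length, 20), 1.0 / 20.0)
    trans = np.tile(
        np.array([0.96, 0.02, 0.02, 0.9, 0.1, 0.9, 0.1]), (length, 1)
    )
    trans[-1] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]
    return ProfileHMM(
        name=name,
        length=length,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        family=family,
    )


def sample_family_protein(profile: ProfileHMM, seed: int) -> str:
    """Draw one peptide by walking the match states and sampling emissions."""
    if profile.length < 1:
        raise ValueError("profile has no match states")
    rng = np.random.default_rng(seed)
    idx = [
        rng.choice(20, p=profile.match_emissions[k])
        for k in range(profile.length)
    ]
    return "".join(AMINO_ACIDS[i] for i in idx)


# ---------------------------------------------------------------------------
# contig construction
# ---------------------------------------------------------------------------

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)


def _encode_peptide(peptide: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly chosen synonymous codons (table 11)."""
    codons = []
    for aa in peptide:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_contig_set(
    spec: CommunitySpec,
    catalog: FamilyCatalog,
    seed: int,
    coverage_scale: float = 20.0,
) -> tuple[list[DepthContig], pd.DataFrame]:
    """Build contigs with planted GH genes and abundance-driven read counts.

    Each planted gene is an ATG-started, single-stop coding sequence whose
    peptide is sampled from the family's first domain model; genes are
    separated by random intergenic spacers (50-300 nt, GC 0.5) and placed on
    either strand.  Read counts are Poisson with mean
    ``abundance_t1 * coverage_scale * contig_length / 400`` (floored at 1),
    mirroring the read-depth weighting convention downstream.

    Returns the contigs and a truth table with one row per planted gene:
    ``contig_id, taxon, gene_id, family, strand, start, end, peptide``
    (coordinates 0-based half-open on the forward strand, including the
    stop codon).
    """
    known = set(catalog.families())
    for taxon in spec.taxa:
        for fam, _ in taxon.gh_genes:
            if fam not in known:
                raise KeyError(f"family {fam!r} not in catalog")
    rng = np.random.default_rng(seed)
    contigs: list[DepthContig] = []
    truth_rows: list[dict] = []
    lo, hi = spec.contig_length_range

    for taxon in spec.taxa:
        genes: list[tuple[str, str]] = []  # (family, peptide)
        for fam, count in taxon.gh_genes:
            profile = catalog.profiles_for(fam)[0]
            for g in range(count):
                pep = sample_family_protein(
                    profile, seed=int(rng.integers(0, 2**31))
                )
                genes.append((fam, "M" + pep))
        queue = list(genes)
        contig_idx = 0
        while queue or contig_idx == 0:
            target = int(rng.integers(lo, hi + 1))
            cid = f"{taxon.label}_c{contig_idx}"
            parts: list[str] = [_random_dna(int(rng.integers(50, 301)), rng)]
            pos = len(parts[0])
            gene_idx = 0
            while queue:
                fam, pep = queue[0]
                nt = _encode_peptide(pep, rng) + "TAA"
                spacer_len = int(rng.integers(50, 301))
                if pos + len(nt) + spacer_len > target and gene_idx > 0:
                    break
                queue.pop(0)
                strand = "+" if rng.random() < 0.5 else "-"
                parts.append(nt if strand == "+" else str(Seq(nt).reverse_complement()))
                truth_rows.append(
                    {
                        "contig_id": cid,
                        "taxon": taxon.label,
                        "gene_id": f"{cid}_g{gene_idx}",
                        "family": fam,
                        "strand": strand,
                        "start": pos,
                        "end": pos + len(nt),
                        "peptide": pep,
                    }
                )
                pos += len(nt)
                parts.append(_random_dna(spacer_len, rng))
                pos += spacer_len
                gene_idx += 1
            seq = "".join(parts)
            if len(seq) < target:
                seq += _random_dna(target - len(seq), rng)
            mean_reads = taxon.abundance_t1 * coverage_scale * len(seq) / 400.0
            n_reads = max(1, int(rng.poisson(mean_reads)))
            # fix coordinates for reverse-strand genes: stored start/end are
            # already forward coords because genes are inserted in forward
            # orientation order
            contigs.append(DepthContig(cid, seq, n_reads))
            contig_idx += 1
            if not queue:
                break
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "contig_id",
            "taxon",
            "gene_id",
            "family",
            "strand",
            "start",
            "end",
            "peptide",
        ],
    )
    return contigs, truth


# ---------------------------------------------------------------------------
# homopolymer frameshift planting
# ---------------------------------------------------------------------------


def homopolymer_runs(seq: str, min_length: int = 2) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases, as (start, end, base) half-open."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_length:
            runs.append((i, j, seq[i]))
        i = j
    return runs


def plant_frameshifts(
    contigs: Sequence[DepthContig],
    model: ErrorModel,
    regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    max_per_contig: int | None = None,
    min_spacing: int = 0,
) -> tuple[list[DepthContig], pd.DataFrame]:
    """Apply single-base homopolymer indels (and optional substitutions).

    Each homopolymer run of length >= 2 mutates with probability
    ``model.indel_prob(run_length)``; a mutation either deletes one run base
    or duplicates one (equal odds), i.e. exactly the error mode of
    pyrosequencing flow miscalls.  ``regions`` optionally restricts
    mutagenesis to intervals per contig (e.g. coding regions);
    ``max_per_contig`` and ``min_spacing`` cap the edit density.

    Returns mutated contigs plus a truth table with columns ``contig_id,
    position, position_mutated, kind, base, run_length, run_start, run_end``
    (positions in original coordinates; ``position_mutated`` maps each edit
    into the final mutated sequence).
    """
    rng = np.random.default_rng(model.seed)
    out: list[DepthContig] = []
    rows: list[dict] = []
    for contig in contigs:
        seq = contig.sequence
        allowed = None if regions is None else list(regions.get(contig.contig_id, []))
        chosen: list[dict] = []
        for start, end, base in homopolymer_runs(seq):
            if allowed is not None and not any(
                lo <= start and end <= hi for lo, hi in allowed
            ):
                continue
            run_len = end - start
            if rng.random() >= model.indel_prob(run_len):
                continue
            if max_per_contig is not None and len(chosen) >= max_per_contig:
                break
            if chosen and start - chosen[-1]["position"] < min_spacing:
                continue
            kind = "delete" if rng.random() < 0.5 else "duplicate"
            pos = int(rng.integers(start, end))
            chosen.append(
                {
                    "contig_id": contig.contig_id,
                    "position": pos,
                    "kind": kind,
                    "base": base,
                    "run_length": run_len,
                    "run_start": start,
                    "run_end": end,
                }
            )
        # apply right-to-left so original coordinates stay valid
        mutated = seq
        for edit in sorted(chosen, key=lambda e: -e["position"]):
            p = edit["position"]
            if edit["kind"] == "delete":
                mutated = mutated[:p] + mutated[p + 1 :]
            else:
                mutated = mutated[:p] + mutated[p] + mutated[p:]
        # original -> mutated coordinate offset for the truth table
        for edit in chosen:
            offset = sum(
                (1 if e["kind"] == "duplicate" else -1)
                for e in chosen
                if e["position"] < edit["position"]
            )
            edit["position_mutated"] = edit["position"] + offset
        if model.substitution_prob > 0.0:
            arr = list(mutated)
            for i in range(len(arr)):
                if rng.random() < model.substitution_prob:
                    alternatives = [b for b in "ACGT" if b != arr[i]]
                    arr[i] = alternatives[rng.integers(0, 3)]
            mutated = "".join(arr)
        rows.extend(chosen)
        out.append(DepthContig(contig.contig_id, mutated, contig.n_reads))
    truth = pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "position",
            "position_mutated",
            "kind",
            "base",
            "run_length",
            "run_start",
            "run_end",
        ],
    )
    return out, truth


# ---------------------------------------------------------------------------
# phylotype tables, amplicon reads
# ---------------------------------------------------------------------------


def make_phylotype_tables(
    spec: CommunitySpec, depth: int, seed: int
) -> pd.DataFrame:
    """Multinomial phylotype counts for the two timepoints (columns t0, t1)."""
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(seed)
    labels = [t.label for t in spec.taxa]
    p0 = np.array([t.abundance_t0 for t in spec.taxa])
    p1 = np.array([t.abundance_t1 for t in spec.taxa])
    return pd.DataFrame(
        {
            "t0": rng.multinomial(depth, p0 / p0.sum()),
            "t1": rng.multinomial(depth, p1 / p1.sum()),
        },
        index=pd.Index(labels, name="phylotype"),
    )


def make_amplicon_reads(
    table: pd.DataFrame,
    barcode_map: Mapping[str, str],
    seed: int,
    length_range: tuple[int, int] = (200, 320),
) -> list[SeqRecord]:
    """Barcoded amplicon-style reads matching a phylotype count table.

    Each read is a sample barcode followed by a random insert whose length is
    uniform over ``length_range``; the phylotype label is carried in the read
    description (``phylotype=<label>``), matching the exact-label tallying
    convention of the amplicon module.  ``barcode_map`` maps barcode ->
    sample for every column of ``table``.
    """
    rng = np.random.default_rng(seed)
    sample_to_barcode = {s: b for b, s in barcode_map.items()}
    missing = set(table.columns) - set(sample_to_barcode)
    if missing:
        raise KeyError(f"no barcode for samples: {sorted(missing)}")
    reads: list[SeqRecord] = []
    i = 0
    for sample in table.columns:
        bc = sample_to_barcode[sample]
        for label, count in table[sample].items():
            for _ in range(int(count)):
                n = int(rng.integers(length_range[0], length_range[1] + 1))
                reads.append(
                    SeqRecord(
                        Seq(bc + _random_dna(n, rng)),
                        id=f"amp{i:07d}",
                        description=f"phylotype={label}",
                    )
                )
                i += 1
    order = rng.permutation(len(reads))
    return [reads[k] for k in order]


# ---------------------------------------------------------------------------
# gas and composition tables
# ---------------------------------------------------------------------------


def make_gas_series(
    cer_profile: Callable[[float], float],
    our_profile: Callable[[float], float],
    flow: float,
    t_end: float,
    interval: float = 20.0 / (24.0 * 60.0),
    co2_in: float = 0.0006,
    o2_in: float = 0.23,
) -> pd.DataFrame:
    """Gas concentrations that invert to the given CER/OUR profiles exactly.

    ``flow`` is in mg air / day / gdw; concentrations in mg gas / mg air;
    ``interval`` defaults to a 20-minute sampling grid in days.  Effluent
    concentrations are set to ``co2_out = co2_in + CER/F`` and
    ``o2_out = o2_in - OUR/F`` so the mass-balance rate equations recover
    the profiles with no discretization error.
    """
    if flow <= 0:
        raise ValueError("air flow must be positive")
    t = np.arange(0.0, t_end + interval / 2, interval)
    cer = np.array([cer_profile(x) for x in t], dtype=float)
    our = np.array([our_profile(x) for x in t], dtype=float)
    co2_out = co2_in + cer / flow
    o2_out = o2_in - our / flow
    if (co2_out < 0).any() or (o2_out < 0).any():
        raise ValueError("profiles imply negative gas concentrations")
    return pd.DataFrame(
        {
            "t_day": t,
            "F": flow,
            "co2_in": co2_in,
            "co2_out": co2_out,
            "o2_in": o2_in,
            "o2_out": o2_out,
            "event": "",
        }
    )


def make_composition_table(
    initial: Mapping[str, float],
    losses: Mapping[str, float],
    ash_initial: float,
    ash_final: float,
    solids_loss: float | None = None,
) -> pd.DataFrame:
    """Composition table with known per-component losses and a real ash pair.

    ``initial`` is g per kg of the initial dry mix; ``losses`` are fractions
    in [0,1].  The adjusted final value is ``initial * (1 - loss)`` (same
    initial-mass basis); the measured final value is per kg of *final* dry
    solids, i.e. adjusted divided by the surviving solids fraction
    ``ash_initial / ash_final``.  If ``solids_loss`` is given it must agree
    with the ash-implied loss ``1 - ash_initial/ash_final``.
    """
    if not 0 < ash_initial < 1 or not 0 < ash_final < 1:
        raise ValueError("ash fractions must be in (0,1)")
    implied = 1.0 - ash_initial / ash_final
    if solids_loss is not None and abs(solids_loss - implied) > 1e-9:
        raise ValueError(
            f"stated solids loss {solids_loss} inconsistent with ash pair "
            f"(implies {implied:.6f})"
        )
    rows = []
    for name, init in initial.items():
        loss = losses[name]
        if not 0.0 <= loss <= 1.0:
            raise ValueError(f"loss for {name} outside [0,1]")
        adjusted = init * (1.0 - loss)
        rows.append(
            {
                "name": name,
                "initial_g_per_kg": init,
                "final_adjusted_g_per_kg": adjusted,
                "final_measured_g_per_kg": adjusted * ash_final / ash_initial
                if ash_initial > 0
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["ash_initial"] = ash_initial
    df.attrs["ash_final"] = ash_final
    return df


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_contigs(
    contigs: Sequence[DepthContig], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write contig FASTA (60-column wrap) plus the read-count sidecar TSV."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="")
        for c in contigs
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    pd.DataFrame(
        {"contig_id": [c.contig_id for c in contigs],
         "n_reads": [c.n_reads for c in contigs]}
    ).to_csv(sidecar_path, sep="\t", index=False)


def load_contigs(
    fasta_path: str | Path, sidecar_path: str | Path
) -> list[DepthContig]:
    """Read contigs plus read counts back from FASTA + sidecar TSV."""
    counts = pd.read_csv(sidecar_path, sep="\t").set_index("contig_id")["n_reads"]
    return [
        DepthContig(rec.id, str(rec.seq).upper(), int(counts[rec.id]))
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]


def reference_set_from_truth(truth: pd.DataFrame, ec_map: Mapping[str, str]):
    """EC-annotated reference enzymes matching the planted genes.

    One reference per unique (family, peptide); EC numbers come from
    ``ec_map`` (family -> EC).  Acts as the curated-database stand-in for
    full-length recovery tests.
    """
    from .fulllength import EnzymeReference

    refs = []
    seen = set()
    for row in truth.itertuples():
        key = (row.family, row.peptide)
        if key in seen:
            continue
        seen.add(key)
        refs.append(
            EnzymeReference(
                ref_id=f"ref_{row.family}_{len(refs)}",
                peptide=row.peptide,
                ec=ec_map.get(row.family),
                family=row.family,
            )
        )
    return refs
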