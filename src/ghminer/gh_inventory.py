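"""Depth-weighted glycoside-hydrolase family inventory from assembled contigs.

Contigs are translated in all six frames and scanned with one profile HMM per
family model (some families carry two domain models).  Scoring follows a
Plan7-style single-hit *local* alignment: a domain may enter the profile at
any match state and leave from any match state, so a conserved domain is
found anywhere inside a longer translation.  Hits are thresholded in bits,
reduced to at most one hit per contig-family pair (the best-scoring one, so a
family represented by several domain models, or the same gene split across
frames, is never counted twice), and weighted by approximate contig fold
coverage ``n_reads * median_read_length / contig_length``.  The weighted
per-family percentages, grouped by functional role, form the inventory table;
dominant community members contribute proportionally more than rare ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .hmmio import AA_INDEX, ProfileHMM

NEG = -1e30  # sentinel for "no path"; any real alignment score is far above

#: The five functional groupings of the inventory.
FUNCTIONAL_GROUPS = (
    "cellulases",
    "endohemicellulases",
    "cell wall elongation",
    "debranching",
    "oligosaccharide-degrading",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DepthContig:
    """A contig plus the number of reads assembled into it."""

    contig_id: str
    sequence: str
    n_reads: int

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains invalid characters: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FamilyEntry:
    family: str
    profiles: list[str]
    group: str
    activity: str = ""

    def __post_init__(self) -> None:
        if self.group not in FUNCTIONAL_GROUPS:
            raise ValueError(
                f"unknown functional group {self.group!r}; "
                f"expected one of {FUNCTIONAL_GROUPS}"
            )


class FamilyCatalog:
    """Maps each GH family to its profile model(s) and functional group."""

    def __init__(
        self,
        entries: Iterable[FamilyEntry],
        profiles: Iterable[ProfileHMM] = (),
    ) -> None:
        self.entries: dict[str, FamilyEntry] = {}
        for e in entries:
            if e.family in self.entries:
                raise ValueError(f"duplicate family {e.family}")
            self.entries[e.family] = e
        self._profiles: dict[str, ProfileHMM] = {}
        for p in profiles:
            self.add_profile(p)

    def add_profile(self, profile: ProfileHMM) -> None:
        self._profiles[profile.name] = profile

    def profiles_for(self, family: str) -> list[ProfileHMM]:
        entry = self.entries[family]
        missing = [n for n in entry.profiles if n not in self._profiles]
        if missing:
            raise KeyError(f"profiles not loaded for {family}: {missing}")
        return [self._profiles[n] for n in entry.profiles]

    def group_of(self, family: str) -> str:
        return self.entries[family].group

    def families(self) -> list[str]:
        return list(self.entries)

    # -- TSV round trip ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "family": e.family,
                "profiles": ",".join(e.profiles),
                "group": e.group,
                "activity": e.activity,
            }
            for e in self.entries.values()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyCatalog":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(
            FamilyEntry(
                family=r.family,
                profiles=r.profiles.split(","),
                group=r.group,
                activity=r.activity,
            )
            for r in df.itertuples()
        )


@dataclass
class DomainHit:
    """Best local profile match of one family on one contig."""

    contig_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    family: str
    profile_name: str
    score: float  # bits
    pep_begin: int  # 0-based half-open span on the frame translation
    pep_end: int

    def nt_span(self, contig_length: int) -> tuple[int, int]:
        """Forward-strand nucleotide span of the hit (0-based half-open)."""
        k = abs(self.frame)
        lo = (k - 1) + 3 * self.pep_begin
        hi = (k - 1) + 3 * self.pep_end
        if self.frame > 0:
            return lo, hi
        return contig_length - hi, contig_length - lo


@dataclass
class WeightingParams:
    """Depth weighting and hit acceptance parameters."""

    median_read_length: int = 400
    score_threshold: float = 25.0  # bits

    def __post_init__(self) -> None:
        if self.median_read_length <= 0:
            raise ValueError("median_read_length must be positive")


# ---------------------------------------------------------------------------
# six-frame translation
# ---------------------------------------------------------------------------

FRAMES = (1, 2, 3, -1, -2, -3)


def _translate_frame(seq: str, offset: int) -> str:
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    pep = str(Seq(sub).translate(table=11))
    if set(sub) <= set("ACGT"):
        return pep
    # any codon containing a non-ACGT base is masked to X
    out = list(pep)
    for i in range(len(out)):
        codon = sub[3 * i : 3 * i + 3]
        if any(b not in "ACGT" for b in codon):
            out[i] = "X"
    return "".join(out)


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate all six frames; stops as ``*``, ambiguous codons as ``X``.

    Frame ``+k`` reads the forward strand from offset ``k-1``; frame ``-k``
    reads the reverse complement from offset ``k-1``.
    """
    seq = dna.upper()
    rc = str(Seq(seq).reverse_complement())
    frames: dict[int, str] = {}
    for k in (1, 2, 3):
        frames[k] = _translate_frame(seq, k - 1)
        frames[-k] = _translate_frame(rc, k - 1)
    return frames


# ---------------------------------------------------------------------------
# Plan7-style local Viterbi
# ---------------------------------------------------------------------------


def _viterbi_segment(
    profile_arrays: tuple,
    residues: str,
) -> tuple[float, int, int]:
    """Best local path score (bits) within one stop-free peptide segment.

    Returns (score, begin, end) with a half-open residue span; ``NEG`` score
    if no positive-scoring path exists.
    """
    mlo, ilo, t, entry = profile_arrays
    L = mlo.shape[0]
    tMM, tMI, tMD = t[:, 0], t[:, 1], t[:, 2]
    tIM, tII = t[:, 3], t[:, 4]
    tDM, tDD = t[:, 5], t[:, 6]
    C = np.concatenate(([0.0], np.cumsum(tDD)))  # C[s] = sum tDD[0..s-1]
    C1 = C[1:]  # C1[j] = C[j+1]
    states = np.arange(L)

    prevM = np.full(L, NEG)
    prevI = np.full(L, NEG)
    prevD = np.full(L, NEG)
    startM = np.zeros(L, dtype=np.int64)
    startI = np.zeros(L, dtype=np.int64)
    startD = np.zeros(L, dtype=np.int64)

    best_score = NEG
    best_end = -1
    best_start = -1

    for i, aa in enumerate(residues):
        if aa == "X":
            emisM = np.zeros(L)
            emisI = np.zeros(L)
        else:
            j = AA_INDEX.get(aa)
            if j is None:
                raise ValueError(f"residue {aa!r} outside amino-acid alphabet")
            emisM = mlo[:, j]
            emisI = ilo[:, j]

        # match state: fresh local entry, or extend from M/I/D at node s-1
        shift = lambda arr, tr: np.concatenate(([NEG], arr[:-1] + tr[:-1]))
        candv = np.stack(
            [
                np.full(L, entry),
                shift(prevM, tMM),
                shift(prevI, tIM),
                shift(prevD, tDM),
            ]
        )
        cands = np.stack(
            [
                np.full(L, i, dtype=np.int64),
                np.concatenate(([0], startM[:-1])),
                np.concatenate(([0], startI[:-1])),
                np.concatenate(([0], startD[:-1])),
            ]
        )
        choice = np.argmax(candv, axis=0)
        M = emisM + np.take_along_axis(candv, choice[None, :], 0)[0]
        sM = np.take_along_axis(cands, choice[None, :], 0)[0]

        # insert state: stay at node s
        iv = np.stack([prevM + tMI, prevI + tII])
        ic = np.stack([startM, startI])
        ichoice = np.argmax(iv, axis=0)
        I = emisI + np.take_along_axis(iv, ichoice[None, :], 0)[0]
        sI = np.take_along_axis(ic, ichoice[None, :], 0)[0]

        # delete states: within-column chain M[j] -> D[j+1] -> ... -> D[s]
        key = M + tMD - C1
        R = np.maximum.accumulate(key)
        newmax = key >= R
        idx = np.maximum.accumulate(np.where(newmax, states, -1))
        D = np.full(L, NEG)
        if L > 1:
            D[1:] = C[1:L] + R[:-1]
            srcs = np.maximum(idx[:-1], 0)
            sD = np.concatenate(([0], sM[srcs]))
        else:
            sD = np.zeros(L, dtype=np.int64)

        col_best = np.argmax(M)
        if M[col_best] > best_score:
            best_score = M[col_best]
            best_end = i + 1
            best_start = int(sM[col_best])

        prevM, prevI, prevD = M, I, D
        startM, startI, startD = sM, sI, sD

    return best_score, best_start, best_end


def _profile_arrays(profile: ProfileHMM) -> tuple:
    mlo = np.maximum(profile.match_log_odds(), NEG)
    ilo = np.maximum(profile.insert_log_odds(), NEG)
    t = np.maximum(profile.transition_log2(), NEG)
    entry = float(np.log2(1.0 / profile.length))
    return mlo, ilo, t, entry


def viterbi_local(
    profile: ProfileHMM, peptide: str
) -> tuple[float, tuple[int, int] | None]:
    """Best single-hit local alignment score of a profile against a peptide.

    The model allows uniform entry into any match state (cost
    ``log2(1/length)``) and free exit from any match state; residues score
    emission log-odds in bits against the profile background, transitions
    score their log2 probabilities.  ``X`` residues score zero bits anywhere;
    alignments never cross a ``*`` stop character.

    Returns ``(score_bits, (begin, end))`` with a 0-based half-open peptide
    span, or ``(-inf, None)`` when no positive-scoring path exists.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    arrays = _profile_arrays(profile)
    best = (NEG, None)
    offset = 0
    for segment in peptide.split("*"):
        if segment:
            score, b, e = _viterbi_segment(arrays, segment)
            if score > best[0]:
                best = (score, (offset + b, offset + e))
        offset += len(segment) + 1
    if best[0] <= 0.0:
        return float("-inf"), None
    return best


# ---------------------------------------------------------------------------
# contig scanning and the weighted inventory
# ---------------------------------------------------------------------------


def scan_contigs(
    contigs: Sequence[DepthContig],
    catalog: FamilyCatalog,
    params: WeightingParams | None = None,
) -> list[DomainHit]:
    """Scan every contig with every family model over all six frames.

    Keeps at most one hit per contig-family pair: the best score across
    frames and across the family's domain models, provided it reaches the
    bit-score threshold.
    """
    params = params or WeightingParams()
    if not catalog.families():
        raise ValueError("family catalog is empty")
    hits: list[DomainHit] = []
    for contig in contigs:
        frames = six_frame_translate(contig.sequence)
        for family in catalog.families():
            best: DomainHit | None = None
            for profile in catalog.profiles_for(family):
                for frame, pep in frames.items():
                    if not pep:
                        continue
                    score, span = viterbi_local(profile, pep)
                    if span is None or score < params.score_threshold:
                        continue
                    if best is None or score > best.score:
                        best = DomainHit(
                            contig_id=contig.contig_id,
                            frame=frame,
                            family=family,
                            profile_name=profile.name,
                            score=score,
                            pep_begin=span[0],
                            pep_end=span[1],
                        )
            if best is not None:
                hits.append(best)
    return hits


def contig_weight(contig: DepthContig, params: WeightingParams | None = None) -> float:
    """Approximate fold coverage: ``n_reads * median_read_length / length``."""
    params = params or WeightingParams()
    if len(contig) == 0:
        raise ValueError("contig has zero length")
    return contig.n_reads * params.median_read_length / len(contig)


def group_percentages(
    family_percentages: Mapping[str, float], catalog: FamilyCatalog
) -> dict[str, float]:
    """Aggregate per-family percentages into functional-group totals."""
    totals = {g: 0.0 for g in FUNCTIONAL_GROUPS}
    for family, pct in family_percentages.items():
        totals[catalog.group_of(family)] += pct
    return totals


def inventory_table(
    hits: Sequence[DomainHit],
    contigs: Sequence[DepthContig],
    catalog: FamilyCatalog,
    params: WeightingParams | None = None,
) -> pd.DataFrame:
    """Depth-weighted family inventory (Table-2-shaped).

    Each family's weight is the sum of the fold-coverage weights of the
    contigs it hits (one count per contig-family pair); percentages are
    weights normalized over all families with at least one hit, so they sum
    to 100.  The returned frame has one row per catalog family with columns
    ``family, group, weight, percentage``.
    """
    params = params or WeightingParams()
    if not hits:
        raise ValueError("no domain hits: cannot build an inventory")
    by_id = {c.contig_id: c for c in contigs}
    missing = {h.contig_id for h in hits} - set(by_id)
    if missing:
        raise KeyError(f"hits reference unknown contigs: {sorted(missing)}")
    weights = {f: 0.0 for f in catalog.families()}
    for h in hits:
        weights[h.family] += contig_weight(by_id[h.contig_id], params)
    total = sum(weights.values())
    rows = [
        {
            "family": f,
            "group": catalog.group_of(f),
            "weight": w,
            "percentage": 100.0 * w / total,
        }
        for f, w in weights.items()
    ]
    return pd.DataFrame(rows)


def gh_fraction_of_genes(
    hits: Sequence[DomainHit],
    genes: Sequence,
    contig_lengths: Mapping[str, int],
) -> float:
    """Percent of predicted genes overlapping a GH domain hit (unweighted).

    ``genes`` are gene calls with ``contig_id``, ``start``, ``end``
    attributes in forward-strand coordinates.
    """
    if not genes:
        raise ValueError("no genes supplied")
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        spans.setdefault(h.contig_id, []).append(
            h.nt_span(contig_lengths[h.contig_id])
        )
    n_gh = 0
    for g in genes:
        for lo, hi in spans.get(g.contig_id, ()):
            if g.start < hi and lo < g.end:
                n_gh += 1
                break
    return 100.0 * n_gh / len(genes)
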