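"""SSU rRNA amplicon preprocessing and two-timepoint community comparison.

Reads are demultiplexed on an exact 5-bp barcode prefix, length-filtered
(>= 220 nt after barcode trimming, boundary inclusive), tallied into a
phylotype count table, and compared between timepoints by relative
abundance, Bray-Curtis dissimilarity and per-phylotype fold enrichment.
A phylotype below the detection floor at t0 gets a lower-bound enrichment
(``p_t1 / tau``, flagged ``>=``) rather than an undefined ratio.

Phylotype assignment here is exact-label tallying (synthetic reads carry
their label in the description field); to analyse a real study, substitute
an externally produced count table via :func:`load_phylotype_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis


@dataclass
class AmpliconParams:
    """Preprocessing and detection parameters.

    ``detection_threshold`` is a proportion of total sample reads
    (0.09% -> 0.0009).
    """

    barcode_length: int = 5
    min_length: int = 220
    detection_threshold: float = 0.0009

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must be in (0,1)")


def demultiplex(
    reads: Sequence,
    barcode_map: Mapping[str, str],
    params: AmpliconParams | None = None,
) -> tuple[dict[str, list], list]:
    """Partition reads by exact barcode prefix; trim barcodes off assigned reads.

    Returns ``(per_sample, unassigned)``; every input read lands in exactly
    one output bucket.  Reads are Biopython ``SeqRecord`` objects.
    """
    params = params or AmpliconParams()
    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate barcodes")
    samples = list(barcode_map.values())
    if len(set(samples)) != len(samples):
        raise ValueError("two barcodes map to the same sample")
    for bc in barcode_map:
        if len(bc) != params.barcode_length:
            raise ValueError(
                f"barcode {bc!r} is not {params.barcode_length} nt"
            )
    per_sample: dict[str, list] = {s: [] for s in samples}
    unassigned: list = []
    for read in reads:
        prefix = str(read.seq[: params.barcode_length])
        sample = barcode_map.get(prefix)
        if sample is None:
            unassigned.append(read)
        else:
            trimmed = read[params.barcode_length :]
            trimmed.id = read.id
            trimmed.description = read.description
            per_sample[sample].append(trimmed)
    return per_sample, unassigned


def length_filter(reads: Iterable, params: AmpliconParams | None = None) -> list:
    """Retain reads of length >= ``min_length`` (inclusive boundary)."""
    params = params or AmpliconParams()
    return [r for r in reads if len(r.seq) >= params.min_length]


def tally_phylotypes(per_sample: Mapping[str, Sequence]) -> pd.DataFrame:
    """Count phylotype labels per sample (labels from ``phylotype=`` tags)."""
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in per_sample.items():
        col: dict[str, int] = {}
        for read in reads:
            label = None
            for token in read.description.split():
                if token.startswith("phylotype="):
                    label = token.split("=", 1)[1]
            if label is None:
                raise ValueError(f"read {read.id} carries no phylotype label")
            col[label] = col.get(label, 0) + 1
        counts[sample] = col
    table = pd.DataFrame(counts).fillna(0).astype(int)
    table.index.name = "phylotype"
    return table.sort_index()


def relative_abundance(table: pd.DataFrame, sample: str) -> pd.Series:
    """Proportions for one sample column; errors on an empty column."""
    col = table[sample]
    total = col.sum()
    if total <= 0:
        raise ValueError(f"sample {sample!r} has zero total count")
    return col / total


def bray_curtis(p: pd.Series, q: pd.Series) -> float:
    """Bray-Curtis dissimilarity ``sum|p-q| / sum(p+q)`` over the label union."""
    union = p.index.union(q.index)
    pv = p.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    qv = q.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    if pv.sum() == 0 and qv.sum() == 0:
        raise ValueError("both profiles are all-zero")
    return float(braycurtis(pv, qv))


def fold_enrichment(
    p_t1: pd.Series,
    p_t0: pd.Series,
    params: AmpliconParams | None = None,
) -> pd.DataFrame:
    """Per-phylotype enrichment between timepoints, with a detection floor.

    For phylotypes detected at t0 (``p_t0 >= tau``) the enrichment is the
    exact ratio ``p_t1 / p_t0``; below the floor only the lower bound
    ``p_t1 / tau`` can be asserted and the row is flagged ``is_lower_bound``.
    Rows are sorted by t1 abundance (rank-abundance overlay order).
    """
    params = params or AmpliconParams()
    tau = params.detection_threshold
    union = p_t1.index.union(p_t0.index)
    t1 = p_t1.reindex(union, fill_value=0.0)
    t0 = p_t0.reindex(union, fill_value=0.0)
    rows = []
    for label in union:
        a1, a0 = float(t1[label]), float(t0[label])
        if a0 >= tau:
            fold, bound = a1 / a0, False
        else:
            fold, bound = a1 / tau, True
        rows.append(
            {
                "phylotype": label,
                "p_t0": a0,
                "p_t1": a1,
                "fold": fold,
                "is_lower_bound": bound,
            }
        )
    report = pd.DataFrame(rows).sort_values(
        "p_t1", ascending=False, kind="mergesort"
    )
    return report.reset_index(drop=True)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def save_phylotype_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def load_phylotype_table(path: str | Path) -> pd.DataFrame:
    """Load an externally produced phylotype count table (TSV)."""
    return pd.read_csv(path, sep="\t", index_col=0)
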