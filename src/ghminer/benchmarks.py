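"""Self-contained recovery benchmarks on synthetic ground truth.

Each function generates its inputs with the :mod:`ghminer.synthetic_data`
module under fixed study conditions, runs the corresponding pipeline stage,
and reports how well the planted truth was recovered.  They back the
acceptance test suite and double as a quick health check on any machine:

* :func:`frameshift_benchmark` — genes with 0-3 planted homopolymer indels;
  fraction of indels corrected within the true run, fraction of gene
  peptides restored exactly, monotonicity/idempotence bookkeeping.
* :func:`inventory_recovery` — a four-family community planted at 40/30/20/10
  expected weight; recovered inventory percentages.
* :func:`fold_enrichment_recovery` — a rare taxon enriched 22-fold;
  enrichment measured from multinomial count tables.
* :func:`respiration_roundtrip` — rates recovered from generated gas series
  and trapezoid integrals against closed forms.
"""

from __future__ import annotations

import numpy as np

from . import amplicon, fulllength, gh_inventory, respiration, synthetic_data as sd


def frameshift_benchmark(n_genes: int = 100, seed: int = 0) -> dict:
    """Plant 0-3 homopolymer indels per synthetic gene and correct them.

    Genes (~250 aa) sit one per contig with ~300 nt flanks; each gene's
    indel budget is drawn uniformly from {0,1,2,3}, indels fall in
    homopolymer runs inside the gene body (75 nt end margins, >=150 nt
    apart so correction windows stay disjoint).  Correction runs against
    the gene's true reference peptide.

    Returns counts plus per-gene bookkeeping: an indel counts as corrected
    in-run when the applied edit maps into the planted run (+/- 1 nt); a
    gene counts as exact when the corrected contig encodes the truth
    peptide again.
    """
    rng = np.random.default_rng(seed)
    prof = sd.make_profile("BM_dom", 250, seed=int(rng.integers(2**31)))
    catalog = gh_inventory.FamilyCatalog(
        [gh_inventory.FamilyEntry("GH5", ["BM_dom"], "cellulases")], [prof]
    )
    spec = sd.CommunitySpec(
        [sd.TaxonSpec("BM", 1.0, 1.0, [("GH5", n_genes)])],
        contig_length_range=(1300, 1700),
        seed=0,
    )
    contigs, truth = sd.build_contig_set(
        spec, catalog, seed=int(rng.integers(2**31)), coverage_scale=20.0
    )
    refs = {}
    for row in truth.itertuples():
        refs[row.contig_id] = fulllength.EnzymeReference(
            f"ref_{row.contig_id}", row.peptide, ec="3.2.1.4", family="GH5"
        )
    originals = {c.contig_id: c.sequence for c in contigs}

    n_planted = n_in_run = n_exact = 0
    n_monotone_violations = n_idempotence_violations = 0
    for contig in contigs:
        row = truth[truth.contig_id == contig.contig_id].iloc[0]
        budget = int(rng.integers(0, 4))
        model = sd.ErrorModel(
            indel_prob=lambda n: 0.6, seed=int(rng.integers(2**31))
        )
        mutated, planted = sd.plant_frameshifts(
            [contig],
            model,
            regions={contig.contig_id: [(row.start + 75, row.end - 75)]},
            max_per_contig=budget,
            min_spacing=150,
        )
        n_planted += len(planted)
        corrected, edits = fulllength.correct_frameshifts(
            mutated[0], refs[contig.contig_id]
        )
        for e in edits:
            if e.score_after < e.score_before:
                n_monotone_violations += 1
            offset = sum(
                1 if k == "delete" else -1
                for k, pm in zip(planted.kind, planted.position_mutated)
                if pm < e.position_input
            )
            pos = e.position_input + offset
            if (
                (planted.run_start - 1 <= pos) & (pos <= planted.run_end)
            ).any():
                n_in_run += 1
        again, edits2 = fulllength.correct_frameshifts(
            corrected, refs[contig.contig_id]
        )
        if edits2 or again.sequence != corrected.sequence:
            n_idempotence_violations += 1
        if corrected.sequence == originals[contig.contig_id]:
            n_exact += 1
        else:
            frames = gh_inventory.six_frame_translate(corrected.sequence)
            if any(row.peptide in p for p in frames.values()):
                n_exact += 1
    return {
        "n_genes": n_genes,
        "n_planted": n_planted,
        "n_in_run": n_in_run,
        "frac_in_run": n_in_run / n_planted if n_planted else 1.0,
        "n_exact": n_exact,
        "frac_exact": n_exact / n_genes,
        "monotone_violations": n_monotone_violations,
        "idempotence_violations": n_idempotence_violations,
    }


INVENTORY_PLAN = (("GH5", 0.4), ("GH10", 0.3), ("GH43", 0.2), ("GH9", 0.1))


def inventory_recovery(seed: int = 0, coverage_scale: float = 50.0) -> dict:
    """Recover planted 40/30/20/10 family proportions from the inventory.

    One taxon per family, each with ten planted genes (enough contigs that
    Poisson read-count noise stays well inside the tolerance); taxon
    abundances equal the target weight shares, so the expected
    depth-weighted family percentages are exactly the planted proportions.
    ``coverage_scale`` 50 puts the rarest taxon at ~5x fold coverage.
    """
    rng = np.random.default_rng(seed)
    entries, profiles = [], []
    group_cycle = list(gh_inventory.FUNCTIONAL_GROUPS)
    for i, (fam, _) in enumerate(INVENTORY_PLAN):
        prof = sd.make_profile(
            f"{fam}_dom", 120, seed=int(rng.integers(2**31)), family=fam
        )
        profiles.append(prof)
        entries.append(
            gh_inventory.FamilyEntry(fam, [prof.name], group_cycle[i % 5])
        )
    catalog = gh_inventory.FamilyCatalog(entries, profiles)
    spec = sd.CommunitySpec(
        taxa=[
            sd.TaxonSpec(f"T{fam}", share, 1.0, [(fam, 10)])
            for fam, share in INVENTORY_PLAN
        ],
        contig_length_range=(1300, 1700),
        seed=0,
    )
    contigs, truth = sd.build_contig_set(
        spec, catalog, seed=int(rng.integers(2**31)), coverage_scale=coverage_scale
    )
    hits = gh_inventory.scan_contigs(contigs, catalog)
    table = gh_inventory.inventory_table(hits, contigs, catalog)
    recovered = dict(zip(table["family"], table["percentage"]))
    return {
        fam: {"planted": 100.0 * share, "recovered": recovered.get(fam, 0.0)}
        for fam, share in INVENTORY_PLAN
    }


def fold_enrichment_recovery(
    seed: int = 0, depth: int = 1_000_000, fold: float = 22.0
) -> dict:
    """Measure a planted fold enrichment from multinomial count tables."""
    a0 = 0.002
    rest0 = 1.0 - a0
    rest1 = 1.0 - a0 * fold
    spec = sd.CommunitySpec(
        [
            sd.TaxonSpec("enriched", a0, fold),
            sd.TaxonSpec("background", rest0, rest1 / rest0),
        ],
        seed=0,
    )
    table = sd.make_phylotype_tables(spec, depth=depth, seed=seed)
    p0 = amplicon.relative_abundance(table, "t0")
    p1 = amplicon.relative_abundance(table, "t1")
    report = amplicon.fold_enrichment(p1, p0)
    measured = float(
        report.loc[report.phylotype == "enriched", "fold"].iloc[0]
    )
    return {"planted": fold, "measured": measured}


def respiration_roundtrip() -> dict:
    """Exactness of the gas-series inversion and trapezoid integration."""
    cer_fn = lambda t: 4.0 + 3.0 * np.sin(2 * np.pi * t / 7.0) ** 2
    our_fn = lambda t: 5.0 + 2.0 * np.cos(2 * np.pi * t / 5.0) ** 2
    df = sd.make_gas_series(cer_fn, our_fn, flow=5000.0, t_end=31.0)
    want_cer = np.array([cer_fn(t) for t in df["t_day"]])
    want_our = np.array([our_fn(t) for t in df["t_day"]])
    rel_cer = np.max(
        np.abs(respiration.cer(df).to_numpy() - want_cer) / np.abs(want_cer)
    )
    rel_our = np.max(
        np.abs(respiration.our(df).to_numpy() - want_our) / np.abs(want_our)
    )

    peak, t_end = 10.0, 4.0

    def tri(t):
        half = t_end / 2
        return peak * (t / half if t <= half else (t_end - t) / half)

    tri_df = sd.make_gas_series(tri, tri, flow=5000.0, t_end=t_end)
    integral = respiration.integrate(tri_df["t_day"], respiration.cer(tri_df))
    tri_err = abs(integral - peak * t_end / 2) / (peak * t_end / 2)
    return {
        "max_rel_err_cer": float(rel_cer),
        "max_rel_err_our": float(rel_our),
        "triangle_rel_err": float(tri_err),
    }
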