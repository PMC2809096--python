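"""Shared fixtures: small family catalogs and synthetic communities."""

import numpy as np
import pytest

from ghminer import gh_inventory as ghi
from ghminer import synthetic_data as sd


def random_profile(length: int, seed: int, conservation: float | None = None):
    """A fully random profile HMM (Dirichlet emissions, random transitions).

    Unlike :func:`ghminer.synthetic_data.make_profile` (peaked, structured),
    this exercises arbitrary emission/transition mixes for oracle tests.
    """
    rng = np.random.default_rng(seed)
    if conservation is None:
        match = rng.dirichlet(np.full(20, 0.5), size=length)
    else:
        dom = rng.integers(0, 20, size=length)
        match = np.full((length, 20), (1 - conservation) / 19.0)
        match[np.arange(length), dom] = conservation
    insert = rng.dirichlet(np.full(20, 5.0), size=length)
    trans = np.empty((length, 7))
    for k in range(length):
        mm, mi, md = rng.dirichlet([20.0, 1.0, 1.0])
        im, ii = rng.dirichlet([5.0, 1.0])
        dm, dd = rng.dirichlet([5.0, 1.0])
        trans[k] = [mm, mi, md, im, ii, dm, dd]
    trans[-1, 2] = 0.0  # no delete state beyond the last node
    trans[-1, 6] = 0.0
    from ghminer.hmmio import ProfileHMM

    return ProfileHMM(
        name=f"rand{seed}",
        length=length,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
    )


@pytest.fixture(scope="session")
def small_catalog():
    """Catalog with three families; GH2 has two domain models."""
    profiles = [
        sd.make_profile("GH5_dom", 80, seed=11, family="GH5"),
        sd.make_profile("GH10_dom", 80, seed=12, family="GH10"),
        sd.make_profile("GH2_dom1", 60, seed=13, family="GH2"),
        sd.make_profile("GH2_dom2", 60, seed=14, family="GH2"),
    ]
    entries = [
        ghi.FamilyEntry("GH5", ["GH5_dom"], "cellulases", "cellulase"),
        ghi.FamilyEntry("GH10", ["GH10_dom"], "endohemicellulases", "xylanase"),
        ghi.FamilyEntry(
            "GH2", ["GH2_dom1", "GH2_dom2"], "oligosaccharide-degrading",
            "beta-galactosidase",
        ),
    ]
    return ghi.FamilyCatalog(entries, profiles)


@pytest.fixture(scope="session")
def planted_community(small_catalog):
    """Small two-taxon community with planted GH genes and truth table."""
    spec = sd.CommunitySpec(
        taxa=[
            sd.TaxonSpec("TaxA", 0.7, 1.0, [("GH5", 2)]),
            sd.TaxonSpec("TaxB", 0.3, 1.0, [("GH10", 1), ("GH2", 1)]),
        ],
        contig_length_range=(1500, 2500),
        seed=0,
    )
    contigs, truth = sd.build_contig_set(
        spec, small_catalog, seed=101, coverage_scale=30.0
    )
    return spec, contigs, truth
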