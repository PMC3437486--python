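"""Shared fixtures: one desk-scale simulation mapped once per session."""

from __future__ import annotations

import numpy as np
import pytest

from tusmine import expression as ex
from tusmine import variants as va
from tusmine.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim():
    """Desk-scale synthetic dataset under the default study conditions."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_mapped(sim):
    """Tag alignments, counts and pileups for both libraries."""
    index = ex.build_index(sim["tus"])
    aln1 = ex.map_tags(sim["tags_g1"], index)
    aln2 = ex.map_tags(sim["tags_g2"], index)
    counts1 = ex.count_tags(aln1, "unique_only")
    counts2 = ex.count_tags(aln2, "unique_only")
    pile1 = va.build_pileup(
        aln1, sim["tus"], {t.id: t.residues for t in sim["tags_g1"]}, "g1"
    )
    pile2 = va.build_pileup(
        aln2, sim["tus"], {t.id: t.residues for t in sim["tags_g2"]}, "g2"
    )
    return {
        "index": index,
        "aln1": aln1,
        "aln2": aln2,
        "counts1": counts1,
        "counts2": counts2,
        "pile1": pile1,
        "pile2": pile2,
        "n1": len({a.tag_id for a in aln1}),
        "n2": len({a.tag_id for a in aln2}),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
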