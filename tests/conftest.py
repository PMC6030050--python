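import numpy as np
import pytest

from honeytrace.reference_db import PrimerPair, build_database
from honeytrace.synthetic_data import (
    CommunityMember,
    CommunitySpec,
    make_host_record,
    make_reference_fixture,
)

# the community shape of a typical honey library: one dominant planthopper
# plus minor aphids, mirrored by the default fixture
SIX_SPECIES_FRACTIONS = (0.65, 0.15, 0.08, 0.04, 0.04, 0.04)


@pytest.fixture(scope="session")
def primers():
    return PrimerPair()


@pytest.fixture(scope="session")
def fixture6():
    """Six Hemiptera species, the dominant one with two mitotypes."""
    return make_reference_fixture(6, [2, 1, 1, 1, 1, 1], divergence=0.10, seed=7)


@pytest.fixture(scope="session")
def host():
    return make_host_record(seed=7)


@pytest.fixture(scope="session")
def db6(fixture6, host):
    host_record, _ = host
    return build_database(list(fixture6.records) + [host_record])


def species_order(fixture):
    order = []
    seen = set()
    for rec in fixture.records:
        sp = rec.lineage.species
        if sp not in seen:
            seen.add(sp)
            order.append(sp)
    return order


def community_spec(fixture, fractions=SIX_SPECIES_FRACTIONS, host_fraction=0.0,
                   dominant_mitotypes=(("Hap1", 0.85), ("Hap2", 0.15))):
    members = []
    for sp, frac in zip(species_order(fixture), fractions):
        haps = [h.haplotype_id for h in fixture.known[sp].entries]
        mito = dominant_mitotypes if len(haps) > 1 else ((haps[0], 1.0),)
        members.append(CommunityMember(sp, frac, tuple(mito)))
    return CommunitySpec(tuple(members), host_fraction=host_fraction)


def overlap_score_oracle(q: str, t: str) -> int:
    """Unbanded full-DP overlap alignment score (match +1 / mismatch -1 /
    gap -2, end gaps free on both sequences).  Independent brute force."""
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), dtype=int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = 1 if q[i - 1] == t[j - 1] else -1
            H[i, j] = max(H[i - 1, j - 1] + s, H[i - 1, j] - 2, H[i, j - 1] - 2)
    return int(max(H[m, :].max(), H[:, n].max()))
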