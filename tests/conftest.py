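import numpy as np
import pytest

from deltameth.datatypes import PooledBetaSet, ProbeAnnotation, RegionGroup


def ann(probe_id, chrom="1", pos=100, entries=()):
    """Shorthand ProbeAnnotation constructor for tests."""
    return ProbeAnnotation(
        probe_id=probe_id,
        chrom=chrom,
        pos=pos,
        gene_entries=tuple(
            (g, RegionGroup.parse(r) if isinstance(r, str) else r)
            for g, r in entries
        ),
    )


def pools(probe_ids, beta_male, beta_female, detp=0.0):
    n = len(probe_ids)
    return PooledBetaSet(
        probe_ids=list(probe_ids),
        beta_male=np.asarray(beta_male, dtype=float),
        beta_female=np.asarray(beta_female, dtype=float),
        detp_male=np.full(n, detp),
        detp_female=np.full(n, detp),
    )


@pytest.fixture
def tiny_manifest():
    return [
        ann("cg001", "1", 50, [("GENEA", "Body")]),
        ann("cg002", "1", 5_000_000, [("GENEA", "TSS200"), ("GENEB", "Body")]),
        ann("cg003", "2", 10, []),
        ann("cg004", "17", 999, [("GENEC", "5'UTR")]),
        ann("cg005", "X", 123, [("GENEX", "Body")]),
        ann("cg006", "Y", 456, [("GENEY", "TSS1500")]),
    ]


@pytest.fixture
def tiny_pools(tiny_manifest):
    ids = [a.probe_id for a in tiny_manifest]
    return pools(
        ids,
        beta_male=[0.50, 0.10, 0.90, 0.40, 0.80, 0.50],
        beta_female=[0.80, 0.10, 0.60, 0.45, 0.45, 0.80],
    )
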