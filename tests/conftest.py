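import numpy as np
import pytest

from firereg import FireScarRecord, TreeRecord


def make_trees(establishment_years, site_id="S1", excluded=None):
    """Build retained dated trees from a list of establishment years."""
    excluded = excluded or set()
    return [
        TreeRecord(
            site_id=site_id,
            tree_id=f"T{i}",
            inner_ring_year=y,
            establishment_year=y,
            excluded=i in excluded,
        )
        for i, y in enumerate(establishment_years)
    ]


def make_scars(tree_years, site_id="S1", season="unknown"):
    """Build scar records from (tree_id, year) or (tree_id, start, end)."""
    out = []
    for ty in tree_years:
        if len(ty) == 2:
            tid, y = ty
            out.append(FireScarRecord(site_id, tid, y, season=season))
        else:
            tid, y0, y1 = ty
            out.append(FireScarRecord(site_id, tid, y0, y1, season=season))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
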