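"""Small numeric helpers shared across the decentralized algorithms."""

from __future__ import annotations

import numpy as np

__all__ = ["pairwise_sum", "derive_site_seed", "check_finite"]


def pairwise_sum(arrays):
    """Sum a sequence of conformable arrays (or scalars) pairwise.

    Pairwise reduction keeps the aggregation error O(log n) in the number of
    sites and, more importantly, makes the summation order a pure function of
    the (sorted) site list, which is the reproducibility contract of the
    aggregator.
    """
    items = [np.asarray(a, dtype=float) for a in arrays]
    if not items:
        raise ValueError("pairwise_sum of an empty sequence")
    while len(items) > 1:
        nxt = []
        for i in range(0, len(items) - 1, 2):
            nxt.append(items[i] + items[i + 1])
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
    return items[0]


def derive_site_seed(master_seed: int, site_index: int) -> int:
    """Per-site RNG stream seed: master_seed + site position (ascending id).

    Appending a site (which sorts last) leaves every existing site's draws
    untouched.
    """
    return int(master_seed) + int(site_index)


def check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
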