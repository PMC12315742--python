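"""Worker pool wrapper: workers=0 means run on a single core.

Parallelism is always over independent units (features, blocks, subsample
draws) with an order-preserving reduction, so results are invariant to the
worker count.
"""

from __future__ import annotations

from joblib import Parallel, delayed


def parallel_map(fn, items, workers: int = 0) -> list:
    if workers in (0, 1):
        return [fn(item) for item in items]
    return Parallel(n_jobs=workers)(delayed(fn)(item) for item in items)
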