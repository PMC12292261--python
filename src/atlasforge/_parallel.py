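"""Deterministic parallel map over subjects.

Subject-level work (registration, feature extraction) is embarrassingly
parallel and purely functional, so results depend only on the inputs and
their order — never on the worker count or scheduling.  joblib's loky
backend preserves input order, which keeps every pipeline artifact
bit-identical across ``n_workers`` settings.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from typing import TypeVar

from joblib import Parallel, delayed

T = TypeVar("T")
R = TypeVar("R")


def parallel_map(fn: Callable[[T], R], items: Sequence[T], n_workers: int = 1) -> list[R]:
    if n_workers <= 1 or len(items) <= 1:
        return [fn(x) for x in items]
    return Parallel(n_jobs=n_workers)(delayed(fn)(x) for x in items)
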