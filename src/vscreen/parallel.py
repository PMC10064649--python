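"""Order-preserving worker-pool map.

The contract is worker-count invariance: for a pure per-item task the
result list is identical (element for element, in input order) for any
number of workers, so every screening output is reproducible regardless of
parallelization.  Tasks are dispatched in chunks to amortize inter-process
overhead.
"""

from __future__ import annotations

import multiprocessing as mp
from typing import Callable, Sequence, TypeVar

from .models import VScreenError

T = TypeVar("T")
R = TypeVar("R")

_CURRENT_TASK: Callable | None = None


def _init_worker(task: Callable) -> None:
    global _CURRENT_TASK
    _CURRENT_TASK = task


def _run_item(indexed: tuple[int, object]):
    idx, item = indexed
    try:
        return _CURRENT_TASK(item)
    except VScreenError:
        raise  # configuration errors carry their own diagnostics
    except Exception as exc:
        raise RuntimeError(f"worker task failed on item {idx}: {exc}") from exc


def parallel_map(task: Callable[[T], R], items: Sequence[T], n_workers: int = 1) -> list[R]:
    """Apply ``task`` to every item, preserving input order.

    ``n_workers == 1`` runs in-process (no pool); higher counts use a
    process pool, so the task and items must be picklable.  A crash in any
    worker propagates as a fatal error naming the offending item's index.
    """
    items = list(items)
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if n_workers == 1 or len(items) <= 1:
        out = []
        for i, item in enumerate(items):
            try:
                out.append(task(item))
            except VScreenError:
                raise
            except Exception as exc:
                raise RuntimeError(f"task failed on item {i}: {exc}") from exc
        return out
    chunksize = max(1, len(items) // (n_workers * 4))
    ctx = mp.get_context("spawn")
    with ctx.Pool(n_workers, initializer=_init_worker, initargs=(task,)) as pool:
        return pool.map(_run_item, list(enumerate(items)), chunksize=chunksize)
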