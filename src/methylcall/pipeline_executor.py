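"""Pipelined batch execution of the four-stage calling workflow.

Batches of reads flow through the four stages — event detection, alignment,
calibration, methylation scoring — concurrently, under two constraints that
together reproduce the pipelined schedule of a heterogeneous CPU/GPU
deployment with portable primitives:

* an *admission window*: at most ``batch_count`` batches are in flight
  (between stage-1 entry and stage-4 exit) at any instant, enforced by a
  semaphore;
* *per-stage exclusivity and in-order entry*: each stage processes one
  batch at a time and batches enter every stage in batch-id order, enforced
  by a per-stage turnstile.

One coordinating thread is launched per in-flight batch.  Stage functions
must be pure per-batch transformations; the per-read call records are then
independent of the window size, thread count and scheduling.
"""

from __future__ import annotations

import logging
import threading
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .model_types import MethylationCall, Read

logger = logging.getLogger(__name__)

STAGE_NAMES = ("event_detection", "alignment", "calibration", "methylation_score")
NUM_STAGES = len(STAGE_NAMES)


@dataclass
class Batch:
    """A unit of pipelined processing with its per-stage artifacts."""

    batch_id: int
    reads: list[Read]
    events: dict = field(default_factory=dict)
    alignments: dict = field(default_factory=dict)
    scalings: dict = field(default_factory=dict)
    calls: list[MethylationCall] = field(default_factory=list)
    status: dict = field(default_factory=dict)  # stage index -> completed
    error: Optional[str] = None


@dataclass(frozen=True)
class PipelineConfig:
    """Executor parameters: reads per batch, window size, worker threads."""

    batch_size: int = 10
    batch_count: int = 3
    threads: int = 1
    stage_resources: tuple[str, ...] = ("cpu", "accelerator", "cpu", "accelerator")

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.batch_count < 1:
            raise ValueError("batch_count must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass(frozen=True)
class TraceRecord:
    timestamp: float
    batch_id: int
    stage: int  # 1-based stage index
    stage_name: str
    action: str  # "enter" | "exit"


class PipelineTrace:
    """Ordered record of stage entries and exits (append order is the
    authoritative event order; timestamps are monotonic-clock seconds)."""

    def __init__(self):
        self.records: list[TraceRecord] = []
        self._lock = threading.Lock()

    def add(self, batch_id: int, stage: int, action: str) -> None:
        rec = TraceRecord(
            timestamp=time.monotonic(),
            batch_id=batch_id,
            stage=stage,
            stage_name=STAGE_NAMES[stage - 1],
            action=action,
        )
        with self._lock:
            self.records.append(rec)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("timestamp\tbatch_id\tstage\tstage_name\taction\n")
            for r in self.records:
                fh.write(
                    f"{r.timestamp:.6f}\t{r.batch_id}\t{r.stage}\t"
                    f"{r.stage_name}\t{r.action}\n"
                )

    def stage_intervals(self) -> dict[int, list[tuple[int, float, float]]]:
        """Per stage: list of (batch_id, enter_ts, exit_ts)."""
        opened: dict[tuple[int, int], float] = {}
        out: dict[int, list[tuple[int, float, float]]] = {
            s: [] for s in range(1, NUM_STAGES + 1)
        }
        for r in self.records:
            key = (r.batch_id, r.stage)
            if r.action == "enter":
                opened[key] = r.timestamp
            else:
                out[r.stage].append((r.batch_id, opened.pop(key), r.timestamp))
        return out


@dataclass
class PipelineRun:
    """Result of a pipeline execution."""

    calls: list[MethylationCall]
    trace: PipelineTrace
    failed: dict[int, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failed


class _StageTurnstile:
    """Admits batches to a stage one at a time, in batch-id order."""

    def __init__(self):
        self._cond = threading.Condition()
        self._next_id = 0

    def enter(self, batch_id: int) -> None:
        with self._cond:
            self._cond.wait_for(lambda: self._next_id == batch_id)

    def exit(self) -> None:
        with self._cond:
            self._next_id += 1
            self._cond.notify_all()


StageFn = Callable[[Batch], None]


def run_pipeline(
    batches: Iterable[Batch],
    config: PipelineConfig,
    stage_fns: tuple[StageFn, StageFn, StageFn, StageFn],
) -> PipelineRun:
    """Drive every batch through the four stages under the window limit.

    Stage functions receive the batch and attach their artifacts in place.
    A stage failure marks the batch failed; the batch then passes through
    the remaining stages as a no-op so the pipeline drains, and the failure
    is reported in ``PipelineRun.failed``.
    """
    if len(stage_fns) != NUM_STAGES:
        raise ValueError(f"exactly {NUM_STAGES} stage functions are required")
    trace = PipelineTrace()
    window = threading.Semaphore(config.batch_count)
    turnstiles = [_StageTurnstile() for _ in range(NUM_STAGES)]
    done: dict[int, Batch] = {}
    failed: dict[int, str] = {}
    lock = threading.Lock()

    def worker(batch: Batch) -> None:
        try:
            for stage_idx, fn in enumerate(stage_fns, start=1):
                turnstiles[stage_idx - 1].enter(batch.batch_id)
                trace.add(batch.batch_id, stage_idx, "enter")
                if batch.error is None:
                    try:
                        fn(batch)
                        batch.status[stage_idx] = True
                    except Exception as exc:
                        batch.error = f"stage {stage_idx} ({STAGE_NAMES[stage_idx-1]}): {exc}"
                        logger.error("batch %d failed at %s", batch.batch_id, batch.error)
                trace.add(batch.batch_id, stage_idx, "exit")
                turnstiles[stage_idx - 1].exit()
        finally:
            window.release()
            with lock:
                done[batch.batch_id] = batch
                if batch.error is not None:
                    failed[batch.batch_id] = batch.error

    threads = []
    expected_id = 0
    for batch in batches:  # stage-0 producer: loading is outside the window
        if batch.batch_id != expected_id:
            raise ValueError(
                f"batches must arrive with consecutive ids; expected "
                f"{expected_id}, got {batch.batch_id}"
            )
        expected_id += 1
        window.acquire()
        t = threading.Thread(target=worker, args=(batch,), daemon=True)
        t.start()
        threads.append(t)
    for t in threads:
        t.join()

    calls: list[MethylationCall] = []
    for bid in sorted(done):
        calls.extend(done[bid].calls)
    return PipelineRun(calls=calls, trace=trace, failed=failed)


def max_concurrency(trace: PipelineTrace) -> int:
    """Maximum number of batches simultaneously in flight (between their
    stage-1 entry and stage-4 exit), by a sweep over the trace's event
    order."""
    current = best = 0
    for r in trace.records:
        if r.stage == 1 and r.action == "enter":
            current += 1
            best = max(best, current)
        elif r.stage == NUM_STAGES and r.action == "exit":
            current -= 1
    return best


def make_batches(reads: list[Read], batch_size: int) -> list[Batch]:
    """Partition reads into consecutive fixed-size batches."""
    return [
        Batch(batch_id=i, reads=reads[start : start + batch_size])
        for i, start in enumerate(range(0, len(reads), batch_size))
    ]
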