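"""Crossover calling from parental phase switches.

A crossover is recorded where the parental phase of an isolate's ordered
marker calls changes and the change is supported by at least ``min_run``
consecutive informative markers of each parent on the two sides of the
breakpoint.  Runs shorter than ``min_run`` are treated as genotyping noise
and masked to MISSING (all sub-threshold runs in a pass, iterated to a fixed
point; equal-parent runs flanking a masked island merge into one longer run).
Missing calls are transparent by default: runs continue across them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import MISSING, ChromosomeDef, CrossoverEvent, GenotypeMatrix

logger = logging.getLogger(__name__)


def _rle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (start indices, end indices inclusive, lengths)."""
    if values.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [values.size - 1]))
    return starts, ends, ends - starts + 1


def mask_short_runs(calls: np.ndarray, min_run: int) -> np.ndarray:
    """Mask maximal same-parent runs shorter than ``min_run`` to MISSING.

    MISSING entries are transparent (excluded from run computation).  All
    sub-threshold runs of a pass are masked simultaneously; surviving
    equal-parent neighbours then merge, and the pass repeats until no short
    run remains.  Returns a masked copy; the input is untouched.
    """
    if min_run < 1:
        raise ValueError(f"min_run must be >= 1, got {min_run}")
    calls = np.asarray(calls, dtype=np.int8).copy()
    info = np.flatnonzero(calls != MISSING)
    vals = calls[info]
    while vals.size:
        starts, ends, lengths = _rle(vals)
        short = lengths < min_run
        if not short.any():
            break
        keep = np.zeros(vals.size, dtype=bool)
        for s, e in zip(starts[~short], ends[~short]):
            keep[s : e + 1] = True
        calls[info[~keep]] = MISSING
        info = info[keep]
        vals = vals[keep]
    return calls


def _events_for_sequence(
    calls: np.ndarray,
    positions: np.ndarray,
    min_run: int,
    break_on_missing: bool,
) -> list[tuple[int, int]]:
    """(left_bp, right_bp) breakpoint intervals for one isolate-chromosome."""
    if break_on_missing:
        # process each contiguous informative block independently
        out: list[tuple[int, int]] = []
        miss = calls == MISSING
        starts, ends, _ = _rle(miss.astype(np.int8))
        for s, e in zip(starts, ends):
            if miss[s]:
                continue
            out.extend(_events_for_sequence(calls[s : e + 1], positions[s : e + 1], min_run, False))
        return out

    masked = mask_short_runs(calls, min_run)
    info = np.flatnonzero(masked != MISSING)
    vals = masked[info]
    switch = np.flatnonzero(np.diff(vals) != 0)
    return [(int(positions[info[i]]), int(positions[info[i + 1]])) for i in switch]


def call_crossovers(
    matrix: GenotypeMatrix,
    min_run: int = 5,
    break_on_missing: bool = False,
) -> list[CrossoverEvent]:
    """Call crossover events for every isolate on every chromosome.

    Per isolate-chromosome the call sequence is run-masked
    (:func:`mask_short_runs`) and one event is emitted at each boundary
    between consecutive surviving runs of different parent, with coordinates
    taken from the flanking informative markers.  Deterministic.

    Chromosomes offering fewer than ``2 * min_run`` informative markers for
    an isolate cannot support any event and are logged as underpowered.
    """
    events: list[CrossoverEvent] = []
    pos = matrix.pos_bp()
    for chrom, sl in matrix.chrom_slices().items():
        cpos = pos[sl]
        sub = matrix.calls[sl]
        for j, iso in enumerate(matrix.isolates):
            seq = sub[:, j]
            n_info = int((seq != MISSING).sum())
            if n_info < 2 * min_run:
                logger.debug(
                    "underpowered: isolate %s chromosome %s has %d informative markers "
                    "(< %d); zero events",
                    iso,
                    chrom,
                    n_info,
                    2 * min_run,
                )
                continue
            for left_bp, right_bp in _events_for_sequence(seq, cpos, min_run, break_on_missing):
                events.append(
                    CrossoverEvent(isolate=iso, chromosome=chrom, left_bp=left_bp, right_bp=right_bp)
                )
    return events


def count_matrix(
    events: list[CrossoverEvent],
    isolates: list[str],
    genome: list[ChromosomeDef],
) -> pd.DataFrame:
    """Per-isolate, per-chromosome crossover counts plus the TCO total.

    Returns a DataFrame indexed by isolate with one column per chromosome
    and a ``TCO`` column (the row sum); isolates/chromosomes without events
    get zeros.
    """
    chroms = [c.name for c in genome]
    df = pd.DataFrame(0, index=pd.Index(isolates, name="isolate"), columns=chroms, dtype=int)
    for e in events:
        df.loc[e.isolate, e.chromosome] += 1
    df["TCO"] = df[chroms].sum(axis=1)
    return df
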