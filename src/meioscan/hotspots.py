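"""Crossover hotspot detection in fixed genomic windows.

The genome is tiled with non-overlapping windows (default 10 kb); each
called crossover is assigned to one window by the midpoint of its breakpoint
interval.  Under a genome-wide Poisson null with rate lambda = total events /
total windows, a window is a hotspot when its count reaches the smallest k
whose exact upper-tail probability P(X >= k) falls below ``alpha``
(default 1e-4).  No normal approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import ChromosomeDef, CrossoverEvent, genome_length, validate_genome

DEFAULT_WINDOW = 10_000
DEFAULT_ALPHA = 1e-4


@dataclass(frozen=True)
class WindowModel:
    """Poisson null for per-window crossover counts."""

    window_size: int
    lam: float
    alpha: float
    threshold_k: int


@dataclass(frozen=True)
class Hotspot:
    """A window whose crossover count reaches the Poisson threshold."""

    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # inclusive; truncated at the chromosome end
    count: int
    fold: float  # count / genome-wide per-window mean
    label: str


def window_counts(
    events: Iterable[CrossoverEvent],
    genome: Sequence[ChromosomeDef],
    window_size: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Crossovers per non-overlapping window.

    Windows are [i*w+1, (i+1)*w] in 1-based coordinates per chromosome, the
    last truncated at the chromosome end; each event lands in exactly one
    window by its ``mid_bp``.  Returns a DataFrame with columns
    (chromosome, start_bp, end_bp, count) covering every window of the genome.
    """
    genome = validate_genome(genome)
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    frames = []
    for c in genome:
        n_win = int(np.ceil(c.length / window_size))
        starts = np.arange(n_win, dtype=np.int64) * window_size + 1
        ends = np.minimum(starts + window_size - 1, c.length)
        frames.append(
            pd.DataFrame(
                {"chromosome": c.name, "start_bp": starts, "end_bp": ends, "count": 0}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    index = {c.name: i for i, c in enumerate(genome)}
    offsets = np.cumsum([0] + [int(np.ceil(c.length / window_size)) for c in genome])
    lengths = {c.name: c.length for c in genome}
    counts = df["count"].to_numpy().copy()
    for e in events:
        if e.chromosome not in index:
            raise ValueError(f"event on unknown chromosome {e.chromosome!r}")
        mid = e.mid_bp
        if not 1 <= mid <= lengths[e.chromosome]:
            raise ValueError(
                f"event midpoint {mid} beyond chromosome {e.chromosome} "
                f"length {lengths[e.chromosome]}"
            )
        counts[offsets[index[e.chromosome]] + (mid - 1) // window_size] += 1
    df["count"] = counts
    return df


def hotspot_threshold(lam: float, alpha: float = DEFAULT_ALPHA) -> int:
    """Smallest k >= 1 with exact Poisson upper tail P(X >= k) < alpha."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    k = 1
    while stats.poisson.sf(k - 1, lam) >= alpha:
        k += 1
    return k


def fit_window_model(
    counts: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
) -> WindowModel:
    """Estimate lambda as the genome-wide mean over ALL windows (zeros
    included) and derive the hotspot count threshold."""
    lam = float(counts["count"].sum()) / len(counts)
    return WindowModel(
        window_size=window_size, lam=lam, alpha=alpha, threshold_k=hotspot_threshold(lam, alpha)
    )


def detect_hotspots(
    counts: pd.DataFrame,
    model: WindowModel,
    merge: bool = False,
) -> list[Hotspot]:
    """Windows with count >= threshold, labelled hotspot1.. in genome order.

    Adjacent significant windows stay separate hotspots by default; with
    ``merge=True`` runs of adjacent significant windows on one chromosome are
    merged into single intervals (count summed, fold from the mean count).
    """
    hits = counts[counts["count"] >= model.threshold_k]
    out: list[Hotspot] = []
    lam = model.lam if model.lam > 0 else np.nan
    if not merge:
        for _, row in hits.iterrows():
            out.append(
                Hotspot(
                    chromosome=row["chromosome"],
                    start_bp=int(row["start_bp"]),
                    end_bp=int(row["end_bp"]),
                    count=int(row["count"]),
                    fold=float(row["count"]) / lam,
                    label=f"hotspot{len(out) + 1}",
                )
            )
        return out
    prev_key: tuple[str, int] | None = None
    acc: list[pd.Series] = []

    def flush() -> None:
        if not acc:
            return
        total = int(sum(r["count"] for r in acc))
        out.append(
            Hotspot(
                chromosome=acc[0]["chromosome"],
                start_bp=int(acc[0]["start_bp"]),
                end_bp=int(acc[-1]["end_bp"]),
                count=total,
                fold=(total / len(acc)) / lam,
                label=f"hotspot{len(out) + 1}",
            )
        )

    for _, row in hits.iterrows():
        key = (row["chromosome"], int(row["start_bp"]))
        if prev_key is not None and (
            key[0] != prev_key[0] or key[1] != prev_key[1] + model.window_size
        ):
            flush()
            acc = []
        acc.append(row)
        prev_key = key
    flush()
    return out


def hotspot_genome_share(
    hotspots: Sequence[Hotspot], genome: Sequence[ChromosomeDef]
) -> float:
    """Fraction of the genome covered by hotspot windows, in [0, 1]."""
    covered = sum(h.end_bp - h.start_bp + 1 for h in hotspots)
    return covered / genome_length(genome)


def hco_per_isolate(
    events: Iterable[CrossoverEvent],
    hotspots: Sequence[Hotspot],
    isolates: Sequence[str],
) -> tuple[pd.Series, float]:
    """Per-isolate count of crossovers inside hotspot windows (HCO) and the
    population share sum(HCO)/sum(TCO); share is 0 when there are no events."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for h in hotspots:
        spans.setdefault(h.chromosome, []).append((h.start_bp, h.end_bp))
    hco = pd.Series(0, index=pd.Index(list(isolates), name="isolate"), dtype=int)
    total = 0
    inside = 0
    for e in events:
        total += 1
        mid = e.mid_bp
        if any(s <= mid <= t for s, t in spans.get(e.chromosome, ())):
            hco[e.isolate] += 1
            inside += 1
    share = inside / total if total else 0.0
    return hco, share


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    mean_hotspot: float
    mean_background: float


def snp_density_test(
    marker_positions: pd.DataFrame,
    hotspots: Sequence[Hotspot],
    genome: Sequence[ChromosomeDef],
    window_size: int = DEFAULT_WINDOW,
) -> AnovaResult:
    """One-way ANOVA of per-window marker counts: hotspot vs background windows.

    ``marker_positions`` needs columns (chromosome, pos_bp).  Each group must
    contribute at least two windows.
    """
    grid = window_counts([], genome, window_size)
    index = {c.name: i for i, c in enumerate(genome)}
    offsets = np.cumsum([0] + [int(np.ceil(c.length / window_size)) for c in genome])
    counts = np.zeros(len(grid), dtype=int)
    for _, row in marker_positions.iterrows():
        counts[offsets[index[row["chromosome"]]] + (int(row["pos_bp"]) - 1) // window_size] += 1
    hot = np.zeros(len(grid), dtype=bool)
    keys = {(h.chromosome, h.start_bp) for h in hotspots}
    for i, row in grid.iterrows():
        if (row["chromosome"], int(row["start_bp"])) in keys:
            hot[i] = True
    a, b = counts[hot], counts[~hot]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two windows for the ANOVA")
    F, p = stats.f_oneway(a, b)
    return AnovaResult(
        F=float(F),
        df_between=1,
        df_within=len(a) + len(b) - 2,
        p=float(p),
        mean_hotspot=float(a.mean()),
        mean_background=float(b.mean()),
    )


def write_hotspots_bed(hotspots: Sequence[Hotspot], path) -> None:
    """BED6 of hotspot windows: name=label, score=count."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for h in sorted(hotspots, key=lambda h: (h.chromosome, h.start_bp)):
            fh.write(f"{h.chromosome}\t{h.start_bp - 1}\t{h.end_bp}\t{h.label}\t{h.count}\t.\n")


def read_hotspots_bed(path) -> list[Hotspot]:
    """Read hotspot BED6 written by :func:`write_hotspots_bed` (fold unset)."""
    out: list[Hotspot] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, score = line.split("\t")[:5]
            out.append(
                Hotspot(
                    chromosome=chrom,
                    start_bp=int(start) + 1,
                    end_bp=int(end),
                    count=int(score),
                    fold=float("nan"),
                    label=name,
                )
            )
    return out
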