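"""Synthetic haploid-progeny simulator with known crossover truth.

Each isolate is an independent gamete from a cross of two haploid parents.
Per chromosome, the crossover count follows Poisson(lambda) when the
interference shape ``nu`` is 1, or a stationary gamma-renewal process with
shape ``nu`` (variance/mean < 1 for nu > 1) scaled so the expected count
stays lambda.  Crossover positions are drawn through a piecewise-constant
intensity: uniform by default, concentrated into declared hotspot windows
otherwise.  Optional crossover-modifier (controller) loci multiply the
target chromosome's lambda by (1+beta) in isolates carrying the parent-2
allele at the locus; the controller's own marker reports that allele with
full linkage to its neighbours.  Genotyping noise (symmetric call flips and
missing calls) is applied last and never touches the returned truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    ChromosomeDef,
    GenotypeMatrix,
    Marker,
    validate_genome,
)


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class HotspotSpec:
    """A window of elevated crossover intensity (relative weight >= 1x)."""

    chromosome: str
    start_bp: int  # 1-based inclusive
    end_bp: int  # inclusive
    weight: float


@dataclass(frozen=True)
class ControllerSpec:
    """A crossover-modifier locus: carriers of the parent-2 allele at
    (chromosome, pos_bp) have the target chromosome's lambda multiplied by
    (1+beta).  ``target`` is a chromosome name or "global"."""

    chromosome: str
    pos_bp: int
    target: str
    beta: float


@dataclass(frozen=True)
class TrueCrossover:
    """Ground-truth breakpoint of one simulated meiosis."""

    isolate: str
    chromosome: str
    pos_bp: int


@dataclass
class SimConfig:
    genome: list[ChromosomeDef]
    n_isolates: int = 110
    markers_per_chrom: int | dict[str, np.ndarray] = 500
    lambda_per_chrom: dict[str, float] = field(default_factory=dict)
    interference_nu: float = 1.0
    hotspot_spec: list[HotspotSpec] = field(default_factory=list)
    error_rate: float = 0.0
    missing_rate: float = 0.0
    qtl_spec: list[ControllerSpec] = field(default_factory=list)
    mat_locus: tuple[str, int] | None = None
    seed: int = 0

    def validate(self) -> None:
        validate_genome(self.genome)
        lengths = {c.name: c.length for c in self.genome}
        if self.n_isolates < 1:
            raise SimConfigError("n_isolates must be >= 1")
        for rate, name in ((self.error_rate, "error_rate"), (self.missing_rate, "missing_rate")):
            if not 0 <= rate <= 1:
                raise SimConfigError(f"{name} must lie in [0,1], got {rate}")
        if self.interference_nu < 1:
            raise SimConfigError("interference_nu must be >= 1")
        for c in self.genome:
            lam = self.lambda_per_chrom.get(c.name, 0.0)
            if lam < 0:
                raise SimConfigError(f"lambda for {c.name} must be non-negative")
        for h in self.hotspot_spec:
            if h.chromosome not in lengths:
                raise SimConfigError(f"hotspot on unknown chromosome {h.chromosome!r}")
            if not 1 <= h.start_bp <= h.end_bp <= lengths[h.chromosome]:
                raise SimConfigError(f"hotspot window {h} outside chromosome")
            if h.weight <= 0:
                raise SimConfigError("hotspot weight must be positive")
        seen_chrom: set[str] = set()
        for q in self.qtl_spec:
            if q.chromosome not in lengths:
                raise SimConfigError(f"controller on unknown chromosome {q.chromosome!r}")
            if not 1 <= q.pos_bp <= lengths[q.chromosome]:
                raise SimConfigError(
                    f"controller locus {q.chromosome}:{q.pos_bp} outside chromosome"
                )
            if q.target != "global" and q.target not in lengths:
                raise SimConfigError(f"controller target {q.target!r} not in genome")
            if q.beta <= -1:
                raise SimConfigError("controller beta must be > -1")
            if q.chromosome in seen_chrom:
                raise SimConfigError(
                    "at most one controller locus per chromosome is supported"
                )
            seen_chrom.add(q.chromosome)
        if self.mat_locus is not None:
            mc, mp = self.mat_locus
            if mc not in lengths or not 1 <= mp <= lengths[mc]:
                raise SimConfigError(f"mat_locus {self.mat_locus} outside genome")


@dataclass
class SimResult:
    matrix: GenotypeMatrix
    truth: list[TrueCrossover]
    mat_alleles: pd.Series | None  # "A1"/"A2" per isolate, if mat_locus set
    controller_alleles: pd.DataFrame  # 0/1 per isolate x controller locus


# ---------------------------------------------------------------------------


def _intensity_segments(
    length: int, windows: Sequence[HotspotSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant intensity over [0, length): (boundaries, weights).

    boundaries has n+1 entries; segment i spans [boundaries[i], boundaries[i+1])
    with relative weight weights[i] (background weight 1).
    """
    cuts = {0, length}
    for w in windows:
        cuts.add(w.start_bp - 1)
        cuts.add(w.end_bp)
    bounds = np.array(sorted(cuts), dtype=np.int64)
    weights = np.ones(len(bounds) - 1)
    for w in windows:
        lo = np.searchsorted(bounds, w.start_bp - 1)
        hi = np.searchsorted(bounds, w.end_bp)
        weights[lo:hi] = w.weight
    return bounds, weights


def place_crossovers(
    lam: float,
    nu: float,
    chrom_length: int,
    hotspot_windows: Sequence[HotspotSpec] = (),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw sorted crossover positions (bp) for one meiosis on one chromosome.

    The count is Poisson(lam) for nu=1, otherwise from a stationary
    gamma-renewal process with shape nu and unit mean interarrival on the
    genetic axis [0, lam].  Positions are mapped through the cumulative
    hotspot-intensity function (uniform when no windows are declared).
    """
    rng = rng or np.random.default_rng()
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return np.empty(0, dtype=np.int64)
    if nu == 1:
        n = rng.poisson(lam)
        fractions = np.sort(rng.random(n))
    else:
        # stationary renewal: first arrival = U * (length-biased interval),
        # the length-biased Gamma(nu, 1/nu) is Gamma(nu+1, 1/nu)
        times: list[float] = []
        t = rng.random() * rng.gamma(nu + 1.0, 1.0 / nu)
        while t <= lam:
            times.append(t)
            t += rng.gamma(nu, 1.0 / nu)
        fractions = np.asarray(times) / lam
    if fractions.size == 0:
        return np.empty(0, dtype=np.int64)
    bounds, weights = _intensity_segments(chrom_length, hotspot_windows)
    seg_mass = np.diff(bounds) * weights
    cum = np.concatenate(([0.0], np.cumsum(seg_mass)))
    mass = fractions * cum[-1]
    seg = np.clip(np.searchsorted(cum, mass, side="right") - 1, 0, len(weights) - 1)
    pos = bounds[seg] + (mass - cum[seg]) / weights[seg]
    pos = np.unique(np.clip(np.round(pos).astype(np.int64), 1, chrom_length - 1))
    return pos


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate the progeny population and its ground-truth crossovers.

    Per isolate and chromosome the starting parental phase is uniform and
    alternates at each true crossover; marker calls read the phase off at
    marker positions.  Controller alleles are assigned before crossover
    placement and the controller's own marker reports the drawn allele.
    Noise is applied to the call grid only; the truth list is clean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    lengths = {c.name: c.length for c in genome}

    # marker grid
    positions: dict[str, np.ndarray] = {}
    for c in genome:
        if isinstance(config.markers_per_chrom, dict):
            pos = np.asarray(config.markers_per_chrom[c.name], dtype=np.int64)
        else:
            pos = np.unique(
                np.round(np.linspace(1, c.length, int(config.markers_per_chrom))).astype(np.int64)
            )
        positions[c.name] = pos
    lam_base = {c.name: float(config.lambda_per_chrom.get(c.name, 0.0)) for c in genome}
    windows_by_chrom: dict[str, list[HotspotSpec]] = {c.name: [] for c in genome}
    for h in config.hotspot_spec:
        windows_by_chrom[h.chromosome].append(h)
    controllers_by_chrom = {q.chromosome: q for q in config.qtl_spec}

    isolates = [f"iso{i + 1:03d}" for i in range(config.n_isolates)]
    n_markers = sum(len(positions[c.name]) for c in genome)
    calls = np.empty((n_markers, config.n_isolates), dtype=np.int8)
    truth: list[TrueCrossover] = []
    mat_alleles = {} if config.mat_locus is not None else None
    ctrl_records = np.zeros((config.n_isolates, len(config.qtl_spec)), dtype=int)

    row_offsets: dict[str, int] = {}
    off = 0
    for c in genome:
        row_offsets[c.name] = off
        off += len(positions[c.name])

    for j, iso in enumerate(isolates):
        alleles = {id(q): int(rng.integers(0, 2)) for q in config.qtl_spec}
        for qi, q in enumerate(config.qtl_spec):
            ctrl_records[j, qi] = alleles[id(q)]
        mult = {c.name: 1.0 for c in genome}
        for q in config.qtl_spec:
            factor = (1.0 + q.beta) ** alleles[id(q)]
            if q.target == "global":
                for name in mult:
                    mult[name] *= factor
            else:
                mult[q.target] *= factor

        for c in genome:
            lam_eff = lam_base[c.name] * mult[c.name]
            xs = place_crossovers(
                lam_eff, config.interference_nu, c.length, windows_by_chrom[c.name], rng
            )
            start = int(rng.integers(0, 2))

            def phase_at(p: int) -> int:
                return start ^ (int(np.searchsorted(xs, p, side="left")) % 2)

            q = controllers_by_chrom.get(c.name)
            if q is not None and phase_at(q.pos_bp) != alleles[id(q)]:
                start ^= 1  # flip the whole chromosome's phase labels
            pos = positions[c.name]
            phases = (start ^ (np.searchsorted(xs, pos, side="left") % 2)).astype(np.int8)
            calls[row_offsets[c.name] : row_offsets[c.name] + len(pos), j] = phases
            truth.extend(TrueCrossover(iso, c.name, int(x)) for x in xs)
            if mat_alleles is not None and config.mat_locus[0] == c.name:
                mat_alleles[iso] = "A1" if phase_at(config.mat_locus[1]) == 0 else "A2"

    # genotyping noise: symmetric flips, then dropouts
    if config.error_rate > 0:
        flip = rng.random(calls.shape) < config.error_rate
        calls[flip] = 1 - calls[flip]
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls[drop] = MISSING

    markers: list[Marker] = []
    for c in genome:
        lam = lam_base[c.name]
        for k, p in enumerate(positions[c.name]):
            markers.append(
                Marker(
                    id=f"{c.name}_m{k + 1:05d}",
                    chromosome=c.name,
                    pos_bp=int(p),
                    pos_cM=100.0 * lam * float(p) / lengths[c.name],
                )
            )
    matrix = GenotypeMatrix(markers, isolates, calls, genome=genome)
    return SimResult(
        matrix=matrix,
        truth=truth,
        mat_alleles=pd.Series(mat_alleles, name="mat_allele") if mat_alleles is not None else None,
        controller_alleles=pd.DataFrame(
            ctrl_records,
            index=pd.Index(isolates, name="isolate"),
            columns=[f"{q.chromosome}:{q.pos_bp}->{q.target}" for q in config.qtl_spec],
        ),
    )


def write_truth_bed(truth: Sequence[TrueCrossover], path) -> None:
    """Ground-truth breakpoints as sorted single-bp BED intervals."""
    recs = sorted(truth, key=lambda t: (t.chromosome, t.pos_bp, t.isolate))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for t in recs:
            fh.write(f"{t.chromosome}\t{t.pos_bp - 1}\t{t.pos_bp}\t{t.isolate}\n")


# ---------------------------------------------------------------------------
# demo conditions: the study-scale defaults


def demo_genome() -> list[ChromosomeDef]:
    """Nine pseudo-chromosomes totalling 37.23 Mb."""
    mb = [6.00, 5.40, 5.00, 4.60, 4.20, 3.80, 3.30, 2.70, 2.23]
    return [ChromosomeDef(f"chr{i + 1}", int(m * 1_000_000)) for i, m in enumerate(mb)]


#: expected crossovers per chromosome per meiosis, decreasing with length,
#: spanning the observed 0.25-1.80 range and summing to ~8 per isolate
DEMO_LAMBDA = [1.80, 1.45, 1.25, 1.05, 0.85, 0.65, 0.45, 0.30, 0.25]

#: planted 10 kb hotspot windows per chromosome (none on the
#: recombination-suppressed chr7)
_DEMO_HOTSPOT_COUNTS = {
    "chr1": 15,
    "chr2": 11,
    "chr3": 10,
    "chr4": 8,
    "chr5": 7,
    "chr6": 5,
    "chr8": 4,
    "chr9": 4,
}


def demo_config(
    seed: int = 0,
    n_isolates: int = 110,
    markers_per_chrom: int = 500,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> SimConfig:
    """The default demonstration conditions at study scale: 9 chromosomes /
    37.23 Mb, 110 isolates, hotspot-concentrated crossovers, one cis and one
    trans crossover-modifier locus, and a mating-type locus on chr2."""
    genome = demo_genome()
    lam = {c.name: v for c, v in zip(genome, DEMO_LAMBDA)}
    hotspots: list[HotspotSpec] = []
    for c in genome:
        n = _DEMO_HOTSPOT_COUNTS.get(c.name, 0)
        for i in range(n):
            start = int(round(c.length * (i + 1) / (n + 1) / 10_000)) * 10_000
            start = min(max(start, 0), c.length - 10_000)
            hotspots.append(HotspotSpec(c.name, start + 1, start + 10_000, 60.0))
    return SimConfig(
        genome=genome,
        n_isolates=n_isolates,
        markers_per_chrom=markers_per_chrom,
        lambda_per_chrom=lam,
        interference_nu=1.0,
        hotspot_spec=hotspots,
        error_rate=error_rate,
        missing_rate=missing_rate,
        qtl_spec=[
            ControllerSpec("chr1", 3_000_000, "chr1", 0.8),  # cis modifier
            ControllerSpec("chr2", 2_700_000, "chr3", 0.8),  # trans modifier
        ],
        mat_locus=("chr2", 4_000_000),
        seed=seed,
    )
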