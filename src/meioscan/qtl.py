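"""Interval-mapping QTL scan for crossover-count traits on a haploid
population.

At each position of a 1 cM grid the trait is regressed on the expected
parental genotype (the conditional probability of the parent-2 allele given
the nearest informative flanking markers, Haldane map function), and
LOD = (n/2) * log10(RSS0/RSS1).  Genome-wide significance comes from
permuting the phenotype vector across isolates (genotypes untouched, so
marker LD is preserved) and taking the (1-alpha) quantile of the maximum
LOD.  Peaks get LOD-1 support intervals, additive effects (half the
parent-2 minus parent-1 mean difference), the percent of phenotypic
variance explained, a cis-prone/trans label for per-chromosome traits, and
an optional hotspot association.

A light composite-interval-mapping variant (``cim=True``) forward-selects up
to five background marker covariates and drops those within a 10 cM window
of the test position.  Plain interval mapping is the default.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, P1, P2, GenotypeMatrix
from .hotspots import Hotspot

_LOD_EPS = 1e-12


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: genetic distance (cM) -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def genotype_prob(
    position_cM: float,
    left: tuple[float, int] | None,
    right: tuple[float, int] | None,
) -> float:
    """P(parent-1 allele at ``position_cM``) given the nearest informative
    flanking markers ``(cM, call)`` on the same chromosome.

    With both flanks the two transition probabilities are combined and
    normalised; with a single flank only that transition applies; with no
    informative marker the probability is 0.5.  At an observed marker the
    probability collapses to 0/1.
    """

    def trans(a: int, b: int, r: float) -> float:
        return 1.0 - r if a == b else r

    if left is None and right is None:
        return 0.5
    if left is not None and left[0] > position_cM + 1e-12:
        raise ValueError("left flank lies right of the test position")
    if right is not None and right[0] < position_cM - 1e-12:
        raise ValueError("right flank lies left of the test position")
    if left is None:
        r2 = float(haldane_r(right[0] - position_cM))
        return trans(P1, right[1], r2)
    if right is None:
        r1 = float(haldane_r(position_cM - left[0]))
        return trans(left[1], P1, r1)
    r1 = float(haldane_r(position_cM - left[0]))
    r2 = float(haldane_r(right[0] - position_cM))
    w1 = trans(left[1], P1, r1) * trans(P1, right[1], r2)
    w2 = trans(left[1], P2, r1) * trans(P2, right[1], r2)
    return w1 / (w1 + w2)


# ---------------------------------------------------------------------------
# dosage grid


def _dosage_chrom(
    cm: np.ndarray, calls: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Expected parent-2 dosage at ``grid`` (cM) for every isolate.

    ``calls``: (k markers x n isolates); fully vectorised when the
    chromosome has no missing calls, per-isolate otherwise.
    """
    n = calls.shape[1]
    D = np.empty((grid.size, n))
    if not (calls == MISSING).any():
        D[:] = _dosage_clean(cm, calls, grid)
        return D
    for j in range(n):
        info = calls[:, j] != MISSING
        if not info.any():
            D[:, j] = 0.5
            continue
        D[:, j] = _dosage_clean(cm[info], calls[info, j : j + 1], grid)[:, 0]
    return D


def _dosage_clean(cm: np.ndarray, calls: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Dosage grid for fully informative markers (shared flank indices)."""
    li = np.searchsorted(cm, grid, side="right") - 1  # last marker cM <= t
    ri = np.searchsorted(cm, grid, side="left")  # first marker cM >= t
    out = np.empty((grid.size, calls.shape[1]))
    exact = (ri < cm.size) & (li >= 0) & (li == ri)
    only_right = li < 0
    only_left = ri >= cm.size
    both = ~(exact | only_right | only_left)

    if exact.any():
        out[exact] = calls[li[exact]].astype(float)
    if only_right.any():
        r2 = haldane_r(cm[ri[only_right]] - grid[only_right])[:, None]
        g = calls[ri[only_right]].astype(float)
        out[only_right] = np.where(g == P2, 1.0 - r2, r2)
    if only_left.any():
        r1 = haldane_r(grid[only_left] - cm[li[only_left]])[:, None]
        g = calls[li[only_left]].astype(float)
        out[only_left] = np.where(g == P2, 1.0 - r1, r1)
    if both.any():
        r1 = haldane_r(grid[both] - cm[li[both]])[:, None]
        r2 = haldane_r(cm[ri[both]] - grid[both])[:, None]
        gl = calls[li[both]].astype(float)
        gr = calls[ri[both]].astype(float)
        w2 = np.where(gl == P2, 1.0 - r1, r1) * np.where(gr == P2, 1.0 - r2, r2)
        w1 = np.where(gl == P1, 1.0 - r1, r1) * np.where(gr == P1, 1.0 - r2, r2)
        out[both] = w2 / (w1 + w2)
    return out


@dataclass
class QTLScanResult:
    """A genome scan of one trait: grid positions, LOD profile and the data
    needed to extract peaks."""

    trait: str
    chrom: np.ndarray  # chromosome name per grid position
    pos_cM: np.ndarray
    lod: np.ndarray
    n: int
    y: np.ndarray  # phenotype aligned to used isolates
    dosage: np.ndarray  # (grid x used isolates) expected P2 dosage
    matrix: GenotypeMatrix
    step_cM: float
    threshold: float | None = None

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"chromosome": self.chrom, "pos_cM": self.pos_cM, "lod": self.lod})


def _scan_grid(matrix: GenotypeMatrix, step_cM: float) -> tuple[np.ndarray, np.ndarray, list]:
    cm_all = matrix.pos_cM()
    if cm_all is None:
        raise ValueError("genotype matrix carries no cM positions; a genetic map is required")
    chroms: list[str] = []
    grids: list[np.ndarray] = []
    blocks = []
    for chrom, sl in matrix.chrom_slices().items():
        cm = cm_all[sl]
        grid = np.arange(cm[0], cm[-1] + 1e-9, step_cM)
        if grid.size == 0 or grid[-1] < cm[-1] - 1e-9:
            grid = np.append(grid, cm[-1])
        chroms.extend([chrom] * grid.size)
        grids.append(grid)
        blocks.append((chrom, sl, cm, grid))
    return np.array(chroms, dtype=object), np.concatenate(grids), blocks


def _align_phenotype(matrix: GenotypeMatrix, phenotype) -> tuple[np.ndarray, np.ndarray]:
    """(used-isolate boolean mask, phenotype values) dropping undefined ones."""
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(matrix.isolates).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.size != len(matrix.isolates):
            raise ValueError("phenotype length does not match isolate count")
    used = ~np.isnan(y)
    return used, y[used]


def _lod_simple(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD per grid row for the single-predictor regression."""
    n = y.size
    yc = y - y.mean()
    sy = float(np.sqrt((yc**2).sum()))
    Xc = D - D.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.nan_to_num(r)
    r2 = np.clip(r**2, 0.0, 1.0 - _LOD_EPS)
    return -(n / 2.0) * np.log10(1.0 - r2)


def _forward_select_covariates(
    matrix: GenotypeMatrix, used: np.ndarray, y: np.ndarray, n_cov: int
) -> list[int]:
    """Greedy forward selection of marker covariates by RSS reduction."""
    M = matrix.calls[:, used].astype(float).T  # n x k
    M[M == MISSING] = 0.5
    n = y.size
    Q = np.ones((n, 1)) / np.sqrt(n)
    resid_y = y - Q @ (Q.T @ y)
    chosen: list[int] = []
    for _ in range(min(n_cov, M.shape[1])):
        Mr = M - Q @ (Q.T @ M)
        ss = (Mr**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = (Mr.T @ resid_y) ** 2 / ss
        gain = np.nan_to_num(gain)
        gain[chosen] = -np.inf
        best = int(np.argmax(gain))
        if gain[best] <= 0:
            break
        chosen.append(best)
        v = Mr[:, best]
        norm = np.linalg.norm(v)
        if norm == 0:
            break
        Q = np.hstack([Q, (v / norm)[:, None]])
        resid_y = y - Q @ (Q.T @ y)
    return chosen


def scan_trait(
    matrix: GenotypeMatrix,
    phenotype,
    trait: str = "trait",
    step_cM: float = 1.0,
    cim: bool = False,
    n_covariates: int = 5,
    window_cM: float = 10.0,
) -> QTLScanResult:
    """Scan one trait across the genome grid; see the module docstring."""
    chrom_arr, grid_all, blocks = _scan_grid(matrix, step_cM)
    used, y = _align_phenotype(matrix, phenotype)
    D = np.vstack(
        [
            _dosage_chrom(cm, matrix.calls[sl][:, used], grid)
            for _, sl, cm, grid in blocks
        ]
    )
    n = y.size
    if np.ptp(y) == 0:
        warnings.warn(f"trait {trait!r} is constant; LOD profile is all zero")
        lod = np.zeros(grid_all.size)
        return QTLScanResult(trait, chrom_arr, grid_all, lod, n, y, D, matrix, step_cM)

    if not cim:
        lod = _lod_simple(D, y)
        return QTLScanResult(trait, chrom_arr, grid_all, lod, n, y, D, matrix, step_cM)

    cov_idx = _forward_select_covariates(matrix, used, y, n_covariates)
    cm_all = matrix.pos_cM()
    cov_chrom = [matrix.markers[i].chromosome for i in cov_idx]
    cov_cm = [cm_all[i] for i in cov_idx]
    C = matrix.calls[cov_idx][:, used].astype(float).T  # n x c
    C[C == MISSING] = 0.5
    ones = np.ones((n, 1))
    lod = np.empty(grid_all.size)
    for i in range(grid_all.size):
        active = [
            k
            for k in range(len(cov_idx))
            if not (cov_chrom[k] == chrom_arr[i] and abs(cov_cm[k] - grid_all[i]) <= window_cM)
        ]
        X0 = np.hstack([ones, C[:, active]]) if active else ones
        rss0 = _rss(X0, y)
        rss1 = _rss(np.hstack([X0, D[i][:, None]]), y)
        ratio = max(rss1, _LOD_EPS * rss0) / rss0 if rss0 > 0 else 1.0
        lod[i] = max(0.0, -(n / 2.0) * np.log10(ratio))
    return QTLScanResult(trait, chrom_arr, grid_all, lod, n, y, D, matrix, step_cM)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def permutation_threshold(
    matrix: GenotypeMatrix,
    phenotype,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    step_cM: float = 1.0,
    cim: bool = False,
    n_covariates: int = 5,
    window_cM: float = 10.0,
) -> float:
    """Genome-wide LOD cutoff: the (1-alpha) quantile of the maximum LOD over
    ``n_perm`` phenotype permutations.  Seeded and reproducible."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    used, y = _align_phenotype(matrix, phenotype)
    n = y.size
    if not cim:
        _, grid_all, blocks = _scan_grid(matrix, step_cM)
        D = np.vstack(
            [_dosage_chrom(cm, matrix.calls[sl][:, used], grid) for _, sl, cm, grid in blocks]
        )
        Xc = D - D.mean(axis=1, keepdims=True)
        sx = np.sqrt((Xc**2).sum(axis=1))
        sx[sx == 0] = np.inf
        Xn = Xc / sx[:, None]
        Y = np.empty((n, n_perm))
        for p in range(n_perm):
            Y[:, p] = rng.permutation(y)
        Yc = Y - Y.mean(axis=0, keepdims=True)
        sy = np.sqrt((Yc**2).sum(axis=0))
        sy[sy == 0] = np.inf
        C = Xn @ (Yc / sy)
        r2max = np.clip((C**2).max(axis=0), 0.0, 1.0 - _LOD_EPS)
        max_lod = -(n / 2.0) * np.log10(1.0 - r2max)
    else:
        max_lod = np.empty(n_perm)
        for p in range(n_perm):
            res = scan_trait(
                matrix,
                pd.Series(rng.permutation(y), index=np.array(matrix.isolates)[used]),
                step_cM=step_cM,
                cim=True,
                n_covariates=n_covariates,
                window_cM=window_cM,
            )
            max_lod[p] = res.lod.max()
    return float(np.quantile(max_lod, 1.0 - alpha))


# ---------------------------------------------------------------------------
# peaks


@dataclass(frozen=True)
class QTLPeak:
    locus_id: str
    trait: str
    chromosome: str
    peak_cM: float
    lod: float
    additive: float
    r2: float  # percent of phenotypic variance
    ci_lo_cM: float
    ci_hi_cM: float
    peak_bp: int
    ci_lo_bp: int
    ci_hi_bp: int
    ci_len_kb: float
    cis_trans: str
    hotspot_assoc: str = "/"
    n_genes: int | None = None


def classify_cis_trans(trait: str, chromosome: str) -> str:
    """cis-prone when a per-chromosome crossover trait maps to its own
    chromosome, trans when it maps elsewhere, n/a for TCO/HCO-type traits."""
    m = re.fullmatch(r"(?i)cochr(.+)", trait.strip())
    if not m:
        return "n/a"
    target = m.group(1).lower()
    chrom = str(chromosome).strip().lower()
    chrom = chrom.removeprefix("chr")
    return "cis-prone" if chrom == target else "trans"


def trait_locus_prefix(trait: str) -> str:
    t = trait.strip().lower()
    return t if re.fullmatch(r"[a-z0-9.]+", t) else re.sub(r"[^a-z0-9]+", "", t)


def extract_peaks(result: QTLScanResult, threshold: float) -> list[QTLPeak]:
    """LOD peaks above ``threshold``, separated by LOD-1 valleys, each with a
    LOD-1 support interval in cM and bp."""
    peaks: list[tuple[str, int]] = []  # (chromosome, grid index)
    for chrom in dict.fromkeys(result.chrom):
        idx = np.flatnonzero(result.chrom == chrom)
        lod = result.lod[idx]
        order = np.argsort(lod)[::-1]
        accepted: list[int] = []
        for o in order:
            if lod[o] < threshold:
                break
            ok = True
            for a in accepted:
                lo, hi = min(a, o), max(a, o)
                if lod[lo : hi + 1].min() > lod[o] - 1.0:
                    ok = False
                    break
            if ok:
                accepted.append(int(o))
        peaks.extend((chrom, int(idx[a])) for a in accepted)

    cm_all = result.matrix.pos_cM()
    bp_all = result.matrix.pos_bp()
    slices = result.matrix.chrom_slices()
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(result.chrom))}

    records: list[QTLPeak] = []
    for chrom, gi in peaks:
        idx = np.flatnonzero(result.chrom == chrom)
        lod = result.lod[idx]
        local = int(np.flatnonzero(idx == gi)[0])
        peak_lod = lod[local]
        lo = local
        while lo > 0 and lod[lo - 1] >= peak_lod - 1.0:
            lo -= 1
        hi = local
        while hi < lod.size - 1 and lod[hi + 1] >= peak_lod - 1.0:
            hi += 1
        x = result.dosage[gi]
        y = result.y
        vx = x.var()
        slope = float(np.cov(x, y, bias=True)[0, 1] / vx) if vx > 0 else 0.0
        r = np.corrcoef(x, y)[0, 1] if vx > 0 and y.var() > 0 else 0.0
        sl = slices[chrom]
        mc, mb = cm_all[sl], bp_all[sl]
        peak_cm = float(result.pos_cM[gi])
        ci_lo_cm = float(result.pos_cM[idx[lo]])
        ci_hi_cm = float(result.pos_cM[idx[hi]])
        to_bp = lambda c: int(round(float(np.interp(c, mc, mb))))
        ci_lo_bp, ci_hi_bp = to_bp(ci_lo_cm), to_bp(ci_hi_cm)
        records.append(
            QTLPeak(
                locus_id="",  # assigned below, in genome order
                trait=result.trait,
                chromosome=chrom,
                peak_cM=peak_cm,
                lod=float(peak_lod),
                additive=slope / 2.0,
                r2=float(100.0 * r**2),
                ci_lo_cM=ci_lo_cm,
                ci_hi_cM=ci_hi_cm,
                peak_bp=to_bp(peak_cm),
                ci_lo_bp=ci_lo_bp,
                ci_hi_bp=ci_hi_bp,
                ci_len_kb=(ci_hi_bp - ci_lo_bp) / 1000.0,
                cis_trans=classify_cis_trans(result.trait, chrom),
            )
        )
    records.sort(key=lambda p: (chrom_order[p.chromosome], p.peak_cM))
    prefix = trait_locus_prefix(result.trait)
    return [replace(p, locus_id=f"{prefix}.{i + 1}") for i, p in enumerate(records)]


def associate_hotspots(
    peaks: Sequence[QTLPeak],
    hotspots: Sequence[Hotspot],
    max_gap_bp: int = 50_000,
) -> list[QTLPeak]:
    """Annotate each peak with the hotspot overlapping its physical CI, the
    nearest hotspot within ``max_gap_bp`` ("near to ..."), or "/"."""
    out: list[QTLPeak] = []
    for p in peaks:
        label = "/"
        best_overlap = None
        best_gap = None
        for h in hotspots:
            if h.chromosome != p.chromosome:
                continue
            if h.start_bp <= p.ci_hi_bp and h.end_bp >= p.ci_lo_bp:
                if h.start_bp <= p.peak_bp <= h.end_bp:
                    dist_to_peak = 0
                else:
                    dist_to_peak = min(abs(h.start_bp - p.peak_bp), abs(h.end_bp - p.peak_bp))
                if best_overlap is None or dist_to_peak < best_overlap[0]:
                    best_overlap = (dist_to_peak, h.label)
            else:
                gap = max(h.start_bp - p.ci_hi_bp, p.ci_lo_bp - h.end_bp)
                if gap <= max_gap_bp and (best_gap is None or gap < best_gap[0]):
                    best_gap = (gap, h.label)
        if best_overlap is not None:
            label = best_overlap[1]
        elif best_gap is not None:
            label = f"near to {best_gap[1]}"
        out.append(replace(p, hotspot_assoc=label))
    return out


def count_genes_in_interval(
    gff_path, chromosome: str, start_bp: int, end_bp: int, feature: str = "gene"
) -> int:
    """Count GFF3 features of the given type overlapping [start_bp, end_bp]."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attr"]
    df = pd.read_csv(gff_path, sep="\t", comment="#", header=None, names=cols)
    hit = (
        (df["seqid"] == chromosome)
        & (df["type"] == feature)
        & (df["start"] <= end_bp)
        & (df["end"] >= start_bp)
    )
    return int(hit.sum())


def peaks_table(peaks: Sequence[QTLPeak]) -> pd.DataFrame:
    """Peak list in the conventional reporting layout."""
    return pd.DataFrame(
        [
            {
                "Locus": p.locus_id,
                "Trait": p.trait,
                "Chr": p.chromosome,
                "Type": p.cis_trans if p.cis_trans != "n/a" else "/",
                "Position (cM)": round(p.peak_cM, 1),
                "LOD": round(p.lod, 2),
                "Additive": round(p.additive, 2),
                "R2 (%)": round(p.r2, 1),
                "CI (cM)": f"{p.ci_lo_cM:.1f}-{p.ci_hi_cM:.1f}",
                "No. of Genes": p.n_genes if p.n_genes is not None else "",
                "Association with Hotspots": p.hotspot_assoc,
                "Length of CI (kb)": round(p.ci_len_kb, 1),
            }
            for p in peaks
        ]
    )
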