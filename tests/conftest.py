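"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from meioscan.genotypes import (
    MISSING,
    P1,
    P2,
    ChromosomeDef,
    GenotypeMatrix,
    Marker,
)

SYMBOL_TO_CODE = {"a": P1, "b": P2, "-": MISSING}


def seq_to_codes(seq: str) -> np.ndarray:
    """'a'/'b'/'-' string (spaces ignored) -> int8 call codes."""
    return np.array([SYMBOL_TO_CODE[c] for c in seq.replace(" ", "")], dtype=np.int8)


def matrix_from_strings(
    call_strings: dict[str, str],
    chromosome: str = "chr1",
    chrom_length: int | None = None,
    positions: list[int] | None = None,
    cm: list[float] | None = None,
) -> GenotypeMatrix:
    """Build a one-chromosome matrix from per-isolate call strings."""
    isolates = list(call_strings)
    cols = [seq_to_codes(s) for s in call_strings.values()]
    n = len(cols[0])
    assert all(len(c) == n for c in cols)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n)]
    markers = [
        Marker(
            id=f"m{i + 1}",
            chromosome=chromosome,
            pos_bp=positions[i],
            pos_cM=cm[i] if cm is not None else None,
        )
        for i in range(n)
    ]
    genome = [ChromosomeDef(chromosome, chrom_length or positions[-1] + 1000)]
    return GenotypeMatrix(markers, isolates, np.column_stack(cols), genome=genome)


# ---------------------------------------------------------------------------
# oracle: naive crossover counter (independent list-based re-implementation
# of the supported-phase-switch definition)


def brute_force_crossover_count(seq: str, min_run: int) -> int:
    """Count supported phase switches by literal repeated deletion.

    Missing markers are dropped; every maximal same-parent run shorter than
    ``min_run`` is deleted (all short runs of a pass at once) until only
    supported runs remain; switches are the parent changes between the
    surviving consecutive markers.  Pure-Python, no shared code with the
    production caller.
    """
    calls = [c for c in seq.replace(" ", "") if c != "-"]
    while calls:
        runs: list[list[str]] = []
        for c in calls:
            if runs and runs[-1][0] == c:
                runs[-1].append(c)
            else:
                runs.append([c])
        if all(len(r) >= min_run for r in runs):
            break
        calls = [c for r in runs if len(r) >= min_run for c in r]
    return sum(1 for x, y in zip(calls, calls[1:]) if x != y)


# ---------------------------------------------------------------------------
# oracle: minimal Poisson hotspot threshold by explicit tail summation


def brute_force_poisson_threshold(lam: float, alpha: float, k_max: int = 400) -> int:
    """Smallest k>=1 with sum_{i>=k} e^-lam lam^i / i! < alpha, summed term
    by term with an explicit factorial recurrence (no scipy)."""
    import math

    pmf = [math.exp(-lam)]
    for i in range(1, k_max + 1):
        pmf.append(pmf[-1] * lam / i)
    for k in range(1, k_max):
        tail = 1.0 - sum(pmf[:k])
        if tail < alpha:
            return k
    raise AssertionError("k_max too small")


# ---------------------------------------------------------------------------
# oracle: exhaustive phase-path enumeration for conditional genotype
# probabilities on a small chromosome


def enumerate_genotype_prob_p1(
    marker_cm: list[float],
    calls: list[int],
    t_cm: float,
) -> float:
    """P(parent-1 phase at ``t_cm``) given observed calls, by summing over
    every phase path of the Markov inheritance chain (Haldane transitions).

    ``calls`` uses P1/P2/MISSING codes; MISSING markers are unobserved.
    """
    import itertools

    loci = sorted(set(marker_cm) | {t_cm})
    t_idx = loci.index(t_cm)
    obs = {loci.index(c): g for c, g in zip(marker_cm, calls) if g != MISSING}

    def r(d: float) -> float:
        return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))

    total = 0.0
    at_p1 = 0.0
    for path in itertools.product((P1, P2), repeat=len(loci)):
        if any(path[i] != g for i, g in obs.items()):
            continue
        w = 0.5
        for i in range(len(loci) - 1):
            rr = r(loci[i + 1] - loci[i])
            w *= 1.0 - rr if path[i] == path[i + 1] else rr
        total += w
        if path[t_idx] == P1:
            at_p1 += w
    return at_p1 / total


# ---------------------------------------------------------------------------
# reference cis/trans classification cases: sixteen trait-chromosome
# combinations spanning all three label classes

QTL_CLASSIFICATION_CASES = [
    ("COchr1", "1", "cis-prone"),
    ("COchr2", "1", "trans"),
    ("COchr2", "1", "trans"),
    ("COchr2", "8", "trans"),
    ("COchr3", "2", "trans"),
    ("COchr3", "2", "trans"),
    ("COchr3", "2", "trans"),
    ("COchr4", "4", "cis-prone"),
    ("COchr4", "4", "cis-prone"),
    ("COchr6", "6", "cis-prone"),
    ("COchr7", "7", "cis-prone"),
    ("COchr8", "1", "trans"),
    ("COchr8", "1", "trans"),
    ("HCO", "1", "n/a"),
    ("HCO", "2", "n/a"),
    ("TCO", "2", "n/a"),
]


@pytest.fixture
def toy_genome() -> list[ChromosomeDef]:
    return [ChromosomeDef("chr1", 100_000), ChromosomeDef("chr2", 60_000)]
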