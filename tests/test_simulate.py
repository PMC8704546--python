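"""Gamete simulator: crossover placement, interference, controllers, noise."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from meioscan.calling import call_crossovers
from meioscan.genotypes import MISSING, ChromosomeDef
from meioscan.simulate import (
    ControllerSpec,
    HotspotSpec,
    SimConfig,
    SimConfigError,
    demo_config,
    demo_genome,
    place_crossovers,
    simulate_population,
    write_truth_bed,
)


class TestPlaceCrossovers:
    def test_zero_rate_always_empty(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert place_crossovers(0.0, 1.0, 1_000_000, rng=rng).size == 0

    def test_poisson_mean(self):
        rng = np.random.default_rng(1)
        counts = [place_crossovers(1.0, 1.0, 1_000_000, rng=rng).size for _ in range(10_000)]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_hotspot_mixture_fraction(self):
        # 50x weight over 1% of the chromosome: expected share of positions
        # = 50*0.01 / (50*0.01 + 0.99) ~ 0.336
        L = 1_000_000
        win = HotspotSpec("chr1", 495_001, 505_000, 50.0)
        rng = np.random.default_rng(2)
        inside = total = 0
        for _ in range(3000):
            pos = place_crossovers(2.0, 1.0, L, [win], rng)
            total += pos.size
            inside += int(((pos >= win.start_bp) & (pos <= win.end_bp)).sum())
        frac = inside / total
        expected = 50 * 0.01 / (50 * 0.01 + 0.99)
        assert abs(frac - expected) < 0.02

    def test_interference_reduces_dispersion(self):
        rng = np.random.default_rng(3)
        counts = [place_crossovers(2.0, 10.0, 1_000_000, rng=rng).size for _ in range(4000)]
        counts = np.asarray(counts)
        assert abs(counts.mean() - 2.0) < 0.1  # mean preserved
        assert counts.var() / counts.mean() < 0.8  # sub-Poisson

    def test_poisson_goodness_of_fit_across_seeds(self):
        """With nu=1 and no hotspots the count distribution is Poisson(lam):
        chi-square GoF not rejected at alpha=0.01 (at most one of 20 seeds)."""
        lam = 1.5
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = np.array(
                [place_crossovers(lam, 1.0, 500_000, rng=rng).size for _ in range(1500)]
            )
            kmax = int(counts.max())
            obs = np.bincount(counts, minlength=kmax + 1).astype(float)
            exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
            exp[-1] = len(counts) - exp[:-1].sum()  # fold the tail into the last cell
            keep = exp >= 5
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            p = stats.chi2.sf(chi2, keep.sum() - 1)
            rejections += p < 0.01
        assert rejections <= 1

    def test_positions_sorted_within_bounds(self):
        rng = np.random.default_rng(4)
        pos = place_crossovers(5.0, 1.0, 10_000, rng=rng)
        assert (np.diff(pos) > 0).all()
        assert pos.min() >= 1 and pos.max() < 10_000


def _tiny_config(**kw) -> SimConfig:
    genome = [ChromosomeDef("chrA", 1_000_000), ChromosomeDef("chrB", 800_000)]
    base = dict(
        genome=genome,
        n_isolates=20,
        markers_per_chrom=60,
        lambda_per_chrom={"chrA": 1.0, "chrB": 0.5},
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePopulation:
    def test_clean_phase_switches_equal_truth(self):
        """Without noise, phase switches in each isolate-chromosome call
        sequence equal the number of truth breakpoints between markers."""
        sim = simulate_population(_tiny_config())
        m = sim.matrix
        pos = m.pos_bp()
        for chrom, sl in m.chrom_slices().items():
            cpos = pos[sl]
            for j, iso in enumerate(m.isolates):
                seq = m.calls[sl, j]
                switches = int((np.diff(seq) != 0).sum())
                xs = sorted(
                    t.pos_bp for t in sim.truth if t.isolate == iso and t.chromosome == chrom
                )
                # breakpoints falling between the first and last marker, not
                # cancelling within one inter-marker gap
                gaps = np.searchsorted(cpos, xs, side="right")
                effective = sum(1 for g, c in zip(*np.unique(gaps, return_counts=True))
                                if 0 < g < len(cpos) and c % 2 == 1)
                assert switches == effective

    def test_same_seed_identical_outputs(self):
        a = simulate_population(_tiny_config(error_rate=0.02, missing_rate=0.05))
        b = simulate_population(_tiny_config(error_rate=0.02, missing_rate=0.05))
        assert (a.matrix.calls == b.matrix.calls).all()
        assert [(t.isolate, t.chromosome, t.pos_bp) for t in a.truth] == [
            (t.isolate, t.chromosome, t.pos_bp) for t in b.truth
        ]

    def test_noise_leaves_truth_untouched(self):
        clean = simulate_population(_tiny_config())
        noisy = simulate_population(_tiny_config(error_rate=0.05, missing_rate=0.1))
        assert [(t.isolate, t.pos_bp) for t in clean.truth] == [
            (t.isolate, t.pos_bp) for t in noisy.truth
        ]
        assert (noisy.matrix.calls == MISSING).sum() > 0

    def test_trans_controller_doubles_target_rate(self):
        """beta=1 controller on chrA targeting chrB: carriers have ~2x the
        chrB crossover rate of non-carriers."""
        carrier_total = noncarrier_total = 0
        carrier_n = noncarrier_n = 0
        for seed in range(40):
            cfg = _tiny_config(
                n_isolates=110,
                qtl_spec=[ControllerSpec("chrA", 500_000, "chrB", 1.0)],
                seed=seed,
            )
            sim = simulate_population(cfg)
            alleles = sim.controller_alleles.iloc[:, 0]
            counts = {}
            for t in sim.truth:
                if t.chromosome == "chrB":
                    counts[t.isolate] = counts.get(t.isolate, 0) + 1
            for iso, a in alleles.items():
                c = counts.get(iso, 0)
                if a == 1:
                    carrier_total += c
                    carrier_n += 1
                else:
                    noncarrier_total += c
                    noncarrier_n += 1
        ratio = (carrier_total / carrier_n) / (noncarrier_total / noncarrier_n)
        assert abs(ratio - 2.0) < 0.2

    def test_controller_marker_reports_allele(self):
        """The marker at the controller position reads the drawn allele."""
        cfg = _tiny_config(
            markers_per_chrom={"chrA": np.array([1, 250_000, 500_000, 750_000, 999_999]),
                               "chrB": np.array([1, 400_000, 799_999])},
            qtl_spec=[ControllerSpec("chrA", 500_000, "chrB", 1.0)],
        )
        sim = simulate_population(cfg)
        idx = [i for i, m in enumerate(sim.matrix.markers)
               if m.chromosome == "chrA" and m.pos_bp == 500_000][0]
        np.testing.assert_array_equal(
            sim.matrix.calls[idx], sim.controller_alleles.iloc[:, 0].to_numpy()
        )

    def test_truth_recoverable_at_min_run_one(self):
        """Clean calls re-derive every breakpoint with non-empty flanking runs."""
        sim = simulate_population(_tiny_config(seed=21))
        events = call_crossovers(sim.matrix, min_run=1)
        called = {(e.isolate, e.chromosome, e.left_bp, e.right_bp) for e in events}
        pos = sim.matrix.pos_bp()
        slices = sim.matrix.chrom_slices()
        for t in sim.truth:
            cpos = pos[slices[t.chromosome]]
            g = int(np.searchsorted(cpos, t.pos_bp, side="right"))
            if g == 0 or g == len(cpos):
                continue  # no marker on one side
            xs = [
                u.pos_bp
                for u in sim.truth
                if u.isolate == t.isolate and u.chromosome == t.chromosome
            ]
            gaps = np.searchsorted(cpos, xs, side="right")
            if (gaps == g).sum() % 2 == 0:
                continue  # cancelled within one gap
            assert (t.isolate, t.chromosome, int(cpos[g - 1]), int(cpos[g])) in called

    def test_mating_type_alleles_recorded(self):
        sim = simulate_population(_tiny_config(mat_locus=("chrA", 600_000)))
        assert sim.mat_alleles is not None
        assert set(sim.mat_alleles.unique()) <= {"A1", "A2"}
        assert len(sim.mat_alleles) == 20

    def test_controller_outside_genome_rejected(self):
        with pytest.raises(SimConfigError, match="outside"):
            simulate_population(
                _tiny_config(qtl_spec=[ControllerSpec("chrA", 2_000_000, "chrB", 1.0)])
            )

    def test_bad_rates_rejected(self):
        with pytest.raises(SimConfigError, match="error_rate"):
            simulate_population(_tiny_config(error_rate=1.5))


class TestDemoConfig:
    def test_demo_genome_scale(self):
        g = demo_genome()
        assert len(g) == 9
        assert sum(c.length for c in g) == 37_230_000

    def test_demo_lambda_range_and_total(self):
        cfg = demo_config()
        lams = list(cfg.lambda_per_chrom.values())
        assert min(lams) == 0.25 and max(lams) == 1.80
        assert abs(sum(lams) - 8.05) < 1e-9

    def test_no_hotspots_on_chr7(self):
        cfg = demo_config()
        assert all(h.chromosome != "chr7" for h in cfg.hotspot_spec)


class TestTruthBed:
    def test_single_breakpoint_line(self, tmp_path):
        from meioscan.simulate import TrueCrossover

        p = tmp_path / "t.bed"
        write_truth_bed([TrueCrossover("iso1", "chr1", 5000)], p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["chr1\t4999\t5000\tiso1"]

    def test_sorted_many(self, tmp_path):
        from meioscan.simulate import TrueCrossover

        rng = np.random.default_rng(0)
        truth = [
            TrueCrossover(f"i{k}", rng.choice(["chr2", "chr1"]), int(rng.integers(1, 9999)))
            for k in range(10)
        ]
        p = tmp_path / "t.bed"
        write_truth_bed(truth, p)
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        keys = [(r[0], int(r[1])) for r in rows]
        assert keys == sorted(keys)
        assert len(rows) == 10
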