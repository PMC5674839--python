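import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdscan.genotype_io import MISSING, GenotypeMatrix, SnpMap
from herdscan.pedigree import Pedigree
from herdscan.roh_inbreeding import (
    GenomeLength,
    RohParams,
    compare_inbreeding,
    detect_roh,
    detect_roh_genome,
    expected_hom,
    f_hom,
    f_roh,
    inbreeding_table,
    lencz_min_snps,
    roh_incidence,
    roh_summaries,
)
from herdscan.synthetic_data import random_snp_map

from roh_oracle import brute_force_roh, random_roh_instance

L_AUTO = GenomeLength(l_auto_kb=2_497_129.0)


class TestLenczMinSnps:
    def test_integer_fixed_point(self):
        # choose het so that (1-het)^l hits alpha/(ns*ni) exactly at l = 20
        ns, ni, alpha = 1000, 10, 0.05
        het = 1 - (alpha / (ns * ni)) ** (1 / 20)
        assert lencz_min_snps(ns, ni, het, alpha) == 20

    def test_reference_inputs(self):
        # 27,612 SNPs x 9,214 individuals at het 0.37 -> 49
        assert lencz_min_snps(27_612, 9_214, 0.37, 0.05) == 49
        assert lencz_min_snps(27_612, 9_214, 0.37, 0.05) == math.ceil(
            math.log(0.05 / (27_612 * 9_214)) / math.log(0.63)
        )

    def test_monotone_in_het(self):
        prev = 10**9
        for het in np.linspace(0.05, 0.95, 19):
            cur = lencz_min_snps(10_000, 100, het)
            assert cur <= prev
            prev = cur

    @pytest.mark.parametrize("het", [0.0, 1.0])
    def test_bad_het(self, het):
        with pytest.raises(ValueError):
            lencz_min_snps(100, 10, het)


class TestDetectRoh:
    def test_periodic_hets_no_roh(self):
        n = 500
        calls = np.zeros(n, dtype=np.int8)
        calls[::25] = 1  # no 50-SNP het-free stretch
        pos = np.arange(1, n + 1) * 50_000
        assert detect_roh(calls, pos, RohParams()) == []

    def test_sixty_homozygous(self):
        pos = np.arange(60) * 50_000 + 1
        calls = np.full(60, 2, dtype=np.int8)
        segs = detect_roh(calls, pos, RohParams())
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snps) == (1, 2_950_001, 60)

    def test_unsorted_positions_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            detect_roh(np.zeros(5, dtype=np.int8), np.array([1, 3, 2, 4, 5]), RohParams())

    def test_crafted_vs_brute_force(self, rng):
        params = RohParams(
            min_snps=30, min_length_kb=800, min_density_kb_per_snp=100,
            max_gap_kb=500, max_missing=3, max_het=0,
        )
        calls = np.zeros(300, dtype=np.int8)
        calls[90:105] = 1  # het island
        calls[200:204] = 1  # second island
        miss_at = rng.choice(300, size=3, replace=False)
        calls[miss_at] = MISSING
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), 300, replace=False))
        got = {(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(calls, pos, params)}
        assert got == brute_force_roh(calls, pos, params)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_instances_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        params = RohParams(
            min_snps=15, min_length_kb=400, min_density_kb_per_snp=100,
            max_gap_kb=300, max_missing=2, max_het=1,
        )
        calls, pos = random_roh_instance(rng, n=250)
        got = {(s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(calls, pos, params)}
        assert got == brute_force_roh(calls, pos, params)

    def test_relaxing_params_never_reduces_total_length(self, rng):
        base = RohParams(min_snps=20, min_length_kb=500, min_density_kb_per_snp=80,
                         max_gap_kb=400, max_missing=1, max_het=0)
        relaxed = [
            RohParams(min_snps=15, min_length_kb=500, min_density_kb_per_snp=80,
                      max_gap_kb=400, max_missing=1, max_het=0),
            RohParams(min_snps=20, min_length_kb=300, min_density_kb_per_snp=80,
                      max_gap_kb=400, max_missing=1, max_het=0),
            RohParams(min_snps=20, min_length_kb=500, min_density_kb_per_snp=120,
                      max_gap_kb=400, max_missing=1, max_het=0),
            RohParams(min_snps=20, min_length_kb=500, min_density_kb_per_snp=80,
                      max_gap_kb=800, max_missing=1, max_het=0),
            RohParams(min_snps=20, min_length_kb=500, min_density_kb_per_snp=80,
                      max_gap_kb=400, max_missing=3, max_het=0),
            RohParams(min_snps=20, min_length_kb=500, min_density_kb_per_snp=80,
                      max_gap_kb=400, max_missing=1, max_het=1),
        ]

        def covered_length(calls, pos, params):
            """Union length of detected segments (overlap-safe)."""
            spans = sorted(
                (s.start_bp, s.end_bp) for s in detect_roh(calls, pos, params)
            )
            total, cur_s, cur_e = 0, None, None
            for s, e in spans:
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
            return total

        for rep in range(8):
            calls, pos = random_roh_instance(rng, n=250, p_het=0.04)
            base_len = covered_length(calls, pos, base)
            for params in relaxed:
                assert covered_length(calls, pos, params) >= base_len


class TestFRoh:
    def test_reference_bs(self):
        seg = pd.DataFrame({"KB": [226_400.0]})
        assert round(f_roh(seg, L_AUTO), 3) == 0.091

    def test_reference_er(self):
        seg = pd.DataFrame({"KB": [66_200.0]})
        assert round(f_roh(seg, L_AUTO), 3) == 0.027

    def test_no_segments(self):
        assert f_roh(pd.DataFrame({"KB": []}), L_AUTO) == 0.0

    def test_min_segment_floor_strict(self):
        seg = pd.DataFrame({"KB": [5000.0, 6000.0]})
        assert f_roh(seg, L_AUTO, min_segment_kb=5000.0) == pytest.approx(
            6000.0 / L_AUTO.l_auto_kb
        )

    def test_bad_genome_length(self):
        with pytest.raises(ValueError):
            GenomeLength(l_auto_kb=0.0)


class TestFHom:
    def test_obs_equals_exp(self):
        assert f_hom(80, 80.0, 100) == 0.0

    def test_fully_homozygous(self):
        assert f_hom(100, 80.0, 100) == 1.0

    def test_arithmetic(self):
        assert f_hom(90, 80.0, 100) == pytest.approx(0.5)

    def test_negative_allowed(self):
        assert f_hom(70, 80.0, 100) < 0

    def test_bad_denominator(self):
        with pytest.raises(ValueError):
            f_hom(50, 100.0, 100)


class TestExpectedHom:
    def test_monomorphic(self, gm_builder):
        gm, _ = gm_builder(np.zeros((5, 40), dtype=np.int8))
        assert expected_hom(gm, "ind0") == pytest.approx(40.0)

    def test_half_frequency_limit(self, gm_builder):
        n = 400
        calls = np.concatenate([np.zeros(n // 2), np.full(n // 2, 2)]).astype(np.int8)
        gm, _ = gm_builder(calls[:, None].T.reshape(n, 1).T)  # n individuals x 1 SNP
        gm, _ = gm_builder(calls.reshape(n, 1))
        assert expected_hom(gm, "ind0") == pytest.approx(0.5, abs=0.01)

    def test_loop_oracle(self, rng, gm_builder):
        calls = rng.choice([0, 1, 2, MISSING], p=[0.4, 0.25, 0.25, 0.1], size=(15, 50)).astype(np.int8)
        gm, _ = gm_builder(calls)
        for iid_idx in (0, 7):
            iid = gm.individuals[iid_idx]
            expect = 0.0
            for j in range(50):
                col = [g for g in calls[:, j] if g != MISSING]
                if calls[iid_idx, j] == MISSING or len(col) < 2:
                    continue
                n = len(col)
                p = sum(col) / (2 * n)
                expect += 1 - 2 * p * (1 - p) * (2 * n / (2 * n - 1))
            assert expected_hom(gm, iid) == pytest.approx(expect, abs=1e-9)


class TestRohSummaries:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"])

    def test_population_without_segments(self):
        table = self._table([])
        out = roh_summaries(table, {"i1": "A", "i2": "A"}, ["i1", "i2"])
        row = out["per_population"].iloc[0]
        assert row["n_without_roh"] == 2 and row["total_roh"] == 0

    def test_length_class_binning(self):
        table = self._table([("i1", 1, 1_000_000, 8_200_000, 7_200.0, 80)])
        out = roh_summaries(table, {"i1": "A"}, ["i1"])
        hist = out["length_classes"].iloc[0]
        assert hist["[5-10)Mb"] == 1
        assert hist["[1-5)Mb"] == 0

    def test_random_histogram_oracle(self, rng):
        lengths_mb = rng.uniform(1, 40, 200)
        rows = [
            (f"i{k % 10}", 1 + k % 5, 1_000_000, int(1_000_000 + l * 1e6), l * 1000, 60)
            for k, l in enumerate(lengths_mb)
        ]
        pops = {f"i{k}": ("A" if k < 5 else "B") for k in range(10)}
        out = roh_summaries(self._table(rows), pops, list(pops))
        bins = [1, 5, 10, 15, 20, 25, 30, np.inf]
        for pop in ("A", "B"):
            sel = [l for k, l in enumerate(lengths_mb) if pops[f"i{k % 10}"] == pop]
            expect, _ = np.histogram(sel, bins=bins)
            got = out["length_classes"].set_index("pop").loc[pop].to_numpy()
            np.testing.assert_array_equal(got, expect)
            n_pop = out["per_population"].set_index("pop").loc[pop, "total_roh"]
            assert n_pop == len(sel)


class TestRohIncidence:
    def _map(self, n=20):
        return SnpMap.from_arrays(
            [f"s{j}" for j in range(n)], [1] * n, [100_000 * (j + 1) for j in range(n)]
        )

    def test_no_segments_zero(self):
        table = pd.DataFrame(columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"])
        out = roh_incidence(table, self._map(), {"i1": "A"}, ["i1"])
        assert (out["fraction"] == 0).all()
        assert not out["flagged"].any()

    def test_quarter_boundary_flagged(self):
        rows = [
            (f"i{k}", 1, 500_000, 1_500_000, 1000.0, 10) for k in range(5)
        ]
        table = pd.DataFrame(rows, columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"])
        pops = {f"i{k}": "A" for k in range(20)}
        out = roh_incidence(table, self._map(), pops, list(pops))
        at_snp = out[out["pos_bp"] == 1_000_000].iloc[0]
        assert at_snp["fraction"] == pytest.approx(0.25)
        assert bool(at_snp["flagged"])

    def test_interval_stabbing_oracle(self, rng):
        sm = self._map(30)
        inds = [f"i{k}" for k in range(8)]
        pops = {i: ("A" if k < 4 else "B") for k, i in enumerate(inds)}
        rows = []
        for k in range(25):
            iid = inds[rng.integers(8)]
            s = int(rng.integers(1, 2_500_000))
            e = s + int(rng.integers(100_000, 1_500_000))
            rows.append((iid, 1, s, e, (e - s) / 1000, 10))
        table = pd.DataFrame(rows, columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP"])
        out = roh_incidence(table, sm, pops, inds)
        for _, r in out.iterrows():
            members = [i for i in inds if pops[i] == r["pop"]]
            covered = sum(
                any(
                    row[0] == i and row[2] <= r["pos_bp"] <= row[3]
                    for row in rows
                )
                for i in members
            )
            assert r["fraction"] == pytest.approx(covered / len(members))


class TestCompareInbreeding:
    def _records(self, f_ped, f_roh_vals, f_hom_vals=None, pci=None):
        n = len(f_ped)
        return pd.DataFrame(
            {
                "iid": [f"i{k}" for k in range(n)],
                "pop": ["A"] * n,
                "F_PED": f_ped,
                "F_HOM": f_hom_vals if f_hom_vals is not None else f_roh_vals,
                "F_ROH": f_roh_vals,
                "F_ROH_gt5": f_roh_vals,
                "PCI5": pci if pci is not None else [1.0] * n,
            }
        )

    def test_identity_perfect_fit(self):
        f = [0.0, 0.1, 0.2, 0.3]
        out = compare_inbreeding(self._records(f, f))
        row = out[out["measure"] == "F_ROH"].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(1.0)
        assert row["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_low_correlation(self, rng):
        x = rng.uniform(0, 0.3, 500)
        y = rng.uniform(0, 0.3, 500)
        out = compare_inbreeding(self._records(x, y))
        assert abs(out.iloc[0]["pearson_r"]) < 0.2

    def test_five_point_ols_oracle(self):
        x = np.array([0.0, 0.05, 0.10, 0.20, 0.25])
        y = np.array([0.02, 0.04, 0.09, 0.18, 0.30])
        out = compare_inbreeding(self._records(x, y))
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        intercept = ym - slope * xm
        r = ((x - xm) * (y - ym)).sum() / np.sqrt(
            ((x - xm) ** 2).sum() * ((y - ym) ** 2).sum()
        )
        row = out[out["measure"] == "F_ROH"].iloc[0]
        assert row["slope"] == pytest.approx(slope)
        assert row["intercept"] == pytest.approx(intercept)
        assert row["pearson_r"] == pytest.approx(r)
        assert row["r_squared"] == pytest.approx(r**2)

    def test_pci_filter_applied(self):
        x = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        pci = [1.0, 1.0, 1.0, 0.2, 0.2, 0.2]
        out = compare_inbreeding(self._records(x, x, pci=pci), pci_min=0.95)
        assert (out["n"] == 3).all()

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_inbreeding(self._records([0.1] * 5, [0.0, 0.1, 0.2, 0.3, 0.4]))


class TestInbreedingTable:
    def test_ordering_invariant(self, rng):
        """F_ROH>5Mb <= F_ROH for every individual, on detected segments."""
        sm = random_snp_map(4, 60_000_000, 660, rng)
        calls = rng.choice([0, 1, 2], p=[0.45, 0.1, 0.45], size=(10, len(sm))).astype(np.int8)
        # plant long homozygous stretches in some individuals
        for k in range(5):
            sl = np.nonzero(sm.chrom == 1 + k % 4)[0][:200]
            calls[k, sl] = 0
        gm = GenotypeMatrix([f"i{k}" for k in range(10)], sm, calls)
        table = detect_roh_genome(gm)
        gl = GenomeLength.from_snp_map(sm)
        inb = inbreeding_table(gm, None, table, gl)
        assert (inb["F_ROH_gt5"] <= inb["F_ROH"] + 1e-12).all()
        assert ((inb["F_ROH"] >= 0) & (inb["F_ROH"] <= 1)).all()
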