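import numpy as np
import pytest

from radpanels.filters import (
    CascadeParams,
    apply_min_coverage,
    filter_biallelic,
    filter_hwe,
    filter_mac,
    filter_max_snps_per_locus,
    filter_pop_callrate,
    run_cascade,
    select_first_snp_per_locus,
)
from radpanels.model import (
    DepthMatrix,
    GenotypeMatrix,
    SNPSite,
    het,
    hom,
    missing_call,
)

from _fixtures import cascade_fixture


def _gm(columns, pop_sizes=(4,)):
    """Matrix from per-SNP call lists; columns = {name: [calls...]}."""
    n = sum(pop_sizes)
    samples = [f"s{i}" for i in range(n)]
    popmap = {}
    i = 0
    for k, size in enumerate(pop_sizes):
        for _ in range(size):
            popmap[samples[i]] = f"pop{k + 1}"
            i += 1
    snps, cols = [], []
    for name, calls in columns.items():
        locus, pos = name.rsplit("_", 1)
        observed = sorted({"ACGT"[c] for pair in calls for c in pair if c >= 0})
        snps.append(SNPSite(locus, int(pos), tuple(observed) or ("A", "C")))
        cols.append(calls)
    arr = np.array(cols, dtype=np.int8).transpose(1, 0, 2)
    return GenotypeMatrix(samples, popmap, snps, arr)


class TestBiallelic:
    def test_triallelic_removed(self):
        gm = _gm({"L1_0": [hom("A"), het("A", "C"), hom("T"), hom("A")]})
        out, _, rec = filter_biallelic(gm)
        assert out.n_snps == 0 and rec.snps_after == 0

    def test_biallelic_unchanged(self):
        gm = _gm({"L1_0": [hom("A"), het("A", "C"), hom("C"), hom("A")]})
        out, _, _ = filter_biallelic(gm)
        assert out.n_snps == 1

    def test_mixed_panel_enumeration(self):
        cols = {}
        for j in range(8):
            cols[f"L{j}_0"] = [hom("A"), het("A", "C"), hom("C"), hom("A")]
        cols["L8_0"] = [hom("A"), het("A", "C"), hom("T"), hom("A")]
        cols["L9_0"] = [hom("G"), het("A", "C"), hom("T"), hom("A")]
        out, _, rec = filter_biallelic(_gm(cols))
        assert (rec.snps_before, rec.snps_after) == (10, 8)


class TestMinCoverage:
    def _pair(self):
        gm = _gm({"L1_0": [hom("A"), hom("A"), het("A", "C"), hom("A")]})
        counts = np.zeros((4, 1, 4), dtype=np.int64)
        counts[:, 0, 0] = [7, 8, 10, 12]
        dm = DepthMatrix(gm.samples, list(gm.snps), counts)
        return gm, dm

    def test_boundary(self):
        gm, dm = self._pair()
        out, _ = apply_min_coverage(gm, dm, threshold=8)
        assert tuple(out.calls[0, 0]) == missing_call()
        assert tuple(out.calls[1, 0]) == hom("A")

    def test_all_deep_unchanged(self):
        gm, dm = self._pair()
        dm.counts[:, 0, 0] = 20
        out, _ = apply_min_coverage(gm, dm, threshold=8)
        assert np.array_equal(out.calls, gm.calls)

    def test_missing_fraction_hand_count(self):
        gm, dm = self._pair()
        out, rec = apply_min_coverage(gm, dm, threshold=8)
        assert rec.missing_fraction_after == pytest.approx(1 / 4)

    def test_snp_set_unchanged(self):
        gm, dm = self._pair()
        out, rec = apply_min_coverage(gm, dm, threshold=8)
        assert rec.snps_before == rec.snps_after == 1

    def test_call_without_depth_errors(self):
        gm, dm = self._pair()
        dm.counts[2, 0] = 0
        with pytest.raises(ValueError):
            apply_min_coverage(gm, dm)


class TestMaxSnpsPerLocus:
    def test_enumeration_1_to_5(self):
        cols = {}
        for k in range(1, 6):  # loci with 1..5 SNPs
            for p in range(k):
                cols[f"L{k}_{p}"] = [hom("A"), het("A", "C"), hom("C"), hom("A")]
        out, _, rec = filter_max_snps_per_locus(_gm(cols), max_snps=3)
        assert (rec.snps_before, rec.snps_after) == (15, 6)
        kept_loci = {s.locus_id for s in out.snps}
        assert kept_loci == {"L1", "L2", "L3"}

    def test_boundary_exactly_three_kept(self):
        cols = {f"L1_{p}": [hom("A"), het("A", "C"), hom("C"), hom("A")] for p in range(3)}
        out, _, _ = filter_max_snps_per_locus(_gm(cols), max_snps=3)
        assert out.n_snps == 3


class TestMac:
    def test_count_three_kept(self):
        gm = _gm({"L1_0": [het("A", "C"), hom("C"), hom("A"), hom("A")]})  # 1 het + 1 minor hom = 3
        out, _, _ = filter_mac(gm, min_count=3)
        assert out.n_snps == 1

    def test_count_two_removed(self):
        gm = _gm({"L1_0": [het("A", "C"), het("A", "C"), hom("A"), hom("A")]})
        out, _, _ = filter_mac(gm, min_count=3)
        assert out.n_snps == 0

    def test_monomorphic_removed(self):
        gm = _gm({"L1_0": [hom("A")] * 4})
        out, _, _ = filter_mac(gm, min_count=3)
        assert out.n_snps == 0

    def test_enumeration_counts_0_to_4(self):
        h, m = hom("A"), hom("C")
        e = het("A", "C")
        cols = {
            "L0_0": [h, h, h, h, h],            # 0 copies
            "L1_0": [e, h, h, h, h],            # 1
            "L2_0": [e, e, h, h, h],            # 2
            "L3_0": [e, m, h, h, h],            # 3
            "L4_0": [m, m, h, h, h],            # 4
        }
        out, _, rec = filter_mac(_gm(cols, pop_sizes=(5,)), min_count=3)
        assert rec.snps_after == 2
        assert {s.locus_id for s in out.snps} == {"L3", "L4"}

    def test_missing_calls_not_counted(self):
        gm = _gm({"L1_0": [het("A", "C"), missing_call(), hom("C"), hom("A")]})
        out, _, _ = filter_mac(gm, min_count=3)
        assert out.n_snps == 1  # het (1) + hom C (2) = 3


class TestPopCallrate:
    def test_boundary_40pct_removed(self):
        col = [hom("A")] * 7 + [missing_call()] * 3 + [hom("A")] * 6 + [missing_call()] * 4
        out, _, _ = filter_pop_callrate(_gm({"L1_0": col}, pop_sizes=(10, 10)), max_missing=0.40)
        assert out.n_snps == 0  # pop2 at exactly 0.40 -> not < 0.40

    def test_no_missing_kept(self):
        out, _, _ = filter_pop_callrate(
            _gm({"L1_0": [hom("A")] * 20}, pop_sizes=(10, 10)), max_missing=0.40
        )
        assert out.n_snps == 1

    def test_three_pop_enumeration(self):
        h, M = hom("A"), missing_call()
        cols = {
            "L1_0": [h, h, h, h] * 3,                      # kept
            "L2_0": [M, M, h, h] + [h] * 8,                # pop1 0.5 -> removed
            "L3_0": [M, h, h, h] * 3,                      # 0.25 everywhere -> kept
            "L4_0": [h] * 8 + [M, M, M, h],                # pop3 0.75 -> removed
        }
        out, _, _ = filter_pop_callrate(_gm(cols, pop_sizes=(4, 4, 4)), max_missing=0.40)
        assert {s.locus_id for s in out.snps} == {"L1", "L3"}


class TestHwe:
    def test_majority_rule(self):
        # 3 pops; pops 1-2 all opposite homozygotes (P < 0.01), pop3 conforms
        bad = [hom("A")] * 5 + [hom("C")] * 5
        good = [hom("A")] * 2 + [het("A", "C")] * 6 + [hom("C")] * 2
        out, _, _ = filter_hwe(_gm({"L1_0": bad + bad + good}, pop_sizes=(10, 10, 10)))
        assert out.n_snps == 0

    def test_half_not_removed(self):
        bad = [hom("A")] * 5 + [hom("C")] * 5
        good = [hom("A")] * 2 + [het("A", "C")] * 6 + [hom("C")] * 2
        out, _, _ = filter_hwe(_gm({"L1_0": bad + good}, pop_sizes=(10, 10)))
        assert out.n_snps == 1  # 1 of 2 is not > half

    def test_type_one_error_rate(self):
        # HWE-conforming simulation: ~1% of per-pop tests significant at 0.01
        rng = np.random.default_rng(7)
        n, m = 40, 4000
        p = rng.uniform(0.2, 0.8, size=m)
        a1 = rng.random((n, m)) < p
        a2 = rng.random((n, m)) < p
        calls = np.stack(
            [np.minimum(a1, a2).astype(np.int8), np.maximum(a1, a2).astype(np.int8)], axis=2
        )
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(n)],
            {f"s{i}": "pop1" for i in range(n)},
            [SNPSite(f"L{j}", 0, ("A", "C")) for j in range(m)],
            calls,
        )
        from radpanels.popgen import hwe_pvalues

        pv = hwe_pvalues(gm)[:, 0]
        rate = (pv[np.isfinite(pv)] < 0.01).mean()
        assert 0.003 <= rate <= 0.015


class TestFirstSnp:
    def test_smallest_position_kept(self):
        cols = {
            "L1_17": [hom("A"), het("A", "C"), hom("C"), hom("A")],
            "L1_5": [hom("A"), het("A", "C"), hom("C"), hom("A")],
        }
        out, _, _ = select_first_snp_per_locus(_gm(cols))
        assert out.snp_names() == ["L1_5"]

    def test_single_snp_loci_unchanged(self):
        cols = {f"L{j}_0": [hom("A"), het("A", "C"), hom("C"), hom("A")] for j in range(4)}
        out, _, _ = select_first_snp_per_locus(_gm(cols))
        assert out.n_snps == 4

    def test_bruteforce_minima(self, rng):
        cols = {}
        for j in range(6):
            for p in rng.choice(36, size=3, replace=False):
                cols[f"L{j}_{p}"] = [hom("A"), het("A", "C"), hom("C"), hom("A")]
        gm = _gm(cols)
        out, _, _ = select_first_snp_per_locus(gm)
        expected = {}
        for s in gm.snps:
            if s.locus_id not in expected or s.position < expected[s.locus_id]:
                expected[s.locus_id] = s.position
        assert {(s.locus_id, s.position) for s in out.snps} == set(expected.items())


class TestCascade:
    def test_designed_fixture_trajectory(self, cascade_data):
        gm, dm, cat, expected, survivors = cascade_data
        panel, _, audit = run_cascade(gm, dm, cat)
        assert audit.snp_trajectory() == expected
        assert panel.snp_names() == survivors

    def test_identity_fixture_no_removals(self):
        cols = {f"L{j}_0": [hom("A")] * 3 + [het("A", "C")] * 4 + [hom("C")] * 3 for j in range(5)}
        gm = _gm(cols, pop_sizes=(5, 5))
        dm = DepthMatrix(gm.samples, list(gm.snps), np.full((10, 5, 4), 5))
        panel, _, audit = run_cascade(gm, dm)
        assert panel.n_snps == 5
        assert all(r.snps_before == r.snps_after for r in audit.records)

    def test_monotone_snp_counts(self, cascade_data):
        gm, dm, cat, _, _ = cascade_data
        _, _, audit = run_cascade(gm, dm, cat)
        counts = [audit.records[0].snps_before] + [r.snps_after for r in audit.records]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_stop_after_step_6(self, cascade_data):
        gm, dm, cat, _, _ = cascade_data
        p6, _, audit = run_cascade(gm, dm, cat, stop_after_step=6)
        assert len(audit.records) == 6
        assert p6.n_snps == 4  # S9, S10, S11, S12

    def test_order_sensitivity(self, cascade_data):
        # POP filter applied before the coverage filter keeps S7
        gm, dm, cat, _, _ = cascade_data
        kept_early, _, _ = filter_pop_callrate(gm, 0.40)
        assert "L4_0" in kept_early.snp_names()
        panel, _, _ = run_cascade(gm, dm, cat)
        assert "L4_0" not in panel.snp_names()

    def test_idempotent_on_own_output(self, cascade_data):
        gm, dm, cat, _, _ = cascade_data
        panel, panel_dm, _ = run_cascade(gm, dm, cat)
        again, _, audit = run_cascade(panel, panel_dm, cat)
        assert again.snp_names() == panel.snp_names()
        assert np.array_equal(again.calls, panel.calls)

    def test_coverage_pop_interaction(self):
        # raising the coverage threshold never lets the POP filter remove fewer
        from radpanels.simdata import SimConfig, build_pipeline_outputs

        removed = []
        for threshold in (5, 8, 12):
            cfg = SimConfig(n_loci=60, pop_sizes=[8, 8], cov_mean=10.0, seed=3)
            sim = build_pipeline_outputs(cfg)
            gm, dm = sim.genotypes["STA"], sim.depths["STA"]
            gm2, _ = apply_min_coverage(gm, dm, threshold)
            _, _, rec = filter_pop_callrate(gm2, 0.40)
            removed.append(rec.snps_before - rec.snps_after)
        assert removed[0] <= removed[1] <= removed[2]

    def test_raw_mode_counts_catalog_snps(self, cascade_data):
        gm, dm, cat, _, _ = cascade_data
        params = CascadeParams(snps_per_locus_mode="raw")
        panel, _, audit = run_cascade(gm, dm, cat, params)
        assert audit.snp_trajectory()[2][0] == "max_snps_per_locus"
        # L2 still has 4 catalogue SNPs either way -> same outcome here
        assert audit.snp_trajectory()[2] == ("max_snps_per_locus", 11, 7)
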