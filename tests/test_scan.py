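"""Scan orchestration, Holm correction, hQTL merging and PVE."""

import numpy as np
import pandas as pd
import pytest

from hetscan import (SimScenario, holm_adjust, hqtl_pve, merge_hqtl,
                     profile_null, reml_multikernel, scan_components,
                     scan_heterotic)
from hetscan.popdata import MarkerPanel
from hetscan.scan import ScanError, ScanResult

pytestmark = []


@pytest.fixture(scope="module")
def scanned(pop200):
    """A 50-marker scan on one simulated phenotype (shared by several tests)."""
    ds = pop200.simulator.simulate(SimScenario.from_id(5), seed=5)
    fit = reml_multikernel(ds.y, pop200.kernels)
    null = profile_null(fit, pop200.kernels)
    markers = list(range(50))
    res = scan_heterotic(pop200.codings, pop200.transform, pop200.panel,
                         null, ds.y, markers=markers)
    return ds, null, markers, res


class TestHolm:
    def test_hand_executed_step_down(self):
        np.testing.assert_allclose(holm_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_bounds(self, rng):
        p = rng.uniform(size=40)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ScanError):
            holm_adjust(np.array([0.1, np.nan]))


class TestScan:
    def test_one_row_per_marker(self, scanned):
        *_, markers, res = scanned
        assert len(res.table) == len(markers)
        assert (res.table["status"] == "ok").all()
        assert np.all(res.table["p_holm"] >= res.table["p"] - 1e-15)

    def test_deterministic_rerun(self, pop200, scanned):
        ds, null, markers, res = scanned
        res2 = scan_heterotic(pop200.codings, pop200.transform, pop200.panel,
                              null, ds.y, markers=markers)
        pd.testing.assert_frame_equal(res.table, res2.table, check_exact=True)

    def test_empty_marker_set(self, pop200, scanned):
        ds, null, *_ = scanned
        with pytest.raises(ScanError, match="empty"):
            scan_heterotic(pop200.codings, pop200.transform, pop200.panel,
                           null, ds.y, markers=[])


def _panel(positions, chrom="chr1"):
    p = len(positions)
    return MarkerPanel([f"m{k}" for k in range(p)], [chrom] * p,
                       np.asarray(positions), np.full(p, 0.5))


def _sig_table(panel, sig_ids, pvals=None):
    rows = []
    for k, m in enumerate(panel.marker_id):
        sig = m in sig_ids
        rows.append({"marker_id": m, "chrom": panel.chromosome[k],
                     "pos": int(panel.position_bp[k]),
                     "p": (pvals or {}).get(m, 1e-9 if sig else 0.9),
                     "significant": sig})
    return ScanResult(pd.DataFrame(rows), alpha=0.05)


class TestMerge:
    def test_close_peaks_high_ld_merge(self):
        panel = _panel([1_000_000, 6_000_000])
        res = _sig_table(panel, {"m0", "m1"})
        qtl = merge_hqtl(res, panel, lambda a, b: 0.5 if a != b else 1.0)
        assert len(qtl) == 1
        assert qtl[0].members == ["m0", "m1"]

    def test_distant_peaks_never_merge(self):
        """Peaks >= 10 Mb apart stay separate however high the mean LD."""
        panel = _panel([1_000_000, 2_000_000, 15_000_000, 16_000_000])
        res = _sig_table(panel, {"m0", "m3"})

        def ld(a, b):
            if a == b:
                return 1.0
            return {frozenset((0, 1)): 0.8, frozenset((2, 3)): 0.8,
                    frozenset((1, 2)): 0.9, frozenset((0, 3)): 0.9}.get(
                        frozenset((a, b)), 0.2)
        qtl = merge_hqtl(res, panel, ld)
        # intervals [1, 2] Mb and [15, 16] Mb; mean cross-interval LD 0.55
        assert len(qtl) == 2
        # the same geometry with close peaks does merge
        panel2 = _panel([1_000_000, 2_000_000, 5_000_000, 6_000_000])
        res2 = _sig_table(panel2, {"m0", "m3"})
        assert len(merge_hqtl(res2, panel2, ld)) == 1

    def test_close_peaks_low_ld_stay_separate(self):
        panel = _panel([1_000_000, 6_000_000])
        res = _sig_table(panel, {"m0", "m1"})
        qtl = merge_hqtl(res, panel, lambda a, b: 0.1 if a != b else 1.0)
        assert len(qtl) == 2

    def test_isolated_snp_is_singleton(self):
        panel = _panel([1_000_000, 2_000_000, 3_000_000])
        res = _sig_table(panel, {"m1"})
        qtl = merge_hqtl(res, panel, lambda a, b: 0.05 if a != b else 1.0)
        assert len(qtl) == 1
        assert qtl[0].start_bp == qtl[0].end_bp == 2_000_000

    def test_interval_extension_stops_below_threshold(self):
        panel = _panel([1, 100, 200, 300, 400])
        res = _sig_table(panel, {"m2"})

        def ld(a, b):
            return {frozenset((2, 1)): 0.8, frozenset((2, 3)): 0.35,
                    frozenset((2, 4)): 0.1, frozenset((2, 0)): 0.0,
                    frozenset((2,)): 1.0}.get(frozenset((a, b)), 0.0)
        qtl = merge_hqtl(res, panel, ld)
        assert (qtl[0].start_bp, qtl[0].end_bp) == (100, 300)

    def test_no_cross_chromosome_merge(self):
        panel = MarkerPanel(["m0", "m1"], ["chr1", "chr2"], [100, 150],
                            np.full(2, 0.5))
        res = _sig_table(panel, {"m0", "m1"})
        qtl = merge_hqtl(res, panel, lambda a, b: 1.0)
        assert len(qtl) == 2

    def test_fixpoint_and_partition(self, pop200, rng):
        """Merged output violates neither rule; every SNP lands in one hQTL."""
        panel = pop200.panel
        codes = pop200.pop.parent_codes

        def ld(a, b):
            from hetscan import pairwise_ld_r2
            return pairwise_ld_r2(codes[:, a], codes[:, b])
        sig_ids = {panel.marker_id[k]
                   for k in rng.choice(panel.n_markers, size=15, replace=False)}
        pvals = {m: float(p) for m, p in
                 zip(sorted(sig_ids), rng.uniform(1e-12, 1e-6, size=15))}
        res = _sig_table(panel, sig_ids, pvals)
        qtl = merge_hqtl(res, panel, ld)
        # partition property
        members = [m for q in qtl for m in q.members]
        assert sorted(members) == sorted(sig_ids)
        for q in qtl:
            assert q.lead in q.members
            assert q.lead_p == min(pvals[m] for m in q.members)
        # fixpoint: no remaining pair satisfies either merge rule
        pos = {m: int(panel.position_bp[panel.index_of(m)]) for m in members}
        idx = {m: panel.index_of(m) for m in members}
        chroms = np.asarray(panel.chromosome)
        for a in range(len(qtl)):
            for b in range(a + 1, len(qtl)):
                qa, qb = qtl[a], qtl[b]
                if qa.chromosome != qb.chromosome:
                    continue
                overlap = (qa.start_bp <= qb.end_bp
                           and qb.start_bp <= qa.end_bp)
                assert not overlap
                if abs(pos[qa.lead] - pos[qb.lead]) < 10e6:
                    ia = np.where((chroms == qa.chromosome)
                                  & (panel.position_bp >= qa.start_bp)
                                  & (panel.position_bp <= qa.end_bp))[0]
                    ib = np.where((chroms == qb.chromosome)
                                  & (panel.position_bp >= qb.start_bp)
                                  & (panel.position_bp <= qb.end_bp))[0]
                    mean_ld = np.mean([ld(int(u), int(v))
                                       for u in ia for v in ib])
                    assert mean_ld <= 0.3


class TestPVE:
    def test_zero_component_gives_zero(self):
        assert hqtl_pve(0.0, 1.0, {"D": 1.0}, 1.0, {"D": 1.0}) == 0.0

    def test_equal_deltas_arithmetic(self):
        sigma2 = {k: 1.0 for k in ("D", "AA", "AD", "DD")}
        deltas = {k: 1.0 for k in sigma2}
        assert hqtl_pve(1.0, 1.0, sigma2, 5.0, deltas) == pytest.approx(0.1)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ScanError):
            hqtl_pve(-0.1, 1.0, {}, 1.0, {})

    def test_refit_matches_direct_formula(self, pop200, scanned):
        from hetscan import hqtl_pve_at_lead, heterosis_kernel, marker_lr_test
        from hetscan.kernels import pair_cross_products
        ds, null, *_ = scanned
        lead = ds.hqtl_index
        pve = hqtl_pve_at_lead(lead, pop200.codings, pop200.transform,
                               pop200.kernels, null, ds.y)
        H = heterosis_kernel(lead, pop200.codings, pop200.transform,
                             S=pair_cross_products(pop200.codings))
        t = marker_lr_test(H, null, ds.y)
        num = H.delta * t.sigma2_h
        denom = num + sum(pop200.kernels.delta[k] * null.ratios[k]
                          * t.sigma2_eps for k in null.ratios) + t.sigma2_eps
        assert pve == pytest.approx(num / denom, rel=1e-12)
        assert 0.0 <= pve <= 1.0


@pytest.fixture(scope="module")
def small(pop200):
    ds = pop200.simulator.simulate_null(seed=17)
    fit = reml_multikernel(ds.y, pop200.kernels)
    return ds, profile_null(fit, pop200.kernels)


class TestComponents:
    def test_dominance_scan_row_count(self, pop200, small):
        ds, null = small
        sub = MarkerPanel(pop200.panel.marker_id[:30],
                          pop200.panel.chromosome[:30],
                          pop200.panel.position_bp[:30],
                          pop200.panel.ref_freq[:30])
        df = scan_components("dominance", pop200.codings, pop200.transform,
                             sub, null, ds.y)
        assert len(df) == 30

    def test_epistasis_scan_row_count(self, pop200, small):
        ds, null = small
        sub = MarkerPanel(pop200.panel.marker_id[:30],
                          pop200.panel.chromosome[:30],
                          pop200.panel.position_bp[:30],
                          pop200.panel.ref_freq[:30])
        df = scan_components("epistasis", pop200.codings, pop200.transform,
                             sub, null, ds.y, focal=3)
        assert len(df) == 4 * 29
        assert set(df["effect"]) == {"aa_ij", "ad_ij", "ad_ji", "dd_ij"}

    def test_missing_focal_rejected(self, pop200, small):
        ds, null = small
        with pytest.raises(ScanError, match="focal"):
            scan_components("epistasis", pop200.codings, pop200.transform,
                            pop200.panel, null, ds.y, focal=None)

    def test_simulated_dd_interaction_ranks_first(self, pop200):
        """A large dd effect at (i, j) tops the dd family of the focal scan."""
        cod, tr, ks = pop200.codings, pop200.transform, pop200.kernels
        i, j = 2, 37
        c = np.asarray(tr.T @ (cod.M_D[:, i] * cod.M_D[:, j]))
        wins = 0
        for seed in range(10):
            ds = pop200.simulator.simulate_null(seed=400 + seed)
            y = ds.y + c * np.sqrt(2.0 * ds.V_t / np.var(c, ddof=1))
            fit = reml_multikernel(y, ks)
            null = profile_null(fit, ks)
            df = scan_components("epistasis", cod, tr, pop200.panel, null, y,
                                 focal=i)
            dd = df[df["effect"] == "dd_ij"].sort_values("p")
            wins += dd.iloc[0]["partner_id"] == pop200.panel.marker_id[j]
        assert wins >= 9
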