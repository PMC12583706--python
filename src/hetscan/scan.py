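"""Genome-wide heterotic-effect scan, multiple-testing control, interval
merging, PVE estimation and component-effect follow-up scans.

The scan applies the per-marker kernel LR test under a shared P3D null fit,
adjusts p-values with the step-down Bonferroni-Holm procedure, and merges
significant SNPs into heterotic QTL intervals with the LD-based rules:
each significant SNP's interval extends over flanking markers while its
r^2 with them stays at or above ``ld_boundary``; intervals are then merged
iteratively when they overlap, or when their peak SNPs lie within
``max_peak_distance`` and the mean cross-interval LD exceeds ``mean_ld``,
until a fixpoint is reached.  Intervals never merge across chromosomes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from hetscan.kernels import (HeterosisKernel, KernelError, KernelSet,
                             heterosis_kernel, pair_cross_products)
from hetscan.lmm import FittedNull, marker_lr_test, wald_component_test
from hetscan.popdata import CodingMatrices, MarkerPanel, MPHTransform

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "HQTL", "scan_heterotic", "holm_adjust",
           "merge_hqtl", "hqtl_pve", "hqtl_pve_at_lead", "scan_components"]


class ScanError(ValueError):
    """Raised for invalid scan configuration."""


#: effect labels of the four digenic families in follow-up scans
WALD_FAMILY_LABELS = {"aa": "aa_ij", "ad": "ad_ij", "da": "ad_ji",
                      "dd": "dd_ij"}


@dataclass
class ScanResult:
    """Per-marker scan table with multiplicity-adjusted significance calls."""

    table: pd.DataFrame
    alpha: float
    correction: str = "holm"

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class HQTL:
    """A merged heterotic-QTL interval (closed, 1-based coordinates)."""

    id: str
    chromosome: str
    start_bp: int
    end_bp: int
    members: list[str]                # significant SNPs, sorted by position
    lead: str
    lead_p: float
    pve: float | None = None
    _member_pos: dict = field(default_factory=dict, repr=False)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Step-down Bonferroni-Holm adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ScanError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="holm")[1]


def scan_heterotic(codings: CodingMatrices, transform: MPHTransform,
                   panel: MarkerPanel, null: FittedNull, y: np.ndarray,
                   X: np.ndarray | None = None,
                   markers: list[int] | None = None,
                   alpha: float = 0.05) -> ScanResult:
    """Run the one-dimensional heterotic-effect scan over a marker set.

    One LR test per marker under the shared null fit; markers whose kernel
    is degenerate or whose eigendecomposition fails are reported with a
    status, never silently dropped.  Deterministic given its inputs.
    """
    if markers is None:
        markers = list(range(panel.n_markers))
    if len(markers) == 0:
        raise ScanError("empty marker set")
    S = pair_cross_products(codings)
    rows = []
    for i in markers:
        rec = {"marker_id": panel.marker_id[i], "chrom": panel.chromosome[i],
               "pos": int(panel.position_bp[i])}
        try:
            H = heterosis_kernel(i, codings, transform, S=S)
            t = marker_lr_test(H, null, y, X=X)
            rec.update(sigma2_h=t.sigma2_h, lr=t.lr, p=t.pvalue, status="ok")
        except (KernelError, np.linalg.LinAlgError) as exc:
            logger.warning("marker %s failed: %s", panel.marker_id[i], exc)
            rec.update(sigma2_h=np.nan, lr=np.nan, p=np.nan,
                       status=f"failed: {exc}")
        rows.append(rec)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    p_holm = np.full(len(table), np.nan)
    if ok.any():
        p_holm[ok.to_numpy()] = holm_adjust(table.loc[ok, "p"].to_numpy())
    table["p_holm"] = p_holm
    table["significant"] = ok & (table["p_holm"] < alpha)
    return ScanResult(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# LD-based merging of significant SNPs into hQTL intervals
# ---------------------------------------------------------------------------

def _extend_interval(k: int, chrom_idx: np.ndarray, panel: MarkerPanel,
                     ld_func, ld_boundary: float) -> tuple[int, int]:
    """Closed interval around significant marker k (panel indices).

    Walk outward over consecutive markers of the chromosome while the LD
    (r^2) between the significant SNP itself and the flanking SNP stays at
    or above ``ld_boundary``; the boundary is the last retained marker.  A
    SNP whose immediate neighbors fall below the threshold yields a
    singleton interval; chromosome ends truncate the walk.
    """
    pos_in_chrom = int(np.where(chrom_idx == k)[0][0])
    left = pos_in_chrom
    while left - 1 >= 0 and ld_func(k, int(chrom_idx[left - 1])) >= ld_boundary:
        left -= 1
    right = pos_in_chrom
    while (right + 1 < len(chrom_idx)
           and ld_func(k, int(chrom_idx[right + 1])) >= ld_boundary):
        right += 1
    return int(chrom_idx[left]), int(chrom_idx[right])


def merge_hqtl(scan: ScanResult | pd.DataFrame, panel: MarkerPanel, ld_func,
               ld_boundary: float = 0.3, max_peak_distance: float = 10e6,
               mean_ld: float = 0.3, id_prefix: str = "hQTL") -> list[HQTL]:
    """Merge significant SNPs into heterotic-QTL intervals.

    ``ld_func(k, l)`` must return the r^2 between panel markers k and l
    (same chromosome only).  Per significant SNP an LD-extended interval is
    built, then intervals are merged to a fixpoint: overlapping intervals
    always merge; non-overlapping ones merge when their peak (most
    significant) SNPs are closer than ``max_peak_distance`` and the mean
    cross-interval LD over all member SNPs exceeds ``mean_ld``.  The lead
    SNP of a merged interval is its most significant member (ties broken by
    smaller position).
    """
    table = scan.table if isinstance(scan, ScanResult) else scan
    sig = table[table["significant"]] if "significant" in table else table
    if sig.empty:
        return []
    chroms = np.asarray(panel.chromosome)
    positions = panel.position_bp
    id_to_idx = {m: k for k, m in enumerate(panel.marker_id)}

    # state per interval: (chrom, start, end, [(marker_idx, p)])
    intervals = []
    for _, row in sig.iterrows():
        k = id_to_idx[row["marker_id"]]
        chrom = panel.chromosome[k]
        chrom_idx = np.where(chroms == chrom)[0]
        if np.any(np.diff(positions[chrom_idx]) <= 0):
            raise ScanError(f"panel not sorted on chromosome {chrom!r}")
        lo, hi = _extend_interval(k, chrom_idx, panel, ld_func, ld_boundary)
        intervals.append({"chrom": chrom, "start": int(positions[lo]),
                          "end": int(positions[hi]),
                          "snps": [(k, float(row["p"]))]})

    def peak(iv):
        return min(iv["snps"], key=lambda t: (t[1], positions[t[0]]))

    def members_in_span(iv):
        """All panel markers inside the interval, for the mean-LD rule."""
        idx = np.where((chroms == iv["chrom"])
                       & (positions >= iv["start"])
                       & (positions <= iv["end"]))[0]
        return idx

    def should_merge(a, b) -> bool:
        if a["chrom"] != b["chrom"]:
            return False
        if a["start"] <= b["end"] and b["start"] <= a["end"]:
            return True
        pa, pb = peak(a)[0], peak(b)[0]
        if abs(int(positions[pa]) - int(positions[pb])) >= max_peak_distance:
            return False
        ma, mb = members_in_span(a), members_in_span(b)
        vals = [ld_func(int(u), int(v)) for u in ma for v in mb]
        return bool(np.mean(vals) > mean_ld)

    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(range(len(intervals)), 2):
            if should_merge(intervals[a], intervals[b]):
                ia, ib = intervals[a], intervals[b]
                merged = {"chrom": ia["chrom"],
                          "start": min(ia["start"], ib["start"]),
                          "end": max(ia["end"], ib["end"]),
                          "snps": ia["snps"] + ib["snps"]}
                intervals = [iv for j, iv in enumerate(intervals)
                             if j not in (a, b)] + [merged]
                changed = True
                break

    intervals.sort(key=lambda iv: (iv["chrom"], iv["start"]))
    out = []
    for num, iv in enumerate(intervals, start=1):
        snps = sorted(set(iv["snps"]), key=lambda t: positions[t[0]])
        lead_idx, lead_p = peak(iv)
        out.append(HQTL(id=f"{id_prefix}{num}", chromosome=iv["chrom"],
                        start_bp=iv["start"], end_bp=iv["end"],
                        members=[panel.marker_id[k] for k, _ in snps],
                        lead=panel.marker_id[lead_idx], lead_p=lead_p,
                        _member_pos={panel.marker_id[k]: int(positions[k])
                                     for k, _ in snps}))
    return out


def hqtl_pve(sigma2_h: float, delta_h: float, sigma2: dict[str, float],
             sigma2_eps: float, deltas: dict[str, float]) -> float:
    """Proportion of phenotypic variance explained by one hQTL.

    PVE = Delta_i s2_h / (Delta_i s2_h + sum_* Delta_* s2_* + s2_eps), with
    the Delta constants converting trace-normalized variance components
    into variance explained.  Inputs come from refitting the alternative
    model at the hQTL's lead SNP.
    """
    vals = [sigma2_h, delta_h, sigma2_eps] + list(sigma2.values())
    if any(v < 0 for v in vals):
        raise ScanError("variance components and Delta constants must be >= 0")
    num = delta_h * sigma2_h
    denom = num + sum(deltas[k] * sigma2[k] for k in sigma2) + sigma2_eps
    if denom <= 0:
        raise ScanError("total variance is zero")
    return float(num / denom)


def hqtl_pve_at_lead(lead_index: int, codings: CodingMatrices,
                     transform: MPHTransform, kernels: KernelSet,
                     null: FittedNull, y: np.ndarray,
                     X: np.ndarray | None = None) -> float:
    """Refit the alternative model at a lead SNP and return its PVE.

    Under P3D the refit profiles delta = sigma2_h / sigma2_eps with the
    background ratios frozen; background components are recovered as
    r_* sigma2_eps.
    """
    H = heterosis_kernel(lead_index, codings, transform,
                         S=pair_cross_products(codings))
    t = marker_lr_test(H, null, y, X=X)
    sigma2 = {k: null.ratios[k] * t.sigma2_eps for k in null.ratios}
    return hqtl_pve(t.sigma2_h, H.delta, sigma2, t.sigma2_eps, kernels.delta)


def scan_components(mode: str, codings: CodingMatrices,
                    transform: MPHTransform, panel: MarkerPanel,
                    null: FittedNull, y: np.ndarray,
                    focal: int | None = None, X: np.ndarray | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Follow-up Wald scans for fixed genetic component effects.

    ``mode='dominance'`` tests the dominance effect of every marker
    (one row each); ``mode='epistasis'`` tests the four digenic effect
    families (aa / ad / da / dd) of a focal marker against every other
    marker (four rows per partner).  P-values are Holm-adjusted at
    ``alpha``.
    """
    from hetscan.lmm import LMMError
    rows = []
    if mode == "dominance":
        for i in range(panel.n_markers):
            rec = {"effect": "d_i", "marker_id": panel.marker_id[i],
                   "partner_id": None, "chrom": panel.chromosome[i],
                   "pos": int(panel.position_bp[i])}
            try:
                res = wald_component_test("dominance", i, None, codings,
                                          transform, null, y, X=X)
                rec.update(estimate=res.estimate, W=res.statistic,
                           p=res.pvalue, status="ok")
            except LMMError as exc:
                logger.warning("dominance test %s failed: %s",
                               panel.marker_id[i], exc)
                rec.update(estimate=np.nan, W=np.nan, p=np.nan,
                           status=f"failed: {exc}")
            rows.append(rec)
    elif mode == "epistasis":
        if focal is None or not 0 <= focal < panel.n_markers:
            raise ScanError("epistasis mode requires a valid focal marker index")
        for j in range(panel.n_markers):
            if j == focal:
                continue
            for fam in ("aa", "ad", "da", "dd"):
                rec = {"effect": WALD_FAMILY_LABELS[fam],
                       "marker_id": panel.marker_id[focal],
                       "partner_id": panel.marker_id[j],
                       "chrom": panel.chromosome[j],
                       "pos": int(panel.position_bp[j])}
                try:
                    res = wald_component_test(fam, focal, j, codings,
                                              transform, null, y, X=X)
                    rec.update(estimate=res.estimate, W=res.statistic,
                               p=res.pvalue, status="ok")
                except LMMError as exc:     # degenerate or collinear pair
                    logger.warning("component %s(%s, %s) failed: %s", fam,
                                   panel.marker_id[focal],
                                   panel.marker_id[j], exc)
                    rec.update(estimate=np.nan, W=np.nan, p=np.nan,
                               status=f"failed: {exc}")
                rows.append(rec)
    else:
        raise ScanError(f"unknown mode {mode!r}: use 'dominance' or 'epistasis'")
    df = pd.DataFrame(rows)
    ok = (df["status"] == "ok").to_numpy()
    p_holm = np.full(len(df), np.nan)
    if ok.any():
        p_holm[ok] = holm_adjust(df.loc[ok, "p"].to_numpy())
    df["p_holm"] = p_holm
    df["significant"] = ok & (df["p_holm"] < alpha)
    return df
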