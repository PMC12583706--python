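"""Synthetic hybrid populations and the five-scenario MPH phenotype simulator.

The population generator emulates a factorial crossing design between
inbred female and male lines: per marker a reference-allele frequency is
drawn uniformly over the MAF-respecting range and parent codes are sampled
in {0, 2}, with rejection until the realized parental MAF clears the
threshold; hybrids are sampled without replacement from the female x male
factorial.

The phenotype simulator reproduces a stated architecture: a single
heterotic QTL whose net effect -- built from a dominance term and/or
digenic interactions with one marker on each of a scenario-dependent
number of other chromosomes -- explains 2.5% of phenotypic variance, on
top of polygenic background effects drawn from the four background kernels
(unit variance components) and residuals with covariance T T'.  Effect
sizes are solved exactly from the per-effect PVE targets; because the
coefficient vectors covary, the realized QTL PVE is only hit up to
tolerance, and the interactor set is resampled until it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from hetscan.kernels import KernelSet
from hetscan.popdata import (CodingMatrices, MarkerPanel, MPHTransform,
                             Pedigree, PopulationGenotypes, build_codings,
                             build_mph_transform, infer_hybrid_genotypes)

__all__ = [
    "SimScenario", "SimDataset", "PowerReport", "generate_population",
    "MPHSimulator", "simulate_mph", "simulate_null", "estimate_power_fpr",
    "heterozygosity_association", "theoretical_speed_ratio",
]


class SimulationError(ValueError):
    """Raised for infeasible simulation settings."""


#: interactor count, per-effect PVE and dominance flag for the five
#: architectures: s1 = 20 x 0.5% epistatic; s2 = 5 x 2%; s3 = dominance +
#: 19 x 0.5%; s4 = dominance + 4 x 2%; s5 = dominance only at 2.5%.
_SCENARIO_TABLE = {
    1: (20, 0.005, False),
    2: (5, 0.02, False),
    3: (19, 0.005, True),
    4: (4, 0.02, True),
    5: (0, 0.025, True),
}


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated heterotic-QTL architecture."""

    id: int
    n_interactors: int
    per_effect_pve: float
    include_dominance: bool
    hqtl_pve: float = 0.025
    heritability: float = 0.5
    pve_tolerance: float = 0.001      # absolute, on the proportion
    max_resample: int = 1000

    @classmethod
    def from_id(cls, scenario_id: int, **overrides) -> "SimScenario":
        if scenario_id not in _SCENARIO_TABLE:
            raise SimulationError(f"unknown scenario {scenario_id}; choose 1-5")
        n_int, pve, dom = _SCENARIO_TABLE[scenario_id]
        return cls(id=scenario_id, n_interactors=n_int, per_effect_pve=pve,
                   include_dominance=dom, **overrides)


@dataclass
class SimDataset:
    """One simulated MPH dataset with its full ground truth."""

    y: np.ndarray
    hqtl_index: int
    interactors: list[tuple[int, str]]     # (marker index, family)
    effects: dict[str, float]              # label -> effect size x
    coefficients: dict[str, np.ndarray]    # label -> coefficient vector c_x
    V_t: float
    sigma2_eps: float
    h: np.ndarray
    background: np.ndarray
    residual: np.ndarray
    realized_pve: float
    n_attempts: int
    seed: int | None
    scenario: SimScenario | None

    @property
    def heritability_parameter(self) -> float:
        """1 - sigma2_eps / V_t: the construction heritability."""
        return 1.0 - self.sigma2_eps / self.V_t


@dataclass
class PowerReport:
    """Marker-level power and false-positive rate over replicates."""

    power: float
    fpr: float
    n_replicates: int
    n_detected: int
    n_false_positives: int
    n_null_markers: int


def generate_population(n_parents: int = 90, n_hybrids: int = 1000,
                        n_markers: int = 5000, n_chromosomes: int = 21,
                        maf_range: tuple[float, float] = (0.05, 0.5),
                        n_females: int | None = None,
                        chromosome_length: int = 600_000_000,
                        seed: int | None = None,
                        ) -> tuple[PopulationGenotypes, MarkerPanel, Pedigree]:
    """Generate an inbred parent panel and a factorial hybrid population.

    Defaults mirror a reduced hybrid wheat panel: 90 parents (75 females,
    15 males by the same 5:1 split), 1000 hybrids, 5000 biallelic markers
    with MAF >= 0.05 spread over 21 chromosomes.  Fully reproducible from
    ``seed``.
    """
    if n_parents < 4:
        raise SimulationError("need at least 4 parents")
    lo, hi = maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise SimulationError(f"invalid MAF range {maf_range}")
    if n_females is None:
        n_females = max(2, round(n_parents * 75 / 90))
    n_males = n_parents - n_females
    if n_males < 2:
        raise SimulationError("need at least 2 male parents")
    if n_females * n_males < n_hybrids:
        raise SimulationError(
            f"factorial {n_females} x {n_males} = {n_females * n_males} "
            f"cannot yield {n_hybrids} distinct crosses")
    rng = np.random.default_rng(seed)

    codes = np.empty((n_parents, n_markers))
    freq = np.empty(n_markers)
    for k in range(n_markers):
        while True:    # rejection: realized parental MAF must clear the bound
            q = rng.uniform(lo, 1.0 - lo)
            col = 2.0 * (rng.random(n_parents) < q)
            p_hat = col.mean() / 2.0
            if lo <= min(p_hat, 1 - p_hat):
                break
        codes[:, k] = col
        freq[k] = col.mean() / 2.0

    per_chrom = np.array_split(np.arange(n_markers), n_chromosomes)
    chroms, positions = [], np.empty(n_markers, dtype=np.int64)
    for c, idx in enumerate(per_chrom, start=1):
        chroms += [f"chr{c}"] * len(idx)
        pos = np.sort(rng.choice(chromosome_length, size=len(idx),
                                 replace=False)) + 1
        positions[idx] = pos

    female_ids = [f"F{i + 1:03d}" for i in range(n_females)]
    male_ids = [f"M{i + 1:03d}" for i in range(n_males)]
    cross = [(f, m) for f in female_ids for m in male_ids]
    pick = rng.choice(len(cross), size=n_hybrids, replace=False)
    ped = Pedigree(hybrid_id=[f"H{i + 1:04d}" for i in range(n_hybrids)],
                   parent1_id=[cross[c][0] for c in pick],
                   parent2_id=[cross[c][1] for c in pick])
    pop = infer_hybrid_genotypes(female_ids + male_ids, codes, ped)
    panel = MarkerPanel([f"snp{k + 1:05d}" for k in range(n_markers)],
                        chroms, positions, freq)
    return pop, panel, ped


class MPHSimulator:
    """Draws MPH phenotypes for a fixed population under a scenario.

    Precomputes the eigen-factorizations of the four background kernels
    and the sparse MPH transform, so repeated replicates are cheap.
    """

    def __init__(self, codings: CodingMatrices, transform: MPHTransform,
                 kernels: KernelSet, panel: MarkerPanel):
        self.codings = codings
        self.transform = transform
        self.kernels = kernels
        self.panel = panel
        self._factors = {}
        for name, K in kernels.kernels.items():
            w, U = np.linalg.eigh(K)
            self._factors[name] = U * np.sqrt(np.clip(w, 0.0, None))
        self._chrom = np.asarray(panel.chromosome)

    # -- component coefficient vectors -------------------------------------
    def _coef(self, family: str, i: int, j: int | None) -> np.ndarray:
        """Full MPH-scale contrast of one component effect.

        This is the vector multiplying the effect in the underlying trait
        model (T l_i for dominance, T(m_i o m_j) etc. for the epistatic
        families) and the basis of the per-effect PVE: an interaction's
        contribution to the phenotype carries the full contrast, and the
        1/2 enters only when the heterotic effect of marker i is assembled,
        because each pairwise interaction is split between the two loci it
        involves.
        """
        T = self.transform.T
        M_A, M_D = self.codings.M_A, self.codings.M_D
        if family == "d":
            return np.asarray(T @ M_D[:, i])
        m_i, l_i = M_A[:, i], M_D[:, i]
        m_j, l_j = M_A[:, j], M_D[:, j]
        prod = {"aa": m_i * m_j, "ad": m_i * l_j,
                "da": l_i * m_j, "dd": l_i * l_j}[family]
        return np.asarray(T @ prod)

    def _background(self, rng: np.random.Generator) -> np.ndarray:
        n = self.kernels.n
        u = np.zeros(n)
        for name in self.kernels.names:
            u += self._factors[name] @ rng.standard_normal(n)
        return u

    def simulate(self, scenario: SimScenario | int,
                 seed: int | None = None,
                 rng: np.random.Generator | None = None,
                 hqtl_index: int | None = None,
                 max_hqtl_redraws: int = 0) -> SimDataset:
        """One simulated dataset under the scenario's stated architecture.

        Steps: (1) background effects from the four kernels with unit
        variance components fix the total variance V_t = S(u) / 0.475;
        (2) the heterotic QTL and one interactor on each of the required
        other chromosomes are sampled, families assigned uniformly, effect
        sizes solved from the per-effect PVE, and the interactor set is
        resampled until the realized QTL PVE S(h)/V_t is within tolerance
        of the target; (3) residuals are drawn with variance 0.5 V_t and
        covariance T T'; (4) y = h + u + eps.

        If the resample cap is exhausted and ``max_hqtl_redraws`` > 0, a
        fresh hQTL marker is drawn and the loop restarts: for a small
        fraction of markers the achievable PVE range simply excludes the
        target, and a study needs an accepted dataset, not that marker.
        A user-supplied ``hqtl_index`` is never redrawn.
        """
        if isinstance(scenario, int):
            scenario = SimScenario.from_id(scenario)
        if rng is None:
            rng = np.random.default_rng(seed)
        u = self._background(rng)
        V_t = float(np.var(u, ddof=1) / (scenario.heritability - scenario.hqtl_pve))
        p = self.panel.n_markers
        all_chroms = list(dict.fromkeys(self.panel.chromosome))
        if scenario.n_interactors > len(all_chroms) - 1:
            raise SimulationError(
                f"scenario needs {scenario.n_interactors} interactor "
                f"chromosomes but only {len(all_chroms) - 1} are available")

        fixed_qtl = hqtl_index is not None
        redraws = 0
        while True:
            i = hqtl_index if fixed_qtl else int(rng.integers(p))
            other_chroms = [c for c in all_chroms if c != self._chrom[i]]

            records_fixed = []
            if scenario.include_dominance:
                c_d = self._coef("d", i, None)
                v = float(np.var(c_d, ddof=1))
                if v <= 0:
                    raise SimulationError(
                        f"hQTL marker {i} has no dominance variation")
                x_d = float(np.sqrt(V_t * scenario.per_effect_pve / v))
                records_fixed.append(("d", None, c_d, x_d))

            best_gap, best_pve = np.inf, np.nan
            accepted = False
            for attempt in range(1, scenario.max_resample + 1):
                records = list(records_fixed)
                ok = True
                if scenario.n_interactors:
                    chosen = rng.choice(len(other_chroms),
                                        size=scenario.n_interactors,
                                        replace=False)
                    for ci in chosen:
                        on_chrom = np.where(
                            self._chrom == other_chroms[ci])[0]
                        j = int(rng.choice(on_chrom))
                        family = str(rng.choice(["aa", "ad", "da", "dd"]))
                        c = self._coef(family, i, j)
                        v = float(np.var(c, ddof=1))
                        if v <= 0:
                            ok = False
                            break
                        x = float(np.sqrt(V_t * scenario.per_effect_pve / v))
                        records.append((family, j, c, x))
                if not ok:
                    continue
                h = np.zeros(self.kernels.n)
                for family, _, c, x in records:
                    h += c * x if family == "d" else 0.5 * c * x
                pve = float(np.var(h, ddof=1) / V_t)
                gap = abs(pve - scenario.hqtl_pve)
                if gap < best_gap:
                    best_gap, best_pve = gap, pve
                if gap <= scenario.pve_tolerance:
                    accepted = True
                    break
            if accepted:
                break
            if fixed_qtl or redraws >= max_hqtl_redraws:
                raise SimulationError(
                    f"could not hit the target QTL PVE "
                    f"{scenario.hqtl_pve:.3%} within "
                    f"{scenario.max_resample} resamples "
                    f"(closest achieved: {best_pve:.4%})")
            redraws += 1

        sigma2_eps = (1.0 - scenario.heritability) * V_t
        eps = np.asarray(self.transform.T @ rng.standard_normal(
            self.transform.T.shape[1])) * np.sqrt(sigma2_eps)
        y = h + u + eps

        effects, coefficients, interactors = {}, {}, []
        for family, j, c, x in records:
            label = "d" if family == "d" else f"{family}_{j}"
            effects[label] = x
            coefficients[label] = c
            if family != "d":
                interactors.append((j, family))
        return SimDataset(y=y, hqtl_index=i, interactors=interactors,
                          effects=effects, coefficients=coefficients,
                          V_t=V_t, sigma2_eps=sigma2_eps, h=h, background=u,
                          residual=eps, realized_pve=pve, n_attempts=attempt,
                          seed=seed, scenario=scenario)

    def simulate_null(self, seed: int | None = None,
                      rng: np.random.Generator | None = None) -> SimDataset:
        """Background-plus-residual phenotype with no heterotic QTL."""
        if rng is None:
            rng = np.random.default_rng(seed)
        u = self._background(rng)
        V_t = float(np.var(u, ddof=1) / 0.475)
        sigma2_eps = 0.5 * V_t
        eps = np.asarray(self.transform.T @ rng.standard_normal(
            self.transform.T.shape[1])) * np.sqrt(sigma2_eps)
        n = self.kernels.n
        return SimDataset(y=u + eps, hqtl_index=-1, interactors=[],
                          effects={}, coefficients={}, V_t=V_t,
                          sigma2_eps=sigma2_eps, h=np.zeros(n), background=u,
                          residual=eps, realized_pve=0.0, n_attempts=0,
                          seed=seed, scenario=None)


def simulate_mph(pop: PopulationGenotypes, panel: MarkerPanel,
                 transform: MPHTransform, kernels: KernelSet,
                 scenario: SimScenario | int, seed: int | None = None,
                 ) -> SimDataset:
    """Convenience wrapper around :class:`MPHSimulator` for a single draw."""
    codings = build_codings(pop, panel)
    sim = MPHSimulator(codings, transform, kernels, panel)
    return sim.simulate(scenario, seed=seed)


def simulate_null(pop: PopulationGenotypes, panel: MarkerPanel,
                  transform: MPHTransform, kernels: KernelSet,
                  seed: int | None = None) -> SimDataset:
    """Convenience wrapper: one phenotype draw with no heterotic QTL."""
    codings = build_codings(pop, panel)
    sim = MPHSimulator(codings, transform, kernels, panel)
    return sim.simulate_null(seed=seed)


def estimate_power_fpr(detected: list[np.ndarray], truth: list[int],
                       ) -> PowerReport:
    """Marker-level power and FPR from per-replicate significance flags.

    ``detected[r]`` is the boolean significance vector over all markers in
    replicate r; ``truth[r]`` the index of the simulated QTL.  Power is the
    proportion of replicates whose true marker is significant; FPR is the
    proportion of null markers called significant, averaged over
    replicates.  Criteria are marker-based, not region-based.
    """
    if len(detected) != len(truth):
        raise SimulationError("detected and truth have different lengths")
    if not detected:
        raise SimulationError("no replicates")
    n_rep = len(detected)
    hits = 0
    fp_rates = []
    n_fp_total = 0
    for det, t in zip(detected, truth):
        det = np.asarray(det, dtype=bool)
        if not 0 <= t < det.size:
            raise SimulationError(f"truth index {t} out of range")
        hits += int(det[t])
        null_mask = np.ones(det.size, dtype=bool)
        null_mask[t] = False
        n_fp = int(det[null_mask].sum())
        n_fp_total += n_fp
        fp_rates.append(n_fp / null_mask.sum())
    return PowerReport(power=hits / n_rep, fpr=float(np.mean(fp_rates)),
                       n_replicates=n_rep, n_detected=hits,
                       n_false_positives=n_fp_total,
                       n_null_markers=int(null_mask.sum()))


def heterozygosity_association(heterozygosity: np.ndarray,
                               detected: np.ndarray,
                               ) -> tuple[np.ndarray, float]:
    """Association between QTL heterozygosity and detection (Fisher exact).

    QTL are split at heterozygosity > 0.5 (exactly 0.5 goes to the lower
    class) and cross-tabulated against detection; returns the 2x2 table
    [[high & detected, high & missed], [low & detected, low & missed]] and
    the two-sided Fisher exact p-value.
    """
    het = np.asarray(heterozygosity, dtype=float)
    det = np.asarray(detected, dtype=bool)
    if het.shape != det.shape:
        raise SimulationError("heterozygosity and detection flags differ in length")
    high = het > 0.5
    table = np.array([[int((high & det).sum()), int((high & ~det).sum())],
                      [int((~high & det).sum()), int((~high & ~det).sum())]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise SimulationError("association undefined: empty margin in the 2x2 table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def theoretical_speed_ratio(p: float, n: float, t: float) -> float:
    """Expected runtime advantage p / (t n) of the one-dimensional scan.

    The exhaustive pairwise alternative costs O(n^2 p^2) while the
    one-dimensional scan costs O(t n^3 p) for t solver iterations, so their
    ratio is approximately p / (t n).
    """
    if p <= 0 or n <= 0 or t <= 0:
        raise SimulationError("p, n and t must all be positive")
    return float(p) / (float(t) * float(n))
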