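# hetscan

One-dimensional mixed-model scans for **heterotic QTL** in hybrid crop
populations.

Mid-parent heterosis (MPH) — the amount by which a hybrid outperforms the
average of its two inbred parents — is driven by dominance and by digenic
epistatic interactions. Mapping its genetic basis by testing every marker
pair is quadratic in marker count and infeasible for whole-genome
sequencing panels. `hetscan` instead tests, for each marker i, its **net
heterotic effect**: the dominance effect d_i together with all aa/ad/da/dd
interactions between i and the rest of the genome, collapsed into a single
random vector

    h_i ~ N(0, H_i σ²_h),   H_i = Z_i Z_i′ / c_i,

where the n×(4p−3) design Z_i holds the MPH-scale contrasts T l_i and
½T(m_i∘m_j), ½T(m_i∘l_j), ½T(l_i∘m_j), ½T(l_i∘l_j) for all j ≠ i. The
per-marker test compares

    y_MPH = Xα + g_D + g_AA + g_AD + g_DD + ε            (null)
    y_MPH = h_i + Xα + g_D + g_AA + g_AD + g_DD + ε      (alternative)

by a restricted likelihood-ratio test of H₀: σ²_h = 0 against the boundary
null ½χ²₀ + ½χ²₁. The background terms g_* carry trace-normalized
dominance/epistasis kernels built via Hadamard identities (never
materializing the O(p²)-column designs), residuals have the covariance
TT′ induced by the MPH transformation T, and the background variance
ratios are frozen after one null fit (P3D), so a genome scan solves one
cheap one-dimensional profile per marker. This makes the scan roughly
p/(t·n) times faster than an exhaustive pairwise search (t = REML
iterations).

The package also provides: Bonferroni–Holm control, LD-based merging of
significant SNPs into QTL intervals with Δ-weighted PVE estimates, Wald
tests for individual dominance/epistatic component effects, and a
simulator of factorial-cross hybrid populations with five heterosis
architectures for power and false-positive-rate studies.

## Worked example

```python
from hetscan import (SimScenario, background_kernels, build_codings,
                     build_mph_transform, generate_population, MPHSimulator,
                     profile_null, reml_multikernel, scan_heterotic)

pop, panel, ped = generate_population(n_parents=90, n_hybrids=300,
                                      n_markers=300, n_chromosomes=21, seed=11)
codings = build_codings(pop, panel)
transform = build_mph_transform(ped, pop.combined_ids)
kernels = background_kernels(codings, transform)

# a strong dominance-driven heterotic QTL (20% PVE) for illustration
scenario = SimScenario(id=5, n_interactors=0, per_effect_pve=0.20,
                       include_dominance=True, hqtl_pve=0.20)
sim = MPHSimulator(codings, transform, kernels, panel)
ds = sim.simulate(scenario, seed=101)
print(f"simulated hQTL: {panel.marker_id[ds.hqtl_index]}, "
      f"realized PVE {ds.realized_pve:.4f}")

fit = reml_multikernel(ds.y, kernels)
null = profile_null(fit, kernels)
result = scan_heterotic(codings, transform, panel, null, ds.y, alpha=0.05)
top = result.table.nsmallest(3, "p")[["marker_id", "lr", "p", "p_holm"]]
print(top.to_string(index=False))
```

Output:

```
simulated hQTL: snp00198, realized PVE 0.2000
marker_id        lr        p   p_holm
 snp00198 13.808543 0.000101 0.030362
 snp00039  4.876708 0.013611 1.000000
 snp00300  4.763976 0.014531 1.000000
```

The simulated QTL tops the scan: its LR statistic of 13.8, referred to the
½χ²₀ + ½χ²₁ boundary null, gives p ≈ 1.0×10⁻⁴, which survives Holm
correction across 300 markers (adjusted p = 0.030 < 0.05) while the
nearest competitor does not come close. At the study architectures (2.5%
QTL PVE) this separation requires the full population and marker scale;
300 hybrids serve to illustrate the mechanics.

A CLI mirrors the library: `hetscan scan`, `hetscan merge`,
`hetscan components --mode {dominance,epistasis}`, `hetscan simulate`
(tab-separated outputs plus a JSON run manifest).

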