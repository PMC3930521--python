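# benguela

Population-genetics pipeline for testing whether an oceanographic barrier has
split a coastal marine fish into two anciently isolated populations — the
situation typified by warm-temperate species (e.g. the sciaenid
*Atractoscion aequidens*) whose range is interrupted by the cold Benguela
Current and its perennial Lüderitz upwelling cell. The package is aimed at
molecular ecologists who have a mitochondrial control-region alignment, a
diploid microsatellite genotype table, and a two-level sampling design
(sites nested in regions), and who want the full marker-based argument in
one reproducible run.

## What it computes

**Mitochondrial DNA.** Haplotype collapsing and diversity (h, π), variable /
parsimony-informative sites and fixed inter-regional differences, K80
distances, hierarchical AMOVA with Φ-statistics

  Φ_ST = (σ²ₐ+σ²ᵦ)/σ²ₜ,  Φ_CT = σ²ₐ/σ²ₜ,  Φ_SC = σ²ᵦ/(σ²ᵦ+σ²꜀),

pairwise Φ_ST with permutation tests, Tajima's D, Fu's F_S (Ewens sampling
probability of the observed haplotype count), the sudden-expansion mismatch
fit (τ, θ₀, θ₁, SSD with parametric bootstrap), expansion-time conversion
τ = 2ut, and median-joining haplotype networks with haplogroup detection.

**Microsatellites.** Na, allelic richness (rarefaction), unbiased H_E, H_O,
F_IS, Monte-Carlo exact HWE and linkage tests, null-allele EM,
Weir–Cockerham θ (F_ST) with individual-level permutation tests, Jost's
D_est (Nei–Chesser estimators, harmonic mean over loci), a drift-simulation
power analysis, and Holm's sequential Bonferroni correction.

**Synthetic data.** A built-in structured coalescent (two demes, split time,
migration, transition-biased finite-sites mutation), a single-population
sudden-expansion simulator, and a hierarchical-drift microsatellite
generator, so every stage can be exercised and calibrated without any
external dataset. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

Simulate a study-like dataset (deep two-population split, 144 CR sequences
over 8 sites, 393 microsatellite genotypes at 8 loci) and run the mtDNA
stages:

```bash
benguela simulate --preset study-like --out-dir demo --seed 4
benguela run-all --fasta demo/sequences.fasta --popmap demo/popmap.tsv \
    --permutations 1000 --bootstraps 200 --seed 1 --out-dir demo_run
```

which prints

```
wrote synthetic dataset to demo
bundle written to demo_run (config hash 9c2417d62a35a4ee)
```

(about 50 s on one core) and leaves TSV tables under `demo_run/tables/`.
For this seed, `demo_run/meta/run.json` contains

```
"amova_mtdna_phi": {"phi_st": 0.917, "phi_ct": 0.913, "phi_sc": 0.047,
                    "p_values": {"phi_st": 0.000999, "phi_ct": 0.033, ...}}
"network": {"n_median_vectors": 5, "total_length": 59,
            "n_haplogroups": 2, "max_bridge_steps": 15}
```

i.e. over 90% of the molecular variance lies between the two regions
(Φ_ST = 0.917; p = 1/1001 at 1,000 permutations — no permuted relabelling
reached the observed value) while populations within regions are
effectively homogeneous (Φ_SC = 0.047, n.s.), and the haplotype network
splits into two haplogroups bridged by 15 mutational steps: the genetic
signature of an old, impermeable barrier. `demo_run/tables/demography.tsv` holds the per-region
neutrality tests and expansion fits, and
`demo_run/tables/pairwise_phist.tsv` the site-level Φ_ST matrix.

Each stage is also exposed as its own subcommand (`diversity`, `phist`,
`amova`, `msat`, `demog`, `network`, `power`, `simulate`); run
`benguela --help` for the full list, or use the library directly
(`benguela.amova_phist.amova`, `benguela.msat_stats.wc_fst`, …).

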