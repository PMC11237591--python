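# nichevol

Eco-evolutionary analysis of microbial **habitat generalists and
specialists** from multi-habitat amplicon (zOTU) count tables.

Microbial taxa differ in niche breadth: generalists persist across many
habitats, specialists are confined to one, and the rest are opportunists.
`nichevol` implements, as one tested pipeline, the analyses this question
requires:

1. **Niche-breadth classification** — three indices per taxon (Levins'
   breadth `B = 1/Σp²`, Shannon breadth `H = −Σp ln p`, occurrence
   frequency `F`) compared against a 95% envelope from a
   margin-preserving permutation null of the whole abundance table.
   A taxon is a generalist only when it exceeds the envelope on **all
   three** indices, a specialist only when it falls below on all three.
   Strict filters then keep generalists in the upper 10th percentile of
   all three indices and specialists with more than 50 total reads.
2. **Beta diversity** — Bray-Curtis and normalised weighted UniFrac
   dissimilarities and the distance-decay regression
   `log(dissimilarity) = β·log(D+1) + c`, whose slope β is the spatial
   turnover rate.
3. **Community assembly** — the five-process partition from two null
   models: the beta nearest-taxon index (βNTI, phylogenetic) and the
   modified Raup-Crick index (RC, taxonomic).  βNTI < −2 → homogeneous
   selection; βNTI > 2 → heterogeneous selection; otherwise RC < −0.95 →
   homogenizing dispersal, RC > 0.95 → dispersal limitation, remainder →
   drift.  Selection processes are deterministic, the rest stochastic.
4. **Co-occurrence networks** — SparCC basis correlations from log-ratio
   variances of compositions (zeros handled by Dirichlet resampling),
   bootstrap edge p-values, thresholding at |R| ≥ 0.6 and p < 0.05,
   greedy modularity modules, Zi–Pi node roles (network hubs Zi ≥ 2.5 &
   Pi ≥ 0.62, module hubs, connectors, peripherals; module hubs +
   connectors = keystone taxa), degree-preserving rewired nulls, and
   stability metrics: 50%-removal experiments, robustness (area under
   the attack-tolerance curve), vulnerability (largest single-node drop
   in global efficiency), functional complementarity and niche overlap
   of interdomain (prokaryote × microeukaryote) networks.
5. **State-dependent diversification (BiSSE)** — joint likelihood of a
   phylogeny and binary tip states (generalist/specialist) with
   state-specific speciation (λ), extinction (μ) and transition (t)
   rates, a two-step constrained/full maximum-likelihood fit compared by
   a χ² likelihood-ratio test (df = 3), and the diversification
   potential `DP = λ + t − μ` per state with its specialist/generalist
   ratio.

Because the analyses are null-model heavy, the package ships a
first-class synthetic-data module (`nichevol.synth`) that generates
habitat-structured count tables with planted generalist/specialist/
background labels, birth–death trees, BiSSE tree+state simulations and
correlation-structured compositions, so every stage is testable without
any sequencing data.

## Worked example

Run the bundled demo (a 150-taxon prokaryote table plus an 80-taxon
microeukaryote table, 90 samples each over 5 habitats × 6 parks):

```bash
nichevol run --demo --out demo_out
```

The run takes well under a minute and writes ~25 TSV/Newick/GraphML
files plus `manifest.json`.  Highlights from the output:

- `prok_niche_profiles.tsv` — 13 generalists, 43 specialists and
  94 opportunists among the 150 taxa, e.g.

  ```
  zotu_id    levins_B  shannon_H  occ_F  total_reads  class
  zotu00001  53.37     4.11       0.80   177          generalist
  zotu00002  16.62     2.85       0.20   524          specialist
  ```

  `levins_B` is measured over the 90 samples, so 90 means perfectly
  even use of every sample and 1 means confinement to a single one.

- `assembly_summary.tsv` — stochastic processes dominate both groups
  (99% of generalist pairs, 98% of specialist pairs), with dispersal
  limitation stronger for specialists (45% vs 33% of pairs) and
  homogeneous selection appearing only among specialists — the
  qualitative pattern expected when specialists are spatially and
  environmentally filtered.

- `bisse_fit.tsv` — on the demo's simulated state tree (true
  λ_g = 1, λ_s = 2) the fit returns λ_g = 1.29, λ_s = 2.10,
  DP_g = 1.44, DP_s = 2.10 (DP ratio 1.46), with the
  likelihood-ratio test χ² = 1.61 (p = 0.66, df = 3) correctly not
  rejecting on a 100-tip tree, where the power to separate six rates
  is limited.

Re-running the same command reproduces every file byte-for-byte; the
manifest records a SHA256 per output and a hash of the resolved
configuration.

The same stages are available as library functions
(`nichevol.niche.null_classify`, `nichevol.assembly.bnti`,
`nichevol.netinfer.sparcc`, `nichevol.evo.bisse_fit`, ...) and as
individual CLI subcommands (`nichevol synth`, `preprocess`, `niche`,
`network`, `run`).

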