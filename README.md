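# ncanet

Dynamic transcriptional regulatory network inference from expression data
and a prior TF–target topology.

Bulk expression profiling measures mRNA abundance, but the activity of a
transcription factor (TF) — the thing that actually drives its targets —
is set post-translationally and is generally **not** proportional to the
TF's own transcript level. `ncanet` reconstructs latent TF activities and
signed regulatory influences across ordered disease stages (control →
incipient → moderate → severe, the staging used for hippocampal
neurodegeneration cohorts) by chaining four stages:

1. **SAM filtering** (`ncanet.preprocess`) — a moderated two-class
   statistic `d_i = (x̄₂ᵢ − x̄₁ᵢ)/(sᵢ + s₀)` with a label-permutation null
   and FDR estimate, to shrink the gene universe per control-vs-stage
   group;
2. **consensus FastICA gene selection** (`ncanet.ica`) — the square ICA
   model `X = A·S` solved by the fixed-point iteration with the
   `tanh(a₁u)` contrast; because the iteration is seeded randomly, it is
   repeated many times and genes recurring among the top |loading| genes
   of some component are selected;
3. **connectivity assembly** (`ncanet.connectivity`) — a curated TF→target
   table is intersected with the selected genes, prolific TFs retained,
   and the 0/1 initial connectivity matrix C₀ built and screened against
   the network-component-analysis uniqueness criteria;
4. **network component analysis** (`ncanet.nca`) — the bilinear model

   ```
   [E] = [C][P] + Γ,   C ∈ Z₀
   ```

   with `[E]` (N genes × M samples) the expression, `[C]` (N × L) the
   control strengths constrained to the prior zero pattern Z₀, and `[P]`
   (L × M) the TF activities, fitted per stage by a two-step alternating
   least squares (`min ‖E − CP‖_F`), each half-step an exact constrained
   least-squares solve. Stage networks and TF-activity trajectories are
   assembled and exported by `ncanet.network`.

Every stage is also exposed as a scikit-learn estimator (`SAMSelector`,
`ConsensusICASelector`, `NetworkComponentAnalysis`) that composes with
sklearn pipelines, and `ncanet.synthetic` generates all three kinds of
ground-truth data (bilinear regulatory datasets, multi-stage cohorts with
planted differentially expressed genes, independent-source mixtures), so
the whole chain is verified by parameter recovery without any download.

## Worked example

```python
import numpy as np
import ncanet as nn

# the packaged curated TF->target table (10 hippocampal TFs)
interactions = nn.read_interaction_table(nn.bundled_interaction_table())
pattern = nn.build_initial_connectivity(interactions)
print(f"{pattern.n_tfs} TFs, {pattern.n_genes} target genes, "
      f"{int(pattern.support.sum())} interactions")
report = nn.check_nca_identifiability(pattern, n_samples=7)
print(f"full column rank: {report.full_column_rank}, "
      f"samples sufficient: {report.samples_sufficient}, "
      f"unique up to scaling: {report.overall}")

# parameter recovery on synthetic ground truth
topo = nn.make_identifiable_topology(n_genes=40, n_tfs=5,
                                     targets_per_tf=8, seed=0).regulated()
ds = nn.generate_regulatory_dataset(topo, n_samples=20, noise_sd=0.1, seed=1)
res = nn.nca_decompose(ds.expression, topo, nn.NCAConfig(n_restarts=3, seed=2))
corr = np.median([abs(np.corrcoef(res.tfa.values[j], ds.true_tfa[j])[0, 1])
                  for j in range(topo.n_tfs)])
print(f"converged: {res.converged} after {res.n_iter} iterations, "
      f"residual {res.final_residual:.3f}")
print(f"median |corr(estimated TFA, true TFA)| = {corr:.3f}")
```

prints

```
10 TFs, 81 target genes, 161 interactions
full column rank: True, samples sufficient: False, unique up to scaling: False
converged: True after 14 iterations, residual 1.964
median |corr(estimated TFA, true TFA)| = 0.999
```

The first two lines are the real-study configuration: with only 7 samples
per stage against 10 TFs, the activity matrix cannot have full row rank,
so the decomposition is *not* unique up to scaling — `ncanet` runs it
anyway with a prominent warning, exactly because this regime occurs in
practice. The last two lines show that on data actually generated by the
bilinear model with an identifiable topology, the alternating solver
recovers the planted TF activities almost perfectly at noise SD 0.1.

A command-line interface covers the same chain end to end:

```sh
ncanet simulate regulatory --n-genes 40 --n-tfs 5 --seed 0 --out-dir sim/
ncanet filter sam --expression expr.tsv --labels labels.tsv --target-n 200 --out sam.tsv
ncanet ica-select --expression filtered.tsv --runs 50 --top-k 50 --out sel.tsv
ncanet connect build --selected-genes sel.tsv --min-targets 13 --out-dir conn/
ncanet nca run --expression expr.tsv --pattern conn/connectivity.tsv --stages labels.tsv --out-dir nca/
ncanet run-all --seed 1 --out-dir study/   # the whole pipeline on a synthetic study
```

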