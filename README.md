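# paralogdiv

Transcriptional vs translational divergence of duplicated genes: analysis
statistics and in-silico post-duplication evolution.

After a gene duplication, the two copies start with identical expression
and drift apart. Measured within-pair divergence in budding yeast is
larger in transcription rate β_m (mRNA/h) than in translation rate β_p
(proteins per mRNA per h). `paralogdiv` implements, end to end on
synthetic yeast-like data, the machinery needed to quantify that pattern
and to test two explanations for it:

- a **precision-economy trade-off**: transcription-heavy expression is
  less noisy but costs more mRNA synthesis, so transcriptional and
  translational changes have different fitness consequences;
- a **larger mutational target size** for transcription: mutations simply
  hit β_m more often than β_p.

The package provides (i) the molecular rate calculus (RPKM shares →
rates → protein abundance p = β_m β_p / (α_m α_p)); (ii) within-pair
divergence statistics — log2-fold changes, the divergence ratio
D = log2[(max β_m/min β_m)/(max β_p/min β_p)], Spearman correlations with
pair-resampling bootstrap CIs, Mann–Whitney/Mood/KS comparisons; (iii)
Monte-Carlo robustness studies of measurement noise, unmodeled mRNA-decay
variation, and the spurious correlations induced by the shared mRNA
abundance in both rate estimates; (iv) parabolic fitness landscapes
W(p) = μ − (μQ/2)(p − p_opt)² with expression noise and transcription
cost, including the derivation of the post-duplication optimum multiple
Δ_opt = 1.87; (v) a sequential-fixation simulator (modified Metropolis
acceptance, P_fix = exp(−2N·ΔlogF) for deleterious mutations) with
normal, skew-normal and correlated-bivariate mutational effects; and
(vi) grid-search assessment of simulations against a reference
divergence pattern. A synthetic-data module generates every input with
known ground truth. See `docs/methods.md` for the model and all
conventions.

## Worked example

```python
import numpy as np
import paralogdiv as pv

# synthetic yeast-like dataset: 4440 genes, 245 WGD + 164 SSD pairs
spec = pv.SyntheticSpec(seed=7)
genes = pv.generate_gene_table(spec)
genes, pairs, truth = pv.generate_paralog_pairs(spec, genes)

# within-pair divergence analysis
div = pv.pair_divergence_table(genes, pairs)
s = pv.summarize_divergence(div, n_boot=2000, rng=1)
print(f"median |log2 fc| beta_m:   {s['median_fc_bm']:.3f}")
print(f"median |log2 fc| beta_p:   {s['median_fc_bp']:.3f}")
print(f"median ratio (bm/bp):      {s['median_ratio_bm_bp']:.2f}")
print(f"transcription-biased:      {100*s['frac_transcription_biased']:.1f}%")

# in-silico evolution under the precision-economy trade-off,
# equal mutational target sizes
cfg = pv.SimulationConfig(model="precision_economy", n_pairs=50,
                          mutation_model=pv.MutationModel(sigma_mut=0.025),
                          reference_fc=np.asarray(truth["fc_p"]), seed=1)
res = pv.run_simulation(cfg, genes)
d = res.divergence_frame()
print(f"rounds to realistic divergence: {res.rounds_used}")
print(f"median |log2 fc|: beta_m {d['fc_bm'].median():.2f}, "
      f"beta_p {d['fc_bp'].median():.2f}, protein {d['fc_p'].median():.2f}")
```

prints

```
median |log2 fc| beta_m:   1.547
median |log2 fc| beta_p:   0.711
median ratio (bm/bp):      2.18
transcription-biased:      73.8%
rounds to realistic divergence: 10778
median |log2 fc|: beta_m 1.29, beta_p 0.10, protein 1.25
```

Reading this: in the synthetic dataset (generated with transcription-
dominant truth), the median transcriptional divergence is ~2.2× the
translational one and ~74% of pairs are transcription-biased. The
simulation then evolves 50 duplicate pairs under selection on cumulative
protein abundance with noise and cost terms; it stops after 10 778
mutation–selection rounds, when the simulated protein-abundance
divergence is statistically indistinguishable (Mood's median test,
p > 0.1) from the reference. Although mutations hit both rates equally
often, the final divergence is almost entirely transcriptional
(median 1.29 vs 0.10 log2 units) — the trade-off alone biases divergence
toward transcription.

A command-line interface mirrors the library:

```sh
paralogdiv synth --seed 7 --out-dir demo/
paralogdiv analyze --genes demo/genes.tsv --pairs demo/pairs.tsv --out-prefix demo/an
paralogdiv simulate --genes demo/genes.tsv --reference demo/an.divergence.tsv \
    --model minimal --sigma-mut 0.025 --ratio 3 --seed 1 --out-prefix demo/sim
paralogdiv assess --run demo/sim.final.tsv --reference demo/an.divergence.tsv \
    --out demo/assess.json
paralogdiv pipeline --out-dir demo/full   # synth -> analyze -> simulate -> assess
```

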