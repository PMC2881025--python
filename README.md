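# mosaic-dna

Mosaic-class analysis of DNA: segmentation of genomic sequence into short
compositional classes with a strand-symmetric hidden Markov model, and
class-enrichment analysis of transcription factor binding sites.

## The problem

Motif scanners flag every place a transcription factor *could* bind, which
drowns real binding sites in false positives.  The sequence that does not
bind is usually modelled crudely — a single background composition.  This
package models the bulk DNA itself: the genome as a mosaic of short classes
(runs of typically tens of bases), each class defined by its dinucleotide
frequencies.  It then asks, for experimentally verified binding sites of
many factors, *which classes the sites fall in* — and separately, which
classes the motif occurrences fall in.  The two distributions differ
sharply: most real sites concentrate in a small "preferred" subset of
classes that holds only about a quarter of genome bases and no excess of
motif matches.  A site's class is therefore informative about binding in a
way the motif itself is not.

## The model

A hidden Markov model where each class is a single state s with

* geometric dwell (mean class length 1/(1 − A[s,s])),
* first-order emissions E[s][y][x] = P(base x | state s, previous base y),
* strand symmetry: states come in pairs with
  E[pair(s)][c(y)][c(x)] = E[s][y][x] (c = base complement) and
  A[pair(i)][pair(j)] = A[i][j], imposed at every EM iteration.

Training follows a replication protocol: several independent Baum–Welch
runs on fresh sequence samples, classes matched across runs in the
composition space (T+A, T+C, T+G) by exact capped assignment over many run
orders, matched classes averaged into a consensus, and a final training
round from the consensus.  Binding sites are assigned to classes by
forward–backward posterior decoding of a ~4 kb window centred on the
motif; class-conditional motif abundance is estimated by scanning
simulated pure-class sequence with an exact-p-value PWM scanner and
apportioning occurrences in proportion to (class base share) × (motifs per
10^7 bases).  See `docs/methods.md` for the full treatment.

## Worked example

Generate a synthetic genome from a known 4-pair mosaic model, plant 2000
motif occurrences with a 75 % bias toward two designated preferred pairs,
and measure where the pipeline says the sites are:

```python
from mosaic import hmm, synthetic, tfbs

cfg = synthetic.GeneratorConfig()          # 4 pairs, 2000 sites, p_pref 0.75
model = synthetic.make_model(cfg)
records, paths = synthetic.generate_genome(
    model, cfg.genome_n_seqs, cfg.genome_seq_len, seed=0)
records, truth, tss = synthetic.plant_sites(records, paths, cfg, model, seed=1)

genome = {r.id: r.sequence for r in records}
tfbs.assign_sites(model, genome, truth.sites, window=4000)
pp = synthetic.preferred_pair_indices(model, cfg)
summary = tfbs.summarize_factor(truth.sites, model, preferred_pairs=pp)
print(f"preferred-class total: {summary.preferred_total:.3f}")
print(f"planting rate:         {cfg.p_pref}")
```

Output:

```
preferred-class total: 0.720
planting rate:         0.75
```

The pipeline recovers the planted enrichment (0.720 vs the 0.75 planting
rate; the realized planted fraction of this draw is 0.747), while the same
preferred pairs hold only 0.286 of genome bases — the enrichment is a
property of the sites, not of the genome composition.

Published per-factor tables (site, motif, TSS-split, low-tag and cell-line
preferred-class proportions for 17 factors) are packaged as fixtures:

```python
from mosaic import stats
r = stats.one_sided_t(stats.load_fixture("table2")["total"], stats.GENOME_PREFERRED)
print(f"t = {r.t:.1f}, p = {r.p:.2g}, 95% lower CL = {r.lower_cl:.3f}")
# t = 13.4, p = 2e-10, 95% lower CL = 0.687
```

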