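# cdgmine

Genome mining of the bacterial **c-di-GMP signaling repertoire**.

The second messenger bis-(3′–5′)-cyclic dimeric GMP (c-di-GMP) governs the
switch between motile and biofilm lifestyles. Its intracellular pool is set
by diguanylate cyclases (DGCs, GGDEF domain) and phosphodiesterases (PDEs,
EAL or HD-GYP domain), and is read out by effectors such as PilZ domain
proteins. Many genomes carry dozens of GGDEF/EAL/HD-GYP genes, but a large
fraction are catalytically *degenerate* — the domain fold is present while
the active site is not. `cdgmine` is for microbiologists who need to turn a
list of annotated domains into a functional prediction: which proteins are
enzymes, which are dead, and which dead ones may still act as c-di-GMP
binding effectors.

## What it computes

**Active-site conservation scoring.** Each candidate domain is globally
aligned (Gotoh affine-gap dynamic programming, BLOSUM62, gap open 10 /
extend 1, deterministic traceback) to a class reference, and the residues
opposite the reference's catalytic positions are read off:

* GGDEF (PleD numbering, 7 sites): D327, K332, N335, D344, D370, K442, R446
* EAL (TBD_1265 numbering, 9 sites): E523, R527, E546, N584, E616, D646,
  D647, E703, Q723
* HD-GYP (Bd1817 numbering, 7 sites): H183, D184, H212, H237, E238 (alt H),
  N265 (alt E), N269 (alt R)

A domain with at most one non-conserved site (gap = not conserved) is
called **active**; proteins are rolled up to DGC / PDE /
hybrid-bifunctional / hybrid-DGC-only / hybrid-PDE-only / degenerate.

**Effector screen.** PilZ domains are scanned for the two c-di-GMP switch
motifs, `RxxxR` followed downstream by `[D/N]zSxxG` (both present and in
order → predicted binder); degenerate GGDEF/EAL proteins are flagged as
effector candidates; orthologs of known effectors are found by best local
hit and percent identity.

**Architecture & orthology.** Domain-architecture strings
(`PAS|GGDEF|EAL`), strict or accessory-tolerant comparison, and orthology
calls requiring identity ≥ threshold (default 25%) plus architecture
conservation.

**RT-qPCR relative expression.** Ct values normalized to the mean of two
reference genes, per-replicate log2 fold changes against the control mean,
a two-sided one-sample t-test, and the significance rule
|log2FC| > 1 and P < 0.05.

**Synthetic data.** A seeded generator produces labeled proteomes (domains
with a controlled number of broken catalytic sites, PilZ domains with
intact or broken motifs, multi-domain architectures) and replicate Ct
tables with injected effects — every stage can be validated against ground
truth. The packaged reference panel consists of synthetic stand-in
sequences that carry the canonical residues at the published positions;
point `load_reference_panel(fasta, sites)` at the public records to run
against a real proteome.

## Worked example

```python
import numpy as np
from cdgmine import (
    load_reference_panel, make_domain_variant, score_site_conservation,
    find_switch_motifs, make_ct_table, relative_expression,
)

panel = load_reference_panel()
model = panel.catalytic["GGDEF"]

# one broken catalytic site: still active under the one-substitution rule
seq, mutated = make_domain_variant(model, 1, rng=np.random.default_rng(7))
v = score_site_conservation(seq, model, protein_id="demo")
print("verdict:", v.conserved_count, "/", v.total_sites, "active =", v.active)
# verdict: 6 / 7 active = True   (site 446 mutated)

# PilZ c-di-GMP switch
pv = find_switch_motifs("MRTKLRAAADWSKKGVVE")
print(pv.rxxxr.match, pv.switch2.match, pv.binder)
# RTKLR DWSKKG True

# qPCR: a ~36-fold induction (log2 effect 5.2) under Ct noise sd 0.2
table = make_ct_table(["pdeA"], [5.2], n_replicates=3, noise_sd=0.2, seed=1)
r = relative_expression(table, "pdeA")
print(f"log2FC = {r.log2_fold_change:.2f}, p = {r.p_value:.2e}, significant = {r.significant}")
# log2FC = 4.96, p = 1.79e-04, significant = True
```

The same pipeline from the shell:

```sh
cdgmine simulate --seed 7 --outdir demo
cdgmine inventory --fasta demo/proteome.fasta --domains demo/domains.tsv --outdir demo/run
```

prints the inventory summary (5 stand-alone DGCs, 3 PDEs, 2 bifunctional
hybrids, 3 degenerate proteins, 3 PilZ-only effectors; 10 of 16 proteins
active) and writes `verdicts.tsv` (site-by-site evidence per domain),
`effectors.tsv`, `architectures.tsv` and `inventory.json`.

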