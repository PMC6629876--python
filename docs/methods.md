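# Methods

## Problem and model

Bacterial c-di-GMP turnover is distributed over many GGDEF (diguanylate
cyclase, DGC), EAL and HD-GYP (phosphodiesterase, PDE) domain proteins,
plus effectors such as PilZ domain proteins. Domain presence alone does not
predict function: a substantial fraction of these domains are degenerate.
`cdgmine` predicts catalytic functionality from **active-site
conservation** against one experimentally characterized reference per
class, and screens effectors by motif content, degeneracy and orthology.

The unit of analysis is an annotated domain (protein id, class, 1-based
inclusive coordinates). Domain location is an input — the package does not
re-implement HMM domain discovery — so the pipeline's scope is "given the
repertoire, predict function".

## Conservation scoring

Each candidate domain is aligned globally to its class reference and the
residues opposite the reference's catalytic positions are compared with
the canonical residue (or its accepted alternates, used at three HD-GYP
positions). The activity rule is a threshold on the count of conserved
sites:

    active  ⇔  conserved_count ≥ total_sites − max_substitutions

with `max_substitutions = 1` by default ("at most one substitution"). This
is deliberately exact-match: no similarity-group credit, because the
reference residue lists name specific catalytic side chains. Two explicit
conventions, both configurable:

* **Gap = substitution.** A catalytic position aligned to a gap counts as
  non-conserved; an absent residue cannot support catalysis.
* **EAL threshold.** The EAL model carries the nine listed catalytic
  residues and the same one-substitution tolerance as the other classes.
  Reports of a ten-residue EAL motif exist; users who prefer a different
  stringency can set `max_substitutions` (0 = strict) at load time.

## Pairwise alignment

Conservation reading requires a *residue correspondence*, so the aligner is
built for determinism rather than search speed:

* Gotoh affine-gap dynamic programming, global (Needleman–Wunsch) for
  reference anchoring and local (Smith–Waterman) for orthology; BLOSUM62;
  gap open 10, extend 1, in matrix units. A gap run of length L costs
  `open + (L−1)·extend` (the first gapped residue pays the opening
  penalty — the same convention as Biopython's `PairwiseAligner` with
  `open_gap_score=-10, extend_gap_score=-1`, against which the kernel is
  cross-checked in the test suite; scores are also verified against
  exhaustive enumeration of alignment paths for short sequences).
* Fixed traceback tie order: diagonal > up (gap in subject) > left (gap in
  query), and first-best-cell selection in local mode, so co-optimal
  alignments always resolve identically and outputs are bit-reproducible.
* Percent identity = identical columns / alignment length (gap columns in
  the denominator), reported to one decimal. This approximates BLASTP
  identity without E-value statistics; on short spurious local hits it can
  stay near 25–30% even for shuffled sequences, which is why orthology
  calls combine identity with architecture conservation rather than
  trusting identity alone.

The choice of single-reference *pairwise* anchoring (rather than a
multiple alignment of all candidates) trades a little sensitivity for
reproducibility: the residue correspondence depends only on the candidate
and the reference, never on the rest of the input set.

## Reference panel

The three catalytic references use the published residue numbering (GGDEF:
PleD; EAL: TBD_1265; HD-GYP: Bd1817) and two PilZ references define the
intact/degenerate switch extremes (PA4608 active, XC1028 inactive). The
**packaged sequences are synthetic stand-ins**: deterministic random
backgrounds with the canonical residues placed at the published positions
(and PilZ motifs embedded or withheld). They preserve the coordinate
system, the scoring semantics and every rule boundary, and make the
package self-contained and testable offline; they are *not* the biological
sequences. `load_reference_panel(fasta, sites)` accepts a panel built from
the public records for analyses of real proteomes, and every model is
self-validated at load (sequence must carry its own canonical residues).

## Effector screen

* **PilZ switch motifs.** `RxxxR` and `[D/N]zSxxG` with `x` any residue.
  `z` is not defined precisely in the source convention; the default is a
  pure wildcard with an option to restrict to hydrophobic residues.
  First-occurrence semantics: the reported second motif is the first one
  starting strictly after the first `RxxxR`; all occurrences are retained.
  Motif order is enforced (the switch is N-terminal in PilZ); inter-motif
  spacing is unconstrained by default with optional min/max bounds.
* **Degenerate effectors.** Any protein with ≥1 GGDEF/EAL domain and no
  active domain keeps the c-di-GMP-contacting fold and is flagged as an
  effector candidate.
* **Orthology.** Best local hit per query; ortholog iff identity ≥
  threshold (default 25%) and, when architectures are supplied,
  architecture conservation (strict token equality, or equality after
  dropping accessory tokens under the relaxed flag).

## qPCR relative expression

Per replicate, ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2); averaging the two
reference Cts is the log-scale equivalent of geometric-mean normalization
of linear quantities, the standard two-reference-gene method. Each treated
replicate is compared to the *mean* control ΔCt (replicates are
independent cultures; there is no natural run pairing):

    log2FC_i = −(ΔCt_treated,i − mean(ΔCt_control))

The gene's log2 fold change is the mean of the replicate values; the
P-value is a two-sided one-sample t-test of those values against 0; the
significance rule is |log2FC| > 1 (more than twofold) **and** P < 0.05.
The twofold bound is interpreted on the log2 scale, matching the
conventional fold-change axis. No multiple-testing correction by default
(the rule is per-gene); Benjamini–Hochberg is available as a flag.
Degenerate zero-variance replicate sets (possible only with noiseless
synthetic data) get p = 0 for a nonzero mean and p = 1 otherwise.

## Synthetic data

The generator emulates exactly the features the pipeline reads, with
ground-truth labels:

* **Domain variants**: copies of a reference with exactly *k* catalytic
  sites mutated to residues outside the allowed set (k = 2 for degenerate
  constructions — one beyond the tolerance), optional off-site mutations
  at a chosen rate, and optional small indels kept > 2 residues from any
  site so labels stay valid.
* **Proteomes**: flank + domain(s) + flank with random flanks (uniform
  residue frequencies), optional accessory-domain insertions, hybrid
  proteins with both GGDEF and EAL domains. Default composition: 5 active
  DGCs, 1 degenerate DGC, 3 active PDEs, 1 degenerate PDE, 2 bifunctional
  hybrids, 1 fully degenerate hybrid, 2 PilZ binders, 1 PilZ non-binder —
  a scaled-down repertoire with every category represented.
* **PilZ domains**: backgrounds drawn from an alphabet without R or S, so
  neither switch motif can arise by chance; binders get `RTKLR … DWSKKG`
  embedded, non-binders nothing.
* **Ct tables**: Ct baselines 20 (target) and 18/22 (references), the
  injected log2 effect subtracted from the treated target Ct, i.i.d.
  Gaussian noise (default sd 0.2) on every measured Ct, three biological
  replicates per condition — mirroring a two-reference-gene, three-replicate
  control-vs-treatment design where a strong induction (e.g. the ~36-fold
  = 5.2 log2 response probed in the acceptance run) must be recovered.

Everything is deterministic under the spec's seed (byte-identical files).

What passing on synthetic data does **not** show: robustness to real
evolutionary divergence (flanks are i.i.d. random, not homologous),
annotation boundary errors, compositional bias, or amplification-efficiency
differences between qPCR runs. The generator validates the machinery, not
the biology of any particular genome.

## Problem sizes and numerics

The test suite and acceptance run use desk-scale inputs chosen to exercise
every code path: a 16-protein labeled proteome (references 280–730
residues), exhaustive alignment-path enumeration up to length 6, 1000
null Ct tables for the type-I rate and 500 tables for effect recovery.
Alignment scores are float64 throughout; verdicts and counts are exact
integers. Ct values are validated to (0, 45) with ≥2 replicates per
condition.

## Known limitations

* Single-reference anchoring can misplace sites for extremely divergent
  domains where a profile/HMM alignment would not; such domains typically
  fail the conservation rule (conservatively called degenerate).
* Percent identity without alignment-length or E-value weighting is a weak
  orthology signal on its own; the architecture requirement compensates,
  and thresholds are configurable.
* The HD-GYP rule mirrors the GGDEF/EAL one-substitution tolerance; HD-GYP
  catalysis is less completely characterized and the threshold may deserve
  class-specific tuning.
* The packaged panel is synthetic; biological conclusions require loading
  the public reference sequences.
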