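"""Synthetic proteomes, reference stand-ins and Ct tables with ground truth.

Every analysis stage in the package can be exercised on generated data with
known labels: domain variants carry a controlled number of catalytic-site
substitutions (the only activity signal), PilZ domains are built with
intact or broken switch motifs, and Ct tables inject a chosen log2 effect
under Gaussian Ct noise. All generators are deterministic under their seed.

The packaged reference panel is produced by :func:`synthetic_reference_panel`:
synthetic stand-in sequences (random background, canonical residues placed
at the published catalytic positions) that preserve the coordinate system
of the real PleD/TBD_1265/Bd1817 references without requiring any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DomainAnnotation, ProteinRecord
from .references import (
    CATALYTIC_SITE_TABLE,
    PILZ_ACTIVE_NAME,
    PILZ_INACTIVE_NAME,
    REFERENCE_NAMES,
    CatalyticSite,
    PilZReferenceModel,
    ReferenceDomainModel,
    ReferencePanel,
)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Background alphabet for PilZ domains: no R (kills RxxxR) and no S
#: (kills D/NzSxxG), so only deliberately embedded motifs can match.
PILZ_BACKGROUND = "ACDEFGHIKLMNPQTVWY"

#: Reference sequence lengths for the synthetic stand-ins (>= last site).
_REFERENCE_LENGTHS = {"GGDEF": 460, "EAL": 730, "HD-GYP": 280}

DEFAULT_PANEL_SEED = 20190709

#: Ct baselines used by the table generator (target, ref1, ref2).
CT_BASELINES = (20.0, 18.0, 22.0)

#: Ground-truth category vocabulary and the per-protein classification each
#: construction must be recovered as.
EXPECTED_CATEGORY = {
    "active-DGC": "DGC",
    "degenerate-DGC": "degenerate",
    "active-PDE": "PDE",
    "degenerate-PDE": "degenerate",
    "hybrid-bifunctional": "hybrid-bifunctional",
    "effector-candidate": "degenerate",
    "PilZ-binder": "non-catalytic",
    "PilZ-nonbinder": "non-catalytic",
}


@dataclass(frozen=True)
class GroundTruthLabel:
    protein_id: str
    category: str
    mutated_sites: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Composition and noise model of a generated proteome.

    Default composition is a scaled-down c-di-GMP repertoire with every
    category represented: stand-alone DGCs and PDEs (active and
    degenerate), bifunctional and fully degenerate hybrids, and PilZ
    effectors with intact and broken switch motifs. Degenerate domains
    carry ``catalytic_mutations`` substitutions (2 > the one tolerated);
    off-site mutations and indels are off by default so the catalytic-site
    signal is the only one present.
    """

    seed: int = 7
    n_active_dgc: int = 5
    n_degenerate_dgc: int = 1
    n_active_pde: int = 3
    n_degenerate_pde: int = 1
    n_hybrid_bifunctional: int = 2
    n_degenerate_hybrid: int = 1
    n_pilz_binder: int = 2
    n_pilz_nonbinder: int = 1
    catalytic_mutations: int = 2
    off_site_mutation_rate: float = 0.0
    flank_length: tuple[int, int] = (20, 60)
    indels: bool = False
    include_accessory: bool = False


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str = RESIDUES) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def synthetic_reference_panel(seed: int = DEFAULT_PANEL_SEED) -> ReferencePanel:
    """Build the synthetic stand-in reference panel deterministically."""
    rng = np.random.default_rng(seed)
    catalytic: dict[str, ReferenceDomainModel] = {}
    for cls, sites in CATALYTIC_SITE_TABLE.items():
        seq = list(_random_sequence(rng, _REFERENCE_LENGTHS[cls]))
        for pos, canonical, _alt in sites:
            seq[pos - 1] = canonical
        catalytic[cls] = ReferenceDomainModel(
            domain_class=cls,
            reference_name=REFERENCE_NAMES[cls],
            reference_sequence="".join(seq),
            catalytic_sites=tuple(
                CatalyticSite(pos, canonical, frozenset(alt) if alt else frozenset())
                for pos, canonical, alt in sites
            ),
        )
    binder_seq = (
        _random_sequence(rng, 30, PILZ_BACKGROUND)
        + "RTKLR"
        + _random_sequence(rng, 15, PILZ_BACKGROUND)
        + "DWSKKG"
        + _random_sequence(rng, 44, PILZ_BACKGROUND)
    )
    nonbinder_seq = _random_sequence(rng, 100, PILZ_BACKGROUND)
    pilz = {
        PILZ_ACTIVE_NAME: PilZReferenceModel(PILZ_ACTIVE_NAME, binder_seq, True),
        PILZ_INACTIVE_NAME: PilZReferenceModel(PILZ_INACTIVE_NAME, nonbinder_seq, False),
    }
    return ReferencePanel(catalytic=catalytic, pilz=pilz)


def make_domain_variant(
    model: ReferenceDomainModel,
    k_catalytic_mutations: int,
    off_site_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    indels: bool = False,
) -> tuple[str, tuple[int, ...]]:
    """Copy the reference with exactly ``k`` catalytic sites broken.

    Mutated sites receive a residue outside canonical ∪ alternates; every
    off-site position independently mutates with ``off_site_rate``. With
    ``indels`` a few 1–3 residue insertions/deletions are applied, kept
    more than two residues away from every catalytic site so the labels
    stay valid. Returns the sequence and the mutated site positions
    (reference numbering).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not (0 <= k_catalytic_mutations <= model.total_sites):
        raise ValueError(
            f"k={k_catalytic_mutations} outside [0, {model.total_sites}]"
        )
    seq = list(model.reference_sequence)
    site_positions = set(model.site_positions)
    chosen = sorted(
        int(p) for p in rng.choice(
            model.site_positions, size=k_catalytic_mutations, replace=False
        )
    ) if k_catalytic_mutations else []
    site_by_pos = {s.position: s for s in model.catalytic_sites}
    for pos in chosen:
        site = site_by_pos[pos]
        forbidden = {site.canonical} | set(site.alternates)
        options = [r for r in RESIDUES if r not in forbidden]
        seq[pos - 1] = str(rng.choice(options))
    if off_site_rate > 0:
        for i in range(len(seq)):
            if (i + 1) in site_positions:
                continue
            if rng.random() < off_site_rate:
                options = [r for r in RESIDUES if r != seq[i]]
                seq[i] = str(rng.choice(options))
    if indels:
        protected = set()
        for p in site_positions:
            protected.update(range(p - 2, p + 3))
        for _ in range(2):
            pos = int(rng.integers(1, len(seq) + 1))
            if pos in protected:
                continue
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del seq[pos - 1 : pos - 1 + size]
            else:
                seq[pos - 1 : pos - 1] = list(_random_sequence(rng, size))
    return "".join(seq), tuple(chosen)


def make_pilz_domain(rng: np.random.Generator, binder: bool) -> str:
    """A PilZ domain with intact (binder) or absent (non-binder) switch
    motifs; the background alphabet cannot form either motif by chance."""
    if binder:
        return (
            _random_sequence(rng, int(rng.integers(10, 30)), PILZ_BACKGROUND)
            + "RTKLR"
            + _random_sequence(rng, int(rng.integers(8, 20)), PILZ_BACKGROUND)
            + "DWSKKG"
            + _random_sequence(rng, int(rng.integers(20, 40)), PILZ_BACKGROUND)
        )
    return _random_sequence(rng, int(rng.integers(80, 120)), PILZ_BACKGROUND)


_ACCESSORY_CYCLE = ("PAS", "GAF", "REC")


def make_synthetic_proteome(
    spec: SyntheticSpec, panel: ReferencePanel | None = None
) -> tuple[list[ProteinRecord], list[DomainAnnotation], list[GroundTruthLabel]]:
    """Assemble a labeled proteome: flank + domain(s) + flank per protein.

    Returns protein records, their domain-annotation table and the
    ground-truth label table, all deterministic under ``spec.seed``.
    """
    if panel is None:
        panel = synthetic_reference_panel()
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    labels: list[GroundTruthLabel] = []
    accessory_counter = 0

    def flank() -> str:
        lo, hi = spec.flank_length
        return _random_sequence(rng, int(rng.integers(lo, hi + 1)))

    def build(tag: str, index: int, parts: list[tuple[str, str]], category: str,
              mutated: tuple[int, ...]) -> None:
        # parts: (domain_class, domain_sequence) in N→C order
        nonlocal accessory_counter
        pid = f"SYN_{tag}_{index:02d}"
        segments: list[str] = [flank()]
        anns: list[DomainAnnotation] = []
        if spec.include_accessory and rng.random() < 0.5:
            acc = _ACCESSORY_CYCLE[accessory_counter % len(_ACCESSORY_CYCLE)]
            accessory_counter += 1
            acc_seq = _random_sequence(rng, 40)
            start = sum(len(s) for s in segments) + 1
            segments.append(acc_seq)
            anns.append(DomainAnnotation(pid, acc, start, start + len(acc_seq) - 1))
        for i, (cls, dom) in enumerate(parts):
            if i > 0:
                segments.append(_random_sequence(rng, int(rng.integers(10, 30))))
            start = sum(len(s) for s in segments) + 1
            segments.append(dom)
            anns.append(DomainAnnotation(pid, cls, start, start + len(dom) - 1))
        segments.append(flank())
        records.append(ProteinRecord(id=pid, sequence="".join(segments)))
        annotations.extend(anns)
        labels.append(GroundTruthLabel(pid, category, mutated))

    k = spec.catalytic_mutations
    rate = spec.off_site_mutation_rate
    ggdef = panel.catalytic["GGDEF"]
    eal = panel.catalytic["EAL"]

    for i in range(spec.n_active_dgc):
        dom, mut = make_domain_variant(ggdef, 0, rate, rng, spec.indels)
        build("DGCA", i + 1, [("GGDEF", dom)], "active-DGC", mut)
    for i in range(spec.n_degenerate_dgc):
        dom, mut = make_domain_variant(ggdef, k, rate, rng, spec.indels)
        build("DGCD", i + 1, [("GGDEF", dom)], "degenerate-DGC", mut)
    for i in range(spec.n_active_pde):
        dom, mut = make_domain_variant(eal, 0, rate, rng, spec.indels)
        build("PDEA", i + 1, [("EAL", dom)], "active-PDE", mut)
    for i in range(spec.n_degenerate_pde):
        dom, mut = make_domain_variant(eal, k, rate, rng, spec.indels)
        build("PDED", i + 1, [("EAL", dom)], "degenerate-PDE", mut)
    for i in range(spec.n_hybrid_bifunctional):
        gdom, gmut = make_domain_variant(ggdef, 0, rate, rng, spec.indels)
        edom, emut = make_domain_variant(eal, 0, rate, rng, spec.indels)
        build("HYBB", i + 1, [("GGDEF", gdom), ("EAL", edom)],
              "hybrid-bifunctional", gmut + emut)
    for i in range(spec.n_degenerate_hybrid):
        gdom, gmut = make_domain_variant(ggdef, k, rate, rng, spec.indels)
        edom, emut = make_domain_variant(eal, k, rate, rng, spec.indels)
        build("HYBD", i + 1, [("GGDEF", gdom), ("EAL", edom)],
              "effector-candidate", gmut + emut)
    for i in range(spec.n_pilz_binder):
        build("PZB", i + 1, [("PilZ", make_pilz_domain(rng, True))], "PilZ-binder", ())
    for i in range(spec.n_pilz_nonbinder):
        build("PZN", i + 1, [("PilZ", make_pilz_domain(rng, False))], "PilZ-nonbinder", ())
    return records, annotations, labels


def write_label_table(labels: Sequence[GroundTruthLabel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (l.protein_id, l.category, ",".join(str(p) for p in l.mutated_sites))
            for l in labels
        ],
        columns=["protein_id", "category", "mutated_sites"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_label_table(path: str | Path) -> list[GroundTruthLabel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        GroundTruthLabel(
            row.protein_id,
            row.category,
            tuple(int(p) for p in row.mutated_sites.split(",") if p),
        )
        for row in df.itertuples(index=False)
    ]


def make_ct_table(
    genes: Sequence[str],
    effects_log2: Sequence[float],
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate Ct table for control vs treated with two reference genes.

    The treated condition's target Ct is shifted by ``−effect_log2`` (a
    positive effect lowers the treated Ct, i.e. upregulation); reference
    gene Cts carry only noise. Baselines are Ct 20 (target) and 18/22
    (references). Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    if len(genes) != len(effects_log2):
        raise ValueError("genes and effects_log2 must have equal length")
    rng = np.random.default_rng(seed)
    t0, r1, r2 = CT_BASELINES
    rows = []
    for gene, effect in zip(genes, effects_log2):
        for condition in ("control", "treated"):
            shift = effect if condition == "treated" else 0.0
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": t0 - shift + rng.normal(0.0, noise_sd),
                        "ct_ref1": r1 + rng.normal(0.0, noise_sd),
                        "ct_ref2": r2 + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
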