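"""Catalytic-site conservation scoring and per-protein activity calls.

A domain is globally aligned to its class reference; the residues opposite
the reference's catalytic positions are read off and compared to the
canonical residue (or its accepted alternates). A domain with at most
``max_substitutions`` non-conserved sites (default 1) is called active:
GGDEF-active proteins are predicted diguanylate cyclases (DGC), EAL- or
HD-GYP-active proteins phosphodiesterases (PDE), and proteins carrying both
GGDEF and EAL domains are classified by which of the two are active.

A catalytic position aligned to a gap counts as a substitution: absence of
the residue cannot support catalysis. Conservation is exact residue match;
no similarity-group credit is given.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentParams, DEFAULT_PARAMS, global_align, map_reference_positions
from .io import ACCESSORY_CLASSES, CATALYTIC_CLASSES, DomainAnnotation
from .references import ReferenceDomainModel

MIN_DOMAIN_LENGTH = 10

#: Per-protein category vocabulary used in reports.
CATEGORIES = (
    "DGC", "PDE", "hybrid-bifunctional", "hybrid-DGC-only",
    "hybrid-PDE-only", "degenerate", "non-catalytic",
)


@dataclass(frozen=True)
class SiteDetail:
    """Evidence for one catalytic position: what was expected, what the
    candidate carries at the aligned position, and whether that conserves."""

    reference_position: int
    expected: str
    query_position: int | None
    observed: str | None
    conserved: bool


@dataclass(frozen=True)
class ActivityVerdict:
    protein_id: str
    domain_class: str
    reference_name: str
    conserved_count: int
    total_sites: int
    site_details: tuple[SiteDetail, ...]
    active: bool
    max_substitutions: int


@dataclass(frozen=True)
class ProteinClassification:
    protein_id: str
    category: str
    basis: tuple[ActivityVerdict, ...]


def score_site_conservation(
    domain_sequence: str,
    model: ReferenceDomainModel,
    protein_id: str = "",
    max_substitutions: int | None = None,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ActivityVerdict:
    """Score one annotated domain against its class reference model."""
    if len(domain_sequence) < MIN_DOMAIN_LENGTH:
        raise ValueError(
            f"domain sequence too short ({len(domain_sequence)} < {MIN_DOMAIN_LENGTH})"
        )
    if model.total_sites == 0:
        raise ValueError(f"reference model {model.reference_name!r} defines no sites")
    if max_substitutions is None:
        max_substitutions = model.max_substitutions
    aln = global_align(domain_sequence, model.reference_sequence, params)
    mapped = map_reference_positions(aln, model.site_positions)
    details = []
    conserved_count = 0
    for site in model.catalytic_sites:
        qpos, observed = mapped[site.position]
        conserved = site.accepts(observed)
        conserved_count += conserved
        details.append(
            SiteDetail(site.position, site.expected, qpos, observed, conserved)
        )
    active = conserved_count >= model.total_sites - max_substitutions
    return ActivityVerdict(
        protein_id=protein_id,
        domain_class=model.domain_class,
        reference_name=model.reference_name,
        conserved_count=conserved_count,
        total_sites=model.total_sites,
        site_details=tuple(details),
        active=active,
        max_substitutions=max_substitutions,
    )


def classify_protein(verdicts: Sequence[ActivityVerdict]) -> ProteinClassification:
    """Roll per-domain verdicts for one protein up to a category.

    GGDEF-only active → DGC; EAL-only (or HD-GYP) active → PDE; GGDEF+EAL
    proteins are hybrids, split by which domains are active; no active
    catalytic domain → degenerate; no catalytic domain at all →
    non-catalytic.
    """
    if not verdicts:
        raise ValueError("need at least one verdict to classify a protein")
    ids = {v.protein_id for v in verdicts}
    if len(ids) != 1:
        raise ValueError(f"verdicts mix protein ids: {sorted(ids)}")
    protein_id = verdicts[0].protein_id

    def active(cls: str) -> bool:
        return any(v.active for v in verdicts if v.domain_class == cls)

    def has(cls: str) -> bool:
        return any(v.domain_class == cls for v in verdicts)

    if has("GGDEF") and has("EAL"):
        if active("GGDEF") and active("EAL"):
            category = "hybrid-bifunctional"
        elif active("GGDEF"):
            category = "hybrid-DGC-only"
        elif active("EAL"):
            category = "hybrid-PDE-only"
        else:
            category = "degenerate"
    elif has("GGDEF"):
        category = "DGC" if active("GGDEF") else "degenerate"
    elif has("EAL") or has("HD-GYP"):
        category = "PDE" if (active("EAL") or active("HD-GYP")) else "degenerate"
    else:
        category = "non-catalytic"
    return ProteinClassification(protein_id, category, tuple(verdicts))


def classify_proteome(
    records,
    annotations: Sequence[DomainAnnotation],
    panel,
    max_substitutions: int | None = None,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[list[ActivityVerdict], list[ProteinClassification]]:
    """Score every annotated catalytic domain and classify every protein.

    Proteins whose annotations contain no catalytic domain are classified
    ``non-catalytic`` (with an empty-basis placeholder skipped: they simply
    do not appear unless they carry at least one annotation).
    """
    by_id = {r.id: r for r in records}
    verdicts: list[ActivityVerdict] = []
    per_protein: dict[str, list[ActivityVerdict]] = {}
    seen_proteins: list[str] = []
    for ann in annotations:
        if ann.protein_id not in by_id:
            raise ValueError(f"annotation refers to unknown protein {ann.protein_id!r}")
        if ann.protein_id not in per_protein:
            per_protein[ann.protein_id] = []
            seen_proteins.append(ann.protein_id)
        if ann.domain_class not in CATALYTIC_CLASSES:
            continue
        model = panel.model_for(ann.domain_class)
        v = score_site_conservation(
            ann.slice_of(by_id[ann.protein_id]),
            model,
            protein_id=ann.protein_id,
            max_substitutions=max_substitutions,
            params=params,
        )
        verdicts.append(v)
        per_protein[ann.protein_id].append(v)

    classifications = []
    for pid in seen_proteins:
        vs = per_protein[pid]
        if vs:
            classifications.append(classify_protein(vs))
        else:
            classifications.append(ProteinClassification(pid, "non-catalytic", ()))
    return verdicts, classifications


def inventory(
    classifications: Iterable[ProteinClassification],
    annotations: Sequence[DomainAnnotation] | None = None,
) -> dict[str, int]:
    """Summary counts by category, domain class and activity.

    With ``annotations`` supplied, also counts stand-alone proteins: those
    whose annotated domains are exclusively catalytic (no accessory module).
    """
    classifications = list(classifications)
    counts: Counter[str] = Counter()
    for c in classifications:
        counts[c.category] += 1
        for v in c.basis:
            key = v.domain_class.replace("-", "_")
            counts[f"{key}_active" if v.active else f"{key}_degenerate"] += 1
    counts["total_proteins"] = len(classifications)
    counts["total_active"] = sum(
        1 for c in classifications if c.category not in ("degenerate", "non-catalytic")
    )
    if annotations is not None:
        accessory_by_protein: dict[str, bool] = {}
        classes_by_protein: dict[str, set[str]] = {}
        for a in annotations:
            classes_by_protein.setdefault(a.protein_id, set()).add(a.domain_class)
            accessory_by_protein.setdefault(a.protein_id, False)
            if a.domain_class in ACCESSORY_CLASSES:
                accessory_by_protein[a.protein_id] = True
        for c in classifications:
            if accessory_by_protein.get(c.protein_id, False):
                continue
            classes = classes_by_protein.get(c.protein_id, set())
            cat = classes & set(CATALYTIC_CLASSES)
            if cat == {"GGDEF"}:
                counts["stand_alone_GGDEF"] += 1
            elif cat == {"EAL"}:
                counts["stand_alone_EAL"] += 1
            elif cat == {"GGDEF", "EAL"}:
                counts["stand_alone_hybrid"] += 1
            elif cat == {"HD-GYP"}:
                counts["stand_alone_HD_GYP"] += 1
    return dict(counts)
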