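"""Domain-architecture strings and architecture-aware orthology calls.

An architecture string is the ordered list of domain-class tokens along a
protein (e.g. ``PAS|GGDEF|EAL``). Orthology between two proteins is called
from percent identity of their best local alignment combined with
architecture conservation — strict token equality by default, or equality
up to accessory-domain insertions under the relaxed flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .align import AlignmentParams, DEFAULT_PARAMS, local_align
from .effectors import OrthologyCall
from .io import ACCESSORY_CLASSES, CATALYTIC_CLASSES, DomainAnnotation, ProteinRecord

SEPARATOR = "|"

DEFAULT_IDENTITY_THRESHOLD = 25.0


@dataclass(frozen=True)
class ArchitectureString:
    """Ordered domain tokens for one protein, sorted by start coordinate
    (ties by end, then token text)."""

    protein_id: str
    tokens: tuple[str, ...]

    def __str__(self) -> str:
        return SEPARATOR.join(self.tokens)

    @property
    def stand_alone(self) -> bool:
        """True when the only annotated domains are catalytic ones."""
        return bool(self.tokens) and all(
            t in CATALYTIC_CLASSES for t in self.tokens
        )


def architecture_string(
    annotations: Sequence[DomainAnnotation], protein_id: str | None = None
) -> ArchitectureString:
    """Build the architecture string for one protein's annotations.

    Overlapping annotations of the same class are an error (they would be
    one domain annotated twice); overlaps across classes are tolerated
    (nested/fused modules occur).
    """
    annotations = list(annotations)
    if protein_id is None:
        ids = {a.protein_id for a in annotations}
        if len(ids) > 1:
            raise ValueError(f"annotations mix protein ids: {sorted(ids)}")
        protein_id = next(iter(ids)) if ids else ""
    ordered = sorted(annotations, key=lambda a: (a.start, a.end, a.domain_class))
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.domain_class == cur.domain_class and cur.start <= prev.end:
            raise ValueError(
                f"{protein_id}: overlapping {cur.domain_class} annotations "
                f"({prev.start}-{prev.end} and {cur.start}-{cur.end})"
            )
    return ArchitectureString(protein_id, tuple(a.domain_class for a in ordered))


def compare_architectures(
    a: ArchitectureString, b: ArchitectureString, relaxed: bool = False
) -> bool:
    """Architecture conservation between two proteins.

    Strict (default): identical token sequences. Relaxed: identical after
    dropping accessory-domain tokens, i.e. the two differ only by accessory
    insertions around the same catalytic/effector core.
    """
    if a.tokens == b.tokens:
        return True
    if relaxed:
        core_a = tuple(t for t in a.tokens if t not in ACCESSORY_CLASSES)
        core_b = tuple(t for t in b.tokens if t not in ACCESSORY_CLASSES)
        return core_a == core_b
    return False


def call_ortholog(
    query: ProteinRecord,
    subjects: Sequence[ProteinRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    query_architecture: ArchitectureString | None = None,
    subject_architectures: Mapping[str, ArchitectureString] | None = None,
    relaxed: bool = False,
) -> OrthologyCall:
    """Best local hit of ``query`` among ``subjects``, with orthology call.

    Ortholog iff identity ≥ threshold AND architecture conserved. When no
    architectures are supplied the architecture check is vacuous (treated
    conserved) and the call reduces to the identity criterion.
    """
    if not subjects:
        raise ValueError("empty subject set")
    best = None
    best_subject = None
    for subject in subjects:
        aln = local_align(query.sequence, subject.sequence, params)
        if best is None or aln.score > best.score:
            best = aln
            best_subject = subject
    arch_conserved = True
    if query_architecture is not None and subject_architectures is not None:
        sub_arch = subject_architectures.get(best_subject.id)
        arch_conserved = sub_arch is not None and compare_architectures(
            query_architecture, sub_arch, relaxed=relaxed
        )
    return OrthologyCall(
        query_id=query.id,
        subject_id=best_subject.id,
        identity_percent=best.identity_percent,
        architecture_conserved=arch_conserved,
        ortholog=(best.identity_percent >= identity_threshold) and arch_conserved,
    )
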