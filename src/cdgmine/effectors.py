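"""c-di-GMP effector prediction.

Three effector routes are screened:

* PilZ domains — presence of the two "c-di-GMP switch" motifs, RxxxR
  followed downstream by [D/N]-z-S-x-x-G, which wrap around the ligand on
  binding. Both motifs found in order → predicted binder.
* Degenerate GGDEF/EAL proteins — a protein carrying catalytic-class
  domains none of which passed the conservation screen may still bind
  c-di-GMP through its degenerate site and is flagged as an effector
  candidate.
* Orthologs of known effectors — best local-alignment hit of each
  reference effector in the proteome, called by percent identity.

``x`` in the motifs is any residue. ``z`` is unspecified in the source
convention; by default it is treated as any residue, optionally restricted
to hydrophobic residues (``z_hydrophobic=True``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import AlignmentParams, DEFAULT_PARAMS, local_align
from .io import ProteinRecord
from .activity import ProteinClassification

HYDROPHOBIC = "AVLIMFWYC"

RXXXR = re.compile(r"(?=(R...R))")


def _switch2_pattern(z_hydrophobic: bool) -> re.Pattern[str]:
    z = f"[{HYDROPHOBIC}]" if z_hydrophobic else "."
    return re.compile(rf"(?=([DN]{z}S..G))")


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based
    match: str


@dataclass(frozen=True)
class PilZVerdict:
    """Switch-motif evidence for one PilZ domain.

    ``binder`` is true iff both motifs are present with the RxxxR start
    strictly before the D/NzSxxG start (first-occurrence semantics; all
    occurrences are kept in the ``*_all`` detail fields).
    """

    protein_id: str
    rxxxr: MotifHit | None
    switch2: MotifHit | None
    binder: bool
    rxxxr_all: tuple[MotifHit, ...] = ()
    switch2_all: tuple[MotifHit, ...] = ()


@dataclass(frozen=True)
class OrthologyCall:
    query_id: str
    subject_id: str
    identity_percent: float
    architecture_conserved: bool
    ortholog: bool


def find_switch_motifs(
    sequence: str,
    protein_id: str = "",
    z_hydrophobic: bool = False,
    min_spacing: int | None = None,
    max_spacing: int | None = None,
) -> PilZVerdict:
    """Scan a PilZ domain sequence for the two c-di-GMP switch motifs.

    The reported RxxxR is its first occurrence; the reported D/NzSxxG is
    the first occurrence starting strictly after the RxxxR start.
    ``min_spacing``/``max_spacing`` optionally bound the residue gap
    between the end of RxxxR and the start of the second motif. Motif
    absence is a negative verdict, not an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    r_hits = tuple(
        MotifHit(m.start() + 1, m.group(1)) for m in RXXXR.finditer(sequence)
    )
    s_hits = tuple(
        MotifHit(m.start() + 1, m.group(1))
        for m in _switch2_pattern(z_hydrophobic).finditer(sequence)
    )
    rxxxr = r_hits[0] if r_hits else None
    switch2 = None
    if rxxxr is not None:
        for hit in s_hits:
            if hit.start <= rxxxr.start:
                continue
            spacing = hit.start - (rxxxr.start + 5)
            if min_spacing is not None and spacing < min_spacing:
                continue
            if max_spacing is not None and spacing > max_spacing:
                continue
            switch2 = hit
            break
    elif s_hits:
        # No RxxxR: still report the first second-motif occurrence as detail.
        switch2 = s_hits[0]
    binder = (
        rxxxr is not None and switch2 is not None and rxxxr.start < switch2.start
    )
    return PilZVerdict(
        protein_id=protein_id,
        rxxxr=rxxxr,
        switch2=switch2,
        binder=binder,
        rxxxr_all=r_hits,
        switch2_all=s_hits,
    )


def flag_degenerate_effectors(
    classifications: Iterable[ProteinClassification],
) -> list[str]:
    """Proteins with ≥1 GGDEF/EAL domain and zero active domains.

    Such degenerate proteins retain the fold that contacts c-di-GMP and are
    therefore kept as potential effectors.
    """
    flagged = []
    for c in classifications:
        catalytic = [v for v in c.basis if v.domain_class in ("GGDEF", "EAL")]
        if catalytic and not any(v.active for v in c.basis):
            flagged.append(c.protein_id)
    return flagged


def orthology_effector_search(
    references: Sequence[ProteinRecord],
    proteome: Sequence[ProteinRecord],
    identity_threshold: float = 25.0,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[OrthologyCall]:
    """Best local-alignment hit in the proteome for each reference effector.

    The hit with the highest local score wins (first by input order on
    ties); it is reported as an ortholog when its percent identity over the
    local alignment reaches ``identity_threshold``. No architecture check
    is applied on this route (reference effectors come without domain
    tables), so ``architecture_conserved`` is reported true.
    """
    if not proteome:
        raise ValueError("empty proteome")
    calls = []
    for ref in references:
        best = None
        best_subject = None
        for subject in proteome:
            aln = local_align(ref.sequence, subject.sequence, params)
            if best is None or aln.score > best.score:
                best = aln
                best_subject = subject
        calls.append(
            OrthologyCall(
                query_id=ref.id,
                subject_id=best_subject.id,
                identity_percent=best.identity_percent,
                architecture_conserved=True,
                ortholog=best.identity_percent >= identity_threshold,
            )
        )
    return calls
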