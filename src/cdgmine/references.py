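"""Reference domain models for the catalytic-site conservation screen.

Three catalytic references anchor the screen — a GGDEF diguanylate-cyclase
model (PleD numbering, *Caulobacter crescentus*), an EAL phosphodiesterase
model (TBD_1265 numbering, *Thiobacillus denitrificans*) and an HD-GYP
model (Bd1817 numbering, *Bdellovibrio bacteriovorus*) — plus two PilZ
effector references: an active c-di-GMP binder (PA4608, *Pseudomonas
aeruginosa*) and a degenerate non-binder (XC1028, *Xanthomonas campestris*).

Catalytic positions and canonical residues follow the published numbering:

* GGDEF (7 sites): D327, K332, N335, D344, D370, K442, R446
* EAL (9 sites): E523, R527, E546, N584, E616, D646, D647, E703, Q723
* HD-GYP (7 sites): H183, D184, H212, H237, E238 (alt H), N265 (alt E),
  N269 (alt R) — the alternates are accepted as conserved.

The packaged panel carries *synthetic stand-in* sequences: random
backgrounds with the canonical residues placed at the published positions,
generated deterministically (see :mod:`cdgmine.synth`). They preserve the
coordinate system and scoring semantics of the real references; swap in the
public sequence records via ``load_reference_panel(fasta, sites)`` for runs
against a real proteome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .io import ProteinRecord, read_fasta

import pandas as pd

#: (position, canonical, alternates) per catalytic class, published numbering.
CATALYTIC_SITE_TABLE: dict[str, tuple[tuple[int, str, str], ...]] = {
    "GGDEF": (
        (327, "D", ""), (332, "K", ""), (335, "N", ""), (344, "D", ""),
        (370, "D", ""), (442, "K", ""), (446, "R", ""),
    ),
    "EAL": (
        (523, "E", ""), (527, "R", ""), (546, "E", ""), (584, "N", ""),
        (616, "E", ""), (646, "D", ""), (647, "D", ""), (703, "E", ""),
        (723, "Q", ""),
    ),
    "HD-GYP": (
        (183, "H", ""), (184, "D", ""), (212, "H", ""), (237, "H", ""),
        (238, "E", "H"), (265, "N", "E"), (269, "N", "R"),
    ),
}

EXPECTED_SITE_COUNTS = {"GGDEF": 7, "EAL": 9, "HD-GYP": 7}

REFERENCE_NAMES = {"GGDEF": "PleD", "EAL": "TBD_1265", "HD-GYP": "Bd1817"}
PILZ_ACTIVE_NAME = "PA4608"
PILZ_INACTIVE_NAME = "XC1028"


@dataclass(frozen=True)
class CatalyticSite:
    """One active-site residue: position in the reference, canonical letter,
    and the possibly-empty set of accepted alternate letters."""

    position: int
    canonical: str
    alternates: frozenset[str] = frozenset()

    def accepts(self, residue: str | None) -> bool:
        return residue is not None and (
            residue == self.canonical or residue in self.alternates
        )

    @property
    def expected(self) -> str:
        return "/".join([self.canonical, *sorted(self.alternates)])


@dataclass(frozen=True)
class ReferenceDomainModel:
    """A catalytic reference sequence with its active-site definition.

    ``max_substitutions`` is the tolerated number of non-conserved sites for
    a domain to still be called active (threshold = total sites − max
    substitutions); default 1, i.e. "at most one substitution".
    """

    domain_class: str
    reference_name: str
    reference_sequence: str
    catalytic_sites: tuple[CatalyticSite, ...]
    max_substitutions: int = 1

    @property
    def total_sites(self) -> int:
        return len(self.catalytic_sites)

    @property
    def site_positions(self) -> list[int]:
        return [s.position for s in self.catalytic_sites]


@dataclass(frozen=True)
class PilZReferenceModel:
    """A PilZ reference sequence with its expected c-di-GMP switch verdict."""

    reference_name: str
    sequence: str
    expected_binder: bool


@dataclass(frozen=True)
class ReferencePanel:
    catalytic: dict[str, ReferenceDomainModel]
    pilz: dict[str, PilZReferenceModel]

    def model_for(self, domain_class: str) -> ReferenceDomainModel:
        try:
            return self.catalytic[domain_class]
        except KeyError:
            raise KeyError(f"no reference model for domain class {domain_class!r}")


@dataclass
class ValidationReport:
    """Self-validation outcome for a reference model."""

    reference_name: str
    checked: int
    failures: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_reference_model(model: ReferenceDomainModel) -> ValidationReport:
    """Confirm the reference sequence carries its own canonical residues.

    Guards against residue-numbering drift between the sequence record and
    the site table. Failures are reported, not raised.
    """
    report = ValidationReport(model.reference_name, checked=model.total_sites)
    last = 0
    seq = model.reference_sequence
    for site in model.catalytic_sites:
        if site.position <= last:
            report.failures.append((site.position, site.canonical, "not-increasing"))
        last = site.position
        if site.position > len(seq) or site.position < 1:
            report.failures.append((site.position, site.canonical, "out-of-range"))
            continue
        observed = seq[site.position - 1]
        if observed != site.canonical:
            report.failures.append((site.position, site.canonical, observed))
    return report


def _sites_from_table(domain_class: str) -> tuple[CatalyticSite, ...]:
    return tuple(
        CatalyticSite(pos, canon, frozenset(alt) if alt else frozenset())
        for pos, canon, alt in CATALYTIC_SITE_TABLE[domain_class]
    )


def _default_panel_paths() -> tuple[Path, Path]:
    data = resources.files("cdgmine") / "data"
    return (
        Path(str(data / "reference_panel_synthetic.fasta")),
        Path(str(data / "reference_panel_sites.tsv")),
    )


def load_reference_panel(
    fasta_path: str | Path | None = None,
    sites_path: str | Path | None = None,
    max_substitutions: int = 1,
) -> ReferencePanel:
    """Load the reference panel (packaged synthetic stand-ins by default).

    The FASTA description's first word is the domain class (``GGDEF``,
    ``EAL``, ``HD-GYP``) or ``PilZ`` followed by ``active``/``inactive``.
    The sites TSV has columns ``reference_name``, ``position``,
    ``canonical``, ``alternates`` (comma-separated, may be empty). All
    catalytic models must validate; a missing catalytic class is an error.
    """
    if fasta_path is None or sites_path is None:
        fasta_path, sites_path = _default_panel_paths()
    records = {r.id: r for r in read_fasta(fasta_path)}
    sites_df = pd.read_csv(sites_path, sep="\t", dtype=str, keep_default_na=False)
    sites_by_name: dict[str, list[CatalyticSite]] = {}
    for row in sites_df.itertuples(index=False):
        alt = frozenset(a for a in row.alternates.split(",") if a)
        sites_by_name.setdefault(row.reference_name, []).append(
            CatalyticSite(int(row.position), row.canonical, alt)
        )

    catalytic: dict[str, ReferenceDomainModel] = {}
    pilz: dict[str, PilZReferenceModel] = {}
    for rec in records.values():
        words = rec.description.split()
        if not words:
            raise ValueError(f"panel record {rec.id!r} lacks a class tag in its description")
        cls = words[0]
        if cls == "PilZ":
            if len(words) < 2 or words[1] not in ("active", "inactive"):
                raise ValueError(
                    f"PilZ panel record {rec.id!r} must be tagged active or inactive"
                )
            pilz[rec.id] = PilZReferenceModel(
                rec.id, rec.sequence, expected_binder=(words[1] == "active")
            )
        elif cls in EXPECTED_SITE_COUNTS:
            sites = sorted(sites_by_name.get(rec.id, []), key=lambda s: s.position)
            model = ReferenceDomainModel(
                domain_class=cls,
                reference_name=rec.id,
                reference_sequence=rec.sequence,
                catalytic_sites=tuple(sites),
                max_substitutions=max_substitutions,
            )
            report = validate_reference_model(model)
            if not report.ok:
                raise ValueError(
                    f"reference model {rec.id!r} failed self-validation: {report.failures}"
                )
            catalytic[cls] = model
        else:
            raise ValueError(f"panel record {rec.id!r} has unknown class tag {cls!r}")

    missing = [c for c in EXPECTED_SITE_COUNTS if c not in catalytic]
    if missing:
        raise ValueError(
            "reference panel missing catalytic model(s): " + ", ".join(missing)
        )
    return ReferencePanel(catalytic=catalytic, pilz=pilz)
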