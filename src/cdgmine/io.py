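"""Reading and writing of the formats the pipeline touches.

Proteomes are plain FASTA files; domain annotations are a four-column TSV
(``protein_id``, ``domain_class``, ``start``, ``end``) with 1-based inclusive
residue coordinates, the convention used throughout the package. Domain
annotations are an *input*: the pipeline scores catalytic-site conservation
inside domains that were already located (e.g. by the source genome
annotation), it does not rediscover them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 standard residues plus X (unknown).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Domain classes with catalytic c-di-GMP chemistry.
CATALYTIC_CLASSES = ("GGDEF", "EAL", "HD-GYP")

#: c-di-GMP binding effector domain.
EFFECTOR_CLASSES = ("PilZ",)

#: Sensory / regulatory modules commonly fused to the catalytic domains.
ACCESSORY_CLASSES = (
    "HAMP", "CACHE", "CBS", "DUF3330", "Tar/Tsr", "GAF", "HisK",
    "CSS", "MHYT", "MASE1", "REC", "PAS",
)

DOMAIN_VOCABULARY = frozenset(CATALYTIC_CLASSES + EFFECTOR_CLASSES + ACCESSORY_CLASSES)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with identifier; residue positions are 1-based."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record needs a non-empty id")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"protein {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A located domain on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_class: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_VOCABULARY:
            raise ValueError(
                f"unknown domain_class {self.domain_class!r}; allowed: "
                + ", ".join(sorted(DOMAIN_VOCABULARY))
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.domain_class}: bad coordinates "
                f"start={self.start} end={self.end} (need 1 <= start <= end)"
            )

    def slice_of(self, record: ProteinRecord) -> str:
        """Extract the annotated domain sequence from its protein."""
        if record.id != self.protein_id:
            raise ValueError(f"annotation is for {self.protein_id!r}, got {record.id!r}")
        if self.end > len(record):
            raise ValueError(
                f"{self.protein_id}/{self.domain_class}: end={self.end} beyond "
                f"sequence length {len(record)}"
            )
        return record.sequence[self.start - 1 : self.end]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated records.

    Sequences are upper-cased; file order is preserved. Empty files,
    duplicate ids and non-amino-acid characters raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


_TABLE_COLUMNS = ["protein_id", "domain_class", "start", "end"]


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read the TSV domain-annotation table; coordinates parsed as integers."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_class": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table {path} missing column(s): {', '.join(missing)}")
    return [
        DomainAnnotation(
            protein_id=row.protein_id,
            domain_class=row.domain_class,
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples(index=False)
    ]


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.domain_class, a.start, a.end) for a in annotations],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def validate_annotations(
    records: Sequence[ProteinRecord], annotations: Sequence[DomainAnnotation]
) -> None:
    """Check every annotation refers to a known protein and fits its length."""
    lengths = {r.id: len(r) for r in records}
    for a in annotations:
        if a.protein_id not in lengths:
            raise ValueError(f"annotation refers to unknown protein {a.protein_id!r}")
        if a.end > lengths[a.protein_id]:
            raise ValueError(
                f"{a.protein_id}/{a.domain_class}: end={a.end} beyond sequence "
                f"length {lengths[a.protein_id]}"
            )


def _verdict_rows(verdicts, categories: Mapping[str, str] | None):
    rows = []
    for v in verdicts:
        rows.append(
            {
                "protein_id": v.protein_id,
                "domain_class": v.domain_class,
                "reference_name": v.reference_name,
                "conserved_count": v.conserved_count,
                "total_sites": v.total_sites,
                "active": v.active,
                "category": (categories or {}).get(v.protein_id, ""),
            }
        )
    return rows


def inventory_summary(verdicts) -> dict[str, int]:
    """Per-class active/degenerate counts over a verdict list."""
    summary: dict[str, int] = {}
    for cls in CATALYTIC_CLASSES:
        key = cls.replace("-", "_")
        summary[f"{key}_active"] = sum(
            1 for v in verdicts if v.domain_class == cls and v.active
        )
        summary[f"{key}_degenerate"] = sum(
            1 for v in verdicts if v.domain_class == cls and not v.active
        )
    summary["total_domains"] = len(list(verdicts))
    return summary


def write_inventory_report(
    verdicts,
    path: str | Path,
    format: str = "tsv",
    categories: Mapping[str, str] | None = None,
) -> None:
    """Serialize per-domain activity verdicts plus a class-count summary.

    ``format`` is ``tsv`` (rows, then a ``#``-prefixed summary footer) or
    ``json`` (object with ``rows`` and ``summary`` keys). One row per domain
    verdict; ``categories`` optionally maps protein ids to their per-protein
    classification for the category column.
    """
    verdicts = list(verdicts)
    rows = _verdict_rows(verdicts, categories)
    summary = inventory_summary(verdicts)
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            rows,
            columns=[
                "protein_id", "domain_class", "reference_name",
                "conserved_count", "total_sites", "active", "category",
            ],
        )
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)
            for key, value in summary.items():
                fh.write(f"# {key}\t{value}\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump({"rows": rows, "summary": summary}, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r} (tsv or json)")
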