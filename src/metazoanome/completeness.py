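"""Genome-completeness QC from coverage of conserved, low-copy eukaryotic genes.

Incomplete genome assemblies/annotations cause valid orthologs to be absent
from clustering output. Coverage of a user-supplied reference list of widely
conserved, low-copy eukaryotic ortholog groups approximates per-species gene
coverage: a species "covers" a reference group if it contributes at least one
member (presence is binary, paralogs do not add). The report is descriptive
QC only — it never gates classification, which instead uses relaxed per-clade
thresholds to absorb incompleteness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .ortho_model import GroupCollection, SpeciesRecord

__all__ = [
    "CoverageReport",
    "coverage_report",
    "parse_reference_ids",
    "summarize_coverage",
]


@dataclass(frozen=True)
class CoverageReport:
    """Per-species coverage fractions against a reference group list."""

    per_species: Mapping[str, float]
    n_present: Mapping[str, int]
    reference_size: int

    def __post_init__(self) -> None:
        if self.reference_size < 1:
            raise ValueError("reference_size must be >= 1")
        for sp, frac in self.per_species.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"coverage for {sp!r} outside [0, 1]: {frac}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_code": sp,
                "n_present": self.n_present[sp],
                "n_reference": self.reference_size,
                "coverage": self.per_species[sp],
            }
            for sp in self.per_species
        ]
        return pd.DataFrame(rows, columns=["species_code", "n_present", "n_reference", "coverage"])

    def write_tsv(self, stream: TextIO) -> None:
        self.to_frame().to_csv(stream, sep="\t", index=False)

    def to_json_obj(self) -> dict:
        return {
            "reference_size": self.reference_size,
            "per_species": dict(self.per_species),
            "n_present": dict(self.n_present),
        }

    def write_json(self, stream: TextIO) -> None:
        json.dump(self.to_json_obj(), stream, indent=2, sort_keys=True)
        stream.write("\n")


def parse_reference_ids(stream: TextIO) -> frozenset[str]:
    """Read the reference list: one group id per line, '#' comments allowed."""
    ids = set()
    for raw in stream:
        line = raw.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return frozenset(ids)


def coverage_report(
    collection: GroupCollection,
    reference_group_ids: Iterable[str],
    species: Sequence[SpeciesRecord],
) -> CoverageReport:
    """Fraction of reference groups in which each species has >= 1 member.

    Every reference id must exist in *collection*; the reference set must be
    non-empty. Species absent from every reference group score 0.0.
    """
    ref_ids = sorted(set(reference_group_ids))
    if not ref_ids:
        raise ValueError("reference group-id set is empty")
    missing = [gid for gid in ref_ids if gid not in collection]
    if missing:
        raise ValueError(f"reference ids not found in the collection: {missing[:5]}")
    n_ref = len(ref_ids)
    present_counts: dict[str, int] = {}
    for rec in species:
        hits = collection.groups_with_species(rec.code)
        present_counts[rec.code] = sum(1 for gid in ref_ids if gid in hits)
    fractions = {sp: n / n_ref for sp, n in present_counts.items()}
    return CoverageReport(per_species=fractions, n_present=present_counts, reference_size=n_ref)


def summarize_coverage(
    report: CoverageReport,
    species: Sequence[SpeciesRecord],
    focal_species: str | None = None,
) -> dict:
    """Mean/min coverage over metazoans, with and without the focal species.

    Both metazoan averages are reported because the denominator convention
    (all metazoans vs. all but the basal focal genome) is a modelling choice
    the caller may care about.
    """
    metazoans = [r.code for r in species if r.is_metazoan and r.code in report.per_species]
    out: dict[str, float | int | None] = {"n_species": len(report.per_species)}

    def _stats(codes: list[str], prefix: str) -> None:
        vals = [report.per_species[c] for c in codes]
        out[f"{prefix}_n"] = len(vals)
        out[f"{prefix}_mean"] = sum(vals) / len(vals) if vals else None
        out[f"{prefix}_min"] = min(vals) if vals else None

    _stats(metazoans, "metazoan")
    if focal_species is not None:
        _stats([c for c in metazoans if c != focal_species], "metazoan_excluding_focal")
    return out
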