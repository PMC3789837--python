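"""Classification of ortholog groups as metazoan-specific, eukaryote-core or other.

The decision procedure identifies ortholog groups that arose on the metazoan
stem and remained broadly conserved. A group is *metazoan-specific* when all
of the following hold:

* per-clade minimum presence in every multi-member metazoan clade
  (defaults: 9 of 11 Craniata, 6 of 8 Arthropoda, 2 of 3 Nematoda) —
  deliberately below clade size to absorb incomplete genomes;
* presence in at least one of the single-representative clades' genomes
  (defaults: the cnidarian Nematostella vectensis or the urochordate
  Ciona intestinalis);
* presence in at least ``total_min_presence`` counted metazoans overall
  (default 20 of 24; the basal focal placozoan is never counted);
* foreign leakage within bounds: at most ``max_foreign_species`` counted
  non-metazoan species in the group (default 2), every foreign member gene
  having at most ``max_foreign_rbbh_links`` RBBH links to the group's
  metazoan members (default 3). Weakly connected non-metazoan singletons in
  an otherwise metazoan group are treated as clustering false positives
  rather than evidence against metazoan specificity.

The *eukaryote-core* control set instead requires a fixed panel of distant
eukaryotes (defaults: H. sapiens, C. elegans, D. melanogaster,
S. cerevisiae, A. thaliana) and forbids prokaryotes.

Species presence is binary per group: paralogs never increase counts.
Presence of the focal species (Trichoplax adhaerens by default) contributes
to no criterion; it only drives the downstream present/absent partition of
the metazoan-specific set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .ortho_model import GeneID, GroupCollection, OrthologGroup, RBBHGraph, SpeciesRecord

__all__ = [
    "METAZOAN_SPECIFIC",
    "EUKARYOTE_CORE",
    "OTHER",
    "ClassificationError",
    "CladeSchema",
    "CladeProfile",
    "ClassificationResult",
    "clade_profile",
    "foreign_leakage_check",
    "is_metazoan_specific",
    "is_eukaryote_core",
    "classify_collection",
    "partition_by_species",
    "results_to_frame",
    "load_schema_config",
    "build_schema",
]

METAZOAN_SPECIFIC = "metazoan_specific"
EUKARYOTE_CORE = "eukaryote_core"
OTHER = "other"

# failed-criterion tags
TAG_ALT_REPRESENTATIVE = "alt_representative"
TAG_TOTAL_MIN = "total_min"
TAG_FOREIGN_SPECIES = "foreign_species"
TAG_FOREIGN_RBBH = "foreign_rbbh"


def clade_tag(clade: str) -> str:
    return f"clade:{clade}"


class ClassificationError(ValueError):
    """Raised on schema violations or members from unknown species."""


@dataclass(frozen=True)
class CladeSchema:
    """Species layout and all numeric selection thresholds.

    ``counted_metazoans`` and ``nonmetazoan_counted`` are explicit rosters
    (never derived by subtraction); genomes excluded from counting — e.g. a
    poorly sequenced species — go in ``uncounted_species`` so their members
    are tolerated without contributing to any criterion.
    """

    clade_members: Mapping[str, frozenset[str]]
    clade_min_presence: Mapping[str, int]
    alternative_representatives: frozenset[str]
    counted_metazoans: frozenset[str]
    total_min_presence: int
    focal_species: str
    nonmetazoan_counted: frozenset[str]
    control_required_species: frozenset[str]
    control_forbidden_species: frozenset[str]
    max_foreign_species: int = 2
    max_foreign_rbbh_links: int = 3
    uncounted_species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for clade, minimum in self.clade_min_presence.items():
            if clade not in self.clade_members:
                raise ValueError(f"clade_min_presence for unknown clade {clade!r}")
            if minimum < 0:
                raise ValueError(f"negative minimum for clade {clade!r}")
            if minimum > len(self.clade_members[clade]):
                raise ValueError(
                    f"clade_min_presence[{clade!r}] = {minimum} exceeds clade size "
                    f"{len(self.clade_members[clade])}"
                )
        if self.total_min_presence < 0 or self.total_min_presence > len(self.counted_metazoans):
            raise ValueError(
                f"total_min_presence {self.total_min_presence} outside "
                f"[0, {len(self.counted_metazoans)}]"
            )
        if self.focal_species in self.counted_metazoans:
            raise ValueError("focal_species must not be in counted_metazoans")
        if self.max_foreign_species < 0 or self.max_foreign_rbbh_links < 0:
            raise ValueError("foreign thresholds must be >= 0")

    @property
    def species_universe(self) -> frozenset[str]:
        return (
            self.counted_metazoans
            | {self.focal_species}
            | self.nonmetazoan_counted
            | self.uncounted_species
            | self.control_required_species
            | self.control_forbidden_species
            | frozenset().union(*self.clade_members.values())
        )

    def metazoan_codes(self) -> frozenset[str]:
        return self.counted_metazoans | {self.focal_species}


@dataclass(frozen=True)
class CladeProfile:
    """Species-level presence profile of one group under a schema."""

    clade_counts: Mapping[str, int]
    total_counted_present: int
    focal_present: bool
    foreign_members: tuple[GeneID, ...]


@dataclass(frozen=True)
class ClassificationResult:
    group_id: str
    label: str
    clade_counts: Mapping[str, int]
    total_counted_present: int
    foreign_species: tuple[tuple[str, str, int], ...]  # (species, gene, links to metazoan members)
    focal_present: bool
    failed_criteria: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.label == METAZOAN_SPECIFIC and self.failed_criteria:
            raise ValueError("metazoan_specific result cannot carry failed criteria")


def _check_known_species(group: OrthologGroup, schema: CladeSchema) -> None:
    unknown = sorted(group.species_present - schema.species_universe)
    if unknown:
        raise ClassificationError(
            f"group {group.group_id!r} has members from species unknown to the schema: {unknown}"
        )


def clade_profile(group: OrthologGroup, schema: CladeSchema) -> CladeProfile:
    """Species-level counts per clade, total counted metazoans, focal flag, foreign members."""
    _check_known_species(group, schema)
    present = group.species_present
    counts = {clade: len(members & present) for clade, members in schema.clade_members.items()}
    total = len(present & schema.counted_metazoans)
    foreign = tuple(sorted(m for m in group.members if m.species_code in schema.nonmetazoan_counted))
    return CladeProfile(
        clade_counts=counts,
        total_counted_present=total,
        focal_present=schema.focal_species in present,
        foreign_members=foreign,
    )


def foreign_leakage_check(
    group: OrthologGroup, schema: CladeSchema, rbbh: RBBHGraph
) -> tuple[bool, tuple[tuple[str, str, int], ...], tuple[str, ...]]:
    """Apply the foreign-member (clustering false-positive) criteria.

    Passes iff the group spans at most ``max_foreign_species`` counted
    non-metazoan species AND every foreign member gene has at most
    ``max_foreign_rbbh_links`` RBBH links to the metazoan members of this
    group. The link threshold is applied per foreign gene.
    """
    profile = clade_profile(group, schema)
    metazoan_members = frozenset(
        m for m in group.members if m.species_code in schema.metazoan_codes()
    )
    annotated = tuple(
        (m.species_code, str(m), rbbh.degree_to_subset(m, metazoan_members))
        for m in profile.foreign_members
    )
    failed: list[str] = []
    n_foreign_species = len({sp for sp, _, _ in annotated})
    if n_foreign_species > schema.max_foreign_species:
        failed.append(TAG_FOREIGN_SPECIES)
    if any(links > schema.max_foreign_rbbh_links for _, _, links in annotated):
        failed.append(TAG_FOREIGN_RBBH)
    return (not failed, annotated, tuple(failed))


def is_metazoan_specific(
    group: OrthologGroup, schema: CladeSchema, rbbh: RBBHGraph
) -> ClassificationResult:
    """Full decision for one group; label is metazoan_specific or other."""
    profile = clade_profile(group, schema)
    failed: list[str] = []
    for clade in sorted(schema.clade_min_presence):
        if profile.clade_counts[clade] < schema.clade_min_presence[clade]:
            failed.append(clade_tag(clade))
    present = group.species_present
    if schema.alternative_representatives and not (present & schema.alternative_representatives):
        failed.append(TAG_ALT_REPRESENTATIVE)
    if profile.total_counted_present < schema.total_min_presence:
        failed.append(TAG_TOTAL_MIN)
    _, annotated_foreign, foreign_failed = foreign_leakage_check(group, schema, rbbh)
    failed.extend(foreign_failed)
    return ClassificationResult(
        group_id=group.group_id,
        label=METAZOAN_SPECIFIC if not failed else OTHER,
        clade_counts=profile.clade_counts,
        total_counted_present=profile.total_counted_present,
        foreign_species=annotated_foreign,
        focal_present=profile.focal_present,
        failed_criteria=tuple(failed),
    )


def is_eukaryote_core(group: OrthologGroup, schema: CladeSchema) -> bool:
    """Control-set rule: all required panel species present, no forbidden species."""
    _check_known_species(group, schema)
    present = group.species_present
    return schema.control_required_species <= present and not (
        present & schema.control_forbidden_species
    )


def classify_collection(
    collection: GroupCollection, schema: CladeSchema, rbbh: RBBHGraph
) -> tuple[list[ClassificationResult], dict]:
    """Classify every group; returns per-group results and a summary.

    Raises if any group satisfies both the metazoan-specific and the
    eukaryote-core predicates: under any sensible schema (required control
    panel containing non-metazoans) the two are mutually exclusive, and a
    violation indicates a mis-configured schema.
    """
    results: list[ClassificationResult] = []
    for group in collection:
        res = is_metazoan_specific(group, schema, rbbh)
        euk = is_eukaryote_core(group, schema)
        if euk:
            if res.label == METAZOAN_SPECIFIC:
                raise ClassificationError(
                    f"group {group.group_id!r} satisfies both the metazoan-specific and "
                    "eukaryote-core criteria; check the schema's control panel"
                )
            res = replace(res, label=EUKARYOTE_CORE)
        results.append(res)
    label_counts = {METAZOAN_SPECIFIC: 0, EUKARYOTE_CORE: 0, OTHER: 0}
    focal_present = focal_absent = 0
    for res in results:
        label_counts[res.label] += 1
        if res.label == METAZOAN_SPECIFIC:
            if res.focal_present:
                focal_present += 1
            else:
                focal_absent += 1
    summary = {
        "n_groups": len(results),
        "label_counts": label_counts,
        "focal_species": schema.focal_species,
        "focal_partition": {"present": focal_present, "absent": focal_absent},
    }
    return results, summary


def partition_by_species(
    results: Sequence[ClassificationResult],
    collection: GroupCollection,
    schema: CladeSchema,
    species_code: str | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Split the metazoan-specific groups by presence of one species.

    Defaults to the schema's focal species. Returns (present ids, absent ids);
    the two sets partition the metazoan-specific groups.
    """
    code = schema.focal_species if species_code is None else species_code
    if code not in schema.species_universe:
        raise ClassificationError(f"species {code!r} unknown to the schema")
    present: set[str] = set()
    absent: set[str] = set()
    for res in results:
        if res.label != METAZOAN_SPECIFIC:
            continue
        if code in collection[res.group_id].species_present:
            present.add(res.group_id)
        else:
            absent.add(res.group_id)
    return frozenset(present), frozenset(absent)


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Flatten results into the report table (one row per group)."""
    clades = sorted({c for r in results for c in r.clade_counts})
    rows = []
    for r in results:
        row: dict[str, object] = {"group_id": r.group_id, "label": r.label}
        for c in clades:
            row[f"n_{c}"] = r.clade_counts.get(c, 0)
        row["total_counted_present"] = r.total_counted_present
        row["focal_present"] = r.focal_present
        row["n_foreign_species"] = len({sp for sp, _, _ in r.foreign_species})
        row["failed_criteria"] = ";".join(r.failed_criteria)
        rows.append(row)
    cols = ["group_id", "label"] + [f"n_{c}" for c in clades] + [
        "total_counted_present",
        "focal_present",
        "n_foreign_species",
        "failed_criteria",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# schema construction


def build_schema(
    species: Sequence[SpeciesRecord],
    *,
    clade_min_presence: Mapping[str, int],
    alternative_representatives: Iterable[str],
    total_min_presence: int,
    focal_species: str,
    control_required_species: Iterable[str],
    control_forbidden_species: Iterable[str] = (),
    control_forbidden_clades: Iterable[str] = ("Bacteria", "Archaea"),
    max_foreign_species: int = 2,
    max_foreign_rbbh_links: int = 3,
) -> CladeSchema:
    """Assemble a CladeSchema from a species table plus thresholds.

    Counted rosters follow the ``well_sequenced`` flag: counted metazoans are
    well-sequenced metazoans other than the focal species; counted
    non-metazoans are well-sequenced non-metazoans. Everything else lands in
    ``uncounted_species``.
    """
    by_code = {r.code: r for r in species}
    if focal_species not in by_code:
        raise ValueError(f"focal species {focal_species!r} not in the species table")
    counted_mz = frozenset(
        r.code for r in species if r.is_metazoan and r.well_sequenced and r.code != focal_species
    )
    counted_nonmz = frozenset(r.code for r in species if not r.is_metazoan and r.well_sequenced)
    uncounted = frozenset(
        r.code for r in species if not r.well_sequenced and r.code != focal_species
    )
    clade_members: dict[str, frozenset[str]] = {}
    for r in species:
        if r.code in counted_mz:
            clade_members.setdefault(r.clade, frozenset())
            clade_members[r.clade] = clade_members[r.clade] | {r.code}
    forbidden_clades = set(control_forbidden_clades)
    forbidden = frozenset(control_forbidden_species) | frozenset(
        r.code for r in species if r.clade in forbidden_clades
    )
    return CladeSchema(
        clade_members=clade_members,
        clade_min_presence=dict(clade_min_presence),
        alternative_representatives=frozenset(alternative_representatives),
        counted_metazoans=counted_mz,
        total_min_presence=total_min_presence,
        focal_species=focal_species,
        nonmetazoan_counted=counted_nonmz,
        control_required_species=frozenset(control_required_species),
        control_forbidden_species=forbidden,
        max_foreign_species=max_foreign_species,
        max_foreign_rbbh_links=max_foreign_rbbh_links,
        uncounted_species=uncounted,
    )


def load_schema_config(stream: TextIO) -> dict:
    """Parse the flat ``key = value`` schema config.

    Recognized keys: ``min_presence.<Clade>`` (int), ``total_min_presence``,
    ``max_foreign_species``, ``max_foreign_rbbh_links`` (ints),
    ``focal_species`` (token), ``alternative_representatives``,
    ``control_required``, ``control_forbidden``, ``control_forbidden_clades``
    (comma-separated lists).
    """
    int_keys = {"total_min_presence", "max_foreign_species", "max_foreign_rbbh_links"}
    list_keys = {
        "alternative_representatives",
        "control_required",
        "control_forbidden",
        "control_forbidden_clades",
    }
    out: dict = {"min_presence": {}}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"schema config line {lineno}: expected 'key = value'")
        key, value = key.strip(), value.strip()
        if key.startswith("min_presence."):
            out["min_presence"][key.split(".", 1)[1]] = int(value)
        elif key in int_keys:
            out[key] = int(value)
        elif key in list_keys:
            out[key] = [tok.strip() for tok in value.split(",") if tok.strip()]
        elif key == "focal_species":
            out[key] = value
        else:
            raise ValueError(f"schema config line {lineno}: unknown key {key!r}")
    return out


def schema_from_config(species: Sequence[SpeciesRecord], config: Mapping) -> CladeSchema:
    return build_schema(
        species,
        clade_min_presence=config.get("min_presence", {}),
        alternative_representatives=config.get("alternative_representatives", ()),
        total_min_presence=config["total_min_presence"],
        focal_species=config["focal_species"],
        control_required_species=config.get("control_required", ()),
        control_forbidden_species=config.get("control_forbidden", ()),
        control_forbidden_clades=config.get("control_forbidden_clades", ("Bacteria", "Archaea")),
        max_foreign_species=config.get("max_foreign_species", 2),
        max_foreign_rbbh_links=config.get("max_foreign_rbbh_links", 3),
    )
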