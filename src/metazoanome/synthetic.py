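"""Seeded generator of synthetic ortholog worlds and annotation bundles.

The generator plants ortholog groups with known class labels so that the
classifier's recovery can be scored against ground truth:

* ``metazoan_core`` — present in every counted metazoan and in the focal
  placozoan;
* ``eumetazoan_core_no_focal`` — present in every counted metazoan but absent
  from the focal genome (eumetazoan innovations);
* ``eukaryote_core`` — the control pattern: the five-species panel plus
  assorted metazoans and non-metazoan eukaryotes, never a prokaryote;
* ``clade_restricted`` — confined to a single metazoan clade;
* ``promiscuous`` — broadly shared with many non-metazoans including at
  least one prokaryote (so it can satisfy neither target predicate);
* ``contaminated_metazoan`` — a metazoan-core pattern plus one or two
  non-metazoan singleton members whose RBBH degree to the group's metazoan
  genes is drawn from a configurable distribution, emulating clustering
  false positives.

Two error processes of real clustering output are emulated: per-(group,
species) gene dropout (incomplete genomes) and the contaminating singletons
above. Truth labels are recorded before dropout, so recall under
incompleteness is measurable. Sequence evolution, branch lengths and BLAST
scores are not modelled.

All randomness flows through one ``numpy.random.Generator``; the same seed
and config give a byte-identical serialized world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import CladeSchema, build_schema
from .compstats import TISSUE_KEYWORDS, AnnotationBundle
from .ortho_model import (
    GeneID,
    GroupCollection,
    OrthologGroup,
    RBBHGraph,
    SpeciesRecord,
    write_groups,
    write_rbbh,
    write_species_table,
)

__all__ = [
    "CRANIATA",
    "ARTHROPODA",
    "NEMATODA",
    "UROCHORDATA",
    "CNIDARIA",
    "FOCAL",
    "default_species_table",
    "default_schema",
    "WorldConfig",
    "GroupTruth",
    "SyntheticWorld",
    "generate_world",
    "write_world",
    "truth_expected_label",
    "AnnotationConfig",
    "generate_annotations",
]

# default metazoan layout: 11 craniates, 1 urochordate, 8 arthropods,
# 3 nematodes, 1 cnidarian (the 24 counted metazoans) + the focal placozoan
CRANIATA = ("hsa", "mmu", "rno", "cfa", "bta", "mdo", "gga", "xtr", "dre", "tni", "gac")
ARTHROPODA = ("dme", "dps", "aga", "aae", "ame", "nvi", "phu", "isc")
NEMATODA = ("cel", "cbr", "bma")
UROCHORDATA = ("cin",)
CNIDARIA = ("nve",)
FOCAL = "tad"

_NAMED_NONMETAZOANS = (
    ("sce", "Saccharomyces cerevisiae", "Fungi"),
    ("spo", "Schizosaccharomyces pombe", "Fungi"),
    ("ncr", "Neurospora crassa", "Fungi"),
    ("ath", "Arabidopsis thaliana", "Viridiplantae"),
    ("osa", "Oryza sativa", "Viridiplantae"),
    ("cre", "Chlamydomonas reinhardtii", "Viridiplantae"),
    ("mbr", "Monosiga brevicollis", "Choanoflagellata"),
    ("ddi", "Dictyostelium discoideum", "Amoebozoa"),
    ("pfa", "Plasmodium falciparum", "Alveolata"),
    ("tth", "Tetrahymena thermophila", "Alveolata"),
    ("tbr", "Trypanosoma brucei", "Euglenozoa"),
    ("eco", "Escherichia coli", "Bacteria"),
    ("bsu", "Bacillus subtilis", "Bacteria"),
    ("sau", "Staphylococcus aureus", "Bacteria"),
    ("mtu", "Mycobacterium tuberculosis", "Bacteria"),
    ("mja", "Methanocaldococcus jannaschii", "Archaea"),
    ("pho", "Pyrococcus horikoshii", "Archaea"),
)

_CLADE_NAMES = {
    "Craniata": CRANIATA,
    "Arthropoda": ARTHROPODA,
    "Nematoda": NEMATODA,
    "Urochordata": UROCHORDATA,
    "Cnidaria": CNIDARIA,
}


def default_species_table(n_nonmetazoans: int = 112) -> list[SpeciesRecord]:
    """Default 138-genome roster: 24 counted metazoans, the focal placozoan,
    ``n_nonmetazoans`` counted non-metazoans and one poorly sequenced,
    uncounted non-metazoan."""
    records: list[SpeciesRecord] = []
    for clade, codes in _CLADE_NAMES.items():
        for code in codes:
            records.append(SpeciesRecord(code, f"{clade} sp. {code}", clade, True, True))
    records.append(SpeciesRecord(FOCAL, "Trichoplax adhaerens", "Placozoa", True, True))
    named = list(_NAMED_NONMETAZOANS)[:n_nonmetazoans]
    for code, name, clade in named:
        records.append(SpeciesRecord(code, name, clade, False, True))
    fillers = n_nonmetazoans - len(named)
    for i in range(fillers):
        clade = ("OtherEukaryota", "Bacteria")[i % 2]
        prefix = "ne" if clade == "OtherEukaryota" else "nb"
        records.append(
            SpeciesRecord(f"{prefix}{i:03d}", f"unnamed {clade} {i}", clade, False, True)
        )
    records.append(
        SpeciesRecord("frg", "fragmentary eukaryote", "OtherEukaryota", False, False)
    )
    return records


DEFAULT_MIN_PRESENCE = {"Craniata": 9, "Arthropoda": 6, "Nematoda": 2}
DEFAULT_CONTROL_REQUIRED = ("hsa", "cel", "dme", "sce", "ath")


def default_schema(species: Sequence[SpeciesRecord] | None = None) -> CladeSchema:
    """Schema carrying the default selection thresholds (9/11, 6/8, 2/3,
    >=1 of {nve, cin}, >=20 of 24, <=2 foreign species with <=3 RBBH links)."""
    if species is None:
        species = default_species_table()
    return build_schema(
        species,
        clade_min_presence=DEFAULT_MIN_PRESENCE,
        alternative_representatives=("nve", "cin"),
        total_min_presence=20,
        focal_species=FOCAL,
        control_required_species=DEFAULT_CONTROL_REQUIRED,
        control_forbidden_clades=("Bacteria", "Archaea"),
        max_foreign_species=2,
        max_foreign_rbbh_links=3,
    )


# ---------------------------------------------------------------------------
# world generation

DEFAULT_GROUP_COUNTS = {
    "metazoan_core": 346,
    "eumetazoan_core_no_focal": 180,
    "eukaryote_core": 1004,
    "clade_restricted": 600,
    "promiscuous": 250,
    "contaminated_metazoan": 120,
}

CLASS_LABELS = tuple(DEFAULT_GROUP_COUNTS)


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for a synthetic world.

    ``contamination_rbbh_degree`` maps RBBH degree -> probability for the
    links a contaminating foreign singleton makes to in-group metazoan genes
    (default uniform on 0–3, i.e. below the leakage threshold).
    """

    n_groups: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    dropout_rate: float = 0.0
    contamination_rbbh_degree: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}
    )
    contaminated_focal_prob: float = 0.66
    paralog_prob: float = 0.1
    n_nonmetazoans: int = 112
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        unknown = set(self.n_groups) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown group classes: {sorted(unknown)}")
        if any(v < 0 for v in self.n_groups.values()):
            raise ValueError("group counts must be >= 0")
        probs = list(self.contamination_rbbh_degree.values())
        if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0):
            raise ValueError("contamination_rbbh_degree must be a probability distribution")


@dataclass(frozen=True)
class GroupTruth:
    """Planted (pre-dropout) ground truth for one group."""

    group_id: str
    class_label: str
    focal_present: bool
    n_foreign: int = 0
    foreign_degrees: tuple[int, ...] = ()


@dataclass(frozen=True)
class SyntheticWorld:
    species: tuple[SpeciesRecord, ...]
    collection: GroupCollection
    rbbh: RBBHGraph
    truth: Mapping[str, GroupTruth]
    config: WorldConfig

    def schema(self) -> CladeSchema:
        return default_schema(self.species)


def truth_expected_label(truth: GroupTruth, schema: CladeSchema) -> str:
    """Label the classifier should assign to a noise-free realization."""
    if truth.class_label in ("metazoan_core", "eumetazoan_core_no_focal"):
        return "metazoan_specific"
    if truth.class_label == "contaminated_metazoan":
        ok = truth.n_foreign <= schema.max_foreign_species and all(
            d <= schema.max_foreign_rbbh_links for d in truth.foreign_degrees
        )
        return "metazoan_specific" if ok else "other"
    if truth.class_label == "eukaryote_core":
        return "eukaryote_core"
    return "other"


def _species_pools(species: Sequence[SpeciesRecord]) -> dict[str, list[str]]:
    pools: dict[str, list[str]] = {
        "counted_metazoans": [],
        "nonmz_eukaryotes": [],
        "prokaryotes": [],
        "all_nonmetazoans": [],
    }
    for r in species:
        if not r.well_sequenced:
            continue
        if r.is_metazoan and r.code != FOCAL:
            pools["counted_metazoans"].append(r.code)
        elif not r.is_metazoan:
            pools["all_nonmetazoans"].append(r.code)
            if r.clade in ("Bacteria", "Archaea"):
                pools["prokaryotes"].append(r.code)
            else:
                pools["nonmz_eukaryotes"].append(r.code)
    return pools


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Realize a synthetic world from the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    species = default_species_table(config.n_nonmetazoans)
    pools = _species_pools(species)
    counted = pools["counted_metazoans"]
    metazoan_clades = {c: list(codes) for c, codes in _CLADE_NAMES.items()}

    degrees = sorted(config.contamination_rbbh_degree)
    degree_p = np.array([config.contamination_rbbh_degree[d] for d in degrees], dtype=float)
    degree_p = degree_p / degree_p.sum()

    groups: list[OrthologGroup] = []
    truth: dict[str, GroupTruth] = {}
    rbbh = RBBHGraph()
    gid_counter = 0

    def _pick(pool: list[str], k: int) -> list[str]:
        k = min(k, len(pool))
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    for class_label in CLASS_LABELS:  # fixed order => determinism
        for _ in range(config.n_groups.get(class_label, 0)):
            gid = f"SOG{gid_counter:05d}"
            gid_counter += 1
            focal = False
            foreign: list[str] = []
            foreign_degrees: list[int] = []
            if class_label == "metazoan_core":
                sp = list(counted)
                focal = True
            elif class_label == "eumetazoan_core_no_focal":
                sp = list(counted)
            elif class_label == "eukaryote_core":
                sp = list(DEFAULT_CONTROL_REQUIRED)
                extra_mz = [c for c in counted if c not in sp]
                sp += _pick(extra_mz, int(rng.integers(5, len(extra_mz) + 1)))
                extra_euk = [c for c in pools["nonmz_eukaryotes"] if c not in sp]
                sp += _pick(extra_euk, int(rng.integers(2, 9)))
                focal = bool(rng.random() < 0.5)
            elif class_label == "clade_restricted":
                clade = list(metazoan_clades)[int(rng.integers(0, len(metazoan_clades)))]
                pool = metazoan_clades[clade]
                sp = _pick(pool, max(1, int(rng.integers(1, len(pool) + 1))))
            elif class_label == "promiscuous":
                sp = _pick(counted, int(rng.integers(10, 21)))
                sp += _pick(pools["nonmz_eukaryotes"], int(rng.integers(3, 8)))
                sp += _pick(pools["prokaryotes"], max(1, int(rng.integers(1, 3))))
                focal = bool(rng.random() < 0.3)
            elif class_label == "contaminated_metazoan":
                sp = list(counted)
                focal = bool(rng.random() < config.contaminated_focal_prob)
                n_foreign = int(rng.integers(1, 3))
                foreign = _pick(pools["all_nonmetazoans"], n_foreign)
                foreign_degrees = [
                    degrees[i] for i in rng.choice(len(degrees), size=len(foreign), p=degree_p)
                ]
            else:  # pragma: no cover
                raise AssertionError(class_label)
            if focal:
                sp = sp + [FOCAL]

            members: list[GeneID] = []
            for code in sp:
                n_genes = 1 + int(rng.random() < config.paralog_prob)
                for k in range(n_genes):
                    members.append(GeneID(code, f"{gid}.{k}" if k else gid))
            metazoan_genes = [
                m for m in members if m.species_code in counted or m.species_code == FOCAL
            ]
            for code, deg in zip(foreign, foreign_degrees):
                fg = GeneID(code, gid)
                members.append(fg)
                for i in rng.choice(len(metazoan_genes), size=min(deg, len(metazoan_genes)), replace=False):
                    rbbh.add_edge(fg, metazoan_genes[i])

            groups.append(OrthologGroup(group_id=gid, members=frozenset(members)))
            truth[gid] = GroupTruth(
                group_id=gid,
                class_label=class_label,
                focal_present=focal,
                n_foreign=len(foreign),
                foreign_degrees=tuple(foreign_degrees),
            )

    # dropout pass: per (group, species) gene omission emulating incomplete
    # genomes. A separate RNG stream keeps group composition identical to the
    # same-seed noise-free world, so dropout strictly thins groups.
    if config.dropout_rate > 0:
        drop_rng = np.random.default_rng([config.seed, 1])
        thinned: list[OrthologGroup] = []
        for g in groups:
            members = sorted(g.members)
            surviving: list[GeneID] = []
            for code in sorted({m.species_code for m in members}):
                if drop_rng.random() >= config.dropout_rate:
                    surviving.extend(m for m in members if m.species_code == code)
            if not surviving:  # keep the group parseable
                keep = members[int(drop_rng.integers(0, len(members)))]
                surviving = [m for m in members if m.species_code == keep.species_code]
            thinned.append(OrthologGroup(group_id=g.group_id, members=frozenset(surviving)))
        groups = thinned

    return SyntheticWorld(
        species=tuple(species),
        collection=GroupCollection(groups),
        rbbh=rbbh,
        truth=truth,
        config=config,
    )


def write_world(world: SyntheticWorld, directory: str | Path) -> None:
    """Serialize a world in the standard file formats plus a truth TSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "species.tsv", "w", encoding="utf-8") as fh:
        write_species_table(list(world.species), fh)
    with open(d / "groups.txt", "w", encoding="utf-8") as fh:
        write_groups(world.collection, fh)
    with open(d / "rbbh.tsv", "w", encoding="utf-8") as fh:
        write_rbbh(world.rbbh, fh)
    with open(d / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("group_id\tclass\tfocal_present\tn_foreign\tforeign_degrees\n")
        for gid in sorted(world.truth):
            t = world.truth[gid]
            degs = ";".join(str(x) for x in t.foreign_degrees)
            fh.write(
                f"{gid}\t{t.class_label}\t{str(t.focal_present).lower()}\t{t.n_foreign}\t{degs}\n"
            )
    with open(d / "config.txt", "w", encoding="utf-8") as fh:
        for label in CLASS_LABELS:
            fh.write(f"n_groups.{label} = {world.config.n_groups.get(label, 0)}\n")
        fh.write(f"dropout_rate = {world.config.dropout_rate}\n")
        fh.write(f"paralog_prob = {world.config.paralog_prob}\n")
        fh.write(f"n_nonmetazoans = {world.config.n_nonmetazoans}\n")
        fh.write(f"seed = {world.config.seed}\n")


# ---------------------------------------------------------------------------
# annotation generation

# phrases per tissue, each containing exactly one tissue's keyword stems
TISSUE_VOCABULARY: dict[str, tuple[str, ...]] = {
    "neuronal": ("head neurons", "ventral nerve cord", "pan-neuronal"),
    "muscle": ("body wall muscle", "vulval myofilaments"),
    "intestinal": ("intestinal cells", "gut granules"),
    "secretory_excretory": ("excretory canal", "gland cells", "secretory vesicles"),
    "hypodermal": ("hypodermal seam cells", "epidermal syncytium"),
    "reproductive": ("gonad sheath", "germline", "spermatheca", "uterine cells"),
}

# phrases hitting no tissue keyword (genes expressed only in unclassified cells)
NEUTRAL_PHRASES = ("pharyngeal cells", "coelomocytes", "rectal epithelial cells")


@dataclass(frozen=True)
class AnnotationConfig:
    """Planted annotation structure per gene set.

    Defaults mirror the proportions the comparative analyses are designed to
    detect: the metazoan-like set shows fewer essential but more
    developmental/behavioural RNAi phenotypes and more neuronal expression
    than the eukaryote-like control set.
    """

    n_categories: int = 40
    enriched_categories: Mapping[str, float] = field(default_factory=dict)  # cat -> fold
    foreground_set: str = "metazoan_specific"
    p_any_phenotype: Mapping[str, float] = field(
        default_factory=lambda: {"metazoan_specific": 0.55, "eukaryote_core": 0.74}
    )
    p_class: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "metazoan_specific": {"essential": 0.56, "development": 0.17, "movement": 0.07},
            "eukaryote_core": {"essential": 0.80, "development": 0.09, "movement": 0.03},
        }
    )
    tissue_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "metazoan_specific": {
                "neuronal": 0.72,
                "muscle": 0.30,
                "intestinal": 0.25,
                "secretory_excretory": 0.15,
                "hypodermal": 0.20,
                "reproductive": 0.25,
            },
            "eukaryote_core": {
                "neuronal": 0.54,
                "muscle": 0.30,
                "intestinal": 0.35,
                "secretory_excretory": 0.15,
                "hypodermal": 0.20,
                "reproductive": 0.25,
            },
        }
    )
    p_interaction_within: Mapping[str, float] = field(
        default_factory=lambda: {"metazoan_specific": 0.01, "eukaryote_core": 0.01}
    )
    p_interaction_cross: float = 0.005
    p_omim_key3: float = 0.16
    p_uncharacterized: float = 0.10

    def __post_init__(self) -> None:
        probs = [self.p_interaction_cross, self.p_omim_key3, self.p_uncharacterized]
        probs += list(self.p_any_phenotype.values())
        for m in self.p_class.values():
            probs += list(m.values())
        for m in self.tissue_probs.values():
            probs += list(m.values())
        probs += list(self.p_interaction_within.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


_ESSENTIAL_CODES = ("Emb", "Ste", "Stp", "Lvl", "Adl")
_DEVELOPMENT_CODES = ("Gro", "Lva", "Dpy", "Bmd", "Bli", "Slm", "Lon", "Sma", "Pvl", "Muv")
_MOVEMENT_CODES = ("Unc", "Prl", "Rol", "Egl")
# placeholder code for phenotypes outside the three super-classes
_OTHER_CODE = "Oth"


def generate_annotations(
    gene_sets: Mapping[str, Sequence[str]],
    config: AnnotationConfig,
    seed: int | np.random.Generator = 0,
) -> AnnotationBundle:
    """Sample an annotation bundle with the configured planted structure.

    ``gene_sets`` maps set name -> gene tokens (sets must be disjoint). Any
    set name appearing in a config table must be a key of ``gene_sets``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(gene_sets)
    all_genes: list[str] = []
    seen: set[str] = set()
    for name in names:
        for g in gene_sets[name]:
            if g in seen:
                raise ValueError(f"gene {g!r} appears in more than one set")
            seen.add(g)
            all_genes.append(g)
    for table in (config.p_any_phenotype, config.p_class, config.tissue_probs,
                  config.p_interaction_within):
        unknown = set(table) - set(names)
        if unknown:
            raise ValueError(f"config refers to unknown gene sets: {sorted(unknown)}")

    # --- categories: one per gene; enriched categories oversample the foreground
    cat_names = [f"cat{i:03d}" for i in range(config.n_categories)]
    for cat in config.enriched_categories:
        if cat not in cat_names:
            raise ValueError(f"enriched category {cat!r} outside cat000..cat{config.n_categories - 1:03d}")
    base_w = np.ones(config.n_categories)
    fg_w = base_w.copy()
    for cat, fold in config.enriched_categories.items():
        fg_w[cat_names.index(cat)] = fold
    base_w /= base_w.sum()
    fg_w /= fg_w.sum()
    categories: dict[str, frozenset[str]] = {}
    for name in names:
        w = fg_w if name == config.foreground_set else base_w
        for g in gene_sets[name]:
            categories[g] = frozenset({cat_names[int(rng.choice(config.n_categories, p=w))]})

    # --- RNAi phenotypes
    phenotypes: dict[str, frozenset[str]] = {}
    has_rnai: set[str] = set()
    for name in names:
        p_any = config.p_any_phenotype.get(name)
        if p_any is None:
            continue
        p_cls = config.p_class.get(name, {})
        for g in gene_sets[name]:
            has_rnai.add(g)
            if rng.random() >= p_any:
                continue
            codes: list[str] = []
            if rng.random() < p_cls.get("essential", 0.0):
                codes.append(_ESSENTIAL_CODES[int(rng.integers(0, len(_ESSENTIAL_CODES)))])
            if rng.random() < p_cls.get("development", 0.0):
                codes.append(_DEVELOPMENT_CODES[int(rng.integers(0, len(_DEVELOPMENT_CODES)))])
            if rng.random() < p_cls.get("movement", 0.0):
                codes.append(_MOVEMENT_CODES[int(rng.integers(0, len(_MOVEMENT_CODES)))])
            if not codes:
                codes.append(_OTHER_CODE)
            phenotypes[g] = frozenset(codes)

    # --- expression text assembled from tissue phrases
    expression: dict[str, str] = {}
    for name in names:
        probs = config.tissue_probs.get(name)
        if probs is None:
            continue
        for g in gene_sets[name]:
            phrases: list[str] = []
            for tissue in TISSUE_KEYWORDS:
                if rng.random() < probs.get(tissue, 0.0):
                    vocab = TISSUE_VOCABULARY[tissue]
                    phrases.append(vocab[int(rng.integers(0, len(vocab)))])
            if not phrases:
                phrases.append(NEUTRAL_PHRASES[int(rng.integers(0, len(NEUTRAL_PHRASES)))])
            expression[g] = "expressed in " + "; ".join(phrases)

    # --- interactions: independent edges within and across sets
    interactions: set[frozenset[str]] = set()
    for name in names:
        p = config.p_interaction_within.get(name, 0.0)
        genes = list(gene_sets[name])
        if p > 0 and len(genes) > 1:
            for i in range(len(genes)):
                hits = np.nonzero(rng.random(len(genes) - i - 1) < p)[0]
                for j in hits:
                    interactions.add(frozenset((genes[i], genes[i + 1 + int(j)])))
    if config.p_interaction_cross > 0 and len(names) >= 2:
        a, b = (list(gene_sets[names[0]]), list(gene_sets[names[1]]))
        for ga in a:
            hits = np.nonzero(rng.random(len(b)) < config.p_interaction_cross)[0]
            for j in hits:
                interactions.add(frozenset((ga, b[int(j)])))

    # --- disease keys and characterization flags
    omim = {
        g: (3 if rng.random() < config.p_omim_key3 else int(rng.integers(1, 3)))
        for g in all_genes
    }
    characterization: dict[str, tuple[bool, bool, bool]] = {}
    for g in all_genes:
        if rng.random() < config.p_uncharacterized:
            characterization[g] = (False, False, False)
        else:
            flags = [bool(rng.random() < 0.8) for _ in range(3)]
            if not any(flags):
                flags[int(rng.integers(0, 3))] = True
            characterization[g] = tuple(flags)  # type: ignore[assignment]

    return AnnotationBundle(
        categories=categories,
        phenotypes=phenotypes,
        has_rnai_data=frozenset(has_rnai),
        expression_text=expression,
        interactions=frozenset(interactions),
        omim_map_key=omim,
        characterized_flags=characterization,
    )
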