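"""Comparative statistics between gene sets.

Downstream of classification, the metazoan-specific genes are compared with a
control set of widely conserved eukaryotic genes along five axes: functional
category enrichment (hypergeometric tails with Benjamini–Hochberg FDR
control), RNAi phenotype super-classes (Essential / Development /
Movement-behaviour, compared by Fisher's exact test), tissue classification of
free-text expression annotations by Boolean keyword matching, partitioning of
a gene–gene interaction network into within-set and cross-set edges, OMIM
disease flagging (phenotype map key 3 = molecular basis known) and an
uncharacterized-gene screen (no annotation in any of three sources).

Exact-test machinery is delegated to scipy/statsmodels; the test suite checks
each against independent enumeration oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationBundle",
    "EnrichmentRow",
    "PhenotypeClassMap",
    "DEFAULT_CLASS_MAP",
    "PhenotypeSummary",
    "TissueFlags",
    "TISSUE_KEYWORDS",
    "ExpressionSummary",
    "InteractionPartition",
    "hypergeom_tail",
    "bh_adjust",
    "enrich_categories",
    "fisher_exact_2x2",
    "classify_phenotypes",
    "compare_proportions",
    "compare_sets_fisher",
    "classify_expression",
    "expression_summary",
    "interaction_partition",
    "disease_filter",
    "flag_uncharacterized",
    "read_annotation_bundle",
    "write_annotation_bundle",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class AnnotationBundle:
    """Static annotation tables keyed by gene token.

    ``characterized_flags`` maps gene -> (uniprot_annotated,
    wormbase_described, pubmed_hit).
    """

    categories: Mapping[str, frozenset[str]]
    phenotypes: Mapping[str, frozenset[str]]
    has_rnai_data: frozenset[str]
    expression_text: Mapping[str, str]
    interactions: frozenset[frozenset[str]]
    omim_map_key: Mapping[str, int]
    characterized_flags: Mapping[str, tuple[bool, bool, bool]]

    def __post_init__(self) -> None:
        for pair in self.interactions:
            if len(pair) != 2:
                raise ValueError(f"interaction self-pair or malformed edge: {set(pair)}")

    @classmethod
    def empty(cls) -> "AnnotationBundle":
        return cls({}, {}, frozenset(), {}, frozenset(), {}, {})


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    k: int  # foreground genes in category
    n: int  # annotated foreground genes
    K: int  # background genes in category
    N: int  # annotated background genes
    p_over: float
    p_under: float
    q: float
    direction: str  # "over" | "under"
    significant: bool


@dataclass(frozen=True)
class PhenotypeClassMap:
    """RNAi phenotype codes grouped into the three super-classes."""

    essential: frozenset[str] = frozenset({"Emb", "Ste", "Stp", "Lvl", "Adl"})
    development: frozenset[str] = frozenset(
        {"Gro", "Lva", "Dpy", "Bmd", "Bli", "Slm", "Lon", "Sma", "Pvl", "Muv"}
    )
    movement: frozenset[str] = frozenset({"Unc", "Prl", "Rol", "Egl"})

    def __post_init__(self) -> None:
        if (
            self.essential & self.development
            or self.essential & self.movement
            or self.development & self.movement
        ):
            raise ValueError("phenotype class code sets must be pairwise disjoint")

    @property
    def classes(self) -> dict[str, frozenset[str]]:
        return {
            "essential": self.essential,
            "development": self.development,
            "movement": self.movement,
        }

    @property
    def known_codes(self) -> frozenset[str]:
        return self.essential | self.development | self.movement


DEFAULT_CLASS_MAP = PhenotypeClassMap()


@dataclass(frozen=True)
class PhenotypeSummary:
    """Set-level RNAi phenotype counts and proportions.

    ``proportion_any`` is over genes with RNAi data; class proportions are
    over genes displaying at least one phenotype.
    """

    per_gene_classes: Mapping[str, frozenset[str]]
    n_rnai: int
    n_any_phenotype: int
    class_counts: Mapping[str, int]

    @property
    def proportion_any(self) -> float:
        return self.n_any_phenotype / self.n_rnai if self.n_rnai else float("nan")

    @property
    def class_proportions(self) -> dict[str, float]:
        denom = self.n_any_phenotype
        return {
            c: (k / denom if denom else float("nan")) for c, k in self.class_counts.items()
        }


TISSUE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "neuronal": ("nerv", "neuron"),
    "muscle": ("muscle", "myo"),
    "intestinal": ("gut", "intestin"),
    "secretory_excretory": ("gland", "secretory", "excretory"),
    "hypodermal": ("hypoderm", "epiderm"),
    "reproductive": ("uter", "gonad", "germ", "sperm", "oocyt", "reproduct"),
}


@dataclass(frozen=True)
class TissueFlags:
    neuronal: bool = False
    muscle: bool = False
    intestinal: bool = False
    secretory_excretory: bool = False
    hypodermal: bool = False
    reproductive: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @property
    def n_true(self) -> int:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class ExpressionSummary:
    """Any-expression and tissue-specific counts over annotated genes."""

    n_annotated: int
    any_counts: Mapping[str, int]
    specific_counts: Mapping[str, int]

    def any_proportions(self) -> dict[str, float]:
        d = self.n_annotated
        return {t: (k / d if d else float("nan")) for t, k in self.any_counts.items()}

    def specific_proportions(self) -> dict[str, float]:
        d = self.n_annotated
        return {t: (k / d if d else float("nan")) for t, k in self.specific_counts.items()}


@dataclass(frozen=True)
class InteractionPartition:
    """Edge partition of an interaction network restricted to two gene sets."""

    within_a: int
    within_b: int
    cross: int
    n_ignored_edges: int
    connected_fraction_a: float
    connected_fraction_b: float
    # per-gene averaged cross-set interaction fractions (see methods note)
    mean_cross_fraction_a: float
    mean_cross_fraction_b: float
    edge_records: tuple[tuple[str, str, str], ...]

    @property
    def n_retained(self) -> int:
        return self.within_a + self.within_b + self.cross

    def pooled_proportions(self) -> dict[str, float]:
        n = self.n_retained
        if n == 0:
            return {"withinA": 0.0, "withinB": 0.0, "cross": 0.0}
        return {"withinA": self.within_a / n, "withinB": self.within_b / n, "cross": self.cross / n}


# ---------------------------------------------------------------------------
# exact tests and multiplicity


def hypergeom_tail(k: int, n: int, K: int, N: int, tail: str) -> float:
    """Exact hypergeometric tail probability.

    X ~ Hypergeometric(population N, K successes, draw n); returns
    P(X >= k) for ``tail="over"`` and P(X <= k) for ``tail="under"``.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not isinstance(v, (int, np.integer)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= k <= n <= N and K <= N and k <= K):
        raise ValueError(f"invalid hypergeometric parameters k={k}, n={n}, K={K}, N={N}")
    rv = stats.hypergeom(N, K, n)
    if tail == "over":
        return float(rv.sf(k - 1))
    if tail == "under":
        return float(rv.cdf(k))
    raise ValueError(f"tail must be 'over' or 'under', got {tail!r}")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Two-sidedness follows the probability-mass rule: sum over tables (with
    the observed margins) whose conditional probability does not exceed the
    observed table's.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"table entry {name} must be a non-negative integer, got {v!r}")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# enrichment


def enrich_categories(
    foreground: Iterable[str],
    background: Iterable[str],
    bundle: AnnotationBundle,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric category enrichment of foreground within background.

    Genes without category annotations are excluded from both denominators.
    Both one-sided tails are computed per category; each tail family is
    BH-adjusted separately across categories, and the reported ``q`` is that
    of the smaller-p direction. Rows are sorted by (q, category).
    """
    fg = frozenset(foreground)
    bg = frozenset(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    annotated = frozenset(g for g in bg if bundle.categories.get(g))
    fg_ann = fg & annotated
    if not fg_ann:
        raise ValueError("no annotated foreground genes")
    n, N = len(fg_ann), len(annotated)
    cat_bg: dict[str, set[str]] = {}
    for g in annotated:
        for cat in bundle.categories[g]:
            cat_bg.setdefault(cat, set()).add(g)
    cats = sorted(cat_bg)
    p_over = []
    p_under = []
    kK = []
    for cat in cats:
        K = len(cat_bg[cat])
        k = len(cat_bg[cat] & fg_ann)
        kK.append((k, K))
        p_over.append(hypergeom_tail(k, n, K, N, "over"))
        p_under.append(hypergeom_tail(k, n, K, N, "under"))
    q_over = bh_adjust(p_over)
    q_under = bh_adjust(p_under)
    rows = []
    for i, cat in enumerate(cats):
        k, K = kK[i]
        over = p_over[i] <= p_under[i]
        q = q_over[i] if over else q_under[i]
        rows.append(
            EnrichmentRow(
                category=cat,
                k=k,
                n=n,
                K=K,
                N=N,
                p_over=p_over[i],
                p_under=p_under[i],
                q=q,
                direction="over" if over else "under",
                significant=q < alpha,
            )
        )
    rows.sort(key=lambda r: (r.q, r.category))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_over": r.p_over,
                "p_under": r.p_under,
                "q": r.q,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# RNAi phenotype classes


def classify_phenotypes(
    bundle: AnnotationBundle,
    genes: Iterable[str],
    class_map: PhenotypeClassMap = DEFAULT_CLASS_MAP,
) -> PhenotypeSummary:
    """Assign genes to phenotype super-classes and summarize proportions.

    A gene belongs to a class iff it carries at least one code of that class
    (multi-class membership allowed). Codes outside the map and outside the
    three classes are tolerated (a gene carrying only such codes still counts
    as displaying a phenotype); codes never seen in the map are logged once.
    """
    gene_set = frozenset(genes)
    per_gene: dict[str, frozenset[str]] = {}
    unknown: set[str] = set()
    n_any = 0
    class_counts = {name: 0 for name in class_map.classes}
    with_codes: set[str] = set()
    for g in sorted(gene_set):
        codes = bundle.phenotypes.get(g, frozenset())
        if codes:
            with_codes.add(g)
            n_any += 1
        unknown |= codes - class_map.known_codes
        classes = frozenset(
            name for name, members in class_map.classes.items() if codes & members
        )
        per_gene[g] = classes
        for name in classes:
            class_counts[name] += 1
    if unknown:
        logger.warning("ignoring %d phenotype codes outside the class map: %s",
                       len(unknown), sorted(unknown)[:10])
    n_rnai = len((gene_set & bundle.has_rnai_data) | with_codes)
    return PhenotypeSummary(
        per_gene_classes=per_gene,
        n_rnai=n_rnai,
        n_any_phenotype=n_any,
        class_counts=class_counts,
    )


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher p for k1/n1 vs k2/n2 (in-class vs not, set 1 vs set 2)."""
    return fisher_exact_2x2(k1, n1 - k1, k2, n2 - k2)


def compare_sets_fisher(a: PhenotypeSummary, b: PhenotypeSummary) -> dict[str, float]:
    """Per-comparison two-sided Fisher p-values between two phenotype summaries.

    "any" compares any-phenotype proportions over genes with RNAi data; each
    class compares class membership over genes displaying any phenotype.
    """
    out = {"any": compare_proportions(a.n_any_phenotype, a.n_rnai, b.n_any_phenotype, b.n_rnai)}
    for name in a.class_counts:
        out[name] = compare_proportions(
            a.class_counts[name], a.n_any_phenotype, b.class_counts[name], b.n_any_phenotype
        )
    return out


# ---------------------------------------------------------------------------
# expression keywords


def classify_expression(
    text: str, keywords: Mapping[str, tuple[str, ...]] = TISSUE_KEYWORDS
) -> TissueFlags:
    """Boolean tissue flags from free-text expression annotation.

    Case-insensitive plain substring match of each keyword stem; a tissue
    flag is true iff at least one of its stems occurs in the text.
    """
    low = text.lower()
    return TissueFlags(**{t: any(stem in low for stem in stems) for t, stems in keywords.items()})


def expression_summary(
    bundle: AnnotationBundle,
    genes: Iterable[str],
    keywords: Mapping[str, tuple[str, ...]] = TISSUE_KEYWORDS,
) -> ExpressionSummary:
    """Tissue counts over genes with non-empty expression text.

    "any" counts a gene for every tissue whose flag is true; "specific"
    counts it only when exactly one of the six flags is true.
    """
    any_counts = {t: 0 for t in keywords}
    specific_counts = {t: 0 for t in keywords}
    n_annotated = 0
    for g in sorted(frozenset(genes)):
        text = bundle.expression_text.get(g, "")
        if not text.strip():
            continue
        n_annotated += 1
        flags = classify_expression(text, keywords)
        d = flags.as_dict()
        for t, on in d.items():
            if on:
                any_counts[t] += 1
        if flags.n_true == 1:
            only = next(t for t, on in d.items() if on)
            specific_counts[only] += 1
    return ExpressionSummary(
        n_annotated=n_annotated, any_counts=any_counts, specific_counts=specific_counts
    )


# ---------------------------------------------------------------------------
# interactions, disease, characterization


def interaction_partition(
    bundle: AnnotationBundle, set_a: Iterable[str], set_b: Iterable[str]
) -> InteractionPartition:
    """Partition interaction edges into within-A / within-B / cross.

    Edges touching genes outside A ∪ B are ignored (counted). Per-gene
    connected fractions and per-gene averaged cross-set fractions are
    computed alongside the pooled edge counts.
    """
    A, B = frozenset(set_a), frozenset(set_b)
    if A & B:
        raise ValueError(f"gene sets overlap: {sorted(A & B)[:5]}")
    within_a = within_b = cross = ignored = 0
    records: list[tuple[str, str, str]] = []
    touched: dict[str, list[str]] = {}
    for pair in bundle.interactions:
        x, y = sorted(pair)
        in_a = (x in A, y in A)
        in_b = (x in B, y in B)
        if not ((in_a[0] or in_b[0]) and (in_a[1] or in_b[1])):
            ignored += 1
            continue
        if all(in_a):
            label = "withinA"
            within_a += 1
        elif all(in_b):
            label = "withinB"
            within_b += 1
        else:
            label = "cross"
            cross += 1
        records.append((x, y, label))
        touched.setdefault(x, []).append(label)
        touched.setdefault(y, []).append(label)
    if ignored:
        logger.info("interaction_partition: ignored %d edges outside the two sets", ignored)

    def _connected_fraction(S: frozenset[str]) -> float:
        return (sum(1 for g in S if g in touched) / len(S)) if S else 0.0

    def _mean_cross_fraction(S: frozenset[str]) -> float:
        fracs = [
            sum(1 for lab in labs if lab == "cross") / len(labs)
            for g, labs in touched.items()
            if g in S
        ]
        return float(np.mean(fracs)) if fracs else 0.0

    return InteractionPartition(
        within_a=within_a,
        within_b=within_b,
        cross=cross,
        n_ignored_edges=ignored,
        connected_fraction_a=_connected_fraction(A),
        connected_fraction_b=_connected_fraction(B),
        mean_cross_fraction_a=_mean_cross_fraction(A),
        mean_cross_fraction_b=_mean_cross_fraction(B),
        edge_records=tuple(sorted(records)),
    )


def disease_filter(bundle: AnnotationBundle, genes: Iterable[str]) -> frozenset[str]:
    """Genes whose OMIM phenotype map key is 3 (molecular basis known)."""
    return frozenset(g for g in genes if bundle.omim_map_key.get(g) == 3)


def flag_uncharacterized(bundle: AnnotationBundle, genes: Iterable[str]) -> frozenset[str]:
    """Genes with no annotation in any of the three characterization sources."""
    out = set()
    for g in sorted(frozenset(genes)):
        if g not in bundle.characterized_flags:
            raise KeyError(f"no characterization flags for gene {g!r}")
        if not any(bundle.characterized_flags[g]):
            out.add(g)
    return frozenset(out)


# ---------------------------------------------------------------------------
# bundle IO (one TSV per table, multi-valued fields semicolon-joined)

_FILES = {
    "categories": "categories.tsv",
    "phenotypes": "phenotypes.tsv",
    "rnai": "rnai_genes.tsv",
    "expression": "expression.tsv",
    "interactions": "interactions.tsv",
    "omim": "omim.tsv",
    "characterization": "characterization.tsv",
}


def _read_two_col(path: Path) -> list[tuple[str, str]]:
    rows = []
    if not path.exists():
        return rows
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows.append((parts[0], parts[1] if len(parts) > 1 else ""))
    return rows


def read_annotation_bundle(directory: str | Path) -> AnnotationBundle:
    """Load a bundle from a directory of TSVs; missing tables read as empty."""
    d = Path(directory)
    categories = {
        g: frozenset(v for v in val.split(";") if v)
        for g, val in _read_two_col(d / _FILES["categories"])
    }
    phenotypes = {
        g: frozenset(v for v in val.split(";") if v)
        for g, val in _read_two_col(d / _FILES["phenotypes"])
    }
    rnai = frozenset(g for g, _ in _read_two_col(d / _FILES["rnai"]))
    expression = {g: val for g, val in _read_two_col(d / _FILES["expression"])}
    interactions = set()
    for g1, g2 in _read_two_col(d / _FILES["interactions"]):
        if g1 == g2:
            raise ValueError(f"interaction self-pair for gene {g1!r}")
        interactions.add(frozenset((g1, g2)))
    omim = {g: int(val) for g, val in _read_two_col(d / _FILES["omim"])}
    characterization = {}
    path = d / _FILES["characterization"]
    if path.exists():
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                g, u, w, p = line.split("\t")
                characterization[g] = tuple(v.lower() == "true" for v in (u, w, p))
    return AnnotationBundle(
        categories=categories,
        phenotypes=phenotypes,
        has_rnai_data=rnai,
        expression_text=expression,
        interactions=frozenset(interactions),
        omim_map_key=omim,
        characterized_flags=characterization,
    )


def write_annotation_bundle(bundle: AnnotationBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    def _dump(name: str, rows: Iterable[tuple[str, ...]]) -> None:
        with open(d / _FILES[name], "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write("\t".join(row) + "\n")

    _dump("categories", ((g, ";".join(sorted(v))) for g, v in sorted(bundle.categories.items())))
    _dump("phenotypes", ((g, ";".join(sorted(v))) for g, v in sorted(bundle.phenotypes.items())))
    _dump("rnai", ((g,) for g in sorted(bundle.has_rnai_data)))
    _dump("expression", ((g, t) for g, t in sorted(bundle.expression_text.items())))
    _dump("interactions", (tuple(sorted(pair)) for pair in sorted(bundle.interactions, key=sorted)))
    _dump("omim", ((g, str(k)) for g, k in sorted(bundle.omim_map_key.items())))
    _dump(
        "characterization",
        (
            (g, *(str(bool(v)).lower() for v in flags))
            for g, flags in sorted(bundle.characterized_flags.items())
        ),
    )
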