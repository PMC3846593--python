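"""GO-slim set summaries and Fisher-exact gene-set enrichment.

Proteins are mapped to reduced Gene Ontology (GO-slim) terms in the three
aspects (cellular component, biological process, molecular function) and
summarized per protein set — here typically the ROS−-unique, ROS+-unique
and common sets from the comparison table. Gene-set enrichment uses the
right-tailed Fisher exact test: with a background universe of size M, a
gene set of size K and a query of size N overlapping the set in k genes,
p = P[X >= k] for X ~ Hypergeometric(M, K, N). The reported ratio is the
fraction of the gene set recovered in the query (k/K).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

UNANNOTATED = "unannotated"


class Aspect(str, enum.Enum):
    CELLULAR_COMPONENT = "cellular_component"
    BIOLOGICAL_PROCESS = "biological_process"
    MOLECULAR_FUNCTION = "molecular_function"


@dataclass(frozen=True)
class GOAnnotation:
    gene_symbol: str
    aspect: Aspect
    term: str
    go_id: str | None = None

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError(f"gene {self.gene_symbol}: empty GO term")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    ratio: float  # overlap / gene-set size
    p_value: float
    overlap_genes: frozenset[str] = frozenset()


def load_go_map(path) -> list[GOAnnotation]:
    """Load a gene→GO-slim TSV (gene_symbol, aspect, go_id, term).

    Duplicate rows are dropped; an unknown aspect string is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_symbol", "aspect", "term"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"GO map {path}: missing columns {missing}")
    annotations: list[GOAnnotation] = []
    seen = set()
    for row in df.itertuples(index=False):
        try:
            aspect = Aspect(row.aspect)
        except ValueError:
            raise ValueError(
                f"GO map {path}: unknown aspect {row.aspect!r} for gene "
                f"{row.gene_symbol!r}"
            ) from None
        key = (row.gene_symbol, aspect, row.term)
        if key in seen:
            continue
        seen.add(key)
        annotations.append(
            GOAnnotation(
                gene_symbol=row.gene_symbol,
                aspect=aspect,
                term=row.term,
                go_id=getattr(row, "go_id", "") or None,
            )
        )
    return annotations


def load_gene_sets(path) -> list[GeneSet]:
    """Load GMT-style gene sets: set_name <TAB> description <TAB> gene ..."""
    gene_sets = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"gene-set file {path}: line needs name, description "
                    f"and at least one gene: {line!r}"
                )
            gene_sets.append(
                GeneSet(
                    name=parts[0],
                    description=parts[1],
                    members=frozenset(g for g in parts[2:] if g),
                )
            )
    return gene_sets


def distribution(
    genes: set[str], annotations: list[GOAnnotation], aspect: Aspect
) -> dict[str, int]:
    """Term → number of query genes annotated to it, within one aspect.

    A gene with several terms counts once per term; genes with no
    annotation in the aspect are tallied under ``"unannotated"``.
    """
    counts: dict[str, int] = {}
    annotated: set[str] = set()
    for ann in annotations:
        if ann.aspect is aspect and ann.gene_symbol in genes:
            counts[ann.term] = counts.get(ann.term, 0) + 1
            annotated.add(ann.gene_symbol)
    n_unannotated = len(set(genes) - annotated)
    if n_unannotated:
        counts[UNANNOTATED] = n_unannotated
    return counts


def comparative_distribution(
    unique_minus: set[str],
    unique_plus: set[str],
    common: set[str],
    annotations: list[GOAnnotation],
) -> pd.DataFrame:
    """Per-set, per-aspect term counts as one tidy table.

    The three sets must be disjoint (they partition the identified
    proteins by pool membership).
    """
    sets = {
        "unique_ROS_minus": set(unique_minus),
        "unique_ROS_plus": set(unique_plus),
        "common": set(common),
    }
    names = list(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = sets[a] & sets[b]
            if overlap:
                raise ValueError(
                    f"protein sets must be disjoint; {a} and {b} share "
                    f"{sorted(overlap)}"
                )
    rows = []
    for set_name, genes in sets.items():
        for aspect in Aspect:
            for term, count in sorted(
                distribution(genes, annotations, aspect).items()
            ):
                rows.append(
                    {"set": set_name, "aspect": aspect.value,
                     "term": term, "count": count}
                )
    return pd.DataFrame(rows, columns=["set", "aspect", "term", "count"])


def enrich(
    dataset: set[str], gene_set: GeneSet, background_size: int
) -> EnrichmentResult:
    """Right-tailed Fisher exact enrichment of one gene set in the dataset."""
    dataset = set(dataset)
    if background_size < len(dataset):
        raise ValueError(
            f"background ({background_size}) smaller than dataset "
            f"({len(dataset)})"
        )
    if background_size < len(gene_set.members):
        raise ValueError(
            f"background ({background_size}) smaller than gene set "
            f"{gene_set.name!r} ({len(gene_set.members)})"
        )
    overlap_genes = dataset & gene_set.members
    k = len(overlap_genes)
    # P[X >= k], X ~ Hypergeom(M=background, K=set size, N=dataset size)
    p = float(
        hypergeom.sf(k - 1, background_size, len(gene_set.members), len(dataset))
    )
    return EnrichmentResult(
        set_name=gene_set.name,
        overlap=k,
        ratio=k / len(gene_set.members),
        p_value=min(p, 1.0),
        overlap_genes=frozenset(overlap_genes),
    )


def enrich_all(
    dataset: set[str],
    gene_sets: list[GeneSet],
    background_size: int,
    fdr: bool = True,
) -> pd.DataFrame:
    """Enrichment of every gene set, optionally with Benjamini–Hochberg q-values."""
    results = [enrich(dataset, gs, background_size) for gs in gene_sets]
    df = pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "ratio": [r.ratio for r in results],
            "p_value": [r.p_value for r in results],
            "overlap_genes": [
                ",".join(sorted(r.overlap_genes)) for r in results
            ],
        }
    )
    if fdr and len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
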