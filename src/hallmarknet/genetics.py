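"""GWAS filtering, windowed SNP-to-gene assignment, and GO over-representation.

The genetic confirmation arm of the pipeline takes genome-wide
association records, keeps genome-wide-significant hits (p < 5e-8) from
the ancestries of interest, assigns each SNP to the gene(s) containing
it or within a distance window (50 kbp by default; 75 kbp for the
re-run on newly prioritized diseases), pools genes over each hallmark's
top-ranked diseases into protein lists, and tests those lists for Gene
Ontology over-representation against an annotated background with a
one-sided Fisher exact (hypergeometric) test.  Finally, significant
terms whose names mention "pathway" or "cascade" are intersected across
all nine hallmark lists to find universally shared signaling pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .lexicon import Matcher

logger = logging.getLogger(__name__)

__all__ = [
    "GwasRecord",
    "GeneInterval",
    "GeneLinkTable",
    "EnrichmentResult",
    "read_gwas_catalog",
    "read_bed",
    "read_gaf_like",
    "read_obo_dag",
    "read_id_map",
    "filter_gwas_records",
    "assign_snps_to_genes",
    "build_hallmark_gene_sets",
    "propagate_annotation",
    "go_enrichment",
    "expected_overlap_count",
    "match_go_terms",
    "shared_significant_pathways",
    "pathway_ard_links",
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class GwasRecord:
    """One SNP–trait association from a GWAS-catalog-style table."""

    snp_id: str
    chrom: str
    position: int  # 1-based
    p_value: float
    mapped_trait: str
    ancestry: str = ""
    study_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"{self.snp_id}: p-value {self.p_value} outside (0, 1]")
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position {self.position} < 1")


@dataclass(frozen=True)
class GeneInterval:
    """A gene's span, 1-based inclusive; strand is informational only."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GeneLinkTable:
    """ARD–gene links with supporting SNPs, plus a gene-to-protein id map."""

    rows: pd.DataFrame  # columns: ard_id, gene_id, snp_ids (tuple of SNP ids)
    id_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.rows) and self.rows.duplicated(["ard_id", "gene_id"]).any():
            raise ValueError("duplicate (ard_id, gene_id) rows")

    def genes_for(self, ard_id: str) -> set[str]:
        if not len(self.rows):
            return set()
        return set(self.rows.loc[self.rows["ard_id"] == ard_id, "gene_id"])

    def ards_for_genes(self, genes: Iterable[str]) -> set[str]:
        gene_set = set(genes)
        if not len(self.rows):
            return set()
        return set(self.rows.loc[self.rows["gene_id"].isin(gene_set), "ard_id"])


@dataclass
class EnrichmentResult:
    """Per-GO-term over-representation statistics for one protein list."""

    table: pd.DataFrame  # term_id, name, list_count, term_size, expected, p_value, significant
    list_size: int
    background_size: int
    n_dropped: int
    method: str = "classic"

    def significant_terms(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "term_id"])


# ---------------------------------------------------------------------------
# readers


def read_gwas_catalog(path: str | Path) -> list[GwasRecord]:
    """Read a GWAS-catalog-dialect tab-delimited association table.

    Expected columns: ``SNPS``, ``CHR_ID``, ``CHR_POS``, ``P-VALUE``,
    ``MAPPED_TRAIT``, and optionally ``INITIAL SAMPLE SIZE`` (ancestry
    description) and ``PUBMEDID``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("SNPS", "CHR_ID", "CHR_POS", "P-VALUE", "MAPPED_TRAIT")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ancestry_col = next(
        (c for c in ("INITIAL SAMPLE SIZE", "ANCESTRY") if c in df.columns), None
    )
    records = []
    for _, d in df.iterrows():
        records.append(
            GwasRecord(
                snp_id=d["SNPS"],
                chrom=str(d["CHR_ID"]),
                position=int(d["CHR_POS"]),
                p_value=float(d["P-VALUE"]),
                mapped_trait=d["MAPPED_TRAIT"],
                ancestry=str(d[ancestry_col]) if ancestry_col else "",
                study_id=str(d["PUBMEDID"]) if "PUBMEDID" in df.columns else "",
            )
        )
    return records


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(
                GeneInterval(gene_id=name, chrom=chrom, start=start + 1, end=end, strand=strand)
            )
    return intervals


def read_gaf_like(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF-like annotation table (protein id, GO id, aspect) -> protein->terms."""
    annotation: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            protein, go_id = fields[0], fields[1]
            annotation.setdefault(protein, set()).add(go_id)
    return annotation


def read_obo_dag(path: str | Path):
    """Parse an OBO file into a DAG keeping only ``is_a`` edges.

    Returns a ``networkx.DiGraph`` with edges child -> parent and node
    attributes ``name`` and ``namespace``.
    """
    import networkx as nx
    import obonet

    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", ""), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (gene id, protein id) mapping file."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, protein = line.split("\t")[:2]
            mapping[gene] = protein
    return mapping


# ---------------------------------------------------------------------------
# filtering and assignment


def filter_gwas_records(
    records: Iterable[GwasRecord],
    p_threshold: float = GENOME_WIDE_P,
    ancestry_include: Sequence[str] = (),
    ancestry_exclude: Sequence[str] = (),
    exclude_study_ids: Iterable[str] = (),
) -> list[GwasRecord]:
    """Keep genome-wide-significant records from the ancestries of interest.

    A record survives if its p-value is strictly below *p_threshold*,
    its ancestry description contains at least one include pattern (no
    patterns = no ancestry requirement) and none of the exclude
    patterns (case-insensitive substring match; e.g. excluding
    ``"Amish"`` drops founder-population studies), and its study id is
    not in *exclude_study_ids* (used to remove studies overlapping the
    mined literature corpus).
    """
    excluded_studies = set(exclude_study_ids)
    kept = []
    for rec in records:
        if not rec.p_value < p_threshold:
            continue
        ancestry = rec.ancestry.lower()
        if ancestry_include and not any(pat.lower() in ancestry for pat in ancestry_include):
            continue
        if any(pat.lower() in ancestry for pat in ancestry_exclude):
            continue
        if rec.study_id in excluded_studies:
            continue
        kept.append(rec)
    return kept


def assign_snps_to_genes(
    records: Iterable[GwasRecord],
    intervals: Sequence[GeneInterval],
    window_bp: int = 50_000,
    trait_to_ard: Mapping[str, str] | None = None,
) -> GeneLinkTable:
    """Link each SNP to containing genes, or genes strictly within *window_bp*.

    Distance for a non-containing gene is to its nearest interval
    boundary (strand ignored).  A SNP 49,999 bp from a gene links at the
    default window; one exactly 50,000 bp away does not.  *trait_to_ard*
    maps each record's mapped-trait id to an ARD id; by default the
    trait id is used as the ARD id.  Records on chromosomes absent from
    the interval set are skipped with a logged count.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chrom_arrays = {
        c: (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
        for c, ivs in by_chrom.items()
    }
    links: dict[tuple[str, str], set[str]] = {}
    skipped = 0
    for rec in records:
        arrays = chrom_arrays.get(rec.chrom)
        if arrays is None:
            skipped += 1
            continue
        starts, ends = arrays
        hit = (rec.position > starts - window_bp) & (rec.position < ends + window_bp)
        ard = trait_to_ard.get(rec.mapped_trait, rec.mapped_trait) if trait_to_ard else rec.mapped_trait
        for idx in np.nonzero(hit)[0]:
            gene = by_chrom[rec.chrom][idx].gene_id
            links.setdefault((ard, gene), set()).add(rec.snp_id)
    if skipped:
        logger.warning("skipped %d records on chromosomes absent from intervals", skipped)
    rows = pd.DataFrame(
        [
            {"ard_id": ard, "gene_id": gene, "snp_ids": tuple(sorted(snps))}
            for (ard, gene), snps in sorted(links.items())
        ],
        columns=["ard_id", "gene_id", "snp_ids"],
    )
    return GeneLinkTable(rows=rows)


def build_hallmark_gene_sets(
    top_ards: Mapping[str, Sequence[str]],
    links: GeneLinkTable,
    id_map: Mapping[str, str] | None = None,
) -> dict[str, set[str]]:
    """Union of linked genes over each hallmark's top ARDs, mapped to proteins.

    *top_ards* maps hallmark id to its ranked ARD list (ids only or
    (id, score) pairs).  Genes without an entry in the id map are
    dropped with a logged count; ARDs without any GWAS link contribute
    nothing.
    """
    if id_map is None:
        id_map = links.id_map
    out: dict[str, set[str]] = {}
    for hallmark, ards in top_ards.items():
        genes: set[str] = set()
        for item in ards:
            ard = item[0] if isinstance(item, tuple) else item
            ard_genes = links.genes_for(ard)
            if not ard_genes:
                logger.info("hallmark %s: ARD %s has no GWAS gene links", hallmark, ard)
            genes |= ard_genes
        proteins = {id_map[g] for g in genes if g in id_map}
        unmapped = sum(1 for g in genes if g not in id_map)
        if unmapped:
            logger.warning("hallmark %s: %d genes without protein mapping", hallmark, unmapped)
        out[hallmark] = proteins
    return out


# ---------------------------------------------------------------------------
# GO over-representation


def propagate_annotation(annotation: Mapping[str, set[str]], dag) -> dict[str, set[str]]:
    """Extend annotations up the is_a hierarchy (true-path rule)."""
    import networkx as nx

    ancestor_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in ancestor_cache:
            ancestor_cache[term] = set(nx.descendants(dag, term)) if term in dag else set()
        return ancestor_cache[term]

    out: dict[str, set[str]] = {}
    for protein, terms in annotation.items():
        full = set(terms)
        for t in terms:
            full |= ancestors(t)
        out[protein] = full
    return out


def expected_overlap_count(list_size: int, term_size: int, background_size: int) -> float:
    """Expected overlap list_size * term_size / background_size under independence."""
    if background_size <= 0:
        raise ValueError("background_size must be positive")
    if term_size > background_size or list_size > background_size:
        raise ValueError("term or list larger than background")
    return list_size * term_size / background_size


def _fisher_upper_tail(x: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n): one-sided Fisher over-representation."""
    return float(hypergeom.sf(x - 1, big_n, big_k, n))


def go_enrichment(
    proteins: Iterable[str],
    annotation: Mapping[str, set[str]],
    background: Iterable[str],
    dag=None,
    min_term_size: int = 5,
    p_cutoff: float = 0.05,
    method: str = "classic",
) -> EnrichmentResult:
    """One-sided Fisher over-representation of GO terms in a protein list.

    The study list is intersected with the *background* universe;
    proteins outside it are dropped and counted.  Annotations are
    propagated up the is_a graph when *dag* is given (pass ``None`` if
    the annotation is already propagated).  Terms annotating fewer than
    *min_term_size* background proteins are not tested.

    ``method="elim"`` additionally processes terms deepest-first and
    removes the study proteins of already-significant descendant terms
    before testing ancestors, reducing the hierarchy redundancy of the
    classic test.
    """
    if method not in ("classic", "elim"):
        raise ValueError(f"unknown method {method!r}")
    background_set = set(background)
    study_all = set(proteins)
    study = study_all & background_set
    n_dropped = len(study_all) - len(study)
    if not study:
        raise ValueError("no study proteins left after intersecting with background")

    if dag is not None:
        annotation = propagate_annotation(annotation, dag)
    term_to_proteins: dict[str, set[str]] = {}
    for protein, terms in annotation.items():
        if protein not in background_set:
            continue
        for t in terms:
            term_to_proteins.setdefault(t, set()).add(protein)

    testable = {t: ps for t, ps in term_to_proteins.items() if len(ps) >= min_term_size}
    if method == "elim":
        order = _deepest_first(testable, dag)
    else:
        order = sorted(testable)

    eliminated: dict[str, set[str]] = {}
    big_n = len(background_set)
    n = len(study)
    rows = []
    for term in order:
        term_proteins = testable[term] - eliminated.get(term, set())
        big_k = len(term_proteins)
        x = len(study & term_proteins)
        p = _fisher_upper_tail(x, big_n, big_k, n) if big_k else 1.0
        significant = p < p_cutoff
        if method == "elim" and significant and dag is not None and term in dag:
            import networkx as nx

            for anc in nx.descendants(dag, term):
                eliminated.setdefault(anc, set()).update(study & term_proteins)
        name = dag.nodes[term].get("name", "") if dag is not None and term in dag else ""
        rows.append(
            {
                "term_id": term,
                "name": name,
                "list_count": x,
                "term_size": big_k,
                "expected": expected_overlap_count(n, big_k, big_n),
                "p_value": p,
                "significant": significant,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["term_id", "name", "list_count", "term_size", "expected", "p_value", "significant"],
    ).sort_values("p_value", kind="stable", ignore_index=True)
    return EnrichmentResult(
        table=table,
        list_size=n,
        background_size=big_n,
        n_dropped=n_dropped,
        method=method,
    )


def _deepest_first(terms: Mapping[str, set[str]], dag) -> list[str]:
    """Order term ids so descendants precede their ancestors (for elim)."""
    if dag is None:
        return sorted(terms)
    import networkx as nx

    def depth(t: str) -> int:
        return len(nx.descendants(dag, t)) if t in dag else 0

    return sorted(terms, key=lambda t: (-depth(t), t))


def match_go_terms(
    result: EnrichmentResult,
    keyword_sets: Mapping[str, Iterable[str]],
) -> dict[str, list[str]]:
    """Significant terms whose names contain a keyword, grouped by keyword set.

    Keywords are matched with the same normalisation and token-boundary
    rules as sentence matching (so "cascade" matches "...ERK1/2
    cascade" but not "cascaded").  *keyword_sets* maps a group label —
    a hallmark id, or e.g. ``"pathway"`` — to its keyword list.
    """
    sig = result.table.loc[result.table["significant"]]
    matcher = Matcher({label: list(kws) for label, kws in keyword_sets.items()})
    out: dict[str, list[str]] = {label: [] for label in keyword_sets}
    for row in sig.itertuples(index=False):
        for label in matcher.match(row.name or ""):
            out[label].append(row.term_id)
    return out


def shared_significant_pathways(
    results: Mapping[str, EnrichmentResult],
    pathway_keywords: Iterable[str] = ("pathway", "cascade"),
    expected_lists: int = 9,
) -> set[str]:
    """Pathway/cascade terms significantly enriched in every hallmark list.

    Requires exactly *expected_lists* results (the nine hallmarks by
    default; pass a different value for an explicit all-of-n run) and
    returns the intersection of their significant pathway-matched term
    ids.
    """
    if len(results) != expected_lists:
        raise ValueError(f"expected {expected_lists} enrichment results, got {len(results)}")
    keyword_sets = {"pathway": list(pathway_keywords)}
    shared: set[str] | None = None
    for result in results.values():
        matched = set(match_go_terms(result, keyword_sets)["pathway"])
        shared = matched if shared is None else shared & matched
    return shared or set()


def pathway_ard_links(
    pathway_terms: Iterable[str],
    protein_lists: Mapping[str, set[str]],
    links: GeneLinkTable,
    annotation: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Trace shared pathways back to genes and diseases.

    For each pathway term: the union, over all hallmark protein lists,
    of listed proteins annotated to the term; their underlying genes
    (via the link table's gene-to-protein map); and the ARDs those
    genes are linked to.  Emits one row per pathway with the protein /
    gene / ARD sets and their counts.
    """
    protein_to_genes: dict[str, set[str]] = {}
    for gene, protein in links.id_map.items():
        protein_to_genes.setdefault(protein, set()).add(gene)
    rows = []
    for term in sorted(set(pathway_terms)):
        proteins: set[str] = set()
        for plist in protein_lists.values():
            proteins |= {p for p in plist if term in annotation.get(p, set())}
        genes: set[str] = set()
        for p in proteins:
            genes |= protein_to_genes.get(p, set())
        ards = links.ards_for_genes(genes)
        rows.append(
            {
                "term_id": term,
                "proteins": tuple(sorted(proteins)),
                "genes": tuple(sorted(genes)),
                "ards": tuple(sorted(ards)),
                "n_proteins": len(proteins),
                "n_genes": len(genes),
                "n_ards": len(ards),
            }
        )
    return pd.DataFrame(
        rows, columns=["term_id", "proteins", "genes", "ards", "n_proteins", "n_genes", "n_ards"]
    )
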