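"""Synthetic corpora, disease networks, and genetics fixtures with known ground truth.

Every stage of the pipeline can be exercised without any external data:
the generators here emit (i) a sentence corpus in which chosen
hallmark–disease pairs co-occur with a configurable lift over
independence, (ii) age-stratified weighted disease networks with
planted dense modules on an Erdős–Rényi background, and (iii) a toy
GWAS / gene-interval / GO bundle with planted causal genes and one
universally enriched pathway term.  Each generator is a pure function
of its spec (seed included) and records the exact realized ground
truth, so downstream expected values never require re-reading the
generated data.

Sentences are templated — adequate because the mining pipeline is
co-mention-based, not syntactic.  Edge weights are drawn uniformly on
(0.05, 0.5] to mimic positive partial correlations while avoiding
zero-weight edges.  Default sizes mirror the real study's shape at desk
scale: 9 hallmarks, 184 ARDs, 4 age strata, 50,000 sentences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .lexicon import DiseaseDictionary, DiseaseEntry, Taxonomy, load_taxonomy
from .comention import CoMentionCounts
from .genetics import GeneInterval, GwasRecord
from .network import MorbidityNetwork

__all__ = [
    "CorpusSpec",
    "NetworkSpec",
    "GeneticsSpec",
    "CorpusResult",
    "NetworkResult",
    "GeneticsResult",
    "make_ard_dictionary",
    "default_corpus_spec",
    "generate_corpus",
    "generate_network",
    "generate_genetics",
    "DEFAULT_STRATA",
]

DEFAULT_STRATA = ("50-59", "60-69", "70-79", "80+")


def make_ard_dictionary(n_ards: int = 184, seed: int = 0) -> DiseaseDictionary:
    """A synthetic ARD dictionary with collision-free invented disease names.

    Entry ids are ``ARD001`` ... and each disease has two synonyms built
    from a unique token, so no synonym can match another disease or any
    hallmark term.  (*seed* is accepted for interface symmetry; the
    dictionary is deterministic.)
    """
    entries = [
        DiseaseEntry(
            ard_id=f"ARD{i:03d}",
            name=f"synthetic disease {i:03d}",
            synonyms=(f"morbus{i:03d}", f"syndroma {i:03d}x"),
        )
        for i in range(1, n_ards + 1)
    ]
    return DiseaseDictionary(entries)


# ---------------------------------------------------------------------------
# corpus


@dataclass
class CorpusSpec:
    """Spec for a synthetic sentence corpus with planted co-mention lift.

    ``planted`` maps (hallmark id, ARD id) to a lift factor L >= 1: the
    pair's joint mention probability is L * p_H * p_D (independence at
    L = 1).  Each ARD may appear in at most one planted pair.
    """

    n_sentences: int
    hallmark_probs: dict[str, float]
    ard_probs: dict[str, float]
    planted: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in list(self.hallmark_probs.values()) + list(self.ard_probs.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"mention probability {p} outside [0, 1]")
        seen_ards: set[str] = set()
        for (h, d), lift in self.planted.items():
            if lift < 1:
                raise ValueError(f"planted lift {lift} < 1 for pair ({h}, {d})")
            if h not in self.hallmark_probs or d not in self.ard_probs:
                raise ValueError(f"planted pair ({h}, {d}) not in marginals")
            joint = lift * self.hallmark_probs[h] * self.ard_probs[d]
            if joint > 1 or lift * self.ard_probs[d] > 1 or lift * self.hallmark_probs[h] > 1:
                raise ValueError(f"planted pair ({h}, {d}): infeasible joint probability")
            if d in seen_ards:
                raise ValueError(f"ARD {d} appears in more than one planted pair")
            seen_ards.add(d)


@dataclass
class CorpusResult:
    rows: list[tuple[str, str]]
    tallies: CoMentionCounts
    spec: CorpusSpec

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "corpus.tsv", "w", encoding="utf-8") as fh:
            for doc_id, sentence in self.rows:
                fh.write(f"{doc_id}\t{sentence}\n")
        with open(out / "corpus_truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("kind\thallmark_id\tard_id\tcount\n")
            for h, n in sorted(self.tallies.n_h.items()):
                fh.write(f"n_H\t{h}\t\t{n}\n")
            for d, n in sorted(self.tallies.n_d.items()):
                fh.write(f"n_D\t\t{d}\t{n}\n")
            for (h, d), n in sorted(self.tallies.n_hd.items()):
                fh.write(f"n_HD\t{h}\t{d}\t{n}\n")


def default_corpus_spec(
    dictionary: DiseaseDictionary,
    taxonomy: Taxonomy | None = None,
    n_sentences: int = 50_000,
    hallmark_prob: float = 0.02,
    ard_prob: float = 0.01,
    planted: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> CorpusSpec:
    """Study-shaped defaults: 9 hallmarks at p=0.02, ARDs at p=0.01, 50k sentences.

    With 50,000 sentences each disease draws ~500 mention sentences, so
    unplanted diseases comfortably clear the 250-sentence rarity filter
    while an order-of-magnitude smaller corpus would drop them.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    hallmark_ids = sorted({t.root_hallmark for t in taxonomy.terms})
    return CorpusSpec(
        n_sentences=n_sentences,
        hallmark_probs={h: hallmark_prob for h in hallmark_ids},
        ard_probs={d: ard_prob for d in dictionary.ard_ids},
        planted=dict(planted or {}),
        seed=seed,
    )


def generate_corpus(
    spec: CorpusSpec,
    dictionary: DiseaseDictionary,
    taxonomy: Taxonomy | None = None,
) -> CorpusResult:
    """Emit templated sentences realizing the spec's mention probabilities.

    Planted pairs are sampled so that the ARD's marginal probability is
    preserved while the joint probability equals lift * p_H * p_D.  The
    returned tallies are the exact realized counts of the emitted
    indicator draws, which sentence-level matching recovers verbatim.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    rng = np.random.default_rng(spec.seed)
    hallmarks = sorted(spec.hallmark_probs)
    ards = sorted(spec.ard_probs)
    n = spec.n_sentences

    h_ind = np.zeros((n, len(hallmarks)), dtype=bool)
    for j, h in enumerate(hallmarks):
        h_ind[:, j] = rng.random(n) < spec.hallmark_probs[h]

    planted_by_ard = {d: (h, lift) for (h, d), lift in spec.planted.items()}
    d_ind = np.zeros((n, len(ards)), dtype=bool)
    h_index = {h: j for j, h in enumerate(hallmarks)}
    for j, d in enumerate(ards):
        p_d = spec.ard_probs[d]
        if d in planted_by_ard:
            h, lift = planted_by_ard[d]
            p_h = spec.hallmark_probs[h]
            p_given_h = min(lift * p_d, 1.0)
            p_given_not = max((p_d - p_given_h * p_h) / (1 - p_h), 0.0) if p_h < 1 else 0.0
            active = h_ind[:, h_index[h]]
            u = rng.random(n)
            d_ind[:, j] = np.where(active, u < p_given_h, u < p_given_not)
        else:
            d_ind[:, j] = rng.random(n) < p_d

    hallmark_synonyms = {
        h: [t.synonyms[0] for t in taxonomy.terms if t.root_hallmark == h] for h in hallmarks
    }
    empty = [h for h, syns in hallmark_synonyms.items() if not syns]
    if empty:
        raise ValueError(f"no taxonomy synonyms for hallmarks: {empty}")
    ard_synonyms = dictionary.synonyms_by_id()
    # scatter synonym mentions column-by-column (vectorised synonym choice);
    # mention order within a sentence is hallmarks then diseases, deterministic
    sentence_mentions: list[list[str]] = [[] for _ in range(n)]
    for j, h in enumerate(hallmarks):
        syns = hallmark_synonyms[h]
        where = np.nonzero(h_ind[:, j])[0]
        for i, c in zip(where, rng.integers(len(syns), size=len(where))):
            sentence_mentions[i].append(syns[c])
    for j, d in enumerate(ards):
        syns = ard_synonyms[d]
        where = np.nonzero(d_ind[:, j])[0]
        for i, c in zip(where, rng.integers(len(syns), size=len(where))):
            sentence_mentions[i].append(syns[c])
    rows: list[tuple[str, str]] = []
    for i, mentions in enumerate(sentence_mentions):
        if mentions:
            sentence = ", ".join(mentions) + " were reported together in an elderly cohort."
        else:
            sentence = "no relevant findings were observed in this cohort."
        rows.append((f"doc{i:06d}", sentence))

    n_h = {h: int(h_ind[:, j].sum()) for j, h in enumerate(hallmarks)}
    n_d = {d: int(d_ind[:, j].sum()) for j, d in enumerate(ards)}
    joint = np.rint(h_ind.astype(np.float64).T @ d_ind.astype(np.float64)).astype(np.int64)
    n_hd = {
        (h, d): int(joint[hi, di])
        for hi, h in enumerate(hallmarks)
        for di, d in enumerate(ards)
        if joint[hi, di]
    }
    tallies = CoMentionCounts(n_h=n_h, n_d=n_d, n_hd=n_hd, total_sentences=n)
    return CorpusResult(rows=rows, tallies=tallies, spec=spec)


# ---------------------------------------------------------------------------
# networks


@dataclass
class NetworkSpec:
    """Spec for Erdős–Rényi disease networks with planted dense modules."""

    nodes: list[str]
    background_p: float = 0.05
    modules: list[tuple[frozenset[str], float]] = field(default_factory=list)
    strata: tuple[str, ...] = DEFAULT_STRATA
    weight_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_p <= 1:
            raise ValueError("background_p outside [0, 1]")
        node_set = set(self.nodes)
        for members, p_in in self.modules:
            if not 0 <= p_in <= 1:
                raise ValueError("module edge probability outside [0, 1]")
            if not members <= node_set:
                raise ValueError("module contains nodes outside the network")
            if len(members) > len(self.nodes):
                raise ValueError("module larger than node count")


@dataclass
class NetworkResult:
    networks: dict[str, MorbidityNetwork]
    ground_truth: dict  # per stratum: module membership and realized densities

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tstratum\n")
            for stratum, net in self.networks.items():
                for u, v, data in sorted(net.graph.edges(data=True)):
                    fh.write(f"{u}\t{v}\t{data['weight']:.6f}\t{stratum}\n")
        with open(out / "network_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=1)


def generate_network(spec: NetworkSpec) -> NetworkResult:
    """Sample one network per age stratum with planted dense modules.

    Within each module, node pairs connect with the module's internal
    probability; all other pairs use the background probability.
    Weights are uniform on the configured range (positive, mimicking
    partial correlations).  Ground truth records each module's realized
    internal density per stratum.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = sorted(spec.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    pair_p = np.full((n, n), spec.background_p)
    for members, p_in in spec.modules:
        idx = [index[v] for v in members]
        pair_p[np.ix_(idx, idx)] = p_in
    lo, hi = spec.weight_range
    networks: dict[str, MorbidityNetwork] = {}
    truth: dict = {"modules": [sorted(m) for m, _ in spec.modules], "strata": {}}
    iu = np.triu_indices(n, k=1)
    for stratum in spec.strata:
        present = rng.random(len(iu[0])) < pair_p[iu]
        weights = lo + (hi - lo) * rng.random(len(iu[0]))
        graph = nx.Graph()
        graph.add_nodes_from(nodes)
        for a, b, keep, w in zip(iu[0], iu[1], present, weights):
            if keep:
                graph.add_edge(nodes[a], nodes[b], weight=float(w))
        net = MorbidityNetwork(graph=graph, stratum=stratum)
        densities = []
        for members, _ in spec.modules:
            sub = graph.subgraph(members)
            v = len(members)
            densities.append(2 * sub.number_of_edges() / (v * (v - 1)) if v > 1 else 0.0)
        truth["strata"][stratum] = {
            "n_edges": graph.number_of_edges(),
            "module_densities": densities,
        }
        networks[stratum] = net
    return NetworkResult(networks=networks, ground_truth=truth)


# ---------------------------------------------------------------------------
# genetics


@dataclass
class GeneticsSpec:
    """Spec for a toy GWAS / gene / GO bundle with planted enrichment.

    ``hallmark_ards`` lists the (top-ranked) diseases per hallmark;
    each disease gets ``genes_per_ard`` causal genes.  True SNPs fall
    inside the gene or strictly within 50 kbp; one SNP per gene is
    placed between 50 and 75 kbp to exercise the wider window; decoy
    records carry sub-threshold p-values.  One GO term — the planted
    pathway — annotates a fixed fraction of every hallmark's causal
    proteins, making it significantly enriched in all nine lists.
    """

    hallmark_ards: dict[str, list[str]]
    genes_per_ard: int = 3
    snps_per_gene: int = 2
    gene_length: int = 20_000
    gene_spacing: int = 200_000
    n_background_extra: int = 200
    pathway_fraction: float = 0.6
    pathway_term: str = "GO:0000001"
    pathway_name: str = "synthetic aging signaling pathway"
    n_decoy_terms: int = 10
    decoy_term_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_ard < 1:
            raise ValueError("genes_per_ard must be >= 1")
        if not 0 < self.pathway_fraction <= 1:
            raise ValueError("pathway_fraction outside (0, 1]")


@dataclass
class GeneticsResult:
    records: list[GwasRecord]
    intervals: list[GeneInterval]
    annotation: dict[str, set[str]]
    dag: "nx.DiGraph"
    id_map: dict[str, str]
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "gwas.tsv", "w", encoding="utf-8") as fh:
            fh.write("SNPS\tCHR_ID\tCHR_POS\tP-VALUE\tMAPPED_TRAIT\tINITIAL SAMPLE SIZE\tPUBMEDID\n")
            for r in self.records:
                fh.write(
                    f"{r.snp_id}\t{r.chrom}\t{r.position}\t{r.p_value:.3e}\t"
                    f"{r.mapped_trait}\t{r.ancestry}\t{r.study_id}\n"
                )
        with open(out / "genes.bed", "w", encoding="utf-8") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n")
        with open(out / "annotation.tsv", "w", encoding="utf-8") as fh:
            for protein, terms in sorted(self.annotation.items()):
                for term in sorted(terms):
                    fh.write(f"{protein}\t{term}\tP\n")
        with open(out / "go.obo", "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.dag.nodes):
                data = self.dag.nodes[term]
                fh.write(f"\n[Term]\nid: {term}\nname: {data.get('name', '')}\n")
                fh.write("namespace: biological_process\n")
                for parent in sorted(self.dag.successors(term)):
                    fh.write(f"is_a: {parent} ! {self.dag.nodes[parent].get('name', '')}\n")
        with open(out / "id_map.tsv", "w", encoding="utf-8") as fh:
            for gene, protein in sorted(self.id_map.items()):
                fh.write(f"{gene}\t{protein}\n")
        with open(out / "genetics_truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=sorted)


def generate_genetics(spec: GeneticsSpec) -> GeneticsResult:
    """Build the GWAS table, gene intervals, GO bundle, and ground truth."""
    rng = np.random.default_rng(spec.seed)
    all_ards = sorted({a for ards in spec.hallmark_ards.values() for a in ards})

    # non-overlapping genes on one chromosome, spaced so windows never bridge genes
    causal: dict[str, list[str]] = {}
    intervals: list[GeneInterval] = []
    id_map: dict[str, str] = {}
    gene_counter = 0

    def new_gene() -> GeneInterval:
        nonlocal gene_counter
        gene_counter += 1
        start = 200_000 + (gene_counter - 1) * spec.gene_spacing
        iv = GeneInterval(
            gene_id=f"G{gene_counter:04d}",
            chrom="1",
            start=start,
            end=start + spec.gene_length - 1,
            strand="+",
        )
        intervals.append(iv)
        id_map[iv.gene_id] = f"P{gene_counter:04d}"
        return iv

    gene_intervals: dict[str, GeneInterval] = {}
    for ard in all_ards:
        causal[ard] = []
        for _ in range(spec.genes_per_ard):
            iv = new_gene()
            causal[ard].append(iv.gene_id)
            gene_intervals[iv.gene_id] = iv
    background_extra = [new_gene().gene_id for _ in range(spec.n_background_extra)]

    records: list[GwasRecord] = []
    snp_counter = 0

    def add_record(pos: int, p: float, trait: str, ancestry: str = "European") -> None:
        nonlocal snp_counter
        snp_counter += 1
        records.append(
            GwasRecord(
                snp_id=f"rs{snp_counter:06d}",
                chrom="1",
                position=pos,
                p_value=p,
                mapped_trait=trait,
                ancestry=ancestry,
                study_id="30000001",
            )
        )

    far_snps: list[str] = []
    for ard in all_ards:
        for gene in causal[ard]:
            iv = gene_intervals[gene]
            for _ in range(spec.snps_per_gene):
                pos = int(rng.integers(iv.start, iv.end + 1))
                add_record(pos, 10.0 ** -float(rng.uniform(9, 20)), ard)
            # one near-intergenic SNP strictly inside the 50 kbp window
            add_record(iv.start - int(rng.integers(1, 50_000)), 1e-10, ard)
            # one SNP in the 50–75 kbp band: invisible at 50 kbp, linked at 75 kbp
            add_record(iv.start - int(rng.integers(50_000, 75_000)), 1e-10, ard)
            far_snps.append(f"rs{snp_counter:06d}")
            # decoys: sub-threshold p-value, and an excluded founder population
            add_record(int(rng.integers(iv.start, iv.end + 1)), 1e-6, ard)
            add_record(int(rng.integers(iv.start, iv.end + 1)), 1e-10, ard, "European, Amish")

    # GO graph: root, a generic bucket term, the planted pathway, decoys
    dag = nx.DiGraph()
    root = "GO:0000000"
    dag.add_node(root, name="biological_process")
    generic = "GO:0000002"
    dag.add_node(generic, name="cellular process")
    dag.add_edge(generic, root)
    dag.add_node(spec.pathway_term, name=spec.pathway_name)
    dag.add_edge(spec.pathway_term, root)
    decoy_terms = []
    for i in range(spec.n_decoy_terms):
        term = f"GO:{1000 + i:07d}"
        name = f"decoy signaling pathway {i}" if i % 2 == 0 else f"decoy process {i}"
        dag.add_node(term, name=name)
        dag.add_edge(term, root)
        decoy_terms.append(term)

    proteins = sorted(id_map.values())
    annotation: dict[str, set[str]] = {p: {generic} for p in proteins}

    pathway_proteins: set[str] = set()
    hallmark_proteins: dict[str, set[str]] = {}
    for hallmark, ards in spec.hallmark_ards.items():
        members = sorted({id_map[g] for a in ards for g in causal[a]})
        hallmark_proteins[hallmark] = set(members)
        n_in = max(1, round(spec.pathway_fraction * len(members)))
        chosen = rng.choice(members, size=n_in, replace=False)
        pathway_proteins.update(chosen)
    extra_in_pathway = rng.choice(
        [id_map[g] for g in background_extra],
        size=min(10, len(background_extra)),
        replace=False,
    )
    pathway_proteins.update(extra_in_pathway)
    for p in pathway_proteins:
        annotation[p].add(spec.pathway_term)
    for term in decoy_terms:
        for p in rng.choice(proteins, size=min(spec.decoy_term_size, len(proteins)), replace=False):
            annotation[p].add(term)

    ground_truth = {
        "causal": {a: sorted(g) for a, g in causal.items()},
        "hallmark_proteins": {h: sorted(ps) for h, ps in hallmark_proteins.items()},
        "pathway_term": spec.pathway_term,
        "pathway_proteins": sorted(pathway_proteins),
        "background_extra_genes": background_extra,
        "far_snps": far_snps,
    }
    return GeneticsResult(
        records=records,
        intervals=intervals,
        annotation=annotation,
        dag=dag,
        id_map=id_map,
        ground_truth=ground_truth,
    )
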