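"""Deterministic synthetic-data generator with machine-readable ground truth.

Emits every input dialect the pipeline consumes — reference FASTA, NCBI
gene2go / gene2accession tables, OBO ontology, tabular similarity hits,
InterProScan-style TSV, enrichment annotation tables — so the whole toolset
is exercisable offline. Every generator takes an explicit seed and is
bit-reproducible; the seed is recorded in the truth object.

What is emulated: GO-shaped DAGs with three namespace roots, genes with
0-6 GO assignments (~10% NOT-qualified), protein sequences of 80-400
residues, point-mutated query homologs whose one true hit has an E-value
log-uniform in [1e-50, 1e-6], and decoy hits above 1e-4. What is not:
realistic protein evolution or realistic E-value/bit-score calibration —
E-values are monotone-plausible placeholders, sufficient for exercising
threshold and collapse logic but not for benchmarking sensitivity on real
proteomes. Fixture GO ids use the reserved high range GO:9000000+ so no
real term is ever implied.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .decoration import encode_decoration
from .errors import InputError
from .ontology import (GoTerm, NAMESPACE_CATEGORY, NAMESPACES, OntologyGraph,
                       serialize_obo)
from .refdb import GeneGoAssignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_TAXA = {9606: "Homo sapiens", 10090: "Mus musculus", 8355: "Xenopus laevis"}
_EVIDENCE_CODES = ("IEA", "IDA", "ISS", "IPI")

ROOT_BASE = 9000000  # GO:9000001..3 are the namespace roots
ALT_BASE = 9900000
ENRICH_TERM_BASE = 9100000


def _go(n: int) -> str:
    return f"GO:{n:07d}"


@dataclass
class ReferenceRecord:
    accession: str
    gene_id: int
    tax_id: int
    symbol: str
    description: str
    sequence: str
    assignments: list[GeneGoAssignment] = field(default_factory=list)


@dataclass
class QueryRecord:
    query_id: str
    source_accession: str
    n_mutations: int


@dataclass
class FixtureTruth:
    """Ground truth for everything a fixture run plants."""

    seed: int
    n_genes: int = 0
    n_terms: int = 0
    reference_records: list[ReferenceRecord] = field(default_factory=list)
    ontology_edges: list[tuple[str, str, str]] = field(default_factory=list)
    term_namespaces: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)
    query_records: list[QueryRecord] = field(default_factory=list)
    expected_transfers: dict[str, list[str]] = field(default_factory=dict)
    enrichment_truth: dict = field(default_factory=dict)

    def expected_transfer_sets(self) -> dict[str, set[str]]:
        return {q: set(v) for q, v in self.expected_transfers.items()}

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        raw = json.loads(text)
        raw["reference_records"] = [
            ReferenceRecord(**{**r, "assignments": [
                GeneGoAssignment(**a) for a in r["assignments"]]})
            for r in raw["reference_records"]]
        raw["query_records"] = [QueryRecord(**q) for q in raw["query_records"]]
        raw["ontology_edges"] = [tuple(e) for e in raw["ontology_edges"]]
        return cls(**raw)


class SimulatedReference(NamedTuple):
    fasta: str
    gene2go: str
    gene2accession: str
    obo: str
    truth: FixtureTruth


class SimulatedQueries(NamedTuple):
    query_fasta: str
    hits_tsv: str
    truth: FixtureTruth


class SimulatedEnrichment(NamedTuple):
    annotation_tsv: str
    study_ids: list[str]
    truth: FixtureTruth


# ---------------------------------------------------------------------------
# Ontology + reference set


def _random_ontology(n_terms: int, rng: np.random.Generator,
                     truth: FixtureTruth) -> OntologyGraph:
    graph = OntologyGraph()
    ids_by_ns: dict[str, list[str]] = {ns: [] for ns in NAMESPACES}
    for i, ns in enumerate(NAMESPACES):
        root = _go(ROOT_BASE + 1 + i)
        graph.add_term(GoTerm(id=root, name=f"{ns} root (synthetic)",
                              namespace=ns))
        ids_by_ns[ns].append(root)
        truth.term_namespaces[root] = ns
    alt_counter = 0
    for i in range(3, n_terms):
        go_id = _go(ROOT_BASE + 1 + i)
        ns = NAMESPACES[int(rng.integers(0, 3))]
        pool = ids_by_ns[ns]
        n_parents = 1 if len(pool) < 2 else int(rng.integers(1, 3))
        parent_idx = rng.choice(len(pool), size=n_parents, replace=False)
        parents = {pool[int(j)] for j in parent_idx}
        edge_types = {}
        for p in sorted(parents):
            etype = "part_of" if rng.random() < 0.2 else "is_a"
            edge_types[p] = etype
            truth.ontology_edges.append((go_id, p, etype))
        alt_ids = []
        if rng.random() < 0.05:
            alt_counter += 1
            alt = _go(ALT_BASE + alt_counter)
            alt_ids.append(alt)
            truth.alt_ids[alt] = go_id
        graph.add_term(GoTerm(id=go_id, name=f"synthetic term {i}",
                              namespace=ns, parents=parents,
                              edge_types=edge_types), alt_ids=alt_ids)
        ids_by_ns[ns].append(go_id)
        truth.term_namespaces[go_id] = ns
    graph.validate()
    return graph


def _random_protein(rng: np.random.Generator) -> str:
    length = int(rng.integers(80, 401))
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_reference(n_genes: int, n_terms: int, seed: int,
                       accessions_per_gene: tuple[int, int] = (1, 1),
                       ) -> SimulatedReference:
    """Reference FASTA + gene2go + gene2accession + OBO, with ground truth.

    Genes carry 0-6 GO assignments (~10% NOT-qualified, qualifier
    "NOT located_in"). By default each gene has one versioned protein
    accession; pass e.g. ``accessions_per_gene=(2, 3)`` to emulate isoform
    accessions, all of which inherit the gene's assignments.
    """
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    if n_terms < 3:
        raise InputError("n_terms must be >= 3 (one root per namespace)")
    lo_acc, hi_acc = accessions_per_gene
    if lo_acc < 1 or hi_acc < lo_acc:
        raise InputError("accessions_per_gene must be a range with lo >= 1")
    rng = np.random.default_rng(seed)
    truth = FixtureTruth(seed=seed, n_genes=n_genes, n_terms=n_terms)
    graph = _random_ontology(n_terms, rng, truth)

    assignable = sorted(t for t in graph.terms
                        if t not in {_go(ROOT_BASE + 1 + i) for i in range(3)})
    taxa = sorted(_TAXA)

    fasta_lines: list[str] = []
    g2g_rows = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed"
                "\tCategory"]
    g2a_rows = ["#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version"
                "\tRNA_nucleotide_gi\tprotein_accession.version\tprotein_gi"
                "\tgenomic_nucleotide_accession.version\tgenomic_nucleotide_gi"
                "\tstart_position_on_the_genomic_accession"
                "\tend_position_on_the_genomic_accession\torientation"
                "\tassembly\tmature_peptide_accession.version"
                "\tmature_peptide_gi\tSymbol"]

    acc_counter = 0
    for g in range(n_genes):
        gene_id = 1001 + g
        tax_id = int(taxa[int(rng.integers(0, len(taxa)))])
        symbol = f"SYN{g + 1:05d}"
        n_assign = int(rng.integers(0, 7))
        n_assign = min(n_assign, len(assignable))
        term_idx = rng.choice(len(assignable), size=n_assign, replace=False)
        assignments = []
        for j in sorted(int(t) for t in term_idx):
            go_id = assignable[j]
            not_flag = rng.random() < 0.10
            evidence = _EVIDENCE_CODES[int(rng.integers(0, len(_EVIDENCE_CODES)))]
            assignments.append(GeneGoAssignment(
                tax_id=tax_id, gene_id=gene_id, go_id=go_id,
                evidence=evidence,
                qualifier="NOT located_in" if not_flag else "",
                category=NAMESPACE_CATEGORY[graph.namespace_of(go_id)]))
        for a in assignments:
            g2g_rows.append("\t".join([
                str(a.tax_id), str(a.gene_id), a.go_id, a.evidence,
                a.qualifier or "-", graph.name_of(a.go_id), "-", a.category]))

        n_acc = int(rng.integers(lo_acc, hi_acc + 1))
        for _ in range(n_acc):
            acc_counter += 1
            version = int(rng.integers(1, 4))
            accession = f"XP_{acc_counter:07d}.{version}"
            sequence = _random_protein(rng)
            description = (f"{accession} synthetic protein {symbol} "
                           f"[{_TAXA[tax_id]}]")
            truth.reference_records.append(ReferenceRecord(
                accession=accession, gene_id=gene_id, tax_id=tax_id,
                symbol=symbol, description=description, sequence=sequence,
                assignments=list(assignments)))
            fasta_lines.append(f">{description}")
            for k in range(0, len(sequence), 60):
                fasta_lines.append(sequence[k:k + 60])
            g2a_row = ["-"] * 16
            g2a_row[0], g2a_row[1] = str(tax_id), str(gene_id)
            g2a_row[5], g2a_row[15] = accession, symbol
            g2a_rows.append("\t".join(g2a_row))

    return SimulatedReference(
        fasta="\n".join(fasta_lines) + "\n",
        gene2go="\n".join(g2g_rows) + "\n",
        gene2accession="\n".join(g2a_rows) + "\n",
        obo=serialize_obo(graph),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Queries + tabular hits (stands in for the external aligner)


def _decorated_title(rec: ReferenceRecord) -> str:
    if not rec.assignments:
        return rec.description
    block = encode_decoration(
        rec.symbol, rec.tax_id,
        [(a.go_id, a.evidence, a.category, a.not_flag)
         for a in rec.assignments])
    return f"{rec.description} {block}"


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        old = chars[int(pos)]
        alternatives = [a for a in AMINO_ACIDS if a != old]
        chars[int(pos)] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(chars)


def _hit_row(qid: str, rec: ReferenceRecord, length: int, mismatches: int,
             evalue: float, rng: np.random.Generator) -> str:
    pident = 100.0 * (length - mismatches) / length
    bit = 2.0 * length * (1.0 - mismatches / length) + float(rng.integers(0, 20))
    return "\t".join([
        qid, rec.accession, f"{pident:.1f}", str(length), str(mismatches),
        "0", "1", str(length), "1", str(length), f"{evalue:.3e}",
        f"{bit:.1f}", _decorated_title(rec)])


def generate_queries_and_hits(truth: FixtureTruth, mutation_rate: float = 0.02,
                              n_decoys: int = 0, seed: int = 0,
                              n_queries: Optional[int] = None,
                              ) -> SimulatedQueries:
    """Point-mutated query copies of the reference plus a tabular hit stream.

    Each query gets exactly one true hit against its source accession with
    an E-value log-uniform in [1e-50, 1e-6]; decoys pair random queries
    with random non-source subjects at E-values log-uniform in
    [1.1e-4, 10]. ``expected_transfers`` records, per query, the source
    gene's non-NOT GO ids (what the pipeline must recover at any cutoff
    in [1e-6, 1e-4]).
    """
    if not 0 <= mutation_rate < 0.5:
        raise InputError("mutation_rate must lie in [0, 0.5)")
    if not truth.reference_records:
        raise InputError("truth carries no reference records")
    rng = np.random.default_rng(seed)
    sources = truth.reference_records
    if n_queries is None:
        n_queries = len(sources)

    truth.query_records = []
    truth.expected_transfers = {}
    fasta_lines: list[str] = []
    hit_rows: list[str] = []
    for i in range(n_queries):
        rec = sources[i % len(sources)]
        qid = f"q{i + 1:06d}"
        n_mut = int(round(mutation_rate * len(rec.sequence)))
        seq = _mutate(rec.sequence, n_mut, rng)
        fasta_lines.append(f">{qid} mutated copy of {rec.accession}")
        for k in range(0, len(seq), 60):
            fasta_lines.append(seq[k:k + 60])
        truth.query_records.append(QueryRecord(qid, rec.accession, n_mut))
        truth.expected_transfers[qid] = sorted(
            {a.go_id for a in rec.assignments if not a.not_flag})
        evalue = float(10 ** rng.uniform(-50, -6))
        hit_rows.append(_hit_row(qid, rec, len(seq), n_mut, evalue, rng))

    for _ in range(n_decoys):
        qi = int(rng.integers(0, n_queries))
        qid = f"q{qi + 1:06d}"
        others = [r for r in sources
                  if r.accession != truth.query_records[qi].source_accession]
        rec = others[int(rng.integers(0, len(others)))] if others else sources[0]
        evalue = float(10 ** rng.uniform(np.log10(1.1e-4), 1.0))
        length = min(len(rec.sequence), 60)
        hit_rows.append(_hit_row(qid, rec, length, int(0.6 * length),
                                 evalue, rng))

    return SimulatedQueries(
        query_fasta="\n".join(fasta_lines) + "\n",
        hits_tsv="\n".join(hit_rows) + ("\n" if hit_rows else ""),
        truth=truth,
    )


def generate_interpro_tsv(truth: FixtureTruth, n_rows: int, seed: int) -> str:
    """Synthetic InterProScan-style 15-column TSV over the truth's queries.

    Rows draw random queries and random ontology terms; ~20% of rows carry
    a '-' GO column and GO tokens alternate between bare accessions and the
    "GO:...(InterPro)" suffixed form, exercising both dialects.
    """
    if not truth.query_records:
        raise InputError("truth carries no query records")
    rng = np.random.default_rng(seed)
    terms = sorted(truth.term_namespaces)
    rows = []
    for i in range(n_rows):
        q = truth.query_records[int(rng.integers(0, len(truth.query_records)))]
        if rng.random() < 0.2 or not terms:
            go_col = "-"
        else:
            k = int(rng.integers(1, 4))
            picks = rng.choice(len(terms), size=min(k, len(terms)),
                               replace=False)
            tokens = []
            for j, p in enumerate(sorted(int(x) for x in picks)):
                token = terms[p]
                if j % 2 == 1:
                    token += "(InterPro)"
                tokens.append(token)
            go_col = "|".join(tokens)
        rows.append("\t".join([
            q.query_id, "-", "300", "Pfam", f"PF{i + 1:05d}",
            "synthetic domain", "1", "120", "1e-10", "T", "-",
            f"IPR{i + 1:06d}", "synthetic entry", go_col, "-"]))
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# Enrichment scenarios


def generate_enrichment_scenario(n_genes: int, n_terms: int, n_enriched: int,
                                 fold: float, seed: int,
                                 study_size: Optional[int] = None,
                                 ) -> SimulatedEnrichment:
    """Annotation table + study list with planted fold-enriched terms.

    Background term frequencies are uniform(0.02, 0.2); planted terms'
    frequencies are capped at 1/fold so the study frequency fold*f is a
    valid probability, and study genes carry planted terms at fold times
    the background rate. fold=1 is an exchangeable null. Genes that would
    end up term-less receive one frequency-weighted term so every gene
    belongs to the default (annotated-genes) universe.
    """
    if fold < 1:
        raise InputError("fold must be >= 1")
    if n_enriched >= n_terms:
        raise InputError("n_enriched must be < n_terms")
    if fold * 0.02 > 1:
        raise InputError(f"infeasible fold {fold}: frequency*fold exceeds 1")
    rng = np.random.default_rng(seed)
    if study_size is None:
        study_size = max(1, n_genes // 10)
    if study_size >= n_genes:
        raise InputError("study_size must be < n_genes")

    freqs = rng.uniform(0.02, 0.2, size=n_terms)
    planted_idx = np.sort(rng.choice(n_terms, size=n_enriched, replace=False))
    if fold > 1 and n_enriched:
        freqs[planted_idx] = rng.uniform(0.02, min(0.2, 1.0 / fold),
                                         size=n_enriched)
    term_ids = [_go(ENRICH_TERM_BASE + 1 + i) for i in range(n_terms)]
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    study = genes[:study_size]

    probs = np.tile(freqs, (n_genes, 1))
    if n_enriched:
        probs[:study_size, planted_idx] = np.minimum(
            1.0, freqs[planted_idx] * fold)
    membership = rng.random((n_genes, n_terms)) < probs
    weights = freqs / freqs.sum()
    for i in range(n_genes):
        if not membership[i].any():
            membership[i, int(rng.choice(n_terms, p=weights))] = True

    rows = ["#query_id\tsymbol\ttaxon\tgo_terms"]
    gene_terms: dict[str, list[str]] = {}
    for i, gene in enumerate(genes):
        terms = [term_ids[j] for j in np.flatnonzero(membership[i])]
        gene_terms[gene] = terms
        entries = ";".join(f"{t}(IEA,-,{1e-10!r})" for t in terms)
        rows.append(f"{gene}\t-\t-\t{entries}")

    truth = FixtureTruth(seed=seed, n_genes=n_genes, n_terms=n_terms)
    truth.enrichment_truth = {
        "planted_terms": [term_ids[int(j)] for j in planted_idx],
        "fold": fold,
        "frequencies": {term_ids[j]: float(freqs[j]) for j in range(n_terms)},
        "study": list(study),
        "study_size": study_size,
        "gene_terms": {g: list(ts) for g, ts in gene_terms.items()},
    }
    return SimulatedEnrichment(
        annotation_tsv="\n".join(rows) + "\n",
        study_ids=list(study),
        truth=truth,
    )
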