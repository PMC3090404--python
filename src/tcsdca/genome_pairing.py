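"""Cognate-pair and orphan extraction from gene and domain-hit tables.

Genes are classified as sensor kinase (SK), response regulator (RR), hybrid
or other from profile-HMM domain hits; operons are called as maximal runs
of same-strand neighbors separated by at most a fixed intergenic distance;
an operon containing exactly one SK and exactly one RR yields a cognate
pair.  SK/RR genes with no adjacent partner become orphans, except RRs that
sit in operons with an alternative kinase class or an Hpt phosphotransfer
domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .msa_io import PairingTable

#: sensor-kinase domain families, in the order used for E-value tie-breaks
SK_DOMAINS: tuple[str, ...] = (
    "HisKA",
    "HWE_HK",
    "HisKA_2",
    "HisKA_3",
    "His_kinase",
)
#: alternative SK classes + Hpt whose presence in an operon disqualifies an
#: RR from orphan status (it likely partners one of them)
ALT_KINASE_DOMAINS: tuple[str, ...] = ("HisKA_2", "HisKA_3", "HWE_HK", "Hpt")
SUPPORT_DOMAIN = "HATPase_c"
RR_DOMAIN = "Response_reg"


@dataclass(frozen=True)
class GeneRecord:
    """A gene's location: replicon, strand and bp coordinates (start < end)."""

    gene_id: str
    replicon: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative coordinate")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain: str
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"{self.gene_id}: E-value must be positive")


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    gene_class: str  # SK | RR | hybrid | other
    sk_domain: str | None = None  # best-E-value SK domain family, if any


def classify_genes(
    hits: list[DomainHit],
    sk_evalue_max: float = 10.0,
    support_evalue_max: float = 0.01,
    rr_evalue_max: float = 0.01,
) -> list[GeneClass]:
    """Classify genes from their domain hits.

    An SK call requires an accepted sensor-kinase domain (best E-value among
    the SK families selects the type) *and* a C-terminal ATPase support
    domain below its own threshold.  An RR call requires a receiver domain
    below threshold.  A gene satisfying both is a hybrid.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    out: list[GeneClass] = []
    for gene_id, gh in by_gene.items():
        sk_hits = [
            h for h in gh if h.domain in SK_DOMAINS and h.evalue <= sk_evalue_max
        ]
        has_support = any(
            h.domain == SUPPORT_DOMAIN and h.evalue <= support_evalue_max
            for h in gh
        )
        is_rr = any(
            h.domain == RR_DOMAIN and h.evalue <= rr_evalue_max for h in gh
        )
        best_sk = None
        if sk_hits and has_support:
            best_sk = min(
                sk_hits, key=lambda h: (h.evalue, SK_DOMAINS.index(h.domain))
            ).domain
        if best_sk and is_rr:
            out.append(GeneClass(gene_id, "hybrid", best_sk))
        elif best_sk:
            out.append(GeneClass(gene_id, "SK", best_sk))
        elif is_rr:
            out.append(GeneClass(gene_id, "RR"))
        else:
            out.append(GeneClass(gene_id, "other"))
    return out


def call_operons(
    genes: list[GeneRecord], max_gap_bp: int = 200
) -> list[list[str]]:
    """Group genes into operons.

    An operon is a maximal run of consecutive same-strand genes on one
    replicon whose intergenic distances (next.start - prev.end, floored at
    0 for overlaps) do not exceed ``max_gap_bp``; the boundary value itself
    is inside the operon.
    """
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start, g.gene_id))
    operons: list[list[str]] = []
    current: list[GeneRecord] = []
    for g in ordered:
        if current:
            prev = current[-1]
            gap = max(0, g.start - prev.end)
            same_run = (
                g.replicon == prev.replicon
                and g.strand == prev.strand
                and gap <= max_gap_bp
            )
            if not same_run:
                operons.append([x.gene_id for x in current])
                current = []
        current.append(g)
    if current:
        operons.append([x.gene_id for x in current])
    return operons


def extract_cognates(
    operons: list[list[str]],
    classes: list[GeneClass],
    genome_id: str = "genome",
    restrict_sk_domain: str | None = "HisKA",
) -> tuple[PairingTable, set[str]]:
    """Extract cognate SK/RR pairs from called operons.

    An operon contributes one cognate pair iff it contains exactly one SK
    and exactly one RR (hybrids never count as either).  Operons with two
    or more SKs or RRs are dropped entirely: their members are *excluded*
    from all further analysis, not funneled into the orphan pool.  By
    default only the HisKA sensor-kinase class enters the model.

    Returns the pairing table (cognates only; orphan slots empty) and the
    set of excluded gene ids.
    """
    cls = {c.gene_id: c for c in classes}

    def is_sk(gid: str) -> bool:
        c = cls.get(gid)
        if c is None or c.gene_class != "SK":
            return False
        return restrict_sk_domain is None or c.sk_domain == restrict_sk_domain

    cognates: list[tuple[str, str, str]] = []
    excluded: set[str] = set()
    for op in operons:
        sks = [g for g in op if is_sk(g)]
        rrs = [g for g in op if cls.get(g) and cls[g].gene_class == "RR"]
        hybrids = [g for g in op if cls.get(g) and cls[g].gene_class == "hybrid"]
        excluded.update(hybrids)
        if len(sks) == 1 and len(rrs) == 1 and not hybrids:
            cognates.append((sks[0], rrs[0], genome_id))
        elif len(sks) >= 2 or len(rrs) >= 2:
            excluded.update(sks)
            excluded.update(rrs)
    return PairingTable(cognates), excluded


def classify_orphans(
    classes: list[GeneClass],
    cognates: PairingTable,
    operons: list[list[str]],
    excluded: set[str] | None = None,
    hpt_genes: set[str] | None = None,
    restrict_sk_domain: str | None = "HisKA",
) -> tuple[list[str], list[str]]:
    """Identify orphan SKs and RRs after cognate extraction.

    Orphan SK: an SK (of the modeled kinase class) in no cognate pair and
    not excluded.  Orphan RR: an RR not cognate, not excluded, and not in
    an operon that also carries an alternative kinase class or Hpt domain
    (``hpt_genes``: genes with an accepted Hpt phosphotransfer hit).
    """
    excluded = excluded or set()
    hpt_genes = hpt_genes or set()
    cls = {c.gene_id: c for c in classes}
    in_cognate = {i for p in cognates.cognates for i in p[:2]}
    operon_of: dict[str, list[str]] = {}
    for op in operons:
        for g in op:
            operon_of[g] = op

    def has_alt_kinase_neighbor(gid: str) -> bool:
        for g in operon_of.get(gid, []):
            if g == gid:
                continue
            if g in hpt_genes:
                return True
            c = cls.get(g)
            if c and c.sk_domain in ALT_KINASE_DOMAINS:
                return True
        return False

    orphan_sk = [
        c.gene_id
        for c in classes
        if c.gene_class == "SK"
        and (restrict_sk_domain is None or c.sk_domain == restrict_sk_domain)
        and c.gene_id not in in_cognate
        and c.gene_id not in excluded
    ]
    orphan_rr = [
        c.gene_id
        for c in classes
        if c.gene_class == "RR"
        and c.gene_id not in in_cognate
        and c.gene_id not in excluded
        and not has_alt_kinase_neighbor(c.gene_id)
    ]
    return sorted(orphan_sk), sorted(orphan_rr)


def classify_from_tables(
    genes: list[GeneRecord],
    hits: list[DomainHit],
    max_gap_bp: int = 200,
    genome_id: str = "genome",
    **thresholds,
) -> tuple[PairingTable, set[str]]:
    """End-to-end extraction: classify, call operons, pair, find orphans."""
    classes = classify_genes(hits, **thresholds)
    hpt = {
        h.gene_id
        for h in hits
        if h.domain == "Hpt" and h.evalue <= thresholds.get("rr_evalue_max", 0.01)
    }
    operons = call_operons(genes, max_gap_bp=max_gap_bp)
    pairs, excluded = extract_cognates(operons, classes, genome_id=genome_id)
    orphan_sk, orphan_rr = classify_orphans(
        classes, pairs, operons, excluded, hpt_genes=hpt
    )
    return (
        PairingTable(pairs.cognates, orphan_sk, orphan_rr),
        excluded,
    )


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Gene TSV with 1-based inclusive coordinates; converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicon": str})
    return [
        GeneRecord(r.gene_id, r.replicon, r.strand, int(r.start) - 1, int(r.end))
        for r in df.itertuples()
    ]


def read_hit_table(
    path: str | Path, columns: dict[str, str] | None = None
) -> list[DomainHit]:
    """Domain-hit TSV: ``gene_id  domain  evalue`` (renameable via columns)."""
    df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns=columns)
    return [
        DomainHit(str(r.gene_id), str(r.domain), float(r.evalue))
        for r in df.itertuples()
    ]
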