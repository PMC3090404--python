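"""Reading, encoding and concatenating domain alignments.

A sensor-kinase (SK) alignment and a response-regulator (RR) alignment,
both over HMM match columns, are paired row-by-row through a pairing table
of cognate (co-operonic) partners and concatenated into a single joint MSA
whose rows are interacting sequence pairs.  All downstream statistics are
computed on that joint matrix of integer codes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DEFAULT_ALPHABET, Alphabet

logger = logging.getLogger(__name__)


@dataclass
class DomainMSA:
    """One domain family's alignment as an M x L integer code matrix."""

    ids: list[str]
    codes: np.ndarray  # (M, L) int8
    domain_tag: str = ""  # "SK" or "RR"
    genome_ids: list[str] | None = None
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)
    n_ambiguous: int = 0

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def row(self, seq_id: str) -> np.ndarray:
        return self.codes[self.ids.index(seq_id)]


@dataclass
class JointMSA:
    """Concatenated SK+RR alignment; one row per cognate pair.

    ``boundary`` is the index of the first RR column (= L_SK), so columns
    ``[0, boundary)`` belong to the SK domain and ``[boundary, L)`` to the
    RR domain.
    """

    codes: np.ndarray  # (M, L_SK + L_RR) int8
    boundary: int
    row_ids: list[tuple[str, str, str]]  # (sk_id, rr_id, genome_id)
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def genome_groups(self) -> dict[str, list[int]]:
        """Row indices grouped by genome id."""
        groups: dict[str, list[int]] = {}
        for k, (_, _, g) in enumerate(self.row_ids):
            groups.setdefault(g, []).append(k)
        return groups


@dataclass
class PairingTable:
    """Cognate pairs plus orphan ids, as produced by genome pairing."""

    cognates: list[tuple[str, str, str]]  # (sk_id, rr_id, genome_id)
    orphan_sk: list[str] = field(default_factory=list)
    orphan_rr: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = {i for p in self.cognates for i in p[:2]}
        clash = members & (set(self.orphan_sk) | set(self.orphan_rr))
        if clash:
            raise ValueError(f"ids both cognate and orphan: {sorted(clash)}")


def encode_sequences(
    ids: list[str], seqs: list[str], alphabet: Alphabet = DEFAULT_ALPHABET
) -> tuple[np.ndarray, int]:
    """Encode aligned sequences to an integer matrix.

    Lowercase characters (HMM insert states) are dropped before the length
    check; ambiguity codes map to the gap state and are tallied.
    """
    cleaned = ["".join(c for c in s if not c.islower()) for s in seqs]
    lengths = {len(s) for s in cleaned}
    if len(lengths) > 1:
        bad = [i for i, s in zip(ids, cleaned) if len(s) != len(cleaned[0])]
        raise ValueError(f"ragged alignment; offending ids: {bad}")
    n_ambiguous = 0
    m, length = len(cleaned), lengths.pop()
    codes = np.empty((m, length), dtype=np.int8)
    for r, s in enumerate(cleaned):
        for c, ch in enumerate(s):
            code, amb = alphabet.encode_char(ch)
            codes[r, c] = code
            n_ambiguous += amb
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} ambiguous residue characters mapped to gap",
            stacklevel=2,
        )
    return codes, n_ambiguous


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    alphabet: Alphabet = DEFAULT_ALPHABET,
    domain_tag: str = "",
) -> DomainMSA:
    """Read a FASTA or Stockholm alignment into a :class:`DomainMSA`.

    Sequence ids of the form ``seqid|genomeid`` carry the genome label in
    the second field; otherwise genome ids are left unset.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    ids = [r.id for r in records]
    codes, n_amb = encode_sequences(ids, [str(r.seq) for r in records], alphabet)
    genome_ids = None
    if all("|" in i for i in ids):
        split = [i.split("|", 1) for i in ids]
        ids = [s[0] for s in split]
        genome_ids = [s[1] for s in split]
    return DomainMSA(
        ids=ids,
        codes=codes,
        domain_tag=domain_tag,
        genome_ids=genome_ids,
        alphabet=alphabet,
        n_ambiguous=n_amb,
    )


def write_alignment(
    msa: DomainMSA, path: str | Path, format: str = "fasta"
) -> None:
    """Write a DomainMSA back to disk (exact code round-trip)."""
    records = []
    for k, sid in enumerate(msa.ids):
        name = sid
        if msa.genome_ids is not None:
            name = f"{sid}|{msa.genome_ids[k]}"
        records.append(
            SeqRecord(Seq(msa.alphabet.decode(msa.codes[k])), id=name, description="")
        )
    if format == "fasta":
        SeqIO.write(records, str(path), "fasta")
    elif format == "stockholm":
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")
    else:
        raise ValueError(f"unsupported format {format!r}")


def build_joint_msa(
    sk: DomainMSA, rr: DomainMSA, pairs: PairingTable
) -> JointMSA:
    """Concatenate cognate SK and RR rows into the joint MSA.

    Each cognate pair (sk_id, rr_id, genome_id) contributes one row: the SK
    row followed by the RR row.  Duplicate pairs are collapsed to one row.
    """
    sk_index = {i: k for k, i in enumerate(sk.ids)}
    rr_index = {i: k for k, i in enumerate(rr.ids)}
    missing = [
        p
        for p in pairs.cognates
        if p[0] not in sk_index or p[1] not in rr_index
    ]
    if missing:
        raise KeyError(f"pairing table ids missing from alignments: {missing}")
    seen: set[tuple[str, str, str]] = set()
    rows, row_ids = [], []
    n_dup = 0
    for p in pairs.cognates:
        if p in seen:
            n_dup += 1
            continue
        seen.add(p)
        rows.append(
            np.concatenate([sk.codes[sk_index[p[0]]], rr.codes[rr_index[p[1]]]])
        )
        row_ids.append(p)
    if n_dup:
        logger.info("deduplicated %d repeated cognate pairs", n_dup)
    codes = (
        np.vstack(rows)
        if rows
        else np.empty((0, sk.length + rr.length), dtype=np.int8)
    )
    return JointMSA(
        codes=codes.astype(np.int8),
        boundary=sk.length,
        row_ids=row_ids,
        alphabet=sk.alphabet,
    )


def read_pairing_table(path: str | Path) -> PairingTable:
    """Read a tab-separated pairing table ``sk_id  rr_id  genome_id``.

    Orphans are rows where one of the two partner columns is ``-``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sk_id", "rr_id", "genome_id"}
    if not required <= set(df.columns):
        raise ValueError(f"pairing table must have columns {sorted(required)}")
    cognates, orphan_sk, orphan_rr = [], [], []
    for _, row in df.iterrows():
        sk, rr = row["sk_id"], row["rr_id"]
        if rr == "-":
            orphan_sk.append(sk)
        elif sk == "-":
            orphan_rr.append(rr)
        else:
            cognates.append((sk, rr, row["genome_id"]))
    return PairingTable(cognates, orphan_sk, orphan_rr)


def write_pairing_table(pairs: PairingTable, path: str | Path) -> None:
    rows = [list(p) for p in pairs.cognates]
    rows += [[i, "-", "-"] for i in pairs.orphan_sk]
    rows += [["-", i, "-"] for i in pairs.orphan_rr]
    pd.DataFrame(rows, columns=["sk_id", "rr_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )
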