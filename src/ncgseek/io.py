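"""FASTA/FASTQ/TSV readers and writers shared by the CLI and tests."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grouping import Group, GroupTable, assign_pointers
from .sequencing import ReadPair
from .strands import DataStrand, OligoPool, ReferenceStrand

Q30 = 30  # constant quality emitted for simulated reads


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [Q30] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_read_pairs(pairs: list[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    write_fastq([(p.read_id, p.r1) for p in pairs], p1)
    write_fastq([(p.read_id, p.r2) for p in pairs], p2)
    return p1, p2


def read_read_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("R1/R2 files have different read counts")
    return [ReadPair(id1, s1, s2, origin="")
            for (id1, s1), (_id2, s2) in zip(r1, r2)]


# ---------------------------------------------------------------------------
# dictionary / pool / primer / segment TSVs

def write_segments(segments, path: str | Path) -> None:
    """Segments table: file_id, segment_index, pairs (pairs joined by '|')."""
    from .corpus import Segment  # noqa: F401  (documented row type)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["file_id", "segment_index", "pairs"])
        for seg in segments:
            w.writerow([seg.file_id, seg.segment_index, "|".join(seg.pairs)])


def read_segments(path: str | Path):
    from .corpus import Segment

    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(Segment(int(row["file_id"]), int(row["segment_index"]),
                               row["pairs"].split("|")))
    return out



def write_dictionary(table: GroupTable, path: str | Path) -> None:
    """Human-readable twin of the reference pool: fragment hex, group, pointer."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["fragment_hex", "group_index", "pointer"])
        for frag, (g, p) in sorted(table.dictionary.items(),
                                   key=lambda kv: (kv[1][0], kv[0])):
            w.writerow([f"{frag:04X}", g, p])


def read_dictionary(path: str | Path) -> GroupTable:
    groups: dict[int, Group] = {}
    dictionary: dict[int, tuple[int, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            frag = int(row["fragment_hex"], 16)
            g = int(row["group_index"])
            p = row["pointer"]
            groups.setdefault(g, Group(index=g))
            groups[g].members.append(frag)
            groups[g].pointers.append(p)
            dictionary[frag] = (g, p)
    table = GroupTable(groups=[groups[g] for g in sorted(groups)],
                       dictionary=dictionary)
    for group in table.groups:
        group.filler = table.matrix.filler(group.index, len(group.members))
    return table


def write_primer_map(primer_map: dict[object, tuple[str, str]],
                     path: str | Path) -> None:
    records = []
    for key in sorted(primer_map, key=str):
        fwd, rev = primer_map[key]
        records.append((f"{key}_fwd", fwd))
        records.append((f"{key}_rev", rev))
    write_fasta(records, path)


def read_primer_map(path: str | Path) -> dict[object, tuple[str, str]]:
    half: dict[str, dict[str, str]] = {}
    for rid, seq in read_fasta(path):
        key, _, which = rid.rpartition("_")
        half.setdefault(key, {})[which] = seq
    out: dict[object, tuple[str, str]] = {}
    for key, d in half.items():
        if set(d) != {"fwd", "rev"}:
            raise ValueError(f"primer records for {key!r} incomplete")
        parsed_key: object = int(key) if key.isdigit() else key
        out[parsed_key] = (d["fwd"], d["rev"])
    return out


def write_pool_fasta(pool: OligoPool, path: str | Path) -> None:
    write_fasta(pool.all_sequences(), path)


def parse_pool_fasta(records: list[tuple[str, str]],
                     primer_map: dict[object, tuple[str, str]]) -> OligoPool:
    """Rebuild an OligoPool from FASTA records written by write_pool_fasta."""
    from .strands import parse_data, parse_reference

    reference: list[ReferenceStrand] = []
    data: dict[int, list[DataStrand]] = {}
    for rid, seq in records:
        kind, a, _b = rid.split("_")
        if kind == "ref":
            strand, _ = parse_reference(seq)
            reference.append(strand)
        else:
            fid = int(a)
            strand, _ = parse_data(seq, file_id=fid)
            data.setdefault(fid, []).append(strand)
    return OligoPool(reference_strands=reference, data_strands=data,
                     primer_map=primer_map)
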