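"""Readers and writers for the pipeline's tabular formats.

Consumes GFF3 / TSV gene tables, HMMER3 tblout/domtblout hit tables and
BLAST outfmt-6-like similarity tables; emits deterministic TSV result
tables plus a JSON run manifest.  Coordinates are 1-based inclusive
throughout; identities are converted from percent to fractions on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    GeneRecord,
    HomologyHit,
    ParseError,
    RawProfileHit,
    Replicon,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENE_TSV_REQUIRED = ("replicon_id", "protein_id", "start", "end", "strand")


def _build_replicons(
    rows: list[dict],
    lengths: Mapping[str, int],
    topologies: Mapping[str, str],
    default_topology: str,
) -> list[Replicon]:
    seen: set[str] = set()
    for r in rows:
        if r["protein_id"] in seen:
            raise ValidationError(f"duplicate protein_id {r['protein_id']!r}")
        seen.add(r["protein_id"])
    replicons = []
    by_rep: dict[str, list[dict]] = {}
    for r in rows:
        by_rep.setdefault(r["replicon_id"], []).append(r)
    for rep_id in sorted(by_rep):
        rep_rows = sorted(
            by_rep[rep_id], key=lambda r: (r["start"], r["end"], r["protein_id"])
        )
        genes = [
            GeneRecord(
                replicon_id=rep_id,
                gene_index=i,
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                protein_id=r["protein_id"],
                length_aa=r.get("length_aa") or max((r["end"] - r["start"] + 1) // 3 - 1, 1),
            )
            for i, r in enumerate(rep_rows, start=1)
        ]
        length_bp = lengths.get(rep_id, max(g.end for g in genes))
        replicons.append(
            Replicon(
                replicon_id=rep_id,
                genes=genes,
                length_bp=length_bp,
                topology=topologies.get(rep_id, default_topology),
            )
        )
    return replicons


def read_gene_table(
    path: Union[str, Path], dialect: str = "gff3", topology: str = "linear"
) -> list[Replicon]:
    """Read an annotated gene table into ordered :class:`Replicon` objects.

    ``dialect="gff3"`` consumes CDS features with an ``ID`` (or
    ``protein_id``) attribute; ``dialect="tsv"`` consumes a header-carrying
    table with columns replicon_id, protein_id, start, end, strand and
    optionally length_aa, topology and replicon_length.  Genes are sorted
    by start (ties by end, then protein_id) and indexed from 1.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path, topology)
    if dialect == "tsv":
        return _read_gene_tsv(path, topology)
    raise ValidationError(f"unknown gene-table dialect {dialect!r}")


def _read_gff3(path: Path, default_topology: str) -> list[Replicon]:
    rows: list[dict] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        lengths[parts[1]] = int(parts[3])
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr_map = {}
            for item in attrs.strip(";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr_map[k.strip()] = v.strip()
            pid = attr_map.get("protein_id") or attr_map.get("ID")
            if pid is None:
                raise ParseError("CDS feature without ID/protein_id attribute", lineno)
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start!r}/{end!r}", lineno)
            rows.append(
                dict(replicon_id=seqid, protein_id=pid, start=s, end=e, strand=strand)
            )
    if not rows:
        return []
    return _build_replicons(rows, lengths, {}, default_topology)


def _read_gene_tsv(path: Path, default_topology: str) -> list[Replicon]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"replicon_id": str, "protein_id": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in _GENE_TSV_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"gene TSV missing columns {missing}", 1)
    rows = []
    for _, r in df.iterrows():
        row = dict(
            replicon_id=r["replicon_id"],
            protein_id=r["protein_id"],
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
        )
        if "length_aa" in df.columns and pd.notna(r.get("length_aa")):
            row["length_aa"] = int(r["length_aa"])
        rows.append(row)
    lengths: dict[str, int] = {}
    topologies: dict[str, str] = {}
    if "replicon_length" in df.columns:
        for rep, sub in df.groupby("replicon_id"):
            lengths[rep] = int(sub["replicon_length"].iloc[0])
    if "topology" in df.columns:
        for rep, sub in df.groupby("replicon_id"):
            topologies[rep] = str(sub["topology"].iloc[0])
    return _build_replicons(rows, lengths, topologies, default_topology)


def read_hmmer_tblout(
    path: Union[str, Path], dialect: str = "domtblout"
) -> list[RawProfileHit]:
    """Read an HMMER3 per-target/per-domain table into raw profile hits.

    For ``domtblout`` the profile coverage is computed from the union of
    per-domain HMM alignment bounds divided by the profile length; rows
    for the same (protein, profile) pair are merged, keeping the
    full-sequence e-value.  For ``tblout`` (which has no alignment
    bounds) the coverage must be supplied as an extra trailing column.
    """
    path = Path(path)
    if dialect not in ("domtblout", "tblout"):
        raise ValidationError(f"unknown HMMER dialect {dialect!r}")
    merged: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if dialect == "domtblout":
                if len(f) < 22:
                    raise ParseError(
                        f"domtblout row has {len(f)} columns, expected >= 22", lineno
                    )
                target, profile = f[0], f[3]
                try:
                    qlen = int(f[5])
                    evalue = float(f[6])
                    score = float(f[7])
                    hmm_from, hmm_to = int(f[15]), int(f[16])
                except ValueError as exc:
                    raise ParseError(f"bad numeric field: {exc}", lineno)
                key = (target, profile)
                rec = merged.setdefault(
                    key,
                    dict(evalue=evalue, score=score, qlen=qlen, intervals=[]),
                )
                if key not in order:
                    order.append(key)
                rec["evalue"] = min(rec["evalue"], evalue)
                rec["score"] = max(rec["score"], score)
                rec["intervals"].append((hmm_from, hmm_to))
            else:
                if len(f) < 19:
                    raise ParseError(
                        f"tblout row has {len(f)} columns; need >= 19 "
                        "(18 standard + trailing profile coverage)",
                        lineno,
                    )
                target, profile = f[0], f[2]
                try:
                    evalue = float(f[4])
                    score = float(f[5])
                    coverage = float(f[18])
                except ValueError as exc:
                    raise ParseError(f"bad numeric field: {exc}", lineno)
                key = (target, profile, lineno)
                merged[key] = dict(evalue=evalue, score=score, coverage=coverage)
                order.append(key)
    hits = []
    for key in order:
        rec = merged[key]
        if "intervals" in rec:
            covered = _union_length(rec["intervals"])
            coverage = min(covered / rec["qlen"], 1.0)
        else:
            coverage = rec["coverage"]
        hits.append(
            RawProfileHit(
                protein_id=key[0],
                profile_id=key[1],
                evalue=rec["evalue"],
                profile_coverage=coverage,
                score=rec["score"],
            )
        )
    logger.info("read %d profile hits from %s", len(hits), path)
    return hits


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, 0
    for s, e in sorted(intervals):
        s = max(s, last_end + 1)
        if e >= s:
            total += e - s + 1
            last_end = max(last_end, e)
    return total


def read_similarity_table(
    path: Union[str, Path],
    sequence_lengths: Optional[Mapping[str, int]] = None,
) -> list[HomologyHit]:
    """Read a BLAST outfmt-6-like similarity table.

    Expects 12 standard columns; columns 13/14, when present, are taken
    as qlen/slen.  Otherwise ``sequence_lengths`` must supply a length
    for every protein so that both coverages can be computed.  The
    percent identity column is stored as a fraction.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(
                    f"similarity row has {len(f)} columns, expected >= 12", lineno
                )
            q, t = f[0], f[1]
            try:
                pident = float(f[2])
                qstart, qend = int(f[6]), int(f[7])
                sstart, send = int(f[8]), int(f[9])
                evalue = float(f[10])
                bitscore = float(f[11])
            except ValueError as exc:
                raise ParseError(f"bad numeric field: {exc}", lineno)
            if len(f) >= 14:
                qlen, tlen = int(f[12]), int(f[13])
            else:
                if sequence_lengths is None or q not in sequence_lengths or t not in sequence_lengths:
                    raise ValidationError(
                        f"line {lineno}: no sequence length available for "
                        f"{q!r}/{t!r}; supply 14-column input or sequence_lengths"
                    )
                qlen, tlen = sequence_lengths[q], sequence_lengths[t]
            hit = HomologyHit(
                query=q,
                target=t,
                identity=pident / 100.0,
                query_coverage=min((abs(qend - qstart) + 1) / qlen, 1.0),
                target_coverage=min((abs(send - sstart) + 1) / tlen, 1.0),
                evalue=evalue,
                bitscore=bitscore,
            )
            hits.append(hit)
    logger.info("read %d similarity hits from %s", len(hits), path)
    return hits


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: Union[str, Path],
    config: Optional[object] = None,
    seed: Optional[int] = None,
    inputs: Sequence[Union[str, Path]] = (),
) -> dict[str, Path]:
    """Write result tables as deterministic TSVs plus a run manifest.

    Every table is written with its given column order, a header row and
    no index; the manifest (``manifest.json``) records the configuration,
    the seed and a sha256 checksum per input so that re-runs can be
    verified byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        dest = outdir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False)
        written[name] = dest
    manifest = {
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        "seed": seed,
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "tables": sorted(tables),
    }
    dest = outdir / "manifest.json"
    with open(dest, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = dest
    return written


def read_manifest(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)
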