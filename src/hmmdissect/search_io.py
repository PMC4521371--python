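"""Readers/writers for search output and the standard sequence formats.

Search results travel in a plain-text carrier with one ``>>`` header line per
domain hit followed by a two-row alignment block in the familiar report
style: the model row marks match columns ('x') and insert columns ('.'), the
query row carries residues with '-' at deletions.  Both rows are flanked by
their 1-based start/end coordinates, which is enough to reconstruct the full
state path::

    >> query1 PF_TOY H3 score=12.3410 evalue=4.5e-07
    model 2 xxx.xx 6
    query 5 ACDKEF 10

The package consumes parsed search output rather than requiring search
binaries; alignments produced by its own Viterbi round-trip through this
format bit-exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import AlignIO, SeqIO

from .profile_models import (
    Dialect,
    PathRecord,
    ProfileHMM,
    SeqDomAlignment,
    validate_alignment,
)

HEADER = "# hmmdissect search output v1"


class SearchOutputError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run-level constants of a scoring run; a fixed seed makes outputs
    byte-identical."""

    profile_paths: tuple = ()
    mask_source: str = "packaged"  # dssp_tsv | predicted | packaged
    calibration_source: str = "packaged_anchor"  # or an empirical TSV path
    db_size: int = 540_261
    min_overlap: float = 0.9
    evalue_list_cutoff: float = 20.0
    h2_e: float = 0.1
    h3_e: float = 1e-3
    h2_fce: float = 10.0**-3.45
    h3_fce: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("db_size", "min_overlap", "evalue_list_cutoff",
                     "h2_e", "h3_e", "h2_fce", "h3_fce"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SearchOutputRecord:
    query_id: str
    model_id: str
    variant: Dialect
    reported_score: float | None
    reported_evalue: float | None
    alignment: SeqDomAlignment
    unmatched: bool = False  # model not found in the supplied profile library


def write_search_output(alignments: Sequence[SeqDomAlignment]) -> str:
    lines = [HEADER]
    for a in alignments:
        score = "." if a.reported_score is None else f"{a.reported_score:.4f}"
        ev = "." if a.reported_evalue is None else f"{a.reported_evalue:.6g}"
        lines.append(
            f">> {a.query_id} {a.model_id} {a.variant.value} score={score} evalue={ev}"
        )
        model_row = []
        query_row = []
        for rec in a.path:
            if rec.state == "M":
                model_row.append("x")
                query_row.append(rec.residue)
            elif rec.state == "D":
                model_row.append("x")
                query_row.append("-")
            else:
                model_row.append(".")
                query_row.append(rec.residue)
        k0, k1 = a.model_span
        q0, q1 = a.seq_span
        lines.append(f"model {k0} {''.join(model_row)} {k1}")
        lines.append(f"query {q0} {''.join(query_row)} {q1}")
    return "\n".join(lines) + "\n"


def parse_search_output(
    text: str,
    variant: Dialect | str | None = None,
    profiles: Mapping[str, ProfileHMM] | None = None,
) -> list[SearchOutputRecord]:
    """Parse a search-output carrier into one record per domain alignment.

    ``variant``, when given, filters records to that dialect.  When a profile
    library is supplied, each alignment is validated against its model;
    records naming a model absent from the library are kept but flagged
    ``unmatched``.
    """
    records: list[SearchOutputRecord] = []
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        ln = lines[i]
        if not ln.startswith(">>"):
            i += 1
            continue
        toks = ln.split()
        if len(toks) != 6:
            raise SearchOutputError(f"line {i + 1}: malformed hit header: {ln!r}")
        _, query_id, model_id, var, score_tok, ev_tok = toks
        var = Dialect(var)
        score = None if score_tok == "score=." else float(score_tok.split("=", 1)[1])
        ev = None if ev_tok == "evalue=." else float(ev_tok.split("=", 1)[1])
        if i + 2 >= n:
            raise SearchOutputError(f"line {i + 1}: truncated alignment block")
        mtoks = lines[i + 1].split()
        if len(mtoks) != 4 or mtoks[0] != "model":
            raise SearchOutputError(f"line {i + 2}: malformed model row")
        qtoks = lines[i + 2].split()
        if len(qtoks) != 4 or qtoks[0] != "query":
            raise SearchOutputError(f"line {i + 3}: malformed query row")
        k0, mrow, k1 = int(mtoks[1]), mtoks[2], int(mtoks[3])
        q0, qrow, q1 = int(qtoks[1]), qtoks[2], int(qtoks[3])
        if len(mrow) != len(qrow):
            raise SearchOutputError(f"line {i + 2}: model/query rows differ in length")
        path: list[PathRecord] = []
        k = k0 - 1
        q = q0 - 1
        last_k = k0 - 1
        for mc, qc in zip(mrow, qrow):
            if mc != ".":
                k += 1
                last_k = k
                if qc == "-":
                    path.append(PathRecord("D", k, None, None))
                else:
                    q += 1
                    path.append(PathRecord("M", k, q, qc))
            else:
                if qc == "-":
                    raise SearchOutputError(
                        f"line {i + 2}: insert column with a gap in the query row"
                    )
                q += 1
                path.append(PathRecord("I", last_k, q, qc))
        aln = SeqDomAlignment(
            query_id=query_id,
            model_id=model_id,
            variant=var,
            seq_span=(q0, q1),
            model_span=(k0, k1),
            path=path,
            reported_score=score,
            reported_evalue=ev,
        )
        if k != k1 or q != q1:
            raise SearchOutputError(
                f"line {i + 2}: alignment rows end at ({k}, {q}), header says ({k1}, {q1})"
            )
        unmatched = False
        if profiles is not None:
            prof = profiles.get(model_id)
            if prof is None:
                unmatched = True
            else:
                diags = validate_alignment(aln, prof)
                if diags:
                    raise SearchOutputError(
                        f"line {i + 1}: alignment inconsistent with profile: {diags[0]}"
                    )
        if variant is None or Dialect(variant) is var:
            records.append(
                SearchOutputRecord(
                    query_id=query_id,
                    model_id=model_id,
                    variant=var,
                    reported_score=score,
                    reported_evalue=ev,
                    alignment=aln,
                    unmatched=unmatched,
                )
            )
        i += 3
    return records


# ---------------------------------------------------------------------------
# sequence formats (thin wrappers over Biopython)


def read_fasta(text: str) -> dict[str, str]:
    handle = io.StringIO(text)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(seqs: Mapping[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in seqs.items())


def read_msa(text: str) -> dict[str, str]:
    """Aligned sequences from Stockholm or aligned-FASTA text (sniffed)."""
    fmt = "stockholm" if text.lstrip().startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(io.StringIO(text), fmt)
    return {rec.id: str(rec.seq).upper().replace(".", "-") for rec in aln}
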