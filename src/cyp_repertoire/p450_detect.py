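"""Motif- and length-based screening of proteomes for P450 candidates.

A cytochrome P450 is recognized here by two diagnostic sequence features:
the K-helix EXXR tetrad (Glu-x-x-Arg) in the C-terminal half of the
protein, and the heme-binding-loop CxG triad (Cys-x-Gly, carrying the
axial cysteine ligand) near the C-terminus and downstream of the K-helix.
Proteins carrying both motifs are retained as candidates; short proteins
lacking both are flagged as fragments and excluded from annotation;
everything else is rejected.  This is a deliberately self-contained
heuristic replacement for a remote conserved-domain search, so the whole
pipeline runs with no external services.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import VERSION_BANNER
from .sequence_io import ProteinRecord

STATUS_CANDIDATE = "candidate"
STATUS_FRAGMENT = "fragment"
STATUS_REJECTED = "rejected"


@dataclass
class DetectionParams:
    """Tunables for the motif/length screen.

    min_full_length: proteins below this (aa) with no motifs are fragments.
    cterm_window: CxG is searched only in the last this-many residues.
    The EXXR pattern is searched in the C-terminal half; CxG must fall
    downstream of the chosen (most N-terminal) EXXR hit when one exists.
    """

    min_full_length: int = 300
    cterm_window: int = 100
    exxr_regex: str = "E..R"
    cxg_regex: str = "C.G"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectionParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown detection params: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str  # "EXXR" or "CXG"
    start: int  # 1-based residue index
    matched_text: str


@dataclass
class P450Candidate:
    record: ProteinRecord
    exxr: MotifHit | None
    cxg: MotifHit | None
    status: str
    exxr_hits: list[MotifHit] = field(default_factory=list)
    cxg_hits: list[MotifHit] = field(default_factory=list)

    @property
    def is_fragment(self) -> bool:
        return self.status == STATUS_FRAGMENT


def _overlapping_matches(pattern: str, seq: str) -> list[tuple[int, str]]:
    # lookahead so overlapping motif instances are all reported
    hits = []
    for m in re.finditer(f"(?=({pattern}))", seq):
        hits.append((m.start(), m.group(1)))
    return hits


def scan_motifs(
    record: ProteinRecord, params: DetectionParams | None = None
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Find EXXR and CxG motif hits in their positional windows.

    EXXR hits are restricted to the C-terminal half of the sequence; CxG
    hits to the last ``cterm_window`` residues, and additionally to
    positions strictly downstream of the first EXXR hit when one exists.
    Returns (exxr_hits, cxg_hits), each in ascending position order,
    positions 1-based.
    """
    params = params or DetectionParams()
    seq = record.sequence
    n = len(seq)
    exxr_min0 = n // 2  # 0-based start of the C-terminal half
    exxr_hits = [
        MotifHit("EXXR", start0 + 1, text)
        for start0, text in _overlapping_matches(params.exxr_regex, seq)
        if start0 >= exxr_min0
    ]
    cxg_min0 = max(0, n - params.cterm_window)
    if exxr_hits:
        # heme loop sits C-terminal of the K-helix
        cxg_min0 = max(cxg_min0, (exxr_hits[0].start - 1) + 4)
    cxg_hits = [
        MotifHit("CXG", start0 + 1, text)
        for start0, text in _overlapping_matches(params.cxg_regex, seq)
        if start0 >= cxg_min0
    ]
    return exxr_hits, cxg_hits


def classify(
    record: ProteinRecord, params: DetectionParams | None = None
) -> P450Candidate:
    """Assign candidate / fragment / rejected status to one protein.

    candidate: both motifs present (first EXXR and last CxG reported);
    fragment: shorter than min_full_length AND neither motif;
    rejected: everything else (e.g. one motif only, or long and motif-free).
    """
    params = params or DetectionParams()
    exxr_hits, cxg_hits = scan_motifs(record, params)
    if exxr_hits and cxg_hits:
        status = STATUS_CANDIDATE
    elif record.length < params.min_full_length and not exxr_hits and not cxg_hits:
        status = STATUS_FRAGMENT
    else:
        status = STATUS_REJECTED
    return P450Candidate(
        record=record,
        exxr=exxr_hits[0] if exxr_hits else None,
        cxg=cxg_hits[-1] if cxg_hits else None,
        status=status,
        exxr_hits=exxr_hits,
        cxg_hits=cxg_hits,
    )


def screen_proteome(
    records: list[ProteinRecord], params: DetectionParams | None = None
) -> tuple[list[P450Candidate], dict[str, int]]:
    """Screen a proteome; return retained candidates and a status report.

    The report counts every input protein exactly once
    (candidate/fragment/rejected); candidates keep input order.
    """
    params = params or DetectionParams()
    report = Counter({STATUS_CANDIDATE: 0, STATUS_FRAGMENT: 0, STATUS_REJECTED: 0})
    candidates = []
    for rec in records:
        c = classify(rec, params)
        report[c.status] += 1
        if c.status == STATUS_CANDIDATE:
            candidates.append(c)
    return candidates, dict(report)


def write_screening_report(
    reports: dict[str, dict[str, int]], path: str | Path
) -> None:
    """Write per-species status counts as TSV (one row per species)."""
    with open(path, "w") as fh:
        fh.write(VERSION_BANNER + "\n")
        fh.write("species_id\tcandidate\tfragment\trejected\n")
        for sp, rep in reports.items():
            fh.write(
                f"{sp}\t{rep.get(STATUS_CANDIDATE, 0)}\t"
                f"{rep.get(STATUS_FRAGMENT, 0)}\t{rep.get(STATUS_REJECTED, 0)}\n"
            )
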