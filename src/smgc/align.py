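"""All-vs-all protein comparison with exact local alignment.

Pairs are aligned with the exact affine-gap local dynamic programme
(Gotoh) under BLOSUM62, gap open 11 / extend 1 (the opening penalty is
charged to the first gap column).  Significance uses the Karlin-Altschul
estimate ``E = K * m * n * exp(-lambda * S)`` with the published gapped
BLOSUM62(11,1) parameters lambda = 0.267, K = 0.041 and the raw
sequence lengths.  Percent identity is identical columns over aligned
columns (gaps included), as BLAST reports it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal, get_sequence_identity

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041
_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()


@dataclass
class AlignParams:
    gap_open: int = 11
    gap_extend: int = 1
    evalue_cutoff: float = 1e-10


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    pident: float
    ali_len: int
    query_cov: float
    raw_score: int
    evalue: float
    q_start: int = 0  # 1-based alignment span on the query
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    @property
    def bitscore(self) -> float:
        return (GAPPED_LAMBDA * self.raw_score - math.log(GAPPED_K)) / math.log(2)


def evalue(raw_score: int, len_a: int, len_b: int) -> float:
    return GAPPED_K * len_a * len_b * math.exp(-GAPPED_LAMBDA * raw_score)


def _as_protein(seq: str, name: str) -> ProteinSequence:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    try:
        return ProteinSequence(seq)
    except Exception as exc:
        raise ValueError(f"{name}: non-amino-acid characters in sequence") from exc


def align_pair(
    seq_a: str,
    seq_b: str,
    params: AlignParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Best local alignment of two proteins, or None below significance."""
    params = params or AlignParams()
    pa = _as_protein(seq_a, query_id)
    pb = _as_protein(seq_b, subject_id)
    aln = align_optimal(
        pa,
        pb,
        _BLOSUM62,
        gap_penalty=(-params.gap_open, -params.gap_extend),
        local=True,
        max_number=1,
    )[0]
    return _hit_from_alignment(aln, len(seq_a), len(seq_b), params, query_id, subject_id)


def _hit_from_alignment(aln, len_a, len_b, params, query_id, subject_id) -> AlignmentHit | None:
    score = int(aln.score)
    ev = evalue(score, len_a, len_b)
    if ev > params.evalue_cutoff:
        return None
    trace = aln.trace
    qpos = trace[:, 0][trace[:, 0] != -1]
    spos = trace[:, 1][trace[:, 1] != -1]
    pident = get_sequence_identity(aln, mode="all") * 100.0
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pident=pident,
        ali_len=len(trace),
        query_cov=len(qpos) / len_a,
        raw_score=score,
        evalue=ev,
        q_start=int(qpos.min()) + 1,
        q_end=int(qpos.max()) + 1,
        s_start=int(spos.min()) + 1,
        s_end=int(spos.max()) + 1,
    )


class HitTable:
    """Best hit per ordered protein pair, all meeting the e-value cutoff."""

    def __init__(self, evalue_cutoff: float):
        self.evalue_cutoff = evalue_cutoff
        self._hits: dict[tuple[str, str], AlignmentHit] = {}

    def add(self, hit: AlignmentHit) -> None:
        key = (hit.query_id, hit.subject_id)
        old = self._hits.get(key)
        if old is None or hit.raw_score > old.raw_score:
            self._hits[key] = hit

    def get(self, query_id: str, subject_id: str) -> AlignmentHit | None:
        return self._hits.get((query_id, subject_id))

    def pident(self, a: str, b: str) -> float:
        """Symmetrised percent identity (best of both directions; 0 if no hit).

        A protein is 100% identical to itself by definition; self-hits
        are never stored.
        """
        if a == b:
            return 100.0
        vals = [
            h.pident for h in (self.get(a, b), self.get(b, a)) if h is not None
        ]
        return max(vals) if vals else 0.0

    def hits_from(self, query_id: str) -> list[AlignmentHit]:
        return [h for (q, _), h in self._hits.items() if q == query_id]

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self):
        return iter(self._hits.values())

    def to_dataframe(self) -> pd.DataFrame:
        """BLAST outfmt-6-like table (qseqid ... evalue bitscore)."""
        rows = [
            (
                h.query_id, h.subject_id, round(h.pident, 3), h.ali_len,
                h.q_start, h.q_end, h.s_start, h.s_end,
                h.evalue, round(h.bitscore, 1), h.raw_score, round(h.query_cov, 4),
            )
            for h in sorted(self, key=lambda h: (h.query_id, h.subject_id))
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "qseqid", "sseqid", "pident", "length", "qstart", "qend",
                "sstart", "send", "evalue", "bitscore", "raw_score", "qcov",
            ],
        )

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, evalue_cutoff: float) -> "HitTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(evalue_cutoff)
        for row in df.itertuples(index=False):
            if row.evalue > evalue_cutoff:
                continue
            table.add(
                AlignmentHit(
                    query_id=row.qseqid, subject_id=row.sseqid,
                    pident=float(row.pident), ali_len=int(row.length),
                    query_cov=float(row.qcov), raw_score=int(row.raw_score),
                    evalue=float(row.evalue),
                    q_start=int(row.qstart), q_end=int(row.qend),
                    s_start=int(row.sstart), s_end=int(row.send),
                )
            )
        return table


def all_vs_all(
    proteomes: dict[str, dict[str, str]],
    evalue_cutoff: float = 1e-10,
    params: AlignParams | None = None,
) -> HitTable:
    """Align every protein pair across (and within) proteomes.

    Protein ids must be globally unique.  Each unordered pair is
    aligned once (the local DP score is symmetric) and both directions
    are recorded with their own query coverage; self-hits are excluded.
    """
    params = params or AlignParams(evalue_cutoff=evalue_cutoff)
    params.evalue_cutoff = evalue_cutoff
    seqs: dict[str, str] = {}
    for species, proteome in proteomes.items():
        for pid, seq in proteome.items():
            if pid in seqs:
                raise ValueError(f"duplicate protein id across proteomes: {pid}")
            seqs[pid] = seq
    prot = {pid: _as_protein(s, pid) for pid, s in seqs.items()}
    table = HitTable(evalue_cutoff)
    ids = sorted(seqs)
    for a, b in itertools.combinations(ids, 2):
        aln = align_optimal(
            prot[a], prot[b], _BLOSUM62,
            gap_penalty=(-params.gap_open, -params.gap_extend),
            local=True, max_number=1,
        )[0]
        fwd = _hit_from_alignment(aln, len(seqs[a]), len(seqs[b]), params, a, b)
        if fwd is None:
            continue
        table.add(fwd)
        # reverse direction: same alignment, coverage relative to b
        trace = aln.trace
        spos = trace[:, 1][trace[:, 1] != -1]
        table.add(
            AlignmentHit(
                query_id=b, subject_id=a, pident=fwd.pident, ali_len=fwd.ali_len,
                query_cov=len(spos) / len(seqs[b]), raw_score=fwd.raw_score,
                evalue=fwd.evalue, q_start=fwd.s_start, q_end=fwd.s_end,
                s_start=fwd.q_start, s_end=fwd.q_end,
            )
        )
    return table
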