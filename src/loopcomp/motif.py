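"""CTCF motif orientation annotation from a PWM and genome sequence.

The orientation of each binding site is taken from the strand of the best
log-odds PWM hit within its peak: loops anchored by CTCF have a strong
preference for convergent motif pairs, so strand assignment is a required
input to the orientation term of the model.  Sites whose best hit falls
below a relative score threshold, or whose best forward and reverse scores
tie, are marked ambiguous and excluded from pairing.

PWMs are read from JASPAR-format count matrices (e.g. the human CTCF motif
MA0139.1) with :mod:`Bio.motifs`; scores are log-odds against a uniform
background with a small pseudocount.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import motifs
from Bio.Seq import Seq
from pyfaidx import Fasta

__all__ = ["read_jaspar_pfm", "build_pssm", "best_hit", "annotate_orientation"]

from .model import AMBIGUOUS, FORWARD, REVERSE

_BASES = "ACGT"


def read_jaspar_pfm(path):
    """Read a JASPAR-format position frequency matrix into a Bio.motifs motif."""
    with open(path) as handle:
        return motifs.read(handle, "jaspar")


def build_pssm(motif, pseudocount: float = 0.8):
    """Log-odds scoring matrix against a uniform background."""
    pwm = motif.counts.normalize(pseudocounts=pseudocount)
    return pwm.log_odds({b: 0.25 for b in _BASES})


def _scan(pssm, seq: str) -> np.ndarray:
    """Per-window log-odds scores on the forward strand of ``seq``.

    Windows containing non-ACGT characters score -inf.
    """
    L = pssm.length
    seq = seq.upper()
    if len(seq) < L:
        return np.empty(0)
    clean = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = np.isin(clean, np.frombuffer(b"ACGT", dtype=np.uint8))
    sanitized = seq if valid.all() else "".join(
        c if ok else "A" for c, ok in zip(seq, valid)
    )
    scores = np.asarray(pssm.calculate(Seq(sanitized)), dtype=float)
    if scores.ndim == 0:
        scores = scores.reshape(1)
    if not valid.all():
        bad_window = np.convolve((~valid).astype(int), np.ones(L, int), mode="valid") > 0
        scores[bad_window] = -np.inf
    return scores


def best_hit(pssm, seq: str) -> tuple[float, float, int, int]:
    """Best forward and reverse log-odds scores and their window offsets."""
    fwd = _scan(pssm, seq)
    rev = _scan(pssm.reverse_complement(), seq)
    if fwd.size == 0:
        return -np.inf, -np.inf, -1, -1
    return (
        float(fwd.max()),
        float(rev.max()),
        int(fwd.argmax()),
        int(rev.argmax()),
    )


def annotate_orientation(
    sites: pd.DataFrame,
    motif,
    genome_fasta,
    rel_threshold: float = 0.8,
) -> pd.DataFrame:
    """Set each site's orientation to the strand of its strongest motif hit.

    ``rel_threshold`` is the fraction of the maximum achievable log-odds
    score a hit must reach to be trusted; weaker or strand-tied sites are
    marked ambiguous.  ``pos`` is moved to the motif midpoint of the winning
    hit (distances in the model are midpoint-to-midpoint).  Raises when a
    peak's chromosome is missing from the FASTA.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    pssm = build_pssm(motif)
    threshold = rel_threshold * pssm.max
    genome = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(str(genome_fasta))
    L = pssm.length

    out = sites.copy().reset_index(drop=True)
    orientations = []
    positions = []
    for row in out.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"chromosome {row.chrom!r} missing from genome FASTA")
        seq = str(genome[row.chrom][int(row.peak_start) : int(row.peak_end)])
        f, r, fo, ro = best_hit(pssm, seq)
        best = max(f, r)
        if best < threshold or f == r:
            orientations.append(AMBIGUOUS)
            positions.append(row.pos)
        elif f > r:
            orientations.append(FORWARD)
            positions.append(int(row.peak_start) + fo + L // 2)
        else:
            orientations.append(REVERSE)
            positions.append(int(row.peak_start) + ro + L // 2)
    out["orientation"] = orientations
    out["pos"] = positions
    return out
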