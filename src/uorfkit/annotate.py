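"""uORF scanning, overlap classification, Kozak scoring, and shuffle nulls.

A canonical uORF begins with an AUG in the 5'UTR and ends at the first
in-frame UAA/UAG/UGA stop codon downstream, which may lie anywhere in the
transcript (5'UTR, CDS, or 3'UTR).  uORF length is unrestricted.  An AUG
that is in frame with the main CDS and has no in-frame stop before the
cAUG is an N-terminal extension, not a uORF, and is excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from uorfkit.models import STOP_CODONS, TranscriptModel, UORF

#: Kozak context window as offsets from the A (offset 0) of the AUG: the six
#: upstream nucleotides plus the first nucleotide after the G (offset 3, the
#: "+4" position in Kozak numbering).  The AUG itself is invariant and would
#: only add a constant to every score.
DEFAULT_KOZAK_WINDOW = (-6, -5, -4, -3, -2, -1, 3)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# uORF scanning
# ---------------------------------------------------------------------------

def _first_inframe_stop(seq: str, start: int) -> int | None:
    """Offset of the first in-frame stop codon at or after ``start + 3``."""
    for j in range(start + 3, len(seq) - 2, 3):
        if seq[j : j + 3] in STOP_CODONS:
            return j
    return None


def scan_uorfs(transcript: TranscriptModel) -> list[UORF]:
    """Find all canonical uORFs in a transcript model.

    Every ATG strictly upstream of the cAUG with an in-frame stop anywhere
    downstream yields one uORF.  ATGs in frame with the CDS whose first
    in-frame stop falls at or beyond the cAUG are N-terminal extensions and
    are skipped.  Output is sorted by start, with overlap classes assigned.
    """
    seq = transcript.sequence
    if any(c not in "ACGT" for c in seq):
        warnings.warn(
            f"{transcript.transcript_id}: non-ACGT symbols present; "
            "ambiguous codons never match start/stop patterns",
            stacklevel=2,
        )
    uorfs: list[UORF] = []
    pos = seq.find("ATG")
    while 0 <= pos < transcript.cds_start:
        stop = _first_inframe_stop(seq, pos)
        if stop is not None:
            in_cds_frame = (transcript.cds_start - pos) % 3 == 0
            if not (in_cds_frame and stop >= transcript.cds_start):
                end = stop + 3
                uorfs.append(
                    UORF(
                        transcript_id=transcript.transcript_id,
                        start=pos,
                        end=end,
                        distance_uaug_to_caug=transcript.cds_start - pos,
                        distance_cap_to_uaug=pos,
                        distance_stop_to_caug=transcript.cds_start - end,
                    )
                )
        pos = seq.find("ATG", pos + 1)
    classify_uorf_overlap(uorfs, transcript)
    return uorfs


def classify_uorf_overlap(uorfs: list[UORF], transcript: TranscriptModel) -> list[str]:
    """Assign an overlap class to each uORF in place and return the classes.

    A uORF sharing at least one nucleotide with the CDS is CDS-overlapping;
    the frame is decided by divisibility by 3 of the uAUG-to-cAUG distance.
    Otherwise, a uORF sharing sequence with another uORF is uORF-overlapping;
    out-of-frame wins when partners disagree, since a single out-of-frame
    partner suffices for that call.
    """
    for u in uorfs:
        if u.end > transcript.cds_start:
            frame = "inframe" if (transcript.cds_start - u.start) % 3 == 0 else "outframe"
            u.overlap_class = f"CDS-overlap-{frame}"
            continue
        partners = [v for v in uorfs if v is not u and v.start < u.end and u.start < v.end]
        if not partners:
            u.overlap_class = "nonoverlapping"
        elif any((v.start - u.start) % 3 != 0 for v in partners):
            u.overlap_class = "uORF-overlap-outframe"
        else:
            u.overlap_class = "uORF-overlap-inframe"
    return [u.overlap_class for u in uorfs]


# ---------------------------------------------------------------------------
# Kozak context scoring
# ---------------------------------------------------------------------------

@dataclass
class KozakPPM:
    """Position probability matrix over a start-codon context window.

    ``matrix`` has one row per window position (in ``window`` order) and one
    column per nucleotide in A, C, G, T order; each row sums to 1.
    """

    matrix: np.ndarray
    window: tuple[int, ...] = DEFAULT_KOZAK_WINDOW

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.window), 4):
            raise ValueError("PPM shape must be (len(window), 4)")
        if np.any(self.matrix < 0):
            raise ValueError("PPM entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PPM row must sum to 1")


def extract_context(transcript: TranscriptModel, aug_offset: int,
                    window: Sequence[int] = DEFAULT_KOZAK_WINDOW) -> str:
    """Context string at ``window`` positions around an AUG; '-' where the
    transcript is too short to cover a position."""
    seq = transcript.sequence
    out = []
    for rel in window:
        p = aug_offset + rel
        out.append(seq[p] if 0 <= p < len(seq) else "-")
    return "".join(out)


def build_kozak_ppm(transcripts: Iterable[TranscriptModel],
                    window: Sequence[int] = DEFAULT_KOZAK_WINDOW,
                    pseudocount: float = 0.0) -> KozakPPM:
    """Derive a PPM from the cAUG contexts of a set of transcripts.

    Contexts truncated by short 5'UTRs (any window position outside the
    transcript) are excluded.  ``pseudocount`` 0 gives a pure frequency
    matrix; a positive value applies Laplace smoothing.
    """
    window = tuple(window)
    counts = np.full((len(window), 4), float(pseudocount))
    n_used = 0
    for t in transcripts:
        ctx = extract_context(t, t.cds_start, window)
        if "-" in ctx or any(c not in _BASE_INDEX for c in ctx):
            continue
        for i, c in enumerate(ctx):
            counts[i, _BASE_INDEX[c]] += 1
        n_used += 1
    if n_used == 0 and pseudocount == 0:
        raise ValueError("no usable cAUG contexts to build a PPM from")
    return KozakPPM(counts / counts.sum(axis=1, keepdims=True), window)


def kozak_score(context: str, ppm: KozakPPM) -> float:
    """Log-odds Kozak score in bits: sum over window positions of
    log2(P[i, base] / 0.25).

    Missing positions (``-`` in the context, from truncated 5'UTRs)
    contribute 0.  A base with probability 0 yields ``-inf``.
    """
    if len(context) != len(ppm.window):
        raise ValueError(
            f"context length {len(context)} != window size {len(ppm.window)}"
        )
    score = 0.0
    for i, c in enumerate(context):
        if c == "-":
            continue
        p = ppm.matrix[i, _BASE_INDEX[c]]
        if p == 0.0:
            return -math.inf
        score += math.log2(p / 0.25)
    return score


def score_uorfs(uorfs: Iterable[UORF], transcript: TranscriptModel, ppm: KozakPPM) -> None:
    """Fill ``kozak_score`` on each uORF from its uAUG context."""
    for u in uorfs:
        u.kozak_score = kozak_score(extract_context(transcript, u.start, ppm.window), ppm)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul–Erickson Euler-path algorithm)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, seed: int | np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact dinucleotide multiset.

    Uses the Euler-path construction: the shuffled string is a random
    Eulerian walk over the dinucleotide multigraph, so the dinucleotide
    counts — and the first and last nucleotide — are preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(seq) <= 3:
        return seq
    vertices = sorted(set(seq))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    # Pick one terminal edge per non-final vertex so the terminal edges form
    # a tree rooted at the final vertex (rejection sampling; standard).
    nonfinal = [v for v in vertices if v != last and edges[v]]
    while True:
        terminal = {v: edges[v][rng.integers(len(edges[v]))] for v in nonfinal}
        ok = True
        for v in nonfinal:
            cur, steps = v, 0
            while cur != last:
                nxt = terminal.get(cur)
                if nxt is None:  # dead end before reaching the sink
                    ok = False
                    break
                cur = nxt
                steps += 1
                if steps > len(vertices):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in terminal:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v in terminal:
            rest.append(terminal[v])
        shuffled[v] = rest
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Shuffle null for uORF counts
# ---------------------------------------------------------------------------

def count_uorfs_in_utr(utr5: str) -> int:
    """Number of ATG-initiated ORFs whose in-frame stop lies within the 5'UTR.

    This is the counting rule used for the shuffle null, where only the UTR
    sequence itself is permuted and overlap with the CDS is undefined.
    """
    n = 0
    pos = utr5.find("ATG")
    while pos >= 0:
        if _first_inframe_stop(utr5, pos) is not None:
            n += 1
        pos = utr5.find("ATG", pos + 1)
    return n


def expected_uorf_count(utr5_set: Sequence[str], n_reps: int = 1000,
                        seed: int = 0) -> dict[str, float]:
    """Null distribution of the total uORF count under dinucleotide shuffling.

    Each replicate shuffles every 5'UTR independently and counts uORFs fully
    contained in the UTR.  Returns the mean, median, and the 2.5% / 97.5%
    quantiles over replicates; an observed count below ``q2.5`` is a
    depletion call at one-sided P < 0.05.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    totals = np.empty(n_reps)
    for r in range(n_reps):
        totals[r] = sum(count_uorfs_in_utr(dinucleotide_shuffle(u, rng)) for u in utr5_set)
    return {
        "mean": float(totals.mean()),
        "median": float(np.median(totals)),
        "q2.5": float(np.quantile(totals, 0.025)),
        "q97.5": float(np.quantile(totals, 0.975)),
    }


# ---------------------------------------------------------------------------
# Relative synonymous codon usage
# ---------------------------------------------------------------------------

def _synonymous_families() -> dict[str, list[str]]:
    from Bio.Data.CodonTable import standard_dna_table

    families: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    return families


def rscu_table(coding_sequences: Iterable[str]) -> dict[str, float]:
    """Relative synonymous codon usage: observed count over the mean count of
    the codon's synonymous family.

    The first (start) and last (stop) codon of each sequence are excluded.
    Codons of families with zero total usage are reported as NaN.
    """
    counts: dict[str, int] = {}
    for seq in coding_sequences:
        if len(seq) % 3 != 0:
            raise ValueError("coding sequence length must be divisible by 3")
        for j in range(3, len(seq) - 3, 3):
            codon = seq[j : j + 3]
            counts[codon] = counts.get(codon, 0) + 1
    rscu: dict[str, float] = {}
    for codons in _synonymous_families().values():
        family_counts = [counts.get(c, 0) for c in codons]
        mean = sum(family_counts) / len(codons)
        for c, k in zip(codons, family_counts):
            rscu[c] = k / mean if mean > 0 else float("nan")
    return rscu
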