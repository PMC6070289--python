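"""Feature-level quantification from P-site coverage.

RPKM for a feature is sum(c_k) / (L * N) * 1e9 over the feature's counted
region, where c_k is per-nucleotide P-site (or mRNA) coverage, L the counted
length, and N the library size (uniquely mapped reads in scope).  TE is the
ratio of RPF RPKM over mRNA RPKM.  For uORFs overlapping the CDS, only the
non-CDS portion is counted, in both L and sum(c_k).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from uorfkit.models import STOP_CODONS, TranscriptModel, UORF

#: Accepted RPF read lengths and their default 5'-end -> P-site offsets.
DEFAULT_PSITE_OFFSETS = {length: 12 for length in range(27, 35)}


@dataclass
class PSiteCoverage:
    """Per-transcript P-site (or mRNA) coverage vectors plus library size."""

    coverage: dict[str, np.ndarray]
    library_size: int
    assay: str = "rpf"
    dropped_reads: int = 0

    def vector(self, transcript_id: str) -> np.ndarray:
        return self.coverage[transcript_id]


@dataclass
class FeatureQuant:
    """Counts, RPKM, and TE for one feature in one sample."""

    feature_id: str
    count_mrna: int
    count_rpf: int
    rpkm_mrna: float
    rpkm_rpf: float
    te: float | None

    @staticmethod
    def from_rpkm(feature_id, count_mrna, count_rpf, rpkm_mrna, rpkm_rpf):
        te = rpkm_rpf / rpkm_mrna if rpkm_mrna > 0 else None
        return FeatureQuant(feature_id, count_mrna, count_rpf, rpkm_mrna, rpkm_rpf, te)


def assign_psites(
    reads: Iterable[tuple[str, int, int]],
    transcript_lengths: dict[str, int],
    offset_table: dict[int, int] | None = None,
) -> PSiteCoverage:
    """Reduce reads (transcript_id, 5'-end position, length) to P-site coverage.

    Each accepted read increments coverage at ``5' position + offset(length)``.
    Reads whose length has no offset (outside 27-34 nt by default) are dropped
    and tallied.
    """
    offsets = DEFAULT_PSITE_OFFSETS if offset_table is None else offset_table
    cov = {tid: np.zeros(n) for tid, n in transcript_lengths.items()}
    n_assigned = dropped = 0
    for tid, pos5, length in reads:
        off = offsets.get(length)
        if off is None:
            dropped += 1
            continue
        p = pos5 + off
        if tid in cov and 0 <= p < len(cov[tid]):
            cov[tid][p] += 1
            n_assigned += 1
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} reads dropped (length without offset or out of range)",
                      stacklevel=2)
    return PSiteCoverage(cov, library_size=n_assigned, dropped_reads=dropped)


def counted_region(feature: UORF | tuple[int, int], cds_start: int | None = None
                   ) -> list[tuple[int, int]]:
    """Intervals of a feature actually counted: for uORFs overlapping the CDS
    only the upstream, non-CDS portion is used."""
    if isinstance(feature, UORF):
        start, end = feature.start, feature.end
    else:
        start, end = feature
    if cds_start is not None:
        end = min(end, cds_start)
    if end <= start:
        return []
    return [(start, end)]


def compute_rpkm(
    coverage: np.ndarray,
    intervals: Sequence[tuple[int, int]],
    library_size: int,
) -> float:
    """RPKM = sum(c_k) / (L * N) * 1e9 over the counted intervals.

    Raises ``ValueError`` for an empty counted region (e.g., a uORF fully
    inside the CDS).
    """
    L = sum(e - s for s, e in intervals)
    if L < 1:
        raise ValueError("feature has an empty counted region")
    if library_size < 1:
        raise ValueError("library size must be >= 1")
    total = float(sum(coverage[s:e].sum() for s, e in intervals))
    return total / (L * library_size) * 1e9


def rpf_count(coverage: np.ndarray, intervals: Sequence[tuple[int, int]]) -> int:
    """RPF read count as the ceiling of the summed P-site coverage."""
    return int(math.ceil(sum(float(coverage[s:e].sum()) for s, e in intervals)))


def compute_te(rpkm_rpf: float, rpkm_mrna: float) -> float:
    """TE = RPF RPKM / mRNA RPKM; undefined when the mRNA RPKM is 0."""
    if rpkm_mrna <= 0:
        raise ValueError("TE undefined for zero mRNA RPKM")
    return rpkm_rpf / rpkm_mrna


def tissue_specificity_hg(expression: Sequence[float]) -> float:
    """Expression-breadth entropy H_g in bits.

    Shannon entropy of the normalized expression profile across samples;
    0 means expression restricted to a single sample, log2(N) means uniform
    expression over all N samples.
    """
    x = np.asarray(expression, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be >= 0")
    total = x.sum()
    if total == 0:
        raise ValueError("H_g undefined for an all-zero profile")
    p = x[x > 0] / total
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Metagene profiles and initiation peaks
# ---------------------------------------------------------------------------

#: (upstream triplets, downstream triplets) — the start triplet itself is
#: included, giving 51 positions for cAUG anchors and 16 for uAUG anchors.
METAGENE_WINDOWS = {"caug": (10, 40), "uaug": (5, 10)}


@dataclass
class MetageneProfile:
    anchor: str
    window: tuple[int, int]
    positions: np.ndarray
    mean_relative_coverage: np.ndarray
    n_genes: int
    n_excluded: int = 0


def metagene_profile(
    coverages: dict[str, np.ndarray],
    anchors: dict[str, int],
    cds_intervals: dict[str, tuple[int, int]],
    anchor_type: str = "caug",
) -> MetageneProfile:
    """Mean relative per-triplet coverage around start codons.

    Per gene, each triplet's coverage is normalized by the median per-triplet
    CDS coverage of that gene, then averaged across genes.  Genes with zero
    median CDS coverage are excluded and tallied.
    """
    up, down = METAGENE_WINDOWS[anchor_type]
    n_pos = up + 1 + down
    acc = np.zeros(n_pos)
    n_genes = n_excluded = 0
    for tid, anchor in anchors.items():
        cov = coverages[tid]
        cs, ce = cds_intervals[tid]
        cds_triplets = cov[cs : cs + 3 * ((ce - cs) // 3)].reshape(-1, 3).sum(axis=1)
        med = float(np.median(cds_triplets))
        if med <= 0:
            n_excluded += 1
            continue
        profile = np.full(n_pos, np.nan)
        for k in range(-up, down + 1):
            s = anchor + 3 * k
            if 0 <= s and s + 3 <= len(cov):
                profile[k + up] = cov[s : s + 3].sum() / med
        if np.isnan(profile).any():
            n_excluded += 1
            continue
        acc += profile
        n_genes += 1
    mean = acc / n_genes if n_genes else np.full(n_pos, np.nan)
    return MetageneProfile(
        anchor=anchor_type,
        window=(up, down),
        positions=np.arange(-up, down + 1),
        mean_relative_coverage=mean,
        n_genes=n_genes,
        n_excluded=n_excluded,
    )


def initiation_peak(occ_minus2: float, occ_minus1: float,
                    occ_plus1: float, occ_plus2: float) -> bool:
    """Start-codon ribosome-occupancy peak call: the +1 codon occupancy must
    strictly exceed the +2 codon and the summed -1/-2 triplet occupancy."""
    return occ_plus1 > occ_plus2 and occ_plus1 > (occ_minus1 + occ_minus2)


# ---------------------------------------------------------------------------
# Hypothetical uORFs and signal-to-noise
# ---------------------------------------------------------------------------

NON_STOP_TRIPLETS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)  # 61 triplets; 60 once ATG is held out as the canonical start


def hypothetical_uorf_scan(
    transcript: TranscriptModel,
    canonical_uorfs: Sequence[UORF],
    triplet: str,
) -> list[tuple[int, int]]:
    """ORFs in the 5'UTR started by ``triplet`` instead of ATG, scanned exactly
    like canonical uORFs but excluding any that overlap a canonical uORF."""
    if triplet in STOP_CODONS:
        raise ValueError("start triplet must not be a stop codon")
    seq = transcript.sequence
    masked = [(u.start, u.end) for u in canonical_uorfs]
    found = []
    pos = seq.find(triplet)
    while 0 <= pos < transcript.cds_start:
        for j in range(pos + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                end = j + 3
                if all(end <= s or pos >= e for s, e in masked):
                    found.append((pos, end))
                break
        pos = seq.find(triplet, pos + 1)
    return found


def signal_to_noise(canonical_prop: float, hypothetical_props: dict[str, float]
                    ) -> tuple[float, list[str]]:
    """Mean over triplets of (canonical proportion / triplet proportion).

    Triplets whose hypothetical proportion is zero cannot form a ratio; they
    are excluded and returned as flags.
    """
    ratios, flagged = [], []
    for trip, p in hypothetical_props.items():
        if p > 0:
            ratios.append(canonical_prop / p)
        else:
            flagged.append(trip)
    if not ratios:
        raise ValueError("no hypothetical triplet with nonzero proportion")
    return float(np.mean(ratios)), flagged


def dominant_isoform(isoform_abundances: dict[str, float]) -> str | None:
    """The 2-fold dominant isoform: the top isoform if it is expressed at
    least twice as much as the second most abundant one; single-isoform
    genes are always dominant."""
    if not isoform_abundances:
        raise ValueError("at least one isoform required")
    ranked = sorted(isoform_abundances.items(), key=lambda kv: -kv[1])
    if ranked[0][1] <= 0:
        raise ValueError("at least one isoform must have positive abundance")
    if len(ranked) == 1 or ranked[0][1] >= 2 * ranked[1][1]:
        return ranked[0][0]
    return None
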