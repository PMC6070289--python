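"""Core domain types shared across modules.

Coordinates are 0-based, half-open throughout; 1-based coordinates appear
only at GFF/BED file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STOP_CODONS = ("TAA", "TAG", "TGA")

OVERLAP_CLASSES = (
    "nonoverlapping",
    "uORF-overlap-inframe",
    "uORF-overlap-outframe",
    "CDS-overlap-inframe",
    "CDS-overlap-outframe",
)


@dataclass
class TranscriptModel:
    """A spliced transcript with 5'UTR / CDS / 3'UTR in transcript coordinates.

    ``cds_start`` is the offset of the A of the main-ORF start codon (cAUG);
    ``cds_end`` is the exclusive end of the CDS stop codon.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside sequence of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")

    def validate_start_codon(self) -> None:
        codon = self.sequence[self.cds_start : self.cds_start + 3]
        if codon != "ATG":
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG ({codon})")

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


@dataclass
class UORF:
    """An AUG-initiated upstream ORF.

    ``start`` is the offset of the uAUG (strictly upstream of the cAUG) and
    ``end`` the exclusive end of the stop codon, which may lie inside the CDS
    or 3'UTR for overlapping uORFs.
    """

    transcript_id: str
    start: int
    end: int
    overlap_class: str = "nonoverlapping"
    kozak_score: float | None = None
    distance_uaug_to_caug: int = 0
    distance_cap_to_uaug: int = 0
    distance_stop_to_caug: int = 0
    planted: bool = field(default=False, compare=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def feature_id(self) -> str:
        return f"{self.transcript_id}:uORF:{self.start}-{self.end}"
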