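"""Domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open, on the forward strand of
the contig; strand is recorded separately as "+" or "-".
"""

from __future__ import annotations

from dataclasses import dataclass, field

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

#: Verdict statuses: insertion present in both genomes, first only, second only.
STATUS_PP = "PP"
STATUS_PM = "PM"
STATUS_MP = "MP"
STATUS_DISCARDED = "discarded"

DISCARD_REASONS = (
    "shortLF", "shortRF", "leftSINE", "rightSINE",
    "low_flank_identity", "low_sine_support", "minus_minus", "none",
)


class InvalidInputError(ValueError):
    """Raised for malformed sequences, configs or inconsistent records."""


@dataclass(frozen=True)
class SineConsensus:
    """A SINE family consensus sequence used as the search query.

    The consensus also forms the third row of the triple alignment used to
    decide whether each locus carries the insertion.
    """

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise InvalidInputError("consensus sequence is empty")
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise InvalidInputError(f"non-IUPAC letters in consensus: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SineHit:
    """A located SINE copy in one genome."""

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    pct_identity: float
    consensus_coverage: float
    hit_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvalidInputError(f"bad hit interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise InvalidInputError(f"bad strand {self.strand!r}")


@dataclass
class Flank:
    """The left (in SINE orientation) flank of a copy.

    ``sequence`` is given 5'->3' in the SINE's orientation: for a minus
    strand copy it is the reverse complement of the forward-strand slice.
    """

    copy_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool = False


@dataclass
class MappedFlank:
    """A flank's alignment to a target genome (primary or secondary)."""

    flank: Flank
    target_genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    aligned_length: int
    score: float


@dataclass
class CandidateLocus:
    """An interval that may contain the orthologous flank+SINE+flank.

    ``origin`` is "query_copy" for intervals derived from a genome's own
    SINE copies, "mapped_flank" for intervals found by mapping the other
    genome's flanks, and "merged" after overlap clustering.
    """

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    origin: str = "query_copy"
    source_ids: list[str] = field(default_factory=list)
    locus_id: str = ""

    def __post_init__(self):
        if not self.locus_id:
            self.locus_id = f"{self.genome_id}:{self.contig}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "CandidateLocus") -> bool:
        return (self.genome_id == other.genome_id
                and self.contig == other.contig
                and self.start < other.end and other.start < self.end)


@dataclass
class ClusterGroup:
    """A connected set of candidate loci across two genomes.

    Category by locus count: double (2), multiple (3-10), poly (>10);
    "unpaired" marks a component of a single unlinked locus.
    """

    group_id: str
    loci: list[CandidateLocus]
    links: list[tuple[str, str]]
    category: str = ""


@dataclass
class TripleAlignment:
    """Alignment of locus A, locus B and the consensus (equal-length rows).

    The SINE region is the column span from the first to last non-gap
    position of the consensus row; columns left of it form the left flank
    (LF) segment and columns right of it the right flank (RF).
    """

    row_a: str
    row_b: str
    row_cons: str
    sine_start_col: int
    sine_end_col: int

    def __post_init__(self):
        if not (len(self.row_a) == len(self.row_b) == len(self.row_cons)):
            raise InvalidInputError("triple alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.row_a)


@dataclass
class SegmentStats:
    """Lengths and identity statistics of one alignment segment."""

    region: str  # LF, SINE or RF
    len_a: int
    len_b: int
    identical_ab: int
    pct_ab: float
    identical_a_cons: int = 0
    pct_a_cons: float = 0.0
    identical_b_cons: int = 0
    pct_b_cons: float = 0.0


@dataclass
class PairVerdict:
    """Classification of one locus pair plus its segment statistics."""

    status: str
    discard_reason: str = "none"
    stats: dict[str, SegmentStats] = field(default_factory=dict)
    locus_a: CandidateLocus | None = None
    locus_b: CandidateLocus | None = None
    foreign_b: bool = False  # unrelated filler where the SINE would be

    def __post_init__(self):
        if (self.status == STATUS_DISCARDED) != (self.discard_reason != "none"):
            raise InvalidInputError("discard_reason inconsistent with status")


@dataclass
class PresencePattern:
    """Per-genome plus/minus vector for a joined locus."""

    locus_id: str
    status_by_genome: dict[str, str]  # genome -> plus | minus | unknown
    category: str = ""
    conflict: bool = False
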