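"""Domain records for promoter/SNP analysis.

Coordinate convention: a proximal promoter is the 70 bp immediately
upstream of the transcription start site (TSS), on the sense strand.
SNP offsets are 1-based negative distances upstream of the TSS, so
offset -45 is the 45th base before the TSS. Internally the 70-mer is
indexed 0..69 with index 0 corresponding to offset -70:

    index = PROMOTER_LENGTH + offset
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROMOTER_LENGTH = 70
ODN_LENGTH = 26
DNA_ALPHABET = frozenset("ACGT")


class SequenceAlphabetError(ValueError):
    """A sequence contains a base outside {A, C, G, T}."""


class SequenceLengthError(ValueError):
    """A sequence does not have the required length."""


class HeaderFormatError(ValueError):
    """A FASTA header does not parse as ``GENE|tss=<int>|strand=+``."""


class ReferenceMismatchError(ValueError):
    """A SNP's reference allele disagrees with the promoter sequence.

    Usually signals stale coordinates or a promoter/SNP table mix-up.
    """


class PairingError(ValueError):
    """ODN records do not come in complete WT/minor pairs."""


def _check_alphabet(seq: str, context: str) -> str:
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{context}: non-ACGT base(s) {sorted(bad)} in sequence"
        )
    return seq


@dataclass
class PromoterRecord:
    """A 70-bp sense-strand proximal promoter with gene metadata."""

    gene_id: str
    sequence: str
    tss: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        self.sequence = _check_alphabet(self.sequence, self.gene_id)
        if len(self.sequence) != PROMOTER_LENGTH:
            raise SequenceLengthError(
                f"{self.gene_id}: promoter length {len(self.sequence)} != "
                f"{PROMOTER_LENGTH}"
            )
        if self.strand != "+":
            raise ValueError(
                f"{self.gene_id}: only sense-strand ('+') promoters are "
                "supported"
            )

    def base_at(self, offset: int) -> str:
        """Base at a 1-based negative offset upstream of the TSS."""
        return self.sequence[offset_to_index(offset)]


def offset_to_index(offset: int) -> int:
    if not -PROMOTER_LENGTH <= offset <= -1:
        raise ValueError(
            f"offset {offset} outside [-{PROMOTER_LENGTH}, -1]"
        )
    return PROMOTER_LENGTH + offset


def index_to_offset(index: int) -> int:
    if not 0 <= index < PROMOTER_LENGTH:
        raise ValueError(f"index {index} outside [0, {PROMOTER_LENGTH})")
    return index - PROMOTER_LENGTH


@dataclass
class SnpRecord:
    """A single-nucleotide substitution within a 70-bp promoter."""

    rsid: str
    gene_id: str
    offset: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        offset_to_index(self.offset)  # range check
        self.ref_allele = _check_alphabet(self.ref_allele, self.rsid)
        self.alt_allele = _check_alphabet(self.alt_allele, self.rsid)
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise SequenceLengthError(
                f"{self.rsid}: only single-base substitutions are supported "
                f"(got ref={self.ref_allele!r} alt={self.alt_allele!r}); "
                "indels are rejected"
            )


@dataclass
class OdnRecord:
    """A 26-bp oligodeoxyribonucleotide probe with predicted and measured
    affinity, one allele of one SNP."""

    gene_id: str
    rsid: str
    allele_class: str  # "WT" or "min"
    sequence: str
    predicted_neglog_kd: float
    measured_kd_nM: float
    measured_kd_sem_nM: float
    rsid_conflict: str = ""

    def __post_init__(self) -> None:
        self.sequence = _check_alphabet(self.sequence, self.rsid)
        if len(self.sequence) != ODN_LENGTH:
            raise SequenceLengthError(
                f"{self.gene_id}/{self.allele_class}: ODN length "
                f"{len(self.sequence)} != {ODN_LENGTH}"
            )
        if self.allele_class not in ("WT", "min"):
            raise ValueError(f"allele_class {self.allele_class!r}")
        if self.measured_kd_sem_nM < 0:
            raise ValueError("SEM must be >= 0")


@dataclass
class AnnotationRecord:
    """Literature-curated link from a gene's expression change to its
    effect on male reproductive potential.

    The (gene, expression_direction) -> potential_effect mapping is
    consumed as data; it is the product of manual curation, not of any
    computation in this package.
    """

    gene_id: str
    expression_direction: str  # "over" or "under"
    potential_effect: str      # "increase" or "decrease"
    citation_tag: str = ""

    def __post_init__(self) -> None:
        if self.expression_direction not in ("over", "under"):
            raise ValueError(
                f"expression_direction {self.expression_direction!r}"
            )
        if self.potential_effect not in ("increase", "decrease"):
            raise ValueError(f"potential_effect {self.potential_effect!r}")


def apply_allele(promoter: PromoterRecord, snp: SnpRecord) -> tuple[str, str]:
    """Return (wild-type sequence, minor-allele sequence) for a SNP.

    The wild-type sequence is the promoter as given; the minor sequence
    differs at exactly the SNP position (or nowhere, if ref == alt).
    """
    idx = offset_to_index(snp.offset)
    ref = promoter.sequence[idx]
    if ref != snp.ref_allele:
        raise ReferenceMismatchError(
            f"{snp.rsid}: promoter {promoter.gene_id} has {ref!r} at offset "
            f"{snp.offset}, SNP table says {snp.ref_allele!r}"
        )
    minor = (
        promoter.sequence[:idx] + snp.alt_allele + promoter.sequence[idx + 1:]
    )
    return promoter.sequence, minor
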