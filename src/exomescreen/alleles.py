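"""Minimal allele representation shared by the depth-QC and screening stages.

Catalogue entries and variant-caller output often describe the same indel
differently (pure vs anchor-base form, extra shared padding). Both sides are
reduced to a minimal representation by trimming the shared suffix and then
the shared prefix of the ref/alt pair. Trimming is reference-sequence-free:
no realignment is attempted, so representations that differ only by shifts
through a repeat run are not unified (that requires the reference genome).

After trimming, a pure insertion has an empty ref and its position is the
base immediately to the right of the insertion point; a pure deletion keeps
the deleted bases as ref with an empty alt, positioned at the first deleted
base.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["NormalizedAllele", "normalize"]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class NormalizedAllele:
    """Minimal trimmed representation of one (chrom, pos, ref, alt) allele."""

    chromosome: str
    position: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


def normalize(chromosome: str, position: int, ref: str, alt: str) -> NormalizedAllele:
    """Trim shared suffix then shared prefix from a ref/alt pair.

    SNVs are fixed points. Anchored indels reduce to the same key as their
    pure form: e.g. (pos 100, "ATG", "A") and (pos 101, "TG", "") both
    normalize to (101, "TG", ""). Trimming is idempotent.

    Raises
    ------
    ValidationError
        On non-ACGT characters or a degenerate ref == alt pair.
    """
    ref, alt = ref.upper(), alt.upper()
    if not set(ref) <= _VALID_BASES or not set(alt) <= _VALID_BASES:
        raise ValidationError(f"non-ACGT characters in alleles {ref!r}/{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref and alt are identical ({ref!r}) at {chromosome}:{position}")
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return NormalizedAllele(chromosome=chromosome, position=position, ref=ref, alt=alt)
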